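"""Label-space construction: ontology parsing, evidence filtering, DAG
propagation, information content, and term selection.

Function labels are Gene Ontology terms (one model per namespace) or EC
numbers.  Annotations pass through an evidence-code filter, are propagated up
the is_a/part_of hierarchy, and terms are kept when their positive count
falls inside a configurable band (defaults 50–5000 for GO; EC keeps only
depth-3/4 identifiers).  Each retained term j carries an information content
IC = -log2(prob) and a class weight w_j = N / N_j^+ used by the weighted
cross-entropy loss.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import networkx as nx
import pandas as pd

logger = logging.getLogger(__name__)

#: Experimental (non-electronic) GO evidence codes.
EXP_CODES = frozenset({"EXP", "IDA", "IPI", "IMP", "IGI", "IEP", "TAS", "IC"})
#: Electronic annotation code.
IEA_CODES = frozenset({"IEA"})

#: Namespace roots, excluded from label spaces (IC = 0, uninformative).
NAMESPACE_ROOTS = {
    "molecular_function": "GO:0003674",
    "biological_process": "GO:0008150",
    "cellular_component": "GO:0005575",
}

DEFAULT_RELATIONS = ("is_a", "part_of")


def information_content(prob: float) -> float:
    """IC of a term observed with probability ``prob``, in bits: -log2(prob)."""
    if not 0.0 < prob <= 1.0:
        raise ValueError(f"probability must be in (0, 1], got {prob}")
    return -math.log2(prob)


@dataclass
class OntologyGraph:
    """Directed acyclic term graph with child -> parent edges."""

    graph: nx.DiGraph
    namespaces: dict = field(default_factory=dict)

    def __post_init__(self):
        if not nx.is_directed_acyclic_graph(self.graph):
            raise ValueError("ontology graph must be acyclic")

    @classmethod
    def from_obo(cls, path, relations=DEFAULT_RELATIONS) -> "OntologyGraph":
        """Read an OBO 1.2 file; keeps only the requested relations
        (default is_a and part_of, both treated as ancestry)."""
        import obonet

        multi = obonet.read_obo(str(path))
        g = nx.DiGraph()
        g.add_nodes_from(multi.nodes)
        for u, v, key in multi.edges(keys=True):
            if key in relations:
                g.add_edge(u, v)
        namespaces = {
            n: d.get("namespace", "") for n, d in multi.nodes(data=True)
        }
        return cls(graph=g, namespaces=namespaces)

    @classmethod
    def from_edges(cls, edges, namespaces=None) -> "OntologyGraph":
        """Build from (child, parent) pairs — convenient for synthetic DAGs."""
        g = nx.DiGraph()
        g.add_edges_from(edges)
        return cls(graph=g, namespaces=namespaces or {})

    def ancestors(self, term: str) -> set:
        """All ancestors of `term` (transitive parents), excluding itself."""
        if term not in self.graph:
            raise KeyError(f"term {term!r} not in ontology graph")
        return nx.descendants(self.graph, term)  # edges point child -> parent


def filter_by_evidence(table: pd.DataFrame, policy: str = "exp") -> pd.DataFrame:
    """Retain annotation rows by evidence policy.

    ``exp`` keeps the experimental codes {EXP, IDA, IPI, IMP, IGI, IEP, TAS,
    IC}; ``exp+iea`` additionally keeps IEA.  Rows with codes outside the
    known vocabulary are dropped with a warning.
    """
    if policy not in ("exp", "exp+iea"):
        raise ValueError("policy must be 'exp' or 'exp+iea'")
    allowed = EXP_CODES | (IEA_CODES if policy == "exp+iea" else frozenset())
    known = EXP_CODES | IEA_CODES | {"ISS", "ISO", "ISA", "ISM", "IGC", "IBA",
                                     "IBD", "IKR", "IRD", "RCA", "NAS", "ND",
                                     "HTP", "HDA", "HMP", "HGI", "HEP"}
    codes = table["evidence"]
    unknown = ~codes.isin(known)
    if unknown.any():
        logger.warning("dropping %d rows with unknown evidence codes: %s",
                       int(unknown.sum()), sorted(codes[unknown].unique()))
    out = table[codes.isin(allowed)].drop_duplicates(
        subset=["protein_id", "term_id"]).reset_index(drop=True)
    return out


def propagate_annotations(table: pd.DataFrame, graph: OntologyGraph,
                          exclude_roots: bool = True) -> pd.DataFrame:
    """Close each (protein, term) row under ancestry in the DAG.

    All ancestors up to (but excluding) the namespace roots are added.
    Idempotent by construction.
    """
    roots = set(NAMESPACE_ROOTS.values()) if exclude_roots else set()
    missing = sorted(set(table["term_id"]) - set(graph.graph.nodes))
    if missing:
        raise KeyError(f"annotated term(s) absent from ontology: {missing}")
    anc_cache: dict[str, set] = {}
    rows = set()
    for pid, tid in zip(table["protein_id"], table["term_id"]):
        rows.add((pid, tid))
        if tid not in anc_cache:
            anc_cache[tid] = graph.ancestors(tid) - roots
        for a in anc_cache[tid]:
            rows.add((pid, a))
    out = pd.DataFrame(sorted(rows), columns=["protein_id", "term_id"])
    if "evidence" in table.columns:
        out["evidence"] = "propagated"
    return out


def _ec_depth(term_id: str) -> int:
    parts = [p for p in term_id.split(".") if p not in ("", "-")]
    return len(parts)


@dataclass
class LabelSpace:
    """Ordered catalogue of selected terms with counts, ICs and class weights."""

    terms: list
    counts: dict
    n_proteins: int
    names: dict = field(default_factory=dict)
    ic: dict = field(default_factory=dict)
    weights: dict = field(default_factory=dict)

    def __post_init__(self):
        for t in self.terms:
            c = self.counts[t]
            if c <= 0:
                raise ValueError(f"term {t!r} has no positive examples")
            self.weights.setdefault(t, self.n_proteins / c)
            self.ic.setdefault(t, information_content(c / self.n_proteins))

    def __len__(self) -> int:
        return len(self.terms)

    def index(self, term: str) -> int:
        return self.terms.index(term)

    @property
    def weight_vector(self):
        import numpy as np
        return np.array([self.weights[t] for t in self.terms])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "term_id": self.terms,
            "name": [self.names.get(t, "") for t in self.terms],
            "count": [self.counts[t] for t in self.terms],
            "ic": [self.ic[t] for t in self.terms],
            "weight": [self.weights[t] for t in self.terms],
        })


def select_terms(table: pd.DataFrame, min_count: int = 50, max_count: int = 5000,
                 kind: str = "go", names: dict | None = None,
                 ic_table: pd.DataFrame | None = None) -> LabelSpace:
    """Build the label space from an evidence-filtered (and, for GO,
    propagated) annotation table.

    Terms are retained when min_count <= N_j^+ <= max_count; EC spaces
    additionally keep only depth-3/4 identifiers.  Term order is
    lexicographic for determinism.  ``ic_table`` optionally supplies a
    separate annotation corpus for the IC probabilities (defaults to the
    training table itself).
    """
    dedup = table.drop_duplicates(subset=["protein_id", "term_id"])
    counts = dedup.groupby("term_id")["protein_id"].nunique()
    n = dedup["protein_id"].nunique()
    keep = counts[(counts >= min_count) & (counts <= max_count)]
    if kind == "ec":
        keep = keep[[_ec_depth(t) in (3, 4) for t in keep.index]]
    else:
        keep = keep[~keep.index.isin(NAMESPACE_ROOTS.values())]
    if keep.empty:
        raise ValueError(
            "no terms satisfy the count band; lower min_count or raise max_count"
        )
    terms = sorted(keep.index)
    space = LabelSpace(terms=terms, counts={t: int(keep[t]) for t in terms},
                       n_proteins=int(n), names=names or {})
    if ic_table is not None:
        ic_dedup = ic_table.drop_duplicates(subset=["protein_id", "term_id"])
        ic_counts = ic_dedup.groupby("term_id")["protein_id"].nunique()
        ic_n = ic_dedup["protein_id"].nunique()
        for t in terms:
            if t in ic_counts:
                space.ic[t] = information_content(ic_counts[t] / ic_n)
    return space


def encode_labels(annotations: pd.DataFrame, protein_ids: list,
                  space: LabelSpace):
    """Encode a binary label tensor y of shape (N, |T|, 2).

    y[i, j, 0] = 1, y[i, j, 1] = 0 when protein i carries term j, and
    (0, 1) otherwise — exactly one of the pair is set.
    """
    import numpy as np

    pos = set(zip(annotations["protein_id"], annotations["term_id"]))
    y = np.zeros((len(protein_ids), len(space), 2), dtype=np.int8)
    for i, pid in enumerate(protein_ids):
        for j, t in enumerate(space.terms):
            if (pid, t) in pos:
                y[i, j, 0] = 1
            else:
                y[i, j, 1] = 1
    return y


def labels_to_pairs(labels):
    """(N, T) 0/1 matrix -> (N, T, 2) paired indicator tensor."""
    import numpy as np

    labels = np.asarray(labels)
    y = np.zeros(labels.shape + (2,), dtype=np.int8)
    y[..., 0] = labels
    y[..., 1] = 1 - labels
    return y
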