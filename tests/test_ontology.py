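"""Label-space construction: evidence filtering, DAG propagation against a
brute-force reachability oracle, information content, term selection."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from strucfun.ontology import (LabelSpace, OntologyGraph, encode_labels,
                               filter_by_evidence, information_content,
                               labels_to_pairs, propagate_annotations,
                               select_terms)


def table(rows):
    return pd.DataFrame(rows, columns=["protein_id", "term_id", "evidence"])


class TestEvidenceFilter:
    def test_experimental_code_retained(self):
        out = filter_by_evidence(table([("p1", "GO:1", "IDA")]), "exp")
        assert len(out) == 1

    def test_iea_dropped_under_exp_only(self):
        out = filter_by_evidence(table([("p1", "GO:1", "IEA")]), "exp")
        assert out.empty

    def test_iea_retained_under_exp_plus_iea(self):
        out = filter_by_evidence(table([("p1", "GO:1", "IEA")]), "exp+iea")
        assert len(out) == 1

    def test_all_exp_codes_retained(self):
        codes = ["EXP", "IDA", "IPI", "IMP", "IGI", "IEP", "TAS", "IC"]
        out = filter_by_evidence(
            table([(f"p{i}", "GO:1", c) for i, c in enumerate(codes)]), "exp")
        assert len(out) == len(codes)

    def test_unknown_code_dropped_with_warning(self, caplog):
        out = filter_by_evidence(table([("p1", "GO:1", "WAT")]), "exp")
        assert out.empty

    def test_empty_table(self):
        assert filter_by_evidence(table([]), "exp").empty


def simple_dag():
    # t1 -> t2 -> root; t3 -> t2; t4 -> root
    return OntologyGraph.from_edges([
        ("t1", "t2"), ("t2", "GO:0003674"), ("t3", "t2"),
        ("t4", "GO:0003674"),
    ])


class TestPropagation:
    def test_root_only_parent_leaves_table_unchanged(self):
        out = propagate_annotations(table([("p1", "t4", "IDA")]), simple_dag())
        assert set(zip(out.protein_id, out.term_id)) == {("p1", "t4")}

    def test_chain_closure(self):
        out = propagate_annotations(table([("p1", "t1", "IDA")]), simple_dag())
        assert set(zip(out.protein_id, out.term_id)) == {("p1", "t1"),
                                                         ("p1", "t2")}

    def test_missing_term_named_in_error(self):
        with pytest.raises(KeyError, match="t99"):
            propagate_annotations(table([("p1", "t99", "IDA")]), simple_dag())

    def test_idempotent_and_monotone(self):
        t = table([("p1", "t1", "IDA"), ("p2", "t3", "EXP")])
        once = propagate_annotations(t, simple_dag())
        twice = propagate_annotations(once, simple_dag())
        assert set(zip(once.protein_id, once.term_id)) == \
            set(zip(twice.protein_id, twice.term_id))
        assert set(zip(t.protein_id, t.term_id)) <= \
            set(zip(once.protein_id, once.term_id))

    def test_matches_brute_force_reachability(self):
        rng = np.random.default_rng(17)
        n = 12
        edges = []
        for child in range(1, n):  # edges to lower ids: guaranteed acyclic
            for parent in rng.choice(child, size=min(child, 2), replace=False):
                edges.append((f"n{child}", f"n{parent}"))
        graph = OntologyGraph.from_edges(edges)
        annots = table([("p", f"n{n - 1}", "IDA"), ("q", "n5", "IDA")])
        out = propagate_annotations(annots, graph)

        def reachable(start):  # independent DFS oracle
            seen, stack = set(), [start]
            adj = {}
            for c, p in edges:
                adj.setdefault(c, []).append(p)
            while stack:
                node = stack.pop()
                for p in adj.get(node, []):
                    if p not in seen:
                        seen.add(p)
                        stack.append(p)
            return seen

        expected = {("p", t) for t in reachable(f"n{n - 1}") | {f"n{n - 1}"}}
        expected |= {("q", t) for t in reachable("n5") | {"n5"}}
        assert set(zip(out.protein_id, out.term_id)) == expected


class TestInformationContent:
    @pytest.mark.parametrize("prob,expected", [(1.0, 0.0), (0.5, 1.0),
                                               (2.0 ** -10, 10.0)])
    def test_values(self, prob, expected):
        assert math.isclose(information_content(prob), expected)

    @pytest.mark.parametrize("bad", [0.0, -0.1, 1.5])
    def test_domain_errors(self, bad):
        with pytest.raises(ValueError):
            information_content(bad)

    @settings(max_examples=30, derandomize=True)
    @given(st.floats(1e-9, 1.0, exclude_min=False),
           st.floats(1e-9, 1.0))
    def test_strictly_decreasing_in_probability(self, a, b):
        if a == b:
            return
        lo, hi = min(a, b), max(a, b)
        assert information_content(lo) > information_content(hi)


def counted_table(counts: dict) -> pd.DataFrame:
    rows = []
    for term, k in counts.items():
        for i in range(k):
            rows.append((f"p{i}", term, "IDA"))
    return table(rows)


class TestSelectTerms:
    def test_count_band_boundaries(self):
        t = counted_table({"GO:a": 49, "GO:b": 50, "GO:c": 300})
        space = select_terms(t, min_count=50, max_count=5000)
        assert space.terms == ["GO:b", "GO:c"]

    def test_upper_bound_exclusive_above(self):
        t = counted_table({"GO:a": 60, "GO:b": 70})
        space = select_terms(t, min_count=50, max_count=65)
        assert space.terms == ["GO:a"]

    def test_ec_depth_filter(self):
        t = counted_table({"1.2": 100, "1.2.3": 100, "1.2.3.4": 100,
                           "1.2.3.-": 80})
        space = select_terms(t, min_count=50, max_count=5000, kind="ec")
        assert "1.2" not in space.terms
        assert {"1.2.3", "1.2.3.4", "1.2.3.-"} <= set(space.terms)

    def test_class_weight_formula(self):
        # 200 proteins, one term with 50 positives -> w = 4
        rows = [(f"p{i}", "GO:x", "IDA") for i in range(50)]
        rows += [(f"p{i}", "GO:y", "IDA") for i in range(200)]
        space = select_terms(table(rows), min_count=50, max_count=5000)
        assert space.weights["GO:x"] == pytest.approx(4.0)
        assert space.n_proteins == 200

    def test_empty_selection_advises(self):
        with pytest.raises(ValueError, match="min_count"):
            select_terms(counted_table({"GO:a": 3}), min_count=50,
                         max_count=5000)

    def test_zero_count_weight_error_at_construction(self):
        with pytest.raises(ValueError):
            LabelSpace(terms=["t"], counts={"t": 0}, n_proteins=10)


class TestEncodeLabels:
    def test_pair_complementarity_and_counts(self):
        t = counted_table({"GO:a": 60, "GO:b": 55})
        space = select_terms(t, min_count=50, max_count=5000)
        proteins = [f"p{i}" for i in range(60)]
        y = encode_labels(t, proteins, space)
        assert np.all(y.sum(axis=2) == 1)
        for j, term in enumerate(space.terms):
            assert y[:, j, 0].sum() == space.counts[term]

    def test_protein_without_terms_is_all_negative(self):
        t = counted_table({"GO:a": 50})
        space = select_terms(t, min_count=50, max_count=5000)
        y = encode_labels(t, ["stranger"], space)
        assert np.array_equal(y[0], [[0, 1]])

    def test_labels_to_pairs_roundtrip(self):
        labels = np.array([[1, 0, 1], [0, 0, 1]])
        y = labels_to_pairs(labels)
        assert np.array_equal(y[..., 0], labels)
        assert np.all(y.sum(axis=-1) == 1)


TINY_OBO = """\
format-version: 1.2

[Term]
id: GO:0003674
name: molecular_function
namespace: molecular_function

[Term]
id: GO:0005488
name: binding
namespace: molecular_function
is_a: GO:0003674 ! molecular_function

[Term]
id: GO:0005509
name: calcium ion binding
namespace: molecular_function
is_a: GO:0005488 ! binding

[Term]
id: GO:0044183
name: protein folding chaperone
namespace: molecular_function
relationship: part_of GO:0005488 ! binding
"""


class TestOboParsing:
    def test_obo_roundtrip_with_part_of(self, tmp_path):
        path = tmp_path / "mini.obo"
        path.write_text(TINY_OBO)
        graph = OntologyGraph.from_obo(path)
        assert graph.ancestors("GO:0005509") == {"GO:0005488", "GO:0003674"}
        assert "GO:0005488" in graph.ancestors("GO:0044183")
        out = propagate_annotations(
            table([("p1", "GO:0005509", "IDA")]), graph)
        # namespace root excluded from the closure
        assert set(out.term_id) == {"GO:0005509", "GO:0005488"}
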