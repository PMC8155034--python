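"""Residue coordinates and contact-map construction.

A protein graph is represented by a binary contact map A in {0,1}^(L x L).
Three contact definitions are supported:

``CA_CA``
    residues i, j are in contact iff the distance between their C-alpha
    atoms is strictly below the threshold (default 10 A);
``ANY_ANY``
    iff the minimum distance over all atom pairs is strictly below the
    threshold (default 6.5 A);
``NBR_NBR``
    iff the distance between the two residues' neighbor atoms (C-beta;
    C-alpha for glycine) is strictly below the sum of the pair's
    per-amino-acid neighbor radii (a configurable table shipped as data).

The diagonal is always zero — self-connections are added only inside the
network's normalized adjacency.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from importlib import resources

import numpy as np
from scipy.spatial.distance import cdist, pdist, squareform

from .records import ProteinRecord

logger = logging.getLogger(__name__)

CA_CA_DEFAULT_THRESHOLD = 10.0
ANY_ANY_DEFAULT_THRESHOLD = 6.5

MODES = ("CA_CA", "ANY_ANY", "NBR_NBR")

# Non-standard residue handling for 3-letter codes seen in PDB files.
_THREE_TO_ONE_EXTRA = {
    "MSE": "M", "SEC": "U", "PYL": "O", "ASX": "B", "GLX": "Z",
    "XLE": "J", "UNK": "X",
}


def load_neighbor_radii() -> dict[str, float]:
    """Default per-amino-acid neighbor-radius table (Angstroms)."""
    text = resources.files("strucfun.data").joinpath("nbr_radii.json").read_text()
    raw = json.loads(text)
    return {k: float(v) for k, v in raw.items() if not k.startswith("_")}


@dataclass
class ResidueCoordinates:
    """Per-residue atom records for one chain.

    ``atoms[i]`` maps atom name -> (3,) coordinate array for residue i;
    ``sequence`` holds the one-letter codes, same length.
    """

    atoms: list[dict]
    sequence: str
    chain_id: str = "A"

    def __post_init__(self):
        if len(self.atoms) != len(self.sequence):
            raise ValueError(
                f"residue count {len(self.atoms)} != sequence length {len(self.sequence)}"
            )

    def __len__(self) -> int:
        return len(self.atoms)

    @classmethod
    def from_bead_coords(cls, coords: np.ndarray, sequence: str | None = None,
                         chain_id: str = "A") -> "ResidueCoordinates":
        """Wrap a plain (L, 3) bead/C-alpha coordinate table."""
        coords = np.asarray(coords, dtype=float)
        if sequence is None:
            sequence = "A" * len(coords)
        atoms = [{"CA": coords[i]} for i in range(len(coords))]
        return cls(atoms=atoms, sequence=sequence, chain_id=chain_id)

    def ca_array(self) -> np.ndarray:
        out = np.empty((len(self), 3))
        missing = [i for i, a in enumerate(self.atoms) if "CA" not in a]
        if missing:
            raise ValueError(f"residues missing C-alpha atom: {missing}")
        for i, a in enumerate(self.atoms):
            out[i] = a["CA"]
        return out


@dataclass
class ContactMap:
    """Symmetric binary residue-residue adjacency with construction metadata."""

    adjacency: np.ndarray
    mode: str
    threshold: float | None = None

    def __post_init__(self):
        A = np.asarray(self.adjacency)
        if A.ndim != 2 or A.shape[0] != A.shape[1]:
            raise ValueError("adjacency must be square")
        if not np.array_equal(A, A.T):
            raise ValueError("adjacency must be symmetric")
        if np.any(np.diag(A) != 0):
            raise ValueError("adjacency must have a zero diagonal")
        if not np.isin(A, (0, 1)).all():
            raise ValueError("adjacency entries must be binary")
        self.adjacency = A.astype(np.uint8)

    @property
    def length(self) -> int:
        return self.adjacency.shape[0]

    def edge_list(self) -> np.ndarray:
        """(E, 2) array of contacts with i < j, 0-based."""
        iu, ju = np.triu_indices(self.length, k=1)
        mask = self.adjacency[iu, ju] == 1
        return np.column_stack([iu[mask], ju[mask]])


def _neighbor_atom_array(coords: ResidueCoordinates) -> np.ndarray:
    out = np.empty((len(coords), 3))
    for i, (atoms, aa) in enumerate(zip(coords.atoms, coords.sequence)):
        name = "CA" if aa == "G" else "CB"
        if name not in atoms:
            # fall back to CA when CB is unresolved (common for termini)
            if "CA" in atoms:
                name = "CA"
            else:
                raise ValueError(f"residue {i} missing neighbor atom ({name})")
        out[i] = atoms[name]
    return out


def build_contact_map(coords: ResidueCoordinates, mode: str = "CA_CA",
                      threshold: float | None = None,
                      radii: dict[str, float] | None = None) -> ContactMap:
    """Build a binary contact map under one of the three contact rules.

    The distance criterion is strict (<): a pair exactly at the threshold is
    not a contact.
    """
    if mode not in MODES:
        raise ValueError(f"unknown mode {mode!r}; expected one of {MODES}")
    L = len(coords)
    if L == 0:
        raise ValueError("empty coordinates")

    if mode == "CA_CA":
        t = CA_CA_DEFAULT_THRESHOLD if threshold is None else float(threshold)
        d = squareform(pdist(coords.ca_array()))
        A = (d < t).astype(np.uint8)
    elif mode == "ANY_ANY":
        t = ANY_ANY_DEFAULT_THRESHOLD if threshold is None else float(threshold)
        A = np.zeros((L, L), dtype=np.uint8)
        stacks = [np.vstack(list(a.values())) for a in coords.atoms]
        for i in range(L):
            for j in range(i + 1, L):
                if cdist(stacks[i], stacks[j]).min() < t:
                    A[i, j] = A[j, i] = 1
    else:  # NBR_NBR
        table = load_neighbor_radii() if radii is None else radii
        unknown = sorted({aa for aa in coords.sequence if aa not in table})
        if unknown:
            raise ValueError(
                f"no neighbor radius for residue code(s): {', '.join(unknown)}"
            )
        pts = _neighbor_atom_array(coords)
        r = np.array([table[aa] for aa in coords.sequence])
        d = squareform(pdist(pts))
        A = (d < (r[:, None] + r[None, :])).astype(np.uint8)
        t = None

    np.fill_diagonal(A, 0)
    return ContactMap(adjacency=A, mode=mode, threshold=t)


def filter_by_length(records: list[ProteinRecord], min_len: int = 60,
                     max_len: int = 1000) -> list[ProteinRecord]:
    """Keep records with min_len <= L <= max_len (inclusive), order preserved."""
    if min_len > max_len:
        raise ValueError("min_len must be <= max_len")
    kept = [r for r in records if min_len <= r.length <= max_len]
    removed = len(records) - len(kept)
    if removed:
        logger.info("filter_by_length removed %d of %d records", removed, len(records))
    return kept


def perturb_contact_map(cmap: ContactMap, flip_rate: float, seed: int) -> ContactMap:
    """Flip each upper-triangle entry independently with probability flip_rate,
    mirrored to keep symmetry.  A desk-scale surrogate for contact maps from
    degraded structural models."""
    if not 0.0 <= flip_rate <= 1.0:
        raise ValueError("flip_rate must be in [0, 1]")
    A = cmap.adjacency.copy()
    L = A.shape[0]
    if flip_rate > 0:
        rng = np.random.default_rng(seed)
        iu, ju = np.triu_indices(L, k=1)
        flips = rng.random(iu.size) < flip_rate
        A[iu[flips], ju[flips]] ^= 1
        A[ju[flips], iu[flips]] = A[iu[flips], ju[flips]]
    return ContactMap(adjacency=A, mode=cmap.mode, threshold=cmap.threshold)


def read_pdb(path, chain: str | None = None, model: int = 1) -> ResidueCoordinates:
    """Read a (single-model slice of a) PDB file into ResidueCoordinates.

    Author numbering (gaps, insertion codes) is remapped to a dense 0-based
    index over resolved residues; altloc conflicts resolve to the
    highest-occupancy conformer (first on tie).
    """
    import biotite.structure as struc
    import biotite.structure.io.pdb as pdb
    from biotite.sequence import ProteinSequence

    f = pdb.PDBFile.read(str(path))
    arr = pdb.get_structure(f, model=model, altloc="occupancy", extra_fields=[])
    arr = arr[struc.filter_amino_acids(arr)]
    if chain is not None:
        arr = arr[arr.chain_id == chain]
        if arr.array_length() == 0:
            raise ValueError(f"no amino-acid atoms in chain {chain!r}")
    elif arr.array_length() == 0:
        raise ValueError("no amino-acid atoms in file")

    atoms: list[dict] = []
    seq_chars: list[str] = []
    for res in struc.residue_iter(arr):
        name3 = res.res_name[0]
        try:
            one = ProteinSequence.convert_letter_3to1(name3)
        except Exception:
            one = _THREE_TO_ONE_EXTRA.get(name3, "X")
        seq_chars.append(one)
        atoms.append({res.atom_name[i]: res.coord[i] for i in range(res.array_length())})
    cid = chain if chain is not None else str(arr.chain_id[0])
    return ResidueCoordinates(atoms=atoms, sequence="".join(seq_chars), chain_id=cid)
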