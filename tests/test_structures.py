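"""Contact-map construction against brute-force distance oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from strucfun.structures import (ContactMap, ResidueCoordinates,
                                 build_contact_map, filter_by_length,
                                 load_neighbor_radii, perturb_contact_map,
                                 read_pdb)
from strucfun.records import ProteinRecord
from strucfun.synthetic import sample_chain


def two_residue_coords(distance):
    pts = np.array([[0.0, 0.0, 0.0], [distance, 0.0, 0.0]])
    return ResidueCoordinates.from_bead_coords(pts, "AA")


class TestBuildContactMap:
    def test_contact_below_threshold(self):
        cm = build_contact_map(two_residue_coords(9.9), mode="CA_CA")
        assert cm.adjacency[0, 1] == 1

    def test_boundary_is_strict(self):
        cm = build_contact_map(two_residue_coords(10.0), mode="CA_CA")
        assert cm.adjacency[0, 1] == 0

    def test_matches_brute_force_all_pairs(self):
        rng = np.random.default_rng(5)
        pts = rng.uniform(0, 30, size=(50, 3))
        rc = ResidueCoordinates.from_bead_coords(pts, "A" * 50)
        cm = build_contact_map(rc, mode="CA_CA", threshold=10.0)
        for i in range(50):
            for j in range(50):
                expected = int(i != j and
                               np.linalg.norm(pts[i] - pts[j]) < 10.0)
                assert cm.adjacency[i, j] == expected

    def test_threshold_monotonicity(self):
        pts = np.random.default_rng(6).uniform(0, 25, size=(30, 3))
        rc = ResidueCoordinates.from_bead_coords(pts, "A" * 30)
        small = build_contact_map(rc, mode="CA_CA", threshold=8.0)
        big = build_contact_map(rc, mode="CA_CA", threshold=12.0)
        assert np.all(small.adjacency <= big.adjacency)

    def test_chain_adjacency_for_bead_chains(self):
        coords = sample_chain(60, 3)
        rc = ResidueCoordinates.from_bead_coords(coords)
        cm = build_contact_map(rc, mode="CA_CA", threshold=10.0)
        off = np.diag(cm.adjacency, k=1)
        assert off.all()  # 3.8 A bonds are always within 10 A

    def test_any_any_uses_all_atoms(self):
        # CA atoms far apart but side-chain atoms close
        atoms = [{"CA": np.array([0.0, 0, 0]), "CB": np.array([5.0, 0, 0])},
                 {"CA": np.array([11.0, 0, 0]), "CB": np.array([7.0, 0, 0])}]
        rc = ResidueCoordinates(atoms=atoms, sequence="AA")
        assert build_contact_map(rc, "CA_CA").adjacency[0, 1] == 0
        assert build_contact_map(rc, "ANY_ANY").adjacency[0, 1] == 1

    def test_nbr_nbr_radius_rule(self):
        radii = load_neighbor_radii()
        d = radii["A"] + radii["A"]
        atoms = [{"CA": np.zeros(3), "CB": np.zeros(3)},
                 {"CA": np.array([d - 0.1, 0, 0]),
                  "CB": np.array([d - 0.1, 0, 0])}]
        rc = ResidueCoordinates(atoms=atoms, sequence="AA")
        assert build_contact_map(rc, "NBR_NBR").adjacency[0, 1] == 1
        atoms[1] = {"CA": np.array([d + 0.1, 0, 0]),
                    "CB": np.array([d + 0.1, 0, 0])}
        rc = ResidueCoordinates(atoms=atoms, sequence="AA")
        assert build_contact_map(rc, "NBR_NBR").adjacency[0, 1] == 0

    def test_nbr_nbr_unknown_residue_named_in_error(self):
        rc = ResidueCoordinates.from_bead_coords(np.zeros((2, 3)), "AX")
        with pytest.raises(ValueError, match="X"):
            build_contact_map(rc, "NBR_NBR")

    def test_missing_ca_reported_per_residue(self):
        rc = ResidueCoordinates(atoms=[{"CA": np.zeros(3)}, {"CB": np.zeros(3)}],
                                sequence="AA")
        with pytest.raises(ValueError, match="1"):
            build_contact_map(rc, "CA_CA")

    def test_symmetry_and_zero_diagonal(self):
        pts = np.random.default_rng(7).uniform(0, 20, size=(25, 3))
        rc = ResidueCoordinates.from_bead_coords(pts, "A" * 25)
        cm = build_contact_map(rc, "CA_CA")
        assert np.array_equal(cm.adjacency, cm.adjacency.T)
        assert np.all(np.diag(cm.adjacency) == 0)


class TestFilterByLength:
    def test_inclusive_bounds(self):
        recs = [ProteinRecord(id=str(n), sequence="A" * n)
                for n in (59, 60, 1000, 1001)]
        kept = filter_by_length(recs, 60, 1000)
        assert [r.length for r in kept] == [60, 1000]

    def test_empty_input(self):
        assert filter_by_length([], 60, 1000) == []

    def test_degenerate_band_keeps_exact_length(self):
        recs = [ProteinRecord(id=str(i), sequence="A" * 80) for i in range(3)]
        assert len(filter_by_length(recs, 80, 80)) == 3

    def test_inverted_bounds_rejected(self):
        with pytest.raises(ValueError):
            filter_by_length([], 10, 5)


class TestPerturbContactMap:
    @pytest.fixture(scope="class")
    def cmap(self):
        pts = np.random.default_rng(8).uniform(0, 40, size=(200, 3))
        rc = ResidueCoordinates.from_bead_coords(pts, "A" * 200)
        return build_contact_map(rc, "CA_CA")

    def test_zero_rate_is_identity(self, cmap):
        out = perturb_contact_map(cmap, 0.0, seed=1)
        assert np.array_equal(out.adjacency, cmap.adjacency)

    def test_rate_one_on_zero_matrix_gives_complement(self):
        zero = ContactMap(adjacency=np.zeros((10, 10), dtype=np.uint8),
                          mode="CA_CA", threshold=10.0)
        out = perturb_contact_map(zero, 1.0, seed=1)
        expected = 1 - np.eye(10)
        assert np.array_equal(out.adjacency, expected)

    def test_flip_fraction_within_three_binomial_sd(self, cmap):
        out = perturb_contact_map(cmap, 0.1, seed=2)
        iu, ju = np.triu_indices(200, k=1)
        flipped = (out.adjacency[iu, ju] != cmap.adjacency[iu, ju]).sum()
        n = len(iu)
        sd = np.sqrt(n * 0.1 * 0.9)
        assert abs(flipped - 0.1 * n) <= 3 * sd

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(rate=st.floats(0, 1), seed=st.integers(0, 10_000))
    def test_perturbed_map_stays_valid(self, cmap, rate, seed):
        out = perturb_contact_map(cmap, rate, seed=seed)
        assert np.array_equal(out.adjacency, out.adjacency.T)
        assert np.all(np.diag(out.adjacency) == 0)
        assert np.isin(out.adjacency, (0, 1)).all()


PDB_SNIPPET = """\
ATOM      1  N   ALA A   5      11.104   6.134  -6.504  1.00  0.00           N
ATOM      2  CA  ALA A   5      11.639   6.071  -5.147  1.00  0.00           C
ATOM      3  C   ALA A   5      12.685   7.148  -4.927  1.00  0.00           C
ATOM      4  O   ALA A   5      13.600   7.280  -5.738  1.00  0.00           O
ATOM      5  CB  ALA A   5      12.232   4.687  -4.886  1.00  0.00           C
ATOM      6  N   GLY A   7      12.541   7.928  -3.862  1.00  0.00           N
ATOM      7  CA  GLY A   7      13.500   8.996  -3.566  1.00  0.00           C
ATOM      8  C   GLY A   7      13.344   9.475  -2.125  1.00  0.00           C
ATOM      9  O   GLY A   7      12.255   9.426  -1.549  1.00  0.00           O
ATOM     10  N   MSE A   8      14.100   9.700  -1.500  1.00  0.00           N
ATOM     11  CA  MSE A   8      15.100  10.500  -1.000  1.00  0.00           C
END
"""


class TestReadPdb:
    def test_dense_reindexing_and_nonstandard_mapping(self, tmp_path):
        # author numbering has a gap (5, 7, 8); output must be dense 0-based
        path = tmp_path / "mini.pdb"
        path.write_text(PDB_SNIPPET)
        rc = read_pdb(path, chain="A")
        assert len(rc) == 3
        assert rc.sequence == "AGM"  # selenomethionine maps to M
        assert np.allclose(rc.atoms[0]["CA"], [11.639, 6.071, -5.147])
        cm = build_contact_map(rc, "CA_CA")
        assert cm.length == 3

    def test_missing_chain_raises(self, tmp_path):
        path = tmp_path / "mini.pdb"
        path.write_text(PDB_SNIPPET)
        with pytest.raises(ValueError):
            read_pdb(path, chain="B")
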