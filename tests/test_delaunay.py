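from itertools import combinations

import numpy as np
import pytest

from thermoforest.constants import PSSM_AA_ORDER
from thermoforest.delaunay import (
    DT_FRAG_FEATURES,
    Tetrahedron,
    build_dt_tables,
    composition_key,
    continuity_class,
    dt_features,
    score_structure,
    tessellate,
)
from thermoforest.records import ValidationError
from thermoforest.simulate import gen_sequence, gen_structure, gen_protein


def brute_force_class(positions):
    """Definition-enumeration oracle: scan runs and adjacent pairs directly."""
    p = list(positions)
    runs = [p[i + 1] - p[i] == 1 and p[i + 2] - p[i + 1] == 1 for i in range(2)]
    pairs = [p[i + 1] - p[i] == 1 for i in range(3)]
    if any(runs):
        return "D43"
    if any(pairs):
        return "D2"
    return "D1"


class TestContinuityClass:
    @pytest.mark.parametrize("positions,expected", [
        ((5, 6, 7, 20), "D43"),
        ((5, 6, 20, 30), "D2"),
        ((5, 10, 20, 30), "D1"),
        ((1, 2, 3, 4), "D43"),
        ((1, 2, 4, 5), "D2"),
    ])
    def test_examples(self, positions, expected):
        assert continuity_class(positions) == expected

    def test_enumeration_oracle_all_tuples(self):
        for positions in combinations(range(1, 13), 4):
            assert continuity_class(positions) == brute_force_class(positions)

    def test_unsorted_rejected(self):
        with pytest.raises(ValidationError):
            continuity_class((5, 3, 8, 9))


def _circumsphere(p):
    """Centre and radius of the sphere through 4 points (oracle helper)."""
    a = 2 * (p[1:] - p[0])
    b = (p[1:] ** 2).sum(axis=1) - (p[0] ** 2).sum()
    centre = np.linalg.solve(a, b)
    return centre, np.linalg.norm(p[0] - centre)


class TestTessellate:
    def test_regular_tetrahedron_single_cell(self):
        pts = np.array([[0, 0, 0], [1, 0, 0], [0.5, np.sqrt(3) / 2, 0],
                        [0.5, np.sqrt(3) / 6, np.sqrt(2.0 / 3)]])
        tets = tessellate(pts, edge_cutoff=None)
        assert len(tets) == 1
        assert tets[0].positions == (1, 2, 3, 4)

    def test_coplanar_rejected(self):
        pts = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [1, 1, 0]], dtype=float)
        with pytest.raises(ValidationError):
            tessellate(pts, edge_cutoff=None)

    def test_duplicate_points_rejected(self):
        pts = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1], [0, 0, 1.0]])
        with pytest.raises(ValidationError, match="duplicate"):
            tessellate(pts)

    def test_too_few_points(self):
        with pytest.raises(ValidationError):
            tessellate(np.zeros((3, 3)))

    def test_empty_circumsphere_property(self, rng):
        """Each reported cell's circumsphere contains no other point (the
        Delaunay definition, checked independently of the library)."""
        pts = rng.uniform(0, 20, size=(15, 3))
        tets = tessellate(pts, edge_cutoff=None)
        assert tets
        for tet in tets:
            idx = [p - 1 for p in tet.positions]
            centre, radius = _circumsphere(pts[idx])
            others = np.delete(np.arange(len(pts)), idx)
            dists = np.linalg.norm(pts[others] - centre, axis=1)
            assert np.all(dists >= radius - 1e-8)

    def test_rigid_motion_invariance(self, rng):
        pts = rng.uniform(0, 15, size=(25, 3))
        tets = {t.positions for t in tessellate(pts)}
        q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
        if np.linalg.det(q) < 0:
            q[:, 0] *= -1
        moved = pts @ q.T + np.array([5.0, -3.0, 12.0])
        tets_moved = {t.positions for t in tessellate(moved)}
        assert tets == tets_moved

    def test_partition_into_classes(self, rng):
        pts = rng.uniform(0, 25, size=(40, 3))
        tets = tessellate(pts)
        counts = {"D43": 0, "D2": 0, "D1": 0}
        for t in tets:
            counts[t.continuity] += 1
        assert sum(counts.values()) == len(tets)

    def test_nan_rows_are_skipped_but_indices_kept(self, rng):
        pts = rng.uniform(0, 12, size=(10, 3))
        pts[4] = np.nan
        tets = tessellate(pts, edge_cutoff=None)
        used = {p for t in tets for p in t.positions}
        assert 5 not in used  # 1-based index of the NaN row
        assert max(used) <= 10

    def test_edge_cutoff_drops_long_cells(self, rng):
        pts = rng.uniform(0, 10, size=(12, 3))
        pts = np.vstack([pts, [200.0, 200.0, 200.0]])  # far outlier
        tets = tessellate(pts, edge_cutoff=10.0)
        assert all(13 not in t.positions for t in tets)


@pytest.fixture(scope="module")
def setup():
    rng = np.random.default_rng(9)
    corpora = []
    for _ in range(2):
        corpus = []
        for j in range(4):
            seq = gen_sequence(40, rng)
            p = gen_structure(gen_protein(40, rng, id=f"s{j}"), "walk", seed=rng)
            corpus.append((seq, tessellate(p.ca_coords)))
        corpora.append(corpus)
    tables = build_dt_tables(*corpora)
    protein = gen_structure(gen_protein(40, rng, id="q"), "walk", seed=rng)
    tets = tessellate(protein.ca_coords)
    return tables, protein, tets, rng


class TestDtFeatures:
    def _mutate(self, seq, rng, n=1):
        letters = list(PSSM_AA_ORDER)
        positions = rng.choice(len(seq), size=n, replace=False)
        mut = list(seq)
        for pos in positions:
            mut[pos] = rng.choice([a for a in letters if a != seq[pos]])
        return "".join(mut)

    def test_identity_zero(self, setup):
        tables, protein, tets, _ = setup
        f = dt_features(protein.sequence, protein.sequence, tets, tables)
        assert set(f) == set(DT_FRAG_FEATURES)
        assert all(v == 0 for v in f.values())

    def test_antisymmetry_exact(self, setup):
        tables, protein, tets, rng = setup
        for _ in range(10):
            mut = self._mutate(protein.sequence, rng, n=int(rng.integers(1, 3)))
            fwd = dt_features(protein.sequence, mut, tets, tables)
            rev = dt_features(mut, protein.sequence, tets, tables)
            for name in fwd:
                assert rev[name] == -fwd[name]

    def test_local_matches_full_rescore(self, setup):
        tables, protein, tets, rng = setup
        for _ in range(10):
            mut = self._mutate(protein.sequence, rng, n=int(rng.integers(1, 3)))
            local = dt_features(protein.sequence, mut, tets, tables)
            full = dt_features(protein.sequence, mut, tets, tables, local=False)
            for name in local:
                assert local[name] == pytest.approx(full[name], abs=1e-12)

    def test_substitution_outside_all_tetrahedra(self, setup):
        """A residue isolated by the edge cutoff contributes to no feature."""
        tables, protein, _, _ = setup
        coords = protein.ca_coords.copy()
        coords[0] = [500.0, 500.0, 500.0]  # push residue 1 beyond any 10 A edge
        tets = tessellate(coords, edge_cutoff=10.0)
        assert all(1 not in t.positions for t in tets)
        mut = list(protein.sequence)
        mut[0] = "W" if mut[0] != "W" else "Y"
        f = dt_features(protein.sequence, "".join(mut), tets, tables)
        assert all(v == 0 for v in f.values())

    def test_score_structure_class_restriction(self, setup):
        tables, protein, tets, _ = setup
        table = tables[("occurrence", "D43")]
        total = score_structure(protein.sequence, tets, table)
        manual = sum(table.value(composition_key(protein.sequence, t.positions))
                     for t in tets if t.continuity == "D43")
        assert total == pytest.approx(manual)

    def test_composition_key_is_sorted(self):
        assert composition_key("MKVW", (2, 1, 4, 3)) == "".join(sorted("MKVW"))
        t = Tetrahedron((1, 2, 3, 5))
        assert t.continuity == "D43"
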