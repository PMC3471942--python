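"""Delaunay tessellation of Ca traces and the 7 spatial fragment features.

The Ca point set is tessellated into tetrahedra (scipy's Qhull wrapper);
each tetrahedron defines a four-residue spatial fragment keyed by the
*composition* of its residues (the four letters sorted, an unordered
multiset: spatial neighbours have no canonical order, and the key space
stays at C(23,4) = 8855). Tetrahedra are classified by sequence continuity:

* D43 — the four positions contain a run of >= 3 consecutive indices;
* D2  — at least one adjacent pair but no such run;
* D1  — no adjacent positions at all.

Potential tables (occurrence per class and unconditioned, plus a
state-conditional propensity per class) share the sequential tables' log-ratio
form and serialization. An event is scored as score(mutant) - score(wild
type) over the fixed wild-type tessellation; only tetrahedra containing a
substituted residue can contribute.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass
from itertools import combinations

import numpy as np
from scipy.spatial import Delaunay, QhullError

from .fragments import PotentialTable, _log_freq
from .records import ValidationError

CONTINUITY_CLASSES = ("D43", "D2", "D1")

#: Number of unordered 4-residue compositions over the 20-letter alphabet.
DT_N_KEYS = math.comb(20 + 3, 4)

#: Default edge-length cutoff (Angstrom) suppressing sliver tetrahedra that
#: span the convex hull.
DEFAULT_EDGE_CUTOFF = 10.0

DT_FRAG_FEATURES = {
    "FBDTocc": ("occurrence", None),
    "FBDTD43": ("occurrence", "D43"),
    "FBDTD2": ("occurrence", "D2"),
    "FBDTD1": ("occurrence", "D1"),
    "FBDTDD43": ("propensity", "D43"),
    "FBDTDD2": ("propensity", "D2"),
    "FBDTDD1": ("propensity", "D1"),
}


def continuity_class(positions) -> str:
    """Classify a sorted 4-tuple of residue indices as D43 / D2 / D1."""
    p = tuple(positions)
    if len(p) != 4 or any(b <= a for a, b in zip(p, p[1:])):
        raise ValidationError(f"positions must be 4 strictly increasing indices, got {p}")
    adjacent = [b - a == 1 for a, b in zip(p, p[1:])]
    if any(a and b for a, b in zip(adjacent, adjacent[1:])):
        return "D43"
    if any(adjacent):
        return "D2"
    return "D1"


@dataclass(frozen=True)
class Tetrahedron:
    positions: tuple[int, int, int, int]  # 1-based residue indices, sorted

    def __post_init__(self):
        continuity_class(self.positions)  # validates sortedness

    @property
    def continuity(self) -> str:
        return continuity_class(self.positions)


def tessellate(ca_coords, edge_cutoff: float | None = DEFAULT_EDGE_CUTOFF
               ) -> list[Tetrahedron]:
    """Delaunay-tessellate a Ca trace into residue-index tetrahedra.

    Rows containing NaN (missing Ca) are excluded from the point set but keep
    their residue numbering. Cells with any edge longer than ``edge_cutoff``
    are dropped.
    """
    coords = np.asarray(ca_coords, dtype=float)
    if coords.ndim != 2 or coords.shape[1] != 3:
        raise ValidationError(f"expected (L, 3) coordinates, got {coords.shape}")
    present = ~np.isnan(coords).any(axis=1)
    points = coords[present]
    index_map = np.flatnonzero(present) + 1  # back to 1-based residue indices
    if len(points) < 4:
        raise ValidationError("need at least 4 residues with coordinates")
    uniq = np.unique(points, axis=0)
    if len(uniq) != len(points):
        raise ValidationError("duplicate Ca coordinates")
    try:
        tri = Delaunay(points)
    except QhullError as exc:
        raise ValidationError(f"degenerate point set: {exc}") from None
    if tri.simplices.shape[1] != 4:
        raise ValidationError("tessellation is not 3-dimensional (coplanar input?)")
    tets = []
    for simplex in tri.simplices:
        if edge_cutoff is not None:
            pts = points[simplex]
            edges = [np.linalg.norm(a - b) for a, b in combinations(pts, 2)]
            if max(edges) > edge_cutoff:
                continue
        tets.append(Tetrahedron(tuple(sorted(int(index_map[i]) for i in simplex))))
    return sorted(tets, key=lambda t: t.positions)


def composition_key(sequence: str, positions) -> str:
    """Unordered 4-residue composition key (sorted letters) for a tetrahedron."""
    return "".join(sorted(sequence[p - 1] for p in positions))


# ---------------------------------------------------------------------------
# Table construction over (sequence, tessellation) corpora
# ---------------------------------------------------------------------------


def _count_dt(corpus, cls=None) -> tuple[Counter, int]:
    counts: Counter = Counter()
    for seq, tets in corpus:
        for tet in tets:
            if cls is not None and tet.continuity != cls:
                continue
            counts[composition_key(seq, tet.positions)] += 1
    return counts, sum(counts.values())


def build_dt_tables(corpus_a, corpus_b, pseudocount: float = 1.0, meta=None
                    ) -> dict[tuple[str, str | None], PotentialTable]:
    """The 7-table set behind the spatial fragment features.

    Each corpus is an iterable of ``(sequence, tetrahedra)`` pairs.
    """
    if not corpus_a or not corpus_b:
        raise ValidationError("both corpora must be nonempty")
    meta = dict(meta or {})
    tables: dict[tuple[str, str | None], PotentialTable] = {}

    def occ(cls):
        ca, na = _count_dt(corpus_a, cls)
        cb, nb = _count_dt(corpus_b, cls)
        values = {}
        for frag in set(ca) | set(cb):
            values[frag] = (_log_freq(ca.get(frag, 0), na, pseudocount, DT_N_KEYS)
                            - _log_freq(cb.get(frag, 0), nb, pseudocount, DT_N_KEYS))
        default = (_log_freq(0, na, pseudocount, DT_N_KEYS)
                   - _log_freq(0, nb, pseudocount, DT_N_KEYS))
        return PotentialTable("occurrence", cls, values, default, pseudocount,
                              DT_N_KEYS, meta)

    def prop_one(corpus, cls):
        c_all, n_all = _count_dt(corpus)
        c_s, n_s = _count_dt(corpus, cls)
        values = {}
        for frag in set(c_all) | set(c_s):
            values[frag] = (_log_freq(c_s.get(frag, 0), n_s, pseudocount, DT_N_KEYS)
                            - _log_freq(c_all.get(frag, 0), n_all, pseudocount, DT_N_KEYS))
        default = (_log_freq(0, n_s, pseudocount, DT_N_KEYS)
                   - _log_freq(0, n_all, pseudocount, DT_N_KEYS))
        return values, default

    tables[("occurrence", None)] = occ(None)
    for cls in CONTINUITY_CLASSES:
        tables[("occurrence", cls)] = occ(cls)
        va, da = prop_one(corpus_a, cls)
        vb, db = prop_one(corpus_b, cls)
        values = {f: va.get(f, da) - vb.get(f, db) for f in set(va) | set(vb)}
        tables[("propensity", cls)] = PotentialTable(
            "propensity", cls, values, da - db, pseudocount, DT_N_KEYS, meta)
    return tables


# ---------------------------------------------------------------------------
# Feature computation
# ---------------------------------------------------------------------------


def score_structure(sequence: str, tets, table: PotentialTable) -> float:
    total = 0.0
    for tet in tets:
        if table.state is not None and tet.continuity != table.state:
            continue
        total += table.value(composition_key(sequence, tet.positions))
    return total


def dt_features(wt_seq: str, mut_seq: str, tets,
                dt_tables: dict[tuple[str, str | None], PotentialTable],
                local: bool = True) -> dict[str, float]:
    """The 7 spatial fragment features, score(mutant) - score(wild type)."""
    if len(wt_seq) != len(mut_seq):
        raise ValidationError("wild-type and mutant sequences differ in length")
    out = {}
    if not local:
        for name, key in DT_FRAG_FEATURES.items():
            table = dt_tables[key]
            out[name] = (score_structure(mut_seq, tets, table)
                         - score_structure(wt_seq, tets, table))
        return out
    changed = {i + 1 for i, (a, b) in enumerate(zip(wt_seq, mut_seq)) if a != b}
    touched = [t for t in tets if changed.intersection(t.positions)]
    for name, key in DT_FRAG_FEATURES.items():
        table = dt_tables[key]
        delta = 0.0
        for tet in touched:
            if table.state is not None and tet.continuity != table.state:
                continue
            delta += (table.value(composition_key(mut_seq, tet.positions))
                      - table.value(composition_key(wt_seq, tet.positions)))
        out[name] = delta
    return out
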