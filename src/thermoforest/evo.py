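"""Evolutionary-information features extracted from a sequence profile.

Ten features per mutation event: the wild-type and mutant residue's log-odds
and weighted scores at the mutated position (Wtlo, Wtwt, Mulo, Muwt), and the
profile conservation in windows of 5, 9 and 15 residues centred on the site
(wtlo5/wtwt5/..., independent of the mutant residue identity). For
multi-point mutations every slot is the arithmetic mean over sites.

The per-position aggregate behind the window features is the sum of the 20
profile entries at that position; the window value is the mean of that
aggregate over the (terminus-truncated) window. ``aggregation="wt_column"``
switches to the wild-type residue's own column. Tree ensembles are invariant
to per-feature monotone rescaling, so this choice does not alter split
behaviour, only the printed feature scale.
"""

from __future__ import annotations

import numpy as np

from .records import Pssm, Substitution, ValidationError

WINDOW_SIZES = (5, 9, 15)

EVO_FEATURE_NAMES = (
    "Wtlo", "Wtwt", "Mulo", "Muwt",
    "wtlo5", "wtwt5", "wtlo9", "wtwt9", "wtlo15", "wtwt15",
)


def point_scores(pssm: Pssm, position: int, wt_aa: str, mut_aa: str
                 ) -> tuple[float, float, float, float]:
    """(wtlo, wtwt, mulo, muwt) at a 1-based position."""
    if not 1 <= position <= len(pssm):
        raise ValidationError(f"position {position} outside profile of length {len(pssm)}")
    row = position - 1
    wt_col, mut_col = pssm.column(wt_aa), pssm.column(mut_aa)
    return (
        float(pssm.log_odds[row, wt_col]),
        float(pssm.weighted[row, wt_col]),
        float(pssm.log_odds[row, mut_col]),
        float(pssm.weighted[row, mut_col]),
    )


def window_scores(pssm: Pssm, position: int, w: int, sequence: str | None = None,
                  aggregation: str = "sum") -> tuple[float, float]:
    """(avg log-odds, avg weighted) over a w-residue window centred at position.

    The window includes the centre and is truncated at the termini.
    """
    if w not in WINDOW_SIZES:
        raise ValidationError(f"window size must be one of {WINDOW_SIZES}, got {w}")
    if not 1 <= position <= len(pssm):
        raise ValidationError(f"position {position} outside profile of length {len(pssm)}")
    half = w // 2
    lo_idx = max(0, position - 1 - half)
    hi_idx = min(len(pssm), position + half)  # exclusive
    lo_block = pssm.log_odds[lo_idx:hi_idx]
    wt_block = pssm.weighted[lo_idx:hi_idx]
    if aggregation == "sum":
        per_pos_lo = lo_block.sum(axis=1)
        per_pos_wt = wt_block.sum(axis=1)
    elif aggregation == "wt_column":
        if sequence is None:
            raise ValidationError("wt_column aggregation needs the sequence")
        cols = [pssm.column(sequence[i]) for i in range(lo_idx, hi_idx)]
        rows = np.arange(lo_idx, hi_idx)
        per_pos_lo = pssm.log_odds[rows, cols]
        per_pos_wt = pssm.weighted[rows, cols]
    else:
        raise ValidationError(f"unknown aggregation {aggregation!r}")
    return float(per_pos_lo.mean()), float(per_pos_wt.mean())


def evo_features(pssm: Pssm, subs: tuple[Substitution, ...], sequence: str | None = None,
                 aggregation: str = "sum") -> dict[str, float]:
    """All 10 evolutionary features; multi-point events average per-site values."""
    acc = {name: 0.0 for name in EVO_FEATURE_NAMES}
    for s in subs:
        wtlo, wtwt, mulo, muwt = point_scores(pssm, s.position, s.wt_aa, s.mut_aa)
        acc["Wtlo"] += wtlo
        acc["Wtwt"] += wtwt
        acc["Mulo"] += mulo
        acc["Muwt"] += muwt
        for w in WINDOW_SIZES:
            alo, awt = window_scores(pssm, s.position, w, sequence, aggregation)
            acc[f"wtlo{w}"] += alo
            acc[f"wtwt{w}"] += awt
    n = len(subs)
    return {name: value / n for name, value in acc.items()}
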