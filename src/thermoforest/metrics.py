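"""Evaluation metrics: zero-threshold classification, midrank AUC, Pearson R,
and the two-sample Kolmogorov-Smirnov feature screen."""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
from scipy import stats

from .records import ValidationError


def classify(predicted_ddg: float) -> str:
    """Zero-threshold call: stabilizing iff predicted ddG > 0.

    A prediction of exactly zero is called destabilizing (conservative
    tie-break)."""
    if not math.isfinite(predicted_ddg):
        raise ValidationError(f"cannot classify non-finite prediction {predicted_ddg}")
    return "stabilizing" if predicted_ddg > 0 else "destabilizing"


def accuracy(y_true_ddg, y_pred_ddg) -> float:
    """Fraction of records whose stabilizing/destabilizing call is correct.

    Records with experimental ddG exactly 0 sit on the class boundary and are
    excluded."""
    y_true = np.asarray(y_true_ddg, dtype=float)
    y_pred = np.asarray(y_pred_ddg, dtype=float)
    keep = y_true != 0
    if not keep.any():
        raise ValidationError("no records off the class boundary")
    return float(np.mean((y_true[keep] > 0) == (y_pred[keep] > 0)))


def auc_midrank(labels, scores) -> float:
    """ROC AUC via the Mann-Whitney rank statistic with midranks for ties.

    ``labels`` are booleans (True = stabilizing); ``scores`` the predicted
    ddG values. Returns NaN if either class is absent.
    """
    labels = np.asarray(labels, dtype=bool)
    scores = np.asarray(scores, dtype=float)
    n_pos = int(labels.sum())
    n_neg = int((~labels).sum())
    if n_pos == 0 or n_neg == 0:
        return float("nan")
    ranks = stats.rankdata(scores)  # midranks
    rank_sum = ranks[labels].sum()
    return (rank_sum - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)


def pearson_r(y_true, y_pred) -> float:
    y_true = np.asarray(y_true, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if len(y_true) < 2 or np.std(y_true) == 0 or np.std(y_pred) == 0:
        return float("nan")
    return float(stats.pearsonr(y_true, y_pred).statistic)


def ks_two_sample(sample_a, sample_b) -> tuple[float, float]:
    """Two-sample KS statistic D = sup|F1 - F2| and its asymptotic p-value."""
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValidationError("KS test needs two nonempty samples")
    res = stats.ks_2samp(a, b, method="asymp")
    return float(res.statistic), float(res.pvalue)


def ks_feature_analysis(features: pd.DataFrame, ddg) -> pd.DataFrame:
    """Per-feature medians/means in stabilizing vs destabilizing records plus
    the two-sample KS p-value, mirroring a feature-screen table.

    ``ddg`` supplies the grouping (stabilizing: ddg > 0); boundary records
    (ddg == 0) are excluded.
    """
    ddg = np.asarray(ddg, dtype=float)
    stab = ddg > 0
    dest = ddg < 0
    if not stab.any() or not dest.any():
        raise ValidationError("need both stabilizing and destabilizing records")
    rows = []
    for name in features.columns:
        col = features[name].to_numpy(dtype=float)
        d_stat, p = ks_two_sample(col[stab], col[dest])
        rows.append({
            "feature": name,
            "median_stab": float(np.median(col[stab])),
            "median_destab": float(np.median(col[dest])),
            "mean_stab": float(np.mean(col[stab])),
            "mean_destab": float(np.mean(col[dest])),
            "ks_D": d_stat,
            "p_value": p,
        })
    return pd.DataFrame(rows).set_index("feature")
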