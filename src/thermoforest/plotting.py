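"""Plot helpers for the evaluation report."""

from __future__ import annotations

import numpy as np


def plot_importance(importance, ax=None, top: int | None = None):
    """Horizontal bar chart of impurity importances with across-fold error bars.

    ``importance`` is the DataFrame produced by
    :func:`thermoforest.forest.feature_importance` (columns mean, se).
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 0.25 * len(importance) + 1))
    df = importance if top is None else importance.head(top)
    df = df.iloc[::-1]
    xerr = np.where(np.isfinite(df["se"]), df["se"], 0.0)
    ax.barh(df.index, df["mean"], xerr=xerr, color="#4878a8")
    ax.set_xlabel("impurity importance")
    ax.figure.tight_layout()
    return ax


def plot_regression(predictions, ax=None):
    """Predicted vs experimental ddG, forward and reverse records marked."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 5))
    for direction, marker in (("forward", "o"), ("reverse", "x")):
        sub = predictions[predictions["direction"] == direction]
        ax.scatter(sub["ddg"], sub["y_pred"], s=12, marker=marker,
                   alpha=0.6, label=direction)
    lims = [predictions["ddg"].min(), predictions["ddg"].max()]
    ax.plot(lims, lims, color="grey", lw=0.8)
    ax.set_xlabel("experimental ddG (kcal/mol)")
    ax.set_ylabel("predicted ddG (kcal/mol)")
    ax.legend()
    return ax
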