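"""Diagnostic plots: rRMSE heatmap, map layout, observed-vs-predicted."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg", force=False)  # headless-safe default

import matplotlib.pyplot as plt
import numpy as np

from .mapping import PredictionMap
from .predict import PredictionResult
from .regression import ModelMatrix, rrmse_matrix
from .table import ShiftTable

__all__ = [
    "plot_rrmse_heatmap",
    "plot_prediction_map",
    "plot_observed_vs_predicted",
]


def plot_rrmse_heatmap(m: ModelMatrix, ax=None, mask_unstable: bool = True):
    """Response x predictor heatmap of rRMSE (%); unstable cells greyed."""
    df = rrmse_matrix(m, mask_unstable=mask_unstable)
    if ax is None:
        _, ax = plt.subplots(figsize=(7.5, 6.5))
    data = np.ma.masked_invalid(df.to_numpy())
    im = ax.imshow(data, cmap="viridis", aspect="auto")
    ax.set_xticks(range(len(df.columns)), df.columns, rotation=90, fontsize=7)
    ax.set_yticks(range(len(df.index)), df.index, fontsize=7)
    ax.set_xlabel("predictor (x)")
    ax.set_ylabel("response (y)")
    ax.figure.colorbar(im, ax=ax, label="rRMSE (%)")
    ax.set_title("Pairwise shift-model rRMSE")
    return ax


def plot_prediction_map(pmap: PredictionMap, ax=None):
    """Simple layered drawing of the rooted map (depth = row)."""
    import networkx as nx

    g = nx.DiGraph()
    for r, e in pmap.parents.items():
        g.add_edge(e.predictor, r)
    depths = {n: pmap.depth(n) for n in pmap.nodes}
    layers: dict[int, list[str]] = {}
    for n, d in depths.items():
        layers.setdefault(d, []).append(n)
    pos = {}
    for d, members in sorted(layers.items()):
        for i, n in enumerate(sorted(members)):
            pos[n] = (i - (len(members) - 1) / 2.0, -d)
    if ax is None:
        _, ax = plt.subplots(figsize=(8, 5))
    nx.draw_networkx(
        g, pos=pos, ax=ax, node_size=900, node_color="#cfe3f5",
        font_size=6, arrows=True,
    )
    for r, e in pmap.alternates.items():
        ax.annotate(
            "", xy=pos[r], xytext=pos[e.predictor],
            arrowprops=dict(arrowstyle="->", linestyle="--", color="purple"),
        )
    ax.set_axis_off()
    ax.set_title(f"Prediction map rooted at {pmap.root}")
    return ax


def plot_observed_vs_predicted(
    p: PredictionResult, observed: ShiftTable, system: str, ax=None
):
    """Observed vs predicted shifts for one system, with the 1:1 line."""
    sub = p.frame[(p.frame["system"] == system)]
    obs = observed.column(system).reindex(sub["sample"]).to_numpy(dtype=float)
    prd = sub["predicted"].to_numpy(dtype=float)
    ok = ~np.isnan(obs) & ~np.isnan(prd)
    if ax is None:
        _, ax = plt.subplots(figsize=(4, 4))
    ax.plot(obs[ok], prd[ok], "k.", ms=3)
    lo, hi = (min(obs[ok].min(), prd[ok].min()), max(obs[ok].max(), prd[ok].max())) \
        if ok.any() else (0, 1)
    ax.plot([lo, hi], [lo, hi], "r-", lw=1, label="1:1")
    ax.set_xlabel("observed delta (ppm)")
    ax.set_ylabel("predicted delta (ppm)")
    ax.set_title(system)
    ax.legend(frameon=False, fontsize=7)
    return ax
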