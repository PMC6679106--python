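"""Figure helpers: difference spectra with significance shading, PCA score
plots with covariance ellipses, and LV-sweep curves."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
from matplotlib.patches import Ellipse

from .chemometrics import CVResult, PCAResult, covariance_ellipse
from .group_statistics import DifferenceResult

__all__ = ["plot_difference", "plot_pca_scores", "plot_lv_sweep"]


def _finish(fig, path):
    if path is not None:
        fig.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(fig)
    return fig


def plot_difference(r: DifferenceResult, path: str | Path | None = None):
    """Difference spectrum with p < alpha regions shaded."""
    fig, ax = plt.subplots(figsize=(9, 3.2))
    ax.plot(r.grid, r.difference, lw=0.8, color="k")
    ax.axhline(0.0, color="grey", lw=0.5)
    mask = np.asarray(r.significant_mask, dtype=bool)
    if mask.any():
        ylo, yhi = ax.get_ylim()
        ax.fill_between(r.grid, ylo, yhi, where=mask, color="tab:orange", alpha=0.25,
                        linewidth=0)
        ax.set_ylim(ylo, yhi)
    ax.set_xlabel("wavenumber (cm$^{-1}$)")
    ax.set_ylabel("abs. difference")
    ax.set_title(f"{r.group_b} $-$ {r.group_a}  (shaded: p < {r.alpha:g})")
    ax.invert_xaxis()
    return _finish(fig, path)


def plot_pca_scores(res: PCAResult, path: str | Path | None = None,
                    confidence: float = 0.95):
    """PC-1/PC-2 scores coloured by group, with covariance ellipses."""
    if res.unit_meta is None:
        raise ValueError("PCA result carries no unit metadata")
    fig, ax = plt.subplots(figsize=(5.5, 5))
    v = res.explained_variance_pct
    for group, idx in res.unit_meta.groupby("group", sort=False).groups.items():
        pts = res.scores[np.asarray(idx)][:, :2]
        line = ax.scatter(pts[:, 0], pts[:, 1], s=14, label=str(group))
        if len(pts) >= 3:
            ell = covariance_ellipse(pts, confidence)
            ax.add_patch(
                Ellipse(ell.center, 2 * ell.axes[0], 2 * ell.axes[1],
                        angle=np.degrees(ell.rotation), fill=False,
                        edgecolor=line.get_facecolor()[0], lw=1.2)
            )
    ax.set_xlabel(f"PC-1 ({v[0]:.1f}%)")
    ax.set_ylabel(f"PC-2 ({v[1]:.1f}%)")
    ax.legend(fontsize=8)
    return _finish(fig, path)


def plot_lv_sweep(r: CVResult, path: str | Path | None = None):
    """Cross-validated sensitivity/specificity against the LV count."""
    fig, ax = plt.subplots(figsize=(6, 4))
    t = r.table
    ax.plot(t["lv"], t["sensitivity_mean"], marker="o", ms=3, label="sensitivity")
    ax.plot(t["lv"], t["specificity_mean"], marker="s", ms=3, label="specificity")
    ax.axvline(r.chosen_m, color="grey", ls="--", lw=0.8,
               label=f"selected m = {r.chosen_m}")
    ax.set_xlabel("latent variables")
    ax.set_ylabel("mean rate (%)")
    ax.set_title(f"{r.group_a} vs {r.group_b}")
    ax.legend(fontsize=8)
    return _finish(fig, path)
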