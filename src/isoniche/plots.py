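"""Optional figure export: ellipse panels, posterior credible boxes, d15N strips.

All functions return a matplotlib Figure; callers decide whether to save.
"""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .bayes import PosteriorDraws, summarize_posterior
from .ellipse import EllipseFit, ellipse_boundary
from scipy.spatial import ConvexHull, QhullError

__all__ = ["plot_ellipses", "plot_posterior_boxes", "plot_d15n_strip"]


def plot_ellipses(
    point_sets: dict[str, np.ndarray], use_seac: bool = True, show_hull: bool = True
):
    """SEAc ellipses (solid) and convex hulls (dashed) for labelled point sets."""
    from .ellipse import fit_standard_ellipse

    fig, ax = plt.subplots(figsize=(7, 6))
    colors = plt.cm.tab10.colors
    for (label, pts), color in zip(point_sets.items(), colors):
        fit = fit_standard_ellipse(pts)
        scale = fit.seac_scale if use_seac else 1.0
        ring = ellipse_boundary(fit, radius_scale=scale, n_vertices=256)
        ring = np.vstack([ring, ring[:1]])
        ax.plot(ring[:, 0], ring[:, 1], color=color, label=f"{label} (SEAc={fit.seac:.2f})")
        ax.scatter(pts[:, 0], pts[:, 1], s=12, color=color, alpha=0.6)
        if show_hull:
            try:
                hull = ConvexHull(pts)
                cycle = np.append(hull.vertices, hull.vertices[0])
                ax.plot(pts[cycle, 0], pts[cycle, 1], color=color, ls="--", lw=0.8)
            except QhullError:
                pass
    ax.set_xlabel("$\\delta^{13}$C (‰)")
    ax.set_ylabel("$\\delta^{15}$N (‰)")
    ax.legend(fontsize=8)
    fig.tight_layout()
    return fig


def plot_posterior_boxes(group_draws: dict[str, PosteriorDraws], seac: dict[str, float] | None = None):
    """Credible-interval boxes (50/75/95%) with posterior modes for each group."""
    fig, ax = plt.subplots(figsize=(6, 4))
    shades = {0.95: "0.85", 0.75: "0.65", 0.50: "0.45"}
    for i, (label, draws) in enumerate(group_draws.items()):
        summ = summarize_posterior(draws)
        for level in (0.95, 0.75, 0.50):
            lo, hi = summ.intervals[level]
            ax.bar(i, hi - lo, bottom=lo, width=0.55, color=shades[level], zorder=1)
        ax.plot(i, summ.mode, "ko", zorder=3)
        if seac and label in seac:
            ax.plot(i, seac[label], "rs", zorder=3)
    ax.set_xticks(range(len(group_draws)), list(group_draws))
    ax.set_ylabel("SEA$_b$ (‰$^2$)")
    fig.tight_layout()
    return fig


def plot_d15n_strip(labels: list[str], d15n: list[float], bands: list[tuple[int, float, float]] | None = None):
    """Ranked d15N strip with optional horizontal trophic-level band edges."""
    order = np.argsort(d15n)
    fig, ax = plt.subplots(figsize=(7, max(3, 0.22 * len(labels))))
    ax.scatter(np.array(d15n)[order], range(len(labels)))
    ax.set_yticks(range(len(labels)), [labels[i] for i in order], fontsize=7)
    if bands:
        for level, lo, hi in bands:
            ax.axvline(hi, color="0.7", lw=0.8)
            ax.text(hi, len(labels) - 1, f"TL{level}|", fontsize=7, ha="right", color="0.4")
    ax.set_xlabel("$\\delta^{15}$N (‰)")
    fig.tight_layout()
    return fig
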