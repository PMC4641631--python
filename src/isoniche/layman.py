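"""Layman community-wide metrics over bivariate isotope points.

Six descriptors of community trophic structure computed on a set of points in
(d13C, d15N) space — typically one point per taxon or per size-class mean:

* CR — d13C range (max - min), niche diversification at the base;
* NR — d15N range, trophic length;
* CD — mean Euclidean distance to the centroid, average trophic diversity;
* MNND — mean distance to the nearest distinct neighbour, species packing
  (small MNND = high trophic redundancy);
* SDNND — standard deviation of those nearest-neighbour distances, evenness
  of packing;
* TA — total area, the convex hull of the points (needs >= 3 points).

SDNND uses the sample SD (divisor n - 1) by default; pass ``sd_ddof=0`` for the
population version.  Ranges are axis-aligned, so CR and NR are not rotation
invariant; CD, MNND, SDNND and TA are.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .ellipse import convex_hull_area

__all__ = ["LaymanMetrics", "layman_metrics", "nearest_neighbour_distances"]


@dataclass(frozen=True)
class LaymanMetrics:
    NR: float
    CR: float
    CD: float
    MNND: float
    SDNND: float
    TA: float | None = None  # None when < 3 points or hull not requested


def nearest_neighbour_distances(points: np.ndarray) -> np.ndarray:
    """Distance of each point to its nearest distinct neighbour (ties share the minimum)."""
    pts = np.asarray(points, dtype=float)
    d = squareform(pdist(pts))
    np.fill_diagonal(d, np.inf)
    return d.min(axis=1)


def layman_metrics(
    points: np.ndarray, include_hull: bool = True, sd_ddof: int = 1
) -> LaymanMetrics:
    """Compute the community-wide metrics for an (n >= 2, 2) point set."""
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("points must be an (n, 2) array")
    n = pts.shape[0]
    if n < 2:
        raise ValueError(f"need at least 2 points, got {n}")
    cr = float(pts[:, 0].max() - pts[:, 0].min())
    nr = float(pts[:, 1].max() - pts[:, 1].min())
    centroid = pts.mean(axis=0)
    cd = float(np.linalg.norm(pts - centroid, axis=1).mean())
    nnd = nearest_neighbour_distances(pts)
    mnnd = float(nnd.mean())
    sdnnd = float(nnd.std(ddof=sd_ddof)) if n > sd_ddof else 0.0
    ta = convex_hull_area(pts) if (include_hull and n >= 3) else None
    return LaymanMetrics(NR=nr, CR=cr, CD=cd, MNND=mnnd, SDNND=sdnnd, TA=ta)
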