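"""Deterministic bivariate ellipse statistics.

The standard ellipse of a bivariate sample is the 1-SD Mahalanobis contour of
the fitted normal: it encloses about 40% of the probability mass (exactly
1 - exp(-1/2) = 39.35% for a bivariate normal) and plays the role the standard
deviation plays in one dimension.  Its area,

    SEA = pi * sqrt(det(S)) = pi * sqrt(lambda1 * lambda2),

with S the unbiased sample covariance and lambda_i its eigenvalues, is the
standard ellipse area in per-mil squared.  The small-sample-corrected point
estimate is SEAc = SEA * (n - 1) / (n - 2).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial import ConvexHull, QhullError
from shapely.geometry import Polygon

__all__ = [
    "EllipseFit",
    "fit_standard_ellipse",
    "ellipse_boundary",
    "ellipse_polygon",
    "ellipse_overlap",
    "convex_hull_area",
    "DegenerateDataError",
]

_DET_TOL = 1e-12


class DegenerateDataError(ValueError):
    """Point set too small or collinear for an ellipse fit."""


@dataclass(frozen=True)
class EllipseFit:
    """Centroid, covariance and standard ellipse areas of a bivariate sample."""

    centroid: np.ndarray  # (2,), (d13C, d15N)
    covariance: np.ndarray  # (2, 2), unbiased (divisor n - 1)
    n: int

    @property
    def sea(self) -> float:
        return float(np.pi * np.sqrt(np.linalg.det(self.covariance)))

    @property
    def seac(self) -> float:
        return self.sea * (self.n - 1) / (self.n - 2)

    @property
    def seac_scale(self) -> float:
        """Radial scale factor that turns the SEA ellipse into the SEAc ellipse."""
        return float(np.sqrt(self.seac / self.sea))


def fit_standard_ellipse(points: np.ndarray) -> EllipseFit:
    """Fit the standard ellipse to an (n, 2) point set.

    Requires n >= 3 and a non-singular sample covariance (points not all
    collinear); raises :class:`DegenerateDataError` otherwise.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("points must be an (n, 2) array")
    n = pts.shape[0]
    if n < 3:
        raise DegenerateDataError(f"need at least 3 points, got {n}")
    centroid = pts.mean(axis=0)
    cov = np.cov(pts, rowvar=False, ddof=1)
    if np.linalg.det(cov) <= _DET_TOL:
        raise DegenerateDataError("degenerate point set (singular covariance)")
    return EllipseFit(centroid=centroid, covariance=cov, n=n)


def ellipse_boundary(
    fit: EllipseFit, radius_scale: float = 1.0, n_vertices: int = 1024
) -> np.ndarray:
    """Vertices of the (scaled) standard ellipse boundary, counter-clockwise.

    ``radius_scale=1`` is the 1-SD Mahalanobis contour (area = SEA); scaling by
    ``fit.seac_scale`` gives the SEAc ellipse.  Returns an (n_vertices, 2) open
    ring (first vertex not repeated).
    """
    if radius_scale <= 0:
        raise ValueError("radius_scale must be > 0")
    if n_vertices < 16:
        raise ValueError("n_vertices must be >= 16")
    lam, vec = np.linalg.eigh(fit.covariance)  # ascending eigenvalues
    theta = np.linspace(0.0, 2.0 * np.pi, n_vertices, endpoint=False)
    circle = np.stack([np.cos(theta), np.sin(theta)], axis=1)
    axes = vec @ np.diag(np.sqrt(lam))
    return fit.centroid + radius_scale * circle @ axes.T


def ellipse_polygon(
    fit: EllipseFit, radius_scale: float = 1.0, n_vertices: int = 1024
) -> Polygon:
    return Polygon(ellipse_boundary(fit, radius_scale, n_vertices))


def ellipse_overlap(
    fit_a: EllipseFit,
    fit_b: EllipseFit,
    use_seac: bool = True,
    n_vertices: int = 1024,
) -> float:
    """Intersection area of two (SEAc-scaled) standard ellipses, per-mil squared.

    With ``use_seac`` each boundary is radially inflated so its enclosed area
    equals that fit's SEAc.  The intersection is computed by polygon clipping of
    ``n_vertices``-gon approximations.
    """
    sa = fit_a.seac_scale if use_seac else 1.0
    sb = fit_b.seac_scale if use_seac else 1.0
    pa = ellipse_polygon(fit_a, sa, n_vertices)
    pb = ellipse_polygon(fit_b, sb, n_vertices)
    return float(pa.intersection(pb).area)


def convex_hull_area(points: np.ndarray) -> float:
    """Convex hull (total) area of an (n, 2) point set; 0 with a warning if collinear."""
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 3:
        raise ValueError("need an (n >= 3, 2) point array")
    try:
        hull = ConvexHull(pts)
    except QhullError:
        warnings.warn("collinear point set: convex hull area is 0", stacklevel=2)
        return 0.0
    # for 2-D input ConvexHull.volume is the enclosed area
    return float(hull.volume)
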