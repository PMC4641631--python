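"""Bayesian posterior for the standard ellipse area (SEA_b).

Under a bivariate normal likelihood with the conjugate Normal-Inverse-Wishart
prior

    Sigma ~ InvWishart(nu0, Lambda0),   mu | Sigma ~ N(mu0, Sigma / kappa0),

the posterior is again Normal-Inverse-Wishart with

    kappa_n = kappa0 + n,           nu_n = nu0 + n,
    mu_n    = (kappa0 mu0 + n xbar) / kappa_n,
    Lambda_n = Lambda0 + S + (kappa0 n / kappa_n)(xbar - mu0)(xbar - mu0)^T,

where S is the centred scatter matrix.  Draws are i.i.d. from the exact
posterior (no MCMC, no burn-in needed); each covariance draw yields one
posterior ellipse area SEA_b = pi * sqrt(det Sigma).

The default hyperparameters (mu0 = 0, kappa0 = 1e-3, nu0 = 3, Lambda0 = 1e-3 I)
are vague: with n >= 10 the data term dominates all four posterior parameters.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .ellipse import EllipseFit

__all__ = [
    "NIWPrior",
    "PosteriorDraws",
    "PosteriorSummary",
    "sample_posterior",
    "prob_larger",
    "summarize_posterior",
    "check_seac_in_ci",
    "bayesian_layman",
]


@dataclass(frozen=True)
class NIWPrior:
    """Normal-Inverse-Wishart hyperparameters (vague defaults)."""

    mu0: tuple[float, float] = (0.0, 0.0)
    kappa0: float = 1e-3
    nu0: float = 3.0
    lambda0_scale: float = 1e-3  # Lambda0 = lambda0_scale * I


@dataclass(frozen=True)
class PosteriorDraws:
    """Joint posterior sample of (mu, Sigma) and the derived SEA_b values."""

    group: str
    mu: np.ndarray  # (n_draws, 2)
    cov: np.ndarray  # (n_draws, 2, 2)
    sea_b: np.ndarray  # (n_draws,)
    seed: int | None
    burn_in: int = 0

    @property
    def n_draws(self) -> int:
        return self.sea_b.shape[0]


@dataclass(frozen=True)
class PosteriorSummary:
    mode: float
    median: float
    intervals: dict  # coverage level -> (low, high), central (equal-tail)


def sample_posterior(
    points: np.ndarray,
    n_draws: int = 10_000,
    burn_in: int = 0,
    seed: int | None = None,
    prior: NIWPrior = NIWPrior(),
    group: str = "",
    rng: np.random.Generator | None = None,
) -> PosteriorDraws:
    """Draw i.i.d. (mu, Sigma) samples from the conjugate posterior.

    ``burn_in`` draws are generated and discarded before the ``n_draws`` kept
    ones, so the kept sequence is reproducible for a given (seed, burn_in).
    Either pass ``seed`` or an explicit ``rng``.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("points must be an (n, 2) array")
    n = pts.shape[0]
    if n < 3:
        raise ValueError(f"need at least 3 points, got {n}")
    if rng is None:
        rng = np.random.default_rng(seed)

    xbar = pts.mean(axis=0)
    scatter = (pts - xbar).T @ (pts - xbar)
    mu0 = np.asarray(prior.mu0, dtype=float)
    kappa_n = prior.kappa0 + n
    nu_n = prior.nu0 + n
    mu_n = (prior.kappa0 * mu0 + n * xbar) / kappa_n
    dev = (xbar - mu0).reshape(2, 1)
    lambda_n = (
        prior.lambda0_scale * np.eye(2)
        + scatter
        + (prior.kappa0 * n / kappa_n) * (dev @ dev.T)
    )

    total = n_draws + burn_in
    cov = stats.invwishart.rvs(df=nu_n, scale=lambda_n, size=total, random_state=rng)
    cov = cov.reshape(total, 2, 2)
    chol = np.linalg.cholesky(cov / kappa_n)
    z = rng.standard_normal((total, 2))
    mu = mu_n + np.einsum("nij,nj->ni", chol, z)
    cov, mu = cov[burn_in:], mu[burn_in:]
    sea_b = np.pi * np.sqrt(np.linalg.det(cov))
    return PosteriorDraws(group=group, mu=mu, cov=cov, sea_b=sea_b, seed=seed, burn_in=burn_in)


def _as_array(draws) -> np.ndarray:
    if isinstance(draws, PosteriorDraws):
        return draws.sea_b
    return np.asarray(draws, dtype=float)


def prob_larger(draws_a, draws_b) -> float:
    """Index-paired P(A > B) over equal-length draw vectors; ties count 0.5.

    Accepts :class:`PosteriorDraws` (compared on SEA_b) or plain arrays.
    Satisfies prob_larger(A, B) + prob_larger(B, A) = 1 exactly.
    """
    a, b = _as_array(draws_a), _as_array(draws_b)
    if a.shape != b.shape:
        raise ValueError(f"draw counts differ: {a.shape} vs {b.shape}")
    return float(np.mean((a > b) + 0.5 * (a == b)))


def summarize_posterior(
    draws, levels: tuple[float, ...] = (0.50, 0.75, 0.95), grid_size: int = 512
) -> PosteriorSummary:
    """Mode and central (equal-tail) credible intervals of a scalar posterior sample.

    The mode is the peak of a Gaussian kernel density estimate (Silverman
    bandwidth) evaluated on a regular grid spanning the sample; for a constant
    sample the mode is that constant and all intervals have zero width.
    """
    x = _as_array(draws)
    lo, hi = float(x.min()), float(x.max())
    if hi == lo:
        mode = lo
    else:
        kde = stats.gaussian_kde(x)  # Silverman-type bandwidth by default
        grid = np.linspace(lo, hi, grid_size)
        mode = float(grid[np.argmax(kde(grid))])
    intervals = {}
    for level in levels:
        tail = (1.0 - level) / 2.0
        qlo, qhi = np.quantile(x, [tail, 1.0 - tail])
        intervals[level] = (float(qlo), float(qhi))
    return PosteriorSummary(mode=mode, median=float(np.median(x)), intervals=intervals)


def check_seac_in_ci(fit: EllipseFit, draws, level: float = 0.95) -> bool:
    """Model sanity check: does the data's SEAc lie inside the central interval of SEA_b?"""
    x = _as_array(draws)
    tail = (1.0 - level) / 2.0
    qlo, qhi = np.quantile(x, [tail, 1.0 - tail])
    return bool(qlo <= fit.seac <= qhi)


def bayesian_layman(group_draws: list[PosteriorDraws], sd_ddof: int = 1) -> dict[str, np.ndarray]:
    """Posterior distributions of the Layman metrics over group centroids.

    Each group contributes its posterior mean-vector draws; for every draw
    index the five metrics (NR, CR, CD, MNND, SDNND) are computed over the
    groups' mean vectors, giving a posterior sample per metric.  Groups must
    hold equally many draws (independent samplers paired by index).
    """
    if len(group_draws) < 2:
        raise ValueError("need at least 2 groups")
    n_draws = {g.n_draws for g in group_draws}
    if len(n_draws) != 1:
        raise ValueError("groups must hold equally many draws")
    mus = np.stack([g.mu for g in group_draws], axis=0)  # (G, D, 2)
    g = mus.shape[0]
    cr = mus[:, :, 0].max(axis=0) - mus[:, :, 0].min(axis=0)
    nr = mus[:, :, 1].max(axis=0) - mus[:, :, 1].min(axis=0)
    centroid = mus.mean(axis=0)  # (D, 2)
    cd = np.linalg.norm(mus - centroid, axis=2).mean(axis=0)
    diff = mus[:, None, :, :] - mus[None, :, :, :]  # (G, G, D, 2)
    dist = np.linalg.norm(diff, axis=3)
    dist[np.arange(g), np.arange(g), :] = np.inf
    nnd = dist.min(axis=1)  # (G, D)
    mnnd = nnd.mean(axis=0)
    sdnnd = nnd.std(axis=0, ddof=sd_ddof) if g > sd_ddof else np.zeros_like(mnnd)
    return {"NR": nr, "CR": cr, "CD": cd, "MNND": mnnd, "SDNND": sdnnd}
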