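"""Marginals, parameter moments and observable pushforward densities.

Marginalizing the point-wise PDF over n_p − 1 dimensions on a grid is
intractable, so marginal and pushforward densities are computed as weighted
Gaussian kernel density estimates over the collocation coordinates, with
quadrature weights ρ(θ_i)·|Θ|/N_valid, reflection at the box edges and an
effective-sample-size Scott bandwidth.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from apmoments.database import SimulationDatabase
from apmoments.omm_core import DiscretePDF

__all__ = [
    "MarginalDensity",
    "parameter_moments",
    "marginal_density",
    "pushforward_density",
]


@dataclass
class MarginalDensity:
    name: str
    grid: np.ndarray
    density: np.ndarray
    bandwidth: float
    meta: dict = field(default_factory=dict)

    def mean(self) -> float:
        return float(np.trapezoid(self.grid * self.density, self.grid))

    def std(self) -> float:
        m1 = self.mean()
        m2 = float(np.trapezoid(self.grid ** 2 * self.density, self.grid))
        return float(np.sqrt(max(m2 - m1 ** 2, 0.0)))


def parameter_moments(pdf: DiscretePDF, name: str, orders=(1, 2)) -> dict[int, float]:
    """Raw moments μ_m(θ_p) = ∫ ρ θ_p^m under the Monte-Carlo quadrature."""
    theta = pdf.points[:, pdf.box.index(name)]
    return {int(m): pdf.quadrature(theta ** m) for m in orders}


def parameter_mean_std(pdf: DiscretePDF, name: str) -> tuple[float, float]:
    """Mean μ_1 and s.d. sqrt(μ_2 − μ_1²); quadrature noise clamps at 0."""
    mu = parameter_moments(pdf, name, orders=(1, 2))
    var = mu[2] - mu[1] ** 2
    if var < 0:
        if var < -1e-8 * max(mu[2], 1.0):
            warnings.warn(
                f"negative variance {var:.3g} for {name!r} (quadrature noise); "
                "clamping s.d. at 0",
                RuntimeWarning,
            )
        var = 0.0
    return mu[1], float(np.sqrt(var))


def _weighted_kde(
    x: np.ndarray,
    weights: np.ndarray,
    grid: np.ndarray,
    bandwidth: float | None,
    bandwidth_factor: float,
    reflect: tuple[float, float] | None,
) -> tuple[np.ndarray, float]:
    total = float(np.sum(weights))
    if total <= 0:
        raise ValueError("zero total weight; cannot form a density")
    w = weights / total
    if bandwidth is None:
        n_eff = 1.0 / float(np.sum(w ** 2))
        mu = float(np.sum(w * x))
        sd = float(np.sqrt(max(np.sum(w * (x - mu) ** 2), 1e-300)))
        bandwidth = sd * n_eff ** (-1.0 / 5.0)  # Scott's rule at the effective n
    bandwidth *= bandwidth_factor
    min_bw = 2.0 * (grid[-1] - grid[0]) / max(grid.size - 1, 1)
    if bandwidth <= min_bw:
        bandwidth = min_bw  # keep the kernel resolvable on the grid

    def kde_at(g):
        u = (g[:, None] - x[None, :]) / bandwidth
        return (np.exp(-0.5 * u ** 2) @ w) / (bandwidth * np.sqrt(2 * np.pi))

    density = kde_at(grid)
    if reflect is not None:
        lo, hi = reflect
        density = density + kde_at(2 * lo - grid) + kde_at(2 * hi - grid)
    norm = np.trapezoid(density, grid)
    if norm <= 0:
        raise ValueError("degenerate density (zero mass on the grid)")
    return density / norm, bandwidth


def marginal_density(
    pdf: DiscretePDF,
    name: str,
    grid: np.ndarray | None = None,
    bandwidth: float | None = None,
    bandwidth_factor: float = 1.0,
    n_grid: int = 200,
) -> MarginalDensity:
    """Weighted-KDE marginal of one parameter, renormalized on its grid."""
    j = pdf.box.index(name)
    lo, hi = float(pdf.box.lower[j]), float(pdf.box.upper[j])
    if grid is None:
        grid = np.linspace(lo, hi, n_grid)
    else:
        grid = np.asarray(grid, dtype=float)
        if grid[0] < lo - 1e-9 or grid[-1] > hi + 1e-9:
            raise ValueError(f"grid outside the box range [{lo}, {hi}] of {name!r}")
    weights = pdf.values * pdf.quad_weight
    density, bw = _weighted_kde(
        pdf.points[:, j], weights, grid, bandwidth, bandwidth_factor, reflect=(lo, hi)
    )
    return MarginalDensity(name, grid, density, bw)


def pushforward_density(
    pdf: DiscretePDF,
    db: SimulationDatabase,
    label: str,
    grid: np.ndarray | None = None,
    bandwidth: float | None = None,
    bandwidth_factor: float = 1.0,
    n_grid: int = 200,
) -> MarginalDensity:
    """Density induced on an observable by pushing ρ through the database."""
    u = db.column(label)
    if u.size != pdf.n_valid:
        raise ValueError("PDF and database collocation points are not aligned")
    if grid is None:
        lo, hi = float(u.min()), float(u.max())
        pad = 0.05 * (hi - lo) if hi > lo else max(abs(hi), 1.0) * 1e-3
        grid = np.linspace(lo - pad, hi + pad, n_grid)
    weights = pdf.values * pdf.quad_weight
    density, bw = _weighted_kde(u, weights, np.asarray(grid, float), bandwidth,
                                bandwidth_factor, reflect=None)
    return MarginalDensity(label, np.asarray(grid, float), density, bw)


def pushforward_moments(pdf: DiscretePDF, db: SimulationDatabase, label: str) -> tuple[float, float]:
    """Quadrature mean and s.d. of one observable under the estimated PDF."""
    u = db.column(label)
    m1 = pdf.quadrature(u)
    m2 = pdf.quadrature(u ** 2)
    return m1, float(np.sqrt(max(m2 - m1 ** 2, 0.0)))
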