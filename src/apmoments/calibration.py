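"""CMA-ES calibration of the non-varying model parameters.

Fits conductance multipliers so the simulated observable matches the most
representative measurement sample, under the regularized cost

    J = (1/N_t) Σ_t ((y_t − u_t)/s_t)²  +  (K/n_p) Σ_j ((g_j − g_j^ref)/g_j^ref)²

with s_t a per-observable scale (group s.d. for mixed-unit biomarker
targets, 1 for raw-trace targets) and K ≥ 0 a user weight.  Multipliers are
bounded below by 0; only g_Na carries an upper bound (5x nominal), enforced
by resampling out-of-bounds candidates.

The optimizer is a self-contained implementation of the standard
(μ/μ_w, λ)-CMA-ES with rank-one and rank-μ covariance updates and
step-size control — deliberately plain, seeded and dependency-free.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np

from apmoments.cell_models import CellModel, PacingProtocol, SolverConfig, simulate_ap
from apmoments.omm_core import MeasurementSet

__all__ = [
    "CalibrationSpec",
    "select_representative_sample",
    "calibration_cost",
    "calibrate_cmaes",
    "cmaes_minimize",
]

_FAILURE_PENALTY = 1e8


@dataclass
class CalibrationSpec:
    """Free multipliers, target observable and optimizer settings."""

    names: list[str]
    target: np.ndarray
    scales: np.ndarray | None = None
    reg_weight: float = 0.0                  # K
    nominal: dict[str, float] = field(default_factory=dict)   # g_j^ref, default 1.0
    lower: dict[str, float] = field(default_factory=dict)     # default 0
    upper: dict[str, float] = field(default_factory=dict)     # default +inf, g_Na -> 5
    sigma0: float = 0.3
    popsize: int | None = None
    max_evals: int = 2000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.reg_weight < 0:
            raise ValueError("regularization weight K must be >= 0")
        self.target = np.asarray(self.target, dtype=float)
        if self.scales is None:
            self.scales = np.ones_like(self.target)
        else:
            self.scales = np.asarray(self.scales, dtype=float)
        if np.any(self.scales <= 0):
            raise ValueError("scales must be positive")
        for name in self.names:
            self.nominal.setdefault(name, 1.0)
            self.lower.setdefault(name, 0.0)
            if name not in self.upper:
                self.upper[name] = 5.0 * self.nominal[name] if name == "g_Na" else math.inf

    def bounds_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        lo = np.array([self.lower[n] for n in self.names])
        hi = np.array([self.upper[n] for n in self.names])
        return lo, hi


def select_representative_sample(
    samples: MeasurementSet, mode: str = "biomarker-median", apd90_label: str = "APD90"
) -> int:
    """Index of the most representative sample.

    ``biomarker-median``: argmin of the Euclidean distance of the
    standardized biomarker vector to the component-wise median;
    ``apd90-median``: argmin of |APD90 − median(APD90)|.  Ties break toward
    the smallest index; samples with missing values are excluded.
    """
    x = samples.samples
    finite = np.all(np.isfinite(x), axis=1)
    if not np.any(finite):
        raise ValueError("no sample with complete biomarkers")
    if not np.all(finite):
        import warnings

        warnings.warn(
            f"{int(np.sum(~finite))} sample(s) with missing biomarkers excluded "
            "from representative selection",
            RuntimeWarning,
        )
    idx = np.nonzero(finite)[0]
    xf = x[finite]
    if mode == "apd90-median":
        apd = samples.column(apd90_label)[finite]
        d = np.abs(apd - np.median(apd))
    elif mode == "biomarker-median":
        sd = np.std(xf, axis=0)
        sd = np.where(sd > 0, sd, 1.0)
        z = (xf - np.median(xf, axis=0)) / sd
        d = np.linalg.norm(z, axis=1)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return int(idx[int(np.argmin(d))])


def calibration_cost(
    candidates: Mapping[str, float] | Sequence[float],
    spec: CalibrationSpec,
    u: np.ndarray,
) -> float:
    """Regularized misfit J for one candidate and its simulated observable."""
    if isinstance(candidates, Mapping):
        g = np.array([candidates[n] for n in spec.names])
    else:
        g = np.asarray(candidates, dtype=float)
    u = np.asarray(u, dtype=float)
    if u.shape != spec.target.shape:
        raise ValueError("simulated observable and target are not aligned")
    misfit = float(np.mean(((spec.target - u) / spec.scales) ** 2))
    g_ref = np.array([spec.nominal[n] for n in spec.names])
    penalty = float(np.sum(((g - g_ref) / g_ref) ** 2))
    return misfit + spec.reg_weight / len(spec.names) * penalty


# ---------------------------------------------------------------------------
# minimal CMA-ES
# ---------------------------------------------------------------------------

def cmaes_minimize(
    f: Callable[[np.ndarray], float],
    x0: np.ndarray,
    sigma0: float,
    lower: np.ndarray,
    upper: np.ndarray,
    popsize: int | None = None,
    max_evals: int = 2000,
    seed: int = 0,
):
    """(μ/μ_w, λ)-CMA-ES with box constraints handled by resampling.

    Returns ``(x_best, f_best, history)`` where history holds one
    ``(eval_index, f, x)`` record per evaluation.
    """
    rng = np.random.default_rng(seed)
    n = x0.size
    lam = popsize or 4 + int(3 * np.log(n))
    mu = lam // 2
    w = np.log(mu + 0.5) - np.log(np.arange(1, mu + 1))
    w /= w.sum()
    mu_eff = 1.0 / np.sum(w ** 2)

    cc = (4 + mu_eff / n) / (n + 4 + 2 * mu_eff / n)
    cs = (mu_eff + 2) / (n + mu_eff + 5)
    c1 = 2 / ((n + 1.3) ** 2 + mu_eff)
    cmu = min(1 - c1, 2 * (mu_eff - 2 + 1 / mu_eff) / ((n + 2) ** 2 + mu_eff))
    damps = 1 + 2 * max(0.0, np.sqrt((mu_eff - 1) / (n + 1)) - 1) + cs
    chi_n = np.sqrt(n) * (1 - 1 / (4 * n) + 1 / (21 * n ** 2))

    mean = np.asarray(x0, dtype=float).copy()
    sigma = float(sigma0)
    cov = np.eye(n)
    pc = np.zeros(n)
    ps = np.zeros(n)
    eigen_b = np.eye(n)
    eigen_d = np.ones(n)

    history: list[tuple[int, float, np.ndarray]] = []
    x_best, f_best = mean.copy(), math.inf
    n_evals = 0
    while n_evals < max_evals:
        xs, zs, fs = [], [], []
        for _ in range(lam):
            for _attempt in range(100):
                z = rng.standard_normal(n)
                x = mean + sigma * eigen_b @ (eigen_d * z)
                if np.all(x >= lower) and np.all(x <= upper):
                    break
            else:
                x = np.clip(mean + sigma * eigen_b @ (eigen_d * z), lower, upper)
                z = (eigen_b.T @ ((x - mean) / sigma)) / eigen_d
            fx = float(f(x))
            n_evals += 1
            history.append((n_evals, fx, x.copy()))
            xs.append(x)
            zs.append(z)
            fs.append(fx)
            if fx < f_best:
                f_best, x_best = fx, x.copy()
            if n_evals >= max_evals:
                break
        if len(xs) < mu:
            break
        order = np.argsort(fs)[:mu]
        xs = np.array(xs)[order]
        zs = np.array(zs)[order]

        z_mean = w @ zs
        mean = w @ xs
        ps = (1 - cs) * ps + np.sqrt(cs * (2 - cs) * mu_eff) * (eigen_b @ z_mean)
        h_sig = (np.linalg.norm(ps)
                 / np.sqrt(1 - (1 - cs) ** (2 * n_evals / lam)) / chi_n) < 1.4 + 2 / (n + 1)
        pc = (1 - cc) * pc + h_sig * np.sqrt(cc * (2 - cc) * mu_eff) * (
            eigen_b @ (eigen_d * z_mean)
        )
        rank_mu = sum(
            wi * np.outer(eigen_b @ (eigen_d * zi), eigen_b @ (eigen_d * zi))
            for wi, zi in zip(w, zs)
        )
        cov = ((1 - c1 - cmu) * cov
               + c1 * (np.outer(pc, pc) + (not h_sig) * cc * (2 - cc) * cov)
               + cmu * rank_mu)
        sigma *= math.exp((cs / damps) * (np.linalg.norm(ps) / chi_n - 1))
        cov = (cov + cov.T) / 2
        eigvals, eigen_b = np.linalg.eigh(cov)
        eigen_d = np.sqrt(np.maximum(eigvals, 1e-20))
    return x_best, f_best, history


def calibrate_cmaes(
    model: CellModel,
    protocol: PacingProtocol,
    spec: CalibrationSpec,
    observable_fn: Callable[..., np.ndarray],
    solver_cfg: SolverConfig | None = None,
    fixed_multipliers: Mapping[str, float] | None = None,
):
    """Fit the multipliers named in ``spec`` with CMA-ES.

    ``observable_fn(trace)`` maps a simulated trace to the observable vector
    aligned with ``spec.target``.  Failed simulations receive a large finite
    penalty.  Returns ``(fitted: dict, J: float, history)``; the run is
    deterministic for a fixed ``spec.seed``.
    """
    solver_cfg = solver_cfg or SolverConfig()
    fixed = dict(fixed_multipliers or {})
    lo, hi = spec.bounds_arrays()

    def objective(g: np.ndarray) -> float:
        multipliers = dict(fixed)
        multipliers.update(zip(spec.names, g))
        trace = simulate_ap(model, multipliers, protocol, solver_cfg)
        if not trace.ok:
            return _FAILURE_PENALTY
        u = np.asarray(observable_fn(trace), dtype=float)
        if not np.all(np.isfinite(u)):
            return _FAILURE_PENALTY
        return calibration_cost(g, spec, u)

    x0 = np.array([spec.nominal[n] for n in spec.names])
    x_best, f_best, history = cmaes_minimize(
        objective, x0, spec.sigma0, lo, hi,
        popsize=spec.popsize, max_evals=spec.max_evals, seed=spec.seed,
    )
    fitted = dict(zip(spec.names, x_best))
    improved = f_best < objective(x0) + 1e-12
    return fitted, f_best, {"history": history, "improved_over_nominal": improved}
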