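"""Maximum-entropy moment matching on the collocation set.

Given a simulation database and the empirical moments of a measurement set,
find the point-wise density ρ(θ_i) that maximizes the differential entropy
S(ρ) = −∫ ρ log ρ subject to normalization and the moment constraints, with
every integral over the parameter box replaced by the Monte-Carlo quadrature
(|Θ|/N_valid) Σ_i f(θ_i).

The constrained problem is solved through its convex Lagrange dual: the
optimum has the exponential form ρ ∝ exp(−Σ_k λ_k c_k(θ)), and the dual
objective log Z(λ) + λ·τ is minimized by a damped Newton iteration whose
Hessian — the constraint-function covariance under ρ_λ, a dense matrix of
size (number of constraints)² — is ridge-regularized on its diagonal.

Observable columns are affinely standardized (empirical mean 0, s.d. 1
across the measurement set) before powers are taken, and the identical
transform is applied to the database columns; matching moments of an affine
transform up to order N_m is equivalent to matching the raw moments.
Pairwise-product observables enter as additional first-order (mean)
constraints.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy.special import logsumexp

from apmoments.biomarkers import PRODUCT_SEP
from apmoments.database import ParameterBox, SimulationDatabase

__all__ = [
    "MeasurementSet",
    "ConstraintEntry",
    "ParameterConstraintEntry",
    "MomentConstraintSet",
    "DiscretePDF",
    "SolveConfig",
    "empirical_moments",
    "count_constraints",
    "solve_maxent",
    "augment_with_parameter_constraints",
    "constraint_residuals",
]

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# measurements and constraints
# ---------------------------------------------------------------------------

@dataclass
class MeasurementSet:
    """N samples of N_t observables, labelled like a database's index."""

    samples: np.ndarray  # N x N_t
    labels: list[str]

    def __post_init__(self) -> None:
        self.samples = np.atleast_2d(np.asarray(self.samples, dtype=float))
        if self.samples.shape[1] != len(self.labels):
            raise ValueError("label count must match sample columns")

    @property
    def n(self) -> int:
        return self.samples.shape[0]

    def column(self, label: str) -> np.ndarray:
        try:
            j = self.labels.index(label)
        except ValueError:
            raise KeyError(f"observable {label!r} not in measurement set") from None
        return self.samples[:, j]

    def select(self, labels: Sequence[str]) -> "MeasurementSet":
        idx = [self.labels.index(lab) for lab in labels]
        return MeasurementSet(self.samples[:, idx], list(labels))

    @classmethod
    def from_dataframe(cls, df) -> "MeasurementSet":
        return cls(df.to_numpy(dtype=float), [str(c) for c in df.columns])


@dataclass(frozen=True)
class ConstraintEntry:
    """One observable moment constraint on the standardized column."""

    label: str
    order: int
    target: float
    scale: float
    center: float
    spread: float


@dataclass(frozen=True)
class ParameterConstraintEntry:
    """A direct moment constraint on one parameter coordinate."""

    name: str
    order: int
    target: float
    scale: float
    center: float
    halfwidth: float


@dataclass
class MomentConstraintSet:
    entries: list[ConstraintEntry] = field(default_factory=list)
    parameter_entries: list[ParameterConstraintEntry] = field(default_factory=list)
    n_m: int = 1

    def __len__(self) -> int:
        return len(self.entries) + len(self.parameter_entries)


def count_constraints(n_base_biomarkers: int, n_m: int, include_pairwise: bool = True) -> int:
    """Constraint count when pairwise products enter as mean constraints:
    ``N_m * b + b (b − 1) / 2``."""
    if n_base_biomarkers < 1:
        raise ValueError("need at least one base biomarker")
    b = n_base_biomarkers
    return n_m * b + (b * (b - 1) // 2 if include_pairwise else 0)


def empirical_moments(
    ms: MeasurementSet,
    n_m: int,
    labels: Sequence[str] | None = None,
    standardize: bool = True,
    product_max_order: int = 1,
) -> MomentConstraintSet:
    """Build moment targets of orders 1..N_m from a measurement set.

    Labels containing the pairwise-product separator are constrained at
    orders 1..``product_max_order`` only (mean constraints by default).
    Constant columns keep their mean constraint but drop orders >= 2.
    """
    if n_m < 1:
        raise ValueError("N_m must be >= 1")
    if n_m > 3:
        warnings.warn(
            f"N_m = {n_m}: high moment orders often lead to numerical instability",
            RuntimeWarning,
        )
    labels = list(labels) if labels is not None else list(ms.labels)
    entries: list[ConstraintEntry] = []
    for label in labels:
        y = ms.column(label)
        max_order = min(n_m, product_max_order) if PRODUCT_SEP in label else n_m
        if standardize:
            center, spread = float(np.mean(y)), float(np.std(y))
        else:
            center, spread = 0.0, 1.0
        if spread < 1e-12 * max(1.0, abs(center)):
            warnings.warn(
                f"observable {label!r} is constant across the measurement set; "
                "keeping only its mean constraint",
                RuntimeWarning,
            )
            spread = 1.0 if standardize else spread
            max_order = 1
        z = (y - center) / spread
        for m in range(1, max_order + 1):
            target = float(np.mean(z ** m))
            entries.append(
                ConstraintEntry(label, m, target, max(1.0, abs(target)), center, spread)
            )
    return MomentConstraintSet(entries=entries, n_m=n_m)


# ---------------------------------------------------------------------------
# the discrete PDF and the dual solver
# ---------------------------------------------------------------------------

@dataclass
class DiscretePDF:
    """Point-wise density on the valid collocation points.

    ``values[i]`` is ρ(θ_i); the Monte-Carlo quadrature of any point-wise
    function f is ``(|Θ|/N_valid) Σ_i ρ_i f_i``, and normalization holds
    exactly under that rule.
    """

    points: np.ndarray          # N_valid x n_p
    values: np.ndarray          # N_valid
    box: ParameterBox
    lagrange_multipliers: np.ndarray  # [λ_0 (normalization), λ_1..λ_K]
    constraints: MomentConstraintSet | None = None
    diagnostics: dict = field(default_factory=dict)

    @property
    def n_valid(self) -> int:
        return self.values.size

    @property
    def quad_weight(self) -> float:
        return self.box.volume / self.n_valid

    def quadrature(self, f_values: np.ndarray) -> float:
        """∫ ρ f approximated on the collocation set."""
        return float(self.quad_weight * np.sum(self.values * np.asarray(f_values)))

    def entropy(self) -> float:
        rho = self.values
        with np.errstate(divide="ignore", invalid="ignore"):
            integrand = np.where(rho > 0, rho * np.log(rho), 0.0)
        return float(-self.quad_weight * np.sum(integrand))

    @classmethod
    def uniform(cls, points: np.ndarray, box: ParameterBox) -> "DiscretePDF":
        n = points.shape[0]
        return cls(
            points=points,
            values=np.full(n, 1.0 / box.volume),
            box=box,
            lagrange_multipliers=np.array([np.log(box.volume) - 1.0]),
            diagnostics={"entropy": float(np.log(box.volume)), "converged": True},
        )

    def save(self, path: str) -> None:
        import h5py, json

        with h5py.File(path, "w") as f:
            f.create_dataset("rho", data=self.values)
            f.create_dataset("points", data=self.points)
            f.create_dataset("lambda", data=self.lagrange_multipliers)
            f.attrs["box_names"] = json.dumps(list(self.box.names))
            f.attrs["box_lower"] = self.box.lower
            f.attrs["box_upper"] = self.box.upper
            f.attrs["diagnostics"] = json.dumps(
                {k: v for k, v in self.diagnostics.items() if np.isscalar(v)},
                default=float,
            )

    @classmethod
    def load(cls, path: str) -> "DiscretePDF":
        import h5py, json

        with h5py.File(path, "r") as f:
            box = ParameterBox(
                json.loads(f.attrs["box_names"]),
                np.asarray(f.attrs["box_lower"]),
                np.asarray(f.attrs["box_upper"]),
            )
            return cls(
                points=f["points"][...],
                values=f["rho"][...],
                box=box,
                lagrange_multipliers=f["lambda"][...],
                diagnostics=json.loads(f.attrs["diagnostics"]),
            )


def filter_feasible(
    db: SimulationDatabase,
    constraints: MomentConstraintSet,
    margin: float = 0.0,
) -> MomentConstraintSet:
    """Drop constraints whose target is provably unreachable on the database.

    A moment target outside the range of its constraint function over the
    collocation points cannot be met by any density on those points (this
    occurs when measurement noise pushes an empirical moment beyond the
    noise-free simulations' reach at a low-information observable).  Dropped
    entries are reported with a warning.
    """
    kept_e, kept_p, dropped = [], [], []
    for e in constraints.entries:
        z = ((db.column(e.label) - e.center) / e.spread) ** e.order
        lo, hi = z.min(), z.max()
        pad = margin * (hi - lo)
        (kept_e if lo - pad <= e.target <= hi + pad else dropped).append(e)
    for e in constraints.parameter_entries:
        z = ((db.valid_points[:, db.box.index(e.name)] - e.center) / e.halfwidth) ** e.order
        lo, hi = z.min(), z.max()
        pad = margin * (hi - lo)
        (kept_p if lo - pad <= e.target <= hi + pad else dropped).append(e)
    if dropped:
        warnings.warn(
            f"dropped {len(dropped)} infeasible moment constraint(s): "
            + ", ".join(f"{getattr(e, 'label', getattr(e, 'name', '?'))}^{e.order}"
                        for e in dropped[:8]),
            RuntimeWarning,
        )
    return MomentConstraintSet(entries=kept_e, parameter_entries=kept_p,
                               n_m=constraints.n_m)


@dataclass(frozen=True)
class SolveConfig:
    tol: float = 1e-6
    max_iter: int = 500
    ridge: float = 1e-8
    lambda_diverged: float = 1e7
    max_step_norm: float = 100.0  # trust cap on each (rescaled) Newton step


def _constraint_matrix(
    db: SimulationDatabase, constraints: MomentConstraintSet
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Standardized constraint functions at the valid collocation points.

    Returns (C, targets, scales) with C of shape (N_valid, K).
    """
    cols = []
    targets = []
    scales = []
    for e in constraints.entries:
        z = (db.column(e.label) - e.center) / e.spread
        cols.append(z ** e.order)
        targets.append(e.target)
        scales.append(e.scale)
    for e in constraints.parameter_entries:
        theta = db.valid_points[:, db.box.index(e.name)]
        z = (theta - e.center) / e.halfwidth
        cols.append(z ** e.order)
        targets.append(e.target)
        scales.append(e.scale)
    if not cols:
        return np.empty((db.n_valid, 0)), np.array([]), np.array([])
    return np.column_stack(cols), np.asarray(targets), np.asarray(scales)


def _rescaled_system(c_mat: np.ndarray, targets: np.ndarray):
    """Divide each constraint function (and target) by its spread over the
    database so every column is O(1); the solution density is unchanged,
    only the dual variables are rescaled.  Returns (C', t', func_scales)."""
    if c_mat.shape[1] == 0:
        return c_mat, targets, np.array([])
    spread = np.maximum(np.ptp(c_mat, axis=0), np.max(np.abs(c_mat), axis=0))
    spread = np.where(spread > 0, spread, 1.0)
    return c_mat / spread, targets / spread, spread


def solve_maxent(
    db: SimulationDatabase,
    constraints: MomentConstraintSet,
    solver_cfg: SolveConfig | None = None,
) -> DiscretePDF:
    """Solve the maximum-entropy moment-matching problem on the database.

    Performs zero forward model evaluations.  Non-convergence returns the
    best iterate flagged in the diagnostics; per-constraint infeasibility
    (target outside the range of the constraint function over the database)
    is reported explicitly.
    """
    cfg = solver_cfg or SolveConfig()
    points = db.valid_points
    if points.shape[0] < 1:
        raise ValueError("database has no valid collocation points")
    vol = db.box.volume
    n_v = points.shape[0]
    c_raw, targets_raw, scales = _constraint_matrix(db, constraints)
    c_mat, targets, func_scales = _rescaled_system(c_raw, targets_raw)
    k = c_mat.shape[1]

    infeasible = []
    for idx in range(k):
        lo, hi = c_raw[:, idx].min(), c_raw[:, idx].max()
        if not (lo - 1e-9 <= targets_raw[idx] <= hi + 1e-9):
            infeasible.append((idx, float(targets_raw[idx]), float(lo), float(hi)))
    if infeasible:
        logger.warning(
            "%d constraint target(s) lie outside the database's achievable range: %s",
            len(infeasible), infeasible[:5],
        )

    lam = np.zeros(k)

    def dual_parts(lam):
        logits = -c_mat @ lam if k else np.zeros(n_v)
        lse = logsumexp(logits)
        log_z = np.log(vol / n_v) + lse
        p = np.exp(logits - lse)  # probability weights over points
        return log_z, p

    def dual_value(lam):
        log_z, _ = dual_parts(lam)
        return log_z + float(lam @ targets) if k else log_z

    converged = False
    max_resid = np.inf
    best_resid, best_lam = np.inf, lam.copy()
    n_iter = 0
    diverged = False
    for n_iter in range(1, cfg.max_iter + 1):
        log_z, p = dual_parts(lam)
        if k == 0:
            converged = True
            max_resid = 0.0
            break
        achieved = p @ c_mat
        grad = targets - achieved
        max_resid = float(np.max(np.abs(grad) * func_scales / scales))
        if max_resid < best_resid:
            best_resid, best_lam = max_resid, lam.copy()
        if max_resid < cfg.tol:
            converged = True
            break
        centered = c_mat - achieved
        hess = (centered * p[:, None]).T @ centered
        ridge = cfg.ridge * max(np.trace(hess) / k, 1e-300)
        hess[np.diag_indices_from(hess)] += ridge
        try:
            step = np.linalg.solve(hess, grad)
        except np.linalg.LinAlgError:
            step = grad
        # minimize D: Newton step is -H^{-1} grad_D with grad_D = targets - achieved
        direction = -step
        d0 = dual_value(lam)
        slope = float(grad @ direction)
        if slope >= 0:  # not a descent direction; fall back to steepest descent
            direction = -grad
            slope = -float(grad @ grad)
        norm = np.linalg.norm(direction)
        if norm > cfg.max_step_norm:
            direction *= cfg.max_step_norm / norm
            slope *= cfg.max_step_norm / norm
        t = 1.0
        for _ in range(40):
            if dual_value(lam + t * direction) <= d0 + 1e-4 * t * slope:
                break
            t *= 0.5
        else:
            t = 0.0
        if t == 0.0:
            break
        lam = lam + t * direction
        if np.linalg.norm(lam) > cfg.lambda_diverged:
            diverged = True
            break

    if not converged:
        lam = best_lam  # return the best iterate, not the last
    log_z, p = dual_parts(lam)
    rho = p * (n_v / vol)  # normalized: (vol/n_v) Σ rho = 1 exactly
    achieved = p @ c_mat if k else np.array([])
    residuals = (achieved - targets) * func_scales / scales if k else np.array([])
    lam_raw = lam / func_scales if k else lam  # dual variables in unscaled units

    pdf = DiscretePDF(
        points=points,
        values=rho,
        box=db.box,
        lagrange_multipliers=np.concatenate([[log_z - 1.0], lam_raw]),
        constraints=constraints,
        diagnostics={
            "converged": bool(converged),
            "n_iter": n_iter,
            "max_residual": float(np.max(np.abs(residuals))) if k else 0.0,
            "residuals": residuals,
            "entropy": None,
            "infeasible_constraints": infeasible,
            "diverged": diverged,
        },
    )
    pdf.diagnostics["entropy"] = pdf.entropy()
    if not converged:
        logger.warning(
            "maxent solve did not converge (max residual %.3g after %d iterations%s)",
            max_resid, n_iter, "; lambda diverged — constraints likely infeasible"
            if diverged or infeasible else "",
        )
    return pdf


def augment_with_parameter_constraints(
    constraints: MomentConstraintSet,
    prior_pdf: DiscretePDF,
    parameter_names: Iterable[str],
    n_m: int,
    box: ParameterBox | None = None,
) -> MomentConstraintSet:
    """Append parameter-moment targets computed from a previously estimated PDF.

    ``box`` is the parameter box of the problem being augmented (defaults to
    the prior's); the standardization of each appended constraint uses that
    box's center and half-width so the constraint functions stay O(1).
    """
    box = box or prior_pdf.box
    new = MomentConstraintSet(
        entries=list(constraints.entries),
        parameter_entries=list(constraints.parameter_entries),
        n_m=constraints.n_m,
    )
    for name in parameter_names:
        box.index(name)  # raises KeyError when absent from the current box
        theta = prior_pdf.points[:, prior_pdf.box.index(name)]
        j = box.index(name)
        center = 0.5 * (box.lower[j] + box.upper[j])
        halfwidth = 0.5 * (box.upper[j] - box.lower[j])
        z = (theta - center) / halfwidth
        for m in range(1, n_m + 1):
            target = prior_pdf.quadrature(z ** m)
            new.parameter_entries.append(
                ParameterConstraintEntry(
                    name, m, target, max(1.0, abs(target)), center, halfwidth
                )
            )
    return new


def constraint_residuals(
    pdf: DiscretePDF,
    db: SimulationDatabase,
    constraints: MomentConstraintSet,
) -> np.ndarray:
    """(achieved − target) / scale for every constraint, by quadrature."""
    c_mat, targets, scales = _constraint_matrix(db, constraints)
    if c_mat.shape[0] != pdf.n_valid:
        raise ValueError("PDF and database collocation points are not aligned")
    achieved = pdf.quad_weight * (pdf.values @ c_mat)
    return (achieved - targets) / scales
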