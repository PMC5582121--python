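"""Sobol discretization of the parameter box and the simulation database.

The inverse procedure never touches the forward model: every AP (or
biomarker vector) it needs is pre-simulated here, once per collocation
point, and stored.  ``eval_counter`` records the number of forward model
evaluations and is the quantity audited by the zero-extra-evaluation
invariant.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.stats import qmc

from apmoments.biomarkers import compute_biomarkers, pairwise_products
from apmoments.cell_models import (
    CellModel,
    PacingProtocol,
    SolverConfig,
    interpolate_to_grid,
    simulate_ap,
)

__all__ = [
    "ParameterBox",
    "CollocationSet",
    "SimulationDatabase",
    "TimeSeriesSpec",
    "BiomarkerSpec",
    "sobol_sample",
    "build_database",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ParameterBox:
    """Axis-aligned box of dimensionless conductance multipliers."""

    names: tuple[str, ...]
    lower: np.ndarray
    upper: np.ndarray

    def __init__(self, names: Sequence[str], lower: Sequence[float], upper: Sequence[float]):
        object.__setattr__(self, "names", tuple(names))
        object.__setattr__(self, "lower", np.asarray(lower, dtype=float))
        object.__setattr__(self, "upper", np.asarray(upper, dtype=float))
        if len(self.names) != self.lower.size or self.lower.size != self.upper.size:
            raise ValueError("names, lower and upper must have equal length")
        if np.any(self.lower >= self.upper):
            raise ValueError("lower bounds must be strictly below upper bounds")

    @classmethod
    def cube(cls, names: Sequence[str], lower: float, upper: float) -> "ParameterBox":
        n = len(names)
        return cls(names, [lower] * n, [upper] * n)

    @property
    def n_p(self) -> int:
        return len(self.names)

    @property
    def volume(self) -> float:
        return float(np.prod(self.upper - self.lower))

    def contains(self, points: np.ndarray, atol: float = 1e-12) -> np.ndarray:
        pts = np.atleast_2d(points)
        return np.all(
            (pts >= self.lower - atol) & (pts <= self.upper + atol), axis=1
        )

    def index(self, name: str) -> int:
        try:
            return self.names.index(name)
        except ValueError:
            raise KeyError(f"parameter {name!r} not in box {self.names}") from None


@dataclass(frozen=True)
class CollocationSet:
    """Parameter samples at which the forward model is evaluated."""

    points: np.ndarray  # N_c x n_p
    sequence_spec: dict = field(default_factory=dict)

    @property
    def n_c(self) -> int:
        return self.points.shape[0]


def sobol_sample(box: ParameterBox, n_points: int, skip: int = 0,
                 scramble: bool = False, seed: int | None = None) -> CollocationSet:
    """First ``n_points`` of the (by default unscrambled) Sobol sequence,
    after skipping ``skip`` elements, affinely mapped onto the box."""
    if n_points < 1:
        raise ValueError("n_points must be >= 1")
    if box.n_p > 21:
        raise ValueError("parameter dimension above the supported cap (21)")
    sampler = qmc.Sobol(d=box.n_p, scramble=scramble, seed=seed)
    if skip:
        sampler.fast_forward(skip)
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message=".*balance properties.*")
        unit = sampler.random(n_points)
    points = qmc.scale(unit, box.lower, box.upper)
    return CollocationSet(
        points=points,
        sequence_spec={"sampler": "sobol", "scramble": scramble, "skip": skip, "seed": seed},
    )


# ---------------------------------------------------------------------------
# observable specifications
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TimeSeriesSpec:
    """Observable = AP voltage on a common uniform grid."""

    grid: np.ndarray

    def __init__(self, grid: Sequence[float]):
        object.__setattr__(self, "grid", np.asarray(grid, dtype=float))

    @classmethod
    def uniform(cls, cycle_length_ms: float, step_ms: float = 1.0) -> "TimeSeriesSpec":
        return cls(np.arange(0.0, cycle_length_ms + 0.5 * step_ms, step_ms))


@dataclass(frozen=True)
class BiomarkerSpec:
    """Observable = named biomarkers (+ optional pairwise products).

    With several protocols, base biomarkers are tagged per protocol and the
    pairwise products are taken over the concatenated base set.
    """

    names: tuple[str, ...]
    pairwise: bool = True
    notch_offset_ms: float = 30.0
    smooth_window: int = 0

    def __init__(self, names: Sequence[str], pairwise: bool = True,
                 notch_offset_ms: float = 30.0, smooth_window: int = 0):
        object.__setattr__(self, "names", tuple(names))
        object.__setattr__(self, "pairwise", pairwise)
        object.__setattr__(self, "notch_offset_ms", notch_offset_ms)
        object.__setattr__(self, "smooth_window", smooth_window)


@dataclass
class SimulationDatabase:
    """Observable values at every collocation point.

    ``observables[i, j]`` is observable ``observable_index[j]`` at collocation
    point ``i``; failed simulations are masked out via ``valid_mask`` and
    excluded from every quadrature (the Monte-Carlo weight becomes
    ``|Θ| / N_c_valid``).
    """

    box: ParameterBox
    collocation: CollocationSet
    observables: np.ndarray
    observable_index: list[str]
    valid_mask: np.ndarray
    eval_counter: int = 0
    config: dict = field(default_factory=dict)

    @property
    def n_valid(self) -> int:
        return int(np.sum(self.valid_mask))

    @property
    def valid_points(self) -> np.ndarray:
        return self.collocation.points[self.valid_mask]

    @property
    def valid_observables(self) -> np.ndarray:
        return self.observables[self.valid_mask]

    def column(self, label: str) -> np.ndarray:
        """Observable column (valid rows only) for one label."""
        try:
            j = self.observable_index.index(label)
        except ValueError:
            raise KeyError(f"observable {label!r} not in database") from None
        return self.observables[self.valid_mask, j]

    # -- persistence --------------------------------------------------------

    def save(self, path: str) -> None:
        import h5py

        with h5py.File(path, "w") as f:
            f.create_dataset("collocation", data=self.collocation.points)
            f.create_dataset("observables", data=self.observables)
            f.create_dataset("valid_mask", data=self.valid_mask)
            f.create_dataset(
                "labels", data=np.array(self.observable_index, dtype="S")
            )
            f.attrs["eval_counter"] = self.eval_counter
            f.attrs["box_names"] = json.dumps(list(self.box.names))
            f.attrs["box_lower"] = self.box.lower
            f.attrs["box_upper"] = self.box.upper
            f.attrs["config"] = json.dumps(self.config, default=str)
            f.attrs["sequence_spec"] = json.dumps(
                self.collocation.sequence_spec, default=str
            )

    @classmethod
    def load(cls, path: str) -> "SimulationDatabase":
        import h5py

        with h5py.File(path, "r") as f:
            box = ParameterBox(
                json.loads(f.attrs["box_names"]),
                np.asarray(f.attrs["box_lower"]),
                np.asarray(f.attrs["box_upper"]),
            )
            return cls(
                box=box,
                collocation=CollocationSet(
                    points=f["collocation"][...],
                    sequence_spec=json.loads(f.attrs["sequence_spec"]),
                ),
                observables=f["observables"][...],
                observable_index=[s.decode() for s in f["labels"][...]],
                valid_mask=f["valid_mask"][...].astype(bool),
                eval_counter=int(f.attrs["eval_counter"]),
                config=json.loads(f.attrs["config"]),
            )


def _evaluate_point(
    model: CellModel,
    multipliers: dict[str, float],
    protocols: Sequence[PacingProtocol],
    spec: TimeSeriesSpec | BiomarkerSpec,
    solver_cfg: SolverConfig,
):
    """Observables for one parameter vector; returns (labels, values, ok, n_evals)."""
    labels: list[str] = []
    values: list[float] = []
    base: dict[str, float] = {}
    n_evals = 0
    multi = len(protocols) > 1
    for protocol in protocols:
        trace = simulate_ap(model, multipliers, protocol, solver_cfg)
        n_evals += 1
        if not trace.ok:
            return [], [], False, n_evals
        tag = protocol.tag if multi else ""
        if isinstance(spec, TimeSeriesSpec):
            common = interpolate_to_grid(trace, spec.grid)
            prefix = f"{tag}_" if tag else ""
            labels.extend(f"{prefix}t{tj:g}" for tj in spec.grid)
            values.extend(common.voltages)
        else:
            bv = compute_biomarkers(
                trace, spec.names,
                notch_offset_ms=spec.notch_offset_ms,
                smooth_window=spec.smooth_window,
                protocol_tag=tag,
            )
            if not bv.ok or bv.missing:
                return [], [], False, n_evals
            base.update(bv.tagged())
    if isinstance(spec, BiomarkerSpec):
        labels.extend(base)
        values.extend(base.values())
        if spec.pairwise:
            prods = pairwise_products(base)
            labels.extend(prods)
            values.extend(prods.values())
    return labels, values, True, n_evals


def build_database(
    model: CellModel,
    box: ParameterBox,
    collocation: CollocationSet,
    protocols: PacingProtocol | Sequence[PacingProtocol],
    observable_spec: TimeSeriesSpec | BiomarkerSpec,
    solver_cfg: SolverConfig | None = None,
    fixed_multipliers: Mapping[str, float] | None = None,
) -> SimulationDatabase:
    """Run one forward simulation per collocation point per protocol.

    ``fixed_multipliers`` lets scenario modifiers (e.g. drug blocks) scale
    conductances that are not part of the box.
    """
    if isinstance(protocols, PacingProtocol):
        protocols = [protocols]
    solver_cfg = solver_cfg or SolverConfig()
    fixed = dict(fixed_multipliers or {})

    n_c = collocation.n_c
    rows: list[np.ndarray | None] = []
    valid = np.zeros(n_c, dtype=bool)
    labels: list[str] | None = None
    eval_counter = 0
    for i in range(n_c):
        multipliers = dict(fixed)
        multipliers.update(zip(box.names, collocation.points[i]))
        lab, vals, ok, n_evals = _evaluate_point(
            model, multipliers, protocols, observable_spec, solver_cfg
        )
        eval_counter += n_evals
        if ok:
            if labels is None:
                labels = lab
            valid[i] = True
            rows.append(np.asarray(vals, dtype=float))
        else:
            rows.append(None)

    if labels is None:
        raise RuntimeError("all collocation-point simulations failed")
    n_t = len(labels)
    observables = np.full((n_c, n_t), np.nan)
    for i, row in enumerate(rows):
        if row is not None:
            observables[i] = row

    n_failed = n_c - int(valid.sum())
    if n_failed:
        bad = collocation.points[~valid]
        logger.warning(
            "%d/%d collocation points failed; they are dropped from all quadratures",
            n_failed, n_c,
        )
        if n_failed > 0.1 * n_c:
            warnings.warn(
                f"{n_failed}/{n_c} collocation points failed; failing ranges: "
                + ", ".join(
                    f"{name} in [{bad[:, k].min():.3g}, {bad[:, k].max():.3g}]"
                    for k, name in enumerate(box.names)
                ),
                RuntimeWarning,
            )

    return SimulationDatabase(
        box=box,
        collocation=collocation,
        observables=observables,
        observable_index=list(labels),
        valid_mask=valid,
        eval_counter=eval_counter,
        config={
            "model": model.name,
            "protocols": [str(p) for p in protocols],
            "observable_spec": str(observable_spec),
            "fixed_multipliers": fixed,
            "solver": str(solver_cfg),
        },
    )
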