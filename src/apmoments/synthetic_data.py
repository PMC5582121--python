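"""Ground-truth-known synthetic measurement sets.

Conductance multipliers are drawn i.i.d. from an uncorrelated multivariate
normal (default mean 1.1, s.d. 0.15) truncated to the parameter box; each
sampled parameter vector is forward-simulated under one or more pacing
protocols (optionally with drug-block modifiers), zero-mean Gaussian noise
at a stated SNR is added to the trace, and observables — time-series values
or biomarkers — are computed *after* noise addition.

SNR convention: amplitude-ratio decibels, τ = A·10^(−SNR/20) with A the
clean trace's peak-to-rest amplitude (the power convention 10·log10 is
selectable).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from apmoments.biomarkers import compute_biomarkers, pairwise_products
from apmoments.cell_models import (
    APTrace,
    CellModel,
    PacingProtocol,
    SolverConfig,
    interpolate_to_grid,
    simulate_ap,
)
from apmoments.database import BiomarkerSpec, ParameterBox, TimeSeriesSpec
from apmoments.omm_core import MeasurementSet

__all__ = [
    "SyntheticSpec",
    "sample_true_parameters",
    "add_noise_snr",
    "generate_measurement_set",
]


@dataclass
class SyntheticSpec:
    """True parameter law, sample count, noise level and scenario modifiers."""

    means: dict[str, float]
    stds: dict[str, float]
    n_samples: int
    snr_db: float = np.inf
    seed: int = 0
    drug_block: dict[str, float] = field(default_factory=dict)  # name -> remaining fraction
    snr_convention: str = "amplitude"  # or "power"

    def __post_init__(self) -> None:
        if self.n_samples < 1:
            raise ValueError("need at least one sample")
        if np.isnan(self.snr_db):
            raise ValueError("SNR must not be NaN")
        for name, frac in self.drug_block.items():
            if not 0.0 <= frac <= 1.0:
                raise ValueError(f"block fraction for {name!r} must be in [0, 1]")
        if self.snr_convention not in ("amplitude", "power"):
            raise ValueError("snr_convention must be 'amplitude' or 'power'")

    def noise_std(self, amplitude: float) -> float:
        if np.isinf(self.snr_db):
            return 0.0
        divisor = 20.0 if self.snr_convention == "amplitude" else 10.0
        return amplitude * 10.0 ** (-self.snr_db / divisor)


def sample_true_parameters(
    spec: SyntheticSpec, box: ParameterBox, rng: np.random.Generator | None = None
) -> tuple[np.ndarray, int]:
    """i.i.d. truncated-normal draws inside the box.

    Out-of-box draws are resampled; returns (N x n_p matrix, total proposals).
    A sub-50% acceptance rate triggers a warning (law poorly matched to box).
    """
    rng = rng if rng is not None else np.random.default_rng(spec.seed)
    mean = np.array([spec.means[name] for name in box.names])
    std = np.array([spec.stds[name] for name in box.names])
    out = np.empty((spec.n_samples, box.n_p))
    filled = 0
    proposals = 0
    accepted = 0
    while filled < spec.n_samples:
        batch = max(spec.n_samples - filled, 64)
        draws = rng.normal(mean, std, size=(batch, box.n_p))
        proposals += batch
        good = draws[box.contains(draws)]
        accepted += good.shape[0]
        take = min(good.shape[0], spec.n_samples - filled)
        out[filled:filled + take] = good[:take]
        filled += take
        if proposals > 100 * spec.n_samples:
            raise RuntimeError("acceptance rate too low; check distribution vs box")
    if accepted / proposals < 0.5:
        warnings.warn(
            f"truncation acceptance rate {spec.n_samples / proposals:.1%} < 50%: "
            "the true distribution is poorly matched to the parameter box",
            RuntimeWarning,
        )
    return out, proposals


def add_noise_snr(
    trace: APTrace,
    snr_db: float,
    amplitude: float | None = None,
    rng: np.random.Generator | int | None = None,
    convention: str = "amplitude",
) -> tuple[APTrace, float]:
    """Additive i.i.d. zero-mean Gaussian noise of s.d. τ = A·10^(−SNR/20).

    ``amplitude`` defaults to the trace's peak-to-minimum voltage range.
    Returns the noisy copy and τ.
    """
    if isinstance(rng, (int, np.integer)) or rng is None:
        rng = np.random.default_rng(rng)
    if amplitude is None:
        amplitude = float(trace.voltages.max() - trace.voltages.min())
    if amplitude <= 0:
        raise ValueError("amplitude must be positive")
    divisor = 20.0 if convention == "amplitude" else 10.0
    tau = 0.0 if np.isinf(snr_db) else amplitude * 10.0 ** (-snr_db / divisor)
    noisy = trace.voltages if tau == 0.0 else trace.voltages + rng.normal(0.0, tau, trace.voltages.shape)
    return APTrace(trace.times, noisy, meta=dict(trace.meta)), tau


def generate_measurement_set(
    model: CellModel,
    protocols: PacingProtocol | Sequence[PacingProtocol],
    spec: SyntheticSpec,
    box: ParameterBox,
    observable_spec: TimeSeriesSpec | BiomarkerSpec,
    solver_cfg: SolverConfig | None = None,
    fixed_multipliers: Mapping[str, float] | None = None,
) -> tuple[MeasurementSet, dict]:
    """Simulate every sampled parameter vector, add noise, assemble observables.

    Drug-block modifiers multiply the sampled values of the named
    conductances by their remaining fraction.  Ground-truth parameters (of
    the retained samples) are returned for recovery scoring; per-sample
    failures are dropped with a warning.
    """
    if isinstance(protocols, PacingProtocol):
        protocols = [protocols]
    solver_cfg = solver_cfg or SolverConfig()
    rng = np.random.default_rng(spec.seed)
    truth, proposals = sample_true_parameters(spec, box, rng)
    fixed = dict(fixed_multipliers or {})
    multi = len(protocols) > 1

    rows: list[list[float]] = []
    kept: list[int] = []
    labels: list[str] | None = None
    taus: list[float] = []
    for i in range(spec.n_samples):
        multipliers = dict(fixed)
        multipliers.update(zip(box.names, truth[i]))
        for name, frac in spec.drug_block.items():
            multipliers[name] = multipliers.get(name, 1.0) * frac
        lab: list[str] = []
        vals: list[float] = []
        base: dict[str, float] = {}
        ok = True
        for protocol in protocols:
            trace = simulate_ap(model, multipliers, protocol, solver_cfg)
            if not trace.ok:
                ok = False
                break
            noisy, tau = add_noise_snr(
                trace, spec.snr_db, rng=rng, convention=spec.snr_convention
            )
            taus.append(tau)
            tag = protocol.tag if multi else ""
            if isinstance(observable_spec, TimeSeriesSpec):
                common = interpolate_to_grid(noisy, observable_spec.grid)
                prefix = f"{tag}_" if tag else ""
                lab.extend(f"{prefix}t{tj:g}" for tj in observable_spec.grid)
                vals.extend(common.voltages)
            else:
                bv = compute_biomarkers(
                    noisy, observable_spec.names,
                    notch_offset_ms=observable_spec.notch_offset_ms,
                    smooth_window=observable_spec.smooth_window,
                    protocol_tag=tag,
                )
                if not bv.ok or bv.missing:
                    ok = False
                    break
                base.update(bv.tagged())
        if not ok:
            continue
        if isinstance(observable_spec, BiomarkerSpec):
            lab.extend(base)
            vals.extend(base.values())
            if observable_spec.pairwise:
                prods = pairwise_products(base)
                lab.extend(prods)
                vals.extend(prods.values())
        if labels is None:
            labels = lab
        rows.append(vals)
        kept.append(i)

    if labels is None:
        raise RuntimeError("all synthetic samples failed to simulate")
    n_dropped = spec.n_samples - len(kept)
    if n_dropped:
        warnings.warn(
            f"{n_dropped}/{spec.n_samples} synthetic samples dropped "
            "(simulation or biomarker failure)",
            RuntimeWarning,
        )
    ms = MeasurementSet(np.asarray(rows, dtype=float), labels)
    truth_record = {
        "parameters": truth[kept],
        "names": list(box.names),
        "dropped": n_dropped,
        "proposals": proposals,
        "noise_std": float(np.mean(taus)) if taus else 0.0,
    }
    return ms, truth_record
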