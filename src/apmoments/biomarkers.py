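"""AP summary biomarkers and their pairwise products.

Conventions (the literature leaves several free):

* the depolarization clock starts at the time of maximum upstroke velocity
  (max first-difference dV/dt);
* RMP is the mean voltage over the 10 ms preceding the upstroke when the
  trace contains that window, otherwise over the trailing 10 ms of the cycle
  (equivalent in a permanent regime, where the cycle end abuts the next
  stimulus);
* APDx is the time from the depolarization reference until the voltage first
  falls below ``V_peak - (x/100) * APA`` during repolarization (linear
  interpolation of the crossing);
* V20 is the sampled voltage at the first grid point at or below the 20%
  repolarization level (kept as a sample value, not the level itself);
* AUC is the trapezoidal integral of V over the whole trace.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np

from apmoments.cell_models import APTrace

__all__ = [
    "BiomarkerVector",
    "DEFAULT_BIOMARKERS",
    "PRODUCT_SEP",
    "compute_biomarkers",
    "pairwise_products",
]

#: the nine biomarkers used for single-protocol biomarker inversions
DEFAULT_BIOMARKERS = (
    "APD90", "APD50", "APD30", "APA", "RMP", "V20", "dVdt_max", "V_notch", "AUC",
)

#: separator used in pairwise-product labels ('*' cannot occur in a name)
PRODUCT_SEP = "*"

_UNITS = {
    "APD90": "ms", "APD50": "ms", "APD30": "ms", "APD20": "ms",
    "APA": "mV", "RMP": "mV", "V20": "mV", "V_notch": "mV",
    "dVdt_max": "mV/ms", "AUC": "mV.ms",
}


@dataclass
class BiomarkerVector:
    """Ordered biomarker values for one AP, optionally tagged by protocol."""

    values: dict[str, float]
    protocol_tag: str = ""
    ok: bool = True
    missing: set[str] = field(default_factory=set)

    @property
    def units(self) -> dict[str, str]:
        return {k: _UNITS.get(k.split("_", 1)[-1], _UNITS.get(k, "")) for k in self.values}

    def tagged(self) -> dict[str, float]:
        """Values keyed by ``tag_name`` (e.g. ``1Hz_APD90``) for concatenation."""
        if not self.protocol_tag:
            return dict(self.values)
        return {f"{self.protocol_tag}_{k}": v for k, v in self.values.items()}


def _moving_average(v: np.ndarray, window: int) -> np.ndarray:
    if window <= 1:
        return v
    kernel = np.ones(window) / window
    return np.convolve(v, kernel, mode="same")


def compute_biomarkers(
    trace: APTrace,
    spec: Iterable[str] = DEFAULT_BIOMARKERS,
    notch_offset_ms: float = 30.0,
    smooth_window: int = 0,
    upstroke_threshold: float = 1.0,
    protocol_tag: str = "",
) -> BiomarkerVector:
    """Compute the requested biomarkers from one AP trace.

    A trace without an upstroke (max dV/dt below ``upstroke_threshold``
    mV/ms) yields a vector flagged invalid; an APD whose repolarization level
    is never reached is reported NaN and listed in ``missing``.
    """
    spec = list(spec)
    if notch_offset_ms < 0:
        raise ValueError("notch_offset_ms must be >= 0")
    if not trace.ok:
        return BiomarkerVector(
            {name: np.nan for name in spec}, protocol_tag, ok=False, missing=set(spec)
        )

    t = trace.times
    v = _moving_average(trace.voltages, smooth_window)
    dt = np.diff(t)
    slopes = np.diff(v) / dt
    i_up = int(np.argmax(slopes))
    dvdt_max = float(slopes[i_up])
    if dvdt_max < upstroke_threshold:
        return BiomarkerVector(
            {name: np.nan for name in spec}, protocol_tag, ok=False, missing=set(spec)
        )
    t_ref = float(t[i_up + 1])  # end of the max-slope segment = depolarization reference
    t_up = float(t[i_up])

    # resting potential: pre-upstroke window if available, else trailing window
    if t_up - t[0] >= 10.0:
        pre = (t >= t_up - 10.0) & (t <= t_up)
        rmp = float(np.mean(v[pre]))
    else:
        rmp = float(np.mean(v[t >= t[-1] - 10.0]))

    after = t >= t_ref
    v_after = v[after]
    t_after = t[after]
    i_peak = int(np.argmax(v_after))
    v_peak = float(v_after[i_peak])
    apa = v_peak - rmp

    def crossing_time(level: float) -> float:
        """First downward crossing of ``level`` after the peak (interpolated)."""
        vv = v_after[i_peak:]
        tt = t_after[i_peak:]
        below = np.nonzero(vv <= level)[0]
        if below.size == 0 or below[0] == 0:
            return np.nan
        k = below[0]
        frac = (vv[k - 1] - level) / (vv[k - 1] - vv[k])
        return float(tt[k - 1] + frac * (tt[k] - tt[k - 1]))

    missing: set[str] = set()
    out: dict[str, float] = {}
    for name in spec:
        if name.startswith("APD"):
            x = float(name[3:])
            tc = crossing_time(v_peak - (x / 100.0) * apa)
            if np.isnan(tc):
                missing.add(name)
                out[name] = np.nan
            else:
                out[name] = tc - t_ref
        elif name == "APA":
            out[name] = apa
        elif name == "RMP":
            out[name] = rmp
        elif name == "V20":
            level = v_peak - 0.20 * apa
            below = np.nonzero(v_after[i_peak:] <= level)[0]
            if below.size == 0:
                missing.add(name)
                out[name] = np.nan
            else:
                out[name] = float(v_after[i_peak + below[0]])
        elif name == "dVdt_max":
            out[name] = dvdt_max
        elif name == "V_notch":
            tn = t_ref + notch_offset_ms
            if tn > t[-1]:
                missing.add(name)
                out[name] = np.nan
            else:
                out[name] = float(np.interp(tn, t, v))
        elif name == "AUC":
            out[name] = float(np.trapezoid(v, t))
        else:
            raise KeyError(f"unknown biomarker {name!r}")
    return BiomarkerVector(out, protocol_tag, ok=True, missing=missing)


def pairwise_products(
    bv: BiomarkerVector | Mapping[str, float],
) -> dict[str, float]:
    """All unordered pairwise products, labelled ``a*b`` in input order."""
    values = bv.values if isinstance(bv, BiomarkerVector) else dict(bv)
    names = list(values)
    for name in names:
        if PRODUCT_SEP in name:
            raise ValueError(f"biomarker name {name!r} contains the product separator")
    out: dict[str, float] = {}
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            out[f"{a}{PRODUCT_SEP}{b}"] = values[a] * values[b]
    return out
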