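"""Quality prediction along arbitrary (dynamic) temperature profiles.

Two equivalent routes are provided for piecewise-constant profiles:

* **Method #1 (effective temperature).**  The profile up to time t is collapsed
  into a single effective rate k_eff = Σ k(T_i)·t_i / t, i.e. the constant rate
  producing the same cumulative quality change; the corresponding effective
  temperature T_eff is the Arrhenius inversion of k_eff.  The prediction is the
  closed-form isothermal solution evaluated at k_eff.

* **Method #2 (stepwise integration).**  The trajectory is marched through the
  profile step by step, applying the exact per-step update (linear for zero
  order, exponential for first order) at each step's own rate constant.

Because both per-step updates are exact within a constant-temperature segment,
the two methods agree to rounding on every piecewise-constant profile; they
differ only in what they expose (T_eff vs. the marched trajectory).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .arrhenius import GAS_CONSTANT, ArrheniusModel, ZERO_CELSIUS, to_kelvin
from .profiles import TemperatureProfile

__all__ = [
    "effective_rate",
    "effective_temperature",
    "PredictionTrace",
    "predict_method1",
    "predict_method2",
    "default_bounds",
]


def _rate_integral(model: ArrheniusModel, profile: TemperatureProfile, until: float) -> float:
    """∫ k(T(t)) dt over [0, until] (days · per-day)."""
    return sum(model.rate_at(T) * d for d, T in profile.segments(until))


def effective_rate(
    model: ArrheniusModel, profile: TemperatureProfile, until: float | None = None
) -> float:
    """Time-average rate constant k_eff over the profile truncated at ``until``.

    k_eff · t_tot = Σ_i k(T_i) · t_i, a partial final step being prorated.
    """
    if until is None:
        until = profile.total_duration
    if until <= 0:
        raise ValueError("until must be positive")
    return _rate_integral(model, profile, until) / float(until)


def effective_temperature(
    model: ArrheniusModel, profile: TemperatureProfile, until: float | None = None
) -> float:
    """Constant temperature (°C) producing the same quality change as the profile.

    Inverts the Arrhenius law at k_eff:
    1/T_eff = 1/T_ref − (R/Ea) · ln(k_eff / k_ref).  Undefined for Ea = 0.
    """
    if model.ea == 0:
        raise ValueError("effective temperature is undefined for Ea = 0")
    keff = effective_rate(model, profile, until)
    inv = 1.0 / float(to_kelvin(model.t_ref)) - (GAS_CONSTANT / model.ea) * math.log(
        keff / model.k_ref
    )
    return 1.0 / inv - ZERO_CELSIUS


@dataclass(frozen=True)
class PredictionTrace:
    """Predicted index values along a profile.

    ``teff`` holds the running effective temperature per evaluation time for
    Method #1 (NaN at t = 0, where it is undefined) and is ``None`` for
    Method #2.
    """

    times: np.ndarray
    values: np.ndarray
    method: str
    teff: np.ndarray | None = None
    index: str | None = None

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "time_days": self.times,
                "index": self.index,
                "method": self.method,
                "value": self.values,
            }
        )
        df["teff_C"] = self.teff if self.teff is not None else np.nan
        return df

    def __len__(self) -> int:
        return self.times.size


def default_bounds(index: str | None) -> tuple[float | None, float | None]:
    """Physical clamp bounds applied when simulating forward.

    Sensory scores are floored at 1 (bottom of the 1–9 scale), lightness at 0;
    TVBN and unknown indices are unbounded.
    """
    if index in ("taste", "overall_acceptability"):
        return 1.0, None
    if index == "L_value":
        return 0.0, None
    return None, None


def _check_args(order: str, direction: str, y0: float, at_times) -> np.ndarray:
    if order not in ("zero", "first"):
        raise ValueError("order must be 'zero' or 'first'")
    if direction not in ("increasing", "decreasing"):
        raise ValueError("direction must be 'increasing' or 'decreasing'")
    if order == "first" and y0 <= 0:
        raise ValueError("first-order kinetics require y0 > 0")
    t = np.atleast_1d(np.asarray(at_times, dtype=float))
    if np.any(t < 0):
        raise ValueError("evaluation times must be non-negative")
    if np.any(np.diff(t) < 0):
        raise ValueError("evaluation times must be sorted ascending")
    return t


def _clamp(values: np.ndarray, floor: float | None, ceiling: float | None) -> np.ndarray:
    if floor is not None:
        values = np.maximum(values, floor)
    if ceiling is not None:
        values = np.minimum(values, ceiling)
    return values


def predict_method1(
    model: ArrheniusModel,
    profile: TemperatureProfile,
    *,
    order: str,
    y0: float,
    at_times,
    direction: str = "decreasing",
    floor: float | None = None,
    ceiling: float | None = None,
    index: str | None = None,
) -> PredictionTrace:
    """Effective-temperature prediction at each requested time.

    At each time t the profile is summarized by k_eff(t) and the closed-form
    isothermal solution is applied: zero order y = y0 ∓ k_eff·t, first order
    y = y0·exp(±k_eff·t) (sign per ``direction``).
    """
    t = _check_args(order, direction, y0, at_times)
    sgn = 1.0 if direction == "increasing" else -1.0
    values = np.empty_like(t)
    teff = np.full_like(t, np.nan)
    for i, ti in enumerate(t):
        if ti == 0:
            values[i] = y0
            continue
        keff = effective_rate(model, profile, ti)
        values[i] = y0 + sgn * keff * ti if order == "zero" else y0 * math.exp(sgn * keff * ti)
        if model.ea != 0:
            teff[i] = effective_temperature(model, profile, ti)
    values = _clamp(values, floor, ceiling)
    return PredictionTrace(times=t, values=values, method="teff", teff=teff, index=index)


def predict_method2(
    model: ArrheniusModel,
    profile: TemperatureProfile,
    *,
    order: str,
    y0: float,
    at_times,
    direction: str = "decreasing",
    floor: float | None = None,
    ceiling: float | None = None,
    index: str | None = None,
    dt: float | None = None,
) -> PredictionTrace:
    """Stepwise prediction marching through the profile's constant-T steps.

    Within each constant-temperature increment the exact update is applied
    (y ∓= k·Δt for zero order, y ·= exp(±k·Δt) for first order), so the result
    is insensitive to further subdivision; ``dt`` optionally caps the increment
    width (useful only to demonstrate that invariance).  Evaluation times may
    subdivide steps.
    """
    t = _check_args(order, direction, y0, at_times)
    total = profile.total_duration
    if t.size and t[-1] > total + 1e-9:
        raise ValueError("evaluation times exceed the profile duration")
    sgn = 1.0 if direction == "increasing" else -1.0

    # Pre-compute segment boundaries and rates.
    durations = np.array([s.duration for s in profile.steps])
    bounds = np.concatenate([[0.0], np.cumsum(durations)])
    rates = np.array([model.rate_at(s.temperature) for s in profile.steps])

    def advance(y: float, t_from: float, t_to: float) -> float:
        cursor = t_from
        while cursor < t_to - 1e-12:
            seg = min(int(np.searchsorted(bounds, cursor, side="right")) - 1, len(rates) - 1)
            seg_end = min(bounds[seg + 1], t_to)
            width = seg_end - cursor
            n_sub = 1 if dt is None else max(1, math.ceil(width / dt - 1e-12))
            sub = width / n_sub
            k = rates[seg]
            for _ in range(n_sub):
                y = y + sgn * k * sub if order == "zero" else y * math.exp(sgn * k * sub)
            cursor = seg_end
        return y

    values = np.empty_like(t)
    y, cursor = float(y0), 0.0
    for i, ti in enumerate(t):
        y = advance(y, cursor, min(ti, total))
        cursor = min(ti, total)
        values[i] = y
    values = _clamp(values, floor, ceiling)
    return PredictionTrace(times=t, values=values, method="stepwise", teff=None, index=index)
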