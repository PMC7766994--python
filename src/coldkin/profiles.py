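"""Time-temperature histories for cold-chain kinetics.

A :class:`TemperatureProfile` is a piecewise-constant temperature path made of
ordered :class:`TemperatureStep` segments; a :class:`LoggerTrace` is a raw
data-logger record of (time, temperature) samples that can be discretized into
a profile.  Time is measured in days throughout and temperatures are degrees
Celsius at every interface (kinetic math converts to kelvin internally).

Two named presets reflect common frozen-chain situations: a cyclic abuse
scenario (``var``: repeated −12 °C/24 h → −5 °C/36 h → −8 °C/24 h cycles) and a
150-day staged distribution chain (``distribution150``: packing plant,
transport, retail and domestic storage stages).
"""

from __future__ import annotations

import math
from collections.abc import Iterable, Iterator, Sequence
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "TemperatureStep",
    "TemperatureProfile",
    "LoggerTrace",
    "make_isothermal",
    "make_var_scenario",
    "make_distribution_scenario",
    "discretize",
    "get_scenario",
    "VAR_CYCLE",
    "DISTRIBUTION_STAGES_150",
]

_EPS = 1e-9


@dataclass(frozen=True)
class TemperatureStep:
    """One constant-temperature segment of a storage history.

    Parameters
    ----------
    duration : float
        Length of the segment in days; strictly positive.
    temperature : float
        Holding temperature in °C; must be finite.
    label : str, optional
        Free-text stage label (e.g. ``"retail storage"``).
    """

    duration: float
    temperature: float
    label: str | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "duration", float(self.duration))
        object.__setattr__(self, "temperature", float(self.temperature))
        if not math.isfinite(self.duration) or self.duration <= 0:
            raise ValueError(f"step duration must be positive and finite, got {self.duration}")
        if not math.isfinite(self.temperature):
            raise ValueError("step temperature must be finite")


class TemperatureProfile:
    """Ordered, contiguous sequence of constant-temperature steps."""

    def __init__(self, steps: Iterable[TemperatureStep], origin: float = 0.0):
        steps = tuple(steps)
        if not steps:
            raise ValueError("a profile needs at least one step")
        if not all(isinstance(s, TemperatureStep) for s in steps):
            raise TypeError("steps must be TemperatureStep instances")
        self._steps = steps
        self.origin = float(origin)
        self._cum = np.concatenate([[0.0], np.cumsum([s.duration for s in steps])])

    # -- basic introspection -------------------------------------------------
    @property
    def steps(self) -> tuple[TemperatureStep, ...]:
        return self._steps

    @property
    def n_steps(self) -> int:
        return len(self._steps)

    @property
    def total_duration(self) -> float:
        """Total span of the profile in days."""
        return float(self._cum[-1])

    @property
    def end(self) -> float:
        return self.origin + self.total_duration

    def step_end_times(self) -> np.ndarray:
        """Elapsed time (days from origin) at which each step finishes."""
        return self._cum[1:].copy()

    def temperature_at(self, t):
        """Temperature (°C) at absolute time(s) ``t``; right-open steps."""
        rel = np.asarray(t, dtype=float) - self.origin
        if np.any(rel < -_EPS) or np.any(rel > self.total_duration + _EPS):
            raise ValueError("time outside the profile span")
        idx = np.searchsorted(self._cum, rel, side="right") - 1
        idx = np.clip(idx, 0, len(self._steps) - 1)
        temps = np.array([s.temperature for s in self._steps])
        out = temps[idx]
        return float(out) if np.isscalar(t) or np.ndim(t) == 0 else out

    def segments(self, until: float | None = None) -> Iterator[tuple[float, float]]:
        """Yield ``(duration, temperature)`` pairs up to elapsed time ``until``.

        A partial final step is prorated so the yielded durations always sum
        to ``until`` exactly.
        """
        total = self.total_duration
        if until is None:
            until = total
        until = float(until)
        if until <= 0:
            raise ValueError("until must be positive")
        if until > total + _EPS:
            raise ValueError(f"until={until} exceeds profile duration {total}")
        remaining = min(until, total)
        for s in self._steps:
            if remaining <= _EPS * total and remaining <= 0:
                break
            d = min(s.duration, remaining)
            if d <= 0:
                break
            yield d, s.temperature
            remaining -= d

    def truncated(self, until: float) -> "TemperatureProfile":
        """Profile restricted to the first ``until`` days."""
        steps = [TemperatureStep(d, T) for d, T in self.segments(until)]
        return TemperatureProfile(steps, origin=self.origin)

    def time_weighted_mean_temperature(self) -> float:
        num = sum(s.duration * s.temperature for s in self._steps)
        return num / self.total_duration

    # -- combination ---------------------------------------------------------
    def __add__(self, other: "TemperatureProfile") -> "TemperatureProfile":
        if not isinstance(other, TemperatureProfile):
            return NotImplemented
        return TemperatureProfile(self._steps + other._steps, origin=self.origin)

    def repeated(self, n: int) -> "TemperatureProfile":
        if n < 1:
            raise ValueError("repetition count must be >= 1")
        return TemperatureProfile(self._steps * int(n), origin=self.origin)

    def __eq__(self, other) -> bool:
        if not isinstance(other, TemperatureProfile):
            return NotImplemented
        return self._steps == other._steps and self.origin == other.origin

    def __hash__(self):
        return hash((self._steps, self.origin))

    def __repr__(self) -> str:
        return (
            f"TemperatureProfile({self.n_steps} steps, "
            f"{self.total_duration:g} d, "
            f"{min(s.temperature for s in self._steps):g}..."
            f"{max(s.temperature for s in self._steps):g} °C)"
        )

    # -- I/O -----------------------------------------------------------------
    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "duration_days": [s.duration for s in self._steps],
                "temperature_C": [s.temperature for s in self._steps],
                "label": [s.label for s in self._steps],
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "TemperatureProfile":
        df = pd.read_csv(path)
        required = {"duration_days", "temperature_C"}
        if not required.issubset(df.columns):
            raise ValueError(f"profile CSV needs columns {sorted(required)}")
        labels = df["label"] if "label" in df.columns else [None] * len(df)
        steps = [
            TemperatureStep(d, T, None if (lbl is None or (isinstance(lbl, float) and math.isnan(lbl))) else str(lbl))
            for d, T, lbl in zip(df["duration_days"], df["temperature_C"], labels)
        ]
        return cls(steps)


@dataclass(frozen=True)
class LoggerTrace:
    """Raw data-logger record: strictly increasing times (days) and °C values."""

    times: np.ndarray
    temperatures: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        temp = np.asarray(self.temperatures, dtype=float)
        if t.ndim != 1 or temp.ndim != 1 or t.size != temp.size:
            raise ValueError("times and temperatures must be 1-D arrays of equal length")
        if t.size < 1:
            raise ValueError("trace must contain at least one sample")
        if np.any(np.diff(t) <= 0):
            raise ValueError("trace times must be strictly increasing")
        if not np.all(np.isfinite(t)) or not np.all(np.isfinite(temp)):
            raise ValueError("trace values must be finite")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "temperatures", temp)

    def __len__(self) -> int:
        return self.times.size

    def to_csv(self, path) -> None:
        pd.DataFrame({"time_days": self.times, "temperature_C": self.temperatures}).to_csv(
            path, index=False
        )

    @classmethod
    def from_csv(cls, path) -> "LoggerTrace":
        df = pd.read_csv(path)
        if not {"time_days", "temperature_C"}.issubset(df.columns):
            raise ValueError("trace CSV needs columns time_days,temperature_C")
        return cls(df["time_days"].to_numpy(), df["temperature_C"].to_numpy())


# --------------------------------------------------------------------------
# constructors

#: One cyclic-abuse cycle: (duration d, °C). Hours converted exactly (24 h = 1 d).
VAR_CYCLE: tuple[tuple[float, float], ...] = ((1.0, -12.0), (1.5, -5.0), (1.0, -8.0))

#: 150-day staged distribution chain: (temperature °C, duration d, label).
DISTRIBUTION_STAGES_150: tuple[tuple[float, float, str], ...] = (
    (-15.6, 25.0, "packing plant"),
    (-13.3, 25.0, "transport & distribution"),
    (-11.8, 50.0, "retail storage"),
    (-10.4, 50.0, "domestic storage"),
)


def make_isothermal(temperature: float, duration: float, label: str | None = None) -> TemperatureProfile:
    """Single-step constant-temperature profile."""
    return TemperatureProfile([TemperatureStep(duration, temperature, label)])


def make_var_scenario(n_cycles: int) -> TemperatureProfile:
    """Cyclic temperature-abuse profile: n repeats of −12 °C/1 d, −5 °C/1.5 d, −8 °C/1 d."""
    if int(n_cycles) != n_cycles or n_cycles < 1:
        raise ValueError("n_cycles must be an integer >= 1")
    steps = [TemperatureStep(d, T) for d, T in VAR_CYCLE] * int(n_cycles)
    return TemperatureProfile(steps)


def make_distribution_scenario(
    stages: Sequence[tuple] | None = None,
) -> TemperatureProfile:
    """Multi-stage distribution profile from per-stage ``(temperature, duration[, label])``.

    With no argument, returns the default 150-day chain
    (:data:`DISTRIBUTION_STAGES_150`): 25 d packing plant at −15.6 °C, 25 d
    transport at −13.3 °C, 50 d retail at −11.8 °C, 50 d domestic at −10.4 °C.
    Each stage temperature is the stage's effective temperature, represented
    as a constant step.
    """
    if stages is None:
        stages = DISTRIBUTION_STAGES_150
    stages = list(stages)
    if not stages:
        raise ValueError("at least one stage is required")
    steps = []
    for st in stages:
        if len(st) == 2:
            T, d = st
            lbl = None
        else:
            T, d, lbl = st
        steps.append(TemperatureStep(d, T, lbl))
    return TemperatureProfile(steps)


def discretize(trace: LoggerTrace, dt: float) -> TemperatureProfile:
    """Convert a logger trace to a step profile with zero-order hold.

    Each increment of width ``dt`` takes the trace temperature at its left
    endpoint (the most recent sample at or before the increment start), the
    natural reading of a data logger that records state changes.  The final
    increment is shortened so total duration is preserved exactly.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    if len(trace) < 2:
        raise ValueError("trace must span a positive duration (>= 2 samples)")
    t0 = trace.times[0]
    span = trace.times[-1] - t0
    n_full = int(math.floor(span / dt + _EPS))
    edges = t0 + dt * np.arange(n_full + 1)
    steps = []
    for left in edges[:-1]:
        idx = np.searchsorted(trace.times, left + _EPS, side="right") - 1
        steps.append(TemperatureStep(dt, trace.temperatures[max(idx, 0)]))
    remainder = span - n_full * dt
    if remainder > _EPS:
        left = edges[-1]
        idx = np.searchsorted(trace.times, left + _EPS, side="right") - 1
        steps.append(TemperatureStep(remainder, trace.temperatures[max(idx, 0)]))
    return TemperatureProfile(steps, origin=t0)


def get_scenario(name: str, **kwargs) -> TemperatureProfile:
    """Named scenario presets: ``var`` (default 24 cycles) and ``distribution150``."""
    if name == "var":
        return make_var_scenario(kwargs.pop("n_cycles", 24))
    if name == "distribution150":
        return make_distribution_scenario(kwargs.pop("stages", None))
    raise KeyError(f"unknown scenario preset {name!r}; choose 'var' or 'distribution150'")
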