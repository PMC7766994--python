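"""Shelf life, remaining shelf life and staged cold-chain scenarios.

Shelf life (SL) is the time for a quality index to move from its initial value
y0 to its acceptability limit at given conditions; remaining shelf life (RSL)
is the time left from the product's *current* quality state at a reference
storage temperature.  Along a staged distribution chain the quality state at
each stage end is predicted by the effective-temperature method, so RSL
reflects the product's actual temperature history instead of a nominal
"use by" date.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .arrhenius import ArrheniusModel
from .dynamic import default_bounds, effective_temperature, predict_method1
from .profiles import TemperatureProfile

__all__ = [
    "ShelfLifeSpec",
    "shelf_life_at",
    "remaining_shelf_life",
    "nominal_remaining_shelf_life",
    "StageResult",
    "ScenarioResult",
    "run_scenario",
]


@dataclass(frozen=True)
class ShelfLifeSpec:
    """Acceptability contract for one quality index.

    ``direction`` defaults from the relative position of limit and y0
    (limit < y0 → decreasing index, e.g. sensory score; limit > y0 →
    increasing, e.g. TVBN).
    """

    index: str
    order: str
    y0: float
    limit: float
    direction: str | None = None

    def __post_init__(self) -> None:
        if self.order not in ("zero", "first"):
            raise ValueError("order must be 'zero' or 'first'")
        direction = self.direction
        if direction is None:
            direction = "decreasing" if self.limit < self.y0 else "increasing"
            object.__setattr__(self, "direction", direction)
        if direction == "decreasing" and not self.limit < self.y0:
            raise ValueError("decreasing index requires limit < y0")
        if direction == "increasing" and not self.limit > self.y0:
            raise ValueError("increasing index requires limit > y0")
        if self.order == "first" and (self.y0 <= 0 or self.limit <= 0):
            raise ValueError("first-order kinetics require positive y0 and limit")

    @property
    def span(self) -> float:
        """Kinetic distance from y0 to the limit: |y0 − limit| for zero order,
        |ln(limit/y0)| for first order."""
        if self.order == "zero":
            return abs(self.y0 - self.limit)
        return abs(math.log(self.limit / self.y0))


def shelf_life_at(spec: ShelfLifeSpec, model: ArrheniusModel, temperature: float) -> float:
    """Days for the index to reach its limit at a constant temperature (°C).

    Returns ``math.inf`` when the rate constant vanishes.
    """
    k = model.rate_at(temperature)
    if k == 0:
        return math.inf
    return spec.span / k


def remaining_shelf_life(
    spec: ShelfLifeSpec, model: ArrheniusModel, value: float, temperature: float
) -> float:
    """Days left until the limit from the current ``value`` at ``temperature``.

    A value already at or past the limit yields 0 (with a warning when past).
    """
    past = value < spec.limit if spec.direction == "decreasing" else value > spec.limit
    if past:
        warnings.warn(
            f"{spec.index} value {value:g} is already past the limit {spec.limit:g}",
            stacklevel=2,
        )
        return 0.0
    if value == spec.limit:
        return 0.0
    if spec.order == "first" and value <= 0:
        raise ValueError("first-order kinetics require a positive current value")
    k = model.rate_at(temperature)
    if k == 0:
        return math.inf
    if spec.order == "zero":
        return abs(value - spec.limit) / k
    return abs(math.log(spec.limit / value)) / k


def nominal_remaining_shelf_life(
    spec: ShelfLifeSpec, model: ArrheniusModel, storage_temperature: float, elapsed: float
) -> float:
    """"Use by"-style RSL ignoring history: SL at the declared storage
    temperature minus elapsed calendar time (floored at 0)."""
    return max(shelf_life_at(spec, model, storage_temperature) - elapsed, 0.0)


@dataclass(frozen=True)
class StageResult:
    """Quality state at the end of one distribution stage."""

    stage: int
    label: str | None
    start_day: float
    end_day: float
    teff: float  # cumulative effective temperature over [0, end_day], °C
    value: float
    rsl: float  # remaining shelf life at the scenario's reference temperature, days


class ScenarioResult:
    """Per-stage quality evolution and RSL along a multi-stage profile."""

    def __init__(
        self,
        spec: ShelfLifeSpec,
        model: ArrheniusModel,
        profile: TemperatureProfile,
        rsl_reference: float,
        stages: list[StageResult],
    ):
        self.spec = spec
        self.model = model
        self.profile = profile
        self.rsl_reference = rsl_reference
        self.stages = stages

    @property
    def final_value(self) -> float:
        return self.stages[-1].value

    @property
    def final_rsl(self) -> float:
        return self.stages[-1].rsl

    def nominal_rsl(self, storage_temperature: float | None = None) -> float:
        """History-blind RSL: full shelf life at the reference (or given)
        storage temperature minus the scenario's total elapsed time."""
        T = self.rsl_reference if storage_temperature is None else storage_temperature
        return nominal_remaining_shelf_life(self.spec, self.model, T, self.profile.total_duration)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "stage": [s.stage for s in self.stages],
                "label": [s.label for s in self.stages],
                "end_time_days": [s.end_day for s in self.stages],
                "teff_C": [s.teff for s in self.stages],
                "value": [s.value for s in self.stages],
                "rsl_days": [s.rsl for s in self.stages],
            }
        )

    def summary(self) -> str:
        lines = [
            f"Cold-chain scenario: {self.spec.index} "
            f"(y0={self.spec.y0:g}, limit={self.spec.limit:g}, {self.spec.order}-order)",
            f"RSL reference temperature: {self.rsl_reference:g} C",
            "-" * 64,
            f"{'stage':>5} {'label':<24} {'end d':>6} {'Teff C':>7} {'value':>7} {'RSL d':>6}",
        ]
        for s in self.stages:
            lines.append(
                f"{s.stage:>5} {(s.label or '-'):<24} {s.end_day:>6.0f} "
                f"{s.teff:>7.2f} {s.value:>7.2f} {s.rsl:>6.0f}"
            )
        lines.append(
            f"nominal RSL ignoring history: {self.nominal_rsl():.0f} d "
            f"(vs {self.final_rsl:.0f} d history-aware)"
        )
        return "\n".join(lines)


def run_scenario(
    spec: ShelfLifeSpec,
    model: ArrheniusModel,
    profile: TemperatureProfile,
    rsl_reference: float = -15.0,
) -> ScenarioResult:
    """Evaluate quality and RSL at the end of every stage of a staged profile.

    Each profile step is treated as one distribution stage.  Stage-end values
    come from the effective-temperature prediction (Method #1); the reported
    T_eff is cumulative from time zero to the stage end; RSL converts the
    stage-end value into days left at ``rsl_reference`` °C.
    """
    floor, ceiling = default_bounds(spec.index)
    ends = profile.step_end_times()
    trace = predict_method1(
        model,
        profile,
        order=spec.order,
        y0=spec.y0,
        at_times=ends,
        direction=spec.direction,
        floor=floor,
        ceiling=ceiling,
        index=spec.index,
    )
    stages = []
    start = 0.0
    for i, (step, end, value) in enumerate(zip(profile.steps, ends, trace.values), start=1):
        teff = effective_temperature(model, profile, until=end)
        rsl = remaining_shelf_life(spec, model, float(value), rsl_reference)
        stages.append(
            StageResult(
                stage=i,
                label=step.label,
                start_day=start,
                end_day=float(end),
                teff=teff,
                value=float(value),
                rsl=rsl,
            )
        )
        start = float(end)
    return ScenarioResult(spec, model, profile, rsl_reference, stages)
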