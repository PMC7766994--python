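"""Primary (within-temperature) kinetics of quality indices.

Quality loss of frozen fish is described by apparent zero-order (linear in
time: lightness L, sensory scores) or apparent first-order (exponential:
TVBN) rate laws.  Fitting is ordinary least squares on the raw values (zero
order) or on ln(values) (first order), mirroring the two-step "apparent
kinetics" workflow: primary fits per storage temperature, then an Arrhenius
regression of the rate constants (see :mod:`coldkin.arrhenius`).

Rate constants are stored as magnitudes; the direction of change (TVBN rises,
L and sensory scores fall) is declared per index rather than inferred from
noisy slopes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = [
    "INDEX_DIRECTIONS",
    "SENSORY_INDICES",
    "QualitySeries",
    "PrimaryKinetics",
    "PrimaryFit",
    "NoGrowthResult",
    "fit_zero_order",
    "fit_first_order",
    "select_order",
    "no_growth_test",
    "read_measurements",
    "series_from_measurements",
]

#: Sign convention per quality index: which way the index moves as quality is lost.
INDEX_DIRECTIONS: dict[str, str] = {
    "L_value": "decreasing",
    "TVBN": "increasing",
    "taste": "decreasing",
    "overall_acceptability": "decreasing",
    "TVC": "increasing",
}

SENSORY_INDICES = frozenset({"taste", "overall_acceptability"})

_MEASUREMENT_COLUMNS = ["product", "index", "temperature_C", "time_days", "value"]


@dataclass(frozen=True)
class QualitySeries:
    """One quality index measured over time at one storage condition.

    Parameters
    ----------
    index : str
        Index name (``L_value``, ``TVBN``, ``taste``, ``overall_acceptability``,
        ``TVC`` or user-defined).
    times : array-like
        Sampling times in days; non-negative, strictly increasing.
    values : array-like
        Measured values (replicate averages) in the index's own units.
    temperature : float, optional
        Storage temperature in °C; ``None`` for dynamic (non-isothermal) storage.
    se : array-like, optional
        Replicate standard errors per point (plotting/reporting only).
    """

    index: str
    times: np.ndarray
    values: np.ndarray
    temperature: float | None = None
    se: np.ndarray | None = None

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        v = np.asarray(self.values, dtype=float)
        if t.ndim != 1 or v.ndim != 1 or t.size != v.size:
            raise ValueError("times and values must be 1-D arrays of equal length")
        if t.size < 1:
            raise ValueError("series must contain at least one point")
        if np.any(t < 0):
            raise ValueError("times must be non-negative")
        if np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing (average replicates first)")
        if not np.all(np.isfinite(v)):
            raise ValueError("values must be finite")
        if self.index in SENSORY_INDICES and (np.any(v < 1.0) or np.any(v > 9.0)):
            raise ValueError("sensory scores must lie within the 1-9 scale")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "values", v)
        if self.se is not None:
            se = np.asarray(self.se, dtype=float)
            if se.shape != t.shape:
                raise ValueError("se must match times in length")
            object.__setattr__(self, "se", se)

    def __len__(self) -> int:
        return self.times.size

    @property
    def n(self) -> int:
        return self.times.size


def _resolve_direction(index: str, direction: str | None) -> str:
    if direction is not None:
        if direction not in ("increasing", "decreasing"):
            raise ValueError("direction must be 'increasing' or 'decreasing'")
        return direction
    try:
        return INDEX_DIRECTIONS[index]
    except KeyError:
        raise ValueError(
            f"no default direction for index {index!r}; pass direction= explicitly"
        ) from None


class PrimaryKinetics:
    """Apparent zero/first-order kinetic model for one isothermal series.

    ``fit(order)`` returns a :class:`PrimaryFit` results object; ``order`` may
    be ``"zero"``, ``"first"`` or ``"auto"`` (pick the better least-squares fit,
    ties going to zero order).
    """

    def __init__(self, series: QualitySeries, direction: str | None = None):
        if not isinstance(series, QualitySeries):
            raise TypeError("series must be a QualitySeries")
        self.series = series
        self.direction = _resolve_direction(series.index, direction)

    def fit(self, order: str = "zero") -> "PrimaryFit":
        if order == "auto":
            order = self.select_order()
        if order == "zero":
            return self._fit(order="zero")
        if order == "first":
            if np.any(self.series.values <= 0):
                raise ValueError("first-order fit requires strictly positive values")
            return self._fit(order="first")
        raise ValueError("order must be 'zero', 'first' or 'auto'")

    def select_order(self) -> str:
        """Order with the higher R² of its least-squares fit; ties → zero."""
        r2_zero = self.fit("zero").rsquared
        r2_first = self.fit("first").rsquared
        return "first" if r2_first > r2_zero else "zero"

    def _fit(self, order: str) -> "PrimaryFit":
        s = self.series
        if s.n < 3:
            raise ValueError("need at least 3 points to fit a primary model")
        if np.ptp(s.times) == 0:
            raise ValueError("zero variance in sampling times")
        y = s.values if order == "zero" else np.log(s.values)
        ols = sm.OLS(y, sm.add_constant(s.times)).fit()
        intercept, slope = ols.params
        if np.ptp(y) == 0:  # constant response: exactly flat, define R^2 = 0
            slope = 0.0
        with np.errstate(divide="ignore", invalid="ignore"):
            r2 = float(ols.rsquared)
        if not math.isfinite(r2):
            r2 = 0.0
        y0 = float(intercept) if order == "zero" else float(np.exp(intercept))
        return PrimaryFit(
            order=order,
            k=abs(float(slope)),
            y0=y0,
            direction=self.direction,
            rsquared=r2,
            resid_se=float(np.sqrt(ols.mse_resid)) if s.n > 2 else float("nan"),
            slope=float(slope),
            series=s,
            _ols=ols,
        )


@dataclass(frozen=True)
class PrimaryFit:
    """Results of an apparent-kinetics fit.

    ``k`` is the magnitude of the fitted rate constant (per day); ``direction``
    carries its sign convention.  ``rsquared`` refers to the fitted scale (raw
    values for zero order, ln values for first order).
    """

    order: str
    k: float
    y0: float
    direction: str
    rsquared: float
    resid_se: float
    slope: float
    series: QualitySeries
    _ols: object = None

    @property
    def nobs(self) -> int:
        return self.series.n

    @property
    def k_se(self) -> float:
        return float(self._ols.bse[1])

    def k_conf_int(self, alpha: float = 0.05) -> tuple[float, float]:
        """Confidence interval for the rate-constant magnitude."""
        lo, hi = self._ols.conf_int(alpha=alpha)[1]
        if lo <= 0 <= hi:
            return 0.0, float(max(abs(lo), abs(hi)))
        lo, hi = sorted((abs(lo), abs(hi)))
        return float(lo), float(hi)

    def predict(self, times) -> np.ndarray:
        """Fitted trajectory at ``times`` (days), honoring the direction sign."""
        t = np.asarray(times, dtype=float)
        sgn = 1.0 if self.direction == "increasing" else -1.0
        if self.order == "zero":
            return self.y0 + sgn * self.k * t
        return self.y0 * np.exp(sgn * self.k * t)

    def summary(self) -> str:
        temp = self.series.temperature
        lines = [
            f"Apparent {self.order}-order fit: {self.series.index}"
            + (f" at {temp:g} C" if temp is not None else " (dynamic storage)"),
            "-" * 46,
            f"n points:   {self.nobs}",
            f"k:          {self.k:.6g} /day ({self.direction})",
            f"y0:         {self.y0:.6g}",
            f"R^2:        {self.rsquared:.4f}",
            f"resid. SE:  {self.resid_se:.4g}"
            + (" (ln scale)" if self.order == "first" else ""),
        ]
        return "\n".join(lines)

    def plot(self, ax=None):
        """Data (with replicate SE bars when available) and fitted curve."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        s = self.series
        ax.errorbar(s.times, s.values, yerr=s.se, fmt="o", capsize=3, label="data")
        ts = np.linspace(s.times.min(), s.times.max(), 100)
        ax.plot(ts, self.predict(ts), label=f"{self.order}-order fit")
        ax.set_xlabel("time (days)")
        ax.set_ylabel(s.index)
        ax.legend()
        return ax


def fit_zero_order(series: QualitySeries, direction: str | None = None) -> PrimaryFit:
    """OLS of value vs time; k = |slope|, y0 = intercept."""
    return PrimaryKinetics(series, direction).fit("zero")


def fit_first_order(series: QualitySeries, direction: str | None = None) -> PrimaryFit:
    """OLS of ln(value) vs time; k = |slope|, y0 = exp(intercept)."""
    return PrimaryKinetics(series, direction).fit("first")


def select_order(series: QualitySeries, direction: str | None = None) -> str:
    """Apparent order ('zero' or 'first') with the better least-squares fit."""
    return PrimaryKinetics(series, direction).select_order()


@dataclass(frozen=True)
class NoGrowthResult:
    """Signed OLS slope of logCFU/g vs time with its 95% CI."""

    slope: float
    conf_int: tuple[float, float]
    significant: bool
    nobs: int

    def summary(self) -> str:
        lo, hi = self.conf_int
        verdict = "significant" if self.significant else "no significant trend"
        return (
            f"TVC slope {self.slope:+.4g} log CFU/g/day "
            f"(95% CI {lo:+.4g} to {hi:+.4g}, n={self.nobs}): {verdict}"
        )


def no_growth_test(series: QualitySeries) -> NoGrowthResult:
    """Test whether microbial counts trend over storage time.

    Returns the signed OLS slope with a 95% confidence interval;
    ``significant`` is True when the interval excludes zero.  Frozen storage is
    expected to show no growth (slope CI covering zero).
    """
    if series.n < 4:
        raise ValueError("no-growth test needs at least 4 points")
    if np.ptp(series.times) == 0:
        raise ValueError("zero variance in sampling times")
    ols = sm.OLS(series.values, sm.add_constant(series.times)).fit()
    slope = float(ols.params[1])
    lo, hi = (float(v) for v in ols.conf_int(alpha=0.05)[1])
    significant = lo > 0 or hi < 0
    return NoGrowthResult(slope=slope, conf_int=(lo, hi), significant=significant, nobs=series.n)


# --------------------------------------------------------------------------
# measurements I/O (long-format CSV)


def read_measurements(path, known_indices: set[str] | None = None) -> pd.DataFrame:
    """Read a long-format measurements CSV.

    Expected columns: ``product,index,temperature_C,time_days,value`` with an
    optional ``replicate_se``.  ``known_indices`` (default: the standard index
    names) restricts allowed index labels; pass ``None``-like empty set to skip.
    """
    df = pd.read_csv(path)
    missing = [c for c in _MEASUREMENT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"measurements CSV missing columns {missing}")
    if known_indices is None:
        known_indices = set(INDEX_DIRECTIONS)
    if known_indices:
        unknown = set(df["index"].unique()) - set(known_indices)
        if unknown:
            raise ValueError(f"unknown index names in measurements: {sorted(unknown)}")
    return df


def series_from_measurements(
    frame: pd.DataFrame,
    index: str,
    temperature: float | None = None,
    product: str | None = None,
) -> QualitySeries:
    """Extract one :class:`QualitySeries`, averaging replicate rows per time."""
    sel = frame[frame["index"] == index]
    if product is not None:
        sel = sel[sel["product"] == product]
    if temperature is None:
        sel = sel[sel["temperature_C"].isna()]
    else:
        sel = sel[np.isclose(sel["temperature_C"].astype(float), temperature)]
    if sel.empty:
        raise ValueError(f"no measurements for index={index!r}, temperature={temperature!r}")
    grouped = sel.groupby("time_days", sort=True)["value"].mean()
    se = None
    if "replicate_se" in sel.columns and sel["replicate_se"].notna().all():
        se = sel.groupby("time_days", sort=True)["replicate_se"].mean().to_numpy()
    return QualitySeries(
        index=index,
        times=grouped.index.to_numpy(dtype=float),
        values=grouped.to_numpy(),
        temperature=temperature,
        se=se,
    )
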