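"""Secondary (temperature-dependence) modelling of quality-loss rates.

The rate constant k of an apparent zero- or first-order quality index follows
the Arrhenius law

    ln k = ln k_ref − (Ea/R) · (1/T − 1/T_ref)

with T in kelvin, Ea the activation energy in J/mol and R = 8.314 J/(mol·K).
:class:`ArrheniusRegression` estimates (k_ref, Ea) by ordinary least squares of
ln k on the predictor (1/T_ref − 1/T), so the intercept is ln k_ref directly
and the slope is +Ea/R.  The reference temperature defaults to −18 °C, the
nominal frozen-storage temperature.
"""

from __future__ import annotations

import json
import math
from collections.abc import Iterable
from dataclasses import dataclass, replace

import numpy as np
import statsmodels.api as sm

__all__ = [
    "GAS_CONSTANT",
    "ZERO_CELSIUS",
    "to_kelvin",
    "ArrheniusModel",
    "ArrheniusRegression",
    "ArrheniusFitResults",
    "fit_arrhenius",
    "similar_temperature_dependence",
]

GAS_CONSTANT = 8.314  # J / (mol K)
ZERO_CELSIUS = 273.15  # K


def to_kelvin(temperature_c):
    """°C → K."""
    return np.asarray(temperature_c, dtype=float) + ZERO_CELSIUS


@dataclass(frozen=True)
class ArrheniusModel:
    """Arrhenius temperature-dependence of a quality-loss rate constant.

    Parameters
    ----------
    k_ref : float
        Rate constant (per day) at the reference temperature.
    ea : float
        Activation energy in J/mol.
    t_ref : float
        Reference temperature in °C (default −18).
    ea_ci95 : float, optional
        Half-width of the 95% confidence interval on ``ea`` (J/mol).
    r2 : float, optional
        Coefficient of determination of the ln k regression.
    index : str, optional
        Name of the quality index the model describes.
    """

    k_ref: float
    ea: float
    t_ref: float = -18.0
    ea_ci95: float | None = None
    r2: float | None = None
    index: str | None = None

    def __post_init__(self) -> None:
        if not (self.k_ref > 0 and math.isfinite(self.k_ref)):
            raise ValueError("k_ref must be positive and finite")
        if not math.isfinite(self.ea):
            raise ValueError("ea must be finite")
        if to_kelvin(self.t_ref) <= 0:
            raise ValueError("reference temperature below absolute zero")

    def rate_at(self, temperature: float):
        """Rate constant (per day) at ``temperature`` in °C."""
        inv = 1.0 / to_kelvin(temperature) - 1.0 / float(to_kelvin(self.t_ref))
        out = self.k_ref * np.exp(-(self.ea / GAS_CONSTANT) * inv)
        return float(out) if np.ndim(temperature) == 0 else out

    def with_reference(self, t_ref: float) -> "ArrheniusModel":
        """Same temperature dependence re-expressed at a new reference (°C)."""
        return replace(self, k_ref=self.rate_at(t_ref), t_ref=float(t_ref))

    # -- JSON round trip -----------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "index": self.index,
            "k_ref_per_day": self.k_ref,
            "T_ref_C": self.t_ref,
            "Ea_kJ_mol": self.ea / 1e3,
            "Ea_ci95_kJ_mol": None if self.ea_ci95 is None else self.ea_ci95 / 1e3,
            "r2": self.r2,
        }

    def to_json(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def from_dict(cls, d: dict) -> "ArrheniusModel":
        ci = d.get("Ea_ci95_kJ_mol")
        return cls(
            k_ref=d["k_ref_per_day"],
            ea=d["Ea_kJ_mol"] * 1e3,
            t_ref=d.get("T_ref_C", -18.0),
            ea_ci95=None if ci is None else ci * 1e3,
            r2=d.get("r2"),
            index=d.get("index"),
        )

    @classmethod
    def from_json(cls, path) -> "ArrheniusModel":
        with open(path, encoding="utf-8") as fh:
            return cls.from_dict(json.load(fh))


class ArrheniusRegression:
    """OLS model for ln k against (1/T_ref − 1/T).

    Parameters
    ----------
    temperatures : array-like
        Storage temperatures in °C; at least three distinct values.
    rates : array-like
        Rate constants (per day) at those temperatures; all positive.
    t_ref : float
        Reference temperature in °C.
    index : str, optional
        Quality-index name carried into the fitted model.
    """

    def __init__(self, temperatures, rates, t_ref: float = -18.0, index: str | None = None):
        temperatures = np.asarray(temperatures, dtype=float)
        rates = np.asarray(rates, dtype=float)
        if temperatures.shape != rates.shape or temperatures.ndim != 1:
            raise ValueError("temperatures and rates must be 1-D arrays of equal length")
        if np.unique(temperatures).size < 3:
            raise ValueError("need rate constants at >= 3 distinct temperatures")
        if np.any(rates <= 0) or not np.all(np.isfinite(rates)):
            raise ValueError("all rate constants must be positive and finite")
        self.temperatures = temperatures
        self.rates = rates
        self.t_ref = float(t_ref)
        self.index = index

    def fit(self) -> "ArrheniusFitResults":
        x = 1.0 / to_kelvin(self.t_ref) - 1.0 / to_kelvin(self.temperatures)
        y = np.log(self.rates)
        ols = sm.OLS(y, sm.add_constant(x)).fit()
        intercept, slope = ols.params
        lo, hi = ols.conf_int(alpha=0.05)[1]
        ea = slope * GAS_CONSTANT
        ea_ci95 = (hi - lo) / 2.0 * GAS_CONSTANT
        r2 = float(ols.rsquared)
        if math.isnan(r2):  # zero spread in ln k
            r2 = 0.0
        model = ArrheniusModel(
            k_ref=float(np.exp(intercept)),
            ea=float(ea),
            t_ref=self.t_ref,
            ea_ci95=float(ea_ci95) if math.isfinite(ea_ci95) else None,
            r2=r2,
            index=self.index,
        )
        return ArrheniusFitResults(model, self, ols)


class ArrheniusFitResults:
    """Fitted Arrhenius regression: the model plus regression diagnostics."""

    def __init__(self, model: ArrheniusModel, regression: ArrheniusRegression, ols):
        self.model = model
        self.regression = regression
        self._ols = ols

    # convenient pass-throughs
    @property
    def ea(self) -> float:
        return self.model.ea

    @property
    def k_ref(self) -> float:
        return self.model.k_ref

    @property
    def t_ref(self) -> float:
        return self.model.t_ref

    @property
    def ea_ci95(self) -> float | None:
        return self.model.ea_ci95

    @property
    def rsquared(self) -> float:
        return self.model.r2

    @property
    def nobs(self) -> int:
        return int(self._ols.nobs)

    def rate_at(self, temperature):
        return self.model.rate_at(temperature)

    def ea_conf_int(self) -> tuple[float, float]:
        """95% confidence interval on Ea (J/mol), Student-t with n−2 df."""
        lo, hi = self._ols.conf_int(alpha=0.05)[1]
        return lo * GAS_CONSTANT, hi * GAS_CONSTANT

    def summary(self) -> str:
        ci = self.model.ea_ci95
        lines = [
            "Arrhenius regression (ln k ~ 1/T_ref - 1/T)",
            "-" * 46,
            f"index:           {self.model.index or '-'}",
            f"n temperatures:  {self.nobs}",
            f"T_ref:           {self.t_ref:.2f} C",
            f"k_ref:           {self.k_ref:.6g} /day",
            f"Ea:              {self.ea / 1e3:.2f} kJ/mol"
            + (f"  (95% CI +/- {ci / 1e3:.2f})" if ci is not None else ""),
            f"R^2:             {self.rsquared:.4f}",
        ]
        return "\n".join(lines)

    def plot(self, ax=None):
        """Arrhenius plot: ln k against 1/T_ref − 1/T with the fitted line."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        x = 1.0 / to_kelvin(self.t_ref) - 1.0 / to_kelvin(self.regression.temperatures)
        ax.scatter(x, np.log(self.regression.rates), label="rates")
        xs = np.linspace(x.min(), x.max(), 50)
        ax.plot(xs, np.log(self.k_ref) + (self.ea / GAS_CONSTANT) * xs, label="fit")
        ax.set_xlabel("1/T_ref - 1/T (1/K)")
        ax.set_ylabel("ln k")
        ax.legend()
        return ax


def fit_arrhenius(
    rates: Iterable[tuple[float, float]], t_ref: float = -18.0, index: str | None = None
) -> ArrheniusModel:
    """Fit the Arrhenius model to ``(temperature °C, rate per day)`` pairs."""
    pairs = list(rates)
    temps = [p[0] for p in pairs]
    ks = [p[1] for p in pairs]
    return ArrheniusRegression(temps, ks, t_ref=t_ref, index=index).fit().model


def similar_temperature_dependence(ea1: float, ea2: float, window: float = 20_000.0) -> bool:
    """Whether two activation energies (J/mol) agree within ±20 kJ/mol.

    Indices within this window respond alike to temperature shifts, so one can
    act as a monitor (e.g. a TTI label) for the other.
    """
    return abs(ea1 - ea2) <= window
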