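"""Synthetic datasets with the statistical structure of a frozen-fish
shelf-life study.

Three product presets — gilthead sea bream fillets, sea bass fillets and
yellowfin tuna slices — are parameterized from the published isothermal
characterization of those products: shelf lives at −5/−8/−12/−15 °C anchor the
rate constants of TVBN (first order, limit-specific) and overall
acceptability (zero order, 9→5 on the 1–9 scale), with activation energies
refit from those anchors; taste and L-value ride on published activation
energies; total viable counts stay flat during frozen storage.

The generator emulates the study design — 5–10 sampling points per isothermal
condition over ≤14 months, triplicate replicates, i.i.d. Gaussian replicate
noise on the measurement scale — and a dynamic mode that samples along an
arbitrary temperature profile from the stepwise-integration truth.  Every
dataset is regenerable bit-identically from (preset, design, seed).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .arrhenius import ArrheniusModel, fit_arrhenius
from .dynamic import default_bounds, predict_method2
from .primary import QualitySeries, series_from_measurements
from .profiles import TemperatureProfile
from .shelf_life import ShelfLifeSpec, shelf_life_at

__all__ = [
    "PRODUCTS",
    "ISO_TEMPERATURES",
    "NOISE_SD",
    "IndexPreset",
    "ProductPreset",
    "make_preset",
    "SyntheticDataset",
    "generate_isothermal",
    "generate_dynamic",
]

PRODUCTS = ("sea_bream", "sea_bass", "tuna")

#: Isothermal study temperatures (°C).
ISO_TEMPERATURES = (-5.0, -8.0, -12.0, -15.0)

# Published isothermal shelf lives (days) at -5/-8/-12/-15 °C that anchor the
# kinetic presets.
_SHELF_LIVES: dict[tuple[str, str], tuple[float, ...]] = {
    ("sea_bream", "TVBN"): (130, 182, 287, 408),
    ("sea_bream", "overall_acceptability"): (134, 186, 293, 415),
    ("sea_bass", "TVBN"): (140, 191, 291, 403),
    ("sea_bass", "overall_acceptability"): (133, 185, 290, 408),
    ("tuna", "TVBN"): (156, 212, 323, 448),
    ("tuna", "overall_acceptability"): (152, 208, 320, 445),
}

_TVBN_INITIAL = {"sea_bream": 6.8, "sea_bass": 8.4, "tuna": 7.6}
_TVBN_LIMIT = {"sea_bream": 15.0, "sea_bass": 20.0, "tuna": 22.0}
_L_INITIAL = {"sea_bream": 66.7, "sea_bass": 56.3, "tuna": 71.7}
_TVC_INITIAL = {"sea_bream": 4.4, "sea_bass": 5.5, "tuna": 3.5}

SENSORY_INITIAL = 9.0
SENSORY_LIMIT = 5.0

# Published activation energies (J/mol) for indices whose rates cannot be
# recovered from the shelf-life anchors (L-value, taste).
_EA_PUBLISHED = {
    ("sea_bream", "L_value"): 48_900.0,
    ("sea_bass", "L_value"): 64_400.0,
    ("tuna", "L_value"): 83_900.0,
    ("sea_bream", "taste"): 65_200.0,
    ("sea_bass", "taste"): 64_500.0,
    ("tuna", "taste"): 69_400.0,
}

# Synthetic stand-in: lightness declines ~10 units over the sensory shelf life
# (figure-scale darkening; no numeric L rate is published).
_L_DROP = 10.0

#: Replicate noise SD per index, on the measurement scale.
NOISE_SD = {
    "L_value": 1.5,
    "TVBN": 0.8,
    "taste": 0.4,
    "overall_acceptability": 0.4,
    "TVC": 0.2,
}

_MAX_HORIZON = 420.0  # days, ~14 months
_DEFAULT_N_POINTS = 8
_DEFAULT_REPLICATES = 3


@dataclass(frozen=True)
class IndexPreset:
    """Generating parameters for one quality index of one product."""

    index: str
    order: str
    direction: str
    y0: float
    limit: float | None
    arrhenius: ArrheniusModel
    noise_sd: float

    def spec(self) -> ShelfLifeSpec:
        if self.limit is None:
            raise ValueError(f"index {self.index!r} has no acceptability limit")
        return ShelfLifeSpec(
            index=self.index, order=self.order, y0=self.y0, limit=self.limit, direction=self.direction
        )


@dataclass(frozen=True)
class ProductPreset:
    """Full generating configuration for one product."""

    product: str
    indices: dict[str, IndexPreset]
    tvc_initial: float
    tvc_noise_sd: float = NOISE_SD["TVC"]

    def index_names(self) -> list[str]:
        return [*self.indices.keys(), "TVC"]


def _anchored_model(product: str, index: str, span: float, t_ref: float = -18.0) -> ArrheniusModel:
    """Arrhenius model refit from the product's shelf-life anchors."""
    sls = _SHELF_LIVES[(product, index)]
    rates = [(T, span / sl) for T, sl in zip(ISO_TEMPERATURES, sls)]
    return fit_arrhenius(rates, t_ref=t_ref, index=index)


def make_preset(product: str) -> ProductPreset:
    """Kinetic preset for ``sea_bream``, ``sea_bass`` or ``tuna``.

    TVBN and overall-acceptability rate constants (and their activation
    energies) are refit from the shelf-life anchors; taste shares the
    acceptability timescale with its own published Ea; L-value uses the
    published Ea with a figure-scale decline anchor.
    """
    if product not in PRODUCTS:
        raise ValueError(f"unknown product {product!r}; choose from {PRODUCTS}")

    tvbn_span = math.log(_TVBN_LIMIT[product] / _TVBN_INITIAL[product])
    tvbn = IndexPreset(
        index="TVBN",
        order="first",
        direction="increasing",
        y0=_TVBN_INITIAL[product],
        limit=_TVBN_LIMIT[product],
        arrhenius=_anchored_model(product, "TVBN", tvbn_span),
        noise_sd=NOISE_SD["TVBN"],
    )

    sens_span = SENSORY_INITIAL - SENSORY_LIMIT
    acc = IndexPreset(
        index="overall_acceptability",
        order="zero",
        direction="decreasing",
        y0=SENSORY_INITIAL,
        limit=SENSORY_LIMIT,
        arrhenius=_anchored_model(product, "overall_acceptability", sens_span),
        noise_sd=NOISE_SD["overall_acceptability"],
    )

    # taste: same panel timescale as overall acceptability, published Ea
    sl15 = _SHELF_LIVES[(product, "overall_acceptability")][ISO_TEMPERATURES.index(-15.0)]
    taste_model = ArrheniusModel(
        k_ref=sens_span / sl15,
        ea=_EA_PUBLISHED[(product, "taste")],
        t_ref=-15.0,
        index="taste",
    ).with_reference(-18.0)
    taste = IndexPreset(
        index="taste",
        order="zero",
        direction="decreasing",
        y0=SENSORY_INITIAL,
        limit=SENSORY_LIMIT,
        arrhenius=taste_model,
        noise_sd=NOISE_SD["taste"],
    )

    l0 = _L_INITIAL[product]
    l_model = ArrheniusModel(
        k_ref=_L_DROP / sl15,
        ea=_EA_PUBLISHED[(product, "L_value")],
        t_ref=-15.0,
        index="L_value",
    ).with_reference(-18.0)
    l_value = IndexPreset(
        index="L_value",
        order="zero",
        direction="decreasing",
        y0=l0,
        limit=l0 - _L_DROP,
        arrhenius=l_model,
        noise_sd=NOISE_SD["L_value"],
    )

    return ProductPreset(
        product=product,
        indices={
            "L_value": l_value,
            "TVBN": tvbn,
            "taste": taste,
            "overall_acceptability": acc,
        },
        tvc_initial=_TVC_INITIAL[product],
    )


@dataclass(frozen=True)
class SyntheticDataset:
    """Generated measurements plus the parameters that produced them."""

    frame: pd.DataFrame
    preset: ProductPreset
    seed: int
    design: dict = field(default_factory=dict)

    def series(self, index: str, temperature: float | None = None) -> QualitySeries:
        return series_from_measurements(self.frame, index, temperature, self.preset.product)

    def to_csv(self, path) -> None:
        self.frame.to_csv(path, index=False)

    def __len__(self) -> int:
        return len(self.frame)


def _observe(
    rng: np.random.Generator,
    truth: np.ndarray,
    index: str,
    noise_sd: float,
    n_replicates: int,
    noise_scale: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Replicate observations: truth + Gaussian noise, averaged; sensory scores
    are rounded to the panel's 0.5 granularity and clamped to [1, 9] before
    averaging."""
    reps = truth[None, :] + noise_scale * rng.normal(0.0, noise_sd, size=(n_replicates, truth.size))
    if index in ("taste", "overall_acceptability"):
        reps = np.clip(np.round(reps * 2.0) / 2.0, 1.0, 9.0)
    value = reps.mean(axis=0)
    if n_replicates > 1:
        se = reps.std(axis=0, ddof=1) / math.sqrt(n_replicates)
    else:
        se = np.zeros_like(value)
    return value, se


def _truth_isothermal(ip: IndexPreset, temperature: float, times: np.ndarray) -> np.ndarray:
    k = ip.arrhenius.rate_at(temperature)
    sgn = 1.0 if ip.direction == "increasing" else -1.0
    if ip.order == "zero":
        y = ip.y0 + sgn * k * times
    else:
        y = ip.y0 * np.exp(sgn * k * times)
    floor, ceiling = default_bounds(ip.index)
    if floor is not None:
        y = np.maximum(y, floor)
    if ceiling is not None:
        y = np.minimum(y, ceiling)
    return y


def generate_isothermal(
    preset: ProductPreset,
    temperatures=ISO_TEMPERATURES,
    n_points: int = _DEFAULT_N_POINTS,
    horizon: float | None = None,
    seed: int = 0,
    n_replicates: int = _DEFAULT_REPLICATES,
    indices: list[str] | None = None,
    noise_scale: float = 1.0,
) -> SyntheticDataset:
    """Isothermal study dataset: evenly spaced sampling of every index at every
    temperature, replicate-averaged with Gaussian noise.

    The sampling horizon per (index, temperature) defaults to that condition's
    own shelf life, capped at 420 days (the 14-month study span); TVC rides on
    the sensory horizon and stays flat.  ``noise_scale`` multiplies all noise
    SDs (0 gives the deterministic truth).
    """
    if n_points < 3:
        raise ValueError("need at least 3 sampling points")
    if n_replicates < 1:
        raise ValueError("need at least 1 replicate")
    if horizon is not None and horizon > _MAX_HORIZON:
        raise ValueError(f"horizon exceeds the {_MAX_HORIZON:.0f}-day study span")
    if indices is None:
        indices = preset.index_names()
    rng = np.random.default_rng(seed)
    rows = []
    for index in indices:
        for T in temperatures:
            if index == "TVC":
                anchor = preset.indices["overall_acceptability"]
                H = horizon or min(shelf_life_at(anchor.spec(), anchor.arrhenius, T), _MAX_HORIZON)
                times = np.linspace(0.0, H, n_points)
                truth = np.full(n_points, preset.tvc_initial)
                sd = preset.tvc_noise_sd
            else:
                ip = preset.indices[index]
                H = horizon or min(shelf_life_at(ip.spec(), ip.arrhenius, T), _MAX_HORIZON)
                times = np.linspace(0.0, H, n_points)
                truth = _truth_isothermal(ip, T, times)
                sd = ip.noise_sd
            value, se = _observe(rng, truth, index, sd, n_replicates, noise_scale)
            for t, v, s in zip(times, value, se):
                rows.append((preset.product, index, T, t, v, s))
    frame = pd.DataFrame(
        rows, columns=["product", "index", "temperature_C", "time_days", "value", "replicate_se"]
    )
    design = {
        "mode": "isothermal",
        "temperatures": tuple(temperatures),
        "n_points": n_points,
        "n_replicates": n_replicates,
        "noise_scale": noise_scale,
    }
    return SyntheticDataset(frame=frame, preset=preset, seed=seed, design=design)


def generate_dynamic(
    preset: ProductPreset,
    profile: TemperatureProfile,
    n_points: int = _DEFAULT_N_POINTS,
    seed: int = 0,
    n_replicates: int = _DEFAULT_REPLICATES,
    indices: list[str] | None = None,
    noise_scale: float = 1.0,
) -> SyntheticDataset:
    """Dataset sampled along a dynamic temperature profile.

    Truth trajectories come from stepwise integration (Method #2) of each
    index's kinetics through the profile; observations add the same replicate
    noise model as the isothermal generator.  ``temperature_C`` is left empty
    (the storage condition is the profile, not a single temperature).
    """
    if n_points < 3:
        raise ValueError("need at least 3 sampling points")
    if indices is None:
        indices = preset.index_names()
    rng = np.random.default_rng(seed)
    times = np.linspace(0.0, profile.total_duration, n_points)
    rows = []
    for index in indices:
        if index == "TVC":
            truth = np.full(n_points, preset.tvc_initial)
            sd = preset.tvc_noise_sd
        else:
            ip = preset.indices[index]
            floor, ceiling = default_bounds(index)
            truth = predict_method2(
                ip.arrhenius,
                profile,
                order=ip.order,
                y0=ip.y0,
                at_times=times,
                direction=ip.direction,
                floor=floor,
                ceiling=ceiling,
                index=index,
            ).values
            sd = ip.noise_sd
        value, se = _observe(rng, truth, index, sd, n_replicates, noise_scale)
        for t, v, s in zip(times, value, se):
            rows.append((preset.product, index, np.nan, t, v, s))
    frame = pd.DataFrame(
        rows, columns=["product", "index", "temperature_C", "time_days", "value", "replicate_se"]
    )
    design = {
        "mode": "dynamic",
        "profile_duration": profile.total_duration,
        "n_points": n_points,
        "n_replicates": n_replicates,
        "noise_scale": noise_scale,
    }
    return SyntheticDataset(frame=frame, preset=preset, seed=seed, design=design)
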