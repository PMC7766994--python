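"""Agreement between predicted and observed quality values.

The accuracy factor Af = 10^(mean |log10(pred/obs)|) measures average absolute
multiplicative disagreement; the bias factor Bf = 10^(mean log10(pred/obs))
measures its signed direction.  Perfect agreement gives Af = Bf = 1.  The
per-observation relative error RE = (obs − pred)/pred is screened against the
acceptable prediction zone −0.3 < RE < 0.15, and Bf against the fail-safe /
fail-dangerous boundaries 0.7 and 1.15 used in predictive microbiology.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

__all__ = [
    "RE_ACCEPTABLE_ZONE",
    "BF_FAIL_SAFE",
    "BF_FAIL_DANGEROUS",
    "accuracy_bias",
    "relative_errors",
    "in_acceptable_zone",
    "classify_bias",
    "ValidationReport",
    "validate_predictions",
    "classify",
]

#: Open interval of acceptable relative errors (observed vs predicted).
RE_ACCEPTABLE_ZONE = (-0.3, 0.15)
BF_FAIL_SAFE = 0.7
BF_FAIL_DANGEROUS = 1.15


def _positive_pair(predicted, observed) -> tuple[np.ndarray, np.ndarray]:
    pred = np.asarray(predicted, dtype=float)
    obs = np.asarray(observed, dtype=float)
    if pred.shape != obs.shape or pred.ndim != 1:
        raise ValueError("predicted and observed must be 1-D arrays of equal length")
    if pred.size < 1:
        raise ValueError("need at least one prediction/observation pair")
    if np.any(pred <= 0) or np.any(obs <= 0):
        raise ValueError("accuracy/bias factors require strictly positive values")
    return pred, obs


def accuracy_bias(predicted, observed) -> tuple[float, float]:
    """Accuracy and bias factors (Af, Bf) with base-10 logarithms."""
    pred, obs = _positive_pair(predicted, observed)
    logs = np.log10(pred / obs)
    return float(10 ** np.mean(np.abs(logs))), float(10 ** np.mean(logs))


def relative_errors(predicted, observed) -> np.ndarray:
    """Per-observation relative error (observed − predicted)/predicted."""
    pred = np.asarray(predicted, dtype=float)
    obs = np.asarray(observed, dtype=float)
    if pred.shape != obs.shape or pred.ndim != 1:
        raise ValueError("predicted and observed must be 1-D arrays of equal length")
    if np.any(pred == 0):
        raise ValueError("relative error undefined for zero predictions")
    return (obs - pred) / pred


def in_acceptable_zone(re) -> np.ndarray:
    """Strict-inequality screen of RE against the acceptable prediction zone."""
    re = np.asarray(re, dtype=float)
    lo, hi = RE_ACCEPTABLE_ZONE
    return (re > lo) & (re < hi)


def classify_bias(bf: float) -> str:
    """fail-safe (Bf < 0.7), fail-dangerous (Bf > 1.15) or acceptable.

    Boundaries are inclusive on the acceptable side ("within the boundaries").
    """
    if bf < BF_FAIL_SAFE:
        return "fail-safe"
    if bf > BF_FAIL_DANGEROUS:
        return "fail-dangerous"
    return "acceptable"


@dataclass(frozen=True)
class ValidationReport:
    """Af/Bf/RE agreement report for one index and prediction method."""

    af: float
    bf: float
    re: np.ndarray
    n: int
    in_zone: np.ndarray
    bias_class: str
    index: str | None = None

    def __post_init__(self) -> None:
        if self.af < 1.0 - 1e-12:
            raise ValueError("accuracy factor cannot be below 1")
        if self.bf <= 0:
            raise ValueError("bias factor must be positive")
        if self.n < 1:
            raise ValueError("report needs at least one observation")

    @property
    def all_in_zone(self) -> bool:
        return bool(np.all(self.in_zone))

    @property
    def re_min(self) -> float:
        return float(np.min(self.re))

    @property
    def re_max(self) -> float:
        return float(np.max(self.re))

    def to_dict(self) -> dict:
        return {
            "index": self.index,
            "n": self.n,
            "af": self.af,
            "bf": self.bf,
            "re_min": self.re_min,
            "re_max": self.re_max,
            "all_in_zone": self.all_in_zone,
            "bias_class": self.bias_class,
        }

    def summary(self) -> str:
        return (
            f"validation ({self.index or '-'}, n={self.n}): "
            f"Af={self.af:.4f}, Bf={self.bf:.4f} [{self.bias_class}], "
            f"RE {self.re_min:+.3f} to {self.re_max:+.3f}"
            f" ({'all' if self.all_in_zone else 'NOT all'} in zone)"
        )


def validate_predictions(predicted, observed, index: str | None = None) -> ValidationReport:
    """Full Af/Bf/RE report, zone flags and bias classification in one call."""
    af, bf = accuracy_bias(predicted, observed)
    re = relative_errors(predicted, observed)
    return ValidationReport(
        af=af,
        bf=bf,
        re=re,
        n=re.size,
        in_zone=in_acceptable_zone(re),
        bias_class=classify_bias(bf),
        index=index,
    )


def classify(report: ValidationReport) -> ValidationReport:
    """Re-derive zone flags and bias classification from the report's numbers."""
    return replace(report, in_zone=in_acceptable_zone(report.re), bias_class=classify_bias(report.bf))
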