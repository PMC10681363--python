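"""Gaussian-noise false-positive model for matched-filter thresholds.

A whitened, calibrated matched-filter score at a pure-noise search location
is standard normal, so the probability that it exceeds a threshold t is the
upper Gaussian tail

    r_f(t) = 1/2 erfc(t / sqrt(2)).

Multiplying by the number of independent search locations (pixels x
orientations x defocus planes) gives the expected number of false
positives, and inverting the relation gives the detection threshold that
admits a chosen number of false positives — the standard practice is one
per micrograph.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from scipy.special import erfc, erfcinv, erfcx

__all__ = [
    "ThresholdReport",
    "false_positive_rate",
    "log10_false_positive_rate",
    "expected_false_positives",
    "threshold_for_expected_count",
    "threshold_report",
]

_SQRT2 = math.sqrt(2.0)


@dataclass
class ThresholdReport:
    snr_threshold: float
    n_locations: float
    false_positive_rate: float
    expected_false_positives: float

    def __str__(self) -> str:
        return (
            f"snr_threshold: {self.snr_threshold:.4f}\n"
            f"n_locations: {self.n_locations:.6g}\n"
            f"false_positive_rate: {self.false_positive_rate:.6e}\n"
            f"expected_false_positives: {self.expected_false_positives:.6g}"
        )


def false_positive_rate(snr_t: float) -> float:
    """Probability that a standard-normal noise score exceeds ``snr_t``."""
    if not math.isfinite(snr_t):
        raise ValueError("snr_t must be finite")
    return 0.5 * erfc(snr_t / _SQRT2)


def log10_false_positive_rate(snr_t: float) -> float:
    """log10 of the false-positive rate, stable far into the tail.

    Uses the scaled complementary error function so thresholds beyond the
    double-precision underflow point (~ t = 38) remain representable.
    """
    if not math.isfinite(snr_t):
        raise ValueError("snr_t must be finite")
    x = snr_t / _SQRT2
    if x < 0:
        return math.log10(false_positive_rate(snr_t))
    # erfc(x) = erfcx(x) exp(-x^2)
    return math.log10(0.5 * erfcx(x)) - x * x / math.log(10.0)


def expected_false_positives(snr_t: float, n_locations: float) -> float:
    """Expected number of noise locations exceeding the threshold."""
    if n_locations < 0:
        raise ValueError("n_locations must be >= 0")
    return false_positive_rate(snr_t) * n_locations


def threshold_for_expected_count(n_locations: float, n_expected: float = 1.0) -> float:
    """Threshold admitting ``n_expected`` false positives over ``n_locations``.

    Solves r_f(t) * n_locations = n_expected exactly via the inverse
    complementary error function.  Thresholds below zero (more than half of
    all locations expected to exceed) are outside the model's range.
    """
    if n_locations < 1:
        raise ValueError("n_locations must be >= 1")
    if not 0 < n_expected < n_locations:
        raise ValueError("need 0 < n_expected < n_locations")
    p = n_expected / n_locations
    if p > 0.5:
        raise ValueError(
            "n_expected exceeds half the search locations; threshold would be "
            "negative (outside the Gaussian tail model)"
        )
    return _SQRT2 * float(erfcinv(2.0 * p))


def threshold_report(n_locations: float, n_expected: float = 1.0) -> ThresholdReport:
    t = threshold_for_expected_count(n_locations, n_expected)
    r = false_positive_rate(t)
    return ThresholdReport(
        snr_threshold=t,
        n_locations=n_locations,
        false_positive_rate=r,
        expected_false_positives=r * n_locations,
    )
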