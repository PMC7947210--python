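"""Standard-curve fitting and Ct-to-amount conversion.

Two calibrations drive quantification:

* a **standard curve** per channel, ``Ct = slope * log10(amount) + intercept``,
  fitted by ordinary least squares to a dilution series of known amounts;
* a **C-T transform**, ``Ct_C_equiv = alpha * Ct_T + beta``, fitted across
  dilutions of a synthetic indicator oligo carrying a degenerate Y (C/T) base
  at the probe's discrimination site. The converted (thymine) allele has no
  standard of its own, so its Ct is first mapped onto the cytosine channel's
  Ct scale and then read off the cytosine standard curve.

A transform with R-squared below 0.99 marks the whole run as unreliable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from .plate import Channel

__all__ = [
    "StandardCurve",
    "CtTransform",
    "Amount",
    "InsufficientStandardsError",
    "InvalidCurveError",
    "IndicatorError",
    "fit_standard_curve",
    "fit_ct_transform",
    "quantify",
    "quantify_short_t",
    "TRANSFORM_R2_MIN",
    "FLAG_NO_SIGNAL",
]

#: minimum transform R-squared for a run to count as reliable
TRANSFORM_R2_MIN = 0.99

FLAG_NO_SIGNAL = "NO_SIGNAL"


class InsufficientStandardsError(ValueError):
    """Fewer than three distinct standard amounts supplied."""


class InvalidCurveError(ValueError):
    """Fitted slope is not negative; more template must not raise Ct."""


class IndicatorError(ValueError):
    """An indicator dilution is unusable (undetermined Ct)."""


@dataclass(frozen=True)
class StandardCurve:
    """OLS fit of Ct on log10(amount) for one channel's dilution series.

    ``pcr_efficiency`` is the per-cycle amplification gain minus one,
    ``10**(-1/slope) - 1`` (1.0 for perfect doubling, slope -3.3219).
    Amount units follow the calibrator: ng for the genomic standard,
    copies for synthetic oligos; never mix curves across units.
    """

    channel: Channel
    slope: float
    intercept: float
    r_squared: float
    pcr_efficiency: float
    n_points: int = 0

    def predict_ct(self, amount: float) -> float:
        return self.slope * math.log10(amount) + self.intercept

    def to_dict(self) -> dict:
        return {
            "channel": self.channel.value,
            "slope": self.slope,
            "intercept": self.intercept,
            "r_squared": self.r_squared,
            "pcr_efficiency": self.pcr_efficiency,
            "n_points": self.n_points,
        }


@dataclass(frozen=True)
class CtTransform:
    """Linear map from a short-T Ct to its short-C-equivalent Ct."""

    alpha: float
    beta: float
    r_squared: float
    n_points: int = 0

    @property
    def reliable(self) -> bool:
        return self.r_squared >= TRANSFORM_R2_MIN

    def apply(self, ct_t: float) -> float:
        return self.alpha * ct_t + self.beta

    def to_dict(self) -> dict:
        return {
            "alpha": self.alpha,
            "beta": self.beta,
            "r_squared": self.r_squared,
            "reliable": self.reliable,
            "n_points": self.n_points,
        }


@dataclass(frozen=True)
class Amount:
    """A quantified template amount per 1-ul reaction.

    Zero with a ``NO_SIGNAL`` flag encodes an undetermined Ct.
    """

    value: float
    flags: frozenset[str] = frozenset()


def _ols(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """Least-squares slope, intercept and R-squared of y on x."""
    res = stats.linregress(x, y)
    return float(res.slope), float(res.intercept), float(res.rvalue**2)


def fit_standard_curve(
    points: Iterable[tuple[float, float]], channel: Channel
) -> StandardCurve:
    """Fit a standard curve from ``(known_amount, ct)`` pairs.

    Requires at least three distinct positive amounts, all Cts numeric.
    Raises :class:`InvalidCurveError` if the fitted slope is >= 0.
    """
    pts = [(float(a), float(c)) for a, c in points]
    if any(a <= 0 for a, _ in pts):
        raise ValueError("standard amounts must be positive")
    if any(not math.isfinite(c) for _, c in pts):
        raise ValueError("all standard Cts must be numeric")
    if len({a for a, _ in pts}) < 3:
        raise InsufficientStandardsError(
            f"need >=3 distinct standard amounts, got {len({a for a, _ in pts})}"
        )
    x = np.log10([a for a, _ in pts])
    y = np.array([c for _, c in pts])
    slope, intercept, r2 = _ols(x, y)
    if slope >= 0:
        raise InvalidCurveError(f"standard-curve slope {slope:.4f} is not negative")
    efficiency = 10.0 ** (-1.0 / slope) - 1.0
    return StandardCurve(
        channel=channel,
        slope=slope,
        intercept=intercept,
        r_squared=r2,
        pcr_efficiency=efficiency,
        n_points=len(pts),
    )


def fit_ct_transform(
    indicator_wells: Iterable[tuple[float, float | None, float | None]],
) -> CtTransform:
    """Fit the short-T -> short-C Ct transform from indicator dilutions.

    ``indicator_wells`` yields ``(copies_per_ul, ct_short_c, ct_short_t)``;
    the nominal design uses four ten-fold dilutions (1e6 .. 1e3 copies/ul).
    The C-channel Ct is regressed on the T-channel Ct -- this direction is
    deliberate (the transform consumes short-T Cts) and differs from the
    inverse fit under noise. An undetermined Ct at any dilution is an error
    naming that dilution: the calibrator must amplify everywhere.
    """
    pts: list[tuple[float, float]] = []
    for copies, ct_c, ct_t in indicator_wells:
        if ct_c is None or ct_t is None:
            raise IndicatorError(
                f"indicator dilution {copies:g} copies/ul has an undetermined Ct"
            )
        pts.append((float(ct_t), float(ct_c)))
    if len(pts) < 2:
        raise IndicatorError("need >=2 indicator dilutions with both channels numeric")
    x = np.array([t for t, _ in pts])
    y = np.array([c for _, c in pts])
    if np.ptp(x) == 0:
        raise IndicatorError("indicator short-T Cts are all identical; cannot fit")
    alpha, beta, r2 = _ols(x, y)
    return CtTransform(alpha=alpha, beta=beta, r_squared=r2, n_points=len(pts))


def quantify(ct: float | None, curve: StandardCurve) -> Amount:
    """Convert a Ct to an amount via ``amount = 10**((ct - intercept)/slope)``.

    An undetermined Ct quantifies to zero with a ``NO_SIGNAL`` flag.
    """
    if ct is None:
        return Amount(0.0, frozenset({FLAG_NO_SIGNAL}))
    return Amount(10.0 ** ((ct - curve.intercept) / curve.slope))


def quantify_short_t(
    ct_t: float | None, transform: CtTransform, short_c_curve: StandardCurve
) -> Amount:
    """Quantify a converted-allele Ct through the transform and the C curve."""
    if ct_t is None:
        return Amount(0.0, frozenset({FLAG_NO_SIGNAL}))
    return quantify(transform.apply(ct_t), short_c_curve)
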