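"""Hearing-capability estimation from inner-ear duct length.

In extant reptiles and birds, the length of the endocochlear duct (or, where
no discrete duct exists, the pars inferior of the labyrinth) predicts both
the mean best hearing frequency and the width of the best hearing range.
Duct length is scaled by basicranium length to remove skull-size effects and
log-transformed; ordinary least squares then gives a linear predictor in Hz
per log-unit.  Applying the fitted (or published) coefficients to a fossil's
scaled duct length yields its estimated hearing capability, summarized as a
symmetric frequency interval around the best frequency.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from otomorph.types import EstimationError, ValidationError


@dataclass(frozen=True)
class SpecimenMeasurements:
    """Linear measurements (mm) entering the hearing predictor."""

    pars_inferior_length: float
    basicranium_length: float

    def __post_init__(self) -> None:
        if self.pars_inferior_length <= 0 or self.basicranium_length <= 0:
            raise ValidationError("both measurements must be positive")


@dataclass(frozen=True)
class HearingModel:
    """OLS line relating scaled log duct length x to a hearing response (Hz)."""

    response: str  # "mean_best_frequency" or "best_range"
    slope: float
    intercept: float
    r_squared: Optional[float] = None
    p_value: Optional[float] = None
    n: Optional[int] = None


@dataclass(frozen=True)
class HearingPrediction:
    best_frequency: float
    best_range_width: float

    @property
    def range_low(self) -> float:
        return self.best_frequency - self.best_range_width / 2.0

    @property
    def range_high(self) -> float:
        return self.best_frequency + self.best_range_width / 2.0


def scale_and_transform(m: SpecimenMeasurements, log_base: float = 10.0) -> float:
    """Scaled, log-transformed duct length: log(pars inferior / basicranium).

    The ratio removes skull size; the log (base 10 by default) normalizes the
    strongly right-skewed length distribution.
    """
    return math.log(m.pars_inferior_length / m.basicranium_length, log_base)


def fit_hearing_model(
    x: Sequence[float],
    y: Sequence[float],
    response: str = "mean_best_frequency",
) -> HearingModel:
    """Ordinary least squares of a hearing response on scaled log duct length.

    Rows with a missing predictor or response (NaN) are dropped before
    fitting, mirroring the exclusion of reference taxa without duct-length
    data.  The p-value is the F-test (equivalently two-sided t-test) on the
    slope.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    keep = ~(np.isnan(x) | np.isnan(y))
    x, y = x[keep], y[keep]
    n = len(x)
    if n < 3:
        raise EstimationError("need at least 3 complete observations")
    if np.ptp(x) == 0:
        raise EstimationError("predictor is constant; slope undefined")
    xm, ym = x.mean(), y.mean()
    sxx = np.sum((x - xm) ** 2)
    sxy = np.sum((x - xm) * (y - ym))
    slope = sxy / sxx
    intercept = ym - slope * xm
    resid = y - (intercept + slope * x)
    ss_res = float(np.sum(resid**2))
    ss_tot = float(np.sum((y - ym) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    if ss_res <= 0:
        p = 0.0
    else:
        f = (ss_tot - ss_res) / (ss_res / (n - 2))
        p = float(stats.f.sf(f, 1, n - 2))
    return HearingModel(
        response=response, slope=float(slope), intercept=float(intercept),
        r_squared=float(r2), p_value=p, n=n,
    )


def predict(model: HearingModel, x: float) -> float:
    """Evaluate the fitted line at a scaled log duct length."""
    return model.slope * x + model.intercept


def round_hz(value: float, decimals: int = 1) -> float:
    """Round a frequency for reporting, half away from zero at 0.1 Hz.

    Binary floating point under-represents values like 330.55, so the value
    is first snapped to 6 decimals before decimal half-up rounding; this
    matches how the reported quantities print.
    """
    from decimal import ROUND_HALF_UP, Decimal

    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(str(round(value, 6))).quantize(q, rounding=ROUND_HALF_UP))


def summarize(best_frequency: float, best_range_width: float) -> HearingPrediction:
    """Combine the two predictions into a symmetric overall hearing interval."""
    if best_range_width < 0:
        raise ValidationError("best hearing range width must be nonnegative")
    return HearingPrediction(
        best_frequency=float(best_frequency),
        best_range_width=float(best_range_width),
    )
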