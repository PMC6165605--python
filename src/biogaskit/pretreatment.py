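"""Combined severity scoring of thermal pretreatment conditions.

The severity factor (log R0) collapses pretreatment temperature and holding
time into a single logarithmic score,

    log R0 = log( t * exp((T - 100) / w) ),

with t the holding time, T the temperature in Celsius and w = 14.75 an
empirical activation parameter (Overend-Chornet convention: base-10 log,
time in minutes, reference temperature 100 degC).  Doubling the holding time
at fixed temperature raises the base-10 score by exactly log10(2) ~ 0.301.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = ["SEVERITY_W", "PretreatmentCondition", "severity_factor"]

#: Empirical severity parameter w (dimensionless temperature scale).
SEVERITY_W = 14.75


@dataclass(frozen=True)
class PretreatmentCondition:
    """A thermal pretreatment: label, temperature (degC), duration (min)."""

    label: str
    temperature_c: float
    duration_min: float

    def __post_init__(self) -> None:
        if self.duration_min < 0:
            raise ValueError("duration must be non-negative")
        if not math.isfinite(self.temperature_c):
            raise ValueError("temperature must be finite")

    @property
    def severity(self) -> float:
        return severity_factor(self.temperature_c, self.duration_min)


def severity_factor(
    temperature_c: float,
    duration_min: float,
    w: float = SEVERITY_W,
    log_base: float = 10.0,
    time_unit: str = "minutes",
) -> float:
    """Combined severity (log R0) of a thermal pretreatment.

    Parameters
    ----------
    temperature_c, duration_min
        Holding temperature (degC) and time (minutes).
    w
        Empirical temperature-scale parameter; must be positive.
    log_base
        Base of the final logarithm; 10 (default) or ``math.e``.
    time_unit
        Unit in which the duration enters R0: ``"minutes"`` (default,
        standard convention) or ``"seconds"``.

    An untreated condition (duration 0) is scored 0 by convention rather
    than evaluating the (divergent) logarithm.
    """
    if w <= 0:
        raise ValueError("severity parameter w must be positive")
    if duration_min < 0:
        raise ValueError("duration must be non-negative")
    if time_unit not in ("minutes", "seconds"):
        raise ValueError("time_unit must be 'minutes' or 'seconds'")
    if duration_min == 0:
        return 0.0
    t = duration_min * (60.0 if time_unit == "seconds" else 1.0)
    r0 = t * math.exp((temperature_c - 100.0) / w)
    return math.log(r0) / math.log(log_base)
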