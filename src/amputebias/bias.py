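"""Bias and dispersion metrics for available-data versus complete-data fits."""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .errors import ParameterError, UndefinedBiasError

__all__ = ["bias_percent", "dispersion_summary", "change_rate", "BiasSummary"]


def bias_percent(theta_available: float, theta_complete: float) -> float:
    """Percentage bias of an available-data estimate against its complete-data value.

    ``100 * (theta_available - theta_complete) / theta_complete``; undefined
    (raises) when the complete-data reference is zero.
    """
    if theta_complete == 0:
        raise UndefinedBiasError("complete-data reference value is zero")
    return 100.0 * (theta_available - theta_complete) / theta_complete


def dispersion_summary(values) -> tuple[float, float, float]:
    """Mean, sample SD (n-1) and coefficient of variation of a value set.

    The demonstration applies this across the loss rates of one mechanism to
    summarize how unstable a statistic is. CV = SD/M; NaN (flagged undefined)
    when the mean is zero.
    """
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ParameterError("dispersion_summary needs at least two values")
    m = float(v.mean())
    sd = float(v.std(ddof=1))
    cv = math.nan if m == 0 else sd / m
    return m, sd, cv


def change_rate(
    group_mean_change: float, group_mean_baseline: float, improvement: str = "lower"
) -> float:
    """A group's mean change as a percentage of its baseline level (ChR).

    Sign-adjusted so that a positive rate always means clinical improvement:
    for outcomes where lower is better a change of -4.38 on a baseline of 10
    is a +43.8% improvement.
    """
    if group_mean_baseline == 0:
        raise UndefinedBiasError("zero baseline mean: change rate undefined")
    if improvement not in ("lower", "higher"):
        raise ParameterError("improvement must be 'lower' or 'higher'")
    raw = 100.0 * group_mean_change / group_mean_baseline
    return -raw if improvement == "lower" else raw


@dataclass
class BiasSummary:
    """Per-rate bias of one statistic under one mechanism, with dispersion.

    ``per_rate_bias_percent`` maps loss rate -> mean percentage bias across
    replicates; M/SD/CV summarize the statistic's mean empirical values over
    the set of loss rates. ``cv_defined`` is False when M = 0.
    """

    statistic: str
    mechanism_id: str
    effect: str
    per_rate_bias_percent: dict = field(default_factory=dict)
    per_rate_value: dict = field(default_factory=dict)
    mean_across_rates: float = math.nan
    sd_across_rates: float = math.nan
    cv_across_rates: float = math.nan

    @property
    def cv_defined(self) -> bool:
        return not math.isnan(self.cv_across_rates)

    @classmethod
    def from_values(cls, statistic, mechanism_id, effect, per_rate_value, per_rate_bias):
        m, sd, cv = dispersion_summary(list(per_rate_value.values()))
        return cls(
            statistic=statistic,
            mechanism_id=mechanism_id,
            effect=effect,
            per_rate_bias_percent=dict(per_rate_bias),
            per_rate_value=dict(per_rate_value),
            mean_across_rates=m,
            sd_across_rates=sd,
            cv_across_rates=cv,
        )
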