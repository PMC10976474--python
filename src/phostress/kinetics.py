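"""Infection-kinetics calls: lysis timing, DNA replication rate, t-tests.

A one-step growth assay tracks OD750 of infected and uninfected cultures on
a common time grid; lysis shows as the infected curve dropping away from the
control.  The delayed-lysis phenotype is a strictly-more-than-2-hour shift
of the phosphate-deplete lysis time relative to the replete one.  Phage DNA
replication rate is the ordinary least-squares slope of intracellular phage
DNA (percent of the initial amount, from qPCR) over a fixed early window,
2–6 h post-infection by default, boundaries included.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .exceptions import (
    DegenerateInputError,
    DesignError,
    FormatError,
    InsufficientDataError,
)

DEFAULT_DROP_FRACTION = 0.25
DEFAULT_DELAY_THRESHOLD = 2.0
DEFAULT_RATE_WINDOW = (2.0, 6.0)


@dataclass(frozen=True)
class GrowthCurve:
    """An OD750 time series for one replicate/condition."""

    replicate: str
    condition: str
    infected: bool
    times: tuple[float, ...]
    od: tuple[float, ...]

    def __post_init__(self) -> None:
        t = np.asarray(self.times)
        if len(t) != len(self.od) or len(t) < 2:
            raise FormatError("curve needs matching times and >= 2 samples")
        if (np.diff(t) <= 0).any():
            raise FormatError("times must be strictly increasing")


@dataclass(frozen=True)
class QPCRSeries:
    """Intracellular phage DNA as percent of the initial amount over time."""

    replicate: str
    condition: str
    times: tuple[float, ...]
    percent: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.times) != len(self.percent) or len(self.times) < 2:
            raise FormatError("series needs matching times and >= 2 samples")


@dataclass(frozen=True)
class LysisCall:
    """Called lysis times for the two conditions and the delay phenotype."""

    lysis_time_replete: float
    lysis_time_deplete: float | None
    delay: float
    delayed: bool
    threshold_used: float
    censored: bool = False


@dataclass(frozen=True)
class RateComparison:
    """Pooled two-sample t comparison of per-replicate replication slopes."""

    mean_a: float
    mean_b: float
    t: float
    df: int
    p: float


def call_lysis_time(
    infected: GrowthCurve,
    control: GrowthCurve,
    drop_fraction: float = DEFAULT_DROP_FRACTION,
) -> float | None:
    """Earliest grid time at which infected OD <= (1−f)·control OD.

    Returns None if the infected curve never departs from the control by the
    required fraction.  Both curves must share the time grid and the control
    must stay positive.
    """
    if not 0 < drop_fraction < 1:
        raise DesignError("drop_fraction must lie in (0, 1)")
    t_i, t_c = np.asarray(infected.times), np.asarray(control.times)
    if t_i.shape != t_c.shape or not np.allclose(t_i, t_c):
        raise FormatError("infected and control curves are on different time grids")
    od_i, od_c = np.asarray(infected.od), np.asarray(control.od)
    if (od_c <= 0).any():
        raise FormatError("control OD must be positive at all times")
    lysed = od_i <= (1.0 - drop_fraction) * od_c
    idx = np.flatnonzero(lysed)
    return float(t_i[idx[0]]) if idx.size else None


def lysis_delay(
    replete: tuple[GrowthCurve, GrowthCurve],
    deplete: tuple[GrowthCurve, GrowthCurve],
    threshold: float = DEFAULT_DELAY_THRESHOLD,
    drop_fraction: float = DEFAULT_DROP_FRACTION,
) -> LysisCall:
    """Call the delayed-lysis phenotype from (infected, control) curve pairs.

    ``delayed`` requires the deplete lysis time to exceed the replete one by
    strictly more than ``threshold`` hours.  A deplete culture that never
    lyses within the horizon is reported as delayed and censored, with the
    delay measured to the end of the horizon.
    """
    t_plus = call_lysis_time(*replete, drop_fraction)
    if t_plus is None:
        raise DegenerateInputError("no lysis called under replete conditions")
    t_minus = call_lysis_time(*deplete, drop_fraction)
    if t_minus is None:
        horizon = float(deplete[0].times[-1])
        delay = horizon - t_plus
        return LysisCall(t_plus, None, delay, delay > threshold, threshold, True)
    delay = t_minus - t_plus
    return LysisCall(t_plus, t_minus, delay, delay > threshold, threshold)


def replication_rate(
    series: QPCRSeries,
    window: tuple[float, float] = DEFAULT_RATE_WINDOW,
) -> float:
    """OLS slope (percent per hour) of a qPCR series inside a closed window."""
    t = np.asarray(series.times, dtype=float)
    y = np.asarray(series.percent, dtype=float)
    mask = (t >= window[0]) & (t <= window[1])
    if mask.sum() < 2:
        raise InsufficientDataError(
            f"only {int(mask.sum())} points inside window {window}; need >= 2"
        )
    slope, _ = np.polyfit(t[mask], y[mask], 1)
    return float(slope)


def two_sample_t(a, b) -> RateComparison:
    """Pooled-variance two-sample t test, two-sided.

    df = n1 + n2 − 2.  Raises on groups smaller than 2 or zero pooled
    variance.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise DesignError("both groups need >= 2 observations")
    n1, n2 = len(a), len(b)
    pooled = ((n1 - 1) * a.var(ddof=1) + (n2 - 1) * b.var(ddof=1)) / (n1 + n2 - 2)
    if pooled == 0:
        raise DegenerateInputError("zero pooled variance")
    t_stat, p = stats.ttest_ind(a, b, equal_var=True)
    return RateComparison(
        mean_a=float(a.mean()),
        mean_b=float(b.mean()),
        t=float(t_stat),
        df=n1 + n2 - 2,
        p=float(p),
    )
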