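"""Sulfite-resistance phenotyping from plate-reader growth curves.

The resistance phenotype is the sulfite-dependent delay in growth: the
difference between the time at which the maximum growth rate is reached
in a sulfite-treated culture and in a water-treated control of the same
strain on the same day.  The maximum-growth-rate time is the peak of the
smoothed derivative of log(OD); for a logistic curve this is the
inflection point, so the statistic is invariant to affine rescaling of
OD and equivariant under time shifts.

Day-to-day variation is removed by a per-day Z-score transformation
before modeling.  Group comparisons use the Kruskal-Wallis test and
pairwise Wilcoxon rank-sum tests with Bonferroni correction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "GrowthCurve",
    "DelayPhenotype",
    "NonGrowerError",
    "max_growth_rate_time",
    "sulfite_delay",
    "zscore_by_day",
    "kruskal_wallis",
    "wilcoxon_bonferroni",
    "delays_from_table",
]


class NonGrowerError(ValueError):
    """Raised when a culture shows no appreciable growth (the delay
    statistic is undefined; some species grow in water but not sulfite)."""


@dataclass(frozen=True)
class GrowthCurve:
    """One well's OD time series. Times in hours, strictly increasing."""

    times: np.ndarray
    od: np.ndarray
    label: str = ""

    def __post_init__(self):
        t = np.asarray(self.times, dtype=float)
        od = np.asarray(self.od, dtype=float)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "od", od)
        if t.size != od.size:
            raise ValueError("times and od must have equal length")
        if np.any(np.diff(t) <= 0):
            raise ValueError("time vector must be strictly increasing")
        if np.any(od < 0):
            raise ValueError("OD readings must be non-negative")


@dataclass(frozen=True)
class DelayPhenotype:
    construct: str
    delay_hours: float
    day: str = ""
    batch: str = ""
    reason: str | None = None  # set when the delay is missing

    @property
    def missing(self) -> bool:
        return self.reason is not None


def max_growth_rate_time(
    curve: GrowthCurve,
    smooth_window: int = 5,
    rate_smooth_window: int = 9,
    min_log_increase: float = np.log(2.0),
) -> float:
    """Time (hours) of the maximum smoothed derivative of log(OD).

    log-OD is smoothed with a centered moving average of ``smooth_window``
    points (odd, >= 3); the derivative is taken by central differences
    spanning the smoothing half-width (the differencing step matches the
    smoothing scale instead of amplifying point-to-point noise); the rate
    series is then smoothed again with a ``rate_smooth_window`` moving
    average before the peak is located.  All windows are symmetric, so
    the landmark is exact on noiseless curves and equivariant under time
    shifts.  Ties break to the earliest time.  A curve whose total log-OD
    increase is below ``min_log_increase`` (default: one doubling) raises
    :class:`NonGrowerError`.
    """
    for w in (smooth_window, rate_smooth_window):
        if w < 3 or w % 2 == 0:
            raise ValueError("smoothing windows must be odd and >= 3")
    if curve.times.size < 10:
        raise ValueError("at least 10 points required for rate estimation")
    if np.any(curve.od <= 0):
        raise ValueError("OD must be positive where the log is taken")
    log_od = np.log(curve.od)
    smoothed = _moving_average(log_od, smooth_window)
    half = smooth_window // 2
    times = curve.times[half : curve.times.size - half]
    if smoothed[-1] - smoothed[0] < min_log_increase:
        raise NonGrowerError(f"no growth detected for {curve.label or 'curve'}")
    h = max(half, 1)
    rate = (smoothed[2 * h :] - smoothed[: -2 * h]) / (times[2 * h :] - times[: -2 * h])
    rate_times = times[h:-h]
    if rate.size < rate_smooth_window:
        raise ValueError("curve too short for the smoothing windows")
    rate = _moving_average(rate, rate_smooth_window)
    rate_times = rate_times[rate_smooth_window // 2 : rate_times.size - rate_smooth_window // 2]
    best = int(np.argmax(rate))  # argmax returns the first (earliest) maximum
    return float(rate_times[best])


def _moving_average(x: np.ndarray, window: int) -> np.ndarray:
    kernel = np.full(window, 1.0 / window)
    return np.convolve(x, kernel, mode="valid")


def sulfite_delay(
    sulfite: GrowthCurve,
    control: GrowthCurve,
    construct: str = "",
    day: str = "",
    batch: str = "",
    smooth_window: int = 5,
) -> DelayPhenotype:
    """Sulfite-dependent growth delay: t_max-rate(sulfite) - t_max-rate(control).

    A negative delay (sulfite culture peaking earlier) is allowed.  If
    either culture fails to grow the phenotype is returned as missing with
    reason ``"control_failed"`` or ``"sulfite_failed"``.
    """
    try:
        t_control = max_growth_rate_time(control, smooth_window)
    except NonGrowerError:
        return DelayPhenotype(construct, float("nan"), day, batch, "control_failed")
    try:
        t_sulfite = max_growth_rate_time(sulfite, smooth_window)
    except NonGrowerError:
        return DelayPhenotype(construct, float("nan"), day, batch, "sulfite_failed")
    return DelayPhenotype(construct, t_sulfite - t_control, day, batch)


def delays_from_table(table: pd.DataFrame, smooth_window: int = 5) -> pd.DataFrame:
    """Compute delays from a long-format table.

    Expected columns: strain, treatment ('control'|'sulfite'), day, batch,
    time_h, od.  One delay row per (strain, day, batch) pair of curves.
    """
    required = {"strain", "treatment", "day", "batch", "time_h", "od"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"missing columns: {sorted(missing)}")
    rows = []
    for (strain, day, batch), grp in table.groupby(["strain", "day", "batch"]):
        curves = {}
        for treatment, sub in grp.groupby("treatment"):
            sub = sub.sort_values("time_h")
            curves[treatment] = GrowthCurve(
                sub["time_h"].to_numpy(), sub["od"].to_numpy(),
                label=f"{strain}:{treatment}",
            )
        if set(curves) != {"control", "sulfite"}:
            raise ValueError(f"{strain}/{day}/{batch}: need control and sulfite curves")
        ph = sulfite_delay(
            curves["sulfite"], curves["control"],
            construct=strain, day=str(day), batch=str(batch),
            smooth_window=smooth_window,
        )
        rows.append(
            {"construct": ph.construct, "day": ph.day, "batch": ph.batch,
             "delay_hours": ph.delay_hours, "reason": ph.reason}
        )
    return pd.DataFrame(rows)


def zscore_by_day(values: pd.Series, days: pd.Series) -> pd.Series:
    """Standardize measurements within each day to mean 0, sd 1.

    Uses the sample standard deviation (n-1).  A day with fewer than two
    values or zero variance is an error naming the day.
    """
    values = pd.Series(values).astype(float)
    days = pd.Series(days)
    out = values.copy()
    for day, idx in values.groupby(days.values).groups.items():
        v = values.loc[idx]
        if len(v) < 2:
            raise ValueError(f"day {day!r} has fewer than 2 values")
        sd = v.std(ddof=1)
        if sd == 0:
            raise ValueError(f"day {day!r} has zero variance")
        out.loc[idx] = (v - v.mean()) / sd
    return out


def kruskal_wallis(groups) -> tuple[float, float]:
    """Kruskal-Wallis H (tie-corrected) and its chi-square(k-1) p-value."""
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2:
        raise ValueError("at least 2 groups required")
    if sum(g.size for g in groups) < 2:
        raise ValueError("at least 2 observations required")
    flat = np.concatenate(groups)
    if np.all(flat == flat[0]):
        return 0.0, 1.0
    h, p = stats.kruskal(*groups)
    return float(h), float(p)


def wilcoxon_bonferroni(pairs, m: int | None = None) -> list[dict]:
    """Wilcoxon rank-sum tests with Bonferroni adjustment.

    ``pairs`` is a list of (groupA, groupB); ``m`` is the number of
    comparisons in the family (defaults to ``len(pairs)``, must be at
    least that).  The statistic is exact for small groups (both n <= 10,
    no ties) and a tie-corrected normal approximation otherwise.
    Adjusted p = min(1, m * p_raw).
    """
    pairs = list(pairs)
    if m is None:
        m = len(pairs)
    if m < len(pairs):
        raise ValueError("m must be at least the number of pairs tested")
    out = []
    for a, b in pairs:
        a = np.asarray(a, dtype=float)
        b = np.asarray(b, dtype=float)
        if a.size == 0 or b.size == 0:
            raise ValueError("empty group in Wilcoxon comparison")
        ties = np.unique(np.concatenate([a, b])).size < a.size + b.size
        method = "exact" if (a.size <= 10 and b.size <= 10 and not ties) else "asymptotic"
        res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
        out.append(
            {
                "statistic": float(res.statistic),
                "p_raw": float(res.pvalue),
                "p_adjusted": min(1.0, m * float(res.pvalue)),
                "method": method,
            }
        )
    return out
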