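"""Visit-to-visit fasting-blood-glucose (FBG) indices.

Seven per-participant predictors are computed from a participant's
time-stamped FBG trajectory:

``fbg_baseline``
    first-visit FBG, mmol/L.
``sd``
    sample standard deviation of the visit values, mmol/L.
``cv``
    coefficient of variation, ``100 * sd / mean``, %.
``vim``
    variation independent of the mean, ``100 * sd / mean**beta`` with the
    exponent ``beta`` fitted cohort-wide (ordinary least squares of
    ``ln(sd)`` on ``ln(mean)``) so that VIM is uncorrelated with the mean.
``arv``
    average real variability: mean absolute difference between
    consecutive (time-ordered) visit values, mmol/L.  A normalized
    percent-of-mean variant ``arv_pct`` is also provided.
``m_fbg``
    mean FBG across visits, mmol/L.
``cum_load``
    cumulative FBG load: the area of the piecewise-linear FBG curve in
    excess of a glycemic threshold (default 5.6 mmol/L, the prediabetes
    cut-off) divided by the total area under the curve, times 100.
    Threshold crossings are located analytically on each segment, so the
    integral is exact for the piecewise-linear interpolant.

All indices are dimensionless or in mmol/L as noted; ``cum_load`` lies in
``[0, 100)`` because the curve is positive and the excess area can never
reach the total area.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "FBGSeries",
    "VIMCalibration",
    "DEFAULT_THRESHOLD",
    "compute_sd",
    "compute_cv",
    "compute_arv",
    "compute_mfbg",
    "compute_cumulative_load",
    "fit_vim_beta",
    "compute_vim",
    "compute_all_indices",
    "standardize_per_sd",
]

#: prediabetes fasting-glucose cut-off, mmol/L
DEFAULT_THRESHOLD = 5.6


@dataclass(frozen=True)
class FBGSeries:
    """One participant's time-stamped FBG trajectory.

    Times are days since the participant's first visit (any shift of the
    time axis leaves every index unchanged); values are mmol/L.
    """

    participant_id: object
    times: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        v = np.asarray(self.values, dtype=float)
        if t.shape != v.shape or t.ndim != 1:
            raise ValueError("times and values must be 1-d arrays of equal length")
        if len(t) and np.any(np.diff(t) <= 0):
            raise ValueError(
                f"participant {self.participant_id!r}: visit times must be "
                "strictly increasing"
            )
        if np.any(v <= 0):
            raise ValueError(
                f"participant {self.participant_id!r}: FBG values must be positive"
            )
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "values", v)

    def __len__(self) -> int:
        return len(self.times)


@dataclass(frozen=True)
class VIMCalibration:
    """Cohort-level power-law calibration for VIM.

    ``beta`` is the OLS slope of ``ln(sd)`` on ``ln(mean)`` across
    participants with positive sd; ``intercept`` the corresponding OLS
    intercept; ``n_used`` the number of participants entering the fit.
    """

    beta: float
    intercept: float
    n_used: int


def compute_sd(series: FBGSeries) -> float:
    """Sample standard deviation (n-1 denominator) of the visit values."""
    if len(series) < 2:
        raise ValueError("sd requires at least two visits")
    return float(np.std(series.values, ddof=1))


def compute_cv(series: FBGSeries) -> float:
    """Coefficient of variation, percent: 100 * sd / mean."""
    mean = float(np.mean(series.values))
    if mean <= 0:
        raise ValueError("cv requires a positive mean")
    return 100.0 * compute_sd(series) / mean


def compute_arv(series: FBGSeries) -> float:
    """Average real variability: mean |successive difference|, mmol/L.

    The values are taken in time order; shuffling visits changes the
    result, unlike sd/cv/mean.
    """
    if len(series) < 2:
        raise ValueError("arv requires at least two visits")
    return float(np.mean(np.abs(np.diff(series.values))))


def compute_mfbg(series: FBGSeries) -> float:
    """Mean FBG across visits, mmol/L."""
    if len(series) == 0:
        raise ValueError("m_fbg requires at least one visit")
    return float(np.mean(series.values))


def _segment_areas(
    t0: np.ndarray,
    t1: np.ndarray,
    v0: np.ndarray,
    v1: np.ndarray,
    threshold: float,
    excess_area: bool = True,
) -> tuple[np.ndarray, np.ndarray]:
    """Total and supra-threshold areas of linear segments, vectorized.

    Returns ``(total, above)`` per segment.  With ``excess_area`` the
    numerator area is the region between the curve and the threshold line
    where the curve exceeds it; otherwise it is the full area under the
    curve restricted to the sub-interval where the curve is >= threshold.
    Crossing points are solved exactly on each segment.
    """
    dt = t1 - t0
    total = dt * (v0 + v1) / 2.0
    g0 = v0 - threshold
    g1 = v1 - threshold

    both_above = (g0 >= 0) & (g1 >= 0)
    both_below = (g0 <= 0) & (g1 <= 0)
    # crossing time offset from segment start (only meaningful when signs differ)
    with np.errstate(divide="ignore", invalid="ignore"):
        tc = np.where(g0 != g1, dt * g0 / (g0 - g1), 0.0)

    if excess_area:
        trap = dt * (g0 + g1) / 2.0
        up_cross = 0.5 * (dt - tc) * g1   # g0 < 0 < g1: triangle after crossing
        down_cross = 0.5 * tc * g0        # g0 > 0 > g1: triangle before crossing
        above = np.where(
            both_above, trap,
            np.where(both_below, 0.0, np.where(g0 < 0, up_cross, down_cross)),
        )
    else:
        # area under the curve itself on the sub-interval where curve >= thr
        up_cross = (dt - tc) * (threshold + v1) / 2.0
        down_cross = tc * (v0 + threshold) / 2.0
        above = np.where(
            both_above, total,
            np.where(both_below, 0.0, np.where(g0 < 0, up_cross, down_cross)),
        )
    return total, above


def compute_cumulative_load(
    series: FBGSeries,
    threshold: float = DEFAULT_THRESHOLD,
    excess_area: bool = True,
) -> float:
    """Cumulative FBG load, percent in [0, 100).

    With ``f(t)`` the piecewise-linear interpolant of the visit series over
    the participant's own ``[t_first, t_last]`` window, returns

        ``100 * integral(max(f - threshold, 0)) / integral(f)``.

    ``excess_area=False`` selects the alternative reading in which the
    numerator is the area under ``f`` itself restricted to the
    supra-threshold sub-intervals.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    if len(series) < 2:
        raise ValueError("cumulative load requires at least two visits")
    t, v = series.times, series.values
    if t[-1] == t[0]:
        raise ValueError("zero-length follow-up window")
    total, above = _segment_areas(t[:-1], t[1:], v[:-1], v[1:], threshold, excess_area)
    return float(100.0 * above.sum() / total.sum())


def fit_vim_beta(series: Iterable[FBGSeries]) -> VIMCalibration:
    """Fit the cohort-wide VIM exponent from a collection of trajectories.

    Participants whose sd is zero are excluded from the log-log fit
    (``ln(0)`` undefined) but still receive ``vim = 0`` downstream.
    """
    means, sds = [], []
    for s in series:
        means.append(compute_mfbg(s))
        sds.append(compute_sd(s))
    return fit_vim_beta_from_moments(np.asarray(means), np.asarray(sds))


def fit_vim_beta_from_moments(means: np.ndarray, sds: np.ndarray) -> VIMCalibration:
    """OLS of ln(sd) on ln(mean) across participants with sd > 0."""
    means = np.asarray(means, dtype=float)
    sds = np.asarray(sds, dtype=float)
    keep = sds > 0
    n_used = int(keep.sum())
    if n_used < 2:
        raise ValueError("VIM calibration needs at least two participants with sd > 0")
    x = np.log(means[keep])
    y = np.log(sds[keep])
    if np.ptp(x) == 0:
        raise ValueError("VIM calibration needs distinct ln(mean) values")
    slope, intercept = np.polyfit(x, y, 1)
    return VIMCalibration(beta=float(slope), intercept=float(intercept), n_used=n_used)


def compute_vim(series: FBGSeries, calibration: VIMCalibration) -> float:
    """Variation independent of the mean: 100 * sd / mean**beta, percent."""
    sd = compute_sd(series)
    if sd == 0:
        return 0.0
    mean = compute_mfbg(series)
    return float(100.0 * sd / mean ** calibration.beta)


# default scaling map for logistic models: indices reported per 1 cohort-SD
# increase versus per unit increase.
DEFAULT_SCALING = {
    "fbg_baseline": "per_unit",
    "sd": "per_unit",
    "m_fbg": "per_unit",
    "cv": "per_cohort_sd",
    "vim": "per_cohort_sd",
    "arv": "per_cohort_sd",
    "arv_pct": "per_cohort_sd",
    "cum_load": "per_cohort_sd",
}


def standardize_per_sd(x, scheme: str = "per_cohort_sd"):
    """Scale a predictor so logistic coefficients are per 1 cohort SD.

    ``per_cohort_sd`` divides by the sample standard deviation of the
    predictor (so the scaled column has unit SD and the fitted odds ratio
    is per 1 SD increase); ``per_unit`` is the identity.
    """
    x = np.asarray(x, dtype=float)
    if scheme == "per_unit":
        return x
    if scheme != "per_cohort_sd":
        raise ValueError(f"unknown scaling scheme {scheme!r}")
    sd = np.std(x, ddof=1)
    if not sd > 0:
        raise ValueError("per_cohort_sd scaling requires a positive cohort SD")
    return x / sd


def compute_all_indices(
    visits: pd.DataFrame,
    threshold: float = DEFAULT_THRESHOLD,
    excess_area: bool = True,
) -> tuple[pd.DataFrame, VIMCalibration]:
    """Compute the full per-participant index table for a cohort.

    Parameters
    ----------
    visits
        Long-format visit table with columns ``participant_id``,
        ``visit_time_days`` and ``fbg_mmol_l``, at least two (normally at
        least three, post-filter) visits per participant.
    threshold
        Glycemic threshold for the cumulative load, mmol/L.

    Returns
    -------
    A table with one row per participant (columns ``fbg_baseline, sd, cv,
    vim, arv, arv_pct, m_fbg, cum_load, n_visits, followup_days``) and the
    cohort-wide :class:`VIMCalibration`.  VIM uses a single calibration for
    the whole cohort; all indices are computed on identical visit sets.
    """
    required = {"participant_id", "visit_time_days", "fbg_mmol_l"}
    missing = required - set(visits.columns)
    if missing:
        raise ValueError(f"visits table missing columns: {sorted(missing)}")
    v = visits.sort_values(["participant_id", "visit_time_days"], kind="mergesort")
    counts = v.groupby("participant_id", sort=True).size()
    if (counts < 2).any():
        bad = counts.index[counts < 2].tolist()
        raise ValueError(f"participants with fewer than two visits: {bad[:5]}")

    grp = v.groupby("participant_id", sort=True)["fbg_mmol_l"]
    m_fbg = grp.mean()
    sd = grp.std(ddof=1)
    baseline = grp.first()
    n_visits = grp.size()

    diffs = v.groupby("participant_id", sort=True)["fbg_mmol_l"].diff().abs()
    arv = diffs.groupby(v["participant_id"], sort=True).sum() / (n_visits - 1)

    t = v["visit_time_days"].to_numpy(dtype=float)
    f = v["fbg_mmol_l"].to_numpy(dtype=float)
    same = (v["participant_id"].to_numpy()[1:] == v["participant_id"].to_numpy()[:-1])
    total_seg, above_seg = _segment_areas(
        t[:-1], t[1:], f[:-1], f[1:], threshold, excess_area
    )
    seg_pid = v["participant_id"].to_numpy()[1:][same]
    total = pd.Series(total_seg[same]).groupby(seg_pid).sum()
    above = pd.Series(above_seg[same]).groupby(seg_pid).sum()
    if (total <= 0).any():
        raise ValueError("zero-length follow-up window for some participant")
    cum_load = 100.0 * above / total
    cum_load = cum_load.reindex(m_fbg.index)

    first_t = v.groupby("participant_id", sort=True)["visit_time_days"].first()
    last_t = v.groupby("participant_id", sort=True)["visit_time_days"].last()

    pos = sd.to_numpy() > 0
    if pos.sum() >= 2 and np.ptp(np.log(m_fbg.to_numpy()[pos])) > 0:
        cal = fit_vim_beta_from_moments(m_fbg.to_numpy(), sd.to_numpy())
        vim = pd.Series(
            np.where(sd > 0, 100.0 * sd / m_fbg ** cal.beta, 0.0), index=m_fbg.index
        )
    else:
        # degenerate cohort (e.g. everyone constant): no power-law fit is
        # possible; zero-variability participants still get vim = 0
        cal = VIMCalibration(beta=float("nan"), intercept=float("nan"),
                             n_used=int(pos.sum()))
        vim = pd.Series(np.where(sd > 0, np.nan, 0.0), index=m_fbg.index)

    out = pd.DataFrame(
        {
            "fbg_baseline": baseline,
            "sd": sd,
            "cv": 100.0 * sd / m_fbg,
            "vim": vim,
            "arv": arv,
            "arv_pct": 100.0 * arv / m_fbg,
            "m_fbg": m_fbg,
            "cum_load": cum_load,
            "n_visits": n_visits,
            "followup_days": last_t - first_t,
        }
    )
    out.index.name = "participant_id"
    return out.reset_index(), cal
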