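"""Exponential growth-rate and promoter-expression quantification from plate-reader data.

Growth rates are obtained from a log-linear least-squares fit to the
background-subtracted signal inside a fixed signal window that brackets the
exponential phase (OD windows of 0.02-0.2 for rich medium and 0.03-0.12 for
minimal medium; luminescence windows of 1e2-1e5 counts per second).
Expression levels are the slope of autofluorescence-corrected reporter
fluorescence against OD during the exponential window, with the
reporter-less control strain's fluorescence interpolated to the reporter's
OD values before subtraction.

All rates are reported in 1/h regardless of the input time unit (minutes).
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass, field
from typing import Optional, Tuple

import numpy as np
from scipy.ndimage import median_filter

__all__ = [
    "SignalKind",
    "Medium",
    "RejectionReason",
    "WellTimeSeries",
    "GrowthFitConfig",
    "GrowthRateEstimate",
    "ExpressionLevel",
    "fit_growth_rate",
    "fit_luminescence_rate",
    "expression_level",
]

MINUTES_PER_HOUR = 60.0


class SignalKind(str, enum.Enum):
    OD = "od"
    LUMINESCENCE = "luminescence"
    FLUORESCENCE = "fluorescence"


class Medium(str, enum.Enum):
    RICH = "rich"
    MINIMAL = "minimal"


class RejectionReason(str, enum.Enum):
    NONE = "none"
    BELOW_MIN_RATE = "below_min_rate"
    INSUFFICIENT_POINTS = "insufficient_points"
    NO_WINDOW = "no_window"


@dataclass
class WellTimeSeries:
    """Signal of one microplate well over time.

    Parameters
    ----------
    time : array
        Measurement times in minutes, strictly increasing.
    signal : array
        Raw instrument signal (OD600 a.u., counts per second, or
        fluorescence a.u.), same length as ``time``.
    signal_kind : SignalKind
        What the signal measures.
    blank : float or array, optional
        Background to subtract (same units as signal). If None, the median
        of the pre-growth signal (first 3 points) is used as a scalar blank.
    medium : Medium
        Selects fit-window defaults (rich vs minimal).
    label : str
        Free-text identifier.
    """

    time: np.ndarray
    signal: np.ndarray
    signal_kind: SignalKind = SignalKind.OD
    blank: Optional[np.ndarray] = None
    medium: Medium = Medium.MINIMAL
    label: str = ""

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.signal = np.asarray(self.signal, dtype=float)
        if self.time.ndim != 1 or self.signal.shape != self.time.shape:
            raise ValueError("time and signal must be 1-D arrays of equal length")
        if not np.all(np.diff(self.time) > 0):
            raise ValueError("time must be strictly increasing")
        self.signal_kind = SignalKind(self.signal_kind)
        self.medium = Medium(self.medium)
        if self.blank is not None:
            blank = np.asarray(self.blank, dtype=float)
            if blank.ndim == 0:
                blank = float(blank)
                if blank < 0:
                    raise ValueError("blank must be non-negative")
                self.blank = blank
            else:
                if blank.shape != self.time.shape:
                    raise ValueError("per-time blank must match series length")
                if np.any(blank < 0):
                    raise ValueError("blank must be non-negative")
                self.blank = blank

    def background_subtracted(self) -> np.ndarray:
        """Signal minus blank; scalar blank defaults to the pre-growth median."""
        if self.blank is None:
            blank = float(np.median(self.signal[: min(3, len(self.signal))]))
        else:
            blank = self.blank
        return self.signal - blank


@dataclass
class GrowthFitConfig:
    """Windowing and acceptance thresholds for log-linear growth fits.

    Defaults follow common plate-reader practice: the exponential OD window
    covers one order of magnitude and at least two doublings; the lowest
    accepted growth rate is ~10% of the unperturbed maximum in the given
    medium; rich-medium data beyond ``max_time`` are discarded to exclude
    sporadic fast-growing mutants late in the experiment.
    """

    od_window_low: float = 0.03
    od_window_high: float = 0.12
    min_rate: float = 0.03  # 1/h
    max_time: Optional[float] = None  # minutes
    lum_low: float = 1e2  # cps
    lum_high: float = 1e5
    hill_min_rate: Optional[float] = None  # optional exclusion for Hill fits
    rate_match_tol: float = 0.20  # relative reporter/control growth-rate tolerance

    def __post_init__(self) -> None:
        if not (0 < self.od_window_low < self.od_window_high):
            raise ValueError("require 0 < od_window_low < od_window_high")
        if self.lum_low >= self.lum_high:
            raise ValueError("require lum_low < lum_high")
        if self.min_rate < 0:
            raise ValueError("min_rate must be >= 0")

    @classmethod
    def for_medium(cls, medium: Medium | str) -> "GrowthFitConfig":
        medium = Medium(medium)
        if medium is Medium.RICH:
            return cls(od_window_low=0.02, od_window_high=0.2, min_rate=0.1,
                       max_time=1000.0)
        return cls(od_window_low=0.03, od_window_high=0.12, min_rate=0.03,
                   max_time=None)


@dataclass
class GrowthRateEstimate:
    """Result of a windowed log-linear growth fit."""

    rate: float  # 1/h
    intercept: float  # ln(signal) at t=0
    window_indices: Tuple[int, int]  # [start, stop) into the truncated series
    r_squared: float
    accepted: bool
    rejection_reason: RejectionReason = RejectionReason.NONE
    n_points: int = 0


@dataclass
class ExpressionLevel:
    """Expression level as fluorescence-per-OD slope over the exponential window."""

    slope: float  # fluorescence a.u. per OD unit
    window_indices: Tuple[int, int]
    r_squared: float
    paired_growth_rate: float  # 1/h
    rate_mismatch_warning: bool = False


def _loglinear_fit(t_min: np.ndarray, values: np.ndarray) -> Tuple[float, float, float]:
    """Least-squares slope/intercept of ln(values) vs time, slope in 1/h."""
    y = np.log(values)
    t_h = t_min / MINUTES_PER_HOUR
    slope, intercept = np.polyfit(t_h, y, 1)
    resid = y - (slope * t_h + intercept)
    ss_res = float(np.sum(resid**2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
    return float(slope), float(intercept), r2


def _longest_true_run(mask: np.ndarray) -> Tuple[int, int]:
    """Bounds [start, stop) of the longest contiguous True run (ties -> earliest)."""
    best = (0, 0)
    start = None
    for i, m in enumerate(np.append(mask, False)):
        if m and start is None:
            start = i
        elif not m and start is not None:
            if i - start > best[1] - best[0]:
                best = (start, i)
            start = None
    return best


def _windowed_fit(series: WellTimeSeries, low: float, high: float,
                  config: GrowthFitConfig) -> GrowthRateEstimate:
    time = series.time
    values = series.background_subtracted()
    if config.max_time is not None:
        keep = time <= config.max_time
        time, values = time[keep], values[keep]

    # window membership is judged on a 3-point rolling median, and one guard
    # sample is trimmed from each end of the selected run: otherwise boundary
    # points enter the window only when measurement noise pushes them inside
    # (upward at entry, downward at exit), which systematically tilts the
    # fitted slope downward
    if len(values) >= 3:
        smoothed = median_filter(values, size=3, mode="nearest")
    else:
        smoothed = values
    in_window = (smoothed >= low) & (smoothed <= high)
    start, stop = _longest_true_run(in_window)
    if stop - start == 0:
        return GrowthRateEstimate(np.nan, np.nan, (0, 0), np.nan, False,
                                  RejectionReason.NO_WINDOW)
    if stop - start >= 5:
        start, stop = start + 1, stop - 1
    t_w = time[start:stop]
    v_w = values[start:stop]
    # drop non-positive values pointwise (possible only if low <= 0 was forced)
    pos = v_w > 0
    t_w, v_w = t_w[pos], v_w[pos]
    if len(t_w) < 3:
        return GrowthRateEstimate(np.nan, np.nan, (start, stop), np.nan, False,
                                  RejectionReason.INSUFFICIENT_POINTS)
    rate, intercept, r2 = _loglinear_fit(t_w, v_w)
    if rate < config.min_rate:
        return GrowthRateEstimate(rate, intercept, (start, stop), r2, False,
                                  RejectionReason.BELOW_MIN_RATE, len(t_w))
    return GrowthRateEstimate(rate, intercept, (start, stop), r2, True,
                              RejectionReason.NONE, len(t_w))


def fit_growth_rate(series: WellTimeSeries,
                    config: Optional[GrowthFitConfig] = None) -> GrowthRateEstimate:
    """Exponential growth rate from an OD time series.

    Performs a least-squares fit of ln(OD - blank) against time over the
    longest contiguous sub-series whose background-subtracted OD lies within
    ``[od_window_low, od_window_high]``. Data after ``max_time`` (if set)
    are discarded before windowing. Rates below ``min_rate`` are flagged as
    rejected.
    """
    if config is None:
        config = GrowthFitConfig.for_medium(series.medium)
    if series.signal_kind is not SignalKind.OD:
        raise ValueError("fit_growth_rate expects an OD series")
    return _windowed_fit(series, config.od_window_low, config.od_window_high, config)


def fit_luminescence_rate(series: WellTimeSeries,
                          config: Optional[GrowthFitConfig] = None) -> GrowthRateEstimate:
    """Growth rate from a luminescence series, windowed on raw counts per second."""
    if config is None:
        config = GrowthFitConfig()
    if series.signal_kind is not SignalKind.LUMINESCENCE:
        raise ValueError("fit_luminescence_rate expects a luminescence series")
    return _windowed_fit(series, config.lum_low, config.lum_high, config)


def expression_level(reporter_fluor: WellTimeSeries,
                     reporter_od: WellTimeSeries,
                     control_fluor: WellTimeSeries,
                     control_od: WellTimeSeries,
                     config: Optional[GrowthFitConfig] = None) -> ExpressionLevel:
    """Promoter/fusion expression level from paired reporter and control strains.

    The control strain (same genotype without the fluorescent reporter) is
    grown under matched conditions. Its background-subtracted fluorescence
    is linearly interpolated to each of the reporter's OD values inside the
    reporter's exponential window and subtracted from the reporter's
    fluorescence; the expression level is the slope of the corrected
    fluorescence against OD over that window.

    Raises if the control's OD range does not cover the reporter window
    (extrapolation is refused). A reporter/control growth-rate mismatch
    beyond ``config.rate_match_tol`` sets ``rate_mismatch_warning``.
    """
    if config is None:
        config = GrowthFitConfig.for_medium(reporter_od.medium)
    if reporter_fluor.signal_kind is not SignalKind.FLUORESCENCE:
        raise ValueError("reporter_fluor must be a fluorescence series")
    if not np.array_equal(reporter_fluor.time, reporter_od.time):
        raise ValueError("reporter fluorescence and OD must share time points")

    rep_fit = fit_growth_rate(reporter_od, config)
    ctl_fit = fit_growth_rate(control_od, config)
    if not rep_fit.accepted:
        raise ValueError(f"reporter growth fit rejected: {rep_fit.rejection_reason.value}")
    if not ctl_fit.accepted:
        raise ValueError(f"control growth fit rejected: {ctl_fit.rejection_reason.value}")
    mismatch = abs(rep_fit.rate - ctl_fit.rate) / ctl_fit.rate > config.rate_match_tol
    if mismatch:
        warnings.warn("reporter and control growth rates differ beyond tolerance",
                      stacklevel=2)

    start, stop = rep_fit.window_indices
    rep_od = reporter_od.background_subtracted()
    rep_fl = reporter_fluor.background_subtracted()
    keep_t = reporter_od.time
    if config.max_time is not None:
        sel = keep_t <= config.max_time
        rep_od, rep_fl = rep_od[sel], rep_fl[sel]
    od_w = rep_od[start:stop]
    fl_w = rep_fl[start:stop]

    ctl_od_v = control_od.background_subtracted()
    ctl_fl_v = control_fluor.background_subtracted()
    if config.max_time is not None:
        sel = control_od.time <= config.max_time
        ctl_od_v, ctl_fl_v = ctl_od_v[sel], ctl_fl_v[sel]
    order = np.argsort(ctl_od_v)
    ctl_od_s, ctl_fl_s = ctl_od_v[order], ctl_fl_v[order]
    if od_w.min() < ctl_od_s.min() or od_w.max() > ctl_od_s.max():
        raise ValueError("control OD range does not cover the reporter window; "
                         "refusing to extrapolate the autofluorescence background")
    background = np.interp(od_w, ctl_od_s, ctl_fl_s)
    corrected = fl_w - background

    slope, intercept = np.polyfit(od_w, corrected, 1)
    resid = corrected - (slope * od_w + intercept)
    ss_tot = float(np.sum((corrected - corrected.mean()) ** 2))
    r2 = 1.0 if ss_tot == 0 else 1.0 - float(np.sum(resid**2)) / ss_tot
    if not np.isfinite(slope):
        raise ValueError("expression slope is not finite")
    return ExpressionLevel(float(slope), (start, stop), r2, rep_fit.rate, mismatch)
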