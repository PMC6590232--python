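"""Semi-quantitative analysis of dynamic contrast-enhanced time-intensity
curves.

Per voxel, the raw dynamic signal is smoothed with a penalized cubic
smoothing spline to give a continuous curve S(t); 13 curve-shape features
(arrival time, time of/to peak, relative enhancements, area under the curve,
wash-in/wash-out derivative extrema and average slopes) are then read off
the smoothed curve with explicit missing-value rules: voxels whose baseline
fails the image-noise inclusion threshold carry no features, voxels without
significant enhancement lose the enhancement-dependent ones, and tail
features are missing when too few dynamics remain after the peak.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.interpolate import make_smoothing_spline

from .datatypes import AcquisitionSeries, DCE_PARAM_NAMES, ParameterMap, PARAM_UNITS

ENHANCEMENT_MULTIPLIER = 5.0  # S(t) > S0 + 5 sigma_voxel marks significant enhancement
INCLUSION_MULTIPLIER = 5.0    # S0 > 5 sigma_image admits a voxel to the analysis
DEFAULT_SMOOTHING = 0.01
MIN_TAIL_DYNAMICS = 5         # WO/NS need at least this many dynamics after the peak


@dataclass
class TicAnalysis:
    """Smoothed time-intensity curve for one voxel."""

    S0: float            # baseline: mean of the pre-contrast dynamics
    sigma_voxel: float   # std of the spline residuals
    t_dense: np.ndarray  # dense time grid, s from scan start
    s_dense: np.ndarray  # smoothed curve on t_dense
    time_grid: np.ndarray
    signal: np.ndarray
    included: Optional[bool] = None
    enhancement_found: Optional[bool] = None


@dataclass
class DceParams:
    """The 13 curve features; NaN marks a missing value."""

    AT: float = np.nan    # s after injection to significant enhancement
    TOP: float = np.nan   # s after injection to the curve maximum
    TTP: float = np.nan   # TOP - AT, s
    SEmax: float = np.nan  # (Smax - S0)/S0
    SE60: float = np.nan  # (S(60 s after injection) - S0)/S0
    SER: float = np.nan   # early (55 s) over late (300 s) relative enhancement
    CER: float = np.nan   # Smax/S0; missing without significant enhancement
    AUCn: float = np.nan  # area under S(t) over 5 min after injection / S0
    WI: float = np.nan    # max dS/dt between AT and TOP, signal/s
    WO: float = np.nan    # most negative dS/dt after TOP (signed), signal/s
    BE: float = np.nan    # t(WO) - t(WI), s
    IS: float = np.nan    # (Smax - S0)/TOP, signal/s
    NS: float = np.nan    # average post-peak slope (signed), signal/s

    def as_dict(self) -> dict[str, float]:
        return {k: getattr(self, k) for k in DCE_PARAM_NAMES}


def smooth_tic(dynamic_signal: Sequence[float], time_grid: Sequence[float],
               smoothing_parameter: float = DEFAULT_SMOOTHING,
               injection_index: int = 6,
               dense_factor: int = 10) -> TicAnalysis:
    """Fit a penalized cubic smoothing spline to one time-intensity curve.

    ``smoothing_parameter`` p in (0, 1] is the mixing weight between the
    residual sum of squares and the curvature penalty: the spline minimizes
    p * SSE + (1 - p) * (h^3/6) * integral S''(t)^2 dt with t in seconds and
    h the sampling interval. The h^3/6 factor places the transition between
    the limits (p -> 1 interpolates, p -> 0 tends to a straight line) near
    p = 0.5 regardless of the time grid; the default p = 0.01 smooths over
    roughly two dynamics on the default 4.2 s grid.

    The baseline S0 is the mean of the raw pre-contrast dynamics (those
    before ``injection_index``, 1-based), and sigma_voxel is the standard
    deviation of the spline residuals at the acquisition times.
    """
    y = np.asarray(dynamic_signal, dtype=float)
    t = np.asarray(time_grid, dtype=float)
    if len(y) < 6:
        raise ValueError("need at least 6 dynamics to smooth a curve")
    if not (0 < smoothing_parameter <= 1):
        raise ValueError("smoothing parameter must be in (0, 1]")
    h = float(np.mean(np.diff(t)))
    lam = (1.0 - smoothing_parameter) / smoothing_parameter * h ** 3 / 6.0
    spl = make_smoothing_spline(t, y, lam=lam)
    resid = y - spl(t)
    n_dense = dense_factor * len(t)
    t_dense = np.linspace(t[0], t[-1], n_dense)
    s_dense = spl(t_dense)
    n_pre = max(injection_index - 1, 1)
    S0 = float(np.mean(y[:n_pre]))
    return TicAnalysis(S0=S0, sigma_voxel=float(np.std(resid)),
                       t_dense=t_dense, s_dense=s_dense,
                       time_grid=t, signal=y)


def qualify_voxel(analysis: TicAnalysis, sigma_image: float,
                  injection_time: float) -> tuple[bool, bool]:
    """Apply the inclusion and significant-enhancement thresholds.

    A voxel is included when its baseline exceeds 5x the image noise (the
    slice mean of sigma_voxel); significant enhancement requires the
    smoothed curve to exceed S0 + 5 sigma_voxel at some post-injection time.
    """
    included = analysis.S0 > INCLUSION_MULTIPLIER * sigma_image
    post = analysis.t_dense >= injection_time
    thr = analysis.S0 + ENHANCEMENT_MULTIPLIER * analysis.sigma_voxel
    enhancement = bool(np.any(analysis.s_dense[post] > thr))
    analysis.included = bool(included)
    analysis.enhancement_found = enhancement
    return bool(included), enhancement


def compute_dce_params(analysis: TicAnalysis, time_grid: Sequence[float],
                       injection_time: float,
                       auc_window_s: float = 300.0) -> DceParams:
    """Evaluate the 13 curve features on the smoothed curve.

    Times named "after injection" are measured relative to
    ``injection_time``. Derivatives are central differences on the dense
    smoothed grid; the area under the curve is trapezoidal over the five
    minutes following injection, normalized by the baseline.
    """
    p = DceParams()
    if analysis.included is False:
        return p
    t = analysis.t_dense
    s = analysis.s_dense
    raw_t = np.asarray(time_grid, dtype=float)
    S0 = analysis.S0
    post = t >= injection_time
    if not post.any() or S0 <= 0:
        return p
    tp = t[post]
    sp = s[post]

    i_max = int(np.argmax(sp))
    smax = float(sp[i_max])
    t_peak_abs = float(tp[i_max])
    p.TOP = t_peak_abs - injection_time
    p.SEmax = (smax - S0) / S0
    if p.TOP > 0:
        p.IS = (smax - S0) / p.TOP

    # relative enhancement at fixed delays after injection
    def rel_enh(delay: float) -> float:
        tq = injection_time + delay
        if tq > t[-1]:
            return np.nan
        return (float(np.interp(tq, t, s)) - S0) / S0

    p.SE60 = rel_enh(60.0)
    early, late = rel_enh(55.0), rel_enh(300.0)
    if np.isfinite(early) and np.isfinite(late) and abs(late) > 1e-12:
        p.SER = early / late

    t_end = min(injection_time + auc_window_s, t[-1])
    win = (t >= injection_time) & (t <= t_end)
    if win.sum() >= 2:
        p.AUCn = float(np.trapezoid(s[win], t[win])) / S0

    thr = S0 + ENHANCEMENT_MULTIPLIER * analysis.sigma_voxel
    enhanced = analysis.enhancement_found
    if enhanced is None:
        enhanced = bool(np.any(sp > thr))
    if enhanced:
        p.CER = smax / S0
        cross = np.nonzero(sp > thr)[0]
        t_at_abs = float(tp[cross[0]])
        p.AT = t_at_abs - injection_time
        p.TTP = p.TOP - p.AT

    deriv = np.gradient(s, t)
    t_wi = np.nan
    if enhanced:
        rise = (t >= t_at_abs) & (t <= t_peak_abs)
        if not rise.any():
            rise = np.isclose(t, t_peak_abs)
        k = int(np.argmax(deriv[rise]))
        p.WI = float(deriv[rise][k])
        t_wi = float(t[rise][k])

    n_tail = int(np.sum(raw_t > t_peak_abs))
    if n_tail >= MIN_TAIL_DYNAMICS:
        fall = t >= t_peak_abs
        k = int(np.argmin(deriv[fall]))
        p.WO = float(deriv[fall][k])
        t_wo = float(t[fall][k])
        if np.isfinite(t_wi):
            p.BE = t_wo - t_wi
        if t[-1] > t_peak_abs:
            p.NS = (float(s[-1]) - smax) / (t[-1] - t_peak_abs)
    return p


def analyze_dce_series(series: AcquisitionSeries,
                       smoothing_parameter: float = DEFAULT_SMOOTHING,
                       auc_window_s: float = 300.0
                       ) -> tuple[dict[str, ParameterMap], pd.DataFrame]:
    """Run the full semi-quantitative analysis over a dynamic series.

    Returns one parameter map per feature plus a per-voxel flag table
    (included / enhancement / tail-missing). The image noise sigma_image is
    the slice mean of sigma_voxel.
    """
    if series.acq_variable != "time":
        raise ValueError("expected a dynamic (time) series")
    if series.injection_index is None:
        raise ValueError("dynamic series needs an injection index")
    t = series.acq_values
    injection_time = t[series.injection_index - 1]
    rows, cols = series.shape
    analyses = np.empty((rows, cols), dtype=object)
    sigma_sum = 0.0
    for i in range(rows):
        for j in range(cols):
            a = smooth_tic(series.frames[:, i, j], t,
                           smoothing_parameter=smoothing_parameter,
                           injection_index=series.injection_index)
            analyses[i, j] = a
            sigma_sum += a.sigma_voxel
    sigma_image = sigma_sum / (rows * cols)

    maps = {name: np.full((rows, cols), np.nan) for name in DCE_PARAM_NAMES}
    flags = []
    for i in range(rows):
        for j in range(cols):
            a = analyses[i, j]
            included, enhanced = qualify_voxel(a, sigma_image, injection_time)
            params = compute_dce_params(a, t, injection_time,
                                        auc_window_s=auc_window_s)
            for name, val in params.as_dict().items():
                maps[name][i, j] = val
            flags.append({"row": i, "col": j, "included": included,
                          "enhancement": enhanced,
                          "tail_missing": not np.isfinite(params.WO)})
    out = {}
    for name, vals in maps.items():
        out[name] = ParameterMap(name, vals, np.isfinite(vals),
                                 PARAM_UNITS[name], series.pixel_size)
    return out, pd.DataFrame(flags)
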