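"""Per-trial dynamic and temporal metrics.

This module turns one conditioned, segmented trial into the scalar
variables a grip-lift analysis works with: force peaks and plateaus,
grip/load ratios, preload and loading durations, the exponential
relaxation of grip force after its peak, and the lagged correlation
between grip- and load-force rates over the loading phase (the standard
read-out of anticipatory grip-load coupling).

The grip-force relaxation is modelled as ``GF(t) = a + b * exp(-c t)``
with ``t`` counted from the grip-force peak: ``a`` is a robust estimate
of the plateau grip force, ``1/c`` the relaxation time constant.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy.optimize import curve_fit

from .errors import (
    FitFailureError,
    GripLiftError,
    ShortSignalError,
    TrialAnalysisError,
    UndefinedCorrelationError,
)
from .preprocess import compute_load_force, force_rate, lowpass_filter
from .records import TrialContext, TrialEvents, TrialRecording
from .segmentation import (
    detect_onset,
    detect_peaks,
    detect_trial_end,
    plateau_means,
    weight_crossing_time,
)

__all__ = [
    "DecayFit",
    "CouplingStats",
    "TrialMetrics",
    "AnalysisParams",
    "fit_gf_decay",
    "xcorr_rates",
    "grip_load_ratios",
    "peak_gf_rate",
    "analyze_trial",
    "analyze_trials",
]

logger = logging.getLogger(__name__)

_C_MIN, _C_MAX = 1e-3, 50.0  # 1/s bounds on the decay rate


@dataclass(frozen=True)
class DecayFit:
    """Exponential grip-force relaxation ``a + b * exp(-c t)``.

    ``a`` N plateau offset, ``b`` N decay amplitude, ``c`` 1/s decay
    rate, ``tau = 1/c`` s (the form usually reported), ``rmse`` N.
    """

    a: float
    b: float
    c: float
    rmse: float

    @property
    def tau(self) -> float:
        return 1.0 / self.c


@dataclass(frozen=True)
class CouplingStats:
    """Grip-load rate coupling over the loading phase.

    ``r_max`` is the largest Pearson correlation over the lag grid;
    ``lag`` (s) is the shift at which it occurs, positive when grip
    force rate leads load force rate.
    """

    r_max: float
    lag: float


@dataclass(frozen=True)
class TrialMetrics:
    """All scalar outcomes of one trial."""

    context: TrialContext
    events: TrialEvents
    gf_max: float
    lf_max: float
    gf_plateau: float
    lf_plateau: float
    ratio_at_lfmax: float
    ratio_plateau: float
    preload: float
    loading: float
    peak_gf_rate: float
    decay: DecayFit
    coupling: CouplingStats
    weight: float


@dataclass(frozen=True)
class AnalysisParams:
    """Thresholds of the conditioning and segmentation rules.

    Defaults are the standard grip-lift values; they are exposed so a
    run can be reproduced from its logged parameter set, not because
    they are meant to be tuned.
    """

    cutoff_hz: float = 20.0
    onset_threshold: float = 0.4      # N/s
    onset_min_duration: float = 0.125  # s
    end_threshold: float = -2.0       # N/s
    end_min_duration: float = 0.125   # s
    end_backoff: float = 0.250        # s
    max_lag_s: float = 0.150          # s, cross-correlation shift window
    plateau_window_s: float = 1.0     # s
    g0: float = 9.81                  # m/s^2, fallback weight conversion


# ---------------------------------------------------------------------------
# Exponential relaxation fit
# ---------------------------------------------------------------------------

def _model(tt, a, b, c):
    return a + b * np.exp(-c * tt)


def fit_gf_decay(
    gf: np.ndarray, t: np.ndarray, t_gf_peak: float, t_end: float
) -> DecayFit:
    """Fit ``a + b exp(-c (t - tGFmax))`` between the grip-force peak and
    the trial end by bounded nonlinear least squares.

    Initialization: ``a0`` = mean over the final second of the segment,
    ``b0`` = first sample minus ``a0``, ``c0`` = 2 1/s, with a ladder of
    rescaled ``c0`` restarts if the solver fails.  Bounds: a, b >= 0 and
    c in [1e-3, 50] 1/s.  A flat segment returns the degenerate fit
    (b = 0, c at its lower bound) exactly.

    Raises :class:`ShortSignalError` for segments under 10 samples and
    :class:`FitFailureError` (carrying the best RMSE) on non-convergence.
    """
    t = np.asarray(t, dtype=float)
    gf = np.asarray(gf, dtype=float)
    m = (t >= t_gf_peak - 1e-12) & (t <= t_end + 1e-12)
    seg = gf[m]
    tt = t[m] - t_gf_peak
    if seg.size < 10:
        raise ShortSignalError(
            f"decay segment has {seg.size} samples; need at least 10"
        )
    if np.ptp(seg) < 1e-12:
        return DecayFit(a=float(seg[0]), b=0.0, c=_C_MIN, rmse=0.0)

    tail = seg[tt >= tt[-1] - 1.0] if tt[-1] > 1.0 else seg[seg.size // 2:]
    a0 = float(np.mean(tail))
    b0 = max(float(seg[0] - a0), 1e-6)
    best_rmse = np.inf
    for scale in (1.0, 0.25, 4.0, 0.1, 10.0):
        c0 = float(np.clip(2.0 * scale, _C_MIN, _C_MAX))
        try:
            popt, _ = curve_fit(
                _model,
                tt,
                seg,
                p0=(max(a0, 0.0), b0, c0),
                bounds=([0.0, 0.0, _C_MIN], [np.inf, np.inf, _C_MAX]),
                maxfev=2000,
            )
        except RuntimeError:
            continue
        resid = seg - _model(tt, *popt)
        rmse = float(np.sqrt(np.mean(resid**2)))
        if rmse < best_rmse:
            best_rmse = rmse
        return DecayFit(a=float(popt[0]), b=float(popt[1]), c=float(popt[2]), rmse=rmse)
    raise FitFailureError(
        "exponential decay fit did not converge after 5 restarts",
        best_rmse=best_rmse,
    )


# ---------------------------------------------------------------------------
# Grip-load rate cross-correlation
# ---------------------------------------------------------------------------

def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    xc = x - x.mean()
    yc = y - y.mean()
    denom = np.sqrt(np.dot(xc, xc) * np.dot(yc, yc))
    return float(np.dot(xc, yc) / denom)


def xcorr_rates(
    gf_rate: np.ndarray,
    lf_rate: np.ndarray,
    t: np.ndarray,
    t_lf_onset: float,
    t_lf_weight: float,
    max_lag: float = 0.150,
) -> CouplingStats:
    """Lagged Pearson correlation of the force rates over the loading phase.

    The load-force rate over [tLFo, tLFw] is the reference; the
    grip-force rate is shifted against it by every integer-sample lag
    within ``+/-max_lag`` (a +/-150 ms window is 37 lags at 120 Hz).
    Returns the maximizing (r, lag); positive lag means grip force rate
    led load force rate.  Ties break to the smallest |lag|, then to the
    positive one.

    Raises :class:`ShortSignalError` for loading windows under 8 samples
    and :class:`UndefinedCorrelationError` if the reference segment has
    (numerically) zero variance.
    """
    t = np.asarray(t, dtype=float)
    gf_rate = np.asarray(gf_rate, dtype=float)
    lf_rate = np.asarray(lf_rate, dtype=float)
    fs = 1.0 / (t[1] - t[0])
    i0 = int(np.searchsorted(t, t_lf_onset - 1e-12))
    i1 = int(np.searchsorted(t, t_lf_weight + 1e-12))  # exclusive
    if i1 - i0 < 8:
        raise ShortSignalError(
            f"loading window holds {i1 - i0} samples; need at least 8"
        )
    ref = lf_rate[i0:i1]
    if np.var(ref) < 1e-12:
        raise UndefinedCorrelationError("load force rate is flat over the loading phase")
    k_max = int(round(max_lag * fs))
    best: Optional[Tuple[float, int]] = None
    for k in range(-k_max, k_max + 1):
        j0, j1 = i0 - k, i1 - k
        if j0 < 0 or j1 > gf_rate.size:
            continue
        seg = gf_rate[j0:j1]
        if np.var(seg) < 1e-12:
            continue
        r = _pearson(ref, seg)
        if best is None:
            best = (r, k)
            continue
        r_b, k_b = best
        if r > r_b or (r == r_b and (abs(k) < abs(k_b) or (abs(k) == abs(k_b) and k > k_b))):
            best = (r, k)
    if best is None:
        raise UndefinedCorrelationError(
            "grip force rate is flat at every lag over the loading phase"
        )
    r, k = best
    return CouplingStats(r_max=r, lag=k / fs)


# ---------------------------------------------------------------------------
# Simple per-trial scalars
# ---------------------------------------------------------------------------

def grip_load_ratios(
    gf: np.ndarray,
    lf: np.ndarray,
    t: np.ndarray,
    t_lf_peak: float,
    plateaus: Tuple[float, float],
) -> Tuple[float, float]:
    """(grip/load at the load-force peak, grip/load over the plateau)."""
    t = np.asarray(t, dtype=float)
    gf_at = float(np.interp(t_lf_peak, t, np.asarray(gf, dtype=float)))
    lf_at = float(np.interp(t_lf_peak, t, np.asarray(lf, dtype=float)))
    gf_plat, lf_plat = plateaus
    if lf_at <= 0:
        raise ValueError(f"load force at its peak is non-positive ({lf_at:.3f} N)")
    if lf_plat <= 0:
        raise ValueError(f"plateau load force is non-positive ({lf_plat:.3f} N)")
    return gf_at / lf_at, gf_plat / lf_plat


def peak_gf_rate(
    gf_rate: np.ndarray,
    t: np.ndarray,
    window: Tuple[float, float],
    t_gf_peak: Optional[float] = None,
) -> Tuple[float, float]:
    """Maximum grip-force rate in ``window``; returns (value, time).

    On a well-formed lift the rate peak precedes the force peak; if
    ``t_gf_peak`` is given and that ordering is violated a warning is
    emitted (the value is still returned).
    """
    t = np.asarray(t, dtype=float)
    lo, hi = window
    m = (t >= lo - 1e-12) & (t <= hi + 1e-12)
    if not np.any(m):
        raise ValueError(f"empty rate-peak window [{lo}, {hi}]")
    seg = np.asarray(gf_rate, dtype=float)[m]
    i = int(np.argmax(seg))
    t_at = float(t[m][i])
    if t_gf_peak is not None and t_at >= t_gf_peak:
        warnings.warn(
            f"grip-force rate peak ({t_at:.3f} s) does not precede the force "
            f"peak ({t_gf_peak:.3f} s); trial may be atypical",
            stacklevel=2,
        )
    return float(seg[i]), t_at


# ---------------------------------------------------------------------------
# End-to-end trial analysis
# ---------------------------------------------------------------------------

def analyze_trial(
    recording: TrialRecording,
    context: TrialContext,
    params: Optional[AnalysisParams] = None,
) -> TrialMetrics:
    """Run the full per-trial pipeline: filter, rates, load-force merge,
    event detection, metrics.

    Steps, in order: zero-phase low-pass of all channels; grip-force
    onset from its rate; load-force onset from the stand-channel rate
    (searched from the grip onset on — fingers contact first); object
    weight estimated as mass times the pre-contact accelerometer
    baseline; channel merge at the stand-force maximum (lift-off);
    weight crossing on the merged trace; trial end from the merged
    load-force rate; peaks, plateaus, decay fit, rate coupling, ratios.

    Any stage failure is re-raised as :class:`TrialAnalysisError`
    carrying the trial identifier.
    """
    p = params or AnalysisParams()
    try:
        recording.validate()
        t, fs = recording.t, recording.fs
        gf_f = lowpass_filter(recording.gf, fs, p.cutoff_hz)
        lfst_f = lowpass_filter(recording.lf_stand, fs, p.cutoff_hz)
        az_f = lowpass_filter(recording.az, fs, p.cutoff_hz)

        gf_rate = force_rate(gf_f, fs)
        t_gf0 = detect_onset(
            gf_rate, fs, p.onset_threshold, p.onset_min_duration, search_start=0.0
        )
        lfst_rate = force_rate(lfst_f, fs)
        t_lf0 = detect_onset(
            lfst_rate, fs, p.onset_threshold, p.onset_min_duration, search_start=t_gf0
        )

        base = az_f[t < t_gf0]
        if base.size >= 5:
            weight = context.mass * float(np.median(base))
        else:  # no usable baseline: fall back to the programmed level
            weight = context.mass * context.g_level * p.g0

        # lift-off estimate for the channel merge: the stand force peaks
        # (at the weight) the instant the object leaves the stand
        m_search = t >= t_lf0
        i_lift = int(np.argmax(lfst_f[m_search]))
        t_lift = float(t[m_search][i_lift])
        lf = compute_load_force(lfst_f, az_f, context.mass, t_lift, t=t)

        t_lfw = weight_crossing_time(lf, t, weight, after=t_lf0)
        lf_rate = force_rate(lf, fs)
        t_end = detect_trial_end(
            lf_rate,
            fs,
            p.end_threshold,
            p.end_min_duration,
            p.end_backoff,
            search_start=t_lfw,
        )

        t_gf_peak, gf_max, t_lf_peak, lf_max = detect_peaks(
            gf_f, lf, t, gf_window=(t_gf0, t_end), lf_window=(t_lf0, t_end)
        )
        events = TrialEvents(
            t_gf_onset=t_gf0,
            t_lf_onset=t_lf0,
            t_lf_weight=t_lfw,
            t_gf_peak=t_gf_peak,
            t_lf_peak=t_lf_peak,
            t_end=t_end,
        ).validate()

        plateaus = plateau_means(
            gf_f, lf, t, t_end, p.plateau_window_s, t_lf_weight=t_lfw
        )
        decay = fit_gf_decay(gf_f, t, t_gf_peak, t_end)
        coupling = xcorr_rates(gf_rate, lf_rate, t, t_lf0, t_lfw, p.max_lag_s)
        ratio_peak, ratio_plat = grip_load_ratios(
            gf_f, lf, t, t_lf_peak, plateaus
        )
        rate_max, _ = peak_gf_rate(
            gf_rate, t, (t_gf0, t_end), t_gf_peak=t_gf_peak
        )
        return TrialMetrics(
            context=context,
            events=events,
            gf_max=gf_max,
            lf_max=lf_max,
            gf_plateau=plateaus[0],
            lf_plateau=plateaus[1],
            ratio_at_lfmax=ratio_peak,
            ratio_plateau=ratio_plat,
            preload=events.preload,
            loading=events.loading,
            peak_gf_rate=rate_max,
            decay=decay,
            coupling=coupling,
            weight=weight,
        )
    except GripLiftError as exc:
        raise TrialAnalysisError(f"trial {context.label}: {exc}") from exc


def analyze_trials(
    trials: Sequence[Tuple[TrialRecording, TrialContext]],
    params: Optional[AnalysisParams] = None,
) -> Tuple[List[TrialMetrics], List[Tuple[TrialContext, str]]]:
    """Analyze a batch; failed trials are flagged and logged, not fatal.

    Returns (metrics, failures) where failures pairs each failed
    trial's context with the error message.
    """
    out: List[TrialMetrics] = []
    failures: List[Tuple[TrialContext, str]] = []
    for recording, context in trials:
        try:
            out.append(analyze_trial(recording, context, params))
        except TrialAnalysisError as exc:
            logger.warning("excluding trial: %s", exc)
            failures.append((context, str(exc)))
    return out, failures
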