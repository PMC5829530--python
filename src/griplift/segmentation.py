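"""Event detection: landmark times and phase durations of a lift.

All detectors operate on filtered forces and their finite-difference
rates and implement the sustained-threshold rules standard in the
grip-lift literature:

* onset: the first sample from which the force rate stays strictly
  above 0.4 N/s for at least 125 ms;
* trial end: the first time the load-force rate stays below -2 N/s for
  at least 125 ms (the set-down), minus a 250 ms backoff;
* lift-off: the first (interpolated) crossing of the object's weight by
  the load force;
* plateau: arithmetic means over the last second before the trial end.

Run lengths round conservatively (ceil), so at 120 Hz the 125 ms rule
requires 15 consecutive qualifying samples and the backoff is 30
samples.  Times are seconds from record start.
"""

from __future__ import annotations

import math
from typing import Optional, Tuple

import numpy as np

from .errors import (
    EndNotFoundError,
    InconsistentTrialError,
    LiftFailureError,
    OnsetNotFoundError,
)
from .records import TrialEvents

__all__ = [
    "detect_onset",
    "detect_trial_end",
    "detect_peaks",
    "weight_crossing_time",
    "plateau_means",
    "phase_durations",
]


def _run_samples(min_duration: float, fs: float) -> int:
    # ceil with a guard against float fuzz (0.125 * 120 must give 15, not 16)
    return max(int(math.ceil(min_duration * fs - 1e-9)), 1)


def _first_qualifying_run(mask: np.ndarray, n_run: int) -> Optional[int]:
    """Index of the first sample from which ``mask`` holds for >= n_run samples."""
    if mask.size < n_run:
        return None
    counts = np.convolve(mask.astype(int), np.ones(n_run, dtype=int), mode="valid")
    hits = np.flatnonzero(counts == n_run)
    return int(hits[0]) if hits.size else None


def detect_onset(
    rate: np.ndarray,
    fs: float,
    threshold: float = 0.4,
    min_duration: float = 0.125,
    search_start: float = 0.0,
) -> float:
    """Force onset: first sample of the first sustained supra-threshold run.

    The rate must exceed ``threshold`` (strictly) contiguously for at
    least ``min_duration`` seconds; the onset time is the first sample
    of that run, in seconds from record start.  The search begins at
    ``search_start``.  Raises :class:`OnsetNotFoundError` if no run
    qualifies (absent or failed lift).
    """
    rate = np.asarray(rate, dtype=float)
    i0 = int(np.ceil(search_start * fs - 1e-9))
    if i0 < 0 or i0 >= rate.size:
        raise OnsetNotFoundError(
            f"search_start {search_start:.3f} s outside the record"
        )
    n_run = _run_samples(min_duration, fs)
    hit = _first_qualifying_run(rate[i0:] > threshold, n_run)
    if hit is None:
        raise OnsetNotFoundError(
            f"no rate run > {threshold} N/s sustained for {min_duration * 1e3:.0f} ms"
        )
    return (i0 + hit) / fs


def detect_trial_end(
    lf_rate: np.ndarray,
    fs: float,
    threshold: float = -2.0,
    min_duration: float = 0.125,
    backoff: float = 0.250,
    search_start: float = 0.0,
) -> float:
    """Trial end: start of the first sustained release run minus ``backoff``.

    The load-force rate must fall below ``threshold`` contiguously for
    at least ``min_duration`` seconds.  Raises
    :class:`EndNotFoundError` if the record contains no such release.
    """
    lf_rate = np.asarray(lf_rate, dtype=float)
    i0 = int(np.ceil(search_start * fs - 1e-9))
    if i0 < 0 or i0 >= lf_rate.size:
        raise EndNotFoundError(f"search_start {search_start:.3f} s outside the record")
    n_run = _run_samples(min_duration, fs)
    hit = _first_qualifying_run(lf_rate[i0:] < threshold, n_run)
    if hit is None:
        raise EndNotFoundError(
            f"no rate run < {threshold} N/s sustained for {min_duration * 1e3:.0f} ms"
        )
    return (i0 + hit) / fs - backoff


def detect_peaks(
    gf: np.ndarray,
    lf: np.ndarray,
    t: np.ndarray,
    gf_window: Tuple[float, float],
    lf_window: Optional[Tuple[float, float]] = None,
) -> Tuple[float, float, float, float]:
    """Global force maxima within the analysis windows.

    Returns ``(t_gf_peak, gf_max, t_lf_peak, lf_max)``.  Ties break to
    the earliest time.  ``lf_window`` defaults to ``gf_window``.
    """
    t = np.asarray(t, dtype=float)
    lf_window = lf_window or gf_window

    def _peak(x: np.ndarray, win: Tuple[float, float]) -> Tuple[float, float]:
        lo, hi = win
        m = (t >= lo - 1e-12) & (t <= hi + 1e-12)
        if not np.any(m):
            raise ValueError(f"empty peak-search window [{lo}, {hi}]")
        seg = np.asarray(x, dtype=float)[m]
        i = int(np.argmax(seg))  # argmax returns the first maximum: earliest tie
        return float(t[m][i]), float(seg[i])

    t_gf, gf_max = _peak(gf, gf_window)
    t_lf, lf_max = _peak(lf, lf_window)
    return t_gf, gf_max, t_lf, lf_max


def weight_crossing_time(
    lf: np.ndarray, t: np.ndarray, weight: float, after: float = 0.0
) -> float:
    """First time (>= ``after``) the load force reaches the object's weight.

    Linearly interpolated between the bracketing samples — this is the
    one event defined by a level crossing rather than a sample test.
    Raises :class:`LiftFailureError` if the weight is never reached.
    """
    if weight <= 0:
        raise ValueError(f"weight must be positive, got {weight}")
    lf = np.asarray(lf, dtype=float)
    t = np.asarray(t, dtype=float)
    start = int(np.searchsorted(t, after - 1e-12))
    above = np.flatnonzero(lf[start:] >= weight)
    if above.size == 0:
        raise LiftFailureError(
            f"load force never reaches the object's weight ({weight:.3f} N)"
        )
    i = start + int(above[0])
    if i == start or lf[i - 1] >= weight:
        return float(t[i])
    frac = (weight - lf[i - 1]) / (lf[i] - lf[i - 1])
    return float(t[i - 1] + frac * (t[i] - t[i - 1]))


def plateau_means(
    gf: np.ndarray,
    lf: np.ndarray,
    t: np.ndarray,
    t_end: float,
    window_s: float = 1.0,
    t_lf_weight: Optional[float] = None,
) -> Tuple[float, float]:
    """Mean grip and load force over the last ``window_s`` before ``t_end``.

    The window must lie within the hold (after lift-off): if
    ``t_lf_weight`` is given and the window would start before it, an
    :class:`InconsistentTrialError` is raised.
    """
    t = np.asarray(t, dtype=float)
    lo = t_end - window_s
    if t_lf_weight is not None and lo < t_lf_weight:
        raise InconsistentTrialError(
            f"plateau window [{lo:.3f}, {t_end:.3f}] starts before lift-off "
            f"({t_lf_weight:.3f} s)"
        )
    m = (t >= lo - 1e-12) & (t <= t_end + 1e-12)
    if not np.any(m):
        raise InconsistentTrialError("plateau window contains no samples")
    return (
        float(np.mean(np.asarray(gf, dtype=float)[m])),
        float(np.mean(np.asarray(lf, dtype=float)[m])),
    )


def phase_durations(events: TrialEvents) -> Tuple[float, float]:
    """(preload, loading) durations in seconds.

    preload = tLFo - tGFo (digit contact before the pull starts);
    loading = tLFw - tLFo (pull until lift-off).
    """
    events.validate()
    return events.preload, events.loading
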