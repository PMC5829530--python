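"""Signal conditioning: zero-phase low-pass filtering, force rates, and
reconstruction of the load force after lift-off.

The conditioning contract is the standard one for grip-lift recordings:
forces and acceleration are low-pass filtered at 20 Hz with a recursive
(Butterworth) filter applied forward and backward, so the effective
response is 4th order with exactly zero phase shift; force rates are
finite differences of the filtered signals.  While the object rests on
its stand the load force comes from the stand sensor; once it is
airborne the stand reads nothing and the load force is reconstructed as
mass times the measured gravitoinertial + kinematic acceleration.
"""

from __future__ import annotations

from typing import Optional

import numpy as np
from scipy import signal as sps

from .errors import NonFiniteSignalError, ShortSignalError

__all__ = ["lowpass_filter", "force_rate", "compute_load_force"]


def _check_finite(x: np.ndarray, name: str = "signal") -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(x)):
        bad = int(np.flatnonzero(~np.isfinite(x))[0])
        raise NonFiniteSignalError(f"{name} has a non-finite sample at index {bad}")
    return x


def lowpass_filter(
    x: np.ndarray, fs: float, cutoff: float = 20.0, order: int = 2
) -> np.ndarray:
    """Zero-phase low-pass filter (forward-backward Butterworth).

    A 2nd-order recursive low-pass with -3 dB at ``cutoff`` is applied
    forward then backward (:func:`scipy.signal.filtfilt`), giving an
    effective 4th-order magnitude response and no phase distortion.
    Output has the same length as the input; passband gain is 1 (a
    constant passes through unchanged).

    Raises :class:`ShortSignalError` if the record is too short for
    stable edge handling and ``ValueError`` if ``cutoff >= fs/2``.
    """
    x = _check_finite(x)
    if cutoff >= fs / 2:
        raise ValueError(f"cutoff {cutoff} Hz must be below Nyquist ({fs / 2} Hz)")
    b, a = sps.butter(order, cutoff / (fs / 2.0))
    padlen = 3 * max(len(a), len(b))
    if x.size <= 4 * max(len(a), len(b)):
        raise ShortSignalError(
            f"signal of {x.size} samples too short to filter stably "
            f"(needs > {4 * max(len(a), len(b))})"
        )
    return sps.filtfilt(b, a, x, padlen=min(padlen, x.size - 1))


def force_rate(x: np.ndarray, fs: float) -> np.ndarray:
    """Finite-difference derivative of a force signal, N/s.

    Central differences in the interior, one-sided (second-order)
    stencils at the two boundary samples; output length equals input
    length.
    """
    x = _check_finite(x)
    if x.size < 3:
        raise ShortSignalError(f"force_rate needs >= 3 samples, got {x.size}")
    return np.gradient(x, 1.0 / fs, edge_order=2)


def compute_load_force(
    lf_stand: np.ndarray,
    az: np.ndarray,
    mass: float,
    t_liftoff: float,
    t: Optional[np.ndarray] = None,
    fs: Optional[float] = None,
) -> np.ndarray:
    """Merge the two load-force sources around lift-off.

    Before ``t_liftoff`` the load force is the stand-sensor reading;
    from ``t_liftoff`` on it is ``mass * az`` (the stand carries nothing
    once the object is airborne).  Provide either the time grid ``t`` or
    the sampling rate ``fs`` (grid assumed to start at 0).  A lift-off
    beyond the record end returns the stand channel unchanged.
    """
    if mass <= 0:
        raise ValueError(f"mass must be positive, got {mass}")
    lf_stand = _check_finite(lf_stand, "lf_stand")
    az = _check_finite(az, "az")
    if lf_stand.shape != az.shape:
        raise ValueError("lf_stand and az must have equal length")
    if t is None:
        if fs is None:
            raise ValueError("provide either t or fs")
        t = np.arange(lf_stand.size) / fs
    else:
        t = np.asarray(t, dtype=float)
    idx = int(np.searchsorted(t, t_liftoff))
    lf = lf_stand.copy()
    if idx < lf.size:
        lf[idx:] = mass * az[idx:]
    return lf
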