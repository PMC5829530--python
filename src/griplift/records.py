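"""Core data containers shared across the pipeline.

A trial is a short (a few seconds) synchronized multichannel record of a
precision-grip lift: grip force ``gf`` (normal force at the digits, N),
stand load force ``lf_stand`` (vertical pull measured through the
instrumented stand while the object rests on it, N) and ``az``, the
combined gravitational + kinematic acceleration along the object's long
axis (m/s^2).  All channels share one uniform time grid sampled at
``fs`` Hz (120 Hz in the centrifuge protocol this package targets).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional

import numpy as np

from .errors import FormatError, NonFiniteSignalError

__all__ = ["TrialRecording", "TrialContext", "TrialEvents", "GroundTruth"]

#: Tolerance on time-grid uniformity, seconds.
GRID_TOL_S = 1e-9


@dataclass
class TrialRecording:
    """Synchronized force/acceleration time series for one lift trial.

    ``lf`` is the merged load-force channel (stand sensor before
    lift-off, mass x acceleration after); it is absent on raw recordings
    and filled in by :func:`griplift.preprocess.compute_load_force`.
    """

    t: np.ndarray
    gf: np.ndarray
    lf_stand: np.ndarray
    az: np.ndarray
    fs: float = 120.0
    lf: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.gf = np.asarray(self.gf, dtype=float)
        self.lf_stand = np.asarray(self.lf_stand, dtype=float)
        self.az = np.asarray(self.az, dtype=float)
        if self.lf is not None:
            self.lf = np.asarray(self.lf, dtype=float)

    @property
    def n_samples(self) -> int:
        return self.t.size

    @property
    def duration(self) -> float:
        return float(self.t[-1] - self.t[0]) if self.t.size else 0.0

    def validate(self) -> "TrialRecording":
        """Check channel lengths, grid uniformity and finiteness.

        Raises :class:`FormatError` (or :class:`NonFiniteSignalError`)
        on the first violation; returns ``self`` so calls can be chained.
        """
        n = self.t.size
        if n < 2:
            raise FormatError("trial record needs at least 2 samples")
        for name in ("gf", "lf_stand", "az"):
            ch = getattr(self, name)
            if ch.size != n:
                raise FormatError(
                    f"channel '{name}' has {ch.size} samples, time grid has {n}"
                )
            if not np.all(np.isfinite(ch)):
                bad = int(np.flatnonzero(~np.isfinite(ch))[0])
                raise NonFiniteSignalError(
                    f"channel '{name}' has a non-finite sample at row {bad}"
                )
        if not np.all(np.isfinite(self.t)):
            raise NonFiniteSignalError("time column has non-finite values")
        if self.fs <= 0:
            raise FormatError("fs must be positive")
        dt = np.diff(self.t)
        if np.any(dt <= 0):
            bad = int(np.flatnonzero(dt <= 0)[0]) + 1
            raise FormatError(f"time grid not strictly increasing at row {bad}")
        if np.max(np.abs(dt - 1.0 / self.fs)) > GRID_TOL_S:
            bad = int(np.argmax(np.abs(dt - 1.0 / self.fs))) + 1
            raise FormatError(
                f"non-uniform time grid at row {bad}: spacing deviates from 1/fs"
            )
        return self

    def with_lf(self, lf: np.ndarray) -> "TrialRecording":
        return replace(self, lf=np.asarray(lf, dtype=float))


@dataclass(frozen=True)
class TrialContext:
    """Experimental labels attached to one trial.

    ``phase_index`` is the chronological index of the stable gravity
    phase within the session (0-based; the default profile has seven
    phases: 1, 1.5, 2, 2.5, 2, 1.5, 1 g).  ``phase`` labels the phase as
    ``"ascending"`` (up to and including the single highest-g phase) or
    ``"descending"``.
    """

    participant: str
    g_level: float
    trial_index: int
    phase: str
    mass: float
    phase_index: int = 0

    def __post_init__(self) -> None:
        if self.trial_index not in (1, 2, 3, 4):
            raise FormatError(f"trial_index must be 1..4, got {self.trial_index}")
        if self.g_level <= 0:
            raise FormatError(f"g_level must be positive, got {self.g_level}")
        if self.mass <= 0:
            raise FormatError(f"mass must be positive, got {self.mass}")
        if self.phase not in ("ascending", "descending"):
            raise FormatError(f"phase must be ascending|descending, got {self.phase!r}")

    @property
    def label(self) -> str:
        return (
            f"{self.participant}/phase{self.phase_index}"
            f"@{self.g_level:g}g/T{self.trial_index}"
        )


@dataclass(frozen=True)
class TrialEvents:
    """Landmark times of one lift, seconds from record start.

    tGFo / tLFo   grip / load force onsets (sustained force-rate rule)
    tLFw          load force reaches object weight (lift-off)
    tGFmax/tLFmax grip / load force peaks
    tEnd          analysis end (sustained release rule minus backoff)
    """

    t_gf_onset: float
    t_lf_onset: float
    t_lf_weight: float
    t_gf_peak: float
    t_lf_peak: float
    t_end: float

    def validate(self) -> "TrialEvents":
        from .errors import InconsistentTrialError

        ok = (
            self.t_gf_onset <= self.t_lf_onset < self.t_lf_weight <= self.t_end
        )
        if not ok:
            raise InconsistentTrialError(
                "event ordering violated: requires "
                f"tGFo ({self.t_gf_onset:.4f}) <= tLFo ({self.t_lf_onset:.4f}) "
                f"< tLFw ({self.t_lf_weight:.4f}) <= tEnd ({self.t_end:.4f})"
            )
        return self

    @property
    def preload(self) -> float:
        return self.t_lf_onset - self.t_gf_onset

    @property
    def loading(self) -> float:
        return self.t_lf_weight - self.t_lf_onset


@dataclass(frozen=True)
class GroundTruth:
    """Every quantity the synthetic generator imposed on one trial.

    Used by recovery tests only; real recordings have no ground truth.
    Forces are pre-noise values; times refer to the (lag-shifted)
    profiles actually written into the record.
    """

    t_gf_onset: float
    t_lf_onset: float
    t_lf_weight: float
    t_gf_peak: float
    t_lf_peak: float
    t_end: float
    gf_peak: float
    lf_peak: float
    gf_plateau: float
    lf_plateau: float
    decay_a: float
    decay_b: float
    decay_c: float
    lag_s: float
    grip_gain: float
    margin: float
    g_realized: float
    weight: float
    peak_gf_rate: float = float("nan")

    @property
    def events(self) -> TrialEvents:
        return TrialEvents(
            self.t_gf_onset,
            self.t_lf_onset,
            self.t_lf_weight,
            self.t_gf_peak,
            self.t_lf_peak,
            self.t_end,
        )
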