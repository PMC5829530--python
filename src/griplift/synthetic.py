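"""Synthetic grip-lift trials under a stepped-gravity schedule.

The generator emulates the structure of a centrifuge grip-lift session:
an instrumented test object (0.13 kg) is lifted four times in each
stable phase of a gravity profile that steps through 1, 1.5, 2, 2.5, 2,
1.5 and back to 1 g.  Each simulated trial reproduces the canonical
five-segment lift profile —

* baseline: both forces at zero, object on its stand;
* preload: grip force rises as the digits contact the object, load
  force still zero;
* loading: load force rises through the object's weight (lift-off) to a
  peak slightly above it, grip force rises in parallel;
* relaxation/hold: grip force decays exponentially to a plateau while
  the object is held stationary for ~2 s (load force = weight);
* release: load force drops steeply as the object is set down, grip
  force follows.

Loading and release ramps use a smoothstep (minimum-jerk-like) primitive
so that force rates are continuous and the sustained-rate onset rules
behave as they do on real data.  Grip force scales on the expected
weight with gain ``grip_gain`` plus an additive safety margin; the first
trial after every gravity transition carries an extra margin
(``first_trial_margin``) on top of the every-trial ``base_margin``,
mirroring the elevated first-trial grip forces seen when entering a new
gravitoinertial environment.  Every imposed quantity is returned as
:class:`~griplift.records.GroundTruth` so downstream stages can be
tested by parameter recovery.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import List, Optional, Tuple

import numpy as np
from scipy.optimize import brentq

from .errors import ConfigurationError
from .records import GroundTruth, TrialContext, TrialRecording

__all__ = [
    "GravitySchedule",
    "SimulationConfig",
    "SimulatedTrial",
    "gz_profile",
    "simulate_trial",
    "simulate_session",
]

STANDARD_GRAVITY = 9.81  # m/s^2 per 1 g


def _smoothstep(x: np.ndarray) -> np.ndarray:
    """Cubic smoothstep 3x^2 - 2x^3 clipped to [0, 1] outside the ramp."""
    x = np.clip(x, 0.0, 1.0)
    return x * x * (3.0 - 2.0 * x)


def _smoothstep_inv(y: float) -> float:
    """Inverse of the cubic smoothstep on [0, 1] (monotone there)."""
    if y <= 0.0:
        return 0.0
    if y >= 1.0:
        return 1.0
    return float(brentq(lambda x: x * x * (3.0 - 2.0 * x) - y, 0.0, 1.0, xtol=1e-12))


# ---------------------------------------------------------------------------
# Gravity schedule
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GravitySchedule:
    """Stepped Gz profile of a centrifuge run.

    ``levels`` are the stable-phase gravity levels in chronological
    order (multiples of standard gravity).  The 1 g bookends are idle
    phases of ``idle_s``; interior phases last ``stable_s``.  Steps
    into or out of 1 g use the slow transition (gentler on the
    vestibular system); all other steps use the fast one.  Both default
    transition slopes stay below 0.32 g/s.
    """

    levels: Tuple[float, ...] = (1.0, 1.5, 2.0, 2.5, 2.0, 1.5, 1.0)
    stable_s: float = 18.4
    idle_s: float = 27.4
    fast_transition_s: float = 1.6
    slow_transition_s: float = 13.4

    def __post_init__(self) -> None:
        if len(self.levels) == 0:
            raise ConfigurationError("schedule levels: empty schedule")
        if any(g <= 0 for g in self.levels):
            raise ConfigurationError("schedule levels: every g level must be > 0")
        for name in ("stable_s", "idle_s", "fast_transition_s", "slow_transition_s"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"schedule {name}: must be > 0")

    @property
    def n_phases(self) -> int:
        return len(self.levels)

    @property
    def peak_phase_index(self) -> int:
        """Chronological index of the (first) highest-g phase."""
        return int(np.argmax(self.levels))

    def phase_label(self, phase_index: int) -> str:
        """"ascending" up to and including the peak phase, then "descending"."""
        return "ascending" if phase_index <= self.peak_phase_index else "descending"

    def _phase_duration(self, phase_index: int) -> float:
        if phase_index in (0, self.n_phases - 1):
            return self.idle_s
        return self.stable_s

    def _transition_duration(self, g_from: float, g_to: float) -> float:
        if min(g_from, g_to) <= 1.0 + 1e-12:
            return self.slow_transition_s
        return self.fast_transition_s

    def breakpoints(self) -> Tuple[np.ndarray, np.ndarray]:
        """Piecewise-linear (time, g) nodes of the full profile."""
        times = [0.0]
        gs = [self.levels[0]]
        t = 0.0
        for i, g in enumerate(self.levels):
            t += self._phase_duration(i)
            times.append(t)
            gs.append(g)
            if i + 1 < self.n_phases:
                g_next = self.levels[i + 1]
                t += self._transition_duration(g, g_next)
                times.append(t)
                gs.append(g_next)
        return np.asarray(times), np.asarray(gs)

    def phase_windows(self) -> List[Tuple[float, float]]:
        """(start, end) of each stable phase, chronological order."""
        out = []
        t = 0.0
        for i, g in enumerate(self.levels):
            dur = self._phase_duration(i)
            out.append((t, t + dur))
            t += dur
            if i + 1 < self.n_phases:
                t += self._transition_duration(g, self.levels[i + 1])
        return out

    @property
    def total_duration(self) -> float:
        return float(self.breakpoints()[0][-1])


def gz_profile(t, schedule: Optional[GravitySchedule] = None):
    """Programmed Gz level (multiples of g) at time ``t`` seconds.

    Piecewise linear: constant during stable phases, linear ramps during
    transitions.  Times beyond the profile clamp to the final level.
    Accepts scalars or arrays.
    """
    schedule = schedule or GravitySchedule()
    tt = np.asarray(t, dtype=float)
    if np.any(tt < 0):
        raise ConfigurationError("gz_profile: t must be >= 0")
    times, gs = schedule.breakpoints()
    out = np.interp(tt, times, gs)
    return float(out) if np.isscalar(t) else out


# ---------------------------------------------------------------------------
# Simulation configuration
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SimulationConfig:
    """Tunable parameters of the trial generator.

    Defaults encode the study conditions the generator emulates:
    0.13 kg object sampled at 120 Hz, per-sample force noise well inside
    the +/-0.1 N sensor accuracy, per-trial gravity jitter of 0.07 g
    (the spread of the realized Gz levels in a long-arm centrifuge),
    load-force peaks 12% above the static plateau, and a grip force
    that tracks expected weight with gain 1.5 plus additive safety
    margins.
    """

    mass: float = 0.13            # kg
    fs: float = 120.0             # Hz
    g0: float = STANDARD_GRAVITY  # m/s^2 per g
    noise_sd: float = 0.05        # N, white, per force channel
    az_noise_sd: float = 0.1      # m/s^2, accelerometer channel
    g_jitter_sd: float = 0.07     # g, per-trial realized-gravity spread
    grip_gain: float = 1.5        # target grip/load ratio (dimensionless)
    base_margin: float = 1.0      # N, safety margin present on every trial
    first_trial_margin: float = 1.44  # N, extra margin on trial 1 after a switch
    overshoot_frac: float = 0.12  # LF peak fraction above plateau
    overshoot_decay_rate: float = 1.2  # N/s, settle rate of the LF overshoot
    decay_tau: float = 0.5        # s, grip-force relaxation time constant
    preload_ms: float = 70.0      # trial-1 preload duration
    later_preload_frac: float = 0.66  # trials 2-4 preload shortening
    loading_ms: float = 300.0     # loading-phase duration
    hold_s: float = 2.0           # stationary hold
    release_rate: float = -8.0    # N/s, peak load-force rate at set-down
    preload_force: float = 1.0    # N, amplitude of the slow grip build-up
    lf_settle_s: float = 0.6      # s, ceiling on LF peak -> plateau settling
    baseline_s: float = 0.5       # s, pre-contact baseline
    tail_s: float = 0.5           # s, post-release tail
    gf_release_s: float = 0.3     # s, grip release ramp
    min_release_s: float = 0.25   # s, floor on LF release ramp duration
    lag_samples: int = 0          # imposed grip->load lead, integer samples
    seed: int = 0

    _POSITIVE = (
        "mass", "fs", "g0", "grip_gain", "decay_tau", "preload_ms",
        "overshoot_decay_rate",
        "loading_ms", "hold_s", "preload_force", "lf_settle_s",
        "baseline_s", "tail_s", "gf_release_s", "min_release_s",
    )
    _NONNEGATIVE = (
        "noise_sd", "az_noise_sd", "g_jitter_sd", "base_margin",
        "first_trial_margin", "overshoot_frac",
    )

    def validate(self) -> "SimulationConfig":
        for name in self._POSITIVE:
            if not getattr(self, name) > 0:
                raise ConfigurationError(
                    f"config field '{name}' must be > 0, got {getattr(self, name)}"
                )
        for name in self._NONNEGATIVE:
            if getattr(self, name) < 0:
                raise ConfigurationError(
                    f"config field '{name}' must be >= 0, got {getattr(self, name)}"
                )
        if not 0.0 < self.later_preload_frac <= 1.0:
            raise ConfigurationError(
                "config field 'later_preload_frac' must be in (0, 1]"
            )
        if self.release_rate >= -2.0:
            raise ConfigurationError(
                "config field 'release_rate' must be more negative than -2 N/s "
                "for the release to be detectable"
            )
        min_preload_s = self.preload_ms / 1000.0 * self.later_preload_frac
        if -self.lag_samples / self.fs > min_preload_s:
            raise ConfigurationError(
                "config field 'lag_samples': a grip lag larger than the preload "
                "duration would put load-force onset before grip-force onset"
            )
        return self


@dataclass(frozen=True)
class SimulatedTrial:
    recording: TrialRecording
    context: TrialContext
    truth: GroundTruth


# ---------------------------------------------------------------------------
# Trial synthesis
# ---------------------------------------------------------------------------


def _shift_earlier(x: np.ndarray, k: int, fill: float = 0.0) -> np.ndarray:
    """Shift a profile earlier by k samples (k may be negative)."""
    if k == 0:
        return x
    out = np.full_like(x, fill)
    if k > 0:
        out[:-k] = x[k:]
        out[-k:] = x[-1]
    else:
        out[-k:] = x[:k]
        out[: -k] = x[0]
    return out


def simulate_trial(
    g_level: float,
    trial_index: int,
    config: Optional[SimulationConfig] = None,
    seed: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
) -> Tuple[TrialRecording, GroundTruth]:
    """Generate one grip-lift trial at gravity ``g_level`` (multiples of g).

    ``trial_index`` (1..4) selects the within-phase repetition: trial 1
    carries ``first_trial_margin`` on top of ``base_margin`` and a
    longer preload.  ``seed`` overrides ``config.seed``; passing an
    explicit ``rng`` overrides both (used by :func:`simulate_session`).
    Identical inputs produce bit-identical output.

    Returns the noisy recording and the imposed ground truth.
    """
    cfg = (config or SimulationConfig()).validate()
    if g_level <= 0:
        raise ConfigurationError(f"g_level must be > 0, got {g_level}")
    if trial_index not in (1, 2, 3, 4):
        raise ConfigurationError(f"trial_index must be 1..4, got {trial_index}")
    if rng is None:
        rng = np.random.default_rng(cfg.seed if seed is None else seed)

    fs = cfg.fs
    w = cfg.mass * g_level * cfg.g0  # object weight, N
    first = trial_index == 1
    preload_s = cfg.preload_ms / 1000.0 * (1.0 if first else cfg.later_preload_frac)
    loading_s = cfg.loading_ms / 1000.0
    margin = cfg.base_margin + (cfg.first_trial_margin if first else 0.0)

    t_gf0 = cfg.baseline_s
    t_lf0 = t_gf0 + preload_s
    t_pk = t_lf0 + loading_s
    t_rel0 = t_pk + cfg.lf_settle_s + cfg.hold_s
    # release ramp sized so its peak (smoothstep) rate matches release_rate
    rel_s = max(1.875 * w / abs(cfg.release_rate), cfg.min_release_s)
    t_gfrel0 = t_rel0 + rel_s
    duration = t_gfrel0 + cfg.gf_release_s + cfg.tail_s

    n = int(round(duration * fs)) + 1
    t = np.arange(n) / fs

    ov = cfg.overshoot_frac
    lf_peak = w * (1.0 + ov)

    # --- load force (true, on the digits) -------------------------------
    # Loading is a smoothstep ramp to the overshoot peak; the overshoot
    # then relaxes linearly to the static weight at overshoot_decay_rate
    # (kept between zero and the -2 N/s set-down criterion so settling
    # can never masquerade as a release, while the peak stays sharp
    # enough to localize).
    lf = np.zeros(n)
    m_load = (t >= t_lf0) & (t < t_pk)
    lf[m_load] = lf_peak * _smoothstep((t[m_load] - t_lf0) / loading_s)
    settle_s = min(ov * w / cfg.overshoot_decay_rate, cfg.lf_settle_s)
    m_hold = (t >= t_pk) & (t < t_rel0)
    if settle_s > 0:
        lf[m_hold] = w + ov * w * np.clip(
            1.0 - (t[m_hold] - t_pk) / settle_s, 0.0, 1.0
        )
    else:
        lf[m_hold] = w
    m_rel = t >= t_rel0
    lf[m_rel] = w * (1.0 - _smoothstep((t[m_rel] - t_rel0) / rel_s))

    # lift-off: load force first equals the weight
    if ov > 0:
        x_w = _smoothstep_inv(1.0 / (1.0 + ov))
    else:
        x_w = 1.0
    t_lfw = t_lf0 + x_w * loading_s

    # --- grip force ------------------------------------------------------
    # The rise is the sum of a contact transient (Gaussian saturation of
    # amplitude preload_force: brisk at contact, essentially complete by
    # load-force onset but with a small residual rate that bridges the
    # junction) and a component proportional to load force.  The total
    # grip-force rate is therefore positive throughout the rise (no
    # stationary point at the preload/loading junction, as in real
    # traces) and tracks the load-force rate over the loading phase.
    a_plateau = cfg.grip_gain * w
    gf_peak = a_plateau + margin
    if gf_peak <= cfg.preload_force:
        raise ConfigurationError(
            "config field 'preload_force' must stay below the grip-force peak "
            f"({gf_peak:.3f} N at {g_level:g} g)"
        )
    k_track = (gf_peak - cfg.preload_force) / lf_peak
    tau_contact = preload_s / 1.6
    gf = np.zeros(n)
    m_rise = (t >= t_gf0) & (t < t_pk)
    contact = cfg.preload_force * (
        1.0 - np.exp(-(((t[m_rise] - t_gf0) / tau_contact) ** 2))
    )
    gf[m_rise] = contact + k_track * lf[m_rise]
    m_post = t >= t_pk
    decay = a_plateau + margin * np.exp(-(t[m_post] - t_pk) / cfg.decay_tau)
    gf[m_post] = decay * (
        1.0 - _smoothstep((t[m_post] - t_gfrel0) / cfg.gf_release_s)
    )

    # impose the grip->load lag as an integer sample shift (earlier = leads)
    k = int(cfg.lag_samples)
    gf = _shift_earlier(gf, k)
    lag_s = k / fs
    t_gf0 -= lag_s
    t_gf_peak = t_pk - lag_s

    # --- stand sensor and accelerometer ---------------------------------
    # The stand reads the finger load force until lift-off, then unloads
    # smoothly over ~100 ms; the accelerometer reads g before lift-off and
    # load/mass afterwards (so that mass x az reconstructs the load force).
    lf_stand = lf.copy()
    m_off = t >= t_lfw
    lf_stand[m_off] = w * (1.0 - _smoothstep((t[m_off] - t_lfw) / 0.1))
    az = np.where(m_off, lf / cfg.mass, g_level * cfg.g0)

    # --- rule-based end time (analytic) ----------------------------------
    # During release, rate = -(w/rel_s) * s'(x); s'(x) = 6x(1-x).  The end
    # rule fires at the first crossing of -2 N/s, minus the 250 ms backoff.
    q = 2.0 * rel_s / w  # 6x(1-x) at the crossing
    if q < 1.5:
        x_cross = (6.0 - math.sqrt(36.0 - 24.0 * q)) / 12.0
        t_end = t_rel0 + x_cross * rel_s - 0.250
    else:  # release too gentle for the rule; should not happen with valid cfg
        t_end = t_rel0 - 0.250

    # peak grip-force rate of the imposed (noiseless) profile
    peak_rate = float(np.max(np.gradient(gf, 1.0 / fs)))

    truth = GroundTruth(
        t_gf_onset=t_gf0,
        t_lf_onset=t_lf0,
        t_lf_weight=t_lfw,
        t_gf_peak=t_gf_peak,
        t_lf_peak=t_pk,
        t_end=t_end,
        gf_peak=gf_peak,
        lf_peak=lf_peak,
        gf_plateau=a_plateau,
        lf_plateau=w,
        decay_a=a_plateau,
        decay_b=margin,
        decay_c=1.0 / cfg.decay_tau,
        lag_s=lag_s,
        grip_gain=cfg.grip_gain,
        margin=margin,
        g_realized=g_level,
        weight=w,
        peak_gf_rate=peak_rate,
    )

    if cfg.noise_sd > 0:
        gf = gf + rng.normal(0.0, cfg.noise_sd, n)
        lf_stand = lf_stand + rng.normal(0.0, cfg.noise_sd, n)
    if cfg.az_noise_sd > 0:
        az = az + rng.normal(0.0, cfg.az_noise_sd, n)

    rec = TrialRecording(t=t, gf=gf, lf_stand=lf_stand, az=az, fs=fs)
    return rec, truth


def simulate_session(
    schedule: Optional[GravitySchedule] = None,
    n_participants: int = 7,
    config: Optional[SimulationConfig] = None,
    seed: Optional[int] = None,
    trials_per_phase: int = 4,
) -> List[SimulatedTrial]:
    """Simulate a full session: every participant lifts ``trials_per_phase``
    times in every stable phase of the schedule.

    The realized gravity of each trial is the programmed level perturbed
    by ``g_jitter_sd`` (clipped positive), emulating the spread of the
    measured Gz.  Trials are returned in chronological order per
    participant.  Fully deterministic under ``seed``: every trial draws
    from an independent child stream keyed by (seed, participant, phase,
    trial).
    """
    schedule = schedule or GravitySchedule()
    cfg = (config or SimulationConfig()).validate()
    if n_participants < 1:
        raise ConfigurationError("n_participants must be >= 1")
    if seed is None:
        seed = cfg.seed

    out: List[SimulatedTrial] = []
    for p in range(n_participants):
        participant = f"P{p + 1:02d}"
        for phase_index, g_nom in enumerate(schedule.levels):
            phase = schedule.phase_label(phase_index)
            for trial_index in range(1, trials_per_phase + 1):
                ss = np.random.SeedSequence([int(seed), p, phase_index, trial_index])
                rng = np.random.default_rng(ss)
                if cfg.g_jitter_sd > 0:
                    g_real = max(g_nom + rng.normal(0.0, cfg.g_jitter_sd), 0.1)
                else:
                    g_real = g_nom
                rec, truth = simulate_trial(
                    g_real, trial_index, cfg, rng=rng
                )
                ctx = TrialContext(
                    participant=participant,
                    g_level=g_nom,
                    trial_index=trial_index,
                    phase=phase,
                    mass=cfg.mass,
                    phase_index=phase_index,
                )
                out.append(SimulatedTrial(rec, ctx, truth))
    return out
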