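"""Session-level aggregation across gravity phases.

The scientific core here is the *switching index*: when the gravity
level steps from one stable phase to the next, how much does the peak
grip force change between the last trial before the step and the first
trial after it?

    dGF = GFmax(trial 1, next phase) - GFmax(trial 4, previous phase)

and likewise dLF for load-force peaks.  The index is decomposed under
the feedforward prediction model

    dGF = alpha * m * dg * g0 + beta

where the first term is the predictive scaling of grip force to the
expected weight change (gain ``alpha``, object mass ``m``, gravity step
``dg`` in multiples of g) and ``beta`` is an additive safety margin
reflecting uncertainty.  Two competing readings are supported:

* fixed gain ("correct prediction"): alpha is held at 1.5 (the mean
  first-trial grip/load ratio) and the margin beta absorbs the rest;
* fixed margin ("incorrect prediction"): beta is held at 1.44 N (the
  margin measured in the familiar 1 g case) and the gain alpha absorbs
  the rest.

Both are exact decompositions — predictive term + beta always equals
dGF by construction; they differ only in which component is pinned.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import List, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigurationError, InsufficientDataError, UndefinedGainError
from .metrics import TrialMetrics

__all__ = [
    "SwitchRecord",
    "PredictionDecomposition",
    "PhaseSwitchSummary",
    "RegressionResult",
    "metrics_to_frame",
    "switching_indices",
    "switches_to_frame",
    "decompose_fixed_gain",
    "decompose_fixed_margin",
    "transition_table",
    "trial1_peak_regression",
    "condition_summary",
    "mean_switch_by_phase",
]

logger = logging.getLogger(__name__)

DEFAULT_ALPHA = 1.5   # fixed-gain hypothesis: mean first-trial grip/load ratio
DEFAULT_BETA = 1.44   # N, fixed-margin hypothesis: margin measured at 1 g
DEFAULT_G0 = 9.81     # m/s^2 per g

#: Columns a session metrics table must provide.
REQUIRED_COLUMNS = (
    "participant",
    "phase_index",
    "g_level",
    "trial_index",
    "gf_max_N",
    "lf_max_N",
)


@dataclass(frozen=True)
class SwitchRecord:
    """Per-participant switching indices across one gravity transition."""

    participant: str
    transition: str          # e.g. "1-1.5"
    g_prev: float
    g_next: float
    delta_g: float           # g_next - g_prev, multiples of g
    d_gf: float              # N
    d_lf: float              # N
    phase: str               # ascending if delta_g > 0 else descending
    prev_phase_index: int


@dataclass(frozen=True)
class PredictionDecomposition:
    """One reading of dGF = alpha * m * dg * g0 + beta.

    ``predictive_term`` is alpha*m*dg*g0 in newtons; the identity
    ``predictive_term + beta == d_gf`` holds exactly by construction.
    """

    mode: str                # "fixed_gain" | "fixed_margin"
    alpha: float
    beta: float
    predictive_term: float
    d_gf: float
    delta_g: float
    mass: float
    g0: float


@dataclass(frozen=True)
class PhaseSwitchSummary:
    mean: float
    sem: float
    n: int
    t_stat: float
    p_value: float


@dataclass(frozen=True)
class RegressionResult:
    slope: float
    intercept: float
    r: float
    p: float
    n: int


# ---------------------------------------------------------------------------
# Metrics table
# ---------------------------------------------------------------------------

def metrics_to_frame(metrics: Sequence[TrialMetrics]) -> pd.DataFrame:
    """Flatten per-trial metrics into a session table (one row per trial).

    Column names carry units (``_N``, ``_s``, ``_N_per_s``) so the
    written TSV is self-describing.
    """
    rows = []
    for m in metrics:
        c, e = m.context, m.events
        rows.append(
            {
                "participant": c.participant,
                "phase_index": c.phase_index,
                "g_level": c.g_level,
                "trial_index": c.trial_index,
                "phase": c.phase,
                "mass_kg": c.mass,
                "gf_max_N": m.gf_max,
                "lf_max_N": m.lf_max,
                "gf_plateau_N": m.gf_plateau,
                "lf_plateau_N": m.lf_plateau,
                "ratio_at_lfmax": m.ratio_at_lfmax,
                "ratio_plateau": m.ratio_plateau,
                "preload_s": m.preload,
                "loading_s": m.loading,
                "peak_gf_rate_N_per_s": m.peak_gf_rate,
                "decay_a_N": m.decay.a,
                "decay_b_N": m.decay.b,
                "decay_c_per_s": m.decay.c,
                "decay_tau_s": m.decay.tau,
                "decay_rmse_N": m.decay.rmse,
                "xcorr_r": m.coupling.r_max,
                "xcorr_lag_s": m.coupling.lag,
                "weight_N": m.weight,
                "t_gf_onset_s": e.t_gf_onset,
                "t_lf_onset_s": e.t_lf_onset,
                "t_lf_weight_s": e.t_lf_weight,
                "t_gf_peak_s": e.t_gf_peak,
                "t_lf_peak_s": e.t_lf_peak,
                "t_end_s": e.t_end,
            }
        )
    return pd.DataFrame(rows)


def _check_columns(df: pd.DataFrame) -> None:
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ConfigurationError(f"metrics table lacks required columns: {missing}")


def _fmt_g(g: float) -> str:
    return f"{g:g}"


# ---------------------------------------------------------------------------
# Switching indices
# ---------------------------------------------------------------------------

def switching_indices(metrics: pd.DataFrame) -> List[SwitchRecord]:
    """One switching record per participant per consecutive-phase pair.

    Requires trial 4 of the previous phase and trial 1 of the next
    phase; transitions with either missing are skipped with a log
    entry.  Records come out in chronological order within participant.
    A single-phase table yields an empty list with a warning.
    """
    _check_columns(metrics)
    records: List[SwitchRecord] = []
    phase_indices = sorted(metrics["phase_index"].unique())
    if len(phase_indices) < 2:
        logger.warning("fewer than 2 phases: no transitions to index")
        return records
    for participant, sub in metrics.groupby("participant", sort=True):
        by_phase = {pi: g for pi, g in sub.groupby("phase_index")}
        for prev_pi, next_pi in zip(phase_indices[:-1], phase_indices[1:]):
            prev = by_phase.get(prev_pi)
            nxt = by_phase.get(next_pi)
            last_trial = None if prev is None else prev[prev["trial_index"] == 4]
            first_trial = None if nxt is None else nxt[nxt["trial_index"] == 1]
            if (
                last_trial is None
                or first_trial is None
                or last_trial.empty
                or first_trial.empty
            ):
                logger.info(
                    "participant %s: transition %s->%s skipped (missing trial 4 or 1)",
                    participant, prev_pi, next_pi,
                )
                continue
            g_prev = float(last_trial["g_level"].iloc[0])
            g_next = float(first_trial["g_level"].iloc[0])
            delta_g = g_next - g_prev
            records.append(
                SwitchRecord(
                    participant=str(participant),
                    transition=f"{_fmt_g(g_prev)}-{_fmt_g(g_next)}",
                    g_prev=g_prev,
                    g_next=g_next,
                    delta_g=delta_g,
                    d_gf=float(first_trial["gf_max_N"].iloc[0])
                    - float(last_trial["gf_max_N"].iloc[0]),
                    d_lf=float(first_trial["lf_max_N"].iloc[0])
                    - float(last_trial["lf_max_N"].iloc[0]),
                    phase="ascending" if delta_g > 0 else "descending",
                    prev_phase_index=int(prev_pi),
                )
            )
    return records


def switches_to_frame(switches: Sequence[SwitchRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "participant": s.participant,
                "transition": s.transition,
                "g_prev": s.g_prev,
                "g_next": s.g_next,
                "delta_g": s.delta_g,
                "d_gf_N": s.d_gf,
                "d_lf_N": s.d_lf,
                "phase": s.phase,
                "prev_phase_index": s.prev_phase_index,
            }
            for s in switches
        ]
    )


# ---------------------------------------------------------------------------
# Prediction-model decomposition
# ---------------------------------------------------------------------------

def decompose_fixed_gain(
    d_gf: float,
    mass: float,
    delta_g: float,
    alpha: float = DEFAULT_ALPHA,
    g0: float = DEFAULT_G0,
) -> PredictionDecomposition:
    """Correct-prediction reading: gain pinned, margin free.

    predictive_term = alpha*m*dg*g0; beta = dGF - predictive_term.
    """
    if mass <= 0:
        raise ValueError(f"mass must be positive, got {mass}")
    pred = alpha * mass * delta_g * g0
    return PredictionDecomposition(
        mode="fixed_gain",
        alpha=alpha,
        beta=d_gf - pred,
        predictive_term=pred,
        d_gf=d_gf,
        delta_g=delta_g,
        mass=mass,
        g0=g0,
    )


def decompose_fixed_margin(
    d_gf: float,
    mass: float,
    delta_g: float,
    beta: float = DEFAULT_BETA,
    g0: float = DEFAULT_G0,
) -> PredictionDecomposition:
    """Incorrect-prediction reading: margin pinned, gain free.

    predictive_term = dGF - beta; alpha = predictive_term/(m*dg*g0).
    Undefined for a zero gravity step.
    """
    if mass <= 0:
        raise ValueError(f"mass must be positive, got {mass}")
    if delta_g == 0:
        raise UndefinedGainError("fixed-margin gain undefined for delta_g = 0")
    pred = d_gf - beta
    return PredictionDecomposition(
        mode="fixed_margin",
        alpha=pred / (mass * delta_g * g0),
        beta=beta,
        predictive_term=pred,
        d_gf=d_gf,
        delta_g=delta_g,
        mass=mass,
        g0=g0,
    )


def transition_table(
    switches: Sequence[SwitchRecord],
    mass: float,
    alpha: float = DEFAULT_ALPHA,
    beta: float = DEFAULT_BETA,
    g0: float = DEFAULT_G0,
) -> pd.DataFrame:
    """Transition-level means with both decompositions.

    Switching indices are first averaged across participants per
    transition (chronological order), then each mean dGF is decomposed
    under the fixed-gain and fixed-margin hypotheses.
    """
    if not switches:
        raise InsufficientDataError("no switching records to tabulate")
    df = switches_to_frame(switches)
    rows = []
    for (prev_pi, transition), sub in df.groupby(
        ["prev_phase_index", "transition"], sort=True
    ):
        d_gf = float(sub["d_gf_N"].mean())
        delta_g = float(sub["delta_g"].iloc[0])
        fg = decompose_fixed_gain(d_gf, mass, delta_g, alpha=alpha, g0=g0)
        fm = decompose_fixed_margin(d_gf, mass, delta_g, beta=beta, g0=g0)
        rows.append(
            {
                "transition": transition,
                "delta_g": delta_g,
                "phase": str(sub["phase"].iloc[0]),
                "n": int(len(sub)),
                "d_lf_N": float(sub["d_lf_N"].mean()),
                "d_gf_N": d_gf,
                "fixed_gain_pred_N": fg.predictive_term,
                "fixed_gain_beta_N": fg.beta,
                "fixed_margin_pred_N": fm.predictive_term,
                "fixed_margin_beta_N": fm.beta,
                "fixed_margin_alpha": fm.alpha,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Regressions and summaries
# ---------------------------------------------------------------------------

def trial1_peak_regression(
    metrics: pd.DataFrame, phase_filter: str = "pooled"
) -> RegressionResult:
    """OLS of first-trial grip-force peaks on load-force peaks.

    Points are per-phase participant means of trial-1 peaks (so at most
    one point per stable phase); ``phase_filter`` selects ascending
    phases (up to and including the single highest-g phase), descending
    ones (from that phase on), or all of them pooled — the highest-g
    phase contributes one point either way.
    """
    _check_columns(metrics)
    if phase_filter not in ("ascending", "descending", "pooled"):
        raise ConfigurationError(
            f"phase_filter must be ascending|descending|pooled, got {phase_filter!r}"
        )
    t1 = metrics[metrics["trial_index"] == 1]
    cells = (
        t1.groupby("phase_index")
        .agg(g_level=("g_level", "first"), lf=("lf_max_N", "mean"), gf=("gf_max_N", "mean"))
        .sort_index()
    )
    if not cells.empty:
        peak_idx = int(cells["g_level"].idxmax())
        if phase_filter == "ascending":
            cells = cells.loc[:peak_idx]
        elif phase_filter == "descending":
            cells = cells.loc[peak_idx:]
    if len(cells) < 3:
        raise InsufficientDataError(
            f"regression needs >= 3 phase-level points, got {len(cells)}"
        )
    res = stats.linregress(cells["lf"].to_numpy(), cells["gf"].to_numpy())
    return RegressionResult(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r=float(res.rvalue),
        p=float(res.pvalue),
        n=len(cells),
    )


_FACTOR_MAP = {
    "GRAVITY": "phase_index",  # chronological phase cells, g shown alongside
    "TRIAL": "trial_index",
    "PHASE": "phase",
}


def condition_summary(
    metrics: pd.DataFrame, factors: Sequence[str] = ("GRAVITY",)
) -> pd.DataFrame:
    """Mean and SEM of every numeric metric per factor cell.

    Factors: GRAVITY (the seven chronological gravity phases), TRIAL
    (1..4), PHASE (ascending/descending; the single highest-g phase is
    excluded from PHASE contrasts since it belongs to both limbs).
    Cells with one observation report SEM as missing.
    """
    if metrics.empty:
        raise InsufficientDataError("empty metrics table")
    _check_columns(metrics)
    unknown = [f for f in factors if f not in _FACTOR_MAP]
    if unknown:
        raise ConfigurationError(f"unknown factor name(s): {unknown}")
    df = metrics
    if "PHASE" in factors:
        peak_idx = df.loc[df["g_level"].idxmax(), "phase_index"]
        df = df[df["phase_index"] != peak_idx]
    keys = [_FACTOR_MAP[f] for f in factors]
    value_cols = [
        c
        for c in df.columns
        if c not in keys + ["participant", "phase", "g_level"]
        and pd.api.types.is_numeric_dtype(df[c])
    ]
    grouped = df.groupby(keys, sort=True)
    out = grouped[value_cols].agg(["mean", "sem", "count"])
    # keep the g level of each chronological cell visible
    if "phase_index" in keys:
        g_map = df.groupby("phase_index")["g_level"].first()
        out.insert(0, ("g_level", "first"), out.index.get_level_values("phase_index").map(g_map))
    return out


def mean_switch_by_phase(
    switches: Sequence[SwitchRecord], phase: str, index: str = "d_gf"
) -> PhaseSwitchSummary:
    """Mean switching index over all participant-level records in a phase,
    with SEM and a one-sample t test against zero.

    ``index`` selects ``d_gf`` (default) or ``d_lf``.
    """
    if phase not in ("ascending", "descending"):
        raise ConfigurationError(f"phase must be ascending|descending, got {phase!r}")
    if index not in ("d_gf", "d_lf"):
        raise ConfigurationError(f"index must be d_gf|d_lf, got {index!r}")
    vals = np.array([getattr(s, index) for s in switches if s.phase == phase])
    if vals.size == 0:
        raise InsufficientDataError(f"no switching records in the {phase} phase")
    mean = float(np.mean(vals))
    if vals.size >= 2:
        sem = float(np.std(vals, ddof=1) / np.sqrt(vals.size))
        t_stat, p_value = stats.ttest_1samp(vals, 0.0)
        t_stat, p_value = float(t_stat), float(p_value)
    else:
        sem = float("nan")
        t_stat = p_value = float("nan")
    return PhaseSwitchSummary(
        mean=mean, sem=sem, n=int(vals.size), t_stat=t_stat, p_value=p_value
    )
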