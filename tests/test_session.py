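"""Switching indices, prediction-model decomposition, session summaries."""

import dataclasses

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from griplift import (
    ConfigurationError,
    InsufficientDataError,
    SimulationConfig,
    UndefinedGainError,
    analyze_trials,
    condition_summary,
    decompose_fixed_gain,
    decompose_fixed_margin,
    mean_switch_by_phase,
    metrics_to_frame,
    simulate_session,
    switching_indices,
    transition_table,
    trial1_peak_regression,
)

MASS = 0.13
G0 = 9.81


def _toy_metrics(rows):
    """Minimal metrics frame: rows of (participant, phase_index, g, trial, gf, lf)."""
    return pd.DataFrame(
        [
            {
                "participant": p,
                "phase_index": pi,
                "g_level": g,
                "trial_index": ti,
                "gf_max_N": gf,
                "lf_max_N": lf,
            }
            for (p, pi, g, ti, gf, lf) in rows
        ]
    )


class TestSwitchingIndices:
    def test_peak_difference_across_transition(self):
        # trial 4 at 1 g: 3.0 N; trial 1 at 1.5 g: 5.39 N -> dGF = 2.39 N
        df = _toy_metrics(
            [
                ("P01", 0, 1.0, 4, 3.00, 1.40),
                ("P01", 0, 1.0, 1, 4.50, 1.40),
                ("P01", 1, 1.5, 1, 5.39, 2.10),
                ("P01", 1, 1.5, 4, 4.20, 2.10),
            ]
        )
        (rec,) = switching_indices(df)
        assert rec.d_gf == pytest.approx(2.39)
        assert rec.transition == "1-1.5"
        assert rec.delta_g == pytest.approx(0.5)
        assert rec.phase == "ascending"

    def test_identical_peaks_give_zero(self):
        df = _toy_metrics(
            [("P01", 0, 2.0, 4, 4.0, 2.0), ("P01", 1, 1.5, 1, 4.0, 2.0)]
        )
        (rec,) = switching_indices(df)
        assert rec.d_gf == 0.0
        assert rec.phase == "descending"

    def test_missing_trial_skips_transition(self):
        df = _toy_metrics(
            [
                ("P01", 0, 1.0, 4, 3.0, 1.4),
                ("P01", 1, 1.5, 2, 5.0, 2.1),  # no trial 1 in next phase
                ("P01", 2, 2.0, 1, 6.0, 2.8),
                ("P01", 1, 1.5, 4, 4.5, 2.1),
            ]
        )
        recs = switching_indices(df)
        assert [r.transition for r in recs] == ["1.5-2"]

    def test_single_phase_yields_empty_list(self):
        df = _toy_metrics([("P01", 0, 1.0, 1, 3.0, 1.4)])
        assert switching_indices(df) == []

    def test_synthetic_session_ascending_mean_matches_model(self):
        # with gain 1.5 and first-trial margin 1.44 N, a +0.5 g step should
        # shift the trial-1 grip peak by 1.5*m*0.5*g0 + 1.44 on average
        cfg = SimulationConfig(grip_gain=1.5, first_trial_margin=1.44)
        trials = simulate_session(n_participants=7, config=cfg, seed=21)
        metrics, _ = analyze_trials([(t.recording, t.context) for t in trials])
        switches = switching_indices(metrics_to_frame(metrics))
        asc = mean_switch_by_phase(switches, "ascending")
        expected = 1.5 * MASS * 0.5 * G0 + 1.44
        assert asc.mean == pytest.approx(expected, rel=0.10)


class TestDecompositions:
    def test_fixed_gain_printed_example(self):
        d = decompose_fixed_gain(2.29, MASS, +0.5)
        assert round(d.predictive_term, 2) == 0.96
        assert round(d.beta, 2) == 1.33

    def test_fixed_gain_negative_step(self):
        d = decompose_fixed_gain(0.81, MASS, -0.5)
        assert round(d.predictive_term, 2) == -0.96
        assert round(d.beta, 2) == 1.77

    def test_fixed_gain_zero_step_puts_everything_in_margin(self):
        d = decompose_fixed_gain(1.7, MASS, 0.0)
        assert d.predictive_term == 0.0
        assert d.beta == pytest.approx(1.7)

    def test_fixed_margin_printed_example(self):
        d = decompose_fixed_margin(2.29, MASS, +0.5)
        assert round(d.predictive_term, 2) == 0.85
        assert round(d.alpha, 2) == 1.33

    def test_fixed_margin_first_descending_step(self):
        d = decompose_fixed_margin(-1.12, MASS, -0.5)
        assert round(d.predictive_term, 2) == -2.56
        assert round(d.alpha, 2) == 4.01

    def test_fixed_margin_margin_only_change(self):
        d = decompose_fixed_margin(1.44, MASS, +0.5)
        assert d.predictive_term == pytest.approx(0.0, abs=1e-12)
        assert d.alpha == pytest.approx(0.0, abs=1e-12)

    def test_fixed_margin_zero_step_undefined(self):
        with pytest.raises(UndefinedGainError):
            decompose_fixed_margin(1.0, MASS, 0.0)

    @given(
        d_gf=st.floats(-10, 10),
        delta_g=st.floats(-2, 2).filter(lambda x: abs(x) > 1e-3),
        alpha=st.floats(-5, 5),
        beta=st.floats(-5, 5),
    )
    @settings(max_examples=200, deadline=None)
    def test_identity_and_duality(self, d_gf, delta_g, alpha, beta):
        # both readings reproduce dGF exactly, and pinning one component
        # at the other mode's estimate round-trips
        fg = decompose_fixed_gain(d_gf, MASS, delta_g, alpha=alpha)
        assert fg.predictive_term + fg.beta == pytest.approx(d_gf, abs=1e-9)
        fm = decompose_fixed_margin(d_gf, MASS, delta_g or 0.5, beta=beta)
        assert fm.predictive_term + fm.beta == pytest.approx(d_gf, abs=1e-9)
        if delta_g != 0:
            back = decompose_fixed_margin(d_gf, MASS, delta_g, beta=fg.beta)
            assert back.alpha == pytest.approx(alpha, abs=1e-6)


class TestTransitionTable:
    def test_six_transitions_in_chronological_order(self, noiseless_metrics_df):
        switches = switching_indices(noiseless_metrics_df)
        table = transition_table(switches, mass=MASS)
        assert list(table["transition"]) == [
            "1-1.5", "1.5-2", "2-2.5", "2.5-2", "2-1.5", "1.5-1",
        ]
        # decomposition identity holds row-wise in both modes
        assert np.allclose(
            table["fixed_gain_pred_N"] + table["fixed_gain_beta_N"],
            table["d_gf_N"], atol=1e-9,
        )
        assert np.allclose(
            table["fixed_margin_pred_N"] + table["fixed_margin_beta_N"],
            table["d_gf_N"], atol=1e-9,
        )

    def test_noiseless_load_steps_are_symmetric(
        self, noiseless_session, noiseless_metrics_df
    ):
        # |dLF| is identical between ascending and descending steps when
        # no noise perturbs the realized gravity: exactly so on the
        # imposed load-force peaks, and to sub-sample-alignment accuracy
        # (the true peak falls between grid points) on the measured ones
        truth_peak = {}
        for tr in noiseless_session:
            if tr.context.participant == "P01":
                truth_peak[(tr.context.phase_index, tr.context.trial_index)] = (
                    tr.truth.lf_peak
                )
        d_truth = [
            truth_peak[(i + 1, 1)] - truth_peak[(i, 4)] for i in range(6)
        ]
        assert np.allclose(
            np.sort(np.abs(d_truth[:3])), np.sort(np.abs(d_truth[3:])), atol=1e-12
        )
        switches = switching_indices(noiseless_metrics_df)
        table = transition_table(switches, mass=MASS)
        asc = table[table["delta_g"] > 0]["d_lf_N"].to_numpy()
        desc = table[table["delta_g"] < 0]["d_lf_N"].to_numpy()
        assert np.allclose(np.sort(np.abs(asc)), np.sort(np.abs(desc)), atol=2e-3)

    def test_alpha_beta_recovery_from_replicate_sessions(self):
        # 20 seeded sessions; regress the six transition-mean dGF values
        # on m*dg*g0 -> both generator parameters within 15 %
        alphas, betas = [], []
        cfg = SimulationConfig(grip_gain=1.5, first_trial_margin=1.44)
        for seed in range(20):
            trials = simulate_session(n_participants=7, config=cfg, seed=100 + seed)
            metrics, _ = analyze_trials([(t.recording, t.context) for t in trials])
            table = transition_table(
                switching_indices(metrics_to_frame(metrics)), mass=MASS
            )
            x = MASS * table["delta_g"].to_numpy() * G0
            y = table["d_gf_N"].to_numpy()
            coef = np.polyfit(x, y, 1)
            alphas.append(coef[0])
            betas.append(coef[1])
        assert np.mean(alphas) == pytest.approx(1.5, rel=0.15)
        assert np.mean(betas) == pytest.approx(1.44, rel=0.15)


class TestTrial1Regression:
    def test_collinear_points_exact(self):
        rows = []
        for pi, g in enumerate([1.0, 1.5, 2.0, 2.5]):
            lf = MASS * g * G0
            rows.append(("P01", pi, g, 1, 1.7 * lf + 0.8, lf))
        res = trial1_peak_regression(_toy_metrics(rows), "pooled")
        assert res.r == pytest.approx(1.0)
        assert res.slope == pytest.approx(1.7)
        assert res.intercept == pytest.approx(0.8)

    def test_anticorrelated_points_negative_r(self):
        rows = [
            ("P01", pi, g, 1, 10.0 - 2.0 * g, MASS * g * G0)
            for pi, g in enumerate([1.0, 1.5, 2.0, 2.5])
        ]
        res = trial1_peak_regression(_toy_metrics(rows), "pooled")
        assert res.r < 0

    def test_generator_gain_recovered_without_overshoot(self):
        # zero kinematic overshoot makes LFmax equal the static weight, so
        # the regression slope is exactly the generator's grip gain
        cfg = SimulationConfig(grip_gain=1.6, overshoot_frac=0.0)
        trials = simulate_session(n_participants=7, config=cfg, seed=31)
        metrics, _ = analyze_trials([(t.recording, t.context) for t in trials])
        res = trial1_peak_regression(metrics_to_frame(metrics), "pooled")
        assert res.slope == pytest.approx(1.6, rel=0.10)
        assert res.r > 0.95

    def test_too_few_points_rejected(self):
        df = _toy_metrics([("P01", 0, 1.0, 1, 3.0, 1.3), ("P01", 1, 1.5, 1, 4.0, 1.9)])
        with pytest.raises(InsufficientDataError):
            trial1_peak_regression(df, "pooled")

    def test_unknown_phase_filter_rejected(self, noiseless_metrics_df):
        with pytest.raises(ConfigurationError):
            trial1_peak_regression(noiseless_metrics_df, "sideways")


class TestConditionSummary:
    def test_gravity_by_trial_has_28_cells(self, noiseless_metrics_df):
        out = condition_summary(noiseless_metrics_df, ("GRAVITY", "TRIAL"))
        assert len(out) == 7 * 4

    def test_noiseless_plateau_cells_equal_weight(self, noiseless_metrics_df):
        out = condition_summary(noiseless_metrics_df, ("GRAVITY",))
        g = out[("g_level", "first")].to_numpy(dtype=float)
        lf = out[("lf_plateau_N", "mean")].to_numpy(dtype=float)
        assert lf == pytest.approx(MASS * g * G0, abs=2e-3)

    def test_single_observation_cell_has_missing_sem(self):
        df = _toy_metrics([("P01", 0, 1.0, 1, 3.0, 1.3)])
        out = condition_summary(df, ("TRIAL",))
        assert np.isnan(out[("gf_max_N", "sem")].iloc[0])

    def test_phase_contrast_excludes_peak_phase(self, noiseless_metrics_df):
        out = condition_summary(noiseless_metrics_df, ("PHASE",))
        # 196 trials minus the 28 in the single 2.5 g phase
        assert int(out[("gf_max_N", "count")].sum()) == 196 - 28

    def test_unknown_factor_rejected(self, noiseless_metrics_df):
        with pytest.raises(ConfigurationError):
            condition_summary(noiseless_metrics_df, ("WEATHER",))


class TestMeanSwitchByPhase:
    def test_printed_ascending_values_average(self):
        from griplift.session import SwitchRecord

        recs = [
            SwitchRecord("P01", tr, g0_, g1_, g1_ - g0_, d, 0.6, "ascending", i)
            for i, (tr, g0_, g1_, d) in enumerate(
                [("1-1.5", 1.0, 1.5, 2.39), ("1.5-2", 1.5, 2.0, 2.29),
                 ("2-2.5", 2.0, 2.5, 2.30)]
            )
        ]
        s = mean_switch_by_phase(recs, "ascending")
        assert round(s.mean, 2) == 2.33

    def test_symmetric_records_average_to_zero(self):
        from griplift.session import SwitchRecord

        recs = [
            SwitchRecord("P01", "a-b", 1.0, 1.5, 0.5, +1.0, 0.5, "ascending", 0),
            SwitchRecord("P02", "a-b", 1.0, 1.5, 0.5, -1.0, 0.5, "ascending", 0),
        ]
        s = mean_switch_by_phase(recs, "ascending")
        assert s.mean == pytest.approx(0.0)

    def test_single_record_has_missing_sem(self):
        from griplift.session import SwitchRecord

        recs = [SwitchRecord("P01", "a-b", 1.0, 1.5, 0.5, 2.0, 0.5, "ascending", 0)]
        s = mean_switch_by_phase(recs, "ascending")
        assert s.n == 1 and np.isnan(s.sem)

    def test_empty_phase_rejected(self):
        with pytest.raises(InsufficientDataError):
            mean_switch_by_phase([], "descending")
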