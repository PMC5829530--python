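# griplift

Analysis pipeline for precision-grip lifting experiments in variable
gravitoinertial environments (long-arm centrifuge or parabolic-flight
style protocols), from raw force/acceleration traces to the
feedforward-prediction decomposition of grip-force switching across
gravity transitions.

## The problem

When a person repeatedly lifts a small instrumented object while the
effective gravity steps through 1, 1.5, 2, 2.5, 2, 1.5, 1 g, the grip
force (GF, normal force at the digits) must track the load force (LF,
the tangential force destabilizing the grasp — the object's weight
`m·g` plus inertial terms).  The interesting physiology is in *how
fast* and *how* the motor system re-scales grip force when the
environment changes.  This package computes the standard read-outs of
that process:

* **per trial** — GF/LF onsets from sustained force-rate thresholds
  (rate > 0.4 N/s for 125 ms), preload and loading durations, lift-off
  (LF = weight), force peaks, last-second plateaus, the exponential
  grip-force relaxation `GF(t) = a + b·e^(−ct)` after the peak, and the
  lagged correlation of GF/LF rates over the loading phase (r and lag,
  positive lag = grip leads);
* **per session** — the switching index across each gravity transition,

  `ΔGF = GF_max(trial 1, next g) − GF_max(trial 4, previous g)`

  (and ΔLF likewise), trial-1 peak regressions, and condition
  summaries;
* **the prediction model** — each ΔGF is decomposed as

  `ΔGF = α·m·Δg·g₀ + β`

  where the first term is the anticipatory scaling of grip force to the
  expected weight change and β is an additive safety margin.  Two
  competing readings are supported: gain pinned at α = 1.5 with β free
  ("correct prediction"), or margin pinned at β = 1.44 N with α free
  ("incorrect prediction").  Both are exact decompositions of the same
  ΔGF.

Because raw centrifuge recordings are rarely shareable, the package
ships a synthetic-trial generator (`griplift.synthetic`) that emulates
the full grip-lift structure — preload, loading, overshoot, exponential
relaxation to a plateau, ~2 s hold, release — under the stepped-gravity
schedule, with per-trial ground truth for every imposed quantity.  The
whole pipeline is validated by parameter recovery against that ground
truth.

## Worked example

```python
from griplift import (SimulationConfig, analyze_trials, mean_switch_by_phase,
                      metrics_to_frame, simulate_session, switching_indices,
                      transition_table)

trials = simulate_session(n_participants=7, config=SimulationConfig(), seed=42)
metrics, failures = analyze_trials([(t.recording, t.context) for t in trials])

df = metrics_to_frame(metrics)
switches = switching_indices(df)
for phase in ("ascending", "descending"):
    s = mean_switch_by_phase(switches, phase)
    print(f"{phase:>10s}: mean dGF = {s.mean:+.2f} N (SEM {s.sem:.2f}, n={s.n})")

table = transition_table(switches, mass=0.13)
print(table[["transition", "delta_g", "d_gf_N", "fixed_gain_beta_N",
             "fixed_margin_alpha"]].round(2).to_string(index=False))
```

prints

```
 ascending: mean dGF = +2.31 N (SEM 0.04, n=21)
descending: mean dGF = +0.45 N (SEM 0.04, n=21)
transition  delta_g  d_gf_N  fixed_gain_beta_N  fixed_margin_alpha
     1-1.5      0.5    2.31               1.35                1.36
     1.5-2      0.5    2.44               1.48                1.57
     2-2.5      0.5    2.17               1.22                1.15
     2.5-2     -0.5    0.45               1.41                1.55
     2-1.5     -0.5    0.42               1.38                1.60
     1.5-1     -0.5    0.48               1.44                1.50
```

Reading: ascending transitions raise the trial-1 grip-force peak by
~2.3 N — roughly 0.96 N of correctly predicted weight change
(1.5 × 0.13 kg × 0.5 g × 9.81 m/s²) plus a ~1.4 N first-trial safety
margin — while descending transitions *lower* the expected load but the
margin keeps ΔGF positive.  Under the fixed-margin reading that
asymmetry appears as a gravity-step-dependent gain α instead.

The same pipeline is available from the shell:

```
griplift simulate -o session/ --seed 42
griplift analyze session/manifest.tsv -o results/
griplift session results/metrics.tsv -o results/
```

which writes per-trial CSVs + JSON sidecars, `metrics.tsv`,
`switches.tsv`, `table2.tsv` and `summary.tsv`.

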