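# phenofuse

Fusing smartphone keyboard dynamics with daily self-report in
longitudinal mental-health studies is awkward: the two sides live at
different time scales and dimensionalities. `phenofuse` implements an
integrated pipeline that brings everything to the participant-day level,
compresses the high-dimensional self-report panel with temporal
independent component analysis, and links the modalities with nested
mixed-effects models — plus a synthetic-study generator with known ground
truth so the whole chain is testable by parameter recovery.

It is aimed at digital-phenotyping and EMA researchers who have raw
keypress event logs, in-session accelerometer traces and daily Likert
panels, and want per-component effect estimates with honest family-wise
error control.

## The analysis

**Passive features.** Keypresses are segmented into typing sessions
(ended by keyboard dismissal or ≥ 6 s of inactivity). Per session:
median, 95th-percentile and mean-absolute-deviation of the inter-key
delays between successive alphanumeric presses, plus autocorrect and
backspace rates. Daily values are session means; keypress counts are
summed, and days under 750 presses are dropped. In-session accelerometer
traces are zero-phase Butterworth filtered (order 2, 4 Hz); a sample is
active when its magnitude leaves [0.95, 1.05] g, a session is active when
> 8% of its samples are, upright when median(z) < 0.1 and
median(x) ∈ [−0.2, 0.2]; daily movement/upright rates follow.

**Temporal ICA.** The log-transformed panel, participants concatenated
along time, is decomposed as

    X ≈ A S,    X: p items × n days,  A: p × q loadings,  S: q × n sources

by FastICA (parallel updates, logcosh contrast). With q = p the residual
is exactly zero. Components are canonicalized (unit-variance sources,
sign and order fixed) and restart stability is summarized by clustering
loadings across seeds.

**Fusion.** Per component, with participant i, week-in-participant j,
day k:

    y_ijk = β0 + b_i + b_ij + β1ᵀ x_ijk + ε_ijk,
    b_i ~ N(0, σ1²),  b_ij ~ N(0, σ2²),  ε_ijk ~ N(0, σ²)

on the complete-case aligned table with standardized features. Random
structure is forwards-fitted with ML likelihood-ratio tests, estimates
reported from REML, and p values Bonferroni-corrected across the whole
family with CF = n_IC · n_fixed (n_fixed = 8).

## Worked example

Generate a synthetic study with a planted effect of phone movement on
component 2 (β = −0.12), run the pipeline, and read off the estimate:

```python
from phenofuse.simulate import SyntheticTruth, simulate_study
from phenofuse.pipeline import PipelineConfig, run_pipeline_frames
from phenofuse.ica import match_components

truth = SyntheticTruth(seed=3)          # 55 participants, 5 weeks, q = 5
bundle = simulate_study(truth)
res = run_pipeline_frames(bundle["keypresses"], bundle["accel"],
                          bundle["selfreport"], PipelineConfig(q=5),
                          write=False)

print(res["provenance"]["attrition"])
perm, signs, corrs = match_components(res["decomposition"].A, truth.A)
fit = res["fits"][f"IC_{perm[1] + 1}"]   # estimated component matching IC 2
print(signs[1] * fit.beta["movement_rate"],
      fit.p_uncorrected["movement_rate"],
      fit.p_corrected["movement_rate"])
```

```
{'keyboard_days_total': 1885, 'keyboard_days_included': 1825,
 'accel_days': 1897, 'selfreport_days': 1888, 'aligned_days': 1762,
 'aligned_days_identifiable': 1762, 'excluded_units': 0}
-0.13236384691137856 1.7291848411788628e-12 6.916739364715452e-11
```

The attrition record mirrors the filters: 1885 participant-days of typing
of which 1825 clear the 750-press rule, and 1762 complete cases with all
three modalities. The matched component's movement-rate coefficient is
−0.132, close to the planted −0.12 (the Wald CI covers it), and it stays
significant after multiplying the p value by the family-wise factor
CF = 5 · 8 = 40.

The same pipeline runs from the shell:

```
phenofuse simulate --out bundle/ --seed 3
phenofuse run --keypresses bundle/keypresses.csv --accel bundle/accel.csv \
              --selfreport bundle/selfreport.csv --out results/
```

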