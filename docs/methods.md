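# Methods

`phenofuse` implements an integrated digital-phenotyping analysis: daily
keyboard-dynamics and accelerometer features are extracted from raw
smartphone event streams, the daily self-report panel is decomposed with
temporal independent component analysis (ICA), and the two sides are fused
with one nested linear mixed-effects model per component under a
family-wise Bonferroni scheme. A synthetic-study generator with known
ground truth makes every stage testable by parameter recovery.

## Keyboard dynamics

Keypresses are aggregated into *typing sessions*: a session starts at the
first press and ends when the keyboard is dismissed or after six seconds
of inactivity. A gap of exactly 6.0 s closes the session (the boundary is
read as ≥ 6 s so the rule is deterministic and testable). Within a
session, inter-key delays (IKDs) are computed between *immediately*
successive alphanumeric presses; an intervening autocorrect, backspace or
other press breaks the pair. Session statistics are

- **median IKD** — an inverse measure of typing speed;
- **95th-percentile IKD** — within-session pausing (linear interpolation
  between order statistics, the numpy default, fixed so golden values are
  stable);
- **MAD IKD** — mean absolute deviation of the session's IKDs about the
  session *median*, chosen to pair with the median-based speed measure
  (the center is a genuine free choice; the median-centered variant is the
  one implemented);
- autocorrect and backspace rates (counts over total presses);
- the total keypress count.

Sessions aggregate to participant-days by averaging (absent IKD statistics
are ignored, not zero-filled) and summing counts. Days with fewer than 750
presses are excluded; a day of exactly 750 is retained. A session belongs
to the civil date of its first keypress and is never split across
midnight; dates are taken from the input as participant-local, with no
timezone arithmetic. Keypress counts are natural-log transformed and all
features are z-scored against the grand mean/SD of the supplied table —
in the full pipeline that table is the complete-case aligned sample, and
the fitted means/SDs are returned so the transform is reproducible and
invertible.

## Accelerometer

In-session traces (gravity units required; the thresholds are meaningless
in m/s²) are low-pass filtered with a second-order Butterworth filter at
4 Hz applied forward and backward (`scipy.signal.filtfilt`). Zero-phase
filtering squares the magnitude response — the gain at the cutoff is 0.5,
not 1/√2 — and leaves peak positions untouched. Samples are *active* when
the filtered magnitude leaves the inclusive [0.95, 1.05] g band; a session
is active when strictly more than 8% of its samples are; a session is
*upright* when median(z) < 0.1 strictly and median(x) ∈ [−0.2, 0.2]
inclusive. Daily movement and upright rates divide the labelled session
counts.

Numerical choices: the sampling rate is a configuration parameter
(default 10 Hz) since magnitudes and medians are insensitive to mild
timing jitter; sessions shorter than the filter's padding minimum
(3·(order+1)+1 = 10 samples) are classified on raw magnitudes and flagged
rather than dropped; even-length medians use the midpoint convention.

## Temporal ICA of the self-report panel

Likert items are strictly positive integers, so the panel is natural-log
transformed; days with any missing item are dropped (no imputation), and
participants' day series are concatenated along the time axis into an
items × days matrix X. FastICA (parallel/symmetric updates, logcosh
contrast with a1 = 1, PCA whitening to q dimensions) estimates X ≈ A S:
A holds the item loadings, S the component time courses. With q equal to
the item count the residual vanishes; the pipeline records ‖ε‖ and all
convergence metadata.

ICA is defined only up to component order, sign and scale, so every
decomposition is canonicalized: sources are scaled to unit sample variance
(loadings absorb the scale, making them comparable across components),
each component's sign makes its largest-magnitude loading positive, and
components are ordered by explained variance ‖A·col‖². Canonicalization is
idempotent and leaves A·S unchanged.

The convergence tolerance defaults to 1e-6 (max 200 iterations, both
configurable). A looser 1e-4 rule was observed to let the symmetric update
stop at a spurious early fixed point on roughly one random start in ten —
three iterations "converged" with badly mixed components — whereas at 1e-6
the same data and start reach the correct basin in ~13 iterations. On very
small panels (a few hundred days) the tighter rule may report
non-convergence; the flag is surfaced, never hidden.

Run-to-run variability of the stochastic optimisation is assessed
ICASSO-style: R restarts with distinct seeds, all canonical mixing columns
pooled, average-linkage agglomerative clustering on dissimilarity
1 − |corr| with a configurable cut height (default 0.3). A stable solution
shows q tight clusters each containing one component from every restart.
Two further diagnostics mirror a known failure mode where one component
captures stable between-participant response offsets instead of dynamics:
the offset correlation (per-participant mean log response vs. the
participant's mean component score) and within-participant mean-centring,
after which a refit ICA should produce no high-offset-correlation
component.

## Mixed-effects fusion

For each component the model is

    y_ijk = β0 + b_i + b_ij + β1ᵀ x_ijk + ε_ijk
    b_i ~ N(0, σ1²),  b_ij ~ N(0, σ2²),  ε_ijk ~ N(0, σ²)

with participants i, weeks j nested within participant, days k within
week, and x the 8 standardized passive features (three IKD statistics,
two key-class rates, log keypress volume, movement and upright rates).
Alignment is complete-case: a day enters only if it passes the keyboard
volume filter and has accelerometer and self-report data. Weeks are 7-day
blocks counted from each participant's first retained day (the
calendar-week alternative is config-selectable). Participant-weeks with
fewer than two observations make the nested intercept unidentifiable and
are removed; the default policy drops only the offending weeks
(`drop-week`) to maximize retained data, with `drop-participant`
available, and every exclusion logged.

Estimation uses statsmodels' MixedLM with a variance-component term for
the nested week intercepts. The optimizer falls back from L-BFGS through
derivative-free methods (Powell, Nelder–Mead) because gradient-based
fits fail when a variance component sits on the zero boundary. Random
structure is chosen by forwards fitting under ML — no random effects →
participant intercept → participant + week-within-participant — each
addition tested with a 1-df chi-square LRT (conservative at the boundary;
no mixture correction, stated openly); the selected model is refit with
REML for reporting. Wald 95% CIs and p values use the normal
approximation; exact small-sample df corrections are out of scope.
Cross-checked against R `lme4` on identical data (fixed effects agree to
~1e-5, variance components to ~1e-4).

Because one model is fitted per component, p values are corrected with
the family-wise factor CF = n_IC · n_fixed (n_fixed = 8, the fixed terms
excluding the intercept); corrected values are capped at 1. Diagnostics
emit QQ tables for residuals and both random-effect sets, a standardized
residual-vs-fitted table, and Shapiro–Wilk summaries (subsampled above
4500 points where the test's p values degrade).

## Synthetic-study generator

The generator emulates the study conditions the pipeline targets: 55
participants, five 7-day weeks, ten typing sessions per day with ~1100
presses/day (log-normal across days, so a few percent of days fall under
the 750-press filter), 2% day-level missingness per modality — leaving
roughly 32 analysable days per participant — a 20-item panel mixed from
q = 5 components, and fixed effects of realistic magnitude, including the
headline planted effect of movement rate on component 2 (β = −0.12).

Raw streams are generated from per-day latent targets: inter-key delays
are log-normal with the target median (the delay law is a modelling
choice — positive, right-skewed, median-parameterizable — capped below
6 s so a session never splits); autocorrect/backspace presses are
Bernoulli-planted at target rates; stationary accelerometer sessions sit
at 1 g with 0.005 g noise while active sessions carry a 1.5 Hz, 0.35 g
burst over ~30% of samples; upright vs. flat orientations set the median
x/z targets. Planted session labels round-trip exactly through the
classifiers.

Two design choices matter for interpreting recovery results:

1. **Outcomes follow measured features.** In `simulate_study` the
   component values y are computed from the features as *measured* by the
   package's own extractors on the generated raw streams (then
   standardized), not from the pre-quantization latent targets. The
   planted β is therefore the true coefficient of the covariates the
   pipeline observes, so end-to-end recovery error isolates pipeline
   defects instead of generator round-trip noise. `simulate_latents`, used
   to validate the mixed model in isolation, instead draws Gaussian
   features directly from the model's own assumptions.
2. **Heavy-tailed latents by default.** The mixed model assumes Gaussian
   random effects and residuals, but a temporally concatenated ICA cannot
   identify Gaussian sources at all; real affect data are non-Gaussian.
   The study generator therefore defaults to Laplace draws for b_i, b_ij
   and ε (`latent_family="laplace"`), which leaves the mixed model's
   fixed-effect estimates and Wald intervals valid while giving FastICA
   the excess kurtosis it needs. Model-recovery experiments use
   `latent_family="gaussian"`.

Likert discretization (round half-up, clip to [1, 7]) is a known,
documented source of mild ICA attenuation. Missingness is completely at
random by day and modality; informative missingness is out of scope, as
are typing content, circadian structure and cycle periodicity.

## What the validation shows — problem sizes and limits

The validation suite and the reproduction script generate all data at run
time. Problem sizes were chosen to give stable estimates at interactive
runtimes: feature-extraction oracles on 500 random streams per modality;
mixing recovery at p = 10, q = 3, n = 2000 over 10 seeds; CI coverage
over 100 replicates of 40 participants × 6 weeks × 4 days; family-wise
error over 200 null replicates of 30 participants × 4 weeks × 4 days
(the reproduction script uses 60 and 100 replicates respectively); and
the end-to-end experiment over 40 seeds at the default 55-participant
scale (10 seeds in the script).

Passing these experiments shows the pipeline recovers what it planted
under its own generative assumptions. It does not certify behaviour on
real data, which departs from the generator in known ways: missingness is
informative, typing and movement have circadian and weekly structure, the
self-report mixing need not be sparse or stable over time, and the
estimated component scale is only defined up to the unit-variance
convention. The β̂ for a planted effect is attenuated by a factor
sd(y)/sd(ŷ) reflecting component-estimation noise; at the default scale
this is a few percent and well inside the Wald interval.
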