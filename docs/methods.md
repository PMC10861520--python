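# Methods

`wearra` implements an end-to-end digital-biomarker analysis for rheumatoid
arthritis (RA) wearable studies: a synthetic cohort generator that encodes the
group structure such studies assume, an activity-recognition layer with
hidden-Markov smoothing, passive (actigraphy) and active (guided-test) feature
extraction, a univariate statistics suite, and penalised multivariate models
evaluated subject-wise. This note documents the models, the choices behind
their defaults, and what the synthetic experiments do and do not demonstrate.

## Synthetic cohort generator

Real studies of this design (tens of participants, two weeks of wrist-worn
sensing plus daily smartphone tests) rarely deposit raw data, so the generator
is a first-class, tested component rather than a fixture. It simulates three
groups — healthy controls (HC), moderate RA (RA_mod) and severe RA (RA_sev) —
with defaults that match the baseline table of the study population the
package targets (28–30 HC, 13 moderate, 15 severe; PRO means such as RAPID-3
3.2 ± 0.7 vs 5.3 ± 1.1, HAQ-DI 0.63 ± 0.36 vs 1.03 ± 0.42, FACIT 49.2 → 31.9
with severity).

**PRO scores** are exact truncated normals on each instrument's range. Scores
are driven by a per-participant latent severity z ~ N(0,1) shared with the
baseline RAPID-3 draw through a coupling ρ (`pro_severity_coupling`, default
0.7), applied through the Gaussian copula so marginals stay exactly truncated
normal. FACIT couples with reversed sign (higher = less fatigue). HC RAPID-3
and HAQ-DI are degenerate at 0, matching the convention of assigning healthy
controls a zero baseline severity. Plain clipping was rejected because it
creates boundary point masses that would break distributional checks.

**Activity sequences** are semi-Markov over the broad taxonomy {sleep,
sedentary, light, MVPA} at 30-s epochs. Each night has one main sleep block
centred near 03:00 (so it spans midnight; duration = 24 h × configured sleep
fraction, jittered per subject and night). Waking segments are filled with
geometric-dwell runs whose entry probabilities are chosen so the expected
fraction of the whole day in each class matches the configured composition
(entry probability ∝ fraction / mean dwell). Group effects: MVPA fraction
HC 0.05 > RA_mod 0.035 > RA_sev 0.02; RA sleeps slightly longer and dwells
longer in sedentary.

**Heterogeneity.** Real actigraphy cohorts show large between-subject and
day-to-day variation, and the reliability and data-sufficiency experiments
are vacuous without it. Multiplicative log-normal factors (mean-one where
they would otherwise bias a configured fraction) act at the subject level on
energetic-class share (log-sd 0.35), sleep duration (sd 0.4 h), overall
movement magnitude (log-sd 0.20), and symptom rates (log-sd 0.3), and at the
day level on energetic share (log-sd 0.40), sleep (sd 0.3 h) and magnitude
(log-sd 0.25). Guided tests use subject and day coefficients of variation of
0.25 each. These values were fixed once as a realism judgement; they put
single-day feature reliability in the ICC ≈ 0.5–0.7 range, rising toward
0.9 over two weeks, which is the regime wrist-sensor studies report.

**Movement magnitudes.** The per-class raw model is gravity (slowly
re-orienting at a class-specific rate) plus zero-mean dynamic acceleration
with sd 0.005 / 0.02 / 0.06 / 0.15 g for sleep / sedentary / light / MVPA;
ambulatory classes add a periodic component at a class-typical step
frequency. Simulating 58 participants × 14 days at 30 Hz is needless at this
scale, so the generator also emits per-epoch mean movement magnitudes
directly from the same model (epoch mean of |‖a‖ − 1| ≈ sd·√(2/π), with
multiplicative noise); raw-stream synthesis is used for the HAR layer on
small cohorts, and the two representations are consistency-checked in tests.
Two RA symptom channels are injected at epoch level: movement in the 30 min
after wake-up is multiplied by the group's morning attenuation (1.0 / 0.7 /
0.5), and movement episodes are superimposed on sleep at 0.5 / 1.5 / 2.0 per
hour.

**Guided tests** per day: a wrist range-of-motion exercise (sinusoidal angle,
ROM 90 / 70 / 55°), a 30-s walk (step oscillation at 110 / 100 / 92
steps/min), a 9-hole peg test (9 touch events, mean interval 1.0 / 1.4 /
1.8 s, jitter 0.3 s), and sit-/lie-to-stand recordings containing one
plateau-ramp-plateau transition (STS 1.5 / 2.4 / 3.0 s; LTS 2.0 / 3.2 /
4.0 s).

All draws are keyed on (config seed, participant id, stream tag), so an
identical configuration reproduces every artefact bit for bit in any call
order.

## Activity recognition and HMM smoothing

Raw streams are cut into half-open 30-s windows (trailing partial window
dropped) and summarised by magnitude statistics, per-axis means,
zero-crossing rate and band power (0.5–3 and 3–8 Hz). A standardised
multinomial logistic model supplies per-epoch class posteriors; it is a
deliberately transparent stand-in for any stronger epoch classifier, and the
smoothing layer consumes only posteriors, so the classifier is replaceable.

The HMM transition matrix is estimated from labelled sequences with additive
smoothing, A[i,j] = (n(i→j) + c) / (n(i→·) + Kc); the prior π uses marginal
class frequencies (few sequences, many epochs, so initial-state frequencies
would be poorly estimated). Decoding is Viterbi in log space with
probabilities floored at 1e-12 and ties broken toward the lower class index.
Emissions default to the scaled-likelihood convention posterior/π — the
correct generative treatment when the classifier's training prior is not
uniform — with raw posteriors available via a flag for comparison.

## Passive features

Computed per participant-day, domain-tagged for the grouped models:

* **SLEEP / sleep detection** — nights run noon-to-noon so the main block
  spans midnight; sleep-labelled runs separated by gaps ≤ 30 min are merged
  (brief awakenings should not split main sleep) and the longest merged run
  whose midpoint falls in the night is that night's main sleep. Wake-up time
  is its offset.
* **TVDA** — fraction of day per class (these sum to 1), MVPA minutes, mean
  and 95th-percentile daytime magnitude (daytime = outside main sleep).
* **MORN** — mean magnitude in [wake, wake+30 min), in [wake+30, wake+90 min),
  and their ratio; null when less than 90 min of data follows wake-up.
* **NTR** — movement episodes inside the main sleep window: maximal runs of
  epochs above threshold. No threshold is standard, so the default is quiet
  reference (below-median half of the window) mean + 3 sd, configurable.
* **AF** — epochs dichotomised to active (light/MVPA-type) vs rest;
  active→rest transition probability (transitions ÷ active epochs), mean
  active bout length, bout count.
* **DEM** — age, sex, BMI replicated per row.

Missing days yield NaN features that are excluded from aggregation
denominators; nothing is imputed as zero.

## Active features

* **Wrist ROM** — angular velocity minus its mean (this removes the constant
  gyro bias, whose integral is the linear drift of the angle), trapezoid
  integration, ROM = peak-to-peak angle. A least-squares line fit on the
  angle was rejected: over a non-integer number of cycles it tilts the
  oscillation and inflates ROM by ~10%.
* **Walk** — magnitude band-passed to 0.5–3 Hz; steps are peaks above
  0.3 × sd (adaptive, so the count is scale-invariant) separated by ≥ 0.25 s;
  cadence = steps/min; regularity = autocorrelation at the dominant period.
* **Peg** — completion time (last − first event) and inter-event interval
  mean/sd.
* **Transitions** — the vertical axis is the one whose low-passed component
  changes most between the first- and last-quarter plateaus; duration is the
  10–90% crossing interval divided by 0.8, which reports the full length of
  an approximately linear transition (the plateau-crossing rule is standard
  in the sit-to-stand literature); plus peak magnitude and −log mean squared
  jerk as smoothness. Absent plateau structure (span < 0.1 g) is flagged
  rather than guessed.

## Univariate statistics

Mann-Whitney U (midrank ties; exact p for combined n ≤ 12 without ties,
tie-corrected normal approximation otherwise), Kruskal-Wallis (tie-corrected
H; exact permutation p for combined n ≤ 8 without ties, χ² with g−1 df
otherwise — the exact small-sample branch keeps the two rank tests mutually
consistent), Brown-Forsythe (ANOVA on absolute deviations from group
medians), all two-sided. Benjamini-Hochberg controls FDR. Correlations
(Pearson, Spearman) carry the conventional strength bands on |r| (> 0.75
good-to-excellent, 0.50–0.75 moderate-to-good, 0.25–0.49 fair, < 0.25 none).

Test-retest reliability is ICC(3,k), the two-way average-measures
consistency ICC with study days as raters: (MS_subjects − MS_error) /
MS_subjects from the two-way ANOVA decomposition. Negative estimates are
reported as computed and categorised poor (< 0.5; moderate to 0.75, good to
0.9, excellent above). The ICC-vs-days curve uses the first d contiguous
days, complete-case per feature, reporting median + IQR across features per
group.

## Penalised models and evaluation

One proximal-gradient solver (monotone FISTA: a momentum step is kept only
if it does not increase the objective, otherwise a plain proximal step is
taken, so the recorded objective never increases) covers the whole family:

* elastic net λ[α‖β‖₁ + (1−α)/2‖β‖₂²] (lasso α=1, ridge α=0), with the ridge
  share folded into the smooth gradient;
* sparse-group lasso λ[α‖β‖₁ + (1−α)Σ_g √p_g‖β_g‖₂] with the composed prox
  (elementwise soft-threshold, then groupwise shrinkage by √p_g), groups
  being the feature domains (DEM and PRO are their own groups).

The intercept is unpenalised; the step size is 1/L with L from the spectral
norm of the intercept-augmented design (×0.25 for logistic loss). Iteration
stops when the relative objective change drops below 1e-8 (10⁴ iterations
cap; non-convergence is flagged, not raised). First-order (KKT) optimality
is checked in the tests at a tightened tolerance, since an objective-change
criterion alone does not bound the stationarity residual.

**Evaluation protocol.** Stratified subject-wise 5-fold CV: folds partition
participants (never observations), per-fold class counts within one of
proportionality, and standardisation and median imputation are learned on
training folds only. λ is chosen by inner 3-fold subject-wise CV over 20
log-spaced points from λ_max (the smallest all-zero λ) down to λ_max·1e-3,
warm-started, with the path cut early once the validation loss is clearly
past an interior minimum. Subject-level classification outcomes are majority
votes over a participant's observation-level predictions, ties broken by the
higher mean positive-class probability (deterministic and score-consistent);
regression uses the mean prediction. Metrics: AUROC, Cohen's κ and macro-F1
(observation-wise as median + IQR across folds, subject-wise as a point
value), and r²/MAE/RMSE for regression.

**Support-recovery benchmark.** CV-minimum λ is prediction-optimal but
systematically overselects groups (measured directly on the benchmark
design). The sparse-group recovery benchmark (10 groups × 5 features, 2
active, n=200, SNR 5) therefore selects λ with the one-standard-error rule
(pointwise SE band across inner folds) on a 40-point path at α=0.3, the
standard recovery-oriented choice; `run_cv` keeps CV-minimum as its default.
The measured success rate sits at 0.88–0.92 across seeds — at, not
comfortably above, the 90% level the benchmark targets.

## Experiments

* **RA identification** — RA vs HC from active, passive and combined sources
  at fortnightly aggregation, with misclassified-participant overlap between
  sources.
* **Severity stratification** — moderate vs severe RA from PRO alone and PRO
  + sensor combinations.
* **RAPID-3 regression** — elastic net on PRO + sensors; HC are fixed at 0,
  and their out-of-fold estimates concentrate near 0.
* **Days-of-data sufficiency** — for each d in {2, 4, 7, 10, 14}, P random
  subsets of d distinct days per participant ("non-contiguous" is read as an
  unconstrained random subset — the contrast is with contiguous windows, not
  with adjacency), features averaged over the subset, folds re-drawn per
  permutation with derived seeds. Averaging d days collapses each
  participant to one observation, so observation- and subject-wise F1
  coincide here. P defaults to 100 (500 is configurable but adds nothing
  qualitative at this cohort size).
* **ICC vs days** — the reliability curve per group (HC vs RA) over the same
  grid.

Default problem sizes throughout are the study conditions: 30 HC / 13 RA_mod
/ 15 RA_sev, 14 days; the oracle benchmarks use the sizes stated above.

## What passing tests show — and what they do not

The synthetic cohort has exactly the group effects, noise structure and
missingness the generator encodes: effects are monotone with severity,
within-group distributions are log-normal/truncated-normal, wear is
continuous, and sensors are noise-free beyond the modelled components. Real
RA cohorts add device non-wear, behavioural confounders, label noise in
severity groupings, and effect sizes that vary by symptom and patient.
Passing pipelines therefore demonstrate correctness of the computations and
internal consistency of the analysis chain (oracle-verified decoding,
solvers, statistics; leakage-free evaluation; qualitative reproduction of
the expected data-volume and reliability behaviour) — not clinical
performance. Headline numbers on synthetic data (e.g. near-perfect RA/HC
separation) exceed what the corresponding real-data analyses report, as
expected for a generative model that matches the analysis assumptions.

## Numerical conventions and degenerate inputs

Probabilities are floored at 1e-12 before logs; Viterbi ties break toward
the lower class index; all-zero posterior epochs are floored with a warning.
Zero-variance features standardise with sd 1 (they contribute nothing).
Empty streams window to empty lists; single-class training folds are skipped
with a warning; AUROC is null on single-class test labels; r² is null for
zero-variance targets. Total ties make the Kruskal-Wallis H equal 0 with
p = 1. ICC matrices must be complete — callers reduce to complete cases, and
`icc_vs_days` does this per feature and day grid, logging dropped subjects.
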