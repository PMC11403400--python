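# Methods

## Problem setting

An incremental (ramp) cycle-ergometer CPET records, breath by breath,
eight channels: ergometer load (W), heart rate (bpm), VO2 and VCO2
(mL/min), minute ventilation VE (L/min), respiratory exchange ratio
RER = VCO2/VO2, and the end-tidal partial pressures PETO2 and PETCO2
(mmHg).  Tests last 8–12 minutes and differ in length between subjects,
so any whole-recording distance must handle variable-length multichannel
series.  The package partitions such recordings into *phenogroups* —
data-driven fitness profiles — and checks whether the phenogroups carry
clinical and prognostic meaning.

## Signal-cleaning cascade

Device exports contain two artefact kinds: invalid tokens ("-", ">>",
blanks) and large movement spikes.  The cascade is, in order:

1. **Sanitation.**  Non-numeric cells become 0 and are indexed.
2. **Correction.**  Each zeroed cell at index t ≥ 2 is replaced by
   `x_{t-1} + 0.5·|x_{t-1} − x_{t-2}|`, applied left to right so that
   consecutive invalid cells chain off already-corrected predecessors.
   The formula always extrapolates *upward* by half the previous step,
   including on locally decreasing traces; it is implemented exactly as
   stated rather than trend-following, and the behaviour is covered by
   tests.  A zeroed cell at t < 2 has no two predecessors; it is
   back-filled with the first subsequent valid value and flagged in the
   QC record (preserves length without inventing a trend).
3. **Quality checks.**  The load ramp must be non-decreasing (ergometer
   protocol); violations reject the recording by default, or are
   repaired by least-squares isotonic regression behind a config flag.
   Recordings of ≤ 10 samples are rejected as too short.
4. **Local-statistics filter.**  For each interior sample, μ and σ
   (population SD — so a σ = 0 neighbourhood acts as an exact-equality
   band, leaving constant series untouched) are computed over the two
   samples before and after, excluding the sample itself.  Samples
   outside μ ± σ are replaced by the mean of their immediate
   neighbours.  All statistics read the original series (single pass);
   edge samples with incomplete neighbourhoods are never altered.
5. **Smoothing.**  Recordings with ≥ 30 samples get a centred 11-sample
   moving average with edge truncation (no padding or reflection —
   truncation adds no synthetic data); shorter recordings get a second
   pass of the local filter instead.

Open ambiguities resolved here: whether the μ±σ check uses corrected or
original neighbours when violations are adjacent (original, single-pass)
and the leading-edge rule above.  Both are config-independent, fixed
choices.

## Distance, clustering and model selection

**DTW.**  The dependent multivariate variant: one warping path over the
joint channel vector with squared-Euclidean local cost.  The distance is
the summed local cost along the optimal path (no terminal square root),
which makes the per-sample decomposition below exact.  An optional
Sakoe–Chiba band (radius on |i−j|) is available for speed but off by
default, since recordings differ in length.  An independent per-channel
variant is available behind a flag.

**Scaling.**  DTW on raw units would be dominated by VO2 (~10³ mL/min)
over RER (~1).  Channels are z-scaled with moments pooled over all
samples of all training recordings of the stratum; external recordings
are transformed with the *training* moments, never refit, so they land
in the space the medoids live in.

**k-medoids.**  PAM-style alternation (nearest-medoid assignment,
in-cluster medoid update) on the precomputed DTW matrix, best of 10
k-medoids++ seeded restarts; the objective never increases across
iterations.  Instances whose medoid-set space is small (C(n,k) ≤ 200)
are solved exactly by enumeration.  Medoids are always members of the
training set.

**Model selection.**  `cvi = silhouette × dunn`, both computed from the
precomputed DTW distances (the silhouette is used on DTW although DTW is
not a metric; this is deliberate and documented).  Dunn is the minimum
between-cluster point-pair distance over the maximum within-cluster
point-pair distance; identical-point degeneracies yield +inf and are
flagged.  Ties in the argmax are broken toward smaller k; the default
search range is k = 2…8.  Men and women are fitted separately; a forced
k (default 5) mirrors the analysis choice of a common cluster count
across sexes.

**Phenogroup numbering.**  Clusters are relabelled 1…k by declining
fitness, measured as the *cluster-mean* peak VO2/kg of the members
(falling back to absolute peak VO2 when weights are unavailable).  The
mean is used rather than the medoid subject's own value because a single
participant's weight is a noisy draw and can swap adjacent labels
between the two sex models, which would corrupt pooled outcome
contrasts.  Ties keep medoid index order.

## Interpretability: distinctive regions

"Per-sample DTW distance" is defined as: from the optimal warping path
of (a, b), sample t of a receives the mean local cost over all path
cells whose a-index is t.  The multiplicity-weighted sum over samples
reconstructs the total DTW distance exactly, and the definition is
insensitive to how often a cell is revisited.

For a cluster under investigation: each in-cluster recording's
per-sample distance is averaged over all out-of-cluster recordings,
pooled onto a normalized time axis of 100 bins (recordings differ in
length, so "time stamps" are only comparable after normalization — an
interpretive choice), and the bins at or above the recording's own
q-quantile (default 0.5, ties included) are retained.  A bin survives if
at least `freq_threshold` (default 0.5) of the in-cluster recordings —
the denominator is the cluster under investigation, not the whole
dataset, since whole-dataset unanimity would be unreachable for small
clusters — retain it; surviving bins are merged into maximal runs and
runs shorter than `min_run = 2` bins are dropped.  Raising the frequency
threshold can only shrink the surviving set (tested property).  The
joint vector cost is pooled by default; per-channel pooling exists
behind a flag.

## Summary metrics

* Peak VO2, PETO2 and PETCO2: highest of the last three consecutive
  30-s interval averages, windows anchored at test end (the rule
  concerns the *last* intervals); recordings shorter than three windows
  fall back to the best available window, flagged.
* Peak HR, VE, RER, load: recording maxima.
* O2 pulse = peak VO2 / peak HR; per-kg ratios divide by body weight.
* VT2 (respiratory compensation point): the VE/VCO2 ventilatory-
  equivalent curve is smoothed (5-sample window), its minimum located,
  and VT2 is the first index after the minimum from which the smoothed
  ratio rises sustainedly; monotone-decreasing ratios yield "missing".
  The exact criterion of the classical ventilatory-equivalent method is
  not standardized; this concretization is configurable.
* VE/VCO2 slope: OLS slope of VE on VCO2 over samples up to VT2.
* Percent-predicted values use a pluggable equation table; defaults are
  HR: 220 − age, VO2: the Hansen/Wasserman cycle equations
  (men: weight·(50.72 − 0.372·age); women: (weight+43)·(22.78 −
  0.17·age)).  Prediction equations vary between labs and should be
  replaced to match local practice.
* Rest values: mean of the first 3 samples.

## Outcome analysis

Hypertension: SBP > 140 mmHg and/or DBP > 90 mmHg and/or
antihypertensive medication.  Diabetes: self-report, fasting glucose
> 7 mmol/L and/or antidiabetic medication.  Only the first
cardiovascular event per participant counts, and events within 90 days
of the test are blanked (attributed to residual therapy): the first
event at or beyond the window becomes the counted event, participants
with only blanked events are censored at their administrative censoring
date.  Blanking can only decrease the event count (tested invariant).

Kaplan–Meier curves and crude rates per 1,000 person-years are reported
per phenogroup.  The Cox model contrasts phenogroups 3, 4, 5 against
merged phenogroups 1+2 (per-phenogroup contrasts against phenogroup 1
alone are available), adjusted for age, sex (pooled model only), BMI,
hypertension, history of diabetes and/or cardiovascular disease,
antihypertensive medication, resting SBP, resting HR and peak VO2,
complete-case.  "Standardized" hazard ratios are implemented as these
covariate-adjusted HRs.  Survival machinery is lifelines; the bespoke
content is the blanking rule, the merged-reference design and the rate
bookkeeping.  Group comparison tables use two-sample Z tests
(continuous) and chi-square tests (categorical) with per-reference
marker symbols and no multiple-testing correction.

## Synthetic cohort generator

The generator emulates the study conditions: a 20 W + 20 W/min ramp
sampled every 3 s, durations uniform on 480–720 s (independent of
cluster, so DTW's variable-length contract is exercised), five
archetypes per sex whose rest/peak levels follow the clinical gradient
(peak VO2 from ≈2866 down to ≈1218 mL/min, peak HR 172→125, VE 103→52,
resting PETO2 rising and PETCO2 falling with phenogroup), female VO2/
VCO2/VE scaled by 0.7.  Channel shapes are simple parametric templates:
power-law rises for VO2/HR/VE, a power-law RER rise from ~0.82 to
~1.16, quadratics for PETO2 (mid-test dip) and PETCO2 (mid-test peak);
VCO2 = RER × VO2 keeps the gas-exchange channels consistent.  Shape
coefficients (rise exponents, dip/rise depths) are free knobs set once
to reproduce the qualitative cluster descriptions — cluster 3's late
RER surge, clusters 4–5 reaching high RER early, clusters 1 and 3 with
shallow end-tidal curves.

Per-subject variability is a multiplicative peak jitter (SD 1%) on
HR/VO2/VE and an additive end-tidal offset (SD 0.4 mmHg) — an offset,
not a scale, because between-subject end-tidal variation is a few mmHg
around an absolute ~100 mmHg level.  Breath-to-breath noise is Gaussian
per channel (HR 2 bpm, VO2/VCO2 60 mL/min, VE 3 L/min, RER 0.025,
PETO2 1.2, PETCO2 1.0 mmHg).  Contamination replaces ~1% of cells with
invalid tokens and perturbs another ~1% with spikes of at least 3
channel-SD; the first two samples are never contaminated (the correction
formula needs two intact predecessors) and the load channel is never
contaminated (it is ergometer-controlled, not a gas-exchange
measurement).  Every altered cell is logged, making the log an exact
diff between clean and contaminated series.

Covariates are drawn with cluster-graded means (age 43→65 y, weight
93→75 kg, SBP 118→131 mmHg, medication/comorbidity prevalences rising
with phenogroup).  Survival is a recurrent exponential event process
per cluster (yearly hazards 0.020, 0.025, 0.040, 0.056, 0.088 —
mirroring a realistic 20–88 per 1,000 person-year gradient) with
uniform administrative censoring at 3–10 years; all event offsets are
retained so the blanking rule has something to blank.

**What the generator does *not* model, and what passing tests therefore
do not show.**  Within-cluster (between-subject) variability is kept
deliberately small relative to archetype separation so that the planted
structure is identifiable — real cohorts have within-phenogroup spreads
comparable to between-phenogroup gaps, no crisp ground-truth labels,
correlated (not independent) channel noise, protocol heterogeneity and
informative censoring.  Recovery of k = 5, ARI ≈ 1 partition agreement
and exact region localization on synthetic data demonstrate that the
*pipeline machinery* is correct, not that five clusters exist in any
particular clinical population.

## Numerical and design choices

* ADF stationarization (diagnostics module): significance level 0.05,
  max differencing order 3, regression with constant, AIC lag
  selection; constant series are degenerate-stationary by convention.
  For cross-correlation all channels of a recording are differenced to
  the maximum order any channel needs, keeping them time-aligned.
  The clustering channel set is a configuration default justified by
  these diagnostics, not recomputed from them.
* DTW backtracking prefers the diagonal step on ties; k-medoids label
  ties go to the lowest medoid position; select_k ties to the smaller
  k; relabeling ties keep medoid order.
* The distance matrix is symmetric by construction (computed once per
  pair); the k-medoids enumeration threshold (C(n,k) ≤ 200) makes tiny
  instances exactly optimal.
* All randomness flows from a single seed per run; reruns produce
  byte-identical artifacts and manifests.

## Problem sizes used in the checks

The automated checks run cohorts of 100 recordings per sex for cluster-
number selection and partition recovery (10 seeds for the former),
24-recording planted-window cohorts for interpretability, n = 1,000 for
hazard-ratio recovery with 100 replicates of n = 400 for null coverage,
and 30-recording cohorts for the end-to-end determinism check.  These
sizes give stable statistics for every quantity measured while keeping
a full run in the minutes range on one CPU.

## Known limitations

* The correction formula's upward bias on decreasing traces is faithful
  to its stated form but physiologically odd; heavy contamination of a
  falling channel (PETO2 early in exercise) can drift upward.
* DTW is not a metric (no triangle inequality); silhouette and Dunn
  values on DTW distances are heuristics, not geometry.
* The VT2 detector and percent-predicted equations are concretizations
  of lab-dependent conventions; treat their defaults as replaceable.
* Nearest-medoid assignment gives hard labels with no uncertainty; no
  soft clustering or barycenter averaging is provided.
* The survival simulator has no competing risks or time-varying
  covariates, and the Cox model assumes proportional hazards.
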