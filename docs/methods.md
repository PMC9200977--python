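# Methods

`pupilperim` implements a chromatic-pupilloperimetry analysis pipeline: it
simulates per-target pupil light reflex (PLR) recordings for a case/control
cohort, extracts 17 kinetic parameters per response, trains one boosted
classifier per (parameter, stimulus condition, eye) feature table, evaluates
each classifier with a stratified out-of-bag bootstrap, and compares the two
groups' pupil response latency at the most discriminative visual-field
targets. This note documents the models, the defaults and why they were
chosen, and what the synthetic validation does and does not show.

## Stimulus protocol and geometry

Four chromatic conditions are modelled: dim red (624 nm, 1000 cd/m², mainly
cone-driven), dim blue (485 nm, 170 cd/m², mainly rod-driven), and bright
red/blue (6000 cd/m², probing the melanopsin-mediated sustained response,
with red as the luminance-matched control), on a 0.04 cd/m² mesopic
background. Dim stimuli last 1 s with a 4 s recording at each of 54 targets;
bright stimuli last 8 s with a 16 s recording at 4 targets (two central, two
peripheral).

The 54 dim targets follow the standard 24-2 perimetry pattern: rows at
y ∈ {±3, ±9, ±15, ±21}°, |x| ≤ 21°, plus two nasal extension points at
(|x| = 27°, y = ±3°). Targets are indexed 1–54 row-major from the superior
field, ascending x. The left-eye grid is the horizontal mirror of the
right-eye grid with identical indices; x > 0 is the temporal field of the
right eye. Indices 27 and 36 are the peripheral temporal pair
(x = +21, y = ±3) where the simulated group effect is injected.

## Waveform model

The generator produces the noise-free diameter

    D(t) = D_b − A · k(t − L) − sustained(t),
    k(u) = (u/t_p)² · exp(2(1 − u/t_p)) · exp(−max(0, u − t_p)/τ_r),

a gamma-shaped contraction kernel with unit peak at u = t_p. It was chosen
for three properties: smooth onset with zero initial velocity, a closed-form
trough (depth A at exactly t = L + t_p), and a closed-form time of maximal
contraction velocity, L + t_p(1 − √2/2), which gives the extraction stage an
analytic oracle. Redilation decays exponentially with time constant τ_r; the
redilation factor equals 1 at the peak so the waveform is continuous there,
but its slope jumps from 0 to A/τ_r — the trough is a corner, which is why
the extractor refines it with a two-sided fit (below). Bright conditions add
a sustained component A_s(1 − e^{−u/τ_s}) while the light is on, decaying
with time constant 2τ_s after offset. Gaussian noise of SD σ is added per
sample.

## Cohort model and its calibration

Defaults reproduce the target study design: 186 subjects (125 FH+ with a
parental history of Alzheimer's disease, 61 FH−), ages drawn from group
normals N(59.93, 6.69) / N(59.08, 5.56) truncated to 44–71 years, and
female fractions 60%/74%. Each subject carries one physiology draw
(baseline ≈ N(6.0, 0.5) mm, fractional contraction ≈ N(15%, 3%) — above the
≥10% the stimulus intensities are chosen to evoke — t_p ≈ N(0.90, 0.08) s,
τ_r ≈ N(1.5, 0.25) s). Latency structure: a subject-level effect latency
drawn from N(0.450, σ_b) for FH+ or N(0.477, σ_b) for FH−, shared across the
two effect targets of both eyes; a subject-level background latency
N(0.460, σ_b) shared across all other targets; and independent per-response
jitter N(0, 0.005 s).

The dispersion defaults (σ_b = 0.012 s between subjects, 0.005 s per-target
jitter, 0.015 mm sample noise) are calibrated so the default cohort lands in
the discriminability regime the analysis is designed for — dim-blue PRL
out-of-bag AUC around 0.85 with the averaged weight map dominated by the two
injected targets — rather than to the raw dispersion of a clinical cohort,
which includes many sources of heterogeneity (optics, fatigue, medication,
iris mechanics) the simulator deliberately omits. Consequences to keep in
mind: synthetic group standard errors are several-fold smaller than clinical
ones, and passing recovery tests demonstrates internal consistency of the
pipeline under Gaussian assumptions, not clinical performance.

Sampling is 30 Hz by default (configurable); infrared video pupillometers
vary, and the acquisition rate of the reference hardware is not specified.

Blinks: with probability `blink_rate` (default 2%) a response receives a
~150 ms gap of missing samples. Mirroring the acquisition rule that targets
blinked on during the first 2.5 s are automatically retested, gaps are only
ever placed after 2.5 s, and each rejected placement is counted as a retest.

Missingness: whole responses are blanked uniformly at random at rate 0.76%
(the documented missing-data rate), which blanks one cell in each of the 17
per-parameter feature tables — missingness is a feature-level phenomenon,
matching an imputation step that operates on feature cells rather than raw
samples.

## Parameter extraction

Velocity and acceleration are the analytic first and second derivatives of a
Savitzky–Golay local-polynomial fit (window 7 samples, order 2 at 30 Hz;
both configurable). Missing samples are linearly interpolated before
smoothing and re-flagged; traces more than 50% missing are rejected
(all 17 parameters missing).

Pupil response latency (PRL) is detected in three stages: (1) locate the
maximal contraction speed (MCV) in the contraction window and require it to
exceed 3× the robust velocity-noise floor (estimated from median absolute
first differences of the raw trace propagated through the derivative
kernel), otherwise PRL is undefined; (2) bracket the onset between the
walk-back 10%-of-MCV crossing and the half-MCV crossing; (3) localise it by
change-point least squares on the *raw* trace — flat baseline before L, a
quadratic decline after L on a first pass, then a gamma-form decline
c·u²·e^{−βu} with β set from the provisional onset-to-trough interval. The
raw-trace change-point is used because smoothing smears the onset kink
across the filter half-window, biasing any smoothed-velocity zero crossing
roughly two samples early at 30 Hz; the change-point detector recovers
noise-free latencies to < 10 ms and noisy (σ = 0.015 mm) latencies with
≈ 3 ms bias and ≈ 13 ms SD.

The trough (LMP, AC) is refined to sub-sample resolution by intersecting a
cubic fitted to the raw samples before the grid minimum with a quadratic
fitted after it, because the model trough is a corner; this recovers
noise-free amplitudes to < 1e-3 mm. Baseline D_b is the mean of the first
two smoothed samples (traces start at stimulus onset, before any
physiological response; a dedicated pre-stimulus window can be configured
when present).

The 17 parameters: AC = D_b − trough, PPC = 100·AC/D_b, PRL, LMP, and the
velocity/acceleration extrema of each arm — MCV/LMCV and MCA/LMCA on
[PRL, LMCV], MCD/LMCD on [LMCV, LMP], MRV/LMRV, MRA/LMRA, MRD/LMRD on the
post-trough redilation, and PRP = 100·(D_end − trough)/AC clipped to
[0, 100], with D_end the mean of the last two smoothed samples. All
latencies are measured from stimulus onset. Contraction-arm latencies are
clamped to LMP so the ordering PRL ≤ LMCV ≤ LMP and PRL ≤ LMCA ≤ LMCD ≤ LMP
holds even when sub-sample refinement moves LMP a fraction of a sample.
AC and PRP are operational readings of the parameter abbreviations and are
isolated behind `ExtractionSettings` so alternative definitions can be
swapped without touching callers.

## Feature tables and preprocessing

Each (parameter, condition, eye) yields one subjects × targets matrix
(54 columns dim, 4 bright); a full cohort gives 17 × 4 × 2 = 136 tables,
each feeding one classifier. Subjects lacking either eye are excluded (the
design requires both eyes eligible). Missing cells are mean-imputed per
column; columns with no observed value are dropped with a warning. All
columns are then min–max rescaled to [0, 1]; constant columns map to 0.5
(equally uninformative wherever they land), and held-out values are imputed
and scaled with training statistics and clipped to [0, 1].

Whether preprocessing is fit once globally or inside each bootstrap
replicate is not fully pinned down by the source description; the default
refits per replicate on in-bag rows (leakage-safe), and
`global_preprocess=True` reproduces the whole-dataset reading.

## Classifier

Discrete AdaBoost over depth-1 threshold stumps, T = 50 rounds by default
(no hyperparameters are documented for the reference analysis; 50 is a
conventional choice). Candidate thresholds sit at midpoints between sorted
distinct feature values; ties in weighted error break to the lowest feature
index, then the lowest threshold, then positive polarity, making training
fully deterministic. Boosting stops early at zero weighted error (stump
kept) or error ≥ 1/2 (stump discarded). Scores are signed margins
Σ α_t h_t(x). Per-feature weights are the normalised sums of |α_t| over the
stumps using each feature; this is the definition behind the visual-field
weight maps. AUC-ROC is the Mann–Whitney concordance probability with ties
counted 1/2.

## Bootstrap inference

Per replicate: a stratified bootstrap draw (class-size samples with
replacement within each class, so the in-bag sample has size n at the
original class frequencies), preprocessing and training on in-bag rows,
scoring of the never-drawn (out-of-bag) subjects, and recording of the AUC
and the model's weight vector. Replicates whose out-of-bag set lacks a class
are skipped and counted, not resampled. B = 2000 replicates by default;
summaries are the mean, SD, and 2.5/97.5 percentile CI of the AUC, and the
renormalised mean weight map. The percentile CI is used because the source
procedure cites non-parametric resampling without naming a CI estimator.
Replicate r draws from a generator seeded with (master_seed, r), so results
are reproducible and order-independent. For n = 186 the expected distinct
out-of-bag count is n(1 − 1/n)^n ≈ 68, and the observed mean out-of-bag size
(~68.4) is reported as-is.

## Focal analysis

Targets whose averaged weight strictly exceeds a threshold are selected
(0.47 is the documented reference value and the package default; synthetic
weight maps are flatter because 50 boosting rounds spread residual weight
over noise stumps, so recovery tests on synthetic cohorts pass an explicit
threshold of 0.08, well above both the uniform level 1/54 ≈ 0.019 and the
noise ceiling ≈ 0.06). Each subject's focal value is the mean of the
parameter over the selected targets (the aggregation rule is not documented;
the mean is the natural reading of a single group mean over two targets).
Groups are compared with a two-sided pooled-variance t-test (the Welch
variant is available via `equal_var=False`) and with the general linear
model value ~ group + age,
whose adjusted group means are evaluated at the overall mean age. P-values
are Bonferroni-corrected by the number of selected targets per eye. Two
identical constant samples compare at p = 1 by convention.

## Problem sizes used in validation

The test suite exercises the full 186-subject design wherever a check is
tied to it (latency recovery, signal recovery, monotonicity: 10 seeded
effect runs, 3 monotonicity cohorts, B = 200), and reduced designs
elsewhere (50 null-calibration cohorts at n = 40, B = 200; pipeline
enumeration at n = 12, B = 4). The acceptance script simulates one full
dim-blue right-eye cohort for latency recovery and one full four-condition,
two-eye cohort (43k traces) for missingness accounting.

## Known limitations

* The generator is Gaussian and stationary: no pupillary hippus, drift,
  fatigue across the ~2×108-target session, or consensual-reflex coupling;
  blinks are single clean gaps rather than partial-occlusion artefacts.
* A single latency effect shared across both eyes is injected; the package
  does not model eye-asymmetric effects (the reference observation of a
  2-target right-eye / 1-target left-eye pattern arises only by sampling
  variation here).
* AC and PRP definitions are stand-ins for undocumented supplementary
  definitions, as is the baseline window.
* Null-calibration results use AdaBoost out-of-bag AUC, whose per-replicate
  distribution is slightly pessimistic (training noise); the mean stays
  within [0.45, 0.55] but individual replicates vary widely at small n.
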