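# Methods

This note documents the models, algorithms, parameter choices and known
limitations of `hypnostates`, in the order data flows through the
pipeline.

## Synthetic cohort generator

The generator emulates a task-EEG cohort losing responsiveness to
auditory stimuli as drowsiness sets in. Each subject is a pure function
of `(CohortSpec, seed)`; all randomness flows through
`numpy.random.default_rng` substreams keyed on the seed.

**Behaviour.** Stimuli arrive with gaps `isi_min + Exp(isi_mean −
isi_min)` (defaults 6.2 s minimum, 8.4 s mean). While responsive, each
stimulus draws a lognormal reaction time with distribution mean 1.5 s and
SD 0.7 s, truncated at 6 s (resampled), except for a 2% miss rate. A
40-s transition band ramps the miss probability linearly to its
unresponsive level; after the onset (default 420 s of a 780-s recording)
responses occur only at a 2% leak rate. The 780-s default is the shortest
round length that comfortably holds the two 5-min analysis windows plus
the transition; longer recordings only add trials.

**Microstate truth.** Four planted topographies are analytic
idealisations of the canonical A–D shapes, given a smooth per-subject
random perturbation (relative amplitude 0.15) and then Löwdin
orthogonalised — orthogonality is what makes "well-separated clusters" a
controlled property rather than an accident of geometry. The label
sequence is semi-Markov: run lengths are geometric with a 2-sample floor
and mean equal to the configured dwell (responsive 40 ms for all maps;
unresponsive 55/50/55/90 ms for A/B/C/D), and successive labels are drawn
from next-state weights solved by fixed-point iteration so that the
stationary occupancy matches the coverage targets (responsive
26/28/27/19%; unresponsive 22/18/25/35%) despite the no-self-transition
constraint.

**Coupling episodes.** The unresponsive span carries a slow alternating
on/off process (exponential episodes, mean 4 s each). During "on"
episodes the theta ROI oscillators are phase-consistent (and 2.5× louder);
during "off" episodes each channel's phase random-walks independently,
destroying phase consistency without changing band power. Microstate D's
coverage is 60% inside episodes and 10% outside (preserving the 35%
state-level target). The episode timescale is deliberately matched to the
memory of a 0.25-Hz narrowband filter (~4 s): a coupling gated strictly
per 90-ms microstate run is invisible after such filtering, whereas
episode-level coupling tracked by D-occupancy is exactly the kind of
slow covariation that microstate-conditioned pooling can recover. This is
the generator's mechanism for "microstate D captures elevated frontal
theta coupling".

**Signal.** Per sample: (active map) × (60 µV amplitude-modulated carrier
at 10 Hz while responsive, 5.5 Hz after onset) + ROI oscillators
(per-channel 4 µV × Gaussian spatial gain; posterior channels phased near
zero, anterior channels a travelling-wave gradient starting π/4 later, so
anterior–anterior and anterior–posterior pairs see constant non-zero
lags) + 2 µV white noise, then average-referenced per sample. Carrier and
oscillator phases each carry slow Brownian drift so the two components
decorrelate over a few seconds; cluster principal components therefore
average the oscillator leak away, keeping planted-map recovery above
0.95 |correlation| at GFP peaks.

**What the generator does not emulate:** sleep grapho-elements (spindles,
K-complexes), ocular/muscle artifacts, 1/f background spectra,
inter-channel noise correlations from volume conduction, bad channels, or
drifting electrode impedances. Consequently, green tests demonstrate that
the *pipeline* recovers what was planted under clean conditions; they do
not certify performance on real recordings.

**Measured vs planted dynamics.** Labelling noise attenuates the planted
dwell contrasts: with an oscillatory carrier, samples near carrier zero
crossings are noise-dominated and fragment runs, more so at 5.5 Hz than
at 10 Hz. The D effects (duration, coverage, GEV, theta coupling) survive
this attenuation by design margin; the smaller uniform duration increase
planted for A–C may not.

## I/O and preprocessing

Recordings travel as 16-bit EDF (1-s records, physical range symmetric
per file, quantisation step ≤ 2·physmax/65534) written by a
self-contained encoder and read back through MNE's EDF reader — the round
trip is checked against that independent implementation. Events are plain
CSV (`stim_time_s, category, response_time_s`), sorted on read.

The band-pass (default 1–40 Hz) is a zero-phase cascade of Butterworth
high-pass and low-pass sections with orders chosen by `buttord` to give,
after the forward–backward pass, ≥ 40 dB attenuation at `low/2` and at
`min(2·high, 0.98·Nyquist)`, ≤ 1 dB passband ripple, and a low-pass
stopband edge at `1.25·high` so that 50 Hz mains is below 1% amplitude
for the standard band. Zero-phase filtering avoids shifting microstate
boundaries. The first/last second is flagged as edge-contaminated and is
excluded from GFP-peak selection. Channel (temporal) mean subtraction
precedes common-average re-referencing; re-referencing is idempotent.

## Segmentation

A trial is a hit if a response follows within the liberal 6-s window,
regardless of correctness. The responsive window is fixed at
[30 s, 330 s); the unresponsive window is found by exhaustive search
(1-s steps) for the 5-min window maximising the miss count (ties: the
smallest miss-to-hit ratio, then the earliest start — the search
objective is stated by the protocol, the tie-breaks are this package's).
Around every hit inside the unresponsive window, ±10 s are excluded from
its sample mask. Half-open second intervals convert to samples by
`floor(t·fs)`.

## Microstate core

**Clustering (modified k-means).** Input samples (GFP peaks) are
average-referenced and unit-normalised; k random samples initialise the
maps; assignment is by highest absolute spatial correlation; each map is
re-estimated as the first principal component of its cluster. On
unit-norm, mean-free samples the GEV reduces to the mean squared spatial
correlation, and both alternating steps provably increase it, so each
restart's GEV trace ascends monotonically; iteration stops at a GEV gain
below 1e-9 or 1000 iterations. Twenty restarts are run and the best kept
(the classic description uses a single initialisation; restarts and
worst-explained-sample reseeding of empty clusters are this package's
robustness additions). Map signs are fixed by making the
largest-magnitude channel positive. k = 4 by convention.

**GEV.** `GEV_i = Σ_{t:label=i} (GFP_t · corr(x_t, map_i))² / Σ_t GFP_t²`
with population-SD GFP (Lehmann–Skrandies convention) and per-map values
summing to the total. The per-map normalisation by total squared GFP is
one of several readings of the phrase "normalised by the GFP of the
microstate topography" found in the literature; this one is the standard
GEV and is locked in by a brute-force oracle test at 1e-12.

**Labelling and smoothing.** Per-sample argmax of |spatial correlation|
(ties → lowest index). Optional windowed smoothing reassigns each sample
to minimise `(unexplained variance)/(2σ²(N−1)) − λ·(same-label neighbours
within ±b)` with b = 5 samples (20 ms at 500 Hz) and λ = 5. σ² is
estimated once from the initial labelling and held fixed — this makes the
objective identical across passes and lets an exact dynamic program over
the global objective serve as an oracle. Updates are simultaneous per
pass (stopping on a fixed point, a 2-cycle, or 100 passes); the smoother
is a local minimiser, tested to reach the DP optimum on constructed cases
and to never increase the shared objective. λ is not fixed by any
published value we rely on; it is exposed in the API.

**Metrics.** Duration = mean contiguous run length (runs truncated by
span or mask edges count; a never-visited map reports 0.0 so downstream
feature vectors stay finite); coverage sums to 100%; GEV as above. With a
sample mask the sequence is split at mask gaps so runs never bridge an
excluded interval.

**Template ordering.** Fitted maps are ordered A–D by exhaustively
maximising summed |correlation| against analytic template shapes
(diagonal gradients, anterior–posterior gradient, fronto-central blob).
These templates are *not* published group-average maps; they only fix
label order, and the exhaustive matcher is verified against an
optimal-assignment oracle.

## Spectral power and connectivity

The filter bank is 76 half-open 0.25-Hz bins spanning 1–20 Hz
(theta = 5–6 Hz, alpha = 9.5–10.5 Hz as named unions of whole bins). Each
bin filter is a zero-phase 4th-order Butterworth with design edges padded
by 0.1 Hz, so a tone at a bin edge keeps ≥ 95% of its amplitude while a
tone 5 Hz away is suppressed below 1e-3. Relative power divides each
bin's mean squared analytic amplitude by the 1–20 Hz total per channel
(× 100).

WPLI is the amplitude-weighted imaginary cross-spectrum ratio, pooled
over arbitrary sample masks and averaged across a band's bins; a
phase-only variant (unit-modulus) is available behind a flag. Pairs with
vanishing denominator are flagged degenerate and reported as 0 so ROI
medians stay defined. `band=None` computes the analytic signal of the
input as given (no filter bank): that is the estimator-level view used
for null calibration — after 0.25-Hz filtering a 20-s record holds only
~T×bandwidth ≈ 10 effective samples, so the narrowband null reflects
filter memory, not the estimator. Microstate-conditioned WPLI pools the
samples of each label (optionally intersected with a state mask),
filtering once per bin and sharing it across the k masks. ROI summaries
are medians over unique within-anterior (171), within-posterior (190) and
between (380) channel pairs.

The cohort pipeline evaluates connectivity on the 39 ROI channels rather
than all 63: every reported quantity is an ROI-pair median, for which the
submatrix is sufficient at ~40% of the cost.

## Responsiveness prediction

For every stimulus, the 5 s immediately preceding it are labelled with
the group model (smoothed, b=5, λ=5) and summarised as 12 microstate
parameters (duration, coverage, GEV × A–D) plus the median-across-channels
theta–alpha power ratio. Trials whose window starts before the recording
or contains any button event are excluded with a recorded reason (~8–10%
on default cohorts). The per-trial band-power series is computed once per
subject on a 10× FIR-decimated signal (50 Hz effective rate, still 2.5×
the 20-Hz ceiling) — windows only average this series, so decimation is
immaterial to the features and ten times cheaper.

Classification is leave-one-subject-out: per fold, features are z-scored
with training statistics; the box constraint and kernel scale are
selected from 7×7 log-decade grids (1e-3…1e3; `gamma = scale⁻²`) by
grouped 3-fold inner cross-validation on training subjects maximising
AUC (the exhaustive-grid convention fixes the candidate set but not the
selection objective; maximising inner AUC is this package's choice); the
final RBF-SVM's margins are
Platt-calibrated on the training fold only. AUC is trapezoidal over the
empirical ROC; accuracy is evaluated at the Youden-optimal threshold
(ties → lower threshold). Both fold-mean and pooled-over-trials summaries
are reported, since either convention appears in practice. Single-class
held-out folds are flagged and omitted from the mean with a warning.
Feature-set comparisons use exact paired Wilcoxon signed-rank tests on
per-subject AUCs.

## Group statistics

The two-way fully-within-subject ANOVA (microstate × state) is computed
directly from the balanced sums of squares, each effect tested against
its subject-interaction error term; Mauchly's test and Greenhouse–Geisser
ε come from the covariance of orthonormal within-subject contrasts
(Kronecker contrasts for the interaction), and the ε-corrected p is
always reported next to the uncorrected one. The implementation matches
pingouin to machine precision and is ~100× faster, which is what makes
1000-cohort null calibration affordable. Terms whose effect sum of
squares is below 1e-12 of the total report F = 0, p = 1 rather than a
ratio of rounding errors.

Simple effects of state within each microstate use q = √2·|t| referred to
the studentized range with k = 4 and df = n−1 (family-wise error ≈ 0.044
at the null, inside the 0.05 ± 0.02 calibration band; reported corrected
p is floored at the uncorrected p). Cohen's d for paired contrasts is
mean(diff)/SD(diff); for ANOVA terms the reported effect size is √(F/n),
a magnitude convention only. Storey's q-values use the smoother π₀
estimate for families of ≥ 10 p-values and fall back to π₀ = 1
(Benjamini–Hochberg-like) below that, where the smoother is unstable —
the D-vs-A/B/C family has m = 3. α = 0.05 throughout.

## Problem sizes in the test suite and acceptance script

Chosen as the package's own balance of statistical resolution against
desk-scale runtimes: group clustering pools 2000 GFP peaks per subject
and state (10 restarts) in the cohort pipeline and the full 5000 × 2 × 20
restarts in the single-subject recovery check; connectivity-recovery
calibration uses 20 planted + 20 null cohorts of 6 subjects × 120-s
unresponsive spans with WPLI on the anterior ROI; type-I calibration uses
1000 null cohorts at n = 16; the permutation null for the classifier uses
50 within-subject permutations on a small random-feature table with a
3×3 grid (null AUC does not depend on the grid). The acceptance script
runs the full default cohort: 16 subjects × 780 s × 63 channels, the
49-point SVM grid, and both connectivity analyses.

## Known limitations

* The synthetic cohort is far cleaner than real drowsy EEG; absolute
  AUCs and GEVs are optimistic, and only the *qualitative* pattern of
  effects is meaningful.
* Measured microstate durations are attenuated relative to planted dwell
  times (labelling noise at carrier zero crossings); cross-state duration
  contrasts for maps A–C can fall below detection at default amplitudes.
* The simultaneous-update smoother is a local minimiser of its objective.
* Storey's smoother is bypassed for small families (π₀ = 1), which is
  conservative.
* Connectivity p-values treat subjects as exchangeable and rely on
  t-distributions at n = 16; no spatial multiple-comparison correction is
  applied beyond the stated families.
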