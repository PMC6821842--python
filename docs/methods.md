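# Methods

## Signal model and preprocessing

Recordings are continuous channels × samples arrays in µV at 500 Hz
(512 Hz input is polyphase-resampled to 500 Hz). Re-referencing subtracts
the per-sample mean of the intact channels; declared-bad channels pass
through and are excluded from the mean.

High-frequency amplitude (HFA) is estimated in nine 10-Hz sub-bands
spanning 48–154 Hz while avoiding 59–61 and 117–121 Hz:
48–58, 62–72, 72–82, 82–92, 92–102, 102–112, 122–132, 132–142, 144–154 Hz.
Only the span, width and avoided ranges are constrained by the design; the
exact edges are configurable (`signal.estimate_hfa(bands=...)`). Each
sub-band is filtered with a zero-phase Hamming-window FIR filter
(`mne.filter.filter_data`, firwin design — the same design family as the
standard EEGLAB filter), its amplitude taken as |Hilbert|, divided by its
own temporal mean so the 1/f spectral profile cannot weight low sub-bands
more, and the nine normalized traces are averaged. The result is
non-negative with temporal mean exactly 1, which the tests assert.

Epochs cover [−200, 500) ms around stimulus onset (half-open windows
throughout: the t = 0 sample belongs to the response side). HFA epochs are
expressed as percent signal change relative to a *global* per-channel
baseline — the mean over all retained trials' [−200, 0) samples — rather
than per-trial baselines; 1-back repeat trials (response trials) are
excluded before anything else is computed. ERP and 8–13 Hz band-limited
power use the common-referenced raw signal and a fixed [125, 250) ms
analysis window.

## Contact screening

Visual responsiveness: per contact, the per-exemplar mean response at
[50, 500) ms is tested against the per-exemplar mean baseline with a
paired t-test; p-values from all contacts are pooled for Benjamini–Hochberg
FDR; and the effect size gate is Glass' Δ > 1 with the SD of the
exemplar-mean baseline values as denominator (the control distribution of
the paired comparison; the design names the statistic but not the SD
source). Contacts with degenerate difference variance are untestable and
excluded.

Face selectivity: two one-sided Wilcoxon rank-sum tests on single-trial
mean responses (faces greater than each of two contrast categories) at
p < 0.05 uncorrected, plus anatomical constraints — V1/V2/frontal labels
and depth > 10 mm force the flag off. The contrast pair defaults to
(places, patterns); task versions whose roster uses houses instead of
places pass `("houses", "patterns")`. Trial-level rather than
exemplar-level samples are used for the rank-sum tests because they give
the test usable sample sizes at 10 exemplars per category.

The exemplar-selectivity index is the d′ between the most- and
least-preferred face exemplars, computed on each trial's [50, 500) ms
temporal mean; its p-value is the proportion of single-trial label
shuffles whose index exceeds the observed one (strict `>`; this
"proportion exceeding" convention is used for every permutation test in
the package, with one documented exception below).

## Grand response matrix, decoding

G is exemplars × contacts × trials × time over [50, 500) ms (225 samples
at 500 Hz); missing repetitions are NaN-marked. The decoder's input is
smoothed with a 50 ms running mean; the representational analyses use the
unsmoothed matrix (the smoothing is stated for decoding only; both are
configurable).

Decoding: per iteration, one random trial per (exemplar, contact) is drawn
into T and the remaining trials averaged into R; rows are concatenations
across contacts. Assignment is greedy on the Euclidean row-distance
matrix — repeatedly retire the globally minimal (test, reference) pair —
with ties broken lexicographically, so results are deterministic given the
seed. The permutation null shuffles *single trials'* exemplar labels
within each contact (preserving per-exemplar repetition counts). Shuffling
whole exemplar cells would merely relabel rows of both T and R coherently
and leave accuracy unchanged; the trial-level shuffle is the null that
actually severs the repetition structure the decoder exploits.

A note on chance levels: on label-exchangeable data the decoder's accuracy
is 1/N in expectation over datasets, but conditioning on one small dataset
biases the conditional chance (row/column norm structure interacts with
the greedy rule). Calibration is therefore always assessed as an average
over independently drawn datasets.

## Representational analyses

Pairwise distances are Euclidean over the exemplar-representation rows, in
fixed (i < j) order. Exemplar-label permutation is implemented as the
induced permutation of the condensed distance vector — relabelling rows
and recomputing distances is exactly d′(i,j) = d(π(i), π(j)), which a test
verifies against direct recomputation. Per layer, the observed statistic
is the Spearman correlation; the null holds layer vectors fixed; BH-FDR
runs across layers.

Cross-set pooling Fisher-z transforms each set's correlation (clipping
|rho| at 1 − 1e−7 with a warning) and weights by face-contact counts:

    R̂_z = Σᵢ R_zⁱ nⁱ / Σᵢ nⁱ
    SE_z = Σᵢ (R_zⁱ − R̂_z)² nⁱ / (√N Σᵢ nⁱ)

both back-transformed with tanh. The SE_z formula is implemented exactly
as printed in its source convention (no square root of the weighted
variance), since it is a reporting quantity, not an inferential one.

Partial correlations are rank-based: neural and layer distance vectors are
rank-transformed, residualized on the ranked covariate distance vectors
(|paramᵢ − paramⱼ| per image parameter; absolute difference is the natural
scalar-covariate pair distance) with an intercept, and the residuals
correlated. Collinear covariate columns are dropped with a warning. With
no covariates this reduces exactly to plain Spearman. Image parameters are
mean gray level, SD of gray levels, summed gradient magnitude and mean
(max−min)/max chromatic saturation, with ITU-R 601 grayscale conversion
(0.299 R + 0.587 G + 0.114 B); native grayscale images are measured on raw
pixels and saturation is omitted.

The evaluation layer list has 22 entries: 13 convolution outputs, 5
pooling outputs, 3 fully connected outputs, and the final class-score
output. The natural layer count of the architecture is 21; the class-score
entry completes the printed count of 22 and is configurable
(`NetworkArchitectureSpec.include_output_layer`).

ROI differences are tested by shuffling contacts' cluster labels with
cluster sizes preserved (two-sided on the rho difference). The 22
per-layer difference p-values of one split share a single contact
partition and are strongly correlated, so null calibration is checked as a
rate over independent datasets and splits, not as a per-layer count in one
split.

## Manipulation impact

delta = rho(neural, original layer) − rho(neural, manipulated layer); the
permutation null shuffles neural exemplar labels and recomputes both
correlations. This is the one test using `≥` rather than strict `>`: a
no-op manipulation makes every null delta exactly 0, and `≥` keeps that
degenerate case non-significant (elsewhere ties have measure zero). The
bootstrap cross-check resamples image pairs for the original correlation
and flags whether the manipulated rho leaves the 95% interval. Luminance
matching shifts the HSV value plane (value = max(R,G,B)), clips to
[0, 255], reports the clipped fraction, and iterates the shift until all
measured luminances sit within 0.5 units of the set mean. Background
removal, appearance changes and rotated views are manual edits in the
source protocol and therefore enter as externally supplied images.

## Model units

Per contact and layer, each leave-one-out fold correlates every unit
(Pearson, on raw values — consistent with the least-squares prediction
that follows; constant units are skipped) with the N−1 training responses;
a candidate must be the argmax in *all* N folds (ties break to the lowest
unit index). Its per-fold least-squares line predicts the held-out
response; significance is a one-sided label permutation on the correlation
between the N predictions and observations. Cluster correction re-runs the
whole search under exemplar-label shuffles and requires the observed
per-layer count to strictly exceed the null 95th percentile. The search is
restricted to layers the representational profile flagged significant.

## Receptive-field visualization

The toy network is a numpy stack of 3×3 stride-1 convolutions, one 2×2
max-pool and a dense readout on a 32×32 input (depth, channels, input size
configurable), with Xavier-normal weights reproducible from a seed.
Deconvolution zeroes all but the target unit and back-projects through
transposed convolutions, unpooling with recorded switches, and the
deconvnet ReLU rule (backward signal masked by the forward activation
pattern, not guided backpropagation). Fully connected units back-project
through the transposed dense weights. For a purely linear network the
backward pass is exactly the adjoint operator, verified to < 1e−6 against
an adjoint built by probing the forward map with pixel impulses.
Activation maximization iteratively adds lr × the deconvolution of the
unit's current activation to the image; the image is not re-clipped during
the ascent (the delta image needs unbounded values; clipping happens only
at PNG export), display contrast stretching is render-time only, and
numeric overflow raises with the iteration index.

## Synthetic data: what it emulates and what it does not

The latent face space is a k = 4 dimensional Gaussian embedding per
exemplar. Synthetic contacts respond with a stimulus-locked 70–150 Hz
burst whose envelope is a gamma-shaped kernel rising 50 ms post-onset and
peaking at 200 ms, with amplitude visual_gain + face_gain ·
softplus(w·z) (softplus keeps amplitudes positive; there is no empirical
forward model to copy). Background is 1/f² (Brownian) noise plus a
broadband floor, a shared common-mode component, and 60 Hz line noise.
Task protocols reproduce the printed totals: set 1 — 360 trials, 24
repeats, 60 stimuli × 6; set 2 — 205 trials, 25 repeats, the unique
37 × 4 + 19 × 3 split of 56 stimuli; set 3 — 26 single-category ten-trial
blocks, 18 repeats. For set 3 the printed totals over-determine
per-exemplar presentation counts, so they fall out of the block assignment
(faces receive the extra 26th block). Repeats are drawn uniformly among
eligible positions subject to the quotas.

Synthetic layer stacks embed α·z + (1−α)·ε through per-layer random
orthonormal projections: α = 1 reproduces latent distances exactly, α = 0
is independent noise, and the Spearman match is monotone in α (tested).

Not emulated: cortical geometry and volume conduction, epileptiform
artifacts, realistic HFA spectro-temporal diversity, inter-patient
variability in tuning dimensionality, and real network activations.
Passing tests therefore demonstrate the *correctness and calibration* of
the analysis chain under a known generative model, not the empirical
findings on patient data.

## Problem sizes and numerical choices

Recovery and calibration suites use 10 exemplars, 40 synthetic contacts, 5
repetitions, 20 seeds, 200–500 permutations; the model-unit family-wise
null uses 100 runs at 200 cluster permutations; demo pipelines run one
task version with 8–16 channels. These sizes give stable rates while
keeping the whole suite and the acceptance script in the tens of seconds
on one CPU. All randomness flows from one integer seed per entry point
through SHA-256-derived sub-seeds (`facespace._rng.derive_seed`), so every
stage is bit-reproducible and stages remain independent when toggled.
Permutation p-values are stored as raw proportions (a value of 0.0 means
"below 1/n_perm"). Fisher-z clipping tolerance is 1e−7; filters are
zero-phase; window conventions are half-open everywhere.
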