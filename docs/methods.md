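# Methods

`songsim` implements a pipeline for learning and validating bird-song
syllable similarity from avian two-alternative perceptual judgments.  This
note records the models, the parameters that matter, and the design
choices made where the design was genuinely open.

## The behavioural task and its data products

In the AXB paradigm a bird trained to discriminate two sets of training
stimuli (8 syllables per side, rewarded left vs. right) is occasionally
presented a probe syllable X; the perch it chooses reveals which side it
perceives as more similar.  The package consumes the data products of such
an experiment: a trial log (one row per response) and the syllable audio.
Per (bird, cycle, probe) the repeated responses are consolidated into one
decision with a side-consistency statistic; quality filters then build two
triplet datasets:

* decisions from (bird, cycle) pairs with cycle accuracy (fraction of
  correct training responses) below 65% are discarded, as are decisions on
  device-fault days;
* **unambiguous** triplets: at least two decisions with the same side
  chosen in strictly more than 70% of them (`u = 1`);
* **ambiguous** triplets: consistency between 50% and 70% inclusive
  (`u = 0`).  A consistency of exactly 70% is ambiguous, and an exact tie
  (consistency 0.5) takes the lexicographically first side as its
  majority — ties are by definition ambiguous, so this choice only affects
  a label that the ambiguous loss ignores.
* An optional stricter evaluation filter keeps only decisions from cycles
  at or above 77% accuracy.

Triplets are stored set-valued (anchor probe + the 8 training stimuli of
each side); expansion into (anchor, positive, negative) exemplar triples
happens at training time by uniform sampling, one pair per occurrence per
epoch.  The train/evaluation split is stratified by cycle with anchors
never shared across splits.

## Acoustic representations

**Preprocessing** — high-pass at 100 Hz (zero-phase Butterworth), peak
normalisation to |max| = 1, and 20 ms raised-cosine fades.  Syllables no
longer than twice the fade are rejected.

**Mel spectrogram** (network input) — power spectrogram with FFT length
2048, hop 128 samples, window 512 at 48 kHz, projected onto 150 triangular
mel bands spanning 100 Hz–16 kHz, expressed in dB relative to the
per-syllable maximum (a corpus-wide reference can be passed instead) with
a floor at −80 dB, and centre-padded with the floor (or centre-cropped) to
exactly 170 frames.  Centre placement avoids systematically privileging
syllable onsets.

**Feature contours** (DTW input) — frames of 10 ms every 5 ms.  Per frame:
fundamental frequency from the normalised autocorrelation peak within
300–4000 Hz (voicing threshold 0.45, parabolic lag interpolation); peak
frequency (spectral argmax) and mean frequency (spectral centroid), all
log-transformed; Wiener entropy as log(geometric mean / arithmetic mean)
of the power spectrum; harmonicity as the power fraction within ±5% of the
first eight harmonics (never narrower than the analysis window's main
lobe); frequency-change features as arcsin(clip(Δf / (Δt · 50 kHz/s)));
the fundamental with its syllable-wide voiced mean subtracted; and vibrato
amplitude as half the peak-to-trough range of the linearly detrended
fundamental in a 50 ms window.  Unvoiced frames carry the last voiced
fundamental forward (leading frames back-filled) so alignment always sees
complete contours; a fully unvoiced syllable falls back to the geometric
midpoint of the search band.  Time itself is a contour feature, so the
comparator penalises warping.

## The DTW comparator

Features are z-scored over all frames of the corpus so weights are
comparable, then the point cost between frames is the weighted Euclidean
distance with non-negative weights normalised to sum to one.  Dynamic
programming finds the monotone alignment (diagonal / insert / delete, no
slope constraint or band) minimising total point cost; the dissimilarity
is the mean cost over that path.  When several alignments tie on total
cost the longest is used, making the mean well defined (it is the smallest
mean among optimal alignments).  The AXB decision from any dissimilarity
matrix uses `Xp = (D_probeA − D_probeB) / (D_probeA + D_probeB)` with the
probe-to-side distance aggregated as the mean over the side's stimuli
(minimum and exemplar-only aggregation are available); side A is chosen
when `Xp < 0`, an exact tie deterministically reports side A, and a
degenerate `D_probeA + D_probeB = 0` abstains.

## Weight calibration by Metropolis–Hastings

The feature weights are tuned against unambiguous bird decisions.  With
each triplet oriented so the bird-chosen side is positive, the decision
log-likelihood is `log(1 / (1 + exp(4 Xp)))`, summed over triplets.  The
chain starts at equal weights and runs 10,000 iterations with the first
1,000 discarded; proposals multiply each weight by `exp(N(0, 0.1))` and
renormalise to sum one, under a flat prior.  The posterior mean of the
retained draws is the tuned weighting.  Because the multiplicative
proposal followed by renormalisation is not symmetric, the acceptance rule
includes the log-proposal-ratio correction by default (the uncorrected
variant is selectable; on the recovery problems below both behave
similarly).  Likelihood evaluation caches per-pair squared feature
differences so only the weighted cost and alignment are recomputed per
iteration (numba-compiled).

A note on recoverability: if synthetic decisions are labelled
*deterministically* by the planted metric (every probe assigned its
strictly nearer side), the fixed-slope likelihood is misspecified and its
maximiser provably exaggerates dominant weights — a margin-expansion
effect, observed here as ~0.2 absolute displacement regardless of sample
size.  The recovery experiments therefore sample choices from the same
logistic decision model the tuner maximises, the well-specified setting
in which the planted weights are the maximum-likelihood point; recovery
there is within ±0.1 (measured ~0.02 at 2,000 triplets).  The
deterministic labelling remains available and still identifies the
correct feature ordering.

Machine-made ("easy") triplets are generated from a tuned matrix by
labelling each probe × stimulus-set pair with the metric's decision and
keeping only `|Xp| ≥ min_margin`.

## The embedding network and losses

The network maps the 150×170 mel image to a d-dimensional unit-norm
embedding: strided 3×3 convolution blocks with batch normalisation and
leaky-ReLU (slope 0.01), then two parallel pooling branches — attention
pooling (1×1-convolution logits, softmax over time–frequency positions,
attention-weighted channel sums) and global max pooling — concatenated and
projected by a dense layer, then L2-normalised.  The default trunk is
16/32/64/64 channels with 2×2 striding and d = 64.  Forward and backward
passes are written directly on numpy (float64 by default) and verified
against finite differences in the test suite; optimisation is Adam
(lr 10⁻³ default).

Losses, on Euclidean embedding distances:

* hinge triplet loss `[D_ap − D_an + δ]₊` (squared distances by default,
  consistent with the mixed loss; the unsquared form is selectable);
* mixed ambiguity-aware loss
  `[u(1 − e^{p_u}) + (1 − u)(1 − e^{−|p_a|})]₊` with
  `p_u = D_an² − D_ap² − δ` and `p_a = D_an² − D_ap²`, used whenever
  ambiguous triplets are in the training stream.  Unambiguous triplets
  (u = 1) are pushed to satisfy the squared-distance margin; ambiguous
  ones (u = 0) are pushed toward equidistance.

The margin default is δ = 0.2 (squared distances on unit-norm embeddings
range over [0, 4]).  A practical property of the mixed loss worth knowing:
its unambiguous branch has gradient magnitude `e^{p_u}`, which decays
exponentially for badly violated triplets, whereas the hinge pushes with
constant force.  Mixed-loss training therefore needs more optimisation
steps to close large violations — with the default batch size (32) and 30
epochs on the synthetic study, U+A training matched or exceeded U-only on
each of the five reference seeds, while doubling the batch (halving the
step count) under-trains the mixed objective and can reverse the
comparison.  The margin is small (a couple of accuracy points) and
seed-dependent; on other seed draws the difference can fluctuate to
slightly negative, so the benefit should be read as a weak directional
trend at this problem size, not a guaranteed gap.  The
batch size defaults to 32 everywhere; only the long 100-epoch single-run
recovery experiments use 64, where the measured accuracy is insensitive
to the choice.  Training runs a fixed epoch budget rather than early
stopping: runs stay deterministic, and on the synthetic studies the loss
plateaus without overfitting within the budget.  Training pools the
configured sources (U unambiguous,
A ambiguous, L machine triplets) into one stream; pre-training on L, then
continuing on the main mix, reproduces the pre-trained configurations.
Within a batch the sampled anchors/exemplars repeat heavily (sides are
shared per cycle), so each unique image is embedded once and gradients are
accumulated per unique image.

## Evaluation harness

Methods are scored by agreement with the birds' consolidated majority
decisions on held-out triplets (abstentions — degenerate distances and
exact ties — excluded from the numerator and denominator and counted
separately), with 95% percentile-bootstrap confidence intervals over
triplets (1,000 replicates).  Two attainable-accuracy estimates
contextualise the scores: the unweighted mean cycle accuracy over
contributing (bird, cycle) pairs (a decision-count-weighted variant is
available), and the mean consistency over multi-decision triplets.
Methods are compared geometrically by classical (Torgerson) MDS of their
pairwise disagreement fractions.  The choice-calibration curve bins
answered probe trials into equal-count bins of the relative rank distance
`(RD_left − RD_right) / (RD_left + RD_right)` (rank of each side's
training stimulus in the probe's sorted dissimilarity row, ties broken by
id order) and reports per-bin log-odds of choosing right minus the
dataset-wide side-bias log-odds, with the Haldane–Anscombe 0.5 correction
so empty cells stay finite.  Matrices exported by external similarity
tools are ingested from delimited text (similarities converted as
max − s); pairs the source scored exactly zero are tracked so triplets
whose probe has zero similarity to both sides can be excluded in a
sensitivity analysis.

## Feature attribution (MRM)

Multiple regression on distance matrices explains an embedding's pairwise
distances from acoustic summary statistics: 26 measures (mean, max, min,
start, end of fundamental frequency, peak frequency, fundamental change,
Wiener entropy and harmonicity, plus log syllable length), each z-scored.
Groupings: 26 single-measure absolute-difference matrices; 6 per-feature
Euclidean matrices over each feature's five statistics (plus length); or
3 per-statistic matrices (mean/start/end pooled across features).  The
vectorised lower triangles (diagonal excluded) are z-scored, so the OLS
coefficients are standardised; inference permutes the rows and columns of
the response matrix jointly (the predictors stay fixed) with a plus-one
correction, so the smallest attainable p is 1/(n_perm + 1).  Per-measure
distances use absolute differences (squared differences are a
configuration choice the data did not force).

## The synthetic study and what it does (not) show

The generator emulates zebra-finch-like syllables as harmonic stacks:
duration 50–300 ms, fundamental ramping linearly between 400 and 1500 Hz
with sinusoidal vibrato (depth up to 80 Hz at 10–40 Hz), up to 8 harmonics
decaying 2–12 dB per harmonic, and a broadband-noise power share up to
0.6.  Each syllable's latent "perceptual" coordinates are a deterministic
function of its parameters — scaled log mean fundamental, scaled log
duration, and noise fraction — so the acoustic pipeline and the decision
pipeline share one ground truth.  Simulated birds answer training trials
correctly with their assigned accuracy (drawn from 0.75–0.92) and probe
trials through a logistic choice model,
`P(choose A) = 1 / (1 + exp(4 Xp / noise_scale))` on latent-space
relative distance.  The logistic family is an assumption — the behavioural
literature this models reports only monotone binned log-odds — and the
default temperature 0.35 was chosen once so that the simulated
consistency ceiling (mean agreement of repeated decisions with their
majority) sits near 0.85, a realistic level for operant work; it is not
adjusted per experiment.

The default recovery study uses 150 syllables, 10 stimulus sets of 8 + 8
training stimuli, 25 probes per set, 6 birds and 4 repeats per probe
(~1,500 consolidated decisions, of which roughly 85% are unambiguous);
the embedding experiments use a compact trunk (input mean-pooled 2×2,
three blocks of 8/16/16 channels, float32, d = 16) sized for single-CPU
runs.  On this study the trained embedding reaches held-out AXB accuracy
around 0.85 against a consistency ceiling of ~0.85, and training on
unambiguous + ambiguous decisions together matches or exceeds
unambiguous-only training seed for seed.

What passing these tests shows: the losses, filters, comparator, sampler
and harness compute what they claim, and the training loop can invert a
known perceptual metric from realistic decision noise.  What it does not
show: performance on real zebra-finch song, whose spectrotemporal
structure (syllable classes, amplitude envelopes, source–filter effects,
recording noise) is far richer than harmonic stacks, and whose perceptual
metric need not be a smooth function of three latent parameters.

## Numerical choices and degenerate inputs

* DTW tie-break: longest among minimal-total-cost alignments; exact-tie
  `Xp = 0` decisions report side A but are excluded from accuracy scoring.
* Constant contour features z-score with a unit denominator instead of
  amplifying numerical noise.
* Zero-variance summary measures are excluded from MRM predictors with a
  warning; collinear predictor sets fall back to the pseudo-inverse with a
  warning.
* Silent audio, empty contours, empty stimulus sides, missing
  spectrograms, thresholds outside [0.5, 1] and margins outside [0, 1]
  raise validation errors naming the offending input.
* All stochastic stages (corpus sampling, trial simulation, MCMC,
  exemplar sampling, bootstrap, permutations) take explicit seeds and are
  deterministic given them.

## Known limitations

* The numpy network is sized for CPU experiments; the default 64-d trunk
  trains slowly on large corpora compared to GPU frameworks.
* The MCMC proposal correction assumes the componentwise log-normal
  density before renormalisation; the exact proposal density on the
  simplex is intractable, and both corrected and uncorrected acceptance
  rules are exposed.
* Luscinia's exact measurement settings and alignment variant are not
  reproduced; the comparator is a clean-room weighted-DTW of the same
  family, validated against exhaustive alignment enumeration rather than
  against Luscinia output.
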