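# Methods

This note records the models and procedures implemented in `vocseg`, the
parameters that matter, the design decisions taken where more than one
reasonable choice existed, and what the synthetic validation does and does not
establish.

## Species scaling

Every duration in the analysis is derived from one species parameter, the
minimum fundamental frequency `min_f0` (Hz): correlation window and buffer
0.5/min_f0, frame step 0.25/min_f0 (two frames per correlation window, so a
"within the same window" relation always spans at least two frame edges),
intensity/entropy window 1/min_f0, pitch window 3/min_f0 (three periods at the
pitch floor, the practical minimum for a reliable autocorrelation peak). The
pitch search ceiling defaults to 15 × min_f0, capped at 0.45 × sample rate.
All are overridable per profile. Two profiles ship as constants: `HUMAN`
(50 Hz) and `BUDGERIGAR` (400 Hz).

## Measurement tracks

All three tracks share one frame grid (centers where every window fits), so
per-frame deltas are aligned across channels.

* **Intensity** — Hann-tapered windowed RMS in dB re digital full scale,
  floored at −100 dB. Only differences enter the segmenter, so the reference
  is arbitrary but fixed.
* **F0** — normalized autocorrelation per frame with a mild lag-bias
  correction; a frame is voiced when the peak reaches the voicing threshold
  (default 0.45). Among candidate peaks within 90 % of the best, the shortest
  lag wins, guarding against octave-down errors on strongly harmonic sounds.
  Sub-sample lag by parabolic interpolation. Unvoiced frames carry NaN.
* **Wiener entropy** — ln(geometric mean / arithmetic mean) of the
  Hann-windowed power spectrum, DC bin excluded. The raw periodogram of white
  noise has exponential bin statistics, which biases the estimator to
  −γ ≈ −0.58 rather than the flat-spectrum limit 0; adjacent bins are
  therefore block-averaged (default 4) before the ratio, which brings white
  noise to ≈ −0.13 while leaving tonal frames far below. At short windows
  (2.5 ms at the budgerigar scale) the estimator's coarse frequency
  resolution makes it track spectral *occupancy* as much as tonality — a
  band-limited noise burst can sit below a multi-harmonic stack. Segmentation
  and clustering only require that the classes be well separated, which they
  are; interpretation of the sign of WE differences at very short windows
  should be avoided.

## Boundary detection

Deltas between consecutive frames are absolute for intensity (dB/frame) and
F0 (Hz/frame) and percent for Wiener entropy (its thresholds, 150/90, are
unitless; a percent reading is the only coherent one, while dB and Hz
thresholds read naturally as absolute). Each channel's mode is switchable.
F0 deltas are defined only between two voiced frames; voicing onsets/offsets
are treated as large F0-channel transitions by default (the segment classes
hinge on the periodic/aperiodic contrast), switchable off.

Default thresholds: large 6 dB / 190 Hz / 150 %, small 2 dB / 7 Hz / 90 % per
frame. F0–entropy correlations are never used as pass-2 evidence: a change in
F0 necessarily perturbs Wiener entropy, so the pair carries no independent
information.

**Candidate selection.** One acoustic transition smears across several frame
edges (the analysis windows overlap), so thresholding alone multiply-marks
each transition. Candidates are therefore the *local maxima* of each channel's
delta series that exceed the threshold. The local-maximum predicate is
threshold-free, which preserves the monotonicity property that raising a
channel's threshold can only remove that channel's candidates. Voicing-flip
chatter closer than half a pitch window is collapsed to its first flip.

**Admission.** Each candidate carries the temporal uncertainty of its
evidence: half the sourcing channel's analysis window (0.5/min_f0 for
intensity/entropy, 1.5/min_f0 for the pitch channel, whose window is three
times longer), plus the correlation window for pass-2 candidates, whose
support only localizes them to within that window. Pass-1 candidates are
admitted before pass-2 (stronger evidence first); within pass 1 the sharper
channels go first, then time order. A candidate is dropped when an admitted
boundary lies within max(buffer, its own uncertainty). Admitted boundaries are
consequently always ≥ buffer = 0.5/min_f0 apart, and the buffer applies across
passes. The naive alternative — admit every above-threshold edge, earliest
first — was implemented first and measured: on clean synthetic corpora the
blunt pitch channel then re-marks each junction 2–4 ms away from the
intensity/entropy mark, roughly doubling the boundary count; the
uncertainty-aware rule removes those duplicates without touching the
thresholds.

Tracks are computed per unit (never per file), so unit-relative measures
cannot leak across units, and returned boundaries are frame-edge times
strictly inside the unit.

## Bouts and syllables

Silence annotation: envelope frames (25 ms window, 5 ms step) more than 45 dB
below the envelope peak for ≥ 1 s are silence; −100 dB re full scale counts as
silence regardless of peak so an all-quiet recording is not one long
"vocalization". Complements are vocalizations; those longer than 2.5 s are
song. Syllable extraction: after a Hann-edged 1–15 kHz band-pass (100 Hz
smoothing), maximal runs where the linear RMS envelope dips below 1/6 of the
whole-song RMS for > 10 ms are gaps; complements are syllables. The 1/6 ratio
is linear (a dB reading would make the fraction meaningless), the peak
reference is the intensity envelope maximum (robust to clicks), the whole-song
RMS is taken on the band-filtered signal, and boundaries are refined to the
envelope's threshold crossings by linear interpolation. All thresholds are
relative, so bout and syllable boundaries are invariant to global gain. The
simple/complex syllable split used downstream is a segment-count heuristic
(complex iff ≥ 3 segments) — deliberately plumbing, not a published typology.

## Features, clustering, classification

Each unit (segment, syllable, snippet) gets a 21-variable vector: duration;
intensity mean/min/max/SD/slope; F0 mean/min/max/SD/slope and proportion of
voiced frames; Wiener entropy mean/min/SD; spectral center of gravity, SD,
skewness, kurtosis; peak frequency and its within-unit SD. The list is a
stated stand-in with the coverage (time, amplitude, pitch, spectral shape) of
the original 21-variable set, whose exact composition is not public; the
`FeatureSpec` config object accepts any replacement list. Formant features are
deliberately absent (short vocal tracts and high F0 make formants an
unreliable cue for the target species).

Intensity/entropy statistics use frames whose analysis window fits inside the
unit (falling back to center-inside frames, then the nearest frame, so short
units always measure). F0 statistics and the voiced proportion are measured
from the unit's *own samples* — sub-windows clipped to the unit, each given a
normalized-autocorrelation estimate with the search floor raised to two cycles
per sub-window. The track-based alternative was measured and rejected: with a
pitch window of 3/min_f0 (7.5 ms at 400 Hz) and segments of ~4–20 ms, track
frames mix neighboring material into every estimate (F0 errors of the order
of ±190 Hz on synthetic stacks), which buries real cluster structure.

Clustering: feature matrices are z-scaled per column (sample SD; zero-variance
columns set to 0 and flagged; missing values — e.g. F0 statistics of unvoiced
units — mean-imputed per column and logged, the neutral choice for units that
genuinely lack the measure). Dissimilarity is 1 − Spearman rank correlation
across the features of each unit pair (average ranks for ties), clustered by
Ward.D2 linkage on that dissimilarity (scipy's Ward update on a precomputed
matrix is the same Lance–Williams recursion R's `hclust(method="ward.D2")`
applies to distances) and cut with `cut_tree`, which yields exactly k clusters
even under tied merge heights (three equidistant points at k = 2 merge the
first-listed pair). Silhouette widths follow the standard formula with
singletons scored 0. Sweeps run k = 2…15 (budgerigar design) or 2…8 (human
design).

Duration-shuffled snippets: per syllable, the recovered segment durations are
permuted (seeded) and boundaries re-cut at the cumulative sums; the snippet
count and total duration are conserved exactly. Snippets control for unit
length: they share the duration distribution of segments while their
boundaries ignore acoustic transitions.

Identity classification: random forest, 500 trees, 3 candidate predictors per
split, scored by out-of-bag accuracy (no held-out split is described in the
original design; OOB reuses the single data set without optimistic bias).
Stratified subsampling follows the sampling plan (defaults: 500 segments per
individual and per group, 60 syllables per individual, 384 per group),
clipped to availability. Chance level is tested with an exact binomial test of
the OOB-correct count against 1/n_classes, Holm-corrected across the four
models of one battery.

## Edge effects

Within each syllable the first segment is initial, the last final, the rest
medial; single-segment syllables are labeled `sole` and excluded from
positional analyses (their edge status is undefined). A segment is "periodic"
when at least half its frames are voiced (configurable; the original reports
percentages of periodic segments without stating a cut). Position summaries
are means of per-individual means, each individual weighted equally;
positions absent for an individual stay missing, never zero.

The four response models are generalized linear mixed models with position
and group as fixed effects and a random intercept per individual: F0 Gaussian
with log link, duration inverse-Gaussian with identity link (fitted in
milliseconds internally — a pure rescaling that conditions the optimization),
intensity Gaussian with identity link, periodicity binomial with logit link.
Each is compared against the same model without position by a
likelihood-ratio chi-square with 2 degrees of freedom; group is retained in
both models. A variance-inflation check on the fixed-effects design is
reported with each result, and non-convergent fits are flagged, never
silently dropped.

No frequentist random-intercept GLMM exists in the Python scientific stack
for these families, so `vocseg.glmm` implements one: the marginal likelihood
integrates the random effect by Gauss–Hermite quadrature (15 nodes) and is
maximized with L-BFGS. Starting values matter — the dispersion start is
matched to the family on the *response* scale (for the inverse Gaussian, the
shape λ = mean(μ)³/var(residual)) because a link-scale start lets null fits
underconverge and inflates the LRT. Both models of a test are additionally
re-polished from each other's solutions so neither side of the ratio is an
optimization artifact, and the statistic is clamped at 0. Fits agree with R's
`lme4::glmer` on simulated binomial data to within optimizer tolerance (the
test suite runs that cross-check when R is available). Under the zero-effect
generator the tests calibrate to nominal level within simulation error
(checked at 200 replicates in the validation suite).

## Evaluation

Frame confusion: the unit extent is tiled into consecutive frames (default
25 ms), half-open and anchored at the extent start (a boundary exactly on an
edge belongs to the later frame; a trailing partial frame is kept); each frame
contributes one boolean per side regardless of how many boundaries fall in it.
Unit start/end boundaries are excluded by default — they are shared by
construction and would inflate agreement. The 25 ms frame belongs to the
50 Hz (human) design; when scoring at another pitch floor the frame should be
scaled like every other window (2.5 × correlation window, i.e. 3.125 ms at
400 Hz), otherwise nearly every frame contains a boundary and the scores
saturate. `match_boundaries` offers the complementary tolerance view (greedy
one-to-one matching within ± one correlation window) used for recall /
spurious-rate reporting; the signed-rank helper returns V = sum of positive
ranks, the statistic R's `wilcox.test` prints, with exact p for n ≤ 25
without ties.

## The synthetic generator

`vocseg.synth` renders corpora with known bout/syllable/segment structure:
syllables are sequences of abutting segments of two classes — periodic
harmonic stacks (1/h rolloff, linear F0 glide, raised-cosine ramps) and
wide-band noise bursts — separated by silent gaps, with a dither floor at
−80 dBFS. Ramps default to 1 ms (budgerigar) / 5 ms (human), clamped to a
quarter of the segment, since a fixed 5 ms ramp cannot fit a 4 ms segment.

The generating process is deliberately the same model family the edge
analyses fit: duration inverse-Gaussian around a positional mean, F0 Gaussian
around an exponentiated positional/individual effect, intensity Gaussian with
positional offsets, class Bernoulli with positional log-odds, plus individual
and group random offsets throughout. Positional effect sizes default to the
published budgerigar means: final duration × 1.8, final F0 × 0.85, intensity
offsets −9.7 dB (initial) and −3.6 dB (final) against medial, periodic
probabilities 0.35 / 0.74 / 0.55 for initial / medial / final. The medial
anchors are ~6.5 ms duration and ~2.7 kHz F0. `zeroed_effects()` switches all
positional effects off for calibration studies.

Segments draw from a discrete stereotyped *type inventory* (default 5
periodic + 3 aperiodic types per corpus): type parameters are stratified
across their ranges ("contrastive" spacing — real inventories do not clump,
and independent uniform draws occasionally produce near-duplicate types),
with individual-specific Dirichlet usage preferences. This inventory is what
gives segments cluster structure at more than one scale, as real repertoires
have; without it, segments carry only the two-class split and the
duration-shuffled null is nearly indistinguishable from real segments
(shuffled boundaries align with true ones when durations are similar — a
caveat the original snippet construction itself acknowledges). Complex
syllables hold 5–12 segments (simple syllables, probability 0.25, hold one);
noise bursts keep ≥ ~4 kHz bandwidth because narrow-band noise is
quasi-periodic and genuinely defeats autocorrelation voicing, which is a
property of the detector, not a bug to paper over.

**What passing on this generator shows — and does not.** The synthetic
corpora are clean: no reverberation, no overlapping singers, no background
noise above the dither floor, no amplitude modulation within segments, no
formant structure, and every boundary is a true rendering discontinuity.
Closed-loop results (≈95 % boundary recall within one correlation window,
a few percent spurious boundaries, the cluster-ordering and dichotomy
reproductions) therefore validate the *implementation logic* — that the rule
set recovers exactly the structure it is designed to mark — not field
performance on recordings, where transitions are slower, noisier and
sometimes absent. The human-scale frame-confusion scores on synthetic breath
groups land in the same range as the published human test, but that is a
consistency observation, not a replication: the original corpora are not
deposited.

## Degenerate inputs and edge cases

Units too short for the analysis windows become single segments with a logged
warning (the corpus analyzer instead pads short units with surrounding
context so they are still measured). All-zero windows hit the −100 dB
intensity floor and carry missing Wiener entropy. Zero-variance feature
columns scale to 0 and are flagged. Signed-rank tests refuse all-zero
difference vectors and fewer than 5 pairs. Per-file failures in corpus runs
are logged and skipped, never fatal. TextGrid point tiers are skipped with a
warning; interval tiers are tiled with empty-label intervals on write so they
partition the file exactly, and empty labels are non-units everywhere
downstream.

## Known limitations

* Thresholds are the published human-optimized values; no automatic
  re-optimization is provided, matching the original design (the same values
  were applied to budgerigars).
* The pitch channel's temporal resolution is 3× coarser than the other
  channels; pitch-only boundaries closer than ~1.5/min_f0 to another event
  are suppressed by design.
* Formant-transition boundaries (human speech) are out of scope; reference
  tiers with such boundaries removed can be supplied for evaluation.
* The 21-variable feature list is a stand-in with matched coverage, not the
  original supplementary list.
* Wiener entropy at very short windows measures band occupancy as much as
  tonality; only contrasts, not signs, should be interpreted.
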