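# Methods

## The measurement problem

Phoneme-locked EEG decoding asks three questions about each phonetic
feature: for how long is it decodable at all (the *diagonal* of a
temporal-generalization matrix), for how long does any single spatial
pattern remain informative (the *generalization width*), and does encoding
strength or speed differ between groups or stimulus conditions. `phonodyn`
implements that measurement chain and pairs it with a generative model in
which all three quantities are set explicitly, so the chain can be
validated end to end.

## Forward model

Each phonetic feature f of each phoneme evokes a response

    r_f(t) = gain_g(t) · P_f[k(t)],   k(t) = floor((t − t_on)/τ),

active from `response_onset_s` (default 0.05 s) after phoneme onset for
`encode_duration_s` (D, default 0.3 s). The `P_f[k]` are unit-norm random
64-channel patterns, each orthogonalized against its predecessor, so the
code *hands off* to a fresh configuration every `dwell_tau_s` (τ, default
0.08 s — the handoff interval reported for continuous speech, matched to
the median phoneme duration). Amplitude is constant within a dwell and
transitions are instantaneous; the pipeline's 25 Hz low-pass supplies the
physiological smoothing. Responses of successive phonemes overlap, as in
real listening, so ~4 phonemes are simultaneously decodable at any moment.

Three manipulations mirror the study designs the package targets:

* **group gain profiles** — a step function of time since phoneme onset per
  group; the shipped aphasia-like profile drops to 0.4 from 0.08 s,
  producing weaker late encoding with intact early processing;
* **entropy duration bonus** — high-cohort-entropy phonemes may be encoded
  `entropy_duration_bonus_s` longer, per group, implementing
  uncertainty-contingent maintenance;
* **static control** — τ = D yields a single maintained pattern, the null
  regime against which dynamic coding is tested.

Noise is an equal-power pink (1/f) + white mixture, i.i.d. across channels,
unit variance per channel; `snr` is the response-vector norm divided by the
per-channel noise SD. Default 2.0: strong enough that recovery experiments
are limited by geometry rather than sample size at desk scale. Per-subject
seeds derive from (master seed, group, subject index) via CRC-hashed
`SeedSequence`; identical configuration and seed reproduce bit-identical
output.

Design choices here that the measurement chain does not dictate: hard
pattern switching (rather than a cross-fade) makes per-row generalization
a width-τ box, so the phase-averaged profile is an exact base-2τ triangle
and the injected dwell is recoverable without shape-dependent bias;
responses carry their natural DC content, and correspondingly the
*synthetic* conditioning chain omits the high-pass stage (see below).

## Stimulus generator

Words are sampled i.i.d. with probability ∝ frequency from a generated
lexicon (Zipf frequencies, rank-1/rank-2 ratio 2^s). Phoneme durations are
log-normal with median 0.070 s clipped to [0.029, 0.359] s — the stimulus
statistics of a 25-minute narrative. Two phonotactic modes:

* `cv` (default): consonant/vowel alternation with Zipf-skewed within-class
  phoneme probabilities. This produces natural-like prefix sharing — cohort
  entropy is graded from 0 to ~5 bits — but makes neighbouring phonemes'
  features statistically dependent (a co-articulation-like confound that
  genuinely inflates decodable windows, as it does in real narratives).
* `iid`: every slot uniform over the inventory; neighbours carry no
  information about each other. The encoding-geometry experiments use this
  mode, with a fresh stimulus per subject so shared-stimulus sampling noise
  cannot accumulate across the cohort.

The shipped Dutch (CGN-style) phoneme→feature map is data, not algorithm:
consonants carry voicing + manner + place + roundness (4 active features),
vowels additionally front-backness (5). Users may substitute their own TSV.

## Conditioning chain

Fixed order: common-average reference → least-squares FIR filters →
resample to 128 Hz → per-channel z-score over the whole recording →
epoch −0.2 to 0.6 s around phoneme onsets (103 samples at 128 Hz, onset
rounded to the nearest sample, no baseline correction, no post-epoch
normalization). Filters are applied forward-backward (zero phase,
attenuation squared; epoch latencies depend on this). Filter order is
specified at the 512 Hz design rate (2000) and scaled with the sampling
rate so the impulse-response duration is rate-invariant.

The high-pass (0.45→0.5 Hz) exists to remove electrode drift in real
recordings. The synthetic noise model is stationary and zero-mean, and the
high-pass's multi-second impulse response would smear each response's DC
content — hence label information — across the entire epoch window; the
synthetic pipeline therefore defaults to `highpass=None`
(`PreprocConfig`), while the full chain remains available and tested for
real data.

## Decoding

One-vs-all logistic regression (L2, inverse strength C = 1) on the
channel vector at each train time; ROC AUC at every test time; stratified
5-fold cross-validation with a fixed shuffle seed, AUC per fold then
averaged (pooled-prediction variant available). AUC is computed by the
rank formulation, hence invariant to monotone transforms of the decision
scores and insensitive to class prevalence; no class weights or resampling
are used. Inputs are the already-normalized epochs; nothing is re-scaled
per fold. Subset evaluation trains on full training folds and scores each
test-set level separately, so all levels share decoders. `train_stride`
decimates train times only (test times stay dense); the desk-scale
experiments use stride 2 (15.6 ms train grid, 7.8 ms lag resolution).

## Summary metrics

*Diagonal*: matched train/test-time AUC; its above-chance extent (via the
one-sample cluster test across subjects) estimates encoding duration.

*Generalization profile*: rows of the TG matrix with train times in
0–0.35 s are rolled so the diagonal lands at lag 0 and averaged across
rows. Lags covered by fewer than half the rows are excluded from width
estimation (edge bias).

*Width, CI recipe* (default, the procedure used in the EEG decoding
literature): z-score the mean
profile across lags, give each lag a 95% CI whose half-width derives from
the SD across the timecourse, and count lags whose lower bound exceeds
zero. A row-SEM variant of the CI is config-exposed. Caveat discovered
during validation: because the across-lag SD grows with the bump's share
of the lag span, this estimator is nearly scale-free — it returns
~0.055–0.08 s for injected dwells anywhere between 0.05 and 0.15 s on a
−0.2..0.6 s epoch. It is faithful to practice and well-behaved in the
regime real speech occupies (τ ≈ median phoneme duration ≈ 0.07–0.08 s),
but it is not a consistent estimator of slow codes.

*Width, half-maximum* (`halfmax_width`): full width at half the peak AUC
excess over chance. For the hard-switch forward model the profile is an
exact triangle of base 2τ, whose half-height width is τ; half-height
crossings sit on linear flanks, which symmetric filter smoothing does not
move. This estimator recovers τ ∈ {0.05, 0.08, 0.15} s within ±1.5 samples
at 128 Hz and is the one used for ground-truth dwell recovery.

*Dynamic delta*: horizontal (across-train-time average) minus diagonal,
per subject, fed to the one-sample cluster test; significant negative
clusters ⇒ dynamic coding. Only rows whose diagonal reaches 90% of the
peak excess over chance enter the horizontal average: including decoders
trained where nothing is encoded (or on the smoothed edges of the
response) drags the horizontal toward chance and makes even a perfectly
static code test as "dynamic". The cluster test on the delta runs over the
span where the group-mean diagonal exceeds half its peak excess: outside
the encoding window the contrast compares two chance quantities
contaminated by the band-limiting filter's ringing (a slight
anti-correlation with the pattern just beyond the response support), which
would otherwise register as spurious "dynamic" clusters. With these
guards, static simulations (τ = D) produce no significant negative
clusters while dynamic ones reliably do.

## Statistics

Cluster permutation tests form clusters of contiguous points exceeding the
two-tailed Student-t quantile at the cluster-forming alpha (df = n−1 or
n₁+n₂−2), positive and negative separately; cluster mass is the summed t;
the null is the maximum |mass| over 10,000 permutations (sign flips for
one-sample, label exchange for two-sample); p = (b+1)/(m+1). Adjacency:
1D contiguity, 4-connectivity on TG grids (8 available), Delaunay
neighbourhood of the montage for sensors. The observed labeling is not
forced into the null sample. Sampled p-values agree with exhaustive
enumeration (2^8 sign patterns; C(10,5) assignments) within ±0.02, and
family-wise error on pure noise is 0.03–0.07 at α = 0.05 for both tests
(500 simulations). Note the null's discreteness: with n subjects the
one-sample test's smallest attainable p is 2/2^n, so group analyses need
n ≥ 6.

The group × entropy interaction subtracts the low- from the high-entropy
diagonal per subject, compares groups with an independent t per lag inside
0.15–0.35 s, and corrects with Benjamini–Hochberg over the window's lags.
Behavioral correlations are per-lag Pearson r with uncorrected two-sided
p, reported with contiguous-significance intervals (exploratory use).

## Verification experiments and problem sizes

The `experiments` module fixes the study conditions used by the tests and
the acceptance script: 6 subjects per cohort (the sign-flip minimum),
~700 events/subject for detection experiments (150 words) and ~1100 for
width/extent estimation (250 words), one or two place features carrying
signal (place features have the weakest neighbour dependence in `cv` mode,
and the chance calibration averages six features because the grand-mean
AUC's sampling noise is dominated by per-fold label/noise alignments that
average out across features). The entropy experiment uses base duration
D = 0.2 s with a 0.1 s bonus so the extension [D, D+bonus] after response
onset falls inside the conventional 0.15–0.35 s analysis window.

## Known limitations

* No biophysical head model: patterns are random vectors, not lead fields;
  sensor topographies are statistically but not anatomically meaningful.
* No artifact model (blinks, muscle) and no artifact-removal stage.
* The CI-recipe width compresses for dwells ≳0.1 s (above); cross-check
  slow codes with `halfmax_width`.
* Shared-stimulus designs (all subjects hear one narrative, as in real
  studies) let stimulus-level sampling correlations reach group-level
  significance; the generator supports per-subject stimuli to quantify
  this, and the recovery experiments use them.
* Decoding results on `cv`-mode stimuli mix the current phoneme's encoding
  with neighbour-phoneme dependencies, as they do for natural speech; the
  package measures, but cannot remove, that collinearity.
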