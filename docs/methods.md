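# Methods

## Problem

Given a window X ∈ ℝ^{t×n} of brain activity (t time samples, n sensors)
time-locked to a word onset, predict the word's embedding Ŷ = f(X) ≈ Y ∈ ℝᵈ
and read the word out by ranking a candidate vocabulary by cosine similarity
to Ŷ.  Training pairs come from subjects reading or listening to sentences
with known word onsets.  Because the target space is a pretrained embedding
space, words never seen in training remain decodable in principle
(zero-shot), which is what separates this from a plain classifier.

## Preprocessing and epoching

Recordings are band-pass filtered 0.1–40 Hz with a zero-phase
forward-backward 4th-order Butterworth (no group delay at word onsets),
resampled to 50 Hz by polyphase rational resampling, scaled per channel by
(x − median)/IQR computed over the whole recording, and clamped to [−5, 5].
A channel whose IQR is zero or negligible relative to the other channels
(e.g. a flat channel reduced to filter residue) is scaled by 1 with a
warning instead of amplifying numerical noise.  No artifact or bad-channel
handling is attempted.

Epochs are 3-s windows starting at the word onset (150 samples at 50 Hz),
mapped to the nearest sample, half-open `[start, start+150)`.  Baseline
correction subtracts each channel's mean over the first 0.5 s of the window
itself; windows that do not fully fit in the recording are dropped and
counted.  Overlapping windows are expected (RSVP words arrive every 0.3 s).
Robust-scaler statistics are per recording, not per split — a deliberate,
logged choice (split-wise statistics would leak nothing anyway, but
per-recording is what one can compute online).

## Splitting

Train/val/test is 80/10/10 at the *sentence* level.  The split label is a
pure function of the sentence text: SHA-1 of the lowercased,
whitespace-collapsed sentence, first 8 bytes as u64 / 2⁶⁴, thresholded at
0.8 and 0.9.  Consequences tests rely on: the same sentence shown to any
subject lands in the same split; adding sentences never moves existing ones;
achieved fractions are binomial around the ratios (±1% at 10⁴ sentences),
not exact quotas.

## Targets

One embedding per word type (non-contextual).  A backend maps a word to one
or more token vectors; multi-token words take the unweighted token mean.
The bundled fallback backend draws a unit-norm Gaussian vector seeded by
(SHA-1(word), seed) — deterministic across platforms, near-orthogonal at
d = 1024 (mean |cos| ≤ 0.05) — so the full pipeline and its tests need no
model download.  A pretrained-LM backend is a drop-in implementation of the
same two-method protocol.  Embeddings are not L2-normalized: every use is
through cosine similarity, so scale is irrelevant.

## Model

- **Spatial attention**: each latent channel j carries learned weights over
  sensors, softmax(w_j · φ(p)) with φ a 2-D Fourier basis (default 8×8
  harmonics) of the sensor positions p ∈ [0,1]².  Weights are
  time-independent; sensors at identical positions are exchangeable.
- **Subject layer**: one identity-initialized D×D linear map per subject,
  pointwise in time.  It absorbs inter-individual sensor-space variability
  and is the only subject-specific part of the model; new subjects require
  fine-tuning a fresh row (no zero-shot subjects).
- **Conv stack**: residual kernel-3 1-D convolutions, dilations cycling
  1/2/4, GELU, length-preserving; a final pointwise projection to d.
- **Temporal pooling**: a single-head attention with one learned query
  collapses (t × d) to one d-vector (weights ≥ 0, sum to 1; value map
  identity-initialized).
- **Sentence transformer**: each word of a sentence is encoded independently
  by the stages above; the sequence of word vectors then passes through a
  pre-norm bidirectional transformer (rotary position encoding, attention
  dropout 0.1 at train time, padded positions neither attend nor are
  attended).  Full-scale defaults are 16 layers / 16 heads / d = 1024; the
  architecture, not the size, is the contract, and tests run compact
  configurations.

The network and its training loop run on an in-package reverse-mode
autodiff core over numpy (float32 in the model path), with every operator
checked against central differences.  This keeps the package free of any
deep-learning framework dependency.

## Objective

With ∡ᵢⱼ = cos(Ŷᵢ, Yⱼ) over a batch of N words, temperature t = exp(t′) and
bias b (both learned):

- CLIP: L = −(1/N) Σᵢ log(e^{t∡ᵢᵢ} / Σⱼ e^{t∡ᵢⱼ}) — one-directional,
  softmax over targets.
- SigLIP: L = −(1/N) Σᵢⱼ log σ(zᵢⱼ(t∡ᵢⱼ − b)), zᵢⱼ = +1 iff i = j.
- D-SigLIP: natural-language batches repeat words; a repeated word's other
  occurrences would enter SigLIP as false negatives.  D-SigLIP keeps only
  the first occurrence of each word in the batch — by default rows *and*
  columns of the repeats are excluded (a rows-only mode, where repeats still
  serve as negative targets, is available; which occurrence survives is
  fixed to the first).

Initialization: t′ = log 10.  The bias starts at b = +10: in this sign
parameterization a negative pair's initial logit is z(t·0 − b) = +10, i.e.
negatives start near-satisfied and the N²−N negative terms cannot swamp the
N positives early in training.  (The equivalent convention stated for the
logit form t∡ + b′ is b′ = −10; with b = −10 *here*, training measurably
stalls at chance.)

## Training

AdamW (weight decay 0.01), learning rate 1e−4 at full scale with half-cosine
decay to 0 over the first 50 epochs, then floor; gradient clipping at global
norm 1.0.  A batch is 64 *sentences* (the transformer consumes sentences;
the loss indexes all words of the batch jointly) — the compact test runs use
32 sentences and lr 3e−3, which converges in ~12 epochs at their scale.
After each epoch the balanced top-10 accuracy on the validation split is
computed against the most-frequent-250-words vocabulary of the train split;
the best checkpoint is kept and training stops after `patience` (default 10)
non-improving epochs.  Train/val sentence-disjointness is asserted before
the first step.

## Evaluation

Retrieval ranks the vocabulary by cosine to Ŷ, ties broken toward earlier
(more frequent) vocabulary entries for determinism.  The headline metric is
balanced top-10: per-word mean hit rate, then unweighted mean over words —
invariant to duplicating a word's trials, chance = k/|V| (4% at k = 10,
|V| = 250).  Words outside the evaluation vocabulary are excluded from
metrics (their count is reported).  Supporting analyses:

- **Repetition averaging**: group predictions of the same word (across
  contexts for a subject, across subjects for a context, or both), average m
  sampled members, re-evaluate; resampling supplies error bars.  Groups with
  fewer than m members are skipped, so large-m points are computed on the
  frequent-word subset that has enough repetitions.
- **Mistake features**: among incorrect top-1 predictions, the fraction
  sharing the true word's first letter, last letter, length, and POS;
  chance from permuting the predicted words across a subject's mistakes
  (default 1000 permutations); one-sided t-test across subjects.
- **Frequency/POS strata**: quartiles of training-set occurrence counts of
  the test words, plus an OOV stratum (0 training occurrences — evaluated
  against the full vocabulary, since an OOV word cannot be in the top-250
  set); per-stratum balanced top-10 with subject-level SEM.  Empty strata
  are absent, not zero.

## Synthetic study generator

The generator emulates the *structure* of word-level M/EEG experiments, not
their physics:

- Zipf lexicon (w_r ∝ r^(−s), default s = 1) with gold POS tags (FUNCTION on
  the top ~15% of mass, content tags below) and word forms of 2–12 letters
  with skewed first/last-letter distributions (so orthographic chance
  baselines are non-degenerate).
- Sentences drawn i.i.d. from the Zipf weights, presented at a 0.3-s
  stimulus-onset asynchrony, 1 s between sentences.
- Per subject: signal = Σ_words mixing·Y_word ⊗ kernel(t − onset) + noise.
  `mixing` is an (n_sensors × d) matrix, entries N(0, 1/d), distinct per
  subject; the kernel is a half-cosine bump with 0.1 s latency and 0.4 s
  duration (evoked energy inside the first 0.5 s); noise is white Gaussian
  per sensor scaled so response-power/noise-power equals `snr` (a pink-noise
  option exists).  A fixed seed determines every output bit.

Because the response is *linear* in the embedding, noiseless recordings make
linear decodability exact: at the kernel-peak lag, the sensor sample is
precisely `mixing @ Y` for the current word (neighbouring words' kernels do
not reach it at a 0.3-s SOA), which the ridge-identifiability tests exploit
(r ≥ 0.99 requires raw epochs without baseline correction — the standard
preprocessing chain caps noiseless recovery near r ≈ 0.88 via baseline
windows containing neighbours, high-pass smear, and clamping).

**What passing tests do and do not show.**  The generator validates the
machinery: preprocessing contracts, leakage-safe splitting, loss algebra,
optimization, retrieval metrics, and recovery of a planted linear code from
noisy multi-subject data (balanced top-10 ≈ 0.81–0.92 vs 0.10 chance at
snr = 5 with ~3000 training epochs).  It does **not** emulate real
linguistic or neural structure: responses are word-local and linear, so
sentence *context* carries no information beyond each word's own window.
Consequently the sentence transformer — which on real data is reported to
add substantial accuracy — does not outperform the CNN-only ablation here
(measured across snr 0.05–5: the CNN-only model is equal or better).  The
transformer's value is a property of real data; on this generator only the
ablation machinery itself is testable.  Similarly, semantic structure in
mistakes cannot arise from isotropic random embeddings; only the chance
calibration of the mistake features is meaningful here.

Numerical footnotes from the tests: (1) even snr = 0.01 remains weakly
decodable (ridge r ≈ 0.2) because tens of sensors pool single-sample
information — the "no signal" control sits at snr = 10⁻³; (2) the ridge
permutation null is run with a flat-ish 250-word vocabulary and averaged
over permutation draws, because with a small skewed vocabulary the permuted
conditional label mean retains a Σp² trace of the true embedding, and in the
noiseless case the null spread scales as 1/d rather than 1/n_test.

## Numerical and engineering choices

- Cosine similarity rejects zero-norm rows instead of silently returning 0.
- Retrieval ties break by vocabulary order via a stable sort.
- Quartile boundaries use `searchsorted(..., side="left")`, so a word
  exactly at a boundary falls into the lower stratum.
- Filters: `scipy.signal.butter` + `sosfiltfilt`, `resample_poly`.
- Ridge: `sklearn.RidgeCV(alphas=10^{-2..8}, alpha_per_target=True)`;
  degenerate (constant-feature) lags report r = 0 with a warning; lags
  outside the epoch window are skipped with a warning.
- float32 model path; matmuls of stacked inputs against 2-D weights collapse
  to one flattened GEMM; on Linux the allocator is tuned (mallopt) so large
  freed buffers are reused across training steps instead of being returned
  to the OS and re-faulted.
- Early stopping keeps a full parameter snapshot of the best epoch; save →
  load reproduces the validation metric to 1e−6 (float32 storage).

## Limitations

- No real-data loaders: recordings enter as arrays + positions + events
  (binary + JSON sidecar + TSV on disk); FIF/EDF adapters would be thin but
  are not bundled or tested.
- The generator omits 1/f-dominated artifacts, eye movements, head geometry
  and lead-field physics; SNR values are free parameters, not calibrated to
  any device.
- Subject layers preclude zero-shot transfer to unseen subjects by design.
- The bundled training scale is a desk-scale configuration; full-scale
  (16-layer, d = 1024) training is supported by the same code but is not
  exercised by the test suite.
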