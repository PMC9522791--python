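# Methods

`voxenc` implements a voxelwise encoding analysis relating the internal
activations of a causal language model to fMRI responses recorded while
subjects listen to spoken narratives, and relating the quality of that
mapping to behavioral comprehension. This note documents the model, the
synthetic world the tests run in, and the numerical choices behind both.

## The encoding model

For one (subject, narrative) pair, stimulus features `X` (scans × dim) are
mapped to BOLD `Y` (scans × voxels) by a spatiotemporal linear estimator
`f ∘ g`:

- **`g` (temporal):** a finite-impulse-response expansion stacking lagged
  copies of `X` at TR offsets (default `{1, 2, 3, 4, 5}`). Lag 0 is
  excluded by default because hemodynamic responses peak seconds after the
  stimulus; the offsets are configurable. The design at scan `j` contains
  feature rows `j − lag`, zero-padded at the series start, so no future
  information enters any row.
- **`f` (spatial):** an l2-penalized linear regression per voxel. The
  penalty is selected for each voxel independently by leave-one-sample-out
  error on the training fold, over ten candidates log-spaced between 1e−1
  and 1e8. The LOO errors are computed with the SVD hat-matrix identity
  (`e_i / (1 − h_ii)`), which is algebraically identical to refitting with
  each row deleted; the test suite checks this equivalence to 1e−6 against
  explicit row deletion and against scikit-learn's `RidgeCV`.

The **brain score** `M` of the pair is the Pearson correlation between
predicted and observed held-out BOLD, computed per voxel over five
contiguous, unshuffled folds of the scan axis (fit on 80%, test on 20%)
and averaged across folds. Contiguous folds respect the temporal
autocorrelation of fMRI; shuffled folds would leak it.

Standardization: the FIR design is z-scored and BOLD mean-centered using
training-fold statistics only. This is a package choice (the contract that
makes one penalty grid meaningful across feature spaces of very different
scales); the encoding literature varies here, and the behavior is
configurable only through the feature matrices themselves. A fold whose
predicted or observed series has zero variance contributes a correlation
of 0 (not NaN) so the fold average stays defined; occurrences are counted
and logged.

## Feature spaces

- **Contextual activations.** Each token's representation is extracted
  with a sliding context window (default 1024 tokens): the model is run on
  the window ending at the token and the final position's residual stream
  at the requested layer is kept. Layer 0 is the non-contextual embedding.
- **Attention-span restriction.** The ablation's "distance" `d` bands
  attention in all layers up to the probed layer `k` so that the extracted
  activation depends on no token further back than `d`. Because banding
  per query row would still leak context through stacked layers, the band
  is anchored at the extracted position; when every layer up to `k` is
  capped this is exactly equivalent to truncating the input window to the
  last `d + 1` tokens, which is the fast path used. Spans are counted in
  tokens, not words: token banding is exact, whereas word banding is
  ill-defined for multi-token words. The mean tokens-per-word ratio of the
  synthetic tokenizer is ~1.3.
- **TR aggregation.** Token vectors are summed over the words presented
  between successive scans. A word belongs to the half-open interval
  `[scan_{j−1}, scan_j)` by its onset; all tokens of a word inherit the
  word's onset; intervals without words are zero rows; words outside the
  scan range are dropped and counted. Column sums are conserved over
  assigned tokens, which the tests assert against a brute-force
  per-interval oracle.
- **Phonological features.** Word rate, phoneme rate, and one-hot counts
  of (phoneme × tone/stress) categories per scan interval. The category
  inventory is corpus-defined: the full cross-product (e.g. 40 phonemes ×
  4 tones = 160) is pruned to the categories actually pronounced (117 in
  the reference corpus), and unknown labels extend the inventory with a
  warning rather than erroring. Stress folds into the tone axis because
  annotated corpora carry one or the other.

## Second-level statistics

Per-pair voxel scores are averaged either across the whole brain
(unweighted over voxels) or within atlas regions (unweighted over member
voxels, background excluded). The correlation `R` between per-pair scores
and comprehension uses Pearson's test; region-level significance of the
scores themselves uses a two-sided Wilcoxon signed-rank across pairs, and
p-values are corrected over all regions jointly with Benjamini–Hochberg
FDR at 0.05. Differences between feature spaces (`M_a − M_b`) isolate the
share of one mapping not accounted for by the other and feed the same
correlation machinery.

The mixed model `comprehension ~ brain_score` includes a per-narrative
random intercept *and* slope (the intercept keeps the model well-posed;
its variance is reported separately). The random-slope significance is a
likelihood-ratio test of intercept+slope vs intercept-only under ML
(REML likelihoods are not comparable across random-effect structures),
with a chi-square df = 2 reference — conservative, since the true null
distribution at the variance boundary is a chi-bar-square mixture.
Singular or non-converged fits are reported with a flag, never dropped.

## The ablation grid and its coefficients

For each (layer `k`, distance `d`) the full pipeline is re-run and two
summaries kept: per-pair-per-region brain scores and per-region
comprehension correlations. Two slopes condense the grid:

- `beta_distance`: OLS slope against `log10(d)` — the tested spans are
  geometric, so the log axis is the natural one. Unrestricted-span cells
  stay in the grid (and must reproduce the plain pipeline exactly, which
  is tested) but are excluded from the fit.
- `beta_layer`: OLS slope against the layer index rescaled to [0, 1], so
  the coefficient reads as the score change from the shallowest to the
  deepest probed layer.

For brain scores the slope is fitted per pair and averaged, with a
Wilcoxon test across pair slopes; for comprehension correlations,
uncertainty comes from bootstrap resampling of pairs with replacement
(default 1000 subsamples; SD across subsamples is the error bar; p is the
two-sided tail fraction against zero; degenerate resamples are redrawn
and counted). Because the functional form behind published coefficient
magnitudes of this kind is not standardized, the absolute values produced
here are not comparable across studies — only signs and contrasts are.

## The synthetic world

The generator emulates the *structure* the analysis assumes, not realistic
physiology:

- **Stories**: inter-word gaps exponential with mean `TR / rate`
  (default 3 words per 1.5 s TR, ~450 words per story), 1–2 tokens per
  word, 2–5 phonemes per word from a 40-symbol inventory with 4 tone
  levels.
- **Toy model**: a 4-layer, 16-dim, 2-head pre-norm transformer with
  fixed seeded weights. Exact block arithmetic is unconstrained; the load-
  bearing contracts — strict causality, determinism, and the span-masking
  invariant — are property-tested directly.
- **BOLD**: `Y = snr · standardize(lagged(F) W^T) + σ ε` with a discrete
  lag profile on TR offsets `{1: 0.3, 2: 0.4, 3: 0.3}` — deliberately
  inside the FIR model class so that noiseless recovery is sharp
  (held-out scores ≥ 0.99 is an acceptance test, and would fail if the
  generator used a continuous hemodynamic function). The noiseless signal
  is standardized per voxel so `snr` *is* the per-voxel signal-to-noise
  ratio at `σ = 1`. The readout source can be a contextual layer
  (default), the bare embedding (context-free, used to show a flat
  distance gradient), or a running mean over the past 50 tokens
  (long-range, used to show span sensitivity).
- **Cohort**: 12 subjects × 5 stories = 60 pairs by default. Per-pair SNR
  is lognormal (`exp(0.4 z)`); comprehension is
  `clip(0.5 + 0.5 · z(snr) + ε, 0, 1)` with ε ~ N(0, 0.1) — a linear
  coupling chosen as a stand-in, not a mechanistic claim; the analysis
  only ever measures the correlation. All randomness derives from streams
  keyed by (master seed, subject index, story index), so any pair
  regenerates identically in isolation.

What a green test does **not** establish: nothing here validates behavior
under realistic hemodynamic variability, motion or physiological noise,
spatial autocorrelation, non-linear brain-behavior coupling, or real
language statistics (the toy model's tokens are uniform noise). The
synthetic oracle for coupling recovery is the direct correlation between
generated comprehension and generated SNR; the pipeline's recovered `R`
tracks it within ±0.12 at 60 pairs, which bounds pipeline-induced
distortion, not real-data effect sizes.

## Numerical and degenerate-case choices

- Constant training voxels get zero coefficients and a flag; constant
  held-out series score 0 with a flag.
- `1 − h_ii` in the LOO identity is clipped at 1e−12 to avoid division
  blow-ups when a penalty interpolates a training row exactly.
- Constant design columns are left centered at zero (std guard at 1);
  the penalty handles rank deficiency.
- Bootstrap p-values are the unsmoothed two-sided tail fraction, so the
  smallest attainable p is `2 / n_boot`.
- Attention masks must keep the softmax diagonal visible; off-band query
  rows in anchored masks retain self-attention so every row stays defined.
- The per-pair slope SEs in the ablation treat pairs as independent; with
  shared stories they are mildly anti-conservative, which is why the
  context-free acceptance check aggregates over replicate cohorts instead
  of trusting a single grid's SE.

## Known limitations

- Real mode consumes precomputed activation matrices and BOLD containers;
  it does not load pretrained transformer weights or NIfTI volumes (no
  deep-learning runtime in the supported environment).
- Noise-ceiling normalization of brain scores is out of scope.
- The attention ablation bands tokens, not words; both conventions exist
  in the literature and word-banding is not implemented.
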