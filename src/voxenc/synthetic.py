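"""Synthetic cohort generator: stories, toy-LM activations, BOLD, comprehension.

Emulates the structure of a naturalistic-listening fMRI cohort — many
(subject, narrative) pairs, word-level timings with phonological
annotations, BOLD sampled every TR — with a *known* generative model so
every downstream stage can be tested against ground truth:

* BOLD is a lagged linear readout of stimulus features (a discrete lag
  profile over TR offsets, deliberately inside the FIR model class),
  scaled per pair by a signal-to-noise ratio and corrupted by white
  Gaussian noise;
* the comprehension score of a pair is a clipped linear function of its
  standardized SNR, so the brain-score/comprehension correlation has a
  known sign and an oracle value.

Nothing here models realistic hemodynamics, head motion, physiological
noise, or spatial autocorrelation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .containers import AtlasLabels, BOLDSeries, CohortIndex, TokenSequence, TRFeatureMatrix, WordTiming
from .features import aggregate_to_trs, extract_activations
from .toylm import ToyCausalLM

__all__ = [
    "ARPABET_PHONEMES",
    "TONE_LEVELS",
    "GroundTruth",
    "CohortConfig",
    "SyntheticStory",
    "SyntheticCohort",
    "make_toy_lm",
    "simulate_story",
    "simulate_bold",
    "simulate_cohort",
]

# 40 English phonemes (ARPAbet) and 4 tone/stress levels: the full
# cross-product gives 160 possible one-hot categories.
ARPABET_PHONEMES = (
    "AA AE AH AO AW AY B CH D DH EH ER EY F G HH IH IY JH K L M N NG OW OY "
    "P R S SH T TH UH UW V W Y Z ZH SIL"
).split()
TONE_LEVELS = ("T0", "T1", "T2", "T3")


def make_toy_lm(
    seed: int = 0,
    n_layers: int = 4,
    dim: int = 16,
    n_heads: int = 2,
    vocab_size: int = 50,
) -> ToyCausalLM:
    """Fixed-weight toy causal transformer (see :class:`ToyCausalLM`)."""
    return ToyCausalLM(
        n_layers=n_layers, dim=dim, n_heads=n_heads, vocab_size=vocab_size, seed=seed
    )


def _rng(*entropy: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(e) for e in entropy]))


def simulate_story(
    seed: int,
    n_words: int = 450,
    tr: float = 1.5,
    words_per_tr_rate: float = 3.0,
    vocab_size: int = 50,
    timing: str = "exponential",
    tokens_per_word_extra_p: float = 0.3,
) -> tuple[TokenSequence, list[WordTiming]]:
    """Timed word sequence with tokens and phonological annotations.

    ``timing='exponential'`` draws inter-word gaps from an exponential
    distribution with mean ``tr / words_per_tr_rate``; ``'regular'`` spaces
    words exactly, which puts precisely ``words_per_tr_rate`` words in
    every scan interval when the rate divides evenly.
    """
    if n_words < 1:
        raise ValueError("n_words must be >= 1")
    if tr <= 0 or words_per_tr_rate <= 0:
        raise ValueError("tr and words_per_tr_rate must be positive")
    rng = _rng(seed, 101)
    mean_gap = tr / words_per_tr_rate
    if timing == "regular":
        onsets = (np.arange(n_words) + 0.5) * mean_gap
    elif timing == "exponential":
        gaps = np.maximum(rng.exponential(mean_gap, n_words), 1e-4)
        onsets = np.cumsum(gaps)
    else:
        raise ValueError(f"unknown timing scheme {timing!r}")

    timings: list[WordTiming] = []
    token_ids: list[int] = []
    token_to_word: list[int] = []
    for i, onset in enumerate(onsets):
        n_tok = 1 + int(rng.random() < tokens_per_word_extra_p)
        ids = rng.integers(0, vocab_size, n_tok)
        token_ids.extend(int(t) for t in ids)
        token_to_word.extend([i] * n_tok)
        n_ph = int(rng.integers(2, 6))
        phonemes = [ARPABET_PHONEMES[int(j)] for j in rng.integers(0, len(ARPABET_PHONEMES), n_ph)]
        tone = TONE_LEVELS[int(rng.integers(0, len(TONE_LEVELS)))]
        duration = min(0.8 * mean_gap, 0.4)
        timings.append(
            WordTiming(
                word=f"w{i:04d}",
                onset=float(onset),
                offset=float(onset + duration),
                phoneme_labels=phonemes,
                stress="",
                tone=tone,
            )
        )
    return TokenSequence(np.array(token_ids), np.array(token_to_word)), timings


@dataclass
class GroundTruth:
    """The generative model behind a synthetic cohort.

    BOLD for pair *p*:  ``Y = snr_p * standardize(lagged(F) @ W.T) + noise``
    where ``F`` are the readout features on the scan grid and ``lagged``
    convolves with ``lag_profile`` over TR offsets.  Comprehension:
    ``clip(a + b * z(snr_p) + eps, 0, 1)``.
    """

    readout_weights: np.ndarray                    # (voxels, dim)
    lag_profile: dict[int, float]                  # TR offset -> weight
    pair_snr: dict[tuple[str, str], float]
    coupling_intercept: float = 0.5                # a
    coupling_slope: float = 0.5                    # b
    noise_sigma: float = 1.0
    comp_noise_sd: float = 0.1
    readout_layer: int = 2
    readout_source: str = "layer"                  # layer | embedding | running_mean
    context_tokens: int = 50

    def __post_init__(self) -> None:
        self.readout_weights = np.asarray(self.readout_weights, dtype=np.float64)
        if not np.all(np.isfinite(self.readout_weights)):
            raise ValueError("readout_weights must be finite")
        weights = np.array(list(self.lag_profile.values()), dtype=float)
        if np.any(weights < 0) or not np.isclose(weights.sum(), 1.0):
            raise ValueError("lag_profile must be non-negative and sum to 1")
        if any(v <= 0 for v in self.pair_snr.values()):
            raise ValueError("pair_snr must be positive")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")


def simulate_bold(
    features: TRFeatureMatrix | np.ndarray,
    truth: GroundTruth,
    pair: tuple[str, str],
    seed: int,
    tr: float = 1.5,
) -> BOLDSeries:
    """BOLD as a lagged linear readout of features, plus Gaussian noise.

    The noiseless signal is standardized per voxel before the pair's SNR
    scaling, so with ``noise_sigma=1`` the per-voxel SNR is exactly
    ``truth.pair_snr[pair]``.  Zero readout weights leave pure noise.
    """
    f = features.values if isinstance(features, TRFeatureMatrix) else np.asarray(features)
    if isinstance(features, TRFeatureMatrix):
        tr = features.tr
    if f.shape[1] != truth.readout_weights.shape[1]:
        raise ValueError(
            f"feature dim {f.shape[1]} does not match readout dim "
            f"{truth.readout_weights.shape[1]}"
        )
    n_scans = f.shape[0]
    lagged = np.zeros_like(f)
    for lag, w in truth.lag_profile.items():
        if lag < n_scans:
            lagged[lag:] += w * f[: n_scans - lag]
    signal = lagged @ truth.readout_weights.T                 # (scans, voxels)
    std = signal.std(axis=0)
    signal = np.divide(signal, std, out=np.zeros_like(signal), where=std > 0)
    rng = _rng(seed, 211)
    snr = truth.pair_snr[pair]
    values = snr * signal + truth.noise_sigma * rng.standard_normal(signal.shape)
    return BOLDSeries(values, tr=tr)


@dataclass
class CohortConfig:
    """Defaults describe the desk-scale stated world: 12 subjects x 5
    stories = 60 pairs, ~450 words per story at 3 words/TR (TR 1.5 s),
    48 voxels in 6 regions, lag profile on TR offsets {1,2,3}."""

    n_subjects: int = 12
    n_stories: int = 5
    n_words: int = 450
    tr: float = 1.5
    words_per_tr_rate: float = 3.0
    timing: str = "exponential"
    n_voxels: int = 48
    n_regions: int = 6
    n_layers: int = 4
    dim: int = 16
    n_heads: int = 2
    vocab_size: int = 50
    readout_layer: int = 2
    readout_source: str = "layer"
    context_tokens: int = 50
    lag_profile: dict[int, float] = field(default_factory=lambda: {1: 0.3, 2: 0.4, 3: 0.3})
    noise_sigma: float = 1.0
    snr_log_sigma: float = 0.4
    coupling_intercept: float = 0.5
    coupling_slope: float = 0.5
    comp_noise_sd: float = 0.1
    extra_scans: int = 8
    zero_readout: bool = False


@dataclass
class SyntheticStory:
    tokens: TokenSequence
    timings: list[WordTiming]
    scan_times: np.ndarray


@dataclass
class SyntheticCohort:
    """A fully simulated cohort with its generative ground truth."""

    cohort: CohortIndex
    stories: dict[str, SyntheticStory]
    bold: dict[tuple[str, str], BOLDSeries]
    truth: GroundTruth
    model: ToyCausalLM
    atlas: AtlasLabels
    config: CohortConfig
    seed: int

    def pair_snr_array(self) -> np.ndarray:
        return np.array([self.truth.pair_snr[p] for p in self.cohort.pairs])

    def oracle_comprehension_correlation(self) -> float:
        """Pearson R between generated comprehension and generated pair SNR.

        Computed directly on the generator's values — independent of the
        encoding pipeline, hence usable as a recovery oracle.
        """
        snr = self.pair_snr_array()
        comp = self.cohort.comprehension
        return float(np.corrcoef(snr, comp)[0, 1])


def _truth_features(
    model: ToyCausalLM, story: SyntheticStory, truth: GroundTruth
) -> TRFeatureMatrix:
    """The feature matrix the generator feeds through the readout."""
    tokens = story.tokens
    if truth.readout_source == "layer":
        act = extract_activations(model, tokens, layer=truth.readout_layer)
        rows = act.values
    elif truth.readout_source == "embedding":
        rows = model.embed(tokens.tokens)
    elif truth.readout_source == "running_mean":
        emb = model.embed(tokens.tokens)
        csum = np.cumsum(emb, axis=0)
        n = len(emb)
        w = truth.context_tokens
        rows = np.empty_like(emb)
        for t in range(n):
            lo = max(0, t - w + 1)
            rows[t] = (csum[t] - (csum[lo - 1] if lo > 0 else 0)) / (t - lo + 1)
    else:
        raise ValueError(f"unknown readout_source {truth.readout_source!r}")
    return aggregate_to_trs(rows, tokens.token_to_word, story.timings, story.scan_times)


def simulate_cohort(config: CohortConfig | None = None, seed: int = 0) -> SyntheticCohort:
    """Generate a complete reproducible cohort from a master seed.

    Per-pair randomness is drawn from streams keyed by (seed, subject
    index, story index), so any pair regenerates identically regardless of
    enumeration order.
    """
    cfg = config or CohortConfig()
    model = make_toy_lm(
        seed=int(_rng(seed, 7).integers(0, 2**31)),
        n_layers=cfg.n_layers,
        dim=cfg.dim,
        n_heads=cfg.n_heads,
        vocab_size=cfg.vocab_size,
    )

    stories: dict[str, SyntheticStory] = {}
    for wi in range(cfg.n_stories):
        story_seed = int(_rng(seed, 1000 + wi).integers(0, 2**31))
        tokens, timings = simulate_story(
            story_seed,
            n_words=cfg.n_words,
            tr=cfg.tr,
            words_per_tr_rate=cfg.words_per_tr_rate,
            vocab_size=cfg.vocab_size,
            timing=cfg.timing,
        )
        last = timings[-1].offset
        n_scans = int(np.ceil(last / cfg.tr)) + cfg.extra_scans
        scan_times = cfg.tr * np.arange(1, n_scans + 1)
        stories[f"story{wi:02d}"] = SyntheticStory(tokens, timings, scan_times)

    w_rng = _rng(seed, 11)
    readout = w_rng.normal(0.0, 1.0, (cfg.n_voxels, cfg.dim)) / np.sqrt(cfg.dim)
    if cfg.zero_readout:
        readout = np.zeros_like(readout)

    subjects = [f"sub{si:03d}" for si in range(cfg.n_subjects)]
    narratives = list(stories)
    pairs = [(s, w) for s in subjects for w in narratives]
    pair_snr = {}
    for si, s in enumerate(subjects):
        for wi, w in enumerate(narratives):
            z = _rng(seed, 23, si, wi).standard_normal()
            pair_snr[(s, w)] = float(np.exp(cfg.snr_log_sigma * z))

    truth = GroundTruth(
        readout_weights=readout,
        lag_profile=dict(cfg.lag_profile),
        pair_snr=pair_snr,
        coupling_intercept=cfg.coupling_intercept,
        coupling_slope=cfg.coupling_slope,
        noise_sigma=cfg.noise_sigma,
        comp_noise_sd=cfg.comp_noise_sd,
        readout_layer=cfg.readout_layer,
        readout_source=cfg.readout_source,
        context_tokens=cfg.context_tokens,
    )

    snr_values = np.array([pair_snr[p] for p in pairs])
    z = (snr_values - snr_values.mean()) / snr_values.std()
    comp = np.empty(len(pairs))
    for i, (s, w) in enumerate(pairs):
        si, wi = subjects.index(s), narratives.index(w)
        eps = cfg.comp_noise_sd * _rng(seed, 29, si, wi).standard_normal()
        comp[i] = cfg.coupling_intercept + cfg.coupling_slope * z[i] + eps
    comp = np.clip(comp, 0.0, 1.0)
    cohort = CohortIndex(pairs=pairs, comprehension=comp)

    feature_cache = {w: _truth_features(model, stories[w], truth) for w in narratives}
    bold: dict[tuple[str, str], BOLDSeries] = {}
    for si, s in enumerate(subjects):
        for wi, w in enumerate(narratives):
            pair_seed = int(_rng(seed, 37, si, wi).integers(0, 2**31))
            bold[(s, w)] = simulate_bold(
                feature_cache[w], truth, (s, w), pair_seed, tr=cfg.tr
            )

    labels = np.array(
        [f"r{v * cfg.n_regions // cfg.n_voxels:02d}" for v in range(cfg.n_voxels)]
    )
    import pandas as pd

    region_info = pd.DataFrame(
        {
            "region": sorted(set(labels)),
            "hemisphere": ["L" if i % 2 == 0 else "R" for i in range(cfg.n_regions)],
        }
    )
    atlas = AtlasLabels(labels=labels, region_info=region_info)

    return SyntheticCohort(
        cohort=cohort,
        stories=stories,
        bold=bold,
        truth=truth,
        model=model,
        atlas=atlas,
        config=cfg,
        seed=seed,
    )
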