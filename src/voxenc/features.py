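"""Stimulus feature construction aligned to the fMRI scan grid.

Covers the three feature spaces the encoding analysis compares:

* **contextual activations** of a causal language model, extracted per
  token with a sliding context window and, optionally, a restricted
  attention span (the ablation's "distance" ``d``);
* the **non-contextual word embedding** (layer 0);
* **phonological features** — word rate, phoneme rate, and one-hot
  (phoneme x tone/stress) category counts per scan interval.

Per-token activations are summed over the words presented between two
successive scans, yielding one feature vector per measurement.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field

import numpy as np

from .containers import ActivationMatrix, TokenSequence, TRFeatureMatrix, WordTiming
from .toylm import ToyCausalLM

__all__ = [
    "format_transcript",
    "extract_activations",
    "aggregate_to_trs",
    "phonological_features",
    "PhonologicalVocabulary",
]

logger = logging.getLogger(__name__)

_DASHES = re.compile(r"[–—]")  # en dash, em dash
_DUP_TERMINALS = re.compile(r"[.?!]{2,}")


def format_transcript(raw_text: str) -> str:
    """Normalize transcript punctuation before tokenization.

    En/em dashes and duplicated terminal marks (``?.``, ``!.``, ``..`` ...)
    are replaced by a single dot; everything else is left untouched.
    """
    text = _DASHES.sub(".", raw_text)
    return _DUP_TERMINALS.sub(".", text)


def extract_activations(
    model: ToyCausalLM,
    tokens: TokenSequence | np.ndarray,
    layer: int,
    context_window: int = 1024,
    span: int | None = None,
    span_layer_cap: int | None = None,
) -> ActivationMatrix:
    """Per-token activations of one layer under a sliding context window.

    Each token's representation is computed from at most ``context_window``
    trailing tokens ending at that token.  When ``span`` is given, every
    layer up to ``span_layer_cap`` (default: the extracted layer) may only
    access the ``span`` previous positions, so the returned activations at
    any capped layer are invariant to tokens further back than ``span``.
    Layer 0 is the non-contextual embedding and ignores span and window.
    """
    ids = tokens.tokens if isinstance(tokens, TokenSequence) else np.asarray(tokens)
    if not 0 <= layer <= model.n_layers:
        raise ValueError(f"layer {layer} out of range 0..{model.n_layers}")
    if context_window < 1:
        raise ValueError("context_window must be >= 1")
    if span is not None and span < 0:
        raise ValueError("span must be >= 0 or None")
    n = len(ids)

    if layer == 0:
        return ActivationMatrix(model.embed(ids), layer=0, span=span)

    if span_layer_cap is None:
        span_layer_cap = layer

    # A span covering the whole usable window is vacuous.
    if span is not None and span >= min(n, context_window) - 1:
        span = None

    if span is None:
        values = _sliding_extract(model, ids, layer, context_window)
    elif layer <= span_layer_cap:
        # Capped layers only ever see the last span+1 tokens, so truncating
        # the input is equivalent to (and cheaper than) masking.
        width = min(context_window, span + 1)
        values = _windowed_extract(model, ids, layer, width)
    else:
        values = _anchored_band_extract(
            model, ids, layer, context_window, span, span_layer_cap
        )
    return ActivationMatrix(values, layer=layer, span=span)


def _sliding_extract(
    model: ToyCausalLM, ids: np.ndarray, layer: int, window: int
) -> np.ndarray:
    n = len(ids)
    head = min(n, window)
    # Causality: one forward over the first `window` tokens yields each
    # prefix-window representation exactly.
    values = np.empty((n, model.dim))
    values[:head] = model.hidden_states(ids[:head])[layer]
    if n > head:
        tails = np.stack([ids[t - window + 1 : t + 1] for t in range(head, n)])
        values[head:] = model.last_hidden_batched(tails, layer)
    return values


def _windowed_extract(
    model: ToyCausalLM, ids: np.ndarray, layer: int, width: int
) -> np.ndarray:
    n = len(ids)
    head = min(n, width)
    values = np.empty((n, model.dim))
    values[:head] = model.hidden_states(ids[:head])[layer]
    if n > head:
        tails = np.stack([ids[t - width + 1 : t + 1] for t in range(head, n)])
        values[head:] = model.last_hidden_batched(tails, layer)
    return values


def _anchored_band_extract(
    model: ToyCausalLM,
    ids: np.ndarray,
    layer: int,
    window: int,
    span: int,
    cap: int,
) -> np.ndarray:
    # General case: layers above the cap keep the full context window while
    # capped layers are banded relative to the extracted position.
    n = len(ids)
    values = np.empty((n, model.dim))
    for t in range(n):
        lo = max(0, t - window + 1)
        chunk = ids[lo : t + 1]
        anchor = len(chunk) - 1
        masks = model.banded_masks(len(chunk), span, cap, anchor=anchor)
        values[t] = model.hidden_states(chunk, masks)[layer][-1]
    return values


def aggregate_to_trs(
    activations: ActivationMatrix | np.ndarray,
    token_to_word: np.ndarray,
    word_timings: list[WordTiming],
    scan_times: np.ndarray,
    tr: float | None = None,
) -> TRFeatureMatrix:
    """Sum per-token activations over the words between successive scans.

    Scan ``j`` collects the tokens of every word whose onset falls in
    ``[scan_times[j-1], scan_times[j])`` (the first interval opens one TR
    before the first scan).  Intervals without words yield zero rows; words
    outside the scan range are dropped, logged, and counted on the result's
    ``n_dropped_words`` attribute.
    """
    if isinstance(activations, ActivationMatrix):
        rows, layer, span = activations.values, activations.layer, activations.span
    else:
        rows, layer, span = np.asarray(activations, dtype=np.float64), None, None
    token_to_word = np.asarray(token_to_word, dtype=np.int64)
    scan_times = np.asarray(scan_times, dtype=np.float64)
    if len(token_to_word) != rows.shape[0]:
        raise ValueError("token_to_word length must equal activation rows")
    if len(scan_times) < 1 or np.any(np.diff(scan_times) <= 0):
        raise ValueError("scan_times must be strictly increasing")

    inferred_tr = tr if tr is not None else _infer_tr(scan_times)
    first_edge = scan_times[0] - inferred_tr
    onsets = np.array([w.onset for w in word_timings])
    word_interval = np.searchsorted(scan_times, onsets, side="right")
    in_range = (onsets >= first_edge) & (word_interval < len(scan_times))
    n_dropped = int((~in_range).sum())
    if n_dropped:
        logger.warning("aggregate_to_trs: dropped %d word(s) outside scan range", n_dropped)

    out = np.zeros((len(scan_times), rows.shape[1]))
    tok_word = token_to_word
    valid_tok = in_range[tok_word]
    np.add.at(out, word_interval[tok_word[valid_tok]], rows[valid_tok])
    mat = TRFeatureMatrix(
        out,
        tr=inferred_tr,
        feature_kind="word_embedding" if layer == 0 else "lm_layer",
        layer=layer,
        span=span,
    )
    mat.n_dropped_words = n_dropped
    return mat


def _infer_tr(scan_times: np.ndarray) -> float:
    if len(scan_times) > 1:
        return float(np.median(np.diff(scan_times)))
    return float(scan_times[0]) if scan_times[0] > 0 else 1.0


@dataclass
class PhonologicalVocabulary:
    """Corpus-defined (phoneme x tone/stress) category inventory.

    The full cross-product ``|phonemes| x |tones|`` counts the *possible*
    categories; ``category_index`` only indexes the categories actually
    pronounced in the corpus, which is what the one-hot block encodes.
    """

    phoneme_set: list[str]
    tone_set: list[str]
    category_index: dict[tuple[str, str], int] = field(default_factory=dict)

    @property
    def full_size(self) -> int:
        return len(self.phoneme_set) * len(self.tone_set)

    @property
    def n_categories(self) -> int:
        return len(self.category_index)

    @classmethod
    def from_corpus(cls, word_timings: list[WordTiming]) -> "PhonologicalVocabulary":
        phonemes: set[str] = set()
        tones: set[str] = set()
        pronounced: set[tuple[str, str]] = set()
        for w in word_timings:
            axis = _tone_axis(w)
            for ph in w.phoneme_labels:
                phonemes.add(ph)
                tones.add(axis)
                pronounced.add((ph, axis))
        index = {cat: i for i, cat in enumerate(sorted(pronounced))}
        return cls(sorted(phonemes), sorted(tones), index)

    def add_category(self, phoneme: str, tone: str) -> int:
        if phoneme not in self.phoneme_set:
            self.phoneme_set.append(phoneme)
        if tone not in self.tone_set:
            self.tone_set.append(tone)
        idx = len(self.category_index)
        self.category_index[(phoneme, tone)] = idx
        return idx


def _tone_axis(w: WordTiming) -> str:
    # Stress folds into the tone axis: corpora annotate one or the other.
    return w.tone if w.tone else (w.stress if w.stress else "0")


def phonological_features(
    word_timings: list[WordTiming],
    scan_times: np.ndarray,
    vocabulary: PhonologicalVocabulary | None = None,
    tr: float | None = None,
) -> tuple[TRFeatureMatrix, PhonologicalVocabulary]:
    """Low-level speech features per scan interval.

    Columns are ``[word_rate, phoneme_rate, one-hot category counts...]``
    where the one-hot block spans the pronounced (phoneme, tone/stress)
    categories.  Unknown phonemes under a supplied vocabulary are added
    with a warning — the inventory is corpus-defined, not fixed.
    """
    scan_times = np.asarray(scan_times, dtype=np.float64)
    if np.any(np.diff(scan_times) <= 0):
        raise ValueError("scan_times must be strictly increasing")
    if vocabulary is None:
        vocabulary = PhonologicalVocabulary.from_corpus(word_timings)

    inferred_tr = tr if tr is not None else _infer_tr(scan_times)
    first_edge = scan_times[0] - inferred_tr
    n_scans = len(scan_times)
    # the category block can grow if unseen phonemes appear
    counts: dict[tuple[int, int], float] = {}
    word_rate = np.zeros(n_scans)
    phoneme_rate = np.zeros(n_scans)
    n_dropped = 0
    for w in word_timings:
        j = int(np.searchsorted(scan_times, w.onset, side="right"))
        if w.onset < first_edge or j >= n_scans:
            n_dropped += 1
            continue
        word_rate[j] += 1
        phoneme_rate[j] += len(w.phoneme_labels)
        axis = _tone_axis(w)
        for ph in w.phoneme_labels:
            key = (ph, axis)
            if key not in vocabulary.category_index:
                logger.warning("phonological_features: new category %s added", key)
                vocabulary.add_category(ph, axis)
            counts[(j, vocabulary.category_index[key])] = (
                counts.get((j, vocabulary.category_index[key]), 0.0) + 1.0
            )
    if n_dropped:
        logger.warning("phonological_features: dropped %d word(s) outside scan range", n_dropped)

    onehot = np.zeros((n_scans, vocabulary.n_categories))
    for (j, c), v in counts.items():
        onehot[j, c] = v
    values = np.column_stack([word_rate, phoneme_rate, onehot])
    names = ["word_rate", "phoneme_rate"] + [
        f"{ph}|{tone}" for (ph, tone), _ in sorted(
            vocabulary.category_index.items(), key=lambda kv: kv[1]
        )
    ]
    mat = TRFeatureMatrix(
        values, tr=inferred_tr, feature_kind="phonological", column_names=names
    )
    mat.n_dropped_words = n_dropped
    return mat, vocabulary
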