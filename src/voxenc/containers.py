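"""Shared in-memory containers for the encoding pipeline.

These are deliberately thin wrappers over numpy arrays / pandas frames:
the heavy lifting happens in :mod:`voxenc.encoding` and friends, and the
containers only carry the metadata (TR, layer, span, labels) that the
pipeline stages need to agree on.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "WordTiming",
    "TokenSequence",
    "ActivationMatrix",
    "TRFeatureMatrix",
    "BOLDSeries",
    "CohortIndex",
    "AtlasLabels",
]


@dataclass
class WordTiming:
    """A single time-aligned word with its phonological annotations."""

    word: str
    onset: float
    offset: float
    phoneme_labels: list[str] = field(default_factory=list)
    stress: str = ""
    tone: str = ""

    def __post_init__(self) -> None:
        if self.onset < 0 or self.offset < self.onset:
            raise ValueError(
                f"invalid timing for {self.word!r}: onset={self.onset}, offset={self.offset}"
            )


@dataclass
class TokenSequence:
    """Token ids plus the token -> word mapping produced by tokenization."""

    tokens: np.ndarray
    token_to_word: np.ndarray

    def __post_init__(self) -> None:
        self.tokens = np.asarray(self.tokens, dtype=np.int64)
        self.token_to_word = np.asarray(self.token_to_word, dtype=np.int64)
        if self.tokens.shape != self.token_to_word.shape:
            raise ValueError("tokens and token_to_word must have equal length")
        if len(self.token_to_word) and np.any(np.diff(self.token_to_word) < 0):
            raise ValueError("token_to_word must be non-decreasing")

    def __len__(self) -> int:
        return len(self.tokens)


@dataclass
class ActivationMatrix:
    """Per-token model activations at one layer, optionally span-restricted.

    ``layer`` 0 is the non-contextual word embedding; ``span`` is the
    attention distance in tokens (``None`` = unrestricted causal attention).
    """

    values: np.ndarray
    layer: int
    span: int | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise ValueError("activation values must be 2-D (tokens x dim)")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("activations contain non-finite values")

    @property
    def n_tokens(self) -> int:
        return self.values.shape[0]

    @property
    def dim(self) -> int:
        return self.values.shape[1]


@dataclass
class TRFeatureMatrix:
    """Stimulus features resampled onto the fMRI scan grid (scans x dim)."""

    values: np.ndarray
    tr: float
    feature_kind: str = "lm_layer"
    layer: int | None = None
    span: int | None = None
    column_names: list[str] | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise ValueError("TR feature values must be 2-D (scans x dim)")
        if self.tr <= 0:
            raise ValueError("tr must be positive")

    @property
    def n_scans(self) -> int:
        return self.values.shape[0]

    @property
    def dim(self) -> int:
        return self.values.shape[1]


@dataclass
class BOLDSeries:
    """BOLD response matrix (scans x voxels) with its repetition time."""

    values: np.ndarray
    tr: float
    voxel_labels: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise ValueError("BOLD values must be 2-D (scans x voxels)")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("BOLD contains non-finite values")
        if self.tr <= 0:
            raise ValueError("tr must be positive")
        if self.voxel_labels is not None:
            self.voxel_labels = np.asarray(self.voxel_labels)
            if len(self.voxel_labels) != self.values.shape[1]:
                raise ValueError("voxel_labels length must equal voxel count")

    @property
    def n_scans(self) -> int:
        return self.values.shape[0]

    @property
    def n_voxels(self) -> int:
        return self.values.shape[1]


@dataclass
class CohortIndex:
    """(subject, narrative) pairing with a comprehension score per pair."""

    pairs: list[tuple[str, str]]
    comprehension: np.ndarray

    def __post_init__(self) -> None:
        self.comprehension = np.asarray(self.comprehension, dtype=np.float64)
        if len(self.pairs) != len(self.comprehension):
            raise ValueError("one comprehension score required per pair")
        if len(set(self.pairs)) != len(self.pairs):
            raise ValueError("pairs must be unique")
        if len(self.comprehension) and (
            self.comprehension.min() < 0 or self.comprehension.max() > 1
        ):
            raise ValueError("comprehension scores must lie in [0, 1]")

    def __len__(self) -> int:
        return len(self.pairs)

    @property
    def subjects(self) -> list[str]:
        return sorted({s for s, _ in self.pairs})

    @property
    def narratives(self) -> list[str]:
        return sorted({w for _, w in self.pairs})

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "subject": [s for s, _ in self.pairs],
                "narrative": [w for _, w in self.pairs],
                "comprehension": self.comprehension,
            }
        )


@dataclass
class AtlasLabels:
    """Voxel -> region lookup; voxels labelled ``background`` are excluded."""

    labels: np.ndarray
    region_info: pd.DataFrame | None = None
    background: str = "background"

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)

    @property
    def regions(self) -> list[str]:
        return sorted(r for r in np.unique(self.labels) if r != self.background)

    @property
    def n_voxels(self) -> int:
        return len(self.labels)
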