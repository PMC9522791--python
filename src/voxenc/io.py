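"""File formats: events TSV, matrix containers, cohort/score tables, config.

All tables are plain TSV; array payloads are ``.npy`` files with a JSON
sidecar carrying their metadata (TR, layer, span, labels, provenance).
Every writer here has a matching reader and round-trips exactly.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .containers import AtlasLabels, BOLDSeries, CohortIndex, TokenSequence, TRFeatureMatrix, WordTiming

__all__ = [
    "FormatError",
    "read_events_tsv",
    "write_events_tsv",
    "save_matrix",
    "load_matrix",
    "write_cohort_tsv",
    "read_cohort_tsv",
    "write_scores_tsv",
    "read_scores_tsv",
    "write_atlas_tsv",
    "read_atlas_tsv",
    "RunConfig",
    "load_config",
    "write_sidecar",
]

logger = logging.getLogger(__name__)

_REQUIRED_EVENT_COLUMNS = ("onset_s", "word")


class FormatError(ValueError):
    """A file does not match the expected format."""


def read_events_tsv(path: str | Path) -> list[WordTiming]:
    """Read word timings; rows come back onset-sorted.

    Required columns: ``onset_s``, ``word``; optional: ``duration_s``,
    ``phonemes`` (space-separated), ``stress``, ``tone``.  Malformed rows
    are skipped with a warning naming their line numbers.
    """
    df = pd.read_csv(path, sep="\t", dtype={"word": str, "stress": str, "tone": str})
    for col in _REQUIRED_EVENT_COLUMNS:
        if col not in df.columns:
            raise FormatError(f"{path}: missing required column {col!r}")
    records: list[WordTiming] = []
    bad_lines: list[int] = []
    for i, row in df.iterrows():
        line_no = i + 2  # header is line 1
        try:
            onset = float(row["onset_s"])
            word = str(row["word"])
            if not np.isfinite(onset) or word in ("", "nan"):
                raise ValueError
            duration = float(row.get("duration_s", 0.0) or 0.0)
            phonemes = str(row.get("phonemes", "") or "")
            records.append(
                WordTiming(
                    word=word,
                    onset=onset,
                    offset=onset + max(duration, 0.0),
                    phoneme_labels=phonemes.split() if phonemes and phonemes != "nan" else [],
                    stress=_opt_str(row.get("stress")),
                    tone=_opt_str(row.get("tone")),
                )
            )
        except (TypeError, ValueError):
            bad_lines.append(line_no)
    if bad_lines:
        logger.warning("%s: skipped malformed row(s) at line(s) %s", path, bad_lines)
    onsets = [r.onset for r in records]
    if onsets != sorted(onsets):
        logger.warning("%s: onsets not sorted; returning records in onset order", path)
        records.sort(key=lambda r: r.onset)
    return records


def _opt_str(v) -> str:
    if v is None or (isinstance(v, float) and np.isnan(v)) or str(v) == "nan":
        return ""
    return str(v)


def write_events_tsv(path: str | Path, timings: list[WordTiming]) -> None:
    pd.DataFrame(
        {
            "onset_s": [w.onset for w in timings],
            "duration_s": [w.offset - w.onset for w in timings],
            "word": [w.word for w in timings],
            "phonemes": [" ".join(w.phoneme_labels) for w in timings],
            "stress": [w.stress for w in timings],
            "tone": [w.tone for w in timings],
        }
    ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# matrix container: .npy + .json sidecar


def save_matrix(prefix: str | Path, values: np.ndarray, **meta) -> Path:
    """Write ``<prefix>.npy`` plus ``<prefix>.json`` metadata; returns the npy path."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    npy = prefix.with_suffix(".npy")
    np.save(npy, np.asarray(values))
    write_sidecar(prefix.with_suffix(".json"), meta)
    return npy


def load_matrix(prefix: str | Path) -> tuple[np.ndarray, dict]:
    prefix = Path(prefix)
    values = np.load(prefix.with_suffix(".npy"))
    sidecar = prefix.with_suffix(".json")
    meta = json.loads(sidecar.read_text()) if sidecar.exists() else {}
    return values, meta


def save_bold(prefix: str | Path, bold: BOLDSeries, **meta) -> Path:
    labels = None if bold.voxel_labels is None else [str(x) for x in bold.voxel_labels]
    return save_matrix(prefix, bold.values, tr=bold.tr, voxel_labels=labels, **meta)


def load_bold(prefix: str | Path) -> BOLDSeries:
    values, meta = load_matrix(prefix)
    labels = meta.get("voxel_labels")
    return BOLDSeries(
        values, tr=float(meta.get("tr", 1.5)),
        voxel_labels=None if labels is None else np.asarray(labels),
    )


def save_features(prefix: str | Path, feats: TRFeatureMatrix, **meta) -> Path:
    return save_matrix(
        prefix, feats.values, tr=feats.tr, feature_kind=feats.feature_kind,
        layer=feats.layer, span=feats.span, **meta,
    )


def load_features(prefix: str | Path) -> TRFeatureMatrix:
    values, meta = load_matrix(prefix)
    return TRFeatureMatrix(
        values, tr=float(meta.get("tr", 1.5)),
        feature_kind=meta.get("feature_kind", "lm_layer"),
        layer=meta.get("layer"), span=meta.get("span"),
    )


def save_tokens(path: str | Path, tokens: TokenSequence) -> None:
    Path(path).write_text(
        json.dumps(
            {"tokens": tokens.tokens.tolist(), "token_to_word": tokens.token_to_word.tolist()}
        )
    )


def load_tokens(path: str | Path) -> TokenSequence:
    d = json.loads(Path(path).read_text())
    return TokenSequence(np.array(d["tokens"]), np.array(d["token_to_word"]))


# ---------------------------------------------------------------------------
# tables


def write_cohort_tsv(path: str | Path, cohort: CohortIndex) -> None:
    cohort.to_frame().to_csv(path, sep="\t", index=False)


def read_cohort_tsv(path: str | Path) -> CohortIndex:
    df = pd.read_csv(path, sep="\t", dtype={"subject": str, "narrative": str})
    for col in ("subject", "narrative", "comprehension"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing required column {col!r}")
    return CohortIndex(
        pairs=list(zip(df["subject"], df["narrative"])),
        comprehension=df["comprehension"].to_numpy(),
    )


def write_scores_tsv(path: str | Path, scores: pd.DataFrame) -> None:
    """Long-format per-voxel scores: subject, narrative, voxel, score."""
    long = scores.stack().rename("score").reset_index()
    long.columns = ["subject", "narrative", "voxel", "score"]
    long.to_csv(path, sep="\t", index=False)


def read_scores_tsv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"subject": str, "narrative": str})
    for col in ("subject", "narrative", "voxel", "score"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing required column {col!r}")
    wide = df.pivot_table(index=["subject", "narrative"], columns="voxel", values="score")
    wide.columns.name = None
    return wide


def write_atlas_tsv(path: str | Path, atlas: AtlasLabels) -> None:
    info = atlas.region_info
    hemi = {}
    name = {}
    if info is not None:
        hemi = dict(zip(info["region"], info.get("hemisphere", ""), strict=False))
        if "name" in info:
            name = dict(zip(info["region"], info["name"], strict=False))
    pd.DataFrame(
        {
            "voxel": np.arange(atlas.n_voxels),
            "region": atlas.labels,
            "hemisphere": [hemi.get(r, "") for r in atlas.labels],
            "name": [name.get(r, str(r)) for r in atlas.labels],
        }
    ).to_csv(path, sep="\t", index=False)


def read_atlas_tsv(path: str | Path) -> AtlasLabels:
    df = pd.read_csv(path, sep="\t", dtype={"region": str})
    for col in ("voxel", "region"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing required column {col!r}")
    df = df.sort_values("voxel")
    info = (
        df.drop_duplicates("region")[["region"] + [c for c in ("hemisphere", "name") if c in df]]
        .reset_index(drop=True)
    )
    return AtlasLabels(labels=df["region"].to_numpy(), region_info=info)


# ---------------------------------------------------------------------------
# configuration and provenance


@dataclass
class RunConfig:
    """End-to-end pipeline configuration (synthetic or real mode)."""

    mode: str = "synthetic"
    seed: int = 0
    out: str | None = None
    layer: int = 2
    span: int | None = None
    context_window: int = 1024
    lags: tuple[int, ...] = (1, 2, 3, 4, 5)
    alphas_logspace: tuple[float, float, int] = (-1.0, 8.0, 10)
    n_folds: int = 5
    per_narrative: bool = True
    mixed_model: bool = True
    roi_level: bool = True
    fdr_q: float = 0.05
    cohort: dict = field(default_factory=dict)
    ablate: bool = False
    ablation_layers: tuple[int, ...] = ()
    ablation_distances: tuple = ()
    n_boot: int = 1000
    cache_dir: str | None = None
    # real mode inputs
    features_path: str | None = None
    bold_path: str | None = None
    cohort_path: str | None = None
    atlas_path: str | None = None

    def config_hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha1(payload.encode()).hexdigest()[:12]


def load_config(path: str | Path) -> RunConfig:
    """Read a YAML or JSON config file into a :class:`RunConfig`."""
    text = Path(path).read_text()
    data = yaml.safe_load(text) or {}
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(data) - known
    if unknown:
        raise FormatError(f"{path}: unknown config key(s) {sorted(unknown)}")
    for key in ("lags", "alphas_logspace", "ablation_layers", "ablation_distances"):
        if key in data and data[key] is not None:
            data[key] = tuple(data[key])
    return RunConfig(**data)


def write_sidecar(path: str | Path, meta: dict) -> None:
    def _default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, tuple):
            return list(o)
        return str(o)

    Path(path).write_text(json.dumps(meta, indent=2, sort_keys=True, default=_default))
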