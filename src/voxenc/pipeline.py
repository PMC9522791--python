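"""End-to-end composition: simulate/load -> extract -> score -> correlate.

``run_pipeline`` ties the stages together under a single :class:`RunConfig`
and returns a :class:`PipelineResult` carrying the headline brain-score /
comprehension correlation, region-level statistics, the per-narrative
replication, and the mixed-model decomposition.  Every output written to
disk gets a JSON sidecar with the config hash and seed, and reruns with an
identical config are deterministic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .ablation import AblationResults, AblationStudy
from .containers import AtlasLabels, CohortIndex
from .encoding import EncodingModel, FIRSpec, FoldSpec, RidgeSpec
from .features import aggregate_to_trs, extract_activations
from .io import RunConfig, load_bold, read_atlas_tsv, read_cohort_tsv, write_sidecar
from .stats import (
    ComprehensionCorrelation,
    MixedEffectsDecomposition,
    correlate_comprehension,
    fdr_bh,
    mixed_effects_decomposition,
    per_narrative_correlations,
    roi_average,
    wilcoxon_second_level,
)
from .synthetic import CohortConfig, SyntheticCohort, simulate_cohort

__all__ = ["PipelineError", "PipelineResult", "score_cohort", "run_pipeline"]

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


def _encoding_specs(config: RunConfig):
    lo, hi, n = config.alphas_logspace
    return (
        FIRSpec(lags=tuple(config.lags)),
        RidgeSpec(alphas=tuple(np.logspace(lo, hi, int(n)))),
        FoldSpec(n_folds=config.n_folds),
    )


def score_cohort(
    dataset,
    layer: int,
    span: int | None = None,
    context_window: int = 1024,
    fir_spec: FIRSpec = FIRSpec(),
    ridge_spec: RidgeSpec = RidgeSpec(),
    fold_spec: FoldSpec = FoldSpec(),
) -> pd.DataFrame:
    """Per-voxel brain scores for every pair; (subject, narrative) x voxel.

    Activations are extracted once per story and reused across subjects.
    """
    feats = {}
    for name, story in dataset.stories.items():
        act = extract_activations(
            dataset.model, story.tokens, layer=layer,
            context_window=context_window, span=span,
            span_layer_cap=layer if span is not None else None,
        )
        feats[name] = aggregate_to_trs(
            act, story.tokens.token_to_word, story.timings, story.scan_times
        )
    rows, index = [], []
    for (s, w) in dataset.cohort.pairs:
        res = EncodingModel(
            feats[w], dataset.bold[(s, w)], fir_spec, ridge_spec, fold_spec
        ).fit()
        rows.append(res.voxel_scores)
        index.append((s, w))
    return pd.DataFrame(
        np.vstack(rows),
        index=pd.MultiIndex.from_tuples(index, names=["subject", "narrative"]),
    )


@dataclass
class PipelineResult:
    """Results bundle of one end-to-end run."""

    config: RunConfig
    cohort: CohortIndex
    pair_scores: pd.DataFrame                       # (subject, narrative) x voxel
    whole_brain: pd.Series                          # per-pair voxel-mean score
    correlation: ComprehensionCorrelation
    region_table: pd.DataFrame | None = None        # region, mean_score, p, q, rejected
    per_narrative: dict[str, ComprehensionCorrelation] = field(default_factory=dict)
    mixed: MixedEffectsDecomposition | None = None
    ablation: AblationResults | None = None
    stage_log: list[str] = field(default_factory=list)
    dataset: SyntheticCohort | None = None

    def summary(self) -> str:
        lines = [
            "Encoding pipeline results",
            "=" * 42,
            f"pairs:               {len(self.cohort)}",
            f"voxels:              {self.pair_scores.shape[1]}",
            f"mean brain score:    {self.whole_brain.mean():+.4f}",
            f"comprehension R:     {self.correlation.R:+.3f} (p={self.correlation.p:.2e})",
        ]
        if self.per_narrative:
            best = max(self.per_narrative.items(), key=lambda kv: kv[1].R)
            lines.append(f"best narrative R:    {best[1].R:+.3f} ({best[0]})")
        if self.mixed is not None:
            lines.append(
                f"mixed fixed slope:   {self.mixed.fixed_slope:+.4f} "
                f"(p={self.mixed.fixed_slope_p:.2e})"
            )
            lines.append(
                f"random slope var:    {self.mixed.random_slope_var:.2e} "
                f"(LRT p={self.mixed.random_slope_lrt_p:.3g})"
            )
        if self.region_table is not None:
            n_sig = int(self.region_table["rejected"].sum())
            lines.append(f"significant regions: {n_sig}/{len(self.region_table)} (BH-FDR)")
        return "\n".join(lines)


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Execute the full analysis described by ``config``.

    Synthetic mode simulates the cohort from ``config.seed``; real mode
    loads cohort/BOLD/atlas tables from the configured paths.  Stage
    failures raise :class:`PipelineError` naming the stage.
    """
    log: list[str] = []

    def stage(name: str, fn, *args, **kwargs):
        try:
            out = fn(*args, **kwargs)
        except Exception as err:
            raise PipelineError(f"stage {name!r} failed: {err}") from err
        log.append(name)
        return out

    if config.mode == "synthetic":
        dataset = stage(
            "simulate", simulate_cohort, CohortConfig(**config.cohort), config.seed
        )
        cohort, atlas = dataset.cohort, dataset.atlas
    elif config.mode == "real":
        dataset = None
        cohort = stage("load-cohort", read_cohort_tsv, config.cohort_path)
        atlas = read_atlas_tsv(config.atlas_path) if config.atlas_path else None
    else:
        raise PipelineError(f"unknown mode {config.mode!r}")

    fir, ridge, folds = _encoding_specs(config)
    if config.mode == "synthetic":
        pair_scores = stage(
            "score", score_cohort, dataset, config.layer,
            span=config.span, context_window=config.context_window,
            fir_spec=fir, ridge_spec=ridge, fold_spec=folds,
        )
    else:
        pair_scores = stage("score", _score_real, config, cohort, fir, ridge, folds)

    whole_brain = pair_scores.mean(axis=1)
    correlation = stage(
        "correlate", correlate_comprehension, whole_brain.to_numpy(), cohort
    )

    region_table = None
    if config.roi_level and atlas is not None:
        region_scores = stage("roi-average", roi_average, pair_scores, atlas)
        p = wilcoxon_second_level(region_scores)
        rejected, q = fdr_bh(p, q=config.fdr_q)
        region_table = pd.DataFrame(
            {
                "region": region_scores.columns,
                "mean_score": region_scores.mean(axis=0).to_numpy(),
                "p": p,
                "q": q,
                "rejected": rejected,
            }
        )
        log.append("region-stats")

    per_narr: dict[str, ComprehensionCorrelation] = {}
    if config.per_narrative:
        per_narr = stage(
            "per-narrative", per_narrative_correlations, whole_brain.to_numpy(), cohort
        )

    mixed = None
    if config.mixed_model:
        mixed = stage(
            "mixed-model", mixed_effects_decomposition, whole_brain.to_numpy(), cohort
        )

    ablation = None
    if config.ablate:
        if config.mode != "synthetic":
            raise PipelineError("stage 'ablate' failed: ablation requires synthetic mode")
        distances = [None if d in (None, "full") else int(d) for d in config.ablation_distances]
        study = AblationStudy(
            dataset.model, dataset,
            layers=list(config.ablation_layers), distances=distances,
            fir_spec=fir, ridge_spec=ridge, fold_spec=folds,
            atlas=atlas, context_window=config.context_window,
            cache_dir=config.cache_dir,
        )
        ablation = stage("ablate", study.run)

    result = PipelineResult(
        config=config, cohort=cohort, pair_scores=pair_scores,
        whole_brain=whole_brain, correlation=correlation,
        region_table=region_table, per_narrative=per_narr,
        mixed=mixed, ablation=ablation, stage_log=log, dataset=dataset,
    )
    if config.out:
        _write_outputs(result, Path(config.out))
        log.append("write")
    return result


def _score_real(config: RunConfig, cohort: CohortIndex, fir, ridge, folds) -> pd.DataFrame:
    """Real mode: one precomputed feature/BOLD container pair per cohort pair."""
    from .io import load_features

    rows, index = [], []
    for (s, w) in cohort.pairs:
        feats = load_features(Path(config.features_path) / w)
        bold = load_bold(Path(config.bold_path) / f"{s}_{w}")
        res = EncodingModel(feats, bold, fir, ridge, folds).fit()
        rows.append(res.voxel_scores)
        index.append((s, w))
    return pd.DataFrame(
        np.vstack(rows),
        index=pd.MultiIndex.from_tuples(index, names=["subject", "narrative"]),
    )


def _write_outputs(result: PipelineResult, outdir: Path) -> None:
    from .io import write_cohort_tsv, write_scores_tsv

    outdir.mkdir(parents=True, exist_ok=True)
    prov = {
        "config_hash": result.config.config_hash(),
        "seed": result.config.seed,
        "stages": result.stage_log,
    }
    write_scores_tsv(outdir / "scores.tsv", result.pair_scores)
    write_sidecar(outdir / "scores.json", prov)
    write_cohort_tsv(outdir / "cohort.tsv", result.cohort)
    corr_rows = [
        {"scope": result.correlation.scope, "R": result.correlation.R,
         "p": result.correlation.p, "n": result.correlation.n}
    ]
    for w, c in result.per_narrative.items():
        corr_rows.append({"scope": c.scope, "R": c.R, "p": c.p, "n": c.n})
    pd.DataFrame(corr_rows).to_csv(outdir / "correlations.tsv", sep="\t", index=False)
    write_sidecar(outdir / "correlations.json", prov)
    if result.region_table is not None:
        result.region_table.to_csv(outdir / "regions.tsv", sep="\t", index=False)
        write_sidecar(outdir / "regions.json", prov)
    if result.mixed is not None:
        write_sidecar(
            outdir / "mixed_model.json",
            {**prov, "fixed_slope": result.mixed.fixed_slope,
             "fixed_slope_p": result.mixed.fixed_slope_p,
             "random_slope_var": result.mixed.random_slope_var,
             "random_slope_lrt_p": result.mixed.random_slope_lrt_p,
             "converged": result.mixed.converged},
        )
    if result.ablation is not None:
        result.ablation.grid_frame().to_csv(outdir / "ablation_grid.tsv", sep="\t", index=False)
        coeffs = pd.concat(
            [
                result.ablation.distance_coefficients().assign(kind="distance"),
                result.ablation.layer_coefficients().assign(kind="layer"),
            ]
        )
        coeffs.to_csv(outdir / "ablation_coefficients.tsv", sep="\t", index=False)
        write_sidecar(outdir / "ablation.json", prov)
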