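"""Attention-span x layer ablation of the encoding model.

For every (layer ``k``, attention distance ``d``) cell, activations are
re-extracted with all layers up to ``k`` banded to the ``d`` previous
positions, the full encoding pipeline is re-run, and two quantities are
stored: per-pair-per-region brain scores, and the per-region correlation
of brain scores with comprehension.  Two slopes summarize the grid:

* ``beta_distance`` — least-squares slope of a score against
  ``log10(distance)`` (tested spans are geometric, so the log scale is
  the natural axis); positive means sensitivity to long-range context;
* ``beta_layer`` — slope against the layer index rescaled to [0, 1];
  positive means deeper layers score better.

For brain scores the slope is fitted per (subject, narrative) pair and
averaged (second-level inference via Wilcoxon across pairs); for
comprehension correlations uncertainty comes from bootstrap resampling
of pairs (1000 subsamples by default).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import AtlasLabels, CohortIndex
from .encoding import EncodingModel, FIRSpec, FoldSpec, RidgeSpec
from .features import aggregate_to_trs, extract_activations
from .stats import roi_average, wilcoxon_second_level

__all__ = [
    "AblationGrid",
    "AblationStudy",
    "AblationResults",
    "CoefficientEstimate",
    "BootstrapEstimate",
    "grid_scores",
    "fit_distance_coefficient",
    "fit_layer_coefficient",
    "bootstrap_coefficients",
]

logger = logging.getLogger(__name__)


@dataclass
class AblationGrid:
    """Scores indexed by (pair, region, layer k, distance d).

    ``distances`` may contain ``None`` for unrestricted attention; those
    cells participate in the grid but not in distance-slope fits.
    """

    layers: list[int]
    distances: list[int | None]
    pairs: list[tuple[str, str]]
    regions: list[str]
    brain_scores: np.ndarray            # (pairs, regions, layers, distances)
    comp_R: np.ndarray                  # (regions, layers, distances)
    cohort: CohortIndex | None = None
    missing: np.ndarray | None = None   # (layers, distances) bool

    def __post_init__(self) -> None:
        expected = (len(self.pairs), len(self.regions), len(self.layers), len(self.distances))
        if tuple(self.brain_scores.shape) != expected:
            raise ValueError(f"brain_scores shape {self.brain_scores.shape} != {expected}")
        if self.missing is None:
            self.missing = np.zeros((len(self.layers), len(self.distances)), dtype=bool)

    def finite_distance_indices(self) -> list[int]:
        return [i for i, d in enumerate(self.distances) if d is not None]

    def pair_scores(self, layer: int, distance: int | None, region: str | None = None) -> np.ndarray:
        """Per-pair scores at one cell (region mean = whole-brain if None)."""
        li, di = self.layers.index(layer), self.distances.index(distance)
        cell = self.brain_scores[:, :, li, di]
        if region is None:
            return cell.mean(axis=1)
        return cell[:, self.regions.index(region)]


@dataclass
class CoefficientEstimate:
    beta: float
    se: float
    per_pair: np.ndarray | None = None  # per-pair slopes (brain-score target)
    wilcoxon_p: float = np.nan

    def __str__(self) -> str:
        return f"beta={self.beta:+.4f} (SE={self.se:.4f})"


@dataclass
class BootstrapEstimate:
    beta: float
    sd: float
    ci_low: float
    ci_high: float
    p: float
    n_boot: int
    n_redrawn: int = 0


def _slope(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """OLS slope and its standard error."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    xc = x - x.mean()
    sxx = (xc ** 2).sum()
    beta = float((xc * y).sum() / sxx)
    resid = y - y.mean() - beta * xc
    dof = max(len(x) - 2, 1)
    se = float(np.sqrt((resid ** 2).sum() / dof / sxx))
    return beta, se


def _target_series(
    grid: AblationGrid, target: str, region: str | None
) -> np.ndarray:
    """(pairs?, layers, distances) series for the requested target/region."""
    if target == "brain_score":
        cube = grid.brain_scores
        if region is None:
            return cube.mean(axis=1)
        return cube[:, grid.regions.index(region)]
    if target == "comprehension_R":
        if region is None:
            if grid.cohort is None:
                raise ValueError("grid carries no cohort; whole-brain R unavailable")
            comp = grid.cohort.comprehension
            wb = grid.brain_scores.mean(axis=1)  # (pairs, layers, distances)
            return _corr_over_pairs(wb, comp)
        return grid.comp_R[grid.regions.index(region)]
    raise ValueError(f"unknown target {target!r}")


def _corr_over_pairs(scores: np.ndarray, comp: np.ndarray) -> np.ndarray:
    """Pearson r over axis 0 of (pairs, ...) against comp, vectorized."""
    s = scores - scores.mean(axis=0)
    c = comp - comp.mean()
    num = np.tensordot(c, s, axes=(0, 0))
    den = np.sqrt((s ** 2).sum(axis=0)) * np.sqrt((c ** 2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(den > 0, num / den, np.nan)


def _layer_axis(layers: list[int]) -> np.ndarray:
    ks = np.asarray(layers, dtype=float)
    if ks.max() == ks.min():
        raise ValueError("need at least two distinct layers")
    return (ks - ks.min()) / (ks.max() - ks.min())


def fit_distance_coefficient(
    grid: AblationGrid,
    layer: int,
    target: str = "brain_score",
    region: str | None = None,
) -> CoefficientEstimate:
    """Slope of the target against log10(distance) at one layer.

    Brain scores: one slope per pair, averaged; SE is the SEM across pairs
    and a two-sided Wilcoxon p across pair slopes is attached.
    Comprehension R: single-series OLS slope (bootstrap for uncertainty).
    """
    didx = grid.finite_distance_indices()
    if len(didx) < 3:
        raise ValueError("need at least 3 finite distances")
    li = grid.layers.index(layer)
    x = np.log10([grid.distances[i] for i in didx])
    series = _target_series(grid, target, region)
    if target == "brain_score":
        y = series[:, li, didx]                       # (pairs, distances)
        xc = x - x.mean()
        slopes = (y * xc).sum(axis=1) / (xc ** 2).sum()
        wp = float(wilcoxon_second_level(slopes[:, None])[0]) if len(slopes) >= 6 else np.nan
        return CoefficientEstimate(
            beta=float(slopes.mean()),
            se=float(slopes.std(ddof=1) / np.sqrt(len(slopes))) if len(slopes) > 1 else np.nan,
            per_pair=slopes,
            wilcoxon_p=wp,
        )
    beta, se = _slope(x, series[li, didx])
    return CoefficientEstimate(beta=beta, se=se)


def fit_layer_coefficient(
    grid: AblationGrid,
    distance: int | None,
    target: str = "brain_score",
    region: str | None = None,
) -> CoefficientEstimate:
    """Slope of the target against the [0,1]-rescaled layer index at one distance."""
    if len(grid.layers) < 3:
        raise ValueError("need at least 3 layers")
    di = grid.distances.index(distance)
    x = _layer_axis(grid.layers)
    series = _target_series(grid, target, region)
    if target == "brain_score":
        y = series[:, :, di]                          # (pairs, layers)
        xc = x - x.mean()
        slopes = (y * xc).sum(axis=1) / (xc ** 2).sum()
        wp = float(wilcoxon_second_level(slopes[:, None])[0]) if len(slopes) >= 6 else np.nan
        return CoefficientEstimate(
            beta=float(slopes.mean()),
            se=float(slopes.std(ddof=1) / np.sqrt(len(slopes))) if len(slopes) > 1 else np.nan,
            per_pair=slopes,
            wilcoxon_p=wp,
        )
    beta, se = _slope(x, series[:, di])
    return CoefficientEstimate(beta=beta, se=se)


def bootstrap_coefficients(
    grid: AblationGrid,
    coefficient: str,
    layer: int | None = None,
    distance: int | None = None,
    region: str | None = None,
    n_boot: int = 1000,
    seed: int = 0,
    max_redraws: int = 1000,
) -> BootstrapEstimate:
    """Bootstrap the comprehension-score coefficient over pair resamples.

    Pairs are resampled with replacement ``n_boot`` times; each subsample's
    comprehension correlations and slope are recomputed.  The standard
    deviation across subsamples is the error bar; ``p`` is the two-sided
    tail fraction of the bootstrap distribution against zero.  Degenerate
    resamples (zero comprehension variance) are redrawn and counted.
    """
    if n_boot < 100:
        raise ValueError("n_boot must be >= 100")
    if grid.cohort is None:
        raise ValueError("grid carries no cohort")
    didx = grid.finite_distance_indices()
    if coefficient == "distance":
        if layer is None:
            raise ValueError("distance coefficient requires a layer")
        li = grid.layers.index(layer)
        x = np.log10([grid.distances[i] for i in didx])
        cells = [(li, di) for di in didx]
    elif coefficient == "layer":
        di = grid.distances.index(distance)
        x = _layer_axis(grid.layers)
        cells = [(li, di) for li in range(len(grid.layers))]
    else:
        raise ValueError(f"unknown coefficient {coefficient!r}")

    if region is None:
        scores = grid.brain_scores.mean(axis=1)      # (pairs, layers, distances)
    else:
        scores = grid.brain_scores[:, grid.regions.index(region)]
    y_full = np.stack([scores[:, li, di] for (li, di) in cells], axis=1)  # (pairs, cells)
    comp = grid.cohort.comprehension
    n_pairs = len(comp)
    xc = x - x.mean()
    sxx = (xc ** 2).sum()

    rng = np.random.default_rng(np.random.SeedSequence([seed, 41]))
    betas = np.empty(n_boot)
    n_redrawn = 0
    # full-sample point estimate
    r_full = _corr_over_pairs(y_full, comp)
    beta_full = float((xc * r_full).sum() / sxx)
    for b in range(n_boot):
        for _ in range(max_redraws):
            idx = rng.integers(0, n_pairs, n_pairs)
            c = comp[idx]
            if c.std() > 0 and np.all(y_full[idx].std(axis=0) > 0):
                break
            n_redrawn += 1
        else:
            raise RuntimeError("could not draw a non-degenerate bootstrap sample")
        r = _corr_over_pairs(y_full[idx], c)
        betas[b] = (xc * r).sum() / sxx
    if n_redrawn:
        logger.warning("bootstrap_coefficients: %d degenerate resample(s) redrawn", n_redrawn)
    sd = float(betas.std(ddof=1))
    lo, hi = np.percentile(betas, [2.5, 97.5])
    p = float(min(1.0, 2.0 * min((betas <= 0).mean(), (betas >= 0).mean())))
    return BootstrapEstimate(
        beta=beta_full, sd=sd, ci_low=float(lo), ci_high=float(hi),
        p=p, n_boot=n_boot, n_redrawn=n_redrawn,
    )


# ---------------------------------------------------------------------------


def grid_scores(
    model,
    dataset,
    layers: list[int],
    distances: list[int | None],
    fir_spec: FIRSpec = FIRSpec(),
    ridge_spec: RidgeSpec = RidgeSpec(),
    fold_spec: FoldSpec = FoldSpec(),
    atlas: AtlasLabels | None = None,
    context_window: int = 1024,
    cache_dir: str | Path | None = None,
) -> AblationGrid:
    """Run the full encoding pipeline for every (layer, distance) cell.

    See :class:`AblationStudy` for the object-oriented surface (this is
    the workhorse it delegates to).  A failed cell is recorded as missing
    and the run continues.
    """
    study = AblationStudy(
        model, dataset, layers, distances,
        fir_spec=fir_spec, ridge_spec=ridge_spec, fold_spec=fold_spec,
        atlas=atlas, context_window=context_window, cache_dir=cache_dir,
    )
    return study.run().grid


class AblationStudy:
    """Layer x attention-distance ablation over a cohort.

    ``dataset`` must expose ``stories`` (name -> object with ``tokens``,
    ``timings``, ``scan_times``), ``bold`` (pair -> BOLDSeries) and
    ``cohort`` (a :class:`CohortIndex`) — a :class:`SyntheticCohort` fits.
    Cells are cached on disk when ``cache_dir`` is given, keyed by model,
    cell and encoding configuration, so reruns are incremental.
    """

    def __init__(
        self,
        model,
        dataset,
        layers: list[int],
        distances: list[int | None],
        fir_spec: FIRSpec = FIRSpec(),
        ridge_spec: RidgeSpec = RidgeSpec(),
        fold_spec: FoldSpec = FoldSpec(),
        atlas: AtlasLabels | None = None,
        context_window: int = 1024,
        cache_dir: str | Path | None = None,
    ) -> None:
        finite = [d for d in distances if d is not None]
        if finite != sorted(finite):
            raise ValueError("distances must be sorted ascending")
        self.model = model
        self.dataset = dataset
        self.layers = list(layers)
        self.distances = list(distances)
        self.fir_spec = fir_spec
        self.ridge_spec = ridge_spec
        self.fold_spec = fold_spec
        self.atlas = atlas
        self.context_window = context_window
        self.cache_dir = Path(cache_dir) if cache_dir is not None else None
        self.cache_hits = 0
        self.cache_misses = 0

    # -- caching -----------------------------------------------------------

    def _cell_key(self, layer: int, distance: int | None) -> str:
        model = self.model
        payload = json.dumps(
            {
                "model": [model.seed, model.n_layers, model.dim, model.n_heads, model.vocab_size],
                "layer": layer,
                "distance": distance,
                "lags": self.fir_spec.lags,
                "alphas": self.ridge_spec.alphas,
                "folds": self.fold_spec.n_folds,
                "window": self.context_window,
                "cohort": [getattr(self.dataset, "seed", None), len(self.dataset.cohort)],
            },
            sort_keys=True,
            default=str,
        )
        return hashlib.sha1(payload.encode()).hexdigest()[:16]

    def _compute_cell(self, layer: int, distance: int | None) -> np.ndarray:
        """Per-pair-per-region brain scores for one (layer, distance) cell."""
        if self.cache_dir is not None:
            path = self.cache_dir / f"cell_{self._cell_key(layer, distance)}.npz"
            if path.exists():
                self.cache_hits += 1
                return np.load(path)["scores"]
        feats = {}
        for name, story in self.dataset.stories.items():
            act = extract_activations(
                self.model, story.tokens, layer=layer,
                context_window=self.context_window,
                span=distance, span_layer_cap=layer,
            )
            feats[name] = aggregate_to_trs(
                act, story.tokens.token_to_word, story.timings, story.scan_times
            )
        rows = []
        for (s, w) in self.dataset.cohort.pairs:
            res = EncodingModel(
                feats[w], self.dataset.bold[(s, w)],
                self.fir_spec, self.ridge_spec, self.fold_spec,
            ).fit()
            rows.append(res.voxel_scores)
        voxel_scores = np.vstack(rows)               # (pairs, voxels)
        if self.atlas is not None:
            region_scores = roi_average(voxel_scores, self.atlas).values
        else:
            region_scores = voxel_scores.mean(axis=1, keepdims=True)
        if self.cache_dir is not None:
            self.cache_dir.mkdir(parents=True, exist_ok=True)
            np.savez(path, scores=region_scores)
            self.cache_misses += 1
        return region_scores

    # -- execution ---------------------------------------------------------

    def run(self) -> "AblationResults":
        regions = self.atlas.regions if self.atlas is not None else ["whole-brain"]
        cohort = self.dataset.cohort
        n_pairs = len(cohort)
        shape = (n_pairs, len(regions), len(self.layers), len(self.distances))
        brain = np.full(shape, np.nan)
        comp_R = np.full((len(regions), len(self.layers), len(self.distances)), np.nan)
        missing = np.zeros((len(self.layers), len(self.distances)), dtype=bool)
        comp = cohort.comprehension
        for li, k in enumerate(self.layers):
            for di, d in enumerate(self.distances):
                try:
                    cell = self._compute_cell(k, d)
                except Exception as err:  # record and continue
                    logger.warning("ablation cell (k=%s, d=%s) failed: %s", k, d, err)
                    missing[li, di] = True
                    continue
                brain[:, :, li, di] = cell
                comp_R[:, li, di] = _corr_over_pairs(cell, comp)
        grid = AblationGrid(
            layers=self.layers, distances=self.distances,
            pairs=list(cohort.pairs), regions=regions,
            brain_scores=brain, comp_R=comp_R, cohort=cohort, missing=missing,
        )
        return AblationResults(grid=grid, study=self)


@dataclass
class AblationResults:
    """Fitted ablation grid with coefficient accessors."""

    grid: AblationGrid
    study: AblationStudy | None = None

    def distance_coefficients(self, target: str = "brain_score") -> pd.DataFrame:
        rows = []
        for k in self.grid.layers:
            est = fit_distance_coefficient(self.grid, k, target=target)
            rows.append({"layer": k, "beta_distance": est.beta, "se": est.se,
                         "wilcoxon_p": est.wilcoxon_p})
        return pd.DataFrame(rows)

    def layer_coefficients(self, target: str = "brain_score") -> pd.DataFrame:
        rows = []
        for d in self.grid.distances:
            est = fit_layer_coefficient(self.grid, d, target=target)
            rows.append({"distance": d, "beta_layer": est.beta, "se": est.se,
                         "wilcoxon_p": est.wilcoxon_p})
        return pd.DataFrame(rows)

    def grid_frame(self) -> pd.DataFrame:
        recs = []
        wb = self.grid.brain_scores.mean(axis=1)     # (pairs, layers, distances)
        for li, k in enumerate(self.grid.layers):
            for di, d in enumerate(self.grid.distances):
                recs.append({
                    "layer": k,
                    "distance": "full" if d is None else d,
                    "mean_brain_score": float(np.nanmean(wb[:, li, di])),
                    "comp_R": float(np.nanmean(self.grid.comp_R[:, li, di])),
                })
        return pd.DataFrame(recs)

    def summary(self) -> str:
        g = self.grid
        lines = [
            "Attention-span x layer ablation",
            "=" * 39,
            f"layers:    {g.layers}",
            f"distances: {['full' if d is None else d for d in g.distances]}",
            f"pairs:     {len(g.pairs)}   regions: {len(g.regions)}",
        ]
        if self.study is not None and self.study.cache_dir is not None:
            lines.append(
                f"cache:     {self.study.cache_hits} hit(s), {self.study.cache_misses} miss(es)"
            )
        lines.append("")
        lines.append(self.grid_frame().to_string(index=False))
        return "\n".join(lines)
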