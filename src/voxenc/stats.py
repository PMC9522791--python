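"""Second-level statistics linking brain scores to behavior.

Brain scores are first-level quantities (one per voxel per (subject,
narrative) pair).  This module aggregates and tests them:

* ROI averaging over an atlas label table;
* Pearson correlation ``R`` between per-pair brain scores and per-pair
  comprehension scores (whole brain, per region, or per narrative);
* score differences between feature spaces, isolating the share of a
  mapping not accounted for by a lower level of representation;
* a two-sided Wilcoxon signed-rank test across pairs (is the score
  distribution's location nonzero?), with Benjamini-Hochberg FDR
  correction across regions;
* a linear mixed model predicting comprehension from brain scores with
  narrative as a random effect, separating the shared (fixed) slope from
  narrative-specific (random) variation.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.regression.mixed_linear_model import MixedLM
from statsmodels.stats.multitest import multipletests

from .containers import AtlasLabels, CohortIndex

__all__ = [
    "ComprehensionCorrelation",
    "roi_average",
    "correlate_comprehension",
    "score_difference",
    "wilcoxon_second_level",
    "fdr_bh",
    "MixedEffectsDecomposition",
    "mixed_effects_decomposition",
    "per_narrative_correlations",
]

logger = logging.getLogger(__name__)


@dataclass
class ComprehensionCorrelation:
    """Pearson correlation between brain scores and comprehension scores."""

    R: float
    p: float
    n: int
    scope: str = "whole-brain"

    def __str__(self) -> str:
        return f"R={self.R:+.3f} (p={self.p:.2e}, n={self.n}, scope={self.scope})"


def roi_average(
    voxel_scores: pd.DataFrame | np.ndarray, atlas: AtlasLabels
) -> pd.DataFrame:
    """Unweighted mean of member-voxel scores per region.

    ``voxel_scores`` is (pairs x voxels); background voxels are excluded;
    an empty region yields NaN with a warning.  Returns (pairs x regions).
    """
    values = voxel_scores.values if isinstance(voxel_scores, pd.DataFrame) else np.asarray(voxel_scores)
    if values.ndim == 1:
        values = values[None, :]
    if values.shape[1] != atlas.n_voxels:
        raise ValueError("atlas does not cover the voxel axis")
    index = voxel_scores.index if isinstance(voxel_scores, pd.DataFrame) else None
    cols: dict[str, np.ndarray] = {}
    for region in atlas.regions:
        mask = atlas.labels == region
        if not mask.any():
            logger.warning("roi_average: region %s is empty", region)
            cols[region] = np.full(values.shape[0], np.nan)
        else:
            cols[region] = values[:, mask].mean(axis=1)
    return pd.DataFrame(cols, index=index)


def correlate_comprehension(
    scores_per_pair: np.ndarray | pd.Series,
    cohort: CohortIndex,
    scope: str = "whole-brain",
) -> ComprehensionCorrelation:
    """Pearson R (and two-sided p) between per-pair scores and comprehension."""
    scores = np.asarray(
        scores_per_pair.values if isinstance(scores_per_pair, pd.Series) else scores_per_pair,
        dtype=np.float64,
    )
    comp = cohort.comprehension
    if len(scores) != len(comp):
        raise ValueError("one score per cohort pair required")
    ok = np.isfinite(scores) & np.isfinite(comp)
    scores, comp = scores[ok], comp[ok]
    if len(scores) < 3:
        raise ValueError("need at least 3 pairs with defined scores")
    if scores.std() == 0 or comp.std() == 0:
        raise ValueError("zero variance: correlation undefined")
    r, p = sps.pearsonr(scores, comp)
    return ComprehensionCorrelation(R=float(r), p=float(p), n=len(scores), scope=scope)


def score_difference(
    scores_a: pd.DataFrame | np.ndarray, scores_b: pd.DataFrame | np.ndarray
) -> pd.DataFrame | np.ndarray:
    """Elementwise M_a - M_b over identical (pair, voxel/region) axes.

    Isolates the share of mapping *a* not accounted for by mapping *b*
    (e.g. contextual-layer minus word-embedding brain scores).
    """
    if isinstance(scores_a, pd.DataFrame) and isinstance(scores_b, pd.DataFrame):
        if not scores_a.index.equals(scores_b.index) or not scores_a.columns.equals(scores_b.columns):
            raise ValueError("score tables must share index and columns")
        return scores_a - scores_b
    a, b = np.asarray(scores_a), np.asarray(scores_b)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    return a - b


def wilcoxon_second_level(pair_scores: np.ndarray | pd.DataFrame) -> np.ndarray:
    """Two-sided Wilcoxon signed-rank p per region, across pairs.

    Tests whether the per-pair score distribution's location differs from
    zero.  All-zero columns are undefined and yield NaN with a warning.
    """
    values = pair_scores.values if isinstance(pair_scores, pd.DataFrame) else np.asarray(pair_scores)
    if values.ndim == 1:
        values = values[:, None]
    if values.shape[0] < 6:
        raise ValueError("need at least 6 pairs for the signed-rank test")
    out = np.empty(values.shape[1])
    for j in range(values.shape[1]):
        col = values[:, j]
        if np.all(col == 0):
            logger.warning("wilcoxon_second_level: column %d all zero, p undefined", j)
            out[j] = np.nan
            continue
        out[j] = sps.wilcoxon(col, alternative="two-sided").pvalue
    return out


def fdr_bh(p_values: np.ndarray, q: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up procedure at level ``q``.

    Returns (rejected mask, adjusted p-values); NaN inputs are never
    rejected and stay NaN.
    """
    p = np.asarray(p_values, dtype=np.float64)
    ok = np.isfinite(p)
    if np.any((p[ok] < 0) | (p[ok] > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    rejected = np.zeros(p.shape, dtype=bool)
    adjusted = np.full(p.shape, np.nan)
    if ok.any():
        rej, adj, _, _ = multipletests(p[ok], alpha=q, method="fdr_bh")
        rejected[ok] = rej
        adjusted[ok] = adj
    return rejected, adjusted


@dataclass
class MixedEffectsDecomposition:
    """Fixed vs narrative-level variation of the comprehension/brain-score link."""

    fixed_slope: float
    fixed_slope_p: float
    fixed_intercept: float
    random_slope_var: float
    random_intercept_var: float
    random_slope_lrt_p: float
    converged: bool
    n_pairs: int
    n_narratives: int

    def summary(self) -> str:
        return "\n".join(
            [
                "Mixed model: comprehension ~ brain_score + (brain_score | narrative)",
                "-" * 66,
                f"fixed slope:          {self.fixed_slope:+.4f} (p={self.fixed_slope_p:.3g})",
                f"fixed intercept:      {self.fixed_intercept:+.4f}",
                f"random slope var:     {self.random_slope_var:.3e} (LRT p={self.random_slope_lrt_p:.3g})",
                f"random intercept var: {self.random_intercept_var:.3e}",
                f"pairs / narratives:   {self.n_pairs} / {self.n_narratives}",
                f"converged:            {self.converged}",
            ]
        )


def mixed_effects_decomposition(
    pair_scores: np.ndarray | pd.Series, cohort: CohortIndex
) -> MixedEffectsDecomposition:
    """comprehension ~ brain_score with per-narrative random intercept + slope.

    The fixed slope is the effect shared across narratives; the random
    slope variance measures narrative-specific departures, with a
    likelihood-ratio test (random intercept+slope vs intercept-only,
    chi-square df=2 — conservative at the variance boundary).
    """
    scores = np.asarray(
        pair_scores.values if isinstance(pair_scores, pd.Series) else pair_scores,
        dtype=np.float64,
    )
    df = cohort.to_frame()
    if len(scores) != len(df):
        raise ValueError("one score per cohort pair required")
    df = df.assign(score=scores)
    counts = df.groupby("narrative").size()
    if len(counts) < 2:
        raise ValueError("need at least 2 narratives")
    if counts.min() < 3:
        raise ValueError("need at least 3 pairs per narrative")

    converged = True
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            full = MixedLM.from_formula(
                "comprehension ~ score", groups="narrative", re_formula="~score", data=df
            ).fit(reml=False)
            reduced = MixedLM.from_formula(
                "comprehension ~ score", groups="narrative", re_formula="~1", data=df
            ).fit(reml=False)
            converged = bool(full.converged and reduced.converged)
        except Exception:  # singular fits must be reported, not dropped
            logger.warning("mixed_effects_decomposition: singular fit")
            full = MixedLM.from_formula(
                "comprehension ~ score", groups="narrative", re_formula="~score", data=df
            ).fit(reml=False, method="nm")
            reduced = None
            converged = False

    cov_re = np.asarray(full.cov_re)
    lrt_p = np.nan
    if reduced is not None:
        lrt = max(0.0, 2.0 * (full.llf - reduced.llf))
        lrt_p = float(sps.chi2.sf(lrt, df=2))
    return MixedEffectsDecomposition(
        fixed_slope=float(full.params["score"]),
        fixed_slope_p=float(full.pvalues["score"]),
        fixed_intercept=float(full.params["Intercept"]),
        random_slope_var=float(cov_re[1, 1]) if cov_re.shape[0] > 1 else 0.0,
        random_intercept_var=float(cov_re[0, 0]),
        random_slope_lrt_p=lrt_p,
        converged=converged,
        n_pairs=len(df),
        n_narratives=len(counts),
    )


def per_narrative_correlations(
    pair_scores: np.ndarray | pd.Series, cohort: CohortIndex
) -> dict[str, ComprehensionCorrelation]:
    """``correlate_comprehension`` restricted to each narrative's pairs.

    Narratives with fewer than 3 subjects or degenerate variance are
    skipped with a warning; the rest are unaffected.
    """
    scores = np.asarray(
        pair_scores.values if isinstance(pair_scores, pd.Series) else pair_scores,
        dtype=np.float64,
    )
    if len(scores) != len(cohort):
        raise ValueError("one score per cohort pair required")
    narratives = np.array([w for _, w in cohort.pairs])
    out: dict[str, ComprehensionCorrelation] = {}
    for w in cohort.narratives:
        mask = narratives == w
        if mask.sum() < 3:
            logger.warning("per_narrative_correlations: %s has <3 subjects, skipped", w)
            continue
        sub = CohortIndex(
            pairs=[p for p, m in zip(cohort.pairs, mask) if m],
            comprehension=cohort.comprehension[mask],
        )
        try:
            out[w] = correlate_comprehension(scores[mask], sub, scope=f"narrative:{w}")
        except ValueError as err:
            logger.warning("per_narrative_correlations: %s skipped (%s)", w, err)
    return out
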