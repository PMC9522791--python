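"""Spatiotemporal encoding model: FIR lags + per-voxel cross-validated ridge.

The mapping from stimulus features to BOLD is the composition ``f ∘ g``:

* ``g`` — a finite-impulse-response (FIR) temporal expansion: the feature
  matrix is stacked at a small set of TR lags (default 1..5), capturing
  hemodynamic delay without assuming a response shape;
* ``f`` — an l2-penalized linear map fitted per voxel, the penalty chosen
  for each voxel independently by leave-one-sample-out error on the
  training fold, over ten candidates log-spaced between 1e-1 and 1e8.

The **brain score** of a (features, BOLD) pair is the Pearson correlation
between predicted and actual held-out BOLD, evaluated over five contiguous
folds of the scan axis and averaged across folds — one value per voxel.

Features are z-scored and BOLD mean-centered using training-fold statistics
only, so no test information leaks into the fit.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import BOLDSeries, TRFeatureMatrix

__all__ = [
    "FIRSpec",
    "RidgeSpec",
    "FoldSpec",
    "build_fir_design",
    "fit_ridge_per_voxel",
    "brain_score",
    "EncodingModel",
    "EncodingResults",
    "pearson_per_column",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class FIRSpec:
    """TR offsets of the FIR expansion (5 delays by default)."""

    lags: tuple[int, ...] = (1, 2, 3, 4, 5)

    def __post_init__(self) -> None:
        lags = tuple(int(l) for l in self.lags)
        if len(lags) == 0:
            raise ValueError("at least one lag required")
        if any(l < 0 for l in lags) or any(b <= a for a, b in zip(lags, lags[1:])):
            raise ValueError("lags must be non-negative and strictly increasing")
        object.__setattr__(self, "lags", lags)

    @property
    def n_delays(self) -> int:
        return len(self.lags)


def _default_alphas() -> tuple[float, ...]:
    return tuple(np.logspace(-1, 8, 10))


@dataclass(frozen=True)
class RidgeSpec:
    """Candidate l2 penalties; selection is per voxel by default."""

    alphas: tuple[float, ...] = field(default_factory=_default_alphas)
    per_voxel: bool = True

    def __post_init__(self) -> None:
        alphas = tuple(float(a) for a in self.alphas)
        if any(a <= 0 for a in alphas):
            raise ValueError("alphas must be positive")
        object.__setattr__(self, "alphas", alphas)


@dataclass(frozen=True)
class FoldSpec:
    """Contiguous, unshuffled partition of the scan axis."""

    n_folds: int = 5

    def __post_init__(self) -> None:
        if self.n_folds < 2:
            raise ValueError("need at least 2 folds")

    def split(self, n_scans: int):
        """Yield (train_idx, test_idx) over contiguous blocks."""
        if n_scans < self.n_folds:
            raise ValueError("fewer scans than folds")
        blocks = np.array_split(np.arange(n_scans), self.n_folds)
        for i, test in enumerate(blocks):
            train = np.concatenate([b for j, b in enumerate(blocks) if j != i])
            yield train, test


def build_fir_design(
    features: TRFeatureMatrix | np.ndarray, fir_spec: FIRSpec = FIRSpec()
) -> np.ndarray:
    """Stack lagged copies of the feature matrix: scans x (dim * n_delays).

    Column block ``l`` at row ``j`` equals feature row ``j - lag_l``,
    zero-padded at the start, so the design never looks into the future.
    """
    x = features.values if isinstance(features, TRFeatureMatrix) else np.asarray(features)
    if x.ndim != 2:
        raise ValueError("features must be 2-D (scans x dim)")
    n, d = x.shape
    design = np.zeros((n, d * fir_spec.n_delays))
    for i, lag in enumerate(fir_spec.lags):
        if lag < n:
            design[lag:, i * d : (i + 1) * d] = x[: n - lag]
    return design


# ---------------------------------------------------------------------------
# per-voxel ridge with leave-one-sample-out penalty selection


@dataclass
class RidgeFit:
    """Per-voxel ridge solution on one training fold."""

    coef: np.ndarray                 # (features, voxels)
    y_mean: np.ndarray               # training BOLD mean, (voxels,)
    x_mean: np.ndarray               # training design mean, (features,)
    x_std: np.ndarray                # training design std, (features,)
    alpha_index: np.ndarray          # selected alpha per voxel, (voxels,)
    alphas: tuple[float, ...]
    constant_voxels: np.ndarray      # flags: training BOLD had zero variance

    @property
    def selected_alphas(self) -> np.ndarray:
        return np.asarray(self.alphas)[self.alpha_index]

    def predict(self, design: np.ndarray) -> np.ndarray:
        xs = (design - self.x_mean) / self.x_std
        return xs @ self.coef + self.y_mean


def _standardize_columns(x: np.ndarray):
    mean = x.mean(axis=0)
    std = x.std(axis=0)
    std = np.where(std > 0, std, 1.0)  # constant columns stay zero after centering
    return (x - mean) / std, mean, std


def _loo_ridge_paths(xs: np.ndarray, yc: np.ndarray, alphas: np.ndarray):
    """LOO mean-squared error per (alpha, voxel) via the SVD hat-matrix identity.

    For ridge, the leave-one-out residual is ``e_i / (1 - h_ii)`` with
    ``h_ii`` the hat-matrix diagonal — no refitting required.  Returns
    (loo_mse (alphas, voxels), svd factors) for coefficient recovery.
    """
    u, s, vt = np.linalg.svd(xs, full_matrices=False)
    uty = u.T @ yc                                    # (k, voxels)
    u2 = u ** 2                                       # (n, k)
    n = xs.shape[0]
    loo = np.empty((len(alphas), yc.shape[1]))
    for ai, alpha in enumerate(alphas):
        shrink = s ** 2 / (s ** 2 + alpha)            # (k,)
        pred = u @ (shrink[:, None] * uty)            # (n, voxels)
        h = u2 @ shrink                               # (n,)
        denom = np.clip(1.0 - h, 1e-12, None)
        resid = (yc - pred) / denom[:, None]
        loo[ai] = np.mean(resid ** 2, axis=0)
    return loo, (u, s, vt, uty)


def fit_ridge_per_voxel(
    design_train: np.ndarray,
    bold_train: np.ndarray,
    ridge_spec: RidgeSpec = RidgeSpec(),
) -> RidgeFit:
    """Fit ridge per voxel, selecting each voxel's penalty by LOO error.

    The design is z-scored and BOLD mean-centered with training statistics.
    Voxels with zero training variance get zero coefficients and a flag.
    """
    x = np.asarray(design_train, dtype=np.float64)
    y = np.asarray(bold_train, dtype=np.float64)
    if y.ndim == 1:
        y = y[:, None]
    if x.shape[0] != y.shape[0]:
        raise ValueError("design and BOLD must share the scan axis")
    if x.shape[0] < 2:
        raise ValueError("need at least 2 training scans")

    xs, x_mean, x_std = _standardize_columns(x)
    y_mean = y.mean(axis=0)
    yc = y - y_mean
    constant = yc.std(axis=0) == 0
    if constant.any():
        logger.warning("fit_ridge_per_voxel: %d constant voxel(s)", int(constant.sum()))

    alphas = np.asarray(ridge_spec.alphas)
    loo, (u, s, vt, uty) = _loo_ridge_paths(xs, yc, alphas)
    if ridge_spec.per_voxel:
        alpha_index = np.argmin(loo, axis=0)
    else:
        alpha_index = np.full(yc.shape[1], int(np.argmin(loo.mean(axis=1))))

    coef = np.empty((x.shape[1], yc.shape[1]))
    for ai in np.unique(alpha_index):
        cols = alpha_index == ai
        shrink = s / (s ** 2 + alphas[ai])
        coef[:, cols] = vt.T @ (shrink[:, None] * uty[:, cols])
    coef[:, constant] = 0.0
    return RidgeFit(coef, y_mean, x_mean, x_std, alpha_index, ridge_spec.alphas, constant)


def pearson_per_column(a: np.ndarray, b: np.ndarray, flag: list | None = None) -> np.ndarray:
    """Column-wise Pearson r; zero-variance columns score 0 (and are flagged)."""
    a = a - a.mean(axis=0)
    b = b - b.mean(axis=0)
    na = np.sqrt((a ** 2).sum(axis=0))
    nb = np.sqrt((b ** 2).sum(axis=0))
    bad = (na == 0) | (nb == 0)
    denom = np.where(bad, 1.0, na * nb)
    r = (a * b).sum(axis=0) / denom
    r[bad] = 0.0
    if flag is not None and bad.any():
        flag.append(int(bad.sum()))
    return np.clip(r, -1.0, 1.0)


def brain_score(
    features: TRFeatureMatrix | np.ndarray,
    bold: BOLDSeries | np.ndarray,
    fir_spec: FIRSpec = FIRSpec(),
    ridge_spec: RidgeSpec = RidgeSpec(),
    fold_spec: FoldSpec = FoldSpec(),
) -> np.ndarray:
    """Across-fold mean of held-out per-voxel Pearson correlations."""
    return EncodingModel(features, bold, fir_spec, ridge_spec, fold_spec).fit().voxel_scores


class EncodingModel:
    """Voxelwise encoding model for one (subject, narrative) pair.

    Parameters
    ----------
    features
        Stimulus features on the scan grid (scans x dim).
    bold
        BOLD responses (scans x voxels) sharing the scan axis.
    fir_spec, ridge_spec, fold_spec
        Temporal expansion, penalty grid, and evaluation folds.

    ``fit()`` runs the contiguous k-fold procedure and returns an
    :class:`EncodingResults` carrying the per-voxel brain scores.
    """

    def __init__(
        self,
        features: TRFeatureMatrix | np.ndarray,
        bold: BOLDSeries | np.ndarray,
        fir_spec: FIRSpec = FIRSpec(),
        ridge_spec: RidgeSpec = RidgeSpec(),
        fold_spec: FoldSpec = FoldSpec(),
    ) -> None:
        self.features = features
        x = features.values if isinstance(features, TRFeatureMatrix) else np.asarray(features)
        y = bold.values if isinstance(bold, BOLDSeries) else np.asarray(bold)
        if x.shape[0] != y.shape[0]:
            raise ValueError(
                f"features ({x.shape[0]} scans) and BOLD ({y.shape[0]} scans) differ"
            )
        self._x = np.asarray(x, dtype=np.float64)
        self._y = np.asarray(y, dtype=np.float64)
        self.bold = bold
        self.fir_spec = fir_spec
        self.ridge_spec = ridge_spec
        self.fold_spec = fold_spec

    def fit(self) -> "EncodingResults":
        design = build_fir_design(self._x, self.fir_spec)
        n_vox = self._y.shape[1]
        fold_scores = []
        fold_alphas = []
        degenerate: list[int] = []
        for train, test in self.fold_spec.split(design.shape[0]):
            rf = fit_ridge_per_voxel(design[train], self._y[train], self.ridge_spec)
            pred = rf.predict(design[test])
            fold_scores.append(pearson_per_column(pred, self._y[test], flag=degenerate))
            fold_alphas.append(rf.selected_alphas)
        fold_scores = np.vstack(fold_scores)            # (folds, voxels)
        return EncodingResults(
            model=self,
            fold_scores=fold_scores,
            voxel_scores=fold_scores.mean(axis=0),
            selected_alphas=np.vstack(fold_alphas),
            n_degenerate_series=int(sum(degenerate)),
            n_voxels=n_vox,
        )


@dataclass
class EncodingResults:
    """Held-out brain scores for one (features, BOLD) pair."""

    model: EncodingModel
    fold_scores: np.ndarray          # (folds, voxels)
    voxel_scores: np.ndarray         # (voxels,) across-fold mean
    selected_alphas: np.ndarray      # (folds, voxels)
    n_degenerate_series: int
    n_voxels: int

    @property
    def whole_brain_score(self) -> float:
        """Unweighted mean brain score across all voxels."""
        return float(self.voxel_scores.mean())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "voxel": np.arange(self.n_voxels),
                "score": self.voxel_scores,
                "score_sem": self.fold_scores.std(axis=0, ddof=1)
                / np.sqrt(self.fold_scores.shape[0]),
            }
        )

    def summary(self) -> str:
        lines = [
            "Voxelwise encoding model (FIR + per-voxel CV ridge)",
            "=" * 51,
            f"voxels:             {self.n_voxels}",
            f"folds:              {self.fold_scores.shape[0]} (contiguous)",
            f"FIR lags (TR):      {self.model.fir_spec.lags}",
            f"alpha grid:         {len(self.model.ridge_spec.alphas)} log-spaced "
            f"[{self.model.ridge_spec.alphas[0]:g}, {self.model.ridge_spec.alphas[-1]:g}]",
            f"mean brain score:   {self.whole_brain_score:+.4f}",
            f"max voxel score:    {self.voxel_scores.max():+.4f}",
            f"degenerate series:  {self.n_degenerate_series}",
        ]
        return "\n".join(lines)
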