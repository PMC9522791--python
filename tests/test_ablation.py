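"""Ablation grid, distance/layer coefficients, and the pair bootstrap."""

import numpy as np
import pytest

from voxenc import (
    AblationGrid,
    AblationStudy,
    CohortConfig,
    bootstrap_coefficients,
    fit_distance_coefficient,
    fit_layer_coefficient,
    simulate_cohort,
)
from voxenc.containers import CohortIndex
from voxenc.pipeline import score_cohort
from voxenc.stats import roi_average

LAYERS = [1, 2, 3, 4]
DISTANCES = [10, 100, 1000]


def _grid(brain, comp=None, distances=DISTANCES, layers=LAYERS):
    n_pairs = brain.shape[0]
    pairs = [(f"s{i:03d}", "w0") for i in range(n_pairs)]
    cohort = None
    if comp is not None:
        cohort = CohortIndex(pairs=pairs, comprehension=comp)
    n_regions = brain.shape[1]
    comp_R = np.full((n_regions, len(layers), len(distances)), np.nan)
    return AblationGrid(
        layers=list(layers), distances=list(distances), pairs=pairs,
        regions=[f"r{i}" for i in range(n_regions)],
        brain_scores=brain, comp_R=comp_R, cohort=cohort,
    )


def test_constant_grid_gives_zero_coefficients():
    brain = np.full((12, 1, len(LAYERS), len(DISTANCES)), 0.3)
    grid = _grid(brain)
    assert fit_distance_coefficient(grid, layer=2).beta == pytest.approx(0.0)
    assert fit_layer_coefficient(grid, distance=100).beta == pytest.approx(0.0)


def test_exact_log_distance_slope_is_recovered_to_1e10():
    vals = 0.1 * np.log10(DISTANCES)
    brain = np.tile(vals, (12, 1, len(LAYERS), 1))
    grid = _grid(brain)
    est = fit_distance_coefficient(grid, layer=3)
    assert est.beta == pytest.approx(0.1, abs=1e-10)


def test_exact_layer_slope_is_recovered_to_1e10():
    vals = np.linspace(0.0, 0.14, len(LAYERS))
    brain = np.tile(vals[:, None], (12, 1, 1, len(DISTANCES)))
    grid = _grid(brain)
    est = fit_layer_coefficient(grid, distance=10)
    assert est.beta == pytest.approx(0.14, abs=1e-10)


def test_coefficients_are_linear_in_the_target(rng):
    brain = 0.2 + 0.05 * rng.standard_normal((12, 1, len(LAYERS), len(DISTANCES)))
    g1, g2 = _grid(brain), _grid(2.0 * brain)
    d1 = fit_distance_coefficient(g1, layer=2).beta
    d2 = fit_distance_coefficient(g2, layer=2).beta
    assert d2 == pytest.approx(2.0 * d1, rel=1e-9)
    l1 = fit_layer_coefficient(g1, distance=100).beta
    l2 = fit_layer_coefficient(g2, distance=100).beta
    assert l2 == pytest.approx(2.0 * l1, rel=1e-9)


def test_unrestricted_cells_are_excluded_from_distance_fits():
    distances = [10, 100, 1000, None]
    vals = np.array([0.1, 0.2, 0.3, 5.0])  # wild unrestricted value
    brain = np.tile(vals, (12, 1, len(LAYERS), 1))
    grid = _grid(brain, distances=distances)
    est = fit_distance_coefficient(grid, layer=2)
    assert est.beta == pytest.approx(0.1, abs=1e-10)


def test_noisy_slope_recovery_within_2se(rng):
    """Independent per-pair noise: truth within 2 SE in >= 95% of replicates."""
    truth = 0.04
    hits = 0
    reps = 100
    for _ in range(reps):
        ld = np.log10(DISTANCES)
        scores = 0.2 + truth * ld[None, :] + 0.03 * rng.standard_normal((24, 3))
        brain = scores[:, None, None, :].repeat(len(LAYERS), axis=2)
        est = fit_distance_coefficient(_grid(brain), layer=1)
        hits += abs(est.beta - truth) <= 2 * est.se
    assert hits / reps >= 0.90


def test_sign_recovery_on_noisy_monotone_grids(rng):
    """At SNR ~3 the fitted slope sign matches the generating sign >= 95%."""
    correct = 0
    reps = 100
    for _ in range(reps):
        lay = (np.array(LAYERS, float) - 1) / 3.0
        signal = 0.09 * lay                       # spread ~0.09 across layers
        scores = 0.2 + signal[None, :] + 0.03 * rng.standard_normal((24, 4))
        brain = scores[:, None, :, None].repeat(len(DISTANCES), axis=3)
        est = fit_layer_coefficient(_grid(brain), distance=10)
        correct += est.beta > 0
    assert correct / reps >= 0.95


def test_fewer_than_three_points_raises():
    brain = np.full((12, 1, len(LAYERS), 2), 0.3)
    grid = _grid(brain, distances=[10, 100])
    with pytest.raises(ValueError, match="3 finite distances"):
        fit_distance_coefficient(grid, layer=2)


# ---------------------------------------------------------------------------
# bootstrap


def test_bootstrap_is_bit_identical_under_fixed_seed(rng):
    comp = rng.uniform(0.1, 0.9, 30)
    brain = comp[:, None, None, None] + 0.1 * rng.standard_normal(
        (30, 1, len(LAYERS), len(DISTANCES))
    )
    grid = _grid(brain, comp=comp)
    a = bootstrap_coefficients(grid, "distance", layer=2, n_boot=200, seed=5)
    b = bootstrap_coefficients(grid, "distance", layer=2, n_boot=200, seed=5)
    assert (a.beta, a.sd, a.ci_low, a.ci_high, a.p) == (b.beta, b.sd, b.ci_low, b.ci_high, b.p)
    c = bootstrap_coefficients(grid, "distance", layer=2, n_boot=200, seed=6)
    assert c.sd != a.sd


def test_bootstrap_degenerate_distribution_has_zero_sd(rng):
    """If every resample gives identical correlations the CI collapses."""
    comp = rng.uniform(0.1, 0.9, 20)
    brain = np.tile(comp[:, None, None, None], (1, 1, len(LAYERS), len(DISTANCES)))
    grid = _grid(brain, comp=comp)  # r = 1 in every cell of every resample
    est = bootstrap_coefficients(grid, "distance", layer=1, n_boot=150, seed=0)
    assert est.sd == 0.0
    assert est.ci_low == est.ci_high == est.beta


def test_bootstrap_null_p_is_calibrated(rng):
    """Unrelated scores and comprehension: bootstrap p roughly uniform."""
    from scipy import stats as sps

    ps = []
    for _ in range(60):
        comp = rng.uniform(0, 1, 40)
        brain = 0.2 + 0.1 * rng.standard_normal((40, 1, len(LAYERS), len(DISTANCES)))
        grid = _grid(brain, comp=comp)
        ps.append(bootstrap_coefficients(grid, "distance", layer=2, n_boot=200, seed=1).p)
    assert sps.kstest(ps, "uniform").pvalue > 0.005
    assert np.mean(np.array(ps) < 0.05) <= 0.15


# ---------------------------------------------------------------------------
# grid over the real pipeline


def test_unrestricted_column_reproduces_plain_pipeline(small_cohort):
    study = AblationStudy(
        small_cohort.model, small_cohort, layers=[2], distances=[4, None],
        atlas=small_cohort.atlas,
    )
    res = study.run()
    plain = score_cohort(small_cohort, layer=2)
    plain_regions = roi_average(plain, small_cohort.atlas).values
    di = res.grid.distances.index(None)
    assert np.array_equal(res.grid.brain_scores[:, :, 0, di], plain_regions)


def test_failed_cell_is_recorded_as_missing(small_cohort, monkeypatch):
    study = AblationStudy(small_cohort.model, small_cohort, layers=[2], distances=[4, 8])
    original = study._compute_cell

    def flaky(layer, distance):
        if distance == 8:
            raise RuntimeError("boom")
        return original(layer, distance)

    monkeypatch.setattr(study, "_compute_cell", flaky)
    res = study.run()
    assert res.grid.missing[0, 1] and not res.grid.missing[0, 0]
    assert np.isnan(res.grid.brain_scores[:, :, 0, 1]).all()
    assert np.isfinite(res.grid.brain_scores[:, :, 0, 0]).all()


def test_cache_makes_second_run_incremental(small_cohort, tmp_path):
    kwargs = dict(layers=[2], distances=[4, None], atlas=small_cohort.atlas,
                  cache_dir=tmp_path)
    first = AblationStudy(small_cohort.model, small_cohort, **kwargs)
    r1 = first.run()
    assert first.cache_hits == 0 and first.cache_misses == 2
    second = AblationStudy(small_cohort.model, small_cohort, **kwargs)
    r2 = second.run()
    assert second.cache_hits == 2 and second.cache_misses == 0
    assert np.array_equal(r1.grid.brain_scores, r2.grid.brain_scores)


def test_context_free_generator_is_flat_in_distance():
    """BOLD from current-word embeddings only: finite-span scores are flat."""
    cfg = CohortConfig(
        n_subjects=4, n_stories=2, readout_source="embedding",
        n_words=300, noise_sigma=0.5,
    )
    co = simulate_cohort(cfg, seed=3)
    res = AblationStudy(co.model, co, layers=[2], distances=[2, 8, 32]).run()
    means = res.grid.brain_scores.mean(axis=(0, 1))[0]
    assert abs(means[-1] - means[0]) < 0.02


def test_long_range_generator_prefers_wide_spans():
    """BOLD from a 50-token running context: d=100 beats d=5."""
    cfg = CohortConfig(
        n_subjects=3, n_stories=2, readout_source="running_mean",
        context_tokens=50, n_words=300, noise_sigma=0.5,
    )
    co = simulate_cohort(cfg, seed=3)
    res = AblationStudy(co.model, co, layers=[2], distances=[5, 100]).run()
    means = res.grid.brain_scores.mean(axis=(0, 1))[0]
    assert means[1] > means[0]


def test_summary_reports_grid_and_cache(small_cohort, tmp_path):
    study = AblationStudy(
        small_cohort.model, small_cohort, layers=[1, 2], distances=[4, None],
        cache_dir=tmp_path,
    )
    text = study.run().summary()
    assert "layers:    [1, 2]" in text and "cache:" in text
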