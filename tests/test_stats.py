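"""Second-level statistics: ROI means, correlations, Wilcoxon, FDR, mixed model."""

from itertools import product

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from voxenc import (
    correlate_comprehension,
    fdr_bh,
    mixed_effects_decomposition,
    per_narrative_correlations,
    roi_average,
    score_difference,
    wilcoxon_second_level,
)
from voxenc.containers import AtlasLabels, CohortIndex


def _cohort(narrative_sizes: dict[str, int], comp: np.ndarray) -> CohortIndex:
    pairs = [
        (f"s{si:03d}", w) for w, n in narrative_sizes.items() for si in range(n)
    ]
    return CohortIndex(pairs=pairs, comprehension=comp)


# ---------------------------------------------------------------------------
# ROI averaging


def test_uniform_region_returns_its_value_and_two_voxel_mean():
    atlas = AtlasLabels(labels=np.array(["a", "a", "b", "b"]))
    scores = np.array([[0.5, 0.5, 0.2, 0.4]])
    out = roi_average(scores, atlas)
    assert out.loc[0, "a"] == pytest.approx(0.5)
    assert out.loc[0, "b"] == pytest.approx(0.3)


def test_roi_average_matches_groupby_oracle(rng):
    labels = rng.choice(["r1", "r2", "r3", "background"], size=30)
    scores = rng.standard_normal((6, 30))
    out = roi_average(scores, AtlasLabels(labels=labels))
    for region in ("r1", "r2", "r3"):
        mask = labels == region
        for i in range(6):
            assert out.loc[i, region] == pytest.approx(scores[i, mask].mean())
    assert "background" not in out.columns


# ---------------------------------------------------------------------------
# comprehension correlation


def test_perfect_correlation_when_scores_equal_comprehension(rng):
    comp = rng.uniform(0.1, 0.9, 20)
    cohort = _cohort({"w0": 20}, comp)
    c = correlate_comprehension(comp.copy(), cohort)
    assert c.R == pytest.approx(1.0)
    assert c.n == 20


def test_null_correlation_is_small_and_p_uniform(rng):
    """Independent scores: |R| stays small and p-values are calibrated."""
    rs, ps = [], []
    for _ in range(200):
        comp = rng.uniform(0, 1, 100)
        cohort = _cohort({"w0": 100}, comp)
        c = correlate_comprehension(rng.standard_normal(100), cohort)
        rs.append(c.R)
        ps.append(c.p)
    assert np.max(np.abs(rs)) < 0.4
    assert np.mean(np.abs(np.array(rs)) < 0.25) > 0.95
    assert sps.kstest(ps, "uniform").pvalue > 0.005


def test_correlation_invariant_to_increasing_affine_transforms(rng):
    comp = rng.uniform(0.2, 0.8, 30)
    scores = 0.5 * comp + 0.1 * rng.standard_normal(30)
    cohort = _cohort({"w0": 30}, comp)
    base = correlate_comprehension(scores, cohort)
    rescaled = correlate_comprehension(5.0 * scores + 2.0, cohort)
    assert rescaled.R == pytest.approx(base.R, abs=1e-12)
    assert rescaled.p == pytest.approx(base.p, rel=1e-9)


def test_zero_variance_raises(rng):
    cohort = _cohort({"w0": 10}, np.full(10, 0.5))
    with pytest.raises(ValueError, match="variance"):
        correlate_comprehension(rng.standard_normal(10), cohort)


# ---------------------------------------------------------------------------
# score differences


def test_score_difference_basic_contracts(rng):
    a = rng.standard_normal((5, 4))
    assert np.all(score_difference(a, a) == 0)
    assert np.allclose(score_difference(a + 0.1, a), 0.1)
    b = rng.standard_normal((5, 4))
    expected = np.array([[a[i, j] - b[i, j] for j in range(4)] for i in range(5)])
    assert np.array_equal(score_difference(a, b), expected)
    with pytest.raises(ValueError, match="mismatch"):
        score_difference(a, rng.standard_normal((4, 5)))


def test_difference_then_correlate_equals_correlating_differences(rng):
    comp = rng.uniform(0, 1, 25)
    cohort = _cohort({"w0": 25}, comp)
    a = comp + 0.3 * rng.standard_normal(25)
    b = 0.2 * rng.standard_normal(25)
    c1 = correlate_comprehension(score_difference(a, b), cohort)
    c2 = correlate_comprehension(a - b, cohort)
    assert c1.R == pytest.approx(c2.R)


# ---------------------------------------------------------------------------
# Wilcoxon second level


def test_wilcoxon_null_calibration_at_nominal_5pct(rng):
    """Type-I error at 0.05 within [0.02, 0.09] over 500 null replicates."""
    rejections = 0
    for _ in range(500):
        p = wilcoxon_second_level(rng.standard_normal(30))[0]
        rejections += p < 0.05
    assert 0.02 <= rejections / 500 <= 0.09


def test_constant_positive_scores_are_highly_significant():
    p = wilcoxon_second_level(np.full(20, 0.3))[0]
    assert p < 0.001


def test_small_n_matches_exact_sign_pattern_enumeration(rng):
    """n=8 two-sided p equals full enumeration of the 2^8 sign assignments."""
    for _ in range(5):
        x = rng.standard_normal(8) + 0.4
        ranks = sps.rankdata(np.abs(x))
        t_obs = ranks[x > 0].sum()
        stats = np.array(
            [sum(r for s, r in zip(signs, ranks) if s) for signs in product([0, 1], repeat=8)]
        )
        p_enum = min(1.0, 2 * min((stats <= t_obs).mean(), (stats >= t_obs).mean()))
        p_ours = wilcoxon_second_level(x)[0]
        assert p_ours == pytest.approx(p_enum)


def test_all_zero_column_is_undefined(caplog):
    scores = np.column_stack([np.random.default_rng(0).standard_normal(10), np.zeros(10)])
    with caplog.at_level("WARNING"):
        p = wilcoxon_second_level(scores)
    assert np.isfinite(p[0]) and np.isnan(p[1])


# ---------------------------------------------------------------------------
# BH-FDR


def _bh_bruteforce(p, q):
    m = len(p)
    order = np.argsort(p)
    k = 0
    for i, idx in enumerate(order, start=1):
        if p[idx] <= i * q / m:
            k = i
    rejected = np.zeros(m, bool)
    rejected[order[:k]] = True
    return rejected


def test_all_small_p_are_rejected():
    rejected, _ = fdr_bh(np.full(284, 0.001), q=0.05)
    assert rejected.all()


def test_stepup_hand_example():
    rejected, adjusted = fdr_bh(np.array([0.01, 0.02, 0.03, 0.5]), q=0.05)
    assert list(rejected) == [True, True, True, False]
    assert np.all(np.diff(np.sort(adjusted)) >= -1e-12)


def test_fdr_matches_bruteforce_on_random_vectors(rng):
    for _ in range(100):
        p = rng.uniform(0, 1, int(rng.integers(3, 40)))
        rejected, _ = fdr_bh(p, q=0.05)
        assert np.array_equal(rejected, _bh_bruteforce(p, 0.05))


def test_fdr_rejects_out_of_range_values():
    with pytest.raises(ValueError):
        fdr_bh(np.array([0.1, 1.5]))


# ---------------------------------------------------------------------------
# mixed model


def test_homogeneous_noiseless_data_has_common_fixed_slope(rng):
    scores = rng.uniform(0, 1, 40)
    comp = np.clip(0.2 + 0.4 * scores, 0, 1)
    cohort = _cohort({f"w{k}": 10 for k in range(4)}, comp)
    m = mixed_effects_decomposition(scores, cohort)
    assert m.fixed_slope == pytest.approx(0.4, abs=1e-3)
    assert m.random_slope_var < 1e-6


def test_fixed_slope_matches_pooled_ols_within_2pct(rng):
    scores = rng.uniform(0, 1, 120)
    comp = np.clip(0.3 + 0.35 * scores + 0.02 * rng.standard_normal(120), 0, 1)
    cohort = _cohort({f"w{k}": 30 for k in range(4)}, comp)
    m = mixed_effects_decomposition(scores, cohort)
    pooled = sps.linregress(scores, comp).slope
    assert abs(m.fixed_slope - pooled) / abs(pooled) < 0.02


def test_narrative_specific_slopes_inflate_random_slope_variance(rng):
    slopes = {"w0": 0.2, "w1": 0.8}
    scores, comp, sizes = [], [], {"w0": 100, "w1": 100}
    for w, n in sizes.items():
        s = rng.uniform(0, 1, n)
        scores.extend(s)
        comp.extend(np.clip(0.1 + slopes[w] * s + 0.03 * rng.standard_normal(n), 0, 1))
    m = mixed_effects_decomposition(np.array(scores), _cohort(sizes, np.array(comp)))
    assert m.random_slope_var > 0.01
    assert m.random_slope_lrt_p < 0.01


def test_null_fixed_slope_p_is_roughly_uniform(rng):
    """No coupling: the fixed-slope p-value should be calibrated."""
    ps = []
    for _ in range(120):
        scores = rng.uniform(0, 1, 36)
        comp = np.clip(0.5 + 0.1 * rng.standard_normal(36), 0, 1)
        m = mixed_effects_decomposition(scores, _cohort({f"w{k}": 12 for k in range(3)}, comp))
        ps.append(m.fixed_slope_p)
    # boundary-singular fits can leave an undefined p; calibration is a
    # statement about the well-posed fits
    ps = np.array([p for p in ps if np.isfinite(p)])
    assert len(ps) >= 100
    assert sps.kstest(ps, "uniform").pvalue > 0.005
    assert np.mean(ps < 0.05) < 0.15


# ---------------------------------------------------------------------------
# per-narrative correlations


def test_single_narrative_equals_whole_cohort(rng):
    comp = rng.uniform(0, 1, 15)
    scores = comp + 0.2 * rng.standard_normal(15)
    cohort = _cohort({"w0": 15}, comp)
    whole = correlate_comprehension(scores, cohort)
    per = per_narrative_correlations(scores, cohort)
    assert per["w0"].R == pytest.approx(whole.R)


def test_constant_comprehension_narrative_is_skipped(rng, caplog):
    comp = np.concatenate([rng.uniform(0, 1, 10), np.full(10, 0.5)])
    scores = comp + 0.1 * rng.standard_normal(20)
    cohort = _cohort({"w0": 10, "w1": 10}, comp)
    with caplog.at_level("WARNING"):
        per = per_narrative_correlations(scores, cohort)
    assert "w0" in per and "w1" not in per


def test_uniform_coupling_gives_compatible_per_narrative_rs(rng):
    """Same coupling in every narrative: Fisher-z Rs within sampling error."""
    sizes = {f"w{k}": 40 for k in range(3)}
    comp, scores = [], []
    for _ in sizes:
        c = rng.uniform(0.1, 0.9, 40)
        comp.extend(c)
        scores.extend(c + 0.35 * rng.standard_normal(40))
    per = per_narrative_correlations(np.array(scores), _cohort(sizes, np.array(comp)))
    zs = np.arctanh([c.R for c in per.values()])
    se = np.sqrt(2.0 / (40 - 3))
    for i, zi in enumerate(zs):
        for zj in zs[i + 1 :]:
            assert abs(zi - zj) < 4 * se
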