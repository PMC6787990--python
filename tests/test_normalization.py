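import numpy as np
import pytest

from exocnv.intervals import TargetInterval
from exocnv.matrix import ReadDepthMatrix
from exocnv.normalization import (
    FilterThresholds,
    NormalizationError,
    RankSelection,
    center_targets,
    determine_K,
    filter_samples,
    filter_targets_post,
    filter_targets_pre,
    normalize_matrix,
    pca_normalize,
    truncated_svd,
    zscore_samples,
)
from exocnv.simulate import SimulationConfig, simulate_cohort

from _oracles import full_spectrum_K, matrix_with_spectrum, random_designed_spectrum
from conftest import make_matrix


def _matrix_from_depths(depths, chrom="1", require_nonnegative=None):
    depths = np.asarray(depths, dtype=float)
    s, t = depths.shape
    targets = [TargetInterval(chrom, 1 + j * 500, 200 + j * 500) for j in range(t)]
    if require_nonnegative is None:
        require_nonnegative = bool(np.all(depths >= 0))
    return ReadDepthMatrix(
        samples=[f"S{i:02d}" for i in range(s)], targets=targets,
        depths=depths, require_nonnegative=require_nonnegative,
    )


# --- filtering ------------------------------------------------------------


def test_pre_filter_flags_gc_length_complexity(rng):
    config = SimulationConfig(
        n_samples=4, n_targets=100, noise_model="none", batch_rank=0,
        gc_violation_targets=(3, 50), length_violation_targets=(7,),
        complexity_violation_targets=(90,), seed=5,
    )
    matrix, _ = simulate_cohort(config)
    kept, report = filter_targets_pre(matrix)
    assert len(report) == 4
    assert kept.n_targets == 96
    reasons = {name: set(r) for name, r in report.excluded.items()}
    assert set(reasons[matrix.targets[3].name]) == {"gc"}
    assert "length" in reasons[matrix.targets[7].name]
    assert set(reasons[matrix.targets[90].name]) == {"complexity"}


def test_pre_filter_mean_depth_rule(rng):
    m = make_matrix(rng, s=6, t=20, loc=100, scale=1)
    m.depths[:, 4] = 2.0  # below the 10x floor
    m.depths[:, 9] = 900.0  # above the 500x ceiling
    kept, report = filter_targets_pre(m)
    assert kept.n_targets == 18
    assert all(r == ["mean_rd"] for r in report.excluded.values())


def test_sample_filter_removes_planted_outlier(rng):
    config = SimulationConfig(
        n_samples=10, n_targets=60, noise_model="none", batch_rank=0,
        outlier_samples=(4,), seed=9,
    )
    matrix, _ = simulate_cohort(config)
    kept, report = filter_samples(matrix)
    assert list(report.excluded) == [matrix.samples[4]]
    assert kept.n_samples == 9


def test_sample_filter_sd_rule(rng):
    m = make_matrix(rng, s=5, t=50, loc=100, scale=1)
    m.depths[2, ::2] = 30.0
    m.depths[2, 1::2] = 170.0  # mean 100, SD ~ 70 -> passes; now blow it up
    m.depths[2, 1::2] = 460.0  # mean ~245 (out) and SD > 150
    kept, report = filter_samples(m)
    assert set(report.excluded[m.samples[2]]) == {"mean_rd", "sd_rd"}
    assert kept.n_samples == 4


def test_all_excluded_is_an_error(rng):
    m = make_matrix(rng, s=3, t=4, loc=2.0, scale=0.1)  # far below depth floors
    with pytest.raises(NormalizationError):
        filter_targets_pre(m)
    with pytest.raises(NormalizationError):
        filter_samples(m)


def test_thresholds_validate():
    with pytest.raises(NormalizationError):
        FilterThresholds(min_gc=0.8, max_gc=0.2)


# --- centering and z-scoring ---------------------------------------------


def test_center_targets_examples_and_tolerance(rng):
    m = _matrix_from_depths(np.array([[1.0, 5.0], [3.0, 5.0]]))
    c = center_targets(m)
    np.testing.assert_allclose(c.depths, [[-1.0, 0.0], [1.0, 0.0]], atol=1e-15)
    big = make_matrix(rng, s=20, t=50)
    centered = center_targets(big)
    assert np.max(np.abs(centered.depths.mean(axis=0))) < 1e-12
    with pytest.raises(NormalizationError):
        center_targets(_matrix_from_depths(np.array([[1.0, 2.0]])))


def test_zscore_rows(rng):
    m = _matrix_from_depths(np.array([[1.0, 2.0, 3.0], [4.0, 4.0, 4.0]]))
    with pytest.raises(NormalizationError, match="S01"):
        zscore_samples(m)
    z = zscore_samples(_matrix_from_depths(np.array([[1.0, 2.0, 3.0]])))
    np.testing.assert_allclose(z.depths, [[-1.0, 0.0, 1.0]], atol=1e-15)
    big = center_targets(make_matrix(rng, s=10, t=80))
    z = zscore_samples(big)
    assert np.max(np.abs(z.depths.mean(axis=1))) < 1e-12
    assert np.max(np.abs(z.depths.std(axis=1, ddof=1) - 1.0)) < 1e-12


# --- truncated SVD --------------------------------------------------------


def test_truncated_svd_rank_one(rng):
    X = np.outer(rng.standard_normal(8), rng.standard_normal(30))
    spectrum, _ = truncated_svd(X, 2)
    assert spectrum.variances[0] > 0
    assert spectrum.variances[1] < 1e-12 * spectrum.variances[0]


def test_truncated_svd_known_singular_values(rng):
    X = matrix_with_spectrum(6, 12, np.array([3.0, 2.0, 1.0]), rng)
    spectrum, _ = truncated_svd(X, 3)
    np.testing.assert_allclose(spectrum.variances, [9.0, 4.0, 1.0], atol=1e-9)


def test_truncated_svd_matches_full_decomposition(rng):
    X = rng.standard_normal((20, 50))
    spectrum, _ = truncated_svd(X, 6)
    full = np.linalg.svd(X, compute_uv=False) ** 2
    np.testing.assert_allclose(spectrum.variances, full[:6], rtol=1e-8)


def test_truncated_svd_k_out_of_range(rng):
    X = rng.standard_normal((5, 9))
    with pytest.raises(NormalizationError):
        truncated_svd(X, 0)
    with pytest.raises(NormalizationError):
        truncated_svd(X, 6)


# --- rank selection -------------------------------------------------------


def test_bracket_arithmetic_on_designed_spectrum(rng):
    """Spectrum (100, 50, 10, 1 x 7) at k=3: over 220, under 160, K=2 certified."""
    sv = np.sqrt(np.array([100.0, 50.0, 10.0] + [1.0] * 7))
    X = matrix_with_spectrum(10, 40, sv, rng)
    n = 10
    spectrum, _ = truncated_svd(X, 3)
    v = spectrum.variances
    over = v.sum() + (n - 3 - 1) * v[-1]
    under = v.sum()
    assert over == pytest.approx(220.0, rel=1e-9)
    assert under == pytest.approx(160.0, rel=1e-9)
    cutoff_over = 0.7 * over / n
    assert cutoff_over == pytest.approx(15.4, rel=1e-9)
    assert int(np.sum(v >= cutoff_over)) == 2
    assert v[2] < 0.7 * under / n  # 10 < 11.2: bracket certifies K=2
    selection = determine_K(X)
    assert selection.K == 2 == full_spectrum_K(X)
    assert selection.certified


def test_single_informative_component(rng):
    X = matrix_with_spectrum(12, 30, np.array([5.0]), rng)
    selection = determine_K(X)
    assert selection.K == 1
    assert selection.certified


def test_determine_K_equals_full_spectrum_rule(rng):
    """Iterative bracketed selection agrees with the exhaustive rule."""
    for trial in range(30):
        s = int(rng.integers(10, 41))
        t = int(rng.integers(50, 200))
        kind = ("steep", "flat", "mixed")[trial % 3]
        sv = np.sqrt(random_designed_spectrum(kind, min(s, t), rng))
        X = matrix_with_spectrum(s, t, sv, rng)
        X = X - X.mean(axis=0)
        selection = determine_K(X)
        assert selection.K == full_spectrum_K(X), (s, t, kind)
        assert selection.certified
        assert selection.over_estimate >= selection.under_estimate - 1e-9


def test_bracket_converges_to_total_variance(rng):
    X = rng.standard_normal((15, 60))
    X = X - X.mean(axis=0)
    n = 15
    total = float(np.sum(np.linalg.svd(X, compute_uv=False) ** 2))
    overs, unders = [], []
    for k in range(2, n):
        spectrum, _ = truncated_svd(X, k)
        v = spectrum.variances
        overs.append(v.sum() + (n - k - 1) * v[-1])
        unders.append(v.sum())
    assert all(o >= u for o, u in zip(overs, unders))
    # at k = n-1 both estimates land on the total (last component is ~0)
    assert overs[-1] == pytest.approx(total, rel=1e-9)
    assert unders[-1] == pytest.approx(total, rel=1e-9)


# --- PCA normalization ----------------------------------------------------


def test_pca_normalize_K0_is_identity(rng):
    X = center_targets(make_matrix(rng, s=10, t=30))
    selection, basis = determine_K(X.depths, return_basis=True)
    out = pca_normalize(X, RankSelection(K=0, certified=True), basis)
    np.testing.assert_array_equal(out.depths, X.depths)


def test_pca_normalize_rank_one_vanishes(rng):
    base = np.outer(rng.standard_normal(8), rng.standard_normal(25))
    m = _matrix_from_depths(base - base.mean(axis=0))
    spectrum, basis = truncated_svd(m.depths, 2)
    out = pca_normalize(m, RankSelection(K=1, certified=True), basis)
    assert np.max(np.abs(out.depths)) < 1e-8


def test_pca_normalize_projections_and_oracle(rng):
    X = rng.standard_normal((15, 50))
    X = X - X.mean(axis=0)
    m = _matrix_from_depths(X)
    spectrum, basis = truncated_svd(X, 10)
    out = pca_normalize(m, RankSelection(K=3, certified=True), basis)
    for j in range(3):
        proj = out.depths @ basis.Vt[j]
        assert np.max(np.abs(proj)) < 1e-8
    U, sv, Vt = np.linalg.svd(X, full_matrices=False)
    expected = X - (U[:, :3] * sv[:3]) @ Vt[:3]
    np.testing.assert_allclose(out.depths, expected, atol=1e-8)


def test_pca_normalize_requires_enough_components(rng):
    X = rng.standard_normal((6, 12))
    m = _matrix_from_depths(X)
    _, basis = truncated_svd(X, 2)
    with pytest.raises(NormalizationError):
        pca_normalize(m, RankSelection(K=5, certified=True), basis)


# --- post filter ----------------------------------------------------------


def test_post_filter_removes_hypervariable_targets(rng):
    X = rng.normal(0.0, 1.0, size=(10, 30))
    planted = [2, 11, 17, 23, 29]
    X[:, planted] = rng.normal(0.0, 100.0, size=(10, 5))
    m = _matrix_from_depths(X)
    kept, report = filter_targets_post(m)
    assert len(report) == 5
    assert kept.n_targets == 25
    zeros = _matrix_from_depths(np.zeros((4, 6)))
    kept, report = filter_targets_post(zeros)
    assert len(report) == 0 and kept.n_targets == 6


# --- whole chain ----------------------------------------------------------


def test_normalize_matrix_chain_outputs(rng):
    config = SimulationConfig(n_samples=20, n_targets=120, seed=3)
    matrix, _ = simulate_cohort(config)
    result = normalize_matrix(matrix)
    z = result.zscores
    assert np.max(np.abs(z.depths.mean(axis=1))) < 1e-12
    assert np.max(np.abs(z.depths.std(axis=1, ddof=1) - 1.0)) < 1e-12
    assert result.selection.certified
    assert result.original.samples == z.samples
    assert [t.name for t in result.original.targets] == [t.name for t in z.targets]
    # deterministic end to end
    again = normalize_matrix(simulate_cohort(config)[0])
    np.testing.assert_array_equal(z.depths, again.zscores.depths)
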