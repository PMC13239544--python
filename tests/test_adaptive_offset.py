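import numpy as np
import pytest
from sklearn.metrics import adjusted_rand_score

from geneclim import adaptive_offset as ao
from geneclim import gea
from geneclim.enm import BinaryMap
from geneclim.geo_io import EnvStack, GridSpec

# ---------------------------------------------------------------------------
# candidate RDA


def test_candidate_rda_with_all_loci_equals_full_fit(rng):
    g = rng.binomial(2, 0.5, (25, 40)).astype(float)
    env = rng.normal(size=(25, 3))
    full = gea.rda_fit(g, env)
    cand = ao.candidate_rda(g, env, np.arange(40))
    np.testing.assert_allclose(full.site_scores, cand.site_scores, atol=1e-9)
    np.testing.assert_allclose(full.eigenvalues, cand.eigenvalues, atol=1e-9)


def test_candidate_order_does_not_change_axes(rng):
    g = rng.binomial(2, 0.5, (20, 30)).astype(float)
    env = rng.normal(size=(20, 2))
    idx = np.arange(10, 25)
    a = ao.candidate_rda(g, env, idx)
    b = ao.candidate_rda(g, env, idx[::-1])
    np.testing.assert_allclose(a.site_scores, b.site_scores, atol=1e-9)


def test_candidate_rda_needs_three_loci(rng):
    g = rng.binomial(2, 0.5, (10, 20)).astype(float)
    with pytest.raises(ValueError, match="3 candidate"):
        ao.candidate_rda(g, rng.normal(size=(10, 2)), [1, 2])


# ---------------------------------------------------------------------------
# AU clustering


def _blobs(rng, centers, n_per=12, sd=0.3):
    pts = np.vstack([c + sd * rng.normal(size=(n_per, len(c)))
                     for c in centers])
    labels = np.repeat(np.arange(len(centers)), n_per)
    return pts, labels


def test_three_blobs_recovered(rng):
    pts, truth = _blobs(rng, [(0, 0, 0), (4, 0, 0), (0, 4, 4)])
    out = ao.cluster_adaptive_units(pts)
    assert out.k == 3
    assert adjusted_rand_score(truth, out.labels) >= 0.9
    assert not out.low_confidence


def test_axis_sign_flip_invariance(rng):
    pts, _ = _blobs(rng, [(0, 0, 0), (3, 3, 0)])
    a = ao.cluster_adaptive_units(pts)
    b = ao.cluster_adaptive_units(pts * np.array([-1, 1, -1]))
    assert a.k == b.k
    assert adjusted_rand_score(a.labels, b.labels) == 1.0


def test_single_blob_flags_low_confidence(rng):
    pts = 0.05 * rng.normal(size=(30, 3))
    out = ao.cluster_adaptive_units(pts)
    assert out.low_confidence


def test_identical_points_error():
    with pytest.raises(ValueError, match="identical"):
        ao.cluster_adaptive_units(np.ones((20, 3)))


# ---------------------------------------------------------------------------
# RF classifier


def test_perfect_separation_by_one_variable(rng):
    n = 40
    x1 = np.r_[rng.uniform(0, 1, n // 2), rng.uniform(2, 3, n // 2)]
    X = np.column_stack([x1, rng.normal(size=n), rng.normal(size=n)])
    y = np.r_[np.ones(n // 2), np.full(n // 2, 2)]
    clf = ao.fit_au_classifier(X, y, ["sep", "n1", "n2"], n_trees=100, seed=0)
    assert clf.cv_accuracy >= 0.95
    assert clf.gini_importance.idxmax() == "sep"


def test_shuffled_labels_accuracy_near_chance(rng):
    n, k = 60, 3
    X = rng.normal(size=(n, 4))
    accs = []
    for seed in range(8):
        y = np.random.default_rng(seed).integers(1, k + 1, n)
        if len(np.unique(y)) < k:
            continue
        clf = ao.fit_au_classifier(X, y, list("abcd"), n_trees=60,
                                   cv_folds=5, seed=seed)
        accs.append(clf.cv_accuracy)
    assert abs(np.mean(accs) - 1 / k) < 0.12


def test_duplicate_covariate_splits_importance(rng):
    n = 40
    x1 = np.r_[np.zeros(n // 2), np.ones(n // 2)] + 0.05 * rng.normal(size=n)
    X = np.column_stack([x1, x1, rng.normal(size=n)])
    y = np.r_[np.ones(n // 2), np.full(n // 2, 2)]
    clf = ao.fit_au_classifier(X, y, ["a", "a2", "noise"], n_trees=200, seed=1)
    assert clf.cv_accuracy >= 0.9
    imp = clf.gini_importance
    assert imp["a"] > imp["noise"] and imp["a2"] > imp["noise"]


def test_singleton_unit_errors(rng):
    X = rng.normal(size=(10, 2))
    y = np.r_[np.ones(9), [2]]
    with pytest.raises(ValueError, match="single member"):
        ao.fit_au_classifier(X, y, ["a", "b"])


# ---------------------------------------------------------------------------
# AU projection


def _stack_blocked(grid):
    """Three horizontal climate bands, distinct enough to classify."""
    vals = np.zeros((2,) + grid.shape)
    third = grid.nrow // 3
    vals[0, :third] = 0.0
    vals[0, third:2 * third] = 5.0
    vals[0, 2 * third:] = 10.0
    vals[1] = np.linspace(0, 1, grid.ncol)[None, :]
    return EnvStack(vals, ["t", "p"], grid)


def test_blocked_fixture_projection_matches_truth(rng):
    grid = GridSpec(30, 30, 0, 0, 100.0)
    stack = _stack_blocked(grid)
    third = 10
    truth = np.zeros(grid.shape, int)
    truth[:third], truth[third:2 * third], truth[2 * third:] = 1, 2, 3
    # train from individuals scattered across the three bands
    rows = rng.integers(0, 30, 60)
    cols = rng.integers(0, 30, 60)
    X = stack.values[:, rows, cols].T
    y = truth[rows, cols]
    clf = ao.fit_au_classifier(X, y, ["t", "p"], n_trees=100, seed=0)
    mask = BinaryMap(np.ones(grid.shape, np.int8), grid)
    amap = ao.project_au_map(clf, stack, mask)
    assert (amap.labels == truth).mean() >= 0.9
    areas = amap.area_km2()
    assert sum(areas.values()) == pytest.approx(mask.area_km2)


def test_empty_mask_empty_map(rng):
    grid = GridSpec(10, 10, 0, 0, 100.0)
    stack = _stack_blocked(grid)
    X = rng.normal(size=(20, 2))
    y = np.r_[np.ones(10), np.full(10, 2)]
    clf = ao.fit_au_classifier(X, y, ["t", "p"], n_trees=20, cv_folds=5, seed=0)
    amap = ao.project_au_map(clf, stack, BinaryMap(np.zeros(grid.shape, np.int8), grid))
    assert amap.labels.sum() == 0 and amap.area_km2() == {}


def test_variable_mismatch_errors(rng):
    grid = GridSpec(10, 10, 0, 0, 100.0)
    stack = _stack_blocked(grid)
    X = rng.normal(size=(20, 2))
    y = np.r_[np.ones(10), np.full(10, 2)]
    clf = ao.fit_au_classifier(X, y, ["t", "other"], n_trees=20, cv_folds=5, seed=0)
    with pytest.raises(ValueError, match="other"):
        ao.project_au_map(clf, stack, BinaryMap(np.ones(grid.shape, np.int8), grid))


# ---------------------------------------------------------------------------
# genetic offset


def _model_and_stacks(rng, grid, p=3, axes=3):
    env_now = EnvStack(rng.normal(size=(p,) + grid.shape),
                       [f"v{j}" for j in range(p)], grid, period="now")
    env_fut = EnvStack(env_now.values + rng.normal(0.5, 0.3,
                                                   (p,) + grid.shape),
                       env_now.var_names, grid, period="fut")
    g = rng.binomial(2, 0.5, (30, 25)).astype(float)
    env_ind = rng.normal(size=(30, p))
    model = gea.rda_fit(g, env_ind, var_names=env_now.var_names,
                        retained_axes=axes)
    return model, env_now, env_fut


def test_offset_zero_when_future_equals_current(rng):
    grid = GridSpec(8, 8, 0, 0, 100.0)
    model, env_now, _ = _model_and_stacks(rng, grid)
    mask = BinaryMap(np.ones(grid.shape, np.int8), grid)
    off = ao.rda_offset(model, env_now, env_now, mask)
    assert np.nanmax(off.values) == pytest.approx(0.0, abs=1e-12)


def test_offset_scale_equivariance_and_symmetry(rng):
    grid = GridSpec(8, 8, 0, 0, 100.0)
    model, env_now, env_fut = _model_and_stacks(rng, grid)
    mask = BinaryMap(np.ones(grid.shape, np.int8), grid)
    off1 = ao.rda_offset(model, env_now, env_fut, mask)
    doubled = EnvStack(env_now.values + 2 * (env_fut.values - env_now.values),
                       env_now.var_names, grid, period="fut2")
    off2 = ao.rda_offset(model, env_now, doubled, mask)
    np.testing.assert_allclose(off2.values, 2 * off1.values, atol=1e-10)
    rev = ao.rda_offset(model, env_fut, env_now, mask)
    np.testing.assert_allclose(rev.values, off1.values, atol=1e-12)


def test_offset_matches_per_cell_loop_oracle(rng):
    grid = GridSpec(6, 6, 0, 0, 100.0)
    model, env_now, env_fut = _model_and_stacks(rng, grid)
    mask = BinaryMap((rng.random(grid.shape) < 0.7).astype(np.int8), grid)
    off = ao.rda_offset(model, env_now, env_fut, mask)
    eig = model.eigenvalues[:model.retained_axes]
    w = eig / eig.sum()
    for r in range(6):
        for c in range(6):
            if not mask.values[r, c]:
                assert np.isnan(off.values[r, c])
                continue
            d = 0.0
            znow = (env_now.values[:, r, c] - model.env_mean) / model.env_sd
            zfut = (env_fut.values[:, r, c] - model.env_mean) / model.env_sd
            a_now = znow @ model.coef
            a_fut = zfut @ model.coef
            d = np.sqrt(np.sum((w * (a_fut - a_now)[:model.retained_axes]) ** 2))
            assert off.values[r, c] == pytest.approx(d, abs=1e-10)


def test_offset_monotone_along_shift_ramp(rng):
    grid = GridSpec(5, 5, 0, 0, 100.0)
    model, env_now, _ = _model_and_stacks(rng, grid)
    mask = BinaryMap(np.ones(grid.shape, np.int8), grid)
    means = []
    for shift in (0.2, 0.5, 1.0, 2.0):
        fut = EnvStack(env_now.values + shift, env_now.var_names, grid,
                       period=f"s{shift}")
        means.append(ao.rda_offset(model, env_now, fut, mask).mean_offset())
    assert means == sorted(means)


def test_offset_and_au_confined_to_mask(rng):
    grid = GridSpec(10, 10, 0, 0, 100.0)
    model, env_now, env_fut = _model_and_stacks(rng, grid)
    mask_vals = np.zeros(grid.shape, np.int8)
    mask_vals[:4, :4] = 1
    mask = BinaryMap(mask_vals, grid)
    off = ao.rda_offset(model, env_now, env_fut, mask)
    assert np.isfinite(off.values[mask_vals.astype(bool)]).all()
    assert np.isnan(off.values[~mask_vals.astype(bool)]).all()
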