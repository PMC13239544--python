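import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from geneclim import enm
from geneclim.enm import BackgroundSet, BinaryMap, SuitabilityMap
from geneclim.geo_io import EnvStack, GridSpec, OccurrenceSet

# ---------------------------------------------------------------------------
# AUC


def auc_pair_counting(scores, labels):
    """Exhaustive pair-counting oracle (ties count half)."""
    pos = [s for s, l in zip(scores, labels) if l == 1]
    neg = [s for s, l in zip(scores, labels) if l == 0]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


def test_auc_perfect_separation():
    assert enm.auc([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0]) == 1.0


def test_auc_matches_pair_counting_oracle(rng):
    for _ in range(20):
        scores = rng.integers(0, 5, 12).astype(float)  # heavy ties
        labels = rng.integers(0, 2, 12)
        if labels.sum() in (0, 12):
            continue
        assert enm.auc(scores, labels) == pytest.approx(
            auc_pair_counting(scores, labels))


def test_auc_random_scores_near_half(rng):
    vals = [enm.auc(rng.normal(size=60), rng.integers(0, 2, 60) | (np.arange(60) < 2))
            for _ in range(300)]
    se = np.std(vals) / np.sqrt(len(vals))
    assert abs(np.mean(vals) - 0.5) < 3 * max(se, 0.01)


@settings(deadline=None, max_examples=25, derandomize=True)
@given(st.lists(st.integers(-1000, 1000), min_size=6, max_size=30),
       st.integers(0, 2 ** 30))
def test_auc_invariant_under_monotone_transform(scores, label_seed):
    labels = np.random.default_rng(label_seed).integers(0, 2, len(scores))
    if labels.sum() in (0, len(labels)):
        labels[0], labels[-1] = 1, 0
    s = np.asarray(scores, dtype=float)
    assert enm.auc(3.0 * s + 7.0, labels) == pytest.approx(
        enm.auc(s, labels), abs=1e-12)


def test_auc_single_class_errors():
    with pytest.raises(ValueError):
        enm.auc([0.1, 0.2], [1, 1])


# ---------------------------------------------------------------------------
# Boyce index


def test_boyce_monotone_near_one_and_antisymmetric(rng):
    land = rng.uniform(0, 1, 4000)
    # occurrences preferentially in high-suitability cells
    occ = land[land > rng.uniform(0, 1, 4000) * 0.9]
    cbi = enm.boyce_index(land, occ)
    assert cbi > 0.7
    flipped = enm.boyce_index(1 - land, 1 - occ)
    assert flipped == pytest.approx(-cbi, abs=1e-9)


def test_boyce_random_occurrences_near_zero(rng):
    vals = []
    for _ in range(30):
        land = rng.uniform(0, 1, 2000)
        occ = rng.choice(land, 150, replace=False)
        vals.append(enm.boyce_index(land, occ))
    assert abs(np.mean(vals)) < 0.15


def test_boyce_degenerate_errors():
    with pytest.raises(ValueError):
        enm.boyce_index([0.5] * 10, [0.5, 0.5])


# ---------------------------------------------------------------------------
# spatial blocks


def _occ(xs, ys, grid=None):
    return OccurrenceSet([str(i) for i in range(len(xs))],
                         np.asarray(xs, float), np.asarray(ys, float), grid)


def _bg_at(xs, ys):
    xs, ys = np.asarray(xs, float), np.asarray(ys, float)
    return BackgroundSet(np.zeros((len(xs), 2), int), xs, ys, np.ones(len(xs)))


def test_folds_28_occurrences_balance_7777(rng):
    occ = _occ(rng.uniform(0, 1000, 28), rng.uniform(0, 1000, 28))
    folds, _ = enm.spatial_block_folds(occ, _bg_at([500.0], [500.0]))
    assert sorted(np.bincount(folds).tolist()) == [7, 7, 7, 7]


def test_folds_four_corner_points():
    occ = _occ([0, 0, 1000, 1000], [0, 1000, 0, 1000])
    folds, _ = enm.spatial_block_folds(occ, _bg_at([1.0], [1.0]))
    assert sorted(folds.tolist()) == [0, 1, 2, 3]


def test_folds_balance_within_one_when_achievable(rng):
    for seed in range(5):
        r = np.random.default_rng(seed)
        occ = _occ(r.uniform(0, 100, 12), r.uniform(0, 100, 12))
        folds, _ = enm.spatial_block_folds(occ, _bg_at([50.0], [50.0]))
        counts = np.bincount(folds, minlength=4)
        assert counts.max() - counts.min() <= 1


def test_background_assigned_by_same_cuts(rng):
    occ = _occ(rng.uniform(0, 1000, 16), rng.uniform(0, 1000, 16))
    bgx, bgy = rng.uniform(0, 1000, 200), rng.uniform(0, 1000, 200)
    ofolds, bfolds = enm.spatial_block_folds(occ, _bg_at(bgx, bgy))
    # every background fold region contains its own occurrences' bin
    assert set(np.unique(bfolds)) <= {0, 1, 2, 3}


# ---------------------------------------------------------------------------
# background sampling


def test_density_weighted_background_concentrates(grid10, rng):
    m = np.ones(grid10.shape, bool)
    occ = _occ([450.0], [450.0], grid10)
    dists_w, dists_u = [], []
    for seed in range(30):
        bg = enm.density_weighted_background(occ, m, grid10, n=20,
                                             bandwidth=0.3, seed=seed)
        dists_w.append(np.hypot(bg.x - 450, bg.y - 450).mean())
        r = np.random.default_rng(seed)
        xs = r.uniform(0, 1000, 20)
        ys = r.uniform(0, 1000, 20)
        dists_u.append(np.hypot(xs - 450, ys - 450).mean())
    assert np.mean(dists_w) < np.mean(dists_u)


def test_background_floor_keeps_far_cells_sampleable(grid10):
    m = np.ones(grid10.shape, bool)
    occ = _occ([50.0, 60.0], [50.0, 70.0], grid10)
    with pytest.warns(UserWarning):  # n exceeds available cells -> use all
        bg = enm.density_weighted_background(occ, m, grid10, n=500, seed=0)
    n_presence_cells = len({tuple(rc) for rc in zip(*grid10.cell_of(occ.x, occ.y))})
    assert len(bg) == 100 - n_presence_cells


# ---------------------------------------------------------------------------
# M area from DEM


def _two_basin_dem(n=12):
    # V-shaped: descends toward column 2 (west basin) and column 9 (east)
    dem = np.zeros((n, n))
    for c in range(n):
        dem[:, c] = min(abs(c - 2), abs(c - 9)) * 10.0
    dem += np.linspace(0, 1, n)[:, None]  # tilt so pits are at the top row
    return dem


def test_two_basin_dem_selects_occupied_basin():
    grid = GridSpec(12, 12, 0, 0, 100.0)
    dem = _two_basin_dem()
    occ = _occ([250.0], [600.0], grid)  # in the west basin (column 2)
    mask = enm.derive_m_area(dem, occ, grid)
    assert mask[5, 2] and not mask[5, 9]
    # occurrences in both basins -> full footprint
    occ2 = _occ([250.0, 950.0], [600.0, 600.0], grid)
    mask2 = enm.derive_m_area(dem, occ2, grid)
    assert mask2.all()


def test_flat_dem_errors_and_polygon_override(grid10):
    import shapely

    from geneclim.geo_io import PolygonLayer, rasterize_mask
    occ = _occ([500.0], [500.0], grid10)
    with pytest.raises(ValueError, match="flat"):
        enm.derive_m_area(np.zeros(grid10.shape), occ, grid10)
    layer = PolygonLayer([shapely.box(0, 0, 400, 400)], ["m"])
    mask = enm.derive_m_area(np.zeros(grid10.shape), occ, grid10,
                             override_polygon=layer)
    np.testing.assert_array_equal(mask, rasterize_mask(layer, grid10).astype(bool))


# ---------------------------------------------------------------------------
# small-model ensembles


class _ConstModel:
    def __init__(self, vals):
        self.vals = np.asarray(vals, float)

    def predict(self, X):
        return self.vals[: len(X)] if self.vals.size > 1 else \
            np.full(len(X), float(self.vals))


def _const_small_model(pair, auc_val, const):
    m = enm.SmallModel(pair=pair, learner="glm", model=None, scaler=None,
                       cv_auc=auc_val, cv_cbi=0.5)
    m.predict = lambda X, c=const: np.full(len(X), c)
    return m


def test_bivariate_pair_enumeration(small_study):
    _, stacks, _, occ, _ = small_study
    # C(6, 2) = 15 pairs for the 6-band fixture stack, per learner
    cur = stacks["current"]
    bg = enm.density_weighted_background(occ, cur.mask, cur.grid, n=200, seed=0)
    ens = enm.fit_small_models(occ, bg, cur, learners=("glm",), seed=0)
    assert len(ens.models) == 15
    assert {frozenset(m.pair) for m in ens.models} == \
        {frozenset(p) for p in itertools.combinations(cur.var_names, 2)}


def test_single_included_model_weight_one_and_identity(small_study):
    _, stacks, _, _, _ = small_study
    cur = stacks["current"]
    m = _const_small_model(("env1", "env2"), 0.9, 0.4)
    ens = enm.SmallModelEnsemble([m, _const_small_model(("env1", "env3"), 0.5, 0.9)])
    assert len(ens.included) == 1
    np.testing.assert_array_equal(ens.weights, [1.0])
    out = enm.ensemble_predict(ens, cur)
    assert np.allclose(out.values[cur.mask], 0.4)


def test_ensemble_weighted_mean_matches_loop_oracle(small_study, rng):
    _, stacks, _, _, _ = small_study
    cur = stacks["current"]
    consts = [0.2, 0.9, 0.5]
    aucs = [0.75, 0.8, 0.95]
    ens = enm.SmallModelEnsemble([
        _const_small_model(("env1", "env2"), a, c) for a, c in zip(aucs, consts)])
    out = enm.ensemble_predict(ens, cur)
    w = np.array(aucs) / np.sum(aucs)
    expected = float(np.dot(w, consts))
    assert np.allclose(out.values[cur.mask], expected, atol=1e-12)
    # equal AUCs -> plain arithmetic mean
    ens2 = enm.SmallModelEnsemble([
        _const_small_model(("env1", "env2"), 0.8, c) for c in consts])
    out2 = enm.ensemble_predict(ens2, cur)
    assert np.allclose(out2.values[cur.mask], np.mean(consts), atol=1e-12)


def test_no_included_models_errors(small_study):
    _, stacks, _, _, _ = small_study
    ens = enm.SmallModelEnsemble([_const_small_model(("env1", "env2"), 0.55, 0.5)])
    with pytest.raises(ValueError, match="AUC"):
        enm.ensemble_predict(ens, stacks["current"])


def test_informative_pairs_score_higher():
    """Pairs containing the suitability-driving variable out-rank pairs
    without it (paired comparison across a few simulated studies)."""
    from geneclim import synthdata
    diffs = []
    for seed in range(3):
        cfg = synthdata.SimConfig(seed=seed, n_loci=20, n_adaptive_loci=0,
                                  n_individuals=10, n_env=4, suit_breadth=0.4)
        stacks, gm, occ, truth = synthdata.simulate(cfg)
        cur = stacks["current"]
        bg = enm.density_weighted_background(occ, cur.mask, cur.grid, n=300,
                                             seed=seed)
        ens = enm.fit_small_models(occ, bg, cur, learners=("glm",), seed=0)
        # all variables drive suitability equally here; instead compare
        # against a stack with two pure-noise distractor bands
        vals = np.concatenate([cur.values,
                               np.random.default_rng(seed).normal(
                                   size=(2,) + cur.grid.shape)])
        stack2 = EnvStack(vals, cur.var_names + ["noise1", "noise2"], cur.grid)
        ens2 = enm.fit_small_models(occ, bg, stack2, learners=("glm",), seed=0)
        signal = [m.cv_auc for m in ens2.models
                  if "noise1" not in m.pair and "noise2" not in m.pair]
        noise = [m.cv_auc for m in ens2.models
                 if "noise1" in m.pair and "noise2" in m.pair]
        diffs.append(np.mean(signal) - np.mean(noise))
    assert np.mean(diffs) > 0


# ---------------------------------------------------------------------------
# MESS


def mess_brute(stack, ref, var_names):
    out = np.full(stack.grid.shape, np.nan)
    for r in range(stack.grid.nrow):
        for c in range(stack.grid.ncol):
            sims = []
            for j, name in enumerate(var_names):
                vals = ref[:, j]
                pval = stack.band(name)[r, c]
                if np.isnan(pval):
                    sims = []
                    break
                f = 100.0 * np.sum(vals < pval) / len(vals)
                lo, hi = vals.min(), vals.max()
                if f == 0:
                    s = (pval - lo) / (hi - lo) * 100
                elif f <= 50:
                    s = 2 * f
                elif f < 100:
                    s = 2 * (100 - f)
                else:
                    s = (hi - pval) / (hi - lo) * 100
                sims.append(s)
            if sims:
                out[r, c] = min(sims)
    return out


def test_mess_median_is_100_and_below_min_negative(grid10):
    ref = np.linspace(0, 1, 10)[:, None]  # half the values below 0.5
    vals = np.full((1,) + grid10.shape, 0.5)
    vals[0, 0, 0] = -0.2  # below reference minimum
    stack = EnvStack(vals, ["v"], grid10)
    out = enm.mess(stack, ref)
    assert out[1, 1] == pytest.approx(100.0)
    assert out[0, 0] < 0


def test_mess_matches_brute_force(grid10, rng):
    ref = rng.normal(size=(10, 3))
    stack = EnvStack(rng.normal(size=(3,) + grid10.shape), ["a", "b", "c"], grid10)
    got = enm.mess(stack, ref)
    want = mess_brute(stack, ref, ["a", "b", "c"])
    np.testing.assert_allclose(got, want, atol=1e-9)


# ---------------------------------------------------------------------------
# binarization + buffer


def _suit_map(vals, grid):
    return SuitabilityMap(np.asarray(vals, float), grid)


def test_p10_linear_interpolation_threshold(grid10):
    vals = np.zeros(grid10.shape)
    vals[0, :10] = np.linspace(0.1, 1.0, 10)
    vals[5, 5] = 0.55
    smap = _suit_map(vals, grid10)
    occ = _occ((np.arange(10) + 0.5) * 100, np.full(10, 950.0), grid10)
    b = enm.binarize(smap, occ, "p10")
    # threshold 0.19 -> cells with suitability >= 0.19
    assert b.values[0, 0] == 0 and b.values[0, 1] == 1
    assert b.values[5, 5] == 1


def test_min_presence_covers_all_occurrences(small_study):
    _, stacks, _, occ, truth = small_study
    smap = _suit_map(truth.suitability["current"], stacks["current"].grid)
    b = enm.binarize(smap, occ, "min_presence")
    r, c = b.grid.cell_of(occ.x, occ.y)
    assert b.values[r, c].all()
    p10 = enm.binarize(smap, occ, "p10")
    # min-presence range contains the p10 range
    assert (b.values >= p10.values).all()


def test_max_tss_perfect_separation(grid10):
    vals = np.zeros(grid10.shape)
    vals[:5] = 0.9
    vals[5:] = 0.1
    smap = _suit_map(vals, grid10)
    occ = _occ([150.0, 250.0, 350.0], [950.0, 950.0, 850.0], grid10)
    bgc = np.array([[8, i] for i in range(8)])
    bg = BackgroundSet(bgc, (bgc[:, 1] + 0.5) * 100, np.full(8, 150.0),
                       np.ones(8))
    b = enm.binarize(smap, occ, "max_tss", bg)
    assert b.values[:5].all() and not b.values[5:].any()


def test_buffer_disc_13_cells_and_monotone(grid10):
    b = BinaryMap(np.zeros(grid10.shape, np.int8), grid10)
    b.values[5, 5] = 1
    out = enm.buffer_binary(b, 200.0)
    assert out.values.sum() == 13
    assert out.values[b.values.astype(bool)].all()  # input subset of output
    # radius below cell size leaves the map unchanged
    same = enm.buffer_binary(b, 50.0)
    np.testing.assert_array_equal(same.values, b.values)
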