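"""Ensemble-of-small-models niche modeling.

With few presences relative to predictors, full multivariate models
overfit; the small-model ensemble instead fits every unordered pair of
predictors with simple learners, scores each bivariate model by spatially
blocked cross-validation (AUC and Continuous Boyce Index), drops models
with AUC < 0.7 and averages the survivors' maps weighted by AUC.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
from scipy import ndimage, stats
from sklearn.ensemble import GradientBoostingClassifier, RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.preprocessing import StandardScaler

from .geo_io import EnvStack, GridSpec, OccurrenceSet

__all__ = [
    "BackgroundSet", "SmallModel", "SmallModelEnsemble", "SuitabilityMap",
    "BinaryMap", "density_weighted_background", "derive_m_area",
    "spatial_block_folds", "fit_small_models", "auc", "boyce_index",
    "ensemble_predict", "mess", "binarize", "buffer_binary",
]

AUC_CUTOFF = 0.7


@dataclass
class BackgroundSet:
    """Background (pseudo-absence) cells sampled within the M area."""

    cells: np.ndarray          # (n, 2) row, col
    x: np.ndarray
    y: np.ndarray
    weights: np.ndarray        # sampling density at the chosen cells

    def __len__(self):
        return len(self.cells)


@dataclass
class SmallModel:
    pair: tuple[str, str]
    learner: str
    model: object
    scaler: object
    cv_auc: float
    cv_cbi: float

    @property
    def included(self) -> bool:
        return self.cv_auc >= AUC_CUTOFF

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.model.predict_proba(self.scaler.transform(X))[:, 1]


@dataclass
class SmallModelEnsemble:
    models: list[SmallModel]

    @property
    def included(self) -> list[SmallModel]:
        return [m for m in self.models if m.included]

    @property
    def weights(self) -> np.ndarray:
        aucs = np.array([m.cv_auc for m in self.included])
        return aucs / aucs.sum()

    def score_table(self):
        import pandas as pd
        rows = [{"pair": "x".join(m.pair), "learner": m.learner,
                 "cv_auc": m.cv_auc, "cv_cbi": m.cv_cbi, "included": m.included}
                for m in self.models]
        df = pd.DataFrame(rows)
        w = {id(m): wt for m, wt in zip(self.included, self.weights)} if self.included else {}
        df["weight"] = [w.get(id(m), 0.0) for m in self.models]
        return df


@dataclass
class SuitabilityMap:
    values: np.ndarray         # (nrow, ncol) in [0, 1], NaN outside mask
    grid: GridSpec
    period: str = "current"
    scenario: str = ""


@dataclass
class BinaryMap:
    values: np.ndarray         # (nrow, ncol) in {0, 1}
    grid: GridSpec
    period: str = "current"
    scenario: str = ""
    threshold_method: str = ""
    buffered: bool = False

    @property
    def area_km2(self) -> float:
        return float(self.values.sum()) * (self.grid.cellsize / 1000.0) ** 2


# ---------------------------------------------------------------------------
# Background design

def density_weighted_background(occ: OccurrenceSet, m_mask: np.ndarray,
                                grid: GridSpec, n: int = 10_000,
                                bandwidth=None, eps: float = 1e-6,
                                seed: int = 0) -> BackgroundSet:
    """Sample background cells with probability ∝ occurrence kernel density.

    A Gaussian KDE of the occurrence coordinates (Scott bandwidth unless
    given) is evaluated at every M-area cell center, floored at ``eps`` of
    its maximum so distant cells stay sampleable, and cells are drawn
    without replacement.  Presence cells are excluded.
    """
    m_mask = np.asarray(m_mask, bool)
    if not m_mask.any():
        raise ValueError("empty M-area mask")
    avail = m_mask.copy()
    orow, ocol = grid.cell_of(occ.x, occ.y)
    avail[orow, ocol] = False
    rows, cols = np.nonzero(avail)
    xc, yc = grid.cell_centers()
    pts = np.column_stack([xc[rows, cols], yc[rows, cols]])
    try:
        kde = stats.gaussian_kde(occ.coords.T, bw_method=bandwidth)
        dens = kde(pts.T)
    except (np.linalg.LinAlgError, ValueError):  # single/collinear points
        bw = bandwidth if isinstance(bandwidth, (int, float)) else 1.0
        sigma = bw * max(grid.cellsize, occ.coords.std() or grid.cellsize)
        d2 = ((pts[:, None, :] - occ.coords[None]) ** 2).sum(-1)
        dens = np.exp(-d2 / (2 * sigma ** 2)).sum(1)
    dens = np.maximum(dens, eps * dens.max() if dens.max() > 0 else eps)
    if n >= len(rows):
        warnings.warn(f"requested {n} background cells, only {len(rows)} "
                      "available: using all")
        sel = np.arange(len(rows))
    else:
        rng = np.random.default_rng(seed)
        sel = rng.choice(len(rows), size=n, replace=False, p=dens / dens.sum())
    return BackgroundSet(np.column_stack([rows[sel], cols[sel]]),
                         pts[sel, 0], pts[sel, 1], dens[sel])


# ---------------------------------------------------------------------------
# M area from a DEM (D8 watersheds)

_D8 = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]


def _watershed_labels(dem: np.ndarray) -> np.ndarray:
    """Label cells by the terminal cell (pit or edge outlet) of D8 descent."""
    nr, nc = dem.shape
    flow = np.full((nr, nc), -1, dtype=np.int64)  # flat index of downstream cell
    for r in range(nr):
        for c in range(nc):
            if np.isnan(dem[r, c]):
                continue
            best, bestdrop = -1, 0.0
            for dr, dc in _D8:
                rr, cc = r + dr, c + dc
                if 0 <= rr < nr and 0 <= cc < nc and not np.isnan(dem[rr, cc]):
                    dist = np.hypot(dr, dc)
                    drop = (dem[r, c] - dem[rr, cc]) / dist
                    if drop > bestdrop:
                        best, bestdrop = rr * nc + cc, drop
            flow[r, c] = best if best >= 0 else r * nc + c  # pit drains to itself
    # follow flow pointers to the terminal (pit) cell; converges because
    # elevation strictly decreases along every pointer chain
    flat = flow.ravel()
    idx = np.arange(nr * nc)
    term = np.where(flat >= 0, flat, idx)
    for _ in range(nr * nc):
        nxt = np.where(flat[term] >= 0, flat[term], term)
        if (nxt == term).all():
            break
        term = nxt
    labels = term.reshape(nr, nc)
    labels[np.isnan(dem)] = -1
    return labels


def derive_m_area(dem: np.ndarray, occ: OccurrenceSet, grid: GridSpec,
                  override_polygon=None) -> np.ndarray:
    """Union of D8 watersheds containing at least one occurrence.

    A user polygon layer overrides the watershed derivation entirely.
    """
    if override_polygon is not None:
        from .geo_io import rasterize_mask
        return rasterize_mask(override_polygon, grid).astype(bool)
    dem = np.asarray(dem, float)
    finite = dem[~np.isnan(dem)]
    if finite.size and np.ptp(finite) == 0:
        raise ValueError("flat DEM: watersheds undefined; supply a polygon override")
    labels = _watershed_labels(dem)
    orow, ocol = grid.cell_of(occ.x, occ.y)
    keep = set(labels[orow, ocol].tolist()) - {-1}
    return np.isin(labels, list(keep))


# ---------------------------------------------------------------------------
# Spatial block cross-validation

def spatial_block_folds(occ: OccurrenceSet, bg: BackgroundSet, k: int = 4):
    """Four geographic quadrant bins balanced on occurrence counts.

    Occurrences are split at their median x, then each half at its own
    median y, giving four corner bins whose occurrence counts differ from
    n/4 by at most one (when coordinates permit).  Background points are
    assigned by the same geographic cuts.
    """
    if k != 4:
        raise ValueError("the blocked design uses k = 4 quadrant bins")
    n = len(occ)
    if n < k:
        raise ValueError("need at least k occurrences")
    ox, oy = occ.x, occ.y
    order = np.argsort(ox, kind="stable")
    n_left = n // 2 + (n % 2)
    left = np.zeros(n, bool)
    left[order[:n_left]] = True
    x_cut = (ox[order[n_left - 1]] + ox[order[min(n_left, n - 1)]]) / 2
    if len(np.unique(ox)) < n and (ox[left].max() >= ox[~left].min() if (~left).any() else False):
        warnings.warn("duplicate x coordinates: occurrence balance is best-effort")
    occ_folds = np.zeros(n, int)
    y_cuts = {}
    for side, fold0 in ((left, 0), (~left, 2)):
        idx = np.nonzero(side)[0]
        m = len(idx)
        oy_side = oy[idx]
        oorder = idx[np.argsort(oy_side, kind="stable")]
        m_low = m // 2 + (m % 2)
        occ_folds[oorder[:m_low]] = fold0
        occ_folds[oorder[m_low:]] = fold0 + 1
        if m_low < m:
            y_cuts[fold0] = (oy[oorder[m_low - 1]] + oy[oorder[m_low]]) / 2
        else:
            y_cuts[fold0] = np.inf
    bx, by = bg.x, bg.y
    bg_left = bx <= x_cut
    bg_folds = np.where(bg_left,
                        np.where(by <= y_cuts[0], 0, 1),
                        np.where(by <= y_cuts[2], 2, 3))
    return occ_folds, bg_folds


# ---------------------------------------------------------------------------
# Scores

def auc(scores, labels) -> float:
    """Mann-Whitney (rank-based) AUC with midranks for ties."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, int)
    n1 = int(labels.sum())
    n0 = len(labels) - n1
    if n1 == 0 or n0 == 0:
        raise ValueError("both classes must be present")
    ranks = stats.rankdata(scores)
    u = ranks[labels == 1].sum() - n1 * (n1 + 1) / 2
    return float(u / (n1 * n0))


def boyce_index(landscape_suit, occ_suit, n_classes: int = 101,
                window: float = 0.1) -> float:
    """Continuous Boyce Index: Spearman of P/E ratio against window rank.

    ``n_classes`` overlapping windows of width ``window`` (as a fraction of
    the landscape suitability range) slide across the range; P is the share
    of occurrence suitabilities in the window, E the share of landscape
    cells.  Windows with E = 0 are dropped.
    """
    land = np.asarray(landscape_suit, float)
    land = land[np.isfinite(land)]
    occv = np.asarray(occ_suit, float)
    occv = occv[np.isfinite(occv)]
    if np.unique(occv).size < 2:
        raise ValueError("occurrence suitabilities are degenerate (constant)")
    lo, hi = land.min(), land.max()
    if hi <= lo:
        raise ValueError("constant landscape suitability")
    width = window * (hi - lo)
    starts = np.linspace(lo, hi - width, n_classes)
    pe, ranks = [], []
    for i, s in enumerate(starts):
        e = ((land >= s) & (land <= s + width)).mean()
        if e == 0:
            continue
        p = ((occv >= s) & (occv <= s + width)).mean()
        pe.append(p / e)
        ranks.append(i)
    if len(pe) < 3:
        raise ValueError("too few populated windows for CBI")
    rho = stats.spearmanr(ranks, pe).statistic
    return float(rho)


# ---------------------------------------------------------------------------
# Learners

def _make_learner(name: str, seed: int):
    if name == "glm":
        est = LogisticRegression(C=1.0, max_iter=2000)
        return est, True
    if name == "rf":
        return RandomForestClassifier(n_estimators=200, min_samples_leaf=5,
                                      random_state=seed, n_jobs=1), False
    if name == "gbm":
        return GradientBoostingClassifier(random_state=seed), False
    raise ValueError(f"unknown learner {name!r}; choose from glm, rf, gbm")


def _expand_quadratic(X: np.ndarray) -> np.ndarray:
    return np.column_stack([X, X ** 2, X[:, :1] * X[:, 1:2]])


class _FittedLearner:
    """Uniform predict_proba front for the learner families."""

    def __init__(self, est, quadratic: bool):
        self.est = est
        self.quadratic = quadratic

    def fit(self, X, y):
        self.est.fit(_expand_quadratic(X) if self.quadratic else X, y)
        return self

    def predict_proba(self, X):
        return self.est.predict_proba(_expand_quadratic(X) if self.quadratic else X)


def fit_small_models(occ: OccurrenceSet, bg: BackgroundSet, stack: EnvStack,
                     learners=("glm", "rf"), folds=None, seed: int = 0,
                     var_names=None) -> SmallModelEnsemble:
    """Fit every unordered predictor pair x learner as a presence/background
    classifier, scored by leave-one-bin-out AUC and CBI.

    Models with mean cross-validated AUC < 0.7 are flagged out of the
    ensemble; the rest get AUC-proportional weights.
    """
    names = list(var_names or stack.var_names)
    if len(names) < 2:
        raise ValueError("need at least two predictors")
    Xp = stack.values_at(occ.x, occ.y)
    Xb = stack.values_at(bg.x, bg.y)
    cols = {n: stack.var_names.index(n) for n in names}
    if folds is None:
        folds = spatial_block_folds(occ, bg)
    occ_folds, bg_folds = folds
    models = []
    for pair in combinations(names, 2):
        ji = [cols[pair[0]], cols[pair[1]]]
        Xp2, Xb2 = Xp[:, ji], Xb[:, ji]
        X = np.vstack([Xp2, Xb2])
        y = np.r_[np.ones(len(Xp2)), np.zeros(len(Xb2))]
        fold_of = np.r_[occ_folds, bg_folds]
        for lname in learners:
            aucs, cbis = [], []
            for f in np.unique(np.r_[occ_folds, bg_folds]):
                tr, te = fold_of != f, fold_of == f
                if y[tr].sum() == 0 or y[te].sum() == 0 or (1 - y[te]).sum() == 0:
                    warnings.warn(f"fold {f} lacks a class for {pair}/{lname}: skipped")
                    continue
                sc = StandardScaler().fit(X[tr])
                est, quad = _make_learner(lname, seed)
                fl = _FittedLearner(est, quad).fit(sc.transform(X[tr]), y[tr])
                prob = fl.predict_proba(sc.transform(X[te]))[:, 1]
                aucs.append(auc(prob, y[te]))
                try:
                    cbis.append(boyce_index(prob[y[te] == 0], prob[y[te] == 1]))
                except ValueError:
                    pass
            sc = StandardScaler().fit(X)
            est, quad = _make_learner(lname, seed)
            fl = _FittedLearner(est, quad).fit(sc.transform(X), y)
            models.append(SmallModel(
                pair=pair, learner=lname, model=fl, scaler=sc,
                cv_auc=float(np.mean(aucs)) if aucs else 0.0,
                cv_cbi=float(np.mean(cbis)) if cbis else np.nan,
            ))
    return SmallModelEnsemble(models)


def ensemble_predict(ens: SmallModelEnsemble, stack: EnvStack,
                     period=None, scenario=None) -> SuitabilityMap:
    """AUC-weighted mean of the included models' probability maps."""
    inc = ens.included
    if not inc:
        aucs = [m.cv_auc for m in ens.models]
        raise ValueError(f"no model reached AUC {AUC_CUTOFF}; CV AUCs: {aucs}")
    ok = stack.mask
    rows, cols = np.nonzero(ok)
    out = np.full(stack.grid.shape, np.nan)
    acc = np.zeros(rows.shape)
    for m, w in zip(inc, ens.weights):
        ji = [stack.var_names.index(m.pair[0]), stack.var_names.index(m.pair[1])]
        X = stack.values[ji][:, rows, cols].T
        acc += w * m.predict(X)
    out[rows, cols] = acc
    return SuitabilityMap(out, stack.grid,
                          period or stack.period, scenario or stack.scenario)


# ---------------------------------------------------------------------------
# MESS

def mess(stack: EnvStack, reference: np.ndarray,
         var_names=None) -> np.ndarray:
    """Multivariate environmental similarity surface.

    For each variable, with f the percentage of reference values strictly
    below the cell value, p the cell value and min/max the reference range::

        sim = (p - min) / (max - min) * 100      if f = 0
              2 f                                if f <= 50
              2 (100 - f)                        if 50 < f < 100
              (max - p) / (max - min) * 100      if f = 100

    MESS is the per-cell minimum across variables; negative values mark
    conditions outside the reference (calibration) envelope.
    """
    names = list(var_names or stack.var_names)
    ref = np.asarray(reference, float)
    if ref.ndim != 2 or ref.shape[1] != len(names):
        raise ValueError("reference must be (n_points, n_var)")
    if ref.shape[0] == 0:
        raise ValueError("empty reference")
    ok = stack.mask
    rows, cols = np.nonzero(ok)
    sims = []
    for j, name in enumerate(names):
        rv = np.sort(ref[:, j])
        lo, hi = rv[0], rv[-1]
        if hi == lo:
            warnings.warn(f"constant reference for {name}: excluded from MESS")
            continue
        p = stack.band(name)[rows, cols]
        f = np.searchsorted(rv, p, side="left") / rv.size * 100.0
        sim = np.where(
            f == 0, (p - lo) / (hi - lo) * 100.0,
            np.where(f <= 50, 2 * f,
                     np.where(f < 100, 2 * (100 - f),
                              (hi - p) / (hi - lo) * 100.0)))
        sims.append(sim)
    if not sims:
        raise ValueError("all reference variables are constant")
    out = np.full(stack.grid.shape, np.nan)
    out[rows, cols] = np.min(sims, axis=0)
    return out


# ---------------------------------------------------------------------------
# Binarization and buffering

def _percentile_linear(values: np.ndarray, q: float) -> float:
    return float(np.percentile(values, q, method="linear"))


def binarize(smap: SuitabilityMap, occ: OccurrenceSet, method: str,
             bg: BackgroundSet | None = None) -> BinaryMap:
    """Threshold a suitability map into a binary range map.

    ``max_tss`` maximizes sensitivity + specificity - 1 over presence vs.
    background scores (threshold ties broken toward the lower, more
    inclusive value); ``min_presence`` uses the minimum occurrence
    suitability; ``p10`` the linear-interpolation 10th percentile of
    occurrence suitabilities.
    """
    vals = smap.values
    row, col = smap.grid.cell_of(occ.x, occ.y)
    pres = vals[row, col]
    if np.unique(vals[np.isfinite(vals)]).size < 2:
        raise ValueError("constant suitability map cannot be thresholded")
    if method == "min_presence":
        thr = float(np.nanmin(pres))
    elif method == "p10":
        thr = _percentile_linear(pres[np.isfinite(pres)], 10)
    elif method == "max_tss":
        if bg is None:
            raise ValueError("max_tss needs background scores")
        bgs = vals[bg.cells[:, 0], bg.cells[:, 1]]
        scores = np.r_[pres, bgs]
        labels = np.r_[np.ones(len(pres)), np.zeros(len(bgs))]
        fin = np.isfinite(scores)
        scores, labels = scores[fin], labels[fin]
        uniq = np.unique(scores)
        cand = np.r_[uniq[0] - 1e-12, (uniq[:-1] + uniq[1:]) / 2]
        best_thr, best_tss = cand[0], -np.inf
        n1, n0 = labels.sum(), (1 - labels).sum()
        for t in cand:
            sens = (scores[labels == 1] >= t).sum() / n1
            spec = (scores[labels == 0] < t).sum() / n0
            tss = sens + spec - 1
            if tss > best_tss:  # ties keep the earlier (lower) threshold
                best_thr, best_tss = t, tss
        thr = float(best_thr)
    else:
        raise ValueError(f"unknown method {method!r}")
    binary = np.where(np.isnan(vals), 0, (vals >= thr)).astype(np.int8)
    return BinaryMap(binary, smap.grid, smap.period, smap.scenario,
                     threshold_method=method)


def _disc_structure(radius_cells: float) -> np.ndarray:
    r = int(np.floor(radius_cells))
    dy, dx = np.mgrid[-r:r + 1, -r:r + 1]
    return (dx ** 2 + dy ** 2) <= radius_cells ** 2 + 1e-9


def buffer_binary(bmap: BinaryMap, radius_m: float = 200.0) -> BinaryMap:
    """Morphological dilation with a Euclidean disc of ``radius_m``."""
    if radius_m < bmap.grid.cellsize:
        return BinaryMap(bmap.values.copy(), bmap.grid, bmap.period,
                         bmap.scenario, bmap.threshold_method, buffered=True)
    struct = _disc_structure(radius_m / bmap.grid.cellsize)
    out = ndimage.binary_dilation(bmap.values.astype(bool), structure=struct)
    return BinaryMap(out.astype(np.int8), bmap.grid, bmap.period,
                     bmap.scenario, bmap.threshold_method, buffered=True)
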