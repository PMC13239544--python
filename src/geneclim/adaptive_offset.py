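"""Adaptive units and genetic offset from the candidate-SNP ordination.

Individuals are clustered in the site-score space of an RDA fitted on the
jointly detected candidate SNPs; the clustering solution (algorithm x k)
is chosen by a summed validity score.  A random-forest classifier then
maps cluster membership onto climate, projecting adaptive units into the
binary suitable range.  The genetic offset of a pixel is the Euclidean
distance between its current and future positions on the
eigenvalue-weighted retained RDA axes: a proxy for the adaptive change
required to track local climate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import cdist
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import calinski_harabasz_score, silhouette_score
from sklearn.model_selection import StratifiedKFold

from .enm import BinaryMap
from .gea import RDAModel, rda_fit
from .geo_io import EnvStack

__all__ = [
    "AUAssignment", "AUMap", "OffsetMap", "candidate_rda",
    "cluster_adaptive_units", "fit_au_classifier", "project_au_map",
    "rda_offset",
]


def candidate_rda(g_imputed: np.ndarray, env: np.ndarray, candidate_idx,
                  var_names=None, locus_ids=None, retained_axes: int = 3) -> RDAModel:
    """RDA restricted to the joint candidate loci (same algorithm as the
    full-matrix fit)."""
    idx = np.asarray(candidate_idx)
    if idx.dtype == bool:
        idx = np.nonzero(idx)[0]
    if idx.size < 3:
        raise ValueError("need at least 3 candidate loci for a 3-axis RDA")
    sub = np.asarray(g_imputed, float)[:, idx]
    lids = None if locus_ids is None else [list(locus_ids)[i] for i in idx]
    return rda_fit(sub, env, var_names=var_names, retained_axes=retained_axes,
                   locus_ids=lids)


# ---------------------------------------------------------------------------
# Clustering into adaptive units

def _pam(X: np.ndarray, k: int, max_iter: int = 100) -> np.ndarray:
    """k-medoids (PAM): greedy BUILD then SWAP on Euclidean distances."""
    D = cdist(X, X)
    n = len(X)
    medoids = [int(np.argmin(D.sum(axis=1)))]
    while len(medoids) < k:
        dmin = D[:, medoids].min(axis=1)
        gains = np.maximum(dmin[None, :] - D, 0).sum(axis=1)
        gains[medoids] = -np.inf
        medoids.append(int(np.argmax(gains)))
    medoids = np.array(medoids)
    cost = D[:, medoids].min(axis=1).sum()
    for _ in range(max_iter):
        improved = False
        for mi in range(k):
            for h in range(n):
                if h in medoids:
                    continue
                trial = medoids.copy()
                trial[mi] = h
                c = D[:, trial].min(axis=1).sum()
                if c < cost - 1e-12:
                    medoids, cost, improved = trial, c, True
        if not improved:
            break
    return np.argmin(D[:, medoids], axis=1)


@dataclass
class AUAssignment:
    labels: np.ndarray          # 1..k per individual
    k: int
    algorithm: str              # "kmedoids" | "ward"
    validity: pd.DataFrame      # columns: algorithm, k, A1, A2, S, rel_change
    low_confidence: bool = False


def cluster_adaptive_units(site_scores: np.ndarray, k_range=range(2, 7),
                           axes: int = 3) -> AUAssignment:
    """Cluster individuals on retained RDA axes and pick (algorithm, k).

    Both k-medoids and Ward agglomerative clustering run for every k; each
    solution is scored by S = A1 + A2 where A1 is the mean silhouette
    width and A2 the Calinski-Harabasz statistic min-max rescaled to
    [0, 1] across all candidate solutions.  The maximal S wins; exact ties
    go to the solution with the larger relative S-change from the previous
    k (then smaller k, then algorithm name).
    """
    X = np.asarray(site_scores, float)[:, :axes]
    n = len(X)
    ks = [k for k in k_range if k < n]
    if not ks:
        raise ValueError("k_range incompatible with the number of individuals")
    if n < 2 * max(ks):
        warnings.warn("fewer than 2*k_max individuals: clustering may be unstable")
    if np.allclose(X, X[0]):
        raise ValueError("identical site scores: no structure to cluster")
    sols = []
    Z = linkage(X, method="ward")
    for k in ks:
        for alg in ("kmedoids", "ward"):
            lab = _pam(X, k) if alg == "kmedoids" else fcluster(Z, k, criterion="maxclust") - 1
            _, sizes = np.unique(lab, return_counts=True)
            # a one-member unit is not an adaptive unit; drop the solution
            if len(sizes) < 2 or sizes.min() < 2:
                continue
            a1 = silhouette_score(X, lab)
            ch = calinski_harabasz_score(X, lab)
            sols.append({"algorithm": alg, "k": k, "labels": lab + 1,
                         "A1": a1, "CH": ch})
    if not sols:
        raise ValueError("no clustering solution without singleton units; "
                         "reduce k_range or add individuals")
    df = pd.DataFrame(sols)
    ch = df["CH"].to_numpy()
    span = ch.max() - ch.min()
    df["A2"] = (ch - ch.min()) / span if span > 0 else 1.0
    df["S"] = df["A1"] + df["A2"]
    df["rel_change"] = 0.0
    for alg in df["algorithm"].unique():
        sub = df[df["algorithm"] == alg].sort_values("k")
        prev = None
        for i in sub.index:
            s = df.at[i, "S"]
            df.at[i, "rel_change"] = 0.0 if prev in (None, 0) else (s - prev) / abs(prev)
            prev = s
    best = df.sort_values(["S", "rel_change", "k", "algorithm"],
                          ascending=[False, False, True, True]).index[0]
    # mean silhouette below ~0.35 signals weak-to-no cluster structure
    low_conf = df.at[best, "A1"] < 0.35
    validity = df.drop(columns="labels")
    return AUAssignment(labels=np.asarray(df.at[best, "labels"]),
                        k=int(df.at[best, "k"]),
                        algorithm=str(df.at[best, "algorithm"]),
                        validity=validity, low_confidence=bool(low_conf))


# ---------------------------------------------------------------------------
# Random-forest AU classifier

@dataclass
class AUClassifier:
    model: RandomForestClassifier
    var_names: list[str]
    cv_accuracy: float
    cv_accuracy_sd: float
    gini_importance: pd.Series


def fit_au_classifier(env_at_individuals: np.ndarray, labels, var_names,
                      n_trees: int = 500, cv_folds: int = 10,
                      seed: int = 0) -> AUClassifier:
    """Random forest predicting adaptive-unit membership from climate.

    Accuracy is the mean over stratified cross-validation folds (the fold
    count drops to the smallest class size when needed so every unit is
    represented in training); importance is mean decrease in Gini.
    """
    X = np.asarray(env_at_individuals, float)
    y = np.asarray(labels)
    classes, counts = np.unique(y, return_counts=True)
    if counts.min() < 2:
        raise ValueError(
            f"adaptive unit {classes[np.argmin(counts)]} has a single member; "
            "it cannot appear in every training fold")
    folds = min(cv_folds, int(counts.min()))
    if folds < cv_folds:
        warnings.warn(f"reducing CV folds to {folds} (smallest unit size)")
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    accs = []
    for tr, te in skf.split(X, y):
        rf = RandomForestClassifier(n_estimators=n_trees, random_state=seed, n_jobs=1)
        rf.fit(X[tr], y[tr])
        accs.append(float((rf.predict(X[te]) == y[te]).mean()))
    rf = RandomForestClassifier(n_estimators=n_trees, random_state=seed, n_jobs=1)
    rf.fit(X, y)
    return AUClassifier(rf, list(var_names), float(np.mean(accs)),
                        float(np.std(accs, ddof=1)) if len(accs) > 1 else 0.0,
                        pd.Series(rf.feature_importances_, index=list(var_names)))


@dataclass
class AUMap:
    labels: np.ndarray          # 0 outside mask, AU code inside
    grid: object
    period: str = ""
    scenario: str = ""
    threshold_method: str = ""

    def area_km2(self) -> dict:
        cell = (self.grid.cellsize / 1000.0) ** 2
        units = np.unique(self.labels[self.labels > 0])
        return {int(u): float((self.labels == u).sum()) * cell for u in units}


def project_au_map(clf: AUClassifier, stack: EnvStack, mask: BinaryMap) -> AUMap:
    """Predict the adaptive unit of every binary-suitable pixel."""
    missing = [v for v in clf.var_names if v not in stack.var_names]
    if missing:
        raise ValueError(f"stack lacks training variables: {missing}")
    out = np.zeros(stack.grid.shape, dtype=int)
    m = mask.values.astype(bool) & stack.mask
    if m.any():
        rows, cols = np.nonzero(m)
        idx = [stack.var_names.index(v) for v in clf.var_names]
        X = stack.values[idx][:, rows, cols].T
        out[rows, cols] = clf.model.predict(X)
    return AUMap(out, stack.grid, mask.period, mask.scenario, mask.threshold_method)


# ---------------------------------------------------------------------------
# Genetic offset

@dataclass
class OffsetMap:
    values: np.ndarray          # NaN outside mask, offset >= 0 inside
    grid: object
    period: str = ""
    scenario: str = ""
    threshold_method: str = ""

    def mean_offset(self, where=None) -> float:
        v = self.values if where is None else np.where(where, self.values, np.nan)
        v = v[np.isfinite(v)]
        return float(v.mean()) if v.size else float("nan")


def rda_offset(model: RDAModel, current: EnvStack, future: EnvStack,
               mask: BinaryMap, weighted: bool = True) -> OffsetMap:
    """Per-pixel global genetic offset inside the binary suitable range.

    Both stacks are standardized with the model's stored constants and
    projected on the retained canonical axes; axis k gets weight
    w_k = eigenvalue_k / sum(retained eigenvalues) and the offset is
    sqrt(sum_k (w_k * (a_k^future - a_k^current))^2).  ``weighted=False``
    uses the plain Euclidean distance across axes.
    """
    for stk in (current, future):
        missing = [v for v in model.var_names if v not in stk.var_names]
        if missing:
            raise ValueError(f"stack {stk.period!r} lacks variables: {missing}")
    m = mask.values.astype(bool) & current.mask & future.mask
    out = np.full(current.grid.shape, np.nan)
    if m.any():
        rows, cols = np.nonzero(m)
        axes = model.retained_axes
        def scores(stk):
            idx = [stk.var_names.index(v) for v in model.var_names]
            vals = stk.values[idx][:, rows, cols].T
            return model.axis_scores(vals)[:, :axes]
        delta = scores(future) - scores(current)
        eig = model.eigenvalues[:axes]
        w = eig / eig.sum() if weighted else np.ones(axes)
        out[rows, cols] = np.sqrt(((w[None, :] * delta) ** 2).sum(axis=1))
    return OffsetMap(out, current.grid, future.period, future.scenario,
                     mask.threshold_method)
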