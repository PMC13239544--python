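"""Candidate-locus detection from genotype-environment association.

Two complementary detectors run on imputed dosage matrices:

* ridge latent-factor association tests (per locus, per climate variable)
  with genomic-inflation-factor calibration and Benjamini-Hochberg FDR;
* redundancy analysis (RDA): constrained ordination of genotypes on
  climate, with loci whose loadings on the retained canonical axes exceed
  a standard-deviation cutoff flagged as outliers.

Only loci flagged by both detectors enter downstream adaptive-unit and
genetic-offset analyses, a deliberately conservative intersection rule.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .geo_io import GenotypeMatrix

__all__ = [
    "LfmmResult", "RDAModel", "CandidateSet",
    "impute_lowrank", "impute_cluster_mean", "lfmm_test",
    "rda_fit", "rda_outliers", "intersect_candidates",
]

CHI2_MEDIAN = float(stats.chi2.ppf(0.5, 1))  # 0.4549...


# ---------------------------------------------------------------------------
# Imputation

def impute_lowrank(g: GenotypeMatrix, rank: int = 5, tol: float = 1e-5,
                   max_iter: int = 200):
    """Low-rank matrix completion of missing dosages (iterative SVD).

    Missing entries start at locus means; each iteration replaces the full
    matrix by its best rank-``rank`` approximation and restores the
    observed entries, until the relative change of the imputed matrix
    drops below ``tol``.  The completed matrix is clipped to [0, 2].
    Returns (matrix, converged flag).
    """
    x = g.as_float()
    n, L = x.shape
    if rank >= min(n, L):
        raise ValueError("rank must be below both matrix dimensions")
    obs = ~np.isnan(x)
    mu = np.nanmean(x, axis=0)
    cur = np.where(obs, x, mu[None, :])
    converged = not (~obs).any()
    for _ in range(0 if converged else max_iter):
        u, s, vt = np.linalg.svd(cur, full_matrices=False)
        low = (u[:, :rank] * s[:rank]) @ vt[:rank]
        nxt = np.where(obs, x, low)
        delta = np.linalg.norm(nxt - cur) / max(np.linalg.norm(cur), 1e-12)
        cur = nxt
        if delta < tol:
            converged = True
            break
    return np.clip(cur, 0.0, 2.0), converged


def impute_cluster_mean(g: GenotypeMatrix, labels) -> np.ndarray:
    """Impute missing dosages with the within-cluster locus mean.

    ``labels`` assigns every individual to a genetic cluster (e.g. the
    argmax-ancestry admixture assignment); a locus entirely missing inside
    a cluster falls back to the global locus mean.
    """
    labels = np.asarray(labels)
    if labels.shape[0] != g.n_ind:
        raise ValueError("every individual needs a cluster label")
    x = g.as_float()
    out = x.copy()
    global_mu = np.nanmean(x, axis=0)
    for lab in np.unique(labels):
        rows = labels == lab
        import warnings as _w
        with _w.catch_warnings():
            _w.simplefilter("ignore", RuntimeWarning)  # all-NaN cluster column
            mu = np.nanmean(x[rows], axis=0)
        mu = np.where(np.isnan(mu), global_mu, mu)
        sub = out[rows]
        idx = np.nonzero(np.isnan(sub))
        sub[idx] = mu[idx[1]]
        out[rows] = sub
    return out


# ---------------------------------------------------------------------------
# Latent-factor association tests

@dataclass
class LfmmResult:
    var_names: list[str]
    z: np.ndarray               # (L, p)
    p_raw: np.ndarray
    gif: np.ndarray             # per-variable inflation factor
    p_calibrated: np.ndarray
    q: np.ndarray               # BH-adjusted per variable
    K: int
    fdr: float
    candidates: np.ndarray      # boolean per locus

    def candidate_counts(self) -> dict:
        """Candidate loci per variable at the stated FDR."""
        return {v: int((self.q[:, j] <= self.fdr).sum())
                for j, v in enumerate(self.var_names)}


def lfmm_test(g_imputed: np.ndarray, env: np.ndarray, var_names=None,
              K: int = 5, fdr: float = 0.05, ridge_lambda: float = 1e-5) -> LfmmResult:
    """Ridge latent-factor association tests per locus and climate variable.

    Latent factors are the first K left singular vectors of the genotype
    matrix after ridge-projecting out the (standardized) environment; each
    locus is then regressed on [environment, factors, intercept] by OLS
    and each environmental coefficient converted to a z-score.  Per
    variable, the genomic inflation factor lambda = median(z^2) / median
    of chi-square(1) recalibrates the p-values, which are then BH-adjusted
    across loci; a locus is a candidate when q <= fdr for any variable.
    """
    G = np.asarray(g_imputed, float)
    X = np.asarray(env, float)
    n, L = G.shape
    p = X.shape[1]
    if var_names is None:
        var_names = [f"env{j + 1}" for j in range(p)]
    if K >= n:
        raise ValueError("K must be below the number of individuals")
    Xs = (X - X.mean(axis=0)) / X.std(axis=0)
    Gc = G - G.mean(axis=0)
    if K > 0:
        H = Xs @ np.linalg.solve(Xs.T @ Xs + ridge_lambda * np.eye(p), Xs.T)
        resid = Gc - H @ Gc
        u, s, _ = np.linalg.svd(resid, full_matrices=False)
        U = u[:, :K]
        D = np.column_stack([np.ones(n), Xs, U])
    else:
        U = np.zeros((n, 0))
        D = np.column_stack([np.ones(n), Xs])
    qr_q, qr_r = np.linalg.qr(D)
    B = np.linalg.solve(qr_r, qr_q.T @ G)               # (1+p+K, L)
    resid = G - D @ B
    dof = n - D.shape[1]
    if dof <= 0:
        raise ValueError("not enough individuals for the design size")
    sigma2 = (resid ** 2).sum(axis=0) / dof             # per locus
    XtX_inv = np.linalg.inv(qr_r.T @ qr_r)
    se = np.sqrt(np.outer(np.diag(XtX_inv)[1:1 + p], sigma2))  # (p, L)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = (B[1:1 + p] / se).T                          # (L, p)
    z = np.nan_to_num(z)
    p_raw = stats.chi2.sf(z ** 2, 1)
    gif = np.median(z ** 2, axis=0) / CHI2_MEDIAN
    gif = np.maximum(gif, 1e-12)
    p_cal = stats.chi2.sf(z ** 2 / gif[None, :], 1)
    qvals = np.column_stack([
        multipletests(p_cal[:, j], method="fdr_bh")[1] for j in range(p)
    ])
    cand = (qvals <= fdr).any(axis=1)
    return LfmmResult(list(var_names), z, p_raw, gif, p_cal, qvals, K, fdr, cand)


# ---------------------------------------------------------------------------
# Redundancy analysis

@dataclass
class RDAModel:
    var_names: list[str]
    env_mean: np.ndarray
    env_sd: np.ndarray
    coef: np.ndarray            # (p, n_axes): standardized-env -> axis scores
    eigenvalues: np.ndarray
    inertia_fractions: np.ndarray
    site_scores: np.ndarray     # (n, n_axes)
    snp_scores: np.ndarray      # (L, n_axes)
    retained_axes: int = 3
    locus_ids: list[str] | None = None

    def axis_scores(self, env_values: np.ndarray) -> np.ndarray:
        """Canonical-axis scores for raw environment rows."""
        z = (np.asarray(env_values, float) - self.env_mean) / self.env_sd
        return z @ self.coef


def rda_fit(g_imputed: np.ndarray, env: np.ndarray, var_names=None,
            retained_axes: int = 3, locus_ids=None) -> RDAModel:
    """Redundancy analysis of centered genotypes on standardized climate.

    Fitted values of the multivariate regression Y ~ X are
    eigen-decomposed; eigenvalues partition the constrained inertia,
    site scores are the projections of individuals on the canonical axes
    and SNP scores the corresponding genotype loadings.  Each axis is
    oriented so its largest-|coefficient| predictor is positive.
    """
    G = np.asarray(g_imputed, float)
    X = np.asarray(env, float)
    n, L = G.shape
    p = X.shape[1]
    if var_names is None:
        var_names = [f"env{j + 1}" for j in range(p)]
    if n <= p:
        raise ValueError("need more individuals than environmental variables")
    mu, sd = X.mean(axis=0), X.std(axis=0)
    if (sd == 0).any():
        bad = [var_names[j] for j in np.nonzero(sd == 0)[0]]
        raise ValueError(f"constant environmental variable(s): {bad}")
    Xs = (X - mu) / sd
    if np.linalg.matrix_rank(Xs) < p:
        r2 = []
        for j in range(p):
            others = np.delete(Xs, j, axis=1)
            bj = np.linalg.lstsq(others, Xs[:, j], rcond=None)[0]
            res = Xs[:, j] - others @ bj
            r2.append(1 - res.var() / Xs[:, j].var())
        bad = [var_names[j] for j in range(p) if r2[j] > 1 - 1e-8]
        raise ValueError(f"collinear environmental variables: {bad}")
    Gc = G - G.mean(axis=0)
    B = np.linalg.lstsq(Xs, Gc, rcond=None)[0]          # (p, L)
    Yhat = Xs @ B
    u, s, vt = np.linalg.svd(Yhat, full_matrices=False)
    eig = s ** 2 / (n - 1)
    pos = eig > max(eig.max(), 1e-300) * 1e-12
    n_axes = min(int(pos.sum()), p)
    u, s, v = u[:, :n_axes], s[:n_axes], vt[:n_axes].T
    coef = B @ v                                        # (p, n_axes)
    for k in range(n_axes):
        j = np.argmax(np.abs(coef[:, k]))
        if coef[j, k] < 0:
            coef[:, k] = -coef[:, k]
            v[:, k] = -v[:, k]
            u[:, k] = -u[:, k]
    eig = eig[:n_axes]
    site = u * s                                        # = Xs @ coef
    snp = v * np.sqrt(eig)[None, :]
    return RDAModel(list(var_names), mu, sd, coef, eig, eig / eig.sum(),
                    site, snp, retained_axes=min(retained_axes, n_axes),
                    locus_ids=list(locus_ids) if locus_ids is not None else None)


def rda_outliers(model: RDAModel, g_imputed=None, env=None, axes: int | None = None,
                 sd_cutoff: float = 2.5):
    """Loci with |standardized loading| > cutoff on any retained axis.

    Returns (candidate boolean array, best_variable index array) where the
    best variable (computed when genotypes and environment are supplied)
    is the one with maximal |Pearson r| to the locus dosage; -1 elsewhere.
    """
    axes = axes or model.retained_axes
    if axes > model.snp_scores.shape[1]:
        raise ValueError("more axes requested than available")
    sc = model.snp_scores[:, :axes]
    sd = sc.std(axis=0)
    zs = (sc - sc.mean(axis=0)) / np.where(sd == 0, 1.0, sd)
    cand = (np.abs(zs) > sd_cutoff).any(axis=1)
    L = sc.shape[0]
    best = np.full(L, -1)
    if g_imputed is not None and env is not None and cand.any():
        G = np.asarray(g_imputed, float)
        X = np.asarray(env, float)
        Gz = (G - G.mean(axis=0)) / np.where(G.std(axis=0) == 0, 1, G.std(axis=0))
        Xz = (X - X.mean(axis=0)) / X.std(axis=0)
        corr = np.abs(Gz.T @ Xz) / G.shape[0]           # (L, p)
        best[cand] = np.argmax(corr[cand], axis=1)
    return cand, best


# ---------------------------------------------------------------------------
# Intersection

@dataclass
class CandidateSet:
    locus_ids: list[str]
    lfmm: set = field(default_factory=set)
    rda: set = field(default_factory=set)
    best_variable: dict = field(default_factory=dict)   # locus id -> var name

    @property
    def joint(self) -> set:
        return self.lfmm & self.rda

    def per_variable_counts(self, var_names) -> dict:
        counts = {v: 0 for v in var_names}
        for loc in sorted(self.joint):
            v = self.best_variable.get(loc)
            if v in counts:
                counts[v] += 1
        return counts


def intersect_candidates(lfmm: LfmmResult, rda_cand: np.ndarray,
                         locus_ids, rda_best=None) -> CandidateSet:
    """Joint candidates: loci flagged by both detectors."""
    locus_ids = list(locus_ids)
    if len(locus_ids) != len(lfmm.candidates) or len(locus_ids) != len(rda_cand):
        raise ValueError("detectors must share one locus universe")
    cs = CandidateSet(locus_ids)
    cs.lfmm = {locus_ids[i] for i in np.nonzero(lfmm.candidates)[0]}
    cs.rda = {locus_ids[i] for i in np.nonzero(np.asarray(rda_cand, bool))[0]}
    if rda_best is not None:
        for i in np.nonzero(np.asarray(rda_cand, bool))[0]:
            if rda_best[i] >= 0:
                cs.best_variable[locus_ids[i]] = lfmm.var_names[rda_best[i]]
    return cs
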