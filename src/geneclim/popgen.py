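"""Neutral population structure: PCA, admixture factorization, IBD.

The admixture estimator factorizes the scaled dosage matrix G/2 into
ancestry proportions Q (rows on the probability simplex) and ancestral
allele frequencies F in [0, 1], minimizing the squared reconstruction
error over observed entries by alternating projected-gradient blocks
(steps of 1/L with L the block Lipschitz constant, so the loss is
guaranteed nonincreasing).  K is selected by masked-entry cross-entropy:
a seeded fraction of genotypes is held out per replicate and scored under
Binomial(2, [QF]) after fitting.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .geo_io import MISSING, GenotypeMatrix

__all__ = ["AdmixtureFit", "pca_genotypes", "snmf_admixture",
           "shared_allele_distance", "mantel_test"]


def _mean_impute(g: GenotypeMatrix) -> np.ndarray:
    x = g.as_float()
    mu = np.nanmean(x, axis=0)
    if np.isnan(mu).any():
        bad = [g.locus_ids[i] for i in np.nonzero(np.isnan(mu))[0][:5]]
        raise ValueError(f"all-missing locus (pre-filter the matrix): {bad}")
    idx = np.nonzero(np.isnan(x))
    x[idx] = mu[idx[1]]
    return x


def pca_genotypes(g: GenotypeMatrix):
    """Genotype PCA after per-locus mean imputation and centering.

    Returns (scores, explained_variance_fractions); components are ordered
    by decreasing eigenvalue.
    """
    if g.n_ind < 2 or g.n_loci < 2:
        raise ValueError("need at least 2 individuals and 2 loci")
    x = _mean_impute(g)
    xc = x - x.mean(axis=0)
    u, s, _ = np.linalg.svd(xc, full_matrices=False)
    # fix sign: largest-|loading| coordinate positive, for reproducibility
    for k in range(u.shape[1]):
        j = np.argmax(np.abs(u[:, k]))
        if u[j, k] < 0:
            u[:, k] = -u[:, k]
    scores = u * s
    ev = s ** 2
    return scores, ev / ev.sum()


# ---------------------------------------------------------------------------
# Admixture (sNMF-style matrix factorization)

@dataclass
class AdmixtureFit:
    K: int
    Q: np.ndarray                       # (n, K), rows on the simplex
    F: np.ndarray                       # (K, L) in [0, 1]
    cross_entropy: list = field(default_factory=list)  # per replicate
    best_replicate: int = 0
    converged: bool = True
    loss_path: np.ndarray | None = None

    @property
    def labels(self) -> np.ndarray:
        """Hard cluster assignment: argmax ancestry per individual."""
        return np.argmax(self.Q, axis=1)


def _project_simplex(v: np.ndarray) -> np.ndarray:
    """Euclidean projection of each row onto the probability simplex."""
    n, k = v.shape
    u = -np.sort(-v, axis=1)
    css = np.cumsum(u, axis=1) - 1.0
    ind = np.arange(1, k + 1)
    cond = u - css / ind > 0
    rho = k - np.argmax(cond[:, ::-1], axis=1) - 1
    theta = css[np.arange(n), rho] / (rho + 1)
    return np.maximum(v - theta[:, None], 0.0)


def _fit_qf(M, W, K, rng, max_sweeps=500, tol=1e-6, inner=2):
    """Weighted NMF with simplex rows (Q) and box [0,1] entries (F)."""
    n, L = M.shape
    Q = rng.dirichlet(np.ones(K), size=n)
    F = np.clip(np.nansum(W * M, axis=0) / np.maximum(W.sum(axis=0), 1), 0.01, 0.99)
    F = np.clip(F[None, :] + 0.1 * rng.standard_normal((K, L)), 0.0, 1.0)

    def loss():
        r = W * (Q @ F - M)
        return 0.5 * float((r * r).sum())

    prev = loss()
    path = [prev]
    converged = False
    for _ in range(max_sweeps):
        lipQ = np.linalg.norm(Q.T @ Q, 2) + 1e-12
        for _ in range(inner):
            F = np.clip(F - (Q.T @ (W * (Q @ F - M))) / lipQ, 0.0, 1.0)
        lipF = np.linalg.norm(F @ F.T, 2) + 1e-12
        for _ in range(inner):
            Q = _project_simplex(Q - ((W * (Q @ F - M)) @ F.T) / lipF)
        cur = loss()
        path.append(cur)
        if prev - cur <= tol * max(prev, 1e-12):
            converged = True
            break
        prev = cur
    return Q, F, np.array(path), converged


def _cross_entropy(g_obs: np.ndarray, P: np.ndarray, where: np.ndarray) -> float:
    """Masked-entry negative mean log Binomial(2, P) likelihood of dosages."""
    p = np.clip(P, 1e-6, 1 - 1e-6)
    gsel = g_obs[where]
    psel = p[where]
    logc = np.where(gsel == 1, np.log(2.0), 0.0)
    ll = logc + gsel * np.log(psel) + (2 - gsel) * np.log1p(-psel)
    return float(-np.mean(ll))


def snmf_admixture(g: GenotypeMatrix, K_range=range(1, 16), replicates: int = 10,
                   mask_fraction: float = 0.05, seed: int = 0,
                   max_sweeps: int = 500):
    """Admixture inference over a K grid with cross-entropy model choice.

    For each K and replicate a seeded random ``mask_fraction`` of the
    observed genotype entries is held out, Q and F are fitted on the rest,
    and the held-out entries are scored by binomial cross-entropy.  The
    best K minimizes the mean cross-entropy across replicates; within a K
    the reported fit is the replicate with the lowest cross-entropy.

    Returns (dict K -> AdmixtureFit, best_K).
    """
    gobs = g.as_float()
    observed = ~np.isnan(gobs)
    M = np.where(observed, gobs / 2.0, 0.0)
    n, L = M.shape
    ss = np.random.SeedSequence(seed)
    fits: dict[int, AdmixtureFit] = {}
    for K in K_range:
        if K < 1:
            raise ValueError("K must be positive")
        ces, results = [], []
        for rep, child in enumerate(ss.spawn(replicates)):
            rng = np.random.default_rng(child)
            holdout = observed & (rng.random((n, L)) < mask_fraction)
            W = (observed & ~holdout).astype(float)
            if K == 1:
                Q = np.ones((n, 1))
                denom = np.maximum(W.sum(axis=0), 1.0)
                F = ((W * M).sum(axis=0) / denom)[None, :]
                path, conv = np.zeros(1), True
            else:
                Q, F, path, conv = _fit_qf(M, W, K, rng, max_sweeps=max_sweeps)
            ce = (_cross_entropy(gobs, Q @ F, holdout) if holdout.any()
                  else _cross_entropy(gobs, Q @ F, observed))
            ces.append(ce)
            results.append((Q, F, path, conv))
        best = int(np.argmin(ces))
        Q, F, path, conv = results[best]
        fits[K] = AdmixtureFit(K=K, Q=Q, F=np.clip(F, 0, 1), cross_entropy=ces,
                               best_replicate=best, converged=conv,
                               loss_path=path)
    best_K = min(fits, key=lambda k: float(np.mean(fits[k].cross_entropy)))
    return fits, best_K


# ---------------------------------------------------------------------------
# Distances and IBD

def shared_allele_distance(g: GenotypeMatrix, literal_inverse: bool = False) -> np.ndarray:
    """Pairwise allele-sharing dissimilarity.

    The per-locus shared-allele proportion for dosages (a, b) is
    1 - |a - b| / 2 (identical homozygotes 1, het vs. hom 0.5, opposite
    homozygotes 0); ps averages it over loci where both individuals are
    genotyped.  Default D = 1 - ps (bounded, zero diagonal);
    ``literal_inverse`` returns 1 / ps instead.
    """
    x = g.as_float()
    n = g.n_ind
    D = np.zeros((n, n))
    obs = ~np.isnan(x)
    for i in range(n):
        for j in range(i + 1, n):
            both = obs[i] & obs[j]
            if not both.any():
                raise ValueError(
                    f"no overlapping loci for pair ({g.ind_ids[i]}, {g.ind_ids[j]})")
            ps = float(np.mean(1.0 - np.abs(x[i, both] - x[j, both]) / 2.0))
            D[i, j] = D[j, i] = (1.0 / ps if literal_inverse else 1.0 - ps)
    np.fill_diagonal(D, 0.0)
    return D


def geographic_distance(coords: np.ndarray) -> np.ndarray:
    """Euclidean distance matrix between projected coordinates (m)."""
    from scipy.spatial.distance import squareform, pdist
    return squareform(pdist(np.asarray(coords, float)))


def mantel_test(D: np.ndarray, G: np.ndarray, n_perm: int = 999, seed: int = 0,
                alternative: str = "greater"):
    """Mantel correlation between two distance matrices with permutation p.

    r is the Pearson correlation of the upper off-diagonal triangles; the
    p-value permutes rows/columns of one matrix jointly,
    p = (1 + #{r_perm >= r_obs}) / (n_perm + 1) for the one-sided
    (positive-association) test.
    """
    D = np.asarray(D, float)
    G = np.asarray(G, float)
    if D.shape != G.shape or D.shape[0] != D.shape[1]:
        raise ValueError("matrices must be square and matching")
    if not (np.allclose(D, D.T) and np.allclose(G, G.T)):
        raise ValueError("matrices must be symmetric")
    n = D.shape[0]
    iu = np.triu_indices(n, k=1)
    d, gvec = D[iu], G[iu]
    if d.std() == 0 or gvec.std() == 0:
        raise ValueError("constant distance matrix")
    r_obs = float(np.corrcoef(d, gvec)[0, 1])
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        dp = D[np.ix_(perm, perm)][iu]
        r = np.corrcoef(dp, gvec)[0, 1]
        if alternative == "greater":
            count += r >= r_obs
        elif alternative == "two-sided":
            count += abs(r) >= abs(r_obs)
        else:
            raise ValueError("alternative must be 'greater' or 'two-sided'")
    p = (1 + count) / (n_perm + 1)
    return r_obs, float(p)
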