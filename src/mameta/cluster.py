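"""Mechanistic clustering of index SNVs on cardiometabolic z-score profiles.

Index-SNV effects on a battery of cardiometabolic phenotypes are placed on a
common scale as sample-size-corrected z-scores, Z_ij = beta_ij/(sqrt(N_i)
s_ij), aligned to the T2D risk allele.  Hard k-means clustering with
iterative imputation of missing z-scores partitions the SNVs into
mechanistic clusters; the number of clusters is chosen by majority vote
across a battery of cluster-validity indices.  Downstream summaries include
cluster-phenotype association profiles ("temperatures"), per-SNV centroid
distances, a disparity PCA, and cluster-level tests on T2D effect sizes and
ancestry-axis z-scores.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import pdist, squareform
from sklearn.metrics import (
    calinski_harabasz_score,
    davies_bouldin_score,
    silhouette_score,
)

from .simulate import ZScoreMatrix

logger = logging.getLogger(__name__)

DEFAULT_INDICES = (
    "calinski_harabasz", "silhouette", "davies_bouldin", "dunn",
    "c_index", "gap", "hartigan", "krzanowski_lai",
)


@dataclass
class ClusterModel:
    """Hard k-means partition with the fully imputed z-score matrix."""

    k: int
    labels: np.ndarray        # (n_snvs,) int cluster ids 0..k-1
    centroids: np.ndarray     # (k, n_phenotypes)
    imputed: np.ndarray       # (n_snvs, n_phenotypes), no NaN
    snv_ids: list[str]
    phenotypes: list[str]
    inertia: float

    def assignment_matrix(self) -> np.ndarray:
        C = np.zeros((len(self.labels), self.k))
        C[np.arange(len(self.labels)), self.labels] = 1.0
        return C

    def sizes(self) -> np.ndarray:
        return np.bincount(self.labels, minlength=self.k)


@dataclass
class ClusterPhenotypeProfile:
    """Per-(cluster, phenotype) regression coefficients and temperatures."""

    gamma: np.ndarray         # (k, n_phenotypes)
    se: np.ndarray
    p: np.ndarray
    temperature: np.ndarray   # sign(gamma) * -log10(p)
    phenotypes: list[str]


# ---------------------------------------------------------------------------
# z-score construction

def compute_zscores(
    trait_stats: pd.DataFrame,
    risk_alleles: pd.DataFrame,
    sample_sizes: dict[str, float],
) -> ZScoreMatrix:
    """Sample-size-corrected z-scores aligned to the T2D risk allele.

    ``trait_stats`` is long-format with columns SNV, PHENOTYPE, EA, NEA,
    BETA, SE; ``risk_alleles`` has columns SNV, RISK, OTHER.  Z_ij =
    beta_ij/(sqrt(N_i) s_ij), sign-flipped when the trait effect allele is
    the non-risk allele; pairs with no reported estimate, or whose alleles
    match neither risk nor other allele, are set missing.
    """
    risk = risk_alleles.set_index("SNV")
    snvs = list(risk.index)
    phen = sorted(trait_stats["PHENOTYPE"].unique())
    N = np.array([float(sample_sizes[p]) for p in phen])
    if np.any(N <= 0):
        raise ValueError("sample sizes must be positive")
    Z = np.full((len(snvs), len(phen)), np.nan)
    row = {s: i for i, s in enumerate(snvs)}
    col = {p: i for i, p in enumerate(phen)}
    for rec in trait_stats.itertuples(index=False):
        if rec.SNV not in row:
            continue
        i, j = row[rec.SNV], col[rec.PHENOTYPE]
        se = float(rec.SE)
        if se <= 0:
            raise ValueError(f"non-positive SE for {rec.SNV}/{rec.PHENOTYPE}")
        z = float(rec.BETA) / (np.sqrt(N[j]) * se)
        ra, oa = str(risk.loc[rec.SNV, "RISK"]), str(risk.loc[rec.SNV, "OTHER"])
        if str(rec.EA) == ra:
            Z[i, j] = z
        elif str(rec.EA) == oa:
            Z[i, j] = -z
        else:
            logger.warning("SNV %s/%s: trait alleles do not match risk allele; "
                           "z-score set missing", rec.SNV, rec.PHENOTYPE)
    mask = np.isnan(Z)
    return ZScoreMatrix(Z, mask, snvs, phen, N)


# ---------------------------------------------------------------------------
# k-means with iterative imputation

def _kmeanspp_init(X: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
    """k-means++ seeding (D^2 sampling)."""
    n = X.shape[0]
    centroids = np.empty((k, X.shape[1]))
    first = int(rng.integers(n))
    centroids[0] = X[first]
    d2 = ((X - centroids[0]) ** 2).sum(axis=1)
    for c in range(1, k):
        total = d2.sum()
        if total <= 0:
            centroids[c] = X[int(rng.integers(n))]
        else:
            centroids[c] = X[int(rng.choice(n, p=d2 / total))]
        d2 = np.minimum(d2, ((X - centroids[c]) ** 2).sum(axis=1))
    return centroids


def _lloyd(
    X: np.ndarray,
    centroids: np.ndarray,
    max_iter: int = 300,
    tol: float = 1e-10,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Lloyd's iterations to convergence from given centroids.

    Empty clusters are re-seeded at the point farthest from its centroid.
    """
    k = centroids.shape[0]
    centroids = centroids.copy()
    labels = np.zeros(X.shape[0], dtype=int)
    for _ in range(max_iter):
        d2 = ((X[:, None, :] - centroids[None, :, :]) ** 2).sum(axis=2)
        labels = d2.argmin(axis=1)
        new = centroids.copy()
        for c in range(k):
            members = X[labels == c]
            if len(members) == 0:
                far = int(d2[np.arange(len(labels)), labels].argmax())
                logger.info("empty cluster %d re-seeded at farthest point", c)
                new[c] = X[far]
                labels[far] = c
            else:
                new[c] = members.mean(axis=0)
        shift = float(((new - centroids) ** 2).sum())
        centroids = new
        if shift < tol:
            break
    d2 = ((X[:, None, :] - centroids[None, :, :]) ** 2).sum(axis=2)
    labels = d2.argmin(axis=1)
    inertia = float(d2[np.arange(len(labels)), labels].sum())
    return labels, centroids, inertia


def _best_lloyd(X: np.ndarray, k: int, rng: np.random.Generator,
                n_init: int = 10) -> tuple[np.ndarray, np.ndarray, float]:
    """Lloyd's k-means from ``n_init`` k-means++ seedings; best inertia wins."""
    best = None
    for _ in range(n_init):
        out = _lloyd(X, _kmeanspp_init(X, k, rng))
        if best is None or out[2] < best[2]:
            best = out
    return best


def plain_kmeans(X: np.ndarray, k: int, seed: int,
                 n_init: int = 10) -> tuple[np.ndarray, np.ndarray, float]:
    """k-means++ initialized Lloyd's k-means on a complete matrix."""
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0]))
    return _best_lloyd(X, k, rng, n_init=n_init)


def impute_kmeans(
    Z: ZScoreMatrix,
    k: int,
    n_iter: int = 10,
    n_end: int = 8,
    seed: int = 0,
) -> ClusterModel:
    """Hard k-means clustering with iterative imputation of missing z-scores.

    Iteration 1 fills each missing cell with a random draw from the
    phenotype's observed marginal distribution and runs k-means.  Later
    iterations redraw missing cells from the observed values of the cell's
    phenotype *within the current cluster* (falling back to the marginal
    when the cluster has none), so between-phenotype correlation enters
    through the cluster conditioning.  Imputed entries are down-weighted
    early on — multiplied by min(1, i/n_end), a penalty decaying to zero by
    iteration ``n_end`` — and the final model carries no penalty.

    With no missing entries the procedure reduces exactly to
    :func:`plain_kmeans` under the same seed.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    X_obs = np.asarray(Z.values, float)
    n, p = X_obs.shape
    if k > n:
        raise ValueError(f"k={k} exceeds number of SNVs {n}")
    if n_end > n_iter:
        raise ValueError("n_end must be <= n_iter")
    mask = np.asarray(Z.mask, bool)
    rng_init = np.random.default_rng(np.random.SeedSequence([seed, 0]))
    rng_imp = np.random.default_rng(np.random.SeedSequence([seed, 1]))

    if not mask.any():
        labels, centroids, inertia = _best_lloyd(X_obs, k, rng_init)
        return ClusterModel(k, labels, centroids, X_obs.copy(), Z.snv_ids,
                            Z.phenotypes, inertia)

    col_obs = [X_obs[~mask[:, j], j] for j in range(p)]
    for j, v in enumerate(col_obs):
        if v.size == 0:
            raise ValueError(f"phenotype column {j} has no observed values")

    X_imp = X_obs.copy()
    labels = None
    centroids = None
    for j in range(p):
        miss = mask[:, j]
        if miss.any():
            X_imp[miss, j] = rng_imp.choice(col_obs[j], size=int(miss.sum()))
    for it in range(1, n_iter + 1):
        if it > 1:
            for c in range(k):
                in_c = labels == c
                for j in range(p):
                    miss = mask[:, j] & in_c
                    if not miss.any():
                        continue
                    pool = X_obs[in_c & ~mask[:, j], j]
                    if pool.size == 0:
                        pool = col_obs[j]
                    X_imp[miss, j] = rng_imp.choice(pool, size=int(miss.sum()))
        weight = min(1.0, it / n_end)
        X_eff = X_imp.copy()
        X_eff[mask] *= weight
        # fresh multi-start seeding every iteration: imputations change the
        # geometry, and warm-starting would lock in early local optima
        labels, centroids, inertia = _best_lloyd(X_eff, k, rng_init)
    # final pass: penalty zero, centroids = member means of the imputed matrix
    labels, centroids, inertia = _lloyd(X_imp, centroids)
    return ClusterModel(k, labels, centroids, X_imp, Z.snv_ids, Z.phenotypes,
                        inertia)


# ---------------------------------------------------------------------------
# optimal-k selection

def _dunn_index(X: np.ndarray, labels: np.ndarray) -> float:
    D = squareform(pdist(X))
    ks = np.unique(labels)
    inter = np.inf
    intra = 0.0
    for a in ks:
        ia = labels == a
        da = D[np.ix_(ia, ia)]
        if da.size > 1:
            intra = max(intra, da.max())
        for b in ks:
            if b <= a:
                continue
            inter = min(inter, D[np.ix_(ia, labels == b)].min())
    return inter / intra if intra > 0 else np.inf


def _c_index(X: np.ndarray, labels: np.ndarray) -> float:
    d = pdist(X)
    D = squareform(d)
    within = []
    for c in np.unique(labels):
        ic = np.where(labels == c)[0]
        for a in range(len(ic)):
            for b in range(a + 1, len(ic)):
                within.append(D[ic[a], ic[b]])
    ell = len(within)
    if ell == 0:
        return np.nan
    s = float(np.sum(within))
    ds = np.sort(d)
    smin = float(ds[:ell].sum())
    smax = float(ds[-ell:].sum())
    return (s - smin) / (smax - smin) if smax > smin else 0.0


def _within_ss(X: np.ndarray, k: int, seed: int) -> float:
    if k == 1:
        return float(((X - X.mean(axis=0)) ** 2).sum())
    _, _, inertia = plain_kmeans(X, k, seed)
    return inertia


def select_k(
    Z: ZScoreMatrix,
    k_range: range | list[int],
    seed: int = 0,
    n_iter: int = 10,
    n_end: int = 8,
    indices: tuple[str, ...] = DEFAULT_INDICES,
    gap_b: int = 10,
) -> tuple[int, dict[str, int]]:
    """Optimal cluster count by majority rule over validity indices.

    Runs :func:`impute_kmeans` at every k in ``k_range`` and lets each
    index vote by its native rule (maxima for Calinski-Harabasz,
    silhouette, Dunn; minima for Davies-Bouldin and C-index; the Tibshirani
    one-standard-error rule for the gap statistic; the <=10 rule for
    Hartigan; the maximum-ratio rule for Krzanowski-Lai).  Returns the
    modal k (ties to the smaller) and the per-index votes.
    """
    ks = sorted(k_range)
    if not ks:
        raise ValueError("empty k_range")
    models = {k: impute_kmeans(Z, k, n_iter=n_iter, n_end=n_end, seed=seed)
              for k in ks}
    if len(ks) == 1:
        return ks[0], {name: ks[0] for name in indices}

    # W_k on each model's own imputed matrix; extended range for difference rules
    X_ref = models[ks[-1]].imputed
    p = X_ref.shape[1]
    W: dict[int, float] = {k: models[k].inertia for k in ks}
    for k in (ks[0] - 1, ks[-1] + 1):
        if 1 <= k <= X_ref.shape[0]:
            W[k] = _within_ss(X_ref, k, seed)

    votes: dict[str, int] = {}
    score_of = {
        "calinski_harabasz": (calinski_harabasz_score, max),
        "silhouette": (silhouette_score, max),
        "davies_bouldin": (davies_bouldin_score, min),
        "dunn": (_dunn_index, max),
        "c_index": (_c_index, min),
    }
    for name in indices:
        if name in score_of:
            fn, best = score_of[name]
            vals = {}
            for k in ks:
                m = models[k]
                if len(np.unique(m.labels)) < 2:
                    continue
                vals[k] = fn(m.imputed, m.labels)
            if vals:
                target = best(vals.values())
                votes[name] = min(k for k, v in vals.items() if v == target)
        elif name == "gap":
            votes[name] = _gap_vote(models, ks, seed, gap_b)
        elif name == "hartigan":
            votes[name] = _hartigan_vote(W, ks, X_ref.shape[0])
        elif name == "krzanowski_lai":
            votes[name] = _kl_vote(W, ks, p)
        else:
            raise ValueError(f"unknown validity index {name!r}")

    counts: dict[int, int] = {}
    for v in votes.values():
        counts[v] = counts.get(v, 0) + 1
    top = max(counts.values())
    best_k = min(k for k, c in counts.items() if c == top)
    return best_k, votes


def _gap_vote(models: dict, ks: list[int], seed: int, B: int) -> int:
    rng = np.random.default_rng(np.random.SeedSequence([seed, 2]))
    X = models[ks[-1]].imputed
    lo, hi = X.min(axis=0), X.max(axis=0)
    gaps, sks = {}, {}
    all_k = ks + [ks[-1] + 1]
    logW = {}
    for k in all_k:
        logW[k] = np.log(models[k].inertia if k in models
                         else _within_ss(X, k, seed))
    for k in all_k:
        ref = np.empty(B)
        for b in range(B):
            Xb = rng.uniform(lo, hi, size=X.shape)
            ref[b] = np.log(_within_ss(Xb, k, seed))
        gaps[k] = ref.mean() - logW[k]
        sks[k] = ref.std(ddof=1) * np.sqrt(1 + 1.0 / B)
    for k in ks:
        if gaps[k] >= gaps[k + 1] - sks[k + 1]:
            return k
    return max(gaps, key=lambda k: gaps[k] if k in ks else -np.inf)


def _hartigan_vote(W: dict[int, float], ks: list[int], n: int) -> int:
    H = {}
    for k in ks:
        if k + 1 in W and W[k + 1] > 0:
            H[k] = (W[k] / W[k + 1] - 1.0) * (n - k - 1)
    for k in sorted(H):
        if H[k] <= 10:
            return k
    return min(H, key=H.get) if H else ks[0]


def _kl_vote(W: dict[int, float], ks: list[int], p: int) -> int:
    def diff(k):
        if k - 1 not in W or k not in W:
            return None
        return (k - 1) ** (2 / p) * W[k - 1] - k ** (2 / p) * W[k]

    kl = {}
    for k in ks:
        d1, d2 = diff(k), diff(k + 1)
        if d1 is None or d2 is None or abs(d2) < 1e-300:
            continue
        kl[k] = abs(d1 / d2)
    return max(kl, key=kl.get) if kl else ks[0]


# ---------------------------------------------------------------------------
# cluster summaries

def cluster_phenotype_association(model: ClusterModel) -> ClusterPhenotypeProfile:
    """Per-phenotype regression of imputed z-scores on cluster indicators.

    The no-intercept indicator regression makes gamma_ik exactly the
    within-cluster mean of the imputed z-score; P values come from the
    coefficient t-test (missing for clusters of fewer than two members).
    Temperature = sign(gamma) * (-log10 P).
    """
    X = model.imputed
    n, p = X.shape
    k = model.k
    sizes = model.sizes()
    gamma = np.zeros((k, p))
    se = np.full((k, p), np.nan)
    pv = np.full((k, p), np.nan)
    df = n - k
    for c in range(k):
        members = X[model.labels == c]
        if len(members):
            gamma[c] = members.mean(axis=0)
    for j in range(p):
        resid = X[:, j] - gamma[model.labels, j]
        sigma2 = float(resid @ resid) / df if df > 0 else np.nan
        for c in range(k):
            if sizes[c] >= 2 and df > 0:
                se[c, j] = np.sqrt(sigma2 / sizes[c])
                tstat = gamma[c, j] / se[c, j] if se[c, j] > 0 else np.inf
                pv[c, j] = 2 * stats.t.sf(abs(tstat), df)
    with np.errstate(divide="ignore", invalid="ignore"):
        temp = np.sign(gamma) * (-np.log10(pv))
    temp[gamma == 0] = 0.0
    return ClusterPhenotypeProfile(gamma, se, pv, temp, model.phenotypes)


def centroid_distances(model: ClusterModel) -> np.ndarray:
    """Euclidean distance of each SNV's imputed profile to every centroid."""
    diff = model.imputed[:, None, :] - model.centroids[None, :, :]
    return np.sqrt((diff ** 2).sum(axis=2))


def disparity_pca(model: ClusterModel, n_components: int | None = None):
    """PCA of the column-centred imputed z-score matrix.

    Returns (scores, variance_explained_fractions).
    """
    X = model.imputed - model.imputed.mean(axis=0)
    U, s, Vt = np.linalg.svd(X, full_matrices=False)
    var = s ** 2
    frac = var / var.sum()
    scores = U * s
    if n_components is not None:
        scores = scores[:, :n_components]
        frac = frac[:n_components]
    return scores, frac


def cluster_t2d_effects(
    betas: np.ndarray,
    variances: np.ndarray,
    model: ClusterModel,
    reported_flags: np.ndarray | None = None,
) -> dict:
    """Inverse-variance-weighted cluster means of T2D effects + heterogeneity.

    Fits E(beta_j) = sum_k gamma_k C_jk with weights 1/var; the
    heterogeneity P compares that model's deviance with the grand-mean
    model E(beta_j) = gamma_0 (chi-square, k-1 df).  When
    ``reported_flags`` is given, a second contrast replaces the cluster
    indicators with the previously-reported / novel grouping.
    """
    betas = np.asarray(betas, float)
    w = 1.0 / np.asarray(variances, float)
    labels = model.labels
    k = model.k
    if len(np.unique(labels)) < 2:
        raise ValueError("heterogeneity undefined with a single cluster")
    gamma = np.zeros(k)
    gse = np.zeros(k)
    for c in range(k):
        ic = labels == c
        gamma[c] = float(w[ic] @ betas[ic] / w[ic].sum())
        gse[c] = float(1.0 / np.sqrt(w[ic].sum()))
    g0 = float(w @ betas / w.sum())
    rss0 = float(w @ (betas - g0) ** 2)
    rss1 = float(w @ (betas - gamma[labels]) ** 2)
    het = max(0.0, rss0 - rss1)
    out = {
        "gamma": gamma,
        "se": gse,
        "mean_or": np.exp(gamma),
        "het_stat": het,
        "het_df": k - 1,
        "het_p": float(stats.chi2.sf(het, k - 1)),
    }
    if reported_flags is not None:
        f = np.asarray(reported_flags, bool)
        if f.all() or (~f).all():
            out["contrast"] = None
        else:
            m1 = float(w[f] @ betas[f] / w[f].sum())
            m0 = float(w[~f] @ betas[~f] / w[~f].sum())
            se_d = float(np.sqrt(1.0 / w[f].sum() + 1.0 / w[~f].sum()))
            zd = (m1 - m0) / se_d
            out["contrast"] = {
                "mean_reported": m1, "mean_novel": m0,
                "difference": m1 - m0, "se": se_d,
                "p": float(2 * stats.norm.sf(abs(zd))),
            }
    return out


def cluster_axis_anova(axis_zscores: np.ndarray, model: ClusterModel) -> pd.DataFrame:
    """One-way ANOVA of per-SNV axis z-scores across clusters, per axis."""
    Zx = np.atleast_2d(np.asarray(axis_zscores, float))
    if Zx.shape[0] != len(model.labels):
        Zx = Zx.T
    if len(np.unique(model.labels)) < 2:
        raise ValueError("ANOVA requires at least 2 clusters")
    rows = []
    for t in range(Zx.shape[1]):
        groups = [Zx[model.labels == c, t] for c in range(model.k)
                  if (model.labels == c).sum() > 0]
        f, p = stats.f_oneway(*groups)
        rows.append({"axis": t + 1, "F": float(f), "P": float(p)})
    return pd.DataFrame(rows)
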