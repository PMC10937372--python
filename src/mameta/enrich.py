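"""Cell-type open-chromatin enrichment via Firth bias-reduced logistic regression.

Index SNVs (cases) are compared against nearby not-in-LD "null" SNVs
(controls) for overlap with cell-type ATAC-seq peaks, adjusting for genic
context (exon, 3'UTR, 5'UTR indicators):

    logit P(Y_j = 1) = a0 + a_EXON G_j + a_3UTR G_j + a_5UTR G_j + theta_i X_ij

where Y marks index vs null SNV and X_ij marks overlap with a peak of the
i-th cell type.  theta_i is the log fold enrichment.  Fits maximize the
Jeffreys-prior-penalized likelihood (Firth), which keeps estimates finite
under separation; the enrichment test is the penalized likelihood-ratio
statistic on 1 df.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .simulate import AnnotationSet

logger = logging.getLogger(__name__)

GENIC_CLASSES = ("exon", "utr3", "utr5")


@dataclass
class FirthFit:
    coefficients: np.ndarray
    ses: np.ndarray
    penalized_loglik: float
    converged: bool
    n_iter: int


@dataclass
class EnrichmentResult:
    cluster: str
    cell_type: str
    theta: float
    se: float
    lrt_stat: float
    p: float
    significant: bool
    genic_coefficients: np.ndarray
    n_index: int
    n_null: int


# ---------------------------------------------------------------------------
# null-SNV selection and annotation

def select_null_snvs(
    index_snv: str,
    candidates: pd.DataFrame,
    ld,
    window: int = 50_000,
    r2_max: float = 0.05,
    index_pos: int | None = None,
) -> list[str]:
    """Nearby SNVs not in LD with the index in ANY continental group.

    ``candidates`` has columns SNV, CHR, POS; a candidate qualifies when
    |pos - index pos| <= window and its r^2 with the index is <= r2_max in
    every group where r^2 is defined.
    """
    if index_pos is None:
        index_pos = int(candidates.set_index("SNV").loc[index_snv, "POS"])
    out: list[str] = []
    for rec in candidates.itertuples(index=False):
        if rec.SNV == index_snv:
            continue
        if abs(int(rec.POS) - index_pos) > window:
            continue
        per_group, _ = ld.r2(index_snv, rec.SNV)
        if any(r > r2_max for r in per_group.values() if np.isfinite(r)):
            continue
        out.append(str(rec.SNV))
    if not out:
        logger.info("no null SNVs found for index %s", index_snv)
    return out


class _IntervalLookup:
    """Membership queries against a union of 0-based half-open intervals."""

    def __init__(self, intervals: pd.DataFrame):
        self.by_chrom: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        if intervals is None or len(intervals) == 0:
            return
        for chrom, grp in intervals.groupby(intervals["chrom"].astype(str)):
            iv = grp[["start", "end"]].sort_values("start").to_numpy()
            merged = []
            for s, e in iv:
                if merged and s <= merged[-1][1]:
                    merged[-1][1] = max(merged[-1][1], e)
                else:
                    merged.append([s, e])
            m = np.array(merged)
            self.by_chrom[str(chrom)] = (m[:, 0], m[:, 1])

    def contains(self, chrom: str, pos_1based: int) -> bool:
        if chrom not in self.by_chrom:
            return False
        starts, ends = self.by_chrom[chrom]
        pos0 = pos_1based - 1  # 1-based SNV position -> 0-based coordinate
        i = np.searchsorted(starts, pos0, side="right") - 1
        return i >= 0 and pos0 < ends[i]


def annotate_snvs(snvs: pd.DataFrame, annotations: AnnotationSet) -> pd.DataFrame:
    """Binary overlap indicators per SNV for genic classes and cell types.

    ``snvs`` has columns SNV, CHR, POS (1-based); intervals are BED-style
    0-based half-open, so a SNV at 1-based position p overlaps [start, end)
    iff start <= p-1 < end.  Unknown chromosomes get indicator 0 with one
    logged warning per chromosome.
    """
    classes = {**annotations.genic, **annotations.peaks}
    lookups = {cls: _IntervalLookup(df) for cls, df in classes.items()}
    known_chroms = set()
    for lk in lookups.values():
        known_chroms |= set(lk.by_chrom)
    warned: set[str] = set()
    out = pd.DataFrame(index=snvs["SNV"].astype(str))
    chroms = snvs["CHR"].astype(str).to_numpy()
    poss = snvs["POS"].astype(int).to_numpy()
    for c in chroms:
        if c not in known_chroms and c not in warned:
            logger.warning("chromosome %s absent from annotations", c)
            warned.add(c)
    for cls, lk in lookups.items():
        out[cls] = [1 if lk.contains(c, p) else 0 for c, p in zip(chroms, poss)]
    return out


# ---------------------------------------------------------------------------
# Firth logistic regression

def _penalized_loglik(beta, X, y):
    eta = X @ beta
    # log-likelihood via logaddexp for numerical stability
    ll = float(y @ eta - np.logaddexp(0.0, eta).sum())
    p = 1.0 / (1.0 + np.exp(-eta))
    W = p * (1 - p)
    I = X.T @ (X * W[:, None])
    sign, logdet = np.linalg.slogdet(I)
    if sign <= 0:
        return -np.inf
    return ll + 0.5 * logdet


def firth_logistic(y: np.ndarray, X: np.ndarray, max_iter: int = 50,
                   tol: float = 1e-8,
                   fixed_zero: list[int] | None = None) -> FirthFit:
    """Firth bias-reduced logistic regression.

    Maximizes l(beta) + 0.5 log det I(beta) by Newton iterations with the
    hat-diagonal-adjusted score U*(beta) = X'(y - p + h(1/2 - p)); step
    halving enforces a non-decreasing penalized log-likelihood.  Estimates
    stay finite even under complete separation.

    ``fixed_zero`` freezes the listed coefficients at zero while keeping
    the full design's Jeffreys penalty — the constrained fit used by the
    penalized likelihood-ratio test, so that full and null fits carry a
    penalty of the same dimension.
    """
    y = np.asarray(y, float)
    X = np.asarray(X, float)
    n, m = X.shape
    if np.linalg.matrix_rank(X) < m:
        raise ValueError("design matrix is rank deficient")
    free = np.ones(m, dtype=bool)
    if fixed_zero:
        free[np.asarray(fixed_zero, int)] = False
    beta = np.zeros(m)
    pll = _penalized_loglik(beta, X, y)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        eta = X @ beta
        p = 1.0 / (1.0 + np.exp(-eta))
        W = p * (1 - p)
        XW = X * W[:, None]
        I = X.T @ XW
        I_inv = np.linalg.inv(I)
        # hat diagonal of the full weighted design (penalty gradient term)
        H = (X @ I_inv * XW).sum(axis=1)
        score = X.T @ (y - p + H * (0.5 - p))
        step = np.zeros(m)
        step[free] = np.linalg.solve(I[np.ix_(free, free)], score[free])
        new_beta = beta + step
        new_pll = _penalized_loglik(new_beta, X, y)
        halves = 0
        while new_pll < pll and halves < 30:
            step *= 0.5
            new_beta = beta + step
            new_pll = _penalized_loglik(new_beta, X, y)
            halves += 1
        delta = float(np.max(np.abs(new_beta - beta)))
        beta, pll = new_beta, new_pll
        if delta < tol:
            converged = True
            break
    if not converged:
        logger.warning("Firth fit did not converge in %d iterations", max_iter)
    eta = X @ beta
    p = 1.0 / (1.0 + np.exp(-eta))
    W = p * (1 - p)
    I_inv = np.linalg.inv(X.T @ (X * W[:, None]))
    ses = np.sqrt(np.diag(I_inv))
    return FirthFit(beta, ses, pll, converged, it)


# ---------------------------------------------------------------------------
# enrichment tests

def enrichment_test(
    indicators: pd.DataFrame,
    y: np.ndarray,
    cell_type: str,
    cluster: str = "",
    genic_classes: tuple[str, ...] = GENIC_CLASSES,
    alpha_threshold: float | None = None,
) -> EnrichmentResult:
    """Penalized likelihood-ratio test of cell-type peak enrichment.

    ``indicators`` holds the 0/1 overlap columns (from
    :func:`annotate_snvs`) for the pooled index + null SNVs; ``y`` is 1 for
    index SNVs, 0 for nulls.  The full model carries intercept + genic
    indicators + the cell-type indicator; the null fit constrains the
    cell-type coefficient to zero within the full model's penalty.
    Statistic = 2 (pll_full - pll_null), chi-square 1 df.
    """
    y = np.asarray(y, float)
    x_ct = indicators[cell_type].to_numpy(dtype=float)
    if x_ct.min() == x_ct.max():
        raise ValueError(f"cell-type indicator {cell_type!r} is constant; "
                         "enrichment undefined")
    genic_cols = [indicators[g].to_numpy(dtype=float) for g in genic_classes
                  if g in indicators and indicators[g].nunique() > 1]
    ones = np.ones_like(y)
    X_full = np.column_stack([ones] + genic_cols + [x_ct])
    fit_full = firth_logistic(y, X_full)
    fit_red = firth_logistic(y, X_full, fixed_zero=[X_full.shape[1] - 1])
    lrt = max(0.0, 2.0 * (fit_full.penalized_loglik - fit_red.penalized_loglik))
    p = float(stats.chi2.sf(lrt, 1))
    return EnrichmentResult(
        cluster=cluster,
        cell_type=cell_type,
        theta=float(fit_full.coefficients[-1]),
        se=float(fit_full.ses[-1]),
        lrt_stat=lrt,
        p=p,
        significant=bool(alpha_threshold is not None and p < alpha_threshold),
        genic_coefficients=fit_full.coefficients[1:-1],
        n_index=int(y.sum()),
        n_null=int((1 - y).sum()),
    )


def enrichment_scan(
    cluster_index_snvs: dict[str, pd.DataFrame],
    null_snvs: pd.DataFrame,
    annotations: AnnotationSet,
    cell_types: list[str] | None = None,
    alpha: float = 0.05,
    min_cluster_size: int = 5,
) -> pd.DataFrame:
    """Per-(cluster, cell type) enrichment with a Bonferroni family per scan.

    Clusters with fewer than ``min_cluster_size`` index SNVs are skipped
    (parameter estimates are unstable for tiny clusters) with a logged
    reason.  The significance threshold is alpha divided by the number of
    cell types scanned.
    """
    if cell_types is None:
        cell_types = sorted(annotations.peaks)
    threshold = alpha / len(cell_types)
    ann_null = annotate_snvs(null_snvs, annotations)
    rows = []
    for cluster, idx in sorted(cluster_index_snvs.items()):
        if len(idx) < min_cluster_size:
            logger.info("cluster %s skipped: only %d index SNVs (< %d)",
                        cluster, len(idx), min_cluster_size)
            continue
        ann_idx = annotate_snvs(idx, annotations)
        ind = pd.concat([ann_idx, ann_null])
        y = np.r_[np.ones(len(ann_idx)), np.zeros(len(ann_null))]
        for ct in cell_types:
            try:
                res = enrichment_test(ind, y, ct, cluster=cluster,
                                      alpha_threshold=threshold)
            except ValueError as exc:
                logger.info("cluster %s / %s skipped: %s", cluster, ct, exc)
                continue
            rows.append({
                "cluster": res.cluster, "cell_type": res.cell_type,
                "theta": res.theta, "se": res.se, "lrt": res.lrt_stat,
                "p": res.p, "significant": res.significant,
                "threshold": threshold,
                "n_index": res.n_index, "n_null": res.n_null,
            })
    return pd.DataFrame(rows)
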