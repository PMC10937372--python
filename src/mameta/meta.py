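"""Axes-of-ancestry meta-regression with heterogeneity decomposition.

The central model: for one SNV reported by K studies with allelic effects
b_k and standard errors s_k, fit the weighted linear regression

    b_k = beta0 + sum_t beta_t x_tk + e_k,   w_k = 1/s_k^2,

where x_tk are the studies' coordinates on T axes of genetic variation
(from classical multidimensional scaling of mean allele-frequency
distances).  Three chi-square statistics partition the evidence:

* association with the trait allowing ancestry-correlated heterogeneity:
  sum w b^2 - RSS(full), df = 1 + n_covariates;
* ancestry-correlated heterogeneity: RSS(baseline) - RSS(full), df = T,
  where the baseline holds intercept (+ any extra covariates such as
  study-level mean BMI) but not the axes;
* residual heterogeneity: RSS(full), df = K - 1 - n_covariates.

The first two statistics plus the third sum to Cochran's Q of the
intercept-only inverse-variance fit when no extra covariates are present.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .simulate import StudySummary

logger = logging.getLogger(__name__)

AMBIGUOUS_PAIRS = {("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")}
CHI2_1DF_MEDIAN = float(stats.chi2.ppf(0.5, 1))  # 0.4549...


class DegenerateAxesError(ValueError):
    """All pairwise study distances are zero; axes are undefined."""


@dataclass
class AxisCoordinates:
    """Per-study coordinates on the leading axes of genetic variation.

    ``coords`` are unit-norm eigenvectors of the double-centred squared
    distance matrix, ordered by decreasing eigenvalue and column-centred.
    ``embedding()`` gives sqrt-eigenvalue-scaled coordinates, which
    reproduce the pairwise distances in the least-squares sense.
    """

    study_ids: list[str]
    coords: np.ndarray       # (n_studies, n_axes)
    eigenvalues: np.ndarray  # (n_axes,)

    def __post_init__(self) -> None:
        if np.any(np.diff(self.eigenvalues) > 1e-9):
            raise ValueError("axes must be ordered by decreasing eigenvalue")

    def embedding(self) -> np.ndarray:
        return self.coords * np.sqrt(np.maximum(self.eigenvalues, 0.0))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.coords,
            index=self.study_ids,
            columns=[f"axis{t + 1}" for t in range(self.coords.shape[1])],
        )


@dataclass
class MetaResult:
    """Per-SNV meta-regression output with partitioned heterogeneity."""

    snv: str
    coefficients: np.ndarray
    coefficient_ses: np.ndarray
    assoc_stat: float
    assoc_df: int
    assoc_p: float
    ancestry_het_stat: float
    ancestry_het_df: int
    ancestry_het_p: float
    residual_het_stat: float
    residual_het_df: int
    residual_het_p: float
    n_studies: int
    n_axes: int = 0
    effect_allele: str = "A"

    def axis_slopes(self) -> np.ndarray:
        return self.coefficients[1:1 + self.n_axes]

    def axis_ses(self) -> np.ndarray:
        return self.coefficient_ses[1:1 + self.n_axes]


@dataclass
class FixedEffectsResult:
    """Inverse-variance-weighted pooled effect with Cochran's Q."""

    snv: str
    beta: float
    se: float
    z: float
    p: float
    q: float
    q_df: int
    q_p: float
    n_studies: int


# ---------------------------------------------------------------------------
# allele alignment

def is_strand_ambiguous(ea: str, nea: str) -> bool:
    return (ea.upper(), nea.upper()) in AMBIGUOUS_PAIRS


def align_to_reference(ea, nea, beta, eaf, ref_ea, ref_nea):
    """Flip a study record to the reference effect allele.

    Returns (beta, eaf) aligned, or None when alleles are inconsistent.
    """
    if ea == ref_ea and nea == ref_nea:
        return beta, eaf
    if ea == ref_nea and nea == ref_ea:
        return -beta, 1.0 - eaf
    return None


# ---------------------------------------------------------------------------
# axes of genetic variation

def study_distance_matrix(
    studies: list[StudySummary], metric: str = "mean_abs"
) -> tuple[np.ndarray, list[str]]:
    """Pairwise study distances from mean effect-allele-frequency differences.

    Only SNVs reported by every study contribute; alleles are aligned to the
    first study's effect allele first, and strand-ambiguous SNVs (A/T, C/G)
    are excluded.  ``metric`` is "mean_abs" (default) or "mean_sq".
    """
    shared = None
    for st in studies:
        ids = set(st.table["SNV"])
        shared = ids if shared is None else shared & ids
    if not shared:
        raise ValueError("no SNV reported in all studies")
    ref = studies[0].table.set_index("SNV")
    shared = sorted(shared)
    keep = [s for s in shared
            if not is_strand_ambiguous(str(ref.loc[s, "EA"]), str(ref.loc[s, "NEA"]))]
    dropped = len(shared) - len(keep)
    if dropped:
        logger.info("excluded %d strand-ambiguous SNVs from distance matrix", dropped)
    if not keep:
        raise ValueError("no strand-unambiguous SNV shared by all studies")
    eaf = np.empty((len(studies), len(keep)))
    for i, st in enumerate(studies):
        t = st.table.set_index("SNV").loc[keep]
        for j, s in enumerate(keep):
            aligned = align_to_reference(
                str(t.loc[s, "EA"]), str(t.loc[s, "NEA"]),
                float(t.loc[s, "BETA"]), float(t.loc[s, "EAF"]),
                str(ref.loc[s, "EA"]), str(ref.loc[s, "NEA"]),
            )
            if aligned is None:
                raise ValueError(f"inconsistent alleles for SNV {s} in {st.study_id}")
            eaf[i, j] = aligned[1]
    diff = np.abs(eaf[:, None, :] - eaf[None, :, :])
    if metric == "mean_abs":
        D = diff.mean(axis=2)
    elif metric == "mean_sq":
        D = (diff ** 2).mean(axis=2)
    else:
        raise ValueError(f"unknown metric {metric!r}")
    return D, [st.study_id for st in studies]


def classical_mds(D: np.ndarray, n_axes: int) -> tuple[np.ndarray, np.ndarray]:
    """Principal-coordinates analysis of a distance matrix.

    Double-centres the squared distances, eigendecomposes, and returns the
    top ``n_axes`` unit-norm eigenvectors and their eigenvalues.
    """
    n = D.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D ** 2) @ J
    evals, evecs = np.linalg.eigh(B)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    # deterministic sign: largest-magnitude entry positive
    for t in range(evecs.shape[1]):
        j = np.argmax(np.abs(evecs[:, t]))
        if evecs[j, t] < 0:
            evecs[:, t] = -evecs[:, t]
    return evecs[:, :n_axes], evals[:n_axes]


def compute_axes(
    studies: list[StudySummary], n_axes: int = 3, metric: str = "mean_abs"
) -> AxisCoordinates:
    """Axes of genetic variation from allele-frequency distances via MDS."""
    if len(studies) < n_axes + 2:
        raise ValueError(
            f"need at least {n_axes + 2} studies for {n_axes} axes, got {len(studies)}"
        )
    D, ids = study_distance_matrix(studies, metric=metric)
    if np.allclose(D, 0):
        raise DegenerateAxesError("all pairwise study distances are zero")
    coords, evals = classical_mds(D, n_axes)
    coords = coords - coords.mean(axis=0)
    return AxisCoordinates(ids, coords, evals)


# ---------------------------------------------------------------------------
# per-SNV meta-regression

def _wls(X: np.ndarray, y: np.ndarray, w: np.ndarray):
    """Weighted least squares; returns (beta_hat, ses, rss, XtWX_inv)."""
    Xw = X * w[:, None]
    XtWX = X.T @ Xw
    try:
        XtWX_inv = np.linalg.inv(XtWX)
    except np.linalg.LinAlgError:
        return None
    cond = np.linalg.cond(XtWX)
    if not np.isfinite(cond) or cond > 1e12:
        return None
    beta = XtWX_inv @ (Xw.T @ y)
    resid = y - X @ beta
    rss = float(w @ resid ** 2)
    ses = np.sqrt(np.diag(XtWX_inv))
    return beta, ses, rss, XtWX_inv


def meta_regress_snv(
    betas: np.ndarray,
    ses: np.ndarray,
    axes: np.ndarray,
    extra_covariates: np.ndarray | None = None,
    snv: str = "",
    effect_allele: str = "A",
) -> MetaResult | None:
    """Weighted meta-regression of one SNV's effects on ancestry axes.

    ``axes`` is (K, T); ``extra_covariates`` (K, m) enter both the full
    model and the baseline of the heterogeneity contrast, so the
    ancestry-correlated test always carries T degrees of freedom.
    Returns None (with a logged reason) on a singular design.
    """
    betas = np.asarray(betas, float)
    ses = np.asarray(ses, float)
    axes = np.atleast_2d(np.asarray(axes, float))
    if axes.size == 0:
        axes = np.empty((len(betas), 0))
    if axes.shape[0] != len(betas):
        axes = axes.T
    if np.any(ses <= 0):
        raise ValueError("all standard errors must be positive")
    K = len(betas)
    T = axes.shape[1]
    extra = (np.empty((K, 0)) if extra_covariates is None
             else np.atleast_2d(np.asarray(extra_covariates, float)))
    if extra.shape[0] != K:
        extra = extra.T
    m = extra.shape[1]
    n_cov = T + m
    if K < n_cov + 1 + 2:
        raise ValueError(f"need >= {n_cov + 3} studies for {n_cov} covariates, got {K}")
    w = 1.0 / ses ** 2
    ones = np.ones((K, 1))
    X_full = np.hstack([ones, axes, extra])
    X_base = np.hstack([ones, extra])
    fit_full = _wls(X_full, betas, w)
    fit_base = _wls(X_base, betas, w)
    if fit_full is None or fit_base is None:
        logger.warning("SNV %s skipped: singular design", snv or "<unnamed>")
        return None
    beta_hat, se_hat, rss_full, _ = fit_full
    _, _, rss_base, _ = fit_base

    total = float(w @ betas ** 2)
    assoc = max(0.0, total - rss_full)
    assoc_df = 1 + n_cov
    het = max(0.0, rss_base - rss_full)
    het_df = T
    resid = max(0.0, rss_full)
    resid_df = K - 1 - n_cov
    return MetaResult(
        snv=snv,
        coefficients=beta_hat,
        coefficient_ses=se_hat,
        assoc_stat=assoc,
        assoc_df=assoc_df,
        assoc_p=float(stats.chi2.sf(assoc, assoc_df)),
        ancestry_het_stat=het,
        ancestry_het_df=het_df,
        ancestry_het_p=float(stats.chi2.sf(het, het_df)) if het_df > 0 else 1.0,
        residual_het_stat=resid,
        residual_het_df=resid_df,
        residual_het_p=float(stats.chi2.sf(resid, resid_df)) if resid_df > 0 else 1.0,
        n_studies=K,
        n_axes=T,
        effect_allele=effect_allele,
    )


def bmi_adjusted_meta(
    betas: np.ndarray,
    ses: np.ndarray,
    axes: np.ndarray,
    bmi_cases: np.ndarray,
    bmi_controls: np.ndarray,
    snv: str = "",
) -> MetaResult | None:
    """Meta-regression with mean control and case BMI as extra covariates.

    Both BMI columns sit in the baseline of the ancestry-correlated
    heterogeneity contrast, so the test compares (intercept + BMI) against
    (intercept + BMI + axes) with df equal to the number of axes.
    """
    bmi = np.column_stack([np.asarray(bmi_controls, float),
                           np.asarray(bmi_cases, float)])
    if np.any(~np.isfinite(bmi)):
        raise ValueError("BMI values required for all contributing studies")
    return meta_regress_snv(betas, ses, axes, extra_covariates=bmi, snv=snv)


def fixed_effects_meta(betas, ses, snv: str = "") -> FixedEffectsResult:
    """Inverse-variance-weighted pooled effect and Cochran's Q."""
    betas = np.asarray(betas, float)
    ses = np.asarray(ses, float)
    if np.any(ses <= 0):
        raise ValueError("all standard errors must be positive")
    w = 1.0 / ses ** 2
    pooled = float(w @ betas / w.sum())
    pooled_se = float(1.0 / np.sqrt(w.sum()))
    z = pooled / pooled_se
    q = float(w @ (betas - pooled) ** 2)
    df = len(betas) - 1
    return FixedEffectsResult(
        snv=snv,
        beta=pooled,
        se=pooled_se,
        z=z,
        p=float(2 * stats.norm.sf(abs(z))),
        q=q,
        q_df=df,
        q_p=float(stats.chi2.sf(q, df)) if df > 0 else 1.0,
        n_studies=len(betas),
    )


# ---------------------------------------------------------------------------
# follow-up statistics

def genomic_control_lambda(pvalues) -> float:
    """Genomic-control inflation factor from two-sided P values.

    Each P is converted to its 1-df chi-square quantile; lambda is the
    median over SNVs divided by the null 1-df median (0.4549), reported to
    three decimals.
    """
    p = np.asarray(pvalues, float)
    if p.size == 0:
        raise ValueError("empty P-value vector")
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("P values must lie in (0, 1]")
    chi = stats.chi2.isf(p, 1)
    return round(float(np.median(chi) / CHI2_1DF_MEDIAN), 3)


def axis_association_zscores(
    meta_result: MetaResult, pooled_beta: float
) -> tuple[np.ndarray, int]:
    """Per-axis z-scores aligned to the trait risk allele.

    The risk allele is the one with positive fixed-effects pooled beta; when
    the stored effect allele is the other allele all slopes flip sign.
    Returns (z-scores, 0-based index of the strongest axis by |z|, ties to
    the lowest index).
    """
    ses = meta_result.axis_ses()
    if np.any(ses <= 0):
        raise ValueError("axis slope SE must be positive")
    z = meta_result.axis_slopes() / ses
    if pooled_beta < 0:  # effect allele is the non-risk allele
        z = -z
    strongest = int(np.argmax(np.abs(z)))
    return z, strongest


def bonferroni_threshold(alpha: float, n_tests: int, rounded: bool = True) -> float:
    """Family-wise threshold alpha/n, presented to two significant figures."""
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    raw = alpha / n_tests
    if not rounded:
        return raw
    return float(f"{raw:.1e}")


def binomial_enrichment_test(
    n_significant: int, n_total: int, per_test_alpha: float
) -> tuple[float, float]:
    """One-sided excess of significant tests over the binomial null.

    Returns (upper-tail P(X >= n_significant | n_total, alpha), expected
    count n_total * alpha).
    """
    if not 0 < per_test_alpha < 1:
        raise ValueError("per-test alpha must lie in (0, 1)")
    if not 0 <= n_significant <= n_total:
        raise ValueError("need 0 <= n_significant <= n_total")
    if n_significant == 0:
        p = 1.0
    else:
        p = float(stats.binom.sf(n_significant - 1, n_total, per_test_alpha))
    return p, n_total * per_test_alpha


# ---------------------------------------------------------------------------
# whole-panel driver

@dataclass
class MetaScanResult:
    """Tables from a meta-regression scan over all SNVs."""

    meta: pd.DataFrame
    fixed: pd.DataFrame
    axes: AxisCoordinates
    skipped: list[str] = field(default_factory=list)


def _collect_snv_effects(studies: list[StudySummary], min_studies: int):
    """Per-SNV aligned effect vectors across studies.

    Alleles are aligned to the first-reporting study's effect allele;
    strand-ambiguous SNVs are dropped.  Yields
    (snv, study_indices, betas, ses, effect_allele, chrom, pos).
    """
    ref_allele: dict[str, tuple[str, str]] = {}
    meta_rows: dict[str, list] = {}
    pos_of: dict[str, tuple] = {}
    for k, st in enumerate(studies):
        t = st.table
        for snv, ea, nea, beta, eaf, se, chrom, pos in zip(
            t["SNV"], t["EA"], t["NEA"], t["BETA"], t["EAF"], t["SE"],
            t["CHR"], t["POS"],
        ):
            ea, nea = str(ea), str(nea)
            if is_strand_ambiguous(ea, nea):
                continue
            if snv not in ref_allele:
                ref_allele[snv] = (ea, nea)
                meta_rows[snv] = []
                pos_of[snv] = (chrom, pos)
            aligned = align_to_reference(ea, nea, float(beta), float(eaf),
                                         *ref_allele[snv])
            if aligned is None:
                logger.warning("SNV %s: inconsistent alleles in %s; record dropped",
                               snv, st.study_id)
                continue
            meta_rows[snv].append((k, aligned[0], float(se)))
    for snv, rows in meta_rows.items():
        if len(rows) < min_studies:
            continue
        ks = np.array([r[0] for r in rows])
        b = np.array([r[1] for r in rows])
        s = np.array([r[2] for r in rows])
        yield snv, ks, b, s, ref_allele[snv][0], pos_of[snv]


def run_meta_scan(
    studies: list[StudySummary],
    n_axes: int = 3,
    min_studies: int = 5,
    with_bmi: bool = False,
    axes: AxisCoordinates | None = None,
) -> MetaScanResult:
    """Axes + per-SNV meta-regression + fixed-effects scan over a study set.

    SNVs reported by fewer than ``min_studies`` studies are dropped, per the
    at-least-five-studies convention; per-SNV df always reflect the
    contributing-study count.
    """
    if axes is None:
        axes = compute_axes(studies, n_axes=n_axes)
    X_axes = axes.coords
    bmi = np.array([[st.mean_bmi_controls, st.mean_bmi_cases] for st in studies])
    meta_rows, fe_rows, skipped = [], [], []
    for snv, ks, b, s, ea, (chrom, pos) in _collect_snv_effects(studies, min_studies):
        fe = fixed_effects_meta(b, s, snv=snv)
        if with_bmi:
            mr = bmi_adjusted_meta(b, s, X_axes[ks], bmi[ks, 1], bmi[ks, 0], snv=snv)
        else:
            mr = meta_regress_snv(b, s, X_axes[ks], snv=snv, effect_allele=ea)
        if mr is None:
            skipped.append(snv)
            continue
        axis_z, strongest = axis_association_zscores(mr, fe.beta)
        row = {
            "SNV": snv, "CHR": chrom, "POS": pos, "EA": ea,
            "N_STUDIES": mr.n_studies,
            "P_ASSOC": mr.assoc_p, "STAT_ASSOC": mr.assoc_stat, "DF_ASSOC": mr.assoc_df,
            "P_ANC_HET": mr.ancestry_het_p, "STAT_ANC_HET": mr.ancestry_het_stat,
            "DF_ANC_HET": mr.ancestry_het_df,
            "P_RES_HET": mr.residual_het_p, "STAT_RES_HET": mr.residual_het_stat,
            "DF_RES_HET": mr.residual_het_df,
        }
        for t in range(mr.n_axes):
            row[f"BETA_AXIS{t + 1}"] = mr.coefficients[1 + t]
            row[f"SE_AXIS{t + 1}"] = mr.coefficient_ses[1 + t]
            row[f"Z_AXIS{t + 1}"] = axis_z[t]
        row["STRONGEST_AXIS"] = strongest + 1
        meta_rows.append(row)
        fe_rows.append({
            "SNV": snv, "CHR": chrom, "POS": pos, "EA": ea,
            "BETA_FE": fe.beta, "SE_FE": fe.se, "Z_FE": fe.z, "P_FE": fe.p,
            "Q": fe.q, "Q_DF": fe.q_df, "Q_P": fe.q_p, "N_STUDIES": fe.n_studies,
        })
    return MetaScanResult(
        meta=pd.DataFrame(meta_rows),
        fixed=pd.DataFrame(fe_rows),
        axes=axes,
        skipped=skipped,
    )
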