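"""Partitioned polygenic scores and outcome association.

Each index SNV carries an ancestry-specific weight (pooled log-OR from the
within-ancestry fixed-effects meta-analysis) and a cluster label.  The raw
cluster score of an individual is the weighted sum of risk-allele dosages
over that cluster's SNVs; the overall score is the sum across clusters.
Scores are standardized to mean 0 / variance 1 within the analysis cohort,
tested against outcomes by generalized linear models (cluster components
adjusted for the overall score), and pooled across ancestry groups by
DerSimonian-Laird random-effects meta-analysis.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.tools.sm_exceptions import PerfectSeparationError

logger = logging.getLogger(__name__)


@dataclass
class PSModel:
    """Per-SNV risk alleles, per-ancestry weights and cluster labels.

    ``weights`` columns: SNV, RISK, ancestry, weight (log-OR), cluster.
    """

    weights: pd.DataFrame

    def __post_init__(self) -> None:
        need = {"SNV", "RISK", "ancestry", "weight", "cluster"}
        missing = need - set(self.weights.columns)
        if missing:
            raise ValueError(f"weights table missing columns {sorted(missing)}")
        if not np.all(np.isfinite(self.weights["weight"])):
            raise ValueError("weights must be finite")
        per = self.weights.groupby("SNV")["cluster"].nunique()
        if (per > 1).any():
            raise ValueError("each SNV must belong to exactly one cluster")

    def clusters(self) -> list[str]:
        return sorted(self.weights["cluster"].astype(str).unique())

    def for_ancestry(self, ancestry: str) -> pd.DataFrame:
        sub = self.weights.loc[self.weights["ancestry"] == ancestry]
        if sub.empty:
            raise ValueError(f"no weights for ancestry {ancestry!r}")
        return sub


@dataclass
class PSResult:
    outcome: str
    cluster: str          # cluster id or "overall"
    effect: float         # log-OR (binary) or units per SD (linear)
    se: float
    p: float
    ancestry: str
    n: int
    family: str


# ---------------------------------------------------------------------------
# variant QC

def hwe_exact_test(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """Exact conditional test of Hardy-Weinberg proportions.

    Sums, over the conditional distribution of heterozygote counts given
    the allele counts, the probabilities of outcomes no more probable than
    the observed one.
    """
    if min(n_AA, n_Aa, n_aa) < 0 or n_AA + n_Aa + n_aa == 0:
        raise ValueError("genotype counts must be non-negative with positive total")
    n = n_AA + n_Aa + n_aa
    n_a = 2 * n_aa + n_Aa  # minor-allele count if aa is the rarer homozygote
    n_A = 2 * n_AA + n_Aa
    rare = min(n_a, n_A)
    if rare == 0:
        return 1.0
    # log-probability of each possible heterozygote count (same parity as rare)
    hets = np.arange(rare % 2, rare + 1, 2)
    homr = (rare - hets) // 2
    homc = n - hets - homr
    from scipy.special import gammaln
    logp = (
        gammaln(n + 1) - gammaln(homr + 1) - gammaln(hets + 1) - gammaln(homc + 1)
        + hets * np.log(2.0)
        + gammaln(rare + 1) + gammaln(2 * n - rare + 1) - gammaln(2 * n + 1)
    )
    probs = np.exp(logp - logp.max())
    probs /= probs.sum()
    obs_het = n_Aa
    p_obs = probs[hets == obs_het]
    if p_obs.size == 0:
        raise ValueError("observed heterozygote count inconsistent with allele counts")
    return float(min(1.0, probs[probs <= p_obs[0] * (1 + 1e-12)].sum()))


def qc_filter_snvs(
    variant_stats: pd.DataFrame,
    maf_min: float = 0.01,
    info_min: float = 0.7,
    hwe_p_min: float = 1e-6,
) -> tuple[list[str], pd.DataFrame]:
    """Retain SNVs with MAF >= 1%, imputation r^2 >= 0.7 and HWE P >= 1e-6.

    ``variant_stats`` columns: SNV, MAF, INFO, HWE_P.  Returns the retained
    SNV list and an exclusion log with one reason per excluded SNV.
    """
    excl = []
    keep = []
    for rec in variant_stats.itertuples(index=False):
        maf = min(float(rec.MAF), 1 - float(rec.MAF))
        if maf < maf_min:
            excl.append({"SNV": rec.SNV, "reason": f"MAF {maf:.4g} < {maf_min}"})
        elif float(rec.INFO) < info_min:
            excl.append({"SNV": rec.SNV,
                         "reason": f"imputation r2 {rec.INFO:.3g} < {info_min}"})
        elif float(rec.HWE_P) < hwe_p_min:
            excl.append({"SNV": rec.SNV,
                         "reason": f"HWE P {rec.HWE_P:.3g} < {hwe_p_min}"})
        else:
            keep.append(str(rec.SNV))
    log = pd.DataFrame(excl, columns=["SNV", "reason"])
    if len(log):
        logger.info("QC excluded %d of %d SNVs", len(log), len(variant_stats))
    return keep, log


# ---------------------------------------------------------------------------
# score construction

def compute_partitioned_ps(
    cohort,
    ps_model: PSModel,
    ancestry: str,
    standardize: bool = True,
) -> pd.DataFrame:
    """Standardized overall and per-cluster polygenic scores.

    Dosages are aligned to the risk allele, missing dosages mean-imputed
    per SNV, and each raw cluster score is the weighted dosage sum over the
    cluster's SNVs.  Raw scores satisfy overall = sum of cluster scores;
    standardization (mean 0, variance 1) is applied within the cohort.
    """
    wtab = ps_model.for_ancestry(ancestry)
    dos = cohort.dosages
    missing = [s for s in wtab["SNV"] if s not in dos.columns]
    if missing:
        raise ValueError(f"cohort lacks dosages for SNVs {missing[:5]}")
    D = dos[list(wtab["SNV"])].to_numpy(dtype=float)
    col_mean = np.nanmean(D, axis=0)
    nan_mask = np.isnan(D)
    if nan_mask.any():
        D[nan_mask] = np.take(col_mean, np.nonzero(nan_mask)[1])
    w = wtab["weight"].to_numpy(dtype=float)
    clusters = wtab["cluster"].astype(str).to_numpy()
    out = {}
    raw_total = np.zeros(D.shape[0])
    for cl in sorted(set(clusters)):
        sel = clusters == cl
        raw = D[:, sel] @ w[sel]
        raw_total += raw
        out[cl] = raw
    out["overall"] = raw_total
    frame = pd.DataFrame(out, index=dos.index)
    if standardize:
        for c in frame.columns:
            sd = frame[c].std(ddof=0)
            if sd == 0:
                raise ValueError(f"score {c!r} has zero variance")
            frame[c] = (frame[c] - frame[c].mean()) / sd
    return frame


# ---------------------------------------------------------------------------
# association testing

def _glm_fit(y, X, family: str):
    fam = sm.families.Binomial() if family == "binomial" else sm.families.Gaussian()
    model = sm.GLM(y, X, family=fam)
    return model.fit()


def associate_outcome(
    scores: pd.DataFrame,
    cohort,
    outcome: str,
    family: str = "binomial",
    covariates: list[str] | None = None,
    adjust_overall: bool = True,
    clusters: list[str] | None = None,
) -> list[PSResult]:
    """GLM association of each score component with an outcome.

    Each cluster component is tested adjusted for the overall score (when
    ``adjust_overall``) plus covariates; the overall score is tested
    without cluster terms.  Binary outcomes use logistic regression, the
    quantitative age-of-onset a linear model.  On perfect separation the
    fit falls back to Firth logistic regression (flagged in the log).
    """
    if outcome == "onset":
        y = cohort.age_of_onset
    else:
        y = cohort.outcomes[outcome]
    keep = y.notna()
    y = y[keep].astype(float)
    if y.nunique() < 2:
        raise ValueError(f"outcome {outcome!r} is constant")
    covariates = covariates or []
    cov = cohort.covariates.loc[keep.index[keep], covariates] if covariates \
        else pd.DataFrame(index=y.index)
    if clusters is None:
        clusters = [c for c in scores.columns if c != "overall"]
    results: list[PSResult] = []
    for comp in ["overall"] + list(clusters):
        cols = [scores.loc[y.index, comp]]
        names = [comp]
        if comp != "overall" and adjust_overall:
            cols.append(scores.loc[y.index, "overall"])
            names.append("overall_adj")
        X = pd.concat(cols, axis=1)
        X.columns = names
        X = pd.concat([X, cov], axis=1)
        X = sm.add_constant(X, has_constant="add")
        Xv = X.to_numpy(dtype=float)
        if np.linalg.matrix_rank(Xv) < Xv.shape[1]:
            raise ValueError(f"rank-deficient design for component {comp!r}")
        if family == "binomial":
            try:
                fit = _glm_fit(y.to_numpy(), Xv, "binomial")
                beta = fit.params
                se = fit.bse
                pvals = fit.pvalues
            except (PerfectSeparationError, np.linalg.LinAlgError):
                from .enrich import firth_logistic
                logger.warning("separation for %s/%s: Firth fallback", outcome, comp)
                ff = firth_logistic(y.to_numpy(), Xv)
                beta, se = ff.coefficients, ff.ses
                z = beta / se
                pvals = 2 * stats.norm.sf(np.abs(z))
        else:
            fit = _glm_fit(y.to_numpy(), Xv, "gaussian")
            beta, se, pvals = fit.params, fit.bse, fit.pvalues
        j = list(X.columns).index(comp)
        results.append(PSResult(
            outcome=outcome, cluster=comp, effect=float(beta[j]),
            se=float(se[j]), p=float(pvals[j]), ancestry=cohort.ancestry,
            n=int(len(y)), family=family,
        ))
    return results


def random_effects_meta(estimates, ses) -> dict:
    """DerSimonian-Laird random-effects pooling across ancestry groups.

    Q from fixed-effects weights; tau^2 = max(0, (Q - df)/C) with
    C = sum w - sum w^2 / sum w; pooled estimate with weights
    1/(se^2 + tau^2).
    """
    b = np.asarray(estimates, float)
    s = np.asarray(ses, float)
    if np.any(s <= 0):
        raise ValueError("standard errors must be positive")
    w = 1.0 / s ** 2
    mu_fe = float(w @ b / w.sum())
    q = float(w @ (b - mu_fe) ** 2)
    df = len(b) - 1
    if df <= 0:
        tau2 = 0.0
    else:
        c = w.sum() - (w ** 2).sum() / w.sum()
        tau2 = max(0.0, (q - df) / c) if c > 0 else 0.0
    w_re = 1.0 / (s ** 2 + tau2)
    pooled = float(w_re @ b / w_re.sum())
    pooled_se = float(1.0 / np.sqrt(w_re.sum()))
    z = pooled / pooled_se
    return {
        "estimate": pooled,
        "se": pooled_se,
        "p": float(2 * stats.norm.sf(abs(z))),
        "tau2": tau2,
        "q": q,
        "q_df": max(df, 0),
        "q_p": float(stats.chi2.sf(q, df)) if df > 0 else 1.0,
    }


def build_ps_model(
    per_ancestry_fe: dict[str, pd.DataFrame],
    cluster_assignments: pd.Series,
) -> PSModel:
    """Assemble a PSModel from ancestry-specific pooled effects.

    ``per_ancestry_fe`` maps ancestry -> fixed-effects table with columns
    SNV, EA, BETA_FE; the weight is the log-OR of the risk allele (pooled
    beta flipped positive, risk allele recorded accordingly) from that
    ancestry's meta-analysis.  ``cluster_assignments`` maps SNV -> cluster.
    """
    rows = []
    for anc, fe in per_ancestry_fe.items():
        for rec in fe.itertuples(index=False):
            if rec.SNV not in cluster_assignments.index:
                continue
            beta = float(rec.BETA_FE)
            risk = str(rec.EA)
            rows.append({
                "SNV": rec.SNV, "RISK": risk, "ancestry": anc,
                "weight": beta,
                "cluster": str(cluster_assignments.loc[rec.SNV]),
            })
    return PSModel(pd.DataFrame(rows))
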