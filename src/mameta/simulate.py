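"""Synthetic-data generation for the multi-ancestry T2D heterogeneity pipeline.

Every input the analysis consumes can be generated here with the statistical
structure the downstream models assume:

* haplotype reference panels per continental group, with Balding-Nichols
  allele-frequency divergence and block-wise LD;
* per-study GWAS summary statistics whose true allelic effects are linear in
  latent axes of ancestry (and optionally in study-level mean BMI), with
  sampling noise driven by effective sample size;
* index-SNV x phenotype z-score matrices with planted cluster structure and
  missing-completely-at-random masking;
* genic and cell-type open-chromatin annotations with a planted enrichment;
* individual-level cohorts whose outcome risk loads on cluster-specific
  polygenic scores.

All randomness flows through a single integer seed; a fixed seed yields
byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm

logger = logging.getLogger(__name__)

STUDY_COLUMNS = [
    "CHR", "POS", "EA", "NEA", "EAF", "BETA", "SE", "N_CASE", "N_CONTROL", "INFO",
]


@dataclass
class SimulationConfig:
    """Parameters of the synthetic study system.

    The defaults define the reference study conditions used throughout the
    test-suite: three continental groups with moderate divergence, effects
    linear in two latent ancestry axes, three planted phenotype clusters and
    a single enriched cell type.
    """

    n_snvs: int = 1000
    n_studies_per_group: dict[str, int] = field(
        default_factory=lambda: {"AFR": 4, "EAS": 4, "EUR": 4}
    )
    group_fst: dict[str, float] = field(
        default_factory=lambda: {"AFR": 0.12, "EAS": 0.08, "EUR": 0.05}
    )
    n_axes_true: int = 2
    axis_effects: tuple[float, ...] = (0.0, 0.0)
    base_effect: float = 0.0
    bmi_effects: tuple[float, float] = (0.0, 0.0)
    n_causal: int | None = None
    n_clusters_true: int = 3
    cluster_centroids: np.ndarray | None = None
    missing_rate: float = 0.0
    peak_overlap_probs: tuple[float, float] = (0.5, 0.1)
    n_haplotypes: int = 500
    block_size: int = 10
    block_rho: float = 0.8
    snv_spacing: int = 1000
    n_eff_range: tuple[float, float] = (10_000.0, 60_000.0)
    axis_spread: float = 1.0
    axis_jitter: float = 0.1
    bmi_mean_controls: float = 27.0
    bmi_case_shift: float = 3.0
    bmi_sd: float = 1.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_snvs <= 0:
            raise ValueError("n_snvs must be positive")
        if self.block_size <= 0:
            raise ValueError("block size must be positive")
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing_rate must lie in [0, 1)")
        for g, f in self.group_fst.items():
            if not 0 <= f < 1:
                raise ValueError(f"F_st for group {g} must lie in [0, 1)")
        for p in self.peak_overlap_probs:
            if not 0 < p < 1:
                raise ValueError("peak overlap probabilities must lie in (0, 1)")

    def rng(self, stream: int) -> np.random.Generator:
        """Independent generator for a named simulation stream."""
        return np.random.default_rng(np.random.SeedSequence([self.seed, stream]))


@dataclass
class HaplotypePanel:
    """Phased 0/1 haplotypes for one continental group on one chromosome."""

    group: str
    haplotypes: np.ndarray  # (n_haplotypes, n_snvs) int8
    positions: np.ndarray   # 1-based bp, strictly increasing
    snv_ids: list[str]

    def __post_init__(self) -> None:
        uniq = np.unique(self.haplotypes)
        if not np.all(np.isin(uniq, [0, 1])):
            raise ValueError("haplotype entries must be 0/1")
        if np.any(np.diff(self.positions) <= 0):
            raise ValueError("positions must be strictly increasing")

    def frequencies(self) -> np.ndarray:
        return self.haplotypes.mean(axis=0)


@dataclass
class StudySummary:
    """One study's per-SNV summary statistics plus ancestry/BMI metadata."""

    study_id: str
    ancestry: str
    table: pd.DataFrame  # columns: SNV, EA, NEA, EAF, BETA, SE, INFO
    n_cases: int
    n_controls: int
    mean_bmi_cases: float
    mean_bmi_controls: float

    @property
    def n_eff(self) -> float:
        return 4.0 / (1.0 / self.n_cases + 1.0 / self.n_controls)


@dataclass
class ZScoreMatrix:
    """Index-SNV x phenotype sample-size-corrected z-scores.

    ``values`` holds NaN where masked missing; ``mask`` is True where missing.
    """

    values: np.ndarray
    mask: np.ndarray
    snv_ids: list[str]
    phenotypes: list[str]
    sample_sizes: np.ndarray | None = None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.snv_ids, columns=self.phenotypes)


@dataclass
class AnnotationSet:
    """Genomic intervals by class: genic features plus per-cell-type peaks.

    Intervals are 0-based half-open (BED convention); SNV positions in the
    rest of the package are 1-based.
    """

    genic: dict[str, pd.DataFrame]
    peaks: dict[str, pd.DataFrame]
    enriched_cell_type: str | None = None
    planted_theta: float | None = None


@dataclass
class CohortData:
    """Individual-level dosages, covariates and outcomes for score testing."""

    dosages: pd.DataFrame        # individuals x SNVs, values in [0, 2]
    covariates: pd.DataFrame     # age, sex, PCs
    outcomes: pd.DataFrame       # binary outcomes (+ t2d status)
    age_of_onset: pd.Series | None
    ancestry: str
    truth: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# haplotype panels

def _ancestral_frequencies(cfg: SimulationConfig, rng: np.random.Generator) -> np.ndarray:
    return rng.uniform(0.05, 0.95, size=cfg.n_snvs)


def _balding_nichols(p0: np.ndarray, fst: float, rng: np.random.Generator) -> np.ndarray:
    """Group frequencies around ancestral p0 at divergence fst."""
    if fst == 0:
        return p0.copy()
    a = p0 * (1 - fst) / fst
    b = (1 - p0) * (1 - fst) / fst
    return rng.beta(a, b)


def simulate_haplotype_panels(config: SimulationConfig) -> dict[str, HaplotypePanel]:
    """Draw one haplotype panel per continental group.

    LD is block-wise: within a block of ``block_size`` consecutive SNVs each
    haplotype shares a latent Gaussian factor with loading sqrt(block_rho);
    alleles are thresholded so that marginal frequencies match the group's
    Balding-Nichols frequencies exactly.  Blocks are mutually independent, so
    between-block r^2 is ~0 and within-block r^2 grows with block_rho.
    """
    rng = config.rng(1)
    p0 = _ancestral_frequencies(config, rng)
    positions = np.arange(1, config.n_snvs + 1) * config.snv_spacing
    snv_ids = [f"snv{j}" for j in range(config.n_snvs)]
    n_blocks = int(np.ceil(config.n_snvs / config.block_size))
    panels: dict[str, HaplotypePanel] = {}
    for group in sorted(config.n_studies_per_group):
        fst = config.group_fst.get(group, 0.0)
        p_g = _balding_nichols(p0, fst, rng)
        H = config.n_haplotypes
        rho = config.block_rho
        block_factor = rng.standard_normal((H, n_blocks))
        noise = rng.standard_normal((H, config.n_snvs))
        block_of = np.arange(config.n_snvs) // config.block_size
        latent = np.sqrt(rho) * block_factor[:, block_of] + np.sqrt(1 - rho) * noise
        u = norm.cdf(latent)
        hap = (u < p_g[None, :]).astype(np.int8)
        panels[group] = HaplotypePanel(group, hap, positions.copy(), list(snv_ids))
    return panels


def estimate_fst(panels: dict[str, HaplotypePanel]) -> float:
    """Variance-component F_st estimate averaged across SNVs.

    For each SNV, the ratio of the between-group variance of allele frequency
    to p_bar(1-p_bar); used in tests to check the Balding-Nichols divergence.
    """
    freqs = np.vstack([p.frequencies() for p in panels.values()])
    pbar = freqs.mean(axis=0)
    var = freqs.var(axis=0, ddof=1)
    keep = (pbar > 0.01) & (pbar < 0.99)
    return float(np.mean(var[keep] / (pbar[keep] * (1 - pbar[keep]))))


# ---------------------------------------------------------------------------
# study summary statistics

def _group_axis_centroids(groups: list[str], n_axes: int, spread: float) -> np.ndarray:
    """Fixed, well-separated group positions on the latent axes.

    Axis t separates groups by a shifted/centred indicator-style contrast so
    that distinct groups occupy distinct positions on at least one axis.
    """
    G = len(groups)
    cents = np.zeros((G, n_axes))
    for t in range(n_axes):
        raw = np.array([np.cos(2 * np.pi * (t + 1) * g / G) for g in range(G)])
        raw = raw - raw.mean()
        denom = np.abs(raw).max()
        if denom > 0:
            raw = raw / denom
        cents[:, t] = spread * raw
    return cents


def simulate_study_summaries(
    config: SimulationConfig, panels: dict[str, HaplotypePanel]
) -> tuple[list[StudySummary], dict]:
    """Generate per-study summary statistics with effects linear in ancestry axes.

    True per-study effect at a causal SNV: b_k = b0 + sum_t axis_effects[t]
    x_tk (+ BMI terms when configured), with x_tk the study's latent axis
    coordinates (group centroid + jitter); non-causal SNVs have effect 0.
    When ``n_causal`` is None every SNV is causal; otherwise the causal SNVs
    are ``n_causal`` evenly spaced positions (hence typically in distinct LD
    blocks).  Observed beta ~ N(b_k, se^2) with se = 1/sqrt(2 f (1-f)
    N_eff).  Monomorphic SNVs (EAF 0 or 1) are dropped from a study's table
    with a logged count.

    Returns the studies and a truth dictionary with the planted axis
    coordinates, per-study true effects, causal indices and BMI values.
    """
    rng = config.rng(2)
    groups = sorted(config.n_studies_per_group)
    cents = _group_axis_centroids(groups, config.n_axes_true, config.axis_spread)
    axis_eff = np.asarray(config.axis_effects, dtype=float)
    if axis_eff.size != config.n_axes_true:
        raise ValueError("axis_effects length must equal n_axes_true")
    if config.n_causal is None:
        causal = np.ones(config.n_snvs, dtype=bool)
    else:
        causal = np.zeros(config.n_snvs, dtype=bool)
        if config.n_causal > 0:
            idx = np.unique(np.linspace(0, config.n_snvs - 1,
                                        config.n_causal).round().astype(int))
            causal[idx] = True

    studies: list[StudySummary] = []
    coords = []
    true_effects = []
    for gi, group in enumerate(groups):
        freq = panels[group].frequencies()
        ids = panels[group].snv_ids
        pos = panels[group].positions
        for s in range(config.n_studies_per_group[group]):
            x = cents[gi] + config.axis_jitter * rng.standard_normal(config.n_axes_true)
            n_eff = rng.uniform(*config.n_eff_range)
            n_case = n_ctrl = int(round(n_eff / 2))
            bmi_ctrl = rng.normal(config.bmi_mean_controls, config.bmi_sd)
            bmi_case = bmi_ctrl + config.bmi_case_shift + rng.normal(0, 0.5)
            b_k = (
                config.base_effect
                + float(axis_eff @ x)
                + config.bmi_effects[0] * (bmi_ctrl - config.bmi_mean_controls)
                + config.bmi_effects[1] * (bmi_case - config.bmi_mean_controls)
            )
            # study EAF: group frequency plus binomial sampling noise
            eaf = rng.binomial(2 * n_case, freq) / (2 * n_case)
            keep = (eaf > 0) & (eaf < 1)
            n_mono = int((~keep).sum())
            if n_mono:
                logger.info(
                    "study %s_%d: excluded %d monomorphic SNVs", group, s, n_mono
                )
            se = 1.0 / np.sqrt(2 * eaf[keep] * (1 - eaf[keep]) * n_eff)
            beta = b_k * causal[keep] + se * rng.standard_normal(keep.sum())
            table = pd.DataFrame(
                {
                    "SNV": np.asarray(ids)[keep],
                    "CHR": 1,
                    "POS": pos[keep],
                    "EA": "A",
                    "NEA": "G",
                    "EAF": eaf[keep],
                    "BETA": beta,
                    "SE": se,
                    "INFO": 1.0,
                }
            )
            studies.append(
                StudySummary(
                    study_id=f"{group}_{s}",
                    ancestry=group,
                    table=table,
                    n_cases=n_case,
                    n_controls=n_ctrl,
                    mean_bmi_cases=bmi_case,
                    mean_bmi_controls=bmi_ctrl,
                )
            )
            coords.append(x)
            true_effects.append(b_k)
    truth = {
        "axis_coordinates": np.array(coords),
        "true_effects": np.array(true_effects),
        "axis_effects": axis_eff,
        "group_centroids": cents,
        "groups": groups,
        "causal": causal,
    }
    return studies, truth


# ---------------------------------------------------------------------------
# phenotype z-scores

def default_centroids(n_clusters: int, n_phenotypes: int, scale: float = 2.0,
                      seed: int = 7) -> np.ndarray:
    """Sign-patterned cluster centroids with mean separation ``scale``."""
    rng = np.random.default_rng(seed)
    signs = rng.choice([-1.0, 0.0, 1.0], size=(n_clusters, n_phenotypes),
                       p=[0.35, 0.3, 0.35])
    return scale * signs


def simulate_phenotype_zscores(
    config: SimulationConfig,
    n_phenotypes: int = 10,
    snv_ids: list[str] | None = None,
) -> tuple[ZScoreMatrix, np.ndarray]:
    """Planted-cluster z-score matrix with MCAR missingness.

    Z_ij ~ Normal(centroid[cluster(j), i], 1); each cell is masked missing
    independently at ``missing_rate``.  Returns the matrix and the true
    assignment vector for recovery testing.
    """
    rng = config.rng(3)
    cents = config.cluster_centroids
    if cents is None:
        cents = default_centroids(config.n_clusters_true, n_phenotypes)
    cents = np.asarray(cents, dtype=float)
    if cents.shape[0] != config.n_clusters_true:
        raise ValueError("cluster_centroids must have n_clusters_true rows")
    n_phenotypes = cents.shape[1]
    n = config.n_snvs if snv_ids is None else len(snv_ids)
    if snv_ids is None:
        snv_ids = [f"snv{j}" for j in range(n)]
    assign = rng.integers(0, config.n_clusters_true, size=n)
    Z = cents[assign] + rng.standard_normal((n, n_phenotypes))
    mask = rng.random((n, n_phenotypes)) < config.missing_rate
    values = Z.copy()
    values[mask] = np.nan
    phen = [f"trait{i}" for i in range(n_phenotypes)]
    N = np.full(n_phenotypes, 100_000.0)
    return ZScoreMatrix(values, mask, list(snv_ids), phen, N), assign


# ---------------------------------------------------------------------------
# annotations

def planted_log_enrichment(p_index: float, p_null: float) -> float:
    """Log odds ratio implied by the two overlap probabilities."""
    return float(np.log(p_index * (1 - p_null) / (p_null * (1 - p_index))))


def simulate_annotations(
    config: SimulationConfig,
    index_snvs: pd.DataFrame,
    null_snvs: pd.DataFrame,
    cell_types: list[str] | None = None,
    genic_rates: dict[str, float] | None = None,
    peak_width: int = 400,
) -> AnnotationSet:
    """Peak and genic intervals with a planted enrichment at one cell type.

    ``index_snvs``/``null_snvs`` are frames with SNV, CHR, POS (1-based) and
    must be disjoint.  For the first cell type, index SNVs fall in a peak with
    probability p_index and null SNVs with p_null; all other cell types use
    p_null for both, so their planted log fold enrichment is 0.
    """
    common = set(index_snvs["SNV"]) & set(null_snvs["SNV"])
    if common:
        raise ValueError("index and null SNV sets must be disjoint")
    p_index, p_null = config.peak_overlap_probs
    if cell_types is None:
        cell_types = ["celltype_enriched", "celltype_a", "celltype_b"]
    if genic_rates is None:
        genic_rates = {"exon": 0.15, "utr3": 0.05, "utr5": 0.05}
    rng = config.rng(4)

    def _peak_rows(snvs: pd.DataFrame, prob: float) -> list[tuple]:
        hit = rng.random(len(snvs)) < prob
        rows = []
        for (_, r), h in zip(snvs.iterrows(), hit):
            if h:
                start0 = max(0, int(r["POS"]) - 1 - peak_width // 2)
                rows.append((str(r["CHR"]), start0, start0 + peak_width))
        return rows

    peaks: dict[str, pd.DataFrame] = {}
    for ci, ct in enumerate(cell_types):
        pi = p_index if ci == 0 else p_null
        rows = _peak_rows(index_snvs, pi) + _peak_rows(null_snvs, p_null)
        peaks[ct] = pd.DataFrame(rows, columns=["chrom", "start", "end"])

    genic: dict[str, pd.DataFrame] = {}
    all_snvs = pd.concat([index_snvs, null_snvs], ignore_index=True)
    for cls, rate in genic_rates.items():
        rows = _peak_rows(all_snvs, rate)
        genic[cls] = pd.DataFrame(rows, columns=["chrom", "start", "end"])

    return AnnotationSet(
        genic=genic,
        peaks=peaks,
        enriched_cell_type=cell_types[0],
        planted_theta=planted_log_enrichment(p_index, p_null),
    )


# ---------------------------------------------------------------------------
# cohorts

def simulate_cohort(
    config: SimulationConfig,
    ps_model,
    panels: dict[str, HaplotypePanel],
    ancestry: str,
    n_individuals: int = 5000,
    outcome_effects: dict[str, float] | None = None,
    onset_effects: dict[str, float] | None = None,
    intercept: float = -2.0,
    onset_mean: float = 55.0,
    onset_sd: float = 8.0,
    n_pcs: int = 2,
) -> CohortData:
    """Individual-level cohort whose outcome risk loads on cluster scores.

    ``outcome_effects``/``onset_effects`` map cluster id (or "overall") to a
    log-OR (resp. years) per SD of the corresponding standardized score.
    Dosages are Binomial(2, f) at the ancestry group's panel frequencies.
    """
    from .ps import compute_partitioned_ps  # local import to avoid cycle

    snvs = list(dict.fromkeys(ps_model.weights["SNV"]))
    missing = [s for s in snvs if s not in panels[ancestry].snv_ids]
    if missing:
        raise ValueError(f"ps_model SNVs absent from panel: {missing[:5]}")
    for cl in (outcome_effects or {}):
        if cl != "overall" and cl not in set(ps_model.weights["cluster"]):
            raise ValueError(f"cluster {cl!r} absent from ps_model")
    rng = config.rng(5)
    idx = [panels[ancestry].snv_ids.index(s) for s in snvs]
    freq = panels[ancestry].frequencies()[idx]
    dos = rng.binomial(2, freq, size=(n_individuals, len(snvs))).astype(float)
    dosages = pd.DataFrame(dos, columns=snvs,
                           index=[f"ind{i}" for i in range(n_individuals)])
    age = rng.normal(58, 10, n_individuals)
    sex = rng.integers(0, 2, n_individuals).astype(float)
    pcs = rng.standard_normal((n_individuals, n_pcs))
    cov = pd.DataFrame({"age": age, "sex": sex}, index=dosages.index)
    for p in range(n_pcs):
        cov[f"PC{p + 1}"] = pcs[:, p]

    cohort_stub = CohortData(dosages, cov, pd.DataFrame(index=dosages.index),
                             None, ancestry)
    scores = compute_partitioned_ps(cohort_stub, ps_model, ancestry)

    lin = np.full(n_individuals, intercept)
    for cl, eff in (outcome_effects or {}).items():
        lin = lin + eff * scores[str(cl)].to_numpy()
    prob = 1.0 / (1.0 + np.exp(-lin))
    y = (rng.random(n_individuals) < prob).astype(int)
    outcomes = pd.DataFrame({"outcome": y}, index=dosages.index)
    outcomes["t2d"] = (rng.random(n_individuals) < 0.3).astype(int)

    onset = onset_mean + onset_sd * rng.standard_normal(n_individuals)
    for cl, eff in (onset_effects or {}).items():
        onset = onset + eff * scores[str(cl)].to_numpy()
    truth = {
        "outcome_effects": dict(outcome_effects or {}),
        "onset_effects": dict(onset_effects or {}),
        "intercept": intercept,
    }
    return CohortData(dosages, cov, outcomes, pd.Series(onset, index=dosages.index),
                      ancestry, truth)


# ---------------------------------------------------------------------------
# writers (tab-delimited external formats)

def write_study_summary(study: StudySummary, path) -> None:
    """Write one study as tab-delimited text with the standard header."""
    out = study.table.rename(columns={"SNV": "SNVID"})
    out = out[["CHR", "POS", "EA", "NEA", "EAF", "BETA", "SE", "INFO"]].copy()
    out.insert(7, "N_CASE", study.n_cases)
    out.insert(8, "N_CONTROL", study.n_controls)
    out.to_csv(path, sep="\t", index=False)


def write_bed(intervals: pd.DataFrame, path, name: str | None = None) -> None:
    out = intervals[["chrom", "start", "end"]].copy()
    if name is not None:
        out["name"] = name
    out.to_csv(path, sep="\t", index=False, header=False)


def write_cohort(cohort: CohortData, dosage_path, meta_path) -> None:
    """Dense tab-delimited dosage matrix plus a sample metadata sidecar."""
    cohort.dosages.to_csv(dosage_path, sep="\t", na_rep="NA")
    meta = cohort.covariates.join(cohort.outcomes)
    if cohort.age_of_onset is not None:
        meta = meta.join(cohort.age_of_onset.rename("age_of_onset"))
    meta.to_csv(meta_path, sep="\t", na_rep="NA")


def write_truth_sidecar(truth: dict, path) -> None:
    """Planted-parameter record as YAML, for recovery tests."""
    import yaml

    def _clean(v):
        if isinstance(v, np.ndarray):
            return v.tolist()
        if isinstance(v, (np.integer, np.floating)):
            return v.item()
        if isinstance(v, dict):
            return {k: _clean(x) for k, x in v.items()}
        if isinstance(v, (list, tuple)):
            return [_clean(x) for x in v]
        return v

    with open(path, "w") as fh:
        yaml.safe_dump(_clean(truth), fh, sort_keys=True)


def write_annotation_set(ann: AnnotationSet, path) -> None:
    """All intervals as one BED file with a 4th column naming the class."""
    frames = []
    for cls, df in {**ann.genic, **ann.peaks}.items():
        f = df[["chrom", "start", "end"]].copy()
        f["name"] = cls
        frames.append(f)
    pd.concat(frames, ignore_index=True).to_csv(path, sep="\t", index=False,
                                                header=False)
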