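"""End-to-end pipeline orchestration, configuration and reporting.

A single seeded run ties all stages together on synthetic inputs:
simulate -> axes -> meta-regression (optionally BMI-adjusted) -> clumping
and locus definition -> z-scores -> clustering -> cluster profiles ->
open-chromatin enrichment -> polygenic scoring -> outcome association ->
report.  Every stage writes its table to the run directory; a manifest
records the config hash, per-stage checksums and wall-clock times so that
a re-run with the same config is verifiably identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cluster import (
    cluster_axis_anova,
    cluster_phenotype_association,
    cluster_t2d_effects,
    impute_kmeans,
    select_k,
)
from .enrich import enrichment_scan, select_null_snvs
from .meta import (
    binomial_enrichment_test,
    bonferroni_threshold,
    fixed_effects_meta,
    genomic_control_lambda,
    run_meta_scan,
)
from .ps import PSModel, associate_outcome, build_ps_model, compute_partitioned_ps, \
    random_effects_meta
from .signals import (
    LDReference,
    flag_novelty,
    greedy_clump,
    loci_to_frame,
    merge_loci,
    signals_to_frame,
    summarize_discovery,
)
from .simulate import (
    SimulationConfig,
    simulate_annotations,
    simulate_cohort,
    simulate_haplotype_panels,
    simulate_phenotype_zscores,
    simulate_study_summaries,
    write_study_summary,
)

logger = logging.getLogger(__name__)

ALL_STAGES = ("simulate", "meta", "clump", "cluster", "enrich", "ps", "report")


@dataclass
class PipelineConfig:
    """Validated configuration of an end-to-end run."""

    seed: int = 0
    outdir: str = "mameta_run"
    stages: tuple[str, ...] = ALL_STAGES
    n_axes: int = 2
    min_studies: int = 5
    with_bmi: bool = False
    p_threshold: float = 5e-8
    r2_threshold: float = 0.05
    clump_window: int = 5_000_000
    merge_distance: int = 1_000_000
    flank: int = 500_000
    null_window: int = 50_000
    null_r2_max: float = 0.05
    n_phenotypes: int = 10
    k_clusters: int | None = None
    k_min: int = 2
    k_max: int = 6
    min_cluster_size: int = 5
    cohort_size: int = 3000
    outcome_effects: dict[str, float] = field(default_factory=dict)
    alpha: float = 0.05
    simulation: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise ValueError(f"unknown stages {sorted(unknown)}")
        if not 0 < self.p_threshold < 1:
            raise ValueError("p_threshold must lie in (0, 1)")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in cls.__dataclass_fields__.values()}
        bad = set(raw) - known
        if bad:
            raise ValueError(f"unknown config keys {sorted(bad)}")
        if "stages" in raw:
            raw["stages"] = tuple(raw["stages"])
        return cls(**raw)

    def sim_config(self) -> SimulationConfig:
        sim = dict(self.simulation)
        sim.setdefault("seed", self.seed)
        return SimulationConfig(**sim)

    def config_hash(self) -> str:
        blob = yaml.safe_dump(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


@dataclass
class RunManifest:
    config_hash: str
    version: str
    checksums: dict[str, str] = field(default_factory=dict)
    wall_clock: dict[str, float] = field(default_factory=dict)

    def write(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2, sort_keys=True)


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


class PipelineRun:
    """Executes stages in dependency order, holding intermediate state."""

    def __init__(self, config: PipelineConfig):
        self.cfg = config
        self.outdir = Path(config.outdir)
        self.outdir.mkdir(parents=True, exist_ok=True)
        self.manifest = RunManifest(config.config_hash(), __version__)
        self.state: dict = {}

    def _write(self, name: str, frame: pd.DataFrame) -> None:
        path = self.outdir / name
        frame.to_csv(path, sep="\t", index=False, na_rep="NA")
        self.manifest.checksums[name] = _checksum(path)

    def _need(self, key: str, stage: str) -> None:
        if key not in self.state:
            raise RuntimeError(
                f"stage {stage!r} requires {key!r}; enable the producing stage"
            )

    # --- stages ----------------------------------------------------------
    def stage_simulate(self) -> None:
        sim = self.cfg.sim_config()
        panels = simulate_haplotype_panels(sim)
        studies, truth = simulate_study_summaries(sim, panels)
        for st in studies:
            write_study_summary(st, self.outdir / f"study_{st.study_id}.tsv")
        from .simulate import write_truth_sidecar

        path = self.outdir / "truth.yaml"
        write_truth_sidecar(truth, path)
        self.manifest.checksums["truth.yaml"] = _checksum(path)
        self.state.update(sim=sim, panels=panels, studies=studies,
                          truth=truth)

    def stage_meta(self) -> None:
        self._need("studies", "meta")
        scan = run_meta_scan(
            self.state["studies"], n_axes=self.cfg.n_axes,
            min_studies=self.cfg.min_studies, with_bmi=self.cfg.with_bmi,
        )
        self._write("meta_results.tsv", scan.meta)
        self._write("fixed_effects.tsv", scan.fixed)
        self._write("axes.tsv", scan.axes.to_frame().reset_index(names="study"))
        self.state["scan"] = scan

    def stage_clump(self) -> None:
        self._need("scan", "clump")
        ld = LDReference(self.state["panels"])
        signals = greedy_clump(
            self.state["scan"].meta, ld, p_threshold=self.cfg.p_threshold,
            r2_threshold=self.cfg.r2_threshold, window=self.cfg.clump_window,
        )
        loci = merge_loci(signals, self.cfg.merge_distance, self.cfg.flank)
        loci = flag_novelty(loci, self.state.get("known_variants",
                                                 pd.DataFrame(columns=["CHR", "POS"])))
        self._write("signals.tsv", signals_to_frame(signals))
        self._write("loci.tsv", loci_to_frame(loci))
        self.state.update(ld=ld, signals=signals, loci=loci)

    def stage_cluster(self) -> None:
        self._need("signals", "cluster")
        sim = self.state["sim"]
        index_ids = [s.index_snv for s in self.state["signals"]]
        if len(index_ids) < 2:
            logger.warning("fewer than 2 signals; clustering skipped")
            return
        Z, true_assign = simulate_phenotype_zscores(
            sim, n_phenotypes=self.cfg.n_phenotypes, snv_ids=index_ids)
        if self.cfg.k_clusters is not None:
            k = self.cfg.k_clusters
            votes = {}
        else:
            hi = min(self.cfg.k_max, len(index_ids) - 1)
            lo = min(self.cfg.k_min, hi)
            k, votes = select_k(Z, range(lo, hi + 1), seed=self.cfg.seed)
        model = impute_kmeans(Z, k, seed=self.cfg.seed)
        profile = cluster_phenotype_association(model)
        self._write("cluster_assignments.tsv", pd.DataFrame({
            "SNV": model.snv_ids, "cluster": model.labels,
            "true_cluster": true_assign,
        }))
        self._write("cluster_centroids.tsv", pd.DataFrame(
            model.centroids, columns=model.phenotypes).assign(
                cluster=range(model.k)))
        temp = pd.DataFrame(profile.temperature, columns=profile.phenotypes)
        temp.insert(0, "cluster", range(model.k))
        self._write("cluster_temperatures.tsv", temp)
        self.state.update(zmatrix=Z, cluster_model=model, profile=profile,
                          true_assign=true_assign, select_k_votes=votes)

        scan = self.state["scan"]
        meta_idx = scan.meta.set_index("SNV").loc[index_ids]
        fe_idx = scan.fixed.set_index("SNV").loc[index_ids]
        betas = np.abs(fe_idx["BETA_FE"].to_numpy())
        variances = fe_idx["SE_FE"].to_numpy() ** 2
        if model.k >= 2:
            eff = cluster_t2d_effects(betas, variances, model)
            self._write("cluster_t2d_effects.tsv", pd.DataFrame({
                "cluster": range(model.k), "gamma": eff["gamma"],
                "se": eff["se"], "mean_or": eff["mean_or"],
            }))
            self.state["cluster_t2d"] = eff
            zcols = [c for c in meta_idx.columns if c.startswith("Z_AXIS")]
            if zcols:
                anova = cluster_axis_anova(meta_idx[zcols].to_numpy(), model)
                self._write("cluster_axis_anova.tsv", anova)
                self.state["axis_anova"] = anova

    def stage_enrich(self) -> None:
        self._need("cluster_model", "enrich")
        sim = self.state["sim"]
        scan = self.state["scan"]
        model = self.state["cluster_model"]
        ld = self.state["ld"]
        all_snvs = scan.meta[["SNV", "CHR", "POS"]]
        index_ids = model.snv_ids
        idx_frame = all_snvs.set_index("SNV").loc[index_ids].reset_index()
        nulls: set[str] = set()
        for snv in index_ids:
            nulls |= set(select_null_snvs(
                snv, all_snvs, ld, window=self.cfg.null_window,
                r2_max=self.cfg.null_r2_max))
        nulls -= set(index_ids)
        null_frame = all_snvs.set_index("SNV").loc[sorted(nulls)].reset_index()
        ann = simulate_annotations(sim, idx_frame, null_frame)
        clusters = {
            str(c): idx_frame.loc[[model.labels[index_ids.index(s)] == c
                                   for s in idx_frame["SNV"]]]
            for c in range(model.k)
        }
        clusters["all"] = idx_frame
        table = enrichment_scan(
            clusters, null_frame, ann,
            alpha=self.cfg.alpha, min_cluster_size=self.cfg.min_cluster_size,
        )
        self._write("enrichment.tsv", table)
        self.state.update(annotations=ann, enrichment=table,
                          null_frame=null_frame)

    def stage_ps(self) -> None:
        self._need("cluster_model", "ps")
        sim = self.state["sim"]
        model = self.state["cluster_model"]
        studies = self.state["studies"]
        panels = self.state["panels"]
        index_ids = model.snv_ids

        per_anc: dict[str, pd.DataFrame] = {}
        groups = sorted({st.ancestry for st in studies})
        for g in groups:
            rows = []
            for snv in index_ids:
                bs, ss = [], []
                ea = "A"
                for st in studies:
                    if st.ancestry != g:
                        continue
                    t = st.table.loc[st.table["SNV"] == snv]
                    if len(t):
                        bs.append(float(t["BETA"].iloc[0]))
                        ss.append(float(t["SE"].iloc[0]))
                        ea = str(t["EA"].iloc[0])
                if bs:
                    fe = fixed_effects_meta(np.array(bs), np.array(ss), snv=snv)
                    rows.append({"SNV": snv, "EA": ea, "BETA_FE": fe.beta})
            per_anc[g] = pd.DataFrame(rows)
        assign = pd.Series(model.labels.astype(str), index=index_ids)
        ps_model = build_ps_model(per_anc, assign)
        self._write("ps_weights.tsv", ps_model.weights)

        results = []
        for g in groups:
            cohort = simulate_cohort(
                sim, ps_model, panels, g, n_individuals=self.cfg.cohort_size,
                outcome_effects=self.cfg.outcome_effects or None,
            )
            scores = compute_partitioned_ps(cohort, ps_model, g)
            results += associate_outcome(scores, cohort, "outcome",
                                         covariates=["age", "sex"])
        res_frame = pd.DataFrame([{
            "outcome": r.outcome, "component": r.cluster, "ancestry": r.ancestry,
            "effect": r.effect, "se": r.se, "p": r.p, "n": r.n,
        } for r in results])
        pooled_rows = []
        for comp, grp in res_frame.groupby("component"):
            pool = random_effects_meta(grp["effect"], grp["se"])
            pooled_rows.append({
                "outcome": "outcome", "component": comp, "ancestry": "pooled",
                "effect": pool["estimate"], "se": pool["se"], "p": pool["p"],
                "tau2": pool["tau2"], "q": pool["q"],
            })
        res_frame = pd.concat([res_frame, pd.DataFrame(pooled_rows)],
                              ignore_index=True)
        self._write("ps_associations.tsv", res_frame)
        self.state.update(ps_model=ps_model, ps_results=res_frame)

    def stage_report(self) -> None:
        report = generate_report(self.state, self.cfg)
        path = self.outdir / "report.txt"
        path.write_text(report)
        self.manifest.checksums["report.txt"] = _checksum(path)
        self.state["report"] = report

    def run(self) -> RunManifest:
        order = [s for s in ALL_STAGES if s in self.cfg.stages]
        for stage in order:
            t0 = time.time()
            try:
                getattr(self, f"stage_{stage}")()
            except Exception:
                logger.error("stage %r failed", stage)
                raise
            self.manifest.wall_clock[stage] = round(time.time() - t0, 3)
            logger.info("stage %s done in %.1fs", stage,
                        self.manifest.wall_clock[stage])
        self.manifest.write(self.outdir / "manifest.json")
        return self.manifest


def run_pipeline(config: PipelineConfig) -> tuple[RunManifest, dict]:
    """Execute the configured stages; returns the manifest and run state."""
    run = PipelineRun(config)
    manifest = run.run()
    return manifest, run.state


def generate_report(state: dict, cfg: PipelineConfig) -> str:
    """Plain-text summary assembled from the emitted tables.

    Every number is recomputed from the underlying tables: discovery counts
    and percentages, the heterogeneity tallies at the Bonferroni threshold
    with the one-sided binomial enrichment P, cluster sizes, enrichment
    hits and pooled score associations.
    """
    lines = ["# mameta run report", ""]
    if "scan" in state:
        meta = state["scan"].meta
        lam = genomic_control_lambda(np.clip(meta["P_ASSOC"], 1e-300, 1.0))
        lines.append(f"SNVs meta-analysed: {len(meta)} "
                     f"(genomic control lambda {lam:.3f})")
    if "signals" in state:
        signals = state["signals"]
        loci = state.get("loci", [])
        n_novel = sum(l.novel for l in loci)
        lines.append(f"Signals: {len(signals)}; loci: {len(loci)}")
        if loci:
            s = summarize_discovery(n_novel, len(loci))
            lines.append(f"Novel loci: {s['count']}/{s['total']} "
                         f"({s['percent']}%)")
        if signals:
            thr = bonferroni_threshold(cfg.alpha, len(signals))
            meta = state["scan"].meta.set_index("SNV")
            idx = [s.index_snv for s in signals]
            n_anc = int((meta.loc[idx, "P_ANC_HET"] < thr).sum())
            n_res = int((meta.loc[idx, "P_RES_HET"] < thr).sum())
            p_anc, expected = binomial_enrichment_test(n_anc, len(signals), thr)
            s_anc = summarize_discovery(n_anc, len(signals))
            s_res = summarize_discovery(n_res, len(signals))
            lines.append(
                f"Heterogeneity threshold (Bonferroni, {len(signals)} signals): "
                f"{thr:.1e}")
            lines.append(
                f"Ancestry-correlated heterogeneity: {s_anc['count']}/"
                f"{s_anc['total']} ({s_anc['percent']}%), expected "
                f"{expected:.2f}, one-sided binomial P = {p_anc:.3g}")
            lines.append(
                f"Residual heterogeneity: {s_res['count']}/{s_res['total']} "
                f"({s_res['percent']}%)")
    if "cluster_model" in state:
        model = state["cluster_model"]
        sizes = ", ".join(str(int(s)) for s in model.sizes())
        lines.append(f"Clusters: k = {model.k} (sizes {sizes})")
    if "enrichment" in state and len(state["enrichment"]):
        enr = state["enrichment"]
        sig = enr.loc[enr["significant"]]
        lines.append(f"Enrichment tests: {len(enr)}; significant: {len(sig)}")
        for rec in sig.itertuples(index=False):
            lines.append(f"  cluster {rec.cluster} x {rec.cell_type}: "
                         f"theta = {rec.theta:.3f} (P = {rec.p:.2e})")
    if "ps_results" in state:
        pooled = state["ps_results"]
        pooled = pooled.loc[pooled["ancestry"] == "pooled"]
        lines.append("Pooled score associations (log-OR per SD):")
        for rec in pooled.itertuples(index=False):
            lines.append(f"  {rec.component}: {rec.effect:+.4f} "
                         f"(SE {rec.se:.4f}, P = {rec.p:.2e})")
    return "\n".join(lines) + "\n"
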