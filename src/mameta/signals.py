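"""Signal and locus definition: greedy LD clumping and locus merging.

Genome-wide-significant SNVs are clumped around index variants in ascending
P-value order; a SNV joins a clump when it lies within the window of the
index and is in LD (max r^2 over continental reference panels above the
threshold).  Index SNVs closer than the merge distance chain into loci, and
loci are flagged novel unless they contain a previously reported variant.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .simulate import HaplotypePanel

logger = logging.getLogger(__name__)

P_GENOME_WIDE = 5e-8
R2_CLUMP = 0.05
CLUMP_WINDOW_BP = 5_000_000
LOCUS_MERGE_BP = 1_000_000
LOCUS_FLANK_BP = 500_000


@dataclass
class Signal:
    index_snv: str
    chrom: str
    pos: int
    p: float
    members: list[str] = field(default_factory=list)


@dataclass
class Locus:
    locus_id: str
    chrom: str
    start: int
    end: int
    signals: list[str] = field(default_factory=list)
    novel: bool = True


class LDReference:
    """r^2 oracle backed by per-group haplotype panels.

    r^2 is the squared Pearson correlation between 0/1 haplotype allele
    vectors; monomorphic SNVs give an undefined r^2 for that group and are
    excluded from the max over groups.
    """

    def __init__(self, panels: dict[str, HaplotypePanel]):
        self.panels = panels
        self._index = {g: {s: j for j, s in enumerate(p.snv_ids)}
                       for g, p in panels.items()}

    def r2(self, snv_a: str, snv_b: str) -> tuple[dict[str, float], float]:
        """Per-group r^2 plus the max over groups with defined values."""
        if snv_a == snv_b:
            return {g: 1.0 for g in self.panels}, 1.0
        per_group: dict[str, float] = {}
        defined = []
        for g, panel in self.panels.items():
            idx = self._index[g]
            if snv_a not in idx or snv_b not in idx:
                raise KeyError(f"SNV missing from panel {g}")
            x = panel.haplotypes[:, idx[snv_a]].astype(float)
            y = panel.haplotypes[:, idx[snv_b]].astype(float)
            if x.std() == 0 or y.std() == 0:
                per_group[g] = np.nan
                continue
            r = np.corrcoef(x, y)[0, 1]
            per_group[g] = float(r * r)
            defined.append(per_group[g])
        if not defined:
            raise ValueError(f"r2({snv_a},{snv_b}) undefined in every group")
        return per_group, max(defined)

    def max_r2(self, snv_a: str, snv_b: str) -> float:
        return self.r2(snv_a, snv_b)[1]


def ld_r2(snv_a: str, snv_b: str, panels: dict[str, HaplotypePanel]):
    """Convenience wrapper: per-group r^2 and max over groups."""
    return LDReference(panels).r2(snv_a, snv_b)


def greedy_clump(
    meta_results: pd.DataFrame,
    ld: LDReference,
    p_threshold: float = P_GENOME_WIDE,
    r2_threshold: float = R2_CLUMP,
    window: int = CLUMP_WINDOW_BP,
    p_column: str = "P_ASSOC",
) -> list[Signal]:
    """Greedy clumping of significant SNVs into independent signals.

    SNVs with P below ``p_threshold`` are visited in ascending P (ties broken
    by chromosome, position, then effect allele for cross-platform
    determinism).  Each unassigned SNV becomes an index; unassigned
    significant SNVs strictly within ``window`` bp of the index, with
    max-over-groups r^2 above ``r2_threshold``, join its clump.  The
    resulting index SNVs are pairwise r^2 <= threshold.
    """
    df = meta_results.loc[meta_results[p_column] < p_threshold].copy()
    if df.empty:
        return []
    ea = df["EA"] if "EA" in df else pd.Series("", index=df.index)
    df = df.assign(_ea=ea.astype(str), _chr=df["CHR"].astype(str))
    df = df.sort_values([p_column, "_chr", "POS", "_ea"], kind="mergesort")
    assigned: set[str] = set()
    signals: list[Signal] = []
    recs = df[["SNV", "_chr", "POS", p_column]].to_records(index=False)
    for i, (snv, chrom, pos, p) in enumerate(recs):
        if snv in assigned:
            continue
        sig = Signal(index_snv=str(snv), chrom=str(chrom), pos=int(pos),
                     p=float(p), members=[str(snv)])
        assigned.add(snv)
        for snv2, chrom2, pos2, _ in recs[i + 1:]:
            if snv2 in assigned or chrom2 != chrom:
                continue
            if abs(int(pos2) - int(pos)) >= window:
                continue
            if ld.max_r2(str(snv), str(snv2)) > r2_threshold:
                sig.members.append(str(snv2))
                assigned.add(snv2)
        signals.append(sig)
    return signals


def merge_loci(
    signals: list[Signal],
    merge_distance: int = LOCUS_MERGE_BP,
    flank: int = LOCUS_FLANK_BP,
) -> list[Locus]:
    """Single-linkage chaining of index SNVs into loci.

    Index SNVs on the same chromosome separated by strictly less than
    ``merge_distance`` bp share a locus (transitively); locus bounds extend
    ``flank`` bp beyond the extreme member indexes, floored at 1.
    """
    loci: list[Locus] = []
    by_chrom: dict[str, list[Signal]] = {}
    for s in signals:
        by_chrom.setdefault(s.chrom, []).append(s)
    n = 0
    for chrom in sorted(by_chrom):
        sigs = sorted(by_chrom[chrom], key=lambda s: s.pos)
        group: list[Signal] = []
        for s in sigs:
            if group and s.pos - group[-1].pos >= merge_distance:
                n += 1
                loci.append(_make_locus(n, chrom, group, flank))
                group = []
            group.append(s)
        if group:
            n += 1
            loci.append(_make_locus(n, chrom, group, flank))
    return loci


def _make_locus(n: int, chrom: str, group: list[Signal], flank: int) -> Locus:
    start = max(1, min(s.pos for s in group) - flank)
    end = max(s.pos for s in group) + flank
    return Locus(locus_id=f"locus{n}", chrom=chrom, start=start, end=end,
                 signals=[s.index_snv for s in group])


def flag_novelty(loci: list[Locus], known_variants: pd.DataFrame) -> list[Locus]:
    """Mark loci previously reported when a known variant falls inside them.

    ``known_variants`` has columns CHR, POS (1-based); bounds are closed.
    """
    for locus in loci:
        if known_variants is None or known_variants.empty:
            locus.novel = True
            continue
        kk = known_variants.loc[known_variants["CHR"].astype(str) == locus.chrom]
        hit = ((kk["POS"] >= locus.start) & (kk["POS"] <= locus.end)).any()
        locus.novel = not bool(hit)
    return loci


def summarize_discovery(numerator: int, denominator: int) -> dict:
    """Count + percentage (one decimal place) for discovery reporting."""
    if denominator <= 0:
        raise ValueError("denominator must be positive")
    return {
        "count": numerator,
        "total": denominator,
        "percent": round(100.0 * numerator / denominator, 1),
    }


def signals_to_frame(signals: list[Signal]) -> pd.DataFrame:
    return pd.DataFrame(
        [{"SNV": s.index_snv, "CHR": s.chrom, "POS": s.pos, "P": s.p,
          "N_MEMBERS": len(s.members), "MEMBERS": ",".join(s.members)}
         for s in signals]
    )


def loci_to_frame(loci: list[Locus]) -> pd.DataFrame:
    return pd.DataFrame(
        [{"LOCUS": l.locus_id, "CHR": l.chrom, "START": l.start, "END": l.end,
          "N_SIGNALS": len(l.signals), "SIGNALS": ",".join(l.signals),
          "NOVEL": l.novel}
         for l in loci]
    )


def loci_to_bed(loci: list[Locus]) -> pd.DataFrame:
    """Loci as BED intervals (1-based closed -> 0-based half-open)."""
    return pd.DataFrame(
        [{"chrom": l.chrom, "start": l.start - 1, "end": l.end,
          "name": l.locus_id} for l in loci]
    )
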