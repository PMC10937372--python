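"""Readers for the package's tab-delimited external formats."""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .simulate import AnnotationSet, StudySummary

GENIC_NAMES = {"exon", "utr3", "utr5"}


def read_study_summary(path, study_id: str | None = None,
                       ancestry: str = "NA",
                       mean_bmi_cases: float = float("nan"),
                       mean_bmi_controls: float = float("nan")) -> StudySummary:
    """Read one study from the standard tab-delimited summary format.

    Header: CHR POS EA NEA EAF BETA SE N_CASE N_CONTROL INFO.  SNV ids are
    synthesized as CHR:POS when no SNVID column is present.
    """
    t = pd.read_csv(path, sep="\t")
    if "SNVID" in t.columns:
        t = t.rename(columns={"SNVID": "SNV"})
    else:
        t["SNV"] = t["CHR"].astype(str) + ":" + t["POS"].astype(str)
    n_case = int(t["N_CASE"].iloc[0])
    n_ctrl = int(t["N_CONTROL"].iloc[0])
    table = t[["SNV", "CHR", "POS", "EA", "NEA", "EAF", "BETA", "SE", "INFO"]]
    return StudySummary(
        study_id=study_id or Path(path).stem,
        ancestry=ancestry,
        table=table,
        n_cases=n_case,
        n_controls=n_ctrl,
        mean_bmi_cases=mean_bmi_cases,
        mean_bmi_controls=mean_bmi_controls,
    )


def read_annotation_bed(path) -> AnnotationSet:
    """Read a 4-column BED (chrom, start, end, class/cell-type name).

    Names in {exon, utr3, utr5} become genic classes; everything else is a
    cell-type peak set.
    """
    t = pd.read_csv(path, sep="\t", header=None,
                    names=["chrom", "start", "end", "name"])
    genic, peaks = {}, {}
    for name, grp in t.groupby("name"):
        df = grp[["chrom", "start", "end"]].reset_index(drop=True)
        (genic if name in GENIC_NAMES else peaks)[str(name)] = df
    return AnnotationSet(genic=genic, peaks=peaks)


def read_zscore_matrix(path):
    """Z-score matrix from tab-delimited text with NA tokens."""
    import numpy as np

    from .simulate import ZScoreMatrix

    t = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA"])
    values = t.to_numpy(dtype=float)
    return ZScoreMatrix(values, np.isnan(values), list(t.index.astype(str)),
                        list(t.columns.astype(str)))


def write_zscore_matrix(Z, path) -> None:
    Z.to_frame().to_csv(path, sep="\t", na_rep="NA")
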