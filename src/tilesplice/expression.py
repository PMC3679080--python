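"""Gene-level expression, fold change and the responsive-gene call.

A gene's expression on one array is the mean log2 intensity of its exon
probes; the intron mean is computed alongside for downstream gating.  Genes
are called stress responsive when a two-sample t-test on the per-array
expression values survives BH correction at FDR 0.05 AND the linear fold
change is at least 2 (|log2 FC| >= 1).

The fold change is treatment − control on the log2 scale: induced genes
are positive.  Only genes represented by more than ``min_probes`` mapped
probes (default 3) carry expression values at all.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .mapping import MappedProbe
from .preprocess import IntensityMatrix
from .stats import bh_adjust, pooled_t_pvalues

__all__ = ["gene_expression", "fold_change_and_test", "write_expression_table"]

GENE_FDR = 0.05
MIN_LINEAR_FC = 2.0
MIN_PROBES_FOR_EXPRESSION = 3  # genes need strictly more probes than this


def _probe_index(m: IntensityMatrix) -> dict[str, int]:
    return {p: i for i, p in enumerate(m.probe_ids)}


def gene_segment_means(
    m: IntensityMatrix, mapped: list[MappedProbe]
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Per-gene mean log2 intensity of exon and intron probes, per array.

    Returns (exon_means, intron_means, counts): the means are genes × arrays
    frames (NaN where a gene has no probes of that kind), counts has columns
    n_probes / n_exon_probes / n_intron_probes.
    """
    if m.state != "normalized_log2":
        raise ValueError("gene expression requires a normalized log2 matrix")
    idx = _probe_index(m)
    rows = [
        (p.gene_id, p.segment_kind, idx[p.probe_id])
        for p in mapped
        if p.probe_id in idx
    ]
    df = pd.DataFrame(rows, columns=["gene_id", "kind", "row"])
    array_ids = [a.array_id for a in m.arrays]

    def kind_means(kind: str) -> pd.DataFrame:
        sub = df[df["kind"] == kind]
        out = {}
        for gene, grp in sub.groupby("gene_id"):
            out[gene] = m.values[grp["row"].to_numpy()].mean(axis=0)
        return pd.DataFrame.from_dict(out, orient="index", columns=array_ids)

    counts = df.groupby("gene_id").agg(
        n_probes=("kind", "size"),
        n_exon_probes=("kind", lambda s: int((s == "exon").sum())),
        n_intron_probes=("kind", lambda s: int((s == "intron").sum())),
    )
    return kind_means("exon"), kind_means("intron"), counts


def gene_expression(
    m: IntensityMatrix,
    mapped: list[MappedProbe],
    min_probes: int = MIN_PROBES_FOR_EXPRESSION,
) -> pd.DataFrame:
    """Expression table: per-condition expression for sufficiently probed genes.

    Rows are genes with more than ``min_probes`` mapped probes; columns
    ``expression_control``/``expression_treatment`` are means over the
    condition's replicate arrays of the per-array exon-probe means.  Genes
    whose probes are all intronic are kept with NaN expression and
    ``flagged=True`` (expression is undefined without exon probes).
    """
    exon_means, intron_means, counts = gene_segment_means(m, mapped)
    eligible = counts.index[counts["n_probes"] > min_probes]
    ctrl_cols = m.columns("control")
    trt_cols = m.columns("treatment")
    exon = exon_means.reindex(eligible)
    intron = intron_means.reindex(eligible)
    tbl = pd.DataFrame(index=eligible)
    tbl.index.name = "gene_id"
    tbl["n_probes"] = counts.loc[eligible, "n_probes"]
    tbl["n_intron_probes"] = counts.loc[eligible, "n_intron_probes"]
    tbl["expression_control"] = exon.iloc[:, ctrl_cols].mean(axis=1)
    tbl["expression_treatment"] = exon.iloc[:, trt_cols].mean(axis=1)
    tbl["intron_mean_control"] = intron.iloc[:, ctrl_cols].mean(axis=1)
    tbl["intron_mean_treatment"] = intron.iloc[:, trt_cols].mean(axis=1)
    tbl["flagged"] = tbl["expression_control"].isna()
    # keep the per-array exon means for the t-test
    tbl.attrs["exon_means"] = exon
    tbl.attrs["control_cols"] = ctrl_cols
    tbl.attrs["treatment_cols"] = trt_cols
    return tbl


def fold_change_and_test(
    tbl: pd.DataFrame,
    fdr: float = GENE_FDR,
    min_linear_fc: float = MIN_LINEAR_FC,
    welch: bool = False,
) -> pd.DataFrame:
    """Add log2 fold change, t-test p, BH-adjusted p and the responsive call.

    Operates on the table from :func:`gene_expression` (which carries the
    per-array exon means).  Genes without exon probes are left NaN and never
    called responsive.
    """
    exon_means: pd.DataFrame = tbl.attrs["exon_means"]
    ctrl_cols = tbl.attrs["control_cols"]
    trt_cols = tbl.attrs["treatment_cols"]
    out = tbl.copy()
    out["log2_fold_change"] = out["expression_treatment"] - out["expression_control"]
    out["linear_fold_change"] = np.sign(out["log2_fold_change"]) * 2 ** np.abs(
        out["log2_fold_change"]
    )
    testable = out.index[~out["flagged"]]
    vals = exon_means.reindex(testable).to_numpy()
    p = pooled_t_pvalues(
        vals[:, trt_cols], vals[:, ctrl_cols], alternative="two-sided", welch=welch
    )
    out["t_p_value"] = np.nan
    out.loc[testable, "t_p_value"] = p
    out["bh_adjusted_p"] = np.nan
    out.loc[testable, "bh_adjusted_p"] = bh_adjust(p)
    out["is_responsive"] = (
        (out["bh_adjusted_p"] <= fdr)
        & (np.abs(out["log2_fold_change"]) >= np.log2(min_linear_fc))
    ).fillna(False)
    out.attrs.update(tbl.attrs)
    return out


def write_expression_table(tbl: pd.DataFrame, path: str) -> None:
    cols = [
        "expression_control", "expression_treatment",
        "log2_fold_change", "linear_fold_change",
        "t_p_value", "bh_adjusted_p", "is_responsive",
    ]
    present = [c for c in cols if c in tbl.columns]
    tbl[present].to_csv(path, sep="\t")
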