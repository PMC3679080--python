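"""Detection of condition-regulated alternative splicing from intron probes.

The core algorithm: among genes whose exons are clearly expressed but whose
introns sit at background level, each intron is tested for differential
expression between conditions by combining probe-level one-sided t-test
p-values with Fisher's method.  Probe intensities are never compared across
probes (sequence-dependent affinity makes absolute levels incomparable);
only the per-probe p-values of the between-condition comparison are
combined.

For every probe a one-sided p-value p_up (treatment > control) is computed
and the complement p_down = 1 − p_up covers the opposite direction, so a
probe moving against the tested direction contributes its complementary
value.  The two directional Fisher combinations give combined p-values for
"intron higher under treatment" and "higher under control"; the smaller of
the two is the intron-level p-value.  Because the minimum over two
directions is taken, the null distribution of that minimum is uniform at
twice the nominal level; by default a factor-2 (Bonferroni over the two
directions) correction restores calibration before BH so the FDR target is
actually met (``double_min_p=False`` reproduces the uncorrected minimum).
BH correction across all tested introns controls the FDR (default 0.1).
A significant intron is classified
as *retained* only when every one of its probes changes significantly
(unadjusted p < 0.05) in the winning direction; any partial pattern —
compatible with alternative 5'/3' sites, exon skipping, or partial
retention — is *unknown*.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .mapping import MappedProbe
from .preprocess import IntensityMatrix
from .stats import bh_adjust, pooled_t_pvalues

__all__ = [
    "GatingThresholds",
    "IntronTestResult",
    "gate_genes",
    "probe_level_tests",
    "fisher_combine",
    "intron_test",
    "classify_splice_type",
    "write_intron_results",
]

logger = logging.getLogger(__name__)

INTRON_FDR = 0.1
PROBE_ALPHA = 0.05
MIN_GENE_PROBES = 9  # "more than eight probes"
P_FLOOR = 1e-300


@dataclass(frozen=True)
class GatingThresholds:
    """Global log2-intensity thresholds separating exon from background.

    ``exon_expression_threshold`` — median of all exon-probe values; a
    gene's exon mean must exceed it.  ``intron_background_threshold`` —
    median of all probe values; a gene's intron mean must stay below it
    (controls for genomic-DNA contamination).  ``exon_mode`` is a
    Freedman–Diaconis histogram mode of the exon-probe values, reported for
    diagnostics only.
    """

    exon_expression_threshold: float
    intron_background_threshold: float
    exon_mode: float = field(default=float("nan"))


def _fd_mode(values: np.ndarray) -> float:
    """Histogram mode (midpoint of tallest Freedman–Diaconis bin)."""
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        return float("nan")
    counts, edges = np.histogram(values, bins="fd")
    i = int(np.argmax(counts))
    return float((edges[i] + edges[i + 1]) / 2)


def compute_thresholds(m: IntensityMatrix, mapped: list[MappedProbe]) -> GatingThresholds:
    idx = {p: i for i, p in enumerate(m.probe_ids)}
    exon_rows = [idx[p.probe_id] for p in mapped if p.segment_kind == "exon" and p.probe_id in idx]
    all_rows = [idx[p.probe_id] for p in mapped if p.probe_id in idx]
    exon_vals = m.values[exon_rows].ravel()
    all_vals = m.values[all_rows].ravel()
    return GatingThresholds(
        exon_expression_threshold=float(np.median(exon_vals)),
        intron_background_threshold=float(np.median(all_vals)),
        exon_mode=_fd_mode(exon_vals),
    )


def gate_genes(
    m: IntensityMatrix,
    mapped: list[MappedProbe],
    tbl: pd.DataFrame,
    min_probes: int = MIN_GENE_PROBES,
) -> tuple[list[str], GatingThresholds]:
    """Select genes eligible for the intron test.

    A gene is eligible when it has at least ``min_probes`` mapped probes of
    which at least one is intronic, and — in at least one condition — its
    exon mean exceeds the exon threshold while its intron mean stays below
    the background threshold.  ``tbl`` is the expression table from
    :func:`tilesplice.expression.gene_expression`.
    """
    if m.state != "normalized_log2":
        raise ValueError("gating requires a normalized log2 matrix")
    thr = compute_thresholds(m, mapped)
    eligible = []
    for gene in tbl.index:
        row = tbl.loc[gene]
        if row["n_probes"] < min_probes or row["n_intron_probes"] < 1:
            continue
        if row["flagged"]:
            continue
        ok = False
        for cond in ("control", "treatment"):
            exon_mean = row[f"expression_{cond}"]
            intron_mean = row[f"intron_mean_{cond}"]
            if (
                np.isfinite(intron_mean)
                and exon_mean > thr.exon_expression_threshold
                and intron_mean < thr.intron_background_threshold
            ):
                ok = True
        if ok:
            eligible.append(gene)
    if not eligible:
        warnings.warn("no genes passed the eligibility gate", stacklevel=2)
    logger.info("gated %d/%d genes (exon>%.3f, intron<%.3f)",
                len(eligible), len(tbl), thr.exon_expression_threshold,
                thr.intron_background_threshold)
    return eligible, thr


def probe_level_tests(
    treatment: np.ndarray, control: np.ndarray, welch: bool = False
) -> tuple[np.ndarray, np.ndarray]:
    """Per-probe one-sided p-values (p_up, p_down) for treatment vs control.

    Rows are probes of one intron; a probe is only ever compared to itself
    across conditions.  p_down is the exact complement 1 − p_up, so a probe
    shifting against the tested direction enters the opposite combination
    with its complementary value.
    """
    p_up = pooled_t_pvalues(treatment, control, alternative="greater", welch=welch)
    return p_up, 1.0 - p_up


def fisher_combine(p_values: np.ndarray) -> float:
    """Fisher's method: X² = −2 Σ ln p against chi-square with 2k df.

    Requires non-overlapping probes so the p-values can be treated as
    independent.  Zero p-values are floored at 1e-300 with a warning.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ValueError("cannot combine an empty p-value set")
    if np.any(p > 1) or np.any(p < 0):
        raise ValueError("p-values must lie in [0, 1]")
    if np.any(p == 0):
        warnings.warn("zero p-value floored at 1e-300 before Fisher combination",
                      stacklevel=2)
        p = np.maximum(p, P_FLOOR)
    x2 = -2.0 * np.sum(np.log(p))
    return float(sps.chi2.sf(x2, df=2 * p.size))


@dataclass
class IntronTestResult:
    """Outcome of the combined-P test for one intron."""

    gene_id: str
    intron_index: int
    n_probes: int
    probe_p_up: np.ndarray
    probe_p_down: np.ndarray
    combined_p_up: float
    combined_p_down: float
    intron_p: float
    bh_adjusted_p: float = float("nan")
    direction: str = ""  # higher_in_treatment | higher_in_control
    presence: str = ""  # condition with the higher intron signal
    significant: bool = False
    splice_type: str = ""  # retained | unknown (significant introns only)


def classify_splice_type(r: IntronTestResult, alpha: float = PROBE_ALPHA) -> str:
    """"retained" iff every probe is individually significant in the winning
    direction (unadjusted p < alpha); any partial pattern is "unknown"."""
    winning = r.probe_p_up if r.direction == "higher_in_treatment" else r.probe_p_down
    return "retained" if bool(np.all(winning < alpha)) else "unknown"


def intron_test(
    m: IntensityMatrix,
    mapped: list[MappedProbe],
    eligible_genes: list[str],
    fdr: float = INTRON_FDR,
    probe_alpha: float = PROBE_ALPHA,
    welch: bool = False,
    double_min_p: bool = True,
    near_exon_delta: float | None = None,
) -> list[IntronTestResult]:
    """Test every intron of the eligible genes for differential expression.

    ``double_min_p`` (default on) Bonferroni-doubles the min-of-directions
    p-value so its null distribution is uniform and BH delivers the stated
    FDR; set it to False for the uncorrected directional minimum, which
    runs at twice the nominal level.  ``near_exon_delta``, if set,
    additionally requires a significant intron's mean in its presence
    condition to come within ``delta`` log2 units of the gene's exon mean in
    that condition.
    """
    idx = {p: i for i, p in enumerate(m.probe_ids)}
    eligible = set(eligible_genes)
    ctrl_cols = m.columns("control")
    trt_cols = m.columns("treatment")

    # group intron probes: (gene, intron_index) -> matrix rows
    groups: dict[tuple[str, int], list[int]] = {}
    for p in mapped:
        if p.segment_kind == "intron" and p.gene_id in eligible and p.probe_id in idx:
            groups.setdefault((p.gene_id, p.segment_index), []).append(idx[p.probe_id])

    if not groups:
        return []

    # vectorize the probe-level tests across all intron probes at once
    keys = sorted(groups)
    all_rows = np.concatenate([groups[k] for k in keys])
    offsets = np.cumsum([0] + [len(groups[k]) for k in keys])
    vals = m.values[all_rows]
    p_up_all, p_down_all = probe_level_tests(
        vals[:, trt_cols], vals[:, ctrl_cols], welch=welch
    )
    mean_trt_all = vals[:, trt_cols].mean(axis=1)
    mean_ctrl_all = vals[:, ctrl_cols].mean(axis=1)

    results: list[IntronTestResult] = []
    for k, (gene, intron_no) in enumerate(keys):
        sl = slice(offsets[k], offsets[k + 1])
        p_up, p_down = p_up_all[sl], p_down_all[sl]
        c_up = fisher_combine(p_up)
        c_down = fisher_combine(p_down)
        intron_p = min(c_up, c_down)
        direction = "higher_in_treatment" if c_up <= c_down else "higher_in_control"
        presence = (
            "treatment"
            if mean_trt_all[sl].mean() >= mean_ctrl_all[sl].mean()
            else "control"
        )
        results.append(
            IntronTestResult(
                gene_id=gene,
                intron_index=intron_no,
                n_probes=int(sl.stop - sl.start),
                probe_p_up=p_up,
                probe_p_down=p_down,
                combined_p_up=c_up,
                combined_p_down=c_down,
                intron_p=intron_p,
                direction=direction,
                presence=presence,
            )
        )

    # intron_p is the reported min of the two directional combinations; the
    # p entering BH is (optionally) doubled so its null law is uniform
    p_for_bh = np.array([r.intron_p for r in results])
    if double_min_p:
        p_for_bh = np.minimum(1.0, 2.0 * p_for_bh)
    adj = bh_adjust(p_for_bh)
    for r, a in zip(results, adj):
        r.bh_adjusted_p = float(a)
        r.significant = a <= fdr
        if r.significant and near_exon_delta is not None:
            r.significant = _near_exon(m, mapped, r, near_exon_delta)
        if r.significant:
            r.splice_type = classify_splice_type(r, alpha=probe_alpha)
    n_sig = sum(r.significant for r in results)
    logger.info("tested %d introns, %d significant at FDR %.2g", len(results), n_sig, fdr)
    return results


def _near_exon(
    m: IntensityMatrix, mapped: list[MappedProbe], r: IntronTestResult, delta: float
) -> bool:
    """Optional filter: intron mean within delta of the exon mean in the
    presence condition (the intron behaves like an exon there)."""
    idx = {p: i for i, p in enumerate(m.probe_ids)}
    cols = m.columns(r.presence)
    exon_rows = [
        idx[p.probe_id]
        for p in mapped
        if p.gene_id == r.gene_id and p.segment_kind == "exon" and p.probe_id in idx
    ]
    intron_rows = [
        idx[p.probe_id]
        for p in mapped
        if p.gene_id == r.gene_id
        and p.segment_kind == "intron"
        and p.segment_index == r.intron_index
        and p.probe_id in idx
    ]
    if not exon_rows or not intron_rows:
        return False
    exon_mean = m.values[np.ix_(exon_rows, cols)].mean()
    intron_mean = m.values[np.ix_(intron_rows, cols)].mean()
    return bool(abs(exon_mean - intron_mean) <= delta)


def results_frame(results: list[IntronTestResult], significant_only: bool = False) -> pd.DataFrame:
    rows = []
    for r in results:
        if significant_only and not r.significant:
            continue
        rows.append(
            {
                "gene_id": r.gene_id,
                "intron_no": r.intron_index,
                "n_probes": r.n_probes,
                "type": {"retained": "r", "unknown": "u"}.get(r.splice_type, ""),
                "presence": r.presence,
                "direction": r.direction,
                "combined_p": r.intron_p,
                "adjusted_p": r.bh_adjusted_p,
                "significant": r.significant,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "gene_id", "intron_no", "n_probes", "type", "presence",
            "direction", "combined_p", "adjusted_p", "significant",
        ],
    )


def write_intron_results(results: list[IntronTestResult], path: str) -> None:
    results_frame(results).to_csv(path, sep="\t", index=False)
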