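"""Vector-based correlation of an experiment against precompiled stress
indexes.

An index distills one reference stress experiment into its strongest
signature: the (up to) 1,000 genes with the largest absolute fold change
among those with an unadjusted p < 0.05, stored with their signed log2 fold
changes.  An experiment is then scored against the index by Pearson
correlation of the signed log2 fold changes over the shared gene set, so
+1 means direction and intensity match the index exactly and −1 means the
exact opposite response.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = ["StressIndex", "build_index", "correlate", "correlation_matrix"]

INDEX_SIZE = 1000
INDEX_P_CUTOFF = 0.05
MIN_SHARED_GENES = 3


@dataclass(frozen=True)
class StressIndex:
    name: str
    entries: dict[str, float]  # gene_id -> signed log2 fold change

    def __len__(self) -> int:
        return len(self.entries)


def build_index(
    fold_changes: pd.DataFrame,
    name: str = "index",
    k: int = INDEX_SIZE,
    p_cutoff: float = INDEX_P_CUTOFF,
) -> StressIndex:
    """Top-k most-changed significant genes of a reference experiment.

    ``fold_changes`` needs columns ``log2_fold_change`` and ``p_value``
    indexed by gene id.  Genes with p < cutoff are ranked by |log2 FC|
    descending (ties broken by gene id) and the top k kept with their
    signed values.  Fewer than k qualifying genes keeps them all with a
    warning.
    """
    sig = fold_changes[fold_changes["p_value"] < p_cutoff]
    if len(sig) < k:
        warnings.warn(
            f"index {name!r}: only {len(sig)} genes pass p < {p_cutoff} (requested {k})",
            stacklevel=2,
        )
    order = sig.loc[
        sorted(sig.index, key=lambda g: (-abs(sig.at[g, "log2_fold_change"]), g))
    ]
    top = order.head(k)
    return StressIndex(name=name, entries=dict(top["log2_fold_change"]))


def correlate(index: StressIndex, experiment: dict[str, float] | pd.Series) -> float:
    """Pearson correlation of signed log2 fold changes over shared genes.

    Returns NaN (with a warning) when fewer than 3 genes are shared.
    """
    exp = dict(experiment)
    shared = sorted(set(index.entries) & set(exp))
    if len(shared) < MIN_SHARED_GENES:
        warnings.warn(
            f"index {index.name!r}: only {len(shared)} shared genes; correlation undefined",
            stacklevel=2,
        )
        return float("nan")
    x = np.array([index.entries[g] for g in shared])
    y = np.array([exp[g] for g in shared])
    return float(sps.pearsonr(x, y).statistic)


def correlation_matrix(
    indexes: list[StressIndex], experiments: dict[str, dict[str, float]]
) -> pd.DataFrame:
    """Experiments × indexes Pearson correlation table (heatmap-ready)."""
    return pd.DataFrame(
        {
            ix.name: {name: correlate(ix, exp) for name, exp in experiments.items()}
            for ix in indexes
        }
    )


def read_index(path: str, name: str | None = None) -> StressIndex:
    df = pd.read_csv(path, sep="\t")
    return StressIndex(
        name=name or path, entries=dict(zip(df["gene_id"], df["log2_fold_change"]))
    )


def write_index(index: StressIndex, path: str) -> None:
    pd.DataFrame(
        sorted(index.entries.items()), columns=["gene_id", "log2_fold_change"]
    ).to_csv(path, sep="\t", index=False)
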