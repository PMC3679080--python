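"""Assigning tiling probes to exon/intron segments of gene models.

Each retained probe lies fully inside exactly one exon or one intron of
exactly one gene.  Everything else is excluded and counted by reason,
mirroring the funnel of a tiling-array preprocessing run:

* ``control``        — probes flagged as array controls
* ``malformed``      — probe interval of the wrong length
* ``multi_location`` — probe id reported at more than one genomic position,
                       or probe contained in segments of more than one gene
* ``border``         — probe overlapping a gene but crossing an exon/intron
                       (or gene) boundary
* ``intergenic``     — probe overlapping no gene

Probe tables use BED conventions (0-based half-open).  Mapping is by
genomic coordinate regardless of probe strand by default (tiling probes are
synthesized from one strand while hybridization targets are double-stranded
cDNA); ``stranded=True`` restricts assignment to same-strand genes for
strand-specific labelings.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import pandas as pd
from intervaltree import IntervalTree

from .annotation import GeneModel

__all__ = [
    "MappedProbe",
    "PROBE_LENGTH",
    "map_probes",
    "probe_counts_per_gene",
    "read_probe_table",
    "write_mapped_probes",
]

logger = logging.getLogger(__name__)

PROBE_LENGTH = 25  # nt, perfect-match tiling probes

EXCLUSION_REASONS = ("control", "malformed", "multi_location", "border", "intergenic")


@dataclass(frozen=True)
class MappedProbe:
    """A probe assigned to one segment of one gene.

    ``start``/``end`` are 0-based half-open, so ``end - start`` equals the
    probe length (25 by default; 1-based inclusive coordinates would read
    ``end - start + 1``).  ``segment_index`` is 1-based in transcript
    orientation.
    """

    probe_id: str
    chromosome: str
    start: int
    end: int
    strand: str
    gene_id: str
    segment_kind: str  # "exon" | "intron"
    segment_index: int


def read_probe_table(path: str) -> pd.DataFrame:
    """Read a BED-like probe TSV: probe_id, chrom, start, end, strand, is_control."""
    df = pd.read_csv(path, sep="\t", dtype={"probe_id": str, "chrom": str})
    required = {"probe_id", "chrom", "start", "end", "strand", "is_control"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"probe table missing columns: {sorted(missing)}")
    df["is_control"] = df["is_control"].astype(bool)
    return df


def _segment_trees(models: dict[str, GeneModel]) -> dict[str, IntervalTree]:
    """Per-chromosome interval tree of all gene segments."""
    trees: dict[str, IntervalTree] = {}
    for m in models.values():
        tree = trees.setdefault(m.chromosome, IntervalTree())
        for rank, (s, e) in enumerate(m.exons):
            tree[s:e] = (m, "exon", rank)
        for rank, (s, e) in enumerate(m.introns):
            tree[s:e] = (m, "intron", rank)
    return trees


def map_probes(
    probes: pd.DataFrame,
    models: dict[str, GeneModel],
    probe_length: int = PROBE_LENGTH,
    stranded: bool = False,
) -> tuple[list[MappedProbe], pd.Series]:
    """Assign probes to segments; return (mapped probes, exclusion counts).

    The exclusion report is a Series indexed by reason (all reasons present,
    zero-filled).  Retained + excluded always partitions the input rows:
    duplicated probe ids are excluded once per occurrence.
    """
    trees = _segment_trees(models)
    mapped: list[MappedProbe] = []
    excluded = {reason: 0 for reason in EXCLUSION_REASONS}

    dup_ids = _multi_position_ids(probes)

    for row in probes.itertuples(index=False):
        start, end = int(row.start), int(row.end)
        if row.is_control:
            excluded["control"] += 1
            continue
        if end - start != probe_length:
            warnings.warn(
                f"probe {row.probe_id}: interval length {end - start} != {probe_length}",
                stacklevel=2,
            )
            excluded["malformed"] += 1
            continue
        if row.probe_id in dup_ids:
            excluded["multi_location"] += 1
            continue

        tree = trees.get(row.chrom)
        hits = tree[start:end] if tree is not None else set()
        if stranded:
            hits = {h for h in hits if h.data[0].strand == row.strand}
        if not hits:
            excluded["intergenic"] += 1
            continue
        containing = [h for h in hits if h.begin <= start and end <= h.end]
        genes_containing = {h.data[0].gene_id for h in containing}
        if len(genes_containing) > 1:
            excluded["multi_location"] += 1
        elif len(containing) == 0:
            # overlaps a gene segment but is not inside any single one
            excluded["border"] += 1
        else:
            model, kind, rank = containing[0].data
            mapped.append(
                MappedProbe(
                    probe_id=str(row.probe_id),
                    chromosome=str(row.chrom),
                    start=start,
                    end=end,
                    strand=str(row.strand),
                    gene_id=model.gene_id,
                    segment_kind=kind,
                    segment_index=model.segment_index(kind, rank),
                )
            )

    report = pd.Series(excluded, name="n_excluded")
    logger.info(
        "mapped %d/%d probes (%s)",
        len(mapped),
        len(probes),
        ", ".join(f"{k}={v}" for k, v in excluded.items() if v),
    )
    return mapped, report


def _multi_position_ids(probes: pd.DataFrame) -> set[str]:
    """Probe ids reported at more than one genomic position."""
    non_control = probes.loc[~probes["is_control"]]
    pos = non_control.drop_duplicates(subset=["probe_id", "chrom", "start", "end"])
    counts = pos["probe_id"].value_counts()
    return set(counts.index[counts > 1])


def probe_counts_per_gene(
    mapped: list[MappedProbe], all_gene_ids: list[str] | None = None
) -> pd.DataFrame:
    """Per-gene total and intron probe counts (genes with no probes get zero)."""
    rows = [(p.gene_id, p.segment_kind) for p in mapped]
    df = pd.DataFrame(rows, columns=["gene_id", "segment_kind"])
    counts = df.groupby("gene_id").agg(
        n_probes=("segment_kind", "size"),
        n_intron_probes=("segment_kind", lambda s: int((s == "intron").sum())),
    )
    if all_gene_ids is not None:
        counts = counts.reindex(all_gene_ids, fill_value=0)
    counts.index.name = "gene_id"
    return counts.reset_index()


def mapped_probes_frame(mapped: list[MappedProbe]) -> pd.DataFrame:
    """Mapped probes as a DataFrame (column order fixed for TSV round-trips)."""
    return pd.DataFrame(
        [
            (p.probe_id, p.chromosome, p.start, p.end, p.strand,
             p.gene_id, p.segment_kind, p.segment_index)
            for p in mapped
        ],
        columns=[
            "probe_id", "chrom", "start", "end", "strand",
            "gene_id", "segment_kind", "segment_index",
        ],
    )


def write_mapped_probes(mapped: list[MappedProbe], path: str) -> None:
    mapped_probes_frame(mapped).to_csv(path, sep="\t", index=False)


def read_mapped_probes(path: str) -> list[MappedProbe]:
    df = pd.read_csv(path, sep="\t", dtype={"probe_id": str, "chrom": str})
    return [
        MappedProbe(
            probe_id=r.probe_id,
            chromosome=r.chrom,
            start=int(r.start),
            end=int(r.end),
            strand=r.strand,
            gene_id=r.gene_id,
            segment_kind=r.segment_kind,
            segment_index=int(r.segment_index),
        )
        for r in df.itertuples(index=False)
    ]
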