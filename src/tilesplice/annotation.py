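"""Gene models from GFF3 annotation.

A gene annotated with several transcript isoforms is reduced to a single
"base" transcript — the isoform with the most exons — so that the gene is
split into as many exon/intron segments as possible.  Introns are derived
as the gaps between consecutive exons of that transcript.

Coordinates are 0-based half-open internally; GFF3 I/O is 1-based
inclusive as the format requires.  Segment numbering (exon 1, intron 1, ...)
follows transcript orientation, so minus-strand genes are numbered from the
genomic right end.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import gffutils
import pandas as pd

__all__ = [
    "GeneModel",
    "derive_introns",
    "select_base_transcript",
    "read_gene_models",
    "write_gene_model_table",
]


@dataclass(frozen=True)
class GeneModel:
    """One gene's base-transcript segmentation on a chromosome.

    ``exons`` and ``introns`` are sorted, non-overlapping 0-based half-open
    intervals in genomic coordinate order.  ``introns`` are exactly the gaps
    between consecutive exons, so ``len(introns) == len(exons) - 1`` unless
    abutting exons produced zero-length gaps (which are dropped).
    """

    gene_id: str
    chromosome: str
    strand: str
    transcript_id: str
    exons: tuple[tuple[int, int], ...]
    introns: tuple[tuple[int, int], ...] = field(default=())

    @property
    def n_exons(self) -> int:
        return len(self.exons)

    @property
    def n_introns(self) -> int:
        return len(self.introns)

    @property
    def span(self) -> tuple[int, int]:
        """Transcript span (first exon start, last exon end)."""
        return self.exons[0][0], self.exons[-1][1]

    def segment_index(self, kind: str, genomic_rank: int) -> int:
        """1-based segment number in transcript (5'→3') orientation.

        ``genomic_rank`` is the 0-based position of the segment in genomic
        coordinate order.  On the minus strand the numbering is reversed.
        """
        n = self.n_exons if kind == "exon" else self.n_introns
        if self.strand == "-":
            return n - genomic_rank
        return genomic_rank + 1


def derive_introns(exons: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """Gaps between consecutive sorted, non-overlapping exon intervals.

    Zero-length gaps (abutting exons) yield no intron.  Raises ``ValueError``
    on overlapping or unsorted exons.
    """
    introns: list[tuple[int, int]] = []
    for (s0, e0), (s1, e1) in zip(exons, exons[1:]):
        if s1 < e0 or s0 > s1:
            raise ValueError(f"exons overlap or are unsorted: ({s0},{e0}) vs ({s1},{e1})")
        if s1 > e0:
            introns.append((e0, s1))
    return introns


def select_base_transcript(
    gene_id: str,
    chromosome: str,
    strand: str,
    transcripts: dict[str, list[tuple[int, int]]],
) -> GeneModel:
    """Pick the isoform with the most exons and segment it.

    ``transcripts`` maps transcript id to its exon interval list (0-based
    half-open, any order).  Ties on exon count are broken by the
    lexicographically smallest transcript id, so the choice is deterministic.
    """
    if not transcripts:
        raise ValueError(f"gene {gene_id} has no transcripts")
    best_id = min(transcripts, key=lambda t: (-len(transcripts[t]), t))
    exons = sorted(transcripts[best_id])
    if not exons:
        raise ValueError(f"gene {gene_id}: transcript {best_id} has no exons")
    introns = derive_introns(exons)
    return GeneModel(
        gene_id=gene_id,
        chromosome=chromosome,
        strand=strand,
        transcript_id=best_id,
        exons=tuple(exons),
        introns=tuple(introns),
    )


def read_gene_models(gff3_path: str) -> dict[str, GeneModel]:
    """Parse a GFF3 file into base-transcript gene models.

    Expects the canonical gene → mRNA/transcript → exon hierarchy with
    ``Parent`` attributes.  GFF3 start/end (1-based inclusive) are converted
    to 0-based half-open.
    """
    db = gffutils.create_db(
        gff3_path,
        ":memory:",
        merge_strategy="create_unique",
        keep_order=True,
    )
    models: dict[str, GeneModel] = {}
    for gene in db.features_of_type("gene"):
        transcripts: dict[str, list[tuple[int, int]]] = {}
        for tx in db.children(gene, level=1):
            if tx.featuretype not in ("mRNA", "transcript"):
                continue
            exons = [
                (ex.start - 1, ex.end)
                for ex in db.children(tx, featuretype="exon")
            ]
            if exons:
                transcripts[tx.id] = exons
        if not transcripts:
            raise ValueError(f"gene {gene.id} has no transcript with exons")
        models[gene.id] = select_base_transcript(
            gene.id, gene.seqid, gene.strand, transcripts
        )
    return models


def write_gene_model_table(models: dict[str, GeneModel], path: str) -> None:
    """Write a summary TSV (one row per gene; intervals as start-end lists)."""
    rows = []
    for m in models.values():
        rows.append(
            {
                "gene_id": m.gene_id,
                "chrom": m.chromosome,
                "strand": m.strand,
                "transcript_id": m.transcript_id,
                "n_exons": m.n_exons,
                "n_introns": m.n_introns,
                "exons": ",".join(f"{s}-{e}" for s, e in m.exons),
                "introns": ",".join(f"{s}-{e}" for s, e in m.introns),
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
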