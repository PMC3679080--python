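"""Synthetic tiling-array experiments with planted splicing events.

Generates a complete fake two-condition experiment — GFF3 annotation, a
tiled probe table, raw linear intensity matrices and truth tables — so the
whole detection pipeline can be exercised without any external data.

The generative model: probes tile each exon/intron segment at a fixed
spacing (35 bp by default, the resolution of the Affymetrix 1.0R design);
a probe's log2 intensity is its segment's base level (exon or intron
background) plus any planted shift plus Normal noise, then exponentiated
to the linear scale (i.e. log-normal multiplicative noise, the standard
microarray error model).  Planted *retention* raises every probe of the
target intron by the effect size in the target condition; *partial* 5'/3'
events raise only the probes in the affected fraction of the intron
(transcript orientation); differentially expressed genes shift all their
exon probes.  Truth tables record every planted event.

Probes are emitted fully inside single segments, so coordinate mapping
recovers the generator's own assignment exactly; border, multi-mapping,
control and intergenic probes can be injected on request to exercise every
exclusion branch.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .annotation import GeneModel, derive_introns
from .preprocess import ArrayInfo, IntensityMatrix

__all__ = ["PlantedEvent", "SimulationConfig", "SimulatedExperiment", "simulate"]

EVENT_TYPES = ("retention", "partial_5prime", "partial_3prime", "none")


@dataclass(frozen=True)
class PlantedEvent:
    gene: int  # gene index (gene_id "G%04d")
    intron: int  # 1-based intron number, transcript orientation
    event_type: str  # retention | partial_5prime | partial_3prime | none
    condition: str = "treatment"
    effect_size: float = 3.0  # log2 units
    affected_fraction: float = 0.5  # for partial events


@dataclass(frozen=True)
class SimulationConfig:
    n_genes: int = 50
    exons_per_gene: tuple[int, int] = (2, 8)
    exon_length: tuple[int, int] = (150, 400)
    intron_length: tuple[int, int] = (90, 250)
    intergenic_length: int = 300
    probe_spacing: int = 35
    probe_length: int = 25
    n_replicates: int = 4
    exon_level: float = 10.0  # mean log2 intensity of expressed exons
    intron_level: float = 6.0  # background level of spliced-out introns
    noise_sd: float = 0.25  # log2 units
    # fraction of genes transcriptionally silent (all probes at background);
    # real transcriptomes are bimodal, which is what makes the global
    # exon-median expression gate meaningful.  The silent genes are the
    # last ceil(fraction * n_genes) gene indices.
    unexpressed_fraction: float = 0.4
    planted_events: tuple[PlantedEvent, ...] = ()
    de_genes: tuple[tuple[int, float], ...] = ()  # (gene index, log2 shift)
    border_probe_fraction: float = 0.0
    n_multimap_probes: int = 0
    n_control_probes: int = 0
    n_intergenic_probes: int = 0
    seed: int = 20130611

    @property
    def n_expressed(self) -> int:
        return self.n_genes - int(np.ceil(self.unexpressed_fraction * self.n_genes))

    def __post_init__(self) -> None:
        if self.probe_spacing <= 0:
            raise ValueError("probe spacing must be positive")
        if not 0 <= self.unexpressed_fraction < 1:
            raise ValueError("unexpressed_fraction must lie in [0, 1)")
        for ev in self.planted_events:
            if ev.event_type not in EVENT_TYPES:
                raise ValueError(f"unknown event type {ev.event_type!r}")
            if not np.isfinite(ev.effect_size):
                raise ValueError("effect sizes must be finite")


@dataclass
class SimulatedExperiment:
    config: SimulationConfig
    models: dict[str, GeneModel]
    probes: pd.DataFrame  # probe_id, chrom, start, end, strand, is_control
    raw: IntensityMatrix
    assignment: pd.DataFrame  # generator's own probe → segment truth
    truth_events: pd.DataFrame
    truth_de: pd.DataFrame
    expressed_genes: tuple[str, ...] = ()

    def write(self, outdir: str | Path) -> None:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        write_gff3(self.models, out / "annotation.gff3")
        self.probes.to_csv(out / "probes.tsv", sep="\t", index=False)
        self.raw.to_frame().to_csv(out / "intensities.tsv", sep="\t")
        pd.DataFrame(
            [(a.array_id, a.condition, a.replicate) for a in self.raw.arrays],
            columns=["array_id", "condition", "replicate"],
        ).to_csv(out / "samples.tsv", sep="\t", index=False)
        self.assignment.to_csv(out / "truth_assignment.tsv", sep="\t", index=False)
        self.truth_events.to_csv(out / "truth_events.tsv", sep="\t", index=False)
        self.truth_de.to_csv(out / "truth_de.tsv", sep="\t", index=False)
        manifest = asdict(self.config)
        manifest["planted_events"] = [asdict(e) for e in self.config.planted_events]
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=list))


def write_gff3(models: dict[str, GeneModel], path: str | Path) -> None:
    """Write gene → mRNA → exon features (1-based inclusive coordinates)."""
    lines = ["##gff-version 3"]
    for m in models.values():
        g0, g1 = m.span
        lines.append(
            f"{m.chromosome}\tsim\tgene\t{g0 + 1}\t{g1}\t.\t{m.strand}\t.\tID={m.gene_id}"
        )
        lines.append(
            f"{m.chromosome}\tsim\tmRNA\t{g0 + 1}\t{g1}\t.\t{m.strand}\t.\t"
            f"ID={m.transcript_id};Parent={m.gene_id}"
        )
        for i, (s, e) in enumerate(m.exons, 1):
            lines.append(
                f"{m.chromosome}\tsim\texon\t{s + 1}\t{e}\t.\t{m.strand}\t.\t"
                f"ID={m.transcript_id}.exon{i};Parent={m.transcript_id}"
            )
    Path(path).write_text("\n".join(lines) + "\n")


def _build_genes(cfg: SimulationConfig, rng: np.random.Generator) -> dict[str, GeneModel]:
    models: dict[str, GeneModel] = {}
    cursor = cfg.intergenic_length
    for g in range(cfg.n_genes):
        n_exons = int(rng.integers(cfg.exons_per_gene[0], cfg.exons_per_gene[1] + 1))
        exons: list[tuple[int, int]] = []
        pos = cursor
        for i in range(n_exons):
            length = int(rng.integers(cfg.exon_length[0], cfg.exon_length[1] + 1))
            exons.append((pos, pos + length))
            pos += length
            if i < n_exons - 1:
                pos += int(rng.integers(cfg.intron_length[0], cfg.intron_length[1] + 1))
        strand = "+" if g % 2 == 0 else "-"
        gene_id = f"G{g:04d}"
        models[gene_id] = GeneModel(
            gene_id=gene_id,
            chromosome="chr1",
            strand=strand,
            transcript_id=f"{gene_id}.1",
            exons=tuple(exons),
            introns=tuple(derive_introns(exons)),
        )
        cursor = pos + cfg.intergenic_length
    return models


def _tile_probes(
    cfg: SimulationConfig, models: dict[str, GeneModel]
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Tile each segment with fully contained probes; return (probes, assignment)."""
    probe_rows, assign_rows = [], []
    n = 0
    for m in models.values():
        segments = [("exon", i, s, e) for i, (s, e) in enumerate(m.exons)] + [
            ("intron", i, s, e) for i, (s, e) in enumerate(m.introns)
        ]
        for kind, rank, s, e in segments:
            pos = s
            while pos + cfg.probe_length <= e:
                pid = f"P{n:07d}"
                probe_rows.append((pid, m.chromosome, pos, pos + cfg.probe_length, "-", False))
                assign_rows.append(
                    (pid, m.gene_id, kind, m.segment_index(kind, rank))
                )
                n += 1
                pos += cfg.probe_spacing
    probes = pd.DataFrame(
        probe_rows, columns=["probe_id", "chrom", "start", "end", "strand", "is_control"]
    )
    assignment = pd.DataFrame(
        assign_rows, columns=["probe_id", "gene_id", "segment_kind", "segment_index"]
    )
    return probes, assignment


def _inject_extras(
    cfg: SimulationConfig,
    models: dict[str, GeneModel],
    probes: pd.DataFrame,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Optionally add border, multi-mapping, control and intergenic probes."""
    rows = []
    n = len(probes)
    if cfg.border_probe_fraction > 0:
        for m in models.values():
            if m.n_introns == 0 or rng.random() >= cfg.border_probe_fraction:
                continue
            # straddle the first exon/intron boundary
            boundary = m.exons[0][1]
            start = boundary - cfg.probe_length // 2
            rows.append((f"B{n:07d}", m.chromosome, start, start + cfg.probe_length, "-", False))
            n += 1
    span_end = max(m.span[1] for m in models.values()) + cfg.intergenic_length
    for _ in range(cfg.n_multimap_probes):
        pid = f"M{n:07d}"
        for start in (span_end + 50, span_end + 500):
            rows.append((pid, "chr1", start, start + cfg.probe_length, "-", False))
        n += 1
    for _ in range(cfg.n_control_probes):
        rows.append((f"AFFX{n:07d}", "chr1", span_end + 1000, span_end + 1000 + cfg.probe_length, "-", True))
        n += 1
    for _ in range(cfg.n_intergenic_probes):
        start = span_end + 2000 + 40 * n
        rows.append((f"I{n:07d}", "chr1", start, start + cfg.probe_length, "-", False))
        n += 1
    if not rows:
        return probes
    extras = pd.DataFrame(rows, columns=probes.columns)
    return pd.concat([probes, extras], ignore_index=True)


def _intron_fraction_mask(
    positions: np.ndarray, strand: str, fraction: float, five_prime: bool
) -> np.ndarray:
    """Mask of probes lying in the affected fraction of an intron.

    ``positions`` are relative genomic offsets in [0, 1); the 5' end of a
    minus-strand intron is its genomic right end.
    """
    if strand == "-":
        five_prime = not five_prime
    return positions < fraction if five_prime else positions >= 1 - fraction


def simulate(cfg: SimulationConfig) -> SimulatedExperiment:
    """Generate annotation, probes, raw intensities and truth tables."""
    rng = np.random.default_rng(cfg.seed)
    models = _build_genes(cfg, rng)
    probes, assignment = _tile_probes(cfg, models)

    # validate planted events against the generated annotation
    n_expressed = cfg.n_expressed
    for ev in cfg.planted_events:
        gid = f"G{ev.gene:04d}"
        if gid not in models:
            raise ValueError(f"planted event references unknown gene {gid}")
        if models[gid].n_introns == 0:
            raise ValueError(f"planted event references single-exon gene {gid}")
        if not 1 <= ev.intron <= models[gid].n_introns:
            raise ValueError(
                f"planted event intron {ev.intron} out of range for {gid} "
                f"({models[gid].n_introns} introns)"
            )
        if ev.gene >= n_expressed:
            raise ValueError(f"planted event references unexpressed gene {gid}")
    for g, _shift in cfg.de_genes:
        if f"G{g:04d}" not in models:
            raise ValueError(f"DE gene G{g:04d} does not exist")
        if g >= n_expressed:
            raise ValueError(f"DE gene G{g:04d} is in the unexpressed set")

    probes = _inject_extras(cfg, models, probes, rng)

    # base log2 level per probe: exon level only for exon probes of
    # expressed genes; silent genes sit at background throughout
    assign_map = assignment.set_index("probe_id")
    kind = probes["probe_id"].map(assign_map["segment_kind"])
    gene_of = probes["probe_id"].map(assign_map["gene_id"])
    expressed_ids = {f"G{g:04d}" for g in range(n_expressed)}
    is_exon = kind.eq("exon").to_numpy(dtype=bool)
    is_expressed = gene_of.isin(expressed_ids).to_numpy(dtype=bool)
    base = np.where(is_exon & is_expressed, cfg.exon_level, cfg.intron_level).astype(float)

    n_arrays = 2 * cfg.n_replicates
    arrays = tuple(
        ArrayInfo(f"{cond}_{r + 1}", cond, r + 1)
        for cond in ("control", "treatment")
        for r in range(cfg.n_replicates)
    )
    shifts = np.zeros((len(probes), n_arrays))
    cond_cols = {
        "control": np.arange(cfg.n_replicates),
        "treatment": np.arange(cfg.n_replicates, n_arrays),
    }

    pid_to_row = {pid: i for i, pid in enumerate(probes["probe_id"])}

    truth_de_rows = []
    for g, shift in cfg.de_genes:
        gid = f"G{g:04d}"
        pids = assignment.loc[
            (assignment["gene_id"] == gid) & (assignment["segment_kind"] == "exon"),
            "probe_id",
        ]
        rows = [pid_to_row[p] for p in pids]
        shifts[np.ix_(rows, cond_cols["treatment"])] += shift
        truth_de_rows.append((gid, shift))

    truth_event_rows = []
    for ev in cfg.planted_events:
        gid = f"G{ev.gene:04d}"
        if ev.event_type == "none":
            truth_event_rows.append((gid, ev.intron, "none", ev.condition, 0.0))
            continue
        model = models[gid]
        # intron rank in genomic order for this transcript-number index
        rank = (
            ev.intron - 1 if model.strand == "+" else model.n_introns - ev.intron
        )
        s, e = model.introns[rank]
        pids = assignment.loc[
            (assignment["gene_id"] == gid)
            & (assignment["segment_kind"] == "intron")
            & (assignment["segment_index"] == ev.intron),
            "probe_id",
        ].tolist()
        starts = probes.set_index("probe_id").loc[pids, "start"].to_numpy(dtype=float)
        rel = (starts - s) / max(e - s - cfg.probe_length, 1)
        if ev.event_type == "retention":
            mask = np.ones(len(pids), dtype=bool)
        else:
            mask = _intron_fraction_mask(
                rel, model.strand, ev.affected_fraction,
                five_prime=(ev.event_type == "partial_5prime"),
            )
        rows = [pid_to_row[p] for p, keep in zip(pids, mask) if keep]
        shifts[np.ix_(rows, cond_cols[ev.condition])] += ev.effect_size
        truth_event_rows.append((gid, ev.intron, ev.event_type, ev.condition, ev.effect_size))

    log2 = (
        base[:, None]
        + shifts
        + rng.normal(0.0, cfg.noise_sd, size=(len(probes), n_arrays))
    )
    raw = IntensityMatrix(
        probe_ids=tuple(probes["probe_id"]),
        arrays=arrays,
        values=np.exp2(log2),
        state="raw",
    )
    truth_events = pd.DataFrame(
        truth_event_rows,
        columns=["gene_id", "intron_index", "event_type", "condition", "effect_size"],
    )
    truth_de = pd.DataFrame(truth_de_rows, columns=["gene_id", "log2_shift"])
    return SimulatedExperiment(
        config=cfg,
        models=models,
        probes=probes,
        raw=raw,
        assignment=assignment,
        truth_events=truth_events,
        truth_de=truth_de,
        expressed_genes=tuple(sorted(expressed_ids)),
    )
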