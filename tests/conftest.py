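import numpy as np
import pytest

from tilesplice.annotation import GeneModel, derive_introns
from tilesplice.simulate import PlantedEvent, SimulationConfig, simulate


def make_gene(gene_id, exons, strand="+", chrom="chr1", transcript_id=None):
    exons = tuple(sorted(exons))
    return GeneModel(
        gene_id=gene_id,
        chromosome=chrom,
        strand=strand,
        transcript_id=transcript_id or f"{gene_id}.1",
        exons=exons,
        introns=tuple(derive_introns(list(exons))),
    )


@pytest.fixture(scope="session")
def small_experiment():
    """A small synthetic experiment with one planted retention, one planted
    partial event and one DE gene."""
    cfg = SimulationConfig(
        n_genes=30,
        exons_per_gene=(3, 6),
        intron_length=(200, 280),  # 5-8 probes per intron
        planted_events=(
            PlantedEvent(gene=1, intron=1, event_type="retention", effect_size=3.0),
            PlantedEvent(gene=3, intron=2, event_type="partial_5prime", effect_size=3.0),
        ),
        de_genes=((5, 2.0),),
        seed=1234,
    )
    return simulate(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(42)
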