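import numpy as np
import pytest

from smorfreg.genome_model import AnnotationSet, GenomeInterval, TranscriptModel


@pytest.fixture
def two_exon_plus():
    return TranscriptModel(
        transcript_id="txp",
        gene_id="gp",
        strand="+",
        exons=[GenomeInterval("chr1", 100, 110), GenomeInterval("chr1", 120, 130)],
        biotype="lncRNA",
    )


@pytest.fixture
def two_exon_minus():
    return TranscriptModel(
        transcript_id="txm",
        gene_id="gm",
        strand="-",
        exons=[
            GenomeInterval("chr1", 100, 110, "-"),
            GenomeInterval("chr1", 120, 130, "-"),
        ],
        biotype="lncRNA",
    )


@pytest.fixture
def rng():
    return np.random.default_rng(0)


def random_transcript(rng, tx_id="tx", chrom="chr1", max_exons=4):
    """Random exon chain for coordinate round-trip properties."""
    n_exons = int(rng.integers(1, max_exons + 1))
    strand = "+" if rng.random() < 0.5 else "-"
    pos = int(rng.integers(0, 1000))
    exons = []
    for _ in range(n_exons):
        pos += int(rng.integers(1, 50))
        length = int(rng.integers(1, 80))
        exons.append(GenomeInterval(chrom, pos, pos + length, strand))
        pos += length
    return TranscriptModel(
        transcript_id=tx_id, gene_id="g_" + tx_id, strand=strand, exons=exons
    )


@pytest.fixture
def default_dataset():
    """Small deterministic simulated dataset shared across tests."""
    from smorfreg.synthetic_data import GenomeSimConfig, simulate_genome_annotation

    rng = np.random.default_rng(42)
    cfg = GenomeSimConfig(n_smorfs=24, n_coding=10, n_lncrna=8)
    return simulate_genome_annotation(cfg, rng)
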