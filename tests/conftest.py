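import numpy as np
import pytest

from nmdase import SimulationConfig, TranscriptModel


@pytest.fixture
def toy_three_exon():
    """Plus-strand transcript with spliced exon lengths 200/300/150.

    The last exon-exon junction sits at spliced position 500; the CDS
    spans spliced positions 10..633 (624 nt).
    """
    return TranscriptModel(
        transcript_id="TOY3",
        gene_id="GTOY3",
        chrom="chr1",
        strand="+",
        exons=[(0, 200), (1000, 1300), (2000, 2150)],
        cds_start=9,
        cds_end=2133,
    )


@pytest.fixture
def toy_minus():
    """Minus-strand toy: genomic exons [100,200) and [300,400), so the
    transcript's 5'-most base is genomic 0-based position 399."""
    return TranscriptModel(
        transcript_id="TOYM",
        gene_id="GTOYM",
        chrom="chr1",
        strand="-",
        exons=[(100, 200), (300, 400)],
    )


def random_toy_model(rng: np.random.Generator, idx: int = 0) -> TranscriptModel:
    """Small random coding transcript (<=1 kb spliced) on either strand,
    built directly so it is independent of the package's generator."""
    n_exons = int(rng.integers(1, 6))
    exons = []
    pos = int(rng.integers(0, 500))
    for _ in range(n_exons):
        length = int(rng.integers(60, 200))
        exons.append((pos, pos + length))
        pos += length + int(rng.integers(30, 200))
    strand = "+" if rng.random() < 0.5 else "-"
    spliced_len = sum(e - s for s, e in exons)
    utr5 = int(rng.integers(3, 20))
    utr3 = int(rng.integers(3, 20))
    cds_len = 3 * ((spliced_len - utr5 - utr3) // 3)
    model = TranscriptModel(
        transcript_id=f"R{idx}", gene_id=f"GR{idx}", chrom="chr1", strand=strand, exons=exons
    )
    g_first = model.spliced_to_genomic(utr5 + 1)
    g_last = model.spliced_to_genomic(utr5 + cds_len)
    return TranscriptModel(
        transcript_id=f"R{idx}", gene_id=f"GR{idx}", chrom="chr1", strand=strand, exons=exons,
        cds_start=min(g_first, g_last), cds_end=max(g_first, g_last) + 1,
    )


@pytest.fixture
def null_config():
    """NMD switched off: every site should be balanced (rho = 0.5)."""
    return SimulationConfig(
        seed=11, n_genes=240, n_targeted_ptv=30, n_escaping_ptv=10, n_other_het=200,
        nmd_efficiency=0.0, n_samples=4,
    )
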