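"""Synthetic inputs with the statistical structure the analysis assumes.

The generators emulate, in order: transcript annotation (GTF), variant
calls with known NMD ground truth (VCF), per-site allele counts whose
reference skew at NMD-targeted sites is governed by an NMD-efficiency
parameter, a differential-expression result table, and a phased haplotype
panel around a founder allele.

The allele-count model: at a heterozygous site the PTC-bearing (alt)
transcript's abundance is scaled by (1 - e), where e in [0,1] is the NMD
efficiency, so the expected reference read fraction is

    rho = 1 / (2 - e)        (e=0 -> 0.5, e=1 -> 1.0)

for NMD-targeted sites and 0.5 for all others.  Total depth is negative
binomial (mean_depth, depth_dispersion) and the reference count
beta-binomial around rho with concentration ``ase_overdispersion``
(infinite concentration collapses to a plain binomial).

Every generator is a pure function of its configuration, including the
seed: re-runs are byte-identical.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .ase import AlleleCountRecord
from .popstats import HaplotypePanel
from .transcripts import GenomicVariant, TranscriptModel

__all__ = [
    "SimulationConfig",
    "gen_transcript_models",
    "gen_variants",
    "gen_allele_counts",
    "gen_deg_table",
    "gen_haplotype_panel",
    "simulate_ase_records",
]

# fixed per-stage stream tags so each generator has an independent,
# reproducible stream derived from the one config seed
_TAG_TX, _TAG_VAR, _TAG_COUNTS, _TAG_DEG = 11, 23, 37, 53

_TRUTH_TO_GROUP = {"targeted": "targeted_ptv", "escaping": "escaping_ptv", "none": "non_ptv"}
_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the synthetic study.

    ``nmd_efficiency`` is the fraction of PTC-bearing transcripts removed
    at NMD-targeted sites; ``ase_overdispersion`` is the beta-binomial
    concentration of per-site allelic fractions (use ``math.inf`` for no
    overdispersion); ``depth_dispersion`` is the negative-binomial size
    parameter of the read-depth law (larger = closer to Poisson);
    ``frac_up``/``frac_down`` are the fractions of truly up-/down-
    regulated genes in the differential-expression table, with effect
    sizes centred on ``effect_logfc_mean`` (log2 units).
    """

    seed: int = 0
    n_genes: int = 200
    n_targeted_ptv: int = 20
    n_escaping_ptv: int = 10
    n_other_het: int = 150
    nmd_efficiency: float = 0.8
    mean_depth: float = 40.0
    depth_dispersion: float = 5.0
    ase_overdispersion: float = 40.0
    frac_up: float = 0.0
    frac_down: float = 0.0
    effect_logfc_mean: float = 1.0
    n_samples: int = 4

    def __post_init__(self) -> None:
        if not 0.0 <= self.nmd_efficiency <= 1.0:
            raise ValueError("nmd_efficiency must lie in [0,1]")
        if not (0.0 <= self.frac_up <= 1.0 and 0.0 <= self.frac_down <= 1.0):
            raise ValueError("frac_up and frac_down must lie in [0,1]")
        if self.frac_up + self.frac_down > 1.0:
            raise ValueError("frac_up + frac_down must not exceed 1")
        if min(self.n_genes, self.n_samples) < 1:
            raise ValueError("n_genes and n_samples must be >= 1")
        if min(self.n_targeted_ptv, self.n_escaping_ptv, self.n_other_het) < 0:
            raise ValueError("variant counts must be non-negative")
        if self.mean_depth <= 0 or self.depth_dispersion <= 0 or self.ase_overdispersion <= 0:
            raise ValueError("mean_depth, depth_dispersion and ase_overdispersion must be positive")


# ----------------------------------------------------------------------
# Transcript models
# ----------------------------------------------------------------------

def gen_transcript_models(config: SimulationConfig, frac_single_exon: float = 0.2) -> list[TranscriptModel]:
    """Random transcript models, one per gene, laid out along one contig.

    Each model has 1-12 exons; ``frac_single_exon`` of genes (in
    expectation) are single-exon.  The CDS is constructed from a codon
    count, so its spliced length is a multiple of 3 by construction, and
    it is flanked by non-empty UTRs.
    """
    rng = np.random.default_rng([config.seed, _TAG_TX])
    models = []
    cursor = 1000
    for i in range(config.n_genes):
        gid = f"G{i + 1:05d}"
        single = rng.random() < frac_single_exon
        n_exons = 1 if single else int(rng.integers(2, 13))
        exon_lens = rng.integers(100, 301, size=n_exons)
        intron_lens = rng.integers(60, 501, size=max(0, n_exons - 1))
        exons = []
        pos = cursor
        for k, length in enumerate(exon_lens):
            exons.append((pos, pos + int(length)))
            pos += int(length)
            if k < n_exons - 1:
                pos += int(intron_lens[k])
        strand = "+" if rng.random() < 0.5 else "-"
        spliced_len = int(exon_lens.sum())
        utr5 = int(rng.integers(5, 31))
        utr3_max = max(6, min(400, spliced_len - utr5 - 33))
        utr3 = int(rng.integers(5, utr3_max))
        n_codons = (spliced_len - utr5 - utr3) // 3
        cds_len = 3 * n_codons
        utr3 = spliced_len - utr5 - cds_len  # absorb the rounding remainder

        model = TranscriptModel(
            transcript_id=f"T{i + 1:05d}",
            gene_id=gid,
            chrom="chr1",
            strand=strand,
            exons=exons,
        )
        # map spliced CDS interval back to a genomic span
        g_first = model.spliced_to_genomic(utr5 + 1)
        g_last = model.spliced_to_genomic(utr5 + cds_len)
        lo, hi = min(g_first, g_last), max(g_first, g_last) + 1
        models.append(
            TranscriptModel(
                transcript_id=model.transcript_id,
                gene_id=gid,
                chrom="chr1",
                strand=strand,
                exons=exons,
                cds_start=lo,
                cds_end=hi,
            )
        )
        cursor = pos + int(rng.integers(1000, 5001))
    return models


# ----------------------------------------------------------------------
# Variants
# ----------------------------------------------------------------------

def _eligible_spliced_positions(model: TranscriptModel, targeted: bool, threshold: int = 50) -> np.ndarray:
    """CDS-interior spliced positions whose 50-nt-rule call matches
    ``targeted`` (start and stop codons excluded)."""
    cds_first, cds_last = model.cds_spliced
    interior = np.arange(cds_first + 3, cds_last - 2)
    junctions = model.junction_spliced_positions()
    if not junctions:
        dist_ok = np.zeros(interior.size, dtype=bool)
    else:
        dist_ok = (junctions[-1] - interior) >= threshold
    return interior[dist_ok] if targeted else interior[~dist_ok]


def gen_variants(models: list[TranscriptModel], config: SimulationConfig) -> list[GenomicVariant]:
    """Place stop-gain variants with known NMD ground truth plus
    non-truncating heterozygous variants; truth labels go to the
    ``nmd_truth`` field (INFO/NMD_TRUTH on disk)."""
    if not models:
        raise ValueError("no transcript models supplied")
    rng = np.random.default_rng([config.seed, _TAG_VAR])
    used: set[tuple[str, int]] = set()
    variants: list[GenomicVariant] = []

    def place(model: TranscriptModel, spliced_pos: int, consequence: str, truth: str) -> bool:
        g0 = model.spliced_to_genomic(int(spliced_pos))
        key = (model.chrom, g0 + 1)
        if key in used:
            return False
        used.add(key)
        ref, alt = rng.choice(_BASES, size=2, replace=False)
        variants.append(
            GenomicVariant(
                chrom=model.chrom, pos=g0 + 1, ref=str(ref), alt=str(alt),
                gene_id=model.gene_id, consequence=consequence, zygosity="het", nmd_truth=truth,
            )
        )
        return True

    for truth, n_wanted in (("targeted", config.n_targeted_ptv), ("escaping", config.n_escaping_ptv)):
        eligible = [
            (m, _eligible_spliced_positions(m, targeted=(truth == "targeted")))
            for m in models
            if m.has_cds
        ]
        eligible = [(m, pos) for m, pos in eligible if pos.size > 0]
        if n_wanted > 0 and not eligible:
            raise ValueError(
                f"no transcript model can host a likely NMD-{truth} stop-gain "
                "(e.g. all models single-exon)"
            )
        placed = 0
        attempts = 0
        while placed < n_wanted:
            attempts += 1
            if attempts > 100 * n_wanted + 100:
                raise ValueError(f"could not place {n_wanted} NMD-{truth} variants without collisions")
            m, pos = eligible[rng.integers(len(eligible))]
            if place(m, pos[rng.integers(pos.size)], "stop_gain", truth):
                placed += 1

    placed = 0
    attempts = 0
    while placed < config.n_other_het:
        attempts += 1
        if attempts > 100 * config.n_other_het + 100:
            raise ValueError("could not place the requested non-truncating variants")
        m = models[rng.integers(len(models))]
        sp = int(rng.integers(1, m.spliced_length + 1))
        if place(m, sp, "other", "none"):
            placed += 1

    return sorted(variants, key=lambda v: (v.chrom, v.pos))


# ----------------------------------------------------------------------
# Allele counts
# ----------------------------------------------------------------------

def ref_fraction_for_efficiency(e: float) -> float:
    """Expected reference read fraction rho = 1/(2-e) at an NMD-targeted
    site when NMD removes a fraction ``e`` of PTC-bearing transcripts."""
    return 1.0 / (2.0 - e)


def gen_allele_counts(variants: list[GenomicVariant], config: SimulationConfig) -> list[AlleleCountRecord]:
    """Beta-binomial allele counts per sample and heterozygous site.

    Depth ~ NegativeBinomial(mean_depth, depth_dispersion); reference
    count ~ BetaBinomial(depth, rho, ase_overdispersion) with rho =
    1/(2 - nmd_efficiency) at truth-targeted sites and 0.5 elsewhere.
    """
    rng = np.random.default_rng([config.seed, _TAG_COUNTS])
    k = config.depth_dispersion
    p_nb = k / (k + config.mean_depth)
    conc = config.ase_overdispersion
    records = []
    for s in range(config.n_samples):
        sample = f"S{s + 1:03d}"
        for v in variants:
            if v.zygosity != "het":
                continue
            rho = ref_fraction_for_efficiency(config.nmd_efficiency) if v.nmd_truth == "targeted" else 0.5
            total = int(rng.negative_binomial(k, p_nb))
            if math.isinf(conc):
                p_site = rho
            else:
                a, b = rho * conc, (1.0 - rho) * conc
                p_site = 1.0 if b == 0 else (0.0 if a == 0 else rng.beta(a, b))
            ref = int(rng.binomial(total, p_site))
            records.append(
                AlleleCountRecord(
                    sample_id=sample, chrom=v.chrom, pos=v.pos,
                    refAllele=v.ref, altAllele=v.alt,
                    refCount=ref, altCount=total - ref, totalCount=total,
                    gene_id=v.gene_id,
                    group=_TRUTH_TO_GROUP.get(v.nmd_truth or "none", "non_ptv"),
                )
            )
    return records


def simulate_ase_records(config: SimulationConfig) -> list[AlleleCountRecord]:
    """Models -> variants -> allele counts in one in-memory step."""
    models = gen_transcript_models(config)
    variants = gen_variants(models, config)
    return gen_allele_counts(variants, config)


# ----------------------------------------------------------------------
# Differential-expression table
# ----------------------------------------------------------------------

def gen_deg_table(config: SimulationConfig) -> pd.DataFrame:
    """Synthetic DE result table (gene, logFC, padj).

    ``frac_up`` of genes are truly upregulated (positive logFC centred on
    ``effect_logfc_mean``, small adjusted p), ``frac_down`` down-
    regulated, and the rest null (logFC near 0, adjusted p uniform).
    """
    rng = np.random.default_rng([config.seed, _TAG_DEG])
    n = config.n_genes
    n_up = int(round(config.frac_up * n))
    n_down = int(round(config.frac_down * n))
    n_null = n - n_up - n_down
    lfc_up = np.abs(rng.normal(config.effect_logfc_mean, 0.3, size=n_up)) + 0.25
    lfc_down = -(np.abs(rng.normal(config.effect_logfc_mean, 0.3, size=n_down)) + 0.25)
    lfc_null = rng.normal(0.0, 0.08, size=n_null)
    padj_sig = 10.0 ** rng.uniform(-12, np.log10(0.049), size=n_up + n_down)
    padj_null = rng.uniform(0.0, 1.0, size=n_null)
    df = pd.DataFrame(
        {
            "gene": [f"G{i + 1:05d}" for i in range(n)],
            "logFC": np.concatenate([lfc_up, lfc_down, lfc_null]),
            "padj": np.concatenate([padj_sig, padj_null]),
            "truth": ["up"] * n_up + ["down"] * n_down + ["null"] * n_null,
        }
    )
    return df.sample(frac=1.0, random_state=np.random.RandomState(config.seed % (2**32))).reset_index(drop=True)


# ----------------------------------------------------------------------
# Haplotype panel
# ----------------------------------------------------------------------

def gen_haplotype_panel(
    n_carriers: int,
    panel_span_bp: float,
    marker_density: float,
    true_segment_bp: float,
    seed: int = 0,
) -> HaplotypePanel:
    """Phased carrier haplotypes sharing an ancestral segment.

    Markers are evenly spaced at ``1/marker_density`` bp.  Carriers are
    identical over a ``true_segment_bp`` interval centred on the focal
    (central) marker and carry independent random 4-state alleles
    outside it; the focal allele is shared by construction.
    """
    if true_segment_bp > panel_span_bp:
        raise ValueError("true_segment_bp must not exceed panel_span_bp")
    if n_carriers < 1 or marker_density <= 0:
        raise ValueError("need >=1 carrier and positive marker density")
    rng = np.random.default_rng(seed)
    spacing = max(1, int(round(1.0 / marker_density)))
    positions = np.arange(1, int(panel_span_bp) + 1, spacing)
    n_markers = positions.size
    focal_index = n_markers // 2
    focal_pos = positions[focal_index]
    in_segment = np.abs(positions - focal_pos) <= true_segment_bp / 2.0
    ancestral = rng.integers(0, 4, size=n_markers)
    haps = rng.integers(0, 4, size=(n_carriers, n_markers))
    haps[:, in_segment] = ancestral[in_segment]
    haps[:, focal_index] = ancestral[focal_index]
    return HaplotypePanel(positions=positions, haplotypes=haps, focal_index=int(focal_index))
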