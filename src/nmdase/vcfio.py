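"""VCF v4.2 reading and writing for biallelic substitutions (via pysam).

Simulation ground-truth NMD labels travel in the INFO field
(``NMD_TRUTH=targeted|escaping|none``) together with ``GENE_ID``,
``CSQ_CLASS`` (stop_gain/other) and ``ZYG``.
"""

from __future__ import annotations

import os

import pysam

from .transcripts import GenomicVariant

__all__ = ["write_vcf", "read_vcf"]

_INFO_DEFS = [
    ("GENE_ID", "1", "String", "Gene identifier"),
    ("CSQ_CLASS", "1", "String", "Consequence class (stop_gain/other)"),
    ("ZYG", "1", "String", "Zygosity (het/hom)"),
    ("NMD_TRUTH", "1", "String", "Simulation truth NMD label (targeted/escaping/none)"),
]


def write_vcf(variants: list[GenomicVariant], path: str | os.PathLike, contig_lengths: dict[str, int]) -> None:
    header = pysam.VariantHeader()
    for name, length in sorted(contig_lengths.items()):
        header.contigs.add(name, length=length)
    for vid, num, typ, desc in _INFO_DEFS:
        header.info.add(vid, num, typ, desc)
    with pysam.VariantFile(os.fspath(path), "w", header=header) as out:
        for v in sorted(variants, key=lambda v: (v.chrom, v.pos, v.ref, v.alt)):
            rec = out.new_record(
                contig=v.chrom, start=v.pos - 1, stop=v.pos, alleles=(v.ref, v.alt)
            )
            rec.info["GENE_ID"] = v.gene_id
            rec.info["CSQ_CLASS"] = v.consequence
            rec.info["ZYG"] = v.zygosity
            if v.nmd_truth is not None:
                rec.info["NMD_TRUTH"] = v.nmd_truth
            out.write(rec)


def read_vcf(path: str | os.PathLike) -> list[GenomicVariant]:
    variants = []
    with pysam.VariantFile(os.fspath(path)) as vcf:
        for rec in vcf:
            if len(rec.alts or ()) != 1:
                raise ValueError(f"{path}: only biallelic records supported at {rec.chrom}:{rec.pos}")
            info = rec.info
            variants.append(
                GenomicVariant(
                    chrom=rec.chrom,
                    pos=rec.pos,
                    ref=rec.ref,
                    alt=rec.alts[0],
                    gene_id=info.get("GENE_ID", ""),
                    consequence=info.get("CSQ_CLASS", "other"),
                    zygosity=info.get("ZYG", "het"),
                    nmd_truth=info.get("NMD_TRUTH"),
                )
            )
    return variants
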