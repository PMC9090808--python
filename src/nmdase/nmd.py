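"""Premature-termination-codon NMD classification and transcript NMD features.

Implements the canonical 50-nt rule: a stop-gain (nonsense) variant is
called *likely NMD-targeted* when its premature termination codon (PTC)
lies at least ``junction_threshold_nt`` spliced nucleotides upstream of the
last exon-exon junction, and *likely NMD-escaping* otherwise — which
covers PTCs in the last exon, PTCs within the threshold window, and every
PTC in a single-exon (junction-free) transcript.  The threshold is a
parameter; ties at exactly the threshold distance count as targeted.

Also annotates transcripts with NMD-sensitising features commonly tabulated
for endogenous NMD substrates: a translated upstream ORF, a long (>1.5 kb)
3'UTR, and an intron in the 3'UTR.
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import pandas as pd

from .transcripts import GenomicVariant, GtfModelError, TranscriptModel, project_to_spliced

__all__ = [
    "NmdClassification",
    "NmdFeatureSet",
    "classify_nmd",
    "detect_nmd_features",
    "write_classification_table",
    "classify_variants",
]

STOP_CODONS = {"TAA", "TAG", "TGA"}


@dataclass(frozen=True)
class NmdClassification:
    """Outcome of the 50-nt rule for one variant/transcript pair."""

    label: str  # targeted | escaping | not_applicable
    ptc_spliced_pos: int | None = None
    distance_to_last_junction: int | None = None
    rule_fired: str = ""


@dataclass(frozen=True)
class NmdFeatureSet:
    """NMD-sensitising transcript features.

    ``has_uorf`` is ``None`` when the uORF scan was not requested.
    """

    has_uorf: bool | None
    long_3utr: bool
    utr3_intron: bool


def classify_nmd(
    variant: GenomicVariant,
    model: TranscriptModel,
    junction_threshold_nt: int = 50,
    start_proximal_escape: bool = False,
    start_proximal_nt: int = 150,
) -> NmdClassification:
    """Classify a stop-gain variant as likely NMD-targeted or NMD-escaping.

    Parameters
    ----------
    junction_threshold_nt
        Minimum spliced distance between the PTC and the last exon-exon
        junction for NMD targeting (>= comparison; default 50).
    start_proximal_escape
        Optionally call PTCs within ``start_proximal_nt`` of the start
        codon escaping (translation-reinitiation escape); off by default.
    """
    if variant.consequence != "stop_gain":
        return NmdClassification(label="not_applicable", rule_fired="not_stop_gain")
    if not model.has_cds:
        raise GtfModelError(f"{model.transcript_id}: cannot classify a PTC in a transcript without CDS")
    sp = project_to_spliced(variant, model)  # raises NotExonicError when intronic
    junctions = model.junction_spliced_positions()
    if not junctions:
        return NmdClassification(
            label="escaping", ptc_spliced_pos=sp, distance_to_last_junction=None, rule_fired="single_exon"
        )
    last_j = junctions[-1]
    dist = last_j - sp
    if start_proximal_escape:
        cds_first, _ = model.cds_spliced
        if sp - cds_first < start_proximal_nt:
            return NmdClassification(
                label="escaping", ptc_spliced_pos=sp, distance_to_last_junction=dist,
                rule_fired="start_proximal",
            )
    if dist >= junction_threshold_nt:
        return NmdClassification(
            label="targeted", ptc_spliced_pos=sp, distance_to_last_junction=dist,
            rule_fired=f"ge_{junction_threshold_nt}nt_upstream_last_junction",
        )
    rule = "last_exon" if sp > last_j else "junction_proximal"
    return NmdClassification(
        label="escaping", ptc_spliced_pos=sp, distance_to_last_junction=dist, rule_fired=rule
    )


def _has_uorf(seq: str, cds_first_sp: int) -> bool:
    """True if an AUG in the 5'UTR opens a frame whose in-frame stop lies
    entirely upstream of the main start codon."""
    seq = seq.upper().replace("U", "T")
    utr5_end = cds_first_sp - 1  # last spliced base of the 5'UTR (1-based)
    for i in range(utr5_end):  # 0-based index of candidate AUG
        if seq[i : i + 3] != "ATG":
            continue
        j = i
        while j + 3 <= len(seq):
            codon = seq[j : j + 3]
            if codon in STOP_CODONS:
                if j + 3 <= utr5_end:
                    return True
                break
            j += 3
    return False


def detect_nmd_features(
    model: TranscriptModel,
    long_3utr_nt: int = 1500,
    scan_uorf: bool = True,
) -> NmdFeatureSet:
    """Flag NMD-sensitising features of a coding transcript.

    ``long_3utr`` is strict: a spliced 3'UTR of exactly ``long_3utr_nt``
    nucleotides is not long.  The uORF scan needs ``cdna_sequence``; pass
    ``scan_uorf=False`` to skip it for sequence-less models.
    """
    if not model.has_cds:
        raise GtfModelError(f"{model.transcript_id}: NMD features require an annotated CDS")
    cds_first, cds_last = model.cds_spliced
    long_3utr = model.utr3_spliced_length > long_3utr_nt
    junctions = model.junction_spliced_positions()
    utr3_intron = any(j >= cds_last for j in junctions)
    has_uorf: bool | None = None
    if scan_uorf:
        if model.cdna_sequence is None:
            raise ValueError(
                f"{model.transcript_id}: cDNA sequence required for uORF scan "
                "(pass scan_uorf=False to skip)"
            )
        has_uorf = _has_uorf(model.cdna_sequence, cds_first)
    return NmdFeatureSet(has_uorf=has_uorf, long_3utr=long_3utr, utr3_intron=utr3_intron)


def classify_variants(
    variants: list[GenomicVariant],
    models: list[TranscriptModel],
    junction_threshold_nt: int = 50,
) -> pd.DataFrame:
    """Classify every stop-gain variant against its gene's transcript model.

    Non-stop-gain variants are included with label ``not_applicable`` so
    the output table covers every input site (needed for the ASE join).
    """
    by_gene = {m.gene_id: m for m in models}
    rows = []
    for v in variants:
        m = by_gene.get(v.gene_id)
        if m is None:
            raise KeyError(f"no transcript model for gene {v.gene_id}")
        c = classify_nmd(v, m, junction_threshold_nt=junction_threshold_nt)
        rows.append(
            {
                "chrom": v.chrom,
                "pos": v.pos,
                "ref": v.ref,
                "alt": v.alt,
                "gene_id": v.gene_id,
                "transcript_id": m.transcript_id,
                "spliced_pos": c.ptc_spliced_pos,
                "distance_to_last_junction": c.distance_to_last_junction,
                "label": c.label,
                "rule_fired": c.rule_fired,
            }
        )
    return pd.DataFrame(rows)


def write_classification_table(table: pd.DataFrame, path: str | os.PathLike) -> None:
    table.to_csv(os.fspath(path), sep="\t", index=False)
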