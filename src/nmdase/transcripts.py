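"""Transcript models, spliced-coordinate projection and GTF input/output.

A :class:`TranscriptModel` holds the exon/CDS structure of a single
transcript.  All internal coordinates are 0-based half-open; GTF input and
output uses the format's native 1-based closed intervals, with the
conversion confined to :func:`load_gtf` and :func:`write_gtf`.

The central geometric primitive is the projection between genomic and
spliced ("cDNA") coordinates, which everything downstream — the premature
termination codon classifier, the NMD feature flags — is built on.  Spliced
positions are 1-based and count transcribed bases from the transcript's
5' end, so on the minus strand both exon order and within-exon direction
are reversed.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import gffutils

__all__ = [
    "TranscriptModel",
    "GenomicVariant",
    "NotExonicError",
    "GtfModelError",
    "load_gtf",
    "write_gtf",
    "project_to_spliced",
]


class NotExonicError(ValueError):
    """A genomic position falls outside every exon of a transcript."""


class GtfModelError(ValueError):
    """A GTF record set does not form a valid transcript model."""


@dataclass(frozen=True)
class GenomicVariant:
    """One biallelic substitution.

    ``pos`` is the 1-based genomic coordinate, matching VCF convention.
    ``consequence`` is ``"stop_gain"`` for nonsense variants and
    ``"other"`` for everything else; ``nmd_truth`` is an optional
    simulation ground-truth label (``targeted``/``escaping``/``none``)
    carried so that tests never re-derive truth from generator internals.
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    gene_id: str
    consequence: str = "other"
    zygosity: str = "het"
    nmd_truth: str | None = None

    def __post_init__(self) -> None:
        if self.ref == self.alt:
            raise ValueError(f"ref and alt alleles are identical at {self.chrom}:{self.pos}")
        if self.pos < 1:
            raise ValueError(f"1-based position must be >= 1, got {self.pos}")


@dataclass
class TranscriptModel:
    """Exon/CDS structure of one transcript.

    Parameters
    ----------
    exons
        Non-overlapping ``(start, end)`` intervals, 0-based half-open,
        sorted in genomic order regardless of strand.
    cds_start, cds_end
        Genomic 0-based half-open span of the coding region (``None`` for
        non-coding transcripts).  The spliced CDS length must be a
        multiple of 3.
    cdna_sequence
        Optional spliced transcript sequence (5'->3'), required only for
        upstream-ORF scanning.
    """

    transcript_id: str
    gene_id: str
    chrom: str
    strand: str
    exons: list[tuple[int, int]]
    cds_start: int | None = None
    cds_end: int | None = None
    cdna_sequence: str | None = None

    # cumulative spliced offsets per exon in transcription order
    _offsets: list[int] = field(default_factory=list, repr=False, compare=False)

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise GtfModelError(f"{self.transcript_id}: strand must be '+' or '-', got {self.strand!r}")
        if not self.exons:
            raise GtfModelError(f"{self.transcript_id}: transcript has no exons")
        self.exons = [(int(s), int(e)) for s, e in self.exons]
        prev_end = None
        for s, e in self.exons:
            if e <= s:
                raise GtfModelError(f"{self.transcript_id}: empty or inverted exon [{s},{e})")
            if prev_end is not None and s < prev_end:
                raise GtfModelError(f"{self.transcript_id}: exons overlap or are unsorted")
            prev_end = e
        if (self.cds_start is None) != (self.cds_end is None):
            raise GtfModelError(f"{self.transcript_id}: cds_start/cds_end must be set together")
        if self.cds_start is not None:
            if not (self.contains(self.cds_start) and self.contains(self.cds_end - 1)):
                raise GtfModelError(f"{self.transcript_id}: CDS endpoints fall outside the exon union")
            if self.cds_length % 3 != 0:
                raise GtfModelError(
                    f"{self.transcript_id}: spliced CDS length {self.cds_length} is not a multiple of 3"
                )
        off = 0
        offsets = []
        for s, e in self._transcription_order():
            offsets.append(off)
            off += e - s
        self._offsets = offsets

    # -- geometry -----------------------------------------------------

    def _transcription_order(self) -> list[tuple[int, int]]:
        return self.exons if self.strand == "+" else list(reversed(self.exons))

    @property
    def n_exons(self) -> int:
        return len(self.exons)

    @property
    def spliced_length(self) -> int:
        return sum(e - s for s, e in self.exons)

    @property
    def has_cds(self) -> bool:
        return self.cds_start is not None

    def contains(self, pos0: int) -> bool:
        """True if 0-based genomic position ``pos0`` lies in an exon."""
        return any(s <= pos0 < e for s, e in self.exons)

    def genomic_to_spliced(self, pos0: int) -> int:
        """Project a 0-based genomic position to a 1-based spliced position."""
        for off, (s, e) in zip(self._offsets, self._transcription_order()):
            if s <= pos0 < e:
                if self.strand == "+":
                    return off + (pos0 - s) + 1
                return off + (e - 1 - pos0) + 1
        raise NotExonicError(
            f"position {self.chrom}:{pos0 + 1} is not exonic in transcript {self.transcript_id}"
        )

    def spliced_to_genomic(self, sp1: int) -> int:
        """Inverse projection: 1-based spliced -> 0-based genomic position."""
        if not 1 <= sp1 <= self.spliced_length:
            raise NotExonicError(
                f"spliced position {sp1} outside 1..{self.spliced_length} in {self.transcript_id}"
            )
        for off, (s, e) in zip(self._offsets, self._transcription_order()):
            if off < sp1 <= off + (e - s):
                within = sp1 - off - 1
                return s + within if self.strand == "+" else e - 1 - within
        raise AssertionError("unreachable")

    def junction_spliced_positions(self) -> list[int]:
        """Spliced positions of the last base before each exon-exon junction.

        Empty for single-exon transcripts.  The final element is the
        "last junction" of the 50-nt rule: ``spliced_length`` minus the
        length of the 3'-most exon.
        """
        return self._offsets[1:]

    @property
    def cds_spliced(self) -> tuple[int, int]:
        """Inclusive 1-based spliced interval of the CDS (first, last base)."""
        if not self.has_cds:
            raise GtfModelError(f"{self.transcript_id}: transcript has no CDS")
        if self.strand == "+":
            first, last = self.cds_start, self.cds_end - 1
        else:
            first, last = self.cds_end - 1, self.cds_start
        return self.genomic_to_spliced(first), self.genomic_to_spliced(last)

    @property
    def cds_length(self) -> int:
        if not self.has_cds:
            return 0
        total = 0
        for s, e in self.exons:
            lo, hi = max(s, self.cds_start), min(e, self.cds_end)
            if hi > lo:
                total += hi - lo
        return total

    @property
    def utr3_spliced_length(self) -> int:
        """Spliced distance from the base after the stop codon to the 3' end."""
        _, cds_last = self.cds_spliced
        return self.spliced_length - cds_last

    @property
    def utr5_spliced_length(self) -> int:
        cds_first, _ = self.cds_spliced
        return cds_first - 1


def project_to_spliced(variant: GenomicVariant, model: TranscriptModel) -> int:
    """Spliced 1-based position of ``variant`` in ``model``.

    Raises :class:`NotExonicError` for intronic or out-of-transcript
    positions.
    """
    if variant.chrom != model.chrom:
        raise NotExonicError(
            f"variant on {variant.chrom} but transcript {model.transcript_id} on {model.chrom}"
        )
    return model.genomic_to_spliced(variant.pos - 1)


# ----------------------------------------------------------------------
# GTF I/O (1-based closed on disk <-> 0-based half-open in memory)
# ----------------------------------------------------------------------

def _prevalidate_gtf(path: str) -> None:
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            if len(line.rstrip("\n").split("\t")) != 9:
                raise GtfModelError(f"{path}:{lineno}: malformed GTF line (expected 9 tab-separated fields)")


def load_gtf(path: str | os.PathLike) -> list[TranscriptModel]:
    """Read transcript models from a GTF file with exon and CDS features.

    Transcripts whose CDS violates the model invariants (outside the exon
    union, spliced length not a multiple of 3) are rejected with a
    diagnostic naming the transcript.
    """
    path = os.fspath(path)
    _prevalidate_gtf(path)
    db = gffutils.create_db(
        path,
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )
    exons: dict[str, list] = {}
    cds: dict[str, list] = {}
    meta: dict[str, tuple[str, str, str]] = {}
    for feat in db.all_features(order_by=("seqid", "start")):
        if feat.featuretype not in ("exon", "CDS"):
            continue
        tid = feat.attributes["transcript_id"][0]
        gid = feat.attributes.get("gene_id", [tid])[0]
        meta.setdefault(tid, (gid, feat.seqid, feat.strand))
        # GTF 1-based closed -> 0-based half-open
        iv = (feat.start - 1, feat.end)
        (exons if feat.featuretype == "exon" else cds).setdefault(tid, []).append(iv)
    models = []
    for tid, ex in exons.items():
        gid, chrom, strand = meta[tid]
        ex = sorted(ex)
        cds_start = cds_end = None
        if tid in cds:
            spans = sorted(cds[tid])
            cds_start, cds_end = spans[0][0], spans[-1][1]
        models.append(
            TranscriptModel(
                transcript_id=tid,
                gene_id=gid,
                chrom=chrom,
                strand=strand,
                exons=ex,
                cds_start=cds_start,
                cds_end=cds_end,
            )
        )
    return models


def write_gtf(models: list[TranscriptModel], path: str | os.PathLike) -> None:
    """Write models as GTF (1-based closed, gene_id/transcript_id attributes)."""
    with open(os.fspath(path), "w") as fh:
        for m in models:
            attrs = f'gene_id "{m.gene_id}"; transcript_id "{m.transcript_id}";'
            start1, end1 = m.exons[0][0] + 1, m.exons[-1][1]
            fh.write(f"{m.chrom}\tnmdase\ttranscript\t{start1}\t{end1}\t.\t{m.strand}\t.\t{attrs}\n")
            for s, e in m.exons:
                fh.write(f"{m.chrom}\tnmdase\texon\t{s + 1}\t{e}\t.\t{m.strand}\t.\t{attrs}\n")
            if m.has_cds:
                for s, e in m.exons:
                    lo, hi = max(s, m.cds_start), min(e, m.cds_end)
                    if hi > lo:
                        fh.write(f"{m.chrom}\tnmdase\tCDS\t{lo + 1}\t{hi}\t.\t{m.strand}\t0\t{attrs}\n")
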