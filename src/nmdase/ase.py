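"""Allele-specific-expression test of PTC-induced NMD functionality.

Functional NMD degrades the transcript carrying a premature termination
codon, so at a heterozygous NMD-targeted site most RNA reads carry the
reference allele: the reference read ratio refCount/(refCount+altCount)
rises above the balanced-expression value of 0.5.  The analysis contrasts
the ratios of likely NMD-targeted stop-gain sites against non-protein-
truncating sites (and, as a negative control, NMD-escaping sites) with a
one-sided Wilcoxon rank-sum test.

Multiple heterozygous variants on one gene share a haplotype and are not
independent observations.  The test therefore resamples: in each of
``n_perm`` iterations exactly one record per (gene, sample) pair is chosen
uniformly at random, the rank-sum test is run on the selection, and the
per-iteration p-values are summarised by their median.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu

__all__ = [
    "AlleleCountRecord",
    "AseComparisonResult",
    "PermutationSummary",
    "read_ase_counts",
    "write_ase_counts",
    "ref_ratio",
    "filter_sites",
    "compare_groups",
    "permuted_test",
    "run_ase_nmd",
    "ase_report",
]

REQUIRED_COLUMNS = ["contig", "position", "refAllele", "altAllele", "refCount", "altCount", "totalCount"]

GROUPS = ("targeted_ptv", "escaping_ptv", "non_ptv")


@dataclass(frozen=True)
class AlleleCountRecord:
    """Per-sample ref/alt RNA read counts at one heterozygous site."""

    sample_id: str
    chrom: str
    pos: int
    refAllele: str
    altAllele: str
    refCount: int
    altCount: int
    totalCount: int
    gene_id: str = ""
    group: str = "non_ptv"
    zygosity: str = "het"

    def __post_init__(self) -> None:
        if min(self.refCount, self.altCount, self.totalCount) < 0:
            raise ValueError(f"negative read count at {self.chrom}:{self.pos}")
        if self.refCount + self.altCount > self.totalCount:
            raise ValueError(
                f"refCount+altCount exceeds totalCount at {self.chrom}:{self.pos} "
                f"({self.refCount}+{self.altCount} > {self.totalCount})"
            )


@dataclass(frozen=True)
class AseComparisonResult:
    """One rank-sum contrast of reference-read ratios between two groups."""

    n_targeted: int
    n_reference_group: int
    statistic: float
    p_value: float
    alternative: str


@dataclass
class PermutationSummary:
    """Distribution of a contrast over one-variant-per-gene subsamples."""

    n_perm: int
    per_perm_p: list[float]
    per_perm_statistic: list[float] = field(default_factory=list)
    median_p: float = float("nan")
    median_statistic: float = float("nan")
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.per_perm_p) != self.n_perm:
            raise ValueError("per_perm_p length must equal n_perm")
        self.median_p = float(np.nanmedian(self.per_perm_p))
        if self.per_perm_statistic:
            self.median_statistic = float(np.nanmedian(self.per_perm_statistic))


# ----------------------------------------------------------------------
# I/O and elementary operations
# ----------------------------------------------------------------------

def read_ase_counts(path: str | os.PathLike, sample_id: str | None = None) -> list[AlleleCountRecord]:
    """Read a tab-separated allele-count table (ASEReadCounter-style columns).

    Mandatory columns: contig, position, refAllele, altAllele, refCount,
    altCount, totalCount.  Optional columns sample_id (overridden by the
    ``sample_id`` argument when given), gene_id and group are used when
    present; other extras are ignored.
    """
    df = pd.read_csv(os.fspath(path), sep="\t")
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing mandatory column(s): {', '.join(missing)}")
    records = []
    for row in df.itertuples(index=False):
        d = row._asdict()
        records.append(
            AlleleCountRecord(
                sample_id=str(sample_id or d.get("sample_id", "sample")),
                chrom=str(d["contig"]),
                pos=int(d["position"]),
                refAllele=str(d["refAllele"]),
                altAllele=str(d["altAllele"]),
                refCount=int(d["refCount"]),
                altCount=int(d["altCount"]),
                totalCount=int(d["totalCount"]),
                gene_id=str(d.get("gene_id", "")),
                group=str(d.get("group", "non_ptv")),
                zygosity=str(d.get("zygosity", "het")),
            )
        )
    return records


def write_ase_counts(records: list[AlleleCountRecord], path: str | os.PathLike) -> None:
    rows = [
        {
            "contig": r.chrom,
            "position": r.pos,
            "refAllele": r.refAllele,
            "altAllele": r.altAllele,
            "refCount": r.refCount,
            "altCount": r.altCount,
            "totalCount": r.totalCount,
            "sample_id": r.sample_id,
            "gene_id": r.gene_id,
            "group": r.group,
            "zygosity": r.zygosity,
        }
        for r in records
    ]
    pd.DataFrame(rows).to_csv(os.fspath(path), sep="\t", index=False)


def ref_ratio(record: AlleleCountRecord) -> float:
    """Reference read ratio refCount / (refCount + altCount)."""
    denom = record.refCount + record.altCount
    if denom == 0:
        raise ValueError(f"undefined reference ratio (no allelic reads) at {record.chrom}:{record.pos}")
    return record.refCount / denom


def filter_sites(
    records: list[AlleleCountRecord],
    min_total: int = 8,
    require_biallelic: bool = True,
) -> list[AlleleCountRecord]:
    """Coverage/heterozygosity filter: keep records with at least
    ``min_total`` allelic reads; drop records not flagged heterozygous."""
    out = []
    for r in records:
        if r.refCount + r.altCount < min_total:
            continue
        if require_biallelic and r.zygosity != "het":
            continue
        out.append(r)
    return out


# ----------------------------------------------------------------------
# Group contrasts
# ----------------------------------------------------------------------

def compare_groups(
    group_a_ratios,
    group_b_ratios,
    alternative: str = "greater",
) -> AseComparisonResult:
    """Wilcoxon rank-sum (Mann-Whitney U) test on two sets of ref ratios.

    ``alternative='greater'`` tests whether group A is stochastically
    larger than group B; the exact null distribution is used for small
    tie-free samples, a tie-corrected normal approximation otherwise.
    """
    a = np.asarray(list(group_a_ratios), dtype=float)
    b = np.asarray(list(group_b_ratios), dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    # exact permutation null for small samples (whether or not ties are
    # present); tie-corrected normal approximation otherwise
    method = "exact" if max(a.size, b.size) <= 8 else "asymptotic"
    res = mannwhitneyu(a, b, alternative=alternative, method=method)
    return AseComparisonResult(
        n_targeted=int(a.size),
        n_reference_group=int(b.size),
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        alternative=alternative,
    )


def permuted_test(
    records: list[AlleleCountRecord],
    n_perm: int = 1000,
    seed: int = 0,
    alternative: str = "greater",
    group_a: str = "targeted_ptv",
    group_b: str = "non_ptv",
) -> PermutationSummary:
    """One-variant-per-gene-per-sample subsampled rank-sum test.

    Each iteration selects uniformly at random exactly one record per
    (gene_id, sample_id) pair among the records belonging to the two
    contrasted groups, then tests group-A vs group-B reference ratios.
    Buckets are visited in sorted (gene, sample) order and draws come from
    one seeded generator, so results are reproducible across platforms.
    """
    relevant = [r for r in records if r.group in (group_a, group_b)]
    if not any(r.group == group_a for r in relevant):
        raise ValueError(f"no record of group {group_a!r}: no iteration can contain one")
    if not any(r.group == group_b for r in relevant):
        raise ValueError(f"no record of group {group_b!r}: no iteration can contain one")

    buckets: dict[tuple[str, str], list[AlleleCountRecord]] = {}
    for r in relevant:
        buckets.setdefault((r.gene_id, r.sample_id), []).append(r)
    keys = sorted(buckets)
    bucket_lists = [sorted(buckets[k], key=lambda r: (r.chrom, r.pos, r.refAllele, r.altAllele)) for k in keys]

    ratios = np.array([ref_ratio(r) for bl in bucket_lists for r in bl])
    is_a = np.array([r.group == group_a for bl in bucket_lists for r in bl])
    starts = np.cumsum([0] + [len(bl) for bl in bucket_lists])[:-1]
    sizes = np.array([len(bl) for bl in bucket_lists])

    multi = sizes > 1
    rng = np.random.default_rng(seed)
    # one choice matrix for all iterations, drawn bucket-major so the
    # stream order matches the documented sorted-bucket convention
    choices = np.zeros((n_perm, len(sizes)), dtype=np.int64)
    for j in np.flatnonzero(multi):
        choices[:, j] = rng.integers(0, sizes[j], size=n_perm)

    per_p = np.empty(n_perm)
    per_stat = np.empty(n_perm)
    for it in range(n_perm):
        idx = starts + choices[it]
        sel = ratios[idx]
        sel_a = sel[is_a[idx]]
        sel_b = sel[~is_a[idx]]
        if sel_a.size == 0 or sel_b.size == 0:
            per_p[it] = np.nan
            per_stat[it] = np.nan
            continue
        res = compare_groups(sel_a, sel_b, alternative=alternative)
        per_p[it] = res.p_value
        per_stat[it] = res.statistic
    return PermutationSummary(
        n_perm=n_perm,
        per_perm_p=per_p.tolist(),
        per_perm_statistic=per_stat.tolist(),
        seed=seed,
    )


# ----------------------------------------------------------------------
# Full analysis
# ----------------------------------------------------------------------

def _group_stats(records, group):
    vals = [ref_ratio(r) for r in records if r.group == group]
    return {"n": len(vals), "mean_ref_ratio": float(np.mean(vals)) if vals else None}


def ase_report(
    records: list[AlleleCountRecord],
    n_perm: int = 1000,
    seed: int = 0,
    min_total: int = 8,
    alternative: str = "greater",
) -> dict:
    """Run both reported contrasts (targeted vs non-PTV, escaping vs
    non-PTV) on labelled allele-count records and return a JSON-ready
    report with group sizes, mean ratios and permutation summaries."""
    kept = filter_sites(records, min_total=min_total)
    if not any(r.group == "targeted_ptv" for r in kept):
        raise ValueError("no NMD-targeted site survives filtering; contrast is undefined")
    report: dict = {
        "n_perm": n_perm,
        "seed": seed,
        "min_total": min_total,
        "alternative": alternative,
        "group_sizes": {g: sum(r.group == g for r in kept) for g in GROUPS},
        "group_mean_ref_ratio": {g: _group_stats(kept, g)["mean_ref_ratio"] for g in GROUPS},
        "contrasts": {},
    }
    for name, group_a in (("targeted_vs_non_ptv", "targeted_ptv"), ("escaping_vs_non_ptv", "escaping_ptv")):
        if not any(r.group == group_a for r in kept):
            report["contrasts"][name] = None
            continue
        summ = permuted_test(
            kept, n_perm=n_perm, seed=seed, alternative=alternative,
            group_a=group_a, group_b="non_ptv",
        )
        report["contrasts"][name] = {
            "n_perm": summ.n_perm,
            "median_p": summ.median_p,
            "median_statistic": summ.median_statistic,
            "per_perm_p": summ.per_perm_p,
        }
    return report


def run_ase_nmd(
    counts_path: str | os.PathLike,
    classification_path: str | os.PathLike,
    n_perm: int = 1000,
    seed: int = 0,
    min_total: int = 8,
    alternative: str = "greater",
    out_path: str | os.PathLike | None = None,
) -> dict:
    """File-based entry point: join allele counts with an NMD
    classification table on (chrom, pos), label groups, and run
    :func:`ase_report`.  Sites absent from the classification table (or
    classified not_applicable) are treated as non-protein-truncating."""
    records = read_ase_counts(counts_path)
    cls = pd.read_csv(os.fspath(classification_path), sep="\t")
    label_by_site = {(str(r.chrom), int(r.pos)): str(r.label) for r in cls.itertuples(index=False)}
    to_group = {"targeted": "targeted_ptv", "escaping": "escaping_ptv"}
    relabelled = []
    for r in records:
        label = label_by_site.get((r.chrom, r.pos), "not_applicable")
        grp = to_group.get(label, "non_ptv")
        relabelled.append(
            AlleleCountRecord(
                sample_id=r.sample_id, chrom=r.chrom, pos=r.pos,
                refAllele=r.refAllele, altAllele=r.altAllele,
                refCount=r.refCount, altCount=r.altCount, totalCount=r.totalCount,
                gene_id=r.gene_id, group=grp, zygosity=r.zygosity,
            )
        )
    report = ase_report(relabelled, n_perm=n_perm, seed=seed, min_total=min_total, alternative=alternative)
    if out_path is not None:
        with open(os.fspath(out_path), "w") as fh:
            json.dump(report, fh, indent=2)
    return report
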