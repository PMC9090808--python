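"""Founder-variant population statistics.

Case-vs-population allele enrichment (odds ratio with the log-symmetric
Woolf confidence interval), the Hardy-Weinberg expected homozygote count
q^2 N, allele-frequency ratios between populations, and pairwise shared
haplotype segments around a focal founder allele.
"""

from __future__ import annotations

import itertools
import os
from dataclasses import dataclass

import numpy as np
from statsmodels.stats.contingency_tables import Table2x2

__all__ = [
    "TwoByTwoTable",
    "HaplotypePanel",
    "odds_ratio_ci",
    "expected_homozygotes",
    "af_ratio",
    "shared_haplotype_segments",
    "read_haplotype_panel",
    "write_haplotype_panel",
]


@dataclass(frozen=True)
class TwoByTwoTable:
    """Allele counts, cases vs population: rows (case, pop) x cols (alt, ref)."""

    case_alt: int
    case_ref: int
    pop_alt: int
    pop_ref: int

    def __post_init__(self) -> None:
        if min(self.case_alt, self.case_ref, self.pop_alt, self.pop_ref) < 0:
            raise ValueError("allele counts must be non-negative")


@dataclass
class HaplotypePanel:
    """Phased carrier haplotypes around a focal marker.

    ``positions`` are strictly increasing 1-based bp coordinates;
    ``haplotypes`` is an (n_haplotypes x n_markers) allele matrix; the
    focal allele is shared by every carrier row.
    """

    positions: np.ndarray
    haplotypes: np.ndarray
    focal_index: int

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions)
        self.haplotypes = np.asarray(self.haplotypes)
        if self.haplotypes.ndim != 2 or self.haplotypes.shape[1] != self.positions.size:
            raise ValueError("haplotype matrix must be n_haplotypes x n_markers")
        if not np.all(np.diff(self.positions) > 0):
            raise ValueError("marker positions must be strictly increasing")
        if not 0 <= self.focal_index < self.positions.size:
            raise ValueError("focal_index out of range")
        focal = self.haplotypes[:, self.focal_index]
        if not np.all(focal == focal[0]):
            raise ValueError("all carrier haplotypes must share the focal allele")


def odds_ratio_ci(table: TwoByTwoTable, conf: float = 0.95) -> dict:
    """Odds ratio (case_alt*pop_ref)/(case_ref*pop_alt) with the Woolf
    log-symmetric confidence interval, so sqrt(lo*hi) equals the OR.

    Any zero cell triggers the Haldane-Anscombe +0.5 correction on all
    four cells; a margin that is entirely zero is an error.
    """
    a, b, c, d = table.case_alt, table.case_ref, table.pop_alt, table.pop_ref
    margins = (a + b, c + d, a + c, b + d)
    if any(m == 0 for m in margins):
        raise ValueError("odds ratio undefined: a table margin is entirely zero")
    if min(a, b, c, d) == 0:
        a, b, c, d = (x + 0.5 for x in (a, b, c, d))
    t = Table2x2(np.array([[a, b], [c, d]], dtype=float))
    lo, hi = t.oddsratio_confint(alpha=1 - conf)
    return {"or": float(t.oddsratio), "lo": float(lo), "hi": float(hi), "conf": conf}


def expected_homozygotes(allele_freq: float, population_size: int) -> float:
    """Hardy-Weinberg expected homozygote count q^2 * N (no inbreeding
    adjustment); e.g. q=0.001598 in N=5.5e6 gives ~14 individuals."""
    if not 0.0 <= allele_freq <= 1.0:
        raise ValueError(f"allele frequency {allele_freq} outside [0,1]")
    if population_size <= 0:
        raise ValueError("population size must be positive")
    return allele_freq ** 2 * population_size


def af_ratio(freq_a: float, freq_b: float) -> float:
    """Allele-frequency ratio between two populations (freq_a / freq_b)."""
    if freq_b <= 0:
        raise ValueError("denominator frequency must be positive")
    return freq_a / freq_b


def _pair_segment(positions: np.ndarray, eq: np.ndarray, focal: int) -> float:
    """bp length of the maximal run of equal markers containing ``focal``."""
    lo = focal
    while lo > 0 and eq[lo - 1]:
        lo -= 1
    hi = focal
    while hi < eq.size - 1 and eq[hi + 1]:
        hi += 1
    return float(positions[hi] - positions[lo])


def shared_haplotype_segments(panel: HaplotypePanel, joint: bool = False) -> dict:
    """Shared segment lengths around the focal marker.

    For every pair of carrier haplotypes, the shared segment is the
    maximal run of consecutive identical markers containing the focal
    marker; its length is last-minus-first shared position in bp.  With
    ``joint=True`` a single segment over which *all* carriers agree is
    reported instead of the pairwise distribution.
    """
    H = panel.haplotypes
    if H.shape[0] < 2:
        raise ValueError("need at least two carrier haplotypes")
    if joint:
        eq = np.all(H == H[0], axis=0)
        length = _pair_segment(panel.positions, eq, panel.focal_index)
        return {"pair_lengths_bp": [length], "median_bp": length}
    lengths = [
        _pair_segment(panel.positions, H[i] == H[j], panel.focal_index)
        for i, j in itertools.combinations(range(H.shape[0]), 2)
    ]
    return {"pair_lengths_bp": lengths, "median_bp": float(np.median(lengths))}


# ----------------------------------------------------------------------
# Panel I/O: '#focal_pos=<bp>' comment, header row of positions, then one
# row per haplotype: hap_id <tab> allele ...
# ----------------------------------------------------------------------

def write_haplotype_panel(panel: HaplotypePanel, path: str | os.PathLike) -> None:
    with open(os.fspath(path), "w") as fh:
        fh.write(f"#focal_pos={int(panel.positions[panel.focal_index])}\n")
        fh.write("hap_id\t" + "\t".join(str(int(p)) for p in panel.positions) + "\n")
        for i, row in enumerate(panel.haplotypes):
            fh.write(f"hap{i + 1}\t" + "\t".join(str(a) for a in row) + "\n")


def read_haplotype_panel(path: str | os.PathLike) -> HaplotypePanel:
    with open(os.fspath(path)) as fh:
        first = fh.readline().strip()
        if not first.startswith("#focal_pos="):
            raise ValueError(f"{path}: expected '#focal_pos=<bp>' comment on line 1")
        focal_pos = int(first.split("=", 1)[1])
        header = fh.readline().rstrip("\n").split("\t")[1:]
        positions = np.array([int(p) for p in header])
        rows = []
        for line in fh:
            if line.strip():
                rows.append([int(a) for a in line.rstrip("\n").split("\t")[1:]])
    focal_index = int(np.flatnonzero(positions == focal_pos)[0])
    return HaplotypePanel(positions=positions, haplotypes=np.array(rows), focal_index=focal_index)
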