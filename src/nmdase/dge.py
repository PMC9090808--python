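"""Differential-expression up/down asymmetry and the exact sign test.

Consumes result tables from an upstream count-based DE fit (gene, log2
fold-change, FDR-adjusted p); significance filtering, the split into up-
and downregulated genes, and the exact binomial sign test of their
symmetry are computed here.  The sign test's two-sided p is the doubled
smaller exact tail, capped at 1.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass

import pandas as pd
from scipy.stats import binom

__all__ = [
    "DegRecord",
    "AsymmetryResult",
    "read_deg_table",
    "filter_significant",
    "sign_test",
    "asymmetry_report",
    "select_highlights",
]


@dataclass(frozen=True)
class DegRecord:
    """One gene's differential-expression outcome (patients vs controls)."""

    gene_id: str
    logFC: float
    padj: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.padj <= 1.0:
            raise ValueError(f"{self.gene_id}: adjusted p {self.padj} outside [0,1]")


@dataclass(frozen=True)
class AsymmetryResult:
    """Counts and sign-test p for up- vs downregulated significant genes.

    ``up_down_ratio`` is ``math.inf`` when no gene is downregulated.
    Genes whose logFC is exactly 0 are excluded from both counts.
    """

    n_sig: int
    n_up: int
    n_down: int
    up_down_ratio: float
    p_sign: float


def read_deg_table(path: str | os.PathLike) -> list[DegRecord]:
    """Read a tab-separated DE table with columns gene, logFC, padj
    (extra columns, e.g. raw p, are ignored)."""
    df = pd.read_csv(os.fspath(path), sep="\t")
    missing = [c for c in ("gene", "logFC", "padj") if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing mandatory column(s): {', '.join(missing)}")
    return [DegRecord(str(r.gene), float(r.logFC), float(r.padj)) for r in df.itertuples(index=False)]


def filter_significant(
    records: list[DegRecord],
    padj_max: float = 0.05,
    min_abs_logfc: float = 0.25,
) -> list[DegRecord]:
    """Significance filter: padj strictly below ``padj_max`` and |logFC|
    at least ``min_abs_logfc`` (non-strict)."""
    return [r for r in records if r.padj < padj_max and abs(r.logFC) >= min_abs_logfc]


def sign_test(n_up: int, n_down: int) -> float:
    """Two-sided exact binomial sign test at success probability 1/2.

    Computed as twice the smaller one-sided tail, capped at 1; for
    example 97 up vs 15 down gives 7.12e-16.
    """
    n = n_up + n_down
    if n < 1:
        raise ValueError("sign test needs at least one signed observation")
    if min(n_up, n_down) < 0:
        raise ValueError("counts must be non-negative")
    k = min(n_up, n_down)
    return min(1.0, float(2.0 * binom.cdf(k, n, 0.5)))


def asymmetry_report(
    records: list[DegRecord],
    padj_max: float = 0.05,
    min_abs_logfc: float = 0.25,
) -> AsymmetryResult:
    """Filter, split significant genes by fold-change sign, and test the
    up/down split for symmetry."""
    sig = filter_significant(records, padj_max=padj_max, min_abs_logfc=min_abs_logfc)
    n_up = sum(r.logFC > 0 for r in sig)
    n_down = sum(r.logFC < 0 for r in sig)
    ratio = math.inf if n_down == 0 else n_up / n_down
    return AsymmetryResult(
        n_sig=n_up + n_down,
        n_up=n_up,
        n_down=n_down,
        up_down_ratio=ratio,
        p_sign=sign_test(n_up, n_down),
    )


def select_highlights(
    records: list[DegRecord],
    min_abs_logfc: float = 2.0,
    padj_max: float = 0.05,
) -> list[DegRecord]:
    """Large-effect selection: |logFC| >= ``min_abs_logfc`` and padj <=
    ``padj_max``, both boundaries inclusive."""
    return [r for r in records if abs(r.logFC) >= min_abs_logfc and r.padj <= padj_max]
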