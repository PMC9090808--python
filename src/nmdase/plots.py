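"""Diagnostic plots: volcano plot of the DE table and reference-ratio
strip plot by NMD class.  Matplotlib is imported lazily so headless
pipelines never pay for it."""

from __future__ import annotations

import numpy as np

from .ase import AlleleCountRecord, ref_ratio
from .dge import DegRecord


def volcano(records: list[DegRecord], padj_max: float = 0.05, min_abs_logfc: float = 0.25, ax=None):
    """Volcano plot (logFC vs -log10 padj) with significant genes highlighted."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    lfc = np.array([r.logFC for r in records])
    padj = np.clip(np.array([r.padj for r in records]), 1e-300, 1.0)
    sig = (padj < padj_max) & (np.abs(lfc) >= min_abs_logfc)
    ax.scatter(lfc[~sig], -np.log10(padj[~sig]), s=6, c="0.7", label="not significant")
    ax.scatter(lfc[sig], -np.log10(padj[sig]), s=8, c="tab:blue", label="significant")
    ax.axhline(-np.log10(padj_max), ls=":", c="k", lw=0.8)
    for x in (-min_abs_logfc, min_abs_logfc):
        ax.axvline(x, ls=":", c="k", lw=0.8)
    ax.set_xlabel("log2 fold-change")
    ax.set_ylabel("-log10 FDR-adjusted p")
    ax.legend(frameon=False, fontsize=8)
    return ax


def ref_ratio_strip(records: list[AlleleCountRecord], ax=None, seed: int = 0):
    """Reference read ratio by NMD group (targeted / escaping / non-PTV)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    rng = np.random.default_rng(seed)
    groups = ["targeted_ptv", "escaping_ptv", "non_ptv"]
    for i, g in enumerate(groups):
        vals = [ref_ratio(r) for r in records if r.group == g and r.refCount + r.altCount > 0]
        if not vals:
            continue
        x = i + rng.uniform(-0.15, 0.15, size=len(vals))
        ax.plot(x, vals, ".", ms=4, alpha=0.5)
    ax.axhline(0.5, ls=":", c="k", lw=0.8)
    ax.set_xticks(range(len(groups)), ["NMD-targeted", "NMD-escaping", "non-PTV"])
    ax.set_ylabel("reference read ratio")
    ax.set_ylim(-0.02, 1.02)
    return ax
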