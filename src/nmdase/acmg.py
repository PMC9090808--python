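"""ACMG/AMP evidence combiner for sequence-variant classification.

Aggregates per-criterion evidence codes (PVS/PS/PM/PP for pathogenic,
BA/BS/BP for benign) into one of five classes with the standard combining
rules.  Deciding *whether* a criterion applies (e.g. PS4 case-control
enrichment) is the caller's job; this module only combines.
"""

from __future__ import annotations

from typing import Iterable

__all__ = ["VALID_CODES", "acmg_classify"]

VALID_CODES = frozenset(
    ["PVS1"]
    + [f"PS{i}" for i in range(1, 5)]
    + [f"PM{i}" for i in range(1, 7)]
    + [f"PP{i}" for i in range(1, 6)]
    + ["BA1"]
    + [f"BS{i}" for i in range(1, 5)]
    + [f"BP{i}" for i in range(1, 8)]
)


def _counts(criteria: frozenset[str]) -> dict[str, int]:
    return {
        "pvs": sum(c == "PVS1" for c in criteria),
        "ps": sum(c.startswith("PS") for c in criteria),
        "pm": sum(c.startswith("PM") for c in criteria),
        "pp": sum(c.startswith("PP") for c in criteria),
        "ba": sum(c == "BA1" for c in criteria),
        "bs": sum(c.startswith("BS") for c in criteria),
        "bp": sum(c.startswith("BP") for c in criteria),
    }


def acmg_classify(evidence: Iterable[str]) -> str:
    """Combine ACMG/AMP evidence codes into a pathogenicity class.

    Returns one of ``pathogenic``, ``likely_pathogenic``, ``vus``,
    ``likely_benign``, ``benign``.  Conflicting pathogenic and benign
    evidence yields ``vus``.  For example {PS4, PM2, PP1, PP3} — one
    strong criterion with one moderate and two supporting — is
    ``likely_pathogenic``.
    """
    criteria = frozenset(evidence)
    unknown = sorted(criteria - VALID_CODES)
    if unknown:
        raise ValueError(
            f"unknown ACMG code(s) {unknown}; valid codes: {', '.join(sorted(VALID_CODES))}"
        )
    n = _counts(criteria)
    pvs, ps, pm, pp = n["pvs"], n["ps"], n["pm"], n["pp"]
    ba, bs, bp = n["ba"], n["bs"], n["bp"]

    pathogenic = (
        (pvs >= 1 and (ps >= 1 or pm >= 2 or (pm >= 1 and pp >= 1) or pp >= 2))
        or ps >= 2
        or (ps >= 1 and (pm >= 3 or (pm >= 2 and pp >= 2) or (pm >= 1 and pp >= 4)))
    )
    likely_pathogenic = (
        (pvs >= 1 and pm >= 1)
        or (ps >= 1 and pm >= 1)
        or (ps >= 1 and pp >= 2)
        or pm >= 3
        or (pm >= 2 and pp >= 2)
        or (pm >= 1 and pp >= 4)
    )
    benign = ba >= 1 or bs >= 2
    likely_benign = (bs >= 1 and bp >= 1) or bp >= 2

    path_call = "pathogenic" if pathogenic else ("likely_pathogenic" if likely_pathogenic else None)
    benign_call = "benign" if benign else ("likely_benign" if likely_benign else None)
    if path_call and benign_call:
        return "vus"
    if path_call:
        return path_call
    if benign_call:
        return benign_call
    return "vus"
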