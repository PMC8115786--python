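"""Dehydration-stress memory gene classification.

Pure, direction-aware set logic over per-contrast DEG flags. The biology:
plants acclimated by one slow soil-drying cycle (SD) acquire rapid
desiccation tolerance (RDT); genes that respond to rapid dehydration only in
acclimated plants (AD/A and A4D/A4, but not in the non-acclimated controls)
are RDT-specific, and memory genes are those whose response was pre-induced
by the acclimation treatment itself (same-direction change in SD/F):

* short-term — responds only at the initial stage (AD/A), erased by A4D/A4;
* mid-term   — responds in AD/A and A4D/A4 but not A18D/A18;
* long-term  — responds in AD/A, A4D/A4 and A18D/A18.

"No significant change or opposite response" in the control contrasts is
encoded literally: an opposite-direction DEG does not disqualify, a
same-direction DEG does.
"""

from __future__ import annotations

import logging

import pandas as pd

from .types import MemoryCall

log = logging.getLogger("methylmem")

RDT_REQUIRED = ("AD/A", "A4D/A4")
RDT_CONTROLS = ("A18D/A18", "FD/F", "F4D/F4", "F18D/F18")
ACCLIMATION = "SD/F"
LONG_REQUIRED = ("AD/A", "A4D/A4", "A18D/A18")
LONG_CONTROLS = ("FD/F", "F4D/F4", "F18D/F18")
SHORT_ERASED = ("A4D/A4", "A18D/A18")
SHORT_CONTROLS = ("FD/F", "F4D/F4")

_ALL_CONTRASTS = sorted(
    {ACCLIMATION, *RDT_REQUIRED, *RDT_CONTROLS, *LONG_REQUIRED, *LONG_CONTROLS}
)


def _check_contrasts(flags: pd.DataFrame, needed) -> None:
    missing = [c for c in needed if c not in flags.columns]
    if missing:
        raise KeyError(f"missing DE table(s) for contrast(s): {missing}")


def _opp(direction: str) -> str:
    return "down" if direction == "up" else "up"


def _not_same(flags: pd.DataFrame, contrast: str, direction: str) -> pd.Series:
    """True where the gene shows no same-direction DEG in ``contrast``."""
    return flags[contrast].isin(["none", _opp(direction)])


def rdt_specific(flags: pd.DataFrame) -> dict[str, set]:
    """Genes responding to rapid dehydration only in RDT (acclimated) plants.

    Same-direction DEG in both AD/A and A4D/A4, and no same-direction DEG in
    A18D/A18, FD/F, F4D/F4 or F18D/F18.
    """
    _check_contrasts(flags, RDT_REQUIRED + RDT_CONTROLS)
    out = {}
    for direction in ("up", "down"):
        mask = pd.Series(True, index=flags.index)
        for c in RDT_REQUIRED:
            mask &= flags[c] == direction
        for c in RDT_CONTROLS:
            mask &= _not_same(flags, c, direction)
        out[direction] = set(flags.index[mask])
    return out


def mid_term_memory(flags: pd.DataFrame) -> dict[str, set]:
    """RDT-specific genes pre-induced by acclimation (same direction in SD/F)."""
    _check_contrasts(flags, (ACCLIMATION,))
    rdt = rdt_specific(flags)
    out = {}
    for direction in ("up", "down"):
        pre = set(flags.index[flags[ACCLIMATION] == direction])
        out[direction] = rdt[direction] & pre
    return out


def short_term_memory(flags: pd.DataFrame) -> dict[str, set]:
    """Memory genes whose rapid-dehydration response is erased after AD/A.

    Same-direction DEG in AD/A and SD/F; erased (none or opposite) in A4D/A4
    and A18D/A18; none or opposite in the non-acclimated controls FD/F and
    F4D/F4.
    """
    _check_contrasts(flags, ("AD/A", ACCLIMATION) + SHORT_ERASED + SHORT_CONTROLS)
    out = {}
    for direction in ("up", "down"):
        mask = (flags["AD/A"] == direction) & (flags[ACCLIMATION] == direction)
        for c in SHORT_ERASED + SHORT_CONTROLS:
            mask &= _not_same(flags, c, direction)
        out[direction] = set(flags.index[mask])
    return out


def long_term_memory(flags: pd.DataFrame) -> dict[str, dict[str, set]]:
    """Genes responding at every acclimated stage, and the memory subset.

    Returns {"specific": {up, down}, "memory": {up, down}} where "specific"
    requires a same-direction DEG in AD/A, A4D/A4 and A18D/A18 with none or
    opposite in the controls, and "memory" additionally requires
    pre-induction in SD/F.
    """
    _check_contrasts(flags, LONG_REQUIRED + LONG_CONTROLS + (ACCLIMATION,))
    specific, memory = {}, {}
    for direction in ("up", "down"):
        mask = pd.Series(True, index=flags.index)
        for c in LONG_REQUIRED:
            mask &= flags[c] == direction
        for c in LONG_CONTROLS:
            mask &= _not_same(flags, c, direction)
        specific[direction] = set(flags.index[mask])
        memory[direction] = specific[direction] & set(
            flags.index[flags[ACCLIMATION] == direction]
        )
    return {"specific": specific, "memory": memory}


def classify_memory(flags: pd.DataFrame) -> list[MemoryCall]:
    """One MemoryCall per gene; categories are disjoint by construction.

    Precedence long > mid > short > rdt_specific (the definitions make the
    first three mutually exclusive; rdt_specific is reported for genes that
    meet the RDT criteria without pre-induction).
    """
    _check_contrasts(flags, _ALL_CONTRASTS)
    rdt = rdt_specific(flags)
    mid = mid_term_memory(flags)
    short = short_term_memory(flags)
    long_ = long_term_memory(flags)

    calls: list[MemoryCall] = []
    for gene in flags.index:
        category, direction = "none", ""
        for d in ("up", "down"):
            if gene in long_["memory"][d]:
                category, direction = "long", d
            elif gene in mid[d]:
                category, direction = "mid", d
            elif gene in short[d]:
                category, direction = "short", d
            elif gene in rdt[d]:
                category, direction = "rdt_specific", d
            if category != "none":
                break
        calls.append(
            MemoryCall(
                gene_id=str(gene),
                direction=direction,
                category=category,
                preinduced_by_acclimation=bool(
                    direction and flags.loc[gene, ACCLIMATION] == direction
                ),
                support={c: flags.loc[gene, c] for c in _ALL_CONTRASTS},
            )
        )
    return calls


def category_sets(calls: list[MemoryCall]) -> dict[str, dict[str, set]]:
    """{category: {direction: gene set}} from a list of calls."""
    out: dict[str, dict[str, set]] = {
        c: {"up": set(), "down": set()}
        for c in ("short", "mid", "long", "rdt_specific")
    }
    for call in calls:
        if call.category in out and call.direction in ("up", "down"):
            out[call.category][call.direction].add(call.gene_id)
    return out


def memory_summary(calls: list[MemoryCall]) -> pd.DataFrame:
    """Per-category, per-direction gene counts (Venn-style summary)."""
    sets = category_sets(calls)
    rows = [
        {"category": cat, "direction": d, "n_genes": len(genes)}
        for cat, dirs in sets.items()
        for d, genes in dirs.items()
    ]
    return pd.DataFrame(rows)


def calls_to_frame(calls: list[MemoryCall]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "gene_id": [c.gene_id for c in calls],
            "category": [c.category for c in calls],
            "direction": [c.direction for c in calls],
            "preinduced_by_acclimation": [
                c.preinduced_by_acclimation for c in calls
            ],
        }
    ).set_index("gene_id")
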