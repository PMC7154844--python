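"""GO-annotation bookkeeping: namespace Venn partitions and percentages.

The counting layer over an annotation table whose rows assign transcripts to
GO terms in the three namespaces (BP = biological process, MF = molecular
function, CC = cellular component). Annotation generation itself happens
upstream; this module only tallies.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Mapping, Sequence

__all__ = [
    "AnnotationRow",
    "AnnotationTable",
    "venn_namespace_counts",
    "category_percentages",
    "round_half_up",
]

NAMESPACES = ("BP", "MF", "CC")


@dataclass(frozen=True)
class AnnotationRow:
    transcript_id: str
    namespace: str  # BP | MF | CC
    term_id: str
    term_label: str = ""

    def __post_init__(self) -> None:
        if self.namespace not in NAMESPACES:
            raise ValueError(f"namespace must be one of {NAMESPACES}")


class AnnotationTable:
    """A list of (transcript, namespace, term) rows; transcripts may be absent."""

    def __init__(self, rows: Iterable[AnnotationRow] = ()) -> None:
        self.rows = list(rows)

    def namespaces_by_transcript(self) -> dict[str, frozenset[str]]:
        out: dict[str, set[str]] = {}
        for row in self.rows:
            out.setdefault(row.transcript_id, set()).add(row.namespace)
        return {t: frozenset(ns) for t, ns in out.items()}


def venn_namespace_counts(
    table: AnnotationTable, universe: Sequence[str]
) -> dict[str, int]:
    """Partition a transcript universe by GO-namespace membership.

    Returns the eight cells of the BP/MF/CC Venn diagram (keys like
    ``"MF"``, ``"MF+CC"``, ``"BP+MF+CC"``, ``"none"``) plus per-namespace
    marginals (``"total_BP"`` etc.) and ``"annotated"``. The eight cells
    always sum to the universe size. A table row referring to a transcript
    outside the universe raises, guarding against identifier drift.
    """
    if not universe:
        raise ValueError("universe must be nonempty")
    uni = set(universe)
    if len(uni) != len(universe):
        raise ValueError("duplicate transcript ids in universe")
    membership = table.namespaces_by_transcript()
    stray = set(membership) - uni
    if stray:
        raise ValueError(f"annotation rows for transcripts outside universe: {sorted(stray)[:5]}")

    counts: dict[str, int] = {}
    for t in universe:
        ns = membership.get(t, frozenset())
        key = "+".join(n for n in NAMESPACES if n in ns) or "none"
        counts[key] = counts.get(key, 0) + 1
    for cell in ["none", "BP", "MF", "CC", "BP+MF", "BP+CC", "MF+CC", "BP+MF+CC"]:
        counts.setdefault(cell, 0)
    for n in NAMESPACES:
        counts[f"total_{n}"] = sum(
            v for k, v in counts.items()
            if not k.startswith("total") and k not in ("none", "annotated") and n in k.split("+")
        )
    counts["annotated"] = len(universe) - counts["none"]
    return counts


def round_half_up(value: float, decimals: int = 0) -> float:
    """Round with ties away from zero at the last kept digit (spreadsheet style)."""
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


def category_percentages(
    counts: Mapping[str, int | float], denominator: float, decimals: int = 0
) -> dict[str, float]:
    """Percentages of ``counts`` over an explicit denominator, half-up rounded.

    The denominator is explicit because surveys switch bases between
    sections (annotated totals vs expressed totals); guessing it would be
    wrong half the time.
    """
    if denominator <= 0:
        raise ValueError("denominator must be positive")
    return {
        k: round_half_up(100.0 * v / denominator, decimals) for k, v in counts.items()
    }
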