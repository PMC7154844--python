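"""Expressed-set logic and tissue/age/genotype expression partitions.

The central container is :class:`ExpressionMatrix`: a nonnegative
transcripts × samples matrix whose sample identifiers carry their group
label (tissue, growing-year or cultivar) as ``"group:sample"``. "Expressed
in a group" means a value strictly above a threshold (default 0) in at
least one sample of that group — quantified transcriptome tables rarely
state a detection floor, so the threshold is an explicit knob.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionMatrix",
    "expressed_set",
    "group_venn",
    "specificity_share",
    "tissue_breadth",
    "heatmap_prep",
    "expressed_count_cv",
]


@dataclass
class ExpressionMatrix:
    """Nonnegative transcripts × samples matrix with per-sample group labels."""

    values: pd.DataFrame  # index = transcript ids, columns = sample ids
    groups: dict[str, str]  # sample id -> group label

    def __post_init__(self) -> None:
        if (self.values.to_numpy() < 0).any():
            raise ValueError("expression values must be nonnegative")
        missing = set(self.values.columns) - set(self.groups)
        if missing:
            raise ValueError(f"samples without group label: {sorted(missing)[:5]}")

    @property
    def transcript_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def group_labels(self) -> list[str]:
        seen: dict[str, None] = {}
        for s in self.values.columns:
            seen.setdefault(self.groups[s], None)
        return list(seen)

    def samples_of(self, group: str) -> list[str]:
        cols = [s for s in self.values.columns if self.groups[s] == group]
        if not cols:
            raise KeyError(f"unknown group {group!r}")
        return cols

    def subset(self, transcript_ids: Sequence[str]) -> "ExpressionMatrix":
        return ExpressionMatrix(self.values.loc[list(transcript_ids)], dict(self.groups))

    # --- TSV round-trip: header encodes groups as "group:sample" ------------

    def to_tsv(self, path: str | Path) -> None:
        df = self.values.copy()
        df.columns = [f"{self.groups[s]}:{s}" for s in df.columns]
        df.to_csv(path, sep="\t", index_label="transcript")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "ExpressionMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        df.index.name = None
        groups: dict[str, str] = {}
        cols: list[str] = []
        for c in df.columns:
            group, _, sample = c.partition(":")
            if not sample:
                raise ValueError(f"sample header {c!r} is not 'group:sample'")
            groups[sample] = group
            cols.append(sample)
        df.columns = cols
        return cls(df, groups)


def expressed_set(
    matrix: ExpressionMatrix, group: str, threshold: float = 0.0
) -> set[str]:
    """Transcripts with a value strictly above ``threshold`` in ≥ 1 sample of ``group``."""
    cols = matrix.samples_of(group)
    mask = (matrix.values[cols] > threshold).any(axis=1)
    return set(matrix.values.index[mask])


def group_venn(
    matrix: ExpressionMatrix,
    groups: Sequence[str] | None = None,
    threshold: float = 0.0,
) -> dict:
    """Full membership partition of expressed transcripts across groups.

    Returns per-group expressed counts, the all-groups intersection count,
    per-group-specific counts, the union count, and the full 2^k partition
    keyed by membership tuples. The partition cells sum to the union by
    construction.
    """
    if groups is None:
        groups = matrix.group_labels
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    sets = {g: expressed_set(matrix, g, threshold) for g in groups}
    union = set().union(*sets.values())

    partition: dict[tuple[str, ...], int] = {}
    for t in union:
        key = tuple(g for g in groups if t in sets[g])
        partition[key] = partition.get(key, 0) + 1

    specific = {g: partition.get((g,), 0) for g in groups}
    return {
        "per_group": {g: len(sets[g]) for g in groups},
        "intersection": partition.get(tuple(groups), 0),
        "specific": specific,
        "union": len(union),
        "partition": partition,
    }


def specificity_share(
    specific_counts: Mapping[str, int], focus: str, decimals: int = 0
) -> float:
    """Share (in %) of one group among all group-specific transcripts."""
    from .annotation import round_half_up

    if focus not in specific_counts:
        raise KeyError(f"focus group {focus!r} not in counts")
    total = sum(specific_counts.values())
    if total == 0:
        raise ValueError("all specific counts are zero")
    return round_half_up(100.0 * specific_counts[focus] / total, decimals)


def tissue_breadth(
    matrix: ExpressionMatrix,
    groups: Sequence[str] | None = None,
    threshold: float = 0.0,
) -> dict:
    """Three-way breadth partition of the expressed union across tissues.

    Classes: expressed in *all* tissues, in exactly *one* tissue (with a
    per-tissue breakdown), and in *several* (more than one but not all).
    """
    if groups is None:
        groups = matrix.group_labels
    if len(groups) < 2:
        raise ValueError("need at least 2 tissue groups")
    sets = {g: expressed_set(matrix, g, threshold) for g in groups}
    union = set().union(*sets.values())

    ubiquitous, single, several = [], {}, []
    for t in union:
        member = [g for g in groups if t in sets[g]]
        if len(member) == len(groups):
            ubiquitous.append(t)
        elif len(member) == 1:
            single[t] = member[0]
        else:
            several.append(t)
    per_tissue_single: dict[str, int] = {}
    for g in single.values():
        per_tissue_single[g] = per_tissue_single.get(g, 0) + 1
    return {
        "expressed": len(union),
        "all_tissues": len(ubiquitous),
        "one_tissue": len(single),
        "several": len(several),
        "one_tissue_by_tissue": per_tissue_single,
        "one_tissue_members": single,
    }


def heatmap_prep(
    matrix: ExpressionMatrix,
    log_base: float = 2.0,
    pseudo: float = 1.0,
    row_scale: bool = False,
) -> pd.DataFrame:
    """log(value + pseudo) transform, optionally z-scaled per row.

    Zero-variance rows map to all-zero under row scaling rather than NaN.
    """
    if pseudo <= 0:
        raise ValueError("pseudo must be positive")
    x = np.log(matrix.values.to_numpy(dtype=float) + pseudo) / np.log(log_base)
    if row_scale:
        mu = x.mean(axis=1, keepdims=True)
        sd = x.std(axis=1, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            x = np.where(sd > 0, (x - mu) / sd, 0.0)
    return pd.DataFrame(x, index=matrix.values.index, columns=matrix.values.columns)


def expressed_count_cv(
    matrix: ExpressionMatrix, threshold: float = 0.0
) -> tuple[float, float]:
    """Mean and sample CV of per-group expressed-transcript counts.

    With one sample per group (e.g. 42 cultivar roots) this is the
    consistency statistic across genotypes.
    """
    counts = np.array(
        [len(expressed_set(matrix, g, threshold)) for g in matrix.group_labels],
        dtype=float,
    )
    if counts.size < 2:
        raise ValueError("need at least 2 groups")
    mean = float(counts.mean())
    cv = float(counts.std(ddof=1) / mean) if mean else float("nan")
    return mean, cv
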