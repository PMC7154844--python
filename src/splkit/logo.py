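"""Position-frequency and information-content statistics of protein alignments.

The math behind a sequence logo: per-column residue counts
(:func:`column_profile`), per-column information content in bits
(:func:`information_content`, Shannon entropy subtracted from log2(20), with
the optional small-sample correction ``e(n) = 19 / (2 ln2 · n)``), and
conserved-position calls at a modal-frequency threshold
(:func:`conserved_positions`). Column coordinates in reports are 1-based,
the convention of alignment viewers.

Gap handling: frequencies are renormalized over non-gap residues; columns
that are majority-gap are flagged, since their apparent conservation is an
alignment artifact more often than a biological signal.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from Bio import AlignIO

__all__ = [
    "AlignmentProfile",
    "column_profile",
    "information_content",
    "conserved_positions",
    "plot_information_profile",
]

AA_ALPHABET = tuple("ACDEFGHIKLMNPQRSTVWY")
GAP_CHARS = ("-", ".")

MAX_BITS = float(np.log2(len(AA_ALPHABET)))  # 20-letter alphabet


@dataclass
class AlignmentProfile:
    """Per-column residue counts over the 20-letter alphabet plus gaps."""

    counts: pd.DataFrame  # index = residues + "-", columns = 0..L-1
    n_sequences: int

    @property
    def n_columns(self) -> int:
        return self.counts.shape[1]

    def gap_fraction(self) -> np.ndarray:
        return self.counts.loc["-"].to_numpy() / self.n_sequences


def _read_alignment(
    alignment: Sequence[tuple[str, str]] | str | Path,
) -> list[str]:
    if isinstance(alignment, (str, Path)):
        aln = AlignIO.read(str(alignment), "fasta")
        seqs = [str(rec.seq).upper() for rec in aln]
    else:
        seqs = [s.upper() for _, s in alignment]
    if len(seqs) < 2:
        raise ValueError("need at least 2 sequences")
    if len({len(s) for s in seqs}) != 1:
        raise ValueError("ragged alignment: unequal sequence lengths")
    return seqs


def column_profile(
    alignment: Sequence[tuple[str, str]] | str | Path,
) -> AlignmentProfile:
    """Exact per-column residue counts; gaps tracked in a separate row."""
    seqs = _read_alignment(alignment)
    L = len(seqs[0])
    rows = list(AA_ALPHABET) + ["-"]
    counts = np.zeros((len(rows), L), dtype=int)
    index = {aa: i for i, aa in enumerate(AA_ALPHABET)}
    for s in seqs:
        for j, ch in enumerate(s):
            if ch in GAP_CHARS:
                counts[-1, j] += 1
            elif ch in index:
                counts[index[ch], j] += 1
            else:
                raise ValueError(f"unexpected character {ch!r} in alignment")
    return AlignmentProfile(
        counts=pd.DataFrame(counts, index=rows), n_sequences=len(seqs)
    )


def information_content(
    profile: AlignmentProfile, small_sample_correction: bool = False
) -> np.ndarray:
    """Per-column information content in bits, floored at zero.

    ``IC = log2(20) - H - e(n)`` with H the Shannon entropy of gap-excluded
    frequencies and ``e(n) = (20 - 1) / (2 ln2 · n)`` when the small-sample
    correction is on (n = number of non-gap residues in the column).
    All-gap columns carry no information and return 0.
    """
    aa_counts = profile.counts.loc[list(AA_ALPHABET)].to_numpy(dtype=float)
    totals = aa_counts.sum(axis=0)
    ic = np.zeros(profile.n_columns)
    for j in range(profile.n_columns):
        n = totals[j]
        if n == 0:
            continue  # all-gap column: flagged by gap_fraction() == 1
        freqs = aa_counts[:, j] / n
        nz = freqs[freqs > 0]
        h = float(-(nz * np.log2(nz)).sum())
        val = MAX_BITS - h
        if small_sample_correction:
            val -= (len(AA_ALPHABET) - 1) / (2.0 * np.log(2) * n)
        ic[j] = max(val, 0.0)
    return ic


def conserved_positions(
    profile: AlignmentProfile, min_fraction: float = 0.9
) -> list[tuple[int, str]]:
    """Columns whose modal gap-excluded residue reaches ``min_fraction``.

    Returns (column, residue) pairs with 1-based column numbers. All-gap
    columns are never conserved.
    """
    if not 0 < min_fraction <= 1:
        raise ValueError("min_fraction must lie in (0, 1]")
    aa_counts = profile.counts.loc[list(AA_ALPHABET)].to_numpy(dtype=float)
    totals = aa_counts.sum(axis=0)
    out: list[tuple[int, str]] = []
    for j in range(profile.n_columns):
        if totals[j] == 0:
            continue
        i = int(aa_counts[:, j].argmax())
        if aa_counts[i, j] / totals[j] >= min_fraction:
            out.append((j + 1, AA_ALPHABET[i]))
    return out


def plot_information_profile(
    profile: AlignmentProfile,
    path=None,
    small_sample_correction: bool = False,
):
    """Bar plot of per-column information content (a logo's stack heights)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    ic = information_content(profile, small_sample_correction)
    fig, ax = plt.subplots(figsize=(max(4, profile.n_columns / 8), 2.6))
    ax.bar(np.arange(1, profile.n_columns + 1), ic, width=0.85)
    ax.set_xlabel("alignment column")
    ax.set_ylabel("bits")
    ax.set_ylim(0, MAX_BITS)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
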