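"""Pairwise Ka/Ks by the Nei–Gojobori (1986) counting method.

The NG86 estimator counts, for a pair of aligned in-frame coding sequences,
the numbers of synonymous (S) and nonsynonymous (N) *sites* — fractional
per-codon counts averaged over the two sequences — and of synonymous (Sd)
and nonsynonymous (Nd) *differences*, averaging over all minimal
substitution pathways between differing codons with equal weights (pathways
through stop codons are excluded). The proportions pS = Sd/S and pN = Nd/N
are corrected for multiple hits with the Jukes–Cantor formula
``d = -(3/4) ln(1 - (4/3) p)``; omega = Ka/Ks. Changes that would create a
stop codon are excluded from the site tally (see :func:`codon_sites`);
codons containing N in either sequence are skipped and reported as excluded.

NG86 underestimates omega when transition/transversion bias or codon usage
bias is strong; for the purifying-selection question it answers here
(is omega well below 1?) the bias is immaterial.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from Bio.Data import CodonTable

__all__ = ["KaKsResult", "ng86_kaks", "kaks_summary", "codon_sites", "codon_path_differences"]

_TABLE = CodonTable.unambiguous_dna_by_id[1]
_STOPS = set(_TABLE.stop_codons)
_CODE = dict(_TABLE.forward_table)
_NT = "ACGT"


@dataclass(frozen=True)
class KaKsResult:
    ka: float
    ks: float
    ratio: float  # NaN when undefined (Ks == 0)
    s_sites: float
    n_sites: float
    s_diffs: float
    n_diffs: float
    excluded_codons: int
    undefined: bool
    saturated: bool


def _aa(codon: str) -> str | None:
    """Amino acid for a codon; None for stops."""
    return None if codon in _STOPS else _CODE[codon]


def codon_sites(codon: str) -> float:
    """Fractional count of synonymous sites in one codon.

    Each position contributes one site, split between the synonymous and
    nonsynonymous classes by the fraction of *viable* (non-stop) single
    nucleotide changes that preserve the amino acid. Stop-creating changes
    are excluded from the denominator: in coding sequence they are not part
    of the substitution process, and counting them as nonsynonymous sites
    biases omega downward. The nonsynonymous site count is ``3 - s``.
    """
    if codon in _STOPS:
        raise ValueError(f"stop codon {codon} has no defined site count")
    s = 0.0
    for pos in range(3):
        syn = viable = 0
        for nt in _NT:
            if nt == codon[pos]:
                continue
            alt = codon[:pos] + nt + codon[pos + 1 :]
            if alt in _STOPS:
                continue
            viable += 1
            if _aa(alt) == _aa(codon):
                syn += 1
        if viable:
            s += syn / viable
    return s


def codon_path_differences(c1: str, c2: str) -> tuple[float, float]:
    """(synonymous, nonsynonymous) differences between two codons.

    Averages over all orderings of the differing positions, excluding
    pathways that pass through a stop codon; if every pathway is blocked,
    all pathways are used (stop steps counted as nonsynonymous) so the
    difference count is never lost.
    """
    diff_pos = [i for i in range(3) if c1[i] != c2[i]]
    if not diff_pos:
        return 0.0, 0.0

    def walk(order: Sequence[int], allow_stops: bool) -> tuple[float, float] | None:
        cur = c1
        sd = nd = 0.0
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1 :]
            if nxt in _STOPS:
                if not allow_stops:
                    return None
                nd += 1.0
            elif _aa(cur) == _aa(nxt):
                sd += 1.0
            else:
                nd += 1.0
            cur = nxt
        return sd, nd

    results = [
        r for order in itertools.permutations(diff_pos) if (r := walk(order, False))
    ]
    if not results:
        results = [walk(order, True) for order in itertools.permutations(diff_pos)]
    sd = float(np.mean([r[0] for r in results]))
    nd = float(np.mean([r[1] for r in results]))
    return sd, nd


def _jc_correct(p: float) -> tuple[float, bool]:
    if p >= 0.75:
        return float("nan"), True
    if p == 0:
        return 0.0, False
    return -0.75 * math.log(1.0 - (4.0 / 3.0) * p), False


def ng86_kaks(seq1: str, seq2: str) -> KaKsResult:
    """NG86 Ka, Ks and omega for a gap-free in-frame codon pair.

    Sequences must be equal length, a multiple of 3, without internal stop
    codons. Codons with N in either sequence are excluded and counted.
    Identical sequences give Ka = Ks = 0 with the ratio flagged undefined;
    saturation (p ≥ 3/4 in either class) flags the result.
    """
    seq1, seq2 = seq1.upper(), seq2.upper()
    if len(seq1) != len(seq2):
        raise ValueError("sequences differ in length")
    if len(seq1) % 3 != 0:
        raise ValueError("sequence length is not a multiple of 3")

    s_sites = n_sites = s_diffs = n_diffs = 0.0
    excluded = 0
    for i in range(0, len(seq1), 3):
        c1, c2 = seq1[i : i + 3], seq2[i : i + 3]
        if "N" in c1 or "N" in c2:
            excluded += 1
            continue
        for c in (c1, c2):
            if c in _STOPS:
                raise ValueError(f"internal stop codon {c} at nt position {i}")
        s_sites += 0.5 * (codon_sites(c1) + codon_sites(c2))
        sd, nd = codon_path_differences(c1, c2)
        s_diffs += sd
        n_diffs += nd
    n_sites = 3.0 * ((len(seq1) // 3) - excluded) - s_sites

    ps = s_diffs / s_sites if s_sites > 0 else 0.0
    pn = n_diffs / n_sites if n_sites > 0 else 0.0
    ks, sat_s = _jc_correct(ps)
    ka, sat_n = _jc_correct(pn)
    saturated = sat_s or sat_n
    undefined = (not saturated) and ks == 0.0
    ratio = float("nan") if (undefined or saturated or ks == 0) else ka / ks
    return KaKsResult(
        ka=ka,
        ks=ks,
        ratio=ratio,
        s_sites=s_sites,
        n_sites=n_sites,
        s_diffs=s_diffs,
        n_diffs=n_diffs,
        excluded_codons=excluded,
        undefined=undefined,
        saturated=saturated,
    )


def kaks_summary(
    ratios: Iterable[tuple[str, float]],
    exclude: Sequence[str] = (),
) -> dict:
    """Mean, sample CV and extremal pairs of a set of labelled omega values.

    Non-finite ratios are ignored; if all are non-finite an error is
    raised. When ``exclude`` names labels (substring match, so one species
    tag can drop several pairs), a re-summary without them is included
    under ``"excluded_resummary"``.
    """
    items = [(lab, r) for lab, r in ratios if np.isfinite(r)]
    if len(items) < 2:
        raise ValueError("need at least 2 finite ratios")

    def _summ(pairs: list[tuple[str, float]]) -> dict:
        vals = np.array([r for _, r in pairs])
        mean = float(vals.mean())
        cv = float(vals.std(ddof=1) / mean) if mean and len(vals) > 1 else 0.0
        lo = min(pairs, key=lambda t: t[1])
        hi = max(pairs, key=lambda t: t[1])
        return {
            "mean": mean,
            "cv": cv,
            "min_pair": lo[0],
            "min": lo[1],
            "max_pair": hi[0],
            "max": hi[1],
            "n": len(pairs),
        }

    out = _summ(items)
    if exclude:
        kept = [
            (lab, r) for lab, r in items if not any(e in lab for e in exclude)
        ]
        if len(kept) >= 2:
            out["excluded_resummary"] = _summ(kept)
    return out
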