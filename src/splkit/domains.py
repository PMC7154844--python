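"""SBP-domain detection and typing.

The SBP (SQUAMOSA promoter binding protein) DNA-binding domain spans 74
aligned residues and carries two zinc fingers followed by an overlapping
basic nuclear localization signal (NLS). Eight residues coordinate the two
zinc ions; their identities define the domain type:

* ``C3HC2HC`` — finger 1 is Cys-Cys-Cys-His, finger 2 Cys-Cys-His-Cys;
* ``C4C2HC``  — finger 1 is all-Cys (the His slot is a Cys), finger 2
  unchanged.

Offsets of the key residues inside the 74-residue domain are derived from
the spacings between the conserved alignment columns reported for plant SBP
domains (zinc finger 1 at columns 214/219/236/239 of the family alignment,
zinc finger 2 at 255/258/262/274, NLS basics at 271/272/284/285/286/287):
relative to the first finger-1 cysteine these are 0, 5, 22, 25 (ZF1),
41, 44, 48, 60 (ZF2) and 57, 58, 70, 71, 72, 73 (NLS). The spacings are
configurable through :class:`DomainSpec` because they vary slightly across
lineages.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "DomainSpec",
    "DomainMatch",
    "DEFAULT_SPEC",
    "scan_sbp_domain",
    "domain_length_ratio",
    "sbp_ratio_ttest",
    "matches_to_tsv_rows",
    "matches_to_gff3_lines",
]

BASIC = set("KR")


@dataclass(frozen=True)
class DomainSpec:
    """Positional template of the SBP domain, 0-based offsets from its start.

    ``zf1_offsets[3]`` is the type-discriminating slot: His there means
    C3HC2HC, Cys means C4C2HC.
    """

    length: int = 74
    zf1_offsets: tuple[int, int, int, int] = (0, 5, 22, 25)
    zf2_offsets: tuple[int, int, int, int] = (41, 44, 48, 60)
    nls_offsets: tuple[int, ...] = (57, 58, 70, 71, 72, 73)
    min_nls_basics: int = 5

    def __post_init__(self) -> None:
        all_off = (*self.zf1_offsets, *self.zf2_offsets, *self.nls_offsets)
        if max(all_off) >= self.length:
            raise ValueError("offsets must fall inside the domain length")


DEFAULT_SPEC = DomainSpec()


@dataclass(frozen=True)
class DomainMatch:
    """A located SBP domain in protein coordinates (0-based half-open)."""

    start: int
    end: int
    zf1_positions: tuple[int, int, int, int]
    zf2_positions: tuple[int, int, int, int]
    nls_span: tuple[int, int]
    type_label: str  # C3HC2HC | C4C2HC | undetermined
    complete: bool
    n_zinc_matched: int = 8


def _score_window(window: str, spec: DomainSpec) -> tuple[int, str, int]:
    """(zinc positions matched, type label, NLS basics) for one window."""
    zf_expect = [
        (spec.zf1_offsets[0], "C"),
        (spec.zf1_offsets[1], "C"),
        (spec.zf1_offsets[2], "C"),
        (spec.zf1_offsets[3], "CH"),  # discriminating slot
        (spec.zf2_offsets[0], "C"),
        (spec.zf2_offsets[1], "C"),
        (spec.zf2_offsets[2], "H"),
        (spec.zf2_offsets[3], "C"),
    ]
    matched = sum(window[off] in allowed for off, allowed in zf_expect)
    disc = window[spec.zf1_offsets[3]]
    if disc == "H":
        label = "C3HC2HC"
    elif disc == "C":
        label = "C4C2HC"
    else:
        label = "undetermined"
    basics = sum(window[off] in BASIC for off in spec.nls_offsets)
    return matched, label, basics


def scan_sbp_domain(
    protein: str, spec: DomainSpec = DEFAULT_SPEC
) -> list[DomainMatch]:
    """Scan a protein for SBP domains by sliding the positional template.

    A *complete* match satisfies all 8 zinc-coordinating positions and the
    NLS rule (≥ ``spec.min_nls_basics`` of the NLS offsets are K/R). Windows
    matching ≥ 6 of 8 zinc positions (with the NLS rule) are reported as
    incomplete candidates. Overlapping candidates are resolved greedily,
    best first (most zinc positions matched, then leftmost); the returned
    list is ordered best-first. No match yields an empty list.
    """
    protein = protein.upper()
    L = spec.length
    candidates: list[tuple[int, int]] = []  # (n_matched, start)
    for i in range(len(protein) - L + 1):
        matched, _, basics = _score_window(protein[i : i + L], spec)
        if matched >= 6 and basics >= spec.min_nls_basics:
            candidates.append((matched, i))
    candidates.sort(key=lambda t: (-t[0], t[1]))

    taken: list[tuple[int, int]] = []
    matches: list[DomainMatch] = []
    for matched, i in candidates:
        if any(i < e and i + L > s for s, e in taken):
            continue
        taken.append((i, i + L))
        window = protein[i : i + L]
        n_matched, label, _ = _score_window(window, spec)
        complete = n_matched == 8
        matches.append(
            DomainMatch(
                start=i,
                end=i + L,
                zf1_positions=tuple(i + o for o in spec.zf1_offsets),
                zf2_positions=tuple(i + o for o in spec.zf2_offsets),
                nls_span=(i + spec.nls_offsets[0], i + spec.nls_offsets[-1] + 1),
                type_label=label if complete else (label if n_matched >= 6 else "undetermined"),
                complete=complete,
                n_zinc_matched=n_matched,
            )
        )
    return matches


def domain_length_ratio(
    seq_length: int, match: DomainMatch | None = None, *, basis: str = "nt"
) -> float:
    """Fraction of a transcript occupied by its SBP domain.

    On the default nucleotide basis the domain span in residues is
    multiplied by 3 and divided by the transcript length in bp; ``basis="aa"``
    divides the residue span by ``seq_length`` taken in amino acids. A ratio
    above 1 signals inconsistent inputs and is returned as-is (callers may
    flag it); an incomplete match contributes its actual matched span.
    """
    if seq_length <= 0:
        raise ValueError("seq_length must be positive")
    span = (match.end - match.start) if match is not None else 0
    if basis == "nt":
        return (span * 3) / seq_length
    if basis == "aa":
        return span / seq_length
    raise ValueError(f"unknown basis {basis!r}")


def sbp_ratio_ttest(
    group_a_ratios: list[float], group_b_ratios: list[float]
) -> tuple[float, float, float]:
    """Welch two-sample t-test on two sets of domain/transcript length ratios.

    Returns ``(t, df, p)`` with the Welch–Satterthwaite degrees of freedom
    and a two-sided p. Two identical zero-variance groups are degenerate:
    the difference is exactly zero with no sampling noise, so ``t = 0`` and
    ``p = 1`` are returned with a warning.
    """
    a = np.asarray(group_a_ratios, dtype=float)
    b = np.asarray(group_b_ratios, dtype=float)
    for name, g in (("a", a), ("b", b)):
        if g.size < 2:
            raise ValueError(f"group {name} needs at least 2 values")
        if ((g < 0) | (g > 1)).any():
            raise ValueError(f"group {name} contains ratios outside [0, 1]")
    if a.std() == 0 and b.std() == 0:
        if a.mean() == b.mean():
            warnings.warn("both groups constant and equal; p set to 1")
            df = a.size + b.size - 2.0
            return 0.0, df, 1.0
        warnings.warn("zero-variance groups with distinct means; p set to 0")
        return float("inf"), a.size + b.size - 2.0, 0.0
    res = stats.ttest_ind(a, b, equal_var=False)
    return float(res.statistic), float(res.df), float(res.pvalue)


def matches_to_tsv_rows(
    named_matches: list[tuple[str, DomainMatch]]
) -> list[str]:
    """Edge-style TSV lines: transcript, start, end, type, complete."""
    rows = ["transcript\tstart\tend\ttype\tcomplete"]
    for name, m in named_matches:
        rows.append(f"{name}\t{m.start}\t{m.end}\t{m.type_label}\t{int(m.complete)}")
    return rows


def matches_to_gff3_lines(
    named_matches: list[tuple[str, DomainMatch]]
) -> list[str]:
    """GFF3-like feature lines in protein space, 1-based inclusive."""
    lines = ["##gff-version 3"]
    for name, m in named_matches:
        attrs = f"ID=sbp_{name};type={m.type_label};complete={int(m.complete)}"
        lines.append(
            f"{name}\tsplkit\tSBP_domain\t{m.start + 1}\t{m.end}\t.\t.\t.\t{attrs}"
        )
    return lines
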