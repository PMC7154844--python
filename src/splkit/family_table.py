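"""Gene-family table model and recomputation contracts.

A family table holds one row per transcript of a gene family as reported in a
transcriptome survey: gene and transcript identifiers, transcript length in
bp, ORF length in amino acids, predicted molecular weight in kDa and
isoelectric point. The module parses and serializes such tables, recomputes
the derived protein parameters (longest ORF, MW, pI) from sequence, and
summarizes family sizes across species.

The packaged ginseng SPL table (106 transcripts from 30 genes) is available
through :func:`load_packaged_table`. Its printed values are stored verbatim —
several rows are internally odd (e.g. an ORF longer than a naive reading of
the transcript length allows) and are deliberately not "corrected".
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio.Seq import Seq
from Bio.SeqUtils.IsoelectricPoint import IsoelectricPoint
from Bio.SeqUtils.ProtParam import ProteinAnalysis

__all__ = [
    "TranscriptRecord",
    "ORFResult",
    "parse_family_table",
    "write_family_table",
    "load_packaged_table",
    "packaged_table_path",
    "find_longest_orf",
    "compute_mw",
    "compute_pi",
    "family_size_summary",
]

STANDARD_AA = set("ACDEFGHIKLMNPQRSTVWY")

#: Average mass of one water molecule in Da (added once per chain).
WATER_MW = 18.0153

_COLUMNS = ["gene", "transcript", "seq_length_bp", "orf_length_aa", "mw_kda", "pi"]


@dataclass(frozen=True)
class TranscriptRecord:
    """One row of a gene-family table, stored as printed.

    ``orf_length * 3 + 3 <= seq_length`` is *not* enforced: published tables
    of this kind contain rows violating the naive expectation, and the record
    is a faithful container, not a validator of upstream ORF calls.
    """

    gene_id: str
    transcript_id: str
    seq_length: int
    orf_length: int
    mw: float
    pi: float

    def __post_init__(self) -> None:
        if not self.transcript_id.startswith(self.gene_id):
            raise ValueError(
                f"transcript_id {self.transcript_id!r} does not begin with "
                f"gene_id {self.gene_id!r}"
            )
        if self.mw <= 0:
            raise ValueError(f"mw must be positive, got {self.mw}")
        if not 0 < self.pi < 14:
            raise ValueError(f"pi must lie in (0, 14), got {self.pi}")


@dataclass(frozen=True)
class ORFResult:
    """Longest open reading frame over six frames.

    Coordinates are 0-based half-open on the forward strand of the input
    sequence; ``protein`` excludes the stop codon and includes the initial M.
    """

    frame: int
    strand: str  # "+" or "-"
    start: int
    end: int
    protein: str


def parse_family_table(path: str | Path) -> list[TranscriptRecord]:
    """Parse a TSV family table into records, preserving row order.

    Raises ``ValueError`` on a malformed numeric cell (naming the row) or a
    duplicate transcript identifier.
    """
    path = Path(path)
    records: list[TranscriptRecord] = []
    seen: set[str] = set()
    with path.open(newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        if reader.fieldnames != _COLUMNS:
            raise ValueError(
                f"unexpected header {reader.fieldnames}; expected {_COLUMNS}"
            )
        for i, row in enumerate(reader, start=2):
            try:
                rec = TranscriptRecord(
                    gene_id=row["gene"],
                    transcript_id=row["transcript"],
                    seq_length=int(row["seq_length_bp"]),
                    orf_length=int(row["orf_length_aa"]),
                    mw=float(row["mw_kda"]),
                    pi=float(row["pi"]),
                )
            except (TypeError, ValueError) as exc:
                raise ValueError(f"malformed row {i} of {path.name}: {exc}") from exc
            if rec.transcript_id in seen:
                raise ValueError(f"duplicate transcript_id {rec.transcript_id!r}")
            seen.add(rec.transcript_id)
            records.append(rec)
    return records


def write_family_table(records: Iterable[TranscriptRecord], path: str | Path) -> None:
    """Serialize records back to TSV so parse/write round-trips identically."""
    with Path(path).open("w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(_COLUMNS)
        for r in records:
            writer.writerow(
                [
                    r.gene_id,
                    r.transcript_id,
                    r.seq_length,
                    r.orf_length,
                    f"{r.mw:.2f}",
                    f"{r.pi:.2f}",
                ]
            )


def packaged_table_path() -> Path:
    """Path to the packaged ginseng SPL family table."""
    return Path(resources.files("splkit").joinpath("data/pgspl_family_table.tsv"))


def load_packaged_table() -> list[TranscriptRecord]:
    """Load the packaged ginseng SPL family table (106 transcripts, 30 genes)."""
    return parse_family_table(packaged_table_path())


def _orfs_in_frame(seq: str, offset: int) -> Iterable[tuple[int, int, str]]:
    """Yield (start, end, protein) for every ATG..stop span in one frame."""
    codons = [seq[i : i + 3] for i in range(offset, len(seq) - 2, 3)]
    protein = str(Seq("".join(codons)).translate())
    i = 0
    while i < len(protein):
        if protein[i] == "M":
            j = protein.find("*", i)
            if j == -1:
                break  # no stop: not a complete ORF
            yield offset + 3 * i, offset + 3 * (j + 1), protein[i:j]
            i = j + 1
        else:
            i += 1


def find_longest_orf(nucleotide_seq: str) -> ORFResult | None:
    """Longest ATG-initiated, stop-terminated ORF over all six frames.

    Ties are broken by strand (forward first) then by smaller start
    coordinate on the reported strand's reading. Coordinates are mapped back
    to the forward strand, 0-based half-open. Returns ``None`` when no ORF
    exists.
    """
    seq = nucleotide_seq.upper()
    if len(seq) < 6:
        raise ValueError("sequence shorter than 6 nt cannot contain an ORF")
    bad = set(seq) - set("ACGTN")
    if bad:
        raise ValueError(f"invalid nucleotide characters: {sorted(bad)}")

    rc = str(Seq(seq).reverse_complement())
    candidates: list[ORFResult] = []
    for strand, s in (("+", seq), ("-", rc)):
        for offset in range(3):
            for start, end, protein in _orfs_in_frame(s, offset):
                if strand == "+":
                    fwd_start, fwd_end = start, end
                else:
                    fwd_start, fwd_end = len(seq) - end, len(seq) - start
                candidates.append(ORFResult(offset, strand, fwd_start, fwd_end, protein))
    if not candidates:
        return None
    # longest wins; ties broken forward-strand-first, then smaller forward start
    return max(candidates, key=lambda o: (len(o.protein), o.strand == "+", -o.start))


def compute_mw(protein: str) -> float:
    """Molecular weight in kDa: sum of average residue masses plus one water.

    The empty chain returns the mass of water alone.
    """
    _check_alphabet(protein)
    if not protein:
        return WATER_MW / 1000.0
    return ProteinAnalysis(protein).molecular_weight() / 1000.0


def compute_pi(protein: str) -> float:
    """Isoelectric point via Henderson–Hasselbalch with Bjellqvist pKa values.

    Charge contributions come from the termini and the D, E, C, Y, H, K, R
    side chains; the net charge is monotone decreasing in pH so the zero
    crossing is unique. Root located by bisection to 1e-4 pH units.
    """
    _check_alphabet(protein)
    if not protein:
        raise ValueError("pI is undefined for the empty sequence")
    return IsoelectricPoint(protein).pi()


def _check_alphabet(protein: str) -> None:
    bad = sorted(set(protein) - STANDARD_AA)
    if bad:
        raise ValueError(f"non-standard amino-acid letters: {bad}")


def family_size_summary(
    per_species_counts: Sequence[tuple[str, int]], *, sample: bool = True
) -> tuple[float, float]:
    """Mean and coefficient of variation of per-species family sizes.

    CV is sd/mean; sample sd by default (population via ``sample=False``).
    With a single species the sample CV is undefined and reported as NaN.
    """
    if not per_species_counts:
        raise ValueError("per_species_counts must be nonempty")
    counts = np.asarray([c for _, c in per_species_counts], dtype=float)
    if (counts < 0).any():
        raise ValueError("counts must be nonnegative")
    mean = float(counts.mean())
    if sample and counts.size < 2:
        return mean, float("nan")
    sd = float(counts.std(ddof=1 if sample else 0))
    cv = sd / mean if mean != 0 else float("nan")
    return mean, cv
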