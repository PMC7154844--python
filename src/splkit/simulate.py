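"""Synthetic data with planted ground truth for every pipeline stage.

Real gene-family surveys of this kind rest on expression matrices and coding
sequences that are rarely redistributable, so the package ships a generator
that emulates their statistical structure:

* **Expression** — a log-normal latent-factor model. Each planted block of
  transcripts shares a per-sample latent factor; a transcript's value is
  ``exp(loading * factor + dispersion * noise)``, optionally zeroed by
  independent Bernoulli dropout. The loading controls the within-block rank
  correlation (on the log scale it is ``loading^2 / (loading^2 +
  dispersion^2)``); loading 0 gives mutually independent transcripts, the
  negative-control regime. Group-specific transcripts are strictly zero
  outside their group and dropout-free inside it, so specificity calls on
  them are exact.
* **Proteins** — SPL-like sequences embedding one 74-residue SBP domain with
  the requested zinc-finger residue pattern (C3HC2HC or C4C2HC) and a basic
  NLS, inside random flanks; true coordinates are returned.
* **Codon pairs** — one sequence evolved from another under a proposal/
  acceptance substitution process whose nonsynonymous/synonymous rate ratio
  equals a target omega, with stop codons rejected.

One global integer seed drives a named substream per generator, so adding a
generator never perturbs the draws of the others.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from Bio.Seq import Seq

from .expression import ExpressionMatrix

__all__ = [
    "SimulationConfig",
    "simulate_expression",
    "simulate_spl_sequences",
    "simulate_codon_pair",
    "named_rng",
]

_NONKEY_AA = "ADEFGILMNPQSTVWY"  # no C/H/K/R: keeps planted key positions unambiguous
_FLANK_AA = "ACDEFGHIKLMNPQRSTVWY"

# SBP-domain template offsets; kept in sync with splkit.domains.DEFAULT_SPEC
_ZF1 = (0, 5, 22, 25)
_ZF2 = (41, 44, 48, 60)
_NLS = (57, 58, 70, 71, 72, 73)
_DOMAIN_LEN = 74


def named_rng(seed: int, name: str) -> np.random.Generator:
    """A reproducible substream: ``(seed, name)`` fully determines the draws."""
    tag = zlib.crc32(name.encode()) & 0x7FFFFFFF
    return np.random.default_rng(np.random.SeedSequence([int(seed), tag]))


@dataclass
class SimulationConfig:
    """Parameters of the synthetic expression study.

    Defaults mirror the surveyed design: ~106 focal transcripts against a
    large pool of unknown background transcripts, and sample groups such as
    14 tissues, 4 root ages or 42 single-sample cultivars.
    """

    n_spl: int = 106
    n_background: int = 2000
    n_samples_per_group: Mapping[str, int] = field(
        default_factory=lambda: {f"tissue{i:02d}": 3 for i in range(1, 15)}
    )
    block_spec: Sequence[tuple[int, float]] = field(
        default_factory=lambda: [(20, 0.9), (15, 0.9), (10, 0.85)]
    )
    specificity_spec: Mapping[str, int] = field(default_factory=dict)
    dropout_rate: float = 0.1
    dispersion: float = 0.5
    seed: int = 0

    def validate(self) -> None:
        if self.n_spl < 0:
            raise ValueError("n_spl must be >= 0")
        if self.n_background < 0:
            raise ValueError("n_background must be >= 0")
        if not self.n_samples_per_group:
            raise ValueError("n_samples_per_group must name at least one group")
        for g, n in self.n_samples_per_group.items():
            if n < 0:
                raise ValueError(f"n_samples_per_group[{g!r}] must be >= 0")
        for size, loading in self.block_spec:
            if size < 0:
                raise ValueError("block_spec sizes must be >= 0")
            if not 0.0 <= loading <= 1.0:
                raise ValueError("block_spec loadings must lie in [0, 1]")
        n_specific = sum(self.specificity_spec.values())
        for g, n in self.specificity_spec.items():
            if g not in self.n_samples_per_group:
                raise ValueError(f"specificity_spec group {g!r} unknown")
            if n < 0:
                raise ValueError(f"specificity_spec[{g!r}] must be >= 0")
        if sum(s for s, _ in self.block_spec) + n_specific > self.n_spl:
            raise ValueError("block_spec + specificity_spec exceed n_spl")
        if not 0.0 <= self.dropout_rate <= 1.0:
            raise ValueError("dropout_rate must lie in [0, 1]")
        if self.dispersion <= 0:
            raise ValueError("dispersion must be positive")


def simulate_expression(
    config: SimulationConfig,
) -> tuple[ExpressionMatrix, pd.DataFrame]:
    """Generate an expression matrix plus a ground-truth label table.

    The truth table has one row per transcript with columns ``role``
    (``block`` / ``specific`` / ``spl_free`` / ``background``), ``block_id``
    and ``specific_group``.
    """
    config.validate()
    rng = named_rng(config.seed, "expression")

    samples: list[str] = []
    groups: dict[str, str] = {}
    sample_group_idx: list[int] = []
    group_names = list(config.n_samples_per_group)
    for gi, g in enumerate(group_names):
        for k in range(config.n_samples_per_group[g]):
            sid = f"{g}_s{k + 1}"
            samples.append(sid)
            groups[sid] = g
            sample_group_idx.append(gi)
    n_samples = len(samples)

    spl_ids = [f"PgSPLsim{i + 1:03d}" for i in range(config.n_spl)]
    bg_ids = [f"UNK{i + 1:05d}" for i in range(config.n_background)]
    ids = spl_ids + bg_ids
    n_total = len(ids)

    role = ["spl_free"] * config.n_spl + ["background"] * config.n_background
    block_id = [""] * n_total
    specific_group = [""] * n_total

    values = np.empty((n_total, n_samples))
    # independent baseline for every transcript
    noise = rng.standard_normal((n_total, n_samples)) * config.dispersion
    values[:] = np.exp(noise)

    cursor = 0
    for b, (size, loading) in enumerate(config.block_spec):
        factor = rng.standard_normal(n_samples)
        sl = slice(cursor, cursor + size)
        eps = rng.standard_normal((size, n_samples)) * config.dispersion
        values[sl] = np.exp(loading * factor + eps)
        for i in range(cursor, cursor + size):
            role[i] = "block"
            block_id[i] = f"block{b + 1}"
        cursor += size

    specific_rows: list[int] = []
    for g, count in config.specificity_spec.items():
        gi = group_names.index(g)
        in_group = np.array([idx == gi for idx in sample_group_idx])
        for _ in range(count):
            i = cursor
            row = np.zeros(n_samples)
            # strictly positive inside the group, exactly zero outside
            row[in_group] = np.exp(
                rng.standard_normal(in_group.sum()) * config.dispersion
            )
            values[i] = row
            role[i] = "specific"
            specific_group[i] = g
            specific_rows.append(i)
            cursor += 1

    if config.dropout_rate > 0:
        drop = rng.random((n_total, n_samples)) < config.dropout_rate
        drop[specific_rows, :] = False  # specificity must stay exact
        values = np.where(drop, 0.0, values)

    matrix = ExpressionMatrix(pd.DataFrame(values, index=ids, columns=samples), groups)
    truth = pd.DataFrame(
        {
            "transcript_id": ids,
            "role": role,
            "block_id": block_id,
            "specific_group": specific_group,
        }
    ).set_index("transcript_id")
    return matrix, truth


def _domain_sequence(rng: np.random.Generator, domain_type: str) -> str:
    residues = list(rng.choice(list(_NONKEY_AA), size=_DOMAIN_LEN))
    zf1_res = "CCCH" if domain_type == "C3HC2HC" else "CCCC"
    for off, aa in zip(_ZF1, zf1_res):
        residues[off] = aa
    for off, aa in zip(_ZF2, "CCHC"):
        residues[off] = aa
    for off, aa in zip(_NLS, "KRRRRK"):
        residues[off] = aa
    return "".join(residues)


def simulate_spl_sequences(
    n: int,
    domain_type: str = "C3HC2HC",
    seed: int = 0,
    flank_range: tuple[int, int] = (30, 80),
) -> tuple[list[tuple[str, str]], list[tuple[int, int]]]:
    """SPL-like proteins, each embedding one SBP domain at a known position.

    Returns ``(records, coords)`` where records are ``(name, sequence)``
    pairs and coords give the true 0-based half-open domain span per
    sequence.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if domain_type not in ("C3HC2HC", "C4C2HC"):
        raise ValueError(f"unknown domain_type {domain_type!r}")
    rng = named_rng(seed, f"spl_sequences:{domain_type}")
    records, coords = [], []
    lo, hi = flank_range
    for i in range(n):
        left = int(rng.integers(lo, hi + 1))
        right = int(rng.integers(lo, hi + 1))
        flank_l = "".join(rng.choice(list(_FLANK_AA), size=left))
        flank_r = "".join(rng.choice(list(_FLANK_AA), size=right))
        domain = _domain_sequence(rng, domain_type)
        records.append((f"sim{domain_type}_{i + 1:03d}", flank_l + domain + flank_r))
        coords.append((left, left + _DOMAIN_LEN))
    return records, coords


_STOPS = {"TAA", "TAG", "TGA"}
_NT = "ACGT"


def _random_cds(rng: np.random.Generator, n_codons: int) -> list[str]:
    codons = []
    while len(codons) < n_codons:
        c = "".join(rng.choice(list(_NT), size=3))
        if c not in _STOPS:
            codons.append(c)
    return codons


def simulate_codon_pair(
    n_codons: int,
    target_omega: float,
    seed: int = 0,
    divergence: float = 0.2,
) -> tuple[str, str]:
    """A pair of in-frame coding sequences diverged at a controlled omega.

    One sequence is evolved from the other by single-nucleotide proposals:
    synonymous changes are always accepted, nonsynonymous changes with
    probability ``min(1, target_omega)`` (for omega > 1 the roles invert),
    and changes creating stop codons are rejected. ``divergence`` is the
    expected number of accepted substitutions per codon, kept below
    saturation by default. ``divergence=0`` returns identical sequences.
    """
    if n_codons < 50:
        raise ValueError("n_codons must be >= 50")
    if target_omega <= 0:
        raise ValueError("target_omega must be positive")
    if divergence < 0:
        raise ValueError("divergence must be >= 0")
    rng = named_rng(seed, "codon_pair")
    ancestor = _random_cds(rng, n_codons)
    derived = list(ancestor)

    accept_nonsyn = min(1.0, target_omega)
    accept_syn = min(1.0, 1.0 / target_omega)
    n_target = int(round(divergence * n_codons))
    accepted = 0
    while accepted < n_target:
        ci = int(rng.integers(n_codons))
        pos = int(rng.integers(3))
        old = derived[ci]
        new_nt = _NT[int(rng.integers(4))]
        if new_nt == old[pos]:
            continue
        new = old[:pos] + new_nt + old[pos + 1 :]
        if new in _STOPS:
            continue
        syn = Seq(old).translate() == Seq(new).translate()
        p = accept_syn if syn else accept_nonsyn
        if rng.random() < p:
            derived[ci] = new
            accepted += 1
    return "".join(ancestor), "".join(derived)
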