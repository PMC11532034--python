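"""Repertoire-level descriptive statistics of an ALP complement.

The headline quantity is the fraction of a genome devoted to coding ALPs:
3 bp per residue over the pooled ALP lengths, divided by genome size. Stop
codons are ignored — including one per gene moves the fraction by less
than 0.01 percentage points at these genome sizes, so the simpler
convention is used. The second quantity is residue composition: ALPs are
characteristically enriched in asparagine and threonine, reported as the
pooled Asn+Thr fraction and, against a background distribution, as per
residue log2 enrichment.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Mapping, Sequence

import numpy as np

from .seqio import AMINO_ACIDS, ProteinRecord


@dataclass(frozen=True)
class RepertoireSummary:
    species_label: str
    genome_size_bp: int
    n_alps: int
    total_alp_aa: int
    coding_fraction_pct: float
    min_len: int
    max_len: int
    mean_len: float
    rationale: str = ""


@dataclass(frozen=True)
class CompositionProfile:
    frequencies: dict[str, float]
    asn_thr_fraction: float
    background: dict[str, float] | None = None
    enrichment: dict[str, float] | None = None


def coding_fraction_pct(total_alp_aa: int, genome_size_bp: int) -> float:
    """Percent of the genome coding for ALPs: 100·3·aa / bp, half-up to 1 dp."""
    if genome_size_bp <= 0:
        raise ValueError("genome size must be positive")
    if total_alp_aa == 0:
        return 0.0
    pct = Decimal(300) * Decimal(total_alp_aa) / Decimal(genome_size_bp)
    return float(pct.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def summarize_repertoire(
    alps: Sequence[ProteinRecord],
    genome_size_bp: int,
    label: str,
) -> RepertoireSummary:
    """Counts, pooled length and genome fraction of one species' ALP set."""
    if genome_size_bp <= 0:
        raise ValueError("genome size must be positive")
    lengths = [len(p) for p in alps]
    if not lengths:
        return RepertoireSummary(
            species_label=label,
            genome_size_bp=genome_size_bp,
            n_alps=0,
            total_alp_aa=0,
            coding_fraction_pct=0.0,
            min_len=0,
            max_len=0,
            mean_len=0.0,
            rationale="no ALPs supplied",
        )
    total = sum(lengths)
    return RepertoireSummary(
        species_label=label,
        genome_size_bp=genome_size_bp,
        n_alps=len(lengths),
        total_alp_aa=total,
        coding_fraction_pct=coding_fraction_pct(total, genome_size_bp),
        min_len=min(lengths),
        max_len=max(lengths),
        mean_len=total / len(lengths),
    )


def composition_profile(
    records: Sequence[ProteinRecord],
    background: Mapping[str, float] | None = None,
) -> CompositionProfile:
    """Pooled residue frequencies; 'X' is excluded from the census.

    With a background distribution, per-residue enrichment is
    log2(freq / background) for residues whose background frequency is
    positive.
    """
    counts: Counter[str] = Counter()
    for rec in records:
        counts.update(r for r in rec.sequence if r != "X")
    total = sum(counts.values())
    if total == 0:
        raise ValueError("no countable residues in the supplied records")
    freqs = {aa: counts.get(aa, 0) / total for aa in AMINO_ACIDS}
    enrichment = None
    bg = dict(background) if background is not None else None
    if bg is not None:
        enrichment = {
            aa: float(np.log2(freqs[aa] / bg[aa]))
            for aa in AMINO_ACIDS
            if bg.get(aa, 0.0) > 0 and freqs[aa] > 0
        }
    return CompositionProfile(
        frequencies=freqs,
        asn_thr_fraction=freqs["N"] + freqs["T"],
        background=bg,
        enrichment=enrichment,
    )
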