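"""Positional-entropy logo matrices for repeat-domain alignments.

The conserved loop glycines of archaeal big domains (ABDs) stand out as
low-entropy alignment columns. Long gap stretches are removed first
(columns whose gap fraction exceeds a threshold), then each retained
column gets a residue frequency vector, its Shannon entropy
H = −Σ p·log2 p and information content log2(20) − H. No small-sample
correction is applied; 'X' is treated as missing and excluded from column
counts, as are gaps.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .seqio import AMINO_ACIDS, GAP, Alignment

MAX_INFORMATION_BITS = math.log2(20)


@dataclass(frozen=True)
class LogoMatrix:
    """Per-column residue frequencies, entropy and information (bits)."""

    frequencies: pd.DataFrame       # rows: retained columns, cols: 20 residues
    entropy_bits: np.ndarray
    information_bits: np.ndarray
    retained_columns: tuple[int, ...]   # 0-based original column indices


def drop_gappy_columns(
    aln: Alignment, max_gap_fraction: float = 0.5
) -> tuple[Alignment, tuple[int, ...]]:
    """Remove columns whose gap fraction exceeds ``max_gap_fraction``.

    Returns the pruned alignment and the 0-based indices of retained
    columns, order preserved. Dropping every column is an error.
    """
    n = aln.n_rows
    retained = [
        j for j in range(aln.n_columns)
        if aln.column(j).count(GAP) / n <= max_gap_fraction
    ]
    if not retained:
        raise ValueError("gap pruning removed every alignment column")
    rows = tuple(
        (rid, "".join(seq[j] for j in retained)) for rid, seq in aln.records
    )
    return Alignment(records=rows), tuple(retained)


def logo_matrix(aln: Alignment, retained_columns: tuple[int, ...] | None = None) -> LogoMatrix:
    """Frequency/entropy/information matrix of a (gap-pruned) alignment.

    A column consisting solely of gaps/'X' has no countable residues and
    is an error — prune with :func:`drop_gappy_columns` first.
    """
    if retained_columns is None:
        retained_columns = tuple(range(aln.n_columns))
    freqs = np.zeros((aln.n_columns, len(AMINO_ACIDS)))
    aa_index = {aa: i for i, aa in enumerate(AMINO_ACIDS)}
    for j in range(aln.n_columns):
        counts = Counter(r for r in aln.column(j) if r != GAP and r != "X")
        total = sum(counts.values())
        if total == 0:
            raise ValueError(f"column {j} has no countable residues")
        for aa, c in counts.items():
            freqs[j, aa_index[aa]] = c / total
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(freqs > 0, freqs * np.log2(freqs), 0.0)
    entropy = -plogp.sum(axis=1)
    information = MAX_INFORMATION_BITS - entropy
    return LogoMatrix(
        frequencies=pd.DataFrame(
            freqs, index=list(retained_columns), columns=list(AMINO_ACIDS)
        ),
        entropy_bits=entropy,
        information_bits=information,
        retained_columns=tuple(retained_columns),
    )


def logo_table(logo: LogoMatrix) -> pd.DataFrame:
    """Flat TSV-ready table: column index, 20 frequencies, entropy, information."""
    df = logo.frequencies.copy()
    df.insert(0, "column", logo.retained_columns)
    df["entropy_bits"] = logo.entropy_bits
    df["information_bits"] = logo.information_bits
    return df.reset_index(drop=True)
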