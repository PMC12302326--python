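"""Per-column conservation profiling of a protein family alignment.

Information content per column is IC = log₂20 − H, with H the Shannon
entropy (bits) of the amino-acid distribution; gaps are excluded from the
entropy but their frequency is reported.  The profile locates variable
positions embedded in otherwise conserved patches — the pattern expected for
positions under relaxed constraint next to catalytic residues.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from Bio import AlignIO

AMINO_ACIDS = tuple("ACDEFGHIKLMNPQRSTVWY")
MAX_IC_BITS = float(np.log2(20))


class ConservationError(ValueError):
    """Raised for malformed alignments or invalid parameters."""


@dataclass
class ConservationProfile:
    """Per-column amino-acid frequencies and information content (bits)."""

    frequencies: np.ndarray     # (n_columns, 20), gap-excluded, sums to 1
    gap_fraction: np.ndarray    # (n_columns,)
    information: np.ndarray     # (n_columns,) bits
    n_sequences: int

    @property
    def n_columns(self) -> int:
        return len(self.information)

    def window_mean(self, window: int = 9) -> np.ndarray:
        """Mean IC over a sliding window, excluding the centre column."""
        if window % 2 == 0:
            raise ConservationError("window must be odd")
        half = window // 2
        ic = self.information
        out = np.empty_like(ic)
        for i in range(len(ic)):
            lo, hi = max(0, i - half), min(len(ic), i + half + 1)
            neighbours = np.concatenate([ic[lo:i], ic[i + 1 : hi]])
            out[i] = neighbours.mean() if len(neighbours) else np.nan
        return out

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.frequencies, columns=list(AMINO_ACIDS))
        df.insert(0, "position", np.arange(1, self.n_columns + 1))
        df["gap_fraction"] = self.gap_fraction
        df["information_bits"] = self.information
        return df


def _sequences_from(msa):
    if isinstance(msa, (str,)) or hasattr(msa, "read"):
        aln = AlignIO.read(msa, "fasta")
        return [str(rec.seq).upper() for rec in aln]
    if hasattr(msa, "__fspath__"):
        aln = AlignIO.read(str(msa), "fasta")
        return [str(rec.seq).upper() for rec in aln]
    return [str(s).upper() for s in msa]


def column_profile(msa, pseudocount: float = 0.0) -> ConservationProfile:
    """Column frequencies and information content of an aligned family.

    ``msa`` is a FASTA path/handle or a sequence of equal-length strings
    (20 amino acids + ``-`` gap).
    """
    seqs = _sequences_from(msa)
    if not seqs:
        raise ConservationError("empty alignment")
    length = len(seqs[0])
    if any(len(s) != length for s in seqs):
        raise ConservationError("ragged alignment: sequences differ in length")
    aa_index = {a: i for i, a in enumerate(AMINO_ACIDS)}
    counts = np.zeros((length, 20))
    gaps = np.zeros(length)
    for s in seqs:
        for j, ch in enumerate(s):
            if ch in ("-", "."):
                gaps[j] += 1
            elif ch in aa_index:
                counts[j, aa_index[ch]] += 1
            else:
                raise ConservationError(f"unknown symbol '{ch}' at column {j + 1}")
    counts += pseudocount
    totals = counts.sum(axis=1)
    freqs = np.zeros_like(counts)
    ic = np.zeros(length)
    for j in range(length):
        if totals[j] == 0:
            ic[j] = 0.0
            continue
        p = counts[j] / totals[j]
        freqs[j] = p
        nz = p[p > 0]
        entropy = float(-(nz * np.log2(nz)).sum())
        ic[j] = MAX_IC_BITS - entropy
    return ConservationProfile(
        frequencies=freqs,
        gap_fraction=gaps / len(seqs),
        information=ic,
        n_sequences=len(seqs),
    )


def variable_in_conserved(profile: ConservationProfile, window: int = 9,
                          ic_high: float = 3.0, ic_low: float = 1.0) -> list[int]:
    """Variable positions inside conserved patches (1-based columns).

    A position qualifies when its own IC is ≤ ``ic_low`` while the mean IC of
    its window neighbourhood (centre excluded) is ≥ ``ic_high``.
    """
    if window % 2 == 0:
        raise ConservationError("window must be odd")
    if window > profile.n_columns:
        raise ConservationError("window larger than the alignment")
    wmean = profile.window_mean(window)
    hits = np.nonzero((profile.information <= ic_low) & (wmean >= ic_high))[0]
    return [int(i) + 1 for i in hits]


def logo_matrix(profile: ConservationProfile) -> pd.DataFrame:
    """Position × residue matrix of IC-scaled letter heights for logo plotters."""
    heights = profile.frequencies * profile.information[:, None]
    df = pd.DataFrame(heights, columns=list(AMINO_ACIDS))
    df.insert(0, "position", np.arange(1, profile.n_columns + 1))
    return df
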