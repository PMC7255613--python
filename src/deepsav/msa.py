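"""Alignment profiles, conservation, and the baseline fitness log-odds score.

An ortholog multiple sequence alignment is summarised column by column into an
estimated amino-acid frequency profile and a conservation score; the baseline
fitness of a substitution is the log2 odds of the wild-type frequency against
the mutant frequency at that column.

Conservation is the normalised Shannon-entropy measure ``1 - H/ln(20)`` in
[0, 1]: 1 for an invariant column, 0 for a column uniform over all 20 amino
acids.  Profile estimation uses gap-excluded relative frequencies with a
uniform pseudocount (default 0.05 per amino acid), optionally with Henikoff
position-based sequence weighting.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio import SeqIO

from .alphabet import AA_INDEX, AMINO_ACIDS, GAP, N_AA

LN20 = math.log(N_AA)

#: Conservation bin labels: low [0, 0.3), medium [0.3, 0.6], high (0.6, 1].
CONSERVATION_BINS = ("Consv1", "Consv2", "Consv3")


class DegenerateColumnError(ValueError):
    """A column holds no countable residues (all gaps / unknowns)."""


@dataclass
class Alignment:
    """An aligned set of ortholog sequences with one designated reference row.

    Parameters
    ----------
    sequences
        Equal-length aligned amino-acid strings using ``-`` for gaps.
    reference_index
        Row index of the human/reference sequence.
    """

    sequences: list[str]
    reference_index: int = 0
    names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.sequences) < 2:
            raise ValueError("alignment needs at least 2 sequences")
        lengths = {len(s) for s in self.sequences}
        if len(lengths) != 1:
            raise ValueError("aligned sequences must have equal length")
        if not 0 <= self.reference_index < len(self.sequences):
            raise ValueError("reference_index out of range")
        ref = self.sequences[self.reference_index]
        bad = {c for c in ref} - set(AMINO_ACIDS) - {GAP, "X"}
        if bad:
            raise ValueError(f"unknown symbols in reference sequence: {sorted(bad)}")

    @property
    def column_count(self) -> int:
        return len(self.sequences[0])

    @property
    def reference(self) -> str:
        return self.sequences[self.reference_index]

    def reference_ungapped(self) -> str:
        """The reference sequence with alignment gaps removed."""
        return self.reference.replace(GAP, "")

    def reference_columns(self) -> np.ndarray:
        """Alignment column index of each (1-based) ungapped reference position."""
        return np.array([i for i, c in enumerate(self.reference) if c != GAP])


def read_alignment_fasta(path: str | Path, reference_name: str | None = None) -> Alignment:
    """Read an aligned FASTA file; the reference is the named record or the first one."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"no sequences in {path}")
    names = [r.id for r in records]
    ref_idx = 0
    if reference_name is not None:
        try:
            ref_idx = names.index(reference_name)
        except ValueError:
            raise ValueError(f"reference {reference_name!r} not found in {path}") from None
    return Alignment([str(r.seq).upper() for r in records], ref_idx, names)


def _column_counts(residues: Iterable[str]) -> np.ndarray:
    counts = np.zeros(N_AA)
    for r in residues:
        idx = AA_INDEX.get(r)
        if idx is not None:  # gaps and 'X'/nonstandard excluded
            counts[idx] += 1
    return counts


def henikoff_weights(alignment: Alignment) -> np.ndarray:
    """Position-based sequence weights (Henikoff & Henikoff 1994), normalised to sum to n."""
    n = len(alignment.sequences)
    L = alignment.column_count
    w = np.zeros(n)
    for j in range(L):
        col = [s[j] for s in alignment.sequences]
        counts: dict[str, int] = {}
        for c in col:
            if c in AA_INDEX:
                counts[c] = counts.get(c, 0) + 1
        r = len(counts)
        if r == 0:
            continue
        for i, c in enumerate(col):
            if c in counts:
                w[i] += 1.0 / (r * counts[c])
    if w.sum() == 0:
        return np.ones(n)
    return w * n / w.sum()


def estimate_profile(
    alignment: Alignment,
    pseudocount: float = 0.05,
    sequence_weighting: bool = False,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-position profile and conservation on the ungapped reference coordinate.

    Returns
    -------
    freqs : (L, 20) array
        Estimated amino-acid frequencies per reference position; rows sum to 1.
    conservation : (L,) array
        Normalised-entropy conservation of each column, in [0, 1].

    Gaps and unknown residues are excluded from the counts.  With
    ``pseudocount == 0`` a column with no countable residue raises
    :class:`DegenerateColumnError`.
    """
    if pseudocount < 0:
        raise ValueError("pseudocount must be non-negative")
    weights = henikoff_weights(alignment) if sequence_weighting else None
    cols = alignment.reference_columns()
    L = len(cols)
    freqs = np.zeros((L, N_AA))
    cons = np.zeros(L)
    for out_i, j in enumerate(cols):
        column = [s[j] for s in alignment.sequences]
        if weights is None:
            counts = _column_counts(column)
        else:
            counts = np.zeros(N_AA)
            for wi, r in zip(weights, column):
                idx = AA_INDEX.get(r)
                if idx is not None:
                    counts[idx] += wi
        total = counts.sum()
        if total == 0 and pseudocount == 0:
            raise DegenerateColumnError(f"column {j} has no countable residues")
        freqs[out_i] = (counts + pseudocount) / (total + N_AA * pseudocount)
        cons[out_i] = conservation_score([c for c in column if c in AA_INDEX])
    return freqs, cons


def conservation_score(residues: Sequence[str]) -> float:
    """Normalised-entropy conservation ``1 - H/ln(20)`` of a column's residues.

    1.0 for an invariant column, 0.0 for a column uniform over the 20 amino
    acids.  Gaps/unknowns must already be removed; an empty multiset raises
    :class:`DegenerateColumnError`.
    """
    counts = _column_counts(residues)
    total = counts.sum()
    if total == 0:
        raise DegenerateColumnError("all-gap column")
    p = counts[counts > 0] / total
    h = float(-(p * np.log(p)).sum())
    return min(1.0, max(0.0, 1.0 - h / LN20))


def bin_conservation(score: float) -> str:
    """Bin a conservation score: [0,0.3) Consv1, [0.3,0.6] Consv2, (0.6,1] Consv3."""
    if not 0.0 <= score <= 1.0:
        raise ValueError(f"conservation score {score} outside [0, 1]")
    if score < 0.3:
        return "Consv1"
    if score <= 0.6:
        return "Consv2"
    return "Consv3"


def baseline_fitness(
    freqs: np.ndarray, wt: str, mut: str, epsilon: float = 1e-4
) -> float:
    """Log2 odds of the wild-type over the mutant amino-acid frequency.

    ``log2((f_wt + eps) / (f_mut + eps))``; larger values indicate a more
    severe substitution.  Antisymmetric under swapping ``wt`` and ``mut``.
    """
    if wt == mut:
        raise ValueError("wild-type and mutant amino acids must differ")
    if wt not in AA_INDEX or mut not in AA_INDEX:
        raise ValueError(f"nonstandard amino acid in substitution {wt}->{mut}")
    f_wt = float(freqs[AA_INDEX[wt]])
    f_mut = float(freqs[AA_INDEX[mut]])
    return math.log2((f_wt + epsilon) / (f_mut + epsilon))


def profile_table(gene: str, freqs: np.ndarray, conservation: np.ndarray):
    """Per-position profile/conservation as a tidy DataFrame (1-based positions)."""
    import pandas as pd

    df = pd.DataFrame(freqs, columns=[f"f_{aa}" for aa in AMINO_ACIDS])
    df.insert(0, "gene", gene)
    df.insert(1, "position", np.arange(1, len(freqs) + 1))
    df["conservation"] = conservation
    return df


def write_profile_tsv(path: str | Path, gene: str, freqs: np.ndarray, conservation: np.ndarray) -> None:
    profile_table(gene, freqs, conservation).to_csv(path, sep="\t", index=False)
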