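"""Gene-level mutation-severity scoring: MAF categories and the GTS score.

GTS (Gene Tolerance of rare SAVs) summarises a gene's burden of predicted
deleterious rare variation::

    GTS = sum_k DeepSAV_score(k) * MAF(k) / protein_len

summed over the gene's rare SAVs (minor allele frequency below 1e-4).  Low
GTS marks mutation-intolerant genes.  Scores are ranked across genes with the
inclusive percentrank convention and discretised into deciles.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

RARE_MAF_CUTOFF = 1e-4
DELETERIOUS_SCORE_CUTOFF = 0.75

#: MAF category boundaries, left-closed: rare < 1e-4 <= low < 1e-3 <= medium < 1e-2 <= common
MAF_CATEGORIES = ("rare", "low", "medium", "common")
_MAF_EDGES = (1e-4, 1e-3, 1e-2)


@dataclass
class GeneVariantSet:
    """One gene's scored variants: (DeepSAV score, MAF) pairs plus protein length."""

    gene: str
    protein_len: int
    scores: np.ndarray
    mafs: np.ndarray

    def __post_init__(self) -> None:
        if self.protein_len < 1:
            raise ValueError("protein_len must be >= 1")
        self.scores = np.asarray(self.scores, dtype=float)
        self.mafs = np.asarray(self.mafs, dtype=float)
        if self.scores.shape != self.mafs.shape:
            raise ValueError("scores and mafs must have equal length")
        if len(self.mafs) and (self.mafs <= 0).any():
            raise ValueError("every MAF must be > 0")


def maf_category(maf: float) -> str:
    """Assign a MAF to rare / low / medium / common (boundaries left-closed)."""
    if not 0.0 < maf <= 1.0:
        raise ValueError(f"MAF {maf} outside (0, 1]")
    if maf < _MAF_EDGES[0]:
        return "rare"
    if maf < _MAF_EDGES[1]:
        return "low"
    if maf < _MAF_EDGES[2]:
        return "medium"
    return "common"


def summarize_maf_spectrum(mafs) -> pd.DataFrame:
    """Counts and percentage shares per MAF category over a variant catalog."""
    mafs = np.asarray(mafs, dtype=float)
    if len(mafs) == 0:
        raise ValueError("empty catalog")
    cats = [maf_category(m) for m in mafs]
    counts = {c: 0 for c in MAF_CATEGORIES}
    for c in cats:
        counts[c] += 1
    return spectrum_shares(counts)


def spectrum_shares(counts: dict[str, int]) -> pd.DataFrame:
    """Percentage share per MAF category from raw counts."""
    total = sum(counts.values())
    if total == 0:
        raise ValueError("empty catalog")
    rows = [
        {"category": c, "count": counts.get(c, 0), "percent": 100.0 * counts.get(c, 0) / total}
        for c in MAF_CATEGORIES
    ]
    return pd.DataFrame(rows)


def gts_score(gvs: GeneVariantSet, rare_maf_cutoff: float = RARE_MAF_CUTOFF) -> float:
    """Length-normalised MAF-weighted sum of DeepSAV scores over rare SAVs.

    Variants with MAF at or above the cutoff are ignored.
    """
    rare = gvs.mafs < rare_maf_cutoff
    return float((gvs.scores[rare] * gvs.mafs[rare]).sum() / gvs.protein_len)


def count_deleterious(
    gvs: GeneVariantSet,
    score_threshold: float = DELETERIOUS_SCORE_CUTOFF,
    rare_only: bool = True,
    rare_maf_cutoff: float = RARE_MAF_CUTOFF,
) -> int:
    """Number of SAVs with DeepSAV score strictly above the threshold (rare only by default)."""
    keep = gvs.scores > score_threshold
    if rare_only:
        keep &= gvs.mafs < rare_maf_cutoff
    return int(keep.sum())


def percentile_and_decile(gts: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Inclusive percentrank and decile of each gene's GTS score.

    percentile(x) = (# values strictly below x) / (n - 1); ties share the
    percentile of their first occurrence.  Decile = floor(percentile * 10),
    capped at 9 so the maximum lands in decile 9.
    """
    gts = np.asarray(gts, dtype=float)
    n = len(gts)
    if n < 2:
        raise ValueError("need at least 2 genes for percentiles")
    order = np.argsort(gts, kind="stable")
    sorted_vals = gts[order]
    # rank of first occurrence of each distinct value = count strictly below
    below = np.searchsorted(sorted_vals, gts, side="left")
    percentile = below / (n - 1)
    # integer arithmetic avoids float truncation at exact decile boundaries
    decile = np.minimum((below * 10) // (n - 1), 9).astype(int)
    return percentile, decile


def dedupe_savs(df: pd.DataFrame) -> pd.DataFrame:
    """Drop duplicate (gene, position, mut) records keeping the maximum MAF."""
    before = len(df)
    df = (
        df.sort_values("maf", ascending=False)
        .drop_duplicates(subset=["gene", "position", "mut"], keep="first")
        .sort_index()
    )
    dropped = before - len(df)
    if dropped:
        logger.info("deduplicated %d SAV records (kept maximum MAF)", dropped)
    return df


def gene_tolerance_table(
    scored: pd.DataFrame,
    gene_lengths: dict[str, int] | pd.Series,
    rare_maf_cutoff: float = RARE_MAF_CUTOFF,
    score_threshold: float = DELETERIOUS_SCORE_CUTOFF,
) -> pd.DataFrame:
    """Per-gene GTS table from a scored variant catalog.

    Parameters
    ----------
    scored
        DataFrame with columns ``gene, position, wt, mut, maf, deepsav_score``.
    gene_lengths
        Protein length (amino acids) per gene id; genes absent from the
        catalog get GTS 0.

    Returns a DataFrame (gene, gts, percentile, decile, n_rare_savs,
    n_deleterious) sorted ascending by GTS.
    """
    if isinstance(gene_lengths, pd.Series):
        gene_lengths = gene_lengths.to_dict()
    scored = dedupe_savs(scored)
    rows = []
    grouped = dict(list(scored.groupby("gene")))
    for gene, length in gene_lengths.items():
        sub = grouped.get(gene)
        if sub is None:
            gvs = GeneVariantSet(gene, int(length), np.array([]), np.array([]))
        else:
            gvs = GeneVariantSet(
                gene, int(length), sub["deepsav_score"].to_numpy(), sub["maf"].to_numpy()
            )
        rows.append(
            {
                "gene": gene,
                "gts": gts_score(gvs, rare_maf_cutoff),
                "n_rare_savs": int((gvs.mafs < rare_maf_cutoff).sum()),
                "n_deleterious": count_deleterious(
                    gvs, score_threshold, rare_only=True, rare_maf_cutoff=rare_maf_cutoff
                ),
            }
        )
    table = pd.DataFrame(rows)
    percentile, decile = percentile_and_decile(table["gts"].to_numpy())
    table["percentile"] = percentile
    table["decile"] = decile
    table = table[["gene", "gts", "percentile", "decile", "n_rare_savs", "n_deleterious"]]
    return table.sort_values("gts", kind="stable").reset_index(drop=True)
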