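"""Annotation enrichment log-odds and disease-class ratio analyses.

The enrichment statistic for a positional property is::

    log2( P(property | subset positions) / P(property | all positions) )

with positive values marking enrichment in the subset (e.g. positions carrying
pathogenic SAVs, or gnomAD SAVs in one MAF range) and negative values marking
depletion.  Counting is over unique amino-acid positions, not variant events.

Disease-class analysis compares the observed frequency of each MeSH disease
class among a gene set's curated gene-disease associations to its expected
frequency over the whole association table.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .features import ANNOTATION_COLUMNS
from .msa import bin_conservation

logger = logging.getLogger(__name__)

_DISORDER = ("disopred", "spotd", "iupred2a")
_SS_COLS = ANNOTATION_COLUMNS[:9]
_FLAG_COLS = ANNOTATION_COLUMNS[14:]  # SIGNAL .. MOTIF


@dataclass
class PropertyCounts:
    """One property x subset cell: raw counts behind a log-odds value."""

    property: str
    count_in_subset: int
    subset_size: int
    count_in_background: int
    background_size: int

    def __post_init__(self) -> None:
        if self.subset_size <= 0 or self.background_size <= 0:
            raise ValueError("sizes must be positive")
        if self.count_in_subset > self.subset_size:
            raise ValueError("subset count exceeds subset size")
        if self.count_in_background > self.background_size:
            raise ValueError("background count exceeds background size")


def property_log_odds(pc: PropertyCounts, pseudocount: float = 0.0) -> float:
    """log2 of subset over background property probability.

    With ``pseudocount == 0`` a zero subset count yields ``-inf`` (sentinel,
    excluded from plots); a zero background probability is an input error.
    An optional pseudo-count (e.g. 0.5) is added to both counts, with twice
    the pseudo-count added to both sizes, keeping the swap-antisymmetry exact.
    """
    p_bg = (pc.count_in_background + pseudocount) / (pc.background_size + 2 * pseudocount)
    if p_bg == 0:
        raise ValueError(f"property {pc.property!r} absent from the background")
    p_sub = (pc.count_in_subset + pseudocount) / (pc.subset_size + 2 * pseudocount)
    if p_sub == 0:
        return -math.inf
    return math.log2(p_sub / p_bg)


def binarize_properties(position_table: pd.DataFrame) -> pd.DataFrame:
    """Boolean per-position property table used for enrichment counting.

    Expects a table with a ``conservation`` column and the 28 annotation
    columns.  Properties: the three conservation bins; the nine secondary-
    structure states (probabilities binarised at 0.5); ordered/disordered
    calls per disorder predictor (disordered when propensity > 0.5); the seg
    and ncoils flags; and the 14 UniProt-style flags.
    """
    props = {}
    cons = position_table["conservation"].to_numpy(dtype=float)
    bins = np.array([bin_conservation(c) for c in cons])
    for label in ("Consv1", "Consv2", "Consv3"):
        props[label] = bins == label
    for col in _SS_COLS:
        props[col] = position_table[col].to_numpy(dtype=float) >= 0.5
    for col in _DISORDER:
        prop = position_table[col].to_numpy(dtype=float)
        props[f"O_{col}"] = prop <= 0.5
        props[f"D_{col}"] = prop > 0.5
    for col in ("seg", "ncoils"):
        props[col] = position_table[col].to_numpy(dtype=float) > 0.5
    for col in _FLAG_COLS:
        props[col] = position_table[col].to_numpy(dtype=float) > 0.5
    return pd.DataFrame(props, index=position_table.index)


def positions_of_variants(variants: pd.DataFrame, position_table: pd.DataFrame) -> np.ndarray:
    """Row indices in the position table of the unique (gene, position) pairs of a variant set."""
    key = pd.MultiIndex.from_frame(position_table[["gene", "position"]])
    lookup = pd.Series(np.arange(len(position_table)), index=key)
    pairs = pd.MultiIndex.from_frame(variants[["gene", "position"]].drop_duplicates())
    found = lookup.reindex(pairs)
    if found.isna().any():
        missing = int(found.isna().sum())
        logger.warning("%d variant positions absent from the position table; skipped", missing)
        found = found.dropna()
    return found.to_numpy(dtype=int)


def enrichment_matrix(
    position_table: pd.DataFrame,
    subsets: dict[str, np.ndarray],
    properties: list[str] | None = None,
    pseudocount: float = 0.0,
) -> tuple[pd.DataFrame, dict[tuple[str, str], PropertyCounts]]:
    """Log2 enrichment of each property in each position subset vs. all positions.

    ``subsets`` maps subset name to row indices (or boolean masks) into the
    position table.  Returns the (property x subset) log-odds matrix and the
    per-cell :class:`PropertyCounts` for audit.  Empty subsets are skipped
    with a warning.
    """
    props = binarize_properties(position_table)
    if properties is not None:
        props = props[properties]
    bg_counts = props.sum(axis=0)
    absent = list(bg_counts.index[bg_counts == 0])
    if absent:
        logger.warning("properties absent from the background dropped: %s", absent)
        props = props.drop(columns=absent)
        bg_counts = bg_counts.drop(absent)
    n_bg = len(props)
    columns: dict[str, list[float]] = {}
    cells: dict[tuple[str, str], PropertyCounts] = {}
    for name, idx in subsets.items():
        idx = np.asarray(idx)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        if len(idx) == 0:
            logger.warning("subset %r is empty; skipped", name)
            continue
        sub = props.iloc[idx]
        col = []
        for prop in props.columns:
            pc = PropertyCounts(
                property=prop,
                count_in_subset=int(sub[prop].sum()),
                subset_size=len(sub),
                count_in_background=int(bg_counts[prop]),
                background_size=n_bg,
            )
            cells[(prop, name)] = pc
            col.append(property_log_odds(pc, pseudocount))
        columns[name] = col
    return pd.DataFrame(columns, index=list(props.columns)), cells


def disease_class_ratios(
    gene_set,
    gda: pd.DataFrame,
    min_expected_count: int = 5,
) -> pd.DataFrame:
    """Observed/expected MeSH disease-class frequency ratios for a gene set.

    ``gda`` has columns ``gene, disease, mesh_class``; frequencies are over
    unique (gene, class) assignments.  Classes whose expected assignment count
    falls below ``min_expected_count`` are excluded (sparse classes).
    """
    gene_set = set(gene_set)
    if not gene_set:
        raise ValueError("empty gene set")
    assignments = gda[["gene", "mesh_class"]].drop_duplicates()
    expected_counts = assignments["mesh_class"].value_counts()
    keep = expected_counts[expected_counts >= min_expected_count].index
    assignments = assignments[assignments["mesh_class"].isin(keep)]
    expected_counts = assignments["mesh_class"].value_counts()
    expected_freq = expected_counts / expected_counts.sum()

    obs = assignments[assignments["gene"].isin(gene_set)]
    obs_counts = obs["mesh_class"].value_counts().reindex(expected_freq.index, fill_value=0)
    total_obs = obs_counts.sum()
    obs_freq = obs_counts / total_obs if total_obs else obs_counts.astype(float)
    out = pd.DataFrame(
        {
            "mesh_class": expected_freq.index,
            "observed_count": obs_counts.to_numpy(),
            "observed_freq": obs_freq.to_numpy(),
            "expected_freq": expected_freq.to_numpy(),
        }
    )
    out["ratio"] = out["observed_freq"] / out["expected_freq"]
    return out.sort_values("mesh_class").reset_index(drop=True)


def decile_distribution(gene_set, tolerance: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    """Counts and frequencies of a gene set across the 10 GTS deciles.

    ``tolerance`` is the per-gene table with ``gene`` and ``decile`` columns.
    Frequencies sum to 1 over the genes of the set that carry a decile.
    """
    gene_set = set(gene_set)
    sub = tolerance[tolerance["gene"].isin(gene_set)]
    counts = np.bincount(sub["decile"].to_numpy(dtype=int), minlength=10)[:10]
    total = counts.sum()
    freqs = counts / total if total else counts.astype(float)
    return counts, freqs
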