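"""Readers and writers for the package's tabular and alignment inputs.

All tables are header-ed TSV with 1-based protein positions; alignments are
aligned FASTA with ``-`` gaps.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .features import ANNOTATION_COLUMNS, GeneData
from .msa import estimate_profile, read_alignment_fasta

logger = logging.getLogger(__name__)

VARIANT_COLUMNS = ("gene", "position", "wt", "mut")


def _require(df: pd.DataFrame, columns, path) -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")


def read_variants_tsv(path: str | Path) -> pd.DataFrame:
    """Variant table: gene, position, wt, mut [, maf, label, deepsav_score]."""
    df = pd.read_csv(path, sep="\t")
    _require(df, VARIANT_COLUMNS, path)
    df["position"] = df["position"].astype(int)
    if "label" in df.columns:
        bad = set(df["label"].dropna().unique()) - {"pathogenic", "benign"}
        if bad:
            raise ValueError(f"{path}: unknown labels {sorted(bad)}")
    return df


def read_annotations_tsv(path: str | Path) -> pd.DataFrame:
    """Per-position annotation table: gene, position, then the 28 annotation columns."""
    df = pd.read_csv(path, sep="\t")
    _require(df, ("gene", "position", *ANNOTATION_COLUMNS), path)
    df["position"] = df["position"].astype(int)
    return df


def read_gene_lengths_tsv(path: str | Path) -> dict[str, int]:
    df = pd.read_csv(path, sep="\t")
    _require(df, ("gene", "length"), path)
    return dict(zip(df["gene"], df["length"].astype(int)))


def read_gene_features_tsv(path: str | Path) -> pd.DataFrame:
    """Gene-level 17-feature table (dbNSFP-style), indexed by gene."""
    df = pd.read_csv(path, sep="\t")
    _require(df, ("gene",), path)
    if df.shape[1] != 18:
        raise ValueError(f"{path}: expected gene + 17 feature columns, got {df.shape[1] - 1}")
    return df.set_index("gene")


def read_gda_tsv(path: str | Path) -> pd.DataFrame:
    """Gene-disease association table: gene, disease, mesh_class."""
    df = pd.read_csv(path, sep="\t")
    _require(df, ("gene", "disease", "mesh_class"), path)
    return df


def load_gene_data(
    alignment_dir: str | Path,
    annotations: pd.DataFrame | None = None,
    pseudocount: float = 0.05,
) -> dict[str, GeneData]:
    """Build per-gene encoding inputs from an alignment directory (+ annotation table).

    Each ``<gene>.fasta`` holds the gene's ortholog alignment with the
    reference sequence first (or named ``reference``).  Genes without rows in
    the annotation table get zero annotations with a logged warning.
    """
    alignment_dir = Path(alignment_dir)
    ann_by_gene = {}
    if annotations is not None:
        ann_by_gene = {g: sub for g, sub in annotations.groupby("gene")}
    genes: dict[str, GeneData] = {}
    for fasta in sorted(alignment_dir.glob("*.fasta")):
        gene = fasta.stem
        aln = read_alignment_fasta(fasta)
        freqs, cons = estimate_profile(aln, pseudocount=pseudocount)
        seq = aln.reference_ungapped()
        ann = None
        sub = ann_by_gene.get(gene)
        if sub is not None:
            sub = sub.sort_values("position")
            if len(sub) != len(seq) or (sub["position"].to_numpy() != np.arange(1, len(seq) + 1)).any():
                raise ValueError(f"annotations for {gene} do not cover positions 1..{len(seq)}")
            ann = sub
        genes[gene] = GeneData(gene, seq, freqs, cons, ann)
    if not genes:
        raise ValueError(f"no .fasta alignments found in {alignment_dir}")
    return genes
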