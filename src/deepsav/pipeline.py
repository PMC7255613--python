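"""End-to-end orchestration: encode -> train/load -> predict -> GTS -> enrichment.

:func:`run_pipeline` drives the whole analysis from a :class:`RunConfig` and
writes header-ed TSV outputs plus a JSON run manifest (config hash, seed,
package version) into the output directory.  A non-empty output directory is
refused unless ``overwrite`` is set, so partial results are never silently
clobbered.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, io
from .enrichment import enrichment_matrix, positions_of_variants
from .features import ANNOTATION_COLUMNS, FeatureMask, WindowEncoder
from .gts import gene_tolerance_table, maf_category
from .model import DeepSAVClassifier, NetworkConfig

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Paths, thresholds, and model settings of one pipeline run."""

    alignment_dir: str
    annotations_tsv: str | None
    train_variants_tsv: str | None
    catalog_tsv: str
    gene_lengths_tsv: str
    output_dir: str
    model_checkpoint: str | None = None
    network: NetworkConfig = field(default_factory=NetworkConfig)
    mask: FeatureMask = field(default_factory=FeatureMask)
    rare_maf_cutoff: float = 1e-4
    deleterious_cutoff: float = 0.75
    seed: int = 0
    overwrite: bool = False

    def config_hash(self) -> str:
        def default(o):
            return asdict(o)

        blob = json.dumps(asdict(self), sort_keys=True, default=default)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def run_pipeline(config: RunConfig) -> Path:
    """Run the full analysis; returns the output directory."""
    out = Path(config.output_dir)
    if out.exists() and any(out.iterdir()) and not config.overwrite:
        raise FileExistsError(f"output directory {out} is not empty (pass overwrite)")
    out.mkdir(parents=True, exist_ok=True)

    annotations = None
    if config.annotations_tsv and Path(config.annotations_tsv).exists():
        annotations = io.read_annotations_tsv(config.annotations_tsv)
    else:
        logger.warning("annotation table missing; all annotations imputed as 0")
    genes = io.load_gene_data(config.alignment_dir, annotations)
    encoder = WindowEncoder(genes, mask=config.mask)

    if config.model_checkpoint:
        model = DeepSAVClassifier.load(config.model_checkpoint)
    else:
        if not config.train_variants_tsv:
            raise ValueError("need either model_checkpoint or train_variants_tsv")
        train_df = io.read_variants_tsv(config.train_variants_tsv)
        if "label" not in train_df.columns:
            raise ValueError(f"{config.train_variants_tsv}: missing 'label' column")
        X = encoder.transform(train_df)
        y = (train_df["label"] == "pathogenic").astype(int).to_numpy()
        model = config.network.to_estimator()
        model.random_state = config.seed
        model.fit(X, y)
        model.save(out / "model.deepsav")

    catalog = io.read_variants_tsv(config.catalog_tsv)
    if "maf" not in catalog.columns:
        raise ValueError(f"{config.catalog_tsv}: missing 'maf' column")
    scores = model.decision_function(encoder.transform(catalog))
    scored = catalog.copy()
    scored["deepsav_score"] = scores
    scored.to_csv(out / "predictions.tsv", sep="\t", index=False)

    lengths = io.read_gene_lengths_tsv(config.gene_lengths_tsv)
    tolerance = gene_tolerance_table(
        scored,
        lengths,
        rare_maf_cutoff=config.rare_maf_cutoff,
        score_threshold=config.deleterious_cutoff,
    )
    tolerance.to_csv(out / "gene_tolerance.tsv", sep="\t", index=False)

    # enrichment of properties in catalog positions split by MAF category
    pos_table = _position_table(genes)
    subsets = {}
    cats = scored["maf"].map(maf_category)
    for cat in ("rare", "low", "medium", "common"):
        sub = scored[cats == cat]
        if len(sub):
            subsets[cat] = positions_of_variants(sub, pos_table)
    matrix, _ = enrichment_matrix(pos_table, subsets)
    matrix.rename_axis("property").reset_index().to_csv(
        out / "enrichment.tsv", sep="\t", index=False
    )

    manifest = {
        "package_version": __version__,
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "n_genes": len(genes),
        "n_catalog_variants": int(len(catalog)),
        "outputs": ["predictions.tsv", "gene_tolerance.tsv", "enrichment.tsv"],
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return out


def _position_table(genes) -> pd.DataFrame:
    frames = []
    for gene, gd in genes.items():
        df = pd.DataFrame(gd.annotations, columns=list(ANNOTATION_COLUMNS))
        df.insert(0, "gene", gene)
        df.insert(1, "position", np.arange(1, len(gd) + 1))
        df.insert(2, "conservation", gd.conservation)
        frames.append(df)
    return pd.concat(frames, ignore_index=True)
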