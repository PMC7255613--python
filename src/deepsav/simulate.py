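"""Synthetic inputs with the statistical structure the method assumes.

Every generator is a pure function of (config, seed) and produces artifacts in
the package's own formats, so the full pipeline is testable without any
download: ortholog-like alignments with a conservation gradient (invariant,
partially conserved, and flat columns), per-position structural/functional
annotation tables, labelled variant sets with pathogenicity signal planted at
conserved and functionally annotated positions, and gnomAD-like variant
catalogs whose MAF spectrum is dominated by rare alleles (~94% below 1e-4,
~0.6% common).

The planting template follows the direction of the real enrichment findings:
pathogenic variants favour conserved columns (multiplier ``exp(beta * c)`` on
conservation c), active sites, disulfides, metal/ligand binding sites and
transmembrane segments, and avoid disordered/low-complexity regions; benign
variants favour variable columns.  Mutant amino acids are mildly biased
(pathogenic toward P/W/C, benign toward A/S/T) so that amino-acid identity
alone carries weak signal while conservation and profile carry strong signal.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .alphabet import AMINO_ACIDS, AA_INDEX, N_AA
from .features import ANNOTATION_COLUMNS, GeneData
from .msa import Alignment, estimate_profile

#: default per-position Bernoulli rates of the binary annotation flags.
#: Rates are kept at 0.05-0.08 so enrichment cells at the default catalog
#: sizes have small binomial error (log2-scale SE below ~0.07 at n=10,000).
DEFAULT_FLAG_RATES: dict[str, float] = {
    "seg": 0.08,
    "ncoils": 0.05,
    "SIGNAL": 0.05,
    "TRANSIT": 0.05,
    "TRANSMEM": 0.08,
    "P_MODRES": 0.06,
    "A_MODRES": 0.05,
    "M_MODRES": 0.05,
    "DISULFID": 0.05,
    "CARBOHYD": 0.05,
    "METAL": 0.05,
    "BINDING": 0.06,
    "ACT_SITE": 0.05,
    "SITE": 0.05,
    "LIPID": 0.05,
    "MOTIF": 0.06,
}

#: default planting odds of pathogenic variants at annotated positions
DEFAULT_PATHOGENIC_ODDS: dict[str, float] = {
    "ACT_SITE": 4.0,
    "DISULFID": 4.0,
    "METAL": 3.0,
    "BINDING": 3.0,
    "SITE": 2.0,
    "MOTIF": 2.0,
    "TRANSMEM": 2.0,
    "P_MODRES": 2.0,
    "A_MODRES": 1.5,
    "M_MODRES": 1.5,
    "TRANSIT": 1.5,
    "SIGNAL": 0.5,
    "seg": 0.5,
    "ncoils": 0.5,
    "disorder": 0.5,  # applies where mean disorder propensity > 0.5
}

#: MAF category weights (rare, low, medium, common); rare-dominated spectrum.
DEFAULT_SPECTRUM = (0.9393, 0.0440, 0.0110, 0.0057)

#: log-uniform MAF ranges per category
_MAF_RANGES = {
    "rare": (1e-6, 1e-4),
    "low": (1e-4, 1e-3),
    "medium": (1e-3, 1e-2),
    "common": (1e-2, 0.5),
}
_CATEGORIES = ("rare", "low", "medium", "common")

GENE_FEATURE_COLUMNS = (
    "PPI_IntAct", "PPI_BioGrid", "PPI_ConsensusPathDB",
    "essential_crispr1", "essential_crispr2", "essential_gt", "essential_trap",
    "P_HI", "HIPred_score", "GHIS", "Gene_indispensability_score",
    "P_rec", "GDI_Phred", "LoFtool_score",
    "gnomAD_pLI", "gnomAD_pRec", "gnomAD_pNull",
)


@dataclass
class SimulationConfig:
    """Study conditions of the synthetic benchmark."""

    n_genes: int = 60
    protein_len_range: tuple[int, int] = (150, 450)
    n_seqs: int = 50
    conserved_fraction: float = 0.3
    intermediate_fraction: float = 0.3
    intermediate_dominance: float = 0.6
    disorder_rate: float = 0.25
    flag_rates: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_FLAG_RATES))
    pathogenic_odds: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_PATHOGENIC_ODDS)
    )
    conservation_beta: float = 2.5
    profile_coupling_floor: float = 0.01
    pathogenic_mut_bias: dict[str, float] = field(
        default_factory=lambda: {"P": 3.0, "W": 3.0, "C": 3.0}
    )
    benign_mut_bias: dict[str, float] = field(
        default_factory=lambda: {"A": 3.0, "S": 3.0, "T": 3.0}
    )
    spectrum_weights: tuple[float, float, float, float] = DEFAULT_SPECTRUM
    pathogenic_spectrum: tuple[float, float, float, float] = (0.99, 0.006, 0.003, 0.001)
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.conserved_fraction <= 1:
            raise ValueError("conserved_fraction must be in [0, 1]")
        if self.conserved_fraction + self.intermediate_fraction > 1 + 1e-12:
            raise ValueError("conserved + intermediate fractions exceed 1")
        for name, w in (("spectrum_weights", self.spectrum_weights),
                        ("pathogenic_spectrum", self.pathogenic_spectrum)):
            if abs(sum(w) - 1.0) > 1e-6:
                raise ValueError(f"{name} must sum to 1")
        for k, v in self.pathogenic_odds.items():
            if v <= 0:
                raise ValueError(f"planting odds must be positive ({k})")


# ---------------------------------------------------------------------------
# alignments


def simulate_alignment(
    length: int,
    n_seqs: int,
    conserved_fraction: float,
    seed: int | np.random.Generator,
    intermediate_fraction: float = 0.0,
    intermediate_dominance: float = 0.6,
) -> Alignment:
    """An alignment with a planted conservation gradient (reference = row 0).

    A ``conserved_fraction`` of columns is invariant; an
    ``intermediate_fraction`` has one dominant residue (probability
    ``intermediate_dominance``, the rest uniform); remaining columns draw each
    residue independently from the flat 20-letter distribution.
    """
    if length < 1 or n_seqs < 2:
        raise ValueError("need length >= 1 and n_seqs >= 2")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    # column kinds come in blocks (domains): keep the previous kind with
    # probability 0.85, otherwise redraw from the marginal mixture, so the
    # marginal fractions are exact while conservation is autocorrelated
    p_kind = np.array(
        [
            conserved_fraction,
            intermediate_fraction,
            1.0 - conserved_fraction - intermediate_fraction,
        ]
    )
    kinds = np.empty(length, dtype=int)
    kinds[0] = rng.choice(3, p=p_kind)
    for j in range(1, length):
        kinds[j] = kinds[j - 1] if rng.random() < 0.85 else rng.choice(3, p=p_kind)
    cols = np.empty((length, n_seqs), dtype="U1")
    aas = np.array(list(AMINO_ACIDS))
    for j in range(length):
        if kinds[j] == 0:
            cols[j, :] = rng.choice(aas)
        elif kinds[j] == 1:
            dom = rng.choice(aas)
            draw = rng.random(n_seqs) < intermediate_dominance
            cols[j, :] = np.where(draw, dom, rng.choice(aas, size=n_seqs))
        else:
            cols[j, :] = rng.choice(aas, size=n_seqs)
    seqs = ["".join(cols[:, i]) for i in range(n_seqs)]
    names = [f"seq{i}" for i in range(n_seqs)]
    names[0] = "reference"
    return Alignment(seqs, reference_index=0, names=names)


# ---------------------------------------------------------------------------
# annotations

_SS_PROBS = (0.35, 0.20, 0.45)  # helix, strand, coil
_SS_RUN = (8.0, 5.0, 6.0)  # mean run length per state
_SS_PREDICTORS = ("psipred", "spd3", "psspred")
_DISORDER_PREDICTORS = ("disopred", "spotd", "iupred2a")
_SS_ACCURACY = 0.9

#: segment-like flags and their mean run lengths; the rest are point features
_SEGMENT_FLAGS = {
    "TRANSMEM": 8.0,
    "SIGNAL": 15.0,
    "TRANSIT": 15.0,
    "seg": 7.0,
    "ncoils": 8.0,
    "MOTIF": 5.0,
}
_DISORDER_RUN = 15.0


def _markov_runs(rng: np.random.Generator, length: int, rate: float, mean_run: float) -> np.ndarray:
    """Stationary two-state Markov chain: marginal on-rate ``rate``, mean on-run ``mean_run``."""
    if rate <= 0:
        return np.zeros(length, dtype=bool)
    b = 1.0 / mean_run  # on -> off
    a = rate * b / (1.0 - rate)  # off -> on
    out = np.empty(length, dtype=bool)
    state = rng.random() < rate
    for i in range(length):
        out[i] = state
        state = rng.random() >= b if state else rng.random() < a
    return out


def _markov_ss(rng: np.random.Generator, length: int) -> np.ndarray:
    """True secondary-structure track with state-typical run lengths."""
    p = np.asarray(_SS_PROBS)
    ss = np.empty(length, dtype=int)
    ss[0] = rng.choice(3, p=p)
    for i in range(1, length):
        prev = ss[i - 1]
        if rng.random() < 1.0 - 1.0 / _SS_RUN[prev]:
            ss[i] = prev
        else:
            others = [s for s in range(3) if s != prev]
            w = p[others] / p[others].sum()
            ss[i] = rng.choice(others, p=w)
    return ss


def simulate_annotations(length: int, config: SimulationConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Per-position annotation table: 9 SS one-hots, 3 disorder propensities, 16 flags.

    Secondary structure, disorder, and region-like flags (transmembrane,
    signal/transit, low-complexity, coiled-coil, motifs) occur in runs with
    realistic mean lengths; site-like flags (active sites, disulfides, metal/
    ligand binding, modified residues) are independent points.  Marginal rates
    follow ``config.flag_rates``.
    """
    true_ss = _markov_ss(rng, length)
    data: dict[str, np.ndarray] = {}
    for pred in _SS_PREDICTORS:
        correct = rng.random(length) < _SS_ACCURACY
        emitted = np.where(correct, true_ss, rng.choice(3, size=length))
        for s, state in enumerate("HEC"):
            data[f"{state}_{pred}"] = (emitted == s).astype(float)
    disordered = _markov_runs(rng, length, config.disorder_rate, _DISORDER_RUN)
    base = np.where(disordered, rng.uniform(0.6, 1.0, length), rng.uniform(0.0, 0.4, length))
    for pred in _DISORDER_PREDICTORS:
        data[pred] = np.clip(base + rng.normal(0.0, 0.08, length), 0.0, 1.0)
    for flag, rate in config.flag_rates.items():
        run = _SEGMENT_FLAGS.get(flag)
        if run is None:
            data[flag] = (rng.random(length) < rate).astype(float)
        else:
            data[flag] = _markov_runs(rng, length, rate, run).astype(float)
    df = pd.DataFrame(data)
    return df[list(ANNOTATION_COLUMNS)]


# ---------------------------------------------------------------------------
# the proteome bundle


@dataclass
class SimulatedProteome:
    """Synthetic gene set: per-gene data, alignments, and the pooled position table."""

    genes: dict[str, GeneData]
    alignments: dict[str, Alignment]
    config: SimulationConfig

    @property
    def gene_lengths(self) -> dict[str, int]:
        return {g: len(gd) for g, gd in self.genes.items()}

    def position_table(self) -> pd.DataFrame:
        """All positions of all genes: gene, position, conservation, 28 annotations."""
        frames = []
        for gene, gd in self.genes.items():
            df = pd.DataFrame(gd.annotations, columns=list(ANNOTATION_COLUMNS))
            df.insert(0, "gene", gene)
            df.insert(1, "position", np.arange(1, len(gd) + 1))
            df.insert(2, "conservation", gd.conservation)
            frames.append(df)
        return pd.concat(frames, ignore_index=True)


def simulate_proteome(config: SimulationConfig | None = None, seed: int | None = None) -> SimulatedProteome:
    """Generate the full synthetic gene set (alignments, profiles, annotations)."""
    config = config or SimulationConfig()
    rng = np.random.default_rng(config.seed if seed is None else seed)
    genes: dict[str, GeneData] = {}
    alignments: dict[str, Alignment] = {}
    lo, hi = config.protein_len_range
    for i in range(config.n_genes):
        gene = f"G{i:04d}"
        length = int(rng.integers(lo, hi + 1))
        aln = simulate_alignment(
            length,
            config.n_seqs,
            config.conserved_fraction,
            rng,
            intermediate_fraction=config.intermediate_fraction,
            intermediate_dominance=config.intermediate_dominance,
        )
        freqs, cons = estimate_profile(aln)
        ann = simulate_annotations(length, config, rng)
        genes[gene] = GeneData(gene, aln.reference_ungapped(), freqs, cons, ann)
        alignments[gene] = aln
    return SimulatedProteome(genes, alignments, config)


# ---------------------------------------------------------------------------
# variants


def _position_pool(proteome: SimulatedProteome) -> pd.DataFrame:
    pool = proteome.position_table()
    pool["wt"] = [
        gd.sequence[p - 1]
        for gd, p in zip(
            (proteome.genes[g] for g in pool["gene"]), pool["position"]
        )
    ]
    return pool


def _pathogenic_weights(pool: pd.DataFrame, config: SimulationConfig) -> np.ndarray:
    w = np.exp(config.conservation_beta * pool["conservation"].to_numpy())
    disorder = pool[list(_DISORDER_PREDICTORS)].mean(axis=1).to_numpy() > 0.5
    for prop, odds in config.pathogenic_odds.items():
        if prop == "disorder":
            w = np.where(disorder, w * odds, w)
        else:
            w = np.where(pool[prop].to_numpy() > 0.5, w * odds, w)
    return w


def _benign_weights(pool: pd.DataFrame, config: SimulationConfig) -> np.ndarray:
    return np.exp(-config.conservation_beta * pool["conservation"].to_numpy())


def _draw_mut(
    rng: np.random.Generator,
    wt: str,
    bias: dict[str, float],
    profile: np.ndarray | None = None,
    toward_profile: bool = True,
    floor: float = 0.01,
) -> str:
    """Draw a mutant residue != wt with amino-acid bias and optional profile coupling.

    With a profile given, benign draws (``toward_profile``) weight residues by
    their column frequency (substitutions seen in orthologs), pathogenic draws
    by the inverse (substitutions alien to the column); ``floor`` keeps the
    weights bounded.
    """
    weights = np.array([bias.get(aa, 1.0) if aa != wt else 0.0 for aa in AMINO_ACIDS])
    if profile is not None:
        f = np.asarray(profile, dtype=float)
        weights = weights * (f + floor) if toward_profile else weights / (f + floor)
    return AMINO_ACIDS[rng.choice(N_AA, p=weights / weights.sum())]


def _draw_mafs(rng: np.random.Generator, n: int, weights) -> np.ndarray:
    cats = rng.choice(4, size=n, p=np.asarray(weights, dtype=float))
    mafs = np.empty(n)
    for c, name in enumerate(_CATEGORIES):
        lo, hi = _MAF_RANGES[name]
        sel = cats == c
        mafs[sel] = np.exp(rng.uniform(np.log(lo), np.log(hi), sel.sum()))
    return mafs


def simulate_labeled_variants(
    proteome: SimulatedProteome,
    n_pathogenic: int = 4000,
    n_benign: int = 4000,
    config: SimulationConfig | None = None,
    seed: int | None = None,
) -> pd.DataFrame:
    """Class-balanced labelled SAV set with planted pathogenicity signal.

    Pathogenic variants are sampled over positions with odds multiplied by
    ``exp(beta * conservation)`` and by the per-annotation planting odds;
    benign variants favour variable, unannotated positions.  Returns a
    DataFrame (gene, position, wt, mut, maf, label), label in
    {pathogenic, benign}.
    """
    config = config or proteome.config
    rng = np.random.default_rng(config.seed if seed is None else seed)
    pool = _position_pool(proteome)
    n_positions = len(pool)
    if n_pathogenic + n_benign > 19 * n_positions:
        raise ValueError("requested variant counts exceed available substitutions")
    rows = []
    for label, n, weights_fn, bias, spectrum in (
        ("pathogenic", n_pathogenic, _pathogenic_weights, config.pathogenic_mut_bias,
         config.pathogenic_spectrum),
        ("benign", n_benign, _benign_weights, config.benign_mut_bias,
         config.spectrum_weights),
    ):
        w = weights_fn(pool, config)
        idx = rng.choice(n_positions, size=n, replace=True, p=w / w.sum())
        mafs = _draw_mafs(rng, n, spectrum)
        toward_profile = label == "benign"
        for k, i in enumerate(idx):
            gene = pool["gene"].iat[i]
            position = int(pool["position"].iat[i])
            wt = pool["wt"].iat[i]
            profile = proteome.genes[gene].profile[position - 1]
            rows.append(
                {
                    "gene": gene,
                    "position": position,
                    "wt": wt,
                    "mut": _draw_mut(
                        rng, wt, bias, profile, toward_profile,
                        floor=config.profile_coupling_floor,
                    ),
                    "maf": mafs[k],
                    "label": label,
                }
            )
    return pd.DataFrame(rows)


def simulate_maf_catalog(
    proteome: SimulatedProteome,
    n_variants: int = 100_000,
    spectrum_weights=None,
    seed: int | None = None,
) -> pd.DataFrame:
    """A gnomAD-like SAV catalog: positions uniform, MAFs log-uniform within categories."""
    config = proteome.config
    weights = spectrum_weights if spectrum_weights is not None else config.spectrum_weights
    rng = np.random.default_rng(config.seed if seed is None else seed)
    pool = _position_pool(proteome)
    idx = rng.choice(len(pool), size=n_variants, replace=True)
    mafs = _draw_mafs(rng, n_variants, weights)
    wt = pool["wt"].to_numpy()[idx]
    mut = [_draw_mut(rng, w, {}) for w in wt]
    return pd.DataFrame(
        {
            "gene": pool["gene"].to_numpy()[idx],
            "position": pool["position"].to_numpy()[idx],
            "wt": wt,
            "mut": mut,
            "maf": mafs,
        }
    )


def simulate_gene_features(
    genes, seed: int = 0, missing_rate: float = 0.05
) -> pd.DataFrame:
    """dbNSFP-style 17-column gene-level feature table (with a few missing values)."""
    rng = np.random.default_rng(seed)
    genes = list(genes)
    n = len(genes)
    data = {}
    for i, col in enumerate(GENE_FEATURE_COLUMNS):
        if col.startswith("PPI"):
            vals = rng.poisson(30, n).astype(float)
        elif col.startswith("essential"):
            vals = (rng.random(n) < 0.2).astype(float)
        elif col == "GDI_Phred":
            vals = rng.gamma(2.0, 2.0, n)
        else:
            vals = rng.random(n)
        vals[rng.random(n) < missing_rate] = np.nan
        data[col] = vals
    df = pd.DataFrame(data, index=pd.Index(genes, name="gene"))
    return df.reset_index()


# ---------------------------------------------------------------------------
# fixture directory


def write_fixture_dir(outdir: str | Path, proteome: SimulatedProteome,
                      variants: pd.DataFrame | None = None,
                      catalog: pd.DataFrame | None = None) -> Path:
    """Write a complete input directory: alignments/, annotations, lengths, features."""
    outdir = Path(outdir)
    aln_dir = outdir / "alignments"
    aln_dir.mkdir(parents=True, exist_ok=True)
    for gene, aln in proteome.alignments.items():
        with open(aln_dir / f"{gene}.fasta", "w") as fh:
            for name, seq in zip(aln.names, aln.sequences):
                fh.write(f">{name}\n{seq}\n")
    pos = proteome.position_table()
    pos.drop(columns=["conservation"]).to_csv(outdir / "annotations.tsv", sep="\t", index=False)
    pd.DataFrame(
        {"gene": list(proteome.gene_lengths), "length": list(proteome.gene_lengths.values())}
    ).to_csv(outdir / "gene_lengths.tsv", sep="\t", index=False)
    simulate_gene_features(proteome.genes, seed=proteome.config.seed).to_csv(
        outdir / "gene_features.tsv", sep="\t", index=False
    )
    if variants is not None:
        variants.to_csv(outdir / "variants.tsv", sep="\t", index=False)
    if catalog is not None:
        catalog.to_csv(outdir / "catalog.tsv", sep="\t", index=False)
    return outdir
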