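# deepsav

Missense-variant pathogenicity scoring with a convolutional sequence-window
classifier, and gene-level mutation-tolerance analyses built on its scores.

## What this package does

A single-amino-acid variant (SAV) replaces one residue of a protein.  Whether
such a change is pathogenic depends on the sequence context: how conserved the
position is across orthologs, which residues the ortholog alignment tolerates
there, the local structural state (secondary structure, disorder, low
complexity, coiled coils), and curated functional annotations (active sites,
disulfides, metal/ligand binding, transmembrane segments, modification sites).

`deepsav` encodes each variant as a 21-residue window centred on the mutated
position.  Every position carries 90 features: wild-type and mutant amino-acid
one-hots (the mutant block is non-zero only at the centre), the 20 alignment
profile frequencies, a normalised-entropy conservation score, 9 secondary-
structure states from three predictors, 3 disorder propensities, low-complexity
and coiled-coil flags, 14 UniProt-style functional flags, and a zero-padding
indicator for window slots beyond the protein ends — 21 × 90 = 1890 values per
variant.  A 1-D convolutional network (seven conv layers of 200 filters with
kernel 3, two residual links, two max-pools, two dense layers of 100 units with
dropout 0.5, softmax output) maps the window to the **DeepSAV score**: the
probability in [0, 1] that the variant is pathogenic.  A **+PG** variant of the
network additionally takes an 18-value side input — `-log10(MAF + 1e-9)` and 17
gene-level features (protein-interaction counts, essentiality, haploinsufficiency
and loss-of-function constraint scores) — concatenated before the dense layers.

Downstream, per-variant scores become gene-level statistics:

- **GTS (Gene Tolerance of rare SAVs)**:
  `GTS = Σ_k DeepSAV_score(k) · MAF(k) / protein_len`, summed over the gene's
  rare SAVs (MAF < 1e-4).  Low GTS marks mutation-intolerant genes.  Scores are
  ranked across genes by the inclusive percentrank convention and split into
  deciles.
- **Enrichment log-odds**: `log2(P(property | subset) / P(property | all positions))`
  for each positional property in a variant position subset (e.g. pathogenic
  positions, or gnomAD-like MAF categories) against the whole-proteome
  background.
- **Disease-class ratios**: observed/expected MeSH disease-class frequencies of
  a gene set over a curated gene–disease association table.
- **Gene clustering**: Z-scored multi-measure gene profiles (GTS, LOEUF, lnGDI,
  rare-variant count, HIPred, P(HI), …) clustered by complete linkage of
  correlation distances, plus three-way Venn overlaps of gene sets.

A synthetic-data module generates every input the method consumes — ortholog
alignments with a conservation gradient, segmental annotation tables, labelled
variant sets with planted pathogenicity signal, and rare-dominated MAF catalogs
— so the full pipeline is testable offline.

## Worked example

```python
from deepsav.simulate import SimulationConfig, simulate_proteome, \
    simulate_labeled_variants, simulate_maf_catalog
from deepsav.features import WindowEncoder
from deepsav.model import DeepSAVClassifier, cross_validate
from deepsav.gts import gene_tolerance_table

config = SimulationConfig(n_genes=20, seed=0)
proteome = simulate_proteome(config)
variants = simulate_labeled_variants(proteome, 1000, 1000, seed=1)

encoder = WindowEncoder(proteome.genes)
X = encoder.transform(variants)                       # (2000, 1890)
y = (variants["label"] == "pathogenic").astype(int).to_numpy()

est = DeepSAVClassifier(filters=32, epochs=30, random_state=0)
result = cross_validate(X, y, k=4, estimator=est, seed=0)
print(result)
# CVResult(folds=[0.879, 0.891, 0.872, 0.895], pooled=0.868)

catalog = simulate_maf_catalog(proteome, 20_000, seed=2)
est.fit(X, y)
catalog["deepsav_score"] = est.decision_function(encoder.transform(catalog))
table = gene_tolerance_table(catalog, proteome.gene_lengths)
print(table.head(3).to_string(index=False))
#  gene      gts  percentile  decile  n_rare_savs  n_deleterious
# G0010 0.000015    0.000000       0          443             54
# G0012 0.000017    0.052632       0         1116            116
# G0009 0.000018    0.105263       1          538             53
```

The pooled AUC says how well the classifier separates the planted pathogenic
variants from benign ones on held-out folds; in the GTS table, genes at the top
(decile 0) are the most mutation-intolerant — their rare variants carry the
least predicted-deleterious burden per residue.  The same pipeline is exposed
on the command line (`deepsav simulate / train / cv / predict / gts / enrich /
cluster / run`).

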