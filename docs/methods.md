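# Methods

## Model

The classifier maps a 21-residue window of per-position features to the
probability that the centre substitution is pathogenic.  Each position carries
90 features in a fixed order (wild-type one-hot, mutant one-hot, 20 profile
frequencies, conservation, 9 secondary-structure states, 3 disorder
propensities, low-complexity and coiled-coil flags, 14 functional flags,
padding indicator); the window is flattened to 1890 inputs.  Neighbouring
positions encode their own residue in the wild-type block and zeros in the
mutant block, so the substitution is visible only at the centre; window slots
beyond the protein ends are zero-filled with the padding indicator set to 1.

The network is a fixed layer plan written in plain numpy (im2col convolutions,
explicit backprop):

```
conv0 -> [conv, conv, +skip] -> maxpool -> [conv, conv, +skip] -> maxpool
      -> conv5 -> conv6 -> flatten (+18 side inputs when +PG)
      -> dense(100) -> dropout -> dense(100) -> dropout -> softmax(2)
```

Seven conv1d layers (kernel 3, 'same' padding, ReLU), two residual additions,
two width-2 max-pools, two dense layers with dropout.  The default width is
200 filters and the batch size 128.  The first conv layer adapts the 90 input
channels to the filter width so the residual additions are shape-compatible.
Training is Adam (default 1e-3) on softmax cross-entropy.  All randomness
(initialisation, batch order, dropout, validation split) flows through one
`numpy.random.Generator`, so a fitted model is a bit-reproducible function of
(data, random_state).

Early stopping monitors the AUC of a held-out stratified validation fraction
(default 10%, patience 5 epochs in the estimator; the benchmark study uses
patience 10) and restores the best weights.  Validation AUC rather than
validation loss is monitored deliberately: once the network becomes
overconfident the cross-entropy deteriorates while the ranking — the model's
actual figure of merit — is still improving, and loss-based stopping quits
several points of AUC too early.

The +PG extension appends 18 side inputs before the dense layers:
`-log10(MAF + 1e-9)` (raw allele frequencies are numerically degenerate near
zero) and 17 gene-level scores.  Missing gene-level values are median-imputed,
with medians computed on the training fold only.

## Alignment statistics

Profiles are gap-excluded relative frequencies with a uniform pseudocount
(default 0.05 per amino acid), optionally with Henikoff position-based
sequence weighting.  Conservation is normalised Shannon entropy,
`1 - H/ln 20`, clamped to [0, 1]: 1 for an invariant column, 0 for a uniform
one.  This choice makes the three conservation bins well defined on [0, 1];
the bin boundaries are [0, 0.3) / [0.3, 0.6] / (0.6, 1], honouring "larger
than 0.6" literally for the top bin.  The baseline fitness of a substitution
is `log2((f_wt + eps)/(f_mut + eps))` with eps = 1e-4; the epsilon bounds the
statistic on sparse columns while keeping exact antisymmetry under swapping
wild-type and mutant.  Positions whose reference residue is unknown ('X') are
excluded from encoding and variant scoring.

## Gene-level scoring

`GTS = Σ score·MAF / protein_len` over rare SAVs (MAF < 1e-4, strict).  The
formula is taken as normative over its prose description.  Deleterious
variants are counted with a strict threshold (score > 0.75), rare-only by
default.  Duplicate records of the same substitution keep the maximum MAF.
Percentiles use the inclusive percentrank convention — count of strictly
smaller values over (n − 1) — so ties share the percentile of their first
occurrence; deciles floor the percentile at 10 bins with the maximum clamped
into decile 9 (computed in integer arithmetic to avoid float truncation at
exact boundaries).

MAF categories are left-closed: rare < 1e-4 ≤ low < 1e-3 ≤ medium < 1e-2 ≤
common.

## Enrichment

A property's enrichment in a position subset is
`log2(P(property|subset)/P(property|background))`, counted over unique
amino-acid positions (not variant events).  Continuous inputs are binarised:
disorder propensities at 0.5 (ordered/disordered per predictor), secondary-
structure probabilities at 0.5, conservation via the three bins.  A zero
subset count yields a −inf sentinel; an optional 0.5 pseudo-count (added to
both counts, twice to both sizes, preserving exact swap-antisymmetry) is
available.  Properties absent from the background are dropped with a warning.
Disease-class ratios compare observed and expected MeSH-class frequencies
over unique (gene, class) assignments; classes with fewer than a configurable
minimum of assignments (default 5) are excluded as sparse.

## Clustering

Gene score matrices are Z-scored per measure (sample standard deviation),
row-centred without scaling, and clustered by complete linkage of correlation
distances `1 − Pearson r` between gene rows.  Correlations are
pairwise-complete over missing values; pairs sharing fewer than two measures
get distance 1.  The agglomeration is implemented directly with a
deterministic lowest-index tie-break (scipy's implementation is used as an
independent cross-check in the tests, not as the implementation).  The number
of flat clusters is a parameter (default 20).

## Synthetic data

The generator produces every input the method consumes, with the statistical
structure the method assumes.  It is test scaffolding: its purpose is planted,
recoverable signal, not population-genetic realism (no coalescent, no
selection model, no linkage to genomic coordinates).

- **Alignments.**  Columns come in three kinds — invariant, partially
  conserved (one dominant residue at probability 0.6), and flat — mixed at
  30/30/40% by default.  Kinds persist along the sequence (keep probability
  0.85 per position), giving domain-like conservation blocks; residues are
  otherwise uniform over the 20 amino acids.  Default 50 sequences per
  alignment, 60 genes of 150–450 residues.
- **Annotations.**  Region-like features occur in runs with realistic mean
  lengths (secondary structure 5–8, transmembrane 8, disorder 15,
  signal/transit 15, low-complexity 7, coiled-coil 8, motifs 5) via
  stationary two-state Markov chains; site-like features (active sites,
  disulfides, metal/ligand binding, modification sites) are independent
  points.  Marginal rates are 5–8% — higher than real proteome rates for
  site-like features — chosen from the binomial-error formula so that one
  enrichment cell at the study size n = 10,000 has log2-scale SE ≲ 0.07.
  Three predictor tracks per modality disagree with controlled noise.
- **Labelled variants.**  Pathogenic variants sample positions with weight
  `exp(2.5·conservation)` times per-annotation odds following the direction
  of the real enrichment findings (4× active sites and disulfides, 3×
  metal/ligand binding, 2× transmembrane and phosphosites, 0.5× disordered/
  low-complexity/coiled-coil); benign variants weight `exp(−2.5·conservation)`.
  Mutant residues couple to the column profile — benign draws weight residues
  by `(f + 0.01)`, pathogenic by its inverse — and carry a mild identity bias
  (pathogenic toward P/W/C, benign toward A/S/T).  The allocation puts the
  largest single share of discriminative signal in conservation and a further
  increment in profile and annotations, so the qualitative feature-ablation
  ordering (AA-only < AA+conservation ≤ all features) is structural, matching
  the published pattern of the feature-combination experiments.
- **MAF catalogs.**  Category weights (93.93 / 4.40 / 1.10 / 0.57%) follow
  the published rare-dominated spectrum; within a category MAFs are
  log-uniform.  Labelled pathogenic variants draw from a more rare-shifted
  spectrum (99% below 1e-4).

What passing tests on this generator do show: the encoder, network, scoring,
and statistics recover signal that is present, and report chance when it is
absent.  What they do not show: performance on real ClinVar/gnomAD data,
where annotation structure, alignment depth, and class balance differ.

## The benchmark study

`deepsav.benchmark` fixes the desk-scale study conditions shared by the test
suite and `scripts/acceptance.py`:

- Classifier evaluation uses the default 4,000+4,000 variant dataset and a
  64-filter network (epochs ≤ 60, patience 10).  The published 200-filter
  width remains the estimator default; the narrower study network is a
  numerical choice for the 8,000-sample problem, where a 4-fold pooled
  cross-validated AUC is the reported discrimination measure (every variant
  scored exactly once, out of fold).  A label-shuffle control on a 75/25
  split verifies the pipeline reports chance on destroyed labels.
- The active-site recovery experiment plants 4× odds on a large sparse
  proteome (1,200 genes, 1% active-site rate, no other planting).  With
  10,000 variants sampled over ~240,000 positions, unique-position counting
  compresses the recovered ratio from 4.0 to an expected
  `4/(1+3p)` ≈ 3.7–3.9 with a further occupancy-saturation factor; the
  configuration keeps the expectation near log2-odds 1.9 with SE ≈ 0.08.
  The null experiment plants nothing and checks every cell is within
  binomial noise of zero.

## Known limitations

- The numpy network trains on CPU only and is sized for desk-scale data; it
  is not a route to full-catalog training.
- The exact published profile-estimation scheme and conservation
  parameterisation are not recoverable from their descriptions; both are
  configurable stand-ins (uniform-pseudocount frequencies; normalised-entropy
  conservation) whose bins and ranges match the published usage.
- The exact layer arrangement of the two residual links and max-pools is a
  documented canonical stand-in; parameter counts therefore differ from the
  original implementation.
- Whether the original training used class weighting or augmentation is
  unstated; none is applied.
- Singleton alleles receive no special MAF treatment in GTS; raw MAF is used.
- PCA-with-imputation variance figures and heatmap rendering of the
  clustering tool being emulated are out of scope; the number of flat
  clusters is a plain parameter.
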