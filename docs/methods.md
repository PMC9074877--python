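# Methods

## Model

A pathway is a gene set measured on up to four omics — RNA abundance,
promoter methylation, copy-number alteration (all indexed by gene
symbol) and miRNA abundance (attached to a gene through a curated
miRNA-target interaction table, keeping only records whose support-type
field exactly equals a configured value, default `"Functional MTI"`).
Assembly builds one table X_g per gene over the intersection of
individual IDs across omics (exact string matching; ID harmonization is
left to preprocessing). A miRNA targeting several pathway genes is
replicated as a column in each target's table, so each gene's block is
self-contained.

Preprocessing removes features that are missing for every individual or
whose raw-value variance (unbiased, n−1 denominator) is strictly below
1e−5 — near-constant features carry no standardizable signal and would
blow up the scaling — then mean-imputes remaining missing cells.
Inputs are assumed already transformed to roughly continuous scales
(log counts, logit beta values); the package applies no transforms.

### Multiple factor analysis

Each table is standardized column-wise (center = mean, scale = SD with
the population denominator n by default; `ddof=1` is available and all
identities hold under either convention). λ_g¹ is the variance of the
table's first principal component, and every feature of table g is
divided by √λ_g¹, which makes the weighted table's first PC variance
exactly 1: tables with many redundant columns (large λ_g¹) are
down-weighted, so no gene dominates by assay count alone. A single SVD
of the concatenation X\* gives eigenvalues s_ℓ²/(n−ddof), factor scores
U·diag(s) and loadings V. The factor-score convention makes the score
space an isometry of the rows of X\*: Σ_ℓ f_{i,ℓ}² = ‖X\*_i‖².

Partial factor scores are f_{i,·,g} = p · (X\*-block of gene g for
individual i) · V_g, which guarantees that their mean over genes equals
the factor score — this identity is the definition the decomposition
relies on.

Numerical conventions: rank L counts singular values above
(largest s) × 1e−10; component signs are fixed by making the
largest-|loading| entry of each component positive (ties broken by the
first index). Sign flips never affect deviation scores or
contributions. Negating a raw feature can flip a component's
orientation under this rule; all derived quantities are invariant.

### Deviation scores and decompositions

d_i = √(Σ_ℓ f_{i,ℓ}²) over a chosen component subset (default: all, so
no information is discarded); the normalized score divides by the
number of *retained* genes p, since only those enter the model. The
per-gene contribution d_{i,g} = Σ_ℓ f_{i,ℓ}(f_{i,ℓ,g} −
f_{i,ℓ}) / Σ_ℓ f_{i,ℓ}², computed over the same component subset so the
sum-to-zero identity survives subsetting. Individuals exactly at the
origin (d_i = 0) get zero contributions and a flag rather than NaN from
0/0. Scaled contributions divide by d_i.

Arbitrary variable groups use an additive construction: write
a_{i,j} = Σ_ℓ f_{i,ℓ} X\*_{i,j} V_{j,ℓ} / Σ_ℓ f_{i,ℓ}² for the share of
column j; each gene carries mass 1/p split equally among its columns,
and a group S contributes d_{i,S} = Σ_{j∈S} (p·a_{i,j} − 1/j_{g(j)}).
This was a genuinely open design point; the additive form was chosen
because it is the unique extension that simultaneously (a) reproduces
d_{i,g} when S is exactly gene g's columns, (b) makes every partition
of the features sum to zero per individual, and (c) makes singleton
contributions add up within a gene.

Inertia decompositions: per-axis percent variance is
eigenvalue/total×100; a variable's contribution to an axis is its
squared loading (so omic/gene aggregates sum to 100 per axis); an
individual's contribution is f_{i,ℓ}²/Σ_i f_{i,ℓ}². The
eigenvalue-weighted overall omic contribution averages per-axis omic
contributions with eigenvalue weights. Per-individual contributions use
the weighted (consensus-space) coordinates.

Supplementary individuals are standardized with the *stored* centers,
scales and λ_g¹ of the reference fit and multiplied by the stored
loadings; no refit occurs, and projecting the reference feature means
lands exactly at the origin.

## Synthetic-data generator

`SimConfig` fixes the study conditions: features within a gene are
equicorrelated Gaussians (default correlation 0.5, a moderate
within-gene coupling typical of expression/methylation/CNA triples),
genes independent, and each aberrant individual is mean-shifted by
`effect_size` SD units (default 5) on the driver genes' driver omics.
Defaults mirror the spike-in design: n = 75 individuals with 5 aberrant,
10 genes with 3 omics each, 3 driver genes × 2 driver omics. Optional
missing-completely-at-random injection exercises the imputation path.
AUC uses the Mann–Whitney rank identity with ties counted 1/2 — exact
and interpolation-free.

What the generator does **not** emulate: batch effects, heavy-tailed or
bounded marginals (methylation beta values), discrete copy-number call
distributions, between-gene correlation, and realistic missingness
structure. Passing tests therefore demonstrate the method's structural
identities and its detection power under a clean mean-shift model, not
performance on real tumor data.

## Tunable parameters

| parameter | default | meaning |
|---|---|---|
| `var_threshold` | 1e−5 | raw-variance cutoff for feature removal (unitless, pre-scaling) |
| `ddof` | 0 | variance denominator convention (0 = population n) |
| `components` | all | 1-based consensus axes used for scores and contributions |
| `support_type` | "Functional MTI" | exact-match filter on the interaction table |
| `effect_size` | 5.0 | aberrant mean shift, in SD units of the baseline marginal |
| `within_gene_correlation` | 0.5 | equicorrelation of a gene's features |
| `top_fraction` | 0.05 | skewness screen cut, count = ceil(fraction × N) |

The skewness screen uses Pearson's moment coefficient g1 = m₃/m₂^{3/2}
(n denominator, no bias correction) on normalized scores; since the
per-pathway normalization is a positive scalar, it does not affect the
ranking. The ceiling rule makes the returned count deterministic
(e.g. 57 of 1136 at 5%); ties are broken by pathway name.

## Degenerate inputs and limitations

- Pathways whose genes all lack data, cohorts with an empty individual
  intersection, and rank-0 weighted matrices raise errors rather than
  returning empty results; batch runs skip such pathways with a logged
  reason.
- Simulation experiments derive per-repetition seeds from the base seed
  (kept below 2³¹), so runs are reproducible bit-for-bit.
- The MFA is not missing-data-aware: imputation is upstream and mean
  imputation shrinks variance slightly for high missingness rates.
- With p = 1 gene all per-gene contributions are identically zero
  (partial equals consensus); the deviation score remains informative.
- Scores scale with cohort composition: the origin is the cohort
  average, so adding strongly aberrant individuals moves it. Use the
  supplementary projection to score new individuals against a frozen
  reference.
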