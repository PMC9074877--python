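# padma — individualized multi-omic pathway deviation scores

`padma` quantifies, per individual, how aberrant a pathway's multi-omic
profile is relative to the population average, and decomposes that
aberration into the genes and omics that drive it. It is aimed at
analysts working with matched per-individual omics (RNA abundance,
promoter methylation, copy-number alteration, miRNA abundance) — e.g.
tumor cohorts — who want single-sample pathway-level scores rather than
cohort-level differential statistics.

## Method

For a pathway of genes g = 1..p, all omic measurements of gene g across
the n matched individuals form a table X_g (n × j_g; the j_g columns may
differ per gene — one gene may have expression, methylation, CNA and a
targeting miRNA, another expression alone). A **multiple factor
analysis** (MFA) standardizes each table column-wise, computes the
variance λ_g¹ of each table's first principal component, and rescales the
table so its first PC variance becomes 1 — redundant tables are
down-weighted, complementary ones are not. A single PCA (SVD) of the
concatenated weighted matrix X\* = [X₁\*, …, X_p\*] yields the consensus:
eigenvalues, factor scores f_{i,ℓ}, and per-gene partial factor scores
f_{i,ℓ,g} whose mean over genes recovers f_{i,ℓ}.

The origin of this consensus space is the average multi-omic profile.
The **pathway deviation score** of individual i is

    d_i = sqrt( Σ_ℓ f_{i,ℓ}² ),        normalized score = d_i / p,

which with all components equals the Euclidean distance of the
individual's weighted standardized data row from the origin. It
decomposes into signed **per-gene contributions**

    d_{i,g} = Σ_ℓ f_{i,ℓ} (f_{i,ℓ,g} − f_{i,ℓ}) / Σ_ℓ f_{i,ℓ}² ,

which sum to zero over genes (positive = the gene pulls the individual
away from the average), and extend additively to arbitrary variable
groups such as whole omics. A spike-in simulation framework with known
aberrant individuals validates detection by ROC/AUC and driver-gene
recovery. See `docs/methods.md` for assumptions and numerical
conventions.

## Worked example

```sh
python examples/01_score_synthetic_pathway.py
```

```
pathway SIM_PATHWAY: 75 individuals, 10 genes, rank 30

top 5 individuals by normalized deviation score (larger = more aberrant multi-omic profile):
  IND0007  score=0.695  top contributing gene=GENE010  truth=ABERRANT
  IND0033  score=0.635  top contributing gene=GENE010  truth=ABERRANT
  IND0056  score=0.588  top contributing gene=GENE001  truth=ABERRANT
  IND0075  score=0.581  top contributing gene=GENE001  truth=ABERRANT
  IND0048  score=0.527  top contributing gene=GENE010  truth=ABERRANT

true driver genes: ['GENE001', 'GENE005', 'GENE010'] on omics ['cna', 'methylation']
```

All five spiked-in individuals top the score ranking, and the gene with
the largest scaled contribution for each is one of the true drivers.
The spike-in validation (`examples/02_spike_in_validation.py`) prints

```
effect 5.0 SD: mean AUC = 1.000  (quartiles 1.000 / 1.000 / 1.000)
effect 0 SD (null):  mean AUC = 0.523
```

— near-perfect separation of aberrant from baseline individuals under
signal, chance-level under the null. Other examples cover driver-gene
recovery and scorer comparisons (`03`) and batch scoring of a pathway
collection with the top-5% skewness screen (`04`).

A thin CLI wraps the same pipeline for shell use:

```sh
padma simulate --seed 3 --out sim/
padma run --gene-sets sim/pathway.gmt \
    --omics expression=sim/expression.tsv --omics methylation=sim/methylation.tsv \
    --omics cna=sim/cna.tsv --out out/
padma validate --seed 1 --repetitions 20
```

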