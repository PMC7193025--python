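# chemscreen

Screening environmental chemicals for association with a disease by
combining three layers of genomic evidence: GWAS summary statistics,
summary-based TWAS, and case/control expression profiles, each tested
against chemical–gene interaction sets (CTD-style) with a weighted
running-sum enrichment statistic and a permutation null.

The intended user is a statistical geneticist or toxicogenomics analyst who
has per-SNP association z-scores for a trait, per-gene expression-weight
models with an LD reference, a collection of chemical gene sets, and
(optionally) a two-group expression matrix — and wants a ranked, multiply
screened list of chemicals whose interacting genes concentrate among the
trait-associated genes.

## Method

**Gene-level statistics.** For each gene, a summary-based TWAS statistic is
computed from the GWAS z-score vector *Z* of the SNPs in the gene's
expression model, the eQTL weight vector *w*, and the SNP-correlation (LD)
matrix *L*:

```
z_TWAS = w'Z / sqrt(w'Lw)
```

which is standard normal under the null. Alternative gene scores are the
best in-window GWAS SNP (max |z| within ±50 kb by default) and the Welch
two-sample *t* comparing case vs control expression.

**Chemical enrichment.** Genes are ranked by score r₁ ≥ … ≥ r_N. For a
chemical's gene set *S* with N_H members in the universe, the enrichment
score is the maximum of the running sum

```
ES(S) = max_{1<=j<=N} [ Σ_{hits<=j} |r|^p / N_R  −  Σ_{misses<=j} 1/(N−N_H) ],
N_R = Σ_{G∈S} |r|^p
```

with weight exponent p = 1 by default. The null distribution is built from
uniformly random same-size gene subsets (5,000 permutations by default,
shared across sets of equal size), the normalized score is
NES = (ES − mean(ES_null)) / SD(ES_null), and the empirical p-value uses the
add-one estimator (1 + #{ES_null ≥ ES_obs}) / (Λ + 1). Chemicals with
p < 0.05 are called significant; Benjamini–Hochberg q-values are reported
alongside.

**Integration.** Per disease, "common" chemicals are those significant in
the expression screen *and* in at least one GWAS/TWAS tissue screen, with
per-tissue counts and the multi-tissue overlap retained; across diseases the
pan-disease common set is the exact name intersection.

A synthetic-data module generates all inputs with planted effects (AR(1)
LD, unit-normalized weights, causal chemicals whose genes carry a TWAS mean
shift λ and an expression mean shift δ), so calibration and power of every
stage are testable without external downloads.

## Worked example

```python
import chemscreen as cs

cfg = cs.SimulationConfig(n_genes=300, n_chemicals=50, set_size_range=(5, 30),
                          n_causal_chemicals=2, causal_fraction=1.0, seed=7)
study = cs.run_study(cfg, cs.EnrichmentConfig(n_permutations=200, seed=3))

for r in study.diseases["colon_cancer"].enrichment["twas:colon"][:3]:
    print(r.chemical_name, r.n_overlap, round(r.es, 4), round(r.nes, 3),
          round(r.p_empirical, 6), r.significant)
print(sorted(study.report.pan_common))
```

prints

```
chem0000 12 0.9097 3.905 0.004975 True
chem0001 18 0.9085 4.696 0.004975 True
chem0012 25 0.6355 2.72 0.004975 True
['chem0000', 'chem0001', 'chem0011', 'chem0012']
```

The two planted causal chemicals (`chem0000`, `chem0001`) top the
TWAS-stream screen at the minimum attainable empirical p = 1/201 with high
enrichment scores, and both appear in the pan-disease common set (the two
extra entries are sets that overlap the causal gene pool). The integration
counts (`study.report.counts`) carry the per-tissue/total bookkeeping, e.g.
`colon_cancer:twas:colon 4`, `colon_cancer:twas:whole_blood 5`,
`colon_cancer:multi_tissue 4`, `colon_cancer:total 5` — totals satisfy
union = sum of tissue counts minus the multi-tissue overlap.

The same pipeline is scriptable from the shell:

```
chemscreen simulate --config config.yaml --out sim/
chemscreen twas --gwas sim/gwas_colon.tsv --weights sim/weights_colon.tsv \
    --ld-dir sim/ld --tissue colon --out twas.tsv
chemscreen score --stream twas --twas-results twas.tsv --out scores.tsv
chemscreen gsea --scores scores.tsv --gmt sim/chemsets.gmt --perms 5000 \
    --seed 1 --out gsea.tsv
chemscreen integrate --gwas-gsea gsea.tsv --expr-gsea expr_gsea.tsv --out report/
chemscreen all --config config.yaml --out study/     # end to end
```

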