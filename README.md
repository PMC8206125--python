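# locusnet

Locus-centric signed weighted gene co-expression network analysis.

`locusnet` asks a question that recurrent copy-number variants pose
constantly: of the genes inside a deleted or duplicated interval, *which ones
drive the phenotype?* When no single gene carries obvious coding evidence,
the co-expression context of each interval gene in the relevant healthy
tissue is a powerful, annotation-free source of hypotheses. The package
builds that context end to end:

1. **Preprocess** a log2 expression matrix (missingness and zero-variance
   filters, sample-network outlier removal, OLS residualization against sex,
   age, death classification, postmortem interval and batch).
2. **Network construction and module detection** — biweight midcorrelation,
   signed soft-threshold adjacency `a_ij = ((1 + cor_ij)/2)^β` with β chosen
   by a scale-free-topology scan, topological overlap (TOM), average-linkage
   clustering of `1 − TOM`, dynamic hybrid tree cut, module eigengenes (ME),
   eigengene-based connectivity kME, merging of modules with `cor(ME) > 0.8`,
   and meta-modules.
3. **Preservation and quality** — permutation-standardized composite
   `Z_summary` statistics (density and connectivity components) against a
   replicate cohort, and against repeated random half-splits of the
   reference; `< 2` no evidence, `2–10` moderate, `> 10` strong.
4. **Driver prioritization** — interval hubs (`kME > 0.8`, `p < 0.05`),
   intramodular *top neighbors* of each interval seed (Spearman `ρ ≥ 0.5`,
   `p < 0.05`), exact hypergeometric overlap of neighbor sets with disease
   gene-set panels next to negative-control panels (Benjamini–Hochberg per
   family), and assembly of the prioritized driver set.
5. **DEG validation** — consensus differential expression from two tests,
   one-to-one homology mapping, and enrichment of the network targets at
   three nested scales (broad interval network, top-neighbor subnetwork,
   prioritized drivers).

A synthetic-cohort generator (`locusnet.simulate`) plants every piece of
ground truth the analysis assumes — modular expression from a factor model,
background noise genes, hub genes, interval genes spread across modules,
covariate nuisance effects, a replicate cohort, enriched disease panels, and
a two-group negative-binomial DEG study — so the full pipeline runs and is
testable without any external download.

## Worked example

The module-detection core is a scikit-learn-style estimator:

```python
from locusnet import SimulationConfig, simulate_cohort, CoexpressionNetwork

ref, test, covariates, truth = simulate_cohort(SimulationConfig(seed=1))
net = CoexpressionNetwork().fit(ref.T)   # samples x genes
print("power:", net.power_)
print(net.partition_.value_counts().sort_index().to_dict())
```

prints

```
power: 4
{0: 823, 1: 433, 2: 312, 3: 200, 4: 147, 5: 85}
```

— the scan selected soft-threshold power β = 4 (lowest power reaching the
scale-free fit target R² = 0.8), and the cut recovered five modules of 433,
312, 200, 147 and 85 genes next to 823 unassigned (label 0) background
genes, closely matching the planted design of 400/300/200/150/100 modules
plus 850 noise genes. Against the planted partition this run scores an
adjusted Rand index of 0.79; the mean over ten seeds is 0.87.

Preservation of the planted modules in the replicate cohort:

```python
from locusnet.preservation import z_summary_pres
pres = z_summary_pres(ref, test, truth.true_partition, n_perm=200, seed=1, beta=6)
print(pres.table[["z_density", "z_connectivity", "z_summary", "category"]])
```

```
        z_density  z_connectivity  z_summary category
module
1       50.168354       -3.365960  23.401197   strong
2       43.142394       -4.145050  19.498672   strong
3       32.371792       -1.587231  15.392281   strong
4       30.729710       -2.179402  14.275154   strong
5       27.058465       -2.480773  12.288846   strong
```

Every planted module is called strongly preserved (`Z_summary > 10`); a
scrambled-assignment negative control centers near zero (98–99% of values
below 2).

The same stages are available from a shell:

```sh
locusnet simulate   --config sim.yaml --outdir data/
locusnet preprocess --expr data/expression_ref.tsv --covariates data/covariates.tsv \
                    --out data/ref.resid.tsv
locusnet network    --expr data/ref.resid.tsv --outdir net/
locusnet preserve   --ref data/ref.resid.tsv --test data/expression_test.tsv \
                    --modules net/modules.tsv --out preservation.tsv
locusnet prioritize --expr data/ref.resid.tsv --modules net/modules.tsv \
                    --kme net/kme.tsv --kme-p net/kme_p.tsv \
                    --interval data/interval_genes.txt \
                    --disease data/panels_disease.gmt --control data/panels_control.gmt \
                    --outdir prio/
locusnet validate-degs --deg-a data/deg_method_a.tsv --deg-b data/deg_method_b.tsv \
                    --homology data/homology.tsv --targets targets.json \
                    --out deg_validation.tsv
```

All stages are byte-deterministic given a config and seed.

## Scope

The package consumes processed, normalized expression values and DEG tables;
it does not align reads, call differential expression with external
frameworks, query annotation databases for pathway enrichment, or translate
gene identifiers beyond an explicit homology table.
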