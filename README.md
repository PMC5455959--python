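# castemk

Molecular-evolution analysis of caste-associated genes in social insects:
maximum-likelihood estimation of the adaptive substitution proportion α from
McDonald–Kreitman count tables, phylostratigraphic gene-age assignment, and
the class-level statistics that link them.

## Who this is for

Population and sociogenomics researchers asking whether genes upregulated in
one caste (e.g. the sterile worker caste, shaped indirectly by kin
selection) evolve under weaker selection than genes upregulated in
reproductives (shaped by direct selection). The package takes per-gene
variant or MK count data for an ingroup panel plus one outgroup, caste
class labels from differential expression, and homology-hit tables, and
produces per-class α estimates with bootstrap inference, gene ages, and
enrichment statistics.

## The model

For gene *i* with nonsynonymous/synonymous polymorphism counts (Pₙᵢ, Pₛᵢ)
and divergence counts (Dₙᵢ, Dₛᵢ):

    Pₛᵢ ~ Poisson(θᵢ)            Pₙᵢ ~ Poisson(f·θᵢ)
    Dₛᵢ ~ Poisson(λᵢ)            Dₙᵢ ~ Poisson(f·λᵢ / (1 − α))

θᵢ and λᵢ are per-gene nuisance intensities; the selective constraint *f*
(the neutral fraction of nonsynonymous mutations) and α (the proportion of
nonsynonymous substitutions fixed by positive selection) are shared across
the genes of a class. Profiling out the nuisances gives a two-binomial
likelihood in the count sums, maximised over α < 1 and f ∈ (0, 1];
inference is by gene-resampling percentile bootstrap, and classes are
compared with a two-tailed bootstrap test on α₁ − α₂. Negative α̂ is
allowed and expected when mildly deleterious polymorphism segregates.

Around the estimator: VCF-style site filtering (indels, multiallelic
sites, >10% missing data, quality < 40 removed), a strand-aware codon
classifier (synonymous / nonsynonymous / stop-affected), phylostratum
assignment (oldest stratum with a BLAST hit at E < 10⁻⁵, longest-isoform
rule, ≥30 aa), a Poisson/quasi-Poisson GLM for mean gene age between
classes, chi-square contingency tables with standardized Pearson residuals
(|r| > 2 ≈ p < 0.05, |r| > 4 ≈ p < 0.001), and hypergeometric GO
over-representation. A synthetic-data module generates every input from
the same models with planted truth.

## Worked example

```python
from castemk import MKSimConfig, sim_mk_counts
from castemk.mk import MKAlphaModel, compare_classes

rep, _ = sim_mk_counts(MKSimConfig(n_genes=3000, alpha_true=0.31, f_true=0.20, seed=1))
wrk, _ = sim_mk_counts(MKSimConfig(n_genes=3000, alpha_true=0.15, f_true=0.30, seed=2))

res = MKAlphaModel(rep, label="reproductive").bootstrap(B=1000, seed=3)
print(res.summary())
cmp = compare_classes(rep, wrk, B=1000, seed=4,
                      label_a="reproductive", label_b="worker")
print(f"delta alpha = {cmp.delta_hat:.3f}, bootstrap P = {cmp.bootstrap_p:.4g}")
```

prints

```
MK alpha maximum-likelihood fit
==============================================
class:            reproductive
n genes:          3000 (0 all-zero dropped)
alpha_hat:         0.3079
f_hat:             0.2008
log-likelihood:   -22789.478
95% CI (perc.):   [ 0.2803,  0.3331]
bootstrap:        B=1000 (dropped 0), seed=3
delta alpha = 0.168, bootstrap P = 0
```

The fit recovers the planted α = 0.31 (point estimate 0.308, CI covering
the truth) and constraint f = 0.20; the class contrast of 0.17 is detected
with bootstrap P below 1/B (reported as 0), i.e. no resampled replicate
reversed the ordering.

## Command line

```bash
castemk simulate mk --n-genes 1000 --alpha 0.3 --f 0.5 --seed 1 --out sim/
castemk mktable --vcf calls.vcf --cds cds.fa --gff models.tsv \
        --outgroup-sample outgroup --out mk_counts.tsv
castemk alpha --counts mk_counts.tsv --classes classes.tsv --bootstrap 1000 \
        --seed 7 --compare reproductive,worker
castemk phylostrat --hits blast.tsv --isoforms isoforms.tsv --out ages.tsv
castemk run --out report/ --seed 7          # full synthetic study
```

## Layout

- `castemk.mk` — `MKAlphaModel` / `MKAlphaResults`, per-gene MK test,
  pooled estimator, bootstrap and class comparison
- `castemk.variants` — site filters, codon classifier, MK tabulation
- `castemk.phylostrat` — lineages, stratum assignment, condensation
- `castemk.classstats` — GLM, contingency residuals, GO enrichment
- `castemk.simulate` — generators with planted truth
- `castemk.pipeline` / `castemk.cli` — orchestration and the `castemk` tool

See `docs/methods.md` for the statistical details and design choices.
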