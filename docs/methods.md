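# Methods

## The MK α model

The McDonald–Kreitman contrast treats synonymous variation as the neutral
yardstick: if nonsynonymous mutations were neutral at the same rate within
and between species, Pₙ/Pₛ would equal Dₙ/Dₛ. An excess of nonsynonymous
divergence indicates adaptive fixation; α is the proportion of
nonsynonymous substitutions attributable to positive selection.

We model the four counts per gene as independent Poissons (see README for
the rates). The per-gene intensities θᵢ, λᵢ absorb gene length, mutation
rate and coalescent/divergence depth; the class-shared parameters are the
constraint f (fraction of nonsynonymous mutations behaving neutrally;
1 − f effectively never seen) and α. Given (α, f) the nuisance MLEs are
closed form, and substituting them collapses the profile log-likelihood,
up to a data-only constant, to

    ℓ(α, f) = ΣPₙ log qₚ + ΣPₛ log(1−qₚ) + ΣDₙ log q_d + ΣDₛ log(1−q_d),

with qₚ = f/(1+f), q_d = g/(1+g), g = f/(1−α): two binomial likelihoods in
the column sums. Two consequences we rely on:

1. **Closed-form optimum.** Unconstrained, f̂ = ΣPₙ/ΣPₛ and
   ĝ = ΣDₙ/ΣDₛ, so α̂ = 1 − ΣDₛΣPₙ/(ΣDₙΣPₛ) — exactly the pooled-counts
   estimator. When ΣPₙ > ΣPₛ the constraint f ≤ 1 binds and
   α̂ = 1 − ΣDₛ/ΣDₙ.
2. **Cheap refits.** Because ℓ depends on the data only through four sums,
   bootstrap replicates cost microseconds.

`MKAlphaModel.fit()` evaluates a coarse grid (α ∈ [−5, 0.99] × f ∈
(0.01, 1]), adds the closed-form candidate, and polishes with Nelder–Mead
(tolerance 1e-8 on the log-likelihood; ties broken toward smaller |α|).
The returned optimum therefore never falls below any evaluated grid point.
The reported log-likelihood includes the per-gene constant, so it is the
actual profiled Poisson log-likelihood.

Degenerate inputs: genes with all four counts zero carry no information
and are dropped (counted on the results object). ΣDₙ = 0 sends α̂ to −∞
and is clamped at the search floor (−5) and flagged; ΣPₙ = 0 sends f̂ to
its lower bound (1e-6) and α̂ toward 1. α̂ is capped strictly below 1.

### Bootstrap

Genes are the unit of replication: each of B replicates resamples genes
with replacement and refits via the closed form. The 95% CI is the
2.5th/97.5th percentile of the replicate α̂ values; replicates with no
divergence or no polymorphism counts are dropped and counted, with a
warning above 5%. Class comparison resamples each class independently,
forms Δᵣ = α̂ₐ,ᵣ − α̂_b,ᵣ and reports the two-tailed
p = 2·min(frac(Δ ≤ 0), frac(Δ ≥ 0)) capped at 1; passing an empty second
class tests α against zero. B defaults to 1000. Measured operating
characteristics (recomputed by the test suite): CI coverage of a planted
α = 0.3 at n = 2000 genes is ~95% over 200 meta-replicates; the null
rejection rate of the class comparison at the 0.05 level over 500
simulations is within 5% ± 2.5%.

### Per-gene statistics

The neutrality index NI = (Pₙ/Pₛ)/(Dₙ/Dₛ) is undefined (NaN) when any of
Pₛ, Dₙ, Dₛ is zero. The per-gene Fisher exact test is two-sided by the
standard enumeration convention — the sum of probabilities of all tables
with the observed margins whose probability does not exceed the observed
table's (relative guard 1e-7 against floating-point ties); the suite
cross-checks it against an independent implementation.

## Variant handling

Filters run in a fixed order — indel, multiallelic, missingness, quality —
and each site is tallied under the first rule it trips, so tallies plus
retained sites always sum to the input. Quality is a strict lower bound
(exactly 40 is retained); missingness is the fraction of all samples
(ingroup + outgroup) without a complete call, removed strictly above 10%.

The codon classifier substitutes the ALT base into the reference codon of
the gene model (complementing both alleles for minus-strand models, since
VCF alleles are forward-strand) and compares translated amino acids under
the standard code. Stop gain/loss is its own category, counted as
nonsynonymous in MK tables by default (flag to exclude); each SNP in a
multi-variant codon is classified independently against the reference
codon. A REF allele inconsistent with the CDS raises an error naming the
site.

Tabulation is unpolarized (one outgroup cannot polarize): a site
segregating in the ingroup increments Pₙ/Pₛ; a site monomorphic in the
ingroup with a confidently homozygous, different outgroup allele
increments Dₙ/Dₛ; a site both polymorphic and divergent counts as
polymorphism only (the conservative standard treatment); a heterozygous or
missing outgroup contributes no divergence.

## Phylostratigraphy

A transcript's age is the oldest stratum (rank 1 = cellular organisms)
containing ≥1 hit with E-value strictly below the threshold (default
1e-5); no passing hit places it in the youngest, species-specific stratum.
Hits to the focal species itself are ignored (no age information). Genes
take the rank of their longest isoform after excluding proteins shorter
than 30 aa; length ties break toward the oldest rank (configurable to
first-listed); genes with no isoform ≥ 30 aa are reported unassigned.

The shipped lineage is the 19-stratum pharaoh-ant path from cellular
organisms to *Monomorium pharaonis*, as an editable TSV (rank, name,
taxon ids); hit tables must carry subject taxon ids resolvable to exactly
one stratum. The default 19→6 condensation (cellular organisms,
eukaryotes, bilaterian animals, insects, hymenopterans, ants) places the
boundaries at Eukaryota, Metazoa, Arthropoda, Hymenoptera and Formicidae;
the exact interior boundaries are a convention and user-overridable — the
map only needs to be surjective and order-preserving, which is validated
by tests. Raising the E-value threshold is provably monotone (assignments
can only move older), and the sensitivity routine reports per-gene ranks
under 1e-5 and 1e-1 plus the agreement fraction.

## Class statistics

The age GLM regresses the positive-integer stratum value (condensed
category index 1–6, or raw rank) on a two-level class indicator with a
log-link Poisson family via IRLS. Treating an ordinal stratum as a count
is a deliberate approximation — it compares means on a multiplicative
scale; both raw and condensed responses give the same coefficient sign
under monotone age shifts. Pearson dispersion φ = X²/df is always
reported; when φ > 1.2 (configurable; the choice of switch point is a
convention) the reported SE/z are quasi-Poisson (SE·√φ). Both SE flavours
are kept on the result.

Contingency analysis uses the omnibus chi-square without continuity
correction and standardized Pearson residuals
(O−E)/√(E(1−rowshare)(1−colshare)), flagged at |r| > 2 (≈ p < 0.05) and
|r| > 4 (≈ p < 0.001); the cell table includes mosaic-ready areas.

GO over-representation is the upper-tail hypergeometric probability of
k annotated genes in a set of n from a background of N with K annotated;
raw p-values are compared to the 0.05 cutoff by default because the
upstream analyses this mirrors apply no multiple-testing correction; a
Benjamini–Hochberg option exists but is off.

## Synthetic data and study conditions

Generators are pure functions of their configuration including the seed.
The MK generator is the estimation model run forward, with θᵢ, λᵢ drawn
log-normally around configurable means (log-scale SD `intensity_dispersion`)
— a generative choice made for realistic across-locus overdispersion; no
empirical per-locus distribution is claimed. Defaults θ̄ = 8, λ̄ = 16,
dispersion 0.6 are plausible for ~20 resequenced genomes against a
congeneric outgroup.

The default study bundle plants the class structure the analysis is built
to detect: α = 0.31 / 0.15 / 0.21 and constraint f = 0.20 / 0.30 / 0.25
for reproductive / worker / NDE genes (worker genes least constrained),
class sizes 5232 / 7392 / 5376 so the two-class age GLM has 12622
residual degrees of freedom, and condensed-category age distributions
shifted young for worker genes (worker over-represented in the four
youngest categories, reproductive in eukaryotes; mean-category ratio
≈ 1.13). Expression counts are negative-binomial with a common dispersion
and a planted fraction of caste-affected genes split evenly in direction;
FPKM derives from simulated gene lengths and library sizes. Hit tables
give every aged gene a strongly passing hit in its true stratum (plus
passing hits in younger strata and non-passing decoys), so recovery is
exact by construction; the `frac_marginal` option plants hits one stratum
older with E-values between the strict and liberal thresholds to exercise
the sensitivity analysis.

What the simulations do not emulate: linkage between sites, segregating
slightly-deleterious DFEs (the generator's α is exact, not an asymptotic
limit), phylogenetic structure in hit E-values, library-level technical
artefacts, and the DE fitting step itself (class labels are planted or
ingested, never re-estimated — differential expression is a solved,
external step). Passing tests therefore certify the estimators and
plumbing under the stated models, not robustness to model violation on
real data.

## Pipeline

`run_pipeline` uses a single class table across all report sections, seeds
every stochastic step from one master seed (all recorded in the
provenance block), and is byte-identical across reruns with the same
config. The expression filter removes a gene only when, in each of the
three tissues separately, at least half (inclusive) of that tissue's
samples fall below FPKM 1; a pooled reading is available behind a flag.
DE labels are taken from a results table at FDR < 0.05 by default (the
threshold is an assumption, configurable).

## Problem sizes

The test suite runs study-scale fits (5000–18000 genes) because fits cost
milliseconds; bootstrap calibration uses 500 null simulations at 1000
genes per class with B = 200, and CI coverage 200 meta-replicates at
n = 2000 with B = 1000 — sizes chosen to keep Monte-Carlo error on the
checked rates below the asserted bands.

## Known limitations

- α is a class-level aggregate; per-gene α is not identifiable at typical
  counts, and the per-gene view is limited to NI and the Fisher test.
- The model omits MKtest-style distributions of selection coefficients
  (γ); only the neutral-fraction constraint f is estimated.
- Ordinal-as-Poisson in the age GLM and the fixed 1.2 dispersion switch
  are conventions, stated above.
- One outgroup means unpolarized counts; divergence is assigned to neither
  lineage.
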