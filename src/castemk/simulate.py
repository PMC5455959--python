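"""Synthetic data with planted truth for every pipeline stage.

The generators draw from the same statistical models the estimators assume,
so planted parameters are recoverable and every downstream stage is
testable without external data:

* :func:`sim_mk_counts` — per-gene MK quadruples from the shared-(alpha, f)
  Poisson model with log-normal per-gene intensities,
* :func:`sim_expression` — negative-binomial counts (and derived FPKM) with
  a planted fraction of caste-affected genes,
* :func:`sim_blast_hits` — homology-hit tables whose oldest passing stratum
  equals a planted age,
* :func:`sim_cds_variants` — random CDS models with SNVs of known
  synonymous/nonsynonymous status,
* :func:`simulate_study` — the full study bundle (three gene classes with
  class-specific alpha/f, ages, hits, GO annotations) under the default
  study conditions.

Every generator is a pure function of its arguments including the seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .phylostrat import CONDENSED_CATEGORIES, Lineage, default_condensation
from .variants import CodingGeneModel, VariantSite, classify_effect

__all__ = [
    "MKSimConfig",
    "SyntheticTruth",
    "StudyConfig",
    "sim_mk_counts",
    "sim_expression",
    "sim_blast_hits",
    "sim_cds_variants",
    "sim_go_annotations",
    "simulate_study",
    "DEFAULT_CLASS_SIZES",
    "DEFAULT_ALPHA",
    "DEFAULT_F",
    "DEFAULT_CATEGORY_PROBS",
]

N_INGROUP = 22  # resequenced focal-species genomes
OUTGROUP_SAMPLE = "outgroup"

# Study conditions: per-class planted adaptive proportion (the printed
# point estimates; NDE takes the genome-wide value), selective constraint
# (worker least constrained), class sizes (reproductive + worker chosen so
# the two-class GLM has 12622 residual df), and condensed-category age
# distributions (worker shifted young, reproductive enriched old).
DEFAULT_ALPHA = {"reproductive": 0.31, "worker": 0.15, "NDE": 0.21}
DEFAULT_F = {"reproductive": 0.20, "worker": 0.30, "NDE": 0.25}
DEFAULT_CLASS_SIZES = {"reproductive": 5232, "worker": 7392, "NDE": 5376}
DEFAULT_CATEGORY_PROBS = {
    "reproductive": (0.27, 0.40, 0.14, 0.085, 0.06, 0.045),
    "worker": (0.27, 0.29, 0.155, 0.11, 0.09, 0.085),
    "NDE": (0.27, 0.34, 0.15, 0.10, 0.08, 0.06),
}
DEFAULT_THETA_MEAN = 8.0
DEFAULT_LAMBDA_MEAN = 16.0
DEFAULT_DISPERSION = 0.6

CLASS_LABELS = ("reproductive", "worker", "NDE")


@dataclass(frozen=True)
class MKSimConfig:
    """Configuration of the forward MK-count model for one gene class.

    ``alpha_true`` may be negative (an excess of segregating mildly
    deleterious nonsynonymous variants pushes the estimand below zero);
    ``f_true`` is the neutral fraction of nonsynonymous mutations, in
    (0, 1].  ``theta_mean``/``lambda_mean`` are mean synonymous
    polymorphism/divergence counts per gene; ``intensity_dispersion`` is
    the log-scale SD of the per-gene intensities.
    """

    n_genes: int
    alpha_true: float
    f_true: float
    theta_mean: float = DEFAULT_THETA_MEAN
    lambda_mean: float = DEFAULT_LAMBDA_MEAN
    intensity_dispersion: float = DEFAULT_DISPERSION
    seed: int = 0

    def __post_init__(self):
        if self.n_genes < 1:
            raise ValueError("n_genes must be >= 1")
        if self.alpha_true >= 1:
            raise ValueError("alpha_true must be < 1")
        if not (0 < self.f_true <= 1):
            raise ValueError("f_true must lie in (0, 1]")
        if self.theta_mean <= 0 or self.lambda_mean <= 0:
            raise ValueError("intensity means must be positive")
        if self.intensity_dispersion < 0:
            raise ValueError("intensity_dispersion must be nonnegative")


@dataclass
class SyntheticTruth:
    """Planted parameters emitted alongside simulated data.

    ``per_gene`` carries one row per gene (intensities, class label, true
    stratum rank — whichever the generator planted); ``globals_`` the
    class-level parameters.
    """

    per_gene: pd.DataFrame
    globals_: dict = field(default_factory=dict)

    def to_json(self, path) -> None:
        payload = {
            "globals": self.globals_,
            "per_gene": self.per_gene.to_dict(orient="records"),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, default=_jsonable)


def _jsonable(x):
    if isinstance(x, (np.integer,)):
        return int(x)
    if isinstance(x, (np.floating,)):
        return float(x)
    raise TypeError(f"not JSON-serialisable: {type(x)}")


def _lognormal_means(rng, mean, sigma, n):
    """Log-normal draws with expectation ``mean`` and log-scale SD sigma."""
    if sigma == 0:
        return np.full(n, float(mean))
    mu = np.log(mean) - 0.5 * sigma**2
    return rng.lognormal(mu, sigma, n)


def sim_mk_counts(cfg: MKSimConfig, gene_prefix: str = "g"):
    """Draw per-gene MK count quadruples from the forward model.

    Per gene i: Ps ~ Poisson(theta_i), Pn ~ Poisson(f * theta_i),
    Ds ~ Poisson(lambda_i), Dn ~ Poisson(f * lambda_i / (1 - alpha)), with
    theta_i, lambda_i log-normal around the configured means.

    Returns ``(counts_df, SyntheticTruth)``.
    """
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_genes
    theta = _lognormal_means(rng, cfg.theta_mean, cfg.intensity_dispersion, n)
    lam = _lognormal_means(rng, cfg.lambda_mean, cfg.intensity_dispersion, n)
    f, a = cfg.f_true, cfg.alpha_true
    ps = rng.poisson(theta)
    pn = rng.poisson(f * theta)
    ds = rng.poisson(lam)
    dn = rng.poisson(f * lam / (1.0 - a))
    gene_ids = [f"{gene_prefix}{i:05d}" for i in range(n)]
    counts = pd.DataFrame(
        {"gene_id": gene_ids, "Pn": pn, "Ps": ps, "Dn": dn, "Ds": ds}
    )
    truth = SyntheticTruth(
        per_gene=pd.DataFrame(
            {"gene_id": gene_ids, "theta_i": theta, "lambda_i": lam}
        ),
        globals_={"alpha_true": a, "f_true": f, "seed": cfg.seed},
    )
    return counts, truth


def sim_expression(n_genes: int, n_samples_per_group: int, frac_de: float,
                   effect_log2fc: float, nb_dispersion: float, seed: int = 0):
    """Negative-binomial expression counts with planted caste effects.

    Two sample groups (reproductive, worker).  A fraction ``frac_de`` of
    genes receives the full ``effect_log2fc`` between group means, split
    evenly between reproductive- and worker-upregulated.  FPKM is derived
    from the counts via simulated gene lengths and per-library totals.

    Returns ``(counts_df, fpkm_df, truth)`` where truth labels every gene
    reproductive / worker / NDE.
    """
    if not (0 <= frac_de <= 1):
        raise ValueError("frac_de must lie in [0, 1]")
    if nb_dispersion <= 0:
        raise ValueError("nb_dispersion must be positive")
    rng = np.random.default_rng(seed)
    genes = [f"g{i:05d}" for i in range(n_genes)]
    base = _lognormal_means(rng, 200.0, 1.2, n_genes)
    n_de = int(round(frac_de * n_genes))
    labels = np.array(["NDE"] * n_genes, dtype=object)
    de_idx = rng.choice(n_genes, size=n_de, replace=False)
    up_rep = rng.random(n_de) < 0.5
    labels[de_idx[up_rep]] = "reproductive"
    labels[de_idx[~up_rep]] = "worker"
    half = 2.0 ** (effect_log2fc / 2.0)
    mean_rep = base.copy()
    mean_wrk = base.copy()
    mean_rep[labels == "reproductive"] *= half
    mean_wrk[labels == "reproductive"] /= half
    mean_wrk[labels == "worker"] *= half
    mean_rep[labels == "worker"] /= half
    r = 1.0 / nb_dispersion  # NB size parameter

    def _draw(mean_vec):
        p = r / (r + mean_vec[:, None])
        return rng.negative_binomial(r, p, size=(n_genes, n_samples_per_group))

    counts = np.hstack([_draw(mean_rep), _draw(mean_wrk)])
    samples = [f"rep_{i}" for i in range(n_samples_per_group)] + [
        f"wrk_{i}" for i in range(n_samples_per_group)
    ]
    counts_df = pd.DataFrame(counts, index=genes, columns=samples)
    lengths_kb = _lognormal_means(rng, 1.5, 0.4, n_genes)
    lib_millions = counts_df.sum(axis=0).to_numpy() / 1e6
    with np.errstate(divide="ignore", invalid="ignore"):
        fpkm = counts / (lengths_kb[:, None] * lib_millions[None, :])
    fpkm_df = pd.DataFrame(np.nan_to_num(fpkm), index=genes, columns=samples)
    truth = SyntheticTruth(
        per_gene=pd.DataFrame(
            {"gene_id": genes, "class_label": labels, "base_mean": base,
             "length_kb": lengths_kb}
        ),
        globals_={
            "frac_de": frac_de, "effect_log2fc": effect_log2fc,
            "nb_dispersion": nb_dispersion, "seed": seed,
        },
    )
    return counts_df, fpkm_df, truth


def sim_blast_hits(gene_ages: Mapping[str, int] | Sequence[int],
                   lineage: Lineage, evalue_pass: float = 1e-5,
                   seed: int = 0, frac_marginal: float = 0.0) -> pd.DataFrame:
    """Outfmt-6-like hit tables from which planted ages are recoverable.

    Each gene with a planted rank older than the focal species receives one
    hit in its true stratum with E-value well below ``evalue_pass``, up to
    two passing hits in younger strata, and decoy hits with E-values above
    any sensible threshold.  Species-specific genes receive only decoys
    (no passing hit), so assignment falls through to the youngest rank.
    ``frac_marginal`` plants, for that fraction of aged genes, an extra hit
    one stratum older with E-value between 1e-5 and 1e-1, exercising the
    liberal-threshold sensitivity analysis.
    """
    if isinstance(gene_ages, Mapping):
        items = list(gene_ages.items())
    else:
        items = [(f"g{i:05d}", r) for i, r in enumerate(gene_ages)]
    youngest = lineage.youngest_rank
    rows = []
    rng = np.random.default_rng(seed)

    def _taxon(rank):
        return sorted(lineage.strata[rank - 1].taxon_ids)[0]

    for gene, rank in items:
        rank = int(rank)
        if not (1 <= rank <= youngest):
            raise ValueError(f"planted rank {rank} outside lineage for {gene!r}")
        q = f"{gene}-RA"
        if rank < youngest:
            strata = [rank] + list(
                rng.choice(np.arange(rank + 1, youngest), size=min(2, youngest - 1 - rank), replace=False)
            ) if rank + 1 < youngest else [rank]
            for s in strata:
                rows.append(_hit_row(q, int(s), 10.0 ** -rng.uniform(6.5, 40.0), rng, _taxon))
            if frac_marginal > 0 and rank > 1 and rng.random() < frac_marginal:
                rows.append(_hit_row(q, rank - 1, 10.0 ** -rng.uniform(1.5, 4.5), rng, _taxon))
        # decoys: never pass any threshold down to 1e-1
        for _ in range(rng.integers(0, 3)):
            s = int(rng.integers(1, youngest))
            rows.append(_hit_row(q, s, float(rng.uniform(0.2, 5.0)), rng, _taxon))
    return pd.DataFrame(
        rows,
        columns=["qseqid", "sseqid", "pident", "length", "evalue", "bitscore", "staxid"],
    )


def _hit_row(q, stratum_rank, evalue, rng, taxon_of):
    return {
        "qseqid": q,
        "sseqid": f"subj_{stratum_rank}_{rng.integers(1e6)}",
        "pident": round(float(rng.uniform(30, 99)), 2),
        "length": int(rng.integers(40, 600)),
        "evalue": evalue,
        "bitscore": round(float(rng.uniform(40, 800)), 1),
        "staxid": taxon_of(stratum_rank),
    }


# ---------------------------------------------------------------------------
# CDS + variant fixtures
# ---------------------------------------------------------------------------

_STOPS = ("TAA", "TAG", "TGA")
_CODONS = [
    a + b + c
    for a in "ACGT" for b in "ACGT" for c in "ACGT"
    if a + b + c not in _STOPS
]


def sim_cds_variants(n_genes: int, codons_per_gene: int, n_poly: int,
                     n_div: int, seed: int = 0):
    """Random coding models with SNVs of known effect.

    Each gene is a single-exon CDS (ATG + stop-free interior + TAA) on its
    own contig, alternating plus/minus strand so strand handling is
    exercised.  ``n_poly`` segregating and ``n_div`` fixed-difference SNVs
    are planted per gene at distinct interior positions; the true effect of
    each is computed by translating the reference vs alternate codon.

    Returns ``(models, contig_seqs, sites, truth_df)``; truth rows carry
    contig, position, gene_id, kind ('poly'|'div') and effect_true.
    """
    if min(n_genes, codons_per_gene) < 1 or min(n_poly, n_div) < 0:
        raise ValueError("sizes must be positive (variant counts nonnegative)")
    if codons_per_gene < 4:
        raise ValueError("need at least 4 codons per gene")
    n_sites_needed = n_poly + n_div
    interior_len = 3 * (codons_per_gene - 2)
    if n_sites_needed > interior_len:
        raise ValueError("more variants requested than interior positions")
    rng = np.random.default_rng(seed)
    models, contigs, sites, truth_rows = [], {}, [], []
    ingroup = [f"mph_{i:02d}" for i in range(N_INGROUP)]
    for gi in range(n_genes):
        gene = f"g{gi:05d}"
        tx = f"{gene}-RA"
        contig = f"ctg{gi:05d}"
        strand = "+" if gi % 2 == 0 else "-"
        interior = "".join(rng.choice(_CODONS, size=codons_per_gene - 2))
        cds = "ATG" + interior + "TAA"
        genomic = cds if strand == "+" else _revcomp(cds)
        contigs[contig] = genomic
        model = CodingGeneModel(
            gene_id=gene, transcript_id=tx, contig=contig,
            exons=[(1, len(cds))], strand=strand, cds=cds,
        )
        models.append(model)
        # distinct CDS indices within the interior (codons 2..n-1)
        cds_positions = rng.choice(
            np.arange(3, 3 + interior_len), size=n_sites_needed, replace=False
        )
        for k, cds_idx in enumerate(cds_positions):
            kind = "poly" if k < n_poly else "div"
            ref_cds = cds[cds_idx]
            alt_cds = rng.choice([b for b in "ACGT" if b != ref_cds])
            # genomic coordinates / alleles
            if strand == "+":
                pos = int(cds_idx) + 1
                ref_g, alt_g = ref_cds, alt_cds
            else:
                pos = len(cds) - int(cds_idx)
                ref_g, alt_g = _revcomp(ref_cds), _revcomp(alt_cds)
            genotypes = {}
            if kind == "poly":
                n_carriers = int(rng.integers(1, N_INGROUP))
                carriers = set(rng.choice(N_INGROUP, size=n_carriers, replace=False))
                for i, s in enumerate(ingroup):
                    genotypes[s] = (1, 1) if i in carriers else (0, 0)
                # ensure segregation (some hom-ref remains)
                genotypes[ingroup[0]] = (0, 0)
                genotypes[ingroup[1]] = (1, 1)
                genotypes[OUTGROUP_SAMPLE] = (0, 0)
            else:
                for s in ingroup:
                    genotypes[s] = (0, 0)
                genotypes[OUTGROUP_SAMPLE] = (1, 1)
            site = VariantSite(
                contig=contig, position=pos, ref=ref_g, alts=(alt_g,),
                quality=float(rng.uniform(50, 500)), genotypes=genotypes,
            )
            sites.append(site)
            codon_start = (int(cds_idx) // 3) * 3
            codon = cds[codon_start:codon_start + 3]
            off = int(cds_idx) - codon_start
            alt_codon = codon[:off] + alt_cds + codon[off + 1:]
            truth_rows.append(
                {
                    "contig": contig, "position": pos, "gene_id": gene,
                    "kind": kind,
                    "effect_true": _true_effect(codon, alt_codon),
                }
            )
    truth = pd.DataFrame(truth_rows)
    return models, contigs, sites, truth


def _revcomp(s: str) -> str:
    return s.translate(str.maketrans("ACGT", "TGCA"))[::-1]


def _true_effect(codon: str, alt_codon: str) -> str:
    from Bio.Seq import Seq

    aa_ref = str(Seq(codon).translate())
    aa_alt = str(Seq(alt_codon).translate())
    if aa_ref == aa_alt:
        return "synonymous"
    if "*" in (aa_ref, aa_alt):
        return "stop_affected"
    return "nonsynonymous"


def sim_go_annotations(labels: pd.Series, categories: pd.Series,
                       n_terms: int = 25, seed: int = 0) -> pd.DataFrame:
    """Gene -> GO term table with one planted enrichment.

    Background terms are assigned at random (0-4 per gene); the term
    GO:0007606 ("sensory perception of chemical stimulus") is planted at
    elevated rate among worker-upregulated genes in the two youngest
    condensed categories, mimicking chemosensory enrichment of young
    worker-associated genes.
    """
    rng = np.random.default_rng(seed)
    terms = [f"GO:{7000000 + i}" for i in range(n_terms)]
    rows = []
    young = set(CONDENSED_CATEGORIES[-2:])
    for gene, label, cat in zip(labels.index, labels.values, categories.values):
        for t in rng.choice(terms, size=rng.integers(0, 5), replace=False):
            rows.append({"gene_id": gene, "term_id": t, "term_name": f"term {t[-2:]}"})
        p_chem = 0.30 if (label == "worker" and cat in young) else 0.04
        if rng.random() < p_chem:
            rows.append(
                {"gene_id": gene, "term_id": "GO:0007606",
                 "term_name": "sensory perception of chemical stimulus"}
            )
    return pd.DataFrame(rows, columns=["gene_id", "term_id", "term_name"])


# ---------------------------------------------------------------------------
# full study bundle
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class StudyConfig:
    """Study-scale simulation: three classes with class-specific (alpha, f).

    Defaults are the study conditions documented in the methods note:
    planted alpha of 0.31 / 0.15 / 0.21 for reproductive / worker / NDE
    genes, worker genes least constrained, class sizes giving the
    two-class GLM 12622 residual df, and age distributions shifted young
    for worker genes.
    """

    class_sizes: Mapping[str, int] = field(
        default_factory=lambda: dict(DEFAULT_CLASS_SIZES)
    )
    alpha: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_ALPHA))
    f: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_F))
    category_probs: Mapping[str, Sequence[float]] = field(
        default_factory=lambda: dict(DEFAULT_CATEGORY_PROBS)
    )
    theta_mean: float = DEFAULT_THETA_MEAN
    lambda_mean: float = DEFAULT_LAMBDA_MEAN
    intensity_dispersion: float = DEFAULT_DISPERSION
    seed: int = 0


@dataclass
class StudyBundle:
    """Everything the pipeline consumes, plus the planted truth."""

    counts: pd.DataFrame        # gene_id, Pn, Ps, Dn, Ds
    classes: pd.Series          # gene_id -> label
    ages: pd.DataFrame          # gene_id, stratum_rank, condensed_category
    hits: pd.DataFrame          # outfmt-6-like
    isoforms: dict              # gene -> [(transcript, aa_len)]
    go: pd.DataFrame            # gene_id, term_id, term_name
    truth: SyntheticTruth


def simulate_study(cfg: StudyConfig = StudyConfig(),
                   lineage: Optional[Lineage] = None) -> StudyBundle:
    """Simulate the full study bundle under the configured conditions."""
    if lineage is None:
        lineage = Lineage.default()
    cmap = default_condensation(lineage)
    rng = np.random.default_rng(cfg.seed)
    counts_parts, truth_parts = [], []
    labels, ranks = {}, {}
    # ranks within each condensed category are drawn uniformly
    cat_ranks = {}
    for r, cat in cmap.items():
        cat_ranks.setdefault(cat, []).append(r)
    offset = 0
    for label in CLASS_LABELS:
        n = int(cfg.class_sizes[label])
        sub = MKSimConfig(
            n_genes=n, alpha_true=float(cfg.alpha[label]),
            f_true=float(cfg.f[label]), theta_mean=cfg.theta_mean,
            lambda_mean=cfg.lambda_mean,
            intensity_dispersion=cfg.intensity_dispersion,
            seed=int(rng.integers(2**31)),
        )
        counts, truth = sim_mk_counts(sub, gene_prefix=f"{label[:3]}_g")
        counts_parts.append(counts)
        probs = np.asarray(cfg.category_probs[label], dtype=float)
        cats = rng.choice(len(CONDENSED_CATEGORIES), size=n, p=probs / probs.sum())
        for gid, ci in zip(counts["gene_id"], cats):
            labels[gid] = label
            ranks[gid] = int(rng.choice(cat_ranks[CONDENSED_CATEGORIES[ci]]))
        tp = truth.per_gene.assign(class_label=label)
        truth_parts.append(tp)
        offset += n
    counts = pd.concat(counts_parts, ignore_index=True)
    classes = pd.Series(labels, name="class_label")
    per_gene = pd.concat(truth_parts, ignore_index=True)
    per_gene["true_stratum_rank"] = per_gene["gene_id"].map(ranks)
    hits = sim_blast_hits(ranks, lineage, seed=int(rng.integers(2**31)))
    isoforms = {
        g: [(f"{g}-RA", int(rng.integers(60, 900)))] for g in counts["gene_id"]
    }
    ages_rows = []
    for g in counts["gene_id"]:
        r = ranks[g]
        ages_rows.append(
            {"gene_id": g, "stratum_rank": r, "condensed_category": cmap[r]}
        )
    ages = pd.DataFrame(ages_rows)
    cats = ages.set_index("gene_id")["condensed_category"]
    go = sim_go_annotations(
        classes, cats.loc[classes.index], seed=int(rng.integers(2**31))
    )
    truth = SyntheticTruth(
        per_gene=per_gene,
        globals_={
            "alpha_true": dict(cfg.alpha), "f_true": dict(cfg.f),
            "class_sizes": {k: int(v) for k, v in cfg.class_sizes.items()},
            "seed": cfg.seed,
        },
    )
    return StudyBundle(
        counts=counts, classes=classes, ages=ages, hits=hits,
        isoforms=isoforms, go=go, truth=truth,
    )


# ---------------------------------------------------------------------------
# writers (all plain text)
# ---------------------------------------------------------------------------

def write_counts_tsv(counts: pd.DataFrame, path) -> None:
    counts.to_csv(path, sep="\t", index=False)


def write_hits_tsv(hits: pd.DataFrame, path) -> None:
    hits.to_csv(path, sep="\t", index=False)


def write_fasta(seqs: Mapping[str, str], path) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i:i + 70] + "\n")


def write_vcf(sites: Sequence[VariantSite], contig_lengths: Mapping[str, int],
              path) -> None:
    """Minimal VCF v4.2 with GT-only genotype columns."""
    samples = list(sites[0].genotypes) if sites else []
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for c, ln in contig_lengths.items():
            fh.write(f"##contig=<ID={c},length={ln}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(samples) + "\n")
        for s in sorted(sites, key=lambda x: (x.contig, x.position)):
            gts = []
            for name in samples:
                gt = s.genotypes.get(name)
                gts.append("./." if gt is None else "/".join(str(a) for a in gt))
            fh.write(
                f"{s.contig}\t{s.position}\t.\t{s.ref}\t{','.join(s.alts)}\t"
                f"{s.quality:.1f}\tPASS\t.\tGT\t" + "\t".join(gts) + "\n"
            )


def write_gff_lite(models, path) -> None:
    rows = []
    for m in models:
        for start, end in m.exons:
            rows.append(
                {"gene_id": m.gene_id, "transcript_id": m.transcript_id,
                 "contig": m.contig, "start": start, "end": end,
                 "strand": m.strand}
            )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
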