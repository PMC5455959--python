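"""Variant site filtering, synonymous/nonsynonymous classification, MK tables.

Sites arrive as VCF-style records with genotypes for an ingroup panel plus a
single outgroup sample.  Filtering applies, in order: indel removal,
multiallelic removal, missing-data fraction, site quality.  Classification
substitutes the alternate allele into the reference codon of a coding gene
model (strand-aware) and compares the translated amino acids.  Aggregation
produces the per-gene (Pn, Ps, Dn, Ds) quadruples consumed by the alpha
estimators: a site segregating in the ingroup counts as polymorphism; a site
monomorphic in the ingroup whose allele differs from a confidently called
homozygous outgroup counts as divergence; a site that is both polymorphic
and divergent counts as polymorphism only.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd
from Bio.Data.CodonTable import standard_dna_table
from Bio.Seq import Seq

__all__ = [
    "VariantSite",
    "CodingGeneModel",
    "ClassifiedSite",
    "FilterTally",
    "Effect",
    "filter_sites",
    "classify_effect",
    "tabulate_mk",
    "read_vcf",
    "read_gene_models",
    "ReferenceMismatchError",
    "MalformedGenotypeError",
]

_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")
_NUCS = frozenset("ACGT")


class ReferenceMismatchError(ValueError):
    """CDS sequence disagrees with a site's REF allele."""


class MalformedGenotypeError(ValueError):
    """Genotype call could not be interpreted; message carries coordinates."""


class Effect:
    SYNONYMOUS = "synonymous"
    NONSYNONYMOUS = "nonsynonymous"
    NONCODING = "noncoding"
    STOP_AFFECTED = "stop_affected"


@dataclass(frozen=True)
class VariantSite:
    """One VCF record: biallelic or not, SNV or not — filtering decides.

    ``genotypes`` maps sample name to a tuple of allele indices
    (0 = REF, 1.. = ALT) or ``None`` for a missing call.
    """

    contig: str
    position: int  # 1-based
    ref: str
    alts: tuple
    quality: float
    genotypes: Mapping[str, Optional[tuple]]

    def __post_init__(self):
        if self.position < 1:
            raise ValueError(f"position must be >= 1, got {self.position}")
        if any(a == self.ref for a in self.alts):
            raise ValueError(
                f"{self.contig}:{self.position}: ALT equals REF"
            )

    @property
    def alt(self) -> str:
        return self.alts[0]

    @property
    def is_indel(self) -> bool:
        alleles = (self.ref, *self.alts)
        return any(len(a) != 1 or a.upper() not in _NUCS for a in alleles)

    @property
    def is_multiallelic(self) -> bool:
        return len(self.alts) > 1

    def missing_fraction(self) -> float:
        gts = list(self.genotypes.values())
        if not gts:
            return 1.0
        n_missing = sum(
            1 for g in gts if g is None or any(a is None for a in g)
        )
        return n_missing / len(gts)


@dataclass
class CodingGeneModel:
    """An in-frame CDS with its genomic mapping.

    ``exons`` are 1-based inclusive (start, end) intervals on the contig in
    ascending genomic order; for minus-strand models the CDS reads from the
    highest genomic coordinate, and ``cds`` is the mRNA-sense sequence.
    """

    gene_id: str
    transcript_id: str
    contig: str
    exons: Sequence[tuple]
    strand: str  # '+' or '-'
    cds: str

    def __post_init__(self):
        self.cds = self.cds.upper()
        if self.strand not in "+-":
            raise ValueError(f"strand must be + or -, got {self.strand!r}")
        if len(self.cds) % 3 != 0:
            raise ValueError(
                f"{self.transcript_id}: CDS length {len(self.cds)} not a multiple of 3"
            )
        span = sum(e - s + 1 for s, e in self.exons)
        if span != len(self.cds):
            raise ValueError(
                f"{self.transcript_id}: exon span {span} != CDS length {len(self.cds)}"
            )
        protein = str(Seq(self.cds).translate())
        if "*" in protein[:-1]:
            raise ValueError(f"{self.transcript_id}: internal stop codon in CDS")

    def cds_index(self, contig: str, position: int) -> Optional[int]:
        """0-based CDS coordinate of a genomic position, or None if outside."""
        if contig != self.contig:
            return None
        offset = 0  # distance from the lowest genomic CDS base
        for start, end in self.exons:
            if start <= position <= end:
                left = offset + (position - start)
                if self.strand == "+":
                    return left
                return len(self.cds) - 1 - left
            offset += end - start + 1
        return None

    @property
    def protein_length(self) -> int:
        aa = len(self.cds) // 3
        return aa - 1 if self.cds[-3:] in ("TAA", "TAG", "TGA") else aa


@dataclass
class FilterTally:
    """Sites removed by each rule, in application order."""

    indel: int = 0
    multiallelic: int = 0
    missingness: int = 0
    quality: int = 0
    retained: int = 0

    @property
    def total_input(self) -> int:
        return self.indel + self.multiallelic + self.missingness + self.quality + self.retained


def filter_sites(sites: Iterable[VariantSite], max_missing: float = 0.10,
                 min_quality: float = 40.0):
    """Apply the site filters in order: indel, multiallelic, missing, quality.

    Quality is a strict lower bound: a site with quality exactly
    ``min_quality`` is retained.  Missingness is the fraction of samples
    (ingroup and outgroup alike) without a complete genotype call; sites
    strictly above ``max_missing`` are removed.

    Returns ``(kept_sites, FilterTally)``.
    """
    kept = []
    tally = FilterTally()
    for site in sites:
        if site.is_indel:
            tally.indel += 1
        elif site.is_multiallelic:
            tally.multiallelic += 1
        elif site.missing_fraction() > max_missing:
            tally.missingness += 1
        elif site.quality < min_quality:
            tally.quality += 1
        else:
            kept.append(site)
            tally.retained += 1
    return kept, tally


def classify_effect(model: CodingGeneModel, site: VariantSite,
                    codon_table=standard_dna_table) -> str:
    """Classify a SNV against a coding model.

    Substitutes the ALT base into the reference codon (complementing for
    minus-strand models, since VCF alleles are on the forward genomic
    strand) and compares translated amino acids.  Stop gain/loss is
    reported as ``stop_affected``; downstream tabulation counts it as
    nonsynonymous by default.
    """
    idx = model.cds_index(site.contig, site.position)
    if idx is None:
        return Effect.NONCODING
    ref = site.ref.upper()
    alt = site.alt.upper()
    if model.strand == "-":
        ref = ref.translate(_COMPLEMENT)
        alt = alt.translate(_COMPLEMENT)
    if model.cds[idx] != ref:
        raise ReferenceMismatchError(
            f"{site.contig}:{site.position}: REF {site.ref!r} inconsistent with "
            f"CDS base {model.cds[idx]!r} of {model.transcript_id} (strand {model.strand})"
        )
    codon_start = (idx // 3) * 3
    codon = model.cds[codon_start:codon_start + 3]
    pos_in_codon = idx - codon_start
    alt_codon = codon[:pos_in_codon] + alt + codon[pos_in_codon + 1:]
    aa_ref = _translate_codon(codon, codon_table)
    aa_alt = _translate_codon(alt_codon, codon_table)
    if aa_ref == aa_alt:
        return Effect.SYNONYMOUS
    if "*" in (aa_ref, aa_alt):
        return Effect.STOP_AFFECTED
    return Effect.NONSYNONYMOUS


def _translate_codon(codon: str, table) -> str:
    if codon in table.stop_codons:
        return "*"
    return table.forward_table[codon]


@dataclass(frozen=True)
class ClassifiedSite:
    """A filtered site with its gene assignment and coding effect."""

    site: VariantSite
    gene_id: str
    effect: str


def _ingroup_outgroup_alleles(site: VariantSite, outgroup_sample: str):
    """Distinct ingroup allele indices and the outgroup's homozygous allele.

    Returns ``(ingroup_alleles, outgroup_allele)``; the outgroup allele is
    None when its call is missing or heterozygous (no confident divergence
    information).
    """
    if outgroup_sample not in site.genotypes:
        raise MalformedGenotypeError(
            f"{site.contig}:{site.position}: outgroup sample "
            f"{outgroup_sample!r} absent from genotypes"
        )
    ingroup = set()
    for sample, gt in site.genotypes.items():
        if sample == outgroup_sample or gt is None:
            continue
        for allele in gt:
            if allele is None:
                continue
            if not isinstance(allele, int) or allele < 0:
                raise MalformedGenotypeError(
                    f"{site.contig}:{site.position}: bad allele {allele!r} "
                    f"for sample {sample!r}"
                )
            ingroup.add(allele)
    og = site.genotypes.get(outgroup_sample)
    out_allele = None
    if og is not None and None not in og and len(set(og)) == 1:
        out_allele = og[0]
    return ingroup, out_allele


def tabulate_mk(classified: Iterable[ClassifiedSite],
                models: Sequence[CodingGeneModel],
                outgroup_sample: str,
                count_stop_affected: bool = True) -> pd.DataFrame:
    """Aggregate classified sites into per-gene MK count quadruples.

    Every gene in ``models`` receives a row, all-zero when no qualifying
    site maps to it.  Each counted site increments exactly one of
    Pn/Ps/Dn/Ds; noncoding sites and sites without ingroup calls or (for
    divergence) a confident outgroup call contribute nothing.
    """
    gene_ids = []
    seen = set()
    for m in models:
        if m.gene_id not in seen:
            seen.add(m.gene_id)
            gene_ids.append(m.gene_id)
    counts = {g: Counter() for g in gene_ids}
    for cs in classified:
        if cs.effect == Effect.NONCODING:
            continue
        if cs.gene_id not in counts:
            raise KeyError(
                f"site {cs.site.contig}:{cs.site.position} assigned to "
                f"unknown gene {cs.gene_id!r}"
            )
        if cs.effect == Effect.STOP_AFFECTED and not count_stop_affected:
            continue
        nonsyn = cs.effect in (Effect.NONSYNONYMOUS, Effect.STOP_AFFECTED)
        ingroup, out_allele = _ingroup_outgroup_alleles(cs.site, outgroup_sample)
        if not ingroup:
            continue
        if len(ingroup) > 1:
            counts[cs.gene_id]["Pn" if nonsyn else "Ps"] += 1
        elif out_allele is not None and out_allele not in ingroup:
            counts[cs.gene_id]["Dn" if nonsyn else "Ds"] += 1
    rows = [
        {"gene_id": g, **{c: counts[g][c] for c in ("Pn", "Ps", "Dn", "Ds")}}
        for g in gene_ids
    ]
    return pd.DataFrame(rows, columns=["gene_id", "Pn", "Ps", "Dn", "Ds"])


# ---------------------------------------------------------------------------
# file readers
# ---------------------------------------------------------------------------

def read_vcf(path) -> list:
    """Read a VCF (plain or bgzipped) into :class:`VariantSite` records."""
    import pysam

    sites = []
    with pysam.VariantFile(str(path)) as vf:
        samples = list(vf.header.samples)
        for rec in vf:
            genotypes = {}
            for s in samples:
                alleles = rec.samples[s].get("GT")
                if alleles is None or all(a is None for a in alleles):
                    genotypes[s] = None
                else:
                    genotypes[s] = tuple(alleles)
            sites.append(
                VariantSite(
                    contig=rec.chrom,
                    position=rec.pos,
                    ref=rec.ref,
                    alts=tuple(rec.alts or ()),
                    quality=float(rec.qual) if rec.qual is not None else 0.0,
                    genotypes=genotypes,
                )
            )
    return sites


def read_gene_models(gff_lite_path, cds_fasta_path) -> list:
    """Build gene models from a GFF3-lite TSV and a CDS FASTA.

    The TSV has columns gene_id, transcript_id, contig, start, end, strand
    (one row per exon, ascending start); the FASTA is keyed by
    transcript_id and holds mRNA-sense CDS sequences.
    """
    from Bio import SeqIO

    cds = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(cds_fasta_path), "fasta")}
    df = pd.read_csv(gff_lite_path, sep="\t")
    models = []
    for (gene, tx), grp in df.groupby(["gene_id", "transcript_id"], sort=False):
        if tx not in cds:
            raise KeyError(f"transcript {tx!r} missing from CDS FASTA")
        grp = grp.sort_values("start")
        models.append(
            CodingGeneModel(
                gene_id=str(gene),
                transcript_id=str(tx),
                contig=str(grp["contig"].iloc[0]),
                exons=[(int(r.start), int(r.end)) for r in grp.itertuples()],
                strand=str(grp["strand"].iloc[0]),
                cds=cds[tx],
            )
        )
    return models
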