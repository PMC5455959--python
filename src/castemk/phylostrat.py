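"""Phylostratigraphic gene-age assignment from homology-hit tables.

Each transcript is aged by the oldest phylostratum (lowest rank; rank 1 =
cellular organisms) containing at least one homology hit with an E-value
strictly below the threshold; transcripts with no passing hit fall into the
youngest, species-specific stratum.  Genes take the age of their longest
protein isoform, with isoforms shorter than 30 amino acids excluded.  The
full lineage (19 strata for the pharaoh ant by default) is condensed into
six analysis categories: cellular organisms, eukaryotes, bilaterian
animals, insects, hymenopterans, ants.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

__all__ = [
    "Phylostratum",
    "Lineage",
    "HitRecord",
    "GeneAge",
    "CONDENSED_CATEGORIES",
    "default_condensation",
    "assign_transcript",
    "assign_all_transcripts",
    "assign_gene",
    "condense",
    "sensitivity_threshold",
    "UnknownTaxonError",
]

DEFAULT_EVALUE = 1e-5
MIN_PROTEIN_AA = 30

CONDENSED_CATEGORIES = (
    "cellular organisms",
    "eukaryotes",
    "bilaterian animals",
    "insects",
    "hymenopterans",
    "ants",
)


class UnknownTaxonError(KeyError):
    """A hit's subject taxon maps to no stratum of the lineage."""


@dataclass(frozen=True)
class Phylostratum:
    rank: int
    name: str
    taxon_ids: frozenset


@dataclass(frozen=True)
class HitRecord:
    query: str
    subject: str
    taxon_id: int
    e_value: float
    bit_score: float = 0.0

    def __post_init__(self):
        if self.e_value < 0:
            raise ValueError("E-value must be nonnegative")


@dataclass(frozen=True)
class GeneAge:
    gene_id: str
    stratum_rank: Optional[int]  # None when no isoform passes the length filter
    condensed_category: Optional[str]
    assigned_from: Optional[str]


class Lineage:
    """Ordered phylostrata, rank 1 (oldest) to the focal species (youngest)."""

    def __init__(self, strata: Sequence[Phylostratum]):
        strata = sorted(strata, key=lambda s: s.rank)
        if [s.rank for s in strata] != list(range(1, len(strata) + 1)):
            raise ValueError("ranks must be consecutive from 1")
        names = [s.name for s in strata]
        if len(set(names)) != len(names):
            raise ValueError("stratum names must be unique")
        self.strata = tuple(strata)
        self._by_taxon = {}
        for s in strata:
            for t in s.taxon_ids:
                if t in self._by_taxon:
                    raise ValueError(f"taxon {t} appears in two strata")
                self._by_taxon[t] = s.rank

    def __len__(self):
        return len(self.strata)

    @property
    def youngest_rank(self) -> int:
        return self.strata[-1].rank

    def rank_of_taxon(self, taxon_id: int) -> int:
        try:
            return self._by_taxon[int(taxon_id)]
        except KeyError:
            raise UnknownTaxonError(
                f"taxon id {taxon_id} not assigned to any stratum"
            ) from None

    def name_of_rank(self, rank: int) -> str:
        return self.strata[rank - 1].name

    # -- constructors -------------------------------------------------------

    @classmethod
    def default(cls) -> "Lineage":
        """The 19-stratum pharaoh-ant lineage shipped with the package."""
        with resources.files("castemk.data").joinpath("lineage_pharaonis.tsv").open() as fh:
            return cls.from_tsv(fh)

    @classmethod
    def from_tsv(cls, path_or_fh) -> "Lineage":
        df = pd.read_csv(path_or_fh, sep="\t")
        return cls(
            [
                Phylostratum(
                    rank=int(r.rank),
                    name=str(r.name),
                    taxon_ids=frozenset(int(t) for t in str(r.taxon_ids).split(";")),
                )
                for r in df.itertuples()
            ]
        )

    @classmethod
    def from_json(cls, path) -> "Lineage":
        with open(path) as fh:
            data = json.load(fh)
        return cls(
            [
                Phylostratum(int(d["rank"]), d["name"], frozenset(d["taxon_ids"]))
                for d in data
            ]
        )


def default_condensation(lineage: Optional[Lineage] = None) -> dict:
    """Default 19 -> 6 order-preserving condensation for the shipped lineage.

    Boundaries: rank 1 alone; Eukaryota-Opisthokonta; Metazoa-Ecdysozoa;
    Arthropoda-Holometabola; Hymenoptera-Aculeata; Formicidae and the focal
    species.  User-overridable by passing any rank -> category mapping to
    :func:`condense`.
    """
    bounds = [(1, 1), (2, 3), (4, 8), (9, 14), (15, 17), (18, 19)]
    cmap = {}
    for (lo, hi), cat in zip(bounds, CONDENSED_CATEGORIES):
        for r in range(lo, hi + 1):
            cmap[r] = cat
    if lineage is not None and len(lineage) != 19:
        raise ValueError(
            "default condensation is defined for the 19-stratum lineage; "
            f"got {len(lineage)} strata"
        )
    return cmap


def condense(rank: int, cmap: Mapping[int, str]) -> str:
    """Condensed category for a stratum rank; raises on unmapped ranks."""
    try:
        return cmap[rank]
    except KeyError:
        raise KeyError(f"rank {rank} missing from condensation map") from None


def assign_transcript(hits: Iterable[HitRecord], lineage: Lineage,
                      threshold: float = DEFAULT_EVALUE,
                      ignore_self: bool = True) -> int:
    """Oldest stratum with a hit below ``threshold`` (strict).

    Falls back to the youngest, species-specific rank when no hit passes.
    Hits to the focal species itself carry no age information and are
    ignored when ``ignore_self`` is set.
    """
    best = lineage.youngest_rank
    found = False
    for h in hits:
        rank = lineage.rank_of_taxon(h.taxon_id)
        if ignore_self and rank == lineage.youngest_rank:
            continue
        if h.e_value < threshold:
            found = True
            best = min(best, rank)
    return best if found else lineage.youngest_rank


def assign_all_transcripts(hits_df: pd.DataFrame, lineage: Lineage,
                           threshold: float = DEFAULT_EVALUE) -> dict:
    """Assign every query in an outfmt-6-like table; returns query -> rank.

    ``hits_df`` needs columns qseqid, evalue, staxid (extra columns are
    ignored).  Queries absent from the table must be handled by the caller
    (they age to the youngest stratum).
    """
    out = {}
    for q, grp in hits_df.groupby("qseqid", sort=False):
        recs = [
            HitRecord(str(q), "", int(t), float(e))
            for t, e in zip(grp["staxid"], grp["evalue"])
        ]
        out[str(q)] = assign_transcript(recs, lineage, threshold)
    return out


def assign_gene(transcript_ranks: Mapping[str, int],
                isoforms: Mapping[str, Sequence[tuple]],
                cmap: Optional[Mapping[int, str]] = None,
                min_aa: int = MIN_PROTEIN_AA,
                tie_break: str = "oldest") -> list:
    """Gene ages from transcript ages via the longest-isoform rule.

    ``isoforms`` maps gene_id to (transcript_id, protein_length_aa) pairs.
    Isoforms shorter than ``min_aa`` are excluded before selection; genes
    left with no isoform are reported unassigned (rank None).  Ties on
    length break toward the oldest rank by default (``tie_break='first'``
    keeps the first-listed isoform).
    """
    if tie_break not in ("oldest", "first"):
        raise ValueError("tie_break must be 'oldest' or 'first'")
    ages = []
    for gene, iso in isoforms.items():
        if not iso:
            raise ValueError(f"gene {gene!r} has no isoforms")
        candidates = [(tx, ln) for tx, ln in iso if ln >= min_aa]
        if not candidates:
            ages.append(GeneAge(gene, None, None, None))
            continue
        max_len = max(ln for _, ln in candidates)
        tied = [tx for tx, ln in candidates if ln == max_len]
        if tie_break == "oldest":
            chosen = min(tied, key=lambda tx: transcript_ranks[tx])
        else:
            chosen = tied[0]
        rank = transcript_ranks[chosen]
        cat = condense(rank, cmap) if cmap is not None else None
        ages.append(GeneAge(gene, rank, cat, chosen))
    return ages


def sensitivity_threshold(hits_df: pd.DataFrame, lineage: Lineage,
                          thresholds: Sequence[float] = (DEFAULT_EVALUE, 1e-1)):
    """Transcript assignments at several E-value thresholds.

    Returns ``(table, agreement)``: the table holds one row per query with a
    rank column per threshold; ``agreement`` is the fraction of queries
    whose rank is identical across all thresholds.  A more liberal
    threshold can only move a query to an older (smaller) rank.
    """
    cols = {}
    queries = None
    for t in thresholds:
        ranks = assign_all_transcripts(hits_df, lineage, threshold=t)
        if queries is None:
            queries = sorted(ranks)
        cols[f"rank_at_{t:g}"] = [ranks[q] for q in queries]
    table = pd.DataFrame({"qseqid": queries, **cols})
    rank_cols = [c for c in table.columns if c != "qseqid"]
    agreement = float((table[rank_cols].nunique(axis=1) == 1).mean()) if len(table) else 1.0
    return table, agreement


def ages_to_frame(ages: Iterable[GeneAge]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "gene_id": a.gene_id,
                "stratum_rank": a.stratum_rank,
                "condensed_category": a.condensed_category,
                "assigned_from": a.assigned_from,
            }
            for a in ages
        ]
    )
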