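"""Site filtering, codon-effect classification, MK tabulation."""

import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from castemk.simulate import sim_cds_variants
from castemk.variants import (
    ClassifiedSite,
    CodingGeneModel,
    Effect,
    ReferenceMismatchError,
    classify_effect,
    filter_sites,
    tabulate_mk,
)

from conftest import make_site

# Independent statement of the standard genetic code: amino acids in
# TCAG-major codon order (T, C, A, G for each of the three positions).
_ORACLE_AA = "FFLLSSSSYY**CC*WLLLLPPPPHHQQRRRRIIIMTTTTNNKKSSRRVVVVAAAADDEEGGGG"
_ORACLE_CODE = {
    a + b + c: _ORACLE_AA[16 * i + 4 * j + k]
    for i, a in enumerate("TCAG")
    for j, b in enumerate("TCAG")
    for k, c in enumerate("TCAG")
}


def _oracle_effect(codon, alt_codon):
    ref_aa, alt_aa = _ORACLE_CODE[codon], _ORACLE_CODE[alt_codon]
    if ref_aa == alt_aa:
        return Effect.SYNONYMOUS
    if "*" in (ref_aa, alt_aa):
        return Effect.STOP_AFFECTED
    return Effect.NONSYNONYMOUS


def model_with_codon(codon, strand="+"):
    """Two-codon CDS 'ATG'+codon; the target codon sits at CDS 4-6."""
    cds = "ATG" + codon
    if strand == "+":
        return CodingGeneModel("g", "g-RA", "ctg", [(1, 6)], "+", cds)
    return CodingGeneModel("g", "g-RA", "ctg", [(1, 6)], "-", cds)


_COMP = str.maketrans("ACGT", "TGCA")


class TestFilterSites:
    def test_indel_removed_and_tallied(self):
        kept, tally = filter_sites([make_site(ref="A", alts=("AT",))])
        assert kept == [] and tally.indel == 1

    def test_multiallelic_removed(self):
        kept, tally = filter_sites([make_site(alts=("G", "C"))])
        assert kept == [] and tally.multiallelic == 1

    def test_quality_boundary_is_strict(self):
        kept, tally = filter_sites(
            [make_site(quality=39.99), make_site(quality=40.0)]
        )
        assert tally.quality == 1 and tally.retained == 1
        assert kept[0].quality == 40.0

    def test_missingness_threshold(self):
        # 3 of 23 samples missing: 0.130 > 0.10 -> removed
        kept, tally = filter_sites([make_site(n_missing=3)])
        assert kept == [] and tally.missingness == 1
        # 2 of 23: 0.087 <= 0.10 -> retained
        kept, tally = filter_sites([make_site(n_missing=2)])
        assert tally.retained == 1

    def test_rules_apply_in_order(self):
        # an indel that is also multiallelic and low quality counts once, as indel
        site = make_site(ref="A", alts=("AT", "C"), quality=1.0)
        _, tally = filter_sites([site])
        assert tally.indel == 1 and tally.multiallelic == 0 and tally.quality == 0

    @given(st.lists(st.tuples(st.sampled_from(["A", "AT"]),
                              st.integers(1, 3),
                              st.floats(0, 100),
                              st.integers(0, 5)), max_size=30))
    @settings(deadline=None, max_examples=50)
    def test_tally_conserves_sites(self, specs):
        sites = []
        for ref, n_alts, qual, n_missing in specs:
            alts = tuple("GCT"[:n_alts])
            sites.append(make_site(ref=ref, alts=alts, quality=qual,
                                   n_missing=n_missing))
        kept, tally = filter_sites(sites)
        assert tally.total_input == len(sites)
        assert tally.retained == len(kept)


class TestClassifyEffect:
    def test_fourfold_site_synonymous(self):
        # GGT -> GGC: Gly -> Gly
        site = make_site(ref="T", position=6)
        site = make_site(ref="T", alts=("C",), position=6)
        assert classify_effect(model_with_codon("GGT"), site) == Effect.SYNONYMOUS

    def test_first_position_nonsynonymous(self):
        # AAA -> GAA: Lys -> Glu
        site = make_site(ref="A", alts=("G",), position=4)
        assert classify_effect(model_with_codon("AAA"), site) == Effect.NONSYNONYMOUS

    def test_stop_gain_reported(self):
        # TAT -> TAA: Tyr -> stop
        site = make_site(ref="T", alts=("A",), position=6)
        assert classify_effect(model_with_codon("TAT"), site) == Effect.STOP_AFFECTED

    def test_noncoding_outside_model(self):
        site = make_site(position=50)
        assert classify_effect(model_with_codon("GGT"), site) == Effect.NONCODING

    def test_reference_mismatch_raises(self):
        site = make_site(ref="C", alts=("G",), position=6)  # CDS has ...GGT
        with pytest.raises(ReferenceMismatchError):
            classify_effect(model_with_codon("GGT"), site)

    def test_minus_strand_uses_complement(self):
        # model CDS ATG GGT on minus strand: genomic = revcomp = ACCCAT;
        # genomic pos 1 ('A') is CDS index 5 ('T'); A->G genomic is T->C in CDS
        m = model_with_codon("GGT", strand="-")
        site = make_site(ref="A", alts=("G",), position=1)
        assert classify_effect(m, site) == Effect.SYNONYMOUS

    def test_exhaustive_codon_enumeration(self):
        """All 576 single-nucleotide codon changes match an independent
        literal statement of the standard genetic code."""
        n = 0
        for codon in _ORACLE_CODE:
            model = model_with_codon(codon)
            for pos in range(3):
                for alt in "ACGT":
                    if alt == codon[pos]:
                        continue
                    site = make_site(ref=codon[pos], alts=(alt,), position=4 + pos)
                    got = classify_effect(model, site)
                    alt_codon = codon[:pos] + alt + codon[pos + 1:]
                    assert got == _oracle_effect(codon, alt_codon), (codon, pos, alt)
                    n += 1
        assert n == 576

    @given(st.sampled_from(sorted(_ORACLE_CODE)), st.integers(0, 2),
           st.sampled_from("ACGT"))
    @settings(deadline=None, max_examples=200)
    def test_ref_alt_swap_preserves_classification(self, codon, pos, alt):
        """Swapping which allele is called REF never changes the effect."""
        if alt == codon[pos]:
            return
        alt_codon = codon[:pos] + alt + codon[pos + 1:]
        fwd = classify_effect(
            model_with_codon(codon),
            make_site(ref=codon[pos], alts=(alt,), position=4 + pos),
        )
        rev = classify_effect(
            model_with_codon(alt_codon),
            make_site(ref=alt, alts=(codon[pos],), position=4 + pos),
        )
        assert fwd == rev


class TestTabulateMK:
    def _classified(self, model, specs):
        out = []
        for effect, kind in specs:
            if kind == "poly":
                site = make_site(ingroup_alt_carriers=5, outgroup_gt=(0, 0))
            else:
                site = make_site(ingroup_alt_carriers=0, outgroup_gt=(1, 1))
            out.append(ClassifiedSite(site, model.gene_id, effect))
        return out

    def test_direct_counts(self):
        m = model_with_codon("GGT")
        specs = (
            [(Effect.NONSYNONYMOUS, "poly")] * 2
            + [(Effect.SYNONYMOUS, "poly")] * 3
            + [(Effect.NONSYNONYMOUS, "div")] * 1
            + [(Effect.SYNONYMOUS, "div")] * 4
        )
        tab = tabulate_mk(self._classified(m, specs), [m], "outgroup")
        row = tab.iloc[0]
        assert (row.Pn, row.Ps, row.Dn, row.Ds) == (2, 3, 1, 4)

    def test_gene_without_sites_gets_zero_row(self):
        m = model_with_codon("GGT")
        tab = tabulate_mk([], [m], "outgroup")
        assert (tab.iloc[0][["Pn", "Ps", "Dn", "Ds"]] == 0).all()

    def test_polymorphic_and_divergent_counts_once_as_polymorphism(self):
        m = model_with_codon("GGT")
        site = make_site(ingroup_alt_carriers=5, outgroup_gt=(1, 1))
        tab = tabulate_mk([ClassifiedSite(site, m.gene_id, Effect.SYNONYMOUS)],
                          [m], "outgroup")
        assert tab.iloc[0].Ps == 1 and tab.iloc[0].Ds == 0

    def test_missing_outgroup_excluded_from_divergence(self):
        m = model_with_codon("GGT")
        site = make_site(ingroup_alt_carriers=0, outgroup_gt=None)
        tab = tabulate_mk([ClassifiedSite(site, m.gene_id, Effect.SYNONYMOUS)],
                          [m], "outgroup")
        assert (tab.iloc[0][["Pn", "Ps", "Dn", "Ds"]] == 0).all()

    def test_stop_affected_counts_nonsynonymous_by_default(self):
        m = model_with_codon("GGT")
        cs = self._classified(m, [(Effect.STOP_AFFECTED, "poly")])
        assert tabulate_mk(cs, [m], "outgroup").iloc[0].Pn == 1
        assert tabulate_mk(cs, [m], "outgroup",
                           count_stop_affected=False).iloc[0].Pn == 0

    def test_unknown_gene_raises(self):
        m = model_with_codon("GGT")
        cs = [ClassifiedSite(make_site(), "nope", Effect.SYNONYMOUS)]
        with pytest.raises(KeyError, match="nope"):
            tabulate_mk(cs, [m], "outgroup")

    def test_round_trip_from_simulated_cds(self):
        """Classification + tabulation reproduce the generator's planted
        per-gene counts exactly, on both strands."""
        models, _, sites, truth = sim_cds_variants(25, 60, 4, 3, seed=17)
        by_contig = {m.contig: m for m in models}
        classified = [
            ClassifiedSite(s, by_contig[s.contig].gene_id,
                           classify_effect(by_contig[s.contig], s))
            for s in sites
        ]
        for cs, (_, t) in zip(classified, truth.iterrows()):
            assert cs.effect == t.effect_true
        tab = tabulate_mk(classified, models, "outgroup").set_index("gene_id")
        truth["nonsyn"] = truth.effect_true != "synonymous"
        for gene, grp in truth.groupby("gene_id"):
            row = tab.loc[gene]
            assert row.Pn == ((grp.kind == "poly") & grp.nonsyn).sum()
            assert row.Ps == ((grp.kind == "poly") & ~grp.nonsyn).sum()
            assert row.Dn == ((grp.kind == "div") & grp.nonsyn).sum()
            assert row.Ds == ((grp.kind == "div") & ~grp.nonsyn).sum()
        # each counted site increments exactly one cell
        assert tab.to_numpy().sum() == len(truth)
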