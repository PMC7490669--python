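"""Pair classification, pileup policies, zygosity bands and the decision table."""

import itertools

import pytest

from scaffoldcall.align import PairPlacement, Placement, align_pair
from scaffoldcall.genotype import (
    CallConfig,
    CallLabel,
    GenotypeCall,
    PairClass,
    PairResult,
    PileupCounts,
    Policy,
    SiteSignature,
    Zygosity,
    call_pairs,
    call_sample,
    call_single_reference,
    call_zygosity,
    classify_pair,
    expected_call,
    pileup_site,
    resolve_genotype,
)
from scaffoldcall.reference_model import Site
from scaffoldcall.simulate import ReadPair, make_haplotypes, revcomp, write_fastq


def _placement(role, start, score, cigar, seq, qual=None, strand="+"):
    return Placement(
        scaffold=role, start=start, score=score, cigar=cigar, strand=strand,
        seq=seq, qual=qual if qual is not None else "I" * len(seq),
    )


def _pp(role, score):
    plc = _placement(role, 1, score, (("M", 10),), "A" * 10)
    return PairPlacement(scaffold=role, mate1=plc, mate2=None)


class TestClassifyPair:
    def test_mu_strict(self):
        assert classify_pair(_pp("wt", 100), _pp("mu", 101)) is PairClass.MU_STRICT

    def test_wt_strict(self):
        assert classify_pair(_pp("wt", 101), _pp("mu", 100)) is PairClass.WT_STRICT

    def test_tie(self):
        assert classify_pair(_pp("wt", 100), _pp("mu", 100)) is PairClass.TIE

    def test_unmapped_side_loses(self):
        empty = PairPlacement(scaffold="mu", mate1=None, mate2=None)
        assert classify_pair(_pp("wt", 5), empty) is PairClass.WT_STRICT
        assert classify_pair(None, _pp("mu", 5)) is PairClass.MU_STRICT
        assert classify_pair(None, None) is PairClass.UNMAPPED

    def test_margin(self):
        assert classify_pair(_pp("wt", 100), _pp("mu", 102), margin=3) is PairClass.TIE

    def test_snv_only_pair_covering_site_ties(self, scaffolds, index):
        """A pair carrying only the SNV has one mismatch against either
        scaffold (at 3184 on WT, at the 3252 image on MU)."""
        hap = make_haplotypes(scaffolds, "SNV_HOM")[0]
        frag = hap[3174:3174 + 300]  # starts inside the duplicated segment
        pair = ReadPair("p", frag[:150], "", revcomp(frag[-150:]), "")
        pp = align_pair(pair, index)
        assert classify_pair(pp["wt"], pp["mu"]) is PairClass.TIE

    def test_junction_pair_is_mu_strict(self, scaffolds, index):
        hap = make_haplotypes(scaffolds, "INS_HOM")[0]
        frag = hap[3100:3400]
        pair = ReadPair("p", frag[:150], "", revcomp(frag[-150:]), "")
        pp = align_pair(pair, index)
        assert classify_pair(pp["wt"], pp["mu"]) is PairClass.MU_STRICT


def _site():
    return Site("wt_snv", "wt", 5, "A", "G")


def _result(cls, role, plc):
    pp = PairPlacement(scaffold=role, mate1=plc, mate2=None)
    return PairResult(
        pair=ReadPair("x", plc.seq, plc.qual, "", ""),
        placements={role: pp},
        pair_class=cls,
    )


class TestPileupPolicies:
    def test_clip_filter_excludes_heavily_clipped_reads(self):
        site = _site()
        clean = _placement("wt", 1, 20, (("M", 20),), "AAAAGAAAAAAAAAAAAAAA")
        clipped = _placement("wt", 1, 8, (("M", 8), ("S", 12)), "AAAAGAAA" + "C" * 12)
        results = [
            _result(PairClass.TIE, "wt", clean),
            _result(PairClass.TIE, "wt", clipped),
        ]
        pile = pileup_site(results, site, Policy.WT_INCLUSIVE_CLIPFILTER, clip_limit=12)
        assert pile.depth == 1 and pile.counts["G"] == 1
        # below the limit the read counts
        pile2 = pileup_site(results, site, Policy.WT_INCLUSIVE_CLIPFILTER, clip_limit=13)
        assert pile2.depth == 2

    def test_mu_strict_only_counts_strict_pairs(self):
        site = Site("mu_marker", "mu", 3, "C", "G")
        strict = _placement("mu", 1, 10, (("M", 10),), "AAGAAAAAAA")
        tie = _placement("mu", 1, 10, (("M", 10),), "AACAAAAAAA")
        results = [
            _result(PairClass.MU_STRICT, "mu", strict),
            _result(PairClass.TIE, "mu", tie),
        ]
        pile = pileup_site(results, site, Policy.MU_STRICT_ONLY)
        assert pile.depth == 1 and pile.alt_fraction == 1.0

    def test_low_quality_bases_dropped(self):
        site = _site()
        lowq = _placement("wt", 1, 10, (("M", 10),), "AAAAGAAAAA", qual="I" * 4 + "#" + "I" * 5)
        results = [_result(PairClass.TIE, "wt", lowq)]
        pile = pileup_site(results, site, Policy.WT_INCLUSIVE_CLIPFILTER)
        assert pile.depth == 0

    def test_bases_under_deletions_not_counted(self):
        site = _site()
        deleted = _placement("wt", 1, 10, (("M", 4), ("D", 2), ("M", 6)), "A" * 10)
        results = [_result(PairClass.TIE, "wt", deleted)]
        assert pileup_site(results, site, Policy.WT_INCLUSIVE_CLIPFILTER).depth == 0

    def test_unknown_policy_rejected(self):
        with pytest.raises(ValueError, match="policy"):
            pileup_site([], _site(), "bogus")


class TestCallZygosity:
    @pytest.mark.parametrize(
        "fraction,expected",
        [
            (0.50, Zygosity.HET),
            (0.20, Zygosity.HET),
            (0.7999, Zygosity.HET),
            (0.80, Zygosity.HOM),
            (1.0, Zygosity.HOM),
            (0.19, Zygosity.ABSENT),
            (0.0, Zygosity.ABSENT),
        ],
    )
    def test_fraction_bands(self, fraction, expected):
        depth = 10000
        alt = int(round(fraction * depth))
        pile = PileupCounts(site=_site(), counts={"A": depth - alt, "C": 0, "G": alt, "T": 0})
        assert call_zygosity(pile, min_depth=15) is expected

    def test_low_depth_no_call(self):
        pile = PileupCounts(site=_site(), counts={"A": 7, "C": 0, "G": 7, "T": 0})
        assert call_zygosity(pile, min_depth=15) is Zygosity.NOCALL_LOWDEPTH


class TestDecisionTable:
    VALID = {
        (Zygosity.ABSENT, Zygosity.HOM, Zygosity.ABSENT): CallLabel.INS,
        (Zygosity.ABSENT, Zygosity.HOM, Zygosity.HOM): CallLabel.COMPLEX,
        (Zygosity.HET, Zygosity.HOM, Zygosity.ABSENT): CallLabel.SNV_TRANS_INS,
        (Zygosity.HET, Zygosity.HOM, Zygosity.HOM): CallLabel.SNV_TRANS_COMPLEX,
        (Zygosity.ABSENT, Zygosity.HOM, Zygosity.HET): CallLabel.INS_TRANS_COMPLEX,
    }

    def test_table_rows(self):
        for sig, label in self.VALID.items():
            assert resolve_genotype(SiteSignature(*sig)).label is label

    def test_snv_and_wild_type_rows(self):
        for marker in (Zygosity.ABSENT, Zygosity.NOCALL_LOWDEPTH):
            call = resolve_genotype(SiteSignature(Zygosity.HET, marker, marker))
            assert (call.label, call.snv_zygosity) == (CallLabel.SNV, Zygosity.HET)
            call = resolve_genotype(SiteSignature(Zygosity.HOM, marker, marker))
            assert (call.label, call.snv_zygosity) == (CallLabel.SNV, Zygosity.HOM)
            call = resolve_genotype(SiteSignature(Zygosity.ABSENT, marker, marker))
            assert call.label is CallLabel.WILD_TYPE

    def test_het_marker_is_anomalous(self):
        call = resolve_genotype(SiteSignature(Zygosity.ABSENT, Zygosity.HET, Zygosity.HOM))
        assert call.label is CallLabel.NO_CALL and "marker" in call.reason

    def test_inconsistent_signature_example(self):
        call = resolve_genotype(SiteSignature(Zygosity.HOM, Zygosity.HOM, Zygosity.ABSENT))
        assert call.label is CallLabel.NO_CALL and call.reason == "inconsistent signature"

    def test_totality_and_uniqueness_over_27_signatures(self):
        """Every (wt, marker, cis) triple over {absent, het, hom} maps to
        exactly one outcome; the 7 genotype rows have pairwise distinct
        signatures."""
        states = (Zygosity.ABSENT, Zygosity.HET, Zygosity.HOM)
        seen = {}
        n_calls = 0
        for trip in itertools.product(states, repeat=3):
            call = resolve_genotype(SiteSignature(*trip))
            assert isinstance(call, GenotypeCall)
            if call.label is not CallLabel.NO_CALL:
                n_calls += 1
                key = (call.label, call.snv_zygosity)
                assert key not in seen, f"duplicate signature for {key}"
                seen[key] = trip
        # 5 insertion-bearing rows + SNV het + SNV hom + wild-type
        assert n_calls == 8
        labels = {k[0] for k in seen}
        assert labels == {
            CallLabel.INS, CallLabel.COMPLEX, CallLabel.SNV_TRANS_INS,
            CallLabel.SNV_TRANS_COMPLEX, CallLabel.INS_TRANS_COMPLEX,
            CallLabel.SNV, CallLabel.WILD_TYPE,
        }

    def test_all_64_states_resolve(self):
        for trip in itertools.product(Zygosity, repeat=3):
            assert isinstance(resolve_genotype(SiteSignature(*trip)), GenotypeCall)


class TestEndToEnd:
    def test_complex_het_called(self, scaffolds, index, simulate_genotype):
        report = call_pairs(simulate_genotype("COMPLEX_HET", seed=41), scaffolds, index=index)
        assert report.call == expected_call("COMPLEX_HET")
        assert report.pileups["mu_cis_snv"].alt_fraction >= 0.8

    def test_marker_purity_error_free(self, scaffolds, index, simulate_genotype):
        report = call_pairs(
            simulate_genotype("INS_HET", seed=43, error_rate=0.0), scaffolds, index=index
        )
        assert report.pileups["mu_marker"].alt_fraction == 1.0
        assert report.pileups["mu_marker"].depth > 15

    def test_wild_type_has_zero_strict_mu_depth(self, scaffolds, index, simulate_genotype):
        report = call_pairs(
            simulate_genotype("WT", seed=44, error_rate=0.0), scaffolds, index=index
        )
        assert report.pileups["mu_marker"].depth == 0
        assert report.call.label is CallLabel.WILD_TYPE

    def test_trans_complex_wt_site_is_balanced_het(self, scaffolds, index, simulate_genotype):
        """SNV in trans with the complex variant: reference-allele leakage
        from the insertion homolog keeps the WT SNV site heterozygous."""
        report = call_pairs(simulate_genotype("SNV_trans_COMPLEX", seed=45), scaffolds, index=index)
        frac = report.pileups["wt_snv"].alt_fraction
        assert 0.20 < frac < 0.80
        assert report.call == expected_call("SNV_trans_COMPLEX")

    def test_rare_allele_complex_het_called(self, scaffolds, index, simulate_genotype):
        from scaffoldcall.simulate import DiploidGenotype, HaplotypeSpec

        g = DiploidGenotype(
            "rare_cpx",
            (
                HaplotypeSpec(has_insertion=True, has_snv=True, insertion_allele="rare"),
                HaplotypeSpec(),
            ),
        )
        from scaffoldcall.fixtures import rare_insertion
        from scaffoldcall.simulate import SimParams, simulate_pairs

        haps = make_haplotypes(scaffolds, g, rare_insertion=rare_insertion())
        pairs = simulate_pairs(haps, SimParams(seed=47, coverage=80))
        report = call_pairs(pairs, scaffolds, index=index)
        assert report.call.label is CallLabel.COMPLEX

    def test_empty_input_is_no_call(self, scaffolds):
        report = call_pairs([], scaffolds)
        assert report.call.label is CallLabel.NO_CALL
        assert report.signature.wt_snv is Zygosity.NOCALL_LOWDEPTH

    def test_call_sample_matches_call_pairs(self, scaffolds, index, simulate_genotype, tmp_path):
        pairs = simulate_genotype("SNV_trans_INS", seed=49, coverage=40)
        paths = write_fastq(pairs, str(tmp_path / "s"))
        from_files = call_sample(paths["r1"], paths["r2"], scaffolds)
        in_memory = call_pairs(pairs, scaffolds, index=index)
        assert from_files.call == in_memory.call
        assert from_files.pileups["wt_snv"].counts == in_memory.pileups["wt_snv"].counts

    def test_report_text(self, scaffolds, index, simulate_genotype):
        report = call_pairs(simulate_genotype("INS_HET", seed=50, coverage=30), scaffolds, index=index)
        text = report.to_text()
        assert "genotype\tins" in text
        assert "site_mu_marker" in text


class TestSingleReference:
    def test_complex_hom_suppressed(self, scaffolds, simulate_genotype):
        """Reference bias: all reads carry the variant in cis yet the naive
        WT-only pileup shows a minority alt fraction."""
        pairs = simulate_genotype("COMPLEX_HOM", seed=51)
        report = call_single_reference(pairs, scaffolds)
        assert report.pileups["wt_snv"].alt_fraction < 0.80
        assert report.call.snv_zygosity is not Zygosity.HOM

    def test_snv_hom_unaffected(self, scaffolds, simulate_genotype):
        pairs = simulate_genotype("SNV_HOM", seed=52)
        report = call_single_reference(pairs, scaffolds)
        assert report.pileups["wt_snv"].alt_fraction > 0.95
        assert report.call.snv_zygosity is Zygosity.HOM

    def test_wild_type_near_zero(self, scaffolds, simulate_genotype):
        pairs = simulate_genotype("WT", seed=53, coverage=40)
        report = call_single_reference(pairs, scaffolds)
        assert report.pileups["wt_snv"].alt_fraction < 0.02
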