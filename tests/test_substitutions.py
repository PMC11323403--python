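"""Outgroup-parsimony inference and windowed aggregation."""

import numpy as np
import pytest
from Bio.Seq import Seq

from gcdrift import (
    SubstitutionEvent,
    TrioAlignment,
    ancestral_base_counts,
    count_events_by_exon,
    find_gc4_sites,
    infer_substitutions,
    net_gc_change_series,
    orf_binned_net_gc,
    substitution_rate_series,
)
from gcdrift.scenarios import trio_inference_oracle


def _aln(s1, s2, s3):
    return TrioAlignment.from_gapped(s1, s2, s3)


class TestInferSubstitutions:
    def test_outgroup_matches_second_ingroup(self):
        # column (A, G, G): ancestral G, event on ingroup1
        events = infer_substitutions(_aln("A", "G", "G"), anchor_offset=0)
        assert len(events) == 1
        ev = events[0]
        assert (ev.lineage, ev.from_base, ev.to_base) == ("ingroup1", "G", "A")
        assert ev.klass == "SW"

    def test_all_three_distinct_no_call(self):
        assert infer_substitutions(_aln("A", "G", "C"), anchor_offset=0) == []

    def test_equal_ingroups_no_call(self):
        assert infer_substitutions(_aln("G", "G", "A"), anchor_offset=0) == []

    @pytest.mark.parametrize("col", [("A", "-", "A"), ("N", "A", "A"), ("A", "A", "-")])
    def test_gap_or_n_columns_skipped(self, col):
        a, b, o = (f"C{x}C" for x in col)
        assert infer_substitutions(_aln(a, b, o), anchor_offset=0) == []

    def test_rel_pos_in_own_ungapped_coordinates(self):
        # ingroup1 has a gap before its event column, ingroup2 does not
        aln = _aln("C-GA", "CTGG", "CTGG")
        events = infer_substitutions(aln, anchor_offset=0)
        assert len(events) == 1
        ev = events[0]
        assert ev.lineage == "ingroup1"
        # event column is the 4th; in ingroup1's ungapped coordinates
        # that is position 2 (C, G, then A)
        assert ev.rel_pos == 2

    def test_cpg_context_on_ancestral_sequence(self):
        # ingroup1 derived TG from ancestral CG: from_base C next to G
        events = infer_substitutions(_aln("TG", "CG", "CG"), anchor_offset=0)
        (ev,) = events
        assert ev.from_base == "C" and ev.to_base == "T"
        assert ev.cpg_context

    def test_anchor_offset_shifts_positions(self):
        events = infer_substitutions(_aln("AAAT", "AAAA", "AAAA"), anchor_offset=2)
        assert events[0].rel_pos == 1


class TestNetGcChangeSeries:
    def test_opposing_events_cancel(self):
        events = [
            SubstitutionEvent("s", 0, "ingroup1", "A", "G"),  # WS
            SubstitutionEvent("s", 0, "ingroup1", "C", "T"),  # SW
            SubstitutionEvent("s", 0, "ingroup1", "A", "T"),  # WW
        ]
        series = net_gc_change_series(events, span=5, window=1, n_sources=1)
        assert series.at(0) == 0.0

    def test_no_events_zero_series(self):
        series = net_gc_change_series([], span=10, window=100, n_sources=3)
        np.testing.assert_array_equal(series.raw, 0.0)

    def test_conservation_of_total_net(self, rng):
        events = []
        pairs = [("A", "G"), ("G", "A"), ("C", "T"), ("T", "C"), ("A", "T"), ("C", "G")]
        for i in range(300):
            f, t = pairs[rng.integers(len(pairs))]
            events.append(
                SubstitutionEvent("s", int(rng.integers(-50, 51)), "ingroup1", f, t)
            )
        n_ws = sum(1 for e in events if e.klass == "WS")
        n_sw = sum(1 for e in events if e.klass == "SW")
        series = net_gc_change_series(events, span=50, window=100, n_sources=7)
        assert series.raw.sum() * 7 == pytest.approx(n_ws - n_sw)


class TestSubstitutionRateSeries:
    def test_simple_rate(self):
        events = [SubstitutionEvent("s", 0, "ingroup1", "A", "G")]
        counts = {b: np.zeros(11, dtype=int) for b in "ACGT"}
        counts["A"][:] = 10
        series = substitution_rate_series(events, counts, "A", "G", span=5, window=1)
        assert series.raw[5] == pytest.approx(0.1)

    def test_zero_denominator_is_undefined(self):
        counts = {b: np.zeros(11, dtype=int) for b in "ACGT"}
        counts["A"][:5] = 10  # offset 0 and beyond have no A's
        series = substitution_rate_series([], counts, "A", "G", span=5, window=1)
        assert np.isnan(series.raw[5])

    def test_mismatched_gene_sets_error(self):
        events = [SubstitutionEvent("s", 0, "ingroup1", "A", "G")]
        counts = {b: np.zeros(11, dtype=int) for b in "ACGT"}  # no A anywhere
        with pytest.raises(ValueError, match="different gene sets"):
            substitution_rate_series(events, counts, "A", "G", span=5)

    def test_pooled_rate_matches_model_expectation(self):
        # single evolving lineage, neutral model: pooled A->G rate within
        # the 99.9% binomial interval of kappa/(kappa+2) * base_rate
        from scipy import stats as sps

        from gcdrift import (
            GenomeSpec,
            MutationModel,
            align_trio,
            generate_sequence,
            simulate_trio,
        )

        model = MutationModel(
            base_rate=0.002, ws_bias=1.0, cpg_multiplier=1.0, gbgc_strength=0.0
        )
        span = 250
        all_events = []
        ancestrals = []
        for i in range(100):
            anc = generate_sequence(GenomeSpec(length=501, seed=500 + i))
            locus = simulate_trio(anc, model, (1.0, 0.0, 0.0), seed=900 + i)
            aln = align_trio(
                locus.seq_ingroup1, locus.seq_ingroup2, locus.seq_outgroup, band=30
            )
            all_events.extend(infer_substitutions(aln, anchor_offset=span))
            ancestrals.append((anc, span))
        counts = ancestral_base_counts(ancestrals, span=span)
        series = substitution_rate_series(all_events, counts, "A", "G", span=span, window=1)
        n_a = counts["A"].sum()
        n_ag = np.nansum(series.raw * counts["A"])
        p_expected = 0.002 * 2.0 / 4.0  # kappa/(kappa+2) of the site rate
        lo, hi = sps.binom.ppf([0.0005, 0.9995], n_a, p_expected)
        assert lo <= n_ag <= hi


class TestFindGc4Sites:
    def test_example_orf(self):
        assert find_gc4_sites("ATGGGAGCT") == [5, 8]

    def test_twofold_codon_excluded(self):
        assert find_gc4_sites("ATGAAA") == []

    def test_preconditions(self):
        with pytest.raises(ValueError):
            find_gc4_sites("ATGAA")  # not divisible by 3
        with pytest.raises(ValueError):
            find_gc4_sites("TTGAAA")  # no ATG start

    def test_all_64_codons_against_translation_oracle(self):
        bases = "ACGT"
        for b1 in bases:
            for b2 in bases:
                for b3 in bases:
                    codon = b1 + b2 + b3
                    aas = {str(Seq(b1 + b2 + x).translate()) for x in bases}
                    fourfold = len(aas) == 1 and "*" not in aas
                    sites = find_gc4_sites("ATG" + codon)
                    assert (5 in sites) == fourfold, codon


class TestOrfBinnedNetGc:
    def test_no_events_zero_profile(self):
        prof = orf_binned_net_gc([("ATG" + "GCT" * 39, [])])
        np.testing.assert_array_equal(prof.values, 0.0)

    def test_single_event_in_first_bin(self):
        orf = "ATG" + "AAA" * 39  # 120 bases, 40 bins of 3
        events = [SubstitutionEvent("g", 4, "ingroup1", "A", "G")]
        prof = orf_binned_net_gc([(orf, events)])
        assert prof.values[1] == 1.0
        assert prof.values[[0] + list(range(2, 40))].sum() == 0.0

    def test_gc4_filter_restricts_to_degenerate_sites(self):
        orf = "ATG" + "GGA" + "AAA" * 38  # GC4 site at position 5 only
        ws_at_gc4 = SubstitutionEvent("g", 5, "ingroup1", "A", "G")
        ws_elsewhere = SubstitutionEvent("g", 7, "ingroup1", "A", "G")
        all_events = orf_binned_net_gc([(orf, [ws_at_gc4, ws_elsewhere])])
        gc4_only = orf_binned_net_gc([(orf, [ws_at_gc4, ws_elsewhere])], gc4_only=True)
        assert all_events.per_gene.sum() == 2.0
        assert gc4_only.per_gene.sum() == 1.0

    def test_invalid_orf_skipped(self):
        prof = orf_binned_net_gc([("TTTAAA", []), ("ATG" + "AAA" * 39, [])])
        assert prof.per_gene.shape[0] == 1


class TestCountEventsByExon:
    def test_fewer_than_four_exons_excluded(self):
        assert count_events_by_exon([], [30, 30, 30], 1) is None

    def test_events_in_other_exons_not_counted(self):
        events = [SubstitutionEvent("g", 35, "ingroup1", "A", "G")]  # exon 2
        assert count_events_by_exon(events, [30, 30, 30, 30], 1) == (0, 0)
        assert count_events_by_exon(events, [30, 30, 30, 30], 4) == (0, 0)

    def test_planted_counts_recovered(self):
        lengths = [30, 30, 30, 30]
        events = [
            SubstitutionEvent("g", 5, "ingroup1", "A", "G"),   # exon1 WS
            SubstitutionEvent("g", 10, "ingroup1", "C", "A"),  # exon1 SW
            SubstitutionEvent("g", 95, "ingroup1", "T", "C"),  # exon4 WS
        ]
        assert count_events_by_exon(events, lengths, 1) == (1, 1)
        assert count_events_by_exon(events, lengths, 4) == (1, 0)


class TestEvolverOracle:
    def test_low_divergence_exact_recovery(self):
        res = trio_inference_oracle(n_loci=40, locus_length=1000, base_rate=0.002, seed=5)
        assert res["precision_single_hit"] == 1.0
        assert res["recall_single_hit"] == 1.0
        assert res["n_false_single_hit"] == 0

    def test_higher_divergence_discrepancies_are_multi_hit(self):
        res = trio_inference_oracle(n_loci=20, locus_length=1000, base_rate=0.02, seed=6)
        # every false call or miss is audited to a multi-hit site
        assert res["n_false_single_hit"] == 0
        assert res["n_multi_hit_sites"] > 0
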