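"""Region extraction: TSS windows, EIB normalization, controls."""

import numpy as np
import pytest

from gcdrift import (
    GeneModel,
    extract_anchor_window,
    extract_eib_regions,
    gc_fraction,
    gc_match,
    sample_intergenic,
    select_best_tss,
)
from gcdrift.seq import revcomp


class TestSelectBestTss:
    def test_max_score_wins(self):
        assert select_best_tss([("t1", 100, 5.0), ("t2", 200, 9.0)]) == "t2"

    def test_single_transcript(self):
        assert select_best_tss([("t1", 50, 0.1)]) == "t1"

    def test_tie_break_five_prime_most(self):
        ts = [("t1", 150, 3.0), ("t2", 100, 3.0)]
        assert select_best_tss(ts, strand="+") == "t2"
        assert select_best_tss(ts, strand="-") == "t1"

    def test_tie_break_lexicographic(self):
        assert select_best_tss([("tb", 100, 1.0), ("ta", 100, 1.0)]) == "ta"

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            select_best_tss([])


def _plus_gene(tss, exons, gene_id="g+"):
    return GeneModel(gene_id=gene_id, chrom="chr1", strand="+", tss=tss, exons=exons)


def _minus_gene(tss, exons, gene_id="g-"):
    return GeneModel(gene_id=gene_id, chrom="chr1", strand="-", tss=tss, exons=exons)


class TestExtractAnchorWindow:
    def test_plus_strand_coordinates(self):
        genome = "".join("ACGT"[i % 4] for i in range(10_000))
        gene = _plus_gene(5000, [(5000, 5100)])
        region = extract_anchor_window(genome, gene, 2)
        assert region.sequence == genome[4998:5002]
        assert region.anchor_offset == 2
        assert region.sequence[region.anchor_offset] == genome[5000]

    def test_minus_strand_reverse_complement(self):
        genome = "".join("ACGT"[i % 4] for i in range(10_000))
        gene = _minus_gene(5000, [(4901, 5001)])
        region = extract_anchor_window(genome, gene, 2)
        assert region.sequence == revcomp(genome[4999:5003])
        assert region.sequence[2] == revcomp(genome[5000])

    def test_hand_checkable_slice(self):
        # window [tss - flank, tss + flank) with the TSS base (C) at the
        # anchor offset
        genome = "AAAACGTAAAA"
        gene = _plus_gene(4, [(4, 8)])
        region = extract_anchor_window(genome, gene, 3)
        assert region.sequence == "AAACGT"
        assert region.sequence[region.anchor_offset] == "C"

    def test_out_of_bounds_skipped(self):
        gene = _plus_gene(10, [(10, 60)])
        assert extract_anchor_window("A" * 100, gene, 50) is None

    def test_strand_round_trip(self):
        # revcomp of a minus-strand window re-maps to the genomic slice
        genome = "".join(
            np.random.default_rng(0).choice(list("ACGT"), 2000)
        )
        gene = _minus_gene(1500, [(1301, 1501)])
        flank = 100
        region = extract_anchor_window(genome, gene, flank)
        genomic = genome[gene.tss - flank + 1 : gene.tss + flank + 1]
        assert revcomp(region.sequence) == genomic


class TestExtractEibRegions:
    def test_plus_strand_lengths_and_content(self):
        genome = "T" * 20 + "G" * 10 + "A" * 30  # upstream Ts, exon Gs, intron As
        gene = _plus_gene(20, [(20, 30), (55, 60)])
        r = extract_eib_regions(genome, gene)
        assert (len(r.upstream), len(r.exon1), len(r.intron1_prefix)) == (20, 10, 10)
        assert r.upstream == "T" * 20
        assert r.exon1 == "G" * 10
        assert r.intron1_prefix == "A" * 10
        assert r.concatenated() == genome[:40]

    def test_minus_strand_concatenation_contiguous(self):
        rng = np.random.default_rng(5)
        genome = "".join(rng.choice(list("ACGT"), 300))
        # transcript orientation: exon1 = (190, 200), intron before it
        gene = _minus_gene(199, [(100, 120), (190, 200)])
        r = extract_eib_regions(genome, gene)
        L = 10
        assert len(r.upstream) == 2 * L
        # concatenation equals the transcript-oriented genomic slice
        assert r.concatenated() == revcomp(genome[190 - L : 200 + 2 * L])

    def test_single_exon_skipped(self):
        gene = _plus_gene(50, [(50, 80)])
        assert extract_eib_regions("A" * 200, gene) is None

    def test_short_intron_skipped(self):
        gene = _plus_gene(50, [(50, 80), (85, 120)])  # intron 5 < L 30
        assert extract_eib_regions("A" * 300, gene) is None


class TestSampleIntergenic:
    def test_zero_regions(self):
        assert sample_intergenic("A" * 1000, [], 0, 100) == []

    def test_buffer_respected(self):
        genome = "A" * 1_000_000
        genes = [_plus_gene(500_000, [(500_000, 505_000)])]
        regions = sample_intergenic(genome, genes, 20, 2000, buffer=10_000, seed=1)
        for r in regions:
            s, e = r.genomic_start, r.genomic_start + len(r.sequence)
            assert e <= 490_000 or s >= 515_000

    def test_gene_free_chromosome_disjoint(self):
        regions = sample_intergenic("A" * 1_000_000, [], 100, 5000, seed=2)
        assert len(regions) == 100
        spans = sorted((r.genomic_start, r.genomic_start + 5000) for r in regions)
        for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
            assert e1 <= s2

    def test_same_seed_identical(self):
        a = sample_intergenic("A" * 100_000, [], 10, 1000, seed=3)
        b = sample_intergenic("A" * 100_000, [], 10, 1000, seed=3)
        assert [r.genomic_start for r in a] == [r.genomic_start for r in b]

    def test_infeasible_raises(self):
        genome = "A" * 50_000
        genes = [_plus_gene(0, [(0, 40_000)])]
        with pytest.raises(RuntimeError):
            sample_intergenic(genome, genes, 5, 5000, buffer=10_000, seed=0)

    def test_anchor_at_midpoint(self):
        (r,) = sample_intergenic("ACGT" * 1000, [], 1, 100, seed=4)
        assert r.anchor_offset == 50


class TestGcMatch:
    def test_exact_single_candidate(self):
        pool = [("r1", 0.40)]
        assert gc_match(pool, [0.401]) == ["r1"]

    def test_empty_target(self):
        assert gc_match([("r1", 0.5)], []) == []

    def test_undersupplied_bin_named(self):
        with pytest.raises(ValueError, match=r"0\.50"):
            gc_match([("r1", 0.40)], [0.505])

    def test_histogram_equality_at_scale(self, rng):
        # selection from a 10x pool reproduces the target histogram bin
        # for bin, exactly
        target = np.clip(rng.normal(0.5, 0.05, 200), 0.0, 1.0)
        pool_gcs = np.clip(rng.normal(0.5, 0.08, 4000), 0.0, 1.0)
        pool = [((f"p{i}", gc), gc) for i, gc in enumerate(pool_gcs)]
        try:
            selected = gc_match(pool, list(target), bin_width=0.01, seed=7)
        except ValueError:
            pytest.skip("pool undersupplied for this draw")
        sel_gcs = [gc for (_, gc) in selected]
        bins = np.arange(0, 1.01, 0.01)
        np.testing.assert_array_equal(
            np.histogram(np.floor(np.array(sel_gcs) / 0.01) * 0.01 + 1e-9, bins)[0],
            np.histogram(np.floor(target / 0.01) * 0.01 + 1e-9, bins)[0],
        )

    def test_sampling_without_replacement(self):
        pool = [(f"r{i}", 0.40) for i in range(3)]
        selected = gc_match(pool, [0.40, 0.40, 0.40], seed=1)
        assert len(set(selected)) == 3
        with pytest.raises(ValueError):
            gc_match(pool, [0.40] * 4, seed=1)
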