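"""Trio evolution simulator: rates, truth tables, DNM sampling."""

import numpy as np
import pytest
from scipy import stats as sps

from gcdrift import (
    GenePlan,
    GenomeSpec,
    MutationModel,
    evolve_sequence,
    generate_dnms,
    generate_sequence,
    place_genes,
    replay_truth,
    simulate_trio,
)
from gcdrift.evolve import target_rate_matrix
from gcdrift.seq import encode


def expected_total_rate(seq: str, model: MutationModel) -> float:
    """Closed-form expected per-branch substitution count for a sequence
    with no anchor effects, computed from base and CpG counts only."""
    k = model.ts_tv_ratio
    w = model.ws_bias
    m = model.cpg_multiplier
    norm = model.base_rate / (k + 2.0)
    n_weak = seq.count("A") + seq.count("T")
    n_strong = seq.count("C") + seq.count("G")
    n_cpg = seq.count("CG")  # CG pairs cannot overlap
    # weak site: transition (k) + one transversion to S, both scaled by w,
    # plus one transversion to W
    weak_rate = norm * (k * w + w + 1.0)
    # strong site, non-CpG: transition (k) + transversions to W and S
    strong_rate = norm * (k + 2.0)
    # each CpG adds (m - 1) * k extra on its C (C->T) and its G (G->A)
    cpg_extra = norm * (m - 1.0) * k * 2.0
    return n_weak * weak_rate + n_strong * strong_rate + n_cpg * cpg_extra


class TestEvolveSequence:
    def test_zero_branch_is_identity(self):
        anc = "ACGTACGTAC"
        derived, truth = evolve_sequence(anc, MutationModel(), 0.0, seed=1)
        assert derived == anc
        assert truth == []

    def test_negative_branch_rejected(self):
        with pytest.raises(ValueError):
            evolve_sequence("ACGT", MutationModel(), -1.0)

    def test_replay_reproduces_derived(self):
        anc = generate_sequence(GenomeSpec(length=2000, seed=6))
        model = MutationModel(base_rate=0.05)
        derived, truth = evolve_sequence(anc, model, 1.0, anchor=1000, seed=7)
        assert replay_truth(anc, truth) == derived
        assert derived != anc  # ~100 expected events

    def test_event_count_within_poisson_interval(self):
        anc = generate_sequence(GenomeSpec(length=100_000, seed=8))
        model = MutationModel(base_rate=0.01, gbgc_strength=0.0)
        lam = expected_total_rate(anc, model)
        _, truth = evolve_sequence(anc, model, 1.0, seed=9)
        lo, hi = sps.poisson.ppf([0.0005, 0.9995], lam)
        assert lo <= len(truth) <= hi

    def test_gbgc_limit_suppresses_strong_to_weak(self):
        # S->W rates inside the anchor window scale by (1 - B) -> 0
        anc = "ACGT" * 50
        codes = encode(anc)
        strong = MutationModel(gbgc_strength=0.99, gbgc_window=200)
        none = MutationModel(gbgc_strength=0.0, gbgc_window=200)
        r_b = target_rate_matrix(codes, strong, anchor=100)
        r_0 = target_rate_matrix(codes, none, anchor=100)
        s_sites = (codes == 1) | (codes == 2)  # C or G
        sw_b = r_b[s_sites][:, [0, 3]]  # -> A or T
        sw_0 = r_0[s_sites][:, [0, 3]]
        np.testing.assert_allclose(sw_b, sw_0 * 0.01)

    def test_hypomethylation_resets_cpg_rates(self):
        anc = "ACGACG" * 100
        model = MutationModel(
            cpg_multiplier=10.0, hypomethyl_window=200, gbgc_strength=0.0
        )
        codes = encode(anc)
        with_anchor = target_rate_matrix(codes, model, anchor=300)
        without = target_rate_matrix(codes, model, anchor=None)
        # C->T rate at a CpG C inside the window is 10x lower
        c_of_cpg = np.array(
            [i for i in range(len(anc) - 1) if anc[i : i + 2] == "CG"]
        )
        inside = c_of_cpg[np.abs(c_of_cpg - 300) <= 100]
        np.testing.assert_allclose(
            with_anchor[inside, 3] * 10.0, without[inside, 3]
        )


class TestSimulateTrio:
    def test_zero_branches_identical(self):
        anc = "ACGTACGTAC"
        locus = simulate_trio(anc, MutationModel(), (0, 0, 0), seed=1)
        assert locus.seq_ingroup1 == locus.seq_ingroup2 == locus.seq_outgroup == anc
        assert locus.truth == []

    def test_zero_outgroup_branch_equals_ancestor(self):
        anc = generate_sequence(GenomeSpec(length=1000, seed=10))
        locus = simulate_trio(anc, MutationModel(base_rate=0.01), (1, 1, 0), seed=2)
        assert locus.seq_outgroup == anc

    def test_per_lineage_replay(self):
        anc = generate_sequence(GenomeSpec(length=10_000, seed=11))
        model = MutationModel(base_rate=0.005)
        locus = simulate_trio(anc, model, (0.005 / 0.005,) * 3, anchor=5000, seed=3)
        for lineage, derived in [
            ("ingroup1", locus.seq_ingroup1),
            ("ingroup2", locus.seq_ingroup2),
            ("outgroup", locus.seq_outgroup),
        ]:
            events = [e for e in locus.truth if e.lineage == lineage]
            assert replay_truth(anc, events) == derived

    def test_deterministic_given_seed(self):
        anc = generate_sequence(GenomeSpec(length=2000, seed=12))
        model = MutationModel(base_rate=0.01)
        a = simulate_trio(anc, model, (1, 1, 2), seed=5)
        b = simulate_trio(anc, model, (1, 1, 2), seed=5)
        assert a.seq_ingroup1 == b.seq_ingroup1
        assert a.seq_outgroup == b.seq_outgroup


@pytest.fixture(scope="module")
def dnm_setup():
    plan = GenePlan(n_genes=5, min_intergenic_gap=3000)
    genes, _ = place_genes(200_000, plan, seed=13)
    genome = generate_sequence(GenomeSpec(length=200_000, seed=13))
    return genome, genes


class TestGenerateDnms:
    def test_zero_mutations(self, dnm_setup):
        genome, genes = dnm_setup
        assert generate_dnms(genome, genes, MutationModel(), 0, seed=1) == []

    def test_ref_matches_genome(self, dnm_setup):
        genome, genes = dnm_setup
        dnms = generate_dnms(genome, genes, MutationModel(), 500, seed=2)
        assert len(dnms) == 500
        for d in dnms:
            assert genome[d.pos - 1] == d.ref
            assert d.ref != d.alt

    def test_cpg_fraction_matches_composition_when_unmultiplied(self, dnm_setup):
        # with cpg_multiplier = 1 the fraction of CpG C->T / G->A records
        # follows from base composition alone (binomial bound)
        genome, genes = dnm_setup
        model = MutationModel(cpg_multiplier=1.0, gbgc_strength=0.0)
        n = 5000
        dnms = generate_dnms(genome, genes, model, n, seed=3)
        k = model.ts_tv_ratio
        w = model.ws_bias
        norm = 1.0 / (k + 2.0)
        n_weak = genome.count("A") + genome.count("T")
        n_strong = genome.count("C") + genome.count("G")
        n_cpg = genome.count("CG")
        total = n_weak * norm * (k * w + w + 1) + n_strong * 1.0
        p_cpg_ts = n_cpg * (2 * norm * k) / total  # C->T on the C + G->A on the G
        observed = sum(
            1
            for d in dnms
            if (d.ref, d.alt) in (("C", "T"), ("G", "A"))
            and (
                (d.ref == "C" and genome[d.pos : d.pos + 1] == "G")
                or (d.ref == "G" and genome[d.pos - 2 : d.pos - 1] == "C")
            )
        )
        lo, hi = sps.binom.ppf([0.0005, 0.9995], n, p_cpg_ts)
        assert lo <= observed <= hi
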