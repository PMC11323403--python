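"""End-to-end simulation studies with known ground truth.

Each function here wires the synthetic generators through the full
analysis pipeline (alignment, inference, mapping, statistics) under a
fixed set of study conditions and returns the measured quantities.  The
problem sizes default to desk-scale settings (hundreds of loci, a few
megabases) chosen so a study completes in minutes on one CPU while the
effects remain many standard errors wide.

Study conditions (see the methods note for rationale):

* ancestors/genomes: 41% background GC, CpG density depleted to ~20% of
  expectation for the comparative scenarios (vertebrate-like);
* mutation process: AT-biased (ws_bias = 2/3, equilibrium GC ~ 0.40),
  CpG transitions x10, transition:transversion 2, promoter
  hypomethylation window 1 kb;
* gBGC, when enabled: B = 0.4 (70:30 W:S repair odds) in a 1 kb window;
* divergence: per-branch expected substitutions chosen per scenario
  (primate-like ~1% per ingroup branch for directionality studies).
"""

from __future__ import annotations

import numpy as np

from .align import align_trio, identity_gate
from .dnm import dnm_profiles, map_dnms
from .evolve import MutationModel, generate_dnms, simulate_trio
from .genome import GcPeakSpec, GenePlan, GenomeSpec, generate_sequence, place_genes
from .profiles import fit_gaussian_peak, positional_profile
from .regions import extract_anchor_window
from .stats import permutation_test
from .substitutions import infer_substitutions


def _spawn(seed: int, k: int) -> int:
    """Derive a stream-specific 31-bit seed."""
    return int(np.random.SeedSequence([seed, k]).generate_state(1)[0] % (2**31))


# ----------------------------------------------------- inference oracle

def trio_inference_oracle(
    n_loci: int = 500,
    locus_length: int = 5000,
    base_rate: float = 0.002,
    branch_lengths=(1.0, 1.0, 1.0),
    seed: int = 0,
    band: int = 100,
):
    """Run the full trio pipeline and score inferred events against the
    simulator's truth table.

    At sites hit exactly once across all three lineages, outgroup
    parsimony is deterministic, so precision and recall restricted to
    those sites measure implementation correctness (both should be 1.0);
    mismatches elsewhere are audited as multi-hit artifacts.
    """
    model = MutationModel(base_rate=base_rate)
    anchor = locus_length // 2
    tp = fp = fn = 0
    fp_multi = fn_multi = 0
    n_events = 0
    n_multi_sites = 0
    n_gapped_loci = 0
    n_discrepant_gapped = 0
    for i in range(n_loci):
        spec = GenomeSpec(length=locus_length, seed=_spawn(seed, 2 * i))
        ancestor = generate_sequence(spec)
        locus = simulate_trio(
            ancestor, model, branch_lengths, anchor=anchor, seed=_spawn(seed, 2 * i + 1)
        )
        aln = align_trio(locus.seq_ingroup1, locus.seq_ingroup2, locus.seq_outgroup, band=band)
        if not identity_gate(aln):
            continue
        # with no simulated indels the optimal alignment is almost always
        # the identity alignment; in rare repetitive stretches a gapped
        # alignment scores equally or better and shifts event coordinates
        # -- such loci are audited separately
        gapped = aln.columns != len(locus.ancestor)
        if gapped:
            n_gapped_loci += 1
        events = infer_substitutions(aln, anchor_offset=anchor, source_id=f"locus{i}")
        n_events += len(events)
        site_hits: dict = {}
        for ev in locus.truth:
            site_hits[ev.site] = site_hits.get(ev.site, 0) + 1
        multi = {s for s, c in site_hits.items() if c > 1}
        n_multi_sites += len(multi)
        truth_keys = {
            (ev.site, ev.lineage, ev.from_base, ev.to_base)
            for ev in locus.truth
            if ev.lineage != "outgroup"
        }
        inferred_keys = {
            (ev.rel_pos + anchor, ev.lineage, ev.from_base, ev.to_base) for ev in events
        }
        for key in inferred_keys:
            if key in truth_keys:
                tp += 1
            elif key[0] in multi:
                fp_multi += 1
            elif gapped:
                n_discrepant_gapped += 1
            else:
                fp += 1
        for key in truth_keys - inferred_keys:
            if key[0] in multi:
                fn_multi += 1
            elif gapped:
                n_discrepant_gapped += 1
            else:
                fn += 1
    precision = tp / (tp + fp) if (tp + fp) else float("nan")
    recall = tp / (tp + fn) if (tp + fn) else float("nan")
    return {
        "precision_single_hit": precision,
        "recall_single_hit": recall,
        "n_inferred": n_events,
        "n_true_positive": tp,
        "n_false_single_hit": fp + fn,
        "n_discrepant_multi_hit": fp_multi + fn_multi,
        "n_multi_hit_sites": n_multi_sites,
        "n_gapped_alignments": n_gapped_loci,
        "n_discrepant_gapped_alignment": n_discrepant_gapped,
        "n_loci": n_loci,
    }


# ----------------------------------------------- directionality studies

def _anchor_net(events, half_span: int) -> float:
    net = 0.0
    for ev in events:
        if abs(ev.rel_pos) <= half_span:
            if ev.klass == "WS":
                net += 1.0
            elif ev.klass == "SW":
                net -= 1.0
    return net


def _evolved_locus_net(ancestor, model, anchor, anchor_offset, half_span, seed, band):
    locus = simulate_trio(ancestor, model, (1.0, 1.0, 2.0), anchor=anchor, seed=seed)
    aln = align_trio(locus.seq_ingroup1, locus.seq_ingroup2, locus.seq_outgroup, band=band)
    if not identity_gate(aln):
        return None
    events = infer_substitutions(aln, anchor_offset=anchor_offset)
    return _anchor_net(events, half_span)


def directionality_study(
    gbgc_strength: float,
    n_loci: int = 500,
    locus_length: int = 2000,
    base_rate: float = 0.01,
    peak_amplitude: float = 0.25,
    peak_sigma: float = 300.0,
    half_span: int = 500,
    n_perm: int = 1000,
    seed: int = 0,
    band: int = 50,
):
    """Net GC change at TSS-like anchors versus flat intergenic controls.

    TSS-like loci carry a planted Gaussian GC peak at the anchor and are
    evolved with the anchor-window effects (promoter hypomethylation,
    and gBGC of the given strength); intergenic controls are flat-GC
    sequences evolved with no anchor.  With ``gbgc_strength = 0`` the
    GC-rich anchors sit above the mutational equilibrium and decay
    (negative net change); with B = 0.4 the anchor-window equilibrium
    rises above the local GC and the anchors gain GC.

    Returns the per-group means, the observed delta, and permutation
    p-values on the per-locus anchor-local net GC counts.
    """
    model = MutationModel(base_rate=base_rate, gbgc_strength=gbgc_strength)
    anchor = locus_length // 2
    tss_stats = []
    for i in range(n_loci):
        spec = GenomeSpec(
            length=locus_length, seed=_spawn(seed, 4 * i), cpg_depletion=0.8
        )
        ancestor = generate_sequence(
            spec, [(anchor, GcPeakSpec(amplitude=peak_amplitude, sigma=peak_sigma))]
        )
        net = _evolved_locus_net(
            ancestor, model, anchor, anchor, half_span, _spawn(seed, 4 * i + 1), band
        )
        if net is not None:
            tss_stats.append(net)
    intergenic_stats = []
    for i in range(n_loci):
        spec = GenomeSpec(
            length=locus_length, seed=_spawn(seed, 4 * i + 2), cpg_depletion=0.8
        )
        ancestor = generate_sequence(spec)
        net = _evolved_locus_net(
            ancestor, model, None, anchor, half_span, _spawn(seed, 4 * i + 3), band
        )
        if net is not None:
            intergenic_stats.append(net)
    res = permutation_test(
        tss_stats, intergenic_stats, n_perm=n_perm, seed=_spawn(seed, 10**6)
    )
    return {
        "tss_mean_net": float(np.mean(tss_stats)),
        "intergenic_mean_net": float(np.mean(intergenic_stats)),
        "observed_delta": res.observed_delta,
        "p_empirical": res.p_empirical,
        "p_gaussian": res.p_gaussian,
        "n_tss": len(tss_stats),
        "n_intergenic": len(intergenic_stats),
    }


# ------------------------------------------------------ DNM suppression

def dnm_hypomethylation_study(
    n_dnms: int = 20_000,
    genome_length: int = 3_000_000,
    n_genes: int = 150,
    flank: int = 2500,
    core_span: int = 250,
    edge_min: int = 1500,
    n_perm: int = 1000,
    seed: int = 0,
):
    """CpG-transition suppression around hypomethylated TSSs.

    Simulates DNMs under CpG hypermutability (x10) with the multiplier
    reset inside a 1 kb promoter window, maps them to TSS windows, and
    compares per-gene CpG-transition rates in the core (|offset| <=
    ``core_span``) against the window edges (|offset| >= ``edge_min``),
    with a one-sided permutation test (core < edge).  Also checks the
    net-series conservation identity and the CpG-transition filter.
    """
    plan = GenePlan(n_genes=n_genes)
    genes, _scores = place_genes(genome_length, plan, seed=_spawn(seed, 0))
    spec = GenomeSpec(length=genome_length, seed=_spawn(seed, 1))
    genome = generate_sequence(spec, [(g.tss, GcPeakSpec()) for g in genes])
    model = MutationModel(gbgc_strength=0.0)
    dnms = generate_dnms(genome, genes, model, n_dnms, seed=_spawn(seed, 2))
    mapped = map_dnms(dnms, genes, genome, flank=flank)

    net, _ = dnm_profiles(mapped, n_genes=len(genes), flank=flank, window=100)
    ws = sum(1 for m in mapped if m.klass == "WS" and abs(m.rel_pos) <= flank)
    sw = sum(1 for m in mapped if m.klass == "SW" and abs(m.rel_pos) <= flank)
    conservation_residual = float(abs(net.raw.sum() * net.n_sources - (ws - sw)))

    filtered = dnm_profiles(
        mapped, n_genes=len(genes), flank=flank, exclude_cpg_transitions=True
    )
    # direct re-check of the filter on the raw mapped records
    from .dnm import drop_cpg_transitions

    survivors = drop_cpg_transitions(mapped)
    n_surviving_cpg_ts = sum(
        1
        for m in survivors
        if m.cpg_context and (m.from_base, m.to_base) in (("C", "T"), ("G", "A"))
    )

    # per-gene CpG-transition rates in core vs edge of the TSS window
    is_cpg_ts = {
        (m.gene_id, m.rel_pos)
        for m in mapped
        if m.cpg_context and (m.from_base, m.to_base) in (("C", "T"), ("G", "A"))
    }
    core_rates, edge_rates = [], []
    for gene in genes:
        # flank + 2 so the CpG check can look one base past the window
        region = extract_anchor_window(genome, gene, flank + 2)
        if region is None:
            continue
        seq = region.sequence
        a0 = region.anchor_offset
        core_sites = edge_sites = 0
        for off in range(-flank, flank + 1):
            in_core = abs(off) <= core_span
            in_edge = abs(off) >= edge_min
            if not (in_core or in_edge):
                continue
            i = a0 + off
            is_cpg_base = (seq[i] == "C" and seq[i + 1] == "G") or (
                seq[i] == "G" and seq[i - 1] == "C"
            )
            if is_cpg_base:
                if in_core:
                    core_sites += 1
                else:
                    edge_sites += 1
        core_hits = sum(
            1 for (gid, off) in is_cpg_ts if gid == gene.gene_id and abs(off) <= core_span
        )
        edge_hits = sum(
            1
            for (gid, off) in is_cpg_ts
            if gid == gene.gene_id and edge_min <= abs(off) <= flank
        )
        if core_sites > 0 and edge_sites > 0:
            core_rates.append(core_hits / core_sites)
            edge_rates.append(edge_hits / edge_sites)
    res = permutation_test(
        core_rates, edge_rates, n_perm=n_perm, seed=_spawn(seed, 3), alternative="less"
    )
    return {
        "conservation_residual": conservation_residual,
        "n_surviving_cpg_transitions": n_surviving_cpg_ts,
        "core_cpg_transition_rate": float(np.mean(core_rates)),
        "edge_cpg_transition_rate": float(np.mean(edge_rates)),
        "p_empirical_one_sided": res.p_empirical,
        "n_mapped": len(mapped),
        "n_genes_used": len(core_rates),
        "net_filtered_at_anchor": float(filtered[0].at(0)),
    }


# ----------------------------------------------------- profiler studies

def peak_recovery_study(
    n_genes: int = 200,
    genome_length: int = 4_000_000,
    amplitude: float = 0.25,
    sigma: float = 500.0,
    flank: int = 2000,
    seed: int = 0,
):
    """Plant one shared Gaussian GC peak at every TSS and recover its
    center from the positional GC profile by least-squares fit."""
    plan = GenePlan(n_genes=n_genes)
    genes, _ = place_genes(genome_length, plan, seed=_spawn(seed, 0))
    spec = GenomeSpec(length=genome_length, seed=_spawn(seed, 1))
    genome = generate_sequence(
        spec, [(g.tss, GcPeakSpec(amplitude=amplitude, sigma=sigma)) for g in genes]
    )
    regions = [
        r
        for r in (extract_anchor_window(genome, g, flank) for g in genes)
        if r is not None
    ]
    prof = positional_profile(regions)
    center, fit_sigma, fit_amp, baseline = fit_gaussian_peak(prof.offsets, prof.gc)
    return {
        "fitted_center": center,
        "fitted_sigma": fit_sigma,
        "fitted_amplitude": fit_amp,
        "fitted_baseline": baseline,
        "n_genes_profiled": len(regions),
    }


# --------------------------------------------------- statistics studies

def permutation_calibration_study(
    n_replicates: int = 1000,
    group_size: int = 30,
    n_perm: int = 200,
    alpha: float = 0.05,
    seed: int = 0,
):
    """Type-I error of the permutation test under a simulated null
    (both groups i.i.d. standard normal)."""
    rng = np.random.default_rng(seed)
    rejections = 0
    for i in range(n_replicates):
        a = rng.standard_normal(group_size)
        b = rng.standard_normal(group_size)
        res = permutation_test(a, b, n_perm=n_perm, seed=_spawn(seed, i))
        if res.p_empirical <= alpha:
            rejections += 1
    return {
        "rejection_rate": rejections / n_replicates,
        "n_replicates": n_replicates,
        "expected_rate": np.floor(alpha * (n_perm + 1)) / (n_perm + 1),
    }
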