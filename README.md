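# gcdrift

Tools for studying the evolutionary dynamics of the GC-content peak that
surrounds the transcription start sites (TSSs) of vertebrate
protein-coding genes — metagene GC/nucleotide/CpG profiling, trio-based
nucleotide-substitution inference with an outgroup, de novo mutation
(DNM) mapping, and the resampling statistics that compare them — plus a
synthetic genome and trio-evolution simulator so that every stage of the
pipeline can be validated against known ground truth without downloading
a single genome.

## The scientific problem

Most vertebrate protein-coding genes carry a peak of GC-content around
their TSS that decays roughly symmetrically into the upstream intergenic
region and the first intron. Whether that peak is maintained by
selection or by non-adaptive forces — GC-biased gene conversion (gBGC)
near recombination sites, and suppressed CpG deamination where promoters
are hypomethylated — can be read off its *substitution dynamics*: if the
weak-to-strong (W→S, A/T→G/C) and strong-to-weak (S→W) substitution
fluxes are out of balance, the peak is moving.

The package measures that balance three ways:

1. **Static profiles.** Metagene GC, per-nucleotide and CpG profiles
   around TSS anchors, either per position or in the field's binning
   schemes (20 bins along the mRNA; 41 bins normalized to the first exon
   length L — 20 upstream over 2L, one single-base bin at the TSS, 10
   exonic, 10 intronic; 40 bins along the ORF).
2. **Comparative inference.** Two ingroup species plus an outgroup are
   globally aligned (Needleman–Wunsch; ingroup pair first, then the
   outgroup against the two-row profile; 60% identity gate). At a column
   where the ingroups disagree and the outgroup matches exactly one of
   them, outgroup parsimony assigns a substitution to the other lineage
   with the outgroup base as the ancestral state. The per-offset net GC
   change is (#W→S − #S→W) per gene, smoothed with a 100-bp sliding
   window; per-type rates divide event counts by ancestral base counts.
   Restrictions to ORFs, 4-fold degenerate third codon positions (GC4),
   and individual coding exons are provided.
3. **De novo mutations.** Trio-sequencing DNMs are mapped onto ±2.5 kb
   TSS windows, classified by CpG context on the reference strand, and
   aggregated into the same net-change and rate series, optionally
   excluding CpG transitions (C→T/G→A in CpG).

Group differences are tested with a label-shuffling permutation test on
the difference of group means (1000 shuffles; both a Gaussian-tail and a
distribution-free empirical p are reported) and with the exact Wilcoxon
signed-rank test for paired bin contrasts (e.g. bin 1 vs bin 11 of the
mRNA).

The simulator closes the loop: synthetic chromosomes with Gaussian GC
peaks planted at TSSs over a 41% GC background, gene annotations with
TSS score tables, and a star-tree substitution process (AT-biased,
CpG-hypermutable, optional gBGC with strength *B* in a window around the
anchor, where (1+B)/(1−B) are the W:S repair odds) that emits an exact
truth table of every event — the oracle for the inference engine.

## Worked example

Simulate 200 TSS-like loci (2 kb, planted GC peak, CpG-depleted
background) and 200 flat intergenic controls, evolve a
human/chimp/gorilla-like trio under an AT-biased mutation model with no
gBGC, infer substitutions by outgroup parsimony, and test the anchor-local
net GC change:

```python
import numpy as np
from gcdrift import (GenomeSpec, GcPeakSpec, MutationModel, generate_sequence,
                     simulate_trio, align_trio, identity_gate, infer_substitutions,
                     net_gc_change_series, permutation_test)

model = MutationModel(base_rate=0.01, gbgc_strength=0.0)   # AT-biased, no gBGC
tss_nets, intergenic_nets, all_events = [], [], []
for i in range(200):
    peak = [(1000, GcPeakSpec(amplitude=0.25, sigma=300))]
    anc_tss = generate_sequence(GenomeSpec(length=2000, seed=i, cpg_depletion=0.8), peak)
    anc_int = generate_sequence(GenomeSpec(length=2000, seed=10_000 + i, cpg_depletion=0.8))
    for anc, anchor, out in ((anc_tss, 1000, tss_nets), (anc_int, None, intergenic_nets)):
        locus = simulate_trio(anc, model, (1.0, 1.0, 2.0), anchor=anchor, seed=20_000 + i)
        aln = align_trio(locus.seq_ingroup1, locus.seq_ingroup2, locus.seq_outgroup, band=50)
        if not identity_gate(aln):
            continue
        events = infer_substitutions(aln, anchor_offset=1000)
        if anchor is not None:
            all_events.extend(events)
        net = sum({"WS": 1, "SW": -1}.get(e.klass, 0) for e in events if abs(e.rel_pos) <= 500)
        out.append(net)

series = net_gc_change_series(all_events, span=1000, window=100, n_sources=len(tss_nets))
res = permutation_test(tss_nets, intergenic_nets, n_perm=1000, seed=0)
print(f"net GC change at the TSS (100-bp window): {series.at(0):+.4f} per gene")
print(f"TSS mean anchor net: {np.mean(tss_nets):+.3f}   intergenic: {np.mean(intergenic_nets):+.3f}")
print(f"permutation test: delta = {res.observed_delta:+.3f}, p_empirical = {res.p_empirical:.4g}")
```

Output:

```
net GC change at the TSS (100-bp window): -0.0047 per gene
TSS mean anchor net: -2.440   intergenic: -0.870
permutation test: delta = -1.570, p_empirical = 0.000999
```

The planted GC peak sits above the mutational equilibrium of the
AT-biased process, so it decays: the net GC change per gene at the TSS
is negative, and significantly more negative than in flat intergenic
controls. Re-running with `gbgc_strength=0.4` flips the sign at the
anchor — GC-biased gene conversion in a 1 kb window outweighs the
AT bias and the anchors gain GC.

A `gcdrift` command-line interface wraps the same stages
(`gcdrift simulate genome`, `gcdrift align`, `gcdrift substitutions`,
`gcdrift dnm`, `gcdrift stats permute`, ...); every input and output is
plain text (FASTA, GTF, BED, VCF, TSV).

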