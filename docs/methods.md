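# Methods

This note records the models, conventions and numerical choices behind
`gcdrift`, and what the simulation studies do and do not demonstrate.

## Coordinates and anchors

All internal coordinates are 0-based, half-open; GTF (1-based,
inclusive) and VCF (1-based) are converted only at the I/O boundary.
Anchor position 0 is the TSS base itself; negative offsets are upstream
in *transcript* orientation. Minus-strand genes store exon intervals in
genomic order and are reverse-complemented at extraction time, so a
TSS window of flank *f* covers genomic `[tss − f, tss + f)` on the plus
strand and the reverse complement of `[tss − f + 1, tss + f + 1)` on the
minus strand, with the TSS base at index *f* in both cases.

## Binning

Sequences are divided into equal bins by rounding cumulative fractions
(`round(i·L/n)`), which keeps every bin within ±1 bp of `L/n`. The
41-bin TSS/EIB scheme normalizes each gene to its first exon length L:
20 bins across the 2L upstream bases, one single-nucleotide bin at the
TSS, 10 bins across the first exon and 10 across the first L intronic
bases. The TSS bin is the single TSS nucleotide and the 10 exonic bins
span the whole exon (TSS base included); this is the only layout in
which "equally sized" bins coexist with a dedicated TSS bin, and it
makes bin 21 identical to the positional profile at offset 0 (a tested
invariant). Ambiguity characters (N) are excluded from numerators and
denominators everywhere. Isoform weighting is within-gene only; the
profile value of a bin is the unweighted mean over genes. CpG density
uses the per-dinucleotide denominator (#CG / (len − 1)); a per-nucleotide
variant would differ only by the factor (len − 1)/len.

## Mutation model

Substitution rates per site compose multiplicatively from:

* `base_rate` — expected substitutions per site per branch-length unit;
* `ts_tv_ratio` κ (default 2): transition weight κ, each transversion 1,
  normalized so the unmodified per-site total equals `base_rate`;
* `ws_bias` w (default 2/3) on all W→S target rates. The CpG-free
  equilibrium GC of the process is w/(1+w); w = 2/3 puts it at 0.40,
  consistent with a ~41% genome-average GC sitting near its mutational
  equilibrium — the default was fixed by this calculation;
* `cpg_multiplier` (default 10) on C→T and G→A at CpG sites — the
  canonical elevation of methylated-CpG transitions — reset to 1 inside
  `hypomethyl_window` (default 1 kb, centered on the anchor), emulating
  promoter hypomethylation;
* `gbgc_strength` B (default 0.4) inside `gbgc_window` (default 1 kb):
  W→S rates × (1+B), S→W rates × (1−B). B = 0.4 corresponds to
  heteroduplex repair favouring G/C about 70% of the time
  ((1+B)/(1−B) = 7/3). gBGC is transmission bias, not mutation bias; the
  rate-multiplier formulation is the standard substitution-level
  approximation.

Windows are total widths centered on the anchor (|pos − anchor| ≤
window/2). Per site, the event *count* is Poisson with the ancestral
site rate times branch length; events are applied in a random global
order with substitution *types* drawn from current-context rates, so
CpG context is re-evaluated as the sequence mutates. The truth table
replays exactly onto each derived sequence (tested byte-for-byte). The
three lineages evolve independently from the same ancestor (star tree),
which matches the parsimony assumption being tested and makes
outgroup-branch misinference measurable. No indels are simulated:
substitution mapping skips gap columns, so indel realism adds nothing
to what the truth table can check; alignment robustness is exercised
separately with manually introduced gaps.

## Synthetic genomes

Bases are sampled independently with
P(G or C at x) = background + Σ amplitude·exp(−(x−c)²/2σ²), clipped to
[0,1]; G/C and A/T are resolved uniformly. The optional
`cpg_depletion` step (default off) destroys each CG dinucleotide with
the given probability (C→T or G→A, equally), emulating the historical
deamination that leaves vertebrate genomes at roughly 20% of expected
CpG density. The comparative studies enable depletion 0.8 as a study
condition: in an undepleted genome ~4% of dinucleotides are CpG, and a
10× CpG transition rate then dominates the intergenic S→W flux, pushing
flat 41% GC controls far out of equilibrium — an artifact of the
independent-base model, not a feature of real genomes. Genes are placed
greedily left to right with a randomized intergenic gap in
[min_gap, 2·min_gap], bounded at 1000 structure redraws; all exon
lengths are drawn from `first_exon_length_range` (the plan has no
separate range for internal exons).

## Alignment

Needleman–Wunsch with linear gap penalties; default match/mismatch/gap
= +1/−1/−2 (the standard choice; configurable). Traceback ties break
deterministically: diagonal, then up, then left. N matches nothing and
scores as mismatch. Trios are aligned progressively — ingroup pair
first, then the outgroup against the two-row profile (column score =
mean of per-row match/mismatch; gap rows score as mismatch) — because a
full 3-D sum-of-pairs DP is cubic and infeasible at 5 kb; the 3-D DP is
provided for short sequences as an independent optimum and the
progressive aligner reproduces it at near-identical, indel-free
settings. The identity gate (default 0.60, inclusive) applies to the
*minimum* of the three pairwise identities, the conservative reading of
a "60% alignment cutoff"; a mean-identity mode is available. An optional
diagonal band accelerates the DP for near-identical sequences; banded
and full DP agree whenever the optimal path stays inside the band
(tested, and trivially true at the divergences simulated here). One
caveat, observed about once per 500 five-kilobase loci: even with zero
indels, a gapped alignment of a locally repetitive stretch can outscore
the identity alignment, shifting a few event coordinates. The inference
oracle audits such loci separately.

## Substitution inference

Outgroup parsimony, strict: a call requires the ingroups to disagree
and the outgroup to match exactly one; gap/N columns and three-way
disagreements are discarded (no fallback is defined for them). Event
positions are in each ingroup's own ungapped coordinates. CpG context
is evaluated on the inferred ancestral sequence of the event's own
ingroup (both CpG positions), so a substitution cannot create or
destroy its own context. Rate denominators use inferred-ancestral base
counts — self-consistent with the numerator, which also counts
ancestral states; extant-base denominators can be computed by passing
extant sequences to the same counting helper. GC4 sites are classified
on the ancestral ORF; ORFs must start with ATG and have length
divisible by 3, and ORF coordinates are spliced (coding sequence
concatenated in transcript order).

## DNM mapping

CpG context is classified on the reference strand (deamination is
symmetric across the CG palindrome, and the C→T/G→A filter is defined
in reference terms); bases are strand-adjusted per gene after
classification. A DNM within the flank of several TSSs counts once per
gene, matching per-gene normalization. Indel records are skipped with a
logged count.

## Statistics

The permutation test shuffles pooled values into groups of the original
sizes; the Gaussian p is the tail area of a normal fitted to the null
deltas, the empirical p is (1 + #{|null| ≥ |obs|})/(n_perm + 1)
(add-one, so p > 0), and exhaustive enumeration replaces sampling for
small pools (where the exact fraction over all assignments is
reported). Two-sided is the default; internal studies assert on the
empirical p because it is distribution-free. The Wilcoxon signed-rank
test drops zeros, mid-ranks ties, and uses the exact null of the
signed-rank sum for n ≤ 25 — computed by convolving the rank generating
function, which stays exact under tied mid-ranks (ranks are doubled to
keep the support integral) — and the tie-corrected normal approximation
above.

## Simulation studies and their scope

`gcdrift.scenarios` wires the generators through the full pipeline at
desk-scale problem sizes (chosen so each study finishes in roughly a
minute on one CPU while effects remain many standard errors wide):
500 × 5 kb trio loci at 0.002 subs/site/branch for the inference
oracle; 500 TSS-like + 500 intergenic 2 kb loci at ~1% per-branch
divergence for the directionality contrast; 20,000 DNMs over a 3 Mb,
150-gene genome for the hypomethylation dip; 200 genes over 4 Mb for
peak recovery; 1000 null replicates for calibration.

What passing these studies shows: the inference engine is exact where
parsimony is determined (single-hit sites), the aggregation conserves
counts, the statistics are calibrated, and the pipeline recovers the
direction and location of planted effects. What they do not show: the
generator has no isochores, repeats, selection, context effects beyond
CpG, or indels, so the studies validate the *machinery*, not the
biological conclusions one would draw from real genomes. Divergence-time
calibration (converting net changes into rates per million years) is
out of scope.

## Known limitations

* Multi-hit sites are intrinsically beyond parsimony; the oracle audits
  rather than corrects them.
* The progressive trio aligner is not guaranteed optimal for divergent,
  indel-rich inputs; the 60% gate bounds the regime it is used in.
* Mean-identity gating, extant-base rate denominators, and one-sided
  permutation p-values exist as options; defaults are the conservative
  choices documented above.
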