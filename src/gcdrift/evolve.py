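"""Forward simulator of nucleotide substitution on a star phylogeny.

An ancestral sequence is evolved independently into two ingroup lineages
and one outgroup lineage under a parameterized point-substitution
process, producing the exact truth table of events that downstream
outgroup-parsimony inference is measured against.

The mutation model composes, per site and target base:

* a transition:transversion ratio ``kappa`` (transition rate ``kappa x``
  each transversion rate ``x``, normalized so the unmodified per-site
  total equals ``base_rate``);
* an AT drift bias: all weak-to-strong (A/T -> G/C) rates are multiplied
  by ``ws_bias`` (< 1 reproduces the genome-wide pull toward AT);
* CpG hypermutability: C->T and G->A rates at CpG sites are multiplied
  by ``cpg_multiplier``, except within ``hypomethyl_window`` bp centered
  on the anchor, emulating promoter hypomethylation;
* GC-biased gene conversion: within ``gbgc_window`` bp centered on the
  anchor, W->S rates are multiplied by (1 + B) and S->W rates by
  (1 - B).  The default B = 0.4 corresponds to heteroduplex mismatches
  being resolved toward G/C about 70% of the time (70:30 odds,
  (1+B)/(1-B) = 7/3).

Per site, the event count is Poisson with the *ancestral* site rate
times the branch length; events are applied in a random global order
with substitution types drawn from the current-context rates, so CpG
context is re-evaluated as the sequence mutates.  No indels are
simulated.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .dnm import DNMRecord
from .seq import A, C, G, T, decode, encode

_TRANSITION = {(A, G), (G, A), (C, T), (T, C)}


@dataclass(frozen=True)
class MutationModel:
    """Defaults: ``ws_bias = 2/3`` puts the CpG-free mutational
    equilibrium at GC = ws_bias / (1 + ws_bias) = 0.40, consistent with a
    ~41% genome-average GC sitting near its mutation-rate equilibrium;
    ``cpg_multiplier = 10`` is the canonical ~10x elevation of methylated
    CpG transitions; ``ts_tv_ratio = 2`` is a typical mammalian
    transition:transversion ratio."""

    base_rate: float = 0.005
    ts_tv_ratio: float = 2.0
    ws_bias: float = 2.0 / 3.0
    cpg_multiplier: float = 10.0
    gbgc_strength: float = 0.4
    gbgc_window: int = 1000
    hypomethyl_window: int = 1000

    def __post_init__(self):
        if self.base_rate < 0 or self.ts_tv_ratio < 0 or self.ws_bias < 0:
            raise ValueError("rates must be >= 0")
        if self.cpg_multiplier < 0:
            raise ValueError("cpg_multiplier must be >= 0")
        if not 0.0 <= self.gbgc_strength < 1.0:
            raise ValueError("gbgc_strength must be in [0, 1)")
        if self.gbgc_window < 0 or self.hypomethyl_window < 0:
            raise ValueError("windows must be >= 0")


@dataclass(frozen=True)
class TruthEvent:
    site: int
    lineage: str
    from_base: str
    to_base: str
    order_index: int

    def __post_init__(self):
        if self.from_base == self.to_base:
            raise ValueError("from_base must differ from to_base")


@dataclass
class TrioLocus:
    """Three sequences evolved from a common ancestor (star tree), with
    the union truth table (per-lineage event order in ``order_index``)."""

    ancestor: str
    seq_ingroup1: str
    seq_ingroup2: str
    seq_outgroup: str
    anchor: int
    truth: list = field(default_factory=list)


def _relative_weights(model: MutationModel) -> np.ndarray:
    """(4, 4) matrix of unmodified rates from base i to base j, scaled so
    each row sums to base_rate."""
    kappa = model.ts_tv_ratio
    w = np.zeros((4, 4))
    for i in range(4):
        for j in range(4):
            if i == j:
                continue
            w[i, j] = kappa if (i, j) in _TRANSITION else 1.0
    return w * (model.base_rate / (kappa + 2.0))


def _anchor_masks(length: int, anchor: int | None, model: MutationModel):
    pos = np.arange(length)
    if anchor is None:
        no = np.zeros(length, dtype=bool)
        return no, no
    gbgc = np.abs(pos - anchor) <= model.gbgc_window // 2
    hypo = np.abs(pos - anchor) <= model.hypomethyl_window // 2
    return gbgc, hypo


def target_rate_matrix(
    codes: np.ndarray, model: MutationModel, anchor: int | None = None
) -> np.ndarray:
    """Per-site, per-target substitution rates, shape (len, 4).

    Entries for the current base and for N sites are zero.  Vectorized;
    used both to draw Poisson event counts from the ancestor and (via
    :func:`site_rates`) as the analytic expectation in tests.
    """
    L = codes.shape[0]
    base_w = _relative_weights(model)
    rates = np.zeros((L, 4))
    acgt = codes < 4
    rates[acgt] = base_w[codes[acgt]]
    # weak->strong bias
    weak = (codes == A) | (codes == T)
    rates[:, [C, G]] *= np.where(weak, model.ws_bias, 1.0)[:, None]
    # CpG hypermutability on the C and the G of each CpG
    is_c_of_cpg = np.zeros(L, dtype=bool)
    is_g_of_cpg = np.zeros(L, dtype=bool)
    is_c_of_cpg[:-1] = (codes[:-1] == C) & (codes[1:] == G)
    is_g_of_cpg[1:] = (codes[1:] == G) & (codes[:-1] == C)
    gbgc_mask, hypo_mask = _anchor_masks(L, anchor, model)
    cpg_factor = np.where(hypo_mask, 1.0, model.cpg_multiplier)
    rates[:, T] *= np.where(is_c_of_cpg, cpg_factor, 1.0)  # C->T
    rates[:, A] *= np.where(is_g_of_cpg, cpg_factor, 1.0)  # G->A
    # gBGC inside the anchor window
    if model.gbgc_strength > 0:
        strong = (codes == C) | (codes == G)
        up = gbgc_mask & weak
        down = gbgc_mask & strong
        rates[:, [C, G]] *= np.where(up, 1.0 + model.gbgc_strength, 1.0)[:, None]
        rates[:, [A, T]] *= np.where(down, 1.0 - model.gbgc_strength, 1.0)[:, None]
    return rates


def site_rates(codes: np.ndarray, model: MutationModel, anchor: int | None = None) -> np.ndarray:
    """Total per-site substitution rate (sum over targets)."""
    return target_rate_matrix(codes, model, anchor).sum(axis=1)


def _site_targets(codes: np.ndarray, site: int, model: MutationModel, gbgc_mask, hypo_mask):
    """Current-context target rates at one site (length-4 vector)."""
    b = codes[site]
    if b >= 4:
        return np.zeros(4)
    r = _relative_weights(model)[b].copy()
    if b in (A, T):
        r[C] *= model.ws_bias
        r[G] *= model.ws_bias
        if gbgc_mask[site] and model.gbgc_strength > 0:
            r[C] *= 1.0 + model.gbgc_strength
            r[G] *= 1.0 + model.gbgc_strength
    else:
        if gbgc_mask[site] and model.gbgc_strength > 0:
            r[A] *= 1.0 - model.gbgc_strength
            r[T] *= 1.0 - model.gbgc_strength
        cpg_factor = 1.0 if hypo_mask[site] else model.cpg_multiplier
        if b == C and site + 1 < len(codes) and codes[site + 1] == G:
            r[T] *= cpg_factor
        if b == G and site > 0 and codes[site - 1] == C:
            r[A] *= cpg_factor
    return r


def evolve_sequence(
    ancestor: str,
    model: MutationModel,
    branch_length: float,
    anchor: int | None = None,
    seed=0,
    lineage: str = "ingroup1",
):
    """Evolve one lineage; returns ``(derived_sequence, truth_events)``.

    Event counts per site are Poisson(ancestral site rate x branch
    length); events are applied sequentially in a random order with the
    substitution type drawn from current-context rates.  Replaying the
    truth list over the ancestor reproduces the derived sequence exactly.
    """
    if branch_length < 0:
        raise ValueError("branch_length must be >= 0")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    codes = encode(ancestor).copy()
    if branch_length == 0:
        return ancestor, []
    total0 = site_rates(codes, model, anchor)
    counts = rng.poisson(total0 * branch_length)
    sites = np.repeat(np.nonzero(counts)[0], counts[counts > 0])
    rng.shuffle(sites)
    gbgc_mask, hypo_mask = _anchor_masks(len(codes), anchor, model)
    events = []
    bases = "ACGT"
    for site in sites:
        r = _site_targets(codes, int(site), model, gbgc_mask, hypo_mask)
        total = r.sum()
        if total <= 0:
            continue
        to = int(rng.choice(4, p=r / total))
        events.append(
            TruthEvent(
                site=int(site),
                lineage=lineage,
                from_base=bases[codes[site]],
                to_base=bases[to],
                order_index=len(events),
            )
        )
        codes[site] = to
    return decode(codes), events


def replay_truth(ancestor: str, events) -> str:
    """Apply truth events in order_index order; the evolver's invariant is
    that this reproduces the derived sequence byte-for-byte."""
    codes = list(ancestor)
    for ev in sorted(events, key=lambda e: e.order_index):
        if codes[ev.site] != ev.from_base:
            raise ValueError(
                f"truth replay mismatch at site {ev.site}: "
                f"sequence has {codes[ev.site]}, event expects {ev.from_base}"
            )
        codes[ev.site] = ev.to_base
    return "".join(codes)


def simulate_trio(
    ancestor: str,
    model: MutationModel,
    branch_lengths,
    anchor: int | None = None,
    seed=0,
) -> TrioLocus:
    """Evolve ingroup1, ingroup2 and the outgroup independently from the
    same ancestor (star tree).  ``branch_lengths`` is (t1, t2, t_out)."""
    t1, t2, t_out = branch_lengths
    ss = np.random.SeedSequence(seed)
    rngs = [np.random.default_rng(s) for s in ss.spawn(3)]
    s1, e1 = evolve_sequence(ancestor, model, t1, anchor, rngs[0], "ingroup1")
    s2, e2 = evolve_sequence(ancestor, model, t2, anchor, rngs[1], "ingroup2")
    s3, e3 = evolve_sequence(ancestor, model, t_out, anchor, rngs[2], "outgroup")
    return TrioLocus(
        ancestor=ancestor,
        seq_ingroup1=s1,
        seq_ingroup2=s2,
        seq_outgroup=s3,
        anchor=anchor if anchor is not None else 0,
        truth=e1 + e2 + e3,
    )


def generate_dnms(
    genome: str,
    genes,
    model: MutationModel,
    n_mutations: int,
    seed=0,
    chrom: str = "chr1",
):
    """Sample de novo mutations proportionally to per-site rates.

    The rate model is the same as for lineage evolution, with the
    anchor-window effects (CpG suppression by hypomethylation, and gBGC
    if enabled) applied around *every* gene TSS.  Records carry 1-based
    positions and are sorted by position; ``ref`` always matches the
    genome.
    """
    if n_mutations < 0:
        raise ValueError("n_mutations must be >= 0")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if n_mutations == 0:
        return []
    codes = encode(genome)
    rates = target_rate_matrix(codes, model, anchor=None)
    if model.cpg_multiplier != 1.0 or model.gbgc_strength > 0:
        pos = np.arange(len(codes))
        hypo = np.zeros(len(codes), dtype=bool)
        gbgc = np.zeros(len(codes), dtype=bool)
        for gene in genes:
            hypo |= np.abs(pos - gene.tss) <= model.hypomethyl_window // 2
            gbgc |= np.abs(pos - gene.tss) <= model.gbgc_window // 2
        # undo CpG hypermutability inside hypomethylated promoter windows
        is_c_of_cpg = np.zeros(len(codes), dtype=bool)
        is_g_of_cpg = np.zeros(len(codes), dtype=bool)
        is_c_of_cpg[:-1] = (codes[:-1] == C) & (codes[1:] == G)
        is_g_of_cpg[1:] = (codes[1:] == G) & (codes[:-1] == C)
        if model.cpg_multiplier != 0:
            rates[:, T] /= np.where(hypo & is_c_of_cpg, model.cpg_multiplier, 1.0)
            rates[:, A] /= np.where(hypo & is_g_of_cpg, model.cpg_multiplier, 1.0)
        if model.gbgc_strength > 0:
            weak = (codes == A) | (codes == T)
            strong = (codes == C) | (codes == G)
            rates[:, [C, G]] *= np.where(gbgc & weak, 1.0 + model.gbgc_strength, 1.0)[:, None]
            rates[:, [A, T]] *= np.where(gbgc & strong, 1.0 - model.gbgc_strength, 1.0)[:, None]
    total = rates.sum(axis=1)
    p = total / total.sum()
    sites = rng.choice(len(codes), size=n_mutations, p=p)
    bases = "ACGT"
    records = []
    for site in np.sort(sites):
        r = rates[site]
        alt = int(rng.choice(4, p=r / r.sum()))
        records.append(
            DNMRecord(
                chrom=chrom,
                pos=int(site) + 1,
                ref=bases[codes[site]],
                alt=bases[alt],
            )
        )
    return records
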