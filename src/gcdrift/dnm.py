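"""Mapping de novo mutations (DNMs) onto TSS-anchored windows.

Single-nucleotide DNMs falling within a flank of a gene's best TSS are
assigned to that gene with strand-adjusted bases (minus-strand genes
complement ref/alt and negate the genomic offset); a DNM within range
of several TSSs counts once per gene.  CpG context is classified on the
*reference* strand of the genome — deamination chemistry is symmetric
across the CG palindrome, and the C->T / G->A filter is expressed in
reference terms.  Aggregation mirrors the substitution series: net GC
change per gene and per-type rates over mutable-base counts, both with
100-bp sliding windows, optionally after removing CpG-context
transitions (C->T and G->A in CpGs).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .regions import extract_anchor_window
from .seq import ws_class
from .substitutions import WindowSeries, sliding_window

logger = logging.getLogger(__name__)

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


@dataclass(frozen=True)
class DNMRecord:
    """One de novo SNV: 1-based genomic position, ref and alt alleles."""

    chrom: str
    pos: int
    ref: str
    alt: str

    def __post_init__(self):
        if self.ref == self.alt:
            raise ValueError("ref must differ from alt")

    @property
    def is_snv(self) -> bool:
        return len(self.ref) == 1 and len(self.alt) == 1 and \
            self.ref in "ACGT" and self.alt in "ACGT"


@dataclass(frozen=True)
class MappedDNM:
    gene_id: str
    rel_pos: int
    from_base: str
    to_base: str
    cpg_context: bool
    klass: str = field(default="")

    def __post_init__(self):
        if not self.klass:
            object.__setattr__(self, "klass", ws_class(self.from_base, self.to_base))


def classify_cpg_context(genome, chrom: str, pos: int, ref: str) -> bool:
    """True iff the (1-based) position lies in a CpG on the reference
    strand: ref C followed by G, or ref G preceded by C.  A missing
    neighbor at a contig edge counts as non-CpG."""
    seq = genome if isinstance(genome, str) else genome[chrom]
    i = pos - 1
    if not 0 <= i < len(seq):
        raise IndexError(f"position {pos} outside {chrom}")
    if seq[i] != ref:
        raise ValueError(
            f"ref {ref} does not match genome base {seq[i]} at {chrom}:{pos}"
        )
    if ref == "C":
        return i + 1 < len(seq) and seq[i + 1] == "G"
    if ref == "G":
        return i >= 1 and seq[i - 1] == "C"
    return False


def map_dnms(dnms, genes, genome, flank: int = 2500) -> list:
    """Assign DNMs to every gene whose TSS lies within ``flank``.

    ``rel_pos`` is the offset from the TSS in transcript orientation;
    bases are complemented for minus-strand genes.  Indel records are
    skipped with a logged count.
    """
    genes = list(genes)
    tss = np.array([g.tss for g in genes])
    order = np.argsort(tss)
    tss_sorted = tss[order]
    mapped = []
    n_indels = 0
    for rec in dnms:
        if not rec.is_snv:
            n_indels += 1
            continue
        pos0 = rec.pos - 1
        lo = int(np.searchsorted(tss_sorted, pos0 - flank, side="left"))
        hi = int(np.searchsorted(tss_sorted, pos0 + flank, side="right"))
        for k in range(lo, hi):
            gene = genes[order[k]]
            if gene.chrom != rec.chrom:
                continue
            rel = pos0 - gene.tss if gene.strand == "+" else gene.tss - pos0
            if abs(rel) > flank:
                continue
            if gene.strand == "+":
                from_b, to_b = rec.ref, rec.alt
            else:
                from_b, to_b = _COMP[rec.ref], _COMP[rec.alt]
            cpg = classify_cpg_context(genome, rec.chrom, rec.pos, rec.ref)
            mapped.append(
                MappedDNM(
                    gene_id=gene.gene_id,
                    rel_pos=int(rel),
                    from_base=from_b,
                    to_base=to_b,
                    cpg_context=cpg,
                )
            )
    if n_indels:
        logger.info("skipped %d non-SNV records", n_indels)
    return mapped


def drop_cpg_transitions(mapped) -> list:
    """Remove CpG-context C->T and G->A records (strand-adjusted bases:
    the reference-strand C->T appears as G->A on minus-strand genes,
    both are removed)."""
    return [
        m
        for m in mapped
        if not (m.cpg_context and (m.from_base, m.to_base) in (("C", "T"), ("G", "A")))
    ]


def mutable_base_counts(genome, genes, flank: int = 2500):
    """Per-offset counts of each base over the TSS windows of ``genes``
    (transcript orientation), the rate denominators for DNM profiles.

    Returns ``(counts, n_genes)`` with counts mapping base -> array over
    offsets [-flank, flank]; genes whose window leaves the chromosome
    are skipped (as in window extraction).
    """
    width = 2 * flank + 1
    counts = {b: np.zeros(width, dtype=np.int64) for b in "ACGT"}
    n_genes = 0
    for gene in genes:
        region = extract_anchor_window(genome, gene, flank + 1)
        if region is None:
            continue
        n_genes += 1
        seq = region.sequence
        a0 = region.anchor_offset
        for off in range(-flank, flank + 1):
            base = seq[a0 + off]
            if base in counts:
                counts[base][off + flank] += 1
    return counts, n_genes


def dnm_profiles(
    mapped,
    n_genes: int,
    mutable_counts: dict | None = None,
    flank: int = 2500,
    window: int = 100,
    exclude_cpg_transitions: bool = False,
):
    """Net-GC-change and per-type rate series for mapped DNMs.

    Returns ``(net, rates)``: ``net`` is the (#WS - #SW)/n_genes series
    over offsets [-flank, flank], smoothed; ``rates`` maps each observed
    (from, to) pair to its rate series (counts / mutable-base counts),
    or is empty when ``mutable_counts`` is None.
    """
    if exclude_cpg_transitions:
        mapped = drop_cpg_transitions(mapped)
    width = 2 * flank + 1
    offsets = np.arange(-flank, flank + 1)
    net_raw = np.zeros(width)
    type_counts: dict = {}
    for m in mapped:
        if abs(m.rel_pos) > flank:
            continue
        if m.klass == "WS":
            net_raw[m.rel_pos + flank] += 1.0
        elif m.klass == "SW":
            net_raw[m.rel_pos + flank] -= 1.0
        key = (m.from_base, m.to_base)
        type_counts.setdefault(key, np.zeros(width))[m.rel_pos + flank] += 1.0
    net_raw /= max(n_genes, 1)
    net = WindowSeries(
        offsets=offsets,
        values=sliding_window(net_raw, window),
        raw=net_raw,
        n_sources=n_genes,
        window=window,
    )
    rates: dict = {}
    if mutable_counts is not None:
        for (from_b, to_b), num in type_counts.items():
            den = mutable_counts[from_b].astype(float)
            if den.shape[0] != width:
                raise ValueError("mutable_counts flank does not match the DNM flank")
            if (num[den == 0] > 0).any():
                raise ValueError(
                    "DNMs present at offsets with zero mutable-base count "
                    "(counts from a different gene set?)"
                )
            with np.errstate(invalid="ignore", divide="ignore"):
                raw = np.where(den > 0, num / den, np.nan)
            rates[(from_b, to_b)] = WindowSeries(
                offsets=offsets,
                values=sliding_window(raw, window),
                raw=raw,
                n_sources=n_genes,
                window=window,
            )
    return net, rates
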