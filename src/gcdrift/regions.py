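"""Resolving gene models to anchored analysis windows.

Operations here turn a genome plus gene annotation into the sequence
sets the profilers and substitution mappers consume: best-TSS selection
from a score table, fixed-flank TSS windows, first-exon-length
normalized TSS/EIB regions, random intergenic controls, and GC-matched
control selection.  Genes whose windows fall off the chromosome are
skipped with a logged reason (silent per-gene attrition, mirroring how
such pipelines shed unusable genes).
"""

from __future__ import annotations

import logging

import numpy as np

from .models import AnchoredRegion, EibNormalizedRegions, GeneModel
from .seq import revcomp

logger = logging.getLogger(__name__)


def _chrom_seq(genome, chrom):
    if isinstance(genome, str):
        return genome
    return genome[chrom]


def select_best_tss(transcripts, strand: str = "+") -> str:
    """Pick the transcript with the highest score (tags per million).

    Ties are broken by the 5'-most TSS in transcript orientation
    (smallest genomic TSS on +, largest on -), then lexicographically by
    transcript id.

    Parameters
    ----------
    transcripts : list of (transcript_id, tss, score)
    """
    transcripts = list(transcripts)
    if not transcripts:
        raise ValueError("select_best_tss on an empty transcript list")
    for _, _, score in transcripts:
        if score < 0:
            raise ValueError("scores must be >= 0")
    sign = 1 if strand == "+" else -1

    def key(t):
        tid, tss, score = t
        return (-score, sign * tss, tid)

    return min(transcripts, key=key)[0]


def extract_anchor_window(genome, gene: GeneModel, flank: int) -> AnchoredRegion | None:
    """Sequence window of 2*flank centered on the TSS, transcript-oriented.

    Position 0 (``anchor_offset = flank``) is the TSS base; positive
    offsets run 5'->3' into the gene.  Minus-strand genes are
    reverse-complemented.  Returns None (with a logged reason) when the
    window exceeds the chromosome bounds.
    """
    seq = _chrom_seq(genome, gene.chrom)
    if gene.strand == "+":
        start, end = gene.tss - flank, gene.tss + flank
    else:
        start, end = gene.tss - flank + 1, gene.tss + flank + 1
    if start < 0 or end > len(seq):
        logger.info(
            "gene %s skipped: TSS window [%d, %d) outside chromosome of length %d",
            gene.gene_id, start, end, len(seq),
        )
        return None
    window = seq[start:end]
    if gene.strand == "-":
        window = revcomp(window)
    return AnchoredRegion(
        source_id=gene.gene_id,
        anchor_kind="TSS",
        sequence=window,
        anchor_offset=flank,
        chrom=gene.chrom,
        strand=gene.strand,
        genomic_start=start,
    )


def extract_eib_regions(genome, gene: GeneModel) -> EibNormalizedRegions | None:
    """First-exon-length normalized regions (upstream 2L, exon L, intron L).

    Returns None with a logged reason for single-exon genes ("no EIB"),
    first introns shorter than L, or upstream spans leaving the
    chromosome.
    """
    seq = _chrom_seq(genome, gene.chrom)
    if gene.n_exons < 2:
        logger.info("gene %s skipped: no EIB", gene.gene_id)
        return None
    L = gene.first_exon_length
    es, ee = gene.first_exon
    isx, ie = gene.first_intron
    if ie - isx < L:
        logger.info(
            "gene %s skipped: first intron (%d bp) shorter than first exon (%d bp)",
            gene.gene_id, ie - isx, L,
        )
        return None
    if gene.strand == "+":
        up_start, up_end = es - 2 * L, es
        if up_start < 0:
            logger.info("gene %s skipped: upstream span out of bounds", gene.gene_id)
            return None
        upstream = seq[up_start:up_end]
        exon1 = seq[es:ee]
        intron_prefix = seq[ee : ee + L]
    else:
        up_start, up_end = ee, ee + 2 * L
        if up_end > len(seq):
            logger.info("gene %s skipped: upstream span out of bounds", gene.gene_id)
            return None
        upstream = revcomp(seq[up_start:up_end])
        exon1 = revcomp(seq[es:ee])
        intron_prefix = revcomp(seq[es - L : es])
    return EibNormalizedRegions(
        source_id=gene.gene_id,
        upstream=upstream,
        exon1=exon1,
        intron1_prefix=intron_prefix,
    )


def sample_intergenic(
    genome,
    genes,
    n: int,
    length: int,
    buffer: int = 10_000,
    seed: int = 0,
    chrom: str | None = None,
    anchor_kind: str = "intergenic",
):
    """Draw n mutually non-overlapping regions >= buffer bp from any gene.

    The anchor sits at the region midpoint.  Deterministic given the
    seed.  Raises RuntimeError if placement fails after 1000 * n draws.
    """
    if n < 0:
        raise ValueError("n must be >= 0")
    seq = _chrom_seq(genome, chrom) if chrom else genome
    if not isinstance(seq, str):
        raise ValueError("pass chrom= when genome is a mapping")
    if length > len(seq):
        raise ValueError("region length exceeds chromosome length")
    spans = sorted((g.start, g.end) for g in genes if chrom is None or g.chrom == chrom)
    starts = np.array([s for s, _ in spans])
    ends = np.array([e for _, e in spans])
    rng = np.random.default_rng(seed)
    chosen: list[tuple[int, int]] = []
    regions = []
    attempts = 0
    max_attempts = max(1000 * n, 1)
    while len(regions) < n:
        if attempts >= max_attempts:
            raise RuntimeError(
                f"could only place {len(regions)}/{n} intergenic regions of "
                f"{length} bp with buffer {buffer} after {max_attempts} draws"
            )
        attempts += 1
        s = int(rng.integers(0, len(seq) - length + 1))
        e = s + length
        # distance >= buffer from every gene span
        if len(starts) and bool(np.any((starts < e + buffer) & (ends > s - buffer))):
            continue
        if any(cs < e and ce > s for cs, ce in chosen):
            continue
        chosen.append((s, e))
        regions.append(
            AnchoredRegion(
                source_id=f"intergenic{len(regions) + 1:05d}",
                anchor_kind=anchor_kind,
                sequence=seq[s:e],
                anchor_offset=length // 2,
                chrom=chrom,
                strand="+",
                genomic_start=s,
            )
        )
    return regions


def gc_match(pool, target_gcs, bin_width: float = 0.01, seed: int = 0):
    """Select, per target GC value, one pool region from the same GC bin.

    Sampling is without replacement within each bin of width
    ``bin_width``; the selected set's per-bin GC histogram therefore
    equals the target's exactly.

    Parameters
    ----------
    pool : list of (region, gc)
    target_gcs : list of float

    Raises
    ------
    ValueError
        If a target bin is undersupplied, naming the bin.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    rng = np.random.default_rng(seed)

    def bin_of(gc):
        # clip so gc == 1.0 falls in the last bin
        return min(int(gc / bin_width), int(1.0 / bin_width) - 1)

    by_bin: dict[int, list] = {}
    for region, gc in pool:
        by_bin.setdefault(bin_of(gc), []).append(region)
    for regions in by_bin.values():
        # shuffle once per bin, then pop: sampling without replacement
        rng.shuffle(regions)
    selected = []
    for gc in target_gcs:
        b = bin_of(gc)
        bucket = by_bin.get(b)
        if not bucket:
            lo, hi = b * bin_width, (b + 1) * bin_width
            raise ValueError(
                f"GC bin [{lo:.3f}, {hi:.3f}) undersupplied in the pool "
                f"(needed for target gc={gc:.4f})"
            )
        selected.append(bucket.pop())
    return selected
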