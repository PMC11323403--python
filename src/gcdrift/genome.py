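"""Synthetic genome generator.

Produces chromosomes whose GC structure mimics empirical vertebrate
genomes at the level this package analyses: a uniform background GC
probability (~0.41 genome-wide in human) with Gaussian-shaped GC peaks
planted at chosen positions (TSSs), plus non-overlapping gene models and
a per-transcript TSS score table emulating CAGE tags-per-million.  Every
base is drawn independently; G vs C and A vs T are chosen uniformly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .models import GeneModel
from .seq import decode


@dataclass(frozen=True)
class GenomeSpec:
    """Chromosome-level parameters.

    ``cpg_depletion`` (default 0 = off) is the fraction of CG
    dinucleotides destroyed after sampling (C->T or G->A, equally),
    emulating the historical deamination that leaves vertebrate genomes
    at ~20% of the expected CpG density; per-base sampling is otherwise
    independent.
    """

    chrom_name: str = "chr1"
    length: int = 1_000_000
    background_gc: float = 0.41
    seed: int = 0
    cpg_depletion: float = 0.0

    def __post_init__(self):
        if self.length <= 0:
            raise ValueError("length must be positive")
        if not 0.0 <= self.background_gc <= 1.0:
            raise ValueError("background_gc must be in [0, 1]")
        if not 0.0 <= self.cpg_depletion <= 1.0:
            raise ValueError("cpg_depletion must be in [0, 1]")


@dataclass(frozen=True)
class GcPeakSpec:
    """Gaussian GC enrichment added on top of the background.

    ``P(G or C at x) = background + amplitude * exp(-(x-c)^2 / (2 sigma^2))``
    where ``c = peak position + center_offset``.
    """

    amplitude: float = 0.25
    sigma: float = 500.0
    center_offset: int = 0

    def __post_init__(self):
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")


@dataclass(frozen=True)
class GenePlan:
    n_genes: int = 50
    first_exon_length_range: tuple = (100, 400)
    n_exons_range: tuple = (2, 8)
    intron_length_range: tuple = (500, 3000)
    min_intergenic_gap: int = 5000
    strand_policy: str = "both"  # or "plus_only"

    def __post_init__(self):
        if self.n_genes < 0:
            raise ValueError("n_genes must be >= 0")
        for name in ("first_exon_length_range", "n_exons_range", "intron_length_range"):
            lo, hi = getattr(self, name)
            if lo <= 0 or hi < lo:
                raise ValueError(f"{name} must be a positive (min, max) range")
        if self.min_intergenic_gap < 0:
            raise ValueError("min_intergenic_gap must be >= 0")
        if self.strand_policy not in ("both", "plus_only"):
            raise ValueError("strand_policy must be 'both' or 'plus_only'")


def generate_sequence(spec: GenomeSpec, peaks=()) -> str:
    """Draw a chromosome sequence with Gaussian GC peaks.

    Parameters
    ----------
    spec : GenomeSpec
    peaks : iterable of (position, GcPeakSpec)
        Peak centers (before ``center_offset``) must lie in [0, length).

    Returns
    -------
    str
        Sequence of length ``spec.length``; deterministic given
        ``spec.seed``.
    """
    p_gc = np.full(spec.length, spec.background_gc)
    x = np.arange(spec.length, dtype=float)
    for pos, peak in peaks:
        if not 0 <= pos < spec.length:
            raise ValueError(f"peak position {pos} outside [0, {spec.length})")
        if spec.background_gc + peak.amplitude > 1.0 + 1e-12:
            raise ValueError("background_gc + amplitude must not exceed 1")
        c = pos + peak.center_offset
        p_gc += peak.amplitude * np.exp(-((x - c) ** 2) / (2 * peak.sigma**2))
    np.clip(p_gc, 0.0, 1.0, out=p_gc)
    rng = np.random.default_rng(spec.seed)
    is_gc = rng.random(spec.length) < p_gc
    second = rng.random(spec.length) < 0.5
    # A=0, C=1, G=2, T=3
    codes = np.where(is_gc, np.where(second, 1, 2), np.where(second, 0, 3)).astype(np.int8)
    if spec.cpg_depletion > 0 and spec.length > 1:
        # CG dinucleotides cannot overlap, so a vectorized pass is exact
        is_cpg = (codes[:-1] == 1) & (codes[1:] == 2)
        destroy = is_cpg & (rng.random(spec.length - 1) < spec.cpg_depletion)
        to_t = destroy & (rng.random(spec.length - 1) < 0.5)
        codes[:-1][to_t] = 3  # C -> T
        codes[1:][destroy & ~to_t] = 0  # G -> A
    return decode(codes)


def place_genes(sequence_length: int, plan: GenePlan, seed: int = 0, chrom: str = "chr1"):
    """Place non-overlapping gene models left to right.

    Gene structures (exon count, exon and intron lengths) are drawn from
    the plan's ranges; all exon lengths use ``first_exon_length_range``.
    Returns ``(genes, tss_scores)`` where ``tss_scores`` is a DataFrame
    with one positive ``tpm_score`` per transcript.

    Raises
    ------
    RuntimeError
        If a gene cannot be fitted after 1000 structure redraws, naming
        the violated constraint.
    """
    rng = np.random.default_rng(seed)
    genes = []
    cursor = plan.min_intergenic_gap
    for g in range(plan.n_genes):
        placed = False
        for _ in range(1000):
            n_exons = int(rng.integers(plan.n_exons_range[0], plan.n_exons_range[1] + 1))
            exon_lens = rng.integers(
                plan.first_exon_length_range[0],
                plan.first_exon_length_range[1] + 1,
                size=n_exons,
            )
            intron_lens = rng.integers(
                plan.intron_length_range[0],
                plan.intron_length_range[1] + 1,
                size=max(n_exons - 1, 0),
            )
            span = int(exon_lens.sum() + intron_lens.sum())
            gap = int(rng.integers(plan.min_intergenic_gap, 2 * plan.min_intergenic_gap + 1))
            start = cursor + gap
            if start + span + plan.min_intergenic_gap <= sequence_length:
                placed = True
                break
        if not placed:
            raise RuntimeError(
                f"could not place gene {g + 1}/{plan.n_genes} on a "
                f"{sequence_length} bp chromosome with "
                f"min_intergenic_gap={plan.min_intergenic_gap}"
            )
        exons = []
        pos = start
        for i in range(n_exons):
            exons.append((pos, pos + int(exon_lens[i])))
            pos += int(exon_lens[i])
            if i < n_exons - 1:
                pos += int(intron_lens[i])
        if plan.strand_policy == "plus_only":
            strand = "+"
        else:
            strand = "+" if rng.random() < 0.5 else "-"
        tss = exons[0][0] if strand == "+" else exons[-1][1] - 1
        gene_id = f"gene{g + 1:05d}"
        genes.append(
            GeneModel(
                gene_id=gene_id,
                chrom=chrom,
                strand=strand,
                tss=tss,
                exons=tuple(exons),
                isoforms=((f"{gene_id}.t1", 1.0),),
            )
        )
        cursor = pos
    tpm = np.round(rng.exponential(scale=10.0, size=len(genes)) + 0.1, 3)
    tss_scores = pd.DataFrame(
        {
            "transcript_id": [g.isoforms[0][0] for g in genes],
            "tpm_score": tpm,
        }
    )
    return genes, tss_scores
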