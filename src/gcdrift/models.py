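"""Shared domain types: gene models and anchored sequence regions.

Coordinate conventions (applied everywhere in the package):

* all internal coordinates are 0-based, half-open; GTF (1-based, inclusive)
  and BED (0-based, half-open) are converted at the I/O boundary;
* the anchor position 0 is the TSS base itself; negative offsets are
  upstream in *transcript* orientation;
* minus-strand genes store exon intervals in genomic order, and are
  reverse-complemented into transcript orientation at extraction time.
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class GeneModel:
    """One protein-coding gene anchored at its best TSS.

    Parameters
    ----------
    gene_id : str
        Stable identifier.
    chrom : str
        Chromosome / contig name.
    strand : str
        ``"+"`` or ``"-"``.
    tss : int
        0-based genomic position of the first transcribed base.
    exons : tuple of (int, int)
        Sorted, non-overlapping 0-based half-open intervals in genomic order.
    cds_start, cds_end : int or None
        Optional 0-based half-open CDS bounds (genomic coordinates).
    isoforms : tuple of (str, float)
        ``(transcript_id, weight)`` pairs; weights sum to 1.
    """

    gene_id: str
    chrom: str
    strand: str
    tss: int
    exons: tuple
    cds_start: int | None = None
    cds_end: int | None = None
    isoforms: tuple = ()

    def __post_init__(self):
        if self.strand not in "+-":
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        exons = tuple(tuple(e) for e in self.exons)
        object.__setattr__(self, "exons", exons)
        if not exons:
            raise ValueError("gene must have at least one exon")
        for (s, e) in exons:
            if e <= s:
                raise ValueError(f"empty exon interval ({s}, {e})")
        for (_, e0), (s1, _) in zip(exons, exons[1:]):
            if s1 < e0:
                raise ValueError("exons must be sorted and non-overlapping")
        expected_tss = exons[0][0] if self.strand == "+" else exons[-1][1] - 1
        if self.tss != expected_tss:
            raise ValueError(
                f"tss {self.tss} does not match the 5'-most exon boundary "
                f"{expected_tss} on strand {self.strand}"
            )
        if not self.isoforms:
            object.__setattr__(self, "isoforms", ((self.gene_id + ".t1", 1.0),))
        else:
            object.__setattr__(self, "isoforms", tuple(tuple(i) for i in self.isoforms))
        total = sum(w for _, w in self.isoforms)
        if abs(total - 1.0) > 1e-6:
            raise ValueError(f"isoform weights sum to {total}, expected 1")

    @property
    def start(self) -> int:
        """Genomic start of the gene span."""
        return self.exons[0][0]

    @property
    def end(self) -> int:
        """Genomic end (half-open) of the gene span."""
        return self.exons[-1][1]

    @property
    def n_exons(self) -> int:
        return len(self.exons)

    @property
    def first_exon(self) -> tuple:
        """First exon in transcript orientation (genomic interval)."""
        return self.exons[0] if self.strand == "+" else self.exons[-1]

    @property
    def first_exon_length(self) -> int:
        s, e = self.first_exon
        return e - s

    @property
    def first_intron(self) -> tuple:
        """First intron in transcript orientation (genomic interval).

        Raises ``ValueError`` for single-exon genes.
        """
        if self.n_exons < 2:
            raise ValueError(f"gene {self.gene_id} has no intron")
        if self.strand == "+":
            return (self.exons[0][1], self.exons[1][0])
        return (self.exons[-2][1], self.exons[-1][0])


@dataclass(frozen=True)
class AnchoredRegion:
    """A sequence window in transcript orientation with a marked anchor.

    ``sequence[anchor_offset]`` is the base at anchor position 0 (the TSS
    base for TSS windows, the midpoint for intergenic controls).
    """

    source_id: str
    anchor_kind: str  # TSS | EIB | intergenic | hotspot
    sequence: str
    anchor_offset: int
    chrom: str | None = None
    strand: str = "+"
    genomic_start: int | None = None  # genomic start of the window (0-based)

    def __post_init__(self):
        if not (0 <= self.anchor_offset < len(self.sequence)):
            raise ValueError(
                f"anchor_offset {self.anchor_offset} outside sequence of "
                f"length {len(self.sequence)}"
            )

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def offsets(self):
        """Range of anchor-relative offsets covered by this region."""
        return range(-self.anchor_offset, len(self.sequence) - self.anchor_offset)


@dataclass(frozen=True)
class EibNormalizedRegions:
    """First-exon-length-normalized sequences around the TSS and first EIB.

    With L = first exon length: ``upstream`` covers the 2L bases 5' of the
    TSS, ``exon1`` the first exon (L bases), and ``intron1_prefix`` the
    first L bases of intron 1 — all in transcript orientation, jointly a
    contiguous genomic slice.
    """

    source_id: str
    upstream: str
    exon1: str
    intron1_prefix: str

    def __post_init__(self):
        L = len(self.exon1)
        if L == 0:
            raise ValueError("empty first exon")
        if len(self.upstream) != 2 * L or len(self.intron1_prefix) != L:
            raise ValueError(
                f"segment lengths must be (2L, L, L); got "
                f"({len(self.upstream)}, {L}, {len(self.intron1_prefix)})"
            )

    @property
    def exon_length(self) -> int:
        return len(self.exon1)

    def concatenated(self) -> str:
        return self.upstream + self.exon1 + self.intron1_prefix
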