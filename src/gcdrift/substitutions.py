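"""Outgroup-parsimony substitution inference and windowed aggregation.

Given a gated trio alignment (two ingroups + outgroup), a substitution
is called at a column where the ingroups disagree and the outgroup
matches exactly one of them: the ancestral state is the outgroup base
and the event is assigned to the other ingroup lineage.  Columns with a
gap or N, identical ingroups, or three distinct bases yield no call.

Events carry positions in each ingroup's own ungapped coordinates
relative to the anchor, a CpG-context flag evaluated on the inferred
ancestral ingroup sequence, and a W/S class (W = A/T, S = G/C).  The
per-offset difference (#WS - #SW), normalized per source and smoothed
with a 100-bp sliding window, is the "net GC change" series; per-type
substitution rates divide event counts by the ancestral count of the
source base at each offset.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .align import TrioAlignment
from .profiles import ORF40, BinnedProfile, sliding_window
from .seq import ws_class

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SubstitutionEvent:
    source_id: str
    rel_pos: int
    lineage: str  # ingroup1 | ingroup2
    from_base: str
    to_base: str
    cpg_context: bool = False
    klass: str = field(default="")

    def __post_init__(self):
        if self.from_base == self.to_base:
            raise ValueError("from_base must differ from to_base")
        expected = ws_class(self.from_base, self.to_base)
        if not self.klass:
            object.__setattr__(self, "klass", expected)
        elif self.klass != expected:
            raise ValueError(f"klass {self.klass} inconsistent with bases")


@dataclass
class WindowSeries:
    """Per-offset values after sliding-window smoothing.

    ``raw`` holds the unsmoothed per-offset values (NaN = undefined);
    ``values`` the smoothed series; ``n_sources`` the normalizer used.
    """

    offsets: np.ndarray
    values: np.ndarray
    raw: np.ndarray
    n_sources: int
    window: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"offset": self.offsets, "value": self.values, "raw": self.raw}
        )

    def at(self, offset: int) -> float:
        idx = int(offset - self.offsets[0])
        if not 0 <= idx < len(self.values):
            raise IndexError(f"offset {offset} outside series")
        return float(self.values[idx])


def infer_substitutions(
    alignment: TrioAlignment,
    anchor_offset: int,
    source_id: str = "",
) -> list:
    """Call lineage-assigned substitutions from a trio alignment.

    ``anchor_offset`` is the index of anchor position 0 in each
    *ungapped* ingroup sequence (the sequences are already in transcript
    orientation).  CpG context is evaluated on the inferred ancestral
    sequence of the event's own ingroup (both CpG positions).
    """
    a = alignment.gapped_in1
    b = alignment.gapped_in2
    o = alignment.gapped_out
    calls = []  # (lineage_idx, ungapped_pos, from, to)
    i1 = i2 = 0
    for col in range(alignment.columns):
        ca, cb, co = a[col], b[col], o[col]
        pa, pb = i1, i2
        if ca != "-":
            i1 += 1
        if cb != "-":
            i2 += 1
        if "-" in (ca, cb, co) or "N" in (ca, cb, co):
            continue
        if ca == cb:
            continue
        if co == cb:
            calls.append((1, pa, co, ca))
        elif co == ca:
            calls.append((2, pb, co, cb))
        # all three distinct: ambiguous, no call
    # ancestral ingroup sequences: revert each lineage's own calls
    anc1 = list(a.replace("-", ""))
    anc2 = list(b.replace("-", ""))
    for lineage_idx, pos, from_b, _ in calls:
        (anc1 if lineage_idx == 1 else anc2)[pos] = from_b
    events = []
    for lineage_idx, pos, from_b, to_b in calls:
        anc = anc1 if lineage_idx == 1 else anc2
        cpg = (
            (from_b == "C" and pos + 1 < len(anc) and anc[pos + 1] == "G")
            or (from_b == "G" and pos > 0 and anc[pos - 1] == "C")
        )
        events.append(
            SubstitutionEvent(
                source_id=source_id,
                rel_pos=pos - anchor_offset,
                lineage=f"ingroup{lineage_idx}",
                from_base=from_b,
                to_base=to_b,
                cpg_context=cpg,
            )
        )
    return events


def ancestral_sequences(alignment: TrioAlignment, events=None, anchor_offset: int = 0):
    """Inferred ancestral (pre-substitution) ungapped ingroup sequences.

    Reverts each lineage's called events on its own ungapped sequence.
    ``anchor_offset`` must match the one used to infer ``events``; if
    ``events`` is None they are inferred here.
    """
    if events is None:
        events = infer_substitutions(alignment, anchor_offset=anchor_offset)
    anc1 = list(alignment.gapped_in1.replace("-", ""))
    anc2 = list(alignment.gapped_in2.replace("-", ""))
    for ev in events:
        target = anc1 if ev.lineage == "ingroup1" else anc2
        target[ev.rel_pos + anchor_offset] = ev.from_base
    return "".join(anc1), "".join(anc2)


def net_gc_change_series(
    events, span: int, window: int = 100, n_sources: int = 1
) -> WindowSeries:
    """Per-offset (#WS - #SW) / n_sources with sliding-window smoothing.

    Offsets cover [-span, span]; WW and SS events contribute nothing.
    """
    offsets = np.arange(-span, span + 1)
    raw = np.zeros(offsets.shape[0])
    for ev in events:
        if not -span <= ev.rel_pos <= span:
            continue
        if ev.klass == "WS":
            raw[ev.rel_pos + span] += 1.0
        elif ev.klass == "SW":
            raw[ev.rel_pos + span] -= 1.0
    raw /= n_sources
    return WindowSeries(
        offsets=offsets,
        values=sliding_window(raw, window),
        raw=raw,
        n_sources=n_sources,
        window=window,
    )


def ancestral_base_counts(ancestral_regions, span: int) -> dict:
    """Per-offset counts of each base over ancestral sequences.

    Parameters
    ----------
    ancestral_regions : iterable of (sequence, anchor_offset)
        Inferred ancestral ingroup sequences with the index of anchor 0.
    span : int
        Offsets covered: [-span, span].

    Returns
    -------
    dict mapping base -> int array of length 2*span + 1.
    """
    width = 2 * span + 1
    counts = {b: np.zeros(width, dtype=np.int64) for b in "ACGT"}
    for seq, anchor in ancestral_regions:
        lo = max(0, anchor - span)
        hi = min(len(seq), anchor + span + 1)
        for pos in range(lo, hi):
            base = seq[pos]
            if base in counts:
                counts[base][pos - anchor + span] += 1
    return counts


def substitution_rate_series(
    events,
    base_counts: dict,
    from_base: str,
    to_base: str,
    span: int,
    window: int = 100,
) -> WindowSeries:
    """Per-offset rate of one substitution type.

    rate(offset) = #events(from->to at offset) / count of ``from_base``
    at that offset in the ancestral sequences.  Offsets with a zero
    denominator are undefined (NaN) and excluded from smoothing.
    """
    offsets = np.arange(-span, span + 1)
    num = np.zeros(offsets.shape[0])
    for ev in events:
        if ev.from_base == from_base and ev.to_base == to_base and -span <= ev.rel_pos <= span:
            num[ev.rel_pos + span] += 1.0
    den = base_counts[from_base].astype(float)
    if den.shape[0] != offsets.shape[0]:
        raise ValueError("base_counts span does not match the requested span")
    if (num[den == 0] > 0).any():
        raise ValueError("events present at offsets with zero ancestral count "
                         "(numerator and denominator from different gene sets?)")
    with np.errstate(invalid="ignore", divide="ignore"):
        raw = np.where(den > 0, num / den, np.nan)
    return WindowSeries(
        offsets=offsets,
        values=sliding_window(raw, window),
        raw=raw,
        n_sources=1,
        window=window,
    )


#: codon prefixes whose four third-base completions encode one amino acid
FOURFOLD_PREFIXES = frozenset(
    {"GC", "GG", "CC", "AC", "GT", "CT", "TC", "CG"}
)


def find_gc4_sites(orf: str) -> list:
    """Third positions of 4-fold degenerate codons in an ORF.

    The ORF must start with ATG and have length divisible by 3.
    """
    if len(orf) % 3 != 0:
        raise ValueError(f"ORF length {len(orf)} not divisible by 3")
    if not orf.upper().startswith("ATG"):
        raise ValueError("ORF must begin with the start codon ATG")
    orf = orf.upper()
    return [
        i + 2
        for i in range(0, len(orf), 3)
        if orf[i : i + 2] in FOURFOLD_PREFIXES
    ]


def orf_binned_net_gc(gene_orfs, n_bins: int = 40, gc4_only: bool = False) -> BinnedProfile:
    """Per-bin mean net GC change along length-normalized ORFs.

    Parameters
    ----------
    gene_orfs : iterable of (ancestral_orf, events)
        One entry per gene; events carry ``rel_pos`` in spliced ORF
        coordinates (0 = first base of ATG).  ORFs failing the ATG /
        length-divisible-by-3 preconditions are skipped with a logged
        reason.
    gc4_only : bool
        Restrict events to 4-fold degenerate third positions of the
        *ancestral* ORF (a substitution cannot reclassify its own site).
    """
    if n_bins != 40:
        raise ValueError("the ORF scheme uses 40 bins")
    per_gene = []
    for idx, (orf, events) in enumerate(gene_orfs):
        try:
            gc4 = set(find_gc4_sites(orf))
        except ValueError as exc:
            logger.info("ORF %d rejected: %s", idx, exc)
            continue
        L = len(orf)
        edges = np.rint(np.linspace(0.0, float(L), n_bins + 1)).astype(np.intp)
        vec = np.zeros(n_bins)
        for ev in events:
            if not 0 <= ev.rel_pos < L:
                continue
            if gc4_only and ev.rel_pos not in gc4:
                continue
            b = int(np.searchsorted(edges, ev.rel_pos, side="right") - 1)
            b = min(b, n_bins - 1)
            if ev.klass == "WS":
                vec[b] += 1.0
            elif ev.klass == "SW":
                vec[b] -= 1.0
        per_gene.append(vec)
    per_gene = np.array(per_gene) if per_gene else np.empty((0, n_bins))
    values = per_gene.mean(axis=0) if len(per_gene) else np.zeros(n_bins)
    return BinnedProfile(
        scheme=ORF40,
        values=values,
        n_genes=np.full(n_bins, len(per_gene)),
        per_gene=per_gene,
    )


def count_events_by_exon(events, coding_exon_lengths, exon_index: int):
    """WS and SW counts confined to one coding exon of an ORF.

    ``coding_exon_lengths`` are the CDS piece lengths per exon in
    transcript order; events carry ``rel_pos`` in spliced ORF
    coordinates.  Genes with fewer than 4 coding exons are excluded
    (returns None with a logged reason).
    """
    lengths = list(coding_exon_lengths)
    if len(lengths) < 4:
        logger.info("gene excluded: %d coding exons < 4", len(lengths))
        return None
    if not 1 <= exon_index <= len(lengths):
        raise ValueError(f"exon_index {exon_index} outside 1..{len(lengths)}")
    bounds = np.concatenate(([0], np.cumsum(lengths)))
    lo, hi = bounds[exon_index - 1], bounds[exon_index]
    ws = sum(1 for ev in events if lo <= ev.rel_pos < hi and ev.klass == "WS")
    sw = sum(1 for ev in events if lo <= ev.rel_pos < hi and ev.klass == "SW")
    return ws, sw
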