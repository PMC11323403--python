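"""Metagene profiling: binned and per-position composition around anchors.

Three binning schemes are supported, matching the standard metagene
layouts for vertebrate protein-coding genes:

* ``MRNA20`` — an mRNA divided into 20 equal bins, 5' to 3';
* ``TSSEIB41`` — 41 bins normalized to the first exon length L: 20 bins
  over the 2L upstream bases, one single-base bin at the TSS, 10 bins over
  the first exon, 10 over the first L intronic bases;
* ``ORF40`` — an ORF divided into 40 equal bins.

Per-gene values are isoform-weighted means; the profile value of a bin is
the unweighted mean over genes.  Per-position profiles report the A/C/G/T,
GC and CpG fractions at every anchor-relative offset.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .models import EibNormalizedRegions
from .seq import C, G, cpg_density, encode, gc_fraction  # noqa: F401 (re-export)

logger = logging.getLogger(__name__)

_SCHEME_BINS = {"MRNA20": 20, "TSSEIB41": 41, "ORF40": 40}


@dataclass(frozen=True)
class BinScheme:
    """A named binning layout; ``n_bins`` is fixed by the name."""

    name: str

    def __post_init__(self):
        if self.name not in _SCHEME_BINS:
            raise ValueError(f"unknown scheme {self.name!r}")

    @property
    def n_bins(self) -> int:
        return _SCHEME_BINS[self.name]


MRNA20 = BinScheme("MRNA20")
TSSEIB41 = BinScheme("TSSEIB41")
ORF40 = BinScheme("ORF40")


@dataclass
class BinnedProfile:
    """Per-bin mean values with contributing-gene counts.

    ``per_gene`` holds the gene × bin matrix the means were taken over
    (NaN where a gene did not contribute), so that downstream statistics
    (bin deltas, Wilcoxon) can reuse exactly the profiled values.
    """

    scheme: BinScheme
    values: np.ndarray
    n_genes: np.ndarray
    per_gene: np.ndarray | None = None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "bin": np.arange(1, self.scheme.n_bins + 1),
                "value": self.values,
                "n_genes": self.n_genes,
            }
        )


@dataclass
class PositionalProfile:
    """Per-offset base composition around an anchor.

    ``fractions`` maps each of A, C, G, T to its per-offset fraction;
    ``gc`` and ``cpg`` are the GC and CpG-start fractions.  CpGs are
    attributed to the offset of their C.
    """

    offsets: np.ndarray
    fractions: dict
    gc: np.ndarray
    cpg: np.ndarray
    coverage: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        data = {"offset": self.offsets}
        for b in "ACGT":
            data[b] = self.fractions[b]
        data["GC"] = self.gc
        data["CpG"] = self.cpg
        data["coverage"] = self.coverage
        return pd.DataFrame(data)


def bin_edges(length: int, n_bins: int) -> np.ndarray:
    """Equal-size bin boundaries by rounding cumulative fractions.

    All bins are within +/-1 bp of ``length / n_bins``.
    """
    return np.rint(np.linspace(0.0, float(length), n_bins + 1)).astype(np.intp)


def _gc_by_edges(codes: np.ndarray, edges: np.ndarray) -> np.ndarray:
    """Per-bin GC fraction given integer codes and bin edges (NaN if a bin
    has no ACGT bases)."""
    gc = np.concatenate(([0], np.cumsum((codes == C) | (codes == G))))
    acgt = np.concatenate(([0], np.cumsum(codes < 4)))
    num = (gc[edges[1:]] - gc[edges[:-1]]).astype(float)
    den = (acgt[edges[1:]] - acgt[edges[:-1]]).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(den > 0, num / den, np.nan)


def _item_bins(item, scheme: BinScheme) -> np.ndarray:
    """41/20/40-bin GC vector for one isoform item, NaN-padded on failure."""
    if scheme.name == "TSSEIB41":
        if not isinstance(item, EibNormalizedRegions):
            raise TypeError("TSSEIB41 profiling requires EibNormalizedRegions items")
        L = item.exon_length
        if L < 10:
            raise _SkipGene(f"first exon length {L} < 10 bins")
        up = encode(item.upstream)
        ex = encode(item.exon1)
        intr = encode(item.intron1_prefix)
        vec = np.empty(41)
        vec[0:20] = _gc_by_edges(up, bin_edges(2 * L, 20))
        # bin 21: the single TSS nucleotide (= first exon base)
        vec[20] = _gc_by_edges(ex[:1], np.array([0, 1]))[0]
        vec[21:31] = _gc_by_edges(ex, bin_edges(L, 10))
        vec[31:41] = _gc_by_edges(intr, bin_edges(L, 10))
        return vec
    seq = item
    if not isinstance(seq, str):
        raise TypeError(f"{scheme.name} profiling requires sequence items")
    n = scheme.n_bins
    if len(seq) < n:
        raise _SkipGene(f"sequence length {len(seq)} < {n} bins")
    return _gc_by_edges(encode(seq), bin_edges(len(seq), n))


class _SkipGene(Exception):
    """Per-gene attrition with a logged reason."""


def bin_profile(genes, scheme: BinScheme) -> BinnedProfile:
    """Binned GC profile over a collection of genes.

    Parameters
    ----------
    genes : sequence
        One entry per gene.  An entry is either a single item (sequence
        string, or :class:`EibNormalizedRegions` for TSSEIB41) or a list of
        ``(item, weight)`` isoform pairs with weights summing to 1.
    scheme : BinScheme

    Returns
    -------
    BinnedProfile
        Bin values are unweighted means over genes of isoform-weighted
        per-gene values; genes whose sequences are shorter than the bin
        count are skipped with a logged reason.
    """
    rows = []
    for idx, entry in enumerate(genes):
        if isinstance(entry, (str, EibNormalizedRegions)):
            entry = [(entry, 1.0)]
        try:
            vecs = np.array([_item_bins(item, scheme) for item, _ in entry])
        except _SkipGene as exc:
            logger.info("gene %d skipped: %s", idx, exc)
            continue
        weights = np.array([w for _, w in entry], dtype=float)
        if abs(weights.sum() - 1.0) > 1e-6:
            raise ValueError("isoform weights must sum to 1")
        rows.append(weights @ vecs)
    if not rows:
        per_gene = np.empty((0, scheme.n_bins))
    else:
        per_gene = np.array(rows)
    with np.errstate(invalid="ignore"):
        values = np.nanmean(per_gene, axis=0) if len(rows) else np.full(scheme.n_bins, np.nan)
    n_genes = np.sum(~np.isnan(per_gene), axis=0).astype(int)
    return BinnedProfile(scheme=scheme, values=values, n_genes=n_genes, per_gene=per_gene)


def positional_profile(regions) -> PositionalProfile:
    """Per-offset A/C/G/T, GC and CpG fractions over anchored regions.

    All regions must share anchor semantics (offset 0 = anchor base).
    CpG dinucleotides are attributed to the offset of the C; the CpG
    denominator at an offset is the number of regions covering both the
    offset and the next one.
    """
    regions = list(regions)
    if not regions:
        raise ValueError("positional_profile of an empty region set")
    lo = min(-r.anchor_offset for r in regions)
    hi = max(len(r.sequence) - r.anchor_offset for r in regions)
    width = hi - lo
    base_counts = np.zeros((4, width), dtype=np.int64)
    coverage = np.zeros(width, dtype=np.int64)
    cpg_counts = np.zeros(width, dtype=np.int64)
    cpg_cov = np.zeros(width, dtype=np.int64)
    for r in regions:
        codes = encode(r.sequence)
        start = -r.anchor_offset - lo
        sl = slice(start, start + len(codes))
        acgt = codes < 4
        for b in range(4):
            base_counts[b, sl] += codes == b
        coverage[sl] += acgt
        is_cpg = (codes[:-1] == C) & (codes[1:] == G)
        cpg_counts[start : start + len(codes) - 1] += is_cpg
        cpg_cov[start : start + len(codes) - 1] += acgt[:-1] & acgt[1:]
    with np.errstate(invalid="ignore", divide="ignore"):
        fr = {
            b: np.where(coverage > 0, base_counts[i] / coverage, np.nan)
            for i, b in enumerate("ACGT")
        }
        gc = np.where(coverage > 0, (base_counts[1] + base_counts[2]) / coverage, np.nan)
        cpg = np.where(cpg_cov > 0, cpg_counts / cpg_cov, np.nan)
    return PositionalProfile(
        offsets=np.arange(lo, hi),
        fractions=fr,
        gc=gc,
        cpg=cpg,
        coverage=coverage,
    )


def sliding_window(series, window: int = 100) -> np.ndarray:
    """Centered moving mean; the window truncates at the edges.

    NaN entries are treated as undefined and excluded (the mean divides
    by the number of defined positions actually in the window).
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    v = np.asarray(series, dtype=float)
    valid = ~np.isnan(v)
    kernel = np.ones(window)
    num = np.convolve(np.where(valid, v, 0.0), kernel, mode="same")
    den = np.convolve(valid.astype(float), kernel, mode="same")
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(den > 0, num / den, np.nan)


def fit_gaussian_peak(offsets, values):
    """Fit baseline + A*exp(-(x-c)^2 / (2 s^2)) to a positional profile.

    Returns ``(center, sigma, amplitude, baseline)``.  Used to locate a
    GC peak; NaN positions are dropped before fitting.
    """
    x = np.asarray(offsets, dtype=float)
    y = np.asarray(values, dtype=float)
    ok = ~np.isnan(y)
    x, y = x[ok], y[ok]
    baseline0 = float(np.median(y))
    amp0 = float(y.max() - baseline0)
    c0 = float(x[np.argmax(y)])
    s0 = max((x.max() - x.min()) / 10.0, 1.0)

    def model(x, c, s, a, b):
        return b + a * np.exp(-((x - c) ** 2) / (2 * s**2))

    popt, _ = curve_fit(model, x, y, p0=[c0, s0, amp0, baseline0], maxfev=20000)
    center, sigma, amplitude, baseline = popt
    return float(center), float(abs(sigma)), float(amplitude), float(baseline)
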