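"""Global alignment of homologous trio sequences.

The pairwise core is Needleman-Wunsch with linear gap penalties and a
deterministic traceback (diagonal preferred over up over left).  Trios
are aligned progressively following the phylogeny: the two ingroups are
aligned first, then the outgroup is aligned against the resulting
two-row profile (column-vs-base score = mean of the per-row match /
mismatch scores, with gap rows scoring as mismatch).  A true 3-D
sum-of-pairs DP (:func:`align_trio_exact`) is provided for short
sequences as an independent optimum, and the 60% identity gate filters
alignments before substitution inference.

N matches nothing (scores as mismatch); gap columns count as non-match
in identity computation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

from .seq import GAP, encode

_GAP_CHAR = "-"


@dataclass(frozen=True)
class ScoringScheme:
    """Match / mismatch scores and linear per-base gap penalty."""

    match: float = 1.0
    mismatch: float = -1.0
    gap: float = -2.0

    def __post_init__(self):
        if self.match <= self.mismatch:
            raise ValueError("match score must exceed mismatch score")
        if self.gap >= 0:
            raise ValueError("gap penalty must be negative")

    def base_matrix(self) -> np.ndarray:
        """5x5 substitution matrix over codes A,C,G,T,N (N never matches)."""
        m = np.full((5, 5), self.mismatch, dtype=np.float64)
        for i in range(4):
            m[i, i] = self.match
        return m

    def profile_matrix(self) -> np.ndarray:
        """36x5 matrix scoring an ingroup-pair column against a base.

        Columns are encoded as ``code1 * 6 + code2`` with codes over
        A,C,G,T,N,- ; a gap or N row contributes the mismatch score.
        """
        base = self.base_matrix()
        m = np.empty((36, 5), dtype=np.float64)
        for c1 in range(6):
            for c2 in range(6):
                for b in range(5):
                    s1 = self.mismatch if c1 >= 4 else base[c1, b]
                    s2 = self.mismatch if c2 >= 4 else base[c2, b]
                    m[c1 * 6 + c2, b] = 0.5 * (s1 + s2)
        return m


@dataclass
class TrioAlignment:
    """Gapped trio alignment (ingroup1, ingroup2, outgroup).

    ``pairwise_identities`` are (in1-in2, in1-out, in2-out) computed as
    matching columns / alignment length; gap and N columns count as
    non-matching.
    """

    gapped_in1: str
    gapped_in2: str
    gapped_out: str
    pairwise_identities: tuple
    columns: int

    def __post_init__(self):
        if not (len(self.gapped_in1) == len(self.gapped_in2) == len(self.gapped_out)):
            raise ValueError("gapped sequences must have equal length")

    @classmethod
    def from_gapped(cls, gapped_in1: str, gapped_in2: str, gapped_out: str):
        ids = (
            _identity(gapped_in1, gapped_in2),
            _identity(gapped_in1, gapped_out),
            _identity(gapped_in2, gapped_out),
        )
        return cls(gapped_in1, gapped_in2, gapped_out, ids, len(gapped_in1))

    def ungapped(self) -> tuple:
        return (
            self.gapped_in1.replace(_GAP_CHAR, ""),
            self.gapped_in2.replace(_GAP_CHAR, ""),
            self.gapped_out.replace(_GAP_CHAR, ""),
        )


def _identity(a: str, b: str) -> float:
    ca, cb = encode(a), encode(b)
    matches = int(np.count_nonzero((ca == cb) & (ca < 4)))
    return matches / len(a) if len(a) else 0.0


@njit(cache=True)
def _nw_fill(a, b, submat, gap, band):  # pragma: no cover - numba kernel
    # band < 0: full DP.  band >= 0: only cells with
    # |j - i * m / n| <= band + |m - n| are filled; everything outside
    # is -inf (caller must verify the band via a full-DP spot check or
    # choose it generously for near-identical sequences).
    n, m = a.shape[0], b.shape[0]
    NEG = np.float64(-1e18)
    prev = np.full(m + 1, NEG)
    cur = np.full(m + 1, NEG)
    ptr = np.zeros((n + 1, m + 1), dtype=np.uint8)  # 1=diag, 2=up, 3=left
    half = band + (m - n if m > n else n - m) if band >= 0 else 0
    jlo0, jhi0 = 0, m
    if band >= 0:
        jhi0 = min(m, half)
    for j in range(jlo0, jhi0 + 1):
        prev[j] = gap * j
        ptr[0, j] = 3
    ptr[0, 0] = 0
    for i in range(1, n + 1):
        center = (i * m) // n
        if band >= 0:
            jlo = max(0, center - half)
            jhi = min(m, center + half)
        else:
            jlo, jhi = 0, m
        if jlo > 0:
            # clear scratch cells just outside the band (the rolling
            # array still holds row i-2 there)
            for j in range(max(0, jlo - 2 - m // n), jlo):
                cur[j] = NEG
        if jlo == 0:
            cur[0] = gap * i
            ptr[i, 0] = 2
            jstart = 1
        else:
            jstart = jlo
        srow = submat[a[i - 1]]
        for j in range(jstart, jhi + 1):
            diag = prev[j - 1] + srow[b[j - 1]]
            up = prev[j] + gap
            left = cur[j - 1] + gap
            # tie-break: diagonal, then up, then left
            best = diag
            p = 1
            if up > best:
                best = up
                p = 2
            if left > best:
                best = left
                p = 3
            cur[j] = best
            ptr[i, j] = p
        for j in range(jhi + 1, min(m, jhi + 2 + m // n) + 1):
            cur[j] = NEG
        prev, cur = cur, prev
    return prev[m], ptr


def _traceback(ptr):
    """Walk the pointer matrix back from (n, m); yields moves reversed."""
    i, j = ptr.shape[0] - 1, ptr.shape[1] - 1
    moves = []
    while i > 0 or j > 0:
        p = ptr[i, j]
        moves.append(p)
        if p == 1:
            i -= 1
            j -= 1
        elif p == 2:
            i -= 1
        else:
            j -= 1
    moves.reverse()
    return moves


def needleman_wunsch(
    seq1: str,
    seq2: str,
    scoring: ScoringScheme = ScoringScheme(),
    band: int | None = None,
):
    """Optimal global alignment under linear gap penalties.

    Returns ``(aligned1, aligned2, score)``.  Traceback ties are broken
    deterministically: diagonal, then up (gap in ``seq2``), then left.

    ``band`` restricts the DP to a diagonal band of that half-width
    (plus the length difference); the result is optimal whenever the
    optimal path stays inside the band, which holds for near-identical
    sequences with far fewer gaps than the band width.
    """
    if not seq1 or not seq2:
        raise ValueError("cannot align empty sequences")
    if band is not None and band < 0:
        raise ValueError("band must be >= 0")
    a, b = encode(seq1), encode(seq2)
    score, ptr = _nw_fill(
        a, b, scoring.base_matrix(), float(scoring.gap), -1 if band is None else band
    )
    out1, out2 = [], []
    i = j = 0
    for p in _traceback(ptr):
        if p == 1:
            out1.append(seq1[i])
            out2.append(seq2[j])
            i += 1
            j += 1
        elif p == 2:
            out1.append(seq1[i])
            out2.append(_GAP_CHAR)
            i += 1
        else:
            out1.append(_GAP_CHAR)
            out2.append(seq2[j])
            j += 1
    return "".join(out1), "".join(out2), float(score)


def align_trio(
    seq_in1: str,
    seq_in2: str,
    seq_out: str,
    scoring: ScoringScheme = ScoringScheme(),
    band: int | None = None,
) -> TrioAlignment:
    """Progressive trio alignment: ingroup pair first, then the outgroup
    against the two-row ingroup profile.  ``band`` is forwarded to both
    pairwise steps (see :func:`needleman_wunsch`)."""
    if not (seq_in1 and seq_in2 and seq_out):
        raise ValueError("cannot align empty sequences")
    g1, g2, _ = needleman_wunsch(seq_in1, seq_in2, scoring, band=band)
    cols = encode(g1).astype(np.int64) * 6 + encode(g2).astype(np.int64)
    out_codes = encode(seq_out)
    _, ptr = _nw_fill(
        cols.astype(np.int8),
        out_codes,
        scoring.profile_matrix(),
        float(scoring.gap),
        -1 if band is None else band,
    )
    r1, r2, r3 = [], [], []
    i = j = 0
    for p in _traceback(ptr):
        if p == 1:
            r1.append(g1[i])
            r2.append(g2[i])
            r3.append(seq_out[j])
            i += 1
            j += 1
        elif p == 2:  # profile column vs gap in outgroup
            r1.append(g1[i])
            r2.append(g2[i])
            r3.append(_GAP_CHAR)
            i += 1
        else:  # outgroup insertion: new gap column in the profile
            r1.append(_GAP_CHAR)
            r2.append(_GAP_CHAR)
            r3.append(seq_out[j])
            j += 1
    return TrioAlignment.from_gapped("".join(r1), "".join(r2), "".join(r3))


def identity_gate(
    alignment: TrioAlignment, threshold: float = 0.60, mode: str = "min"
) -> bool:
    """Identity cutoff for trio alignments (inclusive).

    ``mode="min"`` (default, conservative) requires every pairwise
    identity to reach the threshold; ``mode="mean"`` gates on the mean.
    """
    ids = alignment.pairwise_identities
    if mode == "min":
        return min(ids) >= threshold
    if mode == "mean":
        return sum(ids) / 3.0 >= threshold
    raise ValueError(f"unknown identity gate mode {mode!r}")


def sum_of_pairs_score(alignment: TrioAlignment, scoring: ScoringScheme = ScoringScheme()) -> float:
    """Sum-of-pairs score of a trio alignment: per column, every base-base
    pair scores match/mismatch (N as mismatch), base-gap scores the gap
    penalty, gap-gap scores 0."""
    base = scoring.base_matrix()
    seqs = [encode(alignment.gapped_in1), encode(alignment.gapped_in2), encode(alignment.gapped_out)]
    total = 0.0
    for x in range(3):
        for y in range(x + 1, 3):
            cx, cy = seqs[x], seqs[y]
            both = (cx != GAP) & (cy != GAP)
            one = (cx != GAP) ^ (cy != GAP)
            total += base[cx[both], cy[both]].sum() + scoring.gap * int(one.sum())
    return float(total)


@njit(cache=True)
def _sp3_fill(a, b, c, submat, gap):  # pragma: no cover - numba kernel
    n1, n2, n3 = a.shape[0], b.shape[0], c.shape[0]
    NEG = -1e18
    H = np.full((n1 + 1, n2 + 1, n3 + 1), NEG)
    H[0, 0, 0] = 0.0
    for i in range(n1 + 1):
        for j in range(n2 + 1):
            for k in range(n3 + 1):
                if i == 0 and j == 0 and k == 0:
                    continue
                best = NEG
                if i > 0 and j > 0 and k > 0:
                    s = (
                        H[i - 1, j - 1, k - 1]
                        + submat[a[i - 1], b[j - 1]]
                        + submat[a[i - 1], c[k - 1]]
                        + submat[b[j - 1], c[k - 1]]
                    )
                    if s > best:
                        best = s
                if i > 0 and j > 0:
                    s = H[i - 1, j - 1, k] + submat[a[i - 1], b[j - 1]] + 2 * gap
                    if s > best:
                        best = s
                if i > 0 and k > 0:
                    s = H[i - 1, j, k - 1] + submat[a[i - 1], c[k - 1]] + 2 * gap
                    if s > best:
                        best = s
                if j > 0 and k > 0:
                    s = H[i, j - 1, k - 1] + submat[b[j - 1], c[k - 1]] + 2 * gap
                    if s > best:
                        best = s
                if i > 0:
                    s = H[i - 1, j, k] + 2 * gap
                    if s > best:
                        best = s
                if j > 0:
                    s = H[i, j - 1, k] + 2 * gap
                    if s > best:
                        best = s
                if k > 0:
                    s = H[i, j, k - 1] + 2 * gap
                    if s > best:
                        best = s
                H[i, j, k] = best
    return H[n1, n2, n3]


def align_trio_exact(
    seq1: str, seq2: str, seq3: str, scoring: ScoringScheme = ScoringScheme(), max_len: int = 60
) -> float:
    """Optimal sum-of-pairs score by full 3-D DP (cubic; short sequences
    only — intended as an independent optimum for the progressive
    aligner)."""
    if max(len(seq1), len(seq2), len(seq3)) > max_len:
        raise ValueError(f"3-D DP limited to sequences <= {max_len} bp")
    if not (seq1 and seq2 and seq3):
        raise ValueError("cannot align empty sequences")
    return float(
        _sp3_fill(encode(seq1), encode(seq2), encode(seq3), scoring.base_matrix(), float(scoring.gap))
    )
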