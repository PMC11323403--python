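"""Low-level DNA sequence utilities shared across the package.

Sequences are plain upper-case Python strings over the alphabet ACGTN
(``-`` appears only inside alignments).  For numerical kernels they are
encoded as small integer arrays with :func:`encode`.
"""

from __future__ import annotations

import numpy as np

#: canonical base order used by every integer encoding in the package
BASES = "ACGT"
A, C, G, T, N, GAP = 0, 1, 2, 3, 4, 5

_ENCODE = np.full(128, N, dtype=np.int8)
for _i, _b in enumerate(BASES):
    _ENCODE[ord(_b)] = _i
    _ENCODE[ord(_b.lower())] = _i
_ENCODE[ord("-")] = GAP

_DECODE = np.array(list(BASES + "N-"))

_COMPLEMENT = str.maketrans("ACGTNacgtn-", "TGCANtgcan-")

#: weak (A/T) and strong (G/C) base sets, the W/S classes of substitution work
WEAK = frozenset("AT")
STRONG = frozenset("GC")


def encode(sequence: str) -> np.ndarray:
    """Encode a DNA string as int8 codes (A=0, C=1, G=2, T=3, N=4, -=5)."""
    return _ENCODE[np.frombuffer(sequence.encode("ascii"), dtype=np.uint8)]


def decode(codes: np.ndarray) -> str:
    """Inverse of :func:`encode`."""
    return "".join(_DECODE[codes])


def revcomp(sequence: str) -> str:
    """Reverse complement (N and gap characters are preserved)."""
    return sequence.translate(_COMPLEMENT)[::-1]


def gc_fraction(sequence: str) -> float:
    """GC fraction of a sequence: (#G + #C) / (#A + #C + #G + #T).

    Characters outside ACGT (e.g. N) are excluded from both numerator and
    denominator.  Returns ``nan`` when the sequence has no ACGT bases.

    Raises
    ------
    ValueError
        If the sequence is empty.
    """
    if not sequence:
        raise ValueError("gc_fraction of an empty sequence is undefined")
    codes = encode(sequence)
    acgt = int(np.count_nonzero(codes < 4))
    if acgt == 0:
        return float("nan")
    gc = int(np.count_nonzero((codes == C) | (codes == G)))
    return gc / acgt


def cpg_density(sequence: str) -> float:
    """CpG dinucleotide density: (# of CG dinucleotides) / (len - 1).

    Raises
    ------
    ValueError
        If the sequence is shorter than 2 bases.
    """
    if len(sequence) < 2:
        raise ValueError("cpg_density requires at least 2 bases")
    codes = encode(sequence)
    n_cg = int(np.count_nonzero((codes[:-1] == C) & (codes[1:] == G)))
    return n_cg / (len(sequence) - 1)


def is_weak(base: str) -> bool:
    return base in WEAK


def is_strong(base: str) -> bool:
    return base in STRONG


def ws_class(from_base: str, to_base: str) -> str:
    """Classify a substitution as WS, SW, WW or SS (W = A/T, S = G/C)."""
    f = "W" if from_base in WEAK else "S"
    t = "W" if to_base in WEAK else "S"
    return f + t
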