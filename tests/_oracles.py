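"""Independent brute-force oracles shared by the test modules."""

import numpy as np
from scipy import stats as sps


def brute_force_nw_score(s1, s2, scoring):
    """Maximum global-alignment score by plain recursion over all paths."""

    def rec(i, j):
        if i == len(s1) and j == len(s2):
            return 0.0
        best = -np.inf
        if i < len(s1) and j < len(s2):
            sub = scoring.match if s1[i] == s2[j] else scoring.mismatch
            best = max(best, rec(i + 1, j + 1) + sub)
        if i < len(s1):
            best = max(best, rec(i + 1, j) + scoring.gap)
        if j < len(s2):
            best = max(best, rec(i, j + 1) + scoring.gap)
        return best

    return rec(0, 0)


def brute_force_wilcoxon_p(x, y):
    """Two-sided exact Wilcoxon signed-rank p by enumerating all sign
    assignments over the mid-ranked |differences| (zeros dropped)."""
    d = np.asarray(x, float) - np.asarray(y, float)
    d = d[d != 0]
    n = d.size
    if n == 0:
        return 0.0, 1.0
    ranks = sps.rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    ws = np.array([sum(ranks[k] for k in range(n) if m >> k & 1) for m in range(2**n)])
    p_low = np.mean(ws <= w_obs + 1e-9)
    p_high = np.mean(ws >= w_obs - 1e-9)
    return w_obs, min(1.0, 2.0 * min(p_low, p_high))
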