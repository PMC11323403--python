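"""Resampling statistics: Wilcoxon signed-rank and label-shuffling
permutation tests, plus the bin-delta summaries they consume.

The permutation test shuffles the pooled values of two groups into two
groups of the original sizes and records the difference of group means.
Two p-values are reported: a Gaussian tail area under a normal fitted to
the null deltas (the "area under the curve" construction), and the
distribution-free empirical p ``(1 + #{|null| >= |obs|}) / (n_perm + 1)``.

The Wilcoxon signed-rank test drops zero differences, mid-ranks ties,
and uses the exact null distribution of the signed-rank sum for
n_effective <= 25 (computed by convolving the rank generating function,
which remains exact under tied mid-ranks); above that, the normal
approximation with tie correction.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb

import numpy as np
from scipy import stats as sps

EXACT_WILCOXON_MAX_N = 25


@dataclass
class WilcoxonResult:
    """Signed-rank sum W (sum of ranks of positive differences), its
    two-sided p-value, and the number of nonzero-difference pairs."""

    statistic: float
    p_value: float
    n_effective: int
    exact: bool


@dataclass
class PermutationResult:
    observed_delta: float
    null_deltas: np.ndarray
    p_gaussian: float
    p_empirical: float
    n_perm: int
    seed: int | None = None
    exhaustive: bool = False


def bin_delta(per_gene_values, bin_i: int = 1, bin_j: int = 11):
    """Per-gene difference between two bins of a binned profile.

    Parameters
    ----------
    per_gene_values : array-like, shape (n_genes, n_bins)
        Per-gene bin values (e.g. ``BinnedProfile.per_gene``); NaN marks a
        missing bin.
    bin_i, bin_j : int
        1-based bin numbers; the default (1, 11) contrasts the start of an
        mRNA with its middle under the 20-bin scheme.

    Returns
    -------
    (deltas, mean) : per-gene ``value(bin_i) - value(bin_j)`` for genes
        where both bins are defined (others are excluded), and their mean.
    """
    m = np.asarray(per_gene_values, dtype=float)
    if m.ndim != 2:
        raise ValueError("per_gene_values must be 2-D (genes x bins)")
    for b in (bin_i, bin_j):
        if not (1 <= b <= m.shape[1]):
            raise ValueError(f"bin {b} outside 1..{m.shape[1]}")
    deltas = m[:, bin_i - 1] - m[:, bin_j - 1]
    deltas = deltas[~np.isnan(deltas)]
    mean = float(np.mean(deltas)) if deltas.size else float("nan")
    return deltas, mean


def _signed_rank_exact_sf(ranks: np.ndarray):
    """Exact null distribution of W = sum of ranks of positive differences.

    Under H0 every difference is independently positive with probability
    1/2, so the generating function of 2W (doubled to keep tied mid-ranks
    integral) is the convolution of (1 + z^(2r)) / 2 over ranks r.
    Returns (support_of_2W, pmf).
    """
    doubled = np.rint(2 * ranks).astype(int)
    total = int(doubled.sum())
    pmf = np.zeros(total + 1)
    pmf[0] = 1.0
    for d in doubled:
        shifted = np.zeros_like(pmf)
        shifted[d:] = pmf[: total + 1 - d]
        pmf = 0.5 * (pmf + shifted)
    return np.arange(total + 1), pmf


def wilcoxon_signed_rank(x, y) -> WilcoxonResult:
    """Paired two-sided Wilcoxon signed-rank test.

    Zero differences are dropped; tied |differences| receive mid-ranks.
    If every difference is zero, returns W = 0, p = 1, n_effective = 0.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 1:
        raise ValueError("x and y must be equal-length 1-D arrays, length >= 1")
    d = x - y
    d = d[d != 0]
    n = d.size
    if n == 0:
        return WilcoxonResult(statistic=0.0, p_value=1.0, n_effective=0, exact=True)
    ranks = sps.rankdata(np.abs(d))
    w_pos = float(ranks[d > 0].sum())
    if n <= EXACT_WILCOXON_MAX_N:
        support2, pmf = _signed_rank_exact_sf(ranks)
        w2 = int(round(2 * w_pos))
        p_low = float(pmf[support2 <= w2].sum())
        p_high = float(pmf[support2 >= w2].sum())
        p = min(1.0, 2.0 * min(p_low, p_high))
        return WilcoxonResult(statistic=w_pos, p_value=p, n_effective=n, exact=True)
    # normal approximation with tie correction
    mean = n * (n + 1) / 4.0
    _, counts = np.unique(ranks, return_counts=True)
    tie_term = float(np.sum(counts**3 - counts)) / 48.0
    var = n * (n + 1) * (2 * n + 1) / 24.0 - tie_term
    z = (w_pos - mean) / np.sqrt(var)
    p = float(min(1.0, 2.0 * sps.norm.sf(abs(z))))
    return WilcoxonResult(statistic=w_pos, p_value=p, n_effective=n, exact=False)


def permutation_test(
    group_a,
    group_b,
    n_perm: int = 1000,
    seed: int | None = None,
    alternative: str = "two-sided",
    exhaustive: bool = False,
) -> PermutationResult:
    """Label-shuffling permutation test on the difference of group means.

    Parameters
    ----------
    group_a, group_b : array-like
        Observed values; ``observed_delta = mean(a) - mean(b)``.
    n_perm : int
        Number of random shuffles of the pooled values into groups of the
        original sizes (ignored in exhaustive mode).
    seed : int, optional
        Seed for the shuffles; the result is deterministic given the seed.
    alternative : {"two-sided", "greater", "less"}
        Sidedness of both reported p-values.
    exhaustive : bool
        Enumerate all distinct assignments instead of sampling (only
        sensible for small pooled sizes).
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    na = a.size
    observed = float(a.mean() - b.mean())

    if exhaustive:
        n_total = comb(pooled.size, na)
        null = np.empty(n_total)
        idx_all = np.arange(pooled.size)
        for k, idx in enumerate(combinations(idx_all, na)):
            mask = np.zeros(pooled.size, dtype=bool)
            mask[list(idx)] = True
            null[k] = pooled[mask].mean() - pooled[~mask].mean()
        n_eff = n_total
    else:
        rng = np.random.default_rng(seed)
        # vectorized shuffles: one random permutation per row via argsort
        order = np.argsort(rng.random((n_perm, pooled.size)), axis=1)
        shuffled = pooled[order]
        null = shuffled[:, :na].mean(axis=1) - shuffled[:, na:].mean(axis=1)
        n_eff = n_perm

    if alternative == "two-sided":
        exceed = np.abs(null) >= abs(observed) - 1e-12
    elif alternative == "greater":
        exceed = null >= observed - 1e-12
    elif alternative == "less":
        exceed = null <= observed + 1e-12
    else:
        raise ValueError(f"unknown alternative {alternative!r}")
    if exhaustive:
        # the observed assignment is one of the enumerated ones: exact p
        p_emp = int(exceed.sum()) / n_eff
    else:
        p_emp = (1.0 + int(exceed.sum())) / (n_eff + 1.0)

    mu, sd = float(null.mean()), float(null.std(ddof=1)) if n_eff > 1 else 0.0
    if sd == 0.0:
        p_gauss = 1.0 if observed == mu else 1.0 / (n_eff + 1.0)
    else:
        z = (observed - mu) / sd
        if alternative == "two-sided":
            p_gauss = float(min(1.0, 2.0 * sps.norm.sf(abs(z))))
        elif alternative == "greater":
            p_gauss = float(sps.norm.sf(z))
        else:
            p_gauss = float(sps.norm.cdf(z))

    return PermutationResult(
        observed_delta=observed,
        null_deltas=null,
        p_gaussian=p_gauss,
        p_empirical=float(p_emp),
        n_perm=n_eff,
        seed=seed,
        exhaustive=exhaustive,
    )
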