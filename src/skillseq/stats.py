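"""Small-sample statistics used by the evaluation and saliency modules.

Cross-validated comparisons here involve ~10 paired fold metrics, where
asymptotic p-values are unreliable and ties (identical fold metrics) are
common.  The one-sided Wilcoxon signed-rank test is therefore computed by
exact enumeration of the sign-flip distribution with average ranks for
tied magnitudes whenever the pair count permits, with a tie-corrected
normal approximation beyond that.  A plain sign test is available for the
stricter reading of a "sign test".
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps


@dataclass
class PairedTestResult:
    statistic: float
    p_value: float
    n_pairs: int
    n_nonzero: int
    all_ties: bool
    method: str


def _exact_signflip_pvalue(ranks: np.ndarray, w_plus: float, alternative: str) -> float:
    """P(W+ >= w_plus) (or <=) under uniform random sign assignment.

    Ranks may be half-integers from average-rank tie handling; doubling
    makes them integers so the distribution is a subset-sum convolution.
    """
    scaled = np.round(ranks * 2).astype(int)
    total = int(scaled.sum())
    counts = np.zeros(total + 1)
    counts[0] = 1.0
    for r in scaled:
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[: len(counts) - r]
        counts = counts + shifted
    counts /= counts.sum()
    target = int(np.round(w_plus * 2))
    if alternative == "greater":
        return float(counts[target:].sum())
    if alternative == "less":
        return float(counts[: target + 1].sum())
    tail = min(counts[target:].sum(), counts[: target + 1].sum())
    return float(min(1.0, 2.0 * tail))


def wilcoxon_signed_rank(
    after: np.ndarray,
    before: np.ndarray,
    alternative: str = "greater",
    exact_max_n: int = 20,
) -> PairedTestResult:
    """Paired Wilcoxon signed-rank test on ``after - before``.

    Zero differences are dropped (Wilcoxon's treatment); tied magnitudes
    receive average ranks.  Exact sign-flip enumeration is used for up to
    ``exact_max_n`` non-zero pairs — with all-positive differences over 10
    pairs the one-sided p-value is exactly 2^-10.  If every pair is tied
    the test has no information and returns p = 1 with ``all_ties`` set.
    """
    after = np.asarray(after, dtype=float)
    before = np.asarray(before, dtype=float)
    if after.shape != before.shape:
        raise ValueError("paired samples must have equal length")
    d = after - before
    nz = d != 0
    n = int(nz.sum())
    if n == 0:
        return PairedTestResult(0.0, 1.0, len(d), 0, True, "degenerate")
    d = d[nz]
    ranks = sps.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    if n <= exact_max_n:
        p = _exact_signflip_pvalue(ranks, w_plus, alternative)
        method = "exact"
    else:
        mean = n * (n + 1) / 4.0
        # variance with tie correction
        _, tie_counts = np.unique(ranks, return_counts=True)
        var = n * (n + 1) * (2 * n + 1) / 24.0 - (tie_counts ** 3 - tie_counts).sum() / 48.0
        if alternative == "greater":
            z = (w_plus - 0.5 - mean) / np.sqrt(var)
            p = float(sps.norm.sf(z))
        elif alternative == "less":
            z = (w_plus + 0.5 - mean) / np.sqrt(var)
            p = float(sps.norm.cdf(z))
        else:
            z = (w_plus - mean) / np.sqrt(var)
            p = float(2 * sps.norm.sf(abs(z - 0.5 * np.sign(z))))
        method = "normal"
    return PairedTestResult(w_plus, min(1.0, p), len(after), n, False, method)


def sign_test(
    after: np.ndarray, before: np.ndarray, alternative: str = "greater"
) -> PairedTestResult:
    """Exact binomial sign test on paired differences (ties dropped)."""
    d = np.asarray(after, dtype=float) - np.asarray(before, dtype=float)
    nz = d != 0
    n = int(nz.sum())
    if n == 0:
        return PairedTestResult(0.0, 1.0, len(d), 0, True, "degenerate")
    k = int((d > 0).sum())
    p = sps.binomtest(k, n, 0.5, alternative=alternative).pvalue
    return PairedTestResult(float(k), float(p), len(d), n, False, "exact")


def spearman(x: np.ndarray, y: np.ndarray, exact_below: int = 10) -> tuple[float, float]:
    """Spearman rank correlation with a two-sided p-value.

    The statistic is the Pearson correlation of average ranks.  For fewer
    than ``exact_below`` pairs the p-value comes from the exact permutation
    distribution of the ranks; otherwise from the t approximation.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if n != len(y) or n < 2:
        raise ValueError("need two equal-length samples with n >= 2")
    rx, ry = sps.rankdata(x), sps.rankdata(y)
    sx, sy = rx - rx.mean(), ry - ry.mean()
    denom = np.sqrt((sx ** 2).sum() * (sy ** 2).sum())
    if denom == 0:
        return np.nan, np.nan
    rho = float((sx * sy).sum() / denom)
    if n < exact_below:
        from itertools import permutations

        count = 0
        total = 0
        for perm in permutations(range(n)):
            ryp = sy[list(perm)]
            r = (sx * ryp).sum() / denom
            if abs(r) >= abs(rho) - 1e-12:
                count += 1
            total += 1
        return rho, count / total
    if abs(rho) >= 1.0:
        return rho, 0.0
    t = rho * np.sqrt((n - 2) / (1.0 - rho ** 2))
    return rho, float(2 * sps.t.sf(abs(t), df=n - 2))
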