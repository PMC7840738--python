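"""Statistical helpers: BH-FDR, the corrected resampled t-test, and thin
Wilcoxon wrappers with the conventions used throughout the package."""

from __future__ import annotations

import numpy as np
from scipy import stats

__all__ = [
    "bh_fdr",
    "corrected_resampled_ttest",
    "wilcoxon_signed_rank",
    "wilcoxon_rank_sum",
]


def bh_fdr(pvals, alpha: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up procedure.

    Returns (rejected, p_adjusted).  Rejects hypotheses 1..i* where i* is the
    largest i with p_(i) <= i * alpha / m.
    """
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value array")
    m = p.size
    order = np.argsort(p)
    ranked = p[order]
    thresh = alpha * np.arange(1, m + 1) / m
    below = np.flatnonzero(ranked <= thresh)
    rejected = np.zeros(m, dtype=bool)
    if below.size:
        rejected[order[: below[-1] + 1]] = True
    # adjusted p-values: running minimum of p_(i) * m / i from the top
    adj = np.minimum.accumulate((ranked * m / np.arange(1, m + 1))[::-1])[::-1]
    p_adj = np.empty(m)
    p_adj[order] = np.minimum(adj, 1.0)
    return rejected, p_adj


def corrected_resampled_ttest(diffs, n_train: int, n_test: int,
                              alternative: str = "two-sided",
                              ) -> tuple[float, float]:
    """Corrected resampled t-test for overlapping resamples (cross-validation
    or bootstrap draws that share training data).

    The naive paired t-test is anti-conservative because resample folds
    overlap; the corrected statistic inflates the variance by
    ``(1/n + n_test/n_train)`` instead of ``1/n``:

        t = mean(d) / sqrt((1/n + n_test/n_train) * var(d)),  df = n - 1.
    """
    d = np.asarray(diffs, dtype=float)
    n = d.size
    if n < 2:
        raise ValueError("need at least two paired differences")
    if n_train <= 0 or n_test <= 0:
        raise ValueError("n_train and n_test must be positive")
    var = d.var(ddof=1)
    if var == 0:
        t = np.inf * np.sign(d.mean()) if d.mean() != 0 else 0.0
    else:
        t = d.mean() / np.sqrt((1.0 / n + n_test / n_train) * var)
    df = n - 1
    if alternative == "two-sided":
        p = 2 * stats.t.sf(abs(t), df)
    elif alternative == "greater":
        p = stats.t.sf(t, df)
    elif alternative == "less":
        p = stats.t.cdf(t, df)
    else:
        raise ValueError(f"unknown alternative {alternative!r}")
    return float(t), float(p)


def wilcoxon_signed_rank(x, y=None, alternative: str = "two-sided") -> float:
    """Paired Wilcoxon signed-rank p-value (y omitted: test x against 0)."""
    x = np.asarray(x, dtype=float)
    if x.size == 0:
        raise ValueError("empty sample")
    try:
        _, p = stats.wilcoxon(x, y, alternative=alternative)
    except ValueError:  # all-zero differences
        return 1.0
    return float(p)


def wilcoxon_rank_sum(x, y, alternative: str = "two-sided") -> float:
    """Unpaired Wilcoxon rank-sum p-value."""
    x, y = np.asarray(x, dtype=float), np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("empty sample")
    _, p = stats.ranksums(x, y, alternative=alternative)
    return float(p)
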