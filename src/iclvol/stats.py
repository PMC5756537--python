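"""Shared statistics: t-based confidence intervals, Monte-Carlo Dunnett
many-to-one comparisons, and Benjamini-Hochberg adjustment.

The Dunnett procedure here replaces the classical tabulated critical values
with a seeded Monte-Carlo reference distribution of the maximum absolute
many-to-one t statistic under the null, which makes its family-wise error
rate directly testable by simulation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = ["mean_ci", "mc_dunnett", "DunnettResult", "benjamini_hochberg"]


def mean_ci(x: np.ndarray, confidence: float = 0.95) -> tuple[float, float, float]:
    """Sample mean with a two-sided Student-t confidence interval.

    Returns (mean, low, high).  Requires n >= 2.
    """
    x = np.asarray(x, dtype=float)
    n = x.size
    if n < 2:
        raise ValueError("confidence interval requires at least two observations")
    m = float(np.mean(x))
    sem = float(np.std(x, ddof=1)) / np.sqrt(n)
    tcrit = float(sps.t.ppf(0.5 + confidence / 2.0, n - 1))
    return m, m - tcrit * sem, m + tcrit * sem


@dataclass
class DunnettResult:
    """Many-to-one comparison of k treatment groups against a shared control."""

    statistics: np.ndarray  # t statistic per treatment group
    pvalues: np.ndarray  # Monte-Carlo family-wise adjusted p per group
    raw_pvalues: np.ndarray  # unadjusted two-sided t-test p per group
    df: int


def mc_dunnett(
    treatments: list[np.ndarray],
    control: np.ndarray,
    *,
    n_draws: int = 100_000,
    seed: int | np.random.SeedSequence | None = 0,
) -> DunnettResult:
    """Dunnett-style comparisons of each treatment group against a control.

    t statistics use the variance pooled over all groups.  The adjusted
    p-value of group i is the Monte-Carlo probability, under the global null,
    that max_j |T_j| exceeds |t_i|; this controls the family-wise error rate.

    The null reference simulates the group means and the pooled variance
    directly (means ~ N(0, 1/n_j), pooled variance ~ chi2_df / df), which is
    exact for normal homoscedastic data and fast enough for >= 1e5 draws.
    """
    control = np.asarray(control, dtype=float)
    groups = [np.asarray(t, dtype=float) for t in treatments]
    if control.size < 2 or any(g.size < 2 for g in groups):
        raise ValueError("every group needs at least two observations")
    k = len(groups)
    ns = np.array([g.size for g in groups])
    n0 = control.size
    ntot = int(ns.sum() + n0)
    df = ntot - (k + 1)
    ss = sum(float(np.sum((g - g.mean()) ** 2)) for g in groups + [control])
    s2 = ss / df
    if s2 <= 0:
        raise ValueError("degenerate (zero) pooled variance; comparisons undefined")
    tstats = np.array(
        [(g.mean() - control.mean()) / np.sqrt(s2 * (1.0 / g.size + 1.0 / n0)) for g in groups]
    )
    raw_p = 2.0 * sps.t.sf(np.abs(tstats), df)

    rng = np.random.default_rng(seed)
    null_means = rng.standard_normal((n_draws, k)) / np.sqrt(ns)
    null_ctrl = rng.standard_normal((n_draws, 1)) / np.sqrt(n0)
    null_s2 = rng.chisquare(df, size=(n_draws, 1)) / df
    null_t = (null_means - null_ctrl) / np.sqrt(null_s2 * (1.0 / ns + 1.0 / n0))
    max_abs = np.max(np.abs(null_t), axis=1)
    # add-one correction keeps p > 0 and the MC test exact at level alpha
    pvals = np.array(
        [(1 + int(np.sum(max_abs >= abs(t)))) / (n_draws + 1) for t in tstats]
    )
    return DunnettResult(statistics=tstats, pvalues=pvals, raw_pvalues=raw_p, df=df)


def benjamini_hochberg(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up FDR adjustment, order-preserving.

    Values must lie in [0, 1].  Delegates to statsmodels' ``fdr_bh``.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ValueError("expected a non-empty 1-D array of p-values")
    if np.any(p < 0) or np.any(p > 1) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]
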