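"""Group-comparison and correlation statistics with rank effect sizes.

The layer mirrors the reporting conventions of infant-EEG group studies:
Mann-Whitney-Wilcoxon with the rank sum Ws of the first sample, a normal
deviate z and effect size r = z / sqrt(N); two-tailed p throughout;
Benjamini-Hochberg step-up FDR within explicit test families; Spearman
and Pearson correlations; the D'Agostino-Pearson K2 omnibus normality
test; paired/unpaired t tests, including the pooled two-sample t computed
from printed summary statistics alone.

The normal deviate is computed WITHOUT a continuity correction by
default: published (Ws, z, r) triples in this literature are internally
consistent with the plain tie-corrected approximation (e.g. Ws = 267 at
18 vs 18 gives z = (96 - 162)/sqrt(999) = -2.088 and r = -0.348), and a
``continuity`` flag restores the corrected variant. The returned p-value
switches to exact rank-sum enumeration when n1 + n2 <= 16.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import permutations
from math import comb, inf, sqrt

import numpy as np
from scipy import stats as sps


@dataclass
class StatResult:
    """Unified record for every test the analysis layer reports."""

    test: str
    statistic: float
    p: float
    n: int
    z: float | None = None
    df: float | None = None
    effect_r: float | None = None
    fdr_significant: bool | None = None
    p_adjusted: float | None = None
    q: float | None = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.p <= 1.0 or np.isnan(self.p)):
            raise ValueError("p must lie in [0, 1]")
        if self.effect_r is not None and abs(self.effect_r) > 1 + 1e-12:
            raise ValueError("effect_r must lie in [-1, 1]")


def z_to_p_two_tailed(z: float) -> float:
    """p = 2 Phi(-|z|)."""
    if not np.isfinite(z):
        raise ValueError("z must be finite")
    return float(2.0 * sps.norm.sf(abs(z)))


def effect_size_r(z: float, n_total: int) -> float:
    """Rank-test effect size r = z / sqrt(N)."""
    return float(z / sqrt(n_total))


def _exact_ranksum_p(x: np.ndarray, y: np.ndarray) -> float:
    """Two-tailed exact Mann-Whitney p by enumeration of rank assignments.

    Uses the null distribution of U over all C(n1+n2, n1) subsets of
    ranks (ties handled by midranks, in which case the enumeration is
    over permutations of the observed midranks). p = 2 * min(P(U <= u),
    P(U >= u)), capped at 1.
    """
    n1, n2 = len(x), len(y)
    both = np.concatenate([x, y])
    ranks = sps.rankdata(both)
    u_obs = ranks[:n1].sum() - n1 * (n1 + 1) / 2.0
    total = comb(n1 + n2, n1)
    # enumerate subsets via combinations of rank positions
    from itertools import combinations

    le = ge = 0
    for idx in combinations(range(n1 + n2), n1):
        u = ranks[list(idx)].sum() - n1 * (n1 + 1) / 2.0
        if u <= u_obs + 1e-9:
            le += 1
        if u >= u_obs - 1e-9:
            ge += 1
    p = 2.0 * min(le, ge) / total
    return min(p, 1.0)


def mann_whitney(
    x,
    y,
    continuity: bool = False,
    exact_max_n: int = 16,
    report_u: bool = False,
) -> StatResult:
    """Two-tailed Mann-Whitney-Wilcoxon test.

    Statistic is Ws, the rank sum of the first sample (``report_u``
    switches to U). z uses the tie-corrected normal approximation
    (continuity correction optional, off by default); p is exact by
    enumeration when n1 + n2 <= ``exact_max_n`` and otherwise 2 Phi(-|z|).
    effect_r = z / sqrt(n1 + n2) in all regimes.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = len(x), len(y)
    if n1 < 2 or n2 < 2:
        raise ValueError("each sample needs at least 2 observations")
    N = n1 + n2
    both = np.concatenate([x, y])
    ranks = sps.rankdata(both)
    ws = float(ranks[:n1].sum())
    u1 = ws - n1 * (n1 + 1) / 2.0
    mu = n1 * n2 / 2.0
    # tie correction to the variance
    _, counts = np.unique(both, return_counts=True)
    tie_term = ((counts**3 - counts).sum()) / (N * (N - 1))
    var = n1 * n2 / 12.0 * ((N + 1) - tie_term)
    if var <= 0:
        z = 0.0
    else:
        diff = u1 - mu
        if continuity and diff != 0:
            diff -= 0.5 * np.sign(diff)
        z = diff / sqrt(var)
    if N <= exact_max_n:
        p = _exact_ranksum_p(x, y)
    else:
        p = z_to_p_two_tailed(z) if var > 0 else 1.0
    return StatResult(
        test="mann-whitney",
        statistic=float(u1) if report_u else ws,
        p=p,
        n=N,
        z=float(z),
        effect_r=effect_size_r(z, N),
    )


def bh_fdr(pvals, q: float = 0.05):
    """Benjamini-Hochberg step-up: (reject flags, adjusted p).

    Rejects all hypotheses with rank <= max{k : p(k) <= k q / m};
    adjusted p are the step-up monotone values.
    """
    from statsmodels.stats.multitest import multipletests

    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return np.zeros(0, dtype=bool), np.zeros(0)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    reject, p_adj, _, _ = multipletests(p, alpha=q, method="fdr_bh")
    return reject, p_adj


def spearman(x, y, exact_max_n: int = 9) -> StatResult:
    """Tie-aware Spearman rank correlation, two-tailed.

    Exact permutation p for n < 10 (full enumeration of rank
    permutations); the t approximation otherwise.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if n < 4 or len(y) != n:
        raise ValueError("need paired samples with n >= 4")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValueError("constant input has no rank correlation")
    rs, p_t = sps.spearmanr(x, y)
    if n <= exact_max_n:
        # |rho| is monotone in |sum rx*ry - n*mean_rx*mean_ry|, and rank
        # means/SDs are permutation-invariant, so enumerate dot products
        rx = sps.rankdata(x)
        ry = sps.rankdata(y)
        centre = n * rx.mean() * ry.mean()
        perms = np.array(list(permutations(ry)))
        dots = np.abs(perms @ rx - centre)
        obs = abs(float(rx @ ry) - centre)
        p = float(np.mean(dots >= obs - 1e-9))
    else:
        p = float(p_t)
    return StatResult(test="spearman", statistic=float(rs), p=p, n=n)


def pearson(x, y) -> StatResult:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if n < 3 or len(y) != n:
        raise ValueError("need paired samples with n >= 3")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValueError("constant input has no correlation")
    r, p = sps.pearsonr(x, y)
    return StatResult(test="pearson", statistic=float(r), p=float(p), n=n, df=n - 2)


def dagostino_k2(x) -> StatResult:
    """D'Agostino-Pearson omnibus normality test: K2 = z_skew^2 + z_kurt^2."""
    x = np.asarray(x, dtype=float)
    if len(x) < 8:
        raise ValueError("K2 requires at least 8 observations")
    k2, p = sps.normaltest(x)
    return StatResult(test="dagostino-k2", statistic=float(k2), p=float(p), n=len(x), df=2)


def two_sample_t(x, y, paired: bool = False) -> StatResult:
    """Pooled-variance unpaired t (df = n1+n2-2) or paired t (df = n-1)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if paired:
        if len(x) != len(y):
            raise ValueError("paired test requires equal lengths")
        if len(x) < 2:
            raise ValueError("need at least 2 pairs")
        d = x - y
        sd = d.std(ddof=1)
        n = len(d)
        if sd == 0:
            t = inf if d.mean() > 0 else (-inf if d.mean() < 0 else 0.0)
            p = 0.0 if t != 0 else 1.0
        else:
            t, p = sps.ttest_rel(x, y)
        return StatResult(
            test="t-paired", statistic=float(t), p=float(p), n=n, df=n - 1
        )
    if len(x) < 2 or len(y) < 2:
        raise ValueError("need at least 2 observations per group")
    t, p = sps.ttest_ind(x, y, equal_var=True)
    n = len(x) + len(y)
    return StatResult(
        test="t-unpaired", statistic=float(t), p=float(p), n=n, df=n - 2
    )


def t_from_summary(
    m1: float, s1: float, n1: int, m2: float, s2: float, n2: int
) -> StatResult:
    """Pooled two-sample t from summary statistics (means, SDs, group
    sizes), as needed to recompute published phenotype-table rows."""
    if n1 < 2 or n2 < 2:
        raise ValueError("group sizes must be >= 2")
    if s1 < 0 or s2 < 0:
        raise ValueError("standard deviations must be non-negative")
    t, p = sps.ttest_ind_from_stats(m1, s1, n1, m2, s2, n2, equal_var=True)
    return StatResult(
        test="t-from-summary",
        statistic=float(t),
        p=float(p),
        n=n1 + n2,
        df=n1 + n2 - 2,
    )
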