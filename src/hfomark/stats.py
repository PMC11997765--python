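"""Statistical primitives used across the analyses.

Rank tests and correlations delegate to scipy; Barnard's exact
unconditional test is implemented directly in its pooled-z / nuisance-
grid form, and the Tukey–Kramer post hoc on Kruskal–Wallis rank means
uses the studentized-range distribution.
"""

from __future__ import annotations

import itertools
import math

import numpy as np
from scipy import stats as st

from .types import ValidationError


def barnard_test(table, grid_step: float = 1e-3) -> float:
    """Barnard's exact unconditional test for a 2x2 table, two-sided.

    ``table`` is [[a, b], [c, d]] with rows = groups (fixed sizes
    n1 = a + b, n2 = c + d) and columns = outcomes. The ordering
    statistic is the pooled-variance two-proportion z; the p-value is
    the maximum over a nuisance-parameter grid (step ``grid_step``) of
    the probability of tables at least as extreme as observed.
    """
    t = np.asarray(table, dtype=int)
    if t.shape != (2, 2) or (t < 0).any():
        raise ValidationError("table must be 2x2 with nonnegative counts")
    n1, n2 = int(t[0].sum()), int(t[1].sum())
    if n1 == 0 or n2 == 0:
        raise ValidationError("both row margins must be positive")

    z_obs = abs(_pooled_z(t[0, 0], n1, t[1, 0], n2))

    # all achievable tables
    k1 = np.arange(n1 + 1)
    k2 = np.arange(n2 + 1)
    K1, K2 = np.meshgrid(k1, k2, indexing="ij")
    Z = np.abs(_pooled_z(K1, n1, K2, n2))
    extreme = Z >= z_obs - 1e-12

    ps = np.arange(grid_step, 1.0, grid_step)
    # log binomial pmfs, vectorized over the nuisance grid
    logc1 = _log_binom_coeff(n1, k1)
    logc2 = _log_binom_coeff(n2, k2)
    logp = np.log(ps)
    log1p = np.log1p(-ps)
    pmf1 = np.exp(logc1[:, None] + np.outer(k1, logp) + np.outer(n1 - k1, log1p))
    pmf2 = np.exp(logc2[:, None] + np.outer(k2, logp) + np.outer(n2 - k2, log1p))
    # P(extreme | p) = sum_{k1,k2 extreme} pmf1[k1,p] pmf2[k2,p]
    probs = np.einsum("ip,jp,ij->p", pmf1, pmf2, extreme.astype(float))
    return float(min(1.0, probs.max()))


def _pooled_z(k1, n1, k2, n2):
    k1 = np.asarray(k1, dtype=float)
    k2 = np.asarray(k2, dtype=float)
    p1 = k1 / n1
    p2 = k2 / n2
    pool = (k1 + k2) / (n1 + n2)
    var = pool * (1 - pool) * (1 / n1 + 1 / n2)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(var > 0, (p1 - p2) / np.sqrt(np.where(var > 0, var, 1.0)), 0.0)
    return z


def _log_binom_coeff(n: int, k: np.ndarray) -> np.ndarray:
    return (
        math.lgamma(n + 1)
        - np.array([math.lgamma(v + 1) for v in k])
        - np.array([math.lgamma(n - v + 1) for v in k])
    )


def two_prop_ztest(k1: int, n1: int, k2: int, n2: int) -> tuple[float, float]:
    """Pooled-variance two-proportion z test, two-sided -> (z, p)."""
    if n1 <= 0 or n2 <= 0:
        raise ValidationError("sample sizes must be positive")
    if not (0 <= k1 <= n1 and 0 <= k2 <= n2):
        raise ValidationError("counts must satisfy 0 <= k <= n")
    z = float(_pooled_z(k1, n1, k2, n2))
    p = 2 * st.norm.sf(abs(z))
    return z, float(p)


def signed_rank(x, y) -> tuple[float, float]:
    """Wilcoxon signed-rank on paired samples -> (statistic, p).

    Ties/zeros handled by scipy's default zero-splitting; degenerate
    all-zero differences return p = 1.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(x) != len(y) or len(x) < 2:
        raise ValidationError("need >= 2 pairs of equal length")
    d = x - y
    if np.allclose(d, 0):
        return 0.0, 1.0
    res = st.wilcoxon(x, y, zero_method="wilcox", method="auto")
    return float(res.statistic), float(res.pvalue)


def rank_sum(x, y) -> tuple[float, float]:
    """Wilcoxon rank-sum (Mann-Whitney) two-sided -> (statistic, p)."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(x) < 2 or len(y) < 2:
        raise ValidationError("each group needs >= 2 values")
    if np.array_equal(np.sort(x), np.sort(y)):
        # identical samples: no evidence of shift
        return 0.0, 1.0
    res = st.mannwhitneyu(x, y, alternative="two-sided", method="auto")
    return float(res.statistic), float(res.pvalue)


def spearman(x, y) -> tuple[float, float]:
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(x) != len(y) or len(x) < 3:
        raise ValidationError("need >= 3 paired values")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValidationError("constant input: correlation undefined")
    rho, p = st.spearmanr(x, y)
    return float(rho), float(p)


def kruskal_wallis_tukey(groups: dict[str, np.ndarray]) -> dict:
    """Kruskal-Wallis H test with Tukey-Kramer post hoc on rank means.

    Pairwise comparisons use the studentized-range distribution on the
    difference of mean ranks (the MATLAB ``multcompare`` convention
    after ``kruskalwallis``), with the rank variance N(N+1)/12 and
    infinite error degrees of freedom.

    Returns {"H", "p", "pairwise": {(g1, g2): corrected p}}.
    """
    names = list(groups)
    if len(names) < 2:
        raise ValidationError("need >= 2 groups")
    arrays = [np.asarray(groups[g], float) for g in names]
    for g, a in zip(names, arrays):
        if len(a) < 2:
            raise ValidationError(f"group {g!r} needs >= 2 values")

    pooled = np.concatenate(arrays)
    if np.all(pooled == pooled[0]):
        # all values identical: no group effect by construction
        pairwise = {pair: 1.0 for pair in itertools.combinations(names, 2)}
        return {"H": 0.0, "p": 1.0, "pairwise": pairwise}
    H, p = st.kruskal(*arrays)

    ranks = st.rankdata(pooled)
    sizes = [len(a) for a in arrays]
    splits = np.cumsum(sizes)[:-1]
    mean_ranks = [r.mean() for r in np.split(ranks, splits)]
    N = len(pooled)
    # tie-corrected rank variance
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = (counts**3 - counts).sum()
    s2 = (N * (N + 1) / 12.0) - tie_term / (12.0 * (N - 1))
    k = len(names)
    pairwise = {}
    for (i, gi), (j, gj) in itertools.combinations(enumerate(names), 2):
        se = math.sqrt(s2 * (1.0 / sizes[i] + 1.0 / sizes[j]))
        q = abs(mean_ranks[i] - mean_ranks[j]) / se * math.sqrt(2.0)
        pairwise[(gi, gj)] = float(st.studentized_range.sf(q, k, np.inf))
    return {"H": float(H), "p": float(p), "pairwise": pairwise}
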