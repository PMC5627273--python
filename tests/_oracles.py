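"""Independent brute-force oracles used only by the tests.

Everything here is computed from first principles with plain numpy/scipy
loops, deliberately sharing no code path with the package.
"""

from __future__ import annotations

import math

import numpy as np
from scipy import stats


def bh_step_up(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up by direct enumeration of the definition:
    adj_p(i) = min over j >= rank(i) of m * p_(j) / j, capped at 1."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    running = math.inf
    for rank in range(m, 0, -1):
        idx = order[rank - 1]
        running = min(running, m * p[idx] / rank)
        adj[idx] = min(running, 1.0)
    return adj


def pooled_two_sample_t(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Classical equal-variance two-sample t-test (statistic, two-sided p)."""
    res = stats.ttest_ind(x, y, equal_var=True)
    return float(res.statistic), float(res.pvalue)


def tost_p(est: float, se: float, df: float, margin: float) -> float:
    """TOST equivalence p by direct Student-t CDF evaluation."""
    dist = stats.norm if math.isinf(df) else stats.t(df)
    return max(dist.cdf((est - margin) / se), dist.sf((est + margin) / se))


def cell_stats(values: np.ndarray, groups: list[list[int]]):
    """Cell means and pooled within-cell variance for one gene."""
    means = [values[idx].mean() for idx in groups]
    rss = sum(
        ((values[idx] - m) ** 2).sum() for idx, m in zip(groups, means)
    )
    df = len(values) - len(groups)
    return np.array(means), rss / df, df


def brute_classify_gene(
    cell_means: dict[str, float],
    n_rep: int,
    s_post: float,
    df_total: float,
    alpha: float = 0.05,
    margin: float = 1.0,
) -> tuple[str, float]:
    """Enumerate all ten interplay IUTs from first principles.

    ``cell_means`` maps PBS/MPL/QS21/AS01 to the fitted cell mean at one
    time point.  Returns (category, iut_p); ties broken by the fixed
    taxonomy order.
    """
    dist = stats.norm if math.isinf(df_total) else stats.t(df_total)

    def diff_p(est, k):  # k cells in the contrast, each with n_rep samples
        se = math.sqrt(s_post * k / n_rep)
        return 2 * dist.sf(abs(est) / se)

    def eq_p(est, k):
        se = math.sqrt(s_post * k / n_rep)
        return tost_p(est, se, df_total, margin)

    M = cell_means["MPL"] - cell_means["PBS"]
    Q = cell_means["QS21"] - cell_means["PBS"]
    A = cell_means["AS01"] - cell_means["PBS"]
    AmM = cell_means["AS01"] - cell_means["MPL"]
    AmQ = cell_means["AS01"] - cell_means["QS21"]
    D = A - M - Q

    sgn = np.sign
    candidates: list[tuple[str, float, bool]] = [
        ("irrelevance_of_MPL", max(eq_p(M, 2), eq_p(AmQ, 2)), True),
        ("irrelevance_of_QS21", max(eq_p(Q, 2), eq_p(AmM, 2)), True),
        ("additivity",
         max(diff_p(M, 2), diff_p(Q, 2), eq_p(D, 4)), True),
        ("synergy",
         max(diff_p(M, 2), diff_p(Q, 2), diff_p(D, 4)),
         sgn(D) == sgn(A) and sgn(D) != 0),
        ("antagonism",
         max(diff_p(M, 2), diff_p(Q, 2), diff_p(D, 4)),
         sgn(D) == -sgn(M + Q) and sgn(D) != 0 and sgn(M + Q) != 0),
        ("potentiation_by_MPL",
         max(eq_p(M, 2), diff_p(Q, 2), diff_p(AmQ, 2)),
         sgn(AmQ) == sgn(Q) and sgn(Q) != 0),
        ("potentiation_by_QS21",
         max(eq_p(Q, 2), diff_p(M, 2), diff_p(AmM, 2)),
         sgn(AmM) == sgn(M) and sgn(M) != 0),
        ("inhibition_by_MPL",
         max(eq_p(M, 2), diff_p(Q, 2), diff_p(AmQ, 2)),
         sgn(AmQ) == -sgn(Q) and sgn(Q) != 0 and sgn(AmQ) != 0),
        ("inhibition_by_QS21",
         max(eq_p(Q, 2), diff_p(M, 2), diff_p(AmM, 2)),
         sgn(AmM) == -sgn(M) and sgn(M) != 0 and sgn(AmM) != 0),
        ("emergence", max(eq_p(M, 2), eq_p(Q, 2), diff_p(A, 2)), True),
    ]
    best_name, best_p = "unclassified", math.inf
    for name, p, sign_ok in candidates:
        if sign_ok and p < alpha and p < best_p:
            best_name, best_p = name, p
    return best_name, (best_p if best_name != "unclassified" else math.nan)


def hypergeom_upper_tail(overlap: int, N: int, K: int, n: int) -> float:
    """P(X >= overlap) by direct enumeration of the hypergeometric mass."""
    total = 0.0
    for k in range(overlap, min(K, n) + 1):
        total += (
            math.comb(K, k) * math.comb(N - K, n - k) / math.comb(N, n)
        )
    return total


def mann_whitney_u(inside: np.ndarray, outside: np.ndarray) -> float:
    """U statistic by exhaustive pair counting (ties count half)."""
    u = 0.0
    for a in inside:
        for b in outside:
            if a > b:
                u += 1.0
            elif a == b:
                u += 0.5
    return u
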