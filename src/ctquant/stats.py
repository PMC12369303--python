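"""Group-level comparisons used in the study-style reports.

Two routes are provided for the brushing vs. hair-deflection contrast —
Mann-Whitney U (exact for small samples) and a paired t test on per-unit
differences — because both conventions are common for n ~ 15 unit samples;
reports print both, Mann-Whitney first.
"""

from __future__ import annotations

import numpy as np
from scipy import stats

__all__ = ["compare_groups", "exact_mann_whitney_p"]


def exact_mann_whitney_p(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Two-sided exact Mann-Whitney U by full enumeration (small n only).

    Enumerates all C(n_a + n_b, n_a) label assignments; intended as an
    oracle and for very small groups (combined n <= ~12).
    """
    from itertools import combinations

    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    pooled = np.concatenate([a, b])
    n, na = len(pooled), len(a)
    ranks = stats.rankdata(pooled)

    def u_of(idx):
        r = ranks[list(idx)].sum()
        return r - na * (na + 1) / 2.0

    u_obs = u_of(range(na))
    mean_u = na * (n - na) / 2.0
    dev = abs(u_obs - mean_u)
    count = 0
    total = 0
    for idx in combinations(range(n), na):
        total += 1
        if abs(u_of(idx) - mean_u) >= dev - 1e-12:
            count += 1
    return float(u_obs), count / total


def compare_groups(
    per_unit_a: np.ndarray,
    per_unit_b: np.ndarray,
    method: str = "mann_whitney",
) -> tuple[float, float, dict]:
    """(statistic, p, flags) for a two-group comparison of per-unit values.

    ``mann_whitney``: exact two-sided p for combined n <= 20 without ties;
    normal approximation with tie/continuity correction otherwise (flagged).
    ``paired_t``: paired t on per-unit differences (equal lengths required);
    identical pairs return statistic 0, p 1.
    """
    a = np.asarray(per_unit_a, dtype=float)
    b = np.asarray(per_unit_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need at least two values per group")
    flags: dict = {}
    if method == "mann_whitney":
        has_ties = len(np.unique(np.concatenate([a, b]))) < len(a) + len(b)
        use_exact = (len(a) + len(b) <= 20) and not has_ties
        flags["exact"] = use_exact
        flags["tie_fallback"] = has_ties and (len(a) + len(b) <= 20)
        res = stats.mannwhitneyu(
            a, b, alternative="two-sided",
            method="exact" if use_exact else "asymptotic",
        )
        return float(res.statistic), float(res.pvalue), flags
    if method == "paired_t":
        if len(a) != len(b):
            raise ValueError("paired method requires equal group lengths")
        d = a - b
        if np.allclose(d, d[0]) and np.isclose(d[0], 0.0):
            return 0.0, 1.0, {"degenerate": True}
        res = stats.ttest_rel(a, b)
        return float(res.statistic), float(res.pvalue), flags
    raise ValueError(f"unknown method {method!r}")
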