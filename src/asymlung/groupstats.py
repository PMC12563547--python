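"""Comparison battery for small animal cohorts.

One-way ANOVA with Bonferroni-corrected pairwise t post hoc tests, and exact
rank tests (Mann–Whitney U and Wilcoxon signed-rank) sized for groups of
n = 2–6 animals. For tie-free data within the size limits the rank tests use
the exact null distribution of the statistic (count-based dynamic programming
over rank assignments / sign patterns, equivalent to full enumeration); ties in
the Mann–Whitney case fall back to a seeded mid-rank permutation test, and
beyond the size limit a normal approximation with tie correction is used.
Two-sided p values are the doubled one-sided exact tail, capped at 1. Zeros in
the Wilcoxon differences are dropped (classic convention) and noted in the
result.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "TestResult",
    "oneway_anova",
    "mann_whitney_exact",
    "wilcoxon_signed_rank_exact",
]

MW_EXACT_LIMIT = 25   # max combined n for the exact Mann-Whitney distribution
WSR_EXACT_LIMIT = 20  # max nonzero pairs for the exact signed-rank distribution


@dataclass(frozen=True)
class TestResult:
    statistic: float
    p_two_sided: float
    method: str
    n: tuple[int, ...]
    notes: str = ""


def _as_array(x, name: str) -> np.ndarray:
    a = np.asarray(x, dtype=float).ravel()
    if a.size == 0:
        raise ValueError(f"{name} must be non-empty")
    if not np.isfinite(a).all():
        raise ValueError(f"{name} contains non-finite values")
    return a


# ---------------------------------------------------------------- ANOVA

def oneway_anova(groups: dict[str, np.ndarray],
                 posthoc: bool = True) -> tuple[TestResult, pd.DataFrame]:
    """Classical one-way ANOVA across named groups plus Bonferroni post hocs.

    Pairwise comparisons are ordinary two-sample t tests with their p values
    multiplied by the number of pairs performed, capped at 1.
    """
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    arrays = {}
    for name, vals in groups.items():
        a = _as_array(vals, f"group {name!r}")
        if a.size < 2:
            raise ValueError(f"group {name!r} has n < 2")
        arrays[name] = a
    f_stat, p = stats.f_oneway(*arrays.values())
    # identical groups give 0/0; report F = 0, p = 1
    if not np.isfinite(f_stat):
        f_stat, p = 0.0, 1.0
    overall = TestResult(float(f_stat), float(min(p, 1.0)), "anova_f",
                         tuple(a.size for a in arrays.values()))
    rows = []
    if posthoc:
        names = list(arrays)
        pairs = [(a, b) for i, a in enumerate(names) for b in names[i + 1:]]
        k = len(pairs)
        for a, b in pairs:
            t, praw = stats.ttest_ind(arrays[a], arrays[b])
            if not np.isfinite(t):
                t, praw = 0.0, 1.0
            rows.append({"group_a": a, "group_b": b, "t": float(t),
                         "p_raw": float(praw),
                         "p_bonferroni": float(min(1.0, praw * k))})
    return overall, pd.DataFrame(rows)


# ------------------------------------------------------- Mann-Whitney U

def _mw_exact_p(u: float, n1: int, n2: int) -> float:
    counts = _bounded_partition_counts(n1, n2)
    total = counts.sum()
    u_low = min(u, n1 * n2 - u)
    # doubled lower tail, capped
    tail = counts[: int(np.floor(u_low + 1e-9)) + 1].sum() / total
    return float(min(1.0, 2.0 * tail))


def _bounded_partition_counts(n1: int, n2: int) -> np.ndarray:
    """Number of subsets of ranks giving each U value: partitions of u into at
    most n1 parts each ≤ n2 (Gaussian binomial coefficients)."""
    max_u = n1 * n2
    f = np.zeros(max_u + 1)
    f[0] = 1.0
    for i in range(1, n1 + 1):
        # multiply generating function by (1 - q^(n2 + i)) / (1 - q^i)
        g = f.copy()
        # divide by (1 - q^i): prefix-sum with stride i
        for u in range(i, max_u + 1):
            g[u] += g[u - i]
        # multiply by (1 - q^(n2 + i)); subtract from a pre-update copy
        if n2 + i <= max_u:
            pre = g.copy()
            g[n2 + i:] -= pre[: max_u + 1 - (n2 + i)]
        f = g
    return f


def mann_whitney_exact(x, y, n_resamples: int = 10_000,
                       seed: int | None = None) -> TestResult:
    """Mann–Whitney U test, exact for tie-free samples with combined n ≤ 25.

    Ties trigger a seeded mid-rank permutation test (``n_resamples`` draws);
    larger samples use the normal approximation with tie correction.
    """
    xa, ya = _as_array(x, "x"), _as_array(y, "y")
    n1, n2 = xa.size, ya.size
    combined = np.concatenate([xa, ya])
    ranks = stats.rankdata(combined)
    r1 = ranks[:n1].sum()
    u = r1 - n1 * (n1 + 1) / 2.0
    has_ties = np.unique(combined).size < combined.size
    notes = []
    if not has_ties and n1 + n2 <= MW_EXACT_LIMIT:
        p = _mw_exact_p(u, n1, n2)
        method = "mannwhitney_exact"
    elif has_ties and n1 + n2 <= MW_EXACT_LIMIT:
        rng = np.random.default_rng(seed)
        u_obs_dev = abs(u - n1 * n2 / 2.0)
        count = 0
        for _ in range(n_resamples):
            perm = rng.permutation(ranks)
            u_p = perm[:n1].sum() - n1 * (n1 + 1) / 2.0
            if abs(u_p - n1 * n2 / 2.0) >= u_obs_dev - 1e-12:
                count += 1
        p = count / n_resamples
        method = "mannwhitney_permutation"
        notes.append("ties: mid-rank permutation p")
    else:
        tie_counts = np.unique(combined, return_counts=True)[1]
        n = n1 + n2
        tie_term = ((tie_counts ** 3 - tie_counts).sum()) / (n * (n - 1))
        sigma2 = n1 * n2 / 12.0 * (n + 1 - tie_term)
        z = (u - n1 * n2 / 2.0) / np.sqrt(sigma2)
        p = 2.0 * stats.norm.sf(abs(z))
        method = "mannwhitney_normal"
        notes.append("normal approximation (large n)")
    return TestResult(float(u), float(min(p, 1.0)), method, (n1, n2),
                      "; ".join(notes))


# -------------------------------------------------- Wilcoxon signed-rank

def wilcoxon_signed_rank_exact(paired_diffs) -> TestResult:
    """Exact Wilcoxon signed-rank test on paired differences.

    Zeros are dropped; |differences| are mid-ranked; W is the positive-rank
    sum. For m ≤ 20 nonzero pairs the null distribution over all 2^m sign
    patterns is computed exactly (DP over doubled ranks, which are integers
    even with mid-rank ties).
    """
    d = np.asarray(paired_diffs, dtype=float).ravel()
    if d.size == 0:
        raise ValueError("paired_diffs must be non-empty")
    if not np.isfinite(d).all():
        raise ValueError("paired_diffs contains non-finite values")
    n_zero = int((d == 0).sum())
    d = d[d != 0]
    m = d.size
    if m == 0:
        raise ValueError("no nonzero pairs")
    ranks = stats.rankdata(np.abs(d))
    w = float(ranks[d > 0].sum())
    notes = [f"{n_zero} zero difference(s) dropped"] if n_zero else []
    if m <= WSR_EXACT_LIMIT:
        r2 = np.rint(ranks * 2).astype(int)  # doubled mid-ranks are integers
        total = r2.sum()
        counts = np.zeros(total + 1)
        counts[0] = 1.0
        for r in r2:
            shifted = np.zeros_like(counts)
            shifted[r:] = counts[: total + 1 - r]
            counts = counts + shifted
        w2 = int(round(w * 2))
        n_all = counts.sum()  # == 2**m
        lower = counts[: w2 + 1].sum() / n_all
        upper = counts[w2:].sum() / n_all
        p = min(1.0, 2.0 * min(lower, upper))
        method = "wilcoxon_exact"
    else:
        mu = m * (m + 1) / 4.0
        sigma = np.sqrt(m * (m + 1) * (2 * m + 1) / 24.0)
        z = (w - mu) / sigma
        p = 2.0 * stats.norm.sf(abs(z))
        method = "wilcoxon_normal"
        notes.append("normal approximation (large m)")
    return TestResult(w, float(min(p, 1.0)), method, (m,), "; ".join(notes))
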