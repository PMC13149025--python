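"""Statistical comparisons for distance and diffusion distributions.

Two-sample Kolmogorov-Smirnov, F test of equality of variances,
percentile-bootstrap confidence intervals of the median, and the
Kruskal-Wallis test with Dunn's post hoc comparisons. All tests are
two-sided.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps


@dataclass
class TestResult:
    name: str           # KS_D, F, H, z (Dunn)
    statistic: float
    p_value: float
    n: tuple[int, ...]
    tails: str = "two-sided"
    extra: dict = field(default_factory=dict)


@dataclass
class MedianCI:
    median: float
    ci_lo: float
    ci_hi: float
    n: int
    n_boot: int
    rng_seed: int


def ks_test(sample_a, sample_b) -> TestResult:
    """Two-sided two-sample KS test.

    Uses the exact null distribution when ``n_a * n_b <= 10_000`` and
    the asymptotic one otherwise.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("samples must be non-empty")
    method = "exact" if a.size * b.size <= 10_000 else "asymp"
    res = sps.ks_2samp(a, b, alternative="two-sided", method=method)
    return TestResult("KS_D", float(res.statistic), float(res.pvalue), (a.size, b.size))


def f_test_var(sample_a, sample_b) -> TestResult:
    """F test of equality of variances.

    By convention the larger sample variance goes in the numerator
    (so F >= 1) and the two-sided p value is twice the upper tail,
    capped at 1.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("need at least 2 observations per sample")
    va, vb = np.var(a, ddof=1), np.var(b, ddof=1)
    if min(va, vb) == 0:
        raise ValueError("zero variance in denominator")
    if va >= vb:
        f, dfn, dfd = va / vb, a.size - 1, b.size - 1
    else:
        f, dfn, dfd = vb / va, b.size - 1, a.size - 1
    p = min(1.0, 2.0 * float(sps.f.sf(f, dfn, dfd)))
    return TestResult("F", float(f), p, (a.size, b.size), extra={"dfn": dfn, "dfd": dfd})


def bootstrap_median_ci(sample, n_boot: int = 10_000, seed: int = 0) -> MedianCI:
    """Seeded percentile bootstrap of the median (95% CI)."""
    x = np.asarray(sample, dtype=float)
    if x.size < 3:
        raise ValueError("need at least 3 observations")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, x.size, size=(n_boot, x.size))
    meds = np.median(x[idx], axis=1)
    lo, hi = np.percentile(meds, [2.5, 97.5])
    return MedianCI(float(np.median(x)), float(lo), float(hi), x.size, n_boot, seed)


def kruskal_wallis_dunn(groups, adjust: str = "bonferroni") -> list[TestResult]:
    """Tie-corrected Kruskal-Wallis H plus pairwise Dunn z statistics.

    Returns the omnibus result first, followed by one result per group
    pair with multiplicity-adjusted p values (``bonferroni`` or
    ``holm``). If every value is identical across all groups the
    omnibus result is returned with a ``degenerate`` flag and H = 0.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2 or any(g.size == 0 for g in groups):
        raise ValueError("need >= 2 non-empty groups")
    ns = [g.size for g in groups]
    pooled = np.concatenate(groups)
    n_total = pooled.size

    if np.ptp(pooled) == 0:
        res = TestResult("H", 0.0, 1.0, tuple(ns), extra={"degenerate": True})
        return [res]

    h, p = sps.kruskal(*groups)
    results = [TestResult("H", float(h), float(p), tuple(ns))]

    # Dunn's z: rank all data jointly with average ranks, compare mean ranks
    ranks = sps.rankdata(pooled)
    mean_ranks = []
    start = 0
    for n in ns:
        mean_ranks.append(ranks[start:start + n].mean())
        start += n
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = (tie_counts**3 - tie_counts).sum() / (12.0 * (n_total - 1))
    base_var = n_total * (n_total + 1) / 12.0 - tie_term

    pairs = [(i, j) for i in range(len(groups)) for j in range(i + 1, len(groups))]
    raw = []
    for i, j in pairs:
        se = np.sqrt(base_var * (1.0 / ns[i] + 1.0 / ns[j]))
        z = (mean_ranks[i] - mean_ranks[j]) / se
        raw.append((i, j, float(z), 2.0 * float(sps.norm.sf(abs(z)))))

    m = len(pairs)
    if adjust == "bonferroni":
        adj = [min(1.0, p_ * m) for *_, p_ in raw]
    elif adjust == "holm":
        order = np.argsort([p_ for *_, p_ in raw])
        adj = [0.0] * m
        running = 0.0
        for rank, k in enumerate(order):
            running = max(running, min(1.0, (m - rank) * raw[k][3]))
            adj[k] = running
    else:
        raise ValueError(f"unknown adjustment: {adjust!r}")

    for (i, j, z, p_raw), p_adj in zip(raw, adj):
        results.append(
            TestResult(
                "z", z, p_adj, (ns[i], ns[j]),
                extra={"pair": (i, j), "p_unadjusted": p_raw, "adjust": adjust},
            )
        )
    return results
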