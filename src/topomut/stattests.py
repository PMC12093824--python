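"""Shared statistical machinery.

Every analysis compares a quantity measured on the real cohort against the
same quantity measured on each simulated replicate: a z-test against the
replicate distribution for continuous summaries, Fisher's exact test for
strand count tables, Fisher's method where per-sample p values are combined,
and Benjamini-Hochberg FDR adjustment within each analysis family. Adjusted
p values below ``alpha`` (0.05 by default) are significant; odds-ratio-based
tests additionally require the effect to exceed a threshold (1.10).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, List, Sequence, Tuple

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

SD_FLOOR = 1e-12


@dataclass
class TestResult:
    __test__ = False  # not a pytest collectible despite the name

    statistic: float
    effect: float  # fold change or odds ratio
    p: float
    q: float = float("nan")
    significant: bool = False
    direction: str = "none"  # enriched / depleted / none


def ztest_vs_sims(
    observed: float, sim_values: Sequence[float], tail: str = "two"
) -> Tuple[float, float]:
    """z statistic and p value of an observed summary against simulated replicates.

    The simulated replicates provide the empirical null; their standard
    deviation is floored at ``SD_FLOOR`` so that degenerate (constant)
    simulations still yield a defined statistic. An observation identical
    to every replicate short-circuits to z = 0.
    """
    sims = np.asarray(sim_values, dtype=np.float64)
    if sims.size < 2:
        raise ValueError("z-test requires at least 2 simulated values")
    mean = float(sims.mean())
    sd = float(sims.std(ddof=1))
    if observed == mean:
        z = 0.0
    else:
        z = (observed - mean) / max(sd, SD_FLOOR)
    if tail == "two":
        p = 2.0 * stats.norm.sf(abs(z))
    elif tail == "upper":
        p = stats.norm.sf(z)
    elif tail == "lower":
        p = stats.norm.cdf(z)
    else:
        raise ValueError(f"unknown tail {tail!r}")
    return z, float(min(p, 1.0))


def fisher_combine(pvals: Sequence[float]) -> Tuple[float, int, float]:
    """Fisher's method: X^2 = -2 sum(ln p), df = 2k, chi-square upper tail."""
    ps = np.asarray(pvals, dtype=np.float64)
    if ps.size == 0:
        raise ValueError("no p values to combine")
    if np.any(ps <= 0):
        warnings.warn("p = 0 clipped to 1e-300 in Fisher combination")
        ps = np.clip(ps, 1e-300, 1.0)
    x2, p = stats.combine_pvalues(ps, method="fisher")
    return float(x2), 2 * len(ps), float(p)


def fisher_exact_2x2(a: int, b: int, c: int, d: int) -> Tuple[float, float]:
    """Two-sided Fisher's exact test on [[a, b], [c, d]].

    Returns the conditional odds ratio and the two-sided p value under the
    "sum of tables at most as probable" convention. An all-zero table has no
    information: p = 1 and the odds ratio is reported as 1.
    """
    table = [[a, b], [c, d]]
    if a == b == c == d == 0:
        return 1.0, 1.0
    res = stats.fisher_exact(table, alternative="two-sided")
    odds = res.statistic
    if not np.isfinite(odds) or odds == 0.0:
        # sample OR degenerate (zero cell); use Haldane-Anscombe correction
        odds = ((a + 0.5) * (d + 0.5)) / ((b + 0.5) * (c + 0.5))
    return float(odds), float(res.pvalue)


def bh_adjust(pvals: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up q values, order-preserving, clipped to 1."""
    ps = np.asarray(pvals, dtype=np.float64)
    if ps.size == 0:
        return ps.copy()
    _, q, _, _ = multipletests(ps, method="fdr_bh")
    return q


def finalize_results(
    results: Iterable[TestResult],
    alpha: float,
    effect_threshold: float | None = None,
) -> List[TestResult]:
    """BH-adjust one analysis family and set significance flags.

    ``effect_threshold`` (odds-ratio analyses) additionally requires the
    effect, in whichever direction, to exceed the threshold: OR > t or
    OR < 1/t.
    """
    results = list(results)
    if not results:
        return results
    qs = bh_adjust([r.p for r in results])
    for r, q in zip(results, qs):
        r.q = float(max(q, r.p))
        sig = r.q <= alpha
        if effect_threshold is not None:
            sig = sig and (
                r.effect > effect_threshold or r.effect < 1.0 / effect_threshold
            )
        r.significant = bool(sig)
        if r.significant:
            r.direction = "enriched" if r.effect > 1.0 else "depleted"
        else:
            r.direction = "none"
    return results
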