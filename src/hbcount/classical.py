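"""Conventional tests for blocked choice-count data.

Three comparators commonly applied to replicate-by-choice tables:

* **Friedman test** -- within-replicate ranks of the counts, chi-square
  statistic with K-1 degrees of freedom (tie-corrected).
* **Quade test** -- within-replicate ranks weighted by a ranking of the
  replicates themselves.  Two weighting rules are provided: the classical
  one ranks replicates by the within-replicate range of their counts; the
  ``"block_totals"`` rule ranks replicates by their total count, so a
  replicate with 50 observations carries more weight than one with 10.
* **ANOVA on arcsin-square-root-transformed proportions** -- ANOVA
  across the K choice groups after the variance-stabilizing transform
  arcsin(sqrt(x_jk / n_j)), blocked by replicate by default.  Blocking
  matters: within a replicate the proportions sum to one, and ignoring
  the replicate stratum leaves that negative dependence in the error
  term, making the unblocked test markedly conservative under the null.

Ties are handled by midranks throughout.  None of these tests estimates
the preference parameters themselves; they are included as calibration
comparators for the hierarchical model.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from itertools import permutations, product

import numpy as np
from scipy import stats

from .data import CountTable

__all__ = ["TestResult", "friedman_test", "quade_test", "arcsine_anova"]


@dataclass(frozen=True)
class TestResult:
    """Outcome of a classical test: statistic, degrees of freedom, p-value."""

    statistic: float
    df: tuple
    p_value: float
    method: str

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0):
            raise ValueError(f"p-value {self.p_value} outside [0, 1]")

    def __str__(self) -> str:
        df = ", ".join(str(d) for d in self.df)
        return f"{self.method}: statistic={self.statistic:.4g}, df=({df}), p={self.p_value:.4g}"


def _row_ranks(counts: np.ndarray) -> np.ndarray:
    """Within-replicate midranks of the counts."""
    return np.apply_along_axis(stats.rankdata, 1, counts.astype(np.float64))


def _friedman_statistic(counts: np.ndarray) -> float:
    """Tie-corrected Friedman chi-square statistic.

    Uses the standard correction in which the denominator
    J*K*(K+1) is reduced by sum(t^3 - t)/(K - 1) over tie groups within
    each replicate; reduces to the textbook statistic without ties.
    """
    J, K = counts.shape
    r = _row_ranks(counts)
    col_sums = r.sum(axis=0)
    numer = 12.0 * ((col_sums - J * (K + 1) / 2.0) ** 2).sum()
    ties = 0.0
    for row in counts:
        _, t = np.unique(row, return_counts=True)
        ties += (t.astype(float) ** 3 - t).sum()
    denom = J * K * (K + 1) - ties / (K - 1)
    if denom <= 0.0:
        return 0.0  # every replicate fully tied: no information
    return float(numer / denom)


def friedman_test(table: CountTable, method: str = "asymptotic") -> TestResult:
    """Friedman rank test across choices, blocked by replicate.

    ``method="exact"`` computes the p-value by full enumeration of all
    within-replicate orderings (K!^J equally likely rank assignments under
    the null); feasible only for tiny tables and intended for validation.
    """
    counts = table.counts
    J, K = counts.shape
    if J < 2:
        raise ValueError("Friedman test needs at least 2 replicates")
    stat = _friedman_statistic(counts)
    df = K - 1
    if method == "exact":
        p = _exact_permutation_p(counts, _friedman_statistic)
    else:
        p = 1.0 if stat == 0.0 else float(stats.chi2.sf(stat, df))
    return TestResult(stat, (df,), p, "Friedman test")


def _exact_permutation_p(counts: np.ndarray, stat_fn) -> float:
    """Exact permutation p-value: permute entries within every replicate."""
    J, K = counts.shape
    if math.factorial(K) ** J > 500_000:
        raise ValueError("exact enumeration infeasible for this table size")
    observed = stat_fn(counts)
    perms = list(permutations(range(K)))
    hits = 0
    total = 0
    for combo in product(perms, repeat=J):
        permuted = np.array([counts[j, list(combo[j])] for j in range(J)])
        if stat_fn(permuted) >= observed - 1e-12:
            hits += 1
        total += 1
    return hits / total


def quade_test(
    table: CountTable, weighting: str = "block_totals", method: str = "asymptotic"
) -> TestResult:
    """Quade test: rank-based comparison with replicate weights.

    Within-replicate midranks are centred at (K+1)/2 and multiplied by a
    block weight, itself a midrank over replicates of either the total
    count per replicate (``weighting="block_totals"``: replicates with
    more observations carry more information and more weight) or the
    within-replicate sample range of the counts
    (``weighting="classical_range"``, the textbook definition).  The F
    statistic has (K-1, (J-1)(K-1)) degrees of freedom.
    """
    if weighting not in {"block_totals", "classical_range"}:
        raise ValueError(f"unknown weighting {weighting!r}")
    counts = table.counts
    J, K = counts.shape
    if J < 2:
        raise ValueError("Quade test needs at least 2 replicates")

    def _statistic(c: np.ndarray) -> tuple[float, float, float]:
        r = _row_ranks(c)
        if weighting == "block_totals":
            block_scores = c.sum(axis=1).astype(np.float64)
        else:
            block_scores = (c.max(axis=1) - c.min(axis=1)).astype(np.float64)
        qw = stats.rankdata(block_scores)
        s = qw[:, None] * (r - (K + 1) / 2.0)
        a2 = float((s**2).sum())
        b = float((s.sum(axis=0) ** 2).sum() / J)
        if a2 == b:
            return float("nan"), a2, b
        return (J - 1) * b / (a2 - b), a2, b

    stat, a2, b = _statistic(counts)
    df = (K - 1, (J - 1) * (K - 1))
    if np.isnan(stat):
        if b == 0.0:
            warnings.warn(
                "degenerate table (all within-replicate ranks tied); Quade "
                "statistic undefined, reporting p = 1",
                UserWarning,
                stacklevel=2,
            )
            return TestResult(0.0, df, 1.0, f"Quade test ({weighting})")
        # perfect agreement across replicates: most extreme possible outcome
        p = (1.0 / math.factorial(K)) ** (J - 1)
        return TestResult(float("inf"), df, p, f"Quade test ({weighting})")
    if method == "exact":
        p = _exact_permutation_p(counts, lambda c: _statistic(c)[0])
    else:
        p = float(stats.f.sf(stat, *df))
    return TestResult(float(stat), df, p, f"Quade test ({weighting})")


def arcsine_anova(table: CountTable, blocked: bool = True) -> TestResult:
    """ANOVA on arcsin-square-root-transformed proportions.

    Each replicate's counts are converted to proportions x_jk / n_j and
    transformed by arcsin(sqrt(.)); the F test compares the K choice
    groups.  The default blocked layout removes replicate means first
    (a two-way layout without interaction) with (K-1, (J-1)(K-1)) error
    df -- required for a calibrated type-I error rate, because the
    proportions within a replicate sum to one.  ``blocked=False`` gives
    the one-way layout with (K-1, K(J-1)) df, which is conservative on
    null data.
    """
    counts = table.counts.astype(np.float64)
    J, K = counts.shape
    totals = counts.sum(axis=1)
    if np.any(totals == 0):
        bad = [table.replicate_labels[j] for j in np.flatnonzero(totals == 0)]
        raise ValueError(
            f"replicates with zero total count cannot be converted to "
            f"proportions: {bad}; exclude them before running this test"
        )
    y = np.arcsin(np.sqrt(counts / totals[:, None]))  # (J, K)
    grand = y.mean()
    ss_choice = J * ((y.mean(axis=0) - grand) ** 2).sum()
    if blocked:
        ss_block = K * ((y.mean(axis=1) - grand) ** 2).sum()
        ss_total = ((y - grand) ** 2).sum()
        ss_err = ss_total - ss_choice - ss_block
        df = (K - 1, (J - 1) * (K - 1))
    else:
        ss_err = ((y - y.mean(axis=0)) ** 2).sum()
        df = (K - 1, K * (J - 1))
    ms_choice = ss_choice / df[0]
    ms_err = ss_err / df[1]
    name = "arcsine-sqrt ANOVA" + (" (blocked)" if blocked else "")
    if ms_err <= 0.0:
        if ms_choice <= 1e-300:
            return TestResult(0.0, df, 1.0, name)
        return TestResult(float("inf"), df, 0.0, name)
    f = ms_choice / ms_err
    if f == 0.0:
        return TestResult(0.0, df, 1.0, name)
    return TestResult(float(f), df, float(stats.f.sf(f, *df)), name)
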