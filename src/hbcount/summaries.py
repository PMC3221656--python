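"""Posterior reporting: credible intervals, pairwise comparisons, variance.

All summaries are deterministic functions of a stored chain.  Credible
intervals are equal-tail quantile intervals by default; highest-posterior-
density intervals are available behind a flag.  Pairwise "significance" is
the proportion of post-burnin draws in which one choice's population-level
preference exceeds another's -- a Bayesian analogue of a post-hoc test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .mcmc import PosteriorChain

__all__ = [
    "PreferenceSummary",
    "PairwiseReport",
    "WSummary",
    "summarize",
    "pairwise_probabilities",
    "individual_variation",
    "format_estimate",
]


@dataclass(frozen=True)
class PreferenceSummary:
    """Posterior means and credible intervals for population and individuals."""

    post_mean_q: np.ndarray
    ci_lower: np.ndarray
    ci_upper: np.ndarray
    post_mean_w: float
    per_individual_means: np.ndarray
    ci_level: float = 0.95

    def __post_init__(self) -> None:
        if np.any(self.ci_lower > self.post_mean_q + 1e-12) or np.any(
            self.post_mean_q > self.ci_upper + 1e-12
        ):
            raise ValueError("interval bounds must bracket the posterior mean")

    def to_frame(self, choice_labels=None) -> pd.DataFrame:
        K = self.post_mean_q.size
        labels = list(choice_labels) if choice_labels is not None else [
            f"c{k + 1}" for k in range(K)
        ]
        return pd.DataFrame(
            {
                "choice": labels,
                "mean": self.post_mean_q,
                "ci_lower": self.ci_lower,
                "ci_upper": self.ci_upper,
            }
        )

    def format(self, choice_labels=None, digits: int = 2) -> str:
        """Render each preference as ``estimate (lower, upper)``."""
        df = self.to_frame(choice_labels)
        lines = [
            f"{row.choice}: "
            + format_estimate(row.mean, row.ci_lower, row.ci_upper, digits)
            for row in df.itertuples()
        ]
        return "\n".join(lines)


def format_estimate(mean: float, lower: float, upper: float, digits: int = 2) -> str:
    """Standard ``0.57 (0.37, 0.73)`` rendering of an estimate and interval."""
    fmt = f"{{:.{digits}f}}"
    return f"{fmt.format(mean)} ({fmt.format(lower)}, {fmt.format(upper)})"


def _hpd_interval(draws: np.ndarray, level: float) -> tuple[float, float]:
    """Shortest interval containing ``level`` of the sorted draws."""
    x = np.sort(draws)
    n = x.size
    m = max(1, int(np.ceil(level * n)))
    if m >= n:
        return float(x[0]), float(x[-1])
    widths = x[m:] - x[: n - m]
    i = int(np.argmin(widths))
    return float(x[i]), float(x[i + m])


def summarize(
    chain: PosteriorChain, ci_level: float = 0.95, hpd: bool = False
) -> PreferenceSummary:
    """Posterior means and credible intervals from stored draws.

    Equal-tail intervals use the empirical quantiles at (1-ci)/2 and
    1-(1-ci)/2; ``hpd=True`` switches to the shortest (highest-density)
    interval computed directly from the sorted draws.
    """
    if not (0.0 < ci_level < 1.0):
        raise ValueError("ci_level must be in (0, 1)")
    if chain.n_draws == 0:
        raise ValueError("empty chain")
    q = chain.q_draws
    if hpd:
        bounds = np.array([_hpd_interval(q[:, k], ci_level) for k in range(q.shape[1])])
        lo, hi = bounds[:, 0], bounds[:, 1]
    else:
        tail = (1.0 - ci_level) / 2.0
        lo = np.quantile(q, tail, axis=0)
        hi = np.quantile(q, 1.0 - tail, axis=0)
    return PreferenceSummary(
        post_mean_q=q.mean(axis=0),
        ci_lower=lo,
        ci_upper=hi,
        post_mean_w=float(chain.w_draws.mean()),
        per_individual_means=chain.p_draws.mean(axis=0),
        ci_level=ci_level,
    )


@dataclass(frozen=True)
class PairwiseReport:
    """Matrix of exceedance probabilities between population preferences.

    ``prob_greater[a, b]`` is the fraction of stored draws with
    ``q_a > q_b`` (strictly); tied draws count toward neither side, and
    the diagonal is zero by convention.  If choice a beats choice b in
    99% of draws, the posterior probability that preference for b is
    greater than or equal to preference for a is 0.01.
    """

    prob_greater: np.ndarray
    choice_labels: tuple[str, ...] = ()

    def to_frame(self) -> pd.DataFrame:
        K = self.prob_greater.shape[0]
        labels = list(self.choice_labels) or [f"c{k + 1}" for k in range(K)]
        return pd.DataFrame(self.prob_greater, index=labels, columns=labels)


def pairwise_probabilities(
    chain: PosteriorChain, choice_labels=None
) -> PairwiseReport:
    """Fraction of post-burnin draws in which each choice beats each other."""
    if chain.n_draws == 0:
        raise ValueError("empty chain")
    q = chain.q_draws  # (S, K)
    greater = (q[:, :, None] > q[:, None, :]).mean(axis=0)
    np.fill_diagonal(greater, 0.0)
    return PairwiseReport(
        prob_greater=greater,
        choice_labels=tuple(choice_labels) if choice_labels is not None else (),
    )


@dataclass(frozen=True)
class WSummary:
    """Posterior summary of the concentration w.

    ``w`` is inversely proportional to among-individual variance: high
    values mean individuals share the population mean preference closely;
    low values mean individuals are polarized toward different choices
    even when the population mean is indifferent.
    """

    mean: float
    ci_lower: float
    ci_upper: float
    ci_level: float
    grid: np.ndarray
    density: np.ndarray


def individual_variation(chain: PosteriorChain, ci_level: float = 0.95) -> WSummary:
    """Posterior mean, credible interval, and density grid for w."""
    if chain.n_draws == 0:
        raise ValueError("empty chain")
    w = chain.w_draws
    tail = (1.0 - ci_level) / 2.0
    lo, hi = np.quantile(w, [tail, 1.0 - tail])
    if np.ptp(w) == 0.0:
        grid = np.array([w[0]])
        density = np.array([np.inf])
    else:
        from scipy.stats import gaussian_kde

        kde = gaussian_kde(w)
        grid = np.linspace(w.min(), w.max(), 256)
        density = kde(grid)
    return WSummary(
        mean=float(w.mean()),
        ci_lower=float(lo),
        ci_upper=float(hi),
        ci_level=ci_level,
        grid=grid,
        density=density,
    )
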