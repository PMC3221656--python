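"""Log-densities of the hierarchical multinomial-Dirichlet preference model.

The model has two levels.  Each replicate's counts follow a multinomial
with its own probability vector p_j (the individual's preference), and the
p_j are exchangeable draws from a population Dirichlet whose parameter is
decomposed as ``alpha = w * q``: ``q`` is the population mean preference
(a simplex vector) and ``w`` a scalar concentration inversely proportional
to among-individual variance.  Hyperpriors are Dirichlet on ``q`` and
Uniform(0, u) on ``w``.

All computation is in natural-log space: the likelihood and prior products
over replicates become sums of logs, which is required for numerical
stability once there are more than a handful of replicates.  The deviance
used for model comparison is ``-2 log f`` where ``f`` is the likelihood
times the conditional prior (hyperpriors excluded by definition).
"""

from __future__ import annotations

import numpy as np
from scipy.special import gammaln, xlogy

from .data import CountTable, IndividualPreferences, PopulationParams, PriorConfig

__all__ = [
    "multinomial_loglik",
    "total_loglik",
    "dirichlet_logpdf",
    "conditional_prior_loglik",
    "log_posterior",
    "deviance",
]


def _check_lengths(a: np.ndarray, b: np.ndarray, what: str) -> None:
    if a.shape[-1] != b.shape[-1]:
        raise ValueError(f"{what}: length mismatch {a.shape[-1]} vs {b.shape[-1]}")


def multinomial_loglik(x_row: np.ndarray, p_row: np.ndarray) -> float:
    """Log-probability of one replicate's counts under its multinomial.

    Includes the multinomial coefficient ``n! / prod(x_k!)``; the
    coefficient cancels in MCMC acceptance ratios but matters for deviance
    values comparable across implementations.  A row of all zeros has
    probability one (log 0.0).
    """
    x = np.asarray(x_row, dtype=np.float64)
    p = np.asarray(p_row, dtype=np.float64)
    _check_lengths(x, p, "multinomial_loglik")
    if np.any(x < 0) or np.any(x != np.floor(x)):
        raise ValueError("counts must be non-negative integers")
    n = x.sum()
    coef = gammaln(n + 1.0) - gammaln(x + 1.0).sum()
    return float(coef + xlogy(x, p).sum())


def total_loglik(table: CountTable, prefs: IndividualPreferences) -> float:
    """First-level log-likelihood: sum of per-replicate multinomial terms."""
    x = table.counts.astype(np.float64)
    p = prefs.probs
    if x.shape != p.shape:
        raise ValueError(f"shape mismatch: counts {x.shape} vs probs {p.shape}")
    n = x.sum(axis=1)
    coef = gammaln(n + 1.0).sum() - gammaln(x + 1.0).sum()
    return float(coef + xlogy(x, p).sum())


def dirichlet_logpdf(
    p_row: np.ndarray, alpha: np.ndarray, on_boundary: str = "neginf"
) -> float:
    """Dirichlet log-density at a simplex point.

    Parameters
    ----------
    p_row
        Point on the simplex (should be interior; see ``on_boundary``).
    alpha
        Positive parameter vector.
    on_boundary
        What to do when a component of ``p_row`` is 0 or 1: ``"neginf"``
        returns -inf, ``"raise"`` raises ``ValueError``.
    """
    p = np.asarray(p_row, dtype=np.float64)
    a = np.asarray(alpha, dtype=np.float64)
    _check_lengths(p, a, "dirichlet_logpdf")
    if np.any(a <= 0):
        raise ValueError("alpha must be positive")
    if np.any(p < 0) or abs(p.sum() - 1.0) > 1e-8:
        raise ValueError("p_row must lie on the probability simplex")
    if np.any(p == 0.0):
        if on_boundary == "raise":
            raise ValueError("p_row on the simplex boundary")
        # density is +inf for alpha_k < 1 at the boundary, but -inf is the
        # conservative value for the alpha_k >= 1 case this model works in
        return float("-inf") if np.all(a >= 1.0) else float("inf")
    norm = gammaln(a.sum()) - gammaln(a).sum()
    return float(norm + ((a - 1.0) * np.log(p)).sum())


def conditional_prior_loglik(
    prefs: IndividualPreferences, pop: PopulationParams
) -> float:
    """Log-density of all individual preferences given the population Dirichlet.

    The conditional prior is the product over replicates of
    Dirichlet(p_j | w * q); returned on the log scale.
    """
    p = prefs.probs
    a = pop.alpha
    _check_lengths(p, a, "conditional_prior_loglik")
    J = p.shape[0]
    norm = gammaln(a.sum()) - gammaln(a).sum()
    return float(J * norm + ((a - 1.0) * np.log(p)).sum())


def log_posterior(
    table: CountTable,
    prefs: IndividualPreferences,
    pop: PopulationParams,
    prior: PriorConfig,
) -> float:
    """Unnormalized joint log-posterior of (p, q, w).

    Likelihood x conditional prior x Dirichlet hyperprior on q x
    Uniform(0, u) prior on w, all on the log scale.  Returns -inf when
    ``w`` falls outside the prior support (0, u).
    """
    if not (0.0 < pop.w < prior.w_upper):
        return float("-inf")
    a0 = prior.alpha_for(table.n_choices)
    return (
        total_loglik(table, prefs)
        + conditional_prior_loglik(prefs, pop)
        + dirichlet_logpdf(pop.q, a0)
        - np.log(prior.w_upper)
    )


def deviance(
    table: CountTable, prefs: IndividualPreferences, pop: PopulationParams
) -> float:
    """Model deviance ``-2 log f`` with f = likelihood x conditional prior.

    Hyperpriors are excluded by definition.  The conditional prior is a
    density and can exceed one, so the deviance (and hence DIC) can be
    negative; strongly concentrated preferences with large ``w`` routinely
    produce large negative values.
    """
    return -2.0 * (total_loglik(table, prefs) + conditional_prior_loglik(prefs, pop))
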