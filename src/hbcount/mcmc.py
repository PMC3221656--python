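"""Metropolis-within-Gibbs sampler for the hierarchical preference model.

Each sweep alternates three blocks, passing information up and down the
hierarchy: the individual preference rows are updated by an exact Gibbs
draw from their conjugate full conditional Dirichlet(x_j + w q); the
population mean ``q`` by a Metropolis-Hastings step with a Dirichlet
proposal centred at the current value; and the concentration ``w`` by a
Gaussian random walk on log w with the Jacobian correction.  The
constrained (equal-preference) model fixes ``q`` at the uniform simplex
point and skips its update, leaving the individual rows and ``w`` free.

The internal core (:func:`_run_mcmc`) operates on one or more "blocks" of
count rows that share a single ``q`` -- a single population is one block;
a group of populations constrained to the same preference parameters is
several.  The concentration ``w`` can be shared across blocks or kept
per-block.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.special import gammaln

from .data import (
    CountTable,
    IndividualPreferences,
    PopulationParams,
    PriorConfig,
)

__all__ = [
    "MCMCConfig",
    "PosteriorChain",
    "gibbs_update_individuals",
    "mh_update_q",
    "mh_update_w",
    "run_chain",
]

logger = logging.getLogger(__name__)

_TINY = np.finfo(np.float64).tiny


@dataclass(frozen=True)
class MCMCConfig:
    """Chain-length and proposal settings.

    ``n_steps`` post-burnin sweeps are recorded (after ``burnin`` discarded
    sweeps, keeping every ``thin``-th).  ``q_proposal_scale`` is the
    concentration of the Dirichlet proposal for ``q`` (larger = smaller
    moves); ``w_proposal_sd`` the standard deviation of the random walk on
    log w.
    """

    n_steps: int = 40_000
    burnin: int = 10_000
    thin: int = 1
    seed: int = 0
    q_proposal_scale: float = 100.0
    w_proposal_sd: float = 0.3

    def __post_init__(self) -> None:
        if self.n_steps < 1:
            raise ValueError("n_steps must be >= 1")
        if self.burnin < 0:
            raise ValueError("burnin must be >= 0")
        if not (1 <= self.thin <= self.n_steps):
            raise ValueError("thin must satisfy 1 <= thin <= n_steps")
        if self.q_proposal_scale <= 0 or self.w_proposal_sd <= 0:
            raise ValueError("proposal scales must be positive")

    def to_dict(self) -> dict:
        return {
            "n_steps": self.n_steps,
            "burnin": self.burnin,
            "thin": self.thin,
            "seed": self.seed,
            "q_proposal_scale": self.q_proposal_scale,
            "w_proposal_sd": self.w_proposal_sd,
        }


@dataclass(frozen=True)
class PosteriorChain:
    """Stored post-burnin draws of (p, q, w) for one population (or pooled group).

    ``p_draws`` has shape (S, J, K), ``q_draws`` (S, K), ``w_draws`` (S,),
    where S = floor(n_steps / thin).
    """

    p_draws: np.ndarray
    q_draws: np.ndarray
    w_draws: np.ndarray
    accept_rates: dict = field(default_factory=dict)
    config: MCMCConfig | None = None

    def __post_init__(self) -> None:
        p = np.asarray(self.p_draws, dtype=np.float64)
        q = np.asarray(self.q_draws, dtype=np.float64)
        w = np.asarray(self.w_draws, dtype=np.float64)
        if p.ndim != 3 or q.ndim != 2 or w.ndim != 1:
            raise ValueError("p_draws must be (S,J,K), q_draws (S,K), w_draws (S,)")
        if not (p.shape[0] == q.shape[0] == w.shape[0]):
            raise ValueError("draw counts disagree across p, q, w")
        if p.shape[2] != q.shape[1]:
            raise ValueError("choice dimension disagrees between p and q")
        if p.shape[0] == 0:
            raise ValueError("chain is empty")
        if np.any(np.abs(q.sum(axis=1) - 1.0) > 1e-8):
            raise ValueError("stored q draws must lie on the simplex")
        if np.any(w <= 0):
            raise ValueError("stored w draws must be positive")
        object.__setattr__(self, "p_draws", p)
        object.__setattr__(self, "q_draws", q)
        object.__setattr__(self, "w_draws", w)

    @property
    def n_draws(self) -> int:
        return self.p_draws.shape[0]

    @property
    def n_replicates(self) -> int:
        return self.p_draws.shape[1]

    @property
    def n_choices(self) -> int:
        return self.p_draws.shape[2]


# ---------------------------------------------------------------------------
# single-step public updates (thin wrappers over the array kernels)
# ---------------------------------------------------------------------------


def _gibbs_p(x: np.ndarray, alpha_pop: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """One exact draw of every preference row from Dirichlet(x_j + w q)."""
    g = rng.standard_gamma(x + alpha_pop)
    np.clip(g, _TINY, None, out=g)
    return g / g.sum(axis=1, keepdims=True)


def gibbs_update_individuals(
    table: CountTable, pop: PopulationParams, rng: np.random.Generator
) -> IndividualPreferences:
    """Draw all individual preference rows from their full conditionals.

    Conjugacy of the multinomial likelihood with the Dirichlet conditional
    prior makes the full conditional of row j exactly
    Dirichlet(x_j + w q); this is a Gibbs (always-accepted) update.  A row
    with no observations is drawn from the conditional prior itself.
    """
    p = _gibbs_p(table.counts.astype(np.float64), pop.alpha, rng)
    return IndividualPreferences(p)


def _dirichlet_logpdf_arr(p: np.ndarray, alpha: np.ndarray) -> float:
    return float(
        gammaln(alpha.sum())
        - gammaln(alpha).sum()
        + ((alpha - 1.0) * np.log(p)).sum()
    )


def _q_log_target(
    q: np.ndarray,
    S_blocks: Sequence[np.ndarray],
    J_blocks: Sequence[int],
    w_blocks: Sequence[float],
    hyper_alpha: np.ndarray,
) -> float:
    """Log full conditional of q: conditional prior over all rows + hyperprior.

    ``S_blocks[b]`` holds the column sums of log p over block b's rows.
    """
    logq = np.log(q)
    total = float(((hyper_alpha - 1.0) * logq).sum())
    for S, J, w in zip(S_blocks, J_blocks, w_blocks):
        a = w * q
        total += J * (gammaln(w) - gammaln(a).sum()) + ((a - 1.0) * S).sum()
    return total


def _w_log_target(
    w: float, q: np.ndarray, S: np.ndarray, J: int, w_upper: float
) -> float:
    if not (0.0 < w < w_upper):
        return float("-inf")
    a = w * q
    return float(J * (gammaln(w) - gammaln(a).sum()) + ((a - 1.0) * S).sum())


def mh_update_q(
    current: PopulationParams,
    prefs: IndividualPreferences,
    prior: PriorConfig,
    rng: np.random.Generator,
    proposal_scale: float = 100.0,
) -> PopulationParams:
    """Metropolis-Hastings update of the population mean q.

    Proposes q' ~ Dirichlet(delta * q) centred at the current value and
    accepts with the usual ratio including the Hastings correction for the
    asymmetric proposal.  The target is the q full conditional: the
    conditional prior of all preference rows times the Dirichlet
    hyperprior.
    """
    q = current.q
    logp = np.log(prefs.probs)
    S = logp.sum(axis=0)
    J = prefs.n_replicates
    hyper = prior.alpha_for(q.size)

    q_prop = rng.dirichlet(proposal_scale * q)
    q_prop = np.clip(q_prop, _TINY, None)
    q_prop = q_prop / q_prop.sum()

    log_ratio = (
        _q_log_target(q_prop, [S], [J], [current.w], hyper)
        - _q_log_target(q, [S], [J], [current.w], hyper)
        + _dirichlet_logpdf_arr(q, proposal_scale * q_prop)
        - _dirichlet_logpdf_arr(q_prop, proposal_scale * q)
    )
    if np.log(rng.uniform()) < log_ratio:
        return PopulationParams(q=q_prop, w=current.w)
    return current


def mh_update_w(
    current: PopulationParams,
    prefs: IndividualPreferences,
    prior: PriorConfig,
    rng: np.random.Generator,
    proposal_sd: float = 0.3,
) -> PopulationParams:
    """Random-walk Metropolis update of the concentration w on the log scale.

    Proposes log w' = log w + N(0, sd); the Jacobian of the log transform
    contributes log(w'/w) to the acceptance ratio.  Proposals at or beyond
    the uniform prior's upper bound ``u`` are rejected outright.
    """
    S = np.log(prefs.probs).sum(axis=0)
    J = prefs.n_replicates
    w = current.w
    w_prop = w * np.exp(proposal_sd * rng.standard_normal())
    if w_prop >= prior.w_upper:
        rng.uniform()  # keep stream advancement uniform across branches
        return current
    log_ratio = (
        _w_log_target(w_prop, current.q, S, J, prior.w_upper)
        - _w_log_target(w, current.q, S, J, prior.w_upper)
        + np.log(w_prop)
        - np.log(w)
    )
    if np.log(rng.uniform()) < log_ratio:
        return PopulationParams(q=current.q, w=w_prop)
    return current


# ---------------------------------------------------------------------------
# full chain
# ---------------------------------------------------------------------------


def _init_state(
    xs: Sequence[np.ndarray], fix_q: bool
) -> tuple[list[np.ndarray], np.ndarray, float]:
    """Data-driven interior starting point: add-one smoothed proportions."""
    K = xs[0].shape[1]
    ps = []
    for x in xs:
        n = x.sum(axis=1, keepdims=True)
        ps.append((x + 1.0) / (n + K))
    if fix_q:
        q = np.full(K, 1.0 / K)
    else:
        q = np.concatenate(ps, axis=0).mean(axis=0)
        q = q / q.sum()
    return ps, q, float(K)


def _run_mcmc_single(
    x: np.ndarray,
    prior: PriorConfig,
    config: MCMCConfig,
    fix_q: bool,
):
    """Fused sweep loop for one block (the common case; see :func:`_run_mcmc`).

    Mathematically identical to the generic multi-block path but with the
    per-sweep log-gamma terms cached and batched, since a calibration study
    runs millions of sweeps.
    """
    J, K = x.shape
    hyper = prior.alpha_for(K)
    hyper_m1 = hyper - 1.0
    u = prior.w_upper
    delta = config.q_proposal_scale
    sd = config.w_proposal_sd
    rng = np.random.default_rng(config.seed)

    ps, q, w0 = _init_state([x], fix_q)
    w = min(w0, 0.5 * u)
    logq = np.log(q)
    glw = float(gammaln(w))
    glwq_sum = float(gammaln(w * q).sum())

    n_store = config.n_steps // config.thin
    p_store = np.empty((n_store, J, K))
    q_store = np.empty((n_store, K))
    w_store = np.empty(n_store)
    acc_q = 0
    acc_w = 0

    total = config.burnin + config.n_steps
    idx = 0
    log = np.log
    for step in range(total):
        # Gibbs: p_j ~ Dirichlet(x_j + w q), exact conjugate draw
        g = rng.standard_gamma(x + w * q)
        np.clip(g, _TINY, None, out=g)
        p = g / g.sum(axis=1, keepdims=True)
        logp = log(p)
        S = logp.sum(axis=0)

        if not fix_q:
            # MH: q' ~ Dirichlet(delta q), Hastings-corrected
            gp = rng.standard_gamma(delta * q)
            np.clip(gp, _TINY, None, out=gp)
            qp = gp / gp.sum()
            logqp = log(qp)
            gl = gammaln(np.concatenate([w * qp, delta * q, delta * qp]))
            glwqp_sum = gl[:K].sum()
            target_diff = (
                J * (glwq_sum - glwqp_sum)
                + (w * (qp - q) * S).sum()
                + (hyper_m1 * (logqp - logq)).sum()
            )
            hastings = (
                gl[K : 2 * K].sum()
                - gl[2 * K :].sum()
                + ((delta * qp - 1.0) * logq).sum()
                - ((delta * q - 1.0) * logqp).sum()
            )
            if log(rng.uniform()) < target_diff + hastings:
                q = qp
                logq = logqp
                glwq_sum = float(glwqp_sum)
                acc_q += 1

        # MH: log-scale random walk on w, Jacobian-corrected
        wp = w * np.exp(sd * rng.standard_normal())
        if wp < u:
            glp = gammaln(np.concatenate([wp * q, [wp]]))
            glwqp_sum = glp[:K].sum()
            glwp = glp[K]
            log_ratio = (
                J * ((glwp - glwqp_sum) - (glw - glwq_sum))
                + ((wp - w) * q * S).sum()
                + log(wp)
                - log(w)
            )
            if log(rng.uniform()) < log_ratio:
                w = wp
                glw = float(glwp)
                glwq_sum = float(glwqp_sum)
                acc_w += 1
        else:
            rng.uniform()

        i = step - config.burnin
        if i >= 0 and (i + 1) % config.thin == 0:
            p_store[idx] = p
            q_store[idx] = q
            w_store[idx] = w
            idx += 1

    accept_rates = {
        "q": (acc_q / total) if not fix_q else float("nan"),
        "w": [acc_w / total],
    }
    return {
        "p_draws": [p_store],
        "q_draws": q_store,
        "w_draws": w_store[:, None],
        "accept_rates": accept_rates,
    }


def _run_mcmc(
    xs: Sequence[np.ndarray],
    prior: PriorConfig,
    config: MCMCConfig,
    fix_q: bool = False,
    share_w: bool = True,
):
    """Core sampler over B blocks of count rows sharing one q.

    Returns a dict with per-block ``p_draws`` (list of (S, J_b, K) arrays),
    ``q_draws`` (S, K), ``w_draws`` (S, B) -- identical columns when w is
    shared -- and acceptance rates.
    """
    xs = [np.asarray(x, dtype=np.float64) for x in xs]
    K = xs[0].shape[1]
    if any(x.shape[1] != K for x in xs):
        raise ValueError("all blocks must have the same number of choices")
    B = len(xs)
    if B == 1:
        return _run_mcmc_single(xs[0], prior, config, fix_q)
    Js = [x.shape[0] for x in xs]
    hyper = prior.alpha_for(K)
    u = prior.w_upper
    delta = config.q_proposal_scale
    sd = config.w_proposal_sd
    rng = np.random.default_rng(config.seed)

    ps, q, w0 = _init_state(xs, fix_q)
    ws = np.full(B, min(w0, 0.5 * u))

    n_store = config.n_steps // config.thin
    p_store = [np.empty((n_store, J, K)) for J in Js]
    q_store = np.empty((n_store, K))
    w_store = np.empty((n_store, B))
    acc_q = 0
    acc_w = np.zeros(B)
    n_w_updates = 1 if share_w else B

    total = config.burnin + config.n_steps
    idx = 0
    for step in range(total):
        # --- Gibbs: individual preference rows, block by block
        Ss = []
        for b in range(B):
            g = rng.standard_gamma(xs[b] + ws[b] * q)
            np.clip(g, _TINY, None, out=g)
            p = g / g.sum(axis=1, keepdims=True)
            ps[b] = p
            Ss.append(np.log(p).sum(axis=0))

        # --- MH: population mean q (skipped under the constrained model)
        if not fix_q:
            q_prop = rng.dirichlet(delta * q)
            q_prop = np.clip(q_prop, _TINY, None)
            q_prop /= q_prop.sum()
            log_ratio = (
                _q_log_target(q_prop, Ss, Js, ws, hyper)
                - _q_log_target(q, Ss, Js, ws, hyper)
                + _dirichlet_logpdf_arr(q, delta * q_prop)
                - _dirichlet_logpdf_arr(q_prop, delta * q)
            )
            if np.log(rng.uniform()) < log_ratio:
                q = q_prop
                acc_q += 1

        # --- MH: concentration(s) w, log-scale random walk
        if share_w:
            w = ws[0]
            w_prop = w * np.exp(sd * rng.standard_normal())
            if w_prop < u:
                cur = sum(
                    _w_log_target(w, q, Ss[b], Js[b], u) for b in range(B)
                )
                prop = sum(
                    _w_log_target(w_prop, q, Ss[b], Js[b], u) for b in range(B)
                )
                if np.log(rng.uniform()) < prop - cur + np.log(w_prop / w):
                    ws[:] = w_prop
                    acc_w += 1.0
            else:
                rng.uniform()
        else:
            for b in range(B):
                w = ws[b]
                w_prop = w * np.exp(sd * rng.standard_normal())
                if w_prop < u:
                    log_ratio = (
                        _w_log_target(w_prop, q, Ss[b], Js[b], u)
                        - _w_log_target(w, q, Ss[b], Js[b], u)
                        + np.log(w_prop / w)
                    )
                    if np.log(rng.uniform()) < log_ratio:
                        ws[b] = w_prop
                        acc_w[b] += 1
                else:
                    rng.uniform()

        # --- store post-burnin draws
        i = step - config.burnin
        if i >= 0 and (i + 1) % config.thin == 0:
            for b in range(B):
                p_store[b][idx] = ps[b]
            q_store[idx] = q
            w_store[idx] = ws
            idx += 1

    accept_rates = {
        "q": (acc_q / total) if not fix_q else float("nan"),
        "w": list(acc_w / total),
    }
    logger.info(
        "chain finished: %d stored draws, acceptance q=%.3f w=%s",
        n_store,
        accept_rates["q"],
        ["%.3f" % a for a in acc_w / total],
    )
    return {
        "p_draws": p_store,
        "q_draws": q_store,
        "w_draws": w_store,
        "accept_rates": accept_rates,
    }


def run_chain(
    table: CountTable,
    prior: PriorConfig | None = None,
    config: MCMCConfig | None = None,
    constrain_q: bool = False,
) -> PosteriorChain:
    """Run the full Metropolis-within-Gibbs chain on one count table.

    Parameters
    ----------
    table
        Replicate-by-choice counts.
    prior
        Hyperprior settings; defaults to flat Dirichlet on q and
        Uniform(0, 1000) on w.
    config
        Chain lengths, seed, and proposal scales; defaults to 40000
        recorded sweeps after a burnin of 10000.
    constrain_q
        Fit the equal-preference model: q is fixed at (1/K, ..., 1/K) and
        only the individual rows and w are updated.

    Returns
    -------
    PosteriorChain
        Stored post-burnin draws; bit-reproducible for a fixed
        (data, prior, config).
    """
    prior = prior or PriorConfig()
    config = config or MCMCConfig()
    raw = _run_mcmc([table.counts], prior, config, fix_q=constrain_q, share_w=True)
    return PosteriorChain(
        p_draws=raw["p_draws"][0],
        q_draws=raw["q_draws"],
        w_draws=raw["w_draws"][:, 0],
        accept_rates=raw["accept_rates"],
        config=config,
    )
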