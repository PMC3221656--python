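"""Synthetic choice-count data and the calibration/recovery studies.

The generator reproduces the design of the null simulation study used to
benchmark the hierarchical model against classical tests: each dataset
has J replicates of K choices; the total number of events per replicate
is drawn from a uniform distribution on [total_min, total_max] rounded to
the nearest integer; each replicate's multinomial probabilities are drawn
from a population-level Dirichlet; counts are then multinomial.  The
default configuration -- 20 replicates, 3 choices, totals on [5, 40], a
flat Dirichlet(1, 1, 1) population (no preference), 1000 datasets -- is
the null design used to calibrate p-value and delta-DIC distributions.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .classical import arcsine_anova, friedman_test, quade_test
from .data import CountTable, IndividualPreferences, PopulationParams, PriorConfig
from .mcmc import MCMCConfig, run_chain
from .selection import compare_constrained
from .summaries import summarize

__all__ = [
    "SimulationConfig",
    "CalibrationReport",
    "RecoveryReport",
    "generate_dataset",
    "run_null_calibration",
    "run_recovery_study",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Design of a simulated choice experiment.

    ``pop_q``/``pop_w`` give the population Dirichlet as mean x
    concentration; ``pop_q="uniform"`` with ``pop_w="flat"`` is the
    flat Dirichlet(1, ..., 1) null population of no preference.
    ``totals_mode="rounded_uniform"`` draws continuous U(total_min,
    total_max) totals and rounds to the nearest integer (endpoints get
    half weight); ``"discrete"`` draws a discrete uniform instead.
    """

    n_replicates: int = 20
    n_choices: int = 3
    total_min: int = 5
    total_max: int = 40
    n_datasets: int = 1000
    pop_q: str | Sequence[float] = "uniform"
    pop_w: str | float = "flat"
    seed: int = 0
    totals_mode: str = "rounded_uniform"

    def __post_init__(self) -> None:
        if self.total_min > self.total_max:
            raise ValueError("total_min must be <= total_max")
        if self.n_replicates < 1 or self.n_choices < 2:
            raise ValueError("need n_replicates >= 1 and n_choices >= 2")
        if self.n_datasets < 1:
            raise ValueError("n_datasets must be >= 1")
        if self.totals_mode not in {"rounded_uniform", "discrete"}:
            raise ValueError(f"unknown totals_mode {self.totals_mode!r}")

    def population_alpha(self) -> np.ndarray:
        """Resolve (pop_q, pop_w) into the Dirichlet parameter vector."""
        K = self.n_choices
        if isinstance(self.pop_q, str):
            if self.pop_q != "uniform":
                raise ValueError(f"unknown pop_q {self.pop_q!r}")
            q = np.full(K, 1.0 / K)
        else:
            q = np.asarray(self.pop_q, dtype=np.float64)
            if q.size != K or np.any(q <= 0):
                raise ValueError("pop_q must be a positive length-K vector")
            q = q / q.sum()
        if isinstance(self.pop_w, str):
            if self.pop_w != "flat":
                raise ValueError(f"unknown pop_w {self.pop_w!r}")
            w = float(K)  # Dirichlet(1,...,1) decomposes as q=1/K, w=K
        else:
            w = float(self.pop_w)
            if w <= 0:
                raise ValueError("pop_w must be positive")
        return w * q


def _draw_totals(config: SimulationConfig, rng: np.random.Generator) -> np.ndarray:
    if config.totals_mode == "discrete":
        return rng.integers(config.total_min, config.total_max + 1, config.n_replicates)
    u = rng.uniform(config.total_min, config.total_max, config.n_replicates)
    return np.rint(u).astype(np.int64)


def generate_dataset(
    config: SimulationConfig, rng: np.random.Generator
) -> tuple[CountTable, IndividualPreferences, PopulationParams]:
    """Simulate one replicate-by-choice table plus its generating truth.

    Per replicate: a total count from the uniform total distribution, a
    preference row from the population Dirichlet, and a multinomial draw
    of the counts.  Returns the table along with the true individual
    preferences and population parameters for recovery tests.
    """
    alpha = config.population_alpha()
    K = config.n_choices
    totals = _draw_totals(config, rng)
    p = rng.dirichlet(alpha, size=config.n_replicates)
    p = np.clip(p, np.finfo(float).tiny, None)
    p = p / p.sum(axis=1, keepdims=True)
    counts = rng.multinomial(totals, p)
    table = CountTable(counts=counts)
    truth_p = IndividualPreferences(p)
    truth_pop = PopulationParams(q=alpha / alpha.sum(), w=float(alpha.sum()))
    return table, truth_p, truth_pop


_CLASSICAL = {
    "friedman": lambda t: friedman_test(t),
    "quade": lambda t: quade_test(t, weighting="block_totals"),
    "anova": lambda t: arcsine_anova(t),
}


@dataclass(frozen=True)
class CalibrationReport:
    """Null-calibration results: per-dataset p-values and delta-DIC.

    ``p_value_quantile_05`` holds each test's empirical 5% quantile (the
    threshold below which 5% of null p-values fall; ~0.05 for a
    well-calibrated test).  ``delta_dic`` stores
    DIC(constrained) - DIC(unconstrained) per dataset, with its 95% and
    5% quantiles: the upper tail is the one relevant to falsely favoring
    the unconstrained (preference-exists) model.
    """

    p_values: pd.DataFrame
    p_value_quantile_05: dict
    delta_dic: np.ndarray | None
    delta_dic_quantile_95: float | None
    delta_dic_quantile_05: float | None
    config: SimulationConfig

    def to_frame(self) -> pd.DataFrame:
        df = self.p_values.copy()
        if self.delta_dic is not None:
            df["delta_dic"] = self.delta_dic
        return df


def run_null_calibration(
    config: SimulationConfig,
    tests: Sequence[str] = ("friedman", "quade", "anova"),
    mcmc: MCMCConfig | None = None,
    prior: PriorConfig | None = None,
) -> CalibrationReport:
    """Type-I-error calibration under the no-preference population.

    Generates ``config.n_datasets`` null datasets and records, for each,
    the p-value of every requested classical test and (when an MCMC
    configuration is supplied) the DIC difference between the constrained
    and unconstrained hierarchical fits.  The default DIC chains here are
    shortened (burnin 2000, 8000 recorded sweeps) relative to a full
    analysis because the study refits two models per dataset.
    """
    unknown = set(tests) - set(_CLASSICAL)
    if unknown:
        raise ValueError(f"unknown tests: {sorted(unknown)}")
    rng = np.random.default_rng(config.seed)
    fit_seeds = rng.integers(0, 2**31, size=config.n_datasets)
    rows = {name: np.empty(config.n_datasets) for name in tests}
    deltas = np.empty(config.n_datasets) if mcmc is not None else None
    for i in range(config.n_datasets):
        table, _, _ = generate_dataset(config, rng)
        for name in tests:
            rows[name][i] = _CLASSICAL[name](table).p_value
        if mcmc is not None:
            fit_cfg = replace(mcmc, seed=int(fit_seeds[i]))
            _, _, delta = compare_constrained(table, prior, fit_cfg)
            deltas[i] = delta
    p_df = pd.DataFrame(rows)
    return CalibrationReport(
        p_values=p_df,
        p_value_quantile_05={name: float(np.quantile(rows[name], 0.05)) for name in tests},
        delta_dic=deltas,
        delta_dic_quantile_95=float(np.quantile(deltas, 0.95)) if deltas is not None else None,
        delta_dic_quantile_05=float(np.quantile(deltas, 0.05)) if deltas is not None else None,
        config=config,
    )


@dataclass(frozen=True)
class RecoveryReport:
    """Bias and coverage of posterior inference under the true model."""

    true_q: np.ndarray
    true_w: float
    q_post_means: np.ndarray  # (R, K)
    q_covered: np.ndarray  # (R, K) bool
    w_post_means: np.ndarray
    w_covered: np.ndarray

    @property
    def q_bias(self) -> np.ndarray:
        return self.q_post_means.mean(axis=0) - self.true_q

    @property
    def q_coverage(self) -> np.ndarray:
        return self.q_covered.mean(axis=0)

    @property
    def w_coverage(self) -> float:
        return float(self.w_covered.mean())


def run_recovery_study(
    true_q: Sequence[float],
    true_w: float,
    config: SimulationConfig,
    mcmc: MCMCConfig,
    prior: PriorConfig | None = None,
    ci_level: float = 0.95,
) -> RecoveryReport:
    """Repeated simulate-then-fit cycles at a known truth.

    For each of ``config.n_datasets`` repeats, simulates a table from
    Dirichlet(w q) individuals, fits the unconstrained model, and records
    the posterior mean of q and whether each credible interval covers the
    truth.  Under the correctly specified model, nominal 95% intervals
    should cover ~95% of the time and posterior means should be nearly
    unbiased.
    """
    q = np.asarray(true_q, dtype=np.float64)
    q = q / q.sum()
    sim = replace(config, pop_q=tuple(q), pop_w=float(true_w))
    rng = np.random.default_rng(sim.seed)
    fit_seeds = rng.integers(0, 2**31, size=sim.n_datasets)
    R, K = sim.n_datasets, sim.n_choices
    q_means = np.empty((R, K))
    q_cov = np.empty((R, K), dtype=bool)
    w_means = np.empty(R)
    w_cov = np.empty(R, dtype=bool)
    tail = (1.0 - ci_level) / 2.0
    for i in range(R):
        table, _, _ = generate_dataset(sim, rng)
        fit_cfg = replace(mcmc, seed=int(fit_seeds[i]))
        chain = run_chain(table, prior, fit_cfg)
        summ = summarize(chain, ci_level=ci_level)
        q_means[i] = summ.post_mean_q
        q_cov[i] = (summ.ci_lower <= q) & (q <= summ.ci_upper)
        w_means[i] = summ.post_mean_w
        w_lo, w_hi = np.quantile(chain.w_draws, [tail, 1.0 - tail])
        w_cov[i] = w_lo <= true_w <= w_hi
    return RecoveryReport(
        true_q=q,
        true_w=float(true_w),
        q_post_means=q_means,
        q_covered=q_cov,
        w_post_means=w_means,
        w_covered=w_cov,
    )
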