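"""Core domain types and I/O for replicate-by-choice count data.

A choice (or preference) experiment produces, for each replicate -- one
female in an oviposition arena, one cage, one feeding station -- a vector of
non-negative integer counts across ``K`` offered choices.  The types here
hold those tables and the parameters of the hierarchical model fitted to
them, and enforce the invariants every downstream computation relies on
(integer counts, interior-of-simplex probability vectors, positive
concentrations).

Readers and writers use plain delimited text: count tables as CSV/TSV with
a header row of choice labels and a first column of replicate labels, MCMC
traces as tab-delimited files that round-trip ``float64`` values exactly.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import TYPE_CHECKING, Sequence

import numpy as np
import pandas as pd

if TYPE_CHECKING:  # pragma: no cover
    from .mcmc import PosteriorChain

__all__ = [
    "CountTable",
    "IndividualPreferences",
    "PopulationParams",
    "PriorConfig",
    "GroupingScheme",
    "read_count_table",
    "write_count_table",
    "read_chain",
    "write_chain",
]

_SIMPLEX_TOL = 1e-10


def _as_2d(a, name: str) -> np.ndarray:
    arr = np.asarray(a)
    if arr.ndim != 2:
        raise ValueError(f"{name} must be a 2-D array, got ndim={arr.ndim}")
    return arr


@dataclass(frozen=True)
class CountTable:
    """A J x K table of counts: rows are replicates, columns are choices.

    Parameters
    ----------
    counts
        Non-negative integer matrix; ``counts[j, k]`` is the number of
        events (e.g. eggs laid) recorded for replicate ``j`` on choice ``k``.
    replicate_labels, choice_labels
        Row and column names; generated (``r1..rJ`` / ``c1..cK``) if omitted.
    population_label
        Name of the population the replicates were sampled from.
    """

    counts: np.ndarray
    replicate_labels: tuple[str, ...] = ()
    choice_labels: tuple[str, ...] = ()
    population_label: str = "pop"

    def __post_init__(self) -> None:
        counts = _as_2d(self.counts, "counts")
        if not np.issubdtype(counts.dtype, np.integer):
            as_int = np.asarray(counts)
            if not np.all(np.isfinite(as_int)) or np.any(as_int != np.floor(as_int)):
                bad = np.argwhere(~np.isfinite(as_int) | (as_int != np.floor(as_int)))
                j, k = bad[0]
                raise ValueError(
                    f"counts must be integers; offending cell at row {j}, column {k}"
                )
            counts = as_int.astype(np.int64)
        if np.any(counts < 0):
            j, k = np.argwhere(counts < 0)[0]
            raise ValueError(f"negative count at row {j}, column {k}")
        J, K = counts.shape
        if K < 2:
            raise ValueError(f"need at least 2 choices, got K={K}")
        if J < 1:
            raise ValueError("need at least 1 replicate")
        object.__setattr__(self, "counts", counts.astype(np.int64))
        rlab = tuple(self.replicate_labels) or tuple(f"r{j + 1}" for j in range(J))
        clab = tuple(self.choice_labels) or tuple(f"c{k + 1}" for k in range(K))
        if len(rlab) != J:
            raise ValueError(f"{len(rlab)} replicate labels for {J} rows")
        if len(clab) != K:
            raise ValueError(f"{len(clab)} choice labels for {K} columns")
        object.__setattr__(self, "replicate_labels", rlab)
        object.__setattr__(self, "choice_labels", clab)
        zero = np.flatnonzero(self.totals == 0)
        if zero.size:
            warnings.warn(
                f"replicates with zero total count retained: "
                f"{[rlab[j] for j in zero]} (their posterior preference equals "
                "the population-level conditional prior)",
                UserWarning,
                stacklevel=2,
            )

    @property
    def totals(self) -> np.ndarray:
        """Row totals n_j (number of events per replicate)."""
        return self.counts.sum(axis=1)

    @property
    def n_replicates(self) -> int:
        return self.counts.shape[0]

    @property
    def n_choices(self) -> int:
        return self.counts.shape[1]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CountTable):
            return NotImplemented
        return (
            np.array_equal(self.counts, other.counts)
            and self.replicate_labels == other.replicate_labels
            and self.choice_labels == other.choice_labels
            and self.population_label == other.population_label
        )


def _check_simplex_rows(probs: np.ndarray, tol: float = _SIMPLEX_TOL) -> None:
    if np.any(probs <= 0.0):
        raise ValueError("probabilities must be strictly positive (interior of simplex)")
    row_sums = probs.sum(axis=-1)
    if np.any(np.abs(row_sums - 1.0) > tol):
        j = int(np.argmax(np.abs(row_sums - 1.0)))
        raise ValueError(f"row {j} sums to {row_sums.flat[j]!r}, not 1 within {tol}")


@dataclass(frozen=True)
class IndividualPreferences:
    """J x K matrix of per-replicate multinomial probabilities p_j.

    Each row lies strictly inside the probability simplex: entries are
    positive and sum to one, so log-densities are finite.
    """

    probs: np.ndarray

    def __post_init__(self) -> None:
        probs = np.asarray(self.probs, dtype=np.float64)
        probs = _as_2d(probs, "probs")
        _check_simplex_rows(probs)
        object.__setattr__(self, "probs", probs)

    @property
    def n_replicates(self) -> int:
        return self.probs.shape[0]

    @property
    def n_choices(self) -> int:
        return self.probs.shape[1]


@dataclass(frozen=True)
class PopulationParams:
    """Population-level Dirichlet decomposed as mean ``q`` and concentration ``w``.

    The Dirichlet parameter is ``alpha = w * q`` with ``q`` on the simplex
    (mean expected preference) and scalar ``w > 0`` controlling
    among-individual variance: the variance of each component is
    ``q_k (1 - q_k) / (w + 1)``, so large ``w`` means homogeneous
    individuals and small ``w`` means polarized individuals.
    """

    q: np.ndarray
    w: float

    def __post_init__(self) -> None:
        q = np.asarray(self.q, dtype=np.float64)
        if q.ndim != 1 or q.size < 2:
            raise ValueError("q must be a 1-D simplex vector with K >= 2")
        _check_simplex_rows(q[None, :])
        w = float(self.w)
        if not np.isfinite(w) or w <= 0.0:
            raise ValueError(f"concentration w must be positive, got {w}")
        object.__setattr__(self, "q", q)
        object.__setattr__(self, "w", w)

    @property
    def alpha(self) -> np.ndarray:
        """Dirichlet parameter vector w * q."""
        return self.w * self.q


@dataclass(frozen=True)
class PriorConfig:
    """Hyperpriors: Dirichlet on the population mean, uniform on concentration.

    ``q_prior_alpha`` defaults to the flat Dirichlet(1, ..., 1);
    ``w_upper`` is the upper bound ``u`` of the Uniform(0, u) prior on ``w``.
    """

    q_prior_alpha: np.ndarray | Sequence[float] | None = None
    w_upper: float = 1000.0

    def __post_init__(self) -> None:
        if self.q_prior_alpha is not None:
            a = np.asarray(self.q_prior_alpha, dtype=np.float64)
            if a.ndim != 1 or np.any(a <= 0.0) or not np.all(np.isfinite(a)):
                raise ValueError("q_prior_alpha must be a 1-D vector of positive reals")
            object.__setattr__(self, "q_prior_alpha", a)
        u = float(self.w_upper)
        if not np.isfinite(u) or u <= 0.0:
            raise ValueError(f"w_upper must be positive, got {u}")
        object.__setattr__(self, "w_upper", u)

    def alpha_for(self, n_choices: int) -> np.ndarray:
        """Resolve the hyperprior vector for a K-choice problem."""
        if self.q_prior_alpha is None:
            return np.ones(n_choices)
        a = np.asarray(self.q_prior_alpha, dtype=np.float64)
        if a.size != n_choices:
            raise ValueError(
                f"q_prior_alpha has length {a.size} but the table has {n_choices} choices"
            )
        return a


@dataclass(frozen=True)
class GroupingScheme:
    """A partition of population labels into groups sharing (q, w).

    ``partition`` is a list of non-empty, pairwise-disjoint groups of
    population labels, e.g. ``[["CP", "MR"], ["GV", "VE"], ["LS"]]``.
    """

    partition: tuple[tuple[str, ...], ...]

    def __init__(self, partition: Sequence[Sequence[str]]) -> None:
        groups = tuple(tuple(str(x) for x in g) for g in partition)
        if not groups or any(not g for g in groups):
            raise ValueError("partition must be a non-empty list of non-empty groups")
        flat = [x for g in groups for x in g]
        if len(flat) != len(set(flat)):
            raise ValueError("groups must be pairwise disjoint")
        object.__setattr__(self, "partition", groups)

    @property
    def labels(self) -> frozenset[str]:
        return frozenset(x for g in self.partition for x in g)

    def validate_against(self, population_labels: Sequence[str]) -> None:
        pops = set(population_labels)
        if self.labels != pops:
            missing = pops - self.labels
            extra = self.labels - pops
            raise ValueError(
                f"partition must cover all populations exactly; "
                f"missing={sorted(missing)}, unknown={sorted(extra)}"
            )

    def __str__(self) -> str:
        return "".join("(" + ",".join(g) + ")" for g in self.partition)


# ---------------------------------------------------------------------------
# count-table I/O
# ---------------------------------------------------------------------------


def _delimiter_for(path: Path, delimiter: str | None) -> str:
    if delimiter is not None:
        return delimiter
    return "\t" if path.suffix.lower() in {".tsv", ".tab", ".txt"} else ","


def read_count_table(
    path: str | Path,
    delimiter: str | None = None,
    population_label: str | None = None,
) -> CountTable:
    """Read a count table from delimited text.

    The first row holds choice labels, the first column replicate labels,
    and the body non-negative integer counts.  The delimiter is inferred
    from the file extension (TSV for ``.tsv``/``.tab``/``.txt``, CSV
    otherwise) unless given explicitly.
    """
    path = Path(path)
    sep = _delimiter_for(path, delimiter)
    try:
        df = pd.read_csv(path, sep=sep, index_col=0)
    except pd.errors.ParserError as exc:
        raise ValueError(f"could not parse {path} as a delimited count table: {exc}") from exc
    if df.shape[1] < 2:
        raise ValueError(
            f"{path}: parsed only {df.shape[1]} choice column(s); "
            "check the delimiter (expected header row + replicate-label column)"
        )
    body = df.to_numpy()
    for j in range(body.shape[0]):
        for k in range(body.shape[1]):
            v = body[j, k]
            if isinstance(v, str) or not np.isfinite(v) or float(v) != int(v):
                raise ValueError(
                    f"{path}: non-integer cell {v!r} at row {df.index[j]!r}, "
                    f"column {df.columns[k]!r}"
                )
            if v < 0:
                raise ValueError(
                    f"{path}: negative count {v!r} at row {df.index[j]!r}, "
                    f"column {df.columns[k]!r}"
                )
    return CountTable(
        counts=body.astype(np.int64),
        replicate_labels=tuple(str(x) for x in df.index),
        choice_labels=tuple(str(x) for x in df.columns),
        population_label=population_label if population_label is not None else path.stem,
    )


def write_count_table(table: CountTable, path: str | Path, delimiter: str | None = None) -> None:
    """Write a count table as delimited text; inverse of :func:`read_count_table`."""
    path = Path(path)
    sep = _delimiter_for(path, delimiter)
    df = pd.DataFrame(
        table.counts,
        index=list(table.replicate_labels),
        columns=list(table.choice_labels),
    )
    df.index.name = "replicate"
    df.to_csv(path, sep=sep)


# ---------------------------------------------------------------------------
# chain I/O
# ---------------------------------------------------------------------------

_CHAIN_MAGIC = "# hbcount chain v1"


def chain_column_names(n_replicates: int, n_choices: int) -> list[str]:
    """Deterministic trace column order: p[j][k] row-major, then q[k], then w."""
    cols = [
        f"p[{j}][{k}]" for j in range(n_replicates) for k in range(n_choices)
    ]
    cols += [f"q[{k}]" for k in range(n_choices)]
    cols.append("w")
    return cols


def write_chain(chain: "PosteriorChain", path: str | Path) -> None:
    """Serialize a posterior chain as a tab-delimited trace file.

    One row per stored draw; columns are a step index followed by every
    parameter (``p[j][k]`` row-major, then ``q[k]``, then ``w``).  Values
    are written with 17 significant digits so float64 draws round-trip
    bit-exactly through :func:`read_chain`.
    """
    n = chain.n_draws
    if n == 0:
        raise ValueError("refusing to write an empty chain")
    S, J, K = chain.p_draws.shape
    path = Path(path)
    cols = chain_column_names(J, K)
    flat = np.column_stack(
        [
            np.arange(n, dtype=np.float64),
            chain.p_draws.reshape(S, J * K),
            chain.q_draws,
            chain.w_draws,
        ]
    )
    meta = {
        "n_replicates": J,
        "n_choices": K,
        "accept_rates": chain.accept_rates,
        "config": chain.config.to_dict() if chain.config is not None else None,
    }
    header = "\n".join(
        [
            _CHAIN_MAGIC.lstrip("# "),
            "meta: " + json.dumps(meta),
            "\t".join(["step"] + cols),
        ]
    )
    np.savetxt(path, flat, fmt="%.17g", delimiter="\t", header=header, comments="# ")


def read_chain(path: str | Path) -> "PosteriorChain":
    """Read a trace file written by :func:`write_chain`."""
    from .mcmc import MCMCConfig, PosteriorChain

    path = Path(path)
    meta = None
    with open(path) as fh:
        for line in fh:
            if line.startswith("# meta: "):
                meta = json.loads(line[len("# meta: ") :])
            elif not line.startswith("#"):
                break
    if meta is None:
        raise ValueError(f"{path} is not an hbcount chain file (missing meta header)")
    data = np.loadtxt(path, delimiter="\t", comments="#", ndmin=2)
    J, K = int(meta["n_replicates"]), int(meta["n_choices"])
    expected = 1 + J * K + K + 1
    if data.shape[1] != expected:
        raise ValueError(
            f"{path}: expected {expected} columns for J={J}, K={K}, got {data.shape[1]}"
        )
    S = data.shape[0]
    config = MCMCConfig(**meta["config"]) if meta.get("config") else None
    return PosteriorChain(
        p_draws=data[:, 1 : 1 + J * K].reshape(S, J, K),
        q_draws=data[:, 1 + J * K : 1 + J * K + K],
        w_draws=data[:, -1],
        accept_rates=dict(meta.get("accept_rates") or {}),
        config=config,
    )
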