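"""Exact tests of independence for r x c contingency tables.

The p-value is Fisher-exact in the probability-ordering sense: under fixed
row and column margins the table probability is multivariate hypergeometric,

    P(T) = (prod_i r_i!)(prod_j c_j!) / (n! prod_ij t_ij!),

and the two-sided p-value sums P over every margin-preserving table whose
probability does not exceed the observed one (ties included up to a small
relative tolerance).  Tables with two rows (or two columns) are enumerated
vectorized over the free cells of one row; the general r x c case recurses
over rows.  Probabilities are accumulated in log space via log-gamma so the
method is stable up to the enumeration budget (n of order 10^2 on 2 x 4).

A Patefield-sampling Monte Carlo estimator is provided for tables beyond
the enumeration budget.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Iterator, List, Sequence, Tuple

import numpy as np
from scipy.special import gammaln
from scipy import stats

from .ephys import ResponseCall, ResponseCategory

__all__ = [
    "ContingencyTable",
    "ExactTestResult",
    "build_table",
    "collapse_table",
    "exact_test",
    "exact_test_mc",
    "EnumerationBudgetError",
]

#: canonical column order for the four response categories
CATEGORY_ORDER = [c.value for c in ResponseCategory]

#: relative log-space tolerance for probability ties (see methods note)
_LOG_TIE_TOL = 1e-9


class EnumerationBudgetError(RuntimeError):
    """Raised when a table is too large to enumerate; use exact_test_mc."""


@dataclass
class ContingencyTable:
    row_labels: List[str]
    col_labels: List[str]
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.ndim != 2:
            raise ValueError("counts must be a 2-D matrix")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")
        if self.counts.shape != (len(self.row_labels), len(self.col_labels)):
            raise ValueError("label lengths do not match matrix shape")

    @property
    def n_total(self) -> int:
        return int(self.counts.sum())

    @property
    def row_sums(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    @property
    def col_sums(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    def to_dict(self) -> dict:
        return {
            "row_labels": list(self.row_labels),
            "col_labels": list(self.col_labels),
            "counts": self.counts.tolist(),
        }


@dataclass
class ExactTestResult:
    p_value: float
    observed_probability: float
    n_tables_enumerated: int
    method: str  # "enumeration" | "monte_carlo"
    mc_se: float | None = None


def build_table(
    calls: Sequence[ResponseCall],
    categories: Sequence[str] = CATEGORY_ORDER,
    row_order: Sequence[str] | None = None,
) -> ContingencyTable:
    """Cell-type x category counts from a list of response calls."""
    cats = list(categories)
    for c in calls:
        if c.category.value not in cats:
            raise ValueError(f"unknown category {c.category.value!r}")
    rows = list(row_order) if row_order else sorted({c.cell_type for c in calls})
    counts = np.zeros((len(rows), len(cats)), dtype=np.int64)
    ri = {r: i for i, r in enumerate(rows)}
    ci = {c: j for j, c in enumerate(cats)}
    for c in calls:
        counts[ri[c.cell_type], ci[c.category.value]] += 1
    return ContingencyTable(rows, cats, counts)


def collapse_table(table: ContingencyTable) -> ContingencyTable:
    """Collapse the four categories to two by pooling column pairs.

    Columns must be ordered [Spike, Excitatory, InhibitionOnly, NoResponse];
    the first two (any evoked excitation) and last two (no excitation) are
    summed.  The total count is conserved.
    """
    if table.counts.shape[1] != 4:
        raise ValueError("collapse expects a table with 4 category columns")
    if list(table.col_labels) != CATEGORY_ORDER:
        raise ValueError(f"columns must be ordered {CATEGORY_ORDER}")
    c = table.counts
    merged = np.stack([c[:, 0] + c[:, 1], c[:, 2] + c[:, 3]], axis=1)
    return ContingencyTable(
        list(table.row_labels), ["Spike+Excitatory", "InhibitionOnly+NoResponse"], merged
    )


# ---------------------------------------------------------------------------
# enumeration machinery


def _log_pmf_const(row_sums: np.ndarray, col_sums: np.ndarray) -> float:
    n = int(row_sums.sum())
    return float(gammaln(row_sums + 1).sum() + gammaln(col_sums + 1).sum() - gammaln(n + 1))


def _iter_row_fills(row_sum: int, col_rem: np.ndarray) -> Iterator[Tuple[int, ...]]:
    """All nonneg fills of one row summing to row_sum with per-column caps."""

    def rec(j: int, remaining: int, prefix: Tuple[int, ...]) -> Iterator[Tuple[int, ...]]:
        if j == len(col_rem) - 1:
            if remaining <= col_rem[j]:
                yield prefix + (remaining,)
            return
        tail_cap = int(col_rem[j + 1 :].sum())
        lo = max(0, remaining - tail_cap)
        hi = min(col_rem[j], remaining)
        for v in range(lo, hi + 1):
            yield from rec(j + 1, remaining - v, prefix + (v,))

    yield from rec(0, row_sum, ())


def _enumerate_log_pmfs(
    row_sums: np.ndarray, col_sums: np.ndarray, budget: int
) -> np.ndarray:
    """Log-probabilities of every margin-preserving table.

    Two-row tables are vectorized over the free cells of the first row; the
    general case recurses row by row (last row forced by the column margins).
    """
    r, c = len(row_sums), len(col_sums)
    const = _log_pmf_const(row_sums, col_sums)
    if r == 2:
        return const + _two_row_log_cellsums(row_sums, col_sums, budget)
    if c == 2:
        return const + _two_row_log_cellsums(col_sums, row_sums, budget)

    out: List[float] = []
    count = [0]

    def rec(i: int, col_rem: np.ndarray, acc: float) -> None:
        if i == r - 1:
            out.append(acc - float(gammaln(col_rem + 1).sum()))
            return
        for fill in _iter_row_fills(int(row_sums[i]), col_rem):
            count[0] += 1
            if count[0] > budget:
                raise EnumerationBudgetError(
                    f"enumeration exceeded budget of {budget} partial tables; "
                    "use exact_test_mc for tables this large"
                )
            f = np.array(fill, dtype=np.int64)
            rec(i + 1, col_rem - f, acc - float(gammaln(f + 1).sum()))

    rec(0, col_sums.copy(), const)
    return np.asarray(out)


def _two_row_log_cellsums(
    row_sums: np.ndarray, col_sums: np.ndarray, budget: int
) -> np.ndarray:
    """-sum_ij log(t_ij!) for every 2 x c table, vectorized.

    The first row's first c-1 cells are free (bounded by their column sums);
    everything else is forced by the margins.
    """
    c = len(col_sums)
    r1 = int(row_sums[0])
    free_axes = [np.arange(min(int(col_sums[j]), r1) + 1) for j in range(c - 1)]
    n_grid = int(np.prod([len(a) for a in free_axes]))
    if n_grid > budget:
        raise EnumerationBudgetError(
            f"enumeration grid of {n_grid} candidates exceeds budget {budget}; "
            "use exact_test_mc for tables this large"
        )
    grids = np.meshgrid(*free_axes, indexing="ij") if c > 1 else []
    if c == 1:
        return np.array([-float(gammaln(row_sums + 1).sum())])
    head = np.stack([g.ravel() for g in grids], axis=1)  # (m, c-1)
    last_top = r1 - head.sum(axis=1)
    ok = (last_top >= 0) & (last_top <= int(col_sums[-1]))
    head, last_top = head[ok], last_top[ok]
    top = np.concatenate([head, last_top[:, None]], axis=1)
    bottom = col_sums[None, :] - top
    # bottom >= 0 guaranteed: head capped by col sums, last col checked via margins
    ok2 = np.all(bottom >= 0, axis=1)
    top, bottom = top[ok2], bottom[ok2]
    return -(gammaln(top + 1).sum(axis=1) + gammaln(bottom + 1).sum(axis=1))


def exact_test(
    table: ContingencyTable | np.ndarray, budget: int = 5_000_000
) -> ExactTestResult:
    """Two-sided exact test by full margin-preserving enumeration.

    p = sum of probabilities of all tables as or less probable than the
    observed one.  For 2 x 2 tables this equals the conventional two-sided
    Fisher exact p-value.
    """
    counts = table.counts if isinstance(table, ContingencyTable) else np.asarray(table, dtype=np.int64)
    if np.any(counts < 0):
        raise ValueError("counts must be non-negative")
    row_sums = counts.sum(axis=1)
    col_sums = counts.sum(axis=0)
    if counts.sum() == 0:
        raise ValueError("table is empty")
    logp_all = _enumerate_log_pmfs(row_sums, col_sums, budget)
    logp_obs = _log_pmf_const(row_sums, col_sums) - float(gammaln(counts + 1).sum())
    tol = _LOG_TIE_TOL * max(1.0, abs(logp_obs))
    include = logp_all <= logp_obs + tol
    p = float(np.exp(logp_all[include]).sum())
    return ExactTestResult(
        p_value=min(p, 1.0),
        observed_probability=float(math.exp(logp_obs)),
        n_tables_enumerated=int(len(logp_all)),
        method="enumeration",
    )


def exact_test_mc(
    table: ContingencyTable | np.ndarray, n_draws: int = 100_000, seed=0
) -> ExactTestResult:
    """Monte Carlo exact test: sample margin-fixed tables (Patefield/Boyett
    via scipy) and estimate P(pmf(T) <= pmf(observed))."""
    if n_draws < 10_000:
        raise ValueError("n_draws must be >= 10^4 for a stable estimate")
    counts = table.counts if isinstance(table, ContingencyTable) else np.asarray(table, dtype=np.int64)
    row_sums = counts.sum(axis=1)
    col_sums = counts.sum(axis=0)
    if np.any(row_sums == 0) or np.any(col_sums == 0):
        raise ValueError("degenerate margins: every row and column needs a count")
    rng = np.random.default_rng(seed)
    dist = stats.random_table(row_sums, col_sums)
    draws = dist.rvs(n_draws, method="patefield", random_state=rng)
    const = _log_pmf_const(row_sums, col_sums)
    logp = const - gammaln(draws + 1).sum(axis=(1, 2))
    logp_obs = const - float(gammaln(counts + 1).sum())
    tol = _LOG_TIE_TOL * max(1.0, abs(logp_obs))
    hits = logp <= logp_obs + tol
    p_hat = float(hits.mean())
    se = float(np.sqrt(max(p_hat * (1 - p_hat), 1e-12) / n_draws))
    return ExactTestResult(
        p_value=max(p_hat, 1.0 / n_draws),
        observed_probability=float(math.exp(logp_obs)),
        n_tables_enumerated=int(n_draws),
        method="monte_carlo",
        mc_se=se,
    )
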