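"""Independent oracles used by the test suite.

The Fisher oracle enumerates margin-preserving tables directly, in exact
rational arithmetic (so probability ties are decided without tolerances),
and is deliberately separate from the package's log-space implementation.
"""

from __future__ import annotations

import itertools
from fractions import Fraction
from functools import lru_cache
from math import factorial
from typing import Dict, Iterator, Tuple

import numpy as np

Table = Tuple[Tuple[int, ...], ...]


def _iter_margin_tables(row_sums: Tuple[int, ...], col_sums: Tuple[int, ...]) -> Iterator[Table]:
    """All nonneg integer matrices with the given margins, cell by cell."""
    r, c = len(row_sums), len(col_sums)

    def rec(i, col_rem, rows):
        if i == r - 1:
            if all(v >= 0 for v in col_rem):
                yield rows + (tuple(col_rem),)
            return
        for fill in itertools.product(*(range(min(row_sums[i], cr) + 1) for cr in col_rem)):
            if sum(fill) != row_sums[i]:
                continue
            yield from rec(i + 1, tuple(cr - f for cr, f in zip(col_rem, fill)), rows + (fill,))

    yield from rec(0, col_sums, ())


def _table_probability(t: Table, row_sums, col_sums, n: int) -> Fraction:
    num = 1
    for s in row_sums:
        num *= factorial(s)
    for s in col_sums:
        num *= factorial(s)
    den = factorial(n)
    for row in t:
        for v in row:
            den *= factorial(v)
    return Fraction(num, den)


@lru_cache(maxsize=None)
def _class_probabilities(row_sums: Tuple[int, ...], col_sums: Tuple[int, ...]):
    n = sum(row_sums)
    tabs = list(_iter_margin_tables(row_sums, col_sums))
    probs = [_table_probability(t, row_sums, col_sums, n) for t in tabs]
    return tabs, probs


def fisher_p_bruteforce(counts) -> float:
    """Two-sided Fisher p by direct enumeration with exact rationals."""
    counts = np.asarray(counts, dtype=int)
    row_sums = tuple(int(x) for x in counts.sum(axis=1))
    col_sums = tuple(int(x) for x in counts.sum(axis=0))
    tabs, probs = _class_probabilities(row_sums, col_sums)
    obs = tuple(tuple(int(v) for v in row) for row in counts)
    p_obs = probs[tabs.index(obs)]
    return float(sum(p for p in probs if p <= p_obs))


def iter_all_tables(shape: Tuple[int, int], max_total: int) -> Iterator[np.ndarray]:
    """Every nonneg integer matrix of the given shape with sum <= max_total."""
    cells = shape[0] * shape[1]

    def rec(k, remaining, vals):
        if k == cells - 1:
            for v in range(remaining + 1):
                yield vals + (v,)
            return
        for v in range(remaining + 1):
            yield from rec(k + 1, remaining - v, vals + (v,))

    for flat in rec(0, max_total, ()):
        yield np.asarray(flat, dtype=int).reshape(shape)
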