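"""Independent brute-force oracles used by the unit and acceptance tests.

These deliberately avoid the package's own code paths: exact-rational
enumeration for the Freeman–Halton tail, complete split enumeration for
Mann–Whitney, and a pixel-walking run scanner for band detection.
"""

import itertools
import math
from fractions import Fraction

import numpy as np


def iter_tables(row_margins, col_margins):
    """Every nonnegative integer table with the given margins."""
    r = len(row_margins)

    def rows_for(total):
        for cells in itertools.product(
            *(range(min(total, m) + 1) for m in col_margins[:-1])
        ):
            last = total - sum(cells)
            if 0 <= last <= col_margins[-1]:
                yield cells + (last,)

    def rec(i, cols_left):
        if i == r - 1:
            if all(v >= 0 for v in cols_left):
                yield (tuple(cols_left),)
            return
        for row in rows_for(row_margins[i]):
            nxt = [cl - v for cl, v in zip(cols_left, row)]
            if any(v < 0 for v in nxt):
                continue
            for rest in rec(i + 1, nxt):
                yield (row,) + rest

    for t in rec(0, list(col_margins)):
        if all(sum(row) == m for row, m in zip(t, row_margins)):
            yield t


def exact_table_prob(table, row_margins, col_margins, n):
    num = Fraction(1)
    for m in row_margins:
        num *= math.factorial(m)
    for m in col_margins:
        num *= math.factorial(m)
    den = Fraction(math.factorial(n))
    for row in table:
        for v in row:
            den *= math.factorial(v)
    return num / den


def oracle_freeman_halton(table):
    """Freeman–Halton p by complete enumeration in exact rationals."""
    arr = np.asarray(table)
    rows = tuple(int(v) for v in arr.sum(axis=1))
    cols = tuple(int(v) for v in arr.sum(axis=0))
    n = int(arr.sum())
    p_obs = exact_table_prob(tuple(map(tuple, arr)), rows, cols, n)
    total = Fraction(0)
    for t in iter_tables(rows, cols):
        p = exact_table_prob(t, rows, cols, n)
        if p <= p_obs:
            total += p
    return float(total)


def oracle_mann_whitney(x, y):
    """Two-sided exact Mann–Whitney p over all group assignments."""
    x, y = list(x), list(y)
    pooled = x + y
    n1 = len(x)
    u_obs = sum(1 for xi in x for yj in y if xi > yj)
    us = []
    for idx in itertools.combinations(range(len(pooled)), n1):
        idx_set = set(idx)
        xs = [pooled[i] for i in idx]
        ys = [pooled[i] for i in range(len(pooled)) if i not in idx_set]
        us.append(sum(1 for xi in xs for yj in ys if xi > yj))
    us = np.array(us)
    p_le = (us <= u_obs).mean()
    p_ge = (us >= u_obs).mean()
    return min(1.0, 2 * min(p_le, p_ge))


def brute_force_runs(col, min_band_px=2, gap_bridge_px=1):
    """Pixel-walking run scan of one transect column."""
    runs = []
    start = None
    for i, v in enumerate(list(col) + [False]):
        if v and start is None:
            start = i
        elif not v and start is not None:
            if runs and start - runs[-1][1] <= gap_bridge_px:
                runs[-1] = (runs[-1][0], i)
            else:
                runs.append((start, i))
            start = None
    return [(s, e - s) for s, e in runs if e - s >= min_band_px]
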