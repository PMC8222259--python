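"""Nonparametric statistical battery.

Mann–Whitney, the Freeman–Halton exact test for r×c contingency tables
(sum of fixed-margin tables no more probable than the observed one, which
reduces to the classic two-sided 2×2 Fisher test), Kruskal–Wallis with
Dunn's Bonferroni-adjusted pairwise comparisons, tie-aware Spearman
correlation, and inter-rater agreement.

The Freeman–Halton enumeration is written here from first principles; the
rank tests delegate their distributional machinery to scipy but own the
exact-vs-approximate dispatch and the adjustment rules.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.special import gammaln

#: log-probability slack treated as a tie when accumulating the tail
FH_TIE_TOL = 1e-12
#: enumeration cap before the Monte Carlo fallback is suggested
FH_MAX_TABLES = 10_000_000
FH_MC_DRAWS = 1_000_000


@dataclass(frozen=True)
class ContingencyTable:
    """r×c nonnegative integer counts with optional axis labels."""

    counts: tuple[tuple[int, ...], ...]
    row_labels: tuple[str, ...] | None = None
    col_labels: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        arr = np.asarray(self.counts)
        if arr.ndim != 2 or arr.shape[0] < 2 or arr.shape[1] < 2:
            raise ValueError(f"need an r x c table with r,c >= 2, got {arr.shape}")
        if (arr < 0).any():
            raise ValueError("cells must be nonnegative")
        if not np.issubdtype(arr.dtype, np.integer):
            raise ValueError("cells must be integers")
        if arr.sum() < 1:
            raise ValueError("grand total must be >= 1")
        if self.row_labels is not None and len(self.row_labels) != arr.shape[0]:
            raise ValueError("row_labels length mismatch")
        if self.col_labels is not None and len(self.col_labels) != arr.shape[1]:
            raise ValueError("col_labels length mismatch")

    @classmethod
    def from_array(cls, arr, row_labels=None, col_labels=None) -> "ContingencyTable":
        a = np.asarray(arr, dtype=np.int64)
        return cls(
            counts=tuple(tuple(int(v) for v in row) for row in a),
            row_labels=tuple(row_labels) if row_labels is not None else None,
            col_labels=tuple(col_labels) if col_labels is not None else None,
        )

    def to_array(self) -> np.ndarray:
        return np.asarray(self.counts, dtype=np.int64)


@dataclass(frozen=True)
class TestResult:
    method: str
    statistic: float
    p_value: float
    group_sizes: tuple[int, ...] = ()
    adjustment: str = "none"
    exact: bool = True
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0) and not math.isnan(self.p_value):
            raise ValueError(f"p_value {self.p_value} outside [0, 1]")


@dataclass(frozen=True)
class CorrelationMatrix:
    variables: tuple[str, ...]
    rho: np.ndarray
    p: np.ndarray

    def __post_init__(self) -> None:
        k = len(self.variables)
        if self.rho.shape != (k, k) or self.p.shape != (k, k):
            raise ValueError("matrix shapes must match variable count")
        if not np.allclose(self.rho, self.rho.T, equal_nan=True):
            raise ValueError("rho must be symmetric")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.rho, index=self.variables, columns=self.variables)


def format_p(p: float) -> str:
    """4-decimal p-value string; '< 0.0001' below 0.00005."""
    if math.isnan(p):
        return "NA"
    if p < 0.00005:
        return "< 0.0001"
    return f"{p:.4f}"


# ---------------------------------------------------------------------------
# Mann-Whitney
# ---------------------------------------------------------------------------


def mann_whitney(x: Sequence[float], y: Sequence[float]) -> TestResult:
    """Two-sided Mann–Whitney U test.

    Uses the exact null distribution when ``n_x * n_y <= 400`` and the
    pooled sample has no ties; otherwise the tie-corrected normal
    approximation with continuity correction. The branch taken is recorded
    in ``exact``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be nonempty")
    pooled = np.concatenate([x, y])
    has_ties = np.unique(pooled).size < pooled.size
    exact = (x.size * y.size <= 400) and not has_ties
    res = sps.mannwhitneyu(
        x, y,
        alternative="two-sided",
        method="exact" if exact else "asymptotic",
        use_continuity=True,
    )
    return TestResult(
        method="mann-whitney",
        statistic=float(res.statistic),
        p_value=float(min(res.pvalue, 1.0)),
        group_sizes=(x.size, y.size),
        exact=exact,
    )


# ---------------------------------------------------------------------------
# Freeman-Halton / Fisher exact r x c
# ---------------------------------------------------------------------------


def _log_table_prob(cells: np.ndarray, lg_rows, lg_cols, lg_n) -> float:
    # multivariate hypergeometric with both margins fixed:
    # P = prod(r_i!) prod(c_j!) / (N! prod(n_ij!))
    return lg_rows + lg_cols - lg_n - gammaln(cells + 1).sum()


def _enumerate_tail(
    rows: np.ndarray, cols: np.ndarray, lp_obs: float, max_tables: int
) -> tuple[float, int]:
    """DFS over all fixed-margin tables, accumulating P of tables with
    log-probability <= lp_obs + tol. Returns (tail probability, n tables)."""
    r, c = len(rows), len(cols)
    lg_rows = gammaln(rows + 1).sum()
    lg_cols = gammaln(cols + 1).sum()
    lg_n = gammaln(rows.sum() + 1)
    tail = 0.0
    n_tables = 0

    def fill_row(i: int, remaining: np.ndarray, acc_lg: float) -> None:
        nonlocal tail, n_tables
        if i == r - 1:
            n_tables += 1
            if n_tables > max_tables:
                raise _EnumerationCapExceeded
            lp = lg_rows + lg_cols - lg_n - acc_lg - gammaln(remaining + 1).sum()
            if lp <= lp_obs + FH_TIE_TOL:
                tail += math.exp(lp)
            return
        target = rows[i]

        def fill_cell(j: int, left: int, used: list[int]) -> None:
            if j == c - 1:
                if left <= remaining[c - 1]:
                    cells = np.array(used + [left])
                    fill_row(i + 1, remaining - cells,
                             acc_lg + gammaln(cells + 1).sum())
                return
            for v in range(min(left, int(remaining[j])) + 1):
                fill_cell(j + 1, left - v, used + [v])

        fill_cell(0, int(target), [])

    fill_row(0, cols.copy(), 0.0)
    return tail, n_tables


class _EnumerationCapExceeded(Exception):
    pass


def _monte_carlo_tail(
    arr: np.ndarray, lp_obs: float, n_draws: int, seed: int
) -> float:
    """Estimate the tail by permuting category assignments (fixed margins)."""
    rows = arr.sum(axis=1)
    cols = arr.sum(axis=0)
    row_of = np.repeat(np.arange(len(rows)), rows)
    col_of = np.repeat(np.arange(len(cols)), cols)
    rng = np.random.default_rng(seed)
    lg_rows = gammaln(rows + 1).sum()
    lg_cols = gammaln(cols + 1).sum()
    lg_n = gammaln(rows.sum() + 1)
    hits = 0
    for _ in range(n_draws):
        perm = rng.permutation(col_of)
        t = np.zeros((len(rows), len(cols)), dtype=np.int64)
        np.add.at(t, (row_of, perm), 1)
        lp = lg_rows + lg_cols - lg_n - gammaln(t + 1).sum()
        if lp <= lp_obs + FH_TIE_TOL:
            hits += 1
    return hits / n_draws


def fisher_exact_rxc(
    table: ContingencyTable | np.ndarray,
    max_tables: int = FH_MAX_TABLES,
    monte_carlo: bool = False,
    mc_draws: int = FH_MC_DRAWS,
    seed: int = 0,
) -> TestResult:
    """Freeman–Halton exact test for an r×c contingency table.

    The two-sided p-value is the total null probability (multivariate
    hypergeometric, both margins fixed) of all tables whose probability
    does not exceed the observed table's, with a 1e−12 log-scale tie
    tolerance. For 2×2 tables this is the standard two-sided Fisher test
    under the sum-of-smaller-probabilities rule.

    Enumeration is capped at ``max_tables``; beyond it a seeded Monte
    Carlo estimate is used when ``monte_carlo=True``, otherwise an error
    suggests it.
    """
    if not isinstance(table, ContingencyTable):
        table = ContingencyTable.from_array(table)
    arr = table.to_array()
    rows = arr.sum(axis=1)
    cols = arr.sum(axis=0)
    if (rows == 0).any() or (cols == 0).any():
        raise ValueError("all row and column margins must be positive")

    lg_rows = gammaln(rows + 1).sum()
    lg_cols = gammaln(cols + 1).sum()
    lg_n = gammaln(arr.sum() + 1)
    lp_obs = _log_table_prob(arr, lg_rows, lg_cols, lg_n)

    try:
        tail, n_tables = _enumerate_tail(rows, cols, lp_obs, max_tables)
        return TestResult(
            method="fisher-freeman-halton",
            statistic=float(math.exp(lp_obs)),
            p_value=float(min(tail, 1.0)),
            group_sizes=tuple(int(v) for v in rows),
            exact=True,
            extra={"n_tables": n_tables},
        )
    except _EnumerationCapExceeded:
        if not monte_carlo:
            raise ValueError(
                f"more than {max_tables} fixed-margin tables; rerun with "
                "monte_carlo=True for a seeded estimate"
            ) from None
        p = _monte_carlo_tail(arr, lp_obs, mc_draws, seed)
        return TestResult(
            method="fisher-freeman-halton",
            statistic=float(math.exp(lp_obs)),
            p_value=float(min(p, 1.0)),
            group_sizes=tuple(int(v) for v in rows),
            exact=False,
            extra={"mc_draws": mc_draws, "seed": seed},
        )


# ---------------------------------------------------------------------------
# Kruskal-Wallis + Dunn
# ---------------------------------------------------------------------------


def kruskal_wallis_dunn(
    groups: Sequence[Sequence[float]],
) -> tuple[TestResult, list[TestResult]]:
    """Kruskal–Wallis omnibus test plus Dunn's pairwise comparisons.

    Dunn z-statistics use mean ranks from the pooled ranking with
    tie-corrected variance; two-sided pairwise p-values are multiplied by
    the number of comparisons (Bonferroni) and capped at 1.
    """
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if any(a.size == 0 for a in arrays):
        raise ValueError("all groups must be nonempty")
    sizes = [a.size for a in arrays]
    pooled = np.concatenate(arrays)
    n = pooled.size

    if np.unique(pooled).size == 1:
        omnibus = TestResult(
            "kruskal-wallis", 0.0, 1.0, tuple(sizes), exact=False
        )
    else:
        h, p = sps.kruskal(*arrays)
        omnibus = TestResult(
            "kruskal-wallis", float(h), float(p), tuple(sizes), exact=False
        )

    ranks = sps.rankdata(pooled)
    bounds = np.cumsum([0] + sizes)
    mean_ranks = [
        ranks[bounds[i] : bounds[i + 1]].mean() for i in range(len(arrays))
    ]
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = ((tie_counts**3 - tie_counts).sum()) / (12.0 * (n - 1)) if n > 1 else 0.0
    base_var = n * (n + 1) / 12.0 - tie_term

    k = len(arrays)
    m = k * (k - 1) // 2
    pairwise = []
    for i in range(k):
        for j in range(i + 1, k):
            se = math.sqrt(base_var * (1.0 / sizes[i] + 1.0 / sizes[j]))
            z = (mean_ranks[i] - mean_ranks[j]) / se if se > 0 else 0.0
            p_raw = 2.0 * sps.norm.sf(abs(z))
            pairwise.append(
                TestResult(
                    method="dunn",
                    statistic=float(z),
                    p_value=float(min(p_raw * m, 1.0)),
                    group_sizes=(sizes[i], sizes[j]),
                    adjustment="dunn-bonferroni",
                    exact=False,
                    extra={"pair": (i, j), "p_unadjusted": float(p_raw)},
                )
            )
    return omnibus, pairwise


# ---------------------------------------------------------------------------
# Spearman
# ---------------------------------------------------------------------------


def spearman(x: Sequence[float], y: Sequence[float]) -> TestResult:
    """Tie-aware Spearman correlation (Pearson on mid-ranks), two-sided p.

    Zero variance in either variable leaves ρ undefined (NaN, flagged in
    ``extra``).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y must be paired")
    if x.size < 3:
        raise ValueError("need at least 3 paired observations")
    if np.unique(x).size == 1 or np.unique(y).size == 1:
        return TestResult(
            method="spearman", statistic=float("nan"), p_value=float("nan"),
            group_sizes=(x.size,), exact=False, extra={"undefined": True},
        )
    rho, p = sps.spearmanr(x, y)
    return TestResult(
        method="spearman", statistic=float(rho), p_value=float(p),
        group_sizes=(x.size,), exact=False,
    )


def correlation_matrix(
    data: pd.DataFrame | dict[str, Sequence[float]],
) -> CorrelationMatrix:
    """Pairwise Spearman ρ and p over all variable pairs (pairwise-complete)."""
    df = pd.DataFrame(data)
    names = tuple(df.columns)
    k = len(names)
    rho = np.eye(k)
    p = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            sub = df.iloc[:, [i, j]].dropna()
            if len(sub) < 3:
                r_ij = p_ij = float("nan")
            else:
                res = spearman(sub.iloc[:, 0], sub.iloc[:, 1])
                r_ij, p_ij = res.statistic, res.p_value
            rho[i, j] = rho[j, i] = r_ij
            p[i, j] = p[j, i] = p_ij
    return CorrelationMatrix(variables=names, rho=rho, p=p)


def interrater_agreement(scores) -> pd.DataFrame:
    """Pairwise Spearman ρ between raters of an ordinal score matrix.

    ``scores`` is subjects × raters (DataFrame or array). Returns a long
    table with columns rater_a, rater_b, rho, p_value, defined. A rater
    with constant scores yields an undefined (NaN, flagged) ρ for its
    pairs.
    """
    df = pd.DataFrame(scores)
    if df.shape[1] < 2:
        raise ValueError("need at least 2 raters")
    if df.shape[0] < 3:
        raise ValueError("need at least 3 subjects")
    out = []
    cols = list(df.columns)
    for i in range(len(cols)):
        for j in range(i + 1, len(cols)):
            res = spearman(df[cols[i]], df[cols[j]])
            out.append(
                {
                    "rater_a": str(cols[i]),
                    "rater_b": str(cols[j]),
                    "rho": res.statistic,
                    "p_value": res.p_value,
                    "defined": not res.extra.get("undefined", False),
                }
            )
    return pd.DataFrame(out)
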