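"""The trial's statistical battery.

Two families live here. Raw-data tests (Kruskal–Wallis, Dunn's posttest,
Mann–Whitney U, Tukey HSD, exact contingency tests) operate on value lists.
Summary-statistics tests (one-way ANOVA, two-sample t) operate on published
(n, mean, sd) triples, so p-values printed in a trial report can be
recomputed without the raw data.

All p-values are two-sided and no multiplicity adjustment is applied unless
requested (Bonferroni is available for Dunn's posttest).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats as sps

__all__ = [
    "GroupSummary",
    "ContingencyTable",
    "anova_oneway_summary",
    "t_test_summary",
    "kruskal_wallis",
    "dunn_posttest",
    "mann_whitney_u",
    "fisher_exact",
    "tukey_hsd",
]


@dataclass(frozen=True)
class GroupSummary:
    """Published per-arm summary: subject count, outcome mean and SD."""

    label: str
    n: int
    mean: float
    sd: float

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError(f"group {self.label!r}: n must be >= 2, got {self.n}")
        if self.sd < 0:
            raise ValueError(f"group {self.label!r}: sd must be >= 0")

    @classmethod
    def from_values(cls, label: str, values: Sequence[float]) -> "GroupSummary":
        arr = np.asarray(values, dtype=float)
        return cls(label, len(arr), float(arr.mean()), float(arr.std(ddof=1)))


@dataclass(frozen=True)
class ContingencyTable:
    """Non-negative integer R x C counts with row/column labels."""

    row_labels: tuple[str, ...]
    col_labels: tuple[str, ...]
    cells: tuple[tuple[int, ...], ...]

    def __post_init__(self) -> None:
        arr = np.asarray(self.cells)
        if arr.ndim != 2 or arr.shape[0] < 2 or arr.shape[1] < 2:
            raise ValueError("contingency table must be at least 2x2")
        if (arr < 0).any():
            raise ValueError("contingency table cells must be non-negative")
        if arr.shape != (len(self.row_labels), len(self.col_labels)):
            raise ValueError("label lengths do not match table shape")

    @classmethod
    def from_array(cls, cells, row_labels=None, col_labels=None) -> "ContingencyTable":
        arr = np.asarray(cells, dtype=int)
        rl = tuple(row_labels) if row_labels else tuple(f"r{i}" for i in range(arr.shape[0]))
        cl = tuple(col_labels) if col_labels else tuple(f"c{j}" for j in range(arr.shape[1]))
        return cls(rl, cl, tuple(tuple(int(x) for x in row) for row in arr))

    def as_array(self) -> np.ndarray:
        return np.asarray(self.cells, dtype=int)


def anova_oneway_summary(groups: Sequence[GroupSummary]) -> tuple[float, float]:
    """One-way fixed-effects ANOVA reconstructed from (n, mean, sd).

    Between-group and within-group sums of squares are exact functions of
    the summaries: SSB = sum n_i (m_i - m)^2, SSW = sum (n_i - 1) sd_i^2.
    Returns (F, two-sided p from the F distribution).
    """
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    ns = np.array([g.n for g in groups], dtype=float)
    means = np.array([g.mean for g in groups], dtype=float)
    sds = np.array([g.sd for g in groups], dtype=float)
    total_n = ns.sum()
    grand = float((ns * means).sum() / total_n)
    ssb = float((ns * (means - grand) ** 2).sum())
    ssw = float(((ns - 1) * sds**2).sum())
    df_b = len(groups) - 1
    df_w = int(total_n) - len(groups)
    if ssw == 0:
        if ssb == 0:
            return 0.0, 1.0
        return math.inf, 0.0
    f = (ssb / df_b) / (ssw / df_w)
    return f, float(sps.f.sf(f, df_b, df_w))


def t_test_summary(a: GroupSummary, b: GroupSummary,
                   variant: str = "pooled") -> tuple[float, float]:
    """Two-sample t-test from summary statistics.

    ``pooled`` uses the pooled variance with df = n1 + n2 - 2 (the classical
    equal-variance test); ``welch`` uses Satterthwaite df. Two groups with
    zero variance and equal means return (0, 1).
    """
    if variant not in ("pooled", "welch"):
        raise ValueError(f"unknown variant {variant!r}")
    if a.sd == 0 and b.sd == 0:
        if a.mean == b.mean:
            return 0.0, 1.0
        return math.inf if a.mean > b.mean else -math.inf, 0.0
    if variant == "pooled":
        df = a.n + b.n - 2
        sp2 = ((a.n - 1) * a.sd**2 + (b.n - 1) * b.sd**2) / df
        se = math.sqrt(sp2 * (1 / a.n + 1 / b.n))
    else:
        va, vb = a.sd**2 / a.n, b.sd**2 / b.n
        se = math.sqrt(va + vb)
        df = (va + vb) ** 2 / (va**2 / (a.n - 1) + vb**2 / (b.n - 1))
    t = (a.mean - b.mean) / se
    return t, float(2 * sps.t.sf(abs(t), df))


def kruskal_wallis(groups: Sequence[Sequence[float]],
                   exact_max_n: int = 0) -> tuple[float, float]:
    """Tie-corrected Kruskal–Wallis H with a chi-square p (k-1 df).

    When the total sample size is at most ``exact_max_n`` (and at most 10),
    the p-value is instead computed exactly by enumerating every assignment
    of the pooled observations to groups.
    """
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    if any(len(g) == 0 for g in groups):
        raise ValueError("empty group")
    total_n = sum(len(g) for g in groups)
    if total_n < 3:
        raise ValueError("need at least three observations in total")
    h, p = sps.kruskal(*[np.asarray(g, dtype=float) for g in groups])
    if math.isnan(h):  # all values identical -> zero rank variance
        return 0.0, 1.0
    if 0 < exact_max_n and total_n <= min(exact_max_n, 10):
        p = _kw_exact_p(groups, float(h))
    return float(h), float(p)


def _kw_statistic(values: np.ndarray, sizes: Sequence[int]) -> float:
    ranks = sps.rankdata(values)
    n = len(values)
    start, h = 0, 0.0
    for m in sizes:
        r = ranks[start:start + m]
        h += r.sum() ** 2 / m
        start += m
    h = 12 / (n * (n + 1)) * h - 3 * (n + 1)
    _, tie_counts = np.unique(values, return_counts=True)
    correction = 1 - (tie_counts**3 - tie_counts).sum() / (n**3 - n)
    return h / correction if correction > 0 else 0.0


def _kw_exact_p(groups: Sequence[Sequence[float]], h_obs: float) -> float:
    pooled = np.concatenate([np.asarray(g, dtype=float) for g in groups])
    sizes = [len(g) for g in groups]
    n = len(pooled)
    count = total = 0
    idx = list(range(n))
    for perm in _group_assignments(idx, sizes):
        vals = pooled[perm]
        if _kw_statistic(vals, sizes) >= h_obs - 1e-12:
            count += 1
        total += 1
    return count / total


def _group_assignments(idx: list[int], sizes: Sequence[int]):
    """Yield index orderings distinct up to within-group permutation."""
    if len(sizes) == 1:
        yield list(idx)
        return
    first, rest = sizes[0], sizes[1:]
    for combo in itertools.combinations(range(len(idx)), first):
        chosen = [idx[i] for i in combo]
        remaining = [idx[i] for i in range(len(idx)) if i not in set(combo)]
        for tail in _group_assignments(remaining, rest):
            yield chosen + tail


def dunn_posttest(groups: Sequence[Sequence[float]],
                  labels: Sequence[str] | None = None,
                  adjust: str = "none") -> dict[tuple[str, str], tuple[float, float]]:
    """Dunn's pairwise rank comparisons after a Kruskal–Wallis omnibus test.

    z for a pair (i, j) is the difference of mean pooled ranks scaled by the
    tie-corrected pooled rank variance:

        z = (R_i - R_j) / sqrt((N(N+1)/12 - T/(12(N-1))) (1/n_i + 1/n_j))

    with T = sum over tie groups of (t^3 - t). Returns a map from label pair
    to (z, two-sided p). ``adjust='bonferroni'`` multiplies p by the number
    of pairs (the default is no adjustment).
    """
    if len(groups) < 3:
        raise ValueError("Dunn's posttest needs at least three groups")
    if adjust not in ("none", "bonferroni"):
        raise ValueError(f"unknown adjustment {adjust!r}")
    if labels is None:
        labels = [f"group{i}" for i in range(len(groups))]
    arrays = [np.asarray(g, dtype=float) for g in groups]
    pooled = np.concatenate(arrays)
    n = len(pooled)
    ranks = sps.rankdata(pooled)
    mean_ranks, start = [], 0
    for arr in arrays:
        mean_ranks.append(ranks[start:start + len(arr)].mean())
        start += len(arr)
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float((tie_counts**3 - tie_counts).sum())
    var_base = n * (n + 1) / 12 - tie_term / (12 * (n - 1))
    n_pairs = len(groups) * (len(groups) - 1) // 2
    out: dict[tuple[str, str], tuple[float, float]] = {}
    for i, j in itertools.combinations(range(len(groups)), 2):
        se = math.sqrt(var_base * (1 / len(arrays[i]) + 1 / len(arrays[j])))
        z = (mean_ranks[i] - mean_ranks[j]) / se if se > 0 else 0.0
        p = 2 * sps.norm.sf(abs(z))
        if adjust == "bonferroni":
            p = min(1.0, p * n_pairs)
        out[(labels[i], labels[j])] = (float(z), float(p))
    return out


def mann_whitney_u(a: Sequence[float], b: Sequence[float]) -> tuple[float, float]:
    """Two-sided Mann–Whitney U.

    Exact p when the smaller group has at most 8 observations and there are
    no ties; otherwise the normal approximation with tie correction.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups must be non-empty")
    has_ties = len(np.unique(np.concatenate([a, b]))) < len(a) + len(b)
    method = "exact" if (min(len(a), len(b)) <= 8 and not has_ties) else "asymptotic"
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def fisher_exact(table: ContingencyTable | Sequence[Sequence[int]],
                 max_tables: int = 2_000_000,
                 monte_carlo: int | None = None,
                 seed: int | None = None) -> float:
    """Exact test of independence for an R x C contingency table.

    2x2 tables use the standard two-sided hypergeometric test (the sum of
    the probabilities of all tables, under fixed margins, no more probable
    than the observed one). Larger tables use the Freeman–Halton
    generalization: full enumeration over tables with the observed margins.

    If the enumeration would exceed ``max_tables`` candidate tables and
    ``monte_carlo`` is given, a seeded Monte-Carlo estimate over that many
    random tables (Patefield sampling) is returned instead; without
    ``monte_carlo`` such tables raise.
    """
    if not isinstance(table, ContingencyTable):
        table = ContingencyTable.from_array(table)
    arr = table.as_array()
    if arr.shape == (2, 2):
        return float(sps.fisher_exact(arr, alternative="two-sided")[1])
    return _freeman_halton(arr, max_tables, monte_carlo, seed)


def _log_table_prob(arr: np.ndarray, lg_const: float) -> float:
    return lg_const - sum(math.lgamma(x + 1) for x in arr.flat)


def _freeman_halton(arr: np.ndarray, max_tables: int,
                    monte_carlo: int | None, seed: int | None) -> float:
    rows = arr.sum(axis=1)
    cols = arr.sum(axis=0)
    n = int(arr.sum())
    if n == 0:
        return 1.0
    lg_const = (sum(math.lgamma(r + 1) for r in rows)
                + sum(math.lgamma(c + 1) for c in cols)
                - math.lgamma(n + 1))
    log_p_obs = _log_table_prob(arr, lg_const)
    bound = 1
    for c in cols:
        bound *= (min(c, rows.max()) + 1) ** (len(rows) - 1)
        if bound > max_tables:
            break
    if bound > max_tables:
        if monte_carlo is None:
            raise ValueError(
                "margins too large for exhaustive enumeration; pass "
                "monte_carlo=<n draws> (and a seed) for a randomized estimate"
            )
        return _freeman_halton_mc(arr, lg_const, log_p_obs, monte_carlo, seed)
    total = 0.0
    eps = 1e-10
    for cand in _tables_with_margins(list(rows), list(cols)):
        lp = _log_table_prob(cand, lg_const)
        if lp <= log_p_obs + eps:
            total += math.exp(lp)
    return min(1.0, total)


def _tables_with_margins(rows: list[int], cols: list[int]):
    """Yield every non-negative integer matrix with the given margins."""
    ncol = len(cols)

    def fill_row(remaining_rows: list[int], remaining_cols: list[int],
                 built: list[list[int]]):
        if len(remaining_rows) == 1:
            last = remaining_cols
            if all(x >= 0 for x in last):
                yield np.array(built + [last], dtype=int)
            return
        r = remaining_rows[0]

        def fill_cells(j: int, rem: int, row: list[int]):
            if j == ncol - 1:
                if 0 <= rem <= remaining_cols[j]:
                    yield row + [rem]
                return
            for v in range(min(rem, remaining_cols[j]) + 1):
                yield from fill_cells(j + 1, rem - v, row + [v])

        for row in fill_cells(0, r, []):
            new_cols = [remaining_cols[j] - row[j] for j in range(ncol)]
            yield from fill_row(remaining_rows[1:], new_cols, built + [row])

    yield from fill_row(rows, cols, [])


def _freeman_halton_mc(arr: np.ndarray, lg_const: float, log_p_obs: float,
                       n_draws: int, seed: int | None) -> float:
    rng = np.random.default_rng(seed)
    rows = arr.sum(axis=1)
    cols = arr.sum(axis=0)
    hits = 0
    eps = 1e-10
    for _ in range(n_draws):
        cand = _random_table(rows, cols, rng)
        if _log_table_prob(cand, lg_const) <= log_p_obs + eps:
            hits += 1
    return hits / n_draws


def _random_table(rows: np.ndarray, cols: np.ndarray,
                  rng: np.random.Generator) -> np.ndarray:
    """Draw a table with fixed margins from the hypergeometric null."""
    out = np.zeros((len(rows), len(cols)), dtype=int)
    col_rem = cols.copy()
    for i, r in enumerate(rows[:-1]):
        left = int(r)
        rem_total = int(col_rem.sum())
        for j in range(len(cols) - 1):
            draw = rng.hypergeometric(int(col_rem[j]), rem_total - int(col_rem[j]), left) \
                if left > 0 and col_rem[j] > 0 else 0
            out[i, j] = draw
            left -= draw
            rem_total -= int(col_rem[j])
        out[i, -1] = left
        col_rem = col_rem - out[i]
    out[-1] = col_rem
    return out


def tukey_hsd(groups: Sequence[Sequence[float]],
              labels: Sequence[str] | None = None
              ) -> dict[tuple[str, str], float]:
    """Tukey's honestly-significant-difference adjusted pairwise p-values."""
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    if any(len(g) < 2 for g in groups):
        raise ValueError("every group needs at least two observations")
    if labels is None:
        labels = [f"group{i}" for i in range(len(groups))]
    res = sps.tukey_hsd(*[np.asarray(g, dtype=float) for g in groups])
    out: dict[tuple[str, str], float] = {}
    for i, j in itertools.combinations(range(len(groups)), 2):
        out[(labels[i], labels[j])] = float(res.pvalue[i, j])
    return out
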