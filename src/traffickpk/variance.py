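"""Factorial ANOVA with variance partitioning and post-tests.

The central inferential tool here is the 2x2 Cells-by-Mouse design: labeled
lymphocytes from two sources (strains or treatments) are injected into hosts
of two kinds, and a two-way ANOVA on the uptake measure attributes the
variation to the cell source (Cells), the recipient (Mouse), and their
interaction.  Each effect's importance is summarized as its percentage of
the total sum of squares (eta-squared), so the shares of Cells, Mouse,
interaction and residual sum to 100% in a balanced design.

Sums of squares are computed as error-sum-of-squares differences between
nested least-squares fits on sum-to-zero (effect-coded) design matrices.
For unbalanced data the default is Type III (each effect adjusted for all
others including the interaction, under the sigma-restricted coding);
Types I and II are available and recorded in output.  For balanced designs
all three types coincide.

Post-tests:

* Newman-Keuls — a step-down studentized-range procedure over the ordered
  group means of a one-way layout; the critical value shrinks with the span
  of ordered means, and testing stops inside any span whose extreme pair is
  non-significant, so no significant pair can be nested inside a
  non-significant span.
* Bonferroni-by-time — for two-group time courses: a pooled-residual t test
  at each time, with the p-value multiplied by the number of time points
  (capped at 1).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "FactorialDataset",
    "AnovaRow",
    "AnovaTable",
    "PostTestResult",
    "two_way_anova",
    "one_way_anova",
    "pct_variance",
    "newman_keuls",
    "bonferroni_by_time",
]

_ZERO_RTOL = 1e-12


@dataclass(frozen=True)
class FactorialDataset:
    """Observations of a crossed two-factor (optionally x time) design."""

    response: np.ndarray
    factor_cells: np.ndarray
    factor_mouse: np.ndarray
    time: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        y = np.asarray(self.response, dtype=float)
        a = np.asarray(self.factor_cells)
        b = np.asarray(self.factor_mouse)
        object.__setattr__(self, "response", y)
        object.__setattr__(self, "factor_cells", a)
        object.__setattr__(self, "factor_mouse", b)
        if self.time is not None:
            object.__setattr__(self, "time", np.asarray(self.time, dtype=float))
        if not (len(y) == len(a) == len(b)):
            raise ValueError("response and factor arrays must have equal length")

    def dropna(self) -> "FactorialDataset":
        """Drop observations with missing responses (listwise), logging the count."""
        keep = np.isfinite(self.response)
        n_drop = int((~keep).sum())
        if n_drop:
            logger.warning("dropping %d observation(s) with missing response", n_drop)
        return FactorialDataset(
            self.response[keep],
            self.factor_cells[keep],
            self.factor_mouse[keep],
            None if self.time is None else self.time[keep],
        )


@dataclass(frozen=True)
class AnovaRow:
    effect: str
    ss: float
    df: int
    ms: float
    F: float
    p_value: float
    pct_variance: float

    def to_dict(self) -> dict:
        return {
            "effect": self.effect,
            "ss": self.ss,
            "df": self.df,
            "ms": self.ms,
            "F": self.F,
            "p_value": self.p_value,
            "pct_variance": self.pct_variance,
        }


@dataclass(frozen=True)
class AnovaTable:
    """Effect-wise decomposition with F tests and % variance (eta-squared)."""

    rows: Tuple[AnovaRow, ...]
    ss_type: Optional[int] = None
    degenerate: bool = False  # total SS is zero (all responses identical)

    def __getitem__(self, effect: str) -> AnovaRow:
        for row in self.rows:
            if row.effect == effect:
                return row
        raise KeyError(effect)

    @property
    def effects(self) -> List[str]:
        return [r.effect for r in self.rows]

    @property
    def residual_ms(self) -> float:
        return self["Residual"].ms

    @property
    def residual_df(self) -> int:
        return self["Residual"].df

    @property
    def total_ss(self) -> float:
        return self["Total"].ss

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame([r.to_dict() for r in self.rows])

    def to_dict(self) -> dict:
        return {
            "rows": [r.to_dict() for r in self.rows],
            "ss_type": self.ss_type,
            "degenerate": self.degenerate,
        }


@dataclass(frozen=True)
class PostTestResult:
    """One pairwise (or per-time) comparison from a post-test."""

    comparison: Tuple[str, str]
    statistic: float
    significant: bool
    alpha: float
    critical_value: Optional[float] = None
    adjusted_p: Optional[float] = None
    time: Optional[float] = None
    span: Optional[int] = None  # Newman-Keuls: number of ordered means spanned

    def to_dict(self) -> dict:
        return {
            "comparison": list(self.comparison),
            "statistic": self.statistic,
            "significant": self.significant,
            "alpha": self.alpha,
            "critical_value": self.critical_value,
            "adjusted_p": self.adjusted_p,
            "time": self.time,
            "span": self.span,
        }


# ---------------------------------------------------------------------------
# Design matrices and sums of squares
# ---------------------------------------------------------------------------


def _sum_code(factor: np.ndarray) -> Tuple[np.ndarray, List]:
    """Sum-to-zero (effect) coding: k-1 columns, last level coded -1."""
    levels = sorted(set(factor.tolist()))
    k = len(levels)
    if k < 2:
        raise ValueError(f"factor needs >= 2 levels, got {levels}")
    index = {lv: i for i, lv in enumerate(levels)}
    X = np.zeros((len(factor), k - 1))
    for row, value in enumerate(factor):
        i = index[value]
        if i < k - 1:
            X[row, i] = 1.0
        else:
            X[row, :] = -1.0
    return X, levels


def _interaction(Xa: np.ndarray, Xb: np.ndarray) -> np.ndarray:
    cols = [Xa[:, i] * Xb[:, j] for i in range(Xa.shape[1]) for j in range(Xb.shape[1])]
    return np.column_stack(cols)


def _sse(y: np.ndarray, *blocks: np.ndarray) -> float:
    X = np.column_stack([np.ones(len(y))] + [b for b in blocks if b.size])
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    return float(resid @ resid)


def _f_and_p(ss: float, df: int, ms_res: float, df_res: int, scale: float) -> Tuple[float, float, float]:
    """Mean square, F and p for one effect; F is NaN when residual MS is ~0."""
    ms = ss / df if df > 0 else math.nan
    tiny = _ZERO_RTOL * max(scale, 1.0)
    if df_res <= 0 or not np.isfinite(ms_res) or ms_res <= tiny:
        if df > 0 and ss > tiny:
            return ms, math.inf, 0.0
        return ms, math.nan, math.nan
    F = ms / ms_res
    p = float(stats.f.sf(F, df, df_res))
    return ms, F, p


def two_way_anova(
    data: FactorialDataset,
    ss_type: int = 3,
    effect_names: Tuple[str, str] = ("Cells", "Mouse"),
) -> AnovaTable:
    """Two-way crossed ANOVA with interaction and % variance per effect.

    Parameters
    ----------
    data
        The factorial observations; missing responses are dropped listwise.
    ss_type
        1 (sequential), 2 (each main effect adjusted for the other), or
        3 (each effect adjusted for all others; sum-to-zero coding), the
        default.  Immaterial for balanced designs.
    effect_names
        Labels for the two factors in the output table.
    """
    data = data.dropna()
    y = data.response
    a, b = data.factor_cells, data.factor_mouse
    if ss_type not in (1, 2, 3):
        raise ValueError("ss_type must be 1, 2 or 3")
    Xa, levels_a = _sum_code(a)
    Xb, levels_b = _sum_code(b)
    name_a, name_b = effect_names

    # the full model with interaction needs every design cell populated
    for la in levels_a:
        for lb in levels_b:
            if not np.any((a == la) & (b == lb)):
                raise ValueError(
                    f"empty design cell: {name_a}={la!r}, {name_b}={lb!r}"
                )

    Xab = _interaction(Xa, Xb)
    n = len(y)
    ss_total = float(np.sum((y - y.mean()) ** 2))
    sse_full = _sse(y, Xa, Xb, Xab)

    if ss_type == 3:
        ss_a = _sse(y, Xb, Xab) - sse_full
        ss_b = _sse(y, Xa, Xab) - sse_full
        ss_ab = _sse(y, Xa, Xb) - sse_full
    elif ss_type == 2:
        sse_ab_main = _sse(y, Xa, Xb)
        ss_a = _sse(y, Xb) - sse_ab_main
        ss_b = _sse(y, Xa) - sse_ab_main
        ss_ab = sse_ab_main - sse_full
    else:  # Type I, order: A, B, AB
        sse_0 = ss_total
        sse_a_only = _sse(y, Xa)
        sse_ab_main = _sse(y, Xa, Xb)
        ss_a = sse_0 - sse_a_only
        ss_b = sse_a_only - sse_ab_main
        ss_ab = sse_ab_main - sse_full

    ss_a, ss_b, ss_ab = (max(0.0, s) for s in (ss_a, ss_b, ss_ab))
    sse_full = max(0.0, sse_full)

    df_a = len(levels_a) - 1
    df_b = len(levels_b) - 1
    df_ab = df_a * df_b
    df_res = n - len(levels_a) * len(levels_b)
    ms_res = sse_full / df_res if df_res > 0 else math.nan

    degenerate = bool(ss_total <= _ZERO_RTOL * max(abs(y).max(initial=0.0), 1.0) ** 2 * n)

    def share(ss: float) -> float:
        if degenerate or ss_total == 0:
            return 0.0
        return 100.0 * ss / ss_total

    rows = []
    for effect, ss, df in (
        (name_a, ss_a, df_a),
        (name_b, ss_b, df_b),
        ("Interaction", ss_ab, df_ab),
    ):
        ms, F, p = _f_and_p(ss, df, ms_res, df_res, ss_total)
        if degenerate:
            F, p = math.nan, math.nan
        rows.append(AnovaRow(effect, ss, df, ms, F, p, share(ss)))
    rows.append(
        AnovaRow("Residual", sse_full, df_res, ms_res, math.nan, math.nan, share(sse_full))
    )
    rows.append(AnovaRow("Total", ss_total, n - 1, math.nan, math.nan, math.nan, 100.0 if not degenerate else 0.0))
    return AnovaTable(tuple(rows), ss_type=ss_type, degenerate=degenerate)


def one_way_anova(groups: Sequence[Sequence[float]]) -> AnovaTable:
    """One-way between/within decomposition over a list of groups."""
    if len(groups) < 2:
        raise ValueError("need >= 2 groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    arrays = [g[np.isfinite(g)] for g in arrays]
    if any(len(g) == 0 for g in arrays):
        raise ValueError("every group needs >= 1 observation")
    n = sum(len(g) for g in arrays)
    k = len(arrays)
    df_res = n - k
    if df_res < 1:
        raise ValueError("no residual degrees of freedom (all groups of size 1)")
    y = np.concatenate(arrays)
    grand = y.mean()
    ss_total = float(np.sum((y - grand) ** 2))
    ss_between = float(sum(len(g) * (g.mean() - grand) ** 2 for g in arrays))
    ss_within = float(sum(np.sum((g - g.mean()) ** 2) for g in arrays))
    ms_res = ss_within / df_res
    degenerate = bool(ss_total <= _ZERO_RTOL * max(abs(y).max(initial=0.0), 1.0) ** 2 * n)
    ms, F, p = _f_and_p(ss_between, k - 1, ms_res, df_res, ss_total)
    if degenerate:
        F, p = math.nan, math.nan

    def share(ss: float) -> float:
        return 0.0 if (degenerate or ss_total == 0) else 100.0 * ss / ss_total

    rows = (
        AnovaRow("Group", ss_between, k - 1, ms, F, p, share(ss_between)),
        AnovaRow("Residual", ss_within, df_res, ms_res, math.nan, math.nan, share(ss_within)),
        AnovaRow("Total", ss_total, n - 1, math.nan, math.nan, math.nan, 100.0 if not degenerate else 0.0),
    )
    return AnovaTable(rows, ss_type=None, degenerate=degenerate)


def pct_variance(table: AnovaTable) -> Dict[str, float]:
    """Percent of total variance (eta-squared) per effect, residual included.

    In a degenerate table (zero total SS) every share is 0.
    """
    return {row.effect: row.pct_variance for row in table.rows if row.effect != "Total"}


# ---------------------------------------------------------------------------
# Post-tests
# ---------------------------------------------------------------------------


@lru_cache(maxsize=512)
def _q_critical(alpha: float, n_means: int, df: int) -> float:
    """Upper-alpha studentized-range quantile, computed numerically."""
    return float(stats.studentized_range.ppf(1.0 - alpha, n_means, df))


def newman_keuls(
    groups: Sequence[Sequence[float]],
    alpha: float = 0.05,
    labels: Optional[Sequence[str]] = None,
) -> List[PostTestResult]:
    """Newman-Keuls step-down studentized-range test over group means.

    Means are ordered; a pair spanning ``r`` ordered means is tested with
    q = |m_i - m_j| / sqrt(MS_res/2 * (1/n_i + 1/n_j)) against the
    studentized-range critical value at (r, df_res).  When a span's extreme
    pair is non-significant, every pair nested inside it is declared
    non-significant without testing, which keeps the decisions coherent.
    Unequal group sizes use the averaged 1/n form above.
    """
    k = len(groups)
    if k < 2:
        raise ValueError("need >= 2 groups")
    if labels is None:
        labels = [f"group{i}" for i in range(k)]
    table = one_way_anova(groups)
    ms_res = table.residual_ms
    df_res = table.residual_df
    arrays = [np.asarray(g, dtype=float) for g in groups]
    means = np.array([g.mean() for g in arrays])
    ns = np.array([len(g) for g in arrays])
    order = np.argsort(means, kind="stable")

    results: List[PostTestResult] = []
    nonsig_spans: List[Tuple[int, int]] = []  # inclusive ordered-index spans
    for r in range(k, 1, -1):
        crit = _q_critical(alpha, r, df_res)
        for i in range(0, k - r + 1):
            j = i + r - 1
            gi, gj = order[i], order[j]
            diff = abs(means[gj] - means[gi])
            se = math.sqrt(ms_res / 2.0 * (1.0 / ns[gi] + 1.0 / ns[gj]))
            if se == 0.0:
                q = math.inf if diff > 0 else 0.0
            else:
                q = diff / se
            blocked = any(lo <= i and j <= hi for lo, hi in nonsig_spans)
            if blocked:
                significant = False
            else:
                significant = bool(q > crit)
                if not significant:
                    nonsig_spans.append((i, j))
            results.append(
                PostTestResult(
                    comparison=(labels[gi], labels[gj]),
                    statistic=q,
                    significant=significant,
                    alpha=alpha,
                    critical_value=crit,
                    span=r,
                )
            )
    return results


def bonferroni_by_time(
    response: Sequence[float],
    group: Sequence,
    time: Sequence[float],
    alpha: float = 0.05,
) -> List[PostTestResult]:
    """Bonferroni-adjusted two-group comparisons at each time point.

    A two-way group-by-time ANOVA supplies the pooled residual mean square
    and degrees of freedom; at each time t the statistic is
    |m1 - m2| / sqrt(MS_res * (1/n1 + 1/n2)) with adjusted p = min(1, T*p),
    T being the number of compared time points.  Times at which one group
    is absent are skipped with a warning.
    """
    y = np.asarray(response, dtype=float)
    g = np.asarray(group)
    t = np.asarray(time, dtype=float)
    levels = sorted(set(g.tolist()))
    if len(levels) != 2:
        raise ValueError(f"need exactly 2 groups, got {levels}")
    g1, g2 = levels

    times = sorted(set(t.tolist()))
    testable = [
        tp for tp in times if np.any((t == tp) & (g == g1)) and np.any((t == tp) & (g == g2))
    ]
    skipped = [tp for tp in times if tp not in testable]
    if skipped:
        logger.warning("skipping time point(s) with a group absent: %s", skipped)
    if len(testable) < 1:
        raise ValueError("no time point has both groups present")

    keep = np.isin(t, testable)
    if len(testable) == 1:
        # no time factor left: pooled residual from the two-group layout
        table = one_way_anova([y[keep & (g == g1)], y[keep & (g == g2)]])
    else:
        table = two_way_anova(
            FactorialDataset(y[keep], g[keep], t[keep]),
            ss_type=3,
            effect_names=("Group", "Time"),
        )
    ms_res = table.residual_ms
    df_res = table.residual_df
    T = len(testable)

    results: List[PostTestResult] = []
    for tp in testable:
        y1 = y[(t == tp) & (g == g1)]
        y2 = y[(t == tp) & (g == g2)]
        diff = abs(y1.mean() - y2.mean())
        se = math.sqrt(ms_res * (1.0 / len(y1) + 1.0 / len(y2)))
        if se == 0.0:
            tstat = math.inf if diff > 0 else 0.0
            p = 0.0 if diff > 0 else 1.0
        else:
            tstat = diff / se
            p = 2.0 * float(stats.t.sf(tstat, df_res))
        adj = min(1.0, T * p)
        results.append(
            PostTestResult(
                comparison=(str(g1), str(g2)),
                statistic=tstat,
                significant=bool(adj < alpha),
                alpha=alpha,
                adjusted_p=adj,
                time=float(tp),
            )
        )
    return results
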