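"""Group statistics: independent t-tests (from raw samples or published
summary statistics), balanced two-way and mixed-design ANOVA with Bonferroni
post hoc contrasts, and Pearson correlation.

The summary-based t-test uses the identity, exact for equal group sizes,

    t = (m1 - m2) / sqrt(sem1^2 + sem2^2),    df = n1 + n2 - 2 (pooled),

which lets published mean +/- SEM values be checked without raw data. The
ANOVA routines are written from explicit sums of squares for balanced
designs, so each decomposition can be verified against an independent
brute-force computation; they are not thin wrappers.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .core import DataError, DegenerateDataError, ParameterError

__all__ = [
    "GroupSummary",
    "TTestResult",
    "AnovaResult",
    "CorrelationResult",
    "ttest_from_summary",
    "ttest_independent",
    "anova_two_way",
    "anova_mixed",
    "pearson",
    "bonferroni",
    "significance_marker",
]


@dataclass(frozen=True)
class GroupSummary:
    """Published group statistics: mean, SEM and subject count."""

    mean: float
    sem: float
    n: int

    def __post_init__(self) -> None:
        if self.sem < 0:
            raise DataError(f"SEM must be >= 0, got {self.sem}")
        if self.n < 2:
            raise DataError(f"need n >= 2 per group, got {self.n}")


@dataclass
class TTestResult:
    t: float
    df: float
    p: float
    mean_diff: float

    def to_dict(self) -> dict:
        return {"t": self.t, "df": self.df, "p": self.p, "mean_diff": self.mean_diff}


@dataclass
class AnovaResult:
    """Per-effect F table plus optional Bonferroni post hoc contrasts."""

    table: pd.DataFrame  # columns: effect, ss, df_num, df_den, F, p
    post_hoc: pd.DataFrame | None = None  # columns: pair, t, p_raw, p_adjusted

    def effect(self, name: str) -> pd.Series:
        rows = self.table[self.table["effect"] == name]
        if rows.empty:
            raise KeyError(f"no effect named {name!r}")
        return rows.iloc[0]


@dataclass
class CorrelationResult:
    r: float
    p: float
    n: int

    def to_dict(self) -> dict:
        return {"r": self.r, "p": self.p, "n": self.n}


def _t_to_p(t: float, df: float) -> float:
    return float(2 * sps.t.sf(abs(t), df))


def ttest_from_summary(
    g1: GroupSummary, g2: GroupSummary, welch: bool = False
) -> TTestResult:
    """Two-sample t-test recomputed from mean +/- SEM and n per group.

    With the default pooled flavour, df = n1 + n2 - 2; the statistic
    (m1 - m2) / sqrt(sem1^2 + sem2^2) coincides with the pooled-variance t
    whenever the group sizes are equal. ``welch=True`` uses the
    Welch-Satterthwaite df instead.
    """
    denom_sq = g1.sem**2 + g2.sem**2
    if denom_sq == 0:
        raise DegenerateDataError("both SEMs are zero; t undefined")
    diff = g1.mean - g2.mean
    t = diff / math.sqrt(denom_sq)
    if welch:
        df = denom_sq**2 / (
            g1.sem**4 / (g1.n - 1) + g2.sem**4 / (g2.n - 1)
        )
    else:
        df = g1.n + g2.n - 2
    return TTestResult(t, df, _t_to_p(t, df), diff)


def ttest_independent(
    x: Sequence[float], y: Sequence[float], welch: bool = False
) -> TTestResult:
    """Classical two-sample t-test on raw samples (pooled variance default)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise DataError("each sample needs n >= 2")
    if x.var(ddof=1) == 0 and y.var(ddof=1) == 0 and x.mean() == y.mean():
        raise DegenerateDataError("zero variance in both samples with equal means")
    res = sps.ttest_ind(x, y, equal_var=not welch)
    return TTestResult(
        float(res.statistic), float(res.df), float(res.pvalue),
        float(x.mean() - y.mean()),
    )


def _check_balanced(cells: pd.Series) -> int:
    counts = cells.value_counts()
    if counts.min() != counts.max():
        raise ParameterError(
            "unbalanced design: cell counts range from "
            f"{counts.min()} to {counts.max()}"
        )
    return int(counts.iloc[0])


def _f_and_p(ss: float, df: float, ms_err: float, df_err: float) -> tuple[float, float]:
    if ms_err == 0:
        return (0.0, 1.0) if ss <= 1e-300 else (math.inf, 0.0)
    f = (ss / df) / ms_err
    return f, float(sps.f.sf(f, df, df_err))


def anova_two_way(
    values: Sequence[float],
    factor_a: Sequence,
    factor_b: Sequence,
    post_hoc_pairs: Sequence[tuple[tuple, tuple]] | None = None,
) -> AnovaResult:
    """Balanced two-way ANOVA with replication, from explicit sums of squares.

    ``factor_a`` and ``factor_b`` label each observation (e.g. group and
    zone). Optional ``post_hoc_pairs`` are cell pairs ((a1, b1), (a2, b2))
    tested pairwise against the residual mean square, Bonferroni-adjusted
    over the number of tested pairs.
    """
    df_data = pd.DataFrame({
        "y": np.asarray(values, dtype=float),
        "a": list(factor_a),
        "b": list(factor_b),
    })
    a_levels = df_data["a"].unique()
    b_levels = df_data["b"].unique()
    if len(a_levels) < 2 or len(b_levels) < 2:
        raise ParameterError("each factor needs at least 2 levels")
    cell_key = df_data["a"].astype(str) + "\x00" + df_data["b"].astype(str)
    if cell_key.nunique() != len(a_levels) * len(b_levels):
        raise ParameterError("unbalanced design: at least one empty cell")
    n_cell = _check_balanced(cell_key)
    if n_cell < 2:
        raise ParameterError("need >= 2 observations per cell")

    grand = df_data["y"].mean()
    n_total = len(df_data)
    p, q = len(a_levels), len(b_levels)
    mean_a = df_data.groupby("a")["y"].mean()
    mean_b = df_data.groupby("b")["y"].mean()
    mean_cell = df_data.groupby(["a", "b"])["y"].mean()

    ss_a = q * n_cell * float(((mean_a - grand) ** 2).sum())
    ss_b = p * n_cell * float(((mean_b - grand) ** 2).sum())
    ss_cells = n_cell * float(((mean_cell - grand) ** 2).sum())
    ss_ab = ss_cells - ss_a - ss_b
    ss_total = float(((df_data["y"] - grand) ** 2).sum())
    ss_err = ss_total - ss_cells

    df_a, df_b = p - 1, q - 1
    df_ab = df_a * df_b
    df_err = n_total - p * q
    ms_err = ss_err / df_err
    rows = []
    for name, ss, dfn in (("A", ss_a, df_a), ("B", ss_b, df_b), ("AxB", ss_ab, df_ab)):
        f, pval = _f_and_p(max(ss, 0.0), dfn, ms_err, df_err)
        rows.append({"effect": name, "ss": ss, "df_num": dfn,
                     "df_den": df_err, "F": f, "p": pval})
    rows.append({"effect": "residual", "ss": ss_err, "df_num": df_err,
                 "df_den": np.nan, "F": np.nan, "p": np.nan})
    table = pd.DataFrame(rows)

    post_hoc = None
    if post_hoc_pairs:
        m = len(post_hoc_pairs)
        ph_rows = []
        for (a1, b1), (a2, b2) in post_hoc_pairs:
            m1 = float(mean_cell.loc[(a1, b1)])
            m2 = float(mean_cell.loc[(a2, b2)])
            se = math.sqrt(ms_err * 2 / n_cell) if ms_err > 0 else 0.0
            if se == 0:
                t = 0.0 if m1 == m2 else math.inf
            else:
                t = (m1 - m2) / se
            p_raw = _t_to_p(t, df_err) if math.isfinite(t) else 0.0
            ph_rows.append({
                "pair": f"({a1},{b1}) vs ({a2},{b2})",
                "t": t,
                "p_raw": p_raw,
                "p_adjusted": min(1.0, m * p_raw),
            })
        post_hoc = pd.DataFrame(ph_rows)
    return AnovaResult(table, post_hoc)


def anova_mixed(
    values: Sequence[float],
    between: Sequence,
    within: Sequence,
    subject: Sequence,
) -> AnovaResult:
    """Mixed-design (split-plot) ANOVA: one between factor, one within factor.

    Every subject must be observed exactly once at every within level, with
    equal subject counts per group. The between effect is tested against the
    subject-within-group error; the within and interaction effects against
    the subject x within residual.
    """
    d = pd.DataFrame({
        "y": np.asarray(values, dtype=float),
        "g": list(between),
        "w": list(within),
        "s": list(subject),
    })
    groups = d["g"].unique()
    levels = d["w"].unique()
    subjects = d["s"].unique()
    g_count, w_count = len(groups), len(levels)
    if g_count < 2 or w_count < 2:
        raise ParameterError("need >= 2 between groups and >= 2 within levels")
    # each subject belongs to exactly one group and covers every level once
    per_subj = d.groupby("s")
    if any(len(sub["g"].unique()) != 1 for _, sub in per_subj):
        raise ParameterError("a subject appears in more than one group")
    counts = d.groupby(["s", "w"]).size()
    if len(counts) != len(subjects) * w_count or counts.max() != 1:
        raise ParameterError(
            "every subject must be observed exactly once at every within level"
        )
    subj_per_group = d.groupby("g")["s"].nunique()
    if subj_per_group.min() < 2:
        raise ParameterError("need >= 2 subjects per group (no between-subject df)")
    if subj_per_group.min() != subj_per_group.max():
        raise ParameterError("unbalanced groups are not supported")
    s_per_g = int(subj_per_group.iloc[0])
    n_subj = len(subjects)

    grand = d["y"].mean()
    subj_means = d.groupby("s")["y"].mean()
    group_means = d.groupby("g")["y"].mean()
    level_means = d.groupby("w")["y"].mean()
    cell_means = d.groupby(["g", "w"])["y"].mean()

    ss_total = float(((d["y"] - grand) ** 2).sum())
    ss_between_subj = w_count * float(((subj_means - grand) ** 2).sum())
    ss_g = w_count * s_per_g * float(((group_means - grand) ** 2).sum())
    ss_subj_within = ss_between_subj - ss_g
    ss_w = n_subj * float(((level_means - grand) ** 2).sum())
    gw = cell_means.reset_index()
    gw["dev"] = gw["y"] - gw["g"].map(group_means) - gw["w"].map(level_means) + grand
    ss_gw = s_per_g * float((gw["dev"] ** 2).sum())
    ss_err = ss_total - ss_between_subj - ss_w - ss_gw

    df_g = g_count - 1
    df_subj = g_count * (s_per_g - 1)
    df_w = w_count - 1
    df_gw = df_g * df_w
    df_err = df_subj * df_w

    ms_subj = ss_subj_within / df_subj
    ms_err = ss_err / df_err
    rows = []
    f, pval = _f_and_p(max(ss_g, 0.0), df_g, ms_subj, df_subj)
    rows.append({"effect": "G", "ss": ss_g, "df_num": df_g,
                 "df_den": df_subj, "F": f, "p": pval})
    for name, ss, dfn in (("W", ss_w, df_w), ("GxW", ss_gw, df_gw)):
        f, pval = _f_and_p(max(ss, 0.0), dfn, ms_err, df_err)
        rows.append({"effect": name, "ss": ss, "df_num": dfn,
                     "df_den": df_err, "F": f, "p": pval})
    rows.append({"effect": "subject(G)", "ss": ss_subj_within, "df_num": df_subj,
                 "df_den": np.nan, "F": np.nan, "p": np.nan})
    rows.append({"effect": "residual", "ss": ss_err, "df_num": df_err,
                 "df_den": np.nan, "F": np.nan, "p": np.nan})
    return AnovaResult(pd.DataFrame(rows))


def pearson(x: Sequence[float], y: Sequence[float]) -> CorrelationResult:
    """Pearson product-moment correlation with a two-sided t-based p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise DataError("x and y must have equal length")
    if x.size < 3:
        raise DataError(f"need n >= 3 pairs, got {x.size}")
    if x.var() == 0 or y.var() == 0:
        raise DegenerateDataError("zero variance: correlation undefined")
    res = sps.pearsonr(x, y)
    return CorrelationResult(float(res.statistic), float(res.pvalue), int(x.size))


def bonferroni(p_values: Sequence[float], m: int | None = None) -> np.ndarray:
    """Bonferroni adjustment: p_adj = min(1, m * p), order-preserving."""
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise DataError("p-values must lie in [0, 1]")
    if m is None:
        m = p.size
    if m < 1:
        raise ParameterError(f"number of comparisons must be >= 1, got {m}")
    return np.minimum(1.0, m * p)


def significance_marker(p: float) -> str:
    """The reporting convention: '***' p < 0.001, '**' p < 0.01, else ''."""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    return ""
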