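"""Inferential layer: unpaired Student t, balanced two-way ANOVA with
Sidak/Bonferroni post hoc comparisons, and the sucrose-intake analysis.

The ANOVA is the classical balanced fixed-effects decomposition

    SS_total = SS_A + SS_B + SS_AB + SS_within

computed in closed form (cell means), which keeps degenerate designs
(a single level of one factor) well defined: with one level of B the model
collapses to a one-way ANOVA and F_A = t² for two groups.  Post hoc tests
compare the two A groups within each level of B using the pooled within-cell
mean square, with the family-wise adjustment taken over the B levels
(Sidak: p' = 1-(1-p)^m; Bonferroni: p' = min(1, m·p)).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "StatResult",
    "PosthocEntry",
    "ttest_unpaired",
    "anova_two_way",
    "sucrose_analysis",
    "sidak_adjust",
    "bonferroni_adjust",
]


@dataclass(frozen=True)
class PosthocEntry:
    comparison: str
    t: float
    p_raw: float
    p_adjusted: float
    significant: bool


@dataclass(frozen=True)
class StatResult:
    test: str
    statistic: float
    df: tuple[int, ...] | int
    p_value: float
    tail: Literal["one", "two"] = "two"
    posthoc: tuple[PosthocEntry, ...] = ()
    effects: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError("p-value out of [0, 1]")


def sidak_adjust(p: float, m: int) -> float:
    return 1.0 - (1.0 - p) ** m


def bonferroni_adjust(p: float, m: int) -> float:
    return min(1.0, m * p)


# ---------------------------------------------------------------------------
# Student t
# ---------------------------------------------------------------------------


def ttest_unpaired(
    a: Sequence[float],
    b: Sequence[float],
    tail: Literal["one", "two"] = "two",
    alternative: Literal["greater", "less"] = "greater",
) -> StatResult:
    """Pooled-variance unpaired Student t-test.

    ``tail="one"`` with ``alternative="greater"`` tests mean(a) > mean(b);
    when the observed direction matches, the one-tailed p is half the
    two-tailed p.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    na, nb = len(a), len(b)
    if na < 2 or nb < 2:
        raise ValueError("each group needs at least 2 observations")
    ssa = float(((a - a.mean()) ** 2).sum())
    ssb = float(((b - b.mean()) ** 2).sum())
    df = na + nb - 2
    pooled_var = (ssa + ssb) / df
    diff = float(a.mean() - b.mean())
    if pooled_var == 0:
        t = 0.0 if diff == 0 else math.inf * np.sign(diff)
    else:
        t = diff / math.sqrt(pooled_var * (1.0 / na + 1.0 / nb))
    if tail == "two":
        p = 2.0 * sps.t.sf(abs(t), df)
    else:
        signed = t if alternative == "greater" else -t
        p = float(sps.t.sf(signed, df))
    return StatResult(
        test="unpaired Student t",
        statistic=float(t),
        df=df,
        p_value=min(1.0, float(p)),
        tail=tail,
    )


# ---------------------------------------------------------------------------
# balanced two-way ANOVA
# ---------------------------------------------------------------------------


def anova_two_way(
    table: pd.DataFrame,
    response: str = "response",
    factor_a: str = "group",
    factor_b: str = "layer",
    posthoc: Literal["sidak", "bonferroni", None] = "sidak",
    alpha: float = 0.05,
) -> StatResult:
    """Balanced fixed-effects two-way ANOVA with interaction.

    Requires an equal number of replicates in every (A, B) cell; an
    unbalanced design raises (the closed-form decomposition — and the Sidak
    post hoc path as specified here — assume balance).  The returned result
    carries the A main effect as its headline statistic; all three effects
    are available under ``effects``.
    """
    df = table[[factor_a, factor_b, response]].dropna()
    a_levels = sorted(df[factor_a].unique(), key=str)
    b_levels = sorted(df[factor_b].unique(), key=str)
    I, J = len(a_levels), len(b_levels)
    cell_sizes = df.groupby([factor_a, factor_b], sort=True)[response].count()
    if cell_sizes.nunique() != 1 or len(cell_sizes) != I * J:
        raise ValueError(
            "unbalanced design: the balanced ANOVA decomposition and the "
            "Sidak post hoc comparisons require equal cell counts"
        )
    n = int(cell_sizes.iloc[0])
    if n < 2:
        raise ValueError("at least 2 replicates per cell are required")

    y = df[response].to_numpy(float)
    grand = y.mean()
    cell_mean = df.groupby([factor_a, factor_b])[response].mean()
    a_mean = df.groupby(factor_a)[response].mean()
    b_mean = df.groupby(factor_b)[response].mean()

    ss_a = n * J * float(((a_mean - grand) ** 2).sum())
    ss_b = n * I * float(((b_mean - grand) ** 2).sum())
    ss_cells = n * float(((cell_mean - grand) ** 2).sum())
    ss_ab = ss_cells - ss_a - ss_b
    ss_total = float(((y - grand) ** 2).sum())
    ss_within = ss_total - ss_cells

    df_a, df_b = I - 1, J - 1
    df_ab = df_a * df_b
    df_within = I * J * (n - 1)
    ms_within = ss_within / df_within

    def f_and_p(ss, d):
        if d == 0:
            return 0.0, 1.0
        f = (ss / d) / ms_within if ms_within > 0 else math.inf
        return f, float(sps.f.sf(f, d, df_within))

    f_a, p_a = f_and_p(ss_a, df_a)
    f_b, p_b = f_and_p(ss_b, df_b)
    f_ab, p_ab = f_and_p(ss_ab, df_ab)

    entries: list[PosthocEntry] = []
    if posthoc is not None and I == 2:
        adjust = sidak_adjust if posthoc == "sidak" else bonferroni_adjust
        m = J
        se = math.sqrt(ms_within * 2.0 / n)
        for bl in b_levels:
            m1 = cell_mean[(a_levels[0], bl)]
            m2 = cell_mean[(a_levels[1], bl)]
            t = 0.0 if se == 0 else (m1 - m2) / se
            p_raw = 2.0 * float(sps.t.sf(abs(t), df_within))
            p_adj = adjust(min(1.0, p_raw), m)
            entries.append(
                PosthocEntry(
                    comparison=f"{a_levels[0]} vs {a_levels[1]} @ {factor_b}={bl}",
                    t=float(t),
                    p_raw=min(1.0, p_raw),
                    p_adjusted=float(min(1.0, p_adj)),
                    significant=p_adj < alpha,
                )
            )

    effects = {
        factor_a: {"F": f_a, "df": (df_a, df_within), "p": p_a, "SS": ss_a},
        factor_b: {"F": f_b, "df": (df_b, df_within), "p": p_b, "SS": ss_b},
        "interaction": {"F": f_ab, "df": (df_ab, df_within), "p": p_ab, "SS": ss_ab},
        "within": {"SS": ss_within, "df": df_within, "MS": ms_within},
        "total": {"SS": ss_total, "df": I * J * n - 1},
    }
    return StatResult(
        test=f"two-way ANOVA ({factor_a} x {factor_b}), {posthoc or 'no'} post hoc",
        statistic=f_a,
        df=(df_a, df_within),
        p_value=p_a,
        tail="two",
        posthoc=tuple(entries),
        effects=effects,
    )


# ---------------------------------------------------------------------------
# sucrose-intake analysis
# ---------------------------------------------------------------------------


def sucrose_analysis(
    intake: pd.DataFrame,
    alpha: float = 0.05,
    baseline_week: int = 0,
) -> StatResult:
    """Stress × time ANOVA of weekly sucrose intake with Bonferroni per-week
    comparisons.

    Expects a tidy table (animal_id, group, week, intake_g) whose week
    ``baseline_week`` is the pre-stress baseline; the ANOVA and the post hoc
    family cover the post-baseline weeks only.  The result's ``effects``
    carries ``first_significant_week`` — the earliest week whose adjusted
    group difference falls below alpha.
    """
    required = {"animal_id", "group", "week", "intake_g"}
    missing = required - set(intake.columns)
    if missing:
        raise ValueError(f"intake table is missing columns: {sorted(missing)}")
    groups = sorted(intake["group"].unique())
    if len(groups) != 2:
        raise ValueError("exactly two groups are required")
    if baseline_week not in set(intake["week"]):
        raise ValueError("baseline week missing from intake table")
    post = intake[intake["week"] > baseline_week]
    weeks = sorted(post["week"].unique())
    if len(weeks) < 2:
        raise ValueError("need at least two post-baseline weeks")

    res = anova_two_way(
        post.rename(columns={"intake_g": "response"}),
        response="response",
        factor_a="group",
        factor_b="week",
        posthoc="bonferroni",
        alpha=alpha,
    )
    first = None
    for e in res.posthoc:
        if e.significant:
            wk = int(e.comparison.rsplit("=", 1)[1])
            first = wk if first is None else min(first, wk)
    effects = dict(res.effects)
    effects["first_significant_week"] = first
    effects["n_comparisons"] = len(res.posthoc)
    return StatResult(
        test="two-way ANOVA (stress x time), Bonferroni post hoc",
        statistic=res.statistic,
        df=res.df,
        p_value=res.p_value,
        tail="two",
        posthoc=res.posthoc,
        effects=effects,
    )


def render_p(p: float) -> str:
    """Report-style threshold rendering of a p-value."""
    for cut in (0.001, 0.01, 0.05):
        if p < cut:
            return f"P < {cut}"
    return "n.s."
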