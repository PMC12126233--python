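"""Group-comparison statistics for behavioral readouts.

A small classical-statistics stage: unpaired two-tailed t tests,
one-/two-way ANOVA (type-II sums of squares for unbalanced designs),
and Tukey's HSD post hoc comparisons — the tests used for endpoints
such as mouse-grimace-scale scores in a sex x genotype design.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm
import statsmodels.formula.api as smf
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from .containers import ValidationError

SEXES = ("male", "female")

BEHAVIOR_COLUMNS = ["subject_id", "sex", "genotype", "value"]


def validate_behavioral_table(table: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in BEHAVIOR_COLUMNS if c not in table.columns]
    if missing:
        raise ValidationError(f"behavioral table missing columns: {missing}")
    if not np.isfinite(table["value"].to_numpy(dtype=float)).all():
        raise ValidationError("behavioral values must be finite")
    return table


@dataclass(frozen=True)
class AnovaResult:
    effect: str
    df_effect: int
    df_residual: int
    F: float
    p: float


def unpaired_t_test(a, b) -> tuple[float, float, float]:
    """Classical pooled-variance two-sample t test, two-sided.

    Returns ``(t, df, p)`` with the difference oriented a minus b.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValidationError("t test requires >= 2 observations per group")
    sp2 = ((a.size - 1) * a.var(ddof=1) + (b.size - 1) * b.var(ddof=1)) / (a.size + b.size - 2)
    if sp2 == 0:
        raise ValidationError("pooled variance is zero; t test undefined")
    res = stats.ttest_ind(a, b, equal_var=True)
    df = a.size + b.size - 2
    return float(res.statistic), float(df), float(res.pvalue)


def two_way_anova(table: pd.DataFrame) -> list[AnovaResult]:
    """sex x genotype ANOVA with type-II sums of squares.

    Requires >= 2 observations in every (sex, genotype) cell. Returns
    main effects and the interaction.
    """
    table = validate_behavioral_table(table)
    counts = table.groupby(["sex", "genotype"]).size()
    if len(counts) < 4 or (counts < 2).any():
        raise ValidationError(
            f"two-way ANOVA needs >= 2 observations in each of the 4 cells; got {dict(counts)}"
        )
    model = smf.ols("value ~ C(sex) * C(genotype)", data=table).fit()
    aov = sm.stats.anova_lm(model, typ=2)
    df_resid = int(aov.loc["Residual", "df"])
    label_map = {
        "C(sex)": "sex",
        "C(genotype)": "genotype",
        "C(sex):C(genotype)": "sex:genotype",
    }
    results = []
    for raw, name in label_map.items():
        results.append(
            AnovaResult(
                effect=name,
                df_effect=int(aov.loc[raw, "df"]),
                df_residual=df_resid,
                F=float(aov.loc[raw, "F"]),
                p=float(aov.loc[raw, "PR(>F)"]),
            )
        )
    return results


def one_way_anova(values_by_group: dict[str, list[float]]) -> AnovaResult:
    """One-way ANOVA across named groups."""
    groups = {k: np.asarray(v, dtype=float) for k, v in values_by_group.items()}
    if len(groups) < 2:
        raise ValidationError("one-way ANOVA needs >= 2 groups")
    if any(g.size < 2 for g in groups.values()):
        raise ValidationError("one-way ANOVA needs >= 2 observations per group")
    f, p = stats.f_oneway(*groups.values())
    k = len(groups)
    n = sum(g.size for g in groups.values())
    return AnovaResult(effect="group", df_effect=k - 1, df_residual=n - k, F=float(f), p=float(p))


def tukey_hsd(table: pd.DataFrame, factor: str) -> pd.DataFrame:
    """Tukey HSD pairwise comparisons over the levels of ``factor``.

    ``factor`` may be a single column name or ``"sex:genotype"`` for the
    four-cell combination. Returns a DataFrame with columns group1,
    group2, meandiff, p_adj, lower, upper, reject (studentized-range
    adjusted p values).
    """
    table = validate_behavioral_table(table)
    if factor == "sex:genotype":
        labels = table["sex"].astype(str) + ":" + table["genotype"].astype(str)
    elif factor in table.columns:
        labels = table[factor].astype(str)
    else:
        raise ValidationError(f"unknown factor {factor!r}")
    if labels.nunique() < 2:
        raise ValidationError("Tukey HSD needs >= 2 factor levels")
    res = pairwise_tukeyhsd(table["value"].to_numpy(dtype=float), labels.to_numpy(), alpha=0.05)
    frame = pd.DataFrame(
        res.summary().data[1:],
        columns=["group1", "group2", "meandiff", "p_adj", "lower", "upper", "reject"],
    )
    frame["p_adj"] = res.pvalues  # full precision, not the rounded summary
    frame["meandiff"] = res.meandiffs
    return frame
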