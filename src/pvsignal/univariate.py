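"""Demographic comparisons between target-event and other rows.

Continuous variables (age, height, weight, BMI) are compared with the
two-sided Wilcoxon rank-sum (Mann-Whitney) test; sex with a two-sided Fisher
exact test on the 2x2 sex-by-group table.  Each variable is analysed
complete-case: rows missing that variable are excluded from that comparison
only, and the per-group n actually used is reported alongside means and SDs.

Rank-sum p-values use exact enumeration when both groups are small and
untied, otherwise the normal approximation with tie and continuity
correction.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Optional, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .errors import UndefinedComparisonError

__all__ = ["GroupComparison", "compare_continuous", "compare_sex",
           "characteristics_table", "CONTINUOUS_VARIABLES"]

CONTINUOUS_VARIABLES = {
    "age": "age_years",
    "height": "height_cm",
    "weight": "weight_kg",
    "bmi": "bmi",
}


@dataclass(frozen=True)
class GroupComparison:
    """One row of the characteristics table: target group vs the rest."""

    variable: str
    test: str                                  # "wilcoxon" or "fisher"
    group_means: Tuple[float, float]           # (target, other)
    group_sds: Tuple[float, float]
    n_used: Tuple[int, int]
    p_value: float
    statistic: float
    detail: Optional[Dict] = None


def _split(rows: pd.DataFrame, column: str) -> Tuple[pd.Series, pd.Series]:
    grp = rows["is_target_event"].astype(bool)
    x = rows.loc[grp, column].dropna()
    y = rows.loc[~grp, column].dropna()
    return x, y


def compare_continuous(rows: pd.DataFrame, variable: str,
                       exact_limit: int = 25) -> GroupComparison:
    """Rank-sum comparison of one continuous variable between the groups.

    ``variable`` is one of ``age``, ``height``, ``weight``, ``bmi`` (or a raw
    column name).  Exact enumeration is used when both groups have at most
    ``exact_limit`` observations and the pooled sample is untied.
    """
    column = CONTINUOUS_VARIABLES.get(variable, variable)
    if column not in rows.columns:
        raise KeyError(f"unknown variable {variable!r}")
    x, y = _split(rows, column)
    if not len(x) or not len(y):
        raise UndefinedComparisonError(
            f"{variable}: a group is empty after missing-value exclusion")
    pooled = np.concatenate([x, y])
    no_ties = len(np.unique(pooled)) == len(pooled)
    method = "exact" if (max(len(x), len(y)) <= exact_limit and no_ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return GroupComparison(
        variable=variable,
        test="wilcoxon",
        group_means=(float(x.mean()), float(y.mean())),
        group_sds=(float(x.std(ddof=1)) if len(x) > 1 else float("nan"),
                   float(y.std(ddof=1)) if len(y) > 1 else float("nan")),
        n_used=(len(x), len(y)),
        p_value=float(min(res.pvalue, 1.0)),
        statistic=float(res.statistic),
        detail={"method": method},
    )


def compare_sex(rows: pd.DataFrame) -> GroupComparison:
    """Fisher exact test on the sex-by-group 2x2 table.

    ``group_means`` carries the female proportion of each group; the detail
    dict holds the full 2x2 counts [[target_female, target_male],
    [other_female, other_male]].
    """
    grp = rows["is_target_event"].astype(bool)
    sex = rows["sex"]
    ok = sex.notna()
    tf = int(((sex == "female") & grp & ok).sum())
    tm = int(((sex == "male") & grp & ok).sum())
    of = int(((sex == "female") & ~grp & ok).sum())
    om = int(((sex == "male") & ~grp & ok).sum())
    if tf + tm == 0 or of + om == 0:
        raise UndefinedComparisonError("sex: a group is empty after missing-value exclusion")
    odds, p = stats.fisher_exact([[tf, tm], [of, om]], alternative="two-sided")
    return GroupComparison(
        variable="sex",
        test="fisher",
        group_means=(tf / (tf + tm), of / (of + om)),
        group_sds=(float("nan"), float("nan")),
        n_used=(tf + tm, of + om),
        p_value=float(min(p, 1.0)),
        statistic=float(odds),
        detail={"table": [[tf, tm], [of, om]],
                "female_counts": (tf, of), "male_counts": (tm, om)},
    )


def characteristics_table(rows: pd.DataFrame) -> pd.DataFrame:
    """Characteristics-comparison table: sex then age/height/weight/BMI.

    Layout mirrors the usual reporting style: mean +/- SD with the n used in
    parentheses, the p-value and a marker for the test applied.
    """
    records = []
    sex_cmp = compare_sex(rows)
    tf, of = sex_cmp.detail["female_counts"]
    tm, om = sex_cmp.detail["male_counts"]
    records.append({
        "variable": "sex (male; female)",
        "target": f"{tm}; {tf} ({tf + tm})",
        "other": f"{om}; {of} ({of + om})",
        "p_value": sex_cmp.p_value,
        "test": "fisher",
    })
    for name in ("age", "height", "weight", "bmi"):
        try:
            cmp = compare_continuous(rows, name)
        except UndefinedComparisonError:
            continue
        records.append({
            "variable": name,
            "target": f"{cmp.group_means[0]:.1f} ± {cmp.group_sds[0]:.1f} ({cmp.n_used[0]})",
            "other": f"{cmp.group_means[1]:.1f} ± {cmp.group_sds[1]:.1f} ({cmp.n_used[1]})",
            "p_value": cmp.p_value,
            "test": "wilcoxon",
        })
    return pd.DataFrame(records)
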