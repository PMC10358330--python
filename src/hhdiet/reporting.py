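"""Quintile summary tables and across-quintile association/trend tests.

The homogeneity test is the unstratified Cochran-Mantel-Haenszel general
association statistic, Q = (n-1)/n * Pearson chi-square on the quintile x
category contingency table.  The trend test is an ordinary least-squares
regression of the variable on the quintile index (1..5).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import AlignmentError, DegenerateInputError
from .patterns import QUINTILE_LABELS

_QUINTILE_INDEX = {q: i + 1 for i, q in enumerate(QUINTILE_LABELS)}


@dataclass(frozen=True)
class AssociationTest:
    statistic: float
    p_value: float
    dof: int


@dataclass(frozen=True)
class TrendTest:
    slope: float
    stderr: float
    p_value: float
    defined: bool = True


def quintile_summary(
    values: pd.Series, quintiles: pd.Series, kind: str = "continuous"
) -> pd.DataFrame:
    """Per-stratum summary of one variable.

    ``kind='continuous'`` gives mean and SD per quintile plus the total;
    ``kind='categorical'`` gives column percentages per stratum.
    """
    if len(values) != len(quintiles):
        raise AlignmentError(
            f"values ({len(values)}) and quintiles ({len(quintiles)}) differ in length"
        )
    strata = ["total"] + [q for q in QUINTILE_LABELS if q in set(quintiles)]
    rows = []
    if kind == "continuous":
        for s in strata:
            v = values if s == "total" else values[quintiles == s]
            rows.append(
                {
                    "stratum": s,
                    "stat_kind": "mean_sd",
                    "n": len(v),
                    "mean": float(v.mean()),
                    "sd": float(v.std(ddof=1)) if len(v) > 1 else 0.0,
                }
            )
    elif kind == "categorical":
        levels = sorted(pd.unique(values))
        for s in strata:
            v = values if s == "total" else values[quintiles == s]
            counts = v.value_counts()
            for lev in levels:
                rows.append(
                    {
                        "stratum": s,
                        "stat_kind": "percent",
                        "level": lev,
                        "n": int(counts.get(lev, 0)),
                        "percent": 100.0 * counts.get(lev, 0) / len(v),
                    }
                )
    else:
        raise ValueError("kind must be 'continuous' or 'categorical'")
    return pd.DataFrame(rows)


def homogeneity_test(categorical: pd.Series, quintiles: pd.Series) -> AssociationTest:
    """CMH-style general association test across quintiles.

    Raises
    ------
    DegenerateInputError
        if any quintile or category stratum is empty, or fewer than two
        levels are present on either margin.
    """
    if len(categorical) != len(quintiles):
        raise AlignmentError("categorical and quintiles differ in length")
    table = pd.crosstab(quintiles, categorical)
    if table.shape[0] < 2 or table.shape[1] < 2:
        raise DegenerateInputError(
            f"need >= 2 quintiles and >= 2 categories, got table shape {table.shape}"
        )
    if (table.sum(axis=1) == 0).any() or (table.sum(axis=0) == 0).any():
        raise DegenerateInputError("contingency table has an empty stratum")
    obs = table.to_numpy(dtype=float)
    n = obs.sum()
    expected = np.outer(obs.sum(axis=1), obs.sum(axis=0)) / n
    chi2 = float(((obs - expected) ** 2 / expected).sum())
    q = (n - 1.0) / n * chi2
    dof = (table.shape[0] - 1) * (table.shape[1] - 1)
    return AssociationTest(statistic=q, p_value=float(stats.chi2.sf(q, dof)), dof=dof)


def linear_trend_test(values: pd.Series, quintiles: pd.Series) -> TrendTest:
    """OLS of the variable on the quintile index (1..5).

    Constant values give a flagged, undefined p-value rather than an error.
    """
    if len(values) != len(quintiles):
        raise AlignmentError("values and quintiles differ in length")
    x = np.asarray([_QUINTILE_INDEX[q] for q in quintiles], dtype=float)
    y = np.asarray(values, dtype=float)
    if len(np.unique(x)) < 3:
        raise DegenerateInputError("need >= 3 distinct quintile indices for a trend test")
    if np.ptp(y) == 0:
        return TrendTest(slope=0.0, stderr=0.0, p_value=float("nan"), defined=False)
    res = stats.linregress(x, y)
    return TrendTest(
        slope=float(res.slope), stderr=float(res.stderr), p_value=float(res.pvalue)
    )


def significance_flag(p: float) -> str:
    """Two-tier significance marker: 'ii' for p<0.01, 'i' for p<0.05."""
    if np.isnan(p):
        return "n"
    if p < 0.01:
        return "ii"
    if p < 0.05:
        return "i"
    return ""


def benjamini_hochberg(p_values: pd.Series) -> pd.Series:
    """BH-adjusted p-values (optional multiple-testing correction)."""
    p = p_values.to_numpy(dtype=float)
    n = len(p)
    order = np.argsort(p)
    adj = np.empty(n)
    running = 1.0
    for rank in range(n - 1, -1, -1):
        i = order[rank]
        running = min(running, p[i] * n / (rank + 1))
        adj[i] = running
    return pd.Series(adj, index=p_values.index)


def summary_table(
    data: pd.DataFrame,
    quintiles: pd.DataFrame,
    variables: dict[str, str],
    bh_correct: bool = False,
) -> pd.DataFrame:
    """Publication-style table: per pattern x variable, total and Q1..Q5
    summaries plus trend/association p-values and significance flags.

    ``data`` is indexed by household id; ``variables`` maps column name to
    kind ('continuous' or 'categorical').
    """
    if not set(data.index) == set(quintiles.index):
        raise AlignmentError("data and quintiles do not cover the same households")
    quintiles = quintiles.reindex(data.index)
    rows = []
    for pattern in quintiles.columns:
        labels = quintiles[pattern]
        for var, kind in variables.items():
            summ = quintile_summary(data[var], labels, kind)
            if kind == "continuous":
                test = linear_trend_test(data[var], labels)
                trend_p = test.p_value
                assoc_p = float("nan")
            else:
                test = homogeneity_test(data[var], labels)
                assoc_p = test.p_value
                trend_p = float("nan")
            for _, srow in summ.iterrows():
                rec = {"pattern": pattern, "variable": var, **srow.to_dict()}
                rec["trend_p"] = trend_p
                rec["assoc_p"] = assoc_p
                p = assoc_p if kind == "categorical" else trend_p
                rec["flag"] = significance_flag(p)
                rows.append(rec)
    out = pd.DataFrame(rows)
    if bh_correct:
        for col in ("trend_p", "assoc_p"):
            mask = out[col].notna()
            if mask.any():
                out.loc[mask, f"{col}_bh"] = benjamini_hochberg(out.loc[mask, col])
    return out
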