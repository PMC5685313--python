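"""Univariate baseline-characteristics table.

Dichotomous covariates are compared between remitters and nonremitters
with a chi-square test with continuity correction; continuous ones with
the Kruskal-Wallis rank test.  Output mirrors the conventional clinical
"Table 1": median [Q1; Q3] or count (%) per group, with per-variable n
when missingness reduces it.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import CohortTable


@dataclass
class TestResult:
    statistic: float
    degrees_of_freedom: int
    p_value: float
    method: str

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0):
            raise ValueError(f"p={self.p_value} outside [0,1]")


def chi2_2x2_yates(a: int, b: int, c: int, d: int) -> TestResult:
    """Chi-square test on the 2x2 table [[a, b], [c, d]] with continuity
    correction clamped at |O - E| (a table with O = E gives statistic 0)."""
    table = np.array([[a, b], [c, d]], dtype=float)
    if (table < 0).any() or not np.allclose(table, np.round(table)):
        raise ValueError("cell counts must be nonnegative integers")
    n = table.sum()
    rows, colsums = table.sum(axis=1), table.sum(axis=0)
    if (rows == 0).any() or (colsums == 0).any():
        raise ValueError("degenerate table: zero margin")
    expected = np.outer(rows, colsums) / n
    corrected = np.maximum(np.abs(table - expected) - 0.5, 0.0)
    statistic = float((corrected ** 2 / expected).sum())
    return TestResult(statistic, 1, float(stats.chi2.sf(statistic, 1)),
                      "chi-square with continuity correction")


def kruskal_wallis(values, group_labels) -> TestResult:
    """Kruskal-Wallis rank test with tie correction; missing values are
    dropped together with their group label.  A column constant across
    all observations yields statistic 0, p = 1."""
    values = np.asarray(values, dtype=float)
    group_labels = np.asarray(group_labels)
    keep = ~np.isnan(values)
    values, group_labels = values[keep], group_labels[keep]
    groups = [values[group_labels == g] for g in pd.unique(group_labels)]
    if len(groups) < 2 or any(len(g) == 0 for g in groups):
        raise ValueError("need >=2 groups with >=1 non-missing value each")
    df = len(groups) - 1
    if np.all(values == values[0]):
        return TestResult(0.0, df, 1.0, "Kruskal-Wallis")
    h, p = stats.kruskal(*groups)
    return TestResult(float(h), df, float(p), "Kruskal-Wallis")


def _pct(count: int, total: int) -> str:
    # one decimal, half-up, matching clinical-table presentation
    val = Decimal(100 * count) / Decimal(total)
    return str(val.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def _quartile_cell(x: np.ndarray) -> str:
    q1, med, q3 = np.percentile(x, [25, 50, 75])  # linear interpolation
    return f"{med:g} [{q1:g};{q3:g}]"


def baseline_table(cohort: CohortTable) -> pd.DataFrame:
    """Per-covariate group summaries and univariate p-values.

    One row per covariate with columns: kind, n (non-missing), the
    nonremitter and remitter summary cells, statistic and p_value.
    """
    y = cohort.remission.to_numpy()
    rows = []
    for name in cohort.covariates:
        x = cohort.data[name].to_numpy(dtype=float)
        ok = ~np.isnan(x)
        n_used = int(ok.sum())
        kind = cohort.covariate_kind(name)
        if kind == "dichotomous":
            pos0 = int(x[ok & (y == 0)].sum())
            tot0 = int((ok & (y == 0)).sum())
            pos1 = int(x[ok & (y == 1)].sum())
            tot1 = int((ok & (y == 1)).sum())
            res = chi2_2x2_yates(pos0, tot0 - pos0, pos1, tot1 - pos1)
            cell0 = f"{pos0} ({_pct(pos0, tot0)}%)"
            cell1 = f"{pos1} ({_pct(pos1, tot1)}%)"
        else:
            res = kruskal_wallis(x[ok], y[ok])
            cell0 = _quartile_cell(x[ok & (y == 0)])
            cell1 = _quartile_cell(x[ok & (y == 1)])
        rows.append({"variable": name, "kind": kind, "n": n_used,
                     "nonremitters": cell0, "remitters": cell1,
                     "statistic": res.statistic, "p_value": res.p_value,
                     "method": res.method})
    return pd.DataFrame(rows).set_index("variable")
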