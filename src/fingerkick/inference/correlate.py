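"""Bonferroni-corrected Pearson correlation matrix across the kinematic parameters.

Correlations are computed on trial-level observations, pairwise-complete
(an excluded or missing observation drops only the pairs it belongs to).
Two-sided p-values come from the exact t transform of r; the Bonferroni
family defaults to all 45 off-diagonal pairs of the 10 parameters.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from ..errors import ValidationError
from ..types import PARAMETER_NAMES


@dataclass
class CorrelationMatrix:
    parameters: list[str]
    r: pd.DataFrame
    p_raw: pd.DataFrame
    p_adj: pd.DataFrame
    n: pd.DataFrame
    m: int


def _wide(table: pd.DataFrame) -> pd.DataFrame:
    tab = table.copy()
    tab.loc[tab["excluded"].astype(bool), "value"] = np.nan
    return tab.pivot_table(index="trial_id", columns="parameter", values="value", aggfunc="first")


def correlation_matrix(table: pd.DataFrame, m: int | None = None) -> CorrelationMatrix:
    wide = _wide(table)
    params = [p for p in PARAMETER_NAMES if p in wide.columns]
    if not params:
        raise ValidationError("no known parameters in table")
    k = len(params)
    if m is None:
        m = k * (k - 1) // 2
    r = np.eye(k)
    p_raw = np.zeros((k, k))
    n = np.zeros((k, k), dtype=int)
    np.fill_diagonal(n, wide[params].notna().sum().to_numpy())
    for i in range(k):
        for j in range(i + 1, k):
            pair = wide[[params[i], params[j]]].dropna()
            n[i, j] = n[j, i] = len(pair)
            if len(pair) < 3:
                raise ValidationError(
                    f"fewer than 3 pairwise-complete observations for "
                    f"({params[i]}, {params[j]})"
                )
            x, y = pair.iloc[:, 0], pair.iloc[:, 1]
            if x.std() == 0 or y.std() == 0:
                warnings.warn(
                    f"constant variable in pair ({params[i]}, {params[j]}); "
                    "correlation undefined"
                )
                r[i, j] = r[j, i] = np.nan
                p_raw[i, j] = p_raw[j, i] = np.nan
                continue
            res = stats.pearsonr(x, y)
            r[i, j] = r[j, i] = res.statistic
            p_raw[i, j] = p_raw[j, i] = res.pvalue
    p_adj = np.minimum(1.0, m * p_raw)
    np.fill_diagonal(p_adj, 0.0)
    as_df = lambda a: pd.DataFrame(a, index=params, columns=params)
    return CorrelationMatrix(
        parameters=params,
        r=as_df(r),
        p_raw=as_df(p_raw),
        p_adj=as_df(p_adj),
        n=as_df(n),
        m=m,
    )
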