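"""Pre-model covariate control, group comparisons, and annualized change
metrics.

Every longitudinal variable is controlled for sex and for age in days at
the matching assessment (cognitive testing age for test scores, scan age
for brain volumes) before model fitting.  The covariates are centered
before their effects are removed, so each variable keeps its mean: the
longitudinal mean-change structure the difference score model estimates
must survive the control step.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from . import schema


def residualize(
    data: pd.DataFrame,
    include_sex: bool = True,
    variables: list[str] | None = None,
) -> pd.DataFrame:
    """Remove (centered) sex and age effects from each longitudinal variable.

    Per-variable ordinary least squares on the available cases; missing
    entries stay missing; the variable's mean is preserved.  Non-model
    columns pass through unchanged.
    """
    out = data.copy()
    if variables is None:
        variables = [
            schema.col(v, w)
            for w in schema.WAVES
            for v in list(schema.TESTS) + list(schema.VOLUMES)
            if schema.col(v, w) in data.columns
        ]
    for colname in variables:
        base, wave = colname.rsplit("_", 1)
        age_col = schema.age_col_for(base, wave)
        covs = [age_col]
        if include_sex:
            covs.append(schema.SEX_COL)
        y = data[colname].to_numpy(dtype=float)
        obs = ~np.isnan(y)
        X = data.loc[:, covs].to_numpy(dtype=float)
        if np.isnan(X[obs]).any():
            raise ValueError(
                f"covariates missing where {colname} is observed"
            )
        Xo = X[obs]
        ptp = Xo.max(axis=0) - Xo.min(axis=0)
        if np.any(ptp == 0):
            const = [c for c, s in zip(covs, ptp) if s == 0]
            raise ValueError(f"constant covariate(s) {const} for {colname}")
        Xc = Xo - Xo.mean(axis=0)
        beta, *_ = np.linalg.lstsq(Xc, y[obs] - y[obs].mean(), rcond=None)
        res = y.copy()
        res[obs] = y[obs] - Xc @ beta
        out[colname] = res
    return out


def welch_t(group_a, group_b) -> tuple[float, float, float]:
    """Two-sample t-test with unequal variances (Welch-Satterthwaite df)."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    a, b = a[~np.isnan(a)], b[~np.isnan(b)]
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 observations")
    if np.var(a, ddof=1) == 0 and np.var(b, ddof=1) == 0:
        raise ValueError("zero variance in both groups; t undefined")
    res = stats.ttest_ind(a, b, equal_var=False)
    return float(res.statistic), float(res.df), float(res.pvalue)


def annualized_change(
    mean_change_total: float,
    baseline_mean: float,
    baseline_sd: float,
    years: float = 3.0,
) -> tuple[float, float, float]:
    """Across-study mean change -> (per year, baseline-SDs per year,
    percent of baseline per year).

    The SD and percent metrics use the raw wave-1 sample moments of the
    variable, and the nominal wave spacing (3 years) as the divisor.
    """
    if years <= 0:
        raise ValueError("years must be positive")
    if baseline_mean == 0:
        raise ValueError("baseline mean of zero; percent change undefined")
    per_year = mean_change_total / years
    return (
        per_year,
        per_year / baseline_sd,
        100.0 * per_year / baseline_mean,
    )
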