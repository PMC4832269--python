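"""Fit indices, nested-model likelihood-ratio tests, and the
Benjamini-Hochberg false-discovery-rate correction."""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .engine import FitResult, independence_loglik


@dataclass
class FitIndices:
    chisq: float
    df: int
    p: float
    rmsea: float
    cfi: float
    tli: float
    n: int
    baseline_chisq: float
    baseline_df: int

    def to_dict(self) -> dict:
        return asdict(self)


def chisq(model_loglik: float, saturated_loglik: float, df: int,
          tol: float = 1e-6) -> tuple[float, float]:
    """Likelihood-ratio chi-square T = 2(ll_sat - ll_model) and its p-value."""
    T = 2.0 * (saturated_loglik - model_loglik)
    if T < -tol * max(1.0, abs(saturated_loglik)):
        raise ValueError(
            f"model log-likelihood exceeds the saturated one (T = {T:.4g}); "
            "numerical failure"
        )
    T = max(T, 0.0)
    p = float(stats.chi2.sf(T, df)) if df > 0 else 1.0
    return T, p


def rmsea(T: float, df: int, n: int) -> float:
    """Root mean square error of approximation,
    sqrt(max(T - df, 0) / (df * n))."""
    if df <= 0 or n <= 0:
        raise ValueError("df and n must be positive")
    return float(np.sqrt(max(T - df, 0.0) / (df * n)))


def cfi_tli(T: float, df: int, T_b: float, df_b: int) -> tuple[float, float]:
    """Comparative fit index and Tucker-Lewis index against a baseline."""
    if df_b <= df:
        raise ValueError("baseline must have more df than the model")
    num = max(T - df, 0.0)
    den = max(T_b - df_b, T - df, 0.0)
    cfi = 1.0 - (num / den if den > 0 else 0.0)
    if df == 0:
        tli = float("nan")
    else:
        tli = (T_b / df_b - T / df) / (T_b / df_b - 1.0)
    return float(cfi), float(tli)


def fit_indices(fit: FitResult) -> FitIndices:
    """Chi-square, RMSEA, CFI and TLI for a fitted model.

    The incremental indices use the independence-with-means baseline fitted
    by FIML on the same rows.
    """
    df = fit.df
    T, p = chisq(fit.loglik, fit.loglik_saturated, df)
    ll_b, k_b = independence_loglik(fit._patterns)
    p_obs = len(fit._patterns.columns)
    df_b = p_obs * (p_obs + 1) // 2 + p_obs - k_b
    # independence loglik is computed on the internally rescaled data; shift
    # the saturated loglik back by the units offset so the pair matches
    T_b = max(2.0 * ((fit.loglik_saturated - _units_offset(fit)) - ll_b), 0.0)
    cfi, tli = cfi_tli(T, df, T_b, df_b)
    return FitIndices(
        chisq=T, df=df, p=p, rmsea=rmsea(T, df, fit.n_used),
        cfi=cfi, tli=tli, n=fit.n_used,
        baseline_chisq=T_b, baseline_df=df_b,
    )


def _units_offset(fit: FitResult) -> float:
    """Log-density offset between input-data units and the internal scale."""
    counts = fit._patterns.observed_counts()
    sfac = np.array([fit.scale_factors[c] for c in fit._patterns.columns])
    return -float(np.sum(counts * np.log(sfac)))


def nested_diff_test(fit_free: FitResult, fit_constrained: FitResult,
                     tol: float = 1e-4) -> tuple[float, int, float]:
    """Chi-square difference test of an equality-constrained model against
    its parent.  Raises on swapped or non-nested inputs rather than
    returning a negative statistic."""
    d_df = fit_constrained.df - fit_free.df
    if d_df < 0:
        raise ValueError(
            "constrained model has fewer df than the free model; "
            "arguments swapped or models not nested"
        )
    if fit_free.n_used != fit_constrained.n_used:
        raise ValueError("fits use different data rows; not comparable")
    d_chi = 2.0 * (fit_free.loglik - fit_constrained.loglik)
    if d_chi < -tol * max(1.0, abs(fit_free.loglik)):
        raise ValueError(
            f"constrained model fits better (d_chi2 = {d_chi:.4g}); "
            "models not nested or optimization failed"
        )
    d_chi = max(d_chi, 0.0)
    p = float(stats.chi2.sf(d_chi, d_df)) if d_df > 0 else 1.0
    return d_chi, d_df, p


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (input order kept)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    _, adj, _, _ = multipletests(p, method="fdr_bh")
    return adj
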