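"""Casewise (full-information) likelihood and the saturated model.

Oracles: scipy's dense multivariate-normal density for complete data, and
the factored-likelihood closed form for monotone missingness.
"""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from ldsem import ModelSpec, fiml_loglik, saturated_loglik
from ldsem.engine import EngineError, PatternData


def _saturated_spec(names, theta_cov, theta_mean):
    """Fully parameterized mean/covariance spec with fixed values."""
    spec = ModelSpec()
    for v in names:
        spec.add_variable(v)
    for i, a in enumerate(names):
        for b in names[i:]:
            spec.add_cov(a, b, fixed=theta_cov[(a, b)])
    for v in names:
        spec.set_mean(v, fixed=theta_mean[v])
    return spec


def _spec_from_moments(names, Sigma, mu):
    cov = {}
    for i, a in enumerate(names):
        for j, b in enumerate(names):
            if i <= j:
                cov[(a, b)] = float(Sigma[i, j])
    return _saturated_spec(names, cov, dict(zip(names, mu)))


def test_single_standard_normal_value():
    """One row, one variable, x = 0 under N(0, 1): -0.5 ln(2 pi)."""
    spec = _spec_from_moments(["x"], np.eye(1), [0.0])
    data = pd.DataFrame({"x": [0.0]})
    assert fiml_loglik(spec, {}, data) == pytest.approx(-0.9189385, abs=1e-6)


def test_partial_row_contributes_marginal_term():
    """A row observed on one variable adds exactly its univariate
    marginal log-density, whatever the other variables do."""
    Sigma = np.array([[2.0, 0.8], [0.8, 1.5]])
    mu = [1.0, -0.5]
    spec = _spec_from_moments(["a", "b"], Sigma, mu)
    data = pd.DataFrame({"a": [0.3, np.nan], "b": [np.nan, 2.0]})
    expect = (stats.norm.logpdf(0.3, 1.0, np.sqrt(2.0))
              + stats.norm.logpdf(2.0, -0.5, np.sqrt(1.5)))
    assert fiml_loglik(spec, {}, data) == pytest.approx(expect, rel=1e-12)


def test_complete_data_equals_dense_mvn_loglik():
    """On a 3-variable, 5-row complete fixture the casewise likelihood is
    the standard dense multivariate-normal log-likelihood."""
    rng = np.random.default_rng(4)
    A = rng.normal(size=(3, 3))
    Sigma = A @ A.T + np.eye(3)
    mu = np.array([0.5, -1.0, 2.0])
    X = rng.multivariate_normal(mu, Sigma, size=5)
    data = pd.DataFrame(X, columns=["a", "b", "c"])
    spec = _spec_from_moments(["a", "b", "c"], Sigma, mu)
    expect = stats.multivariate_normal(mu, Sigma).logpdf(X).sum()
    assert fiml_loglik(spec, {}, data) == pytest.approx(expect, rel=1e-10)


def test_nonpd_pattern_submatrix_rejected():
    Sigma = np.array([[1.0, 2.0], [2.0, 1.0]])  # indefinite
    spec = _spec_from_moments(["a", "b"], Sigma, [0.0, 0.0])
    data = pd.DataFrame({"a": [0.1], "b": [0.2]})
    with pytest.raises(EngineError, match="positive definite"):
        fiml_loglik(spec, {}, data)


class TestSaturated:
    def test_complete_data_closed_form(self):
        """With no missingness, the saturated likelihood is the dense MVN
        log-likelihood at the sample MLE (denominator n) moments."""
        rng = np.random.default_rng(7)
        X = rng.normal(size=(40, 3)) @ np.diag([1.0, 2.0, 0.5]) + [1, 2, 3]
        data = pd.DataFrame(X, columns=list("abc"))
        mu = X.mean(axis=0)
        S = np.cov(X.T, bias=True)
        expect = stats.multivariate_normal(mu, S).logpdf(X).sum()
        assert saturated_loglik(data) == pytest.approx(expect, rel=1e-9)

    def test_monotone_missingness_matches_factored_likelihood(self):
        """Two variables, x2 missing for a tail block (monotone pattern):
        the FIML saturated likelihood equals the factored closed form
        ll(x1; all rows) + ll(x2 | x1; complete rows)."""
        rng = np.random.default_rng(12)
        n, nc = 60, 35
        x1 = rng.normal(0, 1.3, n)
        x2 = 0.8 * x1 + rng.normal(0, 0.9, n)
        x2[nc:] = np.nan
        data = pd.DataFrame({"x1": x1, "x2": x2})

        # marginal of x1 over all rows at its MLE
        mu1, v1 = x1.mean(), x1.var()
        ll = stats.norm.logpdf(x1, mu1, np.sqrt(v1)).sum()
        # regression of x2 on x1 over the complete block at its MLE
        xc, yc = x1[:nc], x2[:nc]
        b = np.cov(xc, yc, bias=True)[0, 1] / xc.var()
        a = yc.mean() - b * xc.mean()
        res = yc - a - b * xc
        ll += stats.norm.logpdf(res, 0.0, np.sqrt(res.var())).sum()

        assert saturated_loglik(data) == pytest.approx(ll, rel=1e-7)

    def test_em_loglik_nondecreasing_with_iterations(self):
        rng = np.random.default_rng(3)
        X = rng.multivariate_normal(
            [0, 0, 0],
            [[1, 0.5, 0.3], [0.5, 1, 0.4], [0.3, 0.4, 1]], size=200,
        )
        X[rng.random(X.shape) < 0.3] = np.nan
        X = X[~np.isnan(X).all(axis=1)]
        data = pd.DataFrame(X, columns=list("abc"))
        lls = [saturated_loglik(data, max_iter=k) for k in (1, 2, 5, 20, 200)]
        assert all(b >= a - 1e-8 for a, b in zip(lls, lls[1:]))

    def test_variable_observed_once_raises(self):
        data = pd.DataFrame({"a": [1.0, 2.0, 3.0],
                             "b": [np.nan, 0.5, np.nan]})
        with pytest.raises(EngineError, match="<2 rows"):
            saturated_loglik(data)


def test_all_missing_rows_dropped_with_count():
    data = pd.DataFrame({"a": [1.0, np.nan, 2.0], "b": [0.5, np.nan, np.nan]})
    pats = PatternData.from_dataframe(data, ["a", "b"])
    assert pats.n_used == 2
    assert pats.n_dropped == 1
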