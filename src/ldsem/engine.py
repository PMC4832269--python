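"""Full-information maximum likelihood estimation of covariance-structure
models with arbitrarily missing data.

The model-implied moments follow the RAM parameterization

    Sigma = F (I - A)^-1 S (I - A)^-T F^T,      mu = F (I - A)^-1 m

where ``A`` holds directed path coefficients, ``S`` the (co)variances of
exogenous terms, ``m`` the intercepts/means and ``F`` selects the observed
variables.  The casewise likelihood is evaluated per missing-data pattern
from that pattern's sufficient statistics (count, mean, scatter), so the
cost per evaluation is independent of the number of rows.  Gradients are
analytic; variances are optimized on the log scale and correlation-scale
covariances through the Fisher transform, so the admissible region is
respected without explicit bounds.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import linalg, optimize, stats

from .model import ModelSpec, _ckey

LN2PI = float(np.log(2.0 * np.pi))


class EngineError(RuntimeError):
    pass


class _NotPD(Exception):
    """Implied covariance not positive definite at this point."""


# ---------------------------------------------------------------------------
# data handling
# ---------------------------------------------------------------------------

@dataclass
class PatternData:
    """Rows grouped by missing-data pattern with sufficient statistics."""

    columns: list[str]
    n_used: int
    n_dropped: int
    patterns: list[tuple[np.ndarray, int, np.ndarray, np.ndarray]]
    # each: (observed column indices, count, mean, MLE covariance)

    @staticmethod
    def from_dataframe(data: pd.DataFrame, columns: Sequence[str]) -> "PatternData":
        missing = [c for c in columns if c not in data.columns]
        if missing:
            raise EngineError(f"data is missing columns: {missing}")
        X = data.loc[:, list(columns)].to_numpy(dtype=float)
        obs = ~np.isnan(X)
        keep = obs.any(axis=1)
        n_dropped = int((~keep).sum())
        X, obs = X[keep], obs[keep]
        if X.shape[0] == 0:
            raise EngineError("no rows with any observed data")
        pats, inverse = np.unique(obs, axis=0, return_inverse=True)
        out = []
        for k in range(pats.shape[0]):
            rows = X[inverse == k]
            idx = np.where(pats[k])[0]
            sub = rows[:, idx]
            n = sub.shape[0]
            mean = sub.mean(axis=0)
            dev = sub - mean
            cov = dev.T @ dev / n
            out.append((idx, n, mean, cov))
        return PatternData(list(columns), int(X.shape[0]), n_dropped, out)

    def scaled(self, factors: np.ndarray) -> "PatternData":
        """Divide each column by a positive factor (units change only)."""
        pats = []
        for idx, n, mean, cov in self.patterns:
            f = factors[idx]
            pats.append((idx, n, mean / f, cov / np.outer(f, f)))
        return PatternData(self.columns, self.n_used, self.n_dropped, pats)

    @property
    def log_scale_offset(self) -> float:
        """Placeholder; per-column offsets computed by callers."""
        return 0.0

    def observed_counts(self) -> np.ndarray:
        counts = np.zeros(len(self.columns))
        for idx, n, _, _ in self.patterns:
            counts[idx] += n
        return counts

    def require_min_observations(self, k: int = 2) -> None:
        """Estimation needs every variable observed in at least k rows."""
        counts = self.observed_counts()
        thin = [c for c, n in zip(self.columns, counts) if n < k]
        if thin:
            raise EngineError(f"variables observed in <{k} rows: {thin}")


def _as_patterns(data, columns) -> PatternData:
    if isinstance(data, PatternData):
        return data
    return PatternData.from_dataframe(data, columns)


# ---------------------------------------------------------------------------
# RAM assembly
# ---------------------------------------------------------------------------

class RAM:
    """Prepared index structures for evaluating a ModelSpec."""

    def __init__(self, spec: ModelSpec):
        spec.validate()
        self.spec = spec
        self.var_names = [n for n, _ in spec.variables]
        self.index = {n: i for i, n in enumerate(self.var_names)}
        self.obs_idx = np.array(
            [self.index[n] for n in spec.observed], dtype=int
        )
        self.p = len(self.var_names)
        self.labels = spec.free_labels()
        self.label_pos = {lab: k for k, lab in enumerate(self.labels)}
        scales = spec.label_scales()
        self.transforms = [scales.get(lab, "other") for lab in self.labels]

        self.A0 = np.zeros((self.p, self.p))
        self.S0 = np.zeros((self.p, self.p))
        self.m0 = np.zeros(self.p)
        # locations: per label, list of ("A"|"S"|"m", i, j)
        self.locations: dict[str, list[tuple[str, int, int]]] = {
            lab: [] for lab in self.labels
        }
        self.corr_entries: list[tuple[int, int, str]] = []  # (i, j, label)
        self.fixed_corr: list[tuple[int, int, float]] = []
        self.diag_label: dict[int, str] = {}  # variable index -> variance label

        for (src, dst), e in spec.paths.items():
            i, j = self.index[dst], self.index[src]
            if e.free:
                self.locations[e.label].append(("A", i, j))
            else:
                self.A0[i, j] = e.value
        for (a, b), e in spec.covs.items():
            i, j = self.index[a], self.index[b]
            if e.scale == "corr":
                if e.free:
                    self.corr_entries.append((i, j, e.label))
                else:
                    self.fixed_corr.append((i, j, e.value))
            elif e.free:
                self.locations[e.label].append(("S", i, j))
                if i == j:
                    self.diag_label[i] = e.label
            else:
                self.S0[i, j] = self.S0[j, i] = e.value
        for var, e in spec.means.items():
            i = self.index[var]
            if e.free:
                self.locations[e.label].append(("m", i, 0))
            else:
                self.m0[i] = e.value

    # -- parameter vector handling ----------------------------------------
    @property
    def q(self) -> int:
        return len(self.labels)

    def to_optimizer(self, theta: np.ndarray) -> np.ndarray:
        t = np.array(theta, dtype=float)
        for k, tr in enumerate(self.transforms):
            if tr == "var":
                t[k] = np.log(max(t[k], 1e-300))
            elif tr == "corr":
                t[k] = np.arctanh(np.clip(t[k], -0.999999, 0.999999))
        return t

    def from_optimizer(self, t: np.ndarray) -> np.ndarray:
        theta = np.array(t, dtype=float)
        for k, tr in enumerate(self.transforms):
            if tr == "var":
                theta[k] = np.exp(theta[k])
            elif tr == "corr":
                theta[k] = np.tanh(theta[k])
        return theta

    def _jac_nat_wrt_opt(self, theta: np.ndarray) -> np.ndarray:
        j = np.ones_like(theta)
        for k, tr in enumerate(self.transforms):
            if tr == "var":
                j[k] = theta[k]
            elif tr == "corr":
                j[k] = 1.0 - theta[k] ** 2
        return j

    def matrices(self, theta: np.ndarray):
        """Natural parameter vector -> (A, S, m)."""
        A = self.A0.copy()
        S = self.S0.copy()
        m = self.m0.copy()
        for lab, val in zip(self.labels, theta):
            for kind, i, j in self.locations[lab]:
                if kind == "A":
                    A[i, j] = val
                elif kind == "S":
                    S[i, j] = val
                    S[j, i] = val
                else:
                    m[i] = val
        for i, j, r in self.fixed_corr:
            c = r * np.sqrt(S[i, i] * S[j, j])
            S[i, j] = S[j, i] = c
        for i, j, lab in self.corr_entries:
            r = theta[self.label_pos[lab]]
            c = r * np.sqrt(S[i, i] * S[j, j])
            S[i, j] = S[j, i] = c
        return A, S, m

    def moments_full(self, theta: np.ndarray):
        """Implied covariance/mean over ALL variables (latents included)."""
        A, S, m = self.matrices(theta)
        I = np.eye(self.p)
        try:
            B = np.linalg.inv(I - A)
        except np.linalg.LinAlgError as exc:
            raise EngineError("structural cycle: (I - A) singular") from exc
        Sigma = B @ S @ B.T
        mu = B @ m
        return Sigma, mu, A, S, m, B

    def moments(self, theta: np.ndarray):
        Sigma, mu, *_ = self.moments_full(theta)
        o = self.obs_idx
        return Sigma[np.ix_(o, o)], mu[o]

    # -- likelihood and gradient ------------------------------------------
    def loglik(self, theta: np.ndarray, patterns: PatternData) -> float:
        Sigma, mu = self.moments(theta)
        return _patterns_loglik(Sigma, mu, patterns)

    def loglik_grad(self, theta: np.ndarray, patterns: PatternData):
        """(loglik, gradient wrt natural parameters)."""
        Sigma_full, mu_full, A, S, m, B = self.moments_full(theta)
        o = self.obs_idx
        Sigma = Sigma_full[np.ix_(o, o)]
        mu = mu_full[o]
        p_obs = len(o)

        ll = 0.0
        G_obs = np.zeros((p_obs, p_obs))
        g_mu_obs = np.zeros(p_obs)
        for idx, n, mean, cov in patterns.patterns:
            sub = Sigma[np.ix_(idx, idx)]
            try:
                cf = linalg.cho_factor(sub, check_finite=False)
            except linalg.LinAlgError as exc:
                raise _NotPD(str(exc)) from exc
            logdet = 2.0 * np.sum(np.log(np.diag(cf[0])))
            d = mean - mu[idx]
            W = linalg.cho_solve(cf, np.eye(len(idx)), check_finite=False)
            M = cov + np.outer(d, d)
            ll += -0.5 * n * (len(idx) * LN2PI + logdet + np.sum(W * M))
            WMW = W @ M @ W
            G_obs[np.ix_(idx, idx)] += -0.5 * n * (W - WMW)
            g_mu_obs[idx] += n * (W @ d)

        G = np.zeros((self.p, self.p))
        G[np.ix_(o, o)] = G_obs
        g_mu = np.zeros(self.p)
        g_mu[o] = g_mu_obs

        BtGB = B.T @ G @ B                      # d ll / d S (entries free)
        Bg = B.T @ g_mu
        gA = 2.0 * (B.T @ G @ Sigma_full) + np.outer(Bg, mu_full)
        gm = Bg

        grad = np.zeros(self.q)
        for k, lab in enumerate(self.labels):
            tot = 0.0
            for kind, i, j in self.locations[lab]:
                if kind == "A":
                    tot += gA[i, j]
                elif kind == "S":
                    tot += BtGB[i, j] if i == j else 2.0 * BtGB[i, j]
                else:
                    tot += gm[i]
            grad[k] = tot
        # chain rule through correlation-scale entries
        for i, j, lab in self.corr_entries:
            g_entry = 2.0 * BtGB[i, j]
            sij = S[i, j]
            grad[self.label_pos[lab]] += g_entry * np.sqrt(S[i, i] * S[j, j])
            for v in (i, j):
                vlab = self.diag_label.get(v)
                if vlab is not None:
                    grad[self.label_pos[vlab]] += (
                        g_entry * sij / (2.0 * S[v, v])
                    )
        for i, j, r in self.fixed_corr:
            g_entry = 2.0 * BtGB[i, j]
            sij = S[i, j]
            for v in (i, j):
                vlab = self.diag_label.get(v)
                if vlab is not None:
                    grad[self.label_pos[vlab]] += (
                        g_entry * sij / (2.0 * S[v, v])
                    )
        return ll, grad


def _patterns_loglik(Sigma: np.ndarray, mu: np.ndarray,
                     patterns: PatternData) -> float:
    ll = 0.0
    for idx, n, mean, cov in patterns.patterns:
        sub = Sigma[np.ix_(idx, idx)]
        try:
            cf = linalg.cho_factor(sub, check_finite=False)
        except linalg.LinAlgError as exc:
            raise _NotPD(str(exc)) from exc
        logdet = 2.0 * np.sum(np.log(np.diag(cf[0])))
        d = mean - mu[idx]
        W = linalg.cho_solve(cf, np.eye(len(idx)), check_finite=False)
        M = cov + np.outer(d, d)
        ll += -0.5 * n * (len(idx) * LN2PI + logdet + np.sum(W * M))
    return ll


# ---------------------------------------------------------------------------
# public likelihood functions
# ---------------------------------------------------------------------------

def implied_moments(spec: ModelSpec, theta: Mapping[str, float] | np.ndarray):
    """Model-implied covariance matrix and mean vector of the observed
    variables at a parameter point.
    """
    ram = RAM(spec)
    vec = _theta_vector(ram, theta)
    Sigma, mu = ram.moments(vec)
    names = spec.observed
    return (
        pd.DataFrame(Sigma, index=names, columns=names),
        pd.Series(mu, index=names),
    )


def _theta_vector(ram: RAM, theta) -> np.ndarray:
    if isinstance(theta, Mapping):
        missing = [lab for lab in ram.labels if lab not in theta]
        if missing:
            raise EngineError(f"theta missing labels: {missing[:5]} ...")
        return np.array([theta[lab] for lab in ram.labels], dtype=float)
    vec = np.asarray(theta, dtype=float)
    if vec.shape != (ram.q,):
        raise EngineError(f"theta has wrong length {vec.shape}, want {ram.q}")
    return vec


def fiml_loglik(spec: ModelSpec, theta, data) -> float:
    """Casewise (full-information) Gaussian log-likelihood of the data."""
    ram = RAM(spec)
    patterns = _as_patterns(data, spec.observed)
    try:
        return ram.loglik(_theta_vector(ram, theta), patterns)
    except _NotPD as exc:
        raise EngineError(
            f"implied covariance not positive definite: {exc}"
        ) from exc


def saturated_loglik(data, columns: Sequence[str] | None = None,
                     tol: float = 1e-10, max_iter: int = 5000,
                     return_moments: bool = False):
    """Log-likelihood of the unrestricted mean/covariance model.

    Complete data gives the closed-form MLE in one step; with missing values
    the EM algorithm for the multivariate-normal model is iterated until the
    relative log-likelihood change falls below ``tol``.
    """
    if columns is None:
        if isinstance(data, PatternData):
            columns = data.columns
        else:
            columns = list(data.columns)
    patterns = _as_patterns(data, columns)
    patterns.require_min_observations(2)
    p = len(patterns.columns)
    n = patterns.n_used

    if len(patterns.patterns) == 1 and len(patterns.patterns[0][0]) == p:
        _, _, mean, cov = patterns.patterns[0]
        mu, Sigma = mean, cov
        ll = _patterns_loglik(Sigma, mu, patterns)
        return (ll, mu, Sigma) if return_moments else ll

    # initial values from available-case moments
    mu = np.zeros(p)
    var = np.zeros(p)
    counts = np.zeros(p)
    for idx, ng, mean, cov in patterns.patterns:
        mu[idx] += ng * mean
        var[idx] += ng * (np.diag(cov) + mean**2)
        counts[idx] += ng
    mu /= counts
    var = var / counts - mu**2
    Sigma = np.diag(np.maximum(var, 1e-12))

    ll_old = -np.inf
    ll = -np.inf
    for _ in range(max_iter):
        # E-step: expected sufficient statistics
        sum_x = np.zeros(p)
        sum_xx = np.zeros((p, p))
        ll = 0.0
        for idx, ng, mean, cov in patterns.patterns:
            o = idx
            mset = np.setdiff1d(np.arange(p), o, assume_unique=True)
            Soo = Sigma[np.ix_(o, o)]
            cf = linalg.cho_factor(Soo, check_finite=False)
            d = mean - mu[o]
            W = linalg.cho_solve(cf, np.eye(len(o)), check_finite=False)
            logdet = 2.0 * np.sum(np.log(np.diag(cf[0])))
            M = cov + np.outer(d, d)
            ll += -0.5 * ng * (len(o) * LN2PI + logdet + np.sum(W * M))

            Exo = mean
            Cxoxo = cov
            sum_x[o] += ng * Exo
            sum_xx[np.ix_(o, o)] += ng * (Cxoxo + np.outer(mean, mean))
            if len(mset):
                Smo = Sigma[np.ix_(mset, o)]
                K = Smo @ W                     # regression of missing on obs
                mu_m = mu[mset] + K @ d
                Cmm = Sigma[np.ix_(mset, mset)] - K @ Smo.T
                # E[x_m], E[x_m x_o'], E[x_m x_m'] aggregated over the group
                sum_x[mset] += ng * mu_m
                cross = ng * (np.outer(mu_m, mean) + K @ cov)
                sum_xx[np.ix_(mset, o)] += cross
                sum_xx[np.ix_(o, mset)] += cross.T
                mm = ng * (
                    Cmm + K @ cov @ K.T + np.outer(mu_m, mu_m)
                )
                sum_xx[np.ix_(mset, mset)] += mm
        # M-step
        mu = sum_x / n
        Sigma = sum_xx / n - np.outer(mu, mu)
        Sigma = 0.5 * (Sigma + Sigma.T)
        if abs(ll - ll_old) < tol * max(1.0, abs(ll)):
            break
        ll_old = ll
    ll = _patterns_loglik(Sigma, mu, patterns)
    return (ll, mu, Sigma) if return_moments else ll


def independence_loglik(patterns: PatternData) -> tuple[float, int]:
    """FIML log-likelihood and free-parameter count of the independence
    (zero-covariance, free means/variances) baseline model.

    Under independence the likelihood factorizes over variables, so the
    per-variable MLE over each variable's observed entries is exact even
    with missing data.
    """
    p = len(patterns.columns)
    sum1 = np.zeros(p)
    sumx = np.zeros(p)
    sumxx = np.zeros(p)
    for idx, n, mean, cov in patterns.patterns:
        sum1[idx] += n
        sumx[idx] += n * mean
        sumxx[idx] += n * (np.diag(cov) + mean**2)
    mu = sumx / sum1
    var = sumxx / sum1 - mu**2
    ll = float(np.sum(-0.5 * sum1 * (LN2PI + np.log(var) + 1.0)))
    return ll, 2 * p


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

@dataclass
class FitResult:
    """Converged (or flagged) FIML estimate of a ModelSpec."""

    spec: ModelSpec
    theta: dict[str, float]          # natural parameters, input-data units
    se: dict[str, float]
    loglik: float                    # input-data units
    loglik_saturated: float
    n_used: int
    n_dropped: int
    converged: bool
    grad_norm: float
    iterations: int
    n_restarts: int
    restart_logliks: list[float]
    heywood: list[str]
    vcov: np.ndarray | None
    param_table: pd.DataFrame | None
    scale_factors: dict[str, float]
    _ram: RAM = field(repr=False, default=None)
    _theta_scaled: np.ndarray = field(repr=False, default=None)
    _vcov_scaled: np.ndarray = field(repr=False, default=None)
    _patterns: PatternData = field(repr=False, default=None)

    @property
    def chisq(self) -> float:
        return max(2.0 * (self.loglik_saturated - self.loglik), 0.0)

    @property
    def df(self) -> int:
        from .model import degrees_of_freedom
        return degrees_of_freedom(self.spec)

    def implied_moments(self, full: bool = False):
        """Implied covariance/mean in input-data units."""
        ram = self._ram
        Sigma, mu, *_ = ram.moments_full(
            _theta_vector(ram, self._theta_scaled)
        )
        names = ram.var_names
        s = np.array([self.scale_factors.get(v, 1.0) for v in names])
        Sigma = Sigma * np.outer(s, s)
        mu = mu * s
        if not full:
            o = ram.obs_idx
            names = [names[i] for i in o]
            Sigma = Sigma[np.ix_(o, o)]
            mu = mu[o]
        return (
            pd.DataFrame(Sigma, index=names, columns=names),
            pd.Series(mu, index=names),
        )

    def implied_correlation(self, a: str, b: str) -> float:
        Sigma, _ = self.implied_moments(full=True)
        return float(
            Sigma.loc[a, b] / np.sqrt(Sigma.loc[a, a] * Sigma.loc[b, b])
        )

    def export_parameters(self, path) -> None:
        self.param_table.to_csv(path, index=False)

    def fit_summary(self) -> dict:
        from .indices import fit_indices
        return fit_indices(self).to_dict()


def _variable_scales(spec: ModelSpec, patterns: PatternData) -> dict[str, float]:
    """Per-variable rescaling factor: the wave-1 available-case SD of the
    variable's base name (both waves of a variable share one factor, so
    longitudinal comparability is a pure units change)."""
    cols = patterns.columns
    sums = {c: [0.0, 0.0, 0.0] for c in cols}
    for idx, n, mean, cov in patterns.patterns:
        for k, j in enumerate(idx):
            c = cols[j]
            sums[c][0] += n
            sums[c][1] += n * mean[k]
            sums[c][2] += n * (cov[k, k] + mean[k] ** 2)
    sds = {}
    for c, (n, sx, sxx) in sums.items():
        v = sxx / n - (sx / n) ** 2
        sds[c] = float(np.sqrt(v)) if v > 0 else 1.0
    scales: dict[str, float] = {}
    for c in cols:
        base = c
        for w in ("_w1", "_w2"):
            if c.endswith(w):
                base = c[: -len(w)]
        anchor = f"{base}_w1"
        scales[c] = sds.get(anchor, sds[c])
    # latents inherit the scale of their anchor observed variable; without
    # an explicit anchor, the unit-fixed reference indicator pins the scale
    observed = set(cols)

    def _anchor(v: str, seen: frozenset) -> str | None:
        a = spec.scale_anchor.get(v)
        if a is not None:
            return a
        for (src, dst), e in spec.paths.items():
            if src == v and not e.free and e.value == 1.0:
                if dst in observed:
                    return dst
                if dst not in seen:
                    found = _anchor(dst, seen | {dst})
                    if found is not None:
                        return found
        return None

    for v, _ in spec.variables:
        if v not in scales:
            anchor = _anchor(v, frozenset({v}))
            scales[v] = scales.get(anchor, 1.0)
    return scales


def _label_unit_factors(ram: RAM, scales: Mapping[str, float]) -> np.ndarray:
    """Multiplier turning each scaled-data natural parameter back into
    input-data units."""
    names = ram.var_names
    factors = np.ones(ram.q)
    for k, lab in enumerate(ram.labels):
        facs = []
        for kind, i, j in ram.locations[lab]:
            if kind == "A":
                facs.append(scales[names[i]] / scales[names[j]])
            elif kind == "S":
                facs.append(scales[names[i]] * scales[names[j]])
            else:
                facs.append(scales[names[i]])
        if ram.transforms[k] == "corr":
            facs = [1.0]
        if facs and not np.allclose(facs, facs[0], rtol=1e-8):
            raise EngineError(
                f"label {lab!r} spans locations with inconsistent units"
            )
        factors[k] = facs[0] if facs else 1.0
    return factors


def _start_values(ram: RAM, patterns: PatternData) -> np.ndarray:
    """Deterministic, data-driven starting values (natural scale)."""
    cols = patterns.columns
    col_pos = {c: j for j, c in enumerate(cols)}
    sums = np.zeros((len(cols), 3))
    for idx, n, mean, cov in patterns.patterns:
        for k, j in enumerate(idx):
            sums[j] += (n, n * mean[k], n * (cov[k, k] + mean[k] ** 2))
    means = sums[:, 1] / sums[:, 0]
    varis = np.maximum(sums[:, 2] / sums[:, 0] - means**2, 1e-6)

    names = ram.var_names
    endo = {names[i] for (src, dst), e in ram.spec.paths.items()
            for i in [ram.index[dst]]}
    theta = np.zeros(ram.q)
    for k, lab in enumerate(ram.labels):
        if ram.transforms[k] == "corr":
            theta[k] = 0.0
            continue
        kind, i, j = ram.locations[lab][0]
        vname = names[i]
        if ram.transforms[k] == "var":
            anchor = vname if vname in col_pos else (
                ram.spec.scale_anchor.get(vname, vname)
            )
            base = varis[col_pos[anchor]] if anchor in col_pos else 1.0
            if vname in col_pos:        # observed variable
                theta[k] = 0.5 * base if vname in endo else base
            elif lab.startswith("var_d_"):
                theta[k] = 0.25 * base
            else:
                theta[k] = 0.5 * base
        elif kind == "A":
            theta[k] = 0.8
        elif kind == "m":
            if vname in col_pos:
                theta[k] = means[col_pos[vname]]
            else:
                anchor = ram.spec.scale_anchor.get(vname)
                if lab.startswith("alpha_d_") and anchor in col_pos:
                    a2 = anchor.replace("_w1", "_w2")
                    if a2 in col_pos:
                        theta[k] = means[col_pos[a2]] - means[col_pos[anchor]]
        else:
            theta[k] = 0.0
    return theta


def fit_model(
    spec: ModelSpec,
    data,
    *,
    starts: int = 5,
    seed: int = 0,
    tol: float = 1e-5,
    max_iter: int = 4000,
    compute_se: bool = True,
    standardized: bool = True,
    rescale: bool = True,
    theta0: Mapping[str, float] | None = None,
) -> FitResult:
    """Fit a ModelSpec to data by full-information maximum likelihood.

    Multi-start quasi-Newton optimization (first start deterministic and
    data-driven, the rest jittered with the given seed); ties broken by best
    log-likelihood then smallest gradient norm.  Standard errors come from
    the numerically differentiated observed information.  Internally each
    variable (and both waves of it) is rescaled by its wave-1 standard
    deviation for optimizer conditioning; all reported quantities are mapped
    back to input-data units.
    """
    from .model import degrees_of_freedom

    degrees_of_freedom(spec)  # raises if under-identified
    ram = RAM(spec)
    patterns_raw = _as_patterns(data, spec.observed)
    patterns_raw.require_min_observations(2)

    if rescale:
        scales = _variable_scales(spec, patterns_raw)
        try:
            _label_unit_factors(ram, scales)
        except EngineError:
            # an equality constraint ties parameters across variables with
            # different units; rescaling would silently change its meaning
            scales = {v: 1.0 for v, _ in spec.variables}
    else:
        scales = {v: 1.0 for v, _ in spec.variables}
    sfac = np.array([scales[c] for c in patterns_raw.columns])
    patterns = patterns_raw.scaled(sfac)
    # log-density offset from the units change, per observed entry
    counts = patterns_raw.observed_counts()
    ll_offset = -float(np.sum(counts * np.log(sfac)))

    rng = np.random.default_rng(seed)
    start_nat = _start_values(ram, patterns)
    if theta0 is not None:
        # warm start (e.g. an unconstrained parent fit), in input-data units
        unit = _label_unit_factors(ram, scales)
        for k, lab in enumerate(ram.labels):
            if lab in theta0 and np.isfinite(theta0[lab]):
                val = theta0[lab] / unit[k]
                if ram.transforms[k] == "var" and val <= 0:
                    continue
                if ram.transforms[k] == "corr":
                    val = np.clip(val, -0.99, 0.99)
                start_nat[k] = val
    t0 = ram.to_optimizer(start_nat)

    def objective(t):
        theta = ram.from_optimizer(t)
        try:
            ll, grad = ram.loglik_grad(theta, patterns)
        except _NotPD:
            return 1e12, np.zeros_like(t)
        if not np.isfinite(ll):
            return 1e12, np.zeros_like(t)
        return -ll, -grad * ram._jac_nat_wrt_opt(theta)

    results = []
    for s in range(max(1, starts)):
        t_start = t0 if s == 0 else t0 + rng.normal(0.0, 0.1, size=ram.q)
        res = optimize.minimize(
            objective, t_start, jac=True, method="L-BFGS-B",
            options={"maxiter": max_iter, "maxfun": 10 * max_iter,
                     "ftol": 1e-13, "gtol": 1e-8},
        )
        results.append(res)
    lls = [-r.fun for r in results]
    gnorms = [float(np.max(np.abs(r.jac))) for r in results]
    order = sorted(
        range(len(results)),
        key=lambda k: (-round(lls[k], 6), gnorms[k]),
    )
    best = results[order[0]]
    t_hat = best.x
    theta_hat = ram.from_optimizer(t_hat)
    ll_hat, grad_nat = ram.loglik_grad(theta_hat, patterns)
    grad_t = grad_nat * ram._jac_nat_wrt_opt(theta_hat)
    grad_norm = float(np.max(np.abs(grad_t)))
    converged = grad_norm <= tol * max(1.0, abs(ll_hat))
    if not converged:
        warnings.warn(
            f"fit of {spec.name!r} did not reach the gradient tolerance "
            f"(|g|_inf = {grad_norm:.3g}); result flagged",
            RuntimeWarning,
        )

    ll_sat = saturated_loglik(patterns)

    # Heywood screen: variances at (or escaping to) the boundary
    heywood = []
    med_var = float(np.median([c[3].diagonal().mean()
                               for c in patterns.patterns]))
    for k, lab in enumerate(ram.labels):
        if ram.transforms[k] == "var" and theta_hat[k] < 1e-8 * max(med_var, 1e-8):
            heywood.append(lab)

    vcov_scaled = None
    se_scaled = np.full(ram.q, np.nan)
    if compute_se:
        H = _numerical_hessian(ram, theta_hat, patterns)
        info = -H
        try:
            vcov_scaled = np.linalg.inv(info)
        except np.linalg.LinAlgError:
            vcov_scaled = np.linalg.pinv(info)
        vcov_scaled = 0.5 * (vcov_scaled + vcov_scaled.T)
        diag = np.diag(vcov_scaled).copy()
        diag[diag < 0] = np.nan
        se_scaled = np.sqrt(diag)

    unit = _label_unit_factors(ram, scales)
    theta_nat = theta_hat * unit
    se_nat = se_scaled * unit
    vcov_nat = (
        vcov_scaled * np.outer(unit, unit) if vcov_scaled is not None else None
    )

    fit = FitResult(
        spec=spec,
        theta=dict(zip(ram.labels, theta_nat)),
        se=dict(zip(ram.labels, se_nat)),
        loglik=ll_hat + ll_offset,
        loglik_saturated=ll_sat + ll_offset,
        n_used=patterns.n_used,
        n_dropped=patterns.n_dropped,
        converged=converged,
        grad_norm=grad_norm,
        iterations=int(best.nit),
        n_restarts=max(1, starts),
        restart_logliks=[ll + ll_offset for ll in lls],
        heywood=heywood,
        vcov=vcov_nat,
        param_table=None,
        scale_factors=scales,
        _ram=ram,
        _theta_scaled=theta_hat,
        _vcov_scaled=vcov_scaled,
        _patterns=patterns,
    )
    if standardized:
        fit.param_table = standardized_solution(fit)
    return fit


def _numerical_hessian(ram: RAM, theta: np.ndarray,
                       patterns: PatternData, rel_step: float = 1e-4):
    """Observed information by central differences of the analytic
    gradient with respect to the natural parameters."""
    q = ram.q
    H = np.zeros((q, q))
    for k in range(q):
        h = rel_step * max(abs(theta[k]), 1.0)
        tp = theta.copy(); tp[k] += h
        tm = theta.copy(); tm[k] -= h
        try:
            _, gp = ram.loglik_grad(tp, patterns)
            _, gm = ram.loglik_grad(tm, patterns)
        except _NotPD:
            h = h / 16.0
            tp = theta.copy(); tp[k] += h
            tm = theta.copy(); tm[k] -= h
            _, gp = ram.loglik_grad(tp, patterns)
            _, gm = ram.loglik_grad(tm, patterns)
        H[:, k] = (gp - gm) / (2.0 * h)
    return 0.5 * (H + H.T)


# ---------------------------------------------------------------------------
# standardized solution
# ---------------------------------------------------------------------------

def _entry_rows(spec: ModelSpec):
    for (src, dst), e in spec.paths.items():
        yield ("->", src, dst, e)
    for (a, b), e in spec.covs.items():
        yield ("~~", a, b, e)
    for var, e in spec.means.items():
        yield ("mean", var, "", e)


def _std_vector(ram: RAM, theta: np.ndarray) -> np.ndarray:
    """Standardized value for every spec entry (paths: std regression
    coefficient; covariances: correlation; means: mean in SD units)."""
    Sigma, mu, A, S, m, B = ram.moments_full(theta)
    sd = np.sqrt(np.clip(np.diag(Sigma), 1e-300, None))
    vals = []
    for op, a, b, e in _entry_rows(ram.spec):
        if op == "->":
            i, j = ram.index[b], ram.index[a]      # dst, src
            vals.append(A[i, j] * sd[j] / sd[i])
        elif op == "~~":
            i, j = ram.index[a], ram.index[b]
            if i == j:
                vals.append(S[i, i] / Sigma[i, i])  # residual proportion
            else:
                vals.append(S[i, j] / (sd[i] * sd[j]))
        else:
            i = ram.index[a]
            vals.append(mu[i] / sd[i])
    return np.array(vals)


def standardized_solution(fit: FitResult) -> pd.DataFrame:
    """Parameter table with the standardized solution and delta-method
    standard errors (correlation metric for covariances)."""
    ram = fit._ram
    theta = fit._theta_scaled
    std = _std_vector(ram, theta)

    std_se = np.full(std.shape, np.nan)
    if fit._vcov_scaled is not None:
        J = np.zeros((std.size, ram.q))
        for k in range(ram.q):
            h = 1e-5 * max(abs(theta[k]), 1.0)
            tp = theta.copy(); tp[k] += h
            tm = theta.copy(); tm[k] -= h
            J[:, k] = (_std_vector(ram, tp) - _std_vector(ram, tm)) / (2 * h)
        cov_std = J @ fit._vcov_scaled @ J.T
        d = np.diag(cov_std).copy()
        d[d < 0] = np.nan
        std_se = np.sqrt(d)

    rows = []
    for (op, a, b, e), sv, sse in zip(_entry_rows(fit.spec), std, std_se):
        if e.free:
            est = fit.theta[e.label]
            se = fit.se.get(e.label, np.nan)
            z = est / se if se and np.isfinite(se) and se > 0 else np.nan
            p = 2.0 * stats.norm.sf(abs(z)) if np.isfinite(z) else np.nan
        else:
            # report fixed values in data units
            names = ram.var_names
            if op == "->":
                fac = (fit.scale_factors.get(b, 1.0)
                       / fit.scale_factors.get(a, 1.0))
            elif op == "~~":
                fac = (fit.scale_factors.get(a, 1.0)
                       * fit.scale_factors.get(b, 1.0))
            else:
                fac = fit.scale_factors.get(a, 1.0)
            base = e.value if e.scale != "corr" else e.value
            est, se, z, p = base * (1.0 if e.scale == "corr" else fac), np.nan, np.nan, np.nan
            sse = np.nan
        rows.append({
            "label": e.label if e.free else "",
            "lhs": a,
            "op": op,
            "rhs": b,
            "est": est,
            "se": se,
            "z": z,
            "p": p,
            "std_est": sv,
            "std_se": sse,
            "fixed": not e.free,
        })
    return pd.DataFrame(rows)
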