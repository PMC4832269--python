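"""Synthetic two-wave cohort generator.

Emulates the statistical structure of a narrow-age longitudinal ageing
cohort with 12 cognitive tests (three latent domains) and four brain
volumes measured at mean ages 73 and 76.  The generating parameters default
to the printed estimates of the cohort analysis this package emulates:
standardized factor loadings, the age-73 level correlations and wave-to-wave
stabilities, mean annualized changes, and the level-change / change-change
coupling paths.  The generator draws exact multivariate-normal data on the
residualized (sex/age-controlled) scale and adds sex offsets and small
age-in-days effects back, so the full pipeline (control step -> FIML fit)
can be exercised end to end.

Change SDs are not printed anywhere; they are derived here from quantities
that are printed.  For each volume, the wave-to-wave stability s and the
self level-change correlation rho jointly determine the change SD (in
level-SD units u) through

    corr(X1, X1 + D) = (1 + rho*u) / sqrt(1 + u^2 + 2*rho*u) = s,

a quadratic in u with a single positive root.  For the cognitive factors
rho is not printed; their change SDs are set once (see
``GeneratorConfig.cog_change_sd``) and the self level-change covariance is
then solved from the printed stability (the smaller-magnitude root).  The
defaults 0.45/0.50 for memory/speed are the smallest round values for which
the printed stabilities 0.896/0.867 are attainable (a change SD of u bounds
the stability below by sqrt(1 - u^2)).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, special

from . import schema
from .schema import FACTORS, TESTS, VOLUMES, WAVES, col

DAYS_PER_YEAR = 365.25

#: standardized factor loadings (final-model values)
LOADINGS = {
    "matrix_reasoning": 0.651,
    "block_design": 0.672,
    "digit_span_backward": 0.582,
    "letter_number_sequencing": 0.649,
    "logical_memory": 0.629,
    "verbal_paired_associates": 0.572,
    "spatial_span": 0.532,
    "digit_symbol": 0.521,
    "symbol_search": 0.427,
    "simple_rt": 0.509,
    "choice_rt": 0.795,
    "inspection_time": 0.523,
}
CROSS_LOADINGS = {("digit_symbol", "fluid"): 0.316,
                  ("symbol_search", "fluid"): 0.384}

TEST_MEANS_W1 = {
    "matrix_reasoning": 13.17, "block_design": 33.64,
    "digit_span_backward": 7.81, "letter_number_sequencing": 10.91,
    "logical_memory": 74.23, "verbal_paired_associates": 27.18,
    "spatial_span": 14.70, "digit_symbol": 56.40, "symbol_search": 24.61,
    "simple_rt": 0.275, "choice_rt": 0.649, "inspection_time": 111.22,
}
TEST_SDS_W1 = {
    "matrix_reasoning": 4.96, "block_design": 10.08,
    "digit_span_backward": 2.29, "letter_number_sequencing": 3.08,
    "logical_memory": 17.90, "verbal_paired_associates": 9.46,
    "spatial_span": 2.76, "digit_symbol": 12.31, "symbol_search": 6.18,
    "simple_rt": 0.052, "choice_rt": 0.089, "inspection_time": 11.79,
}

#: pooled wave-1 volume moments and per-sex means (cm^3)
VOLUME_MEANS_W1 = {"tbv": 990.32, "gm": 472.43, "nawm": 476.89, "wmh": 12.23}
VOLUME_SDS_W1 = {"tbv": 89.40, "gm": 44.68, "nawm": 50.55, "wmh": 12.18}
VOLUME_MEANS_FEMALE_W1 = {"tbv": 934.62, "gm": 444.57, "nawm": 448.91,
                          "wmh": 12.49}
VOLUME_MEANS_MALE_W1 = {"tbv": 1038.59, "gm": 496.57, "nawm": 501.13,
                        "wmh": 12.00}

#: age-73 correlations (sex/age-controlled), order tbv gm nawm wmh fluid mem spd
_LEVEL_ORDER = ("tbv", "gm", "nawm", "wmh", "fluid", "memory", "speed")
_LEVEL_CORR_LOWER = [
    [1.000, 0, 0, 0, 0, 0, 0],
    [0.877, 1.000, 0, 0, 0, 0, 0],
    [0.863, 0.663, 1.000, 0, 0, 0, 0],
    [0.099, -0.086, -0.264, 1.000, 0, 0, 0],
    [0.301, 0.314, 0.300, -0.152, 1.000, 0, 0],
    [0.225, 0.257, 0.230, -0.172, 0.860, 1.000, 0],
    [0.273, 0.270, 0.336, -0.233, 0.606, 0.588, 1.000],
]

STABILITIES = {"tbv": 0.966, "gm": 0.925, "nawm": 0.949, "wmh": 0.970,
               "fluid": 0.969, "memory": 0.896, "speed": 0.867}

#: printed self level-change correlations of the volumes
VOLUME_SELF_LC = {"tbv": -0.121, "gm": -0.182, "nawm": -0.010, "wmh": 0.596}

#: mean changes across the 3-year study window: volumes in cm^3, cognitive
#: factors in wave-1 factor-SD units (annual rates 0.074/0.058/0.147 x 3)
CHANGE_MEANS = {
    "tbv": -19.12, "gm": -9.28, "nawm": -14.46, "wmh": 4.06,
    "fluid": -0.222, "memory": -0.174, "speed": -0.441,
}

#: cognitive level -> brain change couplings printed in the results
LEVEL_CHANGE_COUPLINGS = {
    ("memory", "tbv"): 0.159, ("speed", "tbv"): 0.159,
    ("fluid", "nawm"): 0.120, ("memory", "nawm"): 0.180,
    ("speed", "nawm"): 0.210,
    ("speed", "wmh"): -0.189,
    # cross-volume level-change entries
    ("gm", "nawm"): -0.062, ("gm", "wmh"): 0.009,
    ("nawm", "gm"): 0.036, ("nawm", "wmh"): -0.102,
    ("wmh", "gm"): -0.121, ("wmh", "nawm"): -0.285,
}

#: change-change couplings; unprinted cognitive pairs use the printed mean
CHANGE_CHANGE_COUPLINGS = {
    ("fluid", "memory"): 0.634, ("fluid", "speed"): 0.634,
    ("memory", "speed"): 0.634,
    ("tbv", "fluid"): 0.188, ("tbv", "memory"): -0.087,
    ("tbv", "speed"): 0.150,
    ("gm", "fluid"): 0.238, ("gm", "memory"): 0.041, ("gm", "speed"): 0.180,
    ("nawm", "fluid"): 0.189, ("nawm", "memory"): -0.054,
    ("nawm", "speed"): 0.200,
    ("wmh", "fluid"): -0.251, ("wmh", "memory"): -0.172,
    ("wmh", "speed"): -0.334,
    ("gm", "nawm"): 0.060, ("gm", "wmh"): -0.140, ("nawm", "wmh"): -0.384,
}

#: small cross-sectional age trends (units per year) used when covariate
#: effects are simulated; chosen to match the longitudinal rates
AGE_SLOPES_PER_YEAR = {
    "tbv": -6.37, "gm": -3.09, "nawm": -4.82, "wmh": 1.35,
    **{t: -0.05 * TEST_SDS_W1[t] for t in TESTS},
}


@dataclass
class GeneratorConfig:
    """Population parameter set of the synthetic cohort.

    All defaults are the printed estimates of the emulated study (see module
    docstring); edits are allowed and the assembled covariance is checked
    for positive definiteness (nearest-PD repair with a logged shrinkage if
    an edit breaks it).
    """

    loadings: dict = field(default_factory=lambda: dict(LOADINGS))
    cross_loadings: dict = field(default_factory=lambda: dict(CROSS_LOADINGS))
    test_means: dict = field(default_factory=lambda: dict(TEST_MEANS_W1))
    test_sds: dict = field(default_factory=lambda: dict(TEST_SDS_W1))
    volume_sds: dict = field(default_factory=lambda: dict(VOLUME_SDS_W1))
    volume_means_female: dict = field(
        default_factory=lambda: dict(VOLUME_MEANS_FEMALE_W1))
    volume_means_male: dict = field(
        default_factory=lambda: dict(VOLUME_MEANS_MALE_W1))
    level_corr: np.ndarray = field(
        default_factory=lambda: _symmetrize(_LEVEL_CORR_LOWER))
    stabilities: dict = field(default_factory=lambda: dict(STABILITIES))
    volume_self_lc: dict = field(default_factory=lambda: dict(VOLUME_SELF_LC))
    cog_change_sd: dict = field(
        default_factory=lambda: {"fluid": 0.25, "memory": 0.45, "speed": 0.50})
    change_means: dict = field(default_factory=lambda: dict(CHANGE_MEANS))
    level_change: dict = field(
        default_factory=lambda: dict(LEVEL_CHANGE_COUPLINGS))
    change_change: dict = field(
        default_factory=lambda: dict(CHANGE_CHANGE_COUPLINGS))
    residual_cross_wave_corr: float = 0.30
    p_male: float = 0.53
    #: logistic dependence of wave-2 dropout on wave-1 cognition
    attrition_cognitive_fraction: float = 0.195
    attrition_imaging_fraction: float = 0.342
    attrition_slope: float = 0.7
    mmse_low_fraction: float = 16 / 697
    dementia_fraction: float = 25 / 697
    #: sex-specific shift added to a coupling correlation for males,
    #: keyed by core-variable pair, e.g. {("speed", "d_tbv"): 0.15}
    sex_coupling_shift: dict = field(default_factory=dict)
    wmh_lognormal: bool = False
    age_slopes_per_year: dict = field(
        default_factory=lambda: dict(AGE_SLOPES_PER_YEAR))
    age_cog_w1_years: tuple = (72.49, 0.71)
    wave_gap_years: tuple = (3.76, 0.25)
    mri_lag_days: dict = field(
        default_factory=lambda: {"w1": (65.0, 40.0), "w2": (40.0, 32.0)})
    seed: int | None = None


def _symmetrize(lower) -> np.ndarray:
    a = np.array(lower, dtype=float)
    return np.tril(a) + np.tril(a, -1).T


def default_config() -> GeneratorConfig:
    return GeneratorConfig()


def zero_coupling_config() -> GeneratorConfig:
    """Config with every cross-variable level-change and change-change
    coupling set to zero (levels stay correlated; each variable keeps its
    own stability structure).  This is the null world for type-I error
    calibration of the coupling tests."""
    cfg = GeneratorConfig()
    cfg.level_change = {
        (a, b): 0.0 for a in CORE_LEVELS for b in CORE_LEVELS if a != b
    }
    cfg.change_change = {
        (a, b): 0.0
        for i, a in enumerate(CORE_LEVELS)
        for b in CORE_LEVELS[i + 1:]
    }
    return cfg


# ---------------------------------------------------------------------------
# core (level + change) moments
# ---------------------------------------------------------------------------

CORE_LEVELS = ("fluid", "memory", "speed", "tbv", "gm", "nawm", "wmh")


def _change_sd_from_stability(s: float, rho: float) -> float:
    """Positive root u of the stability identity (module docstring)."""
    a = s**2 - rho**2
    b = 2.0 * rho * (s**2 - 1.0)
    c = s**2 - 1.0
    disc = b**2 - 4.0 * a * c
    if a <= 0 or disc < 0:
        raise ValueError(f"stability {s} / self coupling {rho} inconsistent")
    return (-b + np.sqrt(disc)) / (2.0 * a)


def _self_lc_from_stability(s: float, u: float) -> float:
    """Self level-change covariance c (level SD 1) solving the stability
    identity at a given change SD; smaller-magnitude root."""
    vd = u**2
    b = 2.0 * (1.0 - s**2)
    c0 = (1.0 - s**2) - s**2 * vd
    disc = b**2 - 4.0 * c0
    if disc < 0:
        raise ValueError(
            f"stability {s} unattainable with change SD {u}; "
            f"needs at least {np.sqrt(1 - s**2):.3f}"
        )
    roots = ((-b + np.sqrt(disc)) / 2.0, (-b - np.sqrt(disc)) / 2.0)
    return min(roots, key=abs)


@dataclass
class CoreMoments:
    """Population moments of the 7 levels and 7 changes."""

    names: list[str]                 # levels then 'd_' changes
    sds: np.ndarray
    corr: np.ndarray                 # 14 x 14, after any PD repair
    means: np.ndarray
    level_sds: dict
    change_sds: dict
    pd_shrinkage: float              # 0 when no repair was needed

    def cov(self) -> np.ndarray:
        return self.corr * np.outer(self.sds, self.sds)

    def index(self, name: str) -> int:
        return self.names.index(name)

    def corr_of(self, a: str, b: str) -> float:
        return float(self.corr[self.index(a), self.index(b)])


def core_moments(config: GeneratorConfig) -> CoreMoments:
    """Assemble the joint distribution of levels and latent changes."""
    k = len(CORE_LEVELS)
    names = list(CORE_LEVELS) + [schema.change(v) for v in CORE_LEVELS]

    # level SDs on the residualized scale: cognitive factors are standard;
    # volumes shed the between-sex mean variance from their pooled SD
    pm = config.p_male
    level_sds = {}
    for v in CORE_LEVELS:
        if v in VOLUMES:
            off = config.volume_means_male[v] - config.volume_means_female[v]
            pooled = config.volume_sds[v] ** 2
            level_sds[v] = float(
                np.sqrt(max(pooled - pm * (1 - pm) * off**2, 1e-6))
            )
        else:
            level_sds[v] = 1.0

    # change SDs and self level-change correlations
    change_sds = {}
    self_lc = {}
    for v in CORE_LEVELS:
        s = config.stabilities[v]
        if v in VOLUMES:
            rho = config.volume_self_lc[v]
            u = _change_sd_from_stability(s, rho)
            change_sds[v] = u * level_sds[v]
            self_lc[v] = rho
        else:
            u = config.cog_change_sd[v]
            c = _self_lc_from_stability(s, u)
            change_sds[v] = u * level_sds[v]
            self_lc[v] = c / u

    # reorder the configured level correlations to the core order
    lc_in = np.asarray(config.level_corr, dtype=float)
    perm = [_LEVEL_ORDER.index(v) for v in CORE_LEVELS]
    R_LL = lc_in[np.ix_(perm, perm)]

    R = np.eye(2 * k)
    R[:k, :k] = R_LL
    R_LD = np.zeros((k, k))          # level i x change j
    R_DD = np.eye(k)
    for i, a in enumerate(CORE_LEVELS):
        R_LD[i, i] = self_lc[a]
        for j, b in enumerate(CORE_LEVELS):
            if (a, b) in config.level_change:
                R_LD[i, j] = config.level_change[(a, b)]
            elif i != j:
                # unprinted cross couplings: a level relates to another
                # variable's change only through that variable's own level
                R_LD[i, j] = R_LL[i, j] * self_lc[b]
    for i, a in enumerate(CORE_LEVELS):
        for j, b in enumerate(CORE_LEVELS):
            if i == j:
                continue
            key = (a, b) if (a, b) in config.change_change else (b, a)
            if key in config.change_change:
                R_DD[i, j] = R_DD[j, i] = config.change_change[key]

    # total-brain entries not printed anywhere are filled by treating the
    # total-brain change as the sum of the tissue changes (covariance scale)
    sds = np.array([level_sds[v] for v in CORE_LEVELS]
                   + [change_sds[v] for v in CORE_LEVELS])
    i_tbv = CORE_LEVELS.index("tbv")
    tissues = [CORE_LEVELS.index(v) for v in ("gm", "nawm", "wmh")]
    C = R.copy()
    C[:k, k:] = R_LD
    C[k:, :k] = R_LD.T
    C[k:, k:] = R_DD
    Cov = C * np.outer(sds, sds)
    def _configured(table, a, b):
        return (a, b) in table or (b, a) in table

    for j, b in enumerate(CORE_LEVELS):
        if b in ("gm", "nawm", "wmh"):
            # change(tbv) x change(tissue): unprinted, filled by the sum
            # proxy unless the user configured the pair explicitly
            if not _configured(config.change_change, "tbv", b):
                cov_dd = sum(Cov[k + t, k + j] for t in tissues)
                R_DD[i_tbv, j] = R_DD[j, i_tbv] = float(
                    cov_dd / (sds[k + i_tbv] * sds[k + j])
                )
            # level(tissue) x change(tbv) and level(tbv) x change(tissue);
            # level_change keys are directed (level, change-of)
            if (b, "tbv") not in config.level_change:
                cov_ld = sum(Cov[j, k + t] for t in tissues)
                R_LD[j, i_tbv] = float(cov_ld / (sds[j] * sds[k + i_tbv]))
            if ("tbv", b) not in config.level_change:
                cov_lt = sum(Cov[k + j, t] for t in tissues)
                R_LD[i_tbv, j] = float(cov_lt / (sds[i_tbv] * sds[k + j]))

    R[:k, k:] = R_LD
    R[k:, :k] = R_LD.T
    R[k:, k:] = R_DD

    R, shrink = _nearest_pd_corr(R)
    means = np.concatenate([
        np.zeros(k)
        + np.array([_level_mean(config, v) for v in CORE_LEVELS]),
        np.array([config.change_means[v] for v in CORE_LEVELS]),
    ])
    return CoreMoments(names, sds, R, means, level_sds, change_sds, shrink)


def _level_mean(config: GeneratorConfig, v: str) -> float:
    if v in VOLUMES:
        pm = config.p_male
        return (pm * config.volume_means_male[v]
                + (1 - pm) * config.volume_means_female[v])
    return 0.0


def _nearest_pd_corr(R: np.ndarray, floor: float = 1e-6,
                     warn_above: float = 0.08):
    """Eigenvalue-clipped nearest correlation matrix; returns the repaired
    matrix and the applied shrinkage (0 if already PD).

    The default (printed) parameter set is itself mildly inconsistent —
    its values come from two separately fitted models plus rounded
    published tables — so a small repair (eigenvalue shift ~0.06) is part
    of normal construction and moves the printed coupling entries by less
    than 0.002; a warning is raised only when an edit pushes the repair
    beyond that regime."""
    R = 0.5 * (R + R.T)
    w, V = np.linalg.eigh(R)
    if w.min() > floor:
        return R, 0.0
    shrink = float(floor - w.min())
    w = np.clip(w, floor, None)
    R2 = V @ np.diag(w) @ V.T
    d = np.sqrt(np.diag(R2))
    R2 = R2 / np.outer(d, d)
    np.fill_diagonal(R2, 1.0)
    if shrink > warn_above:
        warnings.warn(
            f"core correlation matrix repaired to positive definite "
            f"(eigenvalue shift {shrink:.3g}); generating correlations may "
            f"deviate visibly from the configured values", RuntimeWarning,
        )
    return R2, shrink


# ---------------------------------------------------------------------------
# observed-variable moments
# ---------------------------------------------------------------------------

def observed_columns() -> list[str]:
    return ([col(t, w) for w in WAVES for t in TESTS]
            + [col(v, w) for w in WAVES for v in VOLUMES])


def _measurement(config: GeneratorConfig):
    """Raw-scale loadings and residual variances of the 12 tests."""
    factor_of = {t: f for f in FACTORS for t in schema.FACTOR_TESTS[f]}
    lam = {}           # test -> list of (factor, raw loading)
    theta = {}
    lc = np.asarray(config.level_corr, dtype=float)
    for t in TESTS:
        sd = config.test_sds[t]
        rows = [(factor_of[t], config.loadings[t] * sd)]
        if (t, "fluid") in config.cross_loadings and factor_of[t] != "fluid":
            rows.append((
                "fluid", config.cross_loadings[(t, "fluid")] * sd
            ))
        lam[t] = rows
        # communality on the standardized wave-1 scale
        stds = [l / sd for _, l in rows]
        if len(rows) == 1:
            comm = stds[0] ** 2
        else:
            f1, f2 = rows[0][0], rows[1][0]
            r12 = lc[_LEVEL_ORDER.index(f1), _LEVEL_ORDER.index(f2)]
            comm = stds[0] ** 2 + stds[1] ** 2 + 2 * stds[0] * stds[1] * r12
        if comm >= 1.0:
            raise ValueError(f"communality of {t} is >= 1 ({comm:.3f})")
        theta[t] = sd**2 * (1.0 - comm)
    return lam, theta


def population_moments(config: GeneratorConfig | None = None):
    """Exact population covariance and mean of all observed variables on
    the residualized (sex/age-controlled, sexes-pooled) scale.

    This closes the loop with the model specs: at the generating parameter
    point, the latent difference score models imply exactly these moments.
    """
    config = config or GeneratorConfig()
    core = core_moments(config)
    lam, theta = _measurement(config)
    cols = observed_columns()
    k = len(CORE_LEVELS)

    M = np.zeros((len(cols), 2 * k))
    mu = np.zeros(len(cols))
    Sigma_core = core.cov()
    core_mean = core.means.copy()

    pos = {c: i for i, c in enumerate(cols)}
    for w in WAVES:
        at_w2 = w == "w2"
        for t in TESTS:
            i = pos[col(t, w)]
            mu[i] = config.test_means[t]
            for f, l in lam[t]:
                j = core.index(f)
                M[i, j] += l
                if at_w2:
                    jd = core.index(schema.change(f))
                    M[i, jd] += l
                    mu[i] += l * core_mean[jd]
        for v in VOLUMES:
            i = pos[col(v, w)]
            j = core.index(v)
            M[i, j] = 1.0
            mu[i] = core_mean[j]
            if at_w2:
                jd = core.index(schema.change(v))
                M[i, jd] = 1.0
                mu[i] += core_mean[jd]

    Sigma = M @ Sigma_core @ M.T
    rho = config.residual_cross_wave_corr
    for t in TESTS:
        i1, i2 = pos[col(t, "w1")], pos[col(t, "w2")]
        Sigma[i1, i1] += theta[t]
        Sigma[i2, i2] += theta[t]
        Sigma[i1, i2] += rho * theta[t]
        Sigma[i2, i1] += rho * theta[t]

    return (
        pd.DataFrame(Sigma, index=cols, columns=cols),
        pd.Series(mu, index=cols),
    )


# ---------------------------------------------------------------------------
# simulation
# ---------------------------------------------------------------------------

def simulate_cohort(
    config: GeneratorConfig | None = None,
    n: int = 1000,
    seed: int = 0,
    covariate_effects: bool = True,
) -> pd.DataFrame:
    """Draw a synthetic cohort of ``n`` subjects (complete data; apply
    :func:`apply_attrition` for wave-2 dropout).

    Residualized-scale scores are exact multivariate-normal draws from the
    population moments; with ``covariate_effects`` the (centered) sex
    offsets of the volumes and small linear age-in-days trends are added
    back, so the covariate-control step of the pipeline has real work to do.
    """
    if n < 50:
        raise ValueError("n must be at least 50")
    config = config or GeneratorConfig()
    rng = np.random.default_rng(seed)
    core = core_moments(config)
    lam, theta = _measurement(config)
    k = len(CORE_LEVELS)

    male = rng.random(n) < config.p_male

    # core draws; a sex-specific coupling shift re-draws males from a
    # modified covariance
    def _draw(corr: np.ndarray, rows: int) -> np.ndarray:
        cov = corr * np.outer(core.sds, core.sds)
        L = np.linalg.cholesky(cov)
        return rng.standard_normal((rows, 2 * k)) @ L.T + core.means

    if config.sex_coupling_shift:
        corr_m = core.corr.copy()
        for (a, b), shift in config.sex_coupling_shift.items():
            i, j = core.index(a), core.index(b)
            corr_m[i, j] = corr_m[j, i] = np.clip(
                corr_m[i, j] + shift, -0.99, 0.99
            )
        corr_m, _ = _nearest_pd_corr(corr_m)
        draws = np.empty((n, 2 * k))
        draws[~male] = _draw(core.corr, int((~male).sum()))
        draws[male] = _draw(corr_m, int(male.sum()))
    else:
        draws = _draw(core.corr, n)

    core_df = pd.DataFrame(draws, columns=core.names)

    # ages (days)
    m_age, s_age = config.age_cog_w1_years
    age_cog_w1 = rng.normal(m_age, s_age, n) * DAYS_PER_YEAR
    m_gap, s_gap = config.wave_gap_years
    age_cog_w2 = age_cog_w1 + rng.normal(m_gap, s_gap, n) * DAYS_PER_YEAR
    lag1 = rng.normal(*config.mri_lag_days["w1"], n)
    lag2 = rng.normal(*config.mri_lag_days["w2"], n)
    age_mri_w1 = age_cog_w1 + lag1
    age_mri_w2 = age_cog_w2 + lag2

    out = pd.DataFrame({
        schema.ID_COL: np.arange(1, n + 1),
        schema.SEX_COL: male.astype(int),
        "age_days_cog_w1": age_cog_w1,
        "age_days_cog_w2": age_cog_w2,
        "age_days_mri_w1": age_mri_w1,
        "age_days_mri_w2": age_mri_w2,
    })

    # correlated residual pairs per test across waves
    rho = config.residual_cross_wave_corr
    resid = {}
    for t in TESTS:
        th = theta[t]
        cov2 = np.array([[th, rho * th], [rho * th, th]])
        L2 = np.linalg.cholesky(cov2)
        resid[t] = rng.standard_normal((n, 2)) @ L2.T

    for w_i, w in enumerate(WAVES):
        at_w2 = w == "w2"
        for t in TESTS:
            y = np.full(n, config.test_means[t])
            for f, l in lam[t]:
                y = y + l * core_df[f].to_numpy()
                if at_w2:
                    y = y + l * core_df[schema.change(f)].to_numpy()
            y = y + resid[t][:, w_i]
            out[col(t, w)] = y
        for v in VOLUMES:
            y = core_df[v].to_numpy().copy()
            if at_w2:
                y = y + core_df[schema.change(v)].to_numpy()
            out[col(v, w)] = y

    if covariate_effects:
        pm = config.p_male
        sex_c = male.astype(float) - pm
        for v in VOLUMES:
            off = config.volume_means_male[v] - config.volume_means_female[v]
            for w in WAVES:
                out[col(v, w)] += off * sex_c
        for var in list(TESTS) + list(VOLUMES):
            slope = config.age_slopes_per_year.get(var, 0.0) / DAYS_PER_YEAR
            for w in WAVES:
                age = out[schema.age_col_for(var, w)].to_numpy()
                out[col(var, w)] += slope * (age - age.mean())

    if config.wmh_lognormal:
        for w in WAVES:
            out[col("wmh", w)] = _lognormalize(out[col("wmh", w)].to_numpy())

    out[schema.MMSE_COLS["w1"]] = np.nan
    out[schema.MMSE_COLS["w2"]] = np.nan
    out[schema.DEMENTIA_COL] = 0
    return out


def _lognormalize(x: np.ndarray) -> np.ndarray:
    """Moment-matched lognormal marginal (positively skewed volumes)."""
    m, s = x.mean(), x.std()
    z = (x - m) / s
    sigma2 = np.log(1.0 + (s / m) ** 2)
    mu = np.log(m) - sigma2 / 2.0
    return np.exp(mu + np.sqrt(sigma2) * z)


# ---------------------------------------------------------------------------
# attrition and exclusion flags
# ---------------------------------------------------------------------------

def _cognitive_composite(cohort: pd.DataFrame, wave: str = "w1") -> np.ndarray:
    """Mean of the z-scored wave cognitive tests (factor-score proxy)."""
    z = []
    for t in TESTS:
        y = cohort[col(t, wave)].to_numpy(dtype=float)
        z.append((y - np.nanmean(y)) / np.nanstd(y))
    return np.nanmean(np.column_stack(z), axis=1)


def _calibrated_dropout(z: np.ndarray, fraction: float, slope: float,
                        rng: np.random.Generator) -> np.ndarray:
    """Bernoulli dropout with logistic dependence on -z, intercept solved
    so the expected dropout equals the target fraction."""
    if not 0.0 < fraction < 1.0:
        raise ValueError("dropout fraction must lie in (0, 1)")

    def mean_p(a):
        return special.expit(a - slope * z).mean() - fraction

    a = optimize.brentq(mean_p, -30.0, 30.0)
    p = special.expit(a - slope * z)
    return rng.random(len(z)) < p


def apply_attrition(
    cohort: pd.DataFrame,
    mechanism: str = "MAR",
    seed: int = 0,
    config: GeneratorConfig | None = None,
    cognitive_fraction: float | None = None,
    imaging_fraction: float | None = None,
) -> pd.DataFrame:
    """Mask wave-2 entries for dropouts.

    ``MAR`` makes dropout a logistic function of wave-1 cognition (lower
    scorers drop out more, as in the emulated cohort); ``MCAR`` is purely
    random.  Imaging dropout is a superset of cognitive dropout, topped up
    to its own target fraction.
    """
    config = config or GeneratorConfig()
    if cognitive_fraction is None:
        cognitive_fraction = config.attrition_cognitive_fraction
    if imaging_fraction is None:
        imaging_fraction = config.attrition_imaging_fraction
    if cognitive_fraction == 0 and imaging_fraction == 0:
        return cohort.copy()
    mechanism = mechanism.upper()
    if mechanism not in ("MAR", "MCAR"):
        raise ValueError(f"unknown attrition mechanism {mechanism!r}")
    slope = config.attrition_slope if mechanism == "MAR" else 0.0

    out = cohort.copy()
    # distinct stream per operation: reusing the simulation seed verbatim
    # would replay the same uniforms that assigned sex/ages
    rng = np.random.default_rng([seed, 0xA771])
    n = len(out)
    z = _cognitive_composite(out, "w1")

    cog_drop = np.zeros(n, dtype=bool)
    if cognitive_fraction > 0:
        cog_drop = _calibrated_dropout(z, cognitive_fraction, slope, rng)
    img_drop = cog_drop.copy()
    if imaging_fraction > 0:
        extra_target = (imaging_fraction - img_drop.mean()) / max(
            1.0 - img_drop.mean(), 1e-12
        )
        if extra_target > 0:
            rem = ~img_drop
            extra = _calibrated_dropout(
                z[rem], min(extra_target, 0.999), slope, rng
            )
            img_drop[np.where(rem)[0][extra]] = True

    for t in TESTS:
        out.loc[cog_drop, col(t, "w2")] = np.nan
    out.loc[cog_drop, schema.MMSE_COLS["w2"]] = np.nan
    for v in VOLUMES:
        out.loc[img_drop, col(v, "w2")] = np.nan
    return out


def flag_exclusions(
    cohort: pd.DataFrame,
    config: GeneratorConfig | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Fill MMSE scores (with floor/ceiling) and dementia flags.

    A configurable small fraction of subjects scores below the conventional
    screening cutoff of 24 at one or both waves, and dementia flags land
    preferentially on low-cognition subjects.
    """
    config = config or GeneratorConfig()
    out = cohort.copy()
    rng = np.random.default_rng([seed, 0xF1A6])
    n = len(out)

    raw = {}
    for w in WAVES:
        z = _cognitive_composite(out, w)
        z = np.where(np.isnan(z), _cognitive_composite(out, "w1"), z)
        raw[w] = 1.1 * z + rng.normal(0.0, 0.9, n)
    low = np.minimum(raw["w1"], raw["w2"])

    if config.mmse_low_fraction > 0:
        # rounding sends raw values below 23.5 under the cutoff of 24
        shift = 23.5 - np.quantile(low, config.mmse_low_fraction)
    else:
        shift = 24.0 - low.min() + 5.0   # nobody below the cutoff
    for w in WAVES:
        mmse = np.clip(np.round(raw[w] + shift), 0, 30)
        observed = ~np.isnan(out[col(TESTS[0], w)].to_numpy(dtype=float))
        out[schema.MMSE_COLS[w]] = np.where(observed, mmse, np.nan)

    score = _cognitive_composite(out, "w1") + rng.normal(0.0, 1.0, n)
    n_flag = int(round(config.dementia_fraction * n))
    flags = np.zeros(n, dtype=int)
    if n_flag > 0:
        flags[np.argsort(score)[:n_flag]] = 1
    out[schema.DEMENTIA_COL] = flags
    return out


# ---------------------------------------------------------------------------
# generating parameter values for the model specs
# ---------------------------------------------------------------------------

def generating_parameters(config: GeneratorConfig, model: str = "A") -> dict:
    """Value of every free parameter of Model A/B at the generating point
    (input-data units, residualized scale).

    With these values the model-implied moments equal
    :func:`population_moments` restricted to the model's variables; fitting
    the model to a large simulated cohort must recover them.
    """
    from .model import build_model_a, build_model_b

    spec = build_model_a() if model.upper() == "A" else build_model_b()
    core = core_moments(config)
    lam, theta = _measurement(config)
    factor_of = {t: f for f in FACTORS for t in schema.FACTOR_TESTS[f]}
    first = {f: schema.FACTOR_TESTS[f][0] for f in FACTORS}
    lam_first = {
        f: config.loadings[first[f]] * config.test_sds[first[f]]
        for f in FACTORS
    }

    def core_name(v: str) -> str:
        # model variable -> core variable
        if v.startswith("d_"):
            return v
        for f in FACTORS:
            if v == schema.latent(f, "w1"):
                return f
        for vol in VOLUMES:
            if v == col(vol, "w1"):
                return vol
        raise KeyError(v)

    def core_sd(name: str) -> float:
        if name.startswith("d_"):
            return core.change_sds[name[2:]]
        return core.level_sds[name]

    values: dict[str, float] = {}
    for lab in spec.free_labels():
        if lab.startswith("lam_") and "_on_" in lab:
            t = lab[len("lam_"):lab.index("_on_")]
            extra = lab[lab.index("_on_") + 4:]
            raw = config.cross_loadings[(t, extra)] * config.test_sds[t]
            values[lab] = raw / lam_first[extra]
        elif lab.startswith("lam_"):
            t = lab[len("lam_"):]
            f = factor_of[t]
            values[lab] = (config.loadings[t] * config.test_sds[t]
                           / lam_first[f])
        elif lab.startswith("nu_"):
            values[lab] = config.test_means[lab[len("nu_"):]]
        elif lab.startswith("theta_"):
            t = lab[len("theta_"):].rsplit("_", 1)[0]
            values[lab] = theta[t]
        elif lab.startswith("rtheta_"):
            values[lab] = config.residual_cross_wave_corr
        elif lab.startswith("psi_"):
            f = lab[len("psi_"):].rsplit("_", 1)[0]
            values[lab] = lam_first[f] ** 2
        elif lab.startswith("var_d_"):
            v = lab[len("var_d_"):]
            scale = lam_first[v] if v in FACTORS else 1.0
            values[lab] = (core.change_sds[v] * scale) ** 2 \
                if v in FACTORS else core.change_sds[v] ** 2
        elif lab.startswith("alpha_d_"):
            v = lab[len("alpha_d_"):]
            scale = lam_first[v] if v in FACTORS else 1.0
            values[lab] = core.means[core.index(schema.change(v))] * scale
        elif lab.startswith("var_"):
            v = lab[len("var_"):].rsplit("_", 1)[0]
            values[lab] = core.level_sds[v] ** 2
        elif lab.startswith("mu_"):
            v = lab[len("mu_"):].rsplit("_", 1)[0]
            values[lab] = core.means[core.index(v)]
        elif lab.startswith("r_"):
            a, b = lab[len("r_"):].split("__")
            values[lab] = core.corr_of(core_name(a), core_name(b))
        else:
            raise KeyError(f"no generating rule for label {lab!r}")
    return values
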