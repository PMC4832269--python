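"""The synthetic cohort generator: moment construction, simulation,
attrition, and exclusion flags."""

import numpy as np
import pandas as pd
import pytest

from ldsem import (
    GeneratorConfig,
    apply_attrition,
    build_model_a,
    build_model_b,
    flag_exclusions,
    generating_parameters,
    implied_moments,
    population_moments,
    simulate_cohort,
    zero_coupling_config,
)
from ldsem.cohort import (
    CORE_LEVELS,
    STABILITIES,
    VOLUME_SELF_LC,
    _cognitive_composite,
    core_moments,
)
from ldsem.covariates import welch_t
from ldsem.schema import TESTS, col


@pytest.fixture(scope="module")
def core(config):
    return core_moments(config)


class TestCoreMoments:
    def test_covariance_symmetric_positive_definite(self, core):
        C = core.cov()
        np.testing.assert_allclose(C, C.T)
        assert np.linalg.eigvalsh(C).min() > 0

    def test_volume_change_sds_solve_stability_identity(self, config, core):
        """Change SD of each volume is the positive root of the quadratic
        linking stability and the self level-change correlation (root
        recomputed here with an independent polynomial solver)."""
        for v in ("tbv", "gm", "nawm", "wmh"):
            s, rho = STABILITIES[v], VOLUME_SELF_LC[v]
            roots = np.roots([
                s**2 - rho**2, 2 * rho * (s**2 - 1), s**2 - 1
            ])
            u = float(max(roots))
            assert core.change_sds[v] == pytest.approx(
                u * core.level_sds[v], rel=1e-8
            )

    def test_implied_stabilities_match_printed_diagonal(self, core):
        """corr(X_w1, X_w1 + change) reproduces the published wave-to-wave
        stabilities, for volumes and cognitive factors alike."""
        C = core.cov()
        for v in CORE_LEVELS:
            i, j = core.index(v), core.index("d_" + v)
            s = (C[i, i] + C[i, j]) / np.sqrt(
                C[i, i] * (C[i, i] + C[j, j] + 2 * C[i, j])
            )
            assert s == pytest.approx(STABILITIES[v], abs=0.005), v

    def test_printed_couplings_survive_pd_repair(self, core):
        """The nearest-PD repair of the (jointly inconsistent) printed
        parameter set must not move the key printed couplings."""
        assert core.corr_of("d_wmh", "d_speed") == pytest.approx(
            -0.334, abs=0.005
        )
        assert core.corr_of("wmh", "d_wmh") == pytest.approx(0.596, abs=0.005)
        assert core.corr_of("d_fluid", "d_memory") == pytest.approx(
            0.634, abs=0.005
        )
        assert core.pd_shrinkage < 0.08

    def test_zero_coupling_world_is_block_diagonal_in_changes(self):
        cfg = zero_coupling_config()
        c = core_moments(cfg)
        for a in CORE_LEVELS:
            for b in CORE_LEVELS:
                if a != b:
                    assert abs(c.corr_of("d_" + a, "d_" + b)) < 0.02
                    assert abs(c.corr_of(a, "d_" + b)) < 0.02

    def test_infeasible_stability_raises(self):
        cfg = GeneratorConfig()
        cfg.cog_change_sd["memory"] = 0.10   # far below sqrt(1 - 0.896^2)
        with pytest.raises(ValueError, match="unattainable"):
            core_moments(cfg)


class TestPopulationMoments:
    def test_oracle_closure_with_both_models(self, config):
        """Central link: the population moments equal the model-implied
        moments of Models A and B at the generating parameter point."""
        Sigma, mu = population_moments(config)
        for model, build in (("A", build_model_a), ("B", build_model_b)):
            spec = build()
            S2, m2 = implied_moments(spec, generating_parameters(config,
                                                                 model))
            cols = spec.observed
            np.testing.assert_allclose(
                Sigma.loc[cols, cols].to_numpy(), S2.to_numpy(), atol=1e-8
            )
            np.testing.assert_allclose(
                mu.loc[cols].to_numpy(), m2.to_numpy(), atol=1e-8
            )

    def test_wmh_stability_visible_in_observed_moments(self, config):
        Sigma, _ = population_moments(config)
        r = Sigma.loc["wmh_w1", "wmh_w2"] / np.sqrt(
            Sigma.loc["wmh_w1", "wmh_w1"] * Sigma.loc["wmh_w2", "wmh_w2"]
        )
        assert r == pytest.approx(0.970, abs=0.005)

    def test_brain_cognition_blocks_separate_when_decoupled(self):
        cfg = zero_coupling_config()
        k = len(CORE_LEVELS)
        cfg.level_corr = np.eye(7)      # also cut the level correlations
        Sigma, _ = population_moments(cfg)
        vols = [col(v, w) for v in ("tbv", "gm", "nawm", "wmh")
                for w in ("w1", "w2")]
        tests = [c for c in Sigma.columns if c not in vols]
        cross = Sigma.loc[tests, vols].to_numpy()
        assert np.max(np.abs(cross)) < 1e-8

    def test_zero_change_means_reproduce_wave1_means(self, config):
        cfg = GeneratorConfig()
        cfg.change_means = {v: 0.0 for v in cfg.change_means}
        _, mu = population_moments(cfg)
        for t in TESTS:
            assert mu[col(t, "w2")] == pytest.approx(mu[col(t, "w1")])
        for v in ("tbv", "gm", "nawm", "wmh"):
            assert mu[col(v, "w2")] == pytest.approx(mu[col(v, "w1")])

    def test_matches_empirical_moments_of_large_simulation(self, config):
        """Sampled moments of a large cohort (covariate effects off)
        converge on the analytic population moments."""
        Sigma, mu = population_moments(config)
        df = simulate_cohort(config, n=200000, seed=2,
                             covariate_effects=False)
        X = df.loc[:, list(Sigma.columns)]
        emp_cov = X.cov().to_numpy() * (len(X) - 1) / len(X)
        pop = Sigma.to_numpy()
        scale = np.sqrt(np.outer(np.diag(pop), np.diag(pop)))
        assert np.max(np.abs(emp_cov - pop) / scale) < 0.02
        zmu = (X.mean().to_numpy() - mu.to_numpy()) / np.sqrt(np.diag(pop))
        assert np.max(np.abs(zmu)) < 0.02


class TestSimulate:
    def test_sample_tbv_mean_matches_published(self, config):
        df = simulate_cohort(config, n=100000, seed=9)
        assert df["tbv_w1"].mean() == pytest.approx(990.32, rel=0.005)

    def test_seed_reproducibility_bytewise(self, config):
        a = simulate_cohort(config, n=300, seed=123)
        b = simulate_cohort(config, n=300, seed=123)
        pd.testing.assert_frame_equal(a, b)

    def test_minimum_size_enforced(self, config):
        with pytest.raises(ValueError):
            simulate_cohort(config, n=10, seed=0)

    def test_sex_offsets_emerge_in_volumes(self, config):
        df = simulate_cohort(config, n=60000, seed=14)
        gap = (df.loc[df.sex == 1, "tbv_w1"].mean()
               - df.loc[df.sex == 0, "tbv_w1"].mean())
        assert gap == pytest.approx(103.97, abs=3.0)

    def test_lognormal_wmh_marginal_is_skewed(self, config):
        cfg = GeneratorConfig(wmh_lognormal=True)
        df = simulate_cohort(cfg, n=30000, seed=15)
        from scipy import stats
        assert df["wmh_w1"].min() > 0
        assert stats.skew(df["wmh_w1"]) > 0.5


class TestAttrition:
    def test_mcar_dropout_independent_of_cognition(self, config):
        df = simulate_cohort(config, n=10000, seed=21)
        att = apply_attrition(df, "MCAR", seed=21, config=config)
        z = _cognitive_composite(df, "w1")
        drop = att[col(TESTS[0], "w2")].isna().to_numpy()
        assert abs(np.corrcoef(z, drop)[0, 1]) < 0.03

    def test_mar_nonreturners_score_lower_at_wave1(self, config):
        df = simulate_cohort(config, n=10000, seed=22)
        att = apply_attrition(df, "MAR", seed=22, config=config)
        z = _cognitive_composite(df, "w1")
        drop = att[col(TESTS[0], "w2")].isna().to_numpy()
        t, _, p = welch_t(z[~drop], z[drop])
        assert t > 0 and p < 1e-6

    def test_realized_fractions_near_targets(self, config):
        df = simulate_cohort(config, n=8000, seed=23)
        att = apply_attrition(df, "MAR", seed=23, config=config)
        cog = att[col(TESTS[0], "w2")].isna().mean()
        img = att["tbv_w2"].isna().mean()
        assert cog == pytest.approx(0.195, abs=0.02)
        assert img == pytest.approx(0.342, abs=0.02)

    def test_imaging_dropout_superset_of_cognitive(self, config):
        df = simulate_cohort(config, n=4000, seed=24)
        att = apply_attrition(df, "MAR", seed=24, config=config)
        cogdrop = att[col(TESTS[0], "w2")].isna()
        assert att.loc[cogdrop, "tbv_w2"].isna().all()

    def test_zero_fraction_is_identity(self, config):
        df = simulate_cohort(config, n=500, seed=25)
        out = apply_attrition(df, "MAR", seed=25, config=config,
                              cognitive_fraction=0.0, imaging_fraction=0.0)
        pd.testing.assert_frame_equal(out, df)

    def test_invalid_fraction_raises(self, config):
        df = simulate_cohort(config, n=500, seed=26)
        with pytest.raises(ValueError):
            apply_attrition(df, "MAR", seed=26, config=config,
                            cognitive_fraction=1.5)


class TestExclusionFlags:
    def test_default_mmse_fraction_around_two_percent(self, config):
        df = flag_exclusions(simulate_cohort(config, n=20000, seed=31),
                             config, seed=31)
        low = ((df["mmse_w1"] < 24) | (df["mmse_w2"] < 24)).mean()
        assert 0.01 < low < 0.045
        assert df["mmse_w1"].max() <= 30 and df["mmse_w1"].min() >= 0

    def test_zero_fractions_flag_nobody(self, config):
        cfg = GeneratorConfig(mmse_low_fraction=0.0, dementia_fraction=0.0)
        df = flag_exclusions(simulate_cohort(cfg, n=2000, seed=32), cfg,
                             seed=32)
        assert (df["mmse_w1"] >= 24).all()
        assert (df["dementia_diagnosis"] == 0).all()

    def test_flagged_subjects_have_lower_cognition(self, config):
        df = flag_exclusions(simulate_cohort(config, n=20000, seed=33),
                             config, seed=33)
        z = _cognitive_composite(df, "w1")
        dem = df["dementia_diagnosis"] == 1
        assert z[dem].mean() < z.mean() - 0.5
        assert dem.sum() == round(config.dementia_fraction * 20000)


class TestGeneratingParameters:
    @pytest.mark.parametrize("model,build", [
        ("A", build_model_a), ("B", build_model_b),
    ])
    def test_every_free_label_has_a_value(self, config, model, build):
        vals = generating_parameters(config, model)
        assert set(vals) == set(build().free_labels())
        for lab, v in vals.items():
            if lab.startswith("r_"):
                assert -1 < v < 1, lab
            if lab.startswith(("theta_", "psi_", "var_")):
                assert v > 0, lab
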