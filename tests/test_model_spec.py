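"""Construction rules of the latent difference score model specs."""

import numpy as np
import pytest

from ldsem import (
    ModelSpec,
    add_latent_change,
    build_measurement_model,
    build_model_a,
    build_model_b,
    constrain_equal,
    degrees_of_freedom,
    implied_moments,
)
from ldsem.model import ModelSpecError, REFERENCE_DF


def _labels(spec, prefix):
    return [l for l in spec.free_labels() if l.startswith(prefix)]


class TestMeasurementModel:
    def test_invariant_two_wave_counts(self):
        """1 factor, 3 indicators, 2 waves, invariance: 2 shared loadings,
        3 shared intercepts, 6 residual variances."""
        spec = build_measurement_model(
            {"f": ("t1", "t2", "t3")}, invariance=True,
            correlated_uniqueness=False,
        )
        assert len(_labels(spec, "lam_")) == 2
        assert len(_labels(spec, "nu_")) == 3
        assert len(_labels(spec, "theta_")) == 6

    def test_noninvariant_doubles_loadings_and_intercepts(self):
        spec = build_measurement_model(
            {"f": ("t1", "t2", "t3")}, invariance=False,
            correlated_uniqueness=False,
        )
        assert len(_labels(spec, "lam_")) == 4
        assert len(_labels(spec, "nu_")) == 6

    def test_fluid_factor_has_five_free_loadings(self):
        """Four primary indicators (first fixed) plus the two cross-loaded
        speed tests give fluid intelligence five free loadings."""
        spec = build_model_a()
        fluid = [l for l in spec.free_labels()
                 if l in ("lam_block_design", "lam_digit_span_backward",
                          "lam_letter_number_sequencing")
                 or l.endswith("_on_fluid")]
        assert len(fluid) == 5

    def test_single_wave_three_indicator_model_is_saturated(self):
        """9 observed moments, 9 free parameters, df = 0."""
        spec = build_measurement_model(
            {"f": ("t1", "t2", "t3")}, waves=("w1",), factor_covs=False,
        )
        assert spec.n_observed_moments() == 9
        assert degrees_of_freedom(spec) == 0

    def test_too_few_indicators_raises(self):
        with pytest.raises(ModelSpecError, match="not identified"):
            build_measurement_model({"f": ("t1",)})

    def test_unknown_cross_loading_test_raises(self):
        with pytest.raises(ModelSpecError, match="unknown test"):
            build_measurement_model(
                {"f": ("t1", "t2", "t3")}, cross_loadings=[("zz", "f")],
            )


class TestLatentChange:
    def _pair_spec(self):
        spec = ModelSpec()
        spec.add_variable("x_w1")
        spec.add_variable("x_w2")
        spec.add_cov("x_w1", "x_w1", label="v1")
        spec.set_mean("x_w1", label="m1")
        spec.add_cov("x_w2", "x_w2", label="v2")
        spec.set_mean("x_w2", label="m2")
        return spec

    def test_change_decomposition_moment_identities(self):
        spec = add_latent_change(self._pair_spec(), "x_w1", "x_w2", "d_x")
        theta = {"v1": 2.0, "m1": 5.0, "var_d_x": 0.5, "alpha_d_x": -1.0,
                 "r_x_w1__d_x": -0.3}
        Sigma, mu = implied_moments(spec, theta)
        c = -0.3 * np.sqrt(2.0 * 0.5)
        # cov(w1, w2) = var(w1) + cov(w1, change)
        assert Sigma.loc["x_w1", "x_w2"] == pytest.approx(2.0 + c)
        assert Sigma.loc["x_w2", "x_w2"] == pytest.approx(2.0 + 0.5 + 2 * c)
        # mean(w2) = mean(w1) + mean(change)
        assert mu["x_w2"] == pytest.approx(4.0)

    def test_degenerate_change_reproduces_wave1(self):
        spec = add_latent_change(self._pair_spec(), "x_w1", "x_w2", "d_x")
        theta = {"v1": 2.0, "m1": 5.0, "var_d_x": 1e-12, "alpha_d_x": 0.0,
                 "r_x_w1__d_x": 0.0}
        Sigma, mu = implied_moments(spec, theta)
        assert Sigma.loc["x_w2", "x_w2"] == pytest.approx(2.0, rel=1e-6)
        assert mu["x_w2"] == pytest.approx(5.0)

    def test_double_application_raises(self):
        spec = add_latent_change(self._pair_spec(), "x_w1", "x_w2", "d_x")
        with pytest.raises(ModelSpecError):
            add_latent_change(spec, "x_w1", "x_w2", "d_x2")


class TestBuiltModels:
    @pytest.mark.parametrize("build,n_obs,n_moments,n_change", [
        (build_model_a, 26, 377, 4),
        (build_model_b, 30, 495, 6),
    ])
    def test_shape(self, build, n_obs, n_moments, n_change):
        spec = build()
        assert len(spec.observed) == n_obs
        assert spec.n_observed_moments() == n_moments
        changes = [v for v in spec.latents if v.startswith("d_")]
        assert len(changes) == n_change

    def test_degrees_of_freedom_audited_against_reference(self):
        """The built models land one moment away from the reference df of
        the emulated analysis (whose free-parameter inventory is not
        published); the difference is surfaced, not absorbed."""
        df_a = degrees_of_freedom(build_model_a())
        df_b = degrees_of_freedom(build_model_b())
        assert df_a == 277
        assert df_b == 349
        assert df_a - REFERENCE_DF["A"] == 1
        assert df_b - REFERENCE_DF["B"] == 1

    def test_all_coupling_entries_on_correlation_metric(self):
        spec = build_model_b()
        scales = spec.label_scales()
        rs = [l for l in spec.free_labels() if l.startswith("r_")]
        assert len(rs) == 66  # 12 levels+changes choose 2
        assert all(scales[l] == "corr" for l in rs)


class TestConstrainEqual:
    def test_equality_reduces_free_count_by_one(self):
        spec = build_model_a()
        con = constrain_equal(
            spec, ["r_memory_w1__d_tbv", "r_fluid_w1__d_tbv"]
        )
        assert len(con.free_labels()) == len(spec.free_labels()) - 1
        assert degrees_of_freedom(con) == degrees_of_freedom(spec) + 1

    def test_self_constraint_is_noop(self):
        spec = build_model_a()
        con = constrain_equal(spec, ["r_memory_w1__d_tbv"])
        assert con.free_labels() == spec.free_labels()

    def test_unknown_label_raises(self):
        with pytest.raises(ModelSpecError, match="unknown or fixed"):
            constrain_equal(build_model_a(), ["nope"])

    def test_incommensurable_scales_raise(self):
        with pytest.raises(ModelSpecError, match="different scales"):
            constrain_equal(
                build_model_a(), ["r_memory_w1__d_tbv", "var_d_tbv"]
            )

    def test_transitive_sharing(self):
        spec = build_model_a()
        con = constrain_equal(
            spec, ["r_memory_w1__d_tbv", "r_fluid_w1__d_tbv"]
        )
        con = constrain_equal(
            con, ["r_memory_w1__d_tbv", "r_speed_w1__d_tbv"]
        )
        assert len(con.free_labels()) == len(spec.free_labels()) - 2


class TestSerialization:
    @pytest.mark.parametrize("build", [build_model_a, build_model_b])
    def test_yaml_round_trip_exact(self, build):
        spec = build()
        back = ModelSpec.from_yaml(spec.to_yaml())
        assert back.to_dict() == spec.to_dict()
        assert back.free_labels() == spec.free_labels()

    def test_round_trip_preserves_label_sharing(self):
        spec = constrain_equal(
            build_model_a(), ["r_memory_w1__d_tbv", "r_fluid_w1__d_tbv"]
        )
        back = ModelSpec.from_yaml(spec.to_yaml())
        assert len(back.free_labels()) == len(spec.free_labels())
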