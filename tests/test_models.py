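"""Model construction: log-densities, gradients, limits and the basis."""

import numpy as np
import pytest
from scipy import optimize, stats

from lncass.models import (
    GAMConfig,
    GroupStructure,
    RegressionDataset,
    build_flat_model,
    build_gam_basis,
    build_grouped_model,
    build_hierarchical_gam,
    extract_effect_curves,
    INTERCEPT_SD,
    NOISE_SD_SCALE,
)
from lncass.priors import LNCASSHyperparams, sigm
from lncass.synthetic import generate_gam_scene, generate_grouped_regression
from lncass.synthetic import default_scenarios


HYPER = LNCASSHyperparams()


def _all_models():
    cfg = default_scenarios()[0]
    data, truth = generate_grouped_regression(cfg)
    scene = generate_gam_scene(80, 3)
    ydata = RegressionDataset(data.X, (data.y > np.median(data.y)).astype(float),
                              family="binomial")
    return {
        "flat_gaussian": build_flat_model(data, HYPER),
        "flat_binomial": build_flat_model(ydata, HYPER),
        "flat_frozen": build_flat_model(data, HYPER, freeze_lambda=True, noise_sd=1.0),
        "grouped_gaussian": build_grouped_model(data, truth.groups, HYPER),
        "gam": build_hierarchical_gam(scene.data, HYPER, GAMConfig(n_knots=4)),
    }


class TestDatasetValidation:
    def test_rejects_missing_and_shape_errors(self):
        with pytest.raises(ValueError, match="finite"):
            RegressionDataset(np.array([[1.0], [np.nan]]), np.array([0.0, 1.0]))
        with pytest.raises(ValueError, match="length"):
            RegressionDataset(np.ones((3, 2)), np.ones(4))
        with pytest.raises(ValueError, match="0/1"):
            RegressionDataset(np.ones((3, 1)), np.array([0.0, 1.0, 2.0]),
                              family="binomial")
        with pytest.raises(ValueError, match="family"):
            RegressionDataset(np.ones((3, 1)), np.ones(3), family="poisson")

    def test_group_structure_contracts(self):
        gs = GroupStructure(assignment=["a", "a", "b"])
        assert gs.groups == ["a", "b"]
        np.testing.assert_array_equal(gs.member_indices("a"), [0, 1])
        np.testing.assert_array_equal(gs.group_index_of(), [0, 0, 1])
        with pytest.raises(ValueError):
            GroupStructure(assignment=[])

    def test_group_map_csv(self, tmp_path):
        path = tmp_path / "groups.csv"
        path.write_text("predictor_name,group_label\nx0,g1\nx1,g1\nx2,g2\n")
        gs = GroupStructure.from_csv(path, ["x0", "x1", "x2"])
        assert gs.assignment == ["g1", "g1", "g2"]
        with pytest.raises(ValueError, match="x9"):
            GroupStructure.from_csv(path, ["x0", "x9"])


class TestGradients:
    @pytest.mark.parametrize("name", list(_all_models()))
    def test_gradient_matches_finite_differences(self, name):
        model = _all_models()[name]
        rng = np.random.default_rng(sum(map(ord, name)))  # stable per-variant seed
        h = 1e-5
        for _ in range(5):
            x = rng.normal(size=model.dim) * 0.7
            lp, grad = model.logp_and_grad(x)
            assert np.isfinite(lp)
            fd = np.empty(model.dim)
            for i in range(model.dim):
                xp, xm = x.copy(), x.copy()
                xp[i] += h
                xm[i] -= h
                fd[i] = (model.log_density(xp) - model.log_density(xm)) / (2 * h)
            scale = np.maximum(np.abs(fd), 1.0)
            assert np.max(np.abs(grad - fd) / scale) < 1e-4

    def test_log_density_finite_at_origin(self):
        for model in _all_models().values():
            assert np.isfinite(model.log_density(np.zeros(model.dim)))


class TestLikelihoodCorrectness:
    """The joint density decomposes into std-normal priors + the closed-form
    likelihood; both families recomputed independently with scipy."""

    def _joint_oracle_flat(self, model, data, x):
        der = model.coefficient_map(x)
        lp = stats.norm.logpdf(x).sum()
        eta = der["beta0"] + data.X @ der["beta"]
        if data.family == "gaussian":
            sd = der["sigma_eps"]
            zeta = x[model.blocks["noise"].start]
            # swap the generic N(0,1) term for half-normal(sd) + Jacobian
            lp -= stats.norm.logpdf(zeta)
            lp += stats.halfnorm.logpdf(sd, scale=NOISE_SD_SCALE) + zeta
            lp += stats.norm.logpdf(data.y, loc=eta, scale=sd).sum()
        else:
            lp += stats.bernoulli.logpmf(data.y.astype(int), sigm(eta)).sum()
        return lp

    @pytest.mark.parametrize("family", ["gaussian", "binomial"])
    def test_flat_joint_density(self, family):
        rng = np.random.default_rng(8)
        X = rng.normal(size=(30, 3))
        y = rng.normal(size=30) if family == "gaussian" else rng.integers(0, 2, 30).astype(float)
        data = RegressionDataset(X, y, family=family)
        model = build_flat_model(data, HYPER)
        for _ in range(3):
            x = rng.normal(size=model.dim)
            assert model.log_density(x) == pytest.approx(
                self._joint_oracle_flat(model, data, x), abs=1e-8
            )


class TestFlatModel:
    def test_posterior_mode_approaches_ols_on_noiseless_data(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(50, 2))
        beta_true = np.array([1.2, -0.7])
        y = 0.5 + X @ beta_true  # noiseless
        data = RegressionDataset(X, y)
        model = build_flat_model(data, HYPER, freeze_lambda=True, noise_sd=0.05)
        res = optimize.minimize(
            lambda x: -model.log_density(x),
            np.zeros(model.dim),
            jac=lambda x: -model.logp_and_grad(x)[1],
            method="L-BFGS-B",
        )
        der = model.coefficient_map(res.x)
        A = np.column_stack([np.ones(50), X])
        ols = np.linalg.lstsq(A, y, rcond=None)[0]
        np.testing.assert_allclose(der["beta"], ols[1:], atol=0.05)

    def test_invalid_family_combinations(self):
        rng = np.random.default_rng(0)
        bdata = RegressionDataset(rng.normal(size=(10, 2)),
                                  rng.integers(0, 2, 10).astype(float),
                                  family="binomial")
        with pytest.raises(ValueError, match="gaussian"):
            build_flat_model(bdata, HYPER, noise_sd=1.0)


class TestGroupedModel:
    def _model_and_data(self):
        cfg = default_scenarios()[0]
        data, truth = generate_grouped_regression(cfg)
        return build_grouped_model(data, truth.groups, HYPER), truth

    def test_group_gate_zero_excludes_whole_group(self):
        model, truth = self._model_and_data()
        x = np.random.default_rng(1).normal(size=model.dim)
        x[model.blocks["group_gate"]] = -1e3  # lambda_g -> 0
        beta = model.coefficient_map(x)["beta"]
        np.testing.assert_allclose(beta, 0.0, atol=1e-300)

    def test_member_gates_zero_force_shared_coefficient(self):
        model, truth = self._model_and_data()
        x = np.random.default_rng(2).normal(size=model.dim)
        x[model.blocks["member_gate"]] = -1e3  # lambda_gj -> 0
        der = model.coefficient_map(x)
        beta = der["beta"]
        gidx = truth.groups.group_index_of()
        for g in range(truth.groups.n_groups):
            vals = beta[gidx == g]
            np.testing.assert_allclose(vals, vals[0], rtol=1e-12)

    def test_singleton_groups_with_open_gates_reduce_to_flat_form(self):
        """One group per predictor, group gate at 1, shared effect at 0:
        the grouped coefficient map coincides exactly with the flat map
        applied to the member-level latents."""
        rng = np.random.default_rng(3)
        data = RegressionDataset(rng.normal(size=(20, 4)), rng.normal(size=20))
        gs = GroupStructure(assignment=[f"s{j}" for j in range(4)])
        grouped = build_grouped_model(data, gs, HYPER)
        flat = build_flat_model(data, HYPER)
        for _ in range(5):
            u = rng.normal(size=4)
            w = rng.normal(size=4)
            xg = np.zeros(grouped.dim)
            xg[grouped.blocks["group_gate"]] = 1e3  # lambda_g = 1
            xg[grouped.blocks["group_effect"]] = 0.0
            xg[grouped.blocks["member_gate"]] = u
            xg[grouped.blocks["member_dev"]] = w
            xf = np.zeros(flat.dim)
            xf[flat.blocks["gate"]] = u
            xf[flat.blocks["effect"]] = w
            np.testing.assert_allclose(
                grouped.coefficient_map(xg)["beta"],
                flat.coefficient_map(xf)["beta"],
                rtol=1e-12,
            )

    def test_mismatched_group_size_rejected(self):
        rng = np.random.default_rng(0)
        data = RegressionDataset(rng.normal(size=(10, 3)), rng.normal(size=10))
        with pytest.raises(ValueError, match="predictors"):
            build_grouped_model(data, GroupStructure(assignment=["a", "b"]), HYPER)


class TestGAMBasis:
    def test_hinge_vanishes_at_its_own_knot_and_at_zero(self):
        config = GAMConfig(n_knots=3, knot_positions=np.array([0.25, 0.5, 0.75]))
        B = build_gam_basis(np.array([0.0, 0.25, 0.5, 0.75, 1.0]), config)
        assert B.shape == (5, 4)
        np.testing.assert_allclose(B[0], 0.0)  # all basis functions vanish at 0
        assert B[1, 1] == 0.0 and B[2, 2] == 0.0 and B[3, 3] == 0.0

    def test_linear_functions_are_nested(self):
        config = GAMConfig(n_knots=5)
        x = np.linspace(0, 1, 11)
        B = build_gam_basis(x, config)
        coef = np.zeros(6)
        coef[0] = 3.0  # purely linear: all hinge coefficients zero
        np.testing.assert_allclose(B @ coef, 3.0 * x)

    def test_out_of_range_error_names_index(self):
        with pytest.raises(ValueError, match=r"\[2\]"):
            build_gam_basis(np.array([0.5, 0.2, 1.5]), GAMConfig(n_knots=1))

    def test_knot_validation(self):
        with pytest.raises(ValueError, match="increasing"):
            GAMConfig(n_knots=2, knot_positions=np.array([0.5, 0.5]))
        with pytest.raises(ValueError, match="inside"):
            GAMConfig(n_knots=2, knot_positions=np.array([0.0, 0.5]))


class TestHierarchicalGAM:
    def test_gaussian_family_unsupported(self):
        rng = np.random.default_rng(0)
        data = RegressionDataset(rng.random((20, 2)), rng.normal(size=20))
        with pytest.raises(ValueError, match="binomial"):
            build_hierarchical_gam(data, HYPER, GAMConfig())

    def test_gate_limits(self):
        scene = generate_gam_scene(60, 1)
        model = build_hierarchical_gam(scene.data, HYPER, GAMConfig(n_knots=3))
        rng = np.random.default_rng(4)
        x = rng.normal(size=model.dim)
        # lambda_i -> 0 removes covariate i entirely
        x[model.blocks["gate"]] = -1e3
        der = model.coefficient_map(x)
        np.testing.assert_allclose(der["linear_coef"], 0.0, atol=1e-300)
        np.testing.assert_allclose(der["knot_coef"], 0.0, atol=1e-300)
        # lambda_i = 1, lambda_nl -> 0: exactly linear
        x[model.blocks["gate"]] = 1e3
        x[model.blocks["nl_gate"]] = -1e3
        der = model.coefficient_map(x)
        np.testing.assert_allclose(der["knot_coef"], 0.0, atol=1e-300)
        np.testing.assert_allclose(
            der["linear_coef"], HYPER.tau * x[model.blocks["linear"]], rtol=1e-12
        )

    def test_zero_knots_reduces_to_flat_logistic(self):
        scene = generate_gam_scene(60, 2)
        gam = build_hierarchical_gam(scene.data, HYPER, GAMConfig(n_knots=0))
        flat = build_flat_model(scene.data, HYPER)
        assert gam.dim == flat.dim
        rng = np.random.default_rng(6)
        for _ in range(5):
            x = rng.normal(size=flat.dim)
            assert gam.log_density(x) == pytest.approx(flat.log_density(x), abs=1e-9)


class TestEffectCurves:
    def test_curves_are_exact_basis_combinations(self, gam_fit):
        config, samples, _ = gam_fit
        grid = np.linspace(0, 1, 21)
        curves = extract_effect_curves(samples, config, grid)
        Bg = build_gam_basis(grid, config)
        der = samples.derived
        lin = der["linear_coef"].reshape(-1, 10)
        knot = der["knot_coef"].reshape(-1, 10, config.n_knots)
        coef = np.concatenate([lin[:, :, None], knot], axis=2)
        manual = np.einsum("spk,gk->spg", coef, Bg).mean(axis=0)
        np.testing.assert_allclose(curves.mean, manual, rtol=1e-12)
        assert np.all(curves.lower <= curves.upper)

    def test_excluded_covariates_have_flat_curves(self, gam_fit, gam_scene):
        config, samples, summary = gam_fit
        grid = np.linspace(0, 1, 21)
        curves = extract_effect_curves(samples, config, grid)
        amp = np.abs(curves.mean).max(axis=1)
        # null covariates (3..10) all flatter than either signal covariate
        assert amp[2:].max() < min(amp[0], amp[1])

    def test_shape_mismatch_rejected(self, gam_fit):
        config, samples, _ = gam_fit
        with pytest.raises(ValueError, match="knots"):
            extract_effect_curves(samples, GAMConfig(n_knots=2), np.linspace(0, 1, 5))
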