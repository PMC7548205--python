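"""Feature expansion, penalized fitting, transforms, and response curves."""

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize_scalar
from scipy.special import logsumexp

from nicheshift.maxent_engine import (
    FeatureDefinition, FeatureSet, MaxentModel, apply_transform, build_features,
    feature_penalties, fit_maxent, isolated_gain, predict, response_curve,
    sample_background,
)
from nicheshift.occurrence_prep import occurrence_cells
from nicheshift.synthetic_data import (
    SyntheticSpecies, SyntheticWorldConfig, generate_landscape, sample_presences,
    true_suitability,
)


def _table(columns):
    return pd.DataFrame(columns)


class TestFeatures:
    def test_linear_only_counts(self, background):
        fs = build_features(None, ["BIO1", "BIO6"], classes=("linear",),
                            background=background.values)
        assert fs.n_features == 2

    def test_lqp_combinatorics(self, background):
        fs = build_features(
            None, ["BIO1", "BIO6", "BIO8"],
            classes=("linear", "quadratic", "product"),
            background=background.values,
        )
        assert fs.n_features == 3 + 3 + 3

    def test_hinge_endpoints(self):
        bg = _table({"x": np.linspace(0.0, 10.0, 101)})
        fs = build_features(None, ["x"], classes=("hinge",), hinge_knots=4,
                            background=bg)
        fwd = [d for d in fs.definitions if d.feature_class == "hinge_forward"]
        assert fwd, "expected forward hinges"
        j = fs.definitions.index(fwd[0])
        k = fwd[0].knot
        at_knot = fs.evaluate(np.array([[k]]))[0, j]
        at_max = fs.evaluate(np.array([[10.0]]))[0, j]
        assert at_knot == pytest.approx(0.0, abs=1e-12)
        assert at_max == pytest.approx(1.0, abs=1e-12)

    def test_knots_strictly_inside_range(self, background):
        fs = build_features(None, ["BIO1"], classes=("hinge",), hinge_knots=20,
                            background=background.values)
        lo, hi = fs.var_range["BIO1"]
        for d in fs.definitions:
            assert lo < d.knot < hi

    def test_all_features_in_unit_interval(self, background, lq_features):
        F = lq_features.evaluate(background.values)
        assert F.min() >= 0.0 and F.max() <= 1.0

    def test_constant_variable_dropped_with_warning(self):
        bg = _table({"x": np.linspace(0, 1, 50), "c": np.full(50, 3.0)})
        with pytest.warns(UserWarning, match="constant"):
            fs = build_features(None, ["x", "c"], classes=("linear",), background=bg)
        assert fs.variables == ["x"]


class TestBackgroundSampling:
    def test_exhaustive_sample_hits_every_cell(self, grid_factory):
        from nicheshift.grid_io import align_stack

        g = grid_factory(np.arange(25.0).reshape(5, 5), name="A")
        stack = align_stack([g])
        bg = sample_background(stack, 25, seed=0)
        assert sorted(zip(bg.rows, bg.cols)) == [
            (r, c) for r in range(5) for c in range(5)
        ]

    def test_seed_determinism(self, world):
        a = sample_background(world, 100, seed=9)
        b = sample_background(world, 100, seed=9)
        assert np.array_equal(a.rows, b.rows) and np.array_equal(a.cols, b.cols)

    def test_oversized_request_rejected(self, grid_factory):
        from nicheshift.grid_io import align_stack

        stack = align_stack([grid_factory(np.zeros((3, 3)), name="A")])
        with pytest.raises(ValueError, match="background"):
            sample_background(stack, 10, seed=0)

    def test_inclusion_frequency_uniform(self, grid_factory):
        # Monte-Carlo: per-cell inclusion over reseeded draws is binomial
        from nicheshift.grid_io import align_stack

        stack = align_stack([grid_factory(np.zeros((5, 5)), name="A")])
        n_draws, k = 2000, 5
        counts = np.zeros((5, 5))
        for s in range(n_draws):
            bg = sample_background(stack, k, seed=s)
            counts[bg.rows, bg.cols] += 1
        p = k / 25
        se = np.sqrt(n_draws * p * (1 - p))
        assert np.all(np.abs(counts - n_draws * p) < 5 * se)


class TestFitting:
    def test_null_model_gain_near_zero(self, background, lq_features):
        # presences drawn uniformly from background -> nothing to learn
        rng = np.random.default_rng(0)
        idx = rng.choice(background.n, 150, replace=False)
        pres = background.values.iloc[idx]
        _, report = fit_maxent(pres, background.values, lq_features, beta=1.0)
        assert abs(report.gain) < 0.05

    def test_moment_matching_binary_feature_vs_scalar_oracle(self):
        # single binary feature, beta = 0: moment matching drives E_q[f] -> 1
        x_bg = np.concatenate([np.zeros(50), np.ones(50)])
        fs = FeatureSet(
            definitions=[FeatureDefinition("threshold", ("x",), knot=0.5)],
            variables=["x"],
            var_range={"x": (0.0, 1.0)},
            var_mean={"x": 0.5},
            feature_range=np.array([[0.0, 1.0]]),
        )
        pres = np.ones((20, 1))
        model, report = fit_maxent(pres, x_bg[:, None], fs, beta=0.0)
        F_bg = fs.evaluate(x_bg[:, None])[:, 0]
        w = np.exp(F_bg * model.lambdas[0])
        e_q = (w * F_bg).sum() / w.sum()
        assert e_q == pytest.approx(1.0, abs=1e-4)

        # independent 1-D convex-solver oracle on the same instance
        def neg_ll(lam):
            return logsumexp(lam * F_bg) - lam * 1.0

        res = minimize_scalar(neg_ll, bounds=(0, 50), method="bounded",
                              options={"xatol": 1e-10})
        w_o = np.exp(res.x * F_bg)
        e_q_oracle = (w_o * F_bg).sum() / w_o.sum()
        assert e_q == pytest.approx(e_q_oracle, abs=1e-3)

    def test_gain_monotone_in_beta(self, presence_values, background, lq_features):
        gains = []
        for beta in (0.5, 1.0, 2.0, 4.0):
            _, report = fit_maxent(presence_values, background.values,
                                   lq_features, beta=beta)
            gains.append(report.gain)
        assert all(a >= b - 1e-6 for a, b in zip(gains, gains[1:]))

    def test_raw_scores_sum_to_one_over_background(self, fitted, background,
                                                   lq_features):
        model, _ = fitted
        q = model.raw(background.values[lq_features.variables])
        assert q.sum() == pytest.approx(1.0, abs=1e-8)

    def test_entropy_within_bounds(self, fitted, background):
        model, _ = fitted
        assert 0.0 <= model.entropy <= np.log(background.n)

    def test_kkt_contract(self, presence_values, background, lq_features):
        model, report = fit_maxent(presence_values, background.values,
                                   lq_features, beta=1.0)
        F_pres = lq_features.evaluate(presence_values[lq_features.variables])
        F_bg = lq_features.evaluate(background.values[lq_features.variables])
        eta = F_bg @ model.lambdas
        w = np.exp(eta - logsumexp(eta))
        gap = F_bg.T @ w - F_pres.mean(axis=0)
        pen = feature_penalties(F_pres, lq_features.classes(), 1.0,
                                len(presence_values))
        assert np.all(np.abs(gap) <= pen + 1e-6)
        active = np.abs(model.lambdas) > 1e-6
        assert np.all(np.abs(np.abs(gap[active]) - pen[active]) <= 1e-4)

    def test_objective_monotone_decreasing(self, presence_values, background,
                                           lq_features):
        _, report = fit_maxent(presence_values, background.values, lq_features,
                               beta=1.0, track_objective=True)
        path = np.array(report.objective_path)
        assert len(path) > 2
        assert np.all(np.diff(path) <= 1e-9)

    def test_gain_nonnegative_at_optimum(self, fitted):
        _, report = fitted
        assert report.gain >= -1e-9

    def test_adding_feature_class_never_reduces_unpenalized_gain(
        self, presence_values, background
    ):
        gains = []
        for classes in (("linear",), ("linear", "quadratic"),
                        ("linear", "quadratic", "product")):
            fs = build_features(None, ["BIO11", "BIO8"], classes=classes,
                                background=background.values)
            _, report = fit_maxent(presence_values, background.values, fs, beta=0.0)
            gains.append(report.gain)
        assert gains == sorted(gains) or all(
            b >= a - 1e-4 for a, b in zip(gains, gains[1:])
        )

    def test_huge_beta_gives_uniform_model(self, presence_values, background,
                                           lq_features):
        model, report = fit_maxent(presence_values, background.values,
                                   lq_features, beta=1e6)
        assert np.all(model.lambdas == 0.0)
        assert report.gain == pytest.approx(0.0, abs=1e-9)

    def test_serialization_round_trip(self, fitted, background, lq_features):
        model, _ = fitted
        back = MaxentModel.from_json(model.to_json())
        X = background.values[lq_features.variables].iloc[:50]
        assert np.allclose(back.raw(X), model.raw(X), rtol=0, atol=1e-12)


class TestPredictTransforms:
    def test_uniform_model_constant_cloglog(self, world, background, lq_features):
        model = MaxentModel(
            lambdas=np.zeros(lq_features.n_features), feature_set=lq_features,
            log_z=np.log(background.n), entropy=np.log(background.n),
            beta=1.0, n_presence=10,
        )
        g = predict(model, world, transform="cloglog")
        vals = g.values[~g.mask]
        assert np.allclose(vals, vals[0], atol=1e-12)

    def test_logistic_closed_form_one_third(self):
        # q = e^{-H}  ->  tau*1/(1 + tau*1) = 1/3 at tau = 0.5
        out = apply_transform(np.array([np.exp(-2.0)]), "logistic", entropy=2.0)
        assert out[0] == pytest.approx(1.0 / 3.0, abs=1e-12)

    def test_cloglog_hand_formula_five_cells(self, fitted, world):
        model, _ = fitted
        g = predict(model, world, transform="cloglog", clamp=True)
        raws = predict(model, world, transform="raw", clamp=True)
        rows, cols = np.nonzero(~g.mask)
        pick = (rows[:5], cols[:5])
        expected = 1.0 - np.exp(-np.exp(model.entropy) * raws.values[pick])
        assert np.allclose(g.values[pick], expected, atol=1e-12)

    def test_outputs_in_unit_interval(self, fitted, world):
        model, _ = fitted
        for tr in ("logistic", "cloglog"):
            g = predict(model, world, transform=tr)
            vals = g.values[~g.mask]
            assert vals.min() >= 0.0 and vals.max() <= 1.0

    def test_missing_variable_is_schema_error(self, fitted, world):
        model, _ = fitted
        from nicheshift.grid_io import align_stack

        partial = align_stack([world["BIO1"]], scenario_tag="partial")
        with pytest.raises(KeyError):
            predict(model, partial)


class TestIsolatedGain:
    def test_noise_variable_gain_near_zero(self, world, background):
        rng = np.random.default_rng(3)
        idx = rng.choice(background.n, 150, replace=False)
        pres = background.values.iloc[idx]   # presences carry no signal
        g = isolated_gain(world, pres, background, "BIO1", beta=1.0)
        assert abs(g) < 0.1

    def test_generating_variable_ranks_first(self, world, presence_values,
                                             background, species):
        gains = {
            v: isolated_gain(world, presence_values, background, v, beta=1.0)
            for v in world.names
        }
        top = max(gains, key=gains.get)
        assert top in species.true_variables

    def test_gain_invariant_under_affine_rescaling(self, world, presence_values,
                                                   background):
        g1 = isolated_gain(world, presence_values, background, "BIO11",
                           beta=0.0, classes=("linear", "quadratic"))
        scaled_bg = background.values.copy()
        scaled_pres = presence_values.copy()
        scaled_bg["BIO11"] = 3.5 * scaled_bg["BIO11"] - 7.0
        scaled_pres["BIO11"] = 3.5 * scaled_pres["BIO11"] - 7.0
        from dataclasses import replace

        bg2 = replace(background, values=scaled_bg)
        from nicheshift.grid_io import align_stack

        g11 = world["BIO11"]
        stack2 = align_stack(
            [g11.with_values(3.5 * g11.values - 7.0)], scenario_tag="s"
        )
        g2 = isolated_gain(stack2, scaled_pres, bg2, "BIO11",
                           beta=0.0, classes=("linear", "quadratic"))
        assert g2 == pytest.approx(g1, abs=1e-4)


class TestResponseCurve:
    def test_uniform_model_flat_curve(self, lq_features, background):
        model = MaxentModel(
            lambdas=np.zeros(lq_features.n_features), feature_set=lq_features,
            log_z=np.log(background.n), entropy=np.log(background.n),
            beta=1.0, n_presence=10,
        )
        curve = response_curve(model, "BIO11", n_points=40)
        assert len(curve) == 40
        assert curve.suitability.max() - curve.suitability.min() < 1e-12

    def test_negative_linear_weight_monotone_decreasing(self, background):
        fs = build_features(None, ["BIO11"], classes=("linear",),
                            background=background.values)
        model = MaxentModel(
            lambdas=np.array([-2.0]), feature_set=fs, log_z=0.0, entropy=1.0,
            beta=1.0, n_presence=10,
        )
        curve = response_curve(model, "BIO11", n_points=50)
        assert np.all(np.diff(curve.suitability) < 0)

    def test_optimum_recovery_median_within_curve_step(self):
        # pure linear+quadratic truth: fitted optima concentrate on the
        # true optimum; the median error over replicates sits within one
        # curve-resolution step
        ratios = []
        for seed in range(5):
            wc = SyntheticWorldConfig(
                n_rows=100, n_cols=100,
                layer_names=("BIO1", "BIO6", "BIO8", "BIO11", "BIO12", "BIO18"),
                seed=30 + seed,
            )
            stack = generate_landscape(wc)
            sp = SyntheticSpecies(
                responses={"BIO11": ("gaussian", 12.0, 1.5),
                           "BIO8": ("gaussian", 25.0, 1.5)},
                n_presence=500,
            )
            truth = true_suitability(sp, stack)
            occ = sample_presences(truth, 500, seed=seed)
            rows, cols = occurrence_cells(occ, stack.template)
            pres = pd.DataFrame(stack.value_table(rows, cols), columns=stack.names)
            bg = sample_background(stack, 2000, seed=seed + 2)
            fs = build_features(None, ["BIO11", "BIO8"],
                                classes=("linear", "quadratic"),
                                background=bg.values)
            model, _ = fit_maxent(pres, bg.values, fs, beta=1.0)
            for var, opt_true in (("BIO11", 12.0), ("BIO8", 25.0)):
                curve = response_curve(model, var)
                step = curve.value.iloc[1] - curve.value.iloc[0]
                opt = curve.value.iloc[int(curve.suitability.idxmax())]
                ratios.append(abs(opt - opt_true) / step)
        assert np.median(ratios) <= 1.0
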