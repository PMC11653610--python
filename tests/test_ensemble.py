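import numpy as np
import pytest

from densemble.benchmark import MissingSpeciesError, delta_matrix
from densemble.ensemble import (
    EnsembleModel,
    FitConfig,
    NormalizationError,
    fit,
    load_model,
    normalize_weights,
    predict_delta,
    predict_energy,
    predict_forces,
    save_model,
    search_alpha,
)
from densemble.metrics import global_constant
from densemble.synthetic import ErrorSpec, make_benchmark, make_functionals
from tests.conftest import build_benchmark, oracle_ridge, scaled_sse, table_from_deltas


def _scales(benchmark):
    c = global_constant(benchmark)
    return np.array(
        [
            c / benchmark.subsets[benchmark.subset_of(rid)].mean_abs_ref
            for rid in benchmark.reaction_order
        ]
    )


class TestFitConfig:
    def test_defaults_match_documented_settings(self):
        cfg = FitConfig()
        assert cfg.alpha == 10.0
        assert cfg.split_fraction == 0.8
        assert cfg.include_intercept is False
        assert cfg.penalty == "ridge"

    @pytest.mark.parametrize(
        "kwargs", [{"alpha": -1.0}, {"split_fraction": 0.0}, {"split_fraction": 1.0},
                   {"penalty": "elastic"}]
    )
    def test_invalid_configs_rejected(self, kwargs):
        with pytest.raises(ValueError):
            FitConfig(**kwargs)


class TestFit:
    def test_exact_interpolation_unit_vector(self):
        b = build_benchmark({"s1": [1.0, 2.0, -3.0]})
        table = table_from_deltas(
            b, {"F1": [1.0, 2.0, -3.0], "F2": [0.3, -1.0, 4.0]}
        )
        model = fit(b, table, config=FitConfig(alpha=0.0))
        np.testing.assert_allclose(model.weights, [1.0, 0.0], atol=1e-10)

    def test_worked_identity_case(self):
        # Single subset, refs (1, 2): |dE| = 1.5 = C so every row scale is
        # one; delta columns form the 2x2 identity.  alpha = 1 then gives
        # w = (I + I)^-1 y = (0.5, 1.0).
        b = build_benchmark({"s1": [1.0, 2.0]})
        table = table_from_deltas(b, {"F1": [1.0, 0.0], "F2": [0.0, 1.0]})
        model = fit(b, table, config=FitConfig(alpha=1.0))
        np.testing.assert_allclose(model.weights, [0.5, 1.0], atol=1e-10)

    def test_duplicate_columns_share_weight(self):
        b = build_benchmark({"s1": [1.0, 2.0, -1.5]})
        table = table_from_deltas(
            b, {"F1": [0.9, 2.2, -1.0], "F2": [0.9, 2.2, -1.0]}
        )
        model = fit(b, table, config=FitConfig(alpha=2.0))
        assert model.weights[0] == pytest.approx(model.weights[1], abs=1e-10)

    def test_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(11)
        for trial in range(20):
            b = make_benchmark(3, 5, (1.0, 50.0), seed=100 + trial)
            table = make_functionals(
                b, 4, ErrorSpec(systematic_bias=2.0, noise_sd=1.0, seed=trial)
            )
            alpha = float(rng.uniform(0.1, 20.0))
            model = fit(b, table, config=FitConfig(alpha=alpha))
            x = delta_matrix(b, table).to_numpy()
            expected = oracle_ridge(x, b.references(), _scales(b), alpha)
            np.testing.assert_allclose(model.weights, expected, atol=1e-8)

    def test_training_loss_is_unpenalized_scaled_sse(self):
        b = make_benchmark(3, 6, (1.0, 40.0), seed=5)
        table = make_functionals(b, 3, ErrorSpec(noise_sd=2.0, seed=5))
        model = fit(b, table, config=FitConfig(alpha=10.0))
        preds = model.predictions(delta_matrix(b, table, model.functionals))
        assert model.training_loss == pytest.approx(
            scaled_sse(b, preds, global_constant(b))
        )

    def test_alpha_zero_dominates_single_functionals(self):
        b = make_benchmark(4, 8, (1.0, 80.0), seed=9)
        table = make_functionals(
            b, 5, ErrorSpec(systematic_bias=3.0, noise_sd=2.0, seed=9)
        )
        c = global_constant(b)
        dmat = delta_matrix(b, table)
        model = fit(b, table, config=FitConfig(alpha=0.0))
        for func in table.functionals:
            single = dict(zip(dmat.index, dmat[func].astype(float)))
            assert model.training_loss <= scaled_sse(b, single, c) + 1e-9

    def test_adding_functional_never_raises_loss(self):
        b = make_benchmark(4, 8, (1.0, 80.0), seed=13)
        table = make_functionals(
            b, 5, ErrorSpec(systematic_bias=3.0, noise_sd=2.0, seed=13)
        )
        funcs = list(table.functionals)
        losses = [
            fit(b, table, funcs[: k + 1], FitConfig(alpha=0.0)).training_loss
            for k in range(len(funcs))
        ]
        assert all(b <= a + 1e-9 for a, b in zip(losses, losses[1:]))

    def test_monotone_shrinkage(self):
        b = make_benchmark(3, 8, (1.0, 60.0), seed=21)
        table = make_functionals(
            b, 4, ErrorSpec(systematic_bias=2.0, noise_sd=1.0, seed=21)
        )
        alphas = [0.0, 0.5, 2.0, 10.0, 100.0]
        norms = [
            np.linalg.norm(fit(b, table, config=FitConfig(alpha=a)).weights)
            for a in alphas
        ]
        assert all(n2 <= n1 + 1e-12 for n1, n2 in zip(norms, norms[1:]))

    def test_parameter_recovery_as_noise_vanishes(self):
        w_true = (0.6, 0.25, 0.15)
        errors = []
        for noise in (2.0, 0.1, 0.0):
            b = make_benchmark(4, 25, (1.0, 100.0), seed=31)
            table = make_functionals(
                b, 3, ErrorSpec(systematic_bias=5.0, noise_sd=noise,
                                mixture_weights=w_true, seed=31),
            )
            model = fit(b, table, config=FitConfig(alpha=0.0))
            errors.append(np.max(np.abs(model.weights - np.array(w_true))))
        assert errors[2] < 1e-8
        assert errors[2] <= errors[1] <= errors[0]

    def test_rank_deficient_alpha_zero_warns(self, caplog):
        b = build_benchmark({"s1": [1.0, 2.0]})
        table = table_from_deltas(
            b, {"F1": [1.0, 0.5], "F2": [2.0, 1.0], "F3": [0.1, 0.2]}
        )
        with caplog.at_level("WARNING", logger="densemble.ensemble"):
            fit(b, table, config=FitConfig(alpha=0.0))
        assert any("minimum-norm" in rec.message for rec in caplog.records)

    def test_lasso_penalty_mode_runs(self):
        b = make_benchmark(3, 10, (1.0, 50.0), seed=41)
        table = make_functionals(
            b, 4, ErrorSpec(systematic_bias=2.0, noise_sd=1.0, seed=41)
        )
        model = fit(b, table, config=FitConfig(alpha=0.5, penalty="lasso"))
        assert np.isfinite(model.weights).all()


class TestSearchAlpha:
    def test_singleton_grid_returned_unchanged(self, two_subset_benchmark):
        table = table_from_deltas(
            two_subset_benchmark, {"F1": [8.0, -12.0, 30.0, -50.0, 70.0]}
        )
        cfg = search_alpha(
            two_subset_benchmark, table, config=FitConfig(alpha_grid=(10.0,))
        )
        assert cfg.alpha == 10.0

    def test_noiseless_mixture_prefers_least_shrinkage(self):
        b = make_benchmark(4, 10, (1.0, 100.0), seed=51)
        table = make_functionals(
            b, 3, ErrorSpec(systematic_bias=5.0, noise_sd=0.0,
                            mixture_weights=(0.5, 0.3, 0.2), seed=51),
        )
        cfg = search_alpha(
            b, table, config=FitConfig(alpha_grid=(0.001, 1.0, 10.0, 100.0))
        )
        assert cfg.alpha == 0.001

    def test_same_seed_same_choice(self):
        b = make_benchmark(4, 10, (1.0, 100.0), seed=61)
        table = make_functionals(
            b, 4, ErrorSpec(systematic_bias=2.0, noise_sd=3.0, seed=61)
        )
        cfg = FitConfig(alpha_grid=(0.1, 1.0, 10.0), seed=7)
        a1 = search_alpha(b, table, config=cfg).alpha
        a2 = search_alpha(b, table, config=cfg).alpha
        assert a1 == a2

    def test_empty_grid_rejected(self, two_subset_benchmark):
        table = table_from_deltas(
            two_subset_benchmark, {"F1": [8.0, -12.0, 30.0, -50.0, 70.0]}
        )
        with pytest.raises(ValueError):
            search_alpha(two_subset_benchmark, table, config=FitConfig())


class TestNormalizeWeights:
    def test_basic(self):
        np.testing.assert_allclose(
            normalize_weights(np.array([0.3, 0.9])), [0.25, 0.75]
        )

    def test_identity(self):
        np.testing.assert_allclose(normalize_weights(np.array([1.0])), [1.0])

    def test_zero_sum_error(self):
        with pytest.raises(NormalizationError):
            normalize_weights(np.array([0.5, -0.5]))

    def test_sums_to_one(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            w = rng.normal(size=5)
            if abs(w.sum()) < 1e-6:
                continue
            assert normalize_weights(w).sum() == pytest.approx(1.0, abs=1e-12)


def _toy_model(weights):
    w = np.asarray(weights, dtype=float)
    return EnsembleModel(
        functionals=tuple(f"F{i}" for i in range(len(w))),
        weights=w,
        normalized_weights=w / w.sum(),
    )


class TestPredict:
    def test_selector_weights(self):
        model = _toy_model([1.0, 0.0])
        assert predict_energy(model, {"F0": 5.0, "F1": 99.0}) == 5.0

    def test_mean_weights(self):
        model = _toy_model([0.5, 0.5])
        assert predict_energy(model, {"F0": 2.0, "F1": 4.0}) == pytest.approx(3.0)

    def test_size_consistency(self):
        model = _toy_model([0.4, 0.7])
        e_a = {"F0": 1.5, "F1": -2.0}
        e_b = {"F0": 3.0, "F1": 0.5}
        e_ab = {f: e_a[f] + e_b[f] for f in e_a}
        assert predict_energy(model, e_ab) == pytest.approx(
            predict_energy(model, e_a) + predict_energy(model, e_b)
        )

    def test_missing_functional(self):
        with pytest.raises(MissingSpeciesError):
            predict_energy(_toy_model([1.0, 1.0]), {"F0": 1.0})

    def test_delta_equals_species_route(self):
        b = build_benchmark({"s1": [2.0, -1.0]})
        table = table_from_deltas(b, {"F0": [1.5, -0.5], "F1": [2.5, -1.5]})
        model = _toy_model([0.3, 0.8])
        dmat = delta_matrix(b, table)
        for rid in b.reaction_order:
            via_delta = predict_delta(
                model, {f: dmat.at[rid, f] for f in model.functionals}
            )
            # species route: ensemble energy per species, then stoichiometry
            species_energy = {
                sp: predict_energy(
                    model, {f: table.energy(f, sp) for f in model.functionals}
                )
                for sp in b.species
            }
            rx = b.reactions[rid]
            via_species = sum(c * species_energy[s] for s, c in rx.terms)
            assert via_delta == pytest.approx(via_species, abs=1e-10)

    def test_equal_deltas_scale_with_weight_sum(self):
        model = _toy_model([0.4, 0.4])
        assert predict_delta(model, {"F0": 3.0, "F1": 3.0}) == pytest.approx(
            3.0 * 0.8
        )

    def test_zero_weights_give_zero(self):
        model = EnsembleModel(
            ("F0",), np.array([0.0]), np.array([np.nan])
        )
        assert predict_delta(model, {"F0": 123.0}) == 0.0


class TestPredictForces:
    def test_weighted_average(self):
        model = _toy_model([0.5, 0.5])
        f = predict_forces(
            model,
            {"F0": np.array([[1.0, 0.0, 0.0]]), "F1": np.array([[0.0, 1.0, 0.0]])},
        )
        np.testing.assert_allclose(f, [[0.5, 0.5, 0.0]])

    def test_single_functional_identity(self):
        model = _toy_model([1.0])
        arr = np.array([[1.0, -2.0, 3.0], [0.5, 0.0, -1.0]])
        np.testing.assert_array_equal(predict_forces(model, {"F0": arr}), arr)

    def test_shape_mismatch(self):
        model = _toy_model([0.5, 0.5])
        with pytest.raises(ValueError):
            predict_forces(
                model, {"F0": np.zeros((2, 3)), "F1": np.zeros((3, 3))}
            )

    def test_matches_finite_difference_gradient(self):
        # Toy analytic surface: E_i(x) = k_i |x - c_i|^2 per functional,
        # so F_i = -2 k_i (x - c_i).  The ensemble force must equal the
        # negative central difference of the ensemble energy.
        rng = np.random.default_rng(3)
        model = _toy_model([0.6, -0.2, 0.5])
        ks = rng.uniform(0.5, 2.0, size=3)
        centers = rng.normal(size=(3, 2, 3))
        x = rng.normal(size=(2, 3))

        def energies(pos):
            return {
                f"F{i}": ks[i] * np.sum((pos - centers[i]) ** 2) for i in range(3)
            }

        analytic = predict_forces(
            model,
            {f"F{i}": -2.0 * ks[i] * (x - centers[i]) for i in range(3)},
        )
        step = 1e-5
        numeric = np.zeros_like(x)
        for a in range(x.shape[0]):
            for d in range(3):
                xp, xm = x.copy(), x.copy()
                xp[a, d] += step
                xm[a, d] -= step
                numeric[a, d] = -(
                    predict_energy(model, energies(xp))
                    - predict_energy(model, energies(xm))
                ) / (2 * step)
        np.testing.assert_allclose(numeric, analytic, rtol=1e-6, atol=1e-7)


class TestModelSerialization:
    def test_round_trip(self, tmp_path):
        b = make_benchmark(3, 5, (1.0, 30.0), seed=71)
        table = make_functionals(b, 3, ErrorSpec(noise_sd=1.0, seed=71))
        model = fit(b, table)
        path = tmp_path / "model.json"
        save_model(model, path)
        loaded = load_model(path)
        assert loaded.functionals == model.functionals
        np.testing.assert_array_equal(loaded.weights, model.weights)
        np.testing.assert_array_equal(
            loaded.normalized_weights, model.normalized_weights
        )
        assert loaded.config.alpha == model.config.alpha
        assert loaded.training_subsets == model.training_subsets

    def test_normalized_weights_sum_to_one(self):
        b = make_benchmark(3, 5, (1.0, 30.0), seed=81)
        table = make_functionals(b, 4, ErrorSpec(noise_sd=1.0, seed=81))
        model = fit(b, table)
        assert model.normalized_weights.sum() == pytest.approx(1.0, abs=1e-12)
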