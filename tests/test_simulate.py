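"""Synthetic scenarios: parameter counts, sampling laws, regions, recovery."""

import numpy as np
import pytest

from demogen_ga import (
    Dynamics,
    EngineConfig,
    GAConfig,
    LocalSearchConfig,
    bootstrap_cis,
    expected_afs,
    local_optimize,
    make_bootstrap_regions,
    make_scenario,
    model_loglikelihood,
    run_ga,
    simulate_observed_afs,
)
from demogen_ga.model import decode, encode, epoch_dynamics, vector_spec
from demogen_ga.simulate import SCENARIO_NAMES


class TestScenarioDefinitions:
    @pytest.mark.parametrize(
        "name,expected_params,expected_pops",
        [
            ("bottleneck_1pop", 4, 1),
            ("split_mig_2pop", 5, 2),
            ("secondary_contact_3pop", 8, 3),
        ],
    )
    def test_free_parameter_counts(self, name, expected_params, expected_pops):
        sc = make_scenario(name)
        assert len(sc.free_params) == expected_params
        assert len(sc.sample_sizes) == expected_pops
        assert sc.sample_sizes == (20,) * expected_pops  # 20 chromosomes per pop

    def test_free_params_match_encoding(self):
        for name in SCENARIO_NAMES:
            sc = make_scenario(name)
            spec = vector_spec(sc.model.structure, include_dynamics=False)
            labels = [s.label for s in spec]
            vec = encode(sc.model, include_dynamics=False)
            for label, value in sc.free_params.items():
                assert label in labels
                assert vec[labels.index(label)] == pytest.approx(value)

    def test_all_dynamics_sudden(self):
        for name in SCENARIO_NAMES:
            sc = make_scenario(name)
            for dyn in epoch_dynamics(sc.model):
                assert all(d is Dynamics.SUDDEN for d in dyn)

    def test_unknown_name_rejected(self):
        with pytest.raises(ValueError):
            make_scenario("expansion_4pop")

    @pytest.mark.parametrize("name", ["bottleneck_1pop", "split_mig_2pop"])
    def test_marginal_bins_informative(self, name):
        """Every unmasked marginal bin carries at least one expected count
        at the default theta0 = 1000."""
        sc = make_scenario(name)
        fs = expected_afs(sc.model, sc.engine_config())
        for axis in range(fs.counts.ndim):
            other = tuple(a for a in range(fs.counts.ndim) if a != axis)
            marginal = fs.counts.sum(axis=other) if other else fs.counts
            assert np.all(marginal[1:-1] >= 1.0)

    def test_marginal_bins_informative_3pop(self):
        sc = make_scenario("secondary_contact_3pop")
        fs = expected_afs(sc.model, sc.engine_config())
        for axis in range(3):
            other = tuple(a for a in range(3) if a != axis)
            marginal = fs.counts.sum(axis=other)
            assert np.all(marginal[1:-1] >= 1.0)


class TestSimulateObserved:
    def test_expected_mode_is_passthrough(self):
        sc = make_scenario("bottleneck_1pop")
        cfg = sc.engine_config()
        a = simulate_observed_afs(sc.model, cfg, seed=0, mode="expected")
        b = expected_afs(sc.model, cfg)
        np.testing.assert_array_equal(a.counts, b.counts)

    def test_poisson_mode_deterministic(self):
        sc = make_scenario("bottleneck_1pop")
        cfg = sc.engine_config()
        a = simulate_observed_afs(sc.model, cfg, seed=3)
        b = simulate_observed_afs(sc.model, cfg, seed=3)
        np.testing.assert_array_equal(a.counts, b.counts)
        assert np.all(a.counts == np.round(a.counts))  # integer observations

    def test_poisson_mean_matches_expected(self):
        sc = make_scenario("bottleneck_1pop")
        cfg = sc.engine_config(theta0=50.0)
        expected = expected_afs(sc.model, cfg)
        draws = np.stack(
            [
                simulate_observed_afs(sc.model, cfg, seed=s).counts
                for s in range(400)
            ]
        )
        keep = ~expected.mask
        mean = draws.mean(axis=0)[keep]
        se = draws.std(axis=0)[keep] / np.sqrt(draws.shape[0])
        z = (mean - expected.counts[keep]) / np.maximum(se, 1e-12)
        assert np.abs(z).max() < 4.0

    def test_relative_noise_shrinks_at_large_theta(self):
        sc = make_scenario("bottleneck_1pop")
        rel = []
        for theta in (100.0, 10000.0):
            cfg = sc.engine_config(theta0=theta)
            expected = expected_afs(sc.model, cfg)
            obs = simulate_observed_afs(sc.model, cfg, seed=8)
            keep = ~expected.mask & (expected.counts > 0)
            rel.append(
                np.abs(obs.counts[keep] - expected.counts[keep]).max()
                / expected.counts[keep].max()
            )
        assert rel[1] < rel[0]

    def test_bad_mode_rejected(self):
        sc = make_scenario("bottleneck_1pop")
        with pytest.raises(ValueError):
            simulate_observed_afs(sc.model, sc.engine_config(), seed=0, mode="exact")


class TestBootstrapRegions:
    def test_expected_values_partition_full_spectrum(self):
        sc = make_scenario("bottleneck_1pop")
        cfg = sc.engine_config()
        full = expected_afs(sc.model, cfg)
        region_scale = expected_afs(
            sc.model, sc.engine_config(theta0=cfg.theta0 / 10)
        )
        np.testing.assert_allclose(region_scale.counts * 10, full.counts, rtol=1e-10)

    def test_deterministic_and_independent(self):
        sc = make_scenario("bottleneck_1pop")
        cfg = sc.engine_config(theta0=500.0)
        a = make_bootstrap_regions(sc.model, cfg, 6, seed=2)
        b = make_bootstrap_regions(sc.model, cfg, 6, seed=2)
        for ra, rb in zip(a, b):
            np.testing.assert_array_equal(ra.counts, rb.counts)
        # cross-region correlation of one informative entry is near zero
        entries = np.array(
            [
                [r.counts[1] for r in make_bootstrap_regions(sc.model, cfg, 2, seed=s)]
                for s in range(300)
            ]
        )
        corr = np.corrcoef(entries[:, 0], entries[:, 1])[0, 1]
        assert abs(corr) < 0.2

    def test_minimum_two_regions(self):
        sc = make_scenario("bottleneck_1pop")
        with pytest.raises(ValueError):
            make_bootstrap_regions(sc.model, sc.engine_config(), 1, seed=0)


class TestEndToEndRecovery1Pop:
    @pytest.fixture(scope="class")
    def recovery(self):
        """Five GA runs on Poisson data from the bottleneck scenario,
        followed by local search; bootstrap CIs from region spectra."""
        sc = make_scenario("bottleneck_1pop")
        cfg = sc.engine_config()
        data = simulate_observed_afs(sc.model, cfg, seed=13)
        fit_cfg = EngineConfig(sample_sizes=sc.sample_sizes)

        def fitness_for(spectrum):
            def fitness(m):
                try:
                    return model_loglikelihood(m, spectrum, fit_cfg)[0]
                except Exception:
                    return -np.inf

            return fitness

        ga_cfg = GAConfig(stop_after_no_improvement=30, fixed_dynamics=Dynamics.SUDDEN)
        fits = []
        for r in range(5):
            rng = np.random.default_rng([31, r])
            best, _ = run_ga(fitness_for(data), sc.model.structure, ga_cfg, rng)
            refined = local_optimize(best.model, fitness_for(data))
            fits.append((fitness_for(data)(refined), refined))
        fits.sort(key=lambda t: t[0])
        median_model = fits[2][1]

        regions = make_bootstrap_regions(sc.model, cfg, n_regions=20, seed=55)

        def fit_procedure(spectrum):
            refined = local_optimize(median_model, fitness_for(spectrum))
            return encode(refined, include_dynamics=False)

        cis = bootstrap_cis(fit_procedure, regions, n_boot=10, seed=77)
        return sc, median_model, cis, fitness_for(data)

    def test_median_run_parameters_within_bootstrap_band(self, recovery):
        """True parameters lie inside the (log-space, widened to 3 sd)
        bootstrap band of the median run — a sanity calibration rather than
        a strict 1-sd coverage statement, which would fail by construction
        about a third of the time per parameter."""
        sc, median_model, cis, _ = recovery
        spec = vector_spec(sc.model.structure, include_dynamics=False)
        labels = [s.label for s in spec]
        est = np.log(cis["estimate"].to_numpy())
        half = np.log(cis["high"].to_numpy()) - est  # one log-sd
        for label, truth in sc.free_params.items():
            i = labels.index(label)
            assert abs(np.log(truth) - est[i]) <= 3 * max(half[i], 0.05), label

    def test_median_run_loglik_close_to_truth(self, recovery):
        sc, median_model, _, fitness = recovery
        assert fitness(median_model) >= fitness(sc.model) - 1.0


class TestThreePopIdentifiability:
    def test_truth_beats_single_parameter_perturbations(self):
        """Sensitivity check: on noise-free data every free parameter of the
        3-population scenario is locally identified — perturbing any one of
        them by 15% strictly lowers the composite log-likelihood."""
        sc = make_scenario("secondary_contact_3pop")
        cfg = sc.engine_config()
        data = simulate_observed_afs(sc.model, cfg, seed=0, mode="expected")
        fit_cfg = EngineConfig(sample_sizes=sc.sample_sizes)
        ll_true, _ = model_loglikelihood(sc.model, data, fit_cfg)

        spec = vector_spec(sc.model.structure, include_dynamics=False)
        labels = [s.label for s in spec]
        vec = encode(sc.model, include_dynamics=False)
        dynamics = epoch_dynamics(sc.model)
        for label in sc.free_params:
            i = labels.index(label)
            bumped = vec.copy()
            bumped[i] *= 1.15
            # keep shared-size constraints of the scenario in sync
            if label == "e1_nu1":
                bumped[labels.index("e2_nu1")] = bumped[i]
                bumped[labels.index("e3_nu1")] = bumped[i]
            if label == "e2_nu2":
                bumped[labels.index("e3_nu2")] = bumped[i]
            if label == "e2_nu3":
                bumped[labels.index("e3_nu3")] = bumped[i]
            if label == "e3_m12":
                for other in ("e3_m13", "e3_m21", "e3_m23", "e3_m31", "e3_m32"):
                    bumped[labels.index(other)] = bumped[i]
            model = decode(bumped, sc.model.structure, dynamics=dynamics)
            ll, _ = model_loglikelihood(model, data, fit_cfg)
            assert ll < ll_true - 0.5, label


class TestFreeDynamicsAmbiguity:
    def test_exponential_bottleneck_nearly_matches_sudden(self):
        """The classic AFS non-identifiability: an exponential-decline
        history can fit a sudden-bottleneck spectrum almost equally well."""
        sc = make_scenario("bottleneck_1pop")
        cfg = sc.engine_config()
        data = simulate_observed_afs(sc.model, cfg, seed=13)
        fit_cfg = EngineConfig(sample_sizes=sc.sample_sizes)

        def fitness(m):
            try:
                return model_loglikelihood(m, data, fit_cfg)[0]
            except Exception:
                return -np.inf

        sudden_fit = local_optimize(sc.model, fitness)
        ll_sudden = fitness(sudden_fit)

        # a short GA restricted to exponential dynamics finds a history
        # whose likelihood is within one unit of the sudden optimum
        ll_exp = -np.inf
        for r in range(3):
            rng = np.random.default_rng([91, r])
            best, _ = run_ga(
                fitness,
                sc.model.structure,
                GAConfig(
                    stop_after_no_improvement=30,
                    fixed_dynamics=Dynamics.EXPONENTIAL,
                ),
                rng,
            )
            refined = local_optimize(best.model, fitness)
            ll_exp = max(ll_exp, fitness(refined))
        assert abs(ll_sudden - ll_exp) < 1.0
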