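import numpy as np
import pytest

from esdm.grids import CovariateStack, GridSpec, Layer
from esdm.occurrences import deduplicate_occurrences
from esdm.synthetic import (
    RecoveryConfig,
    SyntheticLandscape,
    define_virtual_species,
    generate_landscape,
    load_table1,
    recovery_experiment,
    sample_occurrences,
)


class TestGenerateLandscape:
    def test_same_seed_bit_identical(self):
        a = generate_landscape(seed=3)
        b = generate_landscape(seed=3)
        for la, lb in zip(a.stack.layers, b.stack.layers):
            np.testing.assert_array_equal(la.values, lb.values)

    def test_layers_standardized(self, landscape):
        for layer in landscape.stack.layers:
            if layer.kind != "continuous":
                continue
            assert abs(layer.values.mean()) < 0.02
            assert abs(layer.values.std() - 1.0) < 0.02

    def test_no_smoothing_is_near_white_noise(self):
        land = generate_landscape(smoothing_length=0.0, seed=4)
        v = land.stack.layers[0].values
        lag1 = np.corrcoef(v[:, :-1].ravel(), v[:, 1:].ravel())[0, 1]
        assert abs(lag1) < 0.2

    def test_smoothing_induces_autocorrelation(self, landscape):
        v = landscape.stack.layers[0].values
        lag1 = np.corrcoef(v[:, :-1].ravel(), v[:, 1:].ravel())[0, 1]
        assert lag1 > 0.8

    def test_independent_layers_weakly_correlated(self, landscape):
        names = landscape.continuous_names
        for i in range(len(names)):
            for j in range(i + 1, len(names)):
                r = np.corrcoef(
                    landscape.stack.get_layer(names[i]).values.ravel(),
                    landscape.stack.get_layer(names[j]).values.ravel(),
                )[0, 1]
                assert abs(r) < 0.5

    def test_categorical_layer_codes(self, landscape):
        lc = landscape.stack.get_layer("landcover")
        assert lc.kind == "categorical"
        assert set(np.unique(lc.values)) == {0.0, 1.0, 2.0, 3.0}

    def test_dimension_validation(self):
        with pytest.raises(ValueError):
            generate_landscape(n_rows=10)
        with pytest.raises(ValueError):
            generate_landscape(k_continuous=1)


class TestDefineVirtualSpecies:
    def test_inert_species_constant_suitability(self, landscape):
        sp = define_virtual_species(landscape, ["env1"], [0.0],
                                    prevalence_target=0.3)
        valid = landscape.stack.valid_mask
        np.testing.assert_allclose(sp.true_suitability[valid], 0.3, atol=1e-6)

    def test_prevalence_calibration_within_tolerance(self, landscape):
        for target in (0.05, 0.1, 0.4):
            sp = define_virtual_species(landscape, ["env1", "env2"], [4.0, -2.0],
                                        prevalence_target=target)
            valid = landscape.stack.valid_mask
            assert abs(np.nanmean(sp.true_suitability[valid]) - target) < 0.01

    def test_symmetric_covariate_half_prevalence_zero_intercept(self):
        grid = GridSpec(20, 20, 0.0, 2.0, 0.1)
        sym = np.linspace(-1, 1, 400).reshape(grid.shape)
        land = SyntheticLandscape(
            stack=CovariateStack(grid, [Layer("env1", sym), Layer("env2", sym.T)]),
            seed=0,
        )
        sp = define_virtual_species(land, ["env1"], [3.0], prevalence_target=0.5)
        assert abs(sp.beta0) < 1e-3

    def test_doubling_beta_increases_suitability_spread(self, landscape):
        s1 = define_virtual_species(landscape, ["env1"], [2.0])
        s2 = define_virtual_species(landscape, ["env1"], [4.0])
        assert np.nanstd(s2.true_suitability) > np.nanstd(s1.true_suitability)

    def test_driver_property_and_validation(self, landscape):
        sp = define_virtual_species(landscape, ["env1", "env2"], [1.0, -5.0])
        assert sp.driver == "env2"
        with pytest.raises(ValueError, match="active layers"):
            define_virtual_species(landscape, ["nope"], [1.0])
        with pytest.raises(ValueError, match="effect size"):
            define_virtual_species(landscape, ["env1"], [1.0, 2.0])

    def test_unimodal_response_peaks_at_covariate_mean(self, landscape):
        sp = define_virtual_species(landscape, ["env1"], [3.0], response="gaussian",
                                    prevalence_target=0.2)
        x = landscape.stack.get_layer("env1").values
        near = np.abs(x) < 0.1
        far = np.abs(x) > 2.0
        assert np.nanmean(sp.true_suitability[near]) > np.nanmean(sp.true_suitability[far])


class TestSampleOccurrences:
    def test_sampling_favors_suitable_cells(self, landscape):
        sp = define_virtual_species(landscape, ["env1"], [6.0])
        valid = landscape.stack.valid_mask
        land_mean = float(np.nanmean(sp.true_suitability[valid]))
        means = []
        for seed in range(30):
            occ = sample_occurrences(sp, 30, seed=seed)
            cells = deduplicate_occurrences(occ, landscape.grid)[sp.name]
            rows, cols = zip(*cells)
            means.append(float(np.mean(sp.true_suitability[list(rows), list(cols)])))
        assert np.mean(means) > land_mean

    def test_duplicates_roundtrip_through_dedup(self, landscape):
        sp = define_virtual_species(landscape, ["env1"], [6.0])
        occ = sample_occurrences(sp, 43, seed=1, n_duplicates=91)
        assert len(occ) == 134
        cells = deduplicate_occurrences(occ, landscape.grid)[sp.name]
        assert len(cells) == 43

    def test_concentrated_suitability_always_sampled(self):
        from esdm.synthetic import VirtualSpecies

        grid = GridSpec(20, 20, 0.0, 2.0, 0.1)
        x = np.zeros(grid.shape)
        land = SyntheticLandscape(
            stack=CovariateStack(grid, [Layer("env1", x), Layer("env2", x)]),
            seed=0)
        suit = np.zeros(grid.shape)
        suit[7, 7] = 1.0
        sp = VirtualSpecies(name="point", landscape=land, beta0=0.0, betas={},
                            true_suitability=suit, prevalence_target=1 / 400)
        for seed in range(5):
            occ = sample_occurrences(sp, 1, seed=seed)
            assert deduplicate_occurrences(occ, grid)[sp.name] == {(7, 7)}

    def test_too_many_presences_rejected(self, landscape):
        sp = define_virtual_species(landscape, ["env1"], [6.0])
        with pytest.raises(ValueError, match="cannot sample"):
            sample_occurrences(sp, 10**6, seed=0)


class TestTable1Fixture:
    def test_totals_and_shape(self):
        table = load_table1()
        assert len(table) == 15
        assert int(table["total_observations"].sum()) == 621
        row = table.set_index("species").loc["Friersonia iridella"]
        assert int(row["total_observations"]) == 134
        assert int(row["unique_observations"]) == 43


class TestRecoveryExperiment:
    def test_small_run_recovers_drivers_and_conserves_richness(self):
        config = RecoveryConfig(
            n_species=3, n_presences=30, n_replicates=6,
            families=["GLM", "MAXENT", "CART"], n_rows=60, n_cols=60,
            n_permutations=3,
        )
        report = recovery_experiment(config, seed=2)
        df = report["species"]
        assert len(df) == 3
        assert df["ensemble_auc"].min() > 0.7
        assert df["driver_ranked_first"].all()
        assert report["richness_conserved"]
        assert report["richness_mae"] >= 0.0
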