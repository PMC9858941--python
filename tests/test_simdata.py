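"""Synthetic-data generator: THI utility, genotypes, pseudo-phenotypes."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import thigblup as tg
from thigblup.simdata import true_allele_frequencies

ENV1, ENV2 = tg.DEFAULT_ENV_LABELS


class TestComputeTHI:
    @pytest.mark.parametrize(
        "temp,rh,expected",
        [
            (20.0, 100.0, 68.0),        # humidity factor cancels: 1.8*20+32
            (25.0, 50.0, 71.775),       # 77 - 0.275*19
            (30.0, 70.0, 81.38),        # 86 - 0.165*28
        ],
    )
    def test_hand_values(self, temp, rh, expected):
        assert tg.compute_thi(temp, rh) == pytest.approx(expected, abs=1e-12)

    @pytest.mark.parametrize("rh", [-0.1, 100.1, 150.0])
    def test_humidity_domain(self, rh):
        with pytest.raises(ValueError):
            tg.compute_thi(25.0, rh)

    @settings(max_examples=50, deadline=None)
    @given(temp=st.floats(-30, 50), rh=st.floats(0, 100))
    def test_saturated_air_reduces_to_dry_bulb_line(self, temp, rh):
        # at rh=100 the humidity factor vanishes; generally THI is linear in rh
        full = tg.compute_thi(temp, 100.0)
        assert full == pytest.approx(1.8 * temp + 32.0, abs=1e-9)
        assert np.isfinite(tg.compute_thi(temp, rh))

    def test_array_input(self):
        out = tg.compute_thi(np.array([20.0, 25.0]), np.array([100.0, 50.0]))
        np.testing.assert_allclose(out, [68.0, 71.775])


class TestConfigValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"maf_low": 0.0},
            {"maf_low": 0.3, "maf_high": 0.2},
            {"maf_high": 0.6},
            {"missing_rate": 1.0},
            {"genetic_corr": 1.5},
            {"env_variances": (-1.0, 1.0)},
            {"n_animals": 1},
            {"n_markers": 0},
        ],
    )
    def test_invalid_configs_rejected(self, kwargs):
        with pytest.raises(ValueError):
            tg.SimulationConfig(**kwargs)


class TestSimulateGenotypes:
    def test_complete_calls_and_dosage_alphabet(self):
        cfg = tg.SimulationConfig(n_animals=100, n_markers=500, missing_rate=0.0, seed=1)
        g = tg.simulate_genotypes(cfg)
        assert not g.has_missing()
        assert set(np.unique(g.dosages)) <= {0.0, 1.0, 2.0}

    def test_pooled_frequency_matches_target(self):
        # p fixed at 0.5: pooled empirical frequency within 3 binomial SEs
        cfg = tg.SimulationConfig(
            n_animals=1000, n_markers=200, maf_low=0.5, maf_high=0.5, seed=2
        )
        g = tg.simulate_genotypes(cfg)
        p_hat = g.dosages.mean() / 2.0
        se = np.sqrt(0.5 * 0.5 / (2 * 1000 * 200))
        assert abs(p_hat - 0.5) < 3 * se

    def test_seed_reproducibility(self):
        cfg = tg.SimulationConfig(n_animals=50, n_markers=100, missing_rate=0.1, seed=7)
        g1 = tg.simulate_genotypes(cfg)
        g2 = tg.simulate_genotypes(cfg)
        np.testing.assert_array_equal(g1.dosages, g2.dosages)
        pd.testing.assert_frame_equal(g1.marker_map, g2.marker_map)

    def test_missingness_rate(self):
        cfg = tg.SimulationConfig(n_animals=200, n_markers=300, missing_rate=0.2, seed=4)
        g = tg.simulate_genotypes(cfg)
        assert np.isnan(g.dosages).mean() == pytest.approx(0.2, abs=0.01)

    def test_map_positions_increase_within_chromosome(self):
        cfg = tg.SimulationConfig(n_animals=5, n_markers=100, n_chromosomes=7, seed=0)
        g = tg.simulate_genotypes(cfg)
        for _, sub in g.marker_map.groupby("chromosome"):
            pos = sub["position"].to_numpy()
            assert (np.diff(pos) > 0).all()
            assert (pos >= 1).all()
        assert set(g.marker_map["chromosome"]) == {str(c) for c in range(1, 8)}

    def test_true_frequencies_match_generator(self):
        cfg = tg.SimulationConfig(n_animals=2000, n_markers=50, seed=9)
        g = tg.simulate_genotypes(cfg)
        p_true = true_allele_frequencies(cfg).p
        p_obs = g.dosages.mean(axis=0) / 2.0
        assert np.abs(p_true - p_obs).max() < 0.05


class TestSimulatePseudoPhenotypes:
    def test_default_scale_matches_study_summary(self):
        # milk-yield-like defaults: THI59 mean 1.13, SD 2.13 at n=1013
        cfg = tg.SimulationConfig(n_markers=800, seed=12)
        g = tg.simulate_genotypes(cfg)
        pheno, _ = tg.simulate_pseudo_phenotypes(g, cfg)
        wide = pheno.pivot()
        se_mean = 2.13 / np.sqrt(1013)
        assert wide[ENV1].mean() == pytest.approx(1.13, abs=4 * se_mean)
        assert wide[ENV1].std() == pytest.approx(2.13, rel=0.10)
        assert wide[ENV2].mean() == pytest.approx(1.00, abs=4 * se_mean)
        assert wide[ENV2].std() == pytest.approx(2.01, rel=0.10)

    def test_unit_correlation_gives_identical_environments_up_to_means(self):
        cfg = tg.SimulationConfig(
            n_animals=50, n_markers=200, seed=5, genetic_corr=1.0,
            env_variances=(1.0, 1.0), noise_variances=(0.0, 0.0),
            trait_mean=(2.0, -1.0),
        )
        g = tg.simulate_genotypes(cfg)
        pheno, truth = tg.simulate_pseudo_phenotypes(g, cfg)
        wide = pheno.pivot()
        np.testing.assert_allclose(
            wide[ENV1] - 2.0, wide[ENV2] + 1.0, atol=1e-10
        )
        np.testing.assert_allclose(truth.effects[:, 0], truth.effects[:, 1])

    def test_zero_genetic_variance_leaves_noise_only(self):
        cfg = tg.SimulationConfig(
            n_animals=2000, n_markers=100, seed=6, env_variances=(0.0, 0.0),
            noise_variances=(2.0, 0.5), trait_mean=(0.0, 0.0),
        )
        g = tg.simulate_genotypes(cfg)
        pheno, truth = tg.simulate_pseudo_phenotypes(g, cfg)
        wide = pheno.pivot()
        assert np.all(truth.effects == 0.0)
        assert wide[ENV1].var() == pytest.approx(2.0, rel=0.10)
        assert wide[ENV2].var() == pytest.approx(0.5, rel=0.10)

    @pytest.mark.parametrize("rg", [-0.5, 0.0, 0.6, 0.95])
    def test_effect_pair_correlation_converges(self, rg):
        cfg = tg.SimulationConfig(
            n_animals=10, n_markers=10_000, seed=8, genetic_corr=rg,
            env_variances=(1.0, 2.0), noise_variances=(0.1, 0.1),
        )
        g = tg.simulate_genotypes(cfg)
        _, truth = tg.simulate_pseudo_phenotypes(g, cfg)
        r = np.corrcoef(truth.effects[:, 0], truth.effects[:, 1])[0, 1]
        assert abs(r - rg) < 0.05

    def test_phenotypic_variance_decomposition(self):
        cfg = tg.SimulationConfig(
            n_animals=1500, n_markers=400, seed=10,
            env_variances=(1.2, 0.8), noise_variances=(0.3, 0.6),
            trait_mean=(0.0, 0.0), genetic_corr=0.5,
        )
        g = tg.simulate_genotypes(cfg)
        pheno, _ = tg.simulate_pseudo_phenotypes(g, cfg)
        wide = pheno.pivot()
        assert wide[ENV1].var() == pytest.approx(1.5, rel=0.10)
        assert wide[ENV2].var() == pytest.approx(1.4, rel=0.10)

    def test_seed_determinism(self):
        cfg = tg.SimulationConfig(n_animals=40, n_markers=80, seed=13)
        g = tg.simulate_genotypes(cfg)
        p1, t1 = tg.simulate_pseudo_phenotypes(g, cfg)
        p2, t2 = tg.simulate_pseudo_phenotypes(g, cfg)
        pd.testing.assert_frame_equal(p1.data, p2.data)
        np.testing.assert_array_equal(t1.effects, t2.effects)
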