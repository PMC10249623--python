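"""Forward simulators: round trips, artifact injection, determinism."""

import math

import numpy as np
import pandas as pd
import pytest

import kawcycle as kc
from kawcycle.artifacts import DropletModel
from kawcycle.exceptions import InvalidInputError, UnderDeterminedError
from kawcycle.simulate import SHARED_SYSTEM


class TestBatchSimulator:
    def test_zero_noise_round_trip(self):
        config = kc.SimulationConfig(true_log_k=2.3, seed=0)
        df = kc.simulate_batch(config)
        for c_w in df["c_water"]:
            k = kc.batch_k_from_water_conc(config.system, c_w)
            assert math.log10(k) == pytest.approx(2.3, abs=1e-9)

    def test_droplet_contamination_matches_closed_form(self):
        """Simulated contamination reproduces the apparent-K model."""
        config = kc.SimulationConfig(true_log_k=4.93, droplet_f=6e-5, seed=0)
        df = kc.simulate_batch(config)
        k_app = kc.batch_k_from_water_conc(config.system, df["c_water"][0])
        closed = kc.apparent_log_k_droplet(4.93, DropletModel(6e-5))
        assert math.log10(k_app) == pytest.approx(closed, abs=0.01)
        assert math.log10(k_app) == pytest.approx(4.14, abs=0.01)

    def test_replicate_sd_matches_delta_method(self):
        """At log K ~ 1 with 5% noise the log-scale replicate SD is
        ~cv/ln10 * |dlogK/dlogC| ~ 0.02-0.03."""
        logs = []
        for seed in range(40):
            config = kc.SimulationConfig(true_log_k=1.0, noise_cv=0.05,
                                         seed=seed, n_replicates=5)
            df = kc.simulate_batch(config)
            logs += [math.log10(kc.batch_k_from_water_conc(config.system, c))
                     for c in df["c_water"]]
        sd = np.std(logs, ddof=1)
        # dlog10K/dlog10Cw = -(1 + Vw/(K*Vhxd)) = -1.1 at K=10, Vw=Vhxd
        expected = 0.05 / math.log(10) * 1.1
        assert sd == pytest.approx(expected, rel=0.25)

    def test_identical_seeds_identical_tables(self):
        a = kc.simulate_batch(kc.SimulationConfig(true_log_k=1.0,
                                                  noise_cv=0.1, seed=42))
        b = kc.simulate_batch(kc.SimulationConfig(true_log_k=1.0,
                                                  noise_cv=0.1, seed=42))
        pd.testing.assert_frame_equal(a, b)

    def test_mass_conserved_across_phases(self):
        config = kc.SimulationConfig(true_log_k=2.0, seed=0)
        df = kc.simulate_batch(config)
        sysm = config.system
        total = (df["c_water"][0] * sysm.v_water
                 + df["c_hxd"][0] * sysm.v_hxd)
        assert total == pytest.approx(sysm.mass, abs=1e-12)

    def test_invalid_config_rejected(self):
        with pytest.raises(InvalidInputError):
            kc.SimulationConfig(true_log_k=1.0, noise_cv=-0.1)
        with pytest.raises(InvalidInputError):
            kc.SimulationConfig(true_log_k=1.0, loss_fraction=1.0)


class TestSharedHeadspaceSimulator:
    def test_zero_noise_round_trip(self):
        config = kc.SimulationConfig(true_log_k=4.93, seed=0,
                                     system=SHARED_SYSTEM)
        df = kc.simulate_shared_headspace(config, log_khxdair=3.33)
        k = kc.shared_headspace_k_from_water_conc(
            SHARED_SYSTEM, df["c_water"][0], 3.33)
        assert math.log10(k) == pytest.approx(4.93, abs=1e-9)

    def test_neglecting_air_term_biases_high_by_air_mass_factor(self):
        """Attributing headspace mass to hexadecane inflates K by
        exactly 1 + V_air/(K_Hxd/air * V_Hxd)."""
        log_khxdair = 2.0
        config = kc.SimulationConfig(true_log_k=3.0, seed=0,
                                     system=SHARED_SYSTEM)
        df = kc.simulate_shared_headspace(config, log_khxdair)
        k_neglect = kc.shared_headspace_k_from_water_conc(
            SHARED_SYSTEM, df["c_water"][0], None)
        bias = math.log10(k_neglect) - 3.0
        expected = math.log10(
            1 + SHARED_SYSTEM.v_air / (10 ** log_khxdair * SHARED_SYSTEM.v_hxd))
        assert bias == pytest.approx(expected, abs=1e-9)
        assert bias > 0

    def test_three_phase_mass_conservation(self):
        config = kc.SimulationConfig(true_log_k=4.0, seed=0,
                                     system=SHARED_SYSTEM)
        df = kc.simulate_shared_headspace(config, log_khxdair=3.0)
        total = (df["c_water"][0] * SHARED_SYSTEM.v_water
                 + df["c_hxd"][0] * SHARED_SYSTEM.v_hxd
                 + df["c_air"][0] * SHARED_SYSTEM.v_air)
        assert total == pytest.approx(SHARED_SYSTEM.mass, abs=1e-12)

    @pytest.mark.parametrize("log_k, log_khxdair", [(4.93, 3.33),
                                                    (5.66, 3.38),
                                                    (4.62, 3.92)])
    def test_hydrophobic_volatile_compounds_keep_mass_in_hexadecane(
            self, log_k, log_khxdair):
        """Configurations mimicking real shared-headspace runs keep
        85-100% of the spike in hexadecane."""
        config = kc.SimulationConfig(true_log_k=log_k, seed=0,
                                     system=SHARED_SYSTEM)
        df = kc.simulate_shared_headspace(config, log_khxdair)
        assert 0.85 <= df["hxd_mass_fraction"][0] <= 1.00


class TestVprhsSimulators:
    def test_minimum_four_vial_design_fits(self):
        config = kc.SimulationConfig(true_log_k=0.75, noise_cv=0.02, seed=9)
        series = kc.simulate_modified_vprhs(config, [0, 5, 10, 20])
        fit = kc.fit_modified_vprhs(series, n_bootstrap=0)
        assert fit.converged
        assert fit.log_k == pytest.approx(0.75, abs=0.1)

    def test_zero_noise_round_trip_modified(self):
        config = kc.SimulationConfig(true_log_k=-0.35, seed=0)
        series = kc.simulate_modified_vprhs(config, [0, 5, 10, 20])
        fit = kc.fit_modified_vprhs(series, n_bootstrap=0)
        assert fit.log_k == pytest.approx(-0.35, abs=1e-6)

    def test_zero_noise_round_trip_standard(self):
        config = kc.SimulationConfig(true_log_k=0.4, seed=0)
        series = kc.simulate_standard_vprhs(config, [2, 6, 12, 18])
        fit = kc.fit_standard_vprhs(series, n_bootstrap=0)
        assert fit.log_k == pytest.approx(0.4, abs=1e-6)

    def test_determinism_bit_for_bit(self):
        cfg = dict(true_log_k=1.2, noise_cv=0.05)
        a = kc.simulate_modified_vprhs(kc.SimulationConfig(**cfg, seed=7),
                                       [0, 5, 10, 20])
        b = kc.simulate_modified_vprhs(kc.SimulationConfig(**cfg, seed=7),
                                       [0, 5, 10, 20])
        assert a.points == b.points

    def test_out_of_vial_volumes_rejected(self):
        config = kc.SimulationConfig(true_log_k=1.0, seed=0)
        with pytest.raises(InvalidInputError):
            kc.simulate_modified_vprhs(config, [0, 25])


class TestHomologuePanel:
    def test_noise_free_slope_recovery(self):
        panel = kc.make_homologue_panel("CF2", [4, 6, 8], intercept=-3.29,
                                        slope=0.43, seed=0)
        slope, _ = kc.series_slope(panel)
        assert slope == pytest.approx(0.43, abs=1e-12)

    def test_ols_recovery_unbiased_over_panels(self):
        """Mean recovered slope over 200 seeded panels within 0.01."""
        slopes = [
            kc.series_slope(
                kc.make_homologue_panel("CF2", [4, 6, 8], intercept=0.0,
                                        slope=0.43, noise_sd=0.05, seed=s)
            )[0]
            for s in range(200)
        ]
        assert np.mean(slopes) == pytest.approx(0.43, abs=0.01)

    def test_single_count_panel_under_determined(self):
        with pytest.raises(UnderDeterminedError):
            kc.make_homologue_panel("CF2", [4, 4], 0.0, 0.43)


class TestEstimatorRecoveryGrid:
    @pytest.mark.parametrize("noise_cv", [0.02, 0.05])
    def test_median_absolute_error_small_across_grid(self, noise_cv):
        """Across log K in {-1,1,3,5} the batch estimator's median
        absolute recovery error at n=5 stays below 0.05 log units."""
        errors = []
        for log_k in (-1.0, 1.0, 3.0, 5.0):
            config = kc.SimulationConfig(true_log_k=log_k, noise_cv=noise_cv,
                                         n_replicates=5, seed=17)
            df = kc.simulate_batch(config)
            logs = [math.log10(kc.batch_k_from_water_conc(config.system, c))
                    for c in df["c_water"]]
            errors.append(abs(np.mean(logs) - log_k))
        assert np.median(errors) < 0.05
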