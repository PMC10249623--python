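"""Thermodynamic cycle, mass-balance inversions, replicate statistics."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import kawcycle as kc
from kawcycle.exceptions import (
    InfeasibleMassBalanceError,
    InsufficientReplicatesError,
    InvalidGeometryError,
    InvalidInputError,
    NoDataError,
)

finite_logk = st.floats(min_value=-8, max_value=8)


class TestCycle:
    @pytest.mark.parametrize(
        "log_khxdw, log_khxdair, expected",
        [
            (2.51, 3.15, -0.64),   # 6:2 FTOH
            (5.0, 5.0, 0.0),       # identical phases cancel
            (4.93, 3.33, 1.60),    # 4:2 FTI
        ],
    )
    def test_known_values(self, log_khxdw, log_khxdair, expected):
        out = kc.cycle_log_kaw(log_khxdw, log_khxdair)
        assert out.value == pytest.approx(expected, abs=1e-12)
        assert out.quantity == kc.Quantity.AW

    def test_rejects_non_finite(self):
        with pytest.raises(InvalidInputError):
            kc.cycle_log_kaw(float("nan"), 1.0)
        with pytest.raises(InvalidInputError):
            kc.cycle_log_kaw(1.0, float("inf"))

    @settings(derandomize=True, max_examples=100)
    @given(a=finite_logk, b=finite_logk)
    def test_cycle_identity(self, a, b):
        """cycle(a, b) + b recovers a exactly."""
        assert kc.cycle_log_kaw(a, b).value + b == pytest.approx(a, abs=1e-12)


class TestBatchInversion:
    @pytest.mark.parametrize(
        "mass, v_w, v_hxd, c_w, expected",
        [
            (1.0, 5.0, 5.0, 0.1, 1.0),
            (1.0, 9.0, 1.0, 0.01, 91.0),
        ],
    )
    def test_hand_mass_balance(self, mass, v_w, v_hxd, c_w, expected):
        system = kc.PhaseSystem(v_water=v_w, v_hxd=v_hxd, mass=mass)
        assert kc.batch_k_from_water_conc(system, c_w) == pytest.approx(expected)

    def test_water_holding_more_than_spike_is_infeasible(self):
        system = kc.PhaseSystem(v_water=1.0, v_hxd=1.0, mass=1.0)
        with pytest.raises(InfeasibleMassBalanceError):
            kc.batch_k_from_water_conc(system, 1.1)

    def test_zero_hexadecane_is_invalid_geometry(self):
        system = kc.PhaseSystem(v_water=5.0, v_hxd=0.0, mass=1.0)
        with pytest.raises(InvalidGeometryError):
            kc.batch_k_from_water_conc(system, 0.01)

    @settings(derandomize=True, max_examples=60)
    @given(log_k=st.floats(min_value=-2, max_value=6))
    def test_exact_inverse_of_forward_model(self, log_k):
        """Batch inversion inverts the zero-noise simulator for any K."""
        config = kc.SimulationConfig(true_log_k=log_k, seed=0, n_replicates=1)
        df = kc.simulate_batch(config)
        system = config.system
        k = kc.batch_k_from_water_conc(system, df["c_water"].iloc[0])
        assert math.log10(k) == pytest.approx(log_k, abs=1e-9)


class TestSharedHeadspaceInversion:
    SYSTEM = kc.PhaseSystem(v_water=1.0, v_hxd=0.35, v_air=8.65, mass=1.0)

    def test_negligible_air_term_at_high_khxdair(self):
        k = kc.shared_headspace_k_from_water_conc(self.SYSTEM, 0.01, 6.0)
        assert k == pytest.approx(282.8, abs=0.1)

    def test_reduces_to_batch_without_khxdair(self):
        k = kc.shared_headspace_k_from_water_conc(self.SYSTEM, 0.01, None)
        batch = kc.batch_k_from_water_conc(self.SYSTEM, 0.01)
        assert k == batch

    def test_low_khxdair_gives_smaller_k(self):
        k_low = kc.shared_headspace_k_from_water_conc(self.SYSTEM, 0.01, 1.0)
        k_none = kc.shared_headspace_k_from_water_conc(self.SYSTEM, 0.01, None)
        assert k_low < k_none

    def test_monotone_in_v_air_and_khxdair(self):
        """More air volume lowers K; higher K_Hxd/air raises it."""
        base = kc.shared_headspace_k_from_water_conc(self.SYSTEM, 0.01, 2.0)
        bigger_air = kc.PhaseSystem(v_water=1.0, v_hxd=0.35, v_air=20.0,
                                    mass=1.0)
        assert kc.shared_headspace_k_from_water_conc(
            bigger_air, 0.01, 2.0) < base
        assert kc.shared_headspace_k_from_water_conc(
            self.SYSTEM, 0.01, 3.0) > base


class TestReplicateStatistics:
    def test_t_multiplier_at_n5(self):
        """The 95% multiplier at n=5 is 2.776 (prints as 2.78)."""
        values = [2.0 - 0.1, 2.0 - 0.05, 2.0, 2.0 + 0.05, 2.0 + 0.1]
        reps = kc.ReplicateSet(values)
        out = kc.replicate_mean_ci(reps, 0.95)
        half = out.ci_high - out.value
        assert half == pytest.approx(2.7764 * reps.sd / math.sqrt(5), rel=1e-4)

    def test_known_halfwidth(self):
        """SD 0.1 at n=5 gives the 2.776*0.1/sqrt(5) = 0.1242 half-width."""
        sd_target = 0.1
        vals = np.array([-1.0, -0.5, 0.0, 0.5, 1.0])
        vals = 2.0 + vals * sd_target / np.std(vals, ddof=1)
        out = kc.replicate_mean_ci(kc.ReplicateSet(vals), 0.95)
        assert out.ci_high - out.value == pytest.approx(0.1242, abs=2e-4)

    def test_zero_sd_gives_zero_width(self):
        out = kc.replicate_mean_ci(kc.ReplicateSet([2.0, 2.0, 2.0]), 0.95)
        assert out.ci_low == out.value == out.ci_high == 2.0

    def test_single_replicate_rejected(self):
        with pytest.raises(InsufficientReplicatesError):
            kc.ReplicateSet([1.0])

    @pytest.mark.parametrize("n", [4, 9, 16, 25])
    def test_halfwidth_scales_as_inverse_sqrt_n(self, n):
        """At fixed SD and large-ish n the width shrinks like 1/sqrt(n)."""
        rng = np.random.default_rng(1)
        vals = rng.normal(size=n)
        vals = (vals - vals.mean()) / vals.std(ddof=1)  # mean 0, sd 1
        out = kc.replicate_mean_ci(kc.ReplicateSet(vals), 0.95)
        from scipy import stats
        expected = stats.t.ppf(0.975, n - 1) / math.sqrt(n)
        assert out.ci_high - out.value == pytest.approx(expected, rel=1e-9)


class TestMassRecovery:
    def test_forward_model_recovers_100_percent(self):
        system = kc.PhaseSystem(v_water=5.0, v_hxd=5.0, mass=1.0)
        assert kc.mass_recovery_percent(system, 0.1, 1.0) == pytest.approx(100.0)

    def test_fractional_measurement(self):
        system = kc.PhaseSystem(v_water=5.0, v_hxd=5.0, mass=1.0)
        assert kc.mass_recovery_percent(system, 0.093, 1.0) == pytest.approx(93.0)

    @settings(derandomize=True, max_examples=40)
    @given(log_k=st.floats(min_value=-2, max_value=5))
    def test_simulated_hexadecane_concentration_is_fully_recovered(self, log_k):
        config = kc.SimulationConfig(true_log_k=log_k, seed=0, n_replicates=1)
        df = kc.simulate_batch(config)
        pct = kc.mass_recovery_percent(
            config.system, df["c_hxd"].iloc[0], 10.0 ** log_k
        )
        assert pct == pytest.approx(100.0, abs=1e-8)


class TestFinalValueSelection:
    def _lp(self, value, method, ci=None):
        lo, hi = (None, None) if ci is None else ci
        return kc.LogPartitionCoefficient(
            quantity=kc.Quantity.HXD_W, value=value, ci_low=lo, ci_high=hi,
            method=method, compound="X",
        )

    def test_shared_wins_above_batch_limit(self):
        batch = self._lp(4.13, kc.Method.BATCH)
        shared = self._lp(4.93, kc.Method.SHARED_HEADSPACE)
        assert kc.select_final_value([batch, shared]).value == 4.93

    def test_batch_wins_below_limit(self):
        batch = self._lp(2.50, kc.Method.BATCH)
        shared = self._lp(2.51, kc.Method.SHARED_HEADSPACE)
        assert kc.select_final_value([batch, shared]).method == kc.Method.BATCH

    def test_modified_vprhs_as_last_resort(self):
        only = self._lp(-0.35, kc.Method.MODIFIED_VPRHS)
        assert kc.select_final_value([only]).value == -0.35

    def test_single_entry_returned(self):
        only = self._lp(1.0, kc.Method.BATCH)
        assert kc.select_final_value([only]) is only

    def test_empty_list_is_no_data(self):
        with pytest.raises(NoDataError):
            kc.select_final_value([])


class TestDomainTypes:
    def test_negative_volume_rejected(self):
        with pytest.raises(InvalidGeometryError):
            kc.PhaseSystem(v_water=-1.0, v_hxd=1.0)

    def test_ci_must_bracket_value(self):
        with pytest.raises(InvalidInputError):
            kc.LogPartitionCoefficient(
                quantity=kc.Quantity.AW, value=5.0, ci_low=1.0, ci_high=2.0
            )

    def test_replicate_summary_recomputable(self):
        reps = kc.ReplicateSet([1.0, 2.0, 3.0])
        assert reps.n == 3
        assert reps.mean == pytest.approx(2.0)
        assert reps.sd == pytest.approx(1.0)
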