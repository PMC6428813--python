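"""Bray-Curtis metric and process-summary tests."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from dispersim.config import NoiseModel, RunConfig, ThermalParams
from dispersim.metrics import (bc_across, bc_within,
                               bray_curtis_dissimilarity,
                               bray_curtis_similarity_relative,
                               cv_growth_rates, growth_over_immigration)
from dispersim.ode import Trajectory, simulate
from dispersim.synthetic import perturb_trajectory

finite_pos = st.lists(st.floats(0.1, 1e6), min_size=3, max_size=3)


class TestBrayCurtisKernels:
    def test_absolute_abundance_worked_example(self):
        # doubling every population: D = 300/900 = 1/3
        d = bray_curtis_dissimilarity([100, 100, 100], [200, 200, 200])
        assert 100 * d == pytest.approx(33.33, abs=0.005)

    def test_relative_abundance_worked_example(self):
        s = bray_curtis_similarity_relative([100, 100, 100], [200, 200, 200])
        assert s == pytest.approx(100.0)

    def test_identical_communities(self):
        assert bray_curtis_dissimilarity([1, 2, 3], [1, 2, 3]) == 0.0

    def test_disjoint_supports_maximal(self):
        assert bray_curtis_dissimilarity([1, 0, 0], [0, 1, 0]) == 1.0
        assert bray_curtis_similarity_relative([1, 0, 0], [0, 1, 0]) == 0.0

    def test_all_zero_undefined(self):
        with pytest.raises(ValueError):
            bray_curtis_dissimilarity([0, 0, 0], [0, 0, 0])

    @given(finite_pos, st.floats(0.1, 100.0))
    @settings(max_examples=60, deadline=None)
    def test_absolute_kernel_is_scale_sensitive(self, x, c):
        x = np.asarray(x)
        d = bray_curtis_dissimilarity(x, c * x)
        assert d == pytest.approx(abs(1 - c) / (1 + c), rel=1e-9)

    @given(finite_pos, st.floats(0.1, 100.0))
    @settings(max_examples=60, deadline=None)
    def test_relative_kernel_is_scale_invariant(self, x, c):
        assert bray_curtis_similarity_relative(x, np.asarray(x) * c) == \
            pytest.approx(100.0)


@pytest.fixture(scope="module")
def traj():
    return simulate(5.0, output_every_min=30.0)


@pytest.fixture(scope="module")
def reference():
    return simulate(0.0, output_every_min=30.0)


class TestBCWithin:
    def test_exactly_21_samples_per_trajectory(self, traj):
        samples = bc_within(traj)
        assert len(samples) == 21
        assert sorted(samples["time_min"].unique()) == [60, 90, 120, 150,
                                                        180, 210, 240]
        assert samples["pair"].nunique() == 3

    def test_exactly_63_samples_over_three_replicates(self, traj):
        reps = perturb_trajectory(traj, NoiseModel(), 3, seed=0)
        assert len(bc_within(reps)) == 63

    def test_identical_communities_give_100(self, default_config):
        nt = 9
        times = np.arange(nt) * 30.0
        dens = np.full((nt, 3, 3), 150.0)
        t = Trajectory(times, np.tile([25.0, 37, 42], (nt, 1)), dens,
                       np.zeros((nt, 3, 3)), 5.0, "full", default_config)
        assert np.allclose(bc_within(t)["value_pct"], 100.0)

    def test_missing_time_point_rejected(self, default_config):
        times = np.arange(4) * 30.0  # stops at 90 min
        dens = np.full((4, 3, 3), 150.0)
        t = Trajectory(times, np.tile([25.0, 37, 42], (4, 1)), dens,
                       np.zeros((4, 3, 3)), 5.0, "full", default_config)
        with pytest.raises(ValueError):
            bc_within(t)


class TestBCAcross:
    def test_exactly_21_samples(self, traj, reference):
        samples = bc_across(traj, reference)
        assert len(samples) == 21

    def test_run_identical_to_reference_gives_100(self, reference,
                                                  default_config):
        clone = Trajectory(reference.times_min, reference.temperatures,
                           reference.densities, reference.growth_rates,
                           5.0, "full", default_config)
        assert np.allclose(bc_across(clone, reference)["value_pct"], 100.0)

    def test_zero_dispersal_undefined(self, reference):
        with pytest.raises(ValueError):
            bc_across(reference, reference)

    def test_replicate_mode_pairs_by_replicate(self, traj, reference):
        reps = perturb_trajectory(traj, NoiseModel(), 3, seed=1)
        refs = perturb_trajectory(reference, NoiseModel(), 3, seed=2)
        assert len(bc_across(reps, refs)) == 63
        with pytest.raises(ValueError):
            bc_across(reps, refs[:2])


class TestGrowthCV:
    def test_identical_temperatures_zero_cv(self):
        cfg = RunConfig(thermal=ThermalParams(
            set_temperatures=(37.0, 37.0, 37.0),
            initial_temperatures=(37.0, 37.0, 37.0)))
        t = simulate(0.0, cfg, output_every_min=10.0)
        cvs = cv_growth_rates(t)
        assert all(cv == pytest.approx(0.0, abs=1e-12) for cv in cvs.values())

    def test_hand_computed_toy_case(self, default_config):
        nt = 25
        times = np.arange(nt) * 10.0
        rates = np.zeros((nt, 3, 3))
        rates[:, 0, :] = [0.01, 0.02, 0.03]  # strain 0, constant in time
        t = Trajectory(times, np.tile([25.0, 37, 42], (nt, 1)),
                       np.full((nt, 3, 3), 100.0), rates, 1.0, "full",
                       default_config)
        cvs = cv_growth_rates(t)
        expected = np.std([0.01, 0.02, 0.03], ddof=1) / 0.02
        assert cvs["B42"] == pytest.approx(expected)
        assert np.isnan(cvs["E310"])  # zero mean rate flagged as NaN


class TestGrowthOverImmigration:
    def test_zero_speed_signalled_infinite(self, default_config):
        nt = 25
        times = np.arange(nt) * 10.0
        t = Trajectory(times, np.tile([25.0, 37, 42], (nt, 1)),
                       np.random.default_rng(0).uniform(50, 500, (nt, 3, 3)),
                       np.full((nt, 3, 3), 0.01), 0.0, "full",
                       default_config)
        assert growth_over_immigration(t) == np.inf

    def test_hand_computed_toy_case(self, default_config):
        # constant state: r*n = 0.01*300 for one strain only; one vessel
        # imbalance 100 vs 200 vs 300 for that strain
        nt = 25
        times = np.arange(nt) * 10.0
        dens = np.zeros((nt, 3, 3))
        dens[:, 0, :] = [100.0, 200.0, 300.0]
        dens[:, 1:, :] = 100.0
        rates = np.zeros((nt, 3, 3))
        rates[:, 0, :] = 0.01
        speed = 30.0  # d = 0.06 per min
        t = Trajectory(times, np.tile([25.0, 37, 42], (nt, 1)), dens,
                       rates, speed, "full", default_config)
        growth_mean = (0.01 * (100 + 200 + 300)) / 9.0
        d = 0.06
        # |I| per vessel for strain 0: |300-100|, |100-200|, |200-300|
        imm_mean = d * (200 + 100 + 100) / 9.0
        assert growth_over_immigration(t) == pytest.approx(
            growth_mean / imm_mean)

    def test_decreases_with_speed_on_default_scan(self):
        vals = [growth_over_immigration(simulate(s, output_every_min=10.0))
                for s in (0.1, 1.0, 5.0)]
        assert vals[0] > vals[1] > vals[2]
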