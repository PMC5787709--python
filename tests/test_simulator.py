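"""Unit and property tests for the stochastic cell-file simulator."""

import math

import numpy as np
import pytest
from scipy import integrate, stats

import rootzone as rz
from rootzone.simulator import InfeasibleConfigError, n_ez_at_entries

LN2 = math.log(2.0)


def _root(**kw):
    base = dict(root_id=0, r_prod=1.0, l0=10.0, r_elong=LN2, threshold=160.0)
    base.update(kw)
    return rz.RootParams(**base)


class TestSamplePopulation:
    def test_zero_spread_returns_cohort_means(self):
        pop = rz.PopulationParams("sizer", r_prod=1.75, l0=8.0, r_elong=0.446,
                                  threshold=160.0, n_roots=5)
        roots = rz.sample_population(pop, seed=1)
        assert all(r.r_prod == 1.75 and r.l0 == 8.0 and r.threshold == 160.0
                   for r in roots)

    def test_matches_truncated_normal_mean(self):
        # oracle: numerical integration of the >0-truncated N(1, 0.2)
        mean, sd, n = 1.0, 0.2, 10_000
        num = integrate.quad(lambda x: x * stats.norm.pdf(x, mean, sd), 0, 10)[0]
        z = 1.0 - stats.norm.cdf(0, mean, sd)
        trunc_mean = num / z
        pop = rz.PopulationParams("sizer", r_prod=mean, l0=8.0, r_elong=0.446,
                                  threshold=160.0, delta={"r_prod": sd},
                                  n_roots=n)
        draws = np.array([r.r_prod for r in rz.sample_population(pop, seed=2)])
        se = draws.std() / math.sqrt(n)
        assert abs(draws.mean() - trunc_mean) < 3 * se
        assert (draws > 0).all()

    def test_rejection_cap_raises(self):
        # a mean many sd below zero can essentially never draw positive
        from rootzone.simulator import _positive_normal
        with pytest.raises(InfeasibleConfigError):
            _positive_normal(np.random.default_rng(0), -10.0, 1.0, 10)

    def test_invariant_validation(self):
        with pytest.raises(ValueError, match="within-root"):
            rz.PopulationParams("sizer", r_prod=1.0, l0=8.0, r_elong=0.4,
                                threshold=160.0, delta={"l0": 0.1},
                                sigma={"l0": 0.2})


class TestDeterministicRules:
    def test_sizer_doubling(self, doubling_sizer):
        traj = doubling_sizer
        tau = traj.stop_time - traj.entry_time
        closed = np.isfinite(traj.stop_time)
        assert np.allclose(tau[closed], 4.0)
        assert np.allclose(traj.stop_length[closed], 160.0)

    def test_timer_time_average_four_cells(self):
        root = _root(threshold=4.0)
        traj = rz.simulate_root_file(root, "timer", 200.0, seed=0)
        n = n_ez_at_entries(traj)
        assert abs(n[50:].mean() - 4.0) < 0.51  # alternates around T0*R_prod

    def test_ruler_first_stop_by_hand_enumeration(self):
        # lengths at the 4th entry: 20, 40, 80; center of the oldest cell is
        # 20 + 40 + 40 = 100 >= L0 -> stops with length 80 at t = 3
        root = _root(threshold=100.0)
        traj = rz.simulate_root_file(root, "ruler", 30.0, seed=0)
        assert traj.stop_time[0] == 3.0
        assert traj.stop_length[0] == pytest.approx(80.0)
        snap = rz.snapshot(traj, 2.5)
        assert snap.n_ez == 3

    def test_dilution_k0_equals_relative_sizer(self):
        # with k=0 a cell stops when l = l0 * (c0/c_thr)
        root = _root(threshold=16.0)  # concentration ratio
        traj = rz.simulate_root_file(root, "dilution", 60.0, seed=0)
        closed = np.isfinite(traj.stop_time)
        assert np.allclose(traj.stop_length[closed], traj.l0[closed] * 16.0)

    def test_dilution_large_k_approaches_timer(self):
        k = 50.0
        root = _root(threshold=16.0)
        traj = rz.simulate_root_file(root, "dilution", 60.0, seed=0, k_decay=k)
        tau = (traj.stop_time - traj.entry_time)[np.isfinite(traj.stop_time)]
        assert np.allclose(tau, math.log(16.0) / (LN2 + k), rtol=1e-12)
        assert tau.max() < 0.1  # essentially length-independent, short times


class TestSnapshot:
    def test_lengths_follow_exponential_law(self, doubling_sizer):
        snap = rz.snapshot(doubling_sizer, 100.5)
        assert snap.n_ez == 4
        expect = np.array([10, 20, 40, 80]) * math.sqrt(2.0)
        assert np.allclose(np.sort(snap.lengths), np.sort(expect))
        assert snap.l_ez == pytest.approx(snap.lengths.sum())
        assert snap.l_max == pytest.approx(80 * math.sqrt(2.0))

    def test_stop_boundary_counts_in_dz(self, doubling_sizer):
        # first cell stops at t=4 exactly: half-open [entry, stop)
        before = rz.snapshot(doubling_sizer, 4.0 - 1e-9)
        at = rz.snapshot(doubling_sizer, 4.0)
        assert at.dz_count == before.dz_count + 1
        assert at.n_ez == before.n_ez  # a new cell also entered at t=4

    def test_empty_before_first_entry(self):
        root = _root()
        traj = rz.simulate_root_file(root, "sizer", 10.0, seed=0)
        # shift: first cell enters at t=0, so probe a fresh trajectory at 0
        snap = rz.snapshot(traj, 0.0)
        assert snap.n_ez == 1  # the founding cell


class TestStationarityAndGrowth:
    def test_onset_after_first_differentiation(self, doubling_sizer):
        t_star = rz.detect_stationary(doubling_sizer, window=1)
        assert t_star is not None and 4.0 <= t_star <= 5.0

    def test_too_short_run_is_flagged(self):
        traj = rz.simulate_root_file(_root(), "sizer", 1.0, seed=0)
        assert rz.detect_stationary(traj) is None

    def test_growth_rate_matches_cell_flux(self, doubling_sizer):
        # one 160-um cell differentiates per hour
        rate = rz.sim_root_growth_rate(doubling_sizer, 10.0)
        assert rate == pytest.approx(160.0, rel=0.02)

    def test_growth_linear_after_onset(self):
        pop = rz.PRESETS["wt_epidermis_sizer"].population()
        root = rz.sample_population(pop, seed=3)[0]
        traj = rz.simulate_root_file(root, "sizer", 240.0, seed=3,
                                     sigma=pop.sigma)
        t_star = rz.detect_stationary(traj)
        grid = np.linspace(t_star, 240.0, 60)
        stops = traj.stop_time[np.isfinite(traj.stop_time)]
        lens = traj.stop_length[np.isfinite(traj.stop_time)]
        order = np.argsort(stops)
        cum = np.concatenate([[0.0], np.cumsum(lens[order])])
        dz = cum[np.searchsorted(stops[order], grid, side="right")]
        r = np.corrcoef(grid, dz)[0, 1]
        assert r**2 > 0.99

    def test_requires_three_grid_points(self, doubling_sizer):
        with pytest.raises(ValueError):
            rz.sim_root_growth_rate(doubling_sizer, 10.0, n_grid=2)


class TestInvariants:
    @pytest.mark.parametrize("model,threshold,k", [
        ("sizer", 160.0, 0.0), ("timer", 4.0, 0.0),
        ("ruler", 100.0, 0.0), ("dilution", 16.0, 0.5)])
    def test_noiseless_simulation_matches_theory(self, model, threshold, k):
        root = _root(threshold=threshold)
        traj = rz.simulate_root_file(root, model, 240.0, seed=0, k_decay=k)
        th = rz.steady_state_traits(model, 10.0, LN2, 1.0, threshold, k)
        n = n_ez_at_entries(traj)
        assert abs(n[100:].mean() - th.n_ez) <= 1.0
        t_star = rz.detect_stationary(traj, window=1)
        assert rz.sim_root_growth_rate(traj, t_star) == pytest.approx(
            th.r_growth, rel=0.05)
        snap = rz.snapshot(traj, 239.5)
        assert snap.l_max <= th.l_max * (1 + 1e-9)
        assert snap.l_max >= th.l_max / th.r_ez * (1 - 1e-9)
        assert abs(snap.l_ez - th.l_ez) / th.l_ez < 1.0 / th.n_ez + 0.35

    @pytest.mark.parametrize("model", rz.MODELS)
    def test_seed_determinism(self, model):
        pop = rz.PRESETS["wt_epidermis_sizer"].population()
        root = rz.sample_population(pop, seed=5)[1]
        a = rz.simulate_root_file(root, model, 60.0, seed=11, sigma=pop.sigma,
                                  k_decay=0.3)
        b = rz.simulate_root_file(root, model, 60.0, seed=11, sigma=pop.sigma,
                                  k_decay=0.3)
        assert np.array_equal(a.entry_time, b.entry_time)
        assert np.array_equal(a.stop_time, b.stop_time)
        assert np.array_equal(a.stop_length, b.stop_length,  equal_nan=True)

    @pytest.mark.parametrize("model", rz.MODELS)
    def test_mass_bookkeeping(self, model):
        pop = rz.PRESETS[f"wt_epidermis_{model}"].population()
        root = rz.sample_population(pop, seed=7)[0]
        traj = rz.simulate_root_file(root, model, 120.0, seed=7,
                                     sigma=pop.sigma, k_decay=pop.k_decay)
        snap = rz.snapshot(traj, 120.0)
        assert snap.n_ez + snap.dz_count == traj.n_cells
        elongating = ~np.isfinite(traj.stop_time)
        assert elongating.sum() == snap.n_ez
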