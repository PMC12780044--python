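"""Generators with known answers: potentials, propagators, oracles."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.optimize import minimize
from scipy.stats import chisquare, kstest

from tpskit.tps_core import StateDefinition
from tpskit.toy_systems import (
    DiscreteChainSpec,
    MembraneConfig,
    analytic_committor_1d,
    boltzmann_density_1d,
    discrete_committor,
    enumerate_tpe_discrete,
    generate_censored_lifetimes,
    generate_membrane_config,
    generate_shot_records,
    make_double_well_1d,
    make_two_channel_2d,
    shoot_committor_batch,
    simulate_discrete,
    simulate_overdamped,
)


# ---------------------------------------------------------------------------
# potentials
# ---------------------------------------------------------------------------

class TestPotentials:
    def test_double_well_barrier_and_symmetry(self, double_well):
        assert double_well.energy(0.0) - double_well.energy(1.0) == pytest.approx(5.0)
        xs = np.linspace(-2, 2, 41)
        assert np.allclose(double_well.energy(xs), double_well.energy(-xs))
        assert double_well.gradient(0.0) == pytest.approx(0.0)

    def test_two_channel_x_reflection_symmetry(self, two_channel):
        pts = np.random.default_rng(0).uniform(-2, 2, (50, 2))
        flipped = pts * np.array([-1.0, 1.0])
        assert np.allclose(two_channel.energy(pts), two_channel.energy(flipped))

    def test_two_channel_intermediate_is_local_minimum(self, two_channel):
        y0 = two_channel.params["y0"]
        res = minimize(lambda z: two_channel.energy(z), [0.0, y0])
        assert np.linalg.norm(two_channel.gradient(res.x)) < 1e-5
        assert abs(res.x[0]) < 0.05 and 0.5 * y0 < res.x[1] < 1.5 * y0
        # the intermediate sits below the pore-channel entry barrier
        assert res.fun < two_channel.params["barrier_P_kT"]

    @pytest.mark.parametrize("factory,dim", [(make_double_well_1d, 1), (make_two_channel_2d, 2)])
    def test_gradient_matches_finite_differences(self, factory, dim):
        pot = factory()
        rng = np.random.default_rng(3)
        pts = rng.uniform(-1.8, 1.8, (30, dim))
        h = 1e-6
        for p in pts:
            g = np.atleast_1d(pot.gradient(p if dim > 1 else p[0]))
            fd = np.array([
                (pot.energy(p + h * e if dim > 1 else p[0] + h)
                 - pot.energy(p - h * e if dim > 1 else p[0] - h)) / (2 * h)
                for e in np.eye(dim)
            ])
            assert np.allclose(g, fd, rtol=1e-5, atol=1e-7)

    def test_parameter_validation(self):
        with pytest.raises(ValueError):
            make_double_well_1d(-1.0)
        with pytest.raises(ValueError):
            make_two_channel_2d(barrier_T_kT=0.0)


# ---------------------------------------------------------------------------
# overdamped propagation
# ---------------------------------------------------------------------------

class TestSimulateOverdamped:
    def test_zero_noise_stays_at_minimum(self, double_well):
        seg = simulate_overdamped(double_well, [1.0], 1e-3, 1.0, 500, seed=0, noise_scale=0.0)
        assert np.allclose(seg.frames, 1.0, atol=1e-10)

    def test_seed_reproducibility(self, two_channel):
        a = simulate_overdamped(two_channel, [0.0, 0.0], 1e-3, 1.0, 2000, seed=42)
        b = simulate_overdamped(two_channel, [0.0, 0.0], 1e-3, 1.0, 2000, seed=42)
        assert np.array_equal(a.frames, b.frames)

    def test_first_entrance_stopping(self, double_well):
        states = [StateDefinition("L", below=-1.0), StateDefinition("U", above=1.0)]
        seg = simulate_overdamped(double_well, [0.0], 5e-3, 1.0, 100_000, seed=7,
                                  state_defs=states)
        assert seg.status == "ok" and seg.terminal_state in ("L", "U")
        inside = [s.contains(fr) for fr in seg.frames for s in states]
        # only the final frame is inside a state
        assert sum(inside) == 1

    def test_unresolved_status(self, double_well):
        states = [StateDefinition("U", above=50.0)]
        seg = simulate_overdamped(double_well, [0.0], 1e-4, 1.0, 50, seed=0, state_defs=states)
        assert seg.status == "unresolved" and seg.terminal_state is None

    def test_boltzmann_distribution_in_single_well(self):
        # confined quartic well: long run thinned to roughly independent samples
        pot = make_double_well_1d(9.0, 2.0)
        seg = simulate_overdamped(pot, [-1.0], 2e-3, 1.0, 100_000, seed=5)
        x = seg.frames[5000::25, 0]  # burn-in + thinning
        assert x.max() < 0.0, "trajectory escaped the well"
        grid, _pdf, cdf = boltzmann_density_1d(pot, 1.0, -2.5, 0.0)
        stat = kstest(x, lambda v: np.interp(v, grid, cdf))
        assert stat.pvalue > 0.01


# ---------------------------------------------------------------------------
# 1D committor oracle
# ---------------------------------------------------------------------------

class TestAnalyticCommittor:
    def test_boundaries_and_symmetry(self, double_well):
        assert analytic_committor_1d(double_well, 1.0, -1, 1, -1.0) == pytest.approx(0.0)
        assert analytic_committor_1d(double_well, 1.0, -1, 1, 1.0) == pytest.approx(1.0)
        assert analytic_committor_1d(double_well, 1.0, -1, 1, 0.0) == pytest.approx(0.5)

    def test_domain_error(self, double_well):
        with pytest.raises(ValueError):
            analytic_committor_1d(double_well, 1.0, -1, 1, 1.5)

    @given(x=st.floats(-0.99, 0.99), dx=st.floats(0.001, 0.5))
    @settings(max_examples=50, deadline=None)
    def test_monotone_nondecreasing(self, double_well, x, dx):
        hi = min(x + dx, 1.0)
        assert (analytic_committor_1d(double_well, 1.0, -1, 1, hi)
                >= analytic_committor_1d(double_well, 1.0, -1, 1, x) - 1e-12)

    def test_agrees_with_brute_force_shooting(self, double_well):
        x0 = 0.25
        phi = analytic_committor_1d(double_well, 1.0, -1, 1, x0)
        n = 1000
        out = shoot_committor_batch(double_well, np.full(n, x0), -1, 1,
                                    dt=2e-3, beta=1.0, max_steps=200_000, seed=9)
        assert (out >= 0).all()
        p_hat = out.mean()
        se = math.sqrt(phi * (1 - phi) / n)
        assert abs(p_hat - phi) < 3 * se


# ---------------------------------------------------------------------------
# discrete chains
# ---------------------------------------------------------------------------

class TestDiscreteChain:
    def test_probability_validation(self):
        with pytest.raises(ValueError):
            DiscreteChainSpec(3, (0, 0.5, 0.6), (0.5, 0, 0.4), (0.5, 0.4, 0))

    def test_forced_three_site_chain_single_path(self):
        spec = DiscreteChainSpec(3, (0.0, 0.0, 1.0), (0.0, 0.0, 0.0), (1.0, 1.0, 0.0))
        paths, trunc, status = enumerate_tpe_discrete(spec, max_len=10)
        assert status == "ok"
        assert paths == {(0, 1, 2): pytest.approx(1.0)}
        assert trunc == pytest.approx(0.0, abs=1e-12)

    def test_probabilities_sum_to_one_minus_truncated(self, hop_chain):
        paths, trunc, _ = enumerate_tpe_discrete(hop_chain, max_len=17)
        assert sum(paths.values()) == pytest.approx(1.0 - trunc, abs=1e-12)

    def test_mean_path_length_matches_direct_simulation(self, hop_chain):
        paths, trunc, _ = enumerate_tpe_discrete(hop_chain, max_len=29)
        assert trunc < 2e-4
        lens = np.array([len(p) - 1 for p in paths])
        probs = np.array(list(paths.values()))
        mean_len = float((lens * probs).sum() / probs.sum())
        # vectorized first-entrance walkers from state A
        rng = np.random.default_rng(11)
        n_sim = 1_000_000
        pr = np.asarray(hop_chain.p_right)
        x = np.zeros(n_sim, dtype=np.int64)
        steps = np.zeros(n_sim, dtype=np.int64)
        active = np.ones(n_sim, dtype=bool)
        hit_b = np.zeros(n_sim, dtype=bool)
        first = True
        for _ in range(500):
            if not active.any():
                break
            idx = np.flatnonzero(active)
            u = rng.random(idx.size)
            right = u < pr[x[idx]]
            x[idx] += np.where(right, 1, -1)
            steps[idx] += 1
            if first:
                first = False  # the first hop leaves state A by construction
            done_b = x[idx] == hop_chain.n_sites - 1
            done_a = x[idx] == 0
            hit_b[idx[done_b]] = True
            active[idx[done_a | done_b]] = False
        sim_lens = steps[hit_b]
        se = sim_lens.std() / math.sqrt(len(sim_lens))
        assert abs(sim_lens.mean() - mean_len) < 3 * se

    def test_exact_committor_is_monotone(self, hop_chain):
        q = discrete_committor(hop_chain)
        assert q[0] == 0.0 and q[-1] == 1.0
        assert np.all(np.diff(q) > 0)

    def test_simulate_stops_in_state(self, hop_chain):
        path = simulate_discrete(hop_chain, 2, 10_000, seed=1)
        assert path[-1] in (0, hop_chain.n_sites - 1)
        assert all(0 < s < hop_chain.n_sites - 1 for s in path[1:-1] if path.index(s))


# ---------------------------------------------------------------------------
# membrane configurations
# ---------------------------------------------------------------------------

class TestMembraneConfig:
    def test_no_pore_means_dry_membrane_core(self):
        cfg = generate_membrane_config(pore_radius=0.0, seed=4)
        waters = cfg.select("water_O")
        half = cfg.metadata["leaflet_sep"] / 2.0
        inside = np.abs(waters[:, 2] - cfg.midplane_z) < half - 0.35
        assert inside.sum() == 0

    def test_seed_reproducibility(self):
        a = generate_membrane_config(pore_radius=0.3, seed=8)
        b = generate_membrane_config(pore_radius=0.3, seed=8)
        assert np.array_equal(a.positions, b.positions)
        assert np.array_equal(a.types, b.types)

    def test_pore_radius_bounds(self):
        with pytest.raises(ValueError):
            generate_membrane_config(pore_radius=4.0, box=(6, 6, 6))
        with pytest.raises(ValueError):
            generate_membrane_config(pore_radius=-0.1)

    def test_csv_round_trip(self, tmp_path):
        cfg = generate_membrane_config(pore_radius=0.3, seed=2)
        p = tmp_path / "cfg.csv"
        cfg.to_csv(p)
        back = MembraneConfig.from_csv(p, cfg.box, cfg.midplane_z)
        assert np.allclose(back.positions, cfg.positions)
        assert np.array_equal(back.types, cfg.types)

    def test_hdf5_round_trip(self, tmp_path):
        import h5py

        cfg = generate_membrane_config(pore_radius=0.3, seed=2)
        with h5py.File(tmp_path / "cfg.h5", "w") as h5:
            cfg.to_hdf5(h5.create_group("frame"))
        with h5py.File(tmp_path / "cfg.h5", "r") as h5:
            back = MembraneConfig.from_hdf5(h5["frame"])
        assert np.allclose(back.positions, cfg.positions)
        assert np.array_equal(back.types, cfg.types)


# ---------------------------------------------------------------------------
# dispersed shot records
# ---------------------------------------------------------------------------

class TestShotRecords:
    def test_alpha_one_is_pure_binomial(self):
        recs = generate_shot_records(100_000, 2, 1.0,
                                     phi_sampler=lambda rng, N: np.full(N, 0.5), seed=0)
        assert np.var(recs.k / 2) == pytest.approx(0.125, abs=0.005)
        counts = np.bincount(recs.k, minlength=3)
        expected = len(recs) * np.array([0.25, 0.5, 0.25])
        assert chisquare(counts, expected).pvalue > 0.01

    def test_alpha_zero_two_point_mixture(self):
        recs = generate_shot_records(5000, 4, 0.0,
                                     phi_sampler=lambda rng, N: np.full(N, 0.5), seed=1)
        assert set(recs.k.unique()) <= {0, 4}
        assert recs.k.mean() / 4 == pytest.approx(0.5, abs=0.05)

    def test_variance_of_p_matches_formula(self):
        # Var[P] = (1 - alpha) phi (1 - phi): measured through the excess
        # variance of k/n beyond binomial at large n
        alpha, phi, n, N = 0.6, 0.3, 50, 40_000
        recs = generate_shot_records(N, n, alpha,
                                     phi_sampler=lambda rng, m: np.full(m, phi), seed=5)
        var_kn = np.var(recs.k / n)
        # Var[k/n] = Var[P] + E[P(1-P)]/n
        var_p_expected = (1 - alpha) * phi * (1 - phi)
        e_p1p = phi * (1 - phi) - var_p_expected
        assert var_kn == pytest.approx(var_p_expected + e_p1p / n, rel=0.1)

    def test_parameter_validation(self):
        with pytest.raises(ValueError):
            generate_shot_records(10, 2, 1.5)
        with pytest.raises(ValueError):
            generate_shot_records(10, 0, 0.5)


class TestCensoredLifetimes:
    def test_infinite_censor_time_no_censoring(self):
        t, c = generate_censored_lifetimes(2.0, 1e9, 1000, seed=0)
        assert not c.any()

    def test_censored_fraction_matches_survival(self):
        rate, tc, N = 2.0, 0.1, 100_000
        t, c = generate_censored_lifetimes(rate, tc, N, seed=1)
        p = math.exp(-rate * tc)
        se = math.sqrt(p * (1 - p) / N)
        assert abs(c.mean() - p) < 3 * se
        assert np.all(t[c] == tc)
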