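"""Pore coordinate xi_P, geometric features, lifetime MLE."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.optimize import minimize_scalar

from tpskit.pore_geometry import (
    PoreParams,
    depletion_features,
    pore_center,
    pore_lifetime_mle,
    pore_radius,
    xi_chain,
    xi_p,
)
from tpskit.toy_systems import (
    MembraneConfig,
    generate_censored_lifetimes,
    generate_membrane_config,
)

MARTINI = PoreParams.martini()


def _config(positions, types, box=(12.0, 12.0, 12.0), mid=6.0):
    return MembraneConfig(np.asarray(positions, float), np.asarray(types), np.asarray(box),
                          midplane_z=mid)


def _slab_config(occupied_slabs, box=(12.0, 12.0, 12.0)):
    """Polar particles in chosen slabs of the membrane region at the center."""
    mid = box[2] / 2
    z_lo = mid - MARTINI.Z_mem / 2
    dz = MARTINI.Z_mem / MARTINI.N_slabs
    pos = [[6.0, 6.0, z_lo + (s + 0.5) * dz] for s in occupied_slabs]
    # anchor heads far from the cylinder so the center stays defined
    pos += [[1.0, 1.0, mid + 1.3], [1.0, 1.0, mid - 1.3]]
    types = ["water_O"] * len(occupied_slabs) + ["head_P", "head_P"]
    return _config(pos, types, box, mid)


class TestPoreParams:
    def test_martini_preset_values(self):
        assert (MARTINI.N_slabs, MARTINI.Z_mem, MARTINI.R_cyl, MARTINI.D,
                MARTINI.xi_ch_s, MARTINI.R0) == (4, 1.8, 1.0, 1.2, 0.9, 0.38)

    def test_validation(self):
        with pytest.raises(ValueError):
            PoreParams(Z_mem=-1.0)
        with pytest.raises(ValueError):
            PoreParams(xi_ch_s=1.5)


class TestPoreCenter:
    def test_cluster_at_known_position(self):
        pos = [[3.0, 3.0, 6.0 + dz] for dz in (-0.2, -0.1, 0.0, 0.1, 0.2)]
        cfg = _config(pos, ["head_P"] * 5)
        assert np.allclose(pore_center(cfg, MARTINI), [3.0, 3.0], atol=1e-9)

    def test_wrapped_cluster_at_boundary(self):
        # heads straddling the periodic boundary near x = 0 / 12
        pos = [[11.7, 3.0, 6.0], [0.3, 3.0, 6.0], [11.9, 3.0, 6.0], [0.1, 3.0, 6.0]]
        cfg = _config(pos, ["head_P"] * 4)
        c = pore_center(cfg, MARTINI)
        # brute-force minimal-spread search over shifted origins
        xs = np.array([p[0] for p in pos])
        shifts = np.linspace(0, 12, 2401)
        spread = [np.var((xs - s) % 12) for s in shifts]
        best = shifts[int(np.argmin(spread))]
        expected = (np.mean((xs - best) % 12) + best) % 12
        assert min(abs(c[0] - expected), 12 - abs(c[0] - expected)) < 0.05
        assert c[1] == pytest.approx(3.0, abs=1e-6)

    def test_translation_equivariance(self):
        cfg = generate_membrane_config(pore_radius=0.4, seed=3)
        c0 = pore_center(cfg, MARTINI)
        shifted = MembraneConfig(cfg.positions + np.array([1.0, 1.0, 0.0]),
                                 cfg.types, cfg.box, cfg.midplane_z)
        c1 = pore_center(shifted, MARTINI)
        delta = (c1 - c0 - 1.0) % cfg.box[:2]
        assert np.all(np.minimum(delta, cfg.box[:2] - delta) < 1e-6)

    def test_no_heads_raises(self):
        cfg = _config([[1, 1, 6.0]], ["water_O"])
        with pytest.raises(ValueError):
            pore_center(cfg, MARTINI)


class TestXiChain:
    @pytest.mark.parametrize("slabs,expected", [
        ((), 0.0), ((0, 2), 0.5), ((0, 1, 2, 3), 1.0),
    ])
    def test_constructed_occupancies_exact(self, slabs, expected):
        cfg = _slab_config(slabs)
        chain, occ = xi_chain(cfg, np.array([6.0, 6.0]), MARTINI)
        assert chain == expected
        assert occ.sum() == len(slabs)

    def test_polar_outside_cylinder_ignored(self):
        cfg = _slab_config((0, 1, 2, 3))
        chain, _ = xi_chain(cfg, np.array([2.0, 2.0]), MARTINI)  # far center
        assert chain == 0.0


class TestPoreRadius:
    def test_no_waters_zero_radius(self):
        cfg = _config([[6, 6, 7.3]], ["head_P"])
        assert pore_radius(cfg, np.array([6.0, 6.0]), MARTINI) == 0.0

    def test_doubling_waters_scales_sqrt2(self):
        w1 = [[6.0, 6.0, 6.0 + 0.01 * i] for i in range(20)]
        cfg1 = _config(w1, ["water_O"] * 20)
        cfg2 = _config(w1 + [[6.1, 6.1, 6.0 + 0.01 * i] for i in range(20)],
                       ["water_O"] * 40)
        c = np.array([6.0, 6.0])
        r1 = pore_radius(cfg1, c, MARTINI)
        r2 = pore_radius(cfg2, c, MARTINI)
        assert r2 == pytest.approx(math.sqrt(2) * r1)

    def test_planted_column_recovery(self):
        devs = []
        for seed in range(5):
            cfg = generate_membrane_config(pore_radius=0.4, seed=seed)
            st = xi_p(cfg, MARTINI)
            devs.append(abs(st.R - 0.4))
        assert max(devs) < 0.1


class TestXiP:
    def test_nucleation_branch(self):
        cfg = _slab_config((0, 1))  # xi_ch = 0.5
        st = xi_p(cfg, MARTINI, center=np.array([6.0, 6.0]))
        assert st.xi_p == pytest.approx(0.5 / 0.9)

    def test_just_nucleated_pore_is_unity(self):
        # full chain with exactly the water count of a pore of radius R0
        n_w = round(math.pi * MARTINI.R0**2 * MARTINI.Z_mem / MARTINI.v_w)
        rng = np.random.default_rng(0)
        r = MARTINI.R0 * np.sqrt(rng.random(n_w))
        th = rng.uniform(0, 2 * math.pi, n_w)
        z = 6.0 + rng.uniform(-MARTINI.Z_mem / 2, MARTINI.Z_mem / 2, n_w)
        pos = np.column_stack([6.0 + r * np.cos(th), 6.0 + r * np.sin(th), z])
        cfg = _config(pos.tolist(), ["water_O"] * n_w)
        st = xi_p(cfg, MARTINI, center=np.array([6.0, 6.0]))
        assert st.xi_ch == 1.0
        assert st.xi_p == pytest.approx(1.0, abs=0.05)

    def test_double_radius_doubles_coordinate(self):
        # R = 2 R0 -> xi_P = 2 (the relaxed open-pore scale)
        n_w = round(math.pi * (2 * MARTINI.R0) ** 2 * MARTINI.Z_mem / MARTINI.v_w)
        rng = np.random.default_rng(1)
        r = 2 * MARTINI.R0 * np.sqrt(rng.random(n_w))
        th = rng.uniform(0, 2 * math.pi, n_w)
        z = 6.0 + rng.uniform(-MARTINI.Z_mem / 2, MARTINI.Z_mem / 2, n_w)
        pos = np.column_stack([6.0 + r * np.cos(th), 6.0 + r * np.sin(th), z])
        cfg = _config(pos.tolist(), ["water_O"] * n_w)
        st = xi_p(cfg, MARTINI, center=np.array([6.0, 6.0]))
        assert st.xi_p == pytest.approx(2.0, abs=0.1)

    def test_continuity_at_switch(self):
        # chain just below complete vs complete-with-R0: xi_P approaches 1
        # from both sides
        below = _slab_config((0, 1, 2))  # 0.75 -> 0.8333
        st_b = xi_p(below, MARTINI, center=np.array([6.0, 6.0]))
        assert st_b.xi_p == pytest.approx(0.75 / 0.9)
        assert st_b.xi_p < 1.0

    @given(n_add=st.integers(0, 60))
    @settings(max_examples=25, deadline=None)
    def test_monotone_in_added_spanning_water(self, n_add):
        rng = np.random.default_rng(42)
        zs = 6.0 + np.linspace(-0.85, 0.85, 80)
        extra = rng.uniform(0, 1, (60, 3))
        extra[:, :2] = 6.0 + (extra[:, :2] - 0.5) * 0.6
        extra[:, 2] = 6.0 + (extra[:, 2] - 0.5) * 1.6
        c = np.array([6.0, 6.0])

        def build(n):
            pos = [[6.0, 6.0, z] for z in zs[:max(2, n)]] + extra[:n].tolist()
            return _config(pos, ["water_O"] * len(pos))

        a = xi_p(build(n_add), MARTINI, center=c).xi_p
        b = xi_p(build(n_add + 5), MARTINI, center=c).xi_p
        assert b >= a - 1e-12

    def test_periodic_translation_invariance(self):
        cfg = generate_membrane_config(pore_radius=0.4, seed=7)
        st0 = xi_p(cfg, MARTINI)
        rng = np.random.default_rng(8)
        for _ in range(3):
            shift = rng.uniform(0, cfg.box[:2].min(), 2)
            moved = MembraneConfig(cfg.positions + np.array([*shift, 0.0]),
                                   cfg.types, cfg.box, cfg.midplane_z)
            st1 = xi_p(moved, MARTINI)
            assert st1.xi_ch == pytest.approx(st0.xi_ch, abs=1e-9)
            assert st1.R == pytest.approx(st0.R, abs=1e-9)
            assert st1.xi_p == pytest.approx(st0.xi_p, abs=1e-9)


class TestDepletionFeatures:
    def test_single_atom_distances(self):
        cfg = _config([[8.0, 6.0, 6.0], [6, 6, 7.3]], ["water_O", "head_P"])
        f = depletion_features(cfg, np.array([6.0, 6.0]))
        assert f["waterO_lateral_d1"] == pytest.approx(2.0)
        assert math.isnan(f["waterO_lateral_d2"])
        assert math.isnan(f["waterO_lateral_mean2"])

    def test_permutation_invariance(self):
        rng = np.random.default_rng(9)
        pos = rng.uniform(0, 12, (30, 3))
        types = np.array(["head_P", "head_N", "water_O"] * 10)
        cfg1 = _config(pos.tolist(), types)
        perm = rng.permutation(30)
        cfg2 = _config(pos[perm].tolist(), types[perm])
        f1 = depletion_features(cfg1, np.array([6.0, 6.0]))
        f2 = depletion_features(cfg2, np.array([6.0, 6.0]))
        for key in f1:
            assert f1[key] == pytest.approx(f2[key], nan_ok=True)

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(10)
        pos = np.column_stack([
            rng.uniform(4, 8, 20), rng.uniform(4, 8, 20), rng.uniform(4.5, 7.5, 20),
        ])
        cfg = _config(pos.tolist(), ["water_O"] * 20)
        center = np.array([6.0, 6.0])
        f = depletion_features(cfg, center)
        lat = np.sort(np.hypot(pos[:, 0] - 6.0, pos[:, 1] - 6.0))
        axial = np.sort(np.abs(pos[:, 2] - 6.0))
        iso = np.sort(np.hypot(np.hypot(pos[:, 0] - 6, pos[:, 1] - 6),
                               np.abs(pos[:, 2] - 6)))
        for r in (1, 2, 3):
            assert f[f"waterO_lateral_d{r}"] == pytest.approx(lat[r - 1])
            assert f[f"waterO_axial_d{r}"] == pytest.approx(axial[r - 1])
            assert f[f"waterO_iso_d{r}"] == pytest.approx(iso[r - 1])
        for m in (2, 3, 4, 5, 10):
            assert f[f"waterO_lateral_mean{m}"] == pytest.approx(lat[:m].mean())

    def test_leaflet_depletion_maximum(self):
        pos = ([[6, 6, 6.2], [6, 6, 6.4], [6, 6, 6.6], [6, 6, 6.8]]      # upper
               + [[6, 6, 5.9], [6, 6, 5.8], [6, 6, 5.7], [6, 6, 5.6]])  # lower
        cfg = _config(pos, ["head_P"] * 8)
        f = depletion_features(cfg, np.array([6.0, 6.0]))
        assert f["dz_NP14_upper"] == pytest.approx(np.mean([0.2, 0.4, 0.6, 0.8]))
        assert f["dz_NP14_lower"] == pytest.approx(np.mean([0.1, 0.2, 0.3, 0.4]))
        assert f["dz_NP14_max"] == pytest.approx(0.5)


class TestLifetimeMLE:
    def test_uncensored_sample_mean(self):
        fit = pore_lifetime_mle([1.0, 2.0, 3.0], [False, False, False])
        assert fit.tau_hat == pytest.approx(2.0)

    def test_censored_formula(self):
        fit = pore_lifetime_mle([2.0, 3.0], [False, True])
        assert fit.tau_hat == pytest.approx(5.0)
        assert fit.n_events == 1

    def test_tau_maximizes_likelihood(self):
        t, c = generate_censored_lifetimes(2.5, 0.5, 2000, seed=0)
        fit = pore_lifetime_mle(t, c)
        res = minimize_scalar(lambda k: -fit.loglik(k),
                              bounds=(1e-3, 100.0), method="bounded",
                              options={"xatol": 1e-10})
        assert 1.0 / res.x == pytest.approx(fit.tau_hat, rel=1e-6)

    def test_simulation_recovery(self):
        # the open-pore use case: tau = 0.4 with ~30% censoring
        rate, tc, N = 2.5, 0.48, 10_000  # S(tc) = exp(-1.2) ~ 0.30
        t, c = generate_censored_lifetimes(rate, tc, N, seed=1)
        fit = pore_lifetime_mle(t, c)
        se = fit.tau_hat / math.sqrt(fit.n_events)
        assert abs(fit.tau_hat - 0.4) < 3 * se

    def test_all_censored_raises(self):
        with pytest.raises(ValueError, match="lower bound"):
            pore_lifetime_mle([1.0, 1.0], [True, True])
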