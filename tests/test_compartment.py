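"""Compartment engine: jump rates, propensities, SSA statistics."""

import numpy as np
import pytest

import blendsim as bs
from blendsim import _kernels


class TestJumpRates:
    def test_constant_d_interior(self, geom):
        f = bs.make_compartment_field(geom, 1 / 30, diffusivity="full")
        assert bs.jump_rates(f, 10) == (900.0, 900.0)

    def test_outer_faces_are_zero_flux(self, geom):
        f = bs.make_compartment_field(geom, 1 / 30, diffusivity="full")
        assert bs.jump_rates(f, 0)[0] == 0.0
        assert bs.jump_rates(f, f.n - 1)[1] == 0.0

    def test_dead_interface_faces(self, geom):
        # D1 chain on [a, I2]: right jump out of the last blending
        # compartment has rate zero (D1(I2) = 0)
        f1 = bs.make_compartment_field(geom, 1 / 30, span=(geom.a, geom.I2),
                                       diffusivity="D1")
        assert bs.jump_rates(f1, f1.n - 1)[1] == 0.0
        # second-to-last face carries D1 evaluated at that face
        assert bs.jump_rates(f1, f1.n - 1)[0] == pytest.approx(
            geom.D1(geom.I2 - 1 / 30) * 900.0)
        # D2 chain on [I1, b]: left face at I1 is dead (D2(I1) = 0)
        f2 = bs.make_compartment_field(geom, 1 / 30, span=(geom.I1, geom.b),
                                       diffusivity="D2")
        assert bs.jump_rates(f2, 0)[0] == 0.0
        assert bs.jump_rates(f2, 1)[0] > 0.0


class TestPropensities:
    def test_empty_field_is_silent(self, geom):
        f = bs.make_compartment_field(geom, 1 / 30, counts=0.0)
        a = bs.propensities(f, bs.ReactionSystem(mu=3.0, kappa1=1.0))
        assert np.all(a == 0.0)

    def test_production_rate_scales_with_volume(self, geom3d):
        # single compartment of volume 1/3 with kappa2 = 89.7 -> 29.9
        f = bs.make_compartment_field(geom3d, 1 / 3,
                                      span=(0.0, 1.0 / 3.0), counts=0.0)
        a = bs.propensities(f, bs.ReactionSystem(kappa2=89.7))
        assert a[0, 2] == pytest.approx(29.9)

    def test_order2_combinatorics(self, geom):
        f = bs.make_compartment_field(geom, 1 / 30, counts=7.0)
        a = bs.propensities(f, bs.ReactionSystem(kappa1=0.5))
        v = f.volume
        assert a[0, 4] == pytest.approx(0.5 * 7 * 6 / (2 * v))

    def test_negative_counts_floor_at_zero(self, geom):
        f = bs.make_compartment_field(geom, 1 / 30, counts=5.0)
        f.C[3] = -0.4   # transiently possible in the blending region
        a = bs.propensities(f, bs.ReactionSystem(mu=2.0))
        assert np.all(a[3] == 0.0)


class TestSSA:
    def test_no_events_leaves_field_unchanged(self, geom, rng):
        f = bs.make_compartment_field(geom, 1 / 30, counts=0.0)
        bs.ssa_advance_window(f, bs.ReactionSystem(), 0.0, 1.0, rng)
        assert np.all(f.C == 0.0)

    def test_diffusion_conserves_count_exactly(self, geom, rng):
        f = bs.make_compartment_field(geom, 1 / 30, counts=50.0)
        total0 = f.C.sum()
        bs.ssa_advance_window(f, bs.ReactionSystem(), 0.0, 0.5, rng)
        assert f.C.sum() == total0
        assert np.all(f.C == np.round(f.C))
        assert np.all(f.C >= 0.0)

    def test_python_path_reports_every_event(self, geom, rng):
        f = bs.make_compartment_field(geom, 1 / 30, counts=5.0)
        start = f.C.copy()
        events = []
        delta = np.zeros(f.n, np.int64)
        bs.ssa_advance_window(f, bs.ReactionSystem(), 0.0, 0.002, rng,
                              event_hook=events.append, delta_out=delta)
        assert len(events) > 0
        # replaying the reported events reproduces the state change
        replay = np.zeros(f.n)
        for ev in events:
            assert ev.kind == "jump"
            replay[ev.i] -= 1
            replay[ev.i + ev.direction] += 1
        np.testing.assert_array_equal(start + replay, f.C)
        np.testing.assert_array_equal(replay.astype(np.int64), delta)

    def test_real_valued_counts_fire_integer_events(self, geom, rng):
        f = bs.make_compartment_field(geom, 1 / 30, counts=0.0)
        f.C[:] = 4.7    # fractional blending-style mass
        bs.ssa_advance_window(f, bs.ReactionSystem(), 0.0, 0.01, rng)
        frac = f.C - np.floor(f.C)
        np.testing.assert_allclose(np.sort(np.unique(np.round(frac, 9))),
                                   [0.7])

    def test_stationary_mean_matches_master_equation(self, geom3d, rng):
        """Single well-mixed compartment with production and pair
        annihilation: the SSA stationary mean must match the stationary
        distribution of the truncated master equation."""
        kappa1, kappa2, V = 0.1, 89.7, 1.0 / 3.0
        # truncated generator on n = 0..nmax
        nmax = 80
        n = np.arange(nmax + 1)
        birth = np.full(nmax + 1, kappa2 * V)
        death = kappa1 * n * (n - 1) / (2 * V)
        Q = np.zeros((nmax + 1, nmax + 1))
        Q[n[:-1], n[:-1] + 1] = birth[:-1]
        Q[n[2:], n[2:] - 2] = death[2:]
        np.fill_diagonal(Q, -Q.sum(axis=1))
        w, v = np.linalg.eig(Q.T)
        pi = np.real(v[:, np.argmin(np.abs(w))])
        pi /= pi.sum()
        mean_me = float(n @ pi)

        f = bs.make_compartment_field(geom3d, 1 / 3, span=(0.0, 1.0 / 3.0))
        rx = bs.ReactionSystem(kappa2=kappa2, kappa1=kappa1)
        M = 600
        finals = np.empty(M)
        var_me = float((n ** 2) @ pi - mean_me ** 2)
        for r in range(M):
            out = _kernels.compartment_run(
                np.array([10.0]), f.rate_left, f.rate_right, f.volume,
                rx.kappa2, 0.0, rx.kappa1, 0.0, np.array([2.0]),
                int(rng.integers(2**31 - 1)))
            finals[r] = out[-1, 0]
        se = np.sqrt(var_me / M)
        assert abs(finals.mean() - mean_me) < 4 * se

    def test_single_particle_msd_is_2dt(self, geom, rng):
        """Compartment-index variance of a lone walker grows as
        2 (D/h^2) t on a wide constant-D lattice."""
        h = 1 / 30
        wide = bs.build_geometry(0.0, 101 * h, h, 2 * h, 1.0)
        f = bs.make_compartment_field(wide, h, diffusivity="full")
        t = 0.01
        target = 2 * (wide.D / h ** 2) * t    # = 18 jumps^2
        M = 3000
        c0 = np.zeros(f.n)
        c0[50] = 1.0
        idx = np.empty(M)
        for r in range(M):
            out = _kernels.compartment_run(
                c0, f.rate_left, f.rate_right, f.volume,
                0.0, 0.0, 0.0, 0.0, np.array([t]),
                int(rng.integers(2**31 - 1)))
            idx[r] = np.argmax(out[-1])
        var = idx.var()
        se = target * np.sqrt(2.0 / M)
        assert abs(var - target) < 5 * se

    def test_varying_d2_preserves_uniform_profile(self, geom, rng):
        """With the face-evaluated jump rates, divergence-form diffusion
        has a uniform steady state even under the linear D2 blend; a
        Fickian-hopping convention would pile mass where D is small."""
        f = bs.make_compartment_field(geom, 1 / 30, span=(geom.I1, geom.b),
                                      diffusivity="D2", counts=250.0)
        times = np.linspace(0.1, 1.0, 10)
        acc = np.zeros(f.n)
        M = 3
        for r in range(M):
            out = _kernels.compartment_run(
                np.full(f.n, 250.0), f.rate_left, f.rate_right, f.volume,
                0.0, 0.0, 0.0, 0.0, times, int(rng.integers(2**31 - 1)))
            acc += out.mean(axis=0)
        mean_counts = acc / M
        assert np.max(np.abs(mean_counts - 250.0)) / 250.0 < 0.1
        blend = mean_counts[:10].sum()
        pure = mean_counts[10:].sum()
        assert abs(blend - 2500.0) / 2500.0 < 0.03
        assert abs(pure - 2500.0) / 2500.0 < 0.03
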