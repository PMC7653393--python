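"""Brownian engine: drift-corrected update, reflection, lambda-rho reactions."""

import numpy as np
import pytest

import blendsim as bs


class _FixedRng:
    """Deterministic deviates for exact update checks."""

    def __init__(self, value):
        self.value = value

    def standard_normal(self, shape):
        return np.full(shape, self.value)


class TestEMStep:
    def test_zero_noise_constant_d_is_identity(self, geom):
        p = bs.make_particles(geom, [0.8, 0.9], span=(geom.I1, geom.b))
        bs.em_step(p, geom, 1e-4, _FixedRng(0.0), diffusivity="full")
        np.testing.assert_allclose(p.x, [0.8, 0.9])

    def test_unit_deviate_displacement(self, geom):
        p = bs.make_particles(geom, [0.9], span=(geom.I1, geom.b))
        bs.em_step(p, geom, 1e-4, _FixedRng(1.0), diffusivity="full")
        assert p.x[0] - 0.9 == pytest.approx(np.sqrt(2e-4))  # ~0.014142

    def test_blend_drift_term(self, geom):
        # linear D2 with slope 3 (D=1 over width 1/3): drift 3e-4 per step
        p = bs.make_particles(geom, [0.5], span=(geom.I1, geom.b))
        bs.em_step(p, geom, 1e-4, _FixedRng(0.0), diffusivity="D2")
        assert p.x[0] - 0.5 == pytest.approx(3e-4)
        # beyond I2 the coefficient is flat: no drift
        p = bs.make_particles(geom, [0.9], span=(geom.I1, geom.b))
        bs.em_step(p, geom, 1e-4, _FixedRng(0.0), diffusivity="D2")
        assert p.x[0] == pytest.approx(0.9)

    def test_free_space_moments(self, geom, rng):
        wide = bs.build_geometry(-50.0, 50.0, -1.0, 1.0, 1.0)
        n = 20000
        p = bs.make_particles(wide, np.zeros(n))
        steps, dt = 200, 1e-4
        for _ in range(steps):
            bs.em_step(p, wide, dt, rng, diffusivity="full")
        t = steps * dt
        var = 2 * wide.D * t
        assert abs(p.x.mean()) < 5 * np.sqrt(var / n)
        assert abs(p.x.var() - var) < 5 * var * np.sqrt(2.0 / n)


class TestBoundaries:
    def test_mirror(self, geom):
        p = bs.make_particles(geom, [1.01, 0.5], span=(geom.I1, geom.b))
        bs.handle_boundaries(p)
        np.testing.assert_allclose(p.x, [0.99, 0.5])

    def test_interface_reflection_is_tallied(self, geom):
        p = bs.make_particles(geom, [1 / 3 - 0.004], span=(geom.I1, geom.b))
        bs.handle_boundaries(p)
        assert p.x[0] == pytest.approx(1 / 3 + 0.004)
        assert p.reflect_tally == 1

    def test_count_conserved(self, geom, rng):
        p = bs.make_particles(geom, rng.uniform(1 / 3, 1, 500),
                              span=(geom.I1, geom.b))
        for _ in range(50):
            bs.em_step(p, geom, 1e-4, rng, diffusivity="D2")
            bs.handle_boundaries(p)
        assert p.N == 500
        assert p.x.min() >= 1 / 3 and p.x.max() <= 1.0

    def test_equilibrium_uniform_under_linear_d2(self, geom, rng):
        """The drift term is exactly what keeps divergence-form diffusion
        uniform: starting uniform on [I1, b], the thirds stay balanced.
        (The single most diagnostic test of the drift sign.)"""
        n = 6000
        p = bs.make_particles(geom, rng.uniform(1 / 3, 1, n),
                              span=(geom.I1, geom.b))
        for _ in range(2500):
            bs.em_step(p, geom, 1e-4, rng, diffusivity="D2")
            bs.handle_boundaries(p)
        in_blend = int(np.count_nonzero(p.x < 2 / 3))
        sigma = np.sqrt(n * 0.25)
        assert abs(in_blend - n / 2) < 5 * sigma


class TestReactions:
    def test_far_pair_never_reacts(self, geom, rng):
        rx = bs.ReactionSystem(kappa1=1.0, rho=0.06, p_lambda=1.0)
        p = bs.make_particles(geom, [0.1, 0.1 + 0.12])
        p, n_rm = bs.react_pairs(p, rx, 1e-4, rng)
        assert n_rm == 0

    def test_close_pair_with_unit_probability(self, geom, rng):
        rx = bs.ReactionSystem(kappa1=1.0, rho=0.06, p_lambda=1.0)
        p = bs.make_particles(geom, [0.1, 0.13])
        p, n_rm = bs.react_pairs(p, rx, 1e-4, rng)
        assert n_rm == 2 and p.N == 0

    def test_single_particle_no_events(self, geom, rng):
        rx = bs.ReactionSystem(kappa1=1.0, rho=0.06, p_lambda=1.0)
        p = bs.make_particles(geom, [0.5])
        p, n_rm = bs.react_pairs(p, rx, 1e-4, rng)
        assert n_rm == 0 and p.N == 1

    def test_pair_survival_is_bernoulli(self, geom, rng):
        # fixed pair at distance rho/2, no diffusion: over n steps
        # P(reacted) = 1 - (1 - p)^n
        rx = bs.ReactionSystem(kappa1=1.0, rho=0.06, p_lambda=0.2)
        n_steps, M = 3, 2000
        reacted = 0
        for _ in range(M):
            p = bs.make_particles(geom, [0.1, 0.13])
            for _ in range(n_steps):
                p, n_rm = bs.react_pairs(p, rx, 1e-4, rng)
                if n_rm:
                    reacted += 1
                    break
        prob = 1.0 - (1.0 - 0.2) ** n_steps
        se = np.sqrt(prob * (1 - prob) / M)
        assert abs(reacted / M - prob) < 5 * se

    def test_consumed_partner_is_ineligible(self, geom, rng):
        # three mutually close particles, p=1: exactly one pair reacts
        rx = bs.ReactionSystem(kappa1=1.0, rho=0.1, p_lambda=1.0)
        p = bs.make_particles(geom, [0.50, 0.52, 0.54])
        p, n_rm = bs.react_pairs(p, rx, 1e-4, rng)
        assert n_rm == 2 and p.N == 1

    def test_scalar_noop(self, geom, rng):
        p = bs.make_particles(geom, [0.2, 0.4])
        bs.react_scalar(p, bs.ReactionSystem(), (0.0, 1.0), 1e-4, rng)
        assert p.N == 2

    def test_decay_uses_exact_exponential(self, geom, rng):
        # mu=10, dt=1e-4 -> per-particle removal prob 1 - exp(-1e-3)
        n = 200000
        p = bs.make_particles(geom, rng.uniform(0, 1, n))
        bs.react_scalar(p, bs.ReactionSystem(mu=10.0), (0.0, 1.0), 1e-4, rng)
        prob = -np.expm1(-1e-3)
        removed = n - p.N
        assert abs(removed - n * prob) < 5 * np.sqrt(n * prob)

    def test_production_mean(self, geom, rng):
        # kappa2=89.7 on a length-10/3 unit-cross-section region:
        # mean additions per step = 89.7 * (10/3) * 1e-4 = 0.0299
        g = bs.build_geometry(0.0, 10.0, 10 / 3, 20 / 3, 1.0)
        rx = bs.ReactionSystem(kappa2=89.7)
        M = 20000
        added = 0
        p = bs.make_particles(g, np.empty(0))
        for _ in range(M):
            before = p.N
            bs.react_scalar(p, rx, (20 / 3, 10.0), 1e-4, rng)
            added += p.N - before
        mean = 89.7 * (10 / 3) * 1e-4
        assert abs(added / M - mean) < 5 * np.sqrt(mean / M)
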