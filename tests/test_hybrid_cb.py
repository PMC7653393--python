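"""Compartment-Brownian coupler: mirroring, exchange, rebinning, conservation."""

import numpy as np
import pytest

import blendsim as bs
from blendsim import ConsistencyError


def _state(geom, mesh_cb, positions, pure_counts=3.0, debug=True):
    counts = np.full(mesh_cb.n_c, pure_counts)
    return bs.make_cb_state(geom, mesh_cb, 1e-4, counts,
                            np.asarray(positions, dtype=float), debug=debug)


class TestMirrorJump:
    def test_rightward_jump_moves_twin_by_h(self, geom, mesh_cb, rng):
        st = _state(geom, mesh_cb, [0.35])
        st.comp.C[10] -= 1     # the engine updates counts first
        st.comp.C[11] += 1
        bs.mirror_jump_event(st, 10, +1, rng)
        assert st.particles.x[0] == pytest.approx(0.35 + 1 / 30)

    def test_particle_count_unchanged(self, geom, mesh_cb, rng):
        st = _state(geom, mesh_cb, [0.35, 0.42])
        bs.mirror_jump_event(st, 10, +1, rng)
        assert st.particles.N == 2

    def test_sequential_moves_track_current_position(self, geom, mesh_cb, rng):
        # singleton walks left twice: the second event must find it at
        # its post-move location
        x0 = 1 / 3 + 2.5 / 30     # compartment 12
        st = _state(geom, mesh_cb, [x0])
        bs.mirror_jump_event(st, 12, -1, rng)
        bs.mirror_jump_event(st, 11, -1, rng)
        assert st.particles.x[0] == pytest.approx(x0 - 2 / 30)
        assert len(st.residents(12)) == 0 and len(st.residents(10)) == 1

    def test_empty_compartment_is_a_fault(self, geom, mesh_cb, rng):
        st = _state(geom, mesh_cb, [0.35])
        with pytest.raises(ConsistencyError):
            bs.mirror_jump_event(st, 15, +1, rng)


class TestInterfaceExchange:
    def test_entry_creates_particle_in_first_blending_compartment(
            self, geom, mesh_cb, rng):
        st = _state(geom, mesh_cb, [0.5])
        bs.exchange_at_interface(st, +1, rng)
        assert st.particles.N == 2
        x_new = st.particles.x[-1]
        assert 1 / 3 <= x_new < 1 / 3 + 1 / 30

    def test_exit_deletes_resident(self, geom, mesh_cb, rng):
        st = _state(geom, mesh_cb, [1 / 3 + 0.01, 0.9])
        bs.exchange_at_interface(st, -1, rng)
        assert st.particles.N == 1
        assert st.particles.x[0] == pytest.approx(0.9)

    def test_exit_then_entry_restores_count(self, geom, mesh_cb, rng):
        st = _state(geom, mesh_cb, [1 / 3 + 0.01])
        bs.exchange_at_interface(st, -1, rng)
        bs.exchange_at_interface(st, +1, rng)
        assert st.particles.N == 1


class TestRebin:
    def test_empty_blending(self, geom, mesh_cb):
        st = _state(geom, mesh_cb, [0.9, 0.95])
        assert np.all(st.comp.C[10:] == 0.0)

    def test_boundary_particle_goes_right(self):
        # exactly on an internal bin edge: half-open convention bins right
        # (binary-exact geometry so the edge is representable)
        g = bs.build_geometry(0.0, 4.0, 1.0, 2.0, 1.0)
        m = bs.build_mesh(g, 1 / 8, 1 / 4, "compartment-brownian")
        st = bs.make_cb_state(g, m, 1e-4, np.zeros(m.n_c),
                              np.array([1.25]), debug=True)
        ib0 = m.n_c
        assert st.comp.C[ib0] == 0.0 and st.comp.C[ib0 + 1] == 1.0

    def test_histogram_completeness(self, geom, mesh_cb, rng):
        x = rng.uniform(1 / 3, 1.0, 200)
        st = _state(geom, mesh_cb, x)
        n_blend = int(np.count_nonzero(x < 2 / 3))
        assert st.comp.C[10:].sum() == n_blend


class TestWindowPythonPath:
    def test_diffusion_conserves_total_exactly(self, geom, mesh_cb, rng):
        st = _state(geom, mesh_cb, rng.uniform(1 / 3, 1, 60), pure_counts=5.0)
        total0 = st.total_count()
        for _ in range(25):
            bs.cb_hybrid_window(st, bs.ReactionSystem(), rng)
        assert st.total_count() == total0
        # debug mode verified the count==histogram invariant every window

    def test_reactive_window_keeps_invariant(self, geom, mesh_cb, rng):
        st = _state(geom, mesh_cb, rng.uniform(1 / 3, 1, 80), pure_counts=8.0)
        rx = bs.ReactionSystem(kappa2=300.0, mu=6.0, influx_left=200.0)
        for _ in range(25):
            bs.cb_hybrid_window(st, rx, rng)
        assert st.t == pytest.approx(25e-4)
        assert np.all(st.comp.C >= 0)


class TestKernelPath:
    def test_counts_match_histogram_at_outputs(self, geom, mesh_cb, rng):
        counts = np.full(10, 33)
        pos = rng.uniform(1 / 3, 1, 670)
        out = bs.run_cb(geom, mesh_cb, 1e-4, counts, pos, bs.ReactionSystem(),
                        [0.01, 0.05], seed=5)
        # blending compartment counts equal the blending bins of the
        # Brownian histogram at every output
        np.testing.assert_array_equal(out["comp_C"][:, 10:],
                                      out["brow_hist"][:, :10])
        np.testing.assert_allclose(out["total"], 1000.0)

    def test_deterministic_given_seed(self, geom, mesh_cb, rng):
        counts = np.full(10, 20)
        pos = np.linspace(0.34, 0.99, 300)
        a = bs.run_cb(geom, mesh_cb, 1e-4, counts, pos, bs.ReactionSystem(),
                      [0.02], seed=11)
        b = bs.run_cb(geom, mesh_cb, 1e-4, counts, pos, bs.ReactionSystem(),
                      [0.02], seed=11)
        np.testing.assert_array_equal(a["comp_C"], b["comp_C"])
        np.testing.assert_array_equal(a["brow_hist"], b["brow_hist"])

    def test_morphogen_channels_run(self, geom, mesh_cb, rng):
        rx = bs.ReactionSystem(mu=10.0, influx_left=1e4)
        counts = np.full(10, 33)
        pos = rng.uniform(1 / 3, 1, 670)
        out = bs.run_cb(geom, mesh_cb, 1e-4, counts, pos, rx,
                        [0.05], seed=3)
        assert 800 < out["total"][0] < 1200
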