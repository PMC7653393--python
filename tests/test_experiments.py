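"""Run configuration, initial conditions, reproducibility, outputs."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import blendsim as bs
from blendsim.experiments import apportion


class TestRunConfig:
    def test_round_trip(self, tmp_path):
        cfg = bs.default_config("morphogen", "compartment-brownian", seed=3)
        path = tmp_path / "cfg.json"
        cfg.to_json(path)
        assert bs.RunConfig.from_json(path) == cfg

    def test_unknown_key_rejected(self):
        with pytest.raises(bs.ConfigurationError, match="unknown config keys"):
            bs.RunConfig.from_dict({"problem": "uniform", "bogus": 1})

    def test_study_defaults(self):
        u = bs.default_config("uniform")
        assert (u.N, u.D, u.h, u.dx, u.dt_p, u.repeats) == \
            (1000.0, 1.0, 1 / 30, 1 / 300, 1e-4, 500)
        m = bs.default_config("morphogen")
        assert (m.J, m.mu, m.repeats) == (1e4, 10.0, 1000)
        b = bs.default_config("bimolecular3d")
        assert (b.kappa1, b.kappa2, b.rho, b.p_lambda) == \
            (0.1, 89.7, 0.06, 2.5e-5)
        assert (b.b, b.I1, b.h, b.dimension, b.N) == (10.0, 10 / 3, 1 / 3, 3, 465.0)


class TestApportion:
    @settings(deadline=None, derandomize=True, max_examples=60)
    @given(w=st.lists(st.floats(0.0, 10.0), min_size=1, max_size=12),
           total=st.integers(0, 500))
    def test_sums_and_bounds(self, w, total):
        out = apportion(w, total)
        assert out.sum() == total
        assert np.all(out >= 0)
        wsum = sum(w)
        if wsum > 0:
            ideal = np.asarray(w) / wsum * total
            assert np.all(np.abs(out - ideal) < 1.0)


class TestInitialConditions:
    def test_uniform_cb_has_exact_particle_number(self, rng):
        cfg = bs.default_config("uniform", "compartment-brownian")
        ic = bs.make_initial_condition(cfg, rng)
        assert ic["counts"].sum() + len(ic["positions"]) == 1000

    def test_redistribution_mass_left_of_interface(self, rng):
        cfg = bs.default_config("redistribution", "compartment-brownian")
        ic = bs.make_initial_condition(cfg, rng)
        assert len(ic["positions"]) == 0
        assert ic["counts"].sum() == 1000
        cfg_pc = bs.default_config("redistribution", "pde-compartment")
        ic_pc = bs.make_initial_condition(cfg_pc, rng)
        assert np.all(ic_pc["q0"][100:] == 0.0)
        assert np.all(ic_pc["counts"] == 0.0)

    def test_bimolecular_cb_totals_and_support(self, rng):
        cfg = bs.default_config("bimolecular3d", "compartment-brownian")
        ic = bs.make_initial_condition(cfg, rng)
        # region shares 255 / 155 / 55 sum to the stated 465
        assert ic["counts"].sum() + len(ic["positions"]) == 465
        x = ic["positions"][:, 0]
        assert np.all((x >= 10 / 3) & (x <= 10.0))
        assert np.count_nonzero(x < 20 / 3) == 155
        yz = ic["positions"][:, 1:]
        assert np.all((yz >= 0) & (yz <= 1))

    def test_bimolecular_pc_matches_coarse_to_fine(self, rng):
        cfg = bs.default_config("bimolecular3d", "pde-compartment")
        geom = bs.build_geometry(0, 10, 10 / 3, 20 / 3, 1.0, dimension=3)
        mesh = bs.build_mesh(geom, cfg.dx, cfg.h, "pde-compartment")
        ic = bs.make_initial_condition(cfg, rng)
        dx = cfg.dx
        mass_p = ic["q0"][:mesh.n_p].sum() * dx
        mass_h = ic["q0"][mesh.n_p:].sum() * dx
        assert mass_p == pytest.approx(255.0)     # exact linear profile
        assert mass_h == pytest.approx(155.0)     # matched to sampled twins
        assert ic["counts"].sum() == 55

    def test_unknown_problem_rejected(self):
        with pytest.raises(bs.ConfigurationError):
            bs.default_config("frobnicate")


class TestRunExperiment:
    def test_reproducible_from_seed(self, rng):
        cfg = bs.default_config("uniform", "compartment-brownian",
                                repeats=2, seed=7, t_final=0.02,
                                output_times=[0.01, 0.02])
        r1 = bs.run_experiment(cfg)
        r2 = bs.run_experiment(cfg)
        np.testing.assert_array_equal(r1.region_masses, r2.region_masses)
        for k in r1.density:
            np.testing.assert_array_equal(r1.density[k][1], r2.density[k][1])

    def test_outputs_written(self, tmp_path):
        cfg = bs.default_config("uniform", "compartment-brownian",
                                repeats=1, seed=1, output_times=[0.01])
        bs.run_experiment(cfg, out_dir=tmp_path)
        for name in ("rme.csv", "config_resolved.json", "run_log.txt",
                     "density_0.01.csv"):
            assert (tmp_path / name).exists()

    def test_pure_pde_tracks_analytic(self):
        cfg = bs.default_config("redistribution", "pure-pde",
                                output_times=[0.05, 0.1])
        res = bs.run_experiment(cfg)
        assert res.rme.max_abs() < 1e-3    # deterministic solver vs series

    def test_ground_truth_shapes(self, rng):
        cfg = bs.default_config("bimolecular3d", output_times=[0.02, 0.05])
        gt = bs.run_ground_truth("compartment", cfg, M=3, seed=5)
        assert gt["mean_counts"].shape == (2, 30)
        assert gt["region_masses"].shape == (2, 3)
        # production/annihilation active: some mass everywhere by t=0.05
        assert np.all(gt["mean_counts"][-1] > 0)
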