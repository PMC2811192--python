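"""Solver unit tests: map assembly, linear-theory identities, precision."""

import numpy as np
import pytest

from snarepb import (ChargedStructure, PBConfig, build_maps, check_precision,
                     free_energy, interaction_energy, solve)
from snarepb._constants import coulomb_constant_kT, kT_kJ_per_mol
from snarepb.errors import BoundsError, ConfigurationError
from snarepb.gridmaps import Grid, spread_charges
from snarepb.pb_solver import fine_grid_for

UNIFORM = dict(ionic_strength=0.135, solvent_probe=0.0, ion_exclusion=0.0,
               eps_solute=78.53, eps_solvent=78.54)


def _atom(q, r, pos=(0.0, 0.0, 0.0)):
    return ChargedStructure([pos], [q], [r])


class TestMaps:
    def test_charge_conservation_single_atom(self):
        cfg = PBConfig()
        grid = Grid((-8, -8, -8), 0.5, (33, 33, 33))
        maps = build_maps([_atom(1.0, 2.0, (0.13, -0.27, 0.41))], cfg, grid)
        assert maps.total_charge == pytest.approx(1.0, abs=1e-9)

    def test_empty_system(self):
        cfg = PBConfig()
        grid = Grid((-4, -4, -4), 0.5, (17, 17, 17))
        maps = build_maps([], cfg, grid)
        assert np.all(maps.eps_node == cfg.eps_solvent)
        assert np.all(maps.kappa2 > 0)
        assert maps.rho.sum() == 0.0

    def test_voxel_classification_brute_force(self):
        rng = np.random.default_rng(7)
        xyz = rng.uniform(-5, 5, size=(20, 3))
        rad = rng.uniform(1.0, 2.5, size=20)
        s = ChargedStructure(xyz, np.zeros(20), rad)
        cfg = PBConfig()
        grid = Grid((-10, -10, -10), 1.0, (21, 21, 21))
        maps = build_maps([s], cfg, grid)
        x, y, z = grid.axes()
        X, Y, Z = np.meshgrid(x, y, z, indexing="ij")
        pts = np.stack([X, Y, Z], axis=-1)
        d = np.linalg.norm(pts[..., None, :] - xyz, axis=-1)
        inside = (d <= rad + cfg.solvent_probe).any(-1)
        assert np.array_equal(maps.eps_node == cfg.eps_solute, inside)
        ion_in = (d <= rad + cfg.ion_exclusion).any(-1) | inside
        assert np.array_equal(maps.kappa2 == 0.0, ion_in)

    def test_lambda_zero_inside_solute(self):
        cfg = PBConfig()
        grid = Grid((-6, -6, -6), 0.5, (25, 25, 25))
        maps = build_maps([_atom(1.0, 2.0)], cfg, grid)
        assert np.all(maps.kappa2[maps.eps_node == cfg.eps_solute] == 0.0)

    def test_out_of_grid_charge_raises(self):
        grid = Grid((-4, -4, -4), 0.5, (17, 17, 17))
        with pytest.raises(BoundsError):
            spread_charges(grid, np.array([[10.0, 0, 0]]), np.array([1.0]))


class TestSolve:
    def test_zero_charge_zero_potential(self):
        cfg = PBConfig(**UNIFORM)
        grid = Grid((-6, -6, -6), 0.5, (25, 25, 25))
        maps = build_maps([_atom(0.0, 0.0)], cfg, grid)
        sol = solve(maps, cfg, "nonlinear")
        assert np.abs(sol.phi).max() < 1e-12
        assert sol.energy == 0.0

    def test_coulomb_closed_form(self):
        # single charge, uniform dielectric, no salt: phi = C q / (eps r)
        cfg = PBConfig(ionic_strength=0.0, solvent_probe=0.0, ion_exclusion=0.0,
                       eps_solute=78.53, eps_solvent=78.54,
                       grid_spacing_fine=0.5, fine_pad=18.0)
        ion = _atom(1.0, 0.0)
        grid = fine_grid_for([ion], cfg)
        sol = solve(build_maps([ion], cfg, grid), cfg, "linear")
        C = coulomb_constant_kT()
        x, y, z = grid.axes()
        i0, j0, k0 = (int(np.argmin(np.abs(a))) for a in (x, y, z))
        for off in (5, 8, 12, 16):
            r = off * grid.h
            assert sol.phi[i0 + off, j0, k0] == pytest.approx(
                C / (78.54 * r), rel=0.02)

    def test_linear_superposition(self):
        cfg = PBConfig(**UNIFORM, grid_spacing_fine=0.5, fine_pad=10.0)
        a = _atom(1.0, 0.0, (-3.0, 0, 0))
        b = _atom(-0.6, 0.0, (3.0, 0, 0))
        grid = fine_grid_for([a, b], cfg)
        maps_ab = build_maps([a, b], cfg, grid)
        phi_ab = solve(maps_ab, cfg, "linear").phi
        phi_a = solve(maps_ab.with_charges([a]), cfg, "linear").phi
        phi_b = solve(maps_ab.with_charges([b]), cfg, "linear").phi
        assert np.abs(phi_ab - phi_a - phi_b).max() < 1e-3

    def test_linear_energy_equals_half_sum_q_phi(self):
        cfg = PBConfig(**UNIFORM, grid_spacing_fine=0.5, fine_pad=10.0)
        a = ChargedStructure([(-3.0, 0, 0), (3.0, 0, 0)], [1.0, -0.6], [0, 0])
        grid = fine_grid_for([a], cfg)
        maps = build_maps([a], cfg, grid)
        sol = solve(maps, cfg, "linear")
        # independent summation over the spread charge map
        oracle = 0.5 * float((maps.rho * sol.phi).sum()) * kT_kJ_per_mol()
        assert free_energy(sol, maps) == pytest.approx(oracle, rel=1e-12)

    def test_nonlinear_matches_linear_in_weak_limit(self):
        # finite-radius ions and a box several Debye lengths wide, so both
        # the sinh correction and the functional's domain truncation vanish
        cfg = PBConfig(ionic_strength=0.135, grid_spacing_fine=0.5,
                       fine_pad=26.0)
        a = _atom(0.05, 1.5, (-5.0, 0, 0))
        b = _atom(0.05, 1.5, (5.0, 0, 0))
        g_lin = interaction_energy(a, b, cfg, mode="linear")
        g_non = interaction_energy(a, b, cfg, mode="nonlinear")
        assert g_non == pytest.approx(g_lin, rel=0.01)

    def test_free_energy_grid_mismatch_raises(self):
        cfg = PBConfig(**UNIFORM)
        g1 = Grid((-4, -4, -4), 0.5, (17, 17, 17))
        g2 = Grid((-4, -4, -4), 1.0, (9, 9, 9))
        m1 = build_maps([_atom(1.0, 0.0)], cfg, g1)
        m2 = build_maps([_atom(1.0, 0.0)], cfg, g2)
        sol = solve(m1, cfg, "linear")
        with pytest.raises(ConfigurationError):
            free_energy(sol, m2)

    def test_unknown_mode_rejected(self):
        cfg = PBConfig()
        grid = Grid((-4, -4, -4), 0.5, (17, 17, 17))
        maps = build_maps([], cfg, grid)
        with pytest.raises(ConfigurationError):
            solve(maps, cfg, "quadratic")


class TestCheckPrecision:
    def test_zero_charge_probe_gives_zero_deltas(self):
        cfg = PBConfig(grid_spacing_fine=1.0, fine_pad=6.0)
        a = _atom(0.0, 1.0, (0, 0, 0))
        b = _atom(1.0, 1.0, (6.0, 0, 0))
        rep = check_precision(a, b, cfg, spacing_alt=2.0)
        assert rep["resolution_delta"] == pytest.approx(0.0, abs=1e-9)
        assert rep["margin_delta"] == pytest.approx(0.0, abs=1e-9)

    def test_delta_symmetry(self):
        # |a-b| is symmetric in which setting is called the reference
        cfg = PBConfig(grid_spacing_fine=1.0)
        a = _atom(0.5, 1.0, (0, 0, 0))
        b = _atom(0.5, 1.0, (8.0, 0, 0))
        g1 = interaction_energy(a, b, cfg)
        from dataclasses import replace
        g2 = interaction_energy(a, b, replace(cfg, grid_spacing_fine=2.0))
        assert abs(g1 - g2) == abs(g2 - g1)
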