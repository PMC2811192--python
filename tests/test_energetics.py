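"""Interaction energies and sweep plumbing (small systems only; the heavy
physics validations live in test_acceptance)."""

import numpy as np
import pytest

from snarepb import (ChargedStructure, EnergyCurve, PBConfig, build_planar,
                     interaction_energy, place_at_distance,
                     rotate_longitudinal, scan_distance)
from snarepb.energetics import curve_interpolator, curvature_curve
from snarepb.errors import InterpolationError, SweepError

SMALL = dict(ionic_strength=0.135, grid_spacing_fine=1.0, fine_pad=8.0)


def _atom(q, r, pos):
    return ChargedStructure([pos], [q], [r])


class TestInteractionEnergy:
    def test_symmetry_in_arguments(self):
        cfg = PBConfig(**SMALL)
        a = _atom(1.0, 1.5, (-4.0, 0, 0))
        b = _atom(-0.7, 1.5, (4.0, 0, 0))
        g1 = interaction_energy(a, b, cfg)
        g2 = interaction_energy(b, a, cfg)
        assert g1 == pytest.approx(g2, abs=1e-6)

    def test_unchargeable_partner_contributes_nothing(self):
        # a zero-charge, zero-radius partner leaves no trace at all
        cfg = PBConfig(**SMALL)
        a = _atom(1.0, 1.5, (-4.0, 0, 0))
        b = _atom(0.0, 0.0, (4.0, 0, 0))
        assert interaction_energy(a, b, cfg) == pytest.approx(0.0, abs=1e-6)

    def test_like_charges_repel(self):
        cfg = PBConfig(**SMALL)
        a = _atom(1.0, 0.0, (-5.0, 0, 0))
        b = _atom(1.0, 0.0, (5.0, 0, 0))
        assert interaction_energy(a, b, cfg, mode="linear") > 0

    def test_dielectric_convention_flag(self):
        cfg = PBConfig(**SMALL)
        a = _atom(1.0, 1.5, (-4.0, 0, 0))
        b = _atom(1.0, 1.5, (4.0, 0, 0))
        g_keep = interaction_energy(a, b, cfg, retain_partner_dielectric=True)
        g_drop = interaction_energy(a, b, cfg, retain_partner_dielectric=False)
        # both finite and repulsive; conventions differ by the cavity term
        assert g_keep > 0 and g_drop > 0


class TestEnergyCurve:
    def c(self):
        return EnergyCurve("distance", [1.0, 2.0, 3.0], "Å",
                           [3.0, 2.0, 1.0], [0.1, 0.2, 0.3],
                           [np.nan] * 3, {"note": "x"})

    def test_monotone_x_enforced(self):
        with pytest.raises(SweepError):
            EnergyCurve("s", [1.0, 1.0, 2.0], "", [0] * 3, [0] * 3, [0] * 3)

    def test_dG_sum(self):
        assert np.allclose(self.c().dG_sum, [3.1, 2.2, 1.3])

    def test_minimum_tie_break_smallest_abs_x(self):
        curve = EnergyCurve("orientation", [-90.0, 0.0, 90.0], "deg",
                            [1.0, 1.0, 1.0], [0.0, 0.0, 0.0], [np.nan] * 3)
        x, v = curve.minimum("dG_sum")
        assert x == 0.0

    def test_json_roundtrip_lossless(self, tmp_path):
        p = tmp_path / "c.json"
        self.c().to_json(str(p))
        back = EnergyCurve.from_json(str(p))
        assert np.array_equal(back.x, self.c().x)
        assert np.array_equal(back.dG_v, self.c().dG_v)
        assert np.isnan(back.dG_vt).all()

    def test_csv_roundtrip(self, tmp_path):
        p = tmp_path / "c.csv"
        self.c().to_csv(str(p))
        back = EnergyCurve.from_csv(str(p), "distance", "Å")
        assert np.allclose(back.dG_v, self.c().dG_v)

    def test_rotation_periodicity_geometric(self, aligned_dipolar_rod):
        # theta and theta+360 produce identical coordinates, hence identical
        # energies for any downstream solve
        a = rotate_longitudinal(aligned_dipolar_rod, 25.0)
        b = rotate_longitudinal(aligned_dipolar_rod, 385.0)
        assert np.abs(a.xyz - b.xyz).max() < 1e-9


class TestInterpolation:
    def test_exact_at_knots_and_inverse_radius(self):
        nan = [np.nan] * 3
        curve = EnergyCurve("curvature", [150.0, 200.0, np.inf], "Å",
                            [14.6, 16.4, 18.0], nan, list(nan))
        f = curve_interpolator(curve, "dG_v")
        assert float(f(150.0)) == pytest.approx(14.6, abs=1e-12)
        assert float(f(np.inf)) == pytest.approx(18.0, abs=1e-12)
        with pytest.raises(InterpolationError):
            f(100.0)


class TestSweepConsistency:
    def test_single_distance_matches_direct_call(self, aligned_dipolar_rod,
                                                 planar_membrane, suite):
        cfg = PBConfig(grid_spacing_fine=1.5)
        t_spec = suite["membrane_planar"]["spec"]
        curve = scan_distance(aligned_dipolar_rod, planar_membrane, t_spec,
                              [3.0], cfg, include_vt=False)
        s2 = place_at_distance(aligned_dipolar_rod, planar_membrane, 3.0,
                               debye_length=cfg.debye_length)
        direct = interaction_energy(s2, planar_membrane, cfg)
        assert curve.dG_v[0] == pytest.approx(direct, abs=1e-9)

    def test_unsorted_distances_rejected(self, aligned_dipolar_rod,
                                         planar_membrane, suite):
        cfg = PBConfig(grid_spacing_fine=1.5)
        with pytest.raises(SweepError):
            scan_distance(aligned_dipolar_rod, planar_membrane,
                          suite["membrane_planar"]["spec"], [5.0, 3.0], cfg)

    def test_one_point_curvature_flagged(self, aligned_dipolar_rod, suite):
        cfg = PBConfig(grid_spacing_fine=1.5)
        curve = curvature_curve(aligned_dipolar_rod,
                                suite["membrane_cap_200"]["spec"], [200.0], cfg)
        assert curve.meta["usable_for_bending"] is False
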