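"""Membrane construction: counting, charge bookkeeping and geometry."""

import numpy as np
import pytest
from dataclasses import replace

from snarepb import (ChargedStructure, MembraneSpec, build_implicit,
                     build_planar, build_vesicle, embed_tmd)
from snarepb.errors import ConfigurationError, EmbeddingError, GeometryError


class TestPlanarCounting:
    def test_528_lipid_patch_counts(self):
        # 200x100 Å patch sized so one leaflet holds 264 lipids (528 total)
        spec = MembraneSpec(extent_x=200, extent_y=100,
                            area_per_lipid=200 * 100 / 264.0,
                            ps_fraction=1.0 / 3.0)
        mem = build_planar(spec)
        assert spec.lipids_per_leaflet == 264
        assert mem.n_lipids == 528
        # counting oracle: 88 PS per leaflet -> net -176 e
        assert mem.net_charge == pytest.approx(-176.0, abs=1e-9)

    @pytest.mark.parametrize("ps,expected", [(0.0, 0.0), (1.0, None)])
    def test_composition_limits(self, ps, expected):
        spec = MembraneSpec(extent_x=80, extent_y=60, thickness=30,
                            ps_fraction=ps, seed=3)
        mem = build_planar(spec)
        if expected is None:
            expected = -mem.n_lipids
        assert mem.net_charge == pytest.approx(expected, abs=1e-9)

    def test_charge_bookkeeping_any_fraction(self):
        # PC zwitterions cancel exactly; net = -(PS count)
        spec = MembraneSpec(extent_x=90, extent_y=70, thickness=30,
                            ps_fraction=0.41, seed=5)
        mem = build_planar(spec)
        st = mem.structure
        n_ps = int((np.asarray(st.resnames) == "PS").sum())
        assert mem.net_charge == pytest.approx(-n_ps, abs=1e-9)

    def test_invalid_spec_rejected(self):
        with pytest.raises(ConfigurationError):
            MembraneSpec(ps_fraction=1.2)
        with pytest.raises(ConfigurationError):
            MembraneSpec(area_per_lipid=-1.0)
        with pytest.raises(ConfigurationError):
            MembraneSpec(thickness=6.0)  # below twice the headgroup depth


class TestImplicitSlab:
    def test_sigma_arithmetic(self):
        slab = build_implicit(MembraneSpec(ps_fraction=1 / 3, area_per_lipid=65.0))
        assert slab.sigma == pytest.approx(-1.0 / 195.0, abs=1e-12)

    def test_pure_pc_sigma_zero(self):
        assert build_implicit(MembraneSpec(ps_fraction=0.0)).sigma == 0.0

    def test_sigma_inverse_in_area(self):
        a = build_implicit(MembraneSpec(area_per_lipid=65.0)).sigma
        b = build_implicit(MembraneSpec(area_per_lipid=130.0)).sigma
        assert b == pytest.approx(a / 2.0, abs=1e-15)

    def test_sample_charge_matches_sigma(self):
        spec = MembraneSpec(extent_x=60, extent_y=40, thickness=30)
        slab = build_implicit(spec)
        pos, q = slab.charge_points()
        # each face carries sigma * area
        assert q.sum() == pytest.approx(2 * slab.sigma * 60 * 40, rel=1e-9)


class TestVesicle:
    def test_planar_limit_positions(self):
        base = dict(extent_x=100, extent_y=80, thickness=30, seed=8)
        flat = build_planar(MembraneSpec(**base))
        cap = build_vesicle(MembraneSpec(geometry="spherical_cap",
                                         radius=1e6, **base))
        d = np.abs(cap.structure.xyz - flat.structure.xyz).max()
        assert d < 0.1

    def test_area_conservation_counting(self):
        base = dict(extent_x=100, extent_y=80, thickness=30,
                    ps_fraction=1 / 3, seed=8)
        flat = build_planar(MembraneSpec(**base))
        cap = build_vesicle(MembraneSpec(geometry="spherical_cap",
                                         radius=200.0, **base))
        assert abs(cap.n_lipids - flat.n_lipids) <= 2
        assert cap.net_charge == pytest.approx(flat.net_charge, abs=1e-9)

    def test_pure_pc_neutral_at_any_radius(self):
        for R in (150.0, 400.0):
            cap = build_vesicle(MembraneSpec(geometry="spherical_cap", radius=R,
                                             extent_x=80, extent_y=60,
                                             thickness=30, ps_fraction=0.0))
            assert cap.net_charge == pytest.approx(0.0, abs=1e-9)

    def test_radius_too_small_raises(self):
        with pytest.raises(GeometryError):
            build_vesicle(MembraneSpec(geometry="spherical_cap", radius=60.0,
                                       extent_x=200, extent_y=200, thickness=30))


class TestEmbedTMD:
    def _slab(self):
        return build_implicit(MembraneSpec(extent_x=80, extent_y=60,
                                           thickness=30))

    def test_empty_segment_is_noop(self):
        s = ChargedStructure([(0, 0, 10.0)], [1.0], [1.0], resnums=[1])
        slab, out = embed_tmd(self._slab(), s, (5, 9))  # empty range
        assert out is s

    def test_segment_inside_core_accepted(self):
        s = ChargedStructure([(0, 0, -15.0)], [0.0], [1.0], resnums=[1])
        embed_tmd(self._slab(), s, (1, 1))

    def test_segment_outside_raises(self):
        s = ChargedStructure([(0, 0, 10.0)], [0.0], [1.0], resnums=[1])
        with pytest.raises(EmbeddingError):
            embed_tmd(self._slab(), s, (1, 1))


def test_stride_ps_placement_is_uniform():
    # quarters of the patch carry near-equal PS counts
    spec = MembraneSpec(extent_x=120, extent_y=120, thickness=30,
                        ps_fraction=1 / 3, seed=2)
    mem = build_planar(spec)
    st = mem.structure
    ps = np.asarray(st.resnames) == "PS"
    xyz = st.xyz[ps]
    counts = np.array([((np.sign(xyz[:, 0]) == sx)
                        & (np.sign(xyz[:, 1]) == sy)).sum()
                       for sx in (-1, 1) for sy in (-1, 1)], float)
    assert counts.std() / counts.mean() < 0.15
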