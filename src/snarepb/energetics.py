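"""Protein-membrane interaction free energies and sweep drivers.

The interaction free energy of two components is

    dG_int = G(A+B) - G(A) - G(B)   (positive = repulsive)

with all three solves performed on the *identical* fine and coarse grids so
that grid self-energies cancel exactly.  By default the single-component
solves zero the partner's charges but retain its dielectric cavity and ion
exclusion, making dG_int a pure charge-interaction quantity; the opposite
convention is available behind ``retain_partner_dielectric=False``.

Sweep drivers reproduce the four study scans: lateral orientation angle,
surface-to-surface distance, PS fraction and v-membrane curvature radius.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace as dc_replace

import numpy as np
import pandas as pd

from .errors import ConfigurationError, InterpolationError, SweepError
from .membranes import MembraneSpec, build_explicit, build_implicit, PLANAR
from .pb_solver import (PBConfig, build_maps, fine_grid_for,
                        focused_solve_chain, focusing_grids)
from .structures import ChargedStructure, place_at_distance, rotate_longitudinal

DEFAULT_DISTANCE = 3.0  # Å, one water layer between vdW surfaces


# -------------------------------------------------------------- energy core
def interaction_energy(A, B, cfg: PBConfig, mode: str | None = None,
                       retain_partner_dielectric: bool = True,
                       fine_grid=None, details: dict | None = None) -> float:
    """Interaction free energy dG_int(A, B) in kJ/mol."""
    comps = [A, B]
    fine = fine_grid or fine_grid_for(comps, cfg)
    grids = focusing_grids(comps, cfg, fine)
    if retain_partner_dielectric:
        # union geometry maps built once, reused for all three charge states
        union = [build_maps(comps, cfg, g) for g in grids]

        def G(subset):
            return focused_solve_chain([m.with_charges(subset) for m in union],
                                       cfg, mode).energy
    else:
        def G(subset):
            return focused_solve_chain([build_maps(subset, cfg, g)
                                        for g in grids], cfg, mode).energy

    g_ab, g_a, g_b = G([A, B]), G([A]), G([B])
    if details is not None:
        details.update(G_AB=g_ab, G_A=g_a, G_B=g_b,
                       fine_grid=fine, coarse_grid=grids[0])
    return g_ab - g_a - g_b


# ------------------------------------------------------------------- curves
@dataclass
class EnergyCurve:
    """One sweep result: interaction free energy versus a swept variable.

    dG_v / dG_t are protein-membrane energies against the v- and t-membrane,
    dG_vt the membrane-membrane energy with the protein extracted, dG_sum
    the sum dG_v + dG_t where both are defined.  NaN marks columns a sweep
    does not compute.
    """

    sweep_name: str
    x: np.ndarray
    x_unit: str
    dG_v: np.ndarray
    dG_t: np.ndarray
    dG_vt: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.x = np.asarray(self.x, float)
        for name in ("dG_v", "dG_t", "dG_vt"):
            setattr(self, name, np.asarray(getattr(self, name), float))
        d = np.diff(self.x)
        if len(self.x) > 1 and not (np.all(d > 0) or np.all(d < 0)):
            raise SweepError("sweep values must be strictly monotone")

    @property
    def dG_sum(self) -> np.ndarray:
        return self.dG_v + self.dG_t

    def minimum(self, column: str = "dG_sum"):
        """(x, value) of the sweep minimum; ties go to the smallest |x|."""
        y = getattr(self, column)
        best = np.min(y)
        cand = np.where(np.isclose(y, best, rtol=0, atol=1e-12))[0]
        i = cand[np.argmin(np.abs(self.x[cand]))]
        return float(self.x[i]), float(y[i])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"x": self.x, "dG_v": self.dG_v, "dG_t": self.dG_t,
                             "dG_vt": self.dG_vt, "dG_sum": self.dG_sum})

    def to_csv(self, path):
        self.to_frame().to_csv(path, index=False)

    def to_json(self, path_or_none=None):
        d = {"sweep_name": self.sweep_name, "x_unit": self.x_unit,
             "x": self.x.tolist(), "dG_v": self.dG_v.tolist(),
             "dG_t": self.dG_t.tolist(), "dG_vt": self.dG_vt.tolist(),
             "meta": _jsonable(self.meta)}
        if path_or_none is None:
            return json.dumps(d)
        with open(path_or_none, "w") as fh:
            json.dump(d, fh, indent=1)

    @classmethod
    def from_json(cls, src) -> "EnergyCurve":
        d = json.loads(src) if isinstance(src, str) and src.lstrip().startswith("{") \
            else json.load(open(src))
        return cls(d["sweep_name"], d["x"], d["x_unit"], d["dG_v"], d["dG_t"],
                   d["dG_vt"], d.get("meta", {}))

    @classmethod
    def from_csv(cls, path, sweep_name="curve", x_unit="") -> "EnergyCurve":
        df = pd.read_csv(path)
        return cls(sweep_name, df["x"], x_unit, df["dG_v"], df["dG_t"],
                   df["dG_vt"])


def _jsonable(d):
    out = {}
    for k, v in d.items():
        try:
            json.dumps(v)
            out[k] = v
        except TypeError:
            out[k] = repr(v)
    return out


# -------------------------------------------------------------- positioning
def _structure_top(s: ChargedStructure) -> float:
    return float((s.xyz[:, 2] + s.radius).max())


def _place_between(s, v_mem, t_spec: MembraneSpec | None, d: float, cfg):
    """Protein d above the v-membrane surface; optional t-membrane rebuilt d
    above the protein's top (facing down)."""
    s2 = place_at_distance(s, v_mem, d, side="above",
                           debye_length=cfg.debye_length)
    t_mem = None
    if t_spec is not None:
        t_mem = build_explicit(dc_replace(
            t_spec, facing=-1, surface_z=_structure_top(s2) + d))
    return s2, t_mem


# ------------------------------------------------------------------- sweeps
def scan_orientation(s: ChargedStructure, v_membrane, t_membrane,
                     angles, cfg: PBConfig, distance: float = DEFAULT_DISTANCE,
                     mode: str | None = None) -> EnergyCurve:
    """Interaction energies versus lateral rotation about the longitudinal
    axis; angle 0 is the structurally preferred (anchor-aligned) orientation."""
    angles = np.asarray(list(angles), float)
    if angles.size < 2:
        raise SweepError("orientation sweep needs at least 2 angles")
    t_spec = t_membrane.spec if hasattr(t_membrane, "spec") else t_membrane
    dv, dt = [], []
    for th in angles:
        s_rot = rotate_longitudinal(s, th)
        s2, t_mem = _place_between(s_rot, v_membrane, t_spec, distance, cfg)
        dv.append(interaction_energy(s2, v_membrane, cfg, mode))
        dt.append(interaction_energy(s2, t_mem, cfg, mode))
    curve = EnergyCurve("orientation", angles, "deg", dv, dt,
                        np.full(angles.size, np.nan))
    ang, val = curve.minimum("dG_sum")
    curve.meta.update(minimum_angle=ang, minimum_dG_sum=val,
                      distance=distance)
    return curve


def scan_distance(s: ChargedStructure, v_membrane, t_membrane,
                  distances, cfg: PBConfig, mode: str | None = None,
                  include_vt: bool = True) -> EnergyCurve:
    """Interaction energies versus the vertical vdW surface-to-surface
    distance (same gap to both membranes)."""
    distances = np.asarray(list(distances), float)
    if np.any(distances < 0) or np.any(np.diff(distances) <= 0):
        raise SweepError("distances must be >= 0 and strictly increasing")
    t_spec = t_membrane.spec if hasattr(t_membrane, "spec") else t_membrane
    dv, dt, dvt = [], [], []
    for d in distances:
        try:
            s2, t_mem = _place_between(s, v_membrane, t_spec, d, cfg)
        except Exception as exc:
            raise SweepError(f"placement failed at distance {d} Å: {exc}") from exc
        dv.append(interaction_energy(s2, v_membrane, cfg, mode))
        dt.append(interaction_energy(s2, t_mem, cfg, mode))
        dvt.append(interaction_energy(v_membrane, t_mem, cfg, mode)
                   if include_vt else np.nan)
    return EnergyCurve("distance", distances, "Å", dv, dt, dvt)


def scan_composition(s: ChargedStructure, spec_base: MembraneSpec,
                     ps_fractions, cfg: PBConfig,
                     distance: float = DEFAULT_DISTANCE,
                     mode: str | None = None) -> EnergyCurve:
    """Interaction energies versus PS fraction (membranes rebuilt per point)."""
    fr = np.asarray(list(ps_fractions), float)
    if np.any((fr < 0) | (fr > 1)):
        raise ConfigurationError("ps_fractions must lie in [0, 1]")
    dv, dt = [], []
    t_spec = dc_replace(spec_base, geometry="planar", radius=PLANAR)
    for f in fr:
        v_mem = build_explicit(dc_replace(spec_base, ps_fraction=float(f)))
        s2, t_mem = _place_between(
            s, v_mem, dc_replace(t_spec, ps_fraction=float(f)), distance, cfg)
        dv.append(interaction_energy(s2, v_mem, cfg, mode))
        dt.append(interaction_energy(s2, t_mem, cfg, mode))
    return EnergyCurve("composition", fr, "PS fraction", dv, dt,
                       np.full(fr.size, np.nan), {"distance": distance})


def curvature_curve(s: ChargedStructure, spec_base: MembraneSpec, radii,
                    cfg: PBConfig, distance: float = DEFAULT_DISTANCE,
                    mode: str | None = None) -> EnergyCurve:
    """Standard curve: protein / v-membrane interaction energy versus the
    vesicle local radius (np.inf entry = planar membrane)."""
    radii = np.asarray(list(radii), float)
    if np.any(np.diff(radii) <= 0):
        raise SweepError("radii must be strictly increasing")
    if np.any(radii[np.isfinite(radii)] <= spec_base.thickness / 2):
        raise SweepError("radii must exceed thickness/2")
    dv = []
    for R in radii:
        if np.isfinite(R):
            spec = dc_replace(spec_base, geometry="spherical_cap", radius=float(R))
        else:
            spec = dc_replace(spec_base, geometry="planar", radius=PLANAR)
        v_mem = build_explicit(spec)
        s2 = place_at_distance(s, v_mem, distance, side="above",
                               debye_length=cfg.debye_length)
        dv.append(interaction_energy(s2, v_mem, cfg, mode))
    nan = np.full(radii.size, np.nan)
    curve = EnergyCurve("curvature", radii, "Å", dv, nan, nan.copy(),
                        {"distance": distance,
                         "usable_for_bending": radii.size >= 2})
    return curve


# ------------------------------------------------- explicit/implicit check
def explicit_implicit_delta(s: ChargedStructure, spec: MembraneSpec,
                            cfg: PBConfig, distance: float = DEFAULT_DISTANCE,
                            mode: str | None = None) -> dict:
    """Interaction energy of ``s`` against the explicit charge-lattice
    membrane and against the matched-sigma implicit slab, same placement."""
    mem_e = build_explicit(spec)
    mem_i = build_implicit(spec)
    s2 = place_at_distance(s, mem_e, distance, side="above",
                           debye_length=cfg.debye_length)
    g_e = interaction_energy(s2, mem_e, cfg, mode)
    g_i = interaction_energy(s2, mem_i, cfg, mode)
    return {"explicit": g_e, "implicit": g_i, "delta": abs(g_e - g_i)}


# ------------------------------------------------------------- interpolation
def curve_interpolator(curve: EnergyCurve, column: str = "dG_v"):
    """Monotone piecewise-cubic interpolant in 1/radius for radius sweeps
    (np.inf maps to 0), plain x otherwise.  Exact at the knots."""
    from scipy.interpolate import PchipInterpolator

    y = getattr(curve, column)
    if curve.sweep_name == "curvature":
        u = 1.0 / curve.x
    else:
        u = curve.x.copy()
    order = np.argsort(u)
    u, y = u[order], y[order]
    if len(u) < 2:
        raise InterpolationError("need at least two knots to interpolate")
    pch = PchipInterpolator(u, y, extrapolate=False)
    lo, hi = u[0], u[-1]

    def f(x):
        ux = 1.0 / np.asarray(x, float) if curve.sweep_name == "curvature" \
            else np.asarray(x, float)
        if np.any((ux < lo - 1e-12) | (ux > hi + 1e-12)):
            raise InterpolationError(f"query outside curve range")
        return pch(np.clip(ux, lo, hi))

    return f
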