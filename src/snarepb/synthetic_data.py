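"""Synthetic fixtures: SNARE-like charged rods, point-charge probes and
paired membrane specifications.

The rod generator emulates the charge motifs that drive the membrane
energetics of a four-helix fusion bundle -- net negative surface charge, a
laterally asymmetric (sectored) charge face, and a C-terminal positive
cluster -- as controllable knobs on a 4-start helical site lattice, without
pretending to be an all-atom SNARE model.

Conventions: the rod axis lies along +x centred at the origin; azimuth is
measured in the yz-plane from +y toward +z, so azimuth +90 deg faces the
t-membrane (+z) and -90 deg the v-membrane (-z) once the rod is placed
between membranes.  Anchors "vamp_cterm" (-z side) and "syx_cterm" (+z side)
sit at the C-terminal (+x) end, so aligning their axis to +z is the identity
for a freshly generated rod.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict, replace
from pathlib import Path

import numpy as np

from .errors import SpecError
from .membranes import MembraneSpec
from .structures import ChargedStructure

PATTERNS = ("uniform_negative", "dipolar_lateral", "cterm_positive_cluster",
            "cylindrically_symmetric")


@dataclass(frozen=True)
class RodSpec:
    """Parameters of a synthetic charged helical bundle."""

    length: float = 120.0            # Å, SNARE-bundle scale
    helix_radius: float = 5.0        # Å
    n_sites: int = 120
    charge_pattern: str = "uniform_negative"
    net_charge: float = -10.0        # e
    site_radius: float = 2.0         # Å vdW radius per site
    n_starts: int = 4
    pitch: float | None = None       # Å per turn; None = pattern default
    sector_halfwidth: float = 60.0   # deg, dipolar sector half-width
    cterm_fraction: float = 0.2      # tail fraction holding the + cluster
    cterm_charge: float = 4.0        # e in the C-terminal cluster
    anchor_offsets: tuple | None = None
    jitter: float = 0.0              # Å uniform site jitter
    seed: int = 0

    def __post_init__(self):
        if self.n_sites < 2:
            raise SpecError("n_sites must be >= 2")
        if self.charge_pattern not in PATTERNS:
            raise SpecError(f"unknown charge pattern {self.charge_pattern!r}")


def _default_pitch(spec: RodSpec) -> float | None:
    # twisted lattice for azimuthal uniformity; straight rows where a
    # well-defined lateral sector is required
    if spec.charge_pattern in ("cylindrically_symmetric",):
        return 60.0
    return None


def make_rod(spec: RodSpec) -> ChargedStructure:
    """Generate the rod as a ChargedStructure; pure function of spec + seed."""
    rng = np.random.default_rng(spec.seed)
    m = spec.n_sites // spec.n_starts
    if m < 2:
        raise SpecError("n_sites too small for the number of helix starts")
    n = m * spec.n_starts
    pitch = spec.pitch if spec.pitch is not None else _default_pitch(spec)

    xs = np.tile(np.linspace(-spec.length / 2, spec.length / 2, m), spec.n_starts)
    phase = np.repeat(np.arange(spec.n_starts) * (360.0 / spec.n_starts), m)
    az = phase + (360.0 * (xs + spec.length / 2) / pitch if pitch else 0.0)
    az_rad = np.deg2rad(az)
    xyz = np.column_stack([xs,
                           spec.helix_radius * np.cos(az_rad),
                           spec.helix_radius * np.sin(az_rad)])
    if spec.jitter > 0:
        xyz = xyz + rng.uniform(-spec.jitter, spec.jitter, xyz.shape)

    q = _charges(spec, xs, az)
    names = [f"S{k}" for k in range(n)]
    anchors = {}
    extra = 0
    if spec.anchor_offsets is not None:
        a0, a1 = (np.asarray(a, float) for a in spec.anchor_offsets)
        xyz = np.vstack([xyz, a0, a1])
        q = np.concatenate([q, [0.0, 0.0]])
        names += ["AV", "AT"]
        anchors = {"vamp_cterm": n, "syx_cterm": n + 1}
        extra = 2
    else:
        for name, zsign in (("vamp_cterm", -1.0), ("syx_cterm", 1.0)):
            target = np.array([spec.length / 2, 0.0, zsign * spec.helix_radius])
            anchors[name] = int(np.argmin(np.linalg.norm(xyz - target, axis=1)))

    radii = np.full(n + extra, spec.site_radius)
    if extra:
        radii[-2:] = 0.1
    s = ChargedStructure(xyz, q, radii, names, ["ROD"] * (n + extra),
                         np.arange(1, n + extra + 1), ["R"] * (n + extra),
                         anchors=anchors,
                         longitudinal_axis=[1.0, 0.0, 0.0],
                         meta={"rod_spec": asdict(spec),
                               "declared_net_charge": spec.net_charge})
    assert abs(s.net_charge - spec.net_charge) < 1e-9
    return s


def _charges(spec: RodSpec, xs, az) -> np.ndarray:
    n = len(xs)
    q = np.zeros(n)
    wrapped = (az + 180.0) % 360.0 - 180.0
    if spec.charge_pattern in ("uniform_negative", "cylindrically_symmetric"):
        q[:] = spec.net_charge / n
    elif spec.charge_pattern == "dipolar_lateral":
        if spec.net_charge >= 0:
            raise SpecError("dipolar_lateral requires a negative net charge")
        sector = np.abs(wrapped) <= spec.sector_halfwidth
        if not sector.any():
            raise SpecError("no lattice sites fall inside the charge sector")
        q[sector] = spec.net_charge / sector.sum()
    elif spec.charge_pattern == "cterm_positive_cluster":
        tail = xs >= spec.length / 2 - spec.cterm_fraction * spec.length
        if not tail.any() or tail.all():
            raise SpecError("C-terminal fraction selects no (or all) sites")
        q[tail] = spec.cterm_charge / tail.sum()
        q[~tail] = (spec.net_charge - spec.cterm_charge) / (~tail).sum()
    return q


def azimuthal_moment(s: ChargedStructure) -> tuple[float, float]:
    """(magnitude, direction deg) of the |q|-weighted azimuthal first moment
    about the +x axis: an independent check of lateral charge asymmetry."""
    w = np.abs(s.charge)
    if w.sum() == 0:
        return 0.0, 0.0
    vy = float((w * s.xyz[:, 1]).sum() / w.sum())
    vz = float((w * s.xyz[:, 2]).sum() / w.sum())
    return float(np.hypot(vy, vz)), float(np.rad2deg(np.arctan2(vz, vy)))


# ------------------------------------------------------------ benchmark set
# Desk-scale benchmark geometry: a compact 40 Å rod between ~110x80 Å
# membrane patches keeps 0.5 Å focused grids tractable on one CPU while
# preserving every qualitative feature (net charge sign, lateral asymmetry,
# 4-Debye-length membrane margins).
BENCH_ROD = dict(length=40.0, helix_radius=5.0, n_sites=96, net_charge=-8.0)
BENCH_MEMBRANE = dict(extent_x=114.0, extent_y=82.0, thickness=30.0,
                      ps_fraction=1.0 / 3.0, area_per_lipid=65.0)


def make_benchmark_suite(seed: int = 0) -> dict:
    """Named fixtures used throughout the validation suite; bit-reproducible
    for a fixed seed."""
    rng = np.random.default_rng(seed)
    seeds = rng.integers(0, 2**31 - 1, size=8)

    def atom(q, r, pos=(0.0, 0.0, 0.0)):
        return ChargedStructure([pos], [q], [r], ["ION"], ["ION"], [1], ["I"])

    suite = {
        "born_ion": {
            "structure": atom(1.0, 2.0),
            "expect": {"charge_e": 1.0, "radius_A": 2.0,
                       "oracle": "born_solvation"},
        },
        "dh_sphere": {
            "structure": atom(1.0, 2.0),
            "expect": {"oracle": "debye_hueckel_sphere", "r_range_A": [6, 15]},
        },
        "screened_pair": {
            "structure_a": atom(1.0, 0.0, (-5.0, 0.0, 0.0)),
            "structure_b": atom(1.0, 0.0, (5.0, 0.0, 0.0)),
            "expect": {"separation_A": 10.0, "oracle": "screened_coulomb"},
        },
        "gouy_chapman_plane": {
            "spec": MembraneSpec(extent_x=150.0, extent_y=150.0, thickness=20.0,
                                 ps_fraction=0.325, area_per_lipid=65.0,
                                 seed=int(seeds[0])),
            "expect": {"sigma_e_per_A2": -0.005, "oracle": "gouy_chapman"},
        },
        "rod_symmetric": {
            # 8-start lattice with an incommensurate twist: the azimuthal
            # envelope is near-continuous, so orientation scans are flat
            "structure": make_rod(RodSpec(charge_pattern="cylindrically_symmetric",
                                          n_starts=8, pitch=52.0,
                                          seed=int(seeds[1]), **BENCH_ROD)),
            "expect": {"orientation_scan": "flat"},
        },
        "rod_dipolar": {
            "structure": make_rod(RodSpec(charge_pattern="dipolar_lateral",
                                          seed=int(seeds[2]), **BENCH_ROD)),
            "expect": {"orientation_minimum_deg": 0.0,
                       "sector_azimuth_deg": 0.0},
        },
        "rod_cterm": {
            "structure": make_rod(RodSpec(charge_pattern="cterm_positive_cluster",
                                          seed=int(seeds[3]), **BENCH_ROD)),
            "expect": {"cterm_charge_e": 4.0},
        },
        "membrane_planar": {
            "spec": MembraneSpec(seed=int(seeds[4]), **BENCH_MEMBRANE),
            "expect": {"composition": "2:1 PC/PS"},
        },
        "membrane_cap_200": {
            "spec": MembraneSpec(geometry="spherical_cap", radius=200.0,
                                 seed=int(seeds[4]), **BENCH_MEMBRANE),
            "expect": {"vesicle_diameter_nm": 40.0},
        },
    }
    return suite


def write_fixtures(outdir, seed: int = 0) -> list[str]:
    """Write every benchmark fixture as PQR (structures) / JSON (specs)."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    written = []
    for name, fx in make_benchmark_suite(seed).items():
        meta = {"name": name, "seed": seed, "expect": fx.get("expect", {})}
        for key, val in fx.items():
            if isinstance(val, ChargedStructure):
                p = out / f"{name}_{key}.pqr"
                val.to_pqr(str(p))
                written.append(str(p))
                meta[f"{key}_net_charge"] = val.net_charge
            elif isinstance(val, MembraneSpec):
                meta[key] = asdict(val)
        p = out / f"{name}.json"
        with open(p, "w") as fh:
            json.dump(meta, fh, indent=1)
        written.append(str(p))
    return written
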