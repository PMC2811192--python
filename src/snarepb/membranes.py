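"""Planar and curved bilayer models with configurable PC/PS composition.

Two representations are provided:

* :class:`ExplicitMembrane` -- a charge lattice (one site set per leaflet) on
  a jittered hexagonal grid, PS headgroups carrying -1 e at the surface plane
  and PC headgroups a +1/-1 zwitterion pair (choline at the surface, phosphate
  4 Å inward).  The low-dielectric, ion-excluded interior is described by an
  analytic region rather than by atom spheres, so the dielectric boundary is
  the headgroup surface itself.

* :class:`ImplicitSlab` -- the same geometry with each headgroup face carrying
  a uniform surface charge density sigma = -ps_fraction / area_per_lipid.

Curved v-membranes are spherical caps built by Lambert equal-area projection
of the *same* planar lattice, so lipid counts and per-lipid charges match the
planar patch exactly and the planar limit is recovered as radius -> inf.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict

import numpy as np

from .errors import ConfigurationError, EmbeddingError, GeometryError
from .structures import ChargedStructure

PC_DIPOLE_SEP = 4.0   # Å between choline (+) and phosphate (-) sites
PLANAR = float("inf")  # radius sentinel for planar geometry


# ----------------------------------------------------------------- spec type
@dataclass
class MembraneSpec:
    """Parametric description of a bilayer patch.

    ``facing`` is +1 when the charged surface faces up (+z, membrane below
    the protein: v-membrane convention) and -1 when it faces down (membrane
    above the protein: t-membrane convention).  ``surface_z`` positions the
    proximal headgroup surface.
    """

    geometry: str = "planar"            # "planar" | "spherical_cap"
    radius: float = PLANAR              # Å, outer-leaflet radius (spherical)
    extent_x: float = 200.0             # Å
    extent_y: float = 100.0             # Å
    thickness: float = 60.0             # Å, full bilayer incl. headgroups
    ps_fraction: float = 1.0 / 3.0      # 2:1 PC/PS default
    area_per_lipid: float = 65.0        # Å^2, fluid-phase PC typical
    headgroup_depth: float = 4.0        # Å of hydrated headgroup region per face
    seed: int = 0
    facing: int = 1
    surface_z: float = 0.0
    center_xy: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self):
        if not (0.0 <= self.ps_fraction <= 1.0):
            raise ConfigurationError("ps_fraction must lie in [0, 1]")
        if self.thickness <= 0 or self.extent_x <= 0 or self.extent_y <= 0:
            raise ConfigurationError("thickness and extents must be positive")
        if self.thickness <= 2 * self.headgroup_depth:
            raise ConfigurationError("thickness must exceed twice the "
                                     "headgroup depth")
        if self.area_per_lipid <= 0:
            raise ConfigurationError("area_per_lipid must be positive")
        if self.geometry not in ("planar", "spherical_cap"):
            raise ConfigurationError(f"unknown geometry {self.geometry!r}")
        if self.geometry == "spherical_cap":
            if not np.isfinite(self.radius) or self.radius <= self.thickness / 2:
                raise GeometryError("spherical cap needs radius > thickness/2")
        if self.facing not in (1, -1):
            raise ConfigurationError("facing must be +1 or -1")

    @property
    def lipids_per_leaflet(self) -> int:
        return int(round(self.extent_x * self.extent_y / self.area_per_lipid))


# -------------------------------------------------------------- hex lattice
def _hex_lattice(spec: MembraneSpec, rng: np.random.Generator) -> np.ndarray:
    """Jittered hexagonal lattice with exactly ``lipids_per_leaflet`` sites.

    Sites are generated on a hex grid slightly larger than the patch and the
    n closest to the patch centre are kept, which pins the count while
    preserving uniform coverage.
    """
    n_target = spec.lipids_per_leaflet
    a = np.sqrt(2.0 * spec.area_per_lipid / np.sqrt(3.0))  # hex spacing
    dy = a * np.sqrt(3.0) / 2.0
    nx = int(np.ceil(spec.extent_x / a)) + 2
    ny = int(np.ceil(spec.extent_y / dy)) + 2
    pts = []
    for j in range(-ny, ny + 1):
        off = 0.5 * a if j % 2 else 0.0
        for i in range(-nx, nx + 1):
            pts.append((i * a + off, j * dy))
    pts = np.array(pts)
    pts += rng.uniform(-0.5, 0.5, size=pts.shape)   # seeded lattice jitter
    # rank by max(|x|/ex, |y|/ey) so the kept set tiles the rectangle
    score = np.maximum(np.abs(pts[:, 0]) / spec.extent_x,
                       np.abs(pts[:, 1]) / spec.extent_y)
    keep = np.argsort(score, kind="stable")[:n_target]
    out = pts[np.sort(keep)]
    out[:, 0] += spec.center_xy[0]
    out[:, 1] += spec.center_xy[1]
    return out


def _assign_ps(n_sites: int, ps_fraction: float, rng: np.random.Generator,
               placement: str = "stride"):
    """PS site selection.

    ``stride`` (default) distributes PS quasi-uniformly over the lattice
    (every 1/ps_fraction-th site, seeded phase), emulating the regular PC/PS
    mixtures of atomic bilayer models; ``random`` draws sites uniformly,
    which adds realistic composition shot noise but makes small-patch
    energies realization-dependent.
    """
    n_ps = int(round(n_sites * ps_fraction))
    if n_ps == 0:
        return np.zeros(n_sites, bool)
    if placement == "stride":
        idx = np.floor((np.arange(n_ps) + rng.uniform(0.0, 1.0))
                       * (n_sites / n_ps)).astype(int)
        idx = np.clip(idx, 0, n_sites - 1)
    else:
        idx = rng.choice(n_sites, size=n_ps, replace=False)
    mask = np.zeros(n_sites, bool)
    mask[idx] = True
    # stride rounding can collide; top up deterministically
    short = n_ps - mask.sum()
    if short > 0:
        mask[np.where(~mask)[0][:short]] = True
    return mask


# ------------------------------------------------------------------ surfaces
class _PlanarSurface:
    def __init__(self, spec: MembraneSpec):
        self.spec = spec
        self.z = spec.surface_z
        self.f = spec.facing

    def height(self, x, y):
        return np.full(np.shape(x), self.z, float)

    def region_mask(self, X, Y, Z, dilate=0.0):
        """Low-dielectric hydrocarbon core (headgroup layers excluded),
        dilated outward by ``dilate`` Å."""
        s = self.spec
        hd = s.headgroup_depth - dilate
        zin = ((Z <= self.z - hd) & (Z >= self.z - s.thickness + hd)
               if self.f > 0 else
               (Z >= self.z + hd) & (Z <= self.z + s.thickness - hd))
        return (zin
                & (np.abs(X - s.center_xy[0]) <= s.extent_x / 2)
                & (np.abs(Y - s.center_xy[1]) <= s.extent_y / 2))


class _SphericalSurface:
    """Upper cap of a sphere (outer leaflet radius R), surface facing +z."""

    def __init__(self, spec: MembraneSpec):
        self.spec = spec
        self.R = spec.radius
        self.center = np.array([spec.center_xy[0], spec.center_xy[1],
                                spec.surface_z - spec.radius])

    def height(self, x, y):
        dx = np.asarray(x, float) - self.center[0]
        dy = np.asarray(y, float) - self.center[1]
        rho2 = dx * dx + dy * dy
        h = np.full(np.shape(rho2), np.nan)
        ok = rho2 < self.R**2
        h[ok] = self.center[2] + np.sqrt(self.R**2 - rho2[ok])
        return h

    def region_mask(self, X, Y, Z, dilate=0.0):
        s = self.spec
        hd = s.headgroup_depth - dilate
        d2 = ((X - self.center[0])**2 + (Y - self.center[1])**2
              + (Z - self.center[2])**2)
        shell = ((d2 <= (self.R - hd)**2)
                 & (d2 >= max(self.R - s.thickness + hd, 0.0)**2))
        return shell & (Z > self.center[2])


# ------------------------------------------------------------------- models
class _MembraneBase:
    """Shared surface-query API for explicit and implicit membranes."""

    spec: MembraneSpec
    surface: object

    def footprint(self):
        s = self.spec
        return (s.center_xy[0] - s.extent_x / 2, s.center_xy[0] + s.extent_x / 2,
                s.center_xy[1] - s.extent_y / 2, s.center_xy[1] + s.extent_y / 2)

    def vertical_gaps(self, xyz, radii, side: str = "above") -> np.ndarray:
        """Per-atom vertical gap between atom sphere and membrane surface.

        NaN for atoms whose (x, y) column misses the surface.
        """
        h = self.surface.height(xyz[:, 0], xyz[:, 1])
        if side == "above":
            return (xyz[:, 2] - radii) - h
        if side == "below":
            return h - (xyz[:, 2] + radii)
        raise ConfigurationError(f"unknown side {side!r}")

    def region_mask(self, X, Y, Z):
        return self.surface.region_mask(X, Y, Z)

    def ion_region_mask(self, X, Y, Z, stern: float):
        """Ion exclusion: everything below the charged headgroup surface plus
        a Stern layer of width ``stern`` beyond it."""
        return self.surface.region_mask(
            X, Y, Z, dilate=self.spec.headgroup_depth + stern)


class ExplicitMembrane(_MembraneBase):
    """Charge-lattice bilayer: a ChargedStructure of headgroup sites plus an
    analytic surface for gap queries and dielectric/ion region marking."""

    def __init__(self, structure: ChargedStructure, spec: MembraneSpec, surface):
        self.structure = structure
        self.spec = spec
        self.surface = surface

    @property
    def net_charge(self) -> float:
        return self.structure.net_charge

    @property
    def n_lipids(self) -> int:
        return int(self.structure.meta["n_lipids"])

    def charge_points(self):
        return self.structure.xyz, self.structure.charge

    def to_pqr(self, path):
        self.structure.to_pqr(path)


class ImplicitSlab(_MembraneBase):
    """Uniformly charged slab: sigma (e/Å^2) on each headgroup face, low
    dielectric interior.  Face charge is realized on the grid by an equal-area
    sample-point sheet, spread with the same trilinear scheme as atoms."""

    SAMPLE_SPACING = 1.0  # Å, surface sample lattice

    def __init__(self, spec: MembraneSpec):
        self.spec = spec
        self.sigma = -spec.ps_fraction / spec.area_per_lipid
        self.surface = (_PlanarSurface(spec) if spec.geometry == "planar"
                        else _SphericalSurface(spec))
        self._samples = None

    def charge_points(self):
        if self._samples is None:
            self._samples = self._build_samples()
        return self._samples

    def _build_samples(self):
        s = self.spec
        ss = self.SAMPLE_SPACING
        nx = max(1, int(round(s.extent_x / ss)))
        ny = max(1, int(round(s.extent_y / ss)))
        x = s.center_xy[0] + (np.arange(nx) - (nx - 1) / 2) * (s.extent_x / nx)
        y = s.center_xy[1] + (np.arange(ny) - (ny - 1) / 2) * (s.extent_y / ny)
        X, Y = np.meshgrid(x, y, indexing="ij")
        flat = np.column_stack([X.ravel(), Y.ravel()])
        q_cell = self.sigma * (s.extent_x / nx) * (s.extent_y / ny)
        pts, qs = [], []
        for face in ("proximal", "distal"):
            if s.geometry == "planar":
                z = (s.surface_z if face == "proximal"
                     else s.surface_z - s.facing * s.thickness)
                P = np.column_stack([flat, np.full(len(flat), z)])
            else:
                R = s.radius if face == "proximal" else s.radius - s.thickness
                P = _lambert_to_sphere(flat, s, R)
            pts.append(P)
            qs.append(np.full(len(P), q_cell))
        return np.vstack(pts), np.concatenate(qs)

    def to_json(self, path):
        d = {"kind": "implicit_slab", "sigma_e_per_A2": self.sigma,
             "spec": asdict(self.spec)}
        with open(path, "w") as fh:
            json.dump(d, fh, indent=1)


# ------------------------------------------------------------------ builders
def _leaflet_sites(lattice_xy, z_surface, z_inner, ps_mask):
    """Positions/charges/names for one leaflet of a planar membrane."""
    n = len(lattice_xy)
    pos, q, names, resn = [], [], [], []
    for i in range(n):
        x, y = lattice_xy[i]
        if ps_mask[i]:
            pos.append((x, y, z_surface)); q.append(-1.0)
            names.append("PS"); resn.append("PS")
        else:
            pos.append((x, y, z_surface)); q.append(1.0)
            names.append("CHL"); resn.append("PC")
            pos.append((x, y, z_inner)); q.append(-1.0)
            names.append("PHO"); resn.append("PC")
    return pos, q, names, resn


def _lambert_to_sphere(lattice_xy, spec: MembraneSpec, R: float) -> np.ndarray:
    """Lambert equal-area projection of planar (x, y) onto a sphere of radius
    R whose top point sits at the planar surface position."""
    cx, cy = spec.center_xy
    dx = lattice_xy[:, 0] - cx
    dy = lattice_xy[:, 1] - cy
    rho = np.hypot(dx, dy)
    arg = rho / (2.0 * R)
    if np.any(arg > np.sin(np.pi / 4)):
        raise GeometryError("radius too small to host the requested extent "
                            "within the lower-hemisphere cap")
    theta = 2.0 * np.arcsin(arg)
    phi = np.arctan2(dy, dx)
    center = np.array([cx, cy, spec.surface_z - spec.radius])
    st = np.sin(theta)
    return center + R * np.column_stack([st * np.cos(phi), st * np.sin(phi),
                                         np.cos(theta)])


def build_planar(spec: MembraneSpec) -> ExplicitMembrane:
    """Two jittered-hex leaflets of headgroup charge sites on a planar patch."""
    if spec.geometry != "planar":
        raise ConfigurationError("build_planar requires planar geometry")
    rng = np.random.default_rng(spec.seed)
    f, z0, th = spec.facing, spec.surface_z, spec.thickness
    pos, q, names, resn = [], [], [], []
    n_lipids = 0
    for z_s, inward in ((z0, -f), (z0 - f * th, f)):
        lat = _hex_lattice(spec, rng)
        ps = _assign_ps(len(lat), spec.ps_fraction, rng)
        p, qq, nm, rs = _leaflet_sites(lat, z_s, z_s + inward * spec.headgroup_depth, ps)
        pos += p; q += qq; names += nm; resn += rs
        n_lipids += len(lat)
    struct = ChargedStructure(np.array(pos).reshape(-1, 3), q,
                              np.zeros(len(q)), names, resn,
                              np.arange(1, len(q) + 1), ["M"] * len(q),
                              meta={"n_lipids": n_lipids})
    return ExplicitMembrane(struct, spec, _PlanarSurface(spec))


def build_vesicle(spec: MembraneSpec) -> ExplicitMembrane:
    """Spherical-cap membrane: the planar lattice Lambert-projected onto
    outer/inner leaflet spheres, preserving lipid count and per-lipid charge."""
    if spec.geometry != "spherical_cap":
        raise ConfigurationError("build_vesicle requires spherical_cap geometry")
    rng = np.random.default_rng(spec.seed)
    pos, q, names, resn = [], [], [], []
    n_lipids = 0
    for R, inward in ((spec.radius, -1.0), (spec.radius - spec.thickness, 1.0)):
        lat = _hex_lattice(spec, rng)
        ps = _assign_ps(len(lat), spec.ps_fraction, rng)
        surf = _lambert_to_sphere(lat, spec, R)
        inner = _lambert_to_sphere(lat, spec, R + inward * spec.headgroup_depth)
        for i in range(len(lat)):
            if ps[i]:
                pos.append(surf[i]); q.append(-1.0)
                names.append("PS"); resn.append("PS")
            else:
                pos.append(surf[i]); q.append(1.0)
                names.append("CHL"); resn.append("PC")
                pos.append(inner[i]); q.append(-1.0)
                names.append("PHO"); resn.append("PC")
        n_lipids += len(lat)
    struct = ChargedStructure(np.array(pos).reshape(-1, 3), q,
                              np.zeros(len(q)), names, resn,
                              np.arange(1, len(q) + 1), ["M"] * len(q),
                              meta={"n_lipids": n_lipids})
    return ExplicitMembrane(struct, spec, _SphericalSurface(spec))


def build_explicit(spec: MembraneSpec) -> ExplicitMembrane:
    return build_planar(spec) if spec.geometry == "planar" else build_vesicle(spec)


def build_implicit(spec: MembraneSpec) -> ImplicitSlab:
    """Uniform surface charge density -ps_fraction/area_per_lipid per face."""
    return ImplicitSlab(spec)


def embed_tmd(slab, s: ChargedStructure, segment) -> tuple:
    """Validate that the ``segment`` atoms of ``s`` lie inside the slab and
    return the composite (slab, structure) system.

    ``segment`` is a residue-number range (lo, hi) or a boolean atom mask.
    Inside the overlap the protein dielectric wins by construction, since
    both the slab region and the atom spheres are marked solute in the maps.
    """
    if isinstance(segment, tuple) and len(segment) == 2:
        mask = (s.resnums >= segment[0]) & (s.resnums <= segment[1])
    else:
        mask = np.asarray(segment, bool)
    if mask.any():
        xyz = s.xyz[mask]
        inside = slab.region_mask(xyz[:, 0], xyz[:, 1], xyz[:, 2])
        if not np.all(inside):
            bad = np.where(~inside)[0]
            raise EmbeddingError(
                f"{bad.size} segment atoms lie outside the slab bounds")
    return slab, s
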