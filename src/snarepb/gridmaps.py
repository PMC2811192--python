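"""Finite-difference grids and map assembly (dielectric, ion accessibility,
source charge).

The dielectric boundary is the van der Waals surface inflated by the solvent
probe radius for atoms, and the analytic headgroup surface for membranes.
Ion accessibility excludes atom spheres inflated by the Stern width and all
membrane interiors.  Charges are spread to the eight surrounding nodes with
trilinear weights, which conserves total charge exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _kernels
from ._constants import coulomb_constant_kT, debye_kappa
from .errors import BoundsError, ConfigurationError
from .structures import ChargedStructure

# grid dims friendly to at least 3 levels of vertex-centred coarsening
_MG_DIMS = sorted({m * 2**k + 1 for k in range(3, 10) for m in range(1, 33)})


def mg_dim(n_min: int) -> int:
    """Smallest multigrid-friendly dimension >= n_min."""
    for n in _MG_DIMS:
        if n >= n_min:
            return n
    raise ConfigurationError(f"requested grid dimension too large: {n_min}")


@dataclass(frozen=True)
class Grid:
    """Uniform node-centred grid: origin (Å), spacing h (Å), shape (nodes)."""

    origin: tuple
    h: float
    shape: tuple

    @classmethod
    def spanning(cls, lo, hi, h, pad=0.0) -> "Grid":
        """Grid covering [lo, hi] + pad (scalar or per-axis) with
        multigrid-friendly dimensions; slack is centred."""
        pad = np.broadcast_to(np.asarray(pad, float), (3,))
        lo = np.asarray(lo, float) - pad
        hi = np.asarray(hi, float) + pad
        dims, orig = [], []
        for a in range(3):
            n = mg_dim(int(np.ceil((hi[a] - lo[a]) / h)) + 1)
            slack = (n - 1) * h - (hi[a] - lo[a])
            dims.append(n)
            orig.append(lo[a] - slack / 2)
        return cls(tuple(orig), float(h), tuple(dims))

    def axes(self):
        return tuple(self.origin[a] + self.h * np.arange(self.shape[a])
                     for a in range(3))

    def extent(self):
        return tuple((n - 1) * self.h for n in self.shape)

    @property
    def n_nodes(self) -> int:
        return int(np.prod(self.shape))

    def boundary_coords(self) -> np.ndarray:
        """Coordinates of all boundary nodes, ordered to match
        set_boundary_values."""
        x, y, z = self.axes()
        faces = []
        for axis, idx in ((0, 0), (0, -1), (1, 0), (1, -1), (2, 0), (2, -1)):
            ax = [x, y, z]
            ax[axis] = np.array([ax[axis][idx]])
            X, Y, Z = np.meshgrid(*ax, indexing="ij")
            faces.append(np.column_stack([X.ravel(), Y.ravel(), Z.ravel()]))
        return np.vstack(faces)

    def get_boundary_values(self, arr: np.ndarray) -> np.ndarray:
        """Boundary node values of ``arr`` in set_boundary_values order."""
        out = []
        for axis, idx in ((0, 0), (0, -1), (1, 0), (1, -1), (2, 0), (2, -1)):
            sl = [slice(None)] * 3
            sl[axis] = idx
            out.append(arr[tuple(sl)].ravel())
        return np.concatenate(out)

    def set_boundary_values(self, arr: np.ndarray, values: np.ndarray) -> None:
        n = 0
        for axis, idx in ((0, 0), (0, -1), (1, 0), (1, -1), (2, 0), (2, -1)):
            sl = [slice(None)] * 3
            sl[axis] = idx
            face = arr[tuple(sl)]
            face[...] = values[n:n + face.size].reshape(face.shape)
            n += face.size


def _classify(components):
    structures, membranes = [], []
    for c in components:
        if isinstance(c, ChargedStructure):
            structures.append(c)
        elif hasattr(c, "region_mask") and hasattr(c, "charge_points"):
            membranes.append(c)
        else:
            raise ConfigurationError(f"unsupported component {type(c).__name__}")
    return structures, membranes


def faces_harmonic(eps_node: np.ndarray):
    """Face dielectrics as harmonic means of the adjacent node values."""
    def hm(a, b):
        return 2.0 * a * b / (a + b)
    return (hm(eps_node[:-1, :, :], eps_node[1:, :, :]),
            hm(eps_node[:, :-1, :], eps_node[:, 1:, :]),
            hm(eps_node[:, :, :-1], eps_node[:, :, 1:]))


def spread_charges(grid: Grid, pos: np.ndarray, q: np.ndarray) -> np.ndarray:
    """Trilinear spreading of point charges onto the grid (e per node)."""
    rho = np.zeros(grid.shape)
    if len(pos) == 0:
        return rho
    g = (pos - np.asarray(grid.origin)) / grid.h
    i0 = np.floor(g).astype(np.int64)
    if (i0 < 0).any() or (i0[:, 0] >= grid.shape[0] - 1).any() \
            or (i0[:, 1] >= grid.shape[1] - 1).any() \
            or (i0[:, 2] >= grid.shape[2] - 1).any():
        raise BoundsError("charge site outside grid")
    f = g - i0
    for dx in (0, 1):
        wx = np.where(dx, f[:, 0], 1 - f[:, 0])
        for dy in (0, 1):
            wy = np.where(dy, f[:, 1], 1 - f[:, 1])
            for dz in (0, 1):
                wz = np.where(dz, f[:, 2], 1 - f[:, 2])
                np.add.at(rho, (i0[:, 0] + dx, i0[:, 1] + dy, i0[:, 2] + dz),
                          q * wx * wy * wz)
    return rho


class GridMaps:
    """Assembled maps for one PB problem on one grid.

    Attributes: eps_node (relative permittivity per node), face arrays
    ex/ey/ez, kappa2 (kappa_bar^2 = eps_solvent * kappa_D^2 where ions reach,
    else 0), rho (spread charge, e per node), and the point sources used for
    analytic Debye-Hueckel boundary values.
    """

    def __init__(self, grid, eps_node, kappa2, rho, sources, cfg):
        self.grid = grid
        self.eps_node = eps_node
        self.ex, self.ey, self.ez = faces_harmonic(eps_node)
        self.kappa2 = kappa2
        self.rho = rho
        self.source_pos, self.source_q = sources
        self.cfg = cfg

    def with_charges(self, components) -> "GridMaps":
        """Same geometry maps, charges restricted to ``components``."""
        pos, q = gather_charges(components)
        out = GridMaps.__new__(GridMaps)
        out.grid = self.grid
        out.eps_node = self.eps_node
        out.ex, out.ey, out.ez = self.ex, self.ey, self.ez
        out.kappa2 = self.kappa2
        out.rho = spread_charges(self.grid, pos, q)
        out.source_pos, out.source_q = pos, q
        out.cfg = self.cfg
        return out

    @property
    def total_charge(self) -> float:
        return float(self.rho.sum())


def gather_charges(components):
    structures, membranes = _classify(components)
    pos = [np.zeros((0, 3))]
    q = [np.zeros(0)]
    for s in structures:
        pos.append(s.xyz)
        q.append(np.where(np.isfinite(s.charge), s.charge, 0.0))
    for m in membranes:
        p, qq = m.charge_points()
        pos.append(p)
        q.append(qq)
    return np.vstack(pos), np.concatenate(q)


def build_maps(components, cfg, grid: Grid) -> GridMaps:
    """Dielectric / ion-accessibility / charge maps for a component system.

    ``components`` may mix ChargedStructures, ExplicitMembranes and
    ImplicitSlabs, all positioned in the common lab frame.
    """
    structures, membranes = _classify(components)
    x, y, z = grid.axes()
    X = x[:, None, None]
    Y = y[None, :, None]
    Z = z[None, None, :]

    inside = np.zeros(grid.shape, bool)
    ion_excl = np.zeros(grid.shape, bool)
    for s in structures:
        if s.n_atoms == 0:
            continue
        rad = np.where(np.isfinite(s.radius), s.radius, 0.0)
        _kernels.mark_spheres(inside, *grid.origin, grid.h,
                              np.ascontiguousarray(s.xyz),
                              np.ascontiguousarray(rad), cfg.solvent_probe)
        _kernels.mark_spheres(ion_excl, *grid.origin, grid.h,
                              np.ascontiguousarray(s.xyz),
                              np.ascontiguousarray(rad), cfg.ion_exclusion)
    for m in membranes:
        inside |= m.region_mask(X, Y, Z)
        ion_excl |= m.ion_region_mask(X, Y, Z, cfg.ion_exclusion)
    ion_excl |= inside  # lambda = 0 wherever eps = eps_solute

    eps_node = np.where(inside, cfg.eps_solute, cfg.eps_solvent)
    kd = debye_kappa(cfg.ionic_strength, cfg.eps_solvent, cfg.temperature)
    kappa2 = np.where(ion_excl, 0.0, cfg.eps_solvent * kd * kd)

    pos, q = gather_charges(components)
    rho = spread_charges(grid, pos, q)
    return GridMaps(grid, eps_node, kappa2, rho, (pos, q), cfg)


def _aggregate_sources(pos: np.ndarray, q: np.ndarray, cell: float):
    """Bin charges into cubic cells (summed charge at the cell's site mean);
    a controlled far-field approximation for boundary-value evaluation."""
    keys = np.floor(pos / cell).astype(np.int64)
    _, inv = np.unique(keys, axis=0, return_inverse=True)
    nbin = inv.max() + 1
    qa = np.bincount(inv, weights=q, minlength=nbin)
    pa = np.column_stack([np.bincount(inv, weights=pos[:, a], minlength=nbin)
                          for a in range(3)])
    pa /= np.bincount(inv, minlength=nbin)[:, None]
    keep = qa != 0.0
    return pa[keep], qa[keep]


def dh_boundary_values(grid: Grid, pos: np.ndarray, q: np.ndarray, cfg,
                       aggregate_above: int = 1500,
                       aggregate_cell: float = 3.0) -> np.ndarray:
    """Single Debye-Hueckel boundary values: superposed screened Coulomb
    potentials of the source charges, in kT/e.

    Large source sets are binned into ``aggregate_cell`` Å cells first; the
    boundary is several Debye lengths from any source, where the multipole
    error of binning is negligible.
    """
    bc = grid.boundary_coords()
    if len(pos) == 0:
        return np.zeros(len(bc))
    if len(pos) > aggregate_above:
        pos, q = _aggregate_sources(pos, q, aggregate_cell)
    C = coulomb_constant_kT(cfg.temperature)
    kd = debye_kappa(cfg.ionic_strength, cfg.eps_solvent, cfg.temperature)
    cutoff2 = (12.0 / kd) ** 2 if kd > 0 else np.inf
    return _kernels.dh_sum(np.ascontiguousarray(bc), np.ascontiguousarray(pos),
                           np.ascontiguousarray(q), kd, C / cfg.eps_solvent,
                           cutoff2)
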