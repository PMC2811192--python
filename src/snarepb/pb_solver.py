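"""Finite-difference nonlinear Poisson-Boltzmann solver with two-level
focusing.

The equation solved (lengths in Å, potential phi in kT/e) is

    div(eps grad phi) - kappa_bar^2(r) sinh(phi) = -4 pi C rho_f(r)

with C = e^2/(4 pi eps0 kB T Å) and kappa_bar^2 = eps_solvent * kappa_D^2
inside the ion-accessible region.  Discretization is the standard 7-point
variable-coefficient stencil with harmonic-mean face dielectrics.  The
nonlinear system is solved by Newton linearization with one geometric
multigrid V-cycle (red-black Gauss-Seidel smoothing, full-weighting
restriction, trilinear prolongation, rediscretized coarse coefficients) per
Newton update.

Focusing follows the classic two-level scheme: the equation is first solved
on a coarse grid several times larger than the system, with single
Debye-Hueckel (screened-Coulomb superposition) Dirichlet boundary values,
and the coarse solution supplies Dirichlet values (and the initial guess)
for the fine grid that just spans the system.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
from . import _kernels
from ._constants import (DEFAULT_TEMPERATURE, coulomb_constant_kT,
                         debye_kappa, debye_length, kT_kJ_per_mol)
from .errors import ConfigurationError, ConvergenceError
from .gridmaps import (Grid, GridMaps, build_maps, dh_boundary_values,
                       faces_harmonic, mg_dim)

log = logging.getLogger(__name__)

_CLIP = 30.0      # kT/e clamp inside sinh/cosh
_STEP_MAX = 3.0   # kT/e max Newton step per cycle


# ------------------------------------------------------------------- config
@dataclass(frozen=True)
class PBConfig:
    """Solver configuration (defaults: physiological KCl, water/protein
    two-dielectric model, 0.5 Å focused fine grids)."""

    ionic_strength: float = 0.135        # mol/L, 1:1 electrolyte
    temperature: float = DEFAULT_TEMPERATURE
    eps_solute: float = 2.0
    eps_solvent: float = 78.54
    solvent_probe: float = 1.4           # Å, water probe for the dielectric map
    ion_exclusion: float = 2.0           # Å Stern width added to atom radii
    grid_spacing_fine: float = 0.5       # Å
    coarse_margin_factor: float = 7.0    # coarse extent / model extent
    coarse_spacing: float = 4.0          # Å target; dims capped below
    coarse_max_dim: int = 161
    fine_pad: float = 6.0                # Å beyond the system bbox
    focus_levels: int = 3                # 2 = classic coarse->fine focusing
    mid_spacing: float = 2.0             # Å, intermediate focusing grid
    tol: float = 1e-6                    # relative residual tolerance
    max_cycles: int = 150
    mode: str = "nonlinear"

    def __post_init__(self):
        if self.eps_solvent <= self.eps_solute:
            raise ConfigurationError("eps_solvent must exceed eps_solute")
        for name in ("temperature", "eps_solute", "solvent_probe",
                     "grid_spacing_fine", "coarse_margin_factor", "tol"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be non-negative")

    @property
    def kappa(self) -> float:
        return debye_kappa(self.ionic_strength, self.eps_solvent, self.temperature)

    @property
    def debye_length(self) -> float:
        return debye_length(self.ionic_strength, self.eps_solvent, self.temperature)


@dataclass
class PBSolution:
    """Converged potential (kT/e) with convergence metadata and the total
    grid free energy (kJ/mol; includes the self-energy of the spread
    charges, so it is meaningful only in differences on identical grids)."""

    phi: np.ndarray
    grid: Grid
    mode: str
    residual_norm: float
    iterations: int
    energy: float
    residual_history: list = field(default_factory=list)


# ---------------------------------------------------------------- multigrid
class _Level:
    __slots__ = ("eps_node", "ex", "ey", "ez", "w", "h", "phi", "f", "r")

    def __init__(self, eps_node, h):
        self.eps_node = eps_node
        self.ex, self.ey, self.ez = (np.ascontiguousarray(a)
                                     for a in faces_harmonic(eps_node))
        self.h = h
        shape = eps_node.shape
        self.w = np.zeros(shape)
        self.phi = np.zeros(shape)
        self.f = np.zeros(shape)
        self.r = np.zeros(shape)


def _coarsenable(shape):
    return all((n - 1) % 2 == 0 and (n - 1) // 2 + 1 >= 5 for n in shape)


def _build_levels(eps_node, h):
    levels = [_Level(np.ascontiguousarray(eps_node), h)]
    while _coarsenable(levels[-1].eps_node.shape) and len(levels) < 10:
        fine = levels[-1]
        cshape = tuple((n - 1) // 2 + 1 for n in fine.eps_node.shape)
        ce = np.empty(cshape)
        _kernels.restrict_fw(fine.eps_node, ce)
        levels.append(_Level(ce, fine.h * 2))
    return levels


def _update_w(levels, w0):
    levels[0].w = np.ascontiguousarray(w0)
    for a, b in zip(levels[:-1], levels[1:]):
        _kernels.restrict_fw(a.w, b.w)


def _vcycle(levels, li=0, nu1=2, nu2=2):
    lvl = levels[li]
    h2 = lvl.h * lvl.h
    if li == len(levels) - 1:
        for _ in range(60):
            _kernels.sweep_rb(lvl.phi, lvl.ex, lvl.ey, lvl.ez, lvl.w, lvl.f,
                              h2, 0, 1.0)
            _kernels.sweep_rb(lvl.phi, lvl.ex, lvl.ey, lvl.ez, lvl.w, lvl.f,
                              h2, 1, 1.0)
        return
    for _ in range(nu1):
        _kernels.sweep_rb(lvl.phi, lvl.ex, lvl.ey, lvl.ez, lvl.w, lvl.f, h2, 0, 1.0)
        _kernels.sweep_rb(lvl.phi, lvl.ex, lvl.ey, lvl.ez, lvl.w, lvl.f, h2, 1, 1.0)
    _kernels.residual(lvl.phi, lvl.ex, lvl.ey, lvl.ez, lvl.w, lvl.f, h2, lvl.r)
    nxt = levels[li + 1]
    _kernels.restrict_fw(lvl.r, nxt.f)
    nxt.f *= 4.0  # h^2-scaling ratio between levels
    nxt.phi[:] = 0.0
    _vcycle(levels, li + 1, nu1, nu2)
    _kernels.prolong_add(nxt.phi, lvl.phi)
    for _ in range(nu2):
        _kernels.sweep_rb(lvl.phi, lvl.ex, lvl.ey, lvl.ez, lvl.w, lvl.f, h2, 0, 1.0)
        _kernels.sweep_rb(lvl.phi, lvl.ex, lvl.ey, lvl.ez, lvl.w, lvl.f, h2, 1, 1.0)


# -------------------------------------------------------------------- solve
def solve(maps: GridMaps, cfg: PBConfig, mode: str | None = None,
          boundary: np.ndarray | None = None,
          phi0: np.ndarray | None = None) -> PBSolution:
    """Solve the (non)linear PB equation on the maps' grid.

    ``boundary`` holds Dirichlet values for the boundary nodes (ordering of
    ``Grid.boundary_coords``); by default single Debye-Hueckel values from
    the maps' own sources are used.  ``phi0`` seeds the iteration.
    """
    mode = mode or cfg.mode
    if mode not in ("nonlinear", "linear"):
        raise ConfigurationError(f"unknown mode {mode!r}")
    grid = maps.grid
    h = grid.h
    h2 = h * h
    C = coulomb_constant_kT(cfg.temperature)

    if boundary is None:
        boundary = dh_boundary_values(grid, maps.source_pos, maps.source_q, cfg)
    if phi0 is None and mode == "nonlinear" and maps.kappa2.any():
        # linear pre-solve: a cheap, saturation-free starting guess that
        # spares the damped Newton ramp from zero
        pre = solve(maps, replace(cfg, tol=cfg.tol * 100), "linear", boundary)
        phi0 = pre.phi
    phi = np.zeros(grid.shape) if phi0 is None else np.array(phi0, float)
    grid.set_boundary_values(phi, boundary)

    fq = np.ascontiguousarray(4.0 * np.pi * C * maps.rho / h)  # h^2-scaled
    kappa2 = np.ascontiguousarray(maps.kappa2)
    nonlin = mode == "nonlinear" and bool(kappa2.any())

    scale = max(float(np.abs(fq).max()),
                float(np.abs(boundary).max()) if boundary.size else 0.0)
    tol_abs = cfg.tol * max(scale, 1e-12)

    phi = np.ascontiguousarray(phi)
    levels = _build_levels(maps.eps_node, h)
    if not nonlin:
        _update_w(levels, kappa2)
    lvl0 = levels[0]
    w = np.zeros(grid.shape)
    f = np.zeros(grid.shape)
    r = np.zeros(grid.shape)
    phi_old = np.zeros(grid.shape)
    history = []
    it = 0
    for it in range(1, cfg.max_cycles + 1):
        if nonlin:
            rmax = float(_kernels.newton_setup(phi, lvl0.ex, lvl0.ey, lvl0.ez,
                                               kappa2, fq, h2, w, f, _CLIP))
            _update_w(levels, w)
        else:
            f = fq
            _kernels.residual(phi, lvl0.ex, lvl0.ey, lvl0.ez, lvl0.w, f, h2, r)
            rmax = float(np.abs(r).max())
        history.append(rmax)
        if rmax <= tol_abs:
            break
        if nonlin:
            phi_old[:] = phi
        lvl0.phi = phi
        lvl0.f = f
        _vcycle(levels)
        phi = lvl0.phi
        if nonlin:
            # damp Newton steps in the ion-accessible region so sinh cannot
            # run away; cavity potentials may build up freely
            _kernels.damp_step(phi, phi_old, kappa2, _STEP_MAX)
    else:
        raise ConvergenceError(
            f"no convergence in {cfg.max_cycles} cycles; residual history "
            f"tail {history[-5:]} (tol {tol_abs:.3g})")

    energy = _free_energy(phi, maps, cfg, mode)
    log.info("PB solve (%s) on %s grid: %d cycles, residual %.3e",
             mode, "x".join(map(str, grid.shape)), it,
             history[-1] if history else 0.0)
    return PBSolution(phi, grid, mode, history[-1] if history else 0.0,
                      it, energy, history)


def _free_energy(phi, maps, cfg, mode) -> float:
    C = coulomb_constant_kT(cfg.temperature)
    h = maps.grid.h
    charge_term = float((maps.rho * phi).sum())  # kT
    if mode == "linear":
        g_kt = 0.5 * charge_term
    else:
        grad = (float((maps.ex * np.diff(phi, axis=0) ** 2).sum())
                + float((maps.ey * np.diff(phi, axis=1) ** 2).sum())
                + float((maps.ez * np.diff(phi, axis=2) ** 2).sum())) * h
        pc = np.clip(phi, -_CLIP, _CLIP)
        ion = float((maps.kappa2 * (np.cosh(pc) - 1.0)).sum()) * h**3
        g_kt = charge_term - grad / (8.0 * np.pi * C) - ion / (4.0 * np.pi * C)
    return g_kt * kT_kJ_per_mol(cfg.temperature)


def free_energy(sol: PBSolution, maps: GridMaps, cfg: PBConfig | None = None,
                mode: str | None = None) -> float:
    """Total electrostatic grid free energy (kJ/mol) of a solution on maps."""
    if sol.grid != maps.grid:
        raise ConfigurationError("solution and maps live on different grids")
    cfg = cfg or maps.cfg
    return _free_energy(sol.phi, maps, cfg, mode or sol.mode)


# ----------------------------------------------------------------- focusing
def system_bbox(components):
    los, his = [], []
    for c in components:
        if hasattr(c, "bbox"):
            lo, hi = c.bbox()
        else:
            pos, _ = c.charge_points()
            lo, hi = pos.min(0) - 2.0, pos.max(0) + 2.0
            if hasattr(c, "footprint"):
                fx0, fx1, fy0, fy1 = c.footprint()
                lo = np.minimum(lo, [fx0, fy0, lo[2]])
                hi = np.maximum(hi, [fx1, fy1, hi[2]])
        los.append(lo)
        his.append(hi)
    return np.min(los, axis=0), np.max(his, axis=0)


def fine_grid_for(components, cfg: PBConfig, spacing: float | None = None) -> Grid:
    lo, hi = system_bbox(components)
    return Grid.spanning(lo, hi, spacing or cfg.grid_spacing_fine, cfg.fine_pad)


def coarse_grid_for(components, cfg: PBConfig, fine: Grid,
                    margin_factor: float | None = None) -> Grid:
    """Coarse focusing grid: margin_factor times the model extent (at least
    1.5x the fine grid), centred on the fine grid."""
    mf = margin_factor or cfg.coarse_margin_factor
    lo, hi = system_bbox(components)
    ext = np.asarray(hi) - np.asarray(lo)
    cen = np.asarray(fine.origin) + np.asarray(fine.extent()) / 2
    cext = np.maximum(mf * np.maximum(ext, 1.0), 1.5 * np.asarray(fine.extent()))
    dims = [min(mg_dim(int(np.ceil(cext[a] / cfg.coarse_spacing)) + 1),
                cfg.coarse_max_dim) for a in range(3)]
    hc = float(np.max(cext / (np.array(dims) - 1)))
    orig = tuple(cen[a] - (dims[a] - 1) * hc / 2 for a in range(3))
    return Grid(orig, hc, tuple(dims))


def focused_solve(fine_maps: GridMaps, coarse_maps: GridMaps,
                  cfg: PBConfig, mode: str | None = None) -> PBSolution:
    """Coarse solve with Debye-Hueckel boundary values, then a fine solve
    with boundary values (and initial guess) interpolated from it."""
    return focused_solve_chain([coarse_maps, fine_maps], cfg, mode)


def focused_solve_chain(maps_seq, cfg: PBConfig,
                        mode: str | None = None) -> PBSolution:
    """Focusing cascade: solve the first (outermost) maps with analytic
    Debye-Hueckel boundary values, then focus inward, each level taking its
    Dirichlet boundary and initial guess from the previous solution."""
    mode = mode or cfg.mode
    sol = solve(maps_seq[0], cfg, mode)
    for maps in maps_seq[1:]:
        pg, fg = sol.grid, maps.grid
        init = np.zeros(fg.shape)
        _kernels.resample_grid(sol.phi, *pg.origin, pg.h, *fg.origin, fg.h, init)
        bc = fg.get_boundary_values(init)
        sol = solve(maps, cfg, mode, boundary=bc, phi0=init)
    return sol


def focusing_grids(components, cfg: PBConfig, fine: Grid,
                   margin_factor: float | None = None) -> list[Grid]:
    """Grid cascade, outermost first.  With focus_levels >= 3 an intermediate
    grid (mid_spacing, padded well clear of all sources) separates the large
    coarse grid from the fine one, so the fine boundary is always
    interpolated from a grid that resolves its neighbourhood."""
    coarse = coarse_grid_for(components, cfg, fine, margin_factor)
    grids = [coarse, fine]
    if cfg.focus_levels >= 3 and coarse.h > 1.5 * cfg.mid_spacing:
        lo = np.asarray(fine.origin)
        hi = lo + np.asarray(fine.extent())
        pad = max(20.0, 2.2 * coarse.h)
        h_mid = max(cfg.mid_spacing, fine.h)
        mid = Grid.spanning(lo, hi, h_mid, pad)
        if mid.h < coarse.h:
            grids = [coarse, mid, fine]
    return grids


def solve_system(components, cfg: PBConfig, mode: str | None = None,
                 fine_grid: Grid | None = None,
                 margin_factor: float | None = None) -> PBSolution:
    """Assemble maps for ``components`` and run the focused solve cascade."""
    fine_grid = fine_grid or fine_grid_for(components, cfg)
    grids = focusing_grids(components, cfg, fine_grid, margin_factor)
    maps_seq = [build_maps(components, cfg, g) for g in grids]
    return focused_solve_chain(maps_seq, cfg, mode)


def check_precision(A, B, cfg: PBConfig, spacing_alt: float = 1.0):
    """Numerical-precision report for an interaction energy: the absolute
    change when the fine spacing is coarsened to ``spacing_alt`` and when
    the coarse-grid margin is doubled."""
    from .energetics import interaction_energy  # late import avoids a cycle

    g_ref = interaction_energy(A, B, cfg)
    g_res = interaction_energy(A, B, replace(cfg, grid_spacing_fine=spacing_alt))
    g_mar = interaction_energy(
        A, B, replace(cfg, coarse_margin_factor=2 * cfg.coarse_margin_factor))
    return {
        "dG_reference": g_ref,
        "dG_low_resolution": g_res,
        "dG_double_margin": g_mar,
        "resolution_delta": abs(g_ref - g_res),
        "margin_delta": abs(g_ref - g_mar),
    }
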