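"""Charged atomic structures: I/O, parameter assignment and rigid placement.

A :class:`ChargedStructure` is the common currency for proteins and explicit
membrane charge lattices: positions (Å), partial charges (e) and van der
Waals radii (Å), plus named *anchors* (atom indices) used to define the
membrane-normal axis, and a recorded longitudinal axis about which lateral
orientation sweeps rotate.

The lab frame convention used throughout the package: membranes are normal
to z, the t-membrane side is +z and the v-membrane side is -z.  The
structurally preferred orientation places the anchor-to-anchor vector
(e.g. VAMP Lys93 C-alpha -> syntaxin Ser259 C-alpha) along +z.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass, field
from typing import Iterator, Mapping, Sequence

import numpy as np

from .errors import (ConfigurationError, DegenerateAxisError, LookupFailure,
                     ParseError, PlacementError)

log = logging.getLogger(__name__)

_Z = np.array([0.0, 0.0, 1.0])


@dataclass
class AtomRecord:
    """One atom: id, name, position (Å), charge (e), radius (Å), residue info."""

    id: int
    name: str
    position: np.ndarray
    charge: float
    radius: float
    chain: str = "A"
    residue_name: str = "UNK"
    residue_number: int = 1


class ChargedStructure:
    """Ordered collection of charged atoms with a rigid-body frame.

    The frame (rotation ``R``, translation ``t``) maps the *original* input
    coordinates to the current lab-frame coordinates; applying the inverse
    frame restores the input coordinates exactly (to 1e-9 Å), which makes
    every geometric operation auditable.
    """

    def __init__(self, xyz, charge, radius, names=None, resnames=None,
                 resnums=None, chains=None, anchors=None,
                 rotation=None, translation=None, longitudinal_axis=None,
                 meta=None):
        self.xyz = np.atleast_2d(np.asarray(xyz, dtype=float)).reshape(-1, 3)
        n = len(self.xyz)
        self.charge = np.asarray(charge, dtype=float).reshape(n)
        self.radius = np.asarray(radius, dtype=float).reshape(n)
        self.names = np.asarray(names if names is not None else ["X"] * n, dtype=object)
        self.resnames = np.asarray(resnames if resnames is not None else ["UNK"] * n, dtype=object)
        self.resnums = np.asarray(resnums if resnums is not None else np.ones(n, int))
        self.chains = np.asarray(chains if chains is not None else ["A"] * n, dtype=object)
        self.anchors: dict[str, int] = dict(anchors or {})
        self.rotation = np.eye(3) if rotation is None else np.asarray(rotation, float)
        self.translation = np.zeros(3) if translation is None else np.asarray(translation, float)
        self.longitudinal_axis = (None if longitudinal_axis is None
                                  else np.asarray(longitudinal_axis, float))
        self.meta = dict(meta or {})
        if not np.all(np.isfinite(self.xyz)):
            raise ConfigurationError("non-finite coordinates")
        if np.any(self.radius < 0):
            raise ConfigurationError("negative van der Waals radius")

    # ------------------------------------------------------------------ basic
    @property
    def n_atoms(self) -> int:
        return len(self.xyz)

    @property
    def net_charge(self) -> float:
        """Sum of partial charges, ignoring unset (NaN) entries."""
        return float(np.nansum(self.charge))

    def bbox(self, pad: float = 0.0):
        """(lo, hi) corners of the van-der-Waals bounding box."""
        if self.n_atoms == 0:
            return np.zeros(3), np.zeros(3)
        r = np.where(np.isfinite(self.radius), self.radius, 0.0)[:, None]
        return (self.xyz - r).min(0) - pad, (self.xyz + r).max(0) + pad

    def atoms(self) -> Iterator[AtomRecord]:
        for i in range(self.n_atoms):
            yield AtomRecord(i + 1, str(self.names[i]), self.xyz[i].copy(),
                             float(self.charge[i]), float(self.radius[i]),
                             str(self.chains[i]), str(self.resnames[i]),
                             int(self.resnums[i]))

    def anchor_position(self, name: str) -> np.ndarray:
        try:
            return self.xyz[self.anchors[name]].copy()
        except KeyError as exc:
            raise ConfigurationError(f"unknown anchor {name!r}") from exc

    # ----------------------------------------------------------- rigid motion
    def transformed(self, R=None, t=None) -> "ChargedStructure":
        """Return a copy with the rigid map x -> R x + t applied."""
        R = np.eye(3) if R is None else np.asarray(R, float)
        t = np.zeros(3) if t is None else np.asarray(t, float)
        axis = None if self.longitudinal_axis is None else R @ self.longitudinal_axis
        return ChargedStructure(
            self.xyz @ R.T + t, self.charge.copy(), self.radius.copy(),
            self.names.copy(), self.resnames.copy(), self.resnums.copy(),
            self.chains.copy(), dict(self.anchors),
            R @ self.rotation, R @ self.translation + t, axis, dict(self.meta))

    def translated(self, t) -> "ChargedStructure":
        return self.transformed(None, t)

    # ------------------------------------------------------------------- I/O
    def to_pqr(self, path_or_buf) -> None:
        """Write a whitespace-delimited PQR file (charge then radius last)."""
        own = isinstance(path_or_buf, (str, bytes))
        fh = open(path_or_buf, "w") if own else path_or_buf
        try:
            for a in self.atoms():
                q = 0.0 if not np.isfinite(a.charge) else a.charge
                r = 0.0 if not np.isfinite(a.radius) else a.radius
                fh.write(f"ATOM  {a.id:6d} {a.name:<4s} {a.residue_name:<4s} "
                         f"{a.chain:1s} {a.residue_number:5d}    "
                         f"{a.position[0]:10.4f} {a.position[1]:10.4f} "
                         f"{a.position[2]:10.4f} {q:9.4f} {r:7.4f}\n")
        finally:
            if own:
                fh.close()


# ---------------------------------------------------------------------- read
def _parse_pqr(lines) -> ChargedStructure:
    xyz, q, r, names, resn, resi, ch = [], [], [], [], [], [], []
    for lineno, line in enumerate(lines, start=1):
        tok = line.split()
        if not tok or tok[0] not in ("ATOM", "HETATM"):
            continue
        try:
            # with or without a chain column:
            # ATOM serial name resname [chain] resnum x y z q r
            if len(tok) >= 11:
                chain, resnum = tok[4], int(tok[5])
                vals = tok[6:11]
            elif len(tok) == 10:
                chain, resnum = "A", int(tok[4])
                vals = tok[5:10]
            else:
                raise ValueError("too few fields")
            x, y, z, qq, rr = (float(v) for v in vals)
        except (ValueError, IndexError) as exc:
            raise ParseError(f"malformed PQR line {lineno}: {line.rstrip()!r}") from exc
        xyz.append((x, y, z)); q.append(qq); r.append(rr)
        names.append(tok[2]); resn.append(tok[3]); resi.append(resnum); ch.append(chain)
    if not xyz:
        return ChargedStructure(np.zeros((0, 3)), [], [])
    return ChargedStructure(xyz, q, r, names, resn, resi, ch)


def _parse_pdb(path) -> ChargedStructure:
    from Bio.PDB import PDBParser  # deferred: Biopython import is slow

    parser = PDBParser(QUIET=True)
    try:
        model = next(iter(parser.get_structure("s", path)))
    except Exception as exc:  # Biopython raises assorted exceptions
        raise ParseError(f"failed to parse PDB file {path}: {exc}") from exc
    xyz, names, resn, resi, ch = [], [], [], [], []
    for chain in model:
        for res in chain:
            for atom in res:
                xyz.append(atom.coord)
                names.append(atom.get_name())
                resn.append(res.get_resname())
                resi.append(res.id[1])
                ch.append(chain.id)
    n = len(xyz)
    nan = np.full(n, np.nan)
    return ChargedStructure(np.array(xyz, float) if n else np.zeros((0, 3)),
                            nan, nan.copy(), names, resn, resi, ch)


def read_structure(path, format: str | None = None) -> ChargedStructure:
    """Read a PDB or PQR file into a :class:`ChargedStructure`.

    PQR charge/radius columns are honored; PDB input leaves charge and radius
    unset (NaN) pending :func:`assign_parameters`.
    """
    if format is None:
        format = "pqr" if str(path).lower().endswith(("pqr", "pqr.txt")) else "pdb"
    format = format.lower()
    if format == "pqr":
        with open(path) as fh:
            return _parse_pqr(fh)
    if format == "pdb":
        return _parse_pdb(path)
    raise ConfigurationError(f"unknown structure format {format!r}")


def read_pqr_string(text: str) -> ChargedStructure:
    return _parse_pqr(io.StringIO(text))


# --------------------------------------------------------------- parameters
@dataclass
class ParameterSet:
    """(residue_name, atom_name) -> (charge e, radius Å) lookup table.

    Unresolved atoms fall back to ``default_radius`` / zero charge (with a
    logged warning) unless ``strict`` is set, in which case assignment raises
    :class:`LookupFailure` listing every offending atom.
    """

    table: Mapping[tuple[str, str], tuple[float, float]]
    element_radii: Mapping[str, float] = field(default_factory=dict)
    default_radius: float = 1.5
    strict: bool = False

    @classmethod
    def default(cls) -> "ParameterSet":
        """Simplified united-charge set: formal charges on ionizable
        sidechain sites, element-based radii.  A stand-in for a full
        force-field table; headline energies on real structures shift by a
        few kJ/mol relative to any specific parameterization."""
        half = 0.5
        table = {
            ("ASP", "OD1"): (-half, 1.52), ("ASP", "OD2"): (-half, 1.52),
            ("GLU", "OE1"): (-half, 1.52), ("GLU", "OE2"): (-half, 1.52),
            ("LYS", "NZ"): (1.0, 1.55),
            ("ARG", "NH1"): (half, 1.55), ("ARG", "NH2"): (half, 1.55),
            ("HIS", "ND1"): (0.0, 1.55), ("HIS", "NE2"): (0.0, 1.55),
        }
        element_radii = {"C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80,
                         "P": 1.80, "H": 1.10}
        return cls(table, element_radii)

    def lookup(self, resname: str, atname: str):
        key = (resname.strip().upper(), atname.strip().upper())
        if key in self.table:
            return self.table[key]
        return None


def assign_parameters(s: ChargedStructure, p: ParameterSet) -> ChargedStructure:
    """Assign charge and radius to every atom from the parameter table."""
    out = s.transformed()  # copy
    missing = []
    for i in range(out.n_atoms):
        hit = p.lookup(str(out.resnames[i]), str(out.names[i]))
        if hit is not None:
            out.charge[i], out.radius[i] = hit
            continue
        elem = str(out.names[i]).strip()[:1].upper()
        rad = p.element_radii.get(elem)
        if rad is not None:
            out.charge[i], out.radius[i] = 0.0, rad
            continue
        missing.append((str(out.resnames[i]), str(out.names[i])))
        if not p.strict:
            out.charge[i], out.radius[i] = 0.0, p.default_radius
    if missing:
        if p.strict:
            raise LookupFailure(f"unparameterized atoms: {sorted(set(missing))}")
        log.warning("assigned default radius %.2f Å / zero charge to %d atoms: %s",
                    p.default_radius, len(missing), sorted(set(missing))[:10])
    return out


# ---------------------------------------------------------------- alignment
def _rotation_between(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Minimal rotation taking unit vector a onto unit vector b (Rodrigues)."""
    v = np.cross(a, b)
    c = float(np.dot(a, b))
    if np.linalg.norm(v) < 1e-12:
        if c > 0:
            return np.eye(3)
        # antiparallel: rotate 180 deg about any perpendicular axis
        perp = np.cross(a, [1.0, 0.0, 0.0])
        if np.linalg.norm(perp) < 1e-6:
            perp = np.cross(a, [0.0, 1.0, 0.0])
        perp /= np.linalg.norm(perp)
        return 2.0 * np.outer(perp, perp) - np.eye(3)
    vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
    return np.eye(3) + vx + vx @ vx * (1.0 / (1.0 + c))


def _principal_axis(xyz: np.ndarray) -> np.ndarray:
    """Largest-variance direction with a deterministic sign convention."""
    c = xyz - xyz.mean(0)
    _, _, vt = np.linalg.svd(c, full_matrices=False)
    e = vt[0]
    k = int(np.argmax(np.abs(e)))
    return e if e[k] > 0 else -e


def align_preferred_orientation(s: ChargedStructure,
                                axis_from: str = "vamp_cterm",
                                axis_to: str = "syx_cterm") -> ChargedStructure:
    """Rigidly rotate so the anchor axis_from -> axis_to vector is along +z.

    The t-membrane side ends up at +z.  In-plane spin is fixed by a
    reproducible convention: the longitudinal principal axis is brought into
    the xz-plane pointing +x (no spin if it already lies along z).  The
    centroid is recentred to x = y = 0.  The resulting structure records its
    longitudinal axis for :func:`rotate_longitudinal`.
    """
    v = s.anchor_position(axis_to) - s.anchor_position(axis_from)
    norm = np.linalg.norm(v)
    if norm < 1e-9:
        raise DegenerateAxisError("anchor atoms coincide")
    R1 = _rotation_between(v / norm, _Z)
    out = s.transformed(R1)
    # in-plane spin: principal axis into the xz-plane, pointing +x
    if out.n_atoms >= 3:
        e = _principal_axis(out.xyz)
        exy = np.hypot(e[0], e[1])
        if exy > 1e-8:
            phi = np.arctan2(e[1], e[0])
            c, sn = np.cos(-phi), np.sin(-phi)
            Rz = np.array([[c, -sn, 0], [sn, c, 0], [0, 0, 1.0]])
            out = out.transformed(Rz)
            e = Rz @ e
        out.longitudinal_axis = e / np.linalg.norm(e)
    else:
        out.longitudinal_axis = _Z.copy()
    cen = out.xyz.mean(0) if out.n_atoms else np.zeros(3)
    return out.translated([-cen[0], -cen[1], 0.0])


def rotate_longitudinal(s: ChargedStructure, angle_deg: float) -> ChargedStructure:
    """Rotate by ``angle_deg`` about the structure's longitudinal axis.

    The axis passes through the origin; it defaults to +z for structures that
    have not been aligned.  Angles are taken mod 360.
    """
    axis = _Z if s.longitudinal_axis is None else np.asarray(s.longitudinal_axis, float)
    axis = axis / np.linalg.norm(axis)
    th = np.deg2rad(float(angle_deg) % 360.0)
    K = np.array([[0, -axis[2], axis[1]],
                  [axis[2], 0, -axis[0]],
                  [-axis[1], axis[0], 0]])
    R = np.eye(3) + np.sin(th) * K + (1 - np.cos(th)) * (K @ K)
    return s.transformed(R)


# ---------------------------------------------------------------- placement
def place_at_distance(s: ChargedStructure, membrane, d: float,
                      side: str = "above",
                      debye_length: float | None = None) -> ChargedStructure:
    """Translate along z so the minimal vertical van-der-Waals gap to the
    membrane surface equals ``d`` (Å).

    ``side="above"`` puts the structure above the membrane surface (v-membrane
    convention), ``"below"`` underneath it (t-membrane convention).  If
    ``debye_length`` is given, the membrane patch must extend at least four
    Debye lengths beyond the structure footprint in x and y, else a
    :class:`PlacementError` is raised.
    """
    if d < 0:
        raise PlacementError("distance must be >= 0")
    if s.n_atoms == 0:
        raise PlacementError("cannot place an empty structure")
    if debye_length is not None and np.isfinite(debye_length):
        lo, hi = s.bbox()
        fx_lo, fx_hi, fy_lo, fy_hi = membrane.footprint()
        m = 4.0 * debye_length
        if (lo[0] - fx_lo < m or fx_hi - hi[0] < m
                or lo[1] - fy_lo < m or fy_hi - hi[1] < m):
            raise PlacementError(
                "membrane patch does not extend 4 Debye lengths "
                f"({m:.1f} Å) beyond the structure footprint")
    gaps = membrane.vertical_gaps(s.xyz, s.radius, side)
    gaps = gaps[np.isfinite(gaps)]
    if gaps.size == 0:
        raise PlacementError("no atom lies over the membrane surface")
    sign = 1.0 if side == "above" else -1.0
    return s.translated([0.0, 0.0, sign * (d - gaps.min())])
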