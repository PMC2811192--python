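"""Minimal OpenDX scalar-grid writer for potential and map export."""

from __future__ import annotations

import numpy as np

from .gridmaps import Grid


def write_dx(path, grid: Grid, field: np.ndarray, comment: str = "") -> None:
    """Write a scalar field on a regular grid in OpenDX format (z fastest)."""
    nx, ny, nz = grid.shape
    if field.shape != tuple(grid.shape):
        raise ValueError("field shape does not match grid")
    vals = np.asarray(field, float).ravel(order="C")
    with open(path, "w") as fh:
        if comment:
            for line in comment.splitlines():
                fh.write(f"# {line}\n")
        fh.write(f"object 1 class gridpositions counts {nx} {ny} {nz}\n")
        fh.write("origin {:.6e} {:.6e} {:.6e}\n".format(*grid.origin))
        fh.write(f"delta {grid.h:.6e} 0.0 0.0\n")
        fh.write(f"delta 0.0 {grid.h:.6e} 0.0\n")
        fh.write(f"delta 0.0 0.0 {grid.h:.6e}\n")
        fh.write(f"object 2 class gridconnections counts {nx} {ny} {nz}\n")
        fh.write(f"object 3 class array type double rank 0 items {vals.size} "
                 "data follows\n")
        for i in range(0, vals.size, 3):
            fh.write(" ".join(f"{v:.6e}" for v in vals[i:i + 3]) + "\n")
        fh.write('attribute "dep" string "positions"\n')
        fh.write('object "regular positions regular connections" class field\n')
        fh.write('component "positions" value 1\n')
        fh.write('component "connections" value 2\n')
        fh.write('component "data" value 3\n')


def read_dx(path):
    """Read back a scalar OpenDX file written by :func:`write_dx`."""
    counts = origin = None
    deltas = []
    vals = []
    with open(path) as fh:
        for line in fh:
            t = line.split()
            if not t or t[0] == "#":
                continue
            if t[:3] == ["object", "1", "class"]:
                counts = tuple(int(v) for v in t[-3:])
            elif t[0] == "origin":
                origin = tuple(float(v) for v in t[1:4])
            elif t[0] == "delta":
                deltas.append([float(v) for v in t[1:4]])
            elif t[0] == "attribute":
                break
            elif counts and origin and len(deltas) == 3:
                try:
                    vals.extend(float(v) for v in t)
                except ValueError:
                    pass
    h = float(deltas[0][0])
    grid = Grid(origin, h, counts)
    return grid, np.array(vals).reshape(counts)
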