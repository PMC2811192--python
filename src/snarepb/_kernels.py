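"""Numba kernels for the finite-difference solver: red-black Gauss-Seidel
smoothing, residual evaluation, grid-transfer operators and sphere marking.

All smoother arithmetic uses the h^2-scaled 7-point stencil

    sum_f eps_f (phi_c - phi_nb) + h^2 w phi_c = f

with face dielectrics eps_f, a node Helmholtz coefficient w (kappa_bar^2
cosh(phi) for the linearized nonlinear problem) and an h^2-scaled source f.
Boundary nodes are Dirichlet and never updated.
"""

from __future__ import annotations

import numba as nb
import numpy as np


@nb.njit(cache=True)
def mark_spheres(mask, ox, oy, oz, h, pos, rad, inflate):
    """Set mask=True at nodes inside any sphere (radius + inflate)."""
    nx, ny, nz = mask.shape
    for n in range(pos.shape[0]):
        r = rad[n] + inflate
        if r <= 0.0:
            continue
        x, y, z = pos[n, 0], pos[n, 1], pos[n, 2]
        i0 = max(0, int(np.floor((x - r - ox) / h)))
        i1 = min(nx - 1, int(np.ceil((x + r - ox) / h)))
        j0 = max(0, int(np.floor((y - r - oy) / h)))
        j1 = min(ny - 1, int(np.ceil((y + r - oy) / h)))
        k0 = max(0, int(np.floor((z - r - oz) / h)))
        k1 = min(nz - 1, int(np.ceil((z + r - oz) / h)))
        r2 = r * r
        for i in range(i0, i1 + 1):
            dx = ox + i * h - x
            for j in range(j0, j1 + 1):
                dy = oy + j * h - y
                dxy2 = dx * dx + dy * dy
                if dxy2 > r2:
                    continue
                for k in range(k0, k1 + 1):
                    dz = oz + k * h - z
                    if dxy2 + dz * dz <= r2:
                        mask[i, j, k] = True


@nb.njit(cache=True)
def sweep_rb(phi, ex, ey, ez, w, f, h2, color, omega):
    nx, ny, nz = phi.shape
    for i in range(1, nx - 1):
        for j in range(1, ny - 1):
            kstart = 2 - ((color + i + j) % 2)
            for k in range(kstart, nz - 1, 2):
                aw = ex[i - 1, j, k]
                ae = ex[i, j, k]
                asn = ey[i, j - 1, k]
                an = ey[i, j, k]
                ab = ez[i, j, k - 1]
                at = ez[i, j, k]
                diag = aw + ae + asn + an + ab + at + h2 * w[i, j, k]
                num = (aw * phi[i - 1, j, k] + ae * phi[i + 1, j, k]
                       + asn * phi[i, j - 1, k] + an * phi[i, j + 1, k]
                       + ab * phi[i, j, k - 1] + at * phi[i, j, k + 1]
                       + f[i, j, k])
                phi[i, j, k] += omega * (num / diag - phi[i, j, k])


@nb.njit(cache=True)
def residual(phi, ex, ey, ez, w, f, h2, out):
    nx, ny, nz = phi.shape
    out[:, :, :] = 0.0
    for i in range(1, nx - 1):
        for j in range(1, ny - 1):
            for k in range(1, nz - 1):
                aw = ex[i - 1, j, k]
                ae = ex[i, j, k]
                asn = ey[i, j - 1, k]
                an = ey[i, j, k]
                ab = ez[i, j, k - 1]
                at = ez[i, j, k]
                c = phi[i, j, k]
                ax = (aw * (c - phi[i - 1, j, k]) + ae * (c - phi[i + 1, j, k])
                      + asn * (c - phi[i, j - 1, k]) + an * (c - phi[i, j + 1, k])
                      + ab * (c - phi[i, j, k - 1]) + at * (c - phi[i, j, k + 1])
                      + h2 * w[i, j, k] * c)
                out[i, j, k] = f[i, j, k] - ax


@nb.njit(cache=True)
def nonlinear_residual(phi, ex, ey, ez, kappa2, fq, h2, out):
    """Residual of the full (sinh) equation; fq is the h^2-scaled charge term."""
    nx, ny, nz = phi.shape
    out[:, :, :] = 0.0
    for i in range(1, nx - 1):
        for j in range(1, ny - 1):
            for k in range(1, nz - 1):
                aw = ex[i - 1, j, k]
                ae = ex[i, j, k]
                asn = ey[i, j - 1, k]
                an = ey[i, j, k]
                ab = ez[i, j, k - 1]
                at = ez[i, j, k]
                c = phi[i, j, k]
                s = np.sinh(min(max(c, -30.0), 30.0))
                ax = (aw * (c - phi[i - 1, j, k]) + ae * (c - phi[i + 1, j, k])
                      + asn * (c - phi[i, j - 1, k]) + an * (c - phi[i, j + 1, k])
                      + ab * (c - phi[i, j, k - 1]) + at * (c - phi[i, j, k + 1])
                      + h2 * kappa2[i, j, k] * s)
                out[i, j, k] = fq[i, j, k] - ax


@nb.njit(cache=True)
def restrict_fw(fine, coarse):
    """27-point full-weighting restriction onto coarse interior; boundary by
    injection."""
    ncx, ncy, ncz = coarse.shape
    for I in range(ncx):
        i = 2 * I
        for J in range(ncy):
            j = 2 * J
            for K in range(ncz):
                k = 2 * K
                if (I == 0 or I == ncx - 1 or J == 0 or J == ncy - 1
                        or K == 0 or K == ncz - 1):
                    coarse[I, J, K] = fine[i, j, k]
                    continue
                acc = 0.0
                for di in range(-1, 2):
                    for dj in range(-1, 2):
                        for dk in range(-1, 2):
                            wgt = 0.125 * (0.5 ** (abs(di) + abs(dj) + abs(dk)))
                            acc += wgt * fine[i + di, j + dj, k + dk]
                coarse[I, J, K] = acc


@nb.njit(cache=True)
def prolong_add(coarse, fine):
    """Trilinear prolongation of the coarse correction added into fine."""
    nfx, nfy, nfz = fine.shape
    for i in range(nfx):
        I = i // 2
        fi = 0.5 * (i % 2)
        I1 = min(I + (i % 2), (nfx - 1) // 2)
        for j in range(nfy):
            J = j // 2
            fj = 0.5 * (j % 2)
            J1 = min(J + (j % 2), (nfy - 1) // 2)
            for k in range(nfz):
                K = k // 2
                fk = 0.5 * (k % 2)
                K1 = min(K + (k % 2), (nfz - 1) // 2)
                c000 = coarse[I, J, K]
                c100 = coarse[I1, J, K]
                c010 = coarse[I, J1, K]
                c110 = coarse[I1, J1, K]
                c001 = coarse[I, J, K1]
                c101 = coarse[I1, J, K1]
                c011 = coarse[I, J1, K1]
                c111 = coarse[I1, J1, K1]
                a = (1 - fi) * ((1 - fj) * ((1 - fk) * c000 + fk * c001)
                                + fj * ((1 - fk) * c010 + fk * c011))
                b = fi * ((1 - fj) * ((1 - fk) * c100 + fk * c101)
                          + fj * ((1 - fk) * c110 + fk * c111))
                fine[i, j, k] += a + b


@nb.njit(cache=True)
def restrict_inject(fine, coarse):
    ncx, ncy, ncz = coarse.shape
    for I in range(ncx):
        for J in range(ncy):
            for K in range(ncz):
                coarse[I, J, K] = fine[2 * I, 2 * J, 2 * K]


@nb.njit(cache=True)
def dh_sum(bc, pos, q, kd, pref, cutoff2):
    """Screened-Coulomb superposition at boundary points; pairs beyond the
    cutoff radius contribute < 1e-5 of the prefactor and are skipped."""
    out = np.zeros(bc.shape[0])
    for i in range(bc.shape[0]):
        acc = 0.0
        for n in range(pos.shape[0]):
            dx = bc[i, 0] - pos[n, 0]
            dy = bc[i, 1] - pos[n, 1]
            dz = bc[i, 2] - pos[n, 2]
            d2 = dx * dx + dy * dy + dz * dz
            if d2 > cutoff2:
                continue
            d = np.sqrt(d2)
            if d < 1e-6:
                d = 1e-6
            acc += q[n] * np.exp(-kd * d) / d
        out[i] = pref * acc
    return out


@nb.njit(cache=True)
def newton_setup(phi, ex, ey, ez, kappa2, fq, h2, w, f, clip):
    """One fused pass per Newton cycle: linearized coefficient w, linear rhs
    f, and the max-norm of the full nonlinear residual (returned)."""
    nx, ny, nz = phi.shape
    rmax = 0.0
    for i in range(nx):
        for j in range(ny):
            for k in range(nz):
                c = phi[i, j, k]
                k2 = kappa2[i, j, k]
                if k2 > 0.0:
                    pc = min(max(c, -clip), clip)
                    sh = np.sinh(pc)
                    ch = np.cosh(pc)
                    w[i, j, k] = k2 * ch
                    f[i, j, k] = fq[i, j, k] - h2 * k2 * sh + h2 * k2 * ch * c
                else:
                    sh = 0.0
                    w[i, j, k] = 0.0
                    f[i, j, k] = fq[i, j, k]
                if 0 < i < nx - 1 and 0 < j < ny - 1 and 0 < k < nz - 1:
                    ax = (ex[i - 1, j, k] * (c - phi[i - 1, j, k])
                          + ex[i, j, k] * (c - phi[i + 1, j, k])
                          + ey[i, j - 1, k] * (c - phi[i, j - 1, k])
                          + ey[i, j, k] * (c - phi[i, j + 1, k])
                          + ez[i, j, k - 1] * (c - phi[i, j, k - 1])
                          + ez[i, j, k] * (c - phi[i, j, k + 1])
                          + h2 * kappa2[i, j, k] * sh)
                    r = fq[i, j, k] - ax
                    if r < 0.0:
                        r = -r
                    if r > rmax:
                        rmax = r
    return rmax


@nb.njit(cache=True)
def damp_step(phi, phi_old, kappa2, step_max):
    """Scale the update (phi - phi_old) down if it exceeds step_max anywhere
    in the ion-accessible region; returns the scale applied."""
    nx, ny, nz = phi.shape
    smax = 0.0
    for i in range(nx):
        for j in range(ny):
            for k in range(nz):
                if kappa2[i, j, k] > 0.0:
                    d = phi[i, j, k] - phi_old[i, j, k]
                    if d < 0.0:
                        d = -d
                    if d > smax:
                        smax = d
    if smax <= step_max or smax == 0.0:
        return 1.0
    sc = step_max / smax
    for i in range(nx):
        for j in range(ny):
            for k in range(nz):
                phi[i, j, k] = phi_old[i, j, k] + sc * (phi[i, j, k]
                                                        - phi_old[i, j, k])
    return sc


@nb.njit(cache=True)
def resample_grid(src, sox, soy, soz, sh, dox, doy, doz, dh, out):
    """Trilinear resampling of a field from one regular grid onto another
    (queries outside the source grid are clamped to its edge)."""
    nx, ny, nz = out.shape
    mx, my, mz = src.shape
    for i in range(nx):
        gx = (dox + i * dh - sox) / sh
        ix = int(np.floor(gx))
        if ix < 0:
            ix = 0
        if ix > mx - 2:
            ix = mx - 2
        fx = gx - ix
        if fx < 0.0:
            fx = 0.0
        if fx > 1.0:
            fx = 1.0
        for j in range(ny):
            gy = (doy + j * dh - soy) / sh
            iy = int(np.floor(gy))
            if iy < 0:
                iy = 0
            if iy > my - 2:
                iy = my - 2
            fy = gy - iy
            if fy < 0.0:
                fy = 0.0
            if fy > 1.0:
                fy = 1.0
            for k in range(nz):
                gz = (doz + k * dh - soz) / sh
                iz = int(np.floor(gz))
                if iz < 0:
                    iz = 0
                if iz > mz - 2:
                    iz = mz - 2
                fz = gz - iz
                if fz < 0.0:
                    fz = 0.0
                if fz > 1.0:
                    fz = 1.0
                c00 = src[ix, iy, iz] * (1 - fx) + src[ix + 1, iy, iz] * fx
                c10 = src[ix, iy + 1, iz] * (1 - fx) + src[ix + 1, iy + 1, iz] * fx
                c01 = src[ix, iy, iz + 1] * (1 - fx) + src[ix + 1, iy, iz + 1] * fx
                c11 = (src[ix, iy + 1, iz + 1] * (1 - fx)
                       + src[ix + 1, iy + 1, iz + 1] * fx)
                c0 = c00 * (1 - fy) + c10 * fy
                c1 = c01 * (1 - fy) + c11 * fy
                out[i, j, k] = c0 * (1 - fz) + c1 * fz
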