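"""Numba kernels for force assembly and the lattice-sum oracle.

Everything here is an internal implementation detail; the public contracts
live in :mod:`peltrans.forces` and :mod:`peltrans.electrostatics`.  The
kernels operate on plain float64/int64 arrays and accumulate forces in
place.  Conventions: positions are wrapped into [0, L); minimum-image is
applied to every pair separation; charges are integer valences and the
Coulomb prefactor is the Bjerrum length λ_B (k_B T = 1).
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

WCA_CUT = 2.0 ** (1.0 / 6.0)


@njit(cache=True, fastmath=True)
def pair_forces(pos, q, n_mono, box, lam, alpha, rcut, sigma_bb, eps_bb, forces, excl_lj=1, excl_coul=1):
    """All-pairs mobile–mobile loop: WCA excluded volume + real-space Ewald.

    Chain neighbors up to ``excl_lj`` bonds apart skip the WCA term, and up
    to ``excl_coul`` bonds apart skip the Coulomb interaction (the bonded
    topology handles those separations).  Excluded charged pairs are
    nonetheless present in the reciprocal-space sum, so their full periodic
    interaction is cancelled here by subtracting the erf complement.
    Returns (E_wca, E_real, min_r2) so the caller can detect singular
    overlaps.
    """
    n = pos.shape[0]
    lx, ly, lz = box[0], box[1], box[2]
    hx, hy, hz = 0.5 * lx, 0.5 * ly, 0.5 * lz
    rcut2 = rcut * rcut
    wca_cut = WCA_CUT * sigma_bb
    wca_cut2 = wca_cut * wca_cut
    sig2 = sigma_bb * sigma_bb
    two_over_sqrt_pi = 2.0 / math.sqrt(math.pi)
    e_wca = 0.0
    e_real = 0.0
    min_r2 = 1.0e30
    for i in range(n - 1):
        xi, yi, zi = pos[i, 0], pos[i, 1], pos[i, 2]
        qi = q[i]
        for j in range(i + 1, n):
            # positions are wrapped to [0, L): one fold gives the minimum image
            dz = zi - pos[j, 2]
            if dz > hz:
                dz -= lz
            elif dz < -hz:
                dz += lz
            if dz >= rcut or dz <= -rcut:
                continue
            dx = xi - pos[j, 0]
            if dx > hx:
                dx -= lx
            elif dx < -hx:
                dx += lx
            dy = yi - pos[j, 1]
            if dy > hy:
                dy -= ly
            elif dy < -hy:
                dy += ly
            r2 = dx * dx + dy * dy + dz * dz
            if r2 >= rcut2:
                continue
            if r2 < min_r2:
                min_r2 = r2
            fr = 0.0  # radial force magnitude / r
            dchain = j - i if j < n_mono else 1 << 30  # chain separation, or "far"
            if r2 < wca_cut2 and dchain > excl_lj:
                s6 = sig2 / r2
                s6 = s6 * s6 * s6
                e_wca += 4.0 * eps_bb * (s6 * s6 - s6 + 0.25)
                fr += 24.0 * eps_bb * (2.0 * s6 * s6 - s6) / r2
            qq = qi * q[j]
            if qq != 0.0:
                r = math.sqrt(r2)
                # erfc via the Abramowitz–Stegun 7.1.26 rational form (abs.
                # error < 1.5e-7), sharing the Gaussian with the force term
                x = alpha * r
                g = math.exp(-x * x)
                t = 1.0 / (1.0 + 0.3275911 * x)
                er = (
                    t
                    * (0.254829592 + t * (-0.284496736 + t * (1.421413741 + t * (-1.453152027 + t * 1.061405429))))
                    * g
                )
                if dchain > excl_coul:
                    e_real += lam * qq * er / r
                    fr += lam * qq * (er / r + two_over_sqrt_pi * alpha * g) / r2
                else:
                    # cancel the reciprocal-space part: subtract erf(x)/r
                    ef = 1.0 - er
                    e_real -= lam * qq * ef / r
                    fr += lam * qq * (two_over_sqrt_pi * alpha * g / r - ef / r2) / r
            if fr != 0.0:
                forces[i, 0] += fr * dx
                forces[i, 1] += fr * dy
                forces[i, 2] += fr * dz
                forces[j, 0] -= fr * dx
                forces[j, 1] -= fr * dy
                forces[j, 2] -= fr * dz
    return e_wca, e_real, min_r2


@njit(cache=True, fastmath=True)
def bond_forces(pos, box, n_mono, k_bond, r0, forces):
    """Harmonic springs along the chain backbone (minimum-image bond vectors)."""
    lx, ly, lz = box[0], box[1], box[2]
    energy = 0.0
    for i in range(n_mono - 1):
        dx = pos[i, 0] - pos[i + 1, 0]
        dy = pos[i, 1] - pos[i + 1, 1]
        dz = pos[i, 2] - pos[i + 1, 2]
        dx -= lx * math.floor(dx / lx + 0.5)
        dy -= ly * math.floor(dy / ly + 0.5)
        dz -= lz * math.floor(dz / lz + 0.5)
        r = math.sqrt(dx * dx + dy * dy + dz * dz)
        energy += 0.5 * k_bond * (r - r0) * (r - r0)
        fr = -k_bond * (r - r0) / r
        forces[i, 0] += fr * dx
        forces[i, 1] += fr * dy
        forces[i, 2] += fr * dz
        forces[i + 1, 0] -= fr * dx
        forces[i + 1, 1] -= fr * dy
        forces[i + 1, 2] -= fr * dz
    return energy


@njit(cache=True, fastmath=True)
def wall_forces(
    pos,
    wall_pos,
    cell_start,
    cell_items,
    ncx,
    ncy,
    cell_size_x,
    cell_size_y,
    box,
    sigma_bw,
    eps_bw,
    wall_zmin,
    wall_zmax,
    forces,
):
    """Bead–wall WCA via a static 2D grid over the immobile wall beads."""
    n = pos.shape[0]
    lx, ly, lz = box[0], box[1], box[2]
    cut = WCA_CUT * sigma_bw
    cut2 = cut * cut
    sig2 = sigma_bw * sigma_bw
    energy = 0.0
    for i in range(n):
        zi = pos[i, 2]
        dz_lo = zi - wall_zmin
        dz_lo -= lz * math.floor(dz_lo / lz + 0.5)
        dz_hi = zi - wall_zmax
        dz_hi -= lz * math.floor(dz_hi / lz + 0.5)
        if dz_lo < -cut or dz_hi > cut:
            continue
        xi, yi = pos[i, 0], pos[i, 1]
        cx = int(xi / cell_size_x) % ncx
        cy = int(yi / cell_size_y) % ncy
        for ox in range(-1, 2):
            ccx = (cx + ox) % ncx
            for oy in range(-1, 2):
                ccy = (cy + oy) % ncy
                c = ccx * ncy + ccy
                for idx in range(cell_start[c], cell_start[c + 1]):
                    jw = cell_items[idx]
                    dx = xi - wall_pos[jw, 0]
                    dy = yi - wall_pos[jw, 1]
                    dz = zi - wall_pos[jw, 2]
                    dx -= lx * math.floor(dx / lx + 0.5)
                    dy -= ly * math.floor(dy / ly + 0.5)
                    dz -= lz * math.floor(dz / lz + 0.5)
                    r2 = dx * dx + dy * dy + dz * dz
                    if r2 >= cut2:
                        continue
                    s6 = sig2 / r2
                    s6 = s6 * s6 * s6
                    energy += 4.0 * eps_bw * (s6 * s6 - s6 + 0.25)
                    fr = 24.0 * eps_bw * (2.0 * s6 * s6 - s6) / r2
                    forces[i, 0] += fr * dx
                    forces[i, 1] += fr * dy
                    forces[i, 2] += fr * dz
    return energy


@njit(cache=True, fastmath=True)
def kspace_forces(pos, q, box, lam, alpha, nvecs, forces):
    """Reciprocal-space Ewald sum (half k-space, phase-table recursion).

    ``nvecs`` holds integer triples (nx, ny, nz) covering one half-space
    (each contributes twice).  Returns the reciprocal energy and adds
    forces in place.
    """
    n = pos.shape[0]
    lx, ly, lz = box[0], box[1], box[2]
    vol = lx * ly * lz
    m = nvecs.shape[0]
    nxmax = 0
    nymax = 0
    nzmax = 0
    for a in range(m):
        if abs(nvecs[a, 0]) > nxmax:
            nxmax = abs(nvecs[a, 0])
        if abs(nvecs[a, 1]) > nymax:
            nymax = abs(nvecs[a, 1])
        if abs(nvecs[a, 2]) > nzmax:
            nzmax = abs(nvecs[a, 2])
    # phase tables e^{i 2pi n x / L}, n = 0..nmax, rows contiguous over beads
    cx = np.empty((nxmax + 1, n))
    sx = np.empty((nxmax + 1, n))
    cy = np.empty((nymax + 1, n))
    sy = np.empty((nymax + 1, n))
    cz = np.empty((nzmax + 1, n))
    sz = np.empty((nzmax + 1, n))
    twopi = 2.0 * math.pi
    for i in range(n):
        cx[0, i] = 1.0
        sx[0, i] = 0.0
        cy[0, i] = 1.0
        sy[0, i] = 0.0
        cz[0, i] = 1.0
        sz[0, i] = 0.0
        c1 = math.cos(twopi * pos[i, 0] / lx)
        s1 = math.sin(twopi * pos[i, 0] / lx)
        for a in range(1, nxmax + 1):
            cx[a, i] = cx[a - 1, i] * c1 - sx[a - 1, i] * s1
            sx[a, i] = sx[a - 1, i] * c1 + cx[a - 1, i] * s1
        c1 = math.cos(twopi * pos[i, 1] / ly)
        s1 = math.sin(twopi * pos[i, 1] / ly)
        for a in range(1, nymax + 1):
            cy[a, i] = cy[a - 1, i] * c1 - sy[a - 1, i] * s1
            sy[a, i] = sy[a - 1, i] * c1 + cy[a - 1, i] * s1
        c1 = math.cos(twopi * pos[i, 2] / lz)
        s1 = math.sin(twopi * pos[i, 2] / lz)
        for a in range(1, nzmax + 1):
            cz[a, i] = cz[a - 1, i] * c1 - sz[a - 1, i] * s1
            sz[a, i] = sz[a - 1, i] * c1 + cz[a - 1, i] * s1

    eik_c = np.empty(n)
    eik_s = np.empty(n)
    energy = 0.0
    four_alpha2 = 4.0 * alpha * alpha
    for a in range(m):
        nx_i, ny_i, nz_i = nvecs[a, 0], nvecs[a, 1], nvecs[a, 2]
        kx = twopi * nx_i / lx
        ky = twopi * ny_i / ly
        kz = twopi * nz_i / lz
        k2 = kx * kx + ky * ky + kz * kz
        coef = math.exp(-k2 / four_alpha2) / k2
        sgx = 1.0 if nx_i >= 0 else -1.0
        sgy = 1.0 if ny_i >= 0 else -1.0
        sgz = 1.0 if nz_i >= 0 else -1.0
        cxa = cx[abs(nx_i)]
        sxa = sx[abs(nx_i)]
        cya = cy[abs(ny_i)]
        sya = sy[abs(ny_i)]
        cza = cz[abs(nz_i)]
        sza = sz[abs(nz_i)]
        s_re = 0.0
        s_im = 0.0
        for i in range(n):
            sxi = sgx * sxa[i]
            syi = sgy * sya[i]
            szi = sgz * sza[i]
            cr = cxa[i] * cya[i] - sxi * syi
            ci = cxa[i] * syi + sxi * cya[i]
            er = cr * cza[i] - ci * szi
            ei = cr * szi + ci * cza[i]
            eik_c[i] = er
            eik_s[i] = ei
            s_re += q[i] * er
            s_im += q[i] * ei
        # half-space: each vector counts for k and -k
        energy += 2.0 * (2.0 * math.pi * lam / vol) * coef * (s_re * s_re + s_im * s_im)
        fpref = 2.0 * (4.0 * math.pi * lam / vol) * coef
        for i in range(n):
            # Im(e^{ik.r_i} S*) = sin_i*S_re - cos_i*S_im
            f = fpref * q[i] * (eik_s[i] * s_re - eik_c[i] * s_im)
            forces[i, 0] += f * kx
            forces[i, 1] += f * ky
            forces[i, 2] += f * kz
    return energy


@njit(cache=True, fastmath=True)
def field_forces(pos, q, box, E, x0, y0, radius, zlo, zhi, forces):
    """Driving force −Z·E ẑ on every charged bead inside the channel volume."""
    n = pos.shape[0]
    lx, ly = box[0], box[1]
    r2max = radius * radius
    n_in = 0
    for i in range(n):
        if q[i] == 0.0:
            continue
        z = pos[i, 2]
        if z < zlo or z > zhi:
            continue
        dx = pos[i, 0] - x0
        dy = pos[i, 1] - y0
        dx -= lx * math.floor(dx / lx + 0.5)
        dy -= ly * math.floor(dy / ly + 0.5)
        if dx * dx + dy * dy <= r2max:
            forces[i, 2] += -q[i] * E
            n_in += 1
    return n_in


@njit(cache=True, fastmath=True)
def barrier_force(z0, z_plane, sigma, eps):
    """One-way exit barrier: repulsive WCA plane felt by the head monomer only.

    Returns (energy, f_z) for head-monomer height z0 above a plane placed at
    ``z_plane``; the repulsion switches on when z0 − z_plane < 2^(1/6)σ and
    pushes toward +z.
    """
    d = z0 - z_plane
    cut = WCA_CUT * sigma
    if d >= cut or d <= 0.0:
        return 0.0, 0.0
    s6 = (sigma / d) ** 6
    e = 4.0 * eps * (s6 * s6 - s6 + 0.25)
    f = 24.0 * eps * (2.0 * s6 * s6 - s6) / d
    return e, f


@njit(cache=True)
def direct_sum_shells(pos, q, box, shells_r2, lam):
    """Spherically-ordered real-space lattice sum of the bare Coulomb energy.

    ``shells_r2`` is a sorted array of squared image-vector radii (in units
    of integer image indices); returns the partial energy accumulated up to
    and including each shell, so callers can inspect convergence.
    """
    n = pos.shape[0]
    lx, ly, lz = box[0], box[1], box[2]
    nmax = int(math.sqrt(shells_r2[-1]) + 1e-9)
    n_shell = shells_r2.shape[0]
    partial = np.zeros(n_shell)
    for ax in range(-nmax, nmax + 1):
        for ay in range(-nmax, nmax + 1):
            for az in range(-nmax, nmax + 1):
                m2 = ax * ax + ay * ay + az * az
                if m2 > shells_r2[-1]:
                    continue
                # index of the shell this image belongs to
                si = np.searchsorted(shells_r2, m2)
                ox = ax * lx
                oy = ay * ly
                oz = az * lz
                cell_e = 0.0
                if m2 == 0:
                    for i in range(n - 1):
                        for j in range(i + 1, n):
                            dx = pos[i, 0] - pos[j, 0]
                            dy = pos[i, 1] - pos[j, 1]
                            dz = pos[i, 2] - pos[j, 2]
                            r = math.sqrt(dx * dx + dy * dy + dz * dz)
                            cell_e += lam * q[i] * q[j] / r
                else:
                    for i in range(n):
                        for j in range(n):
                            dx = pos[i, 0] - pos[j, 0] + ox
                            dy = pos[i, 1] - pos[j, 1] + oy
                            dz = pos[i, 2] - pos[j, 2] + oz
                            r = math.sqrt(dx * dx + dy * dy + dz * dz)
                            cell_e += 0.5 * lam * q[i] * q[j] / r
                partial[si] += cell_e
    return np.cumsum(partial)
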