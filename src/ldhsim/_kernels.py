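"""Numba kernels for the Monte Carlo energy evaluations.

The kernels assume cells with alpha = beta = 90 degrees (gamma free), i.e.
row vectors a=(ax,0,0), b=(bx,by,0), c=(0,0,cz) — the hexagonal and
orthorhombic cells used throughout.  Minimum images are found by wrapping
fractional differences and scanning the in-plane (-1,0,1)^2 shifts, which
is exact for these cells whenever the cell obeys the minimum-image
precondition (width >= 2 cutoff).
"""

import math

from numba import njit

__all__ = ["env_energy", "update_structure_factor", "recip_energy", "min_pair_distance"]


@njit(cache=False, fastmath=True)
def env_energy(mx, mq, msig, meps, ex, eq, esig, eeps, ax, bx, by, cz, rcut, alpha, ck):
    """LJ + real-space (erfc-screened) Coulomb energy between a moved atom
    set and an environment atom set, truncated at ``rcut``.

    Returns (e_lj, e_real) in kcal/mol (``ck`` is the Coulomb constant).
    """
    e_lj = 0.0
    e_real = 0.0
    rcut2 = rcut * rcut
    for i in range(mx.shape[0]):
        xi = mx[i, 0]
        yi = mx[i, 1]
        zi = mx[i, 2]
        qi = mq[i]
        si = msig[i]
        ei = meps[i]
        for j in range(ex.shape[0]):
            dx0 = xi - ex[j, 0]
            dy0 = yi - ex[j, 1]
            dz0 = zi - ex[j, 2]
            v = dy0 / by
            u = (dx0 - v * bx) / ax
            w = dz0 / cz
            u -= round(u)
            v -= round(v)
            w -= round(w)
            dz = w * cz
            best = 1.0e300
            for su in (-1.0, 0.0, 1.0):
                for sv in (-1.0, 0.0, 1.0):
                    dx = (u + su) * ax + (v + sv) * bx
                    dy = (v + sv) * by
                    r2 = dx * dx + dy * dy
                    if r2 < best:
                        best = r2
            r2 = best + dz * dz
            if r2 < rcut2 and r2 > 1.0e-12:
                r = math.sqrt(r2)
                e = ei * eeps[j]
                if e > 0.0:
                    s = 0.5 * (si + esig[j])
                    sr6 = (s * s / r2) ** 3
                    e_lj += 4.0 * math.sqrt(e) * (sr6 * sr6 - sr6)
                qq = qi * eq[j]
                if qq != 0.0:
                    e_real += ck * qq * math.erfc(alpha * r) / r
    return e_lj, e_real


@njit(cache=False, fastmath=True)
def update_structure_factor(kvecs, s_re, s_im, old_xyz, new_xyz, q):
    """In-place update of the structure factor when atoms move from
    ``old_xyz`` to ``new_xyz`` (pass an empty old array for insertion)."""
    nk = kvecs.shape[0]
    for a in range(old_xyz.shape[0]):
        x = old_xyz[a, 0]
        y = old_xyz[a, 1]
        z = old_xyz[a, 2]
        qa = q[a]
        for k in range(nk):
            ph = kvecs[k, 0] * x + kvecs[k, 1] * y + kvecs[k, 2] * z
            s_re[k] -= qa * math.cos(ph)
            s_im[k] -= qa * math.sin(ph)
    for a in range(new_xyz.shape[0]):
        x = new_xyz[a, 0]
        y = new_xyz[a, 1]
        z = new_xyz[a, 2]
        qa = q[a]
        for k in range(nk):
            ph = kvecs[k, 0] * x + kvecs[k, 1] * y + kvecs[k, 2] * z
            s_re[k] += qa * math.cos(ph)
            s_im[k] += qa * math.sin(ph)


@njit(cache=False, fastmath=True)
def recip_energy(coeff, s_re, s_im, prefactor):
    """Reciprocal-space Ewald energy: prefactor * sum coeff |S(k)|^2."""
    e = 0.0
    for k in range(coeff.shape[0]):
        e += coeff[k] * (s_re[k] * s_re[k] + s_im[k] * s_im[k])
    return prefactor * e


@njit(cache=False, fastmath=True)
def min_pair_distance(mx, ex, ax, bx, by, cz):
    """Smallest minimum-image distance between two atom sets."""
    best_r2 = 1.0e300
    for i in range(mx.shape[0]):
        for j in range(ex.shape[0]):
            dx0 = mx[i, 0] - ex[j, 0]
            dy0 = mx[i, 1] - ex[j, 1]
            dz0 = mx[i, 2] - ex[j, 2]
            v = dy0 / by
            u = (dx0 - v * bx) / ax
            w = dz0 / cz
            u -= round(u)
            v -= round(v)
            w -= round(w)
            dz = w * cz
            best = 1.0e300
            for su in (-1.0, 0.0, 1.0):
                for sv in (-1.0, 0.0, 1.0):
                    dx = (u + su) * ax + (v + sv) * bx
                    dy = (v + sv) * by
                    r2 = dx * dx + dy * dy
                    if r2 < best:
                        best = r2
            r2 = best + dz * dz
            if r2 < best_r2:
                best_r2 = r2
    return math.sqrt(best_r2)
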