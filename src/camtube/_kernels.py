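"""Numba-compiled inner loops: pair terms, torsions, constraints, integrator.

Everything here operates on flat float64/int64 arrays prepared by
:mod:`camtube.energy` and :mod:`camtube.dynamics`.  Energies are kJ/mol,
positions nm, velocities nm/ps, forces kJ mol^-1 nm^-1.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

#: distances below this are clamped in the r^-m terms (stats[0] counts hits)
R_MIN = 1.0e-4


# ---------------------------------------------------------------------------
# pair terms
# ---------------------------------------------------------------------------

@njit(cache=True, fastmath=True, error_model="numpy")
def half_harmonic_pairs(pos, F, ii, jj, dd, kappa, count):
    """Sum of kappa (d - r)^2 over pairs with r < d; accumulates forces."""
    e = 0.0
    for p in range(count):
        i = ii[p]
        j = jj[p]
        dx = pos[i, 0] - pos[j, 0]
        dy = pos[i, 1] - pos[j, 1]
        dz = pos[i, 2] - pos[j, 2]
        d = dd[p]
        r2 = dx * dx + dy * dy + dz * dz
        if r2 < d * d:
            r = math.sqrt(r2)
            if r < R_MIN:
                r = R_MIN
            diff = d - r
            e += kappa * diff * diff
            # dE/dr = -2 kappa (d - r); F_i = -dE/dr * (ri-rj)/r
            fmag = 2.0 * kappa * diff / r
            F[i, 0] += fmag * dx
            F[i, 1] += fmag * dy
            F[i, 2] += fmag * dz
            F[j, 0] -= fmag * dx
            F[j, 1] -= fmag * dy
            F[j, 2] -= fmag * dz
    return e


@njit(cache=True, fastmath=True, error_model="numpy")
def half_harmonic_pairs_perpair_kappa(pos, F, ii, jj, dd, kk, count):
    """Variant with a per-pair force constant (used by the fused MD loop)."""
    e = 0.0
    for p in range(count):
        i = ii[p]
        j = jj[p]
        dx = pos[i, 0] - pos[j, 0]
        dy = pos[i, 1] - pos[j, 1]
        dz = pos[i, 2] - pos[j, 2]
        d = dd[p]
        r2 = dx * dx + dy * dy + dz * dz
        if r2 < d * d:
            r = math.sqrt(r2)
            if r < R_MIN:
                r = R_MIN
            diff = d - r
            e += kk[p] * diff * diff
            fmag = 2.0 * kk[p] * diff / r
            F[i, 0] += fmag * dx
            F[i, 1] += fmag * dy
            F[i, 2] += fmag * dz
            F[j, 0] -= fmag * dx
            F[j, 1] -= fmag * dy
            F[j, 2] -= fmag * dz
    return e


@njit(cache=True, fastmath=True, error_model="numpy")
def hbond_pairs(pos, F, oo, hh, count, eps, r0, m, n, rc, stats):
    """Truncated-and-shifted 10-12 potential over directed O...H pairs."""
    A = n / (m - n)
    B = m / (m - n)
    xc = r0 / rc
    shift = eps * (A * xc ** m - B * xc ** n)
    e = 0.0
    for p in range(count):
        i = oo[p]
        j = hh[p]
        dx = pos[i, 0] - pos[j, 0]
        dy = pos[i, 1] - pos[j, 1]
        dz = pos[i, 2] - pos[j, 2]
        r2 = dx * dx + dy * dy + dz * dz
        if r2 < rc * rc:
            r = math.sqrt(r2)
            if r < R_MIN:
                r = R_MIN
                stats[0] += 1
            x = r0 / r
            xm = x ** m
            xn = x ** n
            e += eps * (A * xm - B * xn) - shift
            # dE/dr = -eps (A m x^m - B n x^n) / r
            dedr = -eps * (A * m * xm - B * n * xn) / r
            fmag = -dedr / r
            F[i, 0] += fmag * dx
            F[i, 1] += fmag * dy
            F[i, 2] += fmag * dz
            F[j, 0] -= fmag * dx
            F[j, 1] -= fmag * dy
            F[j, 2] -= fmag * dz
    return e


@njit(cache=True, fastmath=True, error_model="numpy")
def hydrophobic_pairs(pos, F, ii, jj, bb, count, epsw, rc):
    """Sigmoidal CB-CB contact term, truncated at the nonbonded cutoff."""
    e = 0.0
    for p in range(count):
        i = ii[p]
        j = jj[p]
        dx = pos[i, 0] - pos[j, 0]
        dy = pos[i, 1] - pos[j, 1]
        dz = pos[i, 2] - pos[j, 2]
        r2 = dx * dx + dy * dy + dz * dz
        if r2 < rc * rc:
            r = math.sqrt(r2)
            s = 1.0 / (1.0 + math.exp((0.8 - r) / 0.04))
            e += epsw * bb[p] * (1.0 - s)
            # dE/dr = -epsw b s (1-s) / 0.04
            dedr = -epsw * bb[p] * s * (1.0 - s) / 0.04
            fmag = -dedr / r
            F[i, 0] += fmag * dx
            F[i, 1] += fmag * dy
            F[i, 2] += fmag * dz
            F[j, 0] -= fmag * dx
            F[j, 1] -= fmag * dy
            F[j, 2] -= fmag * dz
    return e


# ---------------------------------------------------------------------------
# torsions and angles
# ---------------------------------------------------------------------------

@njit(cache=True, inline="always", fastmath=True, error_model="numpy")
def _dihedral_rad(pos, a, b, c, d):
    b1x = pos[b, 0] - pos[a, 0]
    b1y = pos[b, 1] - pos[a, 1]
    b1z = pos[b, 2] - pos[a, 2]
    b2x = pos[c, 0] - pos[b, 0]
    b2y = pos[c, 1] - pos[b, 1]
    b2z = pos[c, 2] - pos[b, 2]
    b3x = pos[d, 0] - pos[c, 0]
    b3y = pos[d, 1] - pos[c, 1]
    b3z = pos[d, 2] - pos[c, 2]
    n1x = b1y * b2z - b1z * b2y
    n1y = b1z * b2x - b1x * b2z
    n1z = b1x * b2y - b1y * b2x
    n2x = b2y * b3z - b2z * b3y
    n2y = b2z * b3x - b2x * b3z
    n2z = b2x * b3y - b2y * b3x
    nb2 = math.sqrt(b2x * b2x + b2y * b2y + b2z * b2z)
    cxx = n1y * n2z - n1z * n2y
    cxy = n1z * n2x - n1x * n2z
    cxz = n1x * n2y - n1y * n2x
    # IUPAC sign (matches geometry.dihedral_angle)
    y = (cxx * b2x + cxy * b2y + cxz * b2z) / nb2
    x = n1x * n2x + n1y * n2y + n1z * n2z
    return (math.atan2(y, x), b1x, b1y, b1z, b2x, b2y, b2z, b3x, b3y, b3z,
            n1x, n1y, n1z, n2x, n2y, n2z, nb2)


@njit(cache=True, fastmath=True, error_model="numpy")
def dihedral_terms(pos, F, aa, bb, cc, dd, V, gam, mult, count):
    """Periodic proper/improper torsions E = V (1 + cos(n phi - gamma))."""
    e = 0.0
    for p in range(count):
        a = aa[p]
        b = bb[p]
        c = cc[p]
        d = dd[p]
        (phi, b1x, b1y, b1z, b2x, b2y, b2z, b3x, b3y, b3z,
         n1x, n1y, n1z, n2x, n2y, n2z, nb2) = _dihedral_rad(pos, a, b, c, d)
        arg = mult[p] * phi - gam[p]
        e += V[p] * (1.0 + math.cos(arg))
        dedphi = -V[p] * mult[p] * math.sin(arg)
        n1sq = n1x * n1x + n1y * n1y + n1z * n1z
        n2sq = n2x * n2x + n2y * n2y + n2z * n2z
        if n1sq < 1e-18 or n2sq < 1e-18:
            continue
        # dphi/dp_a = -|b2|/|n1|^2 n1 ; dphi/dp_d = +|b2|/|n2|^2 n2
        # (for the IUPAC atan2 convention used in _dihedral_rad)
        ga = -nb2 / n1sq
        gd = nb2 / n2sq
        gax = ga * n1x
        gay = ga * n1y
        gaz = ga * n1z
        gdx = gd * n2x
        gdy = gd * n2y
        gdz = gd * n2z
        s12 = (b1x * b2x + b1y * b2y + b1z * b2z) / (nb2 * nb2)
        s32 = (b3x * b2x + b3y * b2y + b3z * b2z) / (nb2 * nb2)
        gbx = -(1.0 + s12) * gax + s32 * gdx
        gby = -(1.0 + s12) * gay + s32 * gdy
        gbz = -(1.0 + s12) * gaz + s32 * gdz
        gcx = s12 * gax - (1.0 + s32) * gdx
        gcy = s12 * gay - (1.0 + s32) * gdy
        gcz = s12 * gaz - (1.0 + s32) * gdz
        F[a, 0] -= dedphi * gax
        F[a, 1] -= dedphi * gay
        F[a, 2] -= dedphi * gaz
        F[b, 0] -= dedphi * gbx
        F[b, 1] -= dedphi * gby
        F[b, 2] -= dedphi * gbz
        F[c, 0] -= dedphi * gcx
        F[c, 1] -= dedphi * gcy
        F[c, 2] -= dedphi * gcz
        F[d, 0] -= dedphi * gdx
        F[d, 1] -= dedphi * gdy
        F[d, 2] -= dedphi * gdz
    return e


@njit(cache=True, fastmath=True, error_model="numpy")
def angle_terms(pos, F, ii, jj, kk, t0, kf, count):
    """Harmonic angles E = k/2 (theta - theta0)^2, theta0 in radians."""
    e = 0.0
    for p in range(count):
        i = ii[p]
        j = jj[p]
        k = kk[p]
        ux = pos[i, 0] - pos[j, 0]
        uy = pos[i, 1] - pos[j, 1]
        uz = pos[i, 2] - pos[j, 2]
        vx = pos[k, 0] - pos[j, 0]
        vy = pos[k, 1] - pos[j, 1]
        vz = pos[k, 2] - pos[j, 2]
        nu = math.sqrt(ux * ux + uy * uy + uz * uz)
        nv = math.sqrt(vx * vx + vy * vy + vz * vz)
        cosq = (ux * vx + uy * vy + uz * vz) / (nu * nv)
        if cosq > 1.0:
            cosq = 1.0
        elif cosq < -1.0:
            cosq = -1.0
        theta = math.acos(cosq)
        diff = theta - t0[p]
        e += 0.5 * kf[p] * diff * diff
        sinq = math.sqrt(1.0 - cosq * cosq)
        if sinq < 1e-8:
            sinq = 1e-8
        coef = -kf[p] * diff
        # dtheta/dp_i = (cosq u/nu - v/nv) / (nu sinq)
        gix = (cosq * ux / nu - vx / nv) / (nu * sinq)
        giy = (cosq * uy / nu - vy / nv) / (nu * sinq)
        giz = (cosq * uz / nu - vz / nv) / (nu * sinq)
        gkx = (cosq * vx / nv - ux / nu) / (nv * sinq)
        gky = (cosq * vy / nv - uy / nu) / (nv * sinq)
        gkz = (cosq * vz / nv - uz / nu) / (nv * sinq)
        F[i, 0] += coef * gix
        F[i, 1] += coef * giy
        F[i, 2] += coef * giz
        F[k, 0] += coef * gkx
        F[k, 1] += coef * gky
        F[k, 2] += coef * gkz
        F[j, 0] -= coef * (gix + gkx)
        F[j, 1] -= coef * (giy + gky)
        F[j, 2] -= coef * (giz + gkz)
    return e


# ---------------------------------------------------------------------------
# constraints
# ---------------------------------------------------------------------------

@njit(cache=True, fastmath=True, error_model="numpy")
def shake(pos, ci, cj, cd, invm, tol, maxiter):
    """Iterative projection onto the bond-constraint manifold.

    Sqrt-free Gauss-Seidel sweeps with over-relaxation; convergence is
    measured as max |r - d| (approximated via |r^2 - d^2| / 2d).
    Returns the number of sweeps used, or -1 on non-convergence.
    """
    nc = ci.shape[0]
    for it in range(maxiter):
        worst = 0.0
        for p in range(nc):
            i = ci[p]
            j = cj[p]
            dx = pos[i, 0] - pos[j, 0]
            dy = pos[i, 1] - pos[j, 1]
            dz = pos[i, 2] - pos[j, 2]
            d = cd[p]
            r2 = dx * dx + dy * dy + dz * dz
            diff2 = r2 - d * d
            viol = abs(diff2) / (2.0 * d)
            if viol > worst:
                worst = viol
            if viol > 0.1 * tol:
                # over-relax only for small violations; plain Gauss-Seidel
                # for large ones (SOR can diverge far from the manifold)
                omega = 1.4 if viol < 0.01 * d else 1.0
                g = omega * diff2 / (2.0 * r2 * (invm[i] + invm[j]))
                pos[i, 0] -= invm[i] * g * dx
                pos[i, 1] -= invm[i] * g * dy
                pos[i, 2] -= invm[i] * g * dz
                pos[j, 0] += invm[j] * g * dx
                pos[j, 1] += invm[j] * g * dy
                pos[j, 2] += invm[j] * g * dz
        if worst < tol:
            return it + 1
    return -1


@njit(cache=True, fastmath=True, error_model="numpy")
def rattle_velocities(pos, vel, ci, cj, invm, tol, maxiter):
    """Project velocities onto the constraint tangent space.

    Gauss-Seidel with over-relaxation; ``tol`` bounds the residual radial
    velocity (nm/ps) of any constrained bond.
    """
    nc = ci.shape[0]
    omega = 1.4
    for _it in range(maxiter):
        worst = 0.0
        for p in range(nc):
            i = ci[p]
            j = cj[p]
            dx = pos[i, 0] - pos[j, 0]
            dy = pos[i, 1] - pos[j, 1]
            dz = pos[i, 2] - pos[j, 2]
            dvx = vel[i, 0] - vel[j, 0]
            dvy = vel[i, 1] - vel[j, 1]
            dvz = vel[i, 2] - vel[j, 2]
            r2 = dx * dx + dy * dy + dz * dz
            rv = dx * dvx + dy * dvy + dz * dvz
            av = rv * rv / r2  # squared radial velocity
            if av > worst:
                worst = av
            if av > 0.01 * tol * tol:
                lam = omega * rv / (r2 * (invm[i] + invm[j]))
                vel[i, 0] -= invm[i] * lam * dx
                vel[i, 1] -= invm[i] * lam * dy
                vel[i, 2] -= invm[i] * lam * dz
                vel[j, 0] += invm[j] * lam * dx
                vel[j, 1] += invm[j] * lam * dy
                vel[j, 2] += invm[j] * lam * dz
        if worst < tol * tol:
            break


@njit(cache=True, fastmath=True, error_model="numpy")
def remove_com_motion(pos, vel, mass, remove_rotation):
    """Zero the centre-of-mass velocity and (optionally) angular momentum."""
    n = pos.shape[0]
    mtot = 0.0
    cx = cy = cz = 0.0
    vx = vy = vz = 0.0
    for i in range(n):
        m = mass[i]
        mtot += m
        cx += m * pos[i, 0]
        cy += m * pos[i, 1]
        cz += m * pos[i, 2]
        vx += m * vel[i, 0]
        vy += m * vel[i, 1]
        vz += m * vel[i, 2]
    cx /= mtot
    cy /= mtot
    cz /= mtot
    vx /= mtot
    vy /= mtot
    vz /= mtot
    for i in range(n):
        vel[i, 0] -= vx
        vel[i, 1] -= vy
        vel[i, 2] -= vz
    if remove_rotation and n > 1:
        lx = ly = lz = 0.0
        ixx = iyy = izz = ixy = ixz = iyz = 0.0
        for i in range(n):
            m = mass[i]
            rx = pos[i, 0] - cx
            ry = pos[i, 1] - cy
            rz = pos[i, 2] - cz
            lx += m * (ry * vel[i, 2] - rz * vel[i, 1])
            ly += m * (rz * vel[i, 0] - rx * vel[i, 2])
            lz += m * (rx * vel[i, 1] - ry * vel[i, 0])
            ixx += m * (ry * ry + rz * rz)
            iyy += m * (rx * rx + rz * rz)
            izz += m * (rx * rx + ry * ry)
            ixy -= m * rx * ry
            ixz -= m * rx * rz
            iyz -= m * ry * rz
        # solve I w = L for the angular velocity (closed-form 3x3, symmetric I)
        det = (ixx * (iyy * izz - iyz * iyz)
               - ixy * (ixy * izz - iyz * ixz)
               + ixz * (ixy * iyz - iyy * ixz))
        if abs(det) > 1e-12:
            inv = 1.0 / det
            wx = inv * (lx * (iyy * izz - iyz * iyz)
                        - ixy * (ly * izz - iyz * lz)
                        + ixz * (ly * iyz - iyy * lz))
            wy = inv * (ixx * (ly * izz - iyz * lz)
                        - lx * (ixy * izz - iyz * ixz)
                        + ixz * (ixy * lz - ly * ixz))
            wz = inv * (ixx * (iyy * lz - ly * iyz)
                        - ixy * (ixy * lz - ly * ixz)
                        + lx * (ixy * iyz - iyy * ixz))
            for i in range(n):
                rx = pos[i, 0] - cx
                ry = pos[i, 1] - cy
                rz = pos[i, 2] - cz
                vel[i, 0] -= wy * rz - wz * ry
                vel[i, 1] -= wz * rx - wx * rz
                vel[i, 2] -= wx * ry - wy * rx


# ---------------------------------------------------------------------------
# collective variables (value + gradient, for biasing)
# ---------------------------------------------------------------------------

@njit(cache=True, fastmath=True, error_model="numpy")
def _torsion_grads(pos, quads, vals, grads):
    """Torsions (rad) and per-atom gradients for an array of quadruples."""
    nq = quads.shape[0]
    for p in range(nq):
        a = quads[p, 0]
        b = quads[p, 1]
        c = quads[p, 2]
        d = quads[p, 3]
        (phi, b1x, b1y, b1z, b2x, b2y, b2z, b3x, b3y, b3z,
         n1x, n1y, n1z, n2x, n2y, n2z, nb2) = _dihedral_rad(pos, a, b, c, d)
        vals[p] = phi
        n1sq = n1x * n1x + n1y * n1y + n1z * n1z
        n2sq = n2x * n2x + n2y * n2y + n2z * n2z
        if n1sq < 1e-18 or n2sq < 1e-18:
            for q in range(4):
                for x in range(3):
                    grads[p, q, x] = 0.0
            continue
        ga = -nb2 / n1sq
        gd = nb2 / n2sq
        s12 = (b1x * b2x + b1y * b2y + b1z * b2z) / (nb2 * nb2)
        s32 = (b3x * b2x + b3y * b2y + b3z * b2z) / (nb2 * nb2)
        gax = ga * n1x
        gay = ga * n1y
        gaz = ga * n1z
        gdx = gd * n2x
        gdy = gd * n2y
        gdz = gd * n2z
        grads[p, 0, 0] = gax
        grads[p, 0, 1] = gay
        grads[p, 0, 2] = gaz
        grads[p, 3, 0] = gdx
        grads[p, 3, 1] = gdy
        grads[p, 3, 2] = gdz
        grads[p, 1, 0] = -(1.0 + s12) * gax + s32 * gdx
        grads[p, 1, 1] = -(1.0 + s12) * gay + s32 * gdy
        grads[p, 1, 2] = -(1.0 + s12) * gaz + s32 * gdz
        grads[p, 2, 0] = s12 * gax - (1.0 + s32) * gdx
        grads[p, 2, 1] = s12 * gay - (1.0 + s32) * gdy
        grads[p, 2, 2] = s12 * gaz - (1.0 + s32) * gdz


@njit(cache=True, fastmath=True, error_model="numpy")
def cv_rgyr(pos, ca_idx, grad):
    """Radius of gyration of the CA atoms and its coordinate gradient."""
    n = ca_idx.shape[0]
    cx = cy = cz = 0.0
    for p in range(n):
        i = ca_idx[p]
        cx += pos[i, 0]
        cy += pos[i, 1]
        cz += pos[i, 2]
    cx /= n
    cy /= n
    cz /= n
    s2 = 0.0
    for p in range(n):
        i = ca_idx[p]
        s2 += ((pos[i, 0] - cx) ** 2 + (pos[i, 1] - cy) ** 2
               + (pos[i, 2] - cz) ** 2)
    rg = math.sqrt(s2 / n)
    grad[:, :] = 0.0
    if rg > 1e-10:
        for p in range(n):
            i = ca_idx[p]
            grad[i, 0] = (pos[i, 0] - cx) / (n * rg)
            grad[i, 1] = (pos[i, 1] - cy) / (n * rg)
            grad[i, 2] = (pos[i, 2] - cz) / (n * rg)
    return rg


@njit(cache=True, fastmath=True, error_model="numpy")
def cv_dihedral_correlation(pos, phi_quads, psi_quads, vals, tgrads, grad):
    """Sum over adjacent residues of (1 + cos(x_{i+1} - x_i))/2 for phi and psi."""
    grad[:, :] = 0.0
    s = 0.0
    for quads in (phi_quads, psi_quads):
        nq = quads.shape[0]
        if nq < 2:
            continue
        _torsion_grads(pos, quads, vals[:nq], tgrads[:nq])
        for p in range(nq - 1):
            diff = vals[p + 1] - vals[p]
            s += 0.5 * (1.0 + math.cos(diff))
            dsd = -0.5 * math.sin(diff)  # d/d x_{p+1}; d/d x_p is -dsd
            for q in range(4):
                ap1 = quads[p + 1, q]
                ap0 = quads[p, q]
                for x in range(3):
                    grad[ap1, x] += dsd * tgrads[p + 1, q, x]
                    grad[ap0, x] -= dsd * tgrads[p, q, x]
    return s


@njit(cache=True, inline="always", fastmath=True, error_model="numpy")
def _smooth_box(x, lo, hi, w):
    """Differentiable indicator of lo <= x <= hi with logistic edges of width w."""
    a = 1.0 / (1.0 + math.exp(-(x - lo) / w))
    b = 1.0 / (1.0 + math.exp(-(hi - x) / w))
    v = a * b
    dv = (a * (1.0 - a) * b - a * b * (1.0 - b)) / w
    return v, dv


@njit(cache=True, fastmath=True, error_model="numpy")
def cv_ss_count(pos, phi_quads, psi_quads, res_of_phi, res_of_psi,
                n_res, box, w, vals, tgrads, grad, mem, dmem_dphi, dmem_dpsi):
    """Smooth count of 6-residue windows inside a (phi, psi) box.

    ``box`` = (phi_lo, phi_hi, psi_lo, psi_hi) in degrees; residues without a
    defined phi or psi have membership 0 and break every window containing
    them.  The value approaches the crisp window count as w -> 0.
    """
    grad[:, :] = 0.0
    nphi = phi_quads.shape[0]
    npsi = psi_quads.shape[0]
    _torsion_grads(pos, phi_quads, vals[:nphi], tgrads[:nphi])
    phiv = np.empty(nphi)
    phig = np.empty((nphi, 4, 3))
    for p in range(nphi):
        phiv[p] = vals[p]
        for q in range(4):
            for x in range(3):
                phig[p, q, x] = tgrads[p, q, x]
    _torsion_grads(pos, psi_quads, vals[:npsi], tgrads[:npsi])

    deg = 180.0 / math.pi
    mem[:] = 0.0
    dmem_dphi[:] = 0.0
    dmem_dpsi[:] = 0.0
    phi_of_res = np.full(n_res, -1, dtype=np.int64)
    psi_of_res = np.full(n_res, -1, dtype=np.int64)
    for p in range(nphi):
        phi_of_res[res_of_phi[p]] = p
    for p in range(npsi):
        psi_of_res[res_of_psi[p]] = p
    for r in range(n_res):
        pp = phi_of_res[r]
        qq = psi_of_res[r]
        if pp < 0 or qq < 0:
            continue
        fv, fdv = _smooth_box(phiv[pp] * deg, box[0], box[1], w)
        gv, gdv = _smooth_box(vals[qq] * deg, box[2], box[3], w)
        mem[r] = fv * gv
        dmem_dphi[r] = fdv * gv * deg
        dmem_dpsi[r] = fv * gdv * deg

    total = 0.0
    for start in range(n_res - 5):
        prod = 1.0
        for k in range(6):
            prod *= mem[start + k]
        total += prod
        if prod == 0.0 and True:
            # gradient needs leave-one-out products even when prod == 0
            pass
        for k in range(6):
            r = start + k
            loo = 1.0
            for k2 in range(6):
                if k2 != k:
                    loo *= mem[start + k2]
            if loo == 0.0:
                continue
            pp = phi_of_res[r]
            qq = psi_of_res[r]
            if pp >= 0 and dmem_dphi[r] != 0.0:
                c = loo * dmem_dphi[r]
                for q in range(4):
                    a = phi_quads[pp, q]
                    for x in range(3):
                        grad[a, x] += c * phig[pp, q, x]
            if qq >= 0 and dmem_dpsi[r] != 0.0:
                c = loo * dmem_dpsi[r]
                for q in range(4):
                    a = psi_quads[qq, q]
                    for x in range(3):
                        grad[a, x] += c * tgrads[qq, q, x]
    return total


@njit(cache=True, fastmath=True, error_model="numpy")
def bias_value_deriv(s, centers, heights, nh, sigma):
    """Deposited Gaussian bias V(s) and dV/ds."""
    v = 0.0
    dv = 0.0
    inv2s2 = 1.0 / (2.0 * sigma * sigma)
    for p in range(nh):
        z = s - centers[p]
        g = heights[p] * math.exp(-z * z * inv2s2)
        v += g
        dv += -g * z / (sigma * sigma)
    return v, dv


# ---------------------------------------------------------------------------
# fused force evaluation and the BAOAB chunk loop
# ---------------------------------------------------------------------------

@njit(cache=True, fastmath=True, error_model="numpy")
def _total_forces(pos, F,
                  act_i, act_j, act_d, act_n, kappa_tube,
                  ch_i, ch_j, d_ch_arr, on_i, on_j, d_on_arr,
                  cu_i, cu_j, d_cu_arr, kappa_c,
                  hb_o, hb_h, eps_h, r0, m_exp, n_exp, rc_hb, stats,
                  ph_i, ph_j, ph_b, eps_w, rc_nb,
                  di_a, di_b, di_c, di_d, di_V, di_g, di_n,
                  im_a, im_b, im_c, im_d, im_V, im_g, im_n,
                  an_i, an_j, an_k, an_t0, an_kf):
    F[:, :] = 0.0
    e = 0.0
    e += half_harmonic_pairs(pos, F, act_i, act_j, act_d, kappa_tube, act_n)
    e += half_harmonic_pairs(pos, F, ch_i, ch_j, d_ch_arr, kappa_tube, ch_i.shape[0])
    e += half_harmonic_pairs(pos, F, on_i, on_j, d_on_arr, kappa_tube, on_i.shape[0])
    e += half_harmonic_pairs(pos, F, cu_i, cu_j, d_cu_arr, kappa_c, cu_i.shape[0])
    e += hbond_pairs(pos, F, hb_o, hb_h, hb_o.shape[0], eps_h, r0, m_exp, n_exp,
                     rc_hb, stats)
    e += hydrophobic_pairs(pos, F, ph_i, ph_j, ph_b, ph_i.shape[0], eps_w, rc_nb)
    e += dihedral_terms(pos, F, di_a, di_b, di_c, di_d, di_V, di_g, di_n,
                        di_a.shape[0])
    e += dihedral_terms(pos, F, im_a, im_b, im_c, im_d, im_V, im_g, im_n,
                        im_a.shape[0])
    e += angle_terms(pos, F, an_i, an_j, an_k, an_t0, an_kf, an_i.shape[0])
    return e


@njit(cache=True, fastmath=True, error_model="numpy")
def _rebuild_tube_active(pos, tb_i, tb_j, tb_d, act_i, act_j, act_d, skin):
    n = 0
    for p in range(tb_i.shape[0]):
        i = tb_i[p]
        j = tb_j[p]
        dx = pos[i, 0] - pos[j, 0]
        dy = pos[i, 1] - pos[j, 1]
        dz = pos[i, 2] - pos[j, 2]
        lim = tb_d[p] + skin
        if dx * dx + dy * dy + dz * dz < lim * lim:
            act_i[n] = i
            act_j[n] = j
            act_d[n] = tb_d[p]
            n += 1
    return n


@njit(cache=True, fastmath=True, error_model="numpy")
def geodesic_drift(pos, vel, pbuf, ci, cj, cd, invm, h, n_geo, ctol, rtol, riter):
    """Constrained free flight for time h as n_geo drift+project sub-steps.

    Each sub-step drifts, projects positions back onto the constraint
    manifold (SHAKE), updates velocities with the discrete correction and
    re-projects them onto the tangent space (RATTLE).
    """
    n_atoms = pos.shape[0]
    sub = h / n_geo
    for _g in range(n_geo):
        for i in range(n_atoms):
            pbuf[i, 0] = pos[i, 0] + sub * vel[i, 0]
            pbuf[i, 1] = pos[i, 1] + sub * vel[i, 1]
            pbuf[i, 2] = pos[i, 2] + sub * vel[i, 2]
            pos[i, 0] = pbuf[i, 0]
            pos[i, 1] = pbuf[i, 1]
            pos[i, 2] = pbuf[i, 2]
        ok = shake(pos, ci, cj, cd, invm, ctol, 500)
        if ok < 0:
            return -1
        for i in range(n_atoms):
            vel[i, 0] += (pos[i, 0] - pbuf[i, 0]) / sub
            vel[i, 1] += (pos[i, 1] - pbuf[i, 1]) / sub
            vel[i, 2] += (pos[i, 2] - pbuf[i, 2]) / sub
        # loose tangency is enough inside the drift; the O-step and end-of-step
        # projections enforce the tight tolerance where KE is measured
        if riter > 0:
            rattle_velocities(pos, vel, ci, cj, invm, rtol, riter)
    return 0


@njit(cache=True, fastmath=True, error_model="numpy")
def md_chunk(pos, vel, F, mass, invm, normals, dt, c1, sigv, n_steps, step0,
             ci, cj, cd, ctol, n_geo, rtol_sub, riter_sub,
             tb_i, tb_j, tb_d, act_i, act_j, act_d, act_n_io, ref_pos, skin,
             kappa_tube,
             ch_i, ch_j, d_ch_arr, on_i, on_j, d_on_arr,
             cu_i, cu_j, d_cu_arr, kappa_c,
             hb_o, hb_h, eps_h, r0, m_exp, n_exp, rc_hb, stats,
             ph_i, ph_j, ph_b, eps_w, rc_nb,
             di_a, di_b, di_c, di_d, di_V, di_g, di_n,
             im_a, im_b, im_c, im_d, im_V, im_g, im_n,
             an_i, an_j, an_k, an_t0, an_kf,
             pbuf, com_mode,
             cv_id, hill_c, hill_h, nh_io, sigma, height, stride, kb_dT,
             ca_idx, phi_quads, psi_quads, res_of_phi, res_of_psi, n_res,
             box, box_w, ws_vals, ws_tg, cvgrad, mem, dmp, dms, cv_trace,
             ke_acc):
    """Advance n_steps of constrained BAOAB Langevin dynamics in place.

    ``normals`` holds the pre-drawn unit Gaussians for the O-substep,
    shape (n_steps, n_atoms, 3).  ``ke_acc`` accumulates the half-step and
    full-step kinetic energies (leapfrog-style averaging of the two cancels
    the leading O(dt^2) discretisation bias of the kinetic temperature).
    Returns 0 on success, -1 if SHAKE failed and -2 if coordinates went
    non-finite; on failure the last consistent state is left in pos/vel.
    """
    n_atoms = pos.shape[0]
    half = 0.5 * dt

    act_n = _rebuild_tube_active(pos, tb_i, tb_j, tb_d, act_i, act_j, act_d, skin)
    ref_pos[:, :] = pos
    act_n_io[0] = act_n

    for step in range(n_steps):
        # B: half kick
        for i in range(n_atoms):
            f = half * invm[i]
            vel[i, 0] += f * F[i, 0]
            vel[i, 1] += f * F[i, 1]
            vel[i, 2] += f * F[i, 2]
        # A: half drift as n_geo geodesic sub-steps (drift + SHAKE + tangent
        # projection); sub-stepping suppresses the O(h^2) kinetic-energy loss
        # of discrete constrained drift for fast bond rotors
        ok = geodesic_drift(pos, vel, pbuf, ci, cj, cd, invm, half, n_geo, ctol, rtol_sub, riter_sub)
        if ok < 0:
            return -1
        keh = 0.0
        for i in range(n_atoms):
            keh += mass[i] * (vel[i, 0] * vel[i, 0] + vel[i, 1] * vel[i, 1]
                              + vel[i, 2] * vel[i, 2])
        ke_acc[0] += 0.5 * keh
        # O: friction + noise
        if c1 < 1.0:
            for i in range(n_atoms):
                vel[i, 0] = c1 * vel[i, 0] + sigv[i] * normals[step, i, 0]
                vel[i, 1] = c1 * vel[i, 1] + sigv[i] * normals[step, i, 1]
                vel[i, 2] = c1 * vel[i, 2] + sigv[i] * normals[step, i, 2]
            rattle_velocities(pos, vel, ci, cj, invm, 1e-4, 15)
        # A: second half drift
        ok = geodesic_drift(pos, vel, pbuf, ci, cj, cd, invm, half, n_geo, ctol, rtol_sub, riter_sub)
        if ok < 0:
            return -1
        if not math.isfinite(pos[0, 0]):
            return -2
        # neighbour-list maintenance
        maxd2 = 0.0
        for i in range(n_atoms):
            dx = pos[i, 0] - ref_pos[i, 0]
            dy = pos[i, 1] - ref_pos[i, 1]
            dz = pos[i, 2] - ref_pos[i, 2]
            d2 = dx * dx + dy * dy + dz * dz
            if d2 > maxd2:
                maxd2 = d2
        if maxd2 > 0.25 * skin * skin:
            act_n = _rebuild_tube_active(pos, tb_i, tb_j, tb_d,
                                         act_i, act_j, act_d, skin)
            ref_pos[:, :] = pos
            act_n_io[0] = act_n
        # force evaluation (physical + bias)
        _total_forces(pos, F,
                      act_i, act_j, act_d, act_n, kappa_tube,
                      ch_i, ch_j, d_ch_arr, on_i, on_j, d_on_arr,
                      cu_i, cu_j, d_cu_arr, kappa_c,
                      hb_o, hb_h, eps_h, r0, m_exp, n_exp, rc_hb, stats,
                      ph_i, ph_j, ph_b, eps_w, rc_nb,
                      di_a, di_b, di_c, di_d, di_V, di_g, di_n,
                      im_a, im_b, im_c, im_d, im_V, im_g, im_n,
                      an_i, an_j, an_k, an_t0, an_kf)
        s = 0.0
        if cv_id >= 0:
            if cv_id == 0:
                s = cv_dihedral_correlation(pos, phi_quads, psi_quads,
                                            ws_vals, ws_tg, cvgrad)
            elif cv_id == 1:
                s = cv_rgyr(pos, ca_idx, cvgrad)
            else:
                s = cv_ss_count(pos, phi_quads, psi_quads, res_of_phi,
                                res_of_psi, n_res, box, box_w,
                                ws_vals, ws_tg, cvgrad, mem, dmp, dms)
            vbias, dvds = bias_value_deriv(s, hill_c, hill_h, nh_io[0], sigma)
            for i in range(n_atoms):
                F[i, 0] -= dvds * cvgrad[i, 0]
                F[i, 1] -= dvds * cvgrad[i, 1]
                F[i, 2] -= dvds * cvgrad[i, 2]
            cv_trace[step] = s
            if (step0 + step + 1) % stride == 0:
                h = height
                if kb_dT > 0.0:
                    h = height * math.exp(-vbias / kb_dT)
                hill_c[nh_io[0]] = s
                hill_h[nh_io[0]] = h
                nh_io[0] += 1
        # B: second half kick
        for i in range(n_atoms):
            f = half * invm[i]
            vel[i, 0] += f * F[i, 0]
            vel[i, 1] += f * F[i, 1]
            vel[i, 2] += f * F[i, 2]
        rattle_velocities(pos, vel, ci, cj, invm, 1e-4, 15)
        if com_mode > 0:
            remove_com_motion(pos, vel, mass, com_mode > 1)
        kef = 0.0
        for i in range(n_atoms):
            kef += mass[i] * (vel[i, 0] * vel[i, 0] + vel[i, 1] * vel[i, 1]
                              + vel[i, 2] * vel[i, 2])
        ke_acc[1] += 0.5 * kef
    return 0
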