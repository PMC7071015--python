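"""Numba-compiled inner loops for the energy model.

The kernels mirror the vectorised numpy implementation in
:mod:`cyclomimic.forcefield` term for term; the test suite asserts the two
paths agree to machine precision and that the analytic gradient matches
finite differences.  Term sums are returned as a 10-vector:

    0 bond (non-closure)   5 repulsion
    1 bond (closure)       6 omega (non-closure)
    2 angle (non-closure)  7 omega (closure)
    3 angle (closure)      8 chirality
    4 torsion barrier      9 NOE restraint
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["energy_kernel", "energy_grad_kernel"]


@njit(cache=True, fastmath=False)
def _dihedral(p0, p1, p2, p3):
    b1 = p1 - p0
    b2 = p2 - p1
    b3 = p3 - p2
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    b2n = np.sqrt(b2[0] ** 2 + b2[1] ** 2 + b2[2] ** 2)
    m1 = np.cross(n1, b2 / max(b2n, 1e-12))
    return np.arctan2(np.dot(m1, n2), np.dot(n1, n2))


@njit(cache=True, fastmath=False)
def energy_kernel(x,
                  bond_i, bond_j, bond_d0, bond_k, bond_closure,
                  ang_i, ang_j, ang_k, ang_t0, ang_closure, k_angle,
                  tq, k_torsion, periodicity,
                  oq, omega_targets, omega_closure, k_omega,
                  rep_i, rep_j, rep_d0, k_rep,
                  cq, s0, k_chir,
                  noe_i, noe_j, noe_lower, noe_upper, k_noe):
    out = np.zeros(10)
    for m in range(bond_i.shape[0]):
        i, j = bond_i[m], bond_j[m]
        dx0 = x[i, 0] - x[j, 0]
        dx1 = x[i, 1] - x[j, 1]
        dx2 = x[i, 2] - x[j, 2]
        d = np.sqrt(dx0 * dx0 + dx1 * dx1 + dx2 * dx2)
        e = bond_k[m] * (d - bond_d0[m]) ** 2
        if bond_closure[m]:
            out[1] += e
        else:
            out[0] += e
    for m in range(ang_i.shape[0]):
        i, j, k = ang_i[m], ang_j[m], ang_k[m]
        u0 = x[i, 0] - x[j, 0]
        u1 = x[i, 1] - x[j, 1]
        u2 = x[i, 2] - x[j, 2]
        v0 = x[k, 0] - x[j, 0]
        v1 = x[k, 1] - x[j, 1]
        v2 = x[k, 2] - x[j, 2]
        nu = np.sqrt(u0 * u0 + u1 * u1 + u2 * u2)
        nv = np.sqrt(v0 * v0 + v1 * v1 + v2 * v2)
        c = (u0 * v0 + u1 * v1 + u2 * v2) / max(nu * nv, 1e-12)
        if c > 1.0:
            c = 1.0
        elif c < -1.0:
            c = -1.0
        th = np.arccos(c)
        e = k_angle * (th - ang_t0[m]) ** 2
        if ang_closure[m]:
            out[3] += e
        else:
            out[2] += e
    for m in range(tq.shape[0]):
        phi = _dihedral(x[tq[m, 0]], x[tq[m, 1]], x[tq[m, 2]], x[tq[m, 3]])
        out[4] += k_torsion * (1.0 + np.cos(periodicity * phi))
    for m in range(oq.shape[0]):
        om = _dihedral(x[oq[m, 0]], x[oq[m, 1]], x[oq[m, 2]], x[oq[m, 3]])
        e = k_omega * (1.0 - np.cos(om - omega_targets[m]))
        if omega_closure[m]:
            out[7] += e
        else:
            out[6] += e
    for m in range(rep_i.shape[0]):
        i, j = rep_i[m], rep_j[m]
        dx0 = x[i, 0] - x[j, 0]
        dx1 = x[i, 1] - x[j, 1]
        dx2 = x[i, 2] - x[j, 2]
        d2 = dx0 * dx0 + dx1 * dx1 + dx2 * dx2
        r0 = rep_d0[m]
        if d2 < r0 * r0:
            ov = r0 - np.sqrt(d2)
            out[5] += k_rep * ov * ov
    for m in range(cq.shape[0]):
        vn = x[cq[m, 1]] - x[cq[m, 0]]
        vc = x[cq[m, 2]] - x[cq[m, 0]]
        vb = x[cq[m, 3]] - x[cq[m, 0]]
        vn = vn / np.sqrt(vn[0] ** 2 + vn[1] ** 2 + vn[2] ** 2)
        vc = vc / np.sqrt(vc[0] ** 2 + vc[1] ** 2 + vc[2] ** 2)
        vb = vb / np.sqrt(vb[0] ** 2 + vb[1] ** 2 + vb[2] ** 2)
        cr = np.cross(vn, vc)
        s = cr[0] * vb[0] + cr[1] * vb[1] + cr[2] * vb[2]
        out[8] += k_chir * (s - s0) ** 2
    for m in range(noe_i.shape[0]):
        i, j = noe_i[m], noe_j[m]
        dx0 = x[i, 0] - x[j, 0]
        dx1 = x[i, 1] - x[j, 1]
        dx2 = x[i, 2] - x[j, 2]
        d = np.sqrt(dx0 * dx0 + dx1 * dx1 + dx2 * dx2)
        viol = 0.0
        if d < noe_lower[m]:
            viol = noe_lower[m] - d
        elif d > noe_upper[m]:
            viol = d - noe_upper[m]
        out[9] += k_noe * viol * viol
    return out


@njit(cache=True, fastmath=False)
def _dihedral_with_grad(p0, p1, p2, p3):
    b1 = p1 - p0
    b2 = p2 - p1
    b3 = p3 - p2
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    b2n = np.sqrt(b2[0] ** 2 + b2[1] ** 2 + b2[2] ** 2)
    m1 = np.cross(n1, b2 / max(b2n, 1e-12))
    phi = np.arctan2(np.dot(m1, n2), np.dot(n1, n2))
    n1sq = max(np.dot(n1, n1), 1e-12)
    n2sq = max(np.dot(n2, n2), 1e-12)
    g0 = (b2n / n1sq) * n1
    g3 = -(b2n / n2sq) * n2
    s12 = np.dot(b1, b2) / (b2n * b2n)
    s32 = np.dot(b3, b2) / (b2n * b2n)
    g1 = -(1.0 + s12) * g0 + s32 * g3
    g2 = s12 * g0 - (1.0 + s32) * g3
    return phi, g0, g1, g2, g3


@njit(cache=True, fastmath=False)
def energy_grad_kernel(x,
                       bond_i, bond_j, bond_d0, bond_k, bond_closure,
                       ang_i, ang_j, ang_k, ang_t0, ang_closure, k_angle,
                       tq, k_torsion, periodicity,
                       oq, omega_targets, omega_closure, k_omega,
                       rep_i, rep_j, rep_d0, k_rep,
                       cq, s0, k_chir,
                       noe_i, noe_j, noe_lower, noe_upper, k_noe):
    out = np.zeros(10)
    g = np.zeros_like(x)
    for m in range(bond_i.shape[0]):
        i, j = bond_i[m], bond_j[m]
        dx0 = x[i, 0] - x[j, 0]
        dx1 = x[i, 1] - x[j, 1]
        dx2 = x[i, 2] - x[j, 2]
        d = np.sqrt(dx0 * dx0 + dx1 * dx1 + dx2 * dx2)
        dev = d - bond_d0[m]
        e = bond_k[m] * dev * dev
        if bond_closure[m]:
            out[1] += e
        else:
            out[0] += e
        coef = 2.0 * bond_k[m] * dev / max(d, 1e-12)
        g[i, 0] += coef * dx0
        g[i, 1] += coef * dx1
        g[i, 2] += coef * dx2
        g[j, 0] -= coef * dx0
        g[j, 1] -= coef * dx1
        g[j, 2] -= coef * dx2
    for m in range(ang_i.shape[0]):
        i, j, k = ang_i[m], ang_j[m], ang_k[m]
        u0 = x[i, 0] - x[j, 0]
        u1 = x[i, 1] - x[j, 1]
        u2 = x[i, 2] - x[j, 2]
        v0 = x[k, 0] - x[j, 0]
        v1 = x[k, 1] - x[j, 1]
        v2 = x[k, 2] - x[j, 2]
        nu = max(np.sqrt(u0 * u0 + u1 * u1 + u2 * u2), 1e-12)
        nv = max(np.sqrt(v0 * v0 + v1 * v1 + v2 * v2), 1e-12)
        u0 /= nu
        u1 /= nu
        u2 /= nu
        v0 /= nv
        v1 /= nv
        v2 /= nv
        c = u0 * v0 + u1 * v1 + u2 * v2
        if c > 1.0:
            c = 1.0
        elif c < -1.0:
            c = -1.0
        th = np.arccos(c)
        dev = th - ang_t0[m]
        e = k_angle * dev * dev
        if ang_closure[m]:
            out[3] += e
        else:
            out[2] += e
        s = max(np.sqrt(1.0 - c * c), 1e-8)
        pref = 2.0 * k_angle * dev
        gi0 = (c * u0 - v0) / (nu * s)
        gi1 = (c * u1 - v1) / (nu * s)
        gi2 = (c * u2 - v2) / (nu * s)
        gk0 = (c * v0 - u0) / (nv * s)
        gk1 = (c * v1 - u1) / (nv * s)
        gk2 = (c * v2 - u2) / (nv * s)
        g[i, 0] += pref * gi0
        g[i, 1] += pref * gi1
        g[i, 2] += pref * gi2
        g[k, 0] += pref * gk0
        g[k, 1] += pref * gk1
        g[k, 2] += pref * gk2
        g[j, 0] -= pref * (gi0 + gk0)
        g[j, 1] -= pref * (gi1 + gk1)
        g[j, 2] -= pref * (gi2 + gk2)
    for m in range(tq.shape[0]):
        a0, a1, a2, a3 = tq[m, 0], tq[m, 1], tq[m, 2], tq[m, 3]
        phi, g0, g1, g2, g3 = _dihedral_with_grad(x[a0], x[a1], x[a2], x[a3])
        out[4] += k_torsion * (1.0 + np.cos(periodicity * phi))
        pref = -k_torsion * periodicity * np.sin(periodicity * phi)
        for t in range(3):
            g[a0, t] += pref * g0[t]
            g[a1, t] += pref * g1[t]
            g[a2, t] += pref * g2[t]
            g[a3, t] += pref * g3[t]
    for m in range(oq.shape[0]):
        a0, a1, a2, a3 = oq[m, 0], oq[m, 1], oq[m, 2], oq[m, 3]
        om, g0, g1, g2, g3 = _dihedral_with_grad(x[a0], x[a1], x[a2], x[a3])
        e = k_omega * (1.0 - np.cos(om - omega_targets[m]))
        if omega_closure[m]:
            out[7] += e
        else:
            out[6] += e
        pref = k_omega * np.sin(om - omega_targets[m])
        for t in range(3):
            g[a0, t] += pref * g0[t]
            g[a1, t] += pref * g1[t]
            g[a2, t] += pref * g2[t]
            g[a3, t] += pref * g3[t]
    for m in range(rep_i.shape[0]):
        i, j = rep_i[m], rep_j[m]
        dx0 = x[i, 0] - x[j, 0]
        dx1 = x[i, 1] - x[j, 1]
        dx2 = x[i, 2] - x[j, 2]
        d2 = dx0 * dx0 + dx1 * dx1 + dx2 * dx2
        r0 = rep_d0[m]
        if d2 < r0 * r0:
            d = np.sqrt(d2)
            ov = r0 - d
            out[5] += k_rep * ov * ov
            coef = -2.0 * k_rep * ov / max(d, 1e-12)
            g[i, 0] += coef * dx0
            g[i, 1] += coef * dx1
            g[i, 2] += coef * dx2
            g[j, 0] -= coef * dx0
            g[j, 1] -= coef * dx1
            g[j, 2] -= coef * dx2
    for m in range(cq.shape[0]):
        ca, an, ac, ab = cq[m, 0], cq[m, 1], cq[m, 2], cq[m, 3]
        vn = x[an] - x[ca]
        vc = x[ac] - x[ca]
        vb = x[ab] - x[ca]
        nn = np.sqrt(vn[0] ** 2 + vn[1] ** 2 + vn[2] ** 2)
        nc = np.sqrt(vc[0] ** 2 + vc[1] ** 2 + vc[2] ** 2)
        nb = np.sqrt(vb[0] ** 2 + vb[1] ** 2 + vb[2] ** 2)
        un = vn / nn
        uc = vc / nc
        ub = vb / nb
        cr = np.cross(un, uc)
        s = cr[0] * ub[0] + cr[1] * ub[1] + cr[2] * ub[2]
        out[8] += k_chir * (s - s0) ** 2
        pref = 2.0 * k_chir * (s - s0)
        cb_ = np.cross(uc, ub)
        bn_ = np.cross(ub, un)
        nc_ = np.cross(un, uc)
        # (I - u u^T)/n applied to each cross product
        dn = (cb_ - un * np.dot(un, cb_)) / nn
        dc = (bn_ - uc * np.dot(uc, bn_)) / nc
        db = (nc_ - ub * np.dot(ub, nc_)) / nb
        for t in range(3):
            g[an, t] += pref * dn[t]
            g[ac, t] += pref * dc[t]
            g[ab, t] += pref * db[t]
            g[ca, t] -= pref * (dn[t] + dc[t] + db[t])
    for m in range(noe_i.shape[0]):
        i, j = noe_i[m], noe_j[m]
        dx0 = x[i, 0] - x[j, 0]
        dx1 = x[i, 1] - x[j, 1]
        dx2 = x[i, 2] - x[j, 2]
        d = np.sqrt(dx0 * dx0 + dx1 * dx1 + dx2 * dx2)
        viol = 0.0
        if d < noe_lower[m]:
            viol = d - noe_lower[m]
        elif d > noe_upper[m]:
            viol = d - noe_upper[m]
        if viol != 0.0:
            out[9] += k_noe * viol * viol
            coef = 2.0 * k_noe * viol / max(d, 1e-12)
            g[i, 0] += coef * dx0
            g[i, 1] += coef * dx1
            g[i, 2] += coef * dx2
            g[j, 0] -= coef * dx0
            g[j, 1] -= coef * dx1
            g[j, 2] -= coef * dx2
    return out, g


@njit(cache=True, fastmath=False)
def nerf_chain_kernel(n_entries, atom_idx, ref_a, ref_b, ref_c,
                      bond_r, theta, kind, src, res, offset,
                      phi, psi, omega, chi, x):
    """Place atoms sequentially from the encoded z-matrix.

    kind: 0 seed origin, 1 seed x-axis, 2 seed xy-plane, 3 NeRF placement.
    src (for kind 3): 0 phi, 1 psi, 2 omega, 3 chi, 4 constant (offset).
    """
    for e in range(n_entries):
        i = atom_idx[e]
        if kind[e] == 0:
            x[i, 0] = 0.0
            x[i, 1] = 0.0
            x[i, 2] = 0.0
        elif kind[e] == 1:
            c = ref_c[e]
            x[i, 0] = x[c, 0] + bond_r[e]
            x[i, 1] = x[c, 1]
            x[i, 2] = x[c, 2]
        elif kind[e] == 2:
            c = ref_c[e]
            x[i, 0] = x[c, 0] - bond_r[e] * np.cos(theta[e])
            x[i, 1] = x[c, 1] + bond_r[e] * np.sin(theta[e])
            x[i, 2] = x[c, 2]
        else:
            if src[e] == 0:
                tor = phi[res[e]] + offset[e]
            elif src[e] == 1:
                tor = psi[res[e]] + offset[e]
            elif src[e] == 2:
                tor = omega[res[e]] + offset[e]
            elif src[e] == 3:
                tor = chi[res[e]] + offset[e]
            else:
                tor = offset[e]
            a = ref_a[e]
            b = ref_b[e]
            c = ref_c[e]
            bc0 = x[c, 0] - x[b, 0]
            bc1 = x[c, 1] - x[b, 1]
            bc2 = x[c, 2] - x[b, 2]
            nbc = np.sqrt(bc0 * bc0 + bc1 * bc1 + bc2 * bc2)
            bc0 /= nbc
            bc1 /= nbc
            bc2 /= nbc
            ab0 = x[b, 0] - x[a, 0]
            ab1 = x[b, 1] - x[a, 1]
            ab2 = x[b, 2] - x[a, 2]
            # n = ab x bc
            n0 = ab1 * bc2 - ab2 * bc1
            n1 = ab2 * bc0 - ab0 * bc2
            n2 = ab0 * bc1 - ab1 * bc0
            nn = np.sqrt(n0 * n0 + n1 * n1 + n2 * n2)
            if nn < 1e-12:
                n0, n1, n2 = bc1 * 0.0 - bc2 * 0.0, bc2 * 1.0 - bc0 * 0.0, \
                    bc0 * 0.0 - bc1 * 1.0
                n0 = 0.0
                n1 = bc2
                n2 = -bc1
                nn = np.sqrt(n1 * n1 + n2 * n2)
                if nn < 1e-12:
                    n0, n1, n2 = -bc2, 0.0, bc0
                    nn = np.sqrt(n0 * n0 + n2 * n2)
            n0 /= nn
            n1 /= nn
            n2 /= nn
            # m = n x bc
            m0 = n1 * bc2 - n2 * bc1
            m1 = n2 * bc0 - n0 * bc2
            m2 = n0 * bc1 - n1 * bc0
            r = bond_r[e]
            th = theta[e]
            d0 = -r * np.cos(th)
            d1 = r * np.sin(th) * np.cos(tor)
            d2 = -r * np.sin(th) * np.sin(tor)
            x[i, 0] = x[c, 0] + d0 * bc0 + d1 * m0 + d2 * n0
            x[i, 1] = x[c, 1] + d0 * bc1 + d1 * m1 + d2 * n1
            x[i, 2] = x[c, 2] + d0 * bc2 + d1 * m2 + d2 * n2
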