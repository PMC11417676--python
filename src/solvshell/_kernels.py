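"""Numba-compiled inner loops for the classical force field and the linear MLP.

Everything here operates on plain float64/int64 arrays in internal units
(kcal/mol, Å, fs).  Periodic systems are restricted to orthorhombic cells,
passed as a length-3 box vector; ``box[0] <= 0`` signals a non-periodic
system.  All loops are O(N^2) over atom pairs, which is the right trade-off
at the few-hundred-atom scale this package targets.
"""

import math

import numpy as np
from numba import njit

SQRT_PI = math.sqrt(math.pi)


@njit(cache=True)
def _min_image(dx, dy, dz, box, periodic):
    if periodic:
        dx -= box[0] * round(dx / box[0])
        dy -= box[1] * round(dy / box[1])
        dz -= box[2] * round(dz / box[2])
    return dx, dy, dz


@njit(cache=True, fastmath=True)
def nonbonded_ef(pos, mol_id, q, sig, eps, box, periodic, cutoff, alpha, coulomb_k):
    """Damped shifted-force Coulomb + shifted-force LJ, intramolecular pairs excluded.

    Both terms have continuous energies and forces at the cutoff, so NVE
    dynamics conserves energy without neighbour-crossing artefacts.
    Lorentz-Berthelot combination rules.
    """
    n = pos.shape[0]
    forces = np.zeros((n, 3))
    energy = 0.0
    rc = cutoff
    rc2 = rc * rc
    # DSF shift constants
    erfc_rc = math.erfc(alpha * rc)
    e_shift = erfc_rc / rc
    f_shift = erfc_rc / rc2 + 2.0 * alpha / SQRT_PI * math.exp(-alpha * alpha * rc2) / rc
    for i in range(n - 1):
        xi = pos[i, 0]
        yi = pos[i, 1]
        zi = pos[i, 2]
        for j in range(i + 1, n):
            if mol_id[i] == mol_id[j]:
                continue
            dx = xi - pos[j, 0]
            dy = yi - pos[j, 1]
            dz = zi - pos[j, 2]
            dx, dy, dz = _min_image(dx, dy, dz, box, periodic)
            r2 = dx * dx + dy * dy + dz * dz
            if r2 >= rc2:
                continue
            r = math.sqrt(r2)
            fmag = 0.0  # dU/dr with minus sign folded later: force = -dU/dr * rhat
            # --- LJ, shifted-force ---
            e_ij = math.sqrt(eps[i] * eps[j])
            if e_ij > 0.0:
                s_ij = 0.5 * (sig[i] + sig[j])
                sr6 = (s_ij / r) ** 6
                sr12 = sr6 * sr6
                src6 = (s_ij / rc) ** 6
                src12 = src6 * src6
                e_rc = 4.0 * e_ij * (src12 - src6)
                de_rc = -24.0 * e_ij * (2.0 * src12 - src6) / rc  # dU/dr at rc
                energy += 4.0 * e_ij * (sr12 - sr6) - e_rc - de_rc * (r - rc)
                fmag += 24.0 * e_ij * (2.0 * sr12 - sr6) / r + de_rc
            # --- Coulomb, damped shifted force ---
            qq = q[i] * q[j]
            if qq != 0.0:
                erfc_r = math.erfc(alpha * r)
                energy += coulomb_k * qq * (erfc_r / r - e_shift + f_shift * (r - rc))
                fmag += coulomb_k * qq * (
                    erfc_r / r2 + 2.0 * alpha / SQRT_PI * math.exp(-alpha * alpha * r2) / r - f_shift
                )
            fx = fmag * dx / r
            fy = fmag * dy / r
            fz = fmag * dz / r
            forces[i, 0] += fx
            forces[i, 1] += fy
            forces[i, 2] += fz
            forces[j, 0] -= fx
            forces[j, 1] -= fy
            forces[j, 2] -= fz
    return energy, forces


@njit(cache=True)
def bonded_ef(pos, bonds, bond_params, angles, angle_params, box, periodic):
    """Harmonic bonds U = 1/2 k (r-r0)^2 and angles U = 1/2 k (th-th0)^2.

    Linear equilibrium angles (th0 = pi) are handled with the stable
    (pi - th)/sin(th) -> 1 limit so forces stay finite at exact linearity.
    """
    n = pos.shape[0]
    forces = np.zeros((n, 3))
    energy = 0.0
    for b in range(bonds.shape[0]):
        i = bonds[b, 0]
        j = bonds[b, 1]
        k = bond_params[b, 0]
        r0 = bond_params[b, 1]
        dx = pos[i, 0] - pos[j, 0]
        dy = pos[i, 1] - pos[j, 1]
        dz = pos[i, 2] - pos[j, 2]
        dx, dy, dz = _min_image(dx, dy, dz, box, periodic)
        r = math.sqrt(dx * dx + dy * dy + dz * dz)
        energy += 0.5 * k * (r - r0) ** 2
        fmag = -k * (r - r0) / r
        forces[i, 0] += fmag * dx
        forces[i, 1] += fmag * dy
        forces[i, 2] += fmag * dz
        forces[j, 0] -= fmag * dx
        forces[j, 1] -= fmag * dy
        forces[j, 2] -= fmag * dz
    for a in range(angles.shape[0]):
        i = angles[a, 0]  # end
        j = angles[a, 1]  # apex
        k_idx = angles[a, 2]  # end
        kth = angle_params[a, 0]
        th0 = angle_params[a, 1]
        ux = pos[i, 0] - pos[j, 0]
        uy = pos[i, 1] - pos[j, 1]
        uz = pos[i, 2] - pos[j, 2]
        vx = pos[k_idx, 0] - pos[j, 0]
        vy = pos[k_idx, 1] - pos[j, 1]
        vz = pos[k_idx, 2] - pos[j, 2]
        ux, uy, uz = _min_image(ux, uy, uz, box, periodic)
        vx, vy, vz = _min_image(vx, vy, vz, box, periodic)
        cu = math.sqrt(ux * ux + uy * uy + uz * uz)
        cv = math.sqrt(vx * vx + vy * vy + vz * vz)
        cth = (ux * vx + uy * vy + uz * vz) / (cu * cv)
        if cth > 1.0:
            cth = 1.0
        if cth < -1.0:
            cth = -1.0
        th = math.acos(cth)
        energy += 0.5 * kth * (th - th0) ** 2
        # dU/dth * dth/dcos = -kth (th-th0)/sin(th); stable near th = pi when th0 = pi
        sth = math.sin(th)
        if sth < 1.0e-8:
            # (th - th0)/sin(th) -> -1 for th0 = pi as th -> pi
            if abs(th0 - math.pi) < 1.0e-9:
                dU_dcos = kth
            else:
                dU_dcos = -kth * (th - th0) / 1.0e-8
        else:
            dU_dcos = -kth * (th - th0) / sth
        # dcos/dri etc.
        inv_cucv = 1.0 / (cu * cv)
        dci_x = vx * inv_cucv - cth * ux / (cu * cu)
        dci_y = vy * inv_cucv - cth * uy / (cu * cu)
        dci_z = vz * inv_cucv - cth * uz / (cu * cu)
        dck_x = ux * inv_cucv - cth * vx / (cv * cv)
        dck_y = uy * inv_cucv - cth * vy / (cv * cv)
        dck_z = uz * inv_cucv - cth * vz / (cv * cv)
        forces[i, 0] -= dU_dcos * dci_x
        forces[i, 1] -= dU_dcos * dci_y
        forces[i, 2] -= dU_dcos * dci_z
        forces[k_idx, 0] -= dU_dcos * dck_x
        forces[k_idx, 1] -= dU_dcos * dck_y
        forces[k_idx, 2] -= dU_dcos * dck_z
        forces[j, 0] += dU_dcos * (dci_x + dck_x)
        forces[j, 1] += dU_dcos * (dci_y + dck_y)
        forces[j, 2] += dU_dcos * (dci_z + dck_z)
    return energy, forces


# ---------------------------------------------------------------------------
# Linear MLP invariant features
# ---------------------------------------------------------------------------


@njit(cache=True)
def _fcut(r, rc):
    if r >= rc:
        return 0.0
    return 0.5 * (math.cos(math.pi * r / rc) + 1.0)


@njit(cache=True)
def _dfcut(r, rc):
    if r >= rc:
        return 0.0
    return -0.5 * math.pi / rc * math.sin(math.pi * r / rc)


@njit(cache=True, fastmath=True)
def mlp_energy_forces(pos, z, weights, rc, centers2, width2, centers3, width3, n_cos,
                      n_species, box, periodic):
    """Energy and forces of the linear invariant-feature potential.

    Feature layout per atom (dimension D):
      [0]                                  constant (per-element reference energy)
      [1 .. ns*n2]                         2-body: per neighbour species, Gaussian
                                           radial functions x cutoff
      [ns*n2+1 .. +npair*n3*n_cos]         3-body: per unordered species pair,
                                           radial product x (cos theta)^p x cutoffs
    weights has shape (n_species, D); E = sum_i w[z_i] . phi_i, F = -dE/dr.
    """
    n = pos.shape[0]
    n2 = centers2.shape[0]
    n3 = centers3.shape[0]
    npair = n_species * (n_species + 1) // 2
    forces = np.zeros((n, 3))
    energy = 0.0
    rc2 = rc * rc

    # neighbour arrays per atom (O(N^2) build)
    for i in range(n):
        wi = weights[z[i]]
        energy += wi[0]
        # collect neighbours
        nb_idx = np.empty(n, dtype=np.int64)
        nb_vec = np.empty((n, 3))
        nb_r = np.empty(n)
        cnt = 0
        for j in range(n):
            if j == i:
                continue
            dx = pos[j, 0] - pos[i, 0]
            dy = pos[j, 1] - pos[i, 1]
            dz = pos[j, 2] - pos[i, 2]
            dx, dy, dz = _min_image(dx, dy, dz, box, periodic)
            r2 = dx * dx + dy * dy + dz * dz
            if r2 < rc2:
                nb_idx[cnt] = j
                nb_vec[cnt, 0] = dx
                nb_vec[cnt, 1] = dy
                nb_vec[cnt, 2] = dz
                nb_r[cnt] = math.sqrt(r2)
                cnt += 1
        # 2-body
        for a in range(cnt):
            j = nb_idx[a]
            r = nb_r[a]
            fc = _fcut(r, rc)
            dfc = _dfcut(r, rc)
            base = 1 + z[j] * n2
            for m in range(n2):
                g = math.exp(-((r - centers2[m]) / width2) ** 2)
                dg = -2.0 * (r - centers2[m]) / (width2 * width2) * g
                w = wi[base + m]
                energy += w * g * fc
                dEdr = w * (dg * fc + g * dfc)
                # d r/d pos[j] = vec/r ; d r/d pos[i] = -vec/r
                fx = dEdr * nb_vec[a, 0] / r
                fy = dEdr * nb_vec[a, 1] / r
                fz = dEdr * nb_vec[a, 2] / r
                forces[j, 0] -= fx
                forces[j, 1] -= fy
                forces[j, 2] -= fz
                forces[i, 0] += fx
                forces[i, 1] += fy
                forces[i, 2] += fz
        # 3-body
        base3 = 1 + n_species * n2
        for a in range(cnt):
            j = nb_idx[a]
            ra = nb_r[a]
            fca = _fcut(ra, rc)
            dfca = _dfcut(ra, rc)
            for b in range(a + 1, cnt):
                kk = nb_idx[b]
                rb = nb_r[b]
                fcb = _fcut(rb, rc)
                dfcb = _dfcut(rb, rc)
                sa = z[j]
                sb = z[kk]
                if sa <= sb:
                    p_idx = sa * n_species - sa * (sa - 1) // 2 + (sb - sa)
                else:
                    p_idx = sb * n_species - sb * (sb - 1) // 2 + (sa - sb)
                dot = (nb_vec[a, 0] * nb_vec[b, 0] + nb_vec[a, 1] * nb_vec[b, 1]
                       + nb_vec[a, 2] * nb_vec[b, 2])
                cth = dot / (ra * rb)
                # d cth / d u (u = vec a), v
                dcu_x = nb_vec[b, 0] / (ra * rb) - cth * nb_vec[a, 0] / (ra * ra)
                dcu_y = nb_vec[b, 1] / (ra * rb) - cth * nb_vec[a, 1] / (ra * ra)
                dcu_z = nb_vec[b, 2] / (ra * rb) - cth * nb_vec[a, 2] / (ra * ra)
                dcv_x = nb_vec[a, 0] / (ra * rb) - cth * nb_vec[b, 0] / (rb * rb)
                dcv_y = nb_vec[a, 1] / (ra * rb) - cth * nb_vec[b, 1] / (rb * rb)
                dcv_z = nb_vec[a, 2] / (ra * rb) - cth * nb_vec[b, 2] / (rb * rb)
                for m in range(n3):
                    ga = math.exp(-((ra - centers3[m]) / width3) ** 2)
                    dga = -2.0 * (ra - centers3[m]) / (width3 * width3) * ga
                    gb = math.exp(-((rb - centers3[m]) / width3) ** 2)
                    dgb = -2.0 * (rb - centers3[m]) / (width3 * width3) * gb
                    rad = ga * gb * fca * fcb
                    drad_a = (dga * fca + ga * dfca) * gb * fcb  # d/d ra
                    drad_b = (dgb * fcb + gb * dfcb) * ga * fca  # d/d rb
                    cpow = 1.0
                    cpow_prev = 0.0
                    for p in range(n_cos):
                        w = wi[base3 + (p_idx * n3 + m) * n_cos + p]
                        energy += w * rad * cpow
                        if w != 0.0:
                            dcpow = p * cpow_prev
                            # radial parts
                            dEdra = w * drad_a * cpow
                            dEdrb = w * drad_b * cpow
                            # angular part
                            dEdc = w * rad * dcpow
                            fxa = dEdra * nb_vec[a, 0] / ra + dEdc * dcu_x
                            fya = dEdra * nb_vec[a, 1] / ra + dEdc * dcu_y
                            fza = dEdra * nb_vec[a, 2] / ra + dEdc * dcu_z
                            fxb = dEdrb * nb_vec[b, 0] / rb + dEdc * dcv_x
                            fyb = dEdrb * nb_vec[b, 1] / rb + dEdc * dcv_y
                            fzb = dEdrb * nb_vec[b, 2] / rb + dEdc * dcv_z
                            forces[j, 0] -= fxa
                            forces[j, 1] -= fya
                            forces[j, 2] -= fza
                            forces[kk, 0] -= fxb
                            forces[kk, 1] -= fyb
                            forces[kk, 2] -= fzb
                            forces[i, 0] += fxa + fxb
                            forces[i, 1] += fya + fyb
                            forces[i, 2] += fza + fzb
                        cpow_prev = cpow
                        cpow *= cth
    return energy, forces


@njit(cache=True)
def mlp_features(pos, z, rc, centers2, width2, centers3, width3, n_cos, n_species,
                 box, periodic):
    """Per-element-summed features X (ns, D) and Jacobian dX/dr (n, 3, ns, D).

    Used for fitting: the energy design row of a config is X.ravel() and the
    force design rows are -J[a, alpha].ravel().
    """
    n = pos.shape[0]
    n2 = centers2.shape[0]
    n3 = centers3.shape[0]
    npair = n_species * (n_species + 1) // 2
    D = 1 + n_species * n2 + npair * n3 * n_cos
    X = np.zeros((n_species, D))
    J = np.zeros((n, 3, n_species, D))
    rc2 = rc * rc
    for i in range(n):
        zi = z[i]
        X[zi, 0] += 1.0
        nb_idx = np.empty(n, dtype=np.int64)
        nb_vec = np.empty((n, 3))
        nb_r = np.empty(n)
        cnt = 0
        for j in range(n):
            if j == i:
                continue
            dx = pos[j, 0] - pos[i, 0]
            dy = pos[j, 1] - pos[i, 1]
            dz = pos[j, 2] - pos[i, 2]
            dx, dy, dz = _min_image(dx, dy, dz, box, periodic)
            r2 = dx * dx + dy * dy + dz * dz
            if r2 < rc2:
                nb_idx[cnt] = j
                nb_vec[cnt, 0] = dx
                nb_vec[cnt, 1] = dy
                nb_vec[cnt, 2] = dz
                nb_r[cnt] = math.sqrt(r2)
                cnt += 1
        for a in range(cnt):
            j = nb_idx[a]
            r = nb_r[a]
            fc = _fcut(r, rc)
            dfc = _dfcut(r, rc)
            base = 1 + z[j] * n2
            for m in range(n2):
                g = math.exp(-((r - centers2[m]) / width2) ** 2)
                dg = -2.0 * (r - centers2[m]) / (width2 * width2) * g
                X[zi, base + m] += g * fc
                dvdr = dg * fc + g * dfc
                for alpha in range(3):
                    grad = dvdr * nb_vec[a, alpha] / r
                    J[j, alpha, zi, base + m] += grad
                    J[i, alpha, zi, base + m] -= grad
        base3 = 1 + n_species * n2
        for a in range(cnt):
            j = nb_idx[a]
            ra = nb_r[a]
            fca = _fcut(ra, rc)
            dfca = _dfcut(ra, rc)
            for b in range(a + 1, cnt):
                kk = nb_idx[b]
                rb = nb_r[b]
                fcb = _fcut(rb, rc)
                dfcb = _dfcut(rb, rc)
                sa = z[j]
                sb = z[kk]
                if sa <= sb:
                    p_idx = sa * n_species - sa * (sa - 1) // 2 + (sb - sa)
                else:
                    p_idx = sb * n_species - sb * (sb - 1) // 2 + (sa - sb)
                dot = (nb_vec[a, 0] * nb_vec[b, 0] + nb_vec[a, 1] * nb_vec[b, 1]
                       + nb_vec[a, 2] * nb_vec[b, 2])
                cth = dot / (ra * rb)
                dcu = np.empty(3)
                dcv = np.empty(3)
                for alpha in range(3):
                    dcu[alpha] = nb_vec[b, alpha] / (ra * rb) - cth * nb_vec[a, alpha] / (ra * ra)
                    dcv[alpha] = nb_vec[a, alpha] / (ra * rb) - cth * nb_vec[b, alpha] / (rb * rb)
                for m in range(n3):
                    ga = math.exp(-((ra - centers3[m]) / width3) ** 2)
                    dga = -2.0 * (ra - centers3[m]) / (width3 * width3) * ga
                    gb = math.exp(-((rb - centers3[m]) / width3) ** 2)
                    dgb = -2.0 * (rb - centers3[m]) / (width3 * width3) * gb
                    rad = ga * gb * fca * fcb
                    drad_a = (dga * fca + ga * dfca) * gb * fcb
                    drad_b = (dgb * fcb + gb * dfcb) * ga * fca
                    cpow = 1.0
                    cpow_prev = 0.0
                    for p in range(n_cos):
                        col = base3 + (p_idx * n3 + m) * n_cos + p
                        X[zi, col] += rad * cpow
                        dcpow = p * cpow_prev
                        for alpha in range(3):
                            ga_grad = drad_a * cpow * nb_vec[a, alpha] / ra + rad * dcpow * dcu[alpha]
                            gb_grad = drad_b * cpow * nb_vec[b, alpha] / rb + rad * dcpow * dcv[alpha]
                            J[j, alpha, zi, col] += ga_grad
                            J[kk, alpha, zi, col] += gb_grad
                            J[i, alpha, zi, col] -= ga_grad + gb_grad
                        cpow_prev = cpow
                        cpow *= cth
    return X, J


@njit(cache=True)
def core_repulsion(pos, z, rc_mat, amp, box, periodic):
    """Fixed short-range guard wall: U = amp * ((rc - r)/rc)^3 for r < rc.

    rc is per species pair and chosen below every distance in the training
    data, so the wall is exactly zero on the fitted region and only steers
    dynamics out of the unsampled collapse region.
    """
    n = pos.shape[0]
    forces = np.zeros((n, 3))
    energy = 0.0
    for i in range(n - 1):
        for j in range(i + 1, n):
            rc = rc_mat[z[i], z[j]]
            if rc <= 0.0:
                continue
            dx = pos[i, 0] - pos[j, 0]
            dy = pos[i, 1] - pos[j, 1]
            dz = pos[i, 2] - pos[j, 2]
            dx, dy, dz = _min_image(dx, dy, dz, box, periodic)
            r2 = dx * dx + dy * dy + dz * dz
            if r2 >= rc * rc:
                continue
            r = math.sqrt(r2)
            t = (rc - r) / rc
            energy += amp * t * t * t
            fmag = 3.0 * amp * t * t / rc  # -dU/dr
            forces[i, 0] += fmag * dx / r
            forces[i, 1] += fmag * dy / r
            forces[i, 2] += fmag * dz / r
            forces[j, 0] -= fmag * dx / r
            forces[j, 1] -= fmag * dy / r
            forces[j, 2] -= fmag * dz / r
    return energy, forces


@njit(cache=True)
def min_pair_distances(pos, z, n_species, box, periodic):
    """Minimum interatomic distance per species pair; inf where unseen."""
    out = np.full((n_species, n_species), np.inf)
    n = pos.shape[0]
    for i in range(n - 1):
        for j in range(i + 1, n):
            dx = pos[i, 0] - pos[j, 0]
            dy = pos[i, 1] - pos[j, 1]
            dz = pos[i, 2] - pos[j, 2]
            dx, dy, dz = _min_image(dx, dy, dz, box, periodic)
            r = math.sqrt(dx * dx + dy * dy + dz * dz)
            if r < out[z[i], z[j]]:
                out[z[i], z[j]] = r
                out[z[j], z[i]] = r
    return out
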