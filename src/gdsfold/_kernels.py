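"""Numba-compiled numerical kernels.

Everything here operates on plain arrays; the public modules wrap these in
typed containers.  Kernels are deliberately free of Python objects so the
MD / Monte Carlo inner loops run at compiled speed on a single core.

Conventions: reduced units throughout (bead mass 1 mu, energy in epsilon,
distance in Angstrom, time in tu = sqrt(mu A^2 / eps), k_B = 1).
"""

import numpy as np
from numba import njit

_TINY = 1e-12


@njit(cache=False)
def bln_energy_forces(coords, s1, s2, dih, k_b, sigma, k_theta, theta0, eps):
    """BLN potential energy and forces.

    coords : (N, 3) positions
    s1, s2 : (N, N) Lennard-Jones class scalings (symmetric; only |i-j| >= 3
             entries are read)
    dih    : (N-3, 3) per-dihedral (A, B, C) coefficients
    Returns (energy, forces).  Energy is +inf for coincident nonbonded beads.
    """
    n = coords.shape[0]
    forces = np.zeros((n, 3))
    energy = 0.0

    # bonds: k_b * (r - sigma)^2  (full prefactor, no 1/2)
    for i in range(n - 1):
        dx = coords[i + 1, 0] - coords[i, 0]
        dy = coords[i + 1, 1] - coords[i, 1]
        dz = coords[i + 1, 2] - coords[i, 2]
        r = np.sqrt(dx * dx + dy * dy + dz * dz)
        if r < _TINY:
            return np.inf, forces
        energy += k_b * (r - sigma) ** 2
        f = -2.0 * k_b * (r - sigma) / r
        forces[i + 1, 0] += f * dx
        forces[i + 1, 1] += f * dy
        forces[i + 1, 2] += f * dz
        forces[i, 0] -= f * dx
        forces[i, 1] -= f * dy
        forces[i, 2] -= f * dz

    # angles: (k_theta / 2) * (theta - theta0)^2
    for j in range(1, n - 1):
        ux = coords[j - 1, 0] - coords[j, 0]
        uy = coords[j - 1, 1] - coords[j, 1]
        uz = coords[j - 1, 2] - coords[j, 2]
        vx = coords[j + 1, 0] - coords[j, 0]
        vy = coords[j + 1, 1] - coords[j, 1]
        vz = coords[j + 1, 2] - coords[j, 2]
        nu = np.sqrt(ux * ux + uy * uy + uz * uz)
        nv = np.sqrt(vx * vx + vy * vy + vz * vz)
        if nu < _TINY or nv < _TINY:
            return np.inf, forces
        c = (ux * vx + uy * vy + uz * vz) / (nu * nv)
        if c > 1.0:
            c = 1.0
        elif c < -1.0:
            c = -1.0
        theta = np.arccos(c)
        energy += 0.5 * k_theta * (theta - theta0) ** 2
        s = np.sqrt(1.0 - c * c)
        if s < 1e-8:
            s = 1e-8
        dv = k_theta * (theta - theta0)  # dE/dtheta
        # dtheta/dr_i = (c*uhat - vhat) / (nu * s), analogous for r_k
        coef = dv / s
        gix = coef * (c * ux / nu - vx / nv) / nu
        giy = coef * (c * uy / nu - vy / nv) / nu
        giz = coef * (c * uz / nu - vz / nv) / nu
        gkx = coef * (c * vx / nv - ux / nu) / nv
        gky = coef * (c * vy / nv - uy / nu) / nv
        gkz = coef * (c * vz / nv - uz / nu) / nv
        forces[j - 1, 0] -= gix
        forces[j - 1, 1] -= giy
        forces[j - 1, 2] -= giz
        forces[j + 1, 0] -= gkx
        forces[j + 1, 1] -= gky
        forces[j + 1, 2] -= gkz
        forces[j, 0] += gix + gkx
        forces[j, 1] += giy + gky
        forces[j, 2] += giz + gkz

    # dihedrals: A(1+cos phi) + B(1+cos 3phi) + C(1+sin phi)
    for d in range(n - 3):
        b1x = coords[d + 1, 0] - coords[d, 0]
        b1y = coords[d + 1, 1] - coords[d, 1]
        b1z = coords[d + 1, 2] - coords[d, 2]
        b2x = coords[d + 2, 0] - coords[d + 1, 0]
        b2y = coords[d + 2, 1] - coords[d + 1, 1]
        b2z = coords[d + 2, 2] - coords[d + 1, 2]
        b3x = coords[d + 3, 0] - coords[d + 2, 0]
        b3y = coords[d + 3, 1] - coords[d + 2, 1]
        b3z = coords[d + 3, 2] - coords[d + 2, 2]
        n1x = b1y * b2z - b1z * b2y
        n1y = b1z * b2x - b1x * b2z
        n1z = b1x * b2y - b1y * b2x
        n2x = b2y * b3z - b2z * b3y
        n2y = b2z * b3x - b2x * b3z
        n2z = b2x * b3y - b2y * b3x
        n1sq = n1x * n1x + n1y * n1y + n1z * n1z
        n2sq = n2x * n2x + n2y * n2y + n2z * n2z
        nb2 = np.sqrt(b2x * b2x + b2y * b2y + b2z * b2z)
        if n1sq < _TINY or n2sq < _TINY or nb2 < _TINY:
            # collinear backbone: dihedral undefined; skip term (fixture
            # chains carry a transverse dither precisely to avoid this)
            continue
        # phi = atan2((n1 x n2).b2hat, n1.n2)
        mx = n1y * n2z - n1z * n2y
        my = n1z * n2x - n1x * n2z
        mz = n1x * n2y - n1y * n2x
        y = (mx * b2x + my * b2y + mz * b2z) / nb2
        x = n1x * n2x + n1y * n2y + n1z * n2z
        phi = np.arctan2(y, x)
        a_c = dih[d, 0]
        b_c = dih[d, 1]
        c_c = dih[d, 2]
        energy += (a_c * (1.0 + np.cos(phi)) + b_c * (1.0 + np.cos(3.0 * phi))
                   + c_c * (1.0 + np.sin(phi)))
        dv = -a_c * np.sin(phi) - 3.0 * b_c * np.sin(3.0 * phi) + c_c * np.cos(phi)
        # dphi/dr for the four beads (standard result; sums to zero)
        g1x = -nb2 / n1sq * n1x
        g1y = -nb2 / n1sq * n1y
        g1z = -nb2 / n1sq * n1z
        g4x = nb2 / n2sq * n2x
        g4y = nb2 / n2sq * n2y
        g4z = nb2 / n2sq * n2z
        c12 = (b1x * b2x + b1y * b2y + b1z * b2z) / (nb2 * nb2)
        c32 = (b3x * b2x + b3y * b2y + b3z * b2z) / (nb2 * nb2)
        g2x = -(1.0 + c12) * g1x + c32 * g4x
        g2y = -(1.0 + c12) * g1y + c32 * g4y
        g2z = -(1.0 + c12) * g1z + c32 * g4z
        g3x = -(1.0 + c32) * g4x + c12 * g1x
        g3y = -(1.0 + c32) * g4y + c12 * g1y
        g3z = -(1.0 + c32) * g4z + c12 * g1z
        forces[d, 0] -= dv * g1x
        forces[d, 1] -= dv * g1y
        forces[d, 2] -= dv * g1z
        forces[d + 1, 0] -= dv * g2x
        forces[d + 1, 1] -= dv * g2y
        forces[d + 1, 2] -= dv * g2z
        forces[d + 2, 0] -= dv * g3x
        forces[d + 2, 1] -= dv * g3y
        forces[d + 2, 2] -= dv * g3z
        forces[d + 3, 0] -= dv * g4x
        forces[d + 3, 1] -= dv * g4y
        forces[d + 3, 2] -= dv * g4z

    # nonbonded Lennard-Jones, |i - j| >= 3:
    #   4 eps S1 [ (sigma/r)^12 - S2 (sigma/r)^6 ]
    for i in range(n - 3):
        for j in range(i + 3, n):
            dx = coords[i, 0] - coords[j, 0]
            dy = coords[i, 1] - coords[j, 1]
            dz = coords[i, 2] - coords[j, 2]
            r2 = dx * dx + dy * dy + dz * dz
            if r2 < _TINY:
                return np.inf, forces
            sr2 = sigma * sigma / r2
            sr6 = sr2 * sr2 * sr2
            sr12 = sr6 * sr6
            energy += 4.0 * eps * s1[i, j] * (sr12 - s2[i, j] * sr6)
            # f = -dE/dr * 1/r acting along (ri - rj)
            f = 4.0 * eps * s1[i, j] * (12.0 * sr12 - 6.0 * s2[i, j] * sr6) / r2
            forces[i, 0] += f * dx
            forces[i, 1] += f * dy
            forces[i, 2] += f * dz
            forces[j, 0] -= f * dx
            forces[j, 1] -= f * dy
            forces[j, 2] -= f * dz

    return energy, forces


@njit(cache=False)
def grp_new_energy_forces(coords, gmap, k, r_con, r_steric, margin,
                          r_steric13):
    """One-sided harmonic graph restraining potential and forces.

    Three hinge families: contacts (|i-j| >= 3) pulled inside
    r_con - margin, non-contacts (|i-j| >= 3) pushed outside
    r_con + margin, and every nonbonded pair pushed outside a steric
    floor (r_steric for |i-j| >= 3; r_steric13 for second neighbours,
    0 disables).  The margin keeps satisfied pairs strictly clear of the
    contact threshold so the strict r < r_con criterion classifies them
    unambiguously.  Second neighbours get their own floor because the
    harmonic angle term is finite at theta = 0 and so does not by itself
    prevent an angle from collapsing the i/i+2 pair.
    """
    n = coords.shape[0]
    forces = np.zeros((n, 3))
    energy = 0.0
    r_in = r_con - margin
    r_out = r_con + margin
    for i in range(n - 2):
        for j in range(i + 2, n):
            dx = coords[i, 0] - coords[j, 0]
            dy = coords[i, 1] - coords[j, 1]
            dz = coords[i, 2] - coords[j, 2]
            r = np.sqrt(dx * dx + dy * dy + dz * dz)
            if r < _TINY:
                r = _TINY
            dedr = 0.0
            floor = r_steric
            if j - i >= 3:
                if gmap[i, j] != 0:
                    if r > r_in:
                        energy += 0.5 * k * (r - r_in) ** 2
                        dedr += k * (r - r_in)
                else:
                    if r < r_out:
                        energy += 0.5 * k * (r_out - r) ** 2
                        dedr -= k * (r_out - r)
            else:
                floor = r_steric13
            if r < floor:
                energy += 0.5 * k * (floor - r) ** 2
                dedr -= k * (floor - r)
            if dedr != 0.0:
                f = -dedr / r
                forces[i, 0] += f * dx
                forces[i, 1] += f * dy
                forces[i, 2] += f * dz
                forces[j, 0] -= f * dx
                forces[j, 1] -= f * dy
                forces[j, 2] -= f * dz
    return energy, forces


@njit(cache=False)
def md_nvt_run(coords, vels, s1, s2, dih, k_b, sigma, k_theta, theta0, eps,
               n_steps, dt, temperature, collision_rate, seed, sample_every,
               energy_bound):
    """Velocity-Verlet NVT dynamics with an Andersen thermostat.

    Each bead independently suffers a "collision" with probability
    collision_rate per step, resampling all three velocity components from
    the Maxwell-Boltzmann distribution at `temperature`.
    Returns (traj, vtraj, n_saved, ok) where traj holds snapshots every
    sample_every steps (final frame always included).
    """
    np.random.seed(seed)
    n = coords.shape[0]
    pos = coords.copy()
    vel = vels.copy()
    n_save = n_steps // sample_every + 1
    traj = np.empty((n_save, n, 3))
    vtraj = np.empty((n_save, n, 3))
    saved = 0
    energy, forces = bln_energy_forces(pos, s1, s2, dih, k_b, sigma,
                                       k_theta, theta0, eps)
    if not np.isfinite(energy):
        return traj, vtraj, 0, False
    std = np.sqrt(temperature)
    for step in range(n_steps):
        for a in range(n):
            for c in range(3):
                vel[a, c] += 0.5 * dt * forces[a, c]
                pos[a, c] += dt * vel[a, c]
        energy, forces = bln_energy_forces(pos, s1, s2, dih, k_b, sigma,
                                           k_theta, theta0, eps)
        if not np.isfinite(energy) or np.abs(energy) > energy_bound:
            return traj, vtraj, saved, False
        for a in range(n):
            for c in range(3):
                vel[a, c] += 0.5 * dt * forces[a, c]
        if collision_rate > 0.0:
            for a in range(n):
                if np.random.random() < collision_rate:
                    vel[a, 0] = std * np.random.normal()
                    vel[a, 1] = std * np.random.normal()
                    vel[a, 2] = std * np.random.normal()
        if (step + 1) % sample_every == 0:
            traj[saved] = pos
            vtraj[saved] = vel
            saved += 1
    if saved == 0 or (n_steps % sample_every) != 0:
        traj[saved] = pos
        vtraj[saved] = vel
        saved += 1
    return traj, vtraj, saved, True


@njit(cache=False)
def _grp_pair_energy(coords, gmap, k, r_con, r_steric, margin, r_steric13,
                     b, bx, by, bz):
    """GRP energy of all nonbonded pairs involving bead b at (bx,by,bz)."""
    n = coords.shape[0]
    e = 0.0
    r_in = r_con - margin
    r_out = r_con + margin
    for j in range(n):
        if j == b or abs(j - b) < 2:
            continue
        dx = bx - coords[j, 0]
        dy = by - coords[j, 1]
        dz = bz - coords[j, 2]
        r = np.sqrt(dx * dx + dy * dy + dz * dz)
        floor = r_steric
        if abs(j - b) >= 3:
            if gmap[b, j] != 0:
                if r > r_in:
                    e += 0.5 * k * (r - r_in) ** 2
            else:
                if r < r_out:
                    e += 0.5 * k * (r_out - r) ** 2
        else:
            floor = r_steric13
        if r < floor:
            e += 0.5 * k * (floor - r) ** 2
    return e


@njit(cache=False)
def crankshaft_run(coords, gmap, k, r_con, r_steric, margin, r_steric13,
                   n_steps, t_start, t_end, seed):
    """Metropolis crankshaft Monte Carlo on the GRP energy.

    Interior beads rotate about the axis through their two chain neighbours
    (an isometry for both flanking bonds); terminal beads pivot about a
    random axis through their single neighbour (preserves the terminal
    bond).  Moves creating any nonbonded pair closer than r_steric are
    rejected outright.  Temperature decays geometrically t_start -> t_end.
    Returns (coords, final_W, n_accepted).
    """
    np.random.seed(seed)
    n = coords.shape[0]
    pos = coords.copy()
    w = 0.0
    r_in = r_con - margin
    r_out = r_con + margin
    for i in range(n - 2):
        for j in range(i + 2, n):
            dx = pos[i, 0] - pos[j, 0]
            dy = pos[i, 1] - pos[j, 1]
            dz = pos[i, 2] - pos[j, 2]
            r = np.sqrt(dx * dx + dy * dy + dz * dz)
            floor = r_steric
            if j - i >= 3:
                if gmap[i, j] != 0:
                    if r > r_in:
                        w += 0.5 * k * (r - r_in) ** 2
                else:
                    if r < r_out:
                        w += 0.5 * k * (r_out - r) ** 2
            else:
                floor = r_steric13
            if r < floor:
                w += 0.5 * k * (floor - r) ** 2
    decay = (t_end / t_start) ** (1.0 / max(1, n_steps - 1))
    temp = t_start
    accepted = 0
    for step in range(n_steps):
        b = np.random.randint(0, n)
        angle = (np.random.random() * 2.0 - 1.0) * np.pi
        if 0 < b < n - 1:
            ox = pos[b - 1, 0]
            oy = pos[b - 1, 1]
            oz = pos[b - 1, 2]
            ax = pos[b + 1, 0] - ox
            ay = pos[b + 1, 1] - oy
            az = pos[b + 1, 2] - oz
        else:
            nb = 1 if b == 0 else n - 2
            ox = pos[nb, 0]
            oy = pos[nb, 1]
            oz = pos[nb, 2]
            ax = np.random.normal()
            ay = np.random.normal()
            az = np.random.normal()
        norm = np.sqrt(ax * ax + ay * ay + az * az)
        if norm < 1e-10:
            temp *= decay
            continue
        ax /= norm
        ay /= norm
        az /= norm
        vx = pos[b, 0] - ox
        vy = pos[b, 1] - oy
        vz = pos[b, 2] - oz
        ca = np.cos(angle)
        sa = np.sin(angle)
        adotv = ax * vx + ay * vy + az * vz
        # Rodrigues rotation of v about unit axis a
        nx = vx * ca + (ay * vz - az * vy) * sa + ax * adotv * (1.0 - ca)
        ny = vy * ca + (az * vx - ax * vz) * sa + ay * adotv * (1.0 - ca)
        nz = vz * ca + (ax * vy - ay * vx) * sa + az * adotv * (1.0 - ca)
        bx = ox + nx
        by = oy + ny
        bz = oz + nz
        # steric pre-check against all partners beyond the bonded one
        clash = False
        for j in range(n):
            if j == b or abs(j - b) < 2:
                continue
            floor = r_steric if abs(j - b) >= 3 else r_steric13
            dx = bx - pos[j, 0]
            dy = by - pos[j, 1]
            dz = bz - pos[j, 2]
            if dx * dx + dy * dy + dz * dz < floor * floor:
                clash = True
                break
        if not clash:
            e_old = _grp_pair_energy(pos, gmap, k, r_con, r_steric,
                                     margin, r_steric13, b,
                                     pos[b, 0], pos[b, 1], pos[b, 2])
            e_new = _grp_pair_energy(pos, gmap, k, r_con, r_steric,
                                     margin, r_steric13, b, bx, by, bz)
            dw = e_new - e_old
            if dw <= 0.0 or np.random.random() < np.exp(-dw / temp):
                pos[b, 0] = bx
                pos[b, 1] = by
                pos[b, 2] = bz
                w += dw
                accepted += 1
        temp *= decay
    return pos, w, accepted


@njit(cache=False)
def all_pairs_hops(gmap, cap):
    """All-pairs shortest hop counts on a binary contact graph (BFS).

    Pairs in different components get the cap value (conventionally N).
    """
    n = gmap.shape[0]
    hops = np.full((n, n), cap, dtype=np.int64)
    queue = np.empty(n, dtype=np.int64)
    for s in range(n):
        hops[s, s] = 0
        head = 0
        tail = 0
        queue[tail] = s
        tail += 1
        while head < tail:
            u = queue[head]
            head += 1
            du = hops[s, u]
            for v in range(n):
                if gmap[u, v] != 0 and v != s and hops[s, v] == cap:
                    hops[s, v] = du + 1
                    queue[tail] = v
                    tail += 1
    return hops


@njit(cache=False)
def sch_from_hops(hops_a, hops_b):
    """SCH distance from two hop matrices:
    (2 / N(N-1)) * sum_{i<j} |Sa - Sb| / max(Sa, Sb)."""
    n = hops_a.shape[0]
    total = 0.0
    for i in range(n - 1):
        for j in range(i + 1, n):
            sa = hops_a[i, j]
            sb = hops_b[i, j]
            if sa != sb:
                m = sa if sa > sb else sb
                total += abs(sa - sb) / m
    return 2.0 * total / (n * (n - 1))


@njit(cache=False)
def md_vw_run(coords, s1, s2, dih, k_b, sigma, k_theta, theta0, eps,
              gmap, k_grp, r_con, r_steric, margin, r_steric13,
              n_steps_per_stage, t_ladder, dt, collision_rate, seed):
    """Thermostatted MD on the restrained surface V + W with a cooling
    ladder; used to thermally escape local minima during back-mapping."""
    np.random.seed(seed)
    n = coords.shape[0]
    pos = coords.copy()
    for stage in range(t_ladder.shape[0]):
        temp = t_ladder[stage]
        std = np.sqrt(temp)
        vel = np.empty((n, 3))
        for a in range(n):
            for c in range(3):
                vel[a, c] = std * np.random.normal()
        e, f = bln_energy_forces(pos, s1, s2, dih, k_b, sigma, k_theta,
                                 theta0, eps)
        we, wf = grp_new_energy_forces(pos, gmap, k_grp, r_con, r_steric,
                                       margin, r_steric13)
        if not np.isfinite(e + we):
            return pos, False
        forces = f + wf
        for step in range(n_steps_per_stage):
            for a in range(n):
                for c in range(3):
                    vel[a, c] += 0.5 * dt * forces[a, c]
                    pos[a, c] += dt * vel[a, c]
            e, f = bln_energy_forces(pos, s1, s2, dih, k_b, sigma, k_theta,
                                     theta0, eps)
            we, wf = grp_new_energy_forces(pos, gmap, k_grp, r_con,
                                           r_steric, margin, r_steric13)
            if not np.isfinite(e + we) or np.abs(e + we) > 1e10:
                return pos, False
            forces = f + wf
            for a in range(n):
                for c in range(3):
                    vel[a, c] += 0.5 * dt * forces[a, c]
            for a in range(n):
                if np.random.random() < collision_rate:
                    vel[a, 0] = std * np.random.normal()
                    vel[a, 1] = std * np.random.normal()
                    vel[a, 2] = std * np.random.normal()
    return pos, True
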