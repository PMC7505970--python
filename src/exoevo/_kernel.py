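"""Compiled event loop of the spatial hybrid model.

This module re-implements, in a single numba-jitted function, the event loop
whose individual operations are specified (and unit-tested) in
:mod:`exoevo.microsite` and :mod:`exoevo.lattice`:

1. draw the global death waiting time T ~ Exp(d_M * M_total);
2. advance every microsite's c/d/z pools and the common storage increment
   by an adaptive explicit Euler scheme over ``min(T, tau_diff)``;
3. apply divisions and place newborns (uniformly shuffled order, dispersal
   with micro-disturbances);
4. apply one explicit diffusion update of DOC with Neumann boundaries;
5. if the death clock fired first, remove one uniformly chosen cell.

Cells are stored per site in fixed-capacity arrays; the driver retries with
a larger capacity when the kernel reports overflow (status 1).

Randomness uses numba's internal Mersenne Twister seeded once per call, so a
fixed seed gives a bit-identical trajectory.
"""

import numpy as np
from numba import njit

# record columns
REC_T = 0
REC_C = 1
REC_D = 2
REC_Z = 3
REC_M = 4
REC_M0 = 5          # cells of strain 0 (resident)
REC_M1 = 6          # cells of strain 1 (mutant)
REC_PHISUM = 7
REC_PHIMIN = 8
REC_PHIMAX = 9
REC_STOT = 10       # total stored reserve
REC_INPUTS = 11
REC_LEACH = 12
REC_RESP = 13
REC_LEACHREC = 14
REC_CLIP = 15
N_REC = 16

# counter slots
CNT_BIRTHS = 0
CNT_DEATHS = 1
CNT_DISTURB = 2
CNT_DISP_ATT = 3
CNT_DISP_MOVE = 4
CNT_MUT = 5
CNT_CLIPS = 6
CNT_EXTINCT_AT = 7   # -1 if never extinct
CNT_ACC_DUR = 8
CNT_NEXT_STRAIN = 9
N_CNT = 10


@njit(cache=True)
def _mutate(phi_parent, p_mut, sigma_mut):
    """Daughter trait: Normal(parent, sigma) rejected into [0, 1] with
    probability p_mut.  Returns (phi, mutated?)."""
    if p_mut <= 0.0 or np.random.random() >= p_mut:
        return phi_parent, False
    while True:
        phi = np.random.normal(phi_parent, sigma_mut)
        if 0.0 <= phi <= 1.0:
            return phi, True


@njit(cache=True)
def run_lattice_kernel(
        seed, L, T, tau_diff,
        c, d, z,                    # float64[n], modified in place
        phi, S, strain,             # [n, cap], [n, cap] float64, [n, cap] i8
        M,                          # int64[n], modified in place
        I_C, I_D, l_C, l_D, theta, K_m, V_max, gamma_M, gamma_Z,
        d_M, d_Z, leach, p_soc, omega_M,
        p_disp, p_open, p_mut, sigma_mut,
        diff_rate,                  # sigma_diff / (Vk)^(2/3)
        eta,                        # Euler sub-step fraction
        rec_times, rec_out,         # float64[ns], float64[ns, N_REC]
        acc_start,                  # h; time-integral accumulation start
        acc_site_c, acc_site_d, acc_site_z,   # float64[n]
        counters,                   # float64[N_CNT]
        next_strain,
):
    np.random.seed(seed)
    n = L * L
    cap = phi.shape[1]

    # 4-neighbour topology with Neumann boundaries
    nb = np.full((n, 4), -1, dtype=np.int64)
    nnb = np.zeros(n, dtype=np.int64)
    for i in range(L):
        for j in range(L):
            s = i * L + j
            if i > 0:
                nb[s, nnb[s]] = s - L
                nnb[s] += 1
            if i < L - 1:
                nb[s, nnb[s]] = s + L
                nnb[s] += 1
            if j > 0:
                nb[s, nnb[s]] = s - 1
                nnb[s] += 1
            if j < L - 1:
                nb[s, nnb[s]] = s + 1
                nnb[s] += 1

    psum = np.zeros(n)
    G = np.zeros(n)
    lap = np.zeros(n)
    nb_site = np.empty(n * cap, dtype=np.int64)
    nb_phi = np.empty(n * cap)
    nb_S = np.empty(n * cap)
    nb_strain = np.empty(n * cap, dtype=np.int64)
    order = np.empty(n * cap, dtype=np.int64)

    cum_in = 0.0
    cum_leach = 0.0
    cum_resp = 0.0
    cum_leachrec = 0.0
    clip_res = 0.0
    counters[CNT_EXTINCT_AT] = -1.0

    t = 0.0
    rec_j = 0
    # initial sample(s) at or before t = 0
    while rec_j < rec_times.shape[0] and rec_times[rec_j] <= t:
        _record(rec_out, rec_j, t, c, d, z, phi, S, strain, M, n,
                cum_in, cum_leach, cum_resp, cum_leachrec, clip_res)
        rec_j += 1

    while t < T:
        M_tot = 0
        for s in range(n):
            M_tot += M[s]
        death_rate = d_M * M_tot
        if death_rate > 0.0:
            T_death = np.random.exponential(1.0 / death_rate)
        else:
            T_death = np.inf
        tau = tau_diff
        died = False
        if T_death <= tau:
            tau = T_death
            died = True
        if t + tau > T:
            tau = T - t
            died = False

        accumulate = t >= acc_start
        if accumulate:
            counters[CNT_ACC_DUR] += tau

        # --- deterministic flows, per site, adaptive explicit Euler -------
        for s in range(n):
            Ms = M[s]
            ps = 0.0
            for ci in range(Ms):
                ps += phi[s, ci]
            psum[s] = ps
            cs = c[s]
            ds = d[s]
            zs = z[s]
            Gs = 0.0
            remaining = tau
            while remaining > 0.0:
                u1 = V_max * ds / (K_m + ds)
                dep = theta * zs * cs
                dc = I_C - l_C * cs - dep
                dd = (I_D - l_D * ds + dep + (1.0 - leach) * d_Z * zs
                      - u1 * omega_M * Ms)
                dz = gamma_Z * u1 * omega_M * ps - d_Z * zs
                J_d = l_D + V_max * omega_M * Ms * K_m / ((K_m + ds) ** 2)
                J_c = l_C + theta * zs
                J = J_d
                if J_c > J:
                    J = J_c
                if d_Z > J:
                    J = d_Z
                if J < 1e-12:
                    J = 1e-12
                h = eta / J
                if h > remaining:
                    h = remaining
                cum_in += (I_C + I_D) * h
                cum_leach += (l_C * cs + l_D * ds) * h
                cum_leachrec += leach * d_Z * zs * h
                cum_resp += u1 * omega_M * h * (
                    Ms - gamma_M * (Ms - ps) - gamma_Z * ps)
                if accumulate:
                    acc_site_c[s] += cs * h
                    acc_site_d[s] += ds * h
                    acc_site_z[s] += zs * h
                cn = cs + dc * h
                dn = ds + dd * h
                zn = zs + dz * h
                if cn < 0.0:
                    clip_res += -cn
                    counters[CNT_CLIPS] += 1
                    cn = 0.0
                if dn < 0.0:
                    clip_res += -dn
                    counters[CNT_CLIPS] += 1
                    dn = 0.0
                if zn < 0.0:
                    clip_res += -zn
                    counters[CNT_CLIPS] += 1
                    zn = 0.0
                cs = cn
                ds = dn
                zs = zn
                Gs += u1 * h
                remaining -= h
            c[s] = cs
            d[s] = ds
            z[s] = zs
            G[s] = Gs

        # --- divisions ----------------------------------------------------
        n_new = 0
        for s in range(n):
            gm = gamma_M * omega_M * G[s]
            for ci in range(M[s]):
                total = S[s, ci] + (1.0 - phi[s, ci]) * gm
                if total >= omega_M:
                    share = (total - omega_M) * 0.5
                    S[s, ci] = share
                    child_phi, mut = _mutate(phi[s, ci], p_mut, sigma_mut)
                    child_strain = strain[s, ci]
                    if mut:
                        child_strain = next_strain
                        next_strain += 1
                        counters[CNT_MUT] += 1
                    nb_site[n_new] = s
                    nb_phi[n_new] = child_phi
                    nb_S[n_new] = share
                    nb_strain[n_new] = child_strain
                    n_new += 1
                    counters[CNT_BIRTHS] += 1
                else:
                    S[s, ci] = total

        # --- newborn placement, uniformly shuffled order --------------------
        if n_new > 0:
            for i in range(n_new):
                order[i] = i
            for i in range(n_new - 1, 0, -1):   # Fisher-Yates
                j = np.random.randint(0, i + 1)
                tmp = order[i]
                order[i] = order[j]
                order[j] = tmp
            for oi in range(n_new):
                b = order[oi]
                origin = nb_site[b]
                dest = origin
                if np.random.random() >= 1.0 - p_disp and nnb[origin] > 0:
                    counters[CNT_DISP_ATT] += 1
                    n_empty = 0
                    for q in range(nnb[origin]):
                        if M[nb[origin, q]] == 0:
                            n_empty += 1
                    if n_empty > 0:
                        pick = np.random.randint(0, n_empty)
                        for q in range(nnb[origin]):
                            tgt = nb[origin, q]
                            if M[tgt] == 0:
                                if pick == 0:
                                    dest = tgt
                                    break
                                pick -= 1
                        counters[CNT_DISP_MOVE] += 1
                    elif np.random.random() >= 1.0 - p_open:
                        tgt = nb[origin, np.random.randint(0, nnb[origin])]
                        # micro-disturbance: local mass death + recycling
                        dead_c = 0.0
                        for ci in range(M[tgt]):
                            dead_c += omega_M + S[tgt, ci]
                        c[tgt] += (1.0 - leach) * p_soc * dead_c
                        d[tgt] += (1.0 - leach) * (1.0 - p_soc) * dead_c
                        cum_leachrec += leach * dead_c
                        M[tgt] = 0
                        counters[CNT_DISTURB] += 1
                        dest = tgt
                        counters[CNT_DISP_MOVE] += 1
                if M[dest] >= cap:
                    return 1, next_strain
                ci = M[dest]
                phi[dest, ci] = nb_phi[b]
                S[dest, ci] = nb_S[b]
                strain[dest, ci] = nb_strain[b]
                M[dest] = ci + 1

        # --- DOC diffusion (explicit, Neumann) ------------------------------
        if diff_rate > 0.0 and n > 1:
            f = diff_rate * tau
            for s in range(n):
                acc = -nnb[s] * d[s]
                for q in range(nnb[s]):
                    acc += d[nb[s, q]]
                lap[s] = acc
            for s in range(n):
                d[s] += f * lap[s]

        # --- death -----------------------------------------------------------
        if died:
            alive = 0
            for s in range(n):
                alive += M[s]
            if alive > 0:
                v = np.random.randint(0, alive)
                for s in range(n):
                    if v < M[s]:
                        dead_c = omega_M + S[s, v]
                        c[s] += (1.0 - leach) * p_soc * dead_c
                        d[s] += (1.0 - leach) * (1.0 - p_soc) * dead_c
                        cum_leachrec += leach * dead_c
                        last = M[s] - 1
                        phi[s, v] = phi[s, last]
                        S[s, v] = S[s, last]
                        strain[s, v] = strain[s, last]
                        M[s] = last
                        counters[CNT_DEATHS] += 1
                        break
                    v -= M[s]
                alive -= 1
            if alive == 0 and counters[CNT_EXTINCT_AT] < 0:
                counters[CNT_EXTINCT_AT] = t + tau

        t += tau
        while rec_j < rec_times.shape[0] and rec_times[rec_j] <= t:
            _record(rec_out, rec_j, t, c, d, z, phi, S, strain, M, n,
                    cum_in, cum_leach, cum_resp, cum_leachrec, clip_res)
            rec_j += 1

    # fill any remaining samples with the final state
    while rec_j < rec_times.shape[0]:
        _record(rec_out, rec_j, t, c, d, z, phi, S, strain, M, n,
                cum_in, cum_leach, cum_resp, cum_leachrec, clip_res)
        rec_j += 1
    counters[CNT_NEXT_STRAIN] = next_strain
    return 0, next_strain


@njit(cache=True)
def _record(rec_out, j, t, c, d, z, phi, S, strain, M, n,
            cum_in, cum_leach, cum_resp, cum_leachrec, clip_res):
    c_tot = 0.0
    d_tot = 0.0
    z_tot = 0.0
    s_tot = 0.0
    m_tot = 0
    m0 = 0
    m1 = 0
    phisum = 0.0
    phimin = np.inf
    phimax = -np.inf
    for s in range(n):
        c_tot += c[s]
        d_tot += d[s]
        z_tot += z[s]
        m_tot += M[s]
        for ci in range(M[s]):
            s_tot += S[s, ci]
            ph = phi[s, ci]
            phisum += ph
            if ph < phimin:
                phimin = ph
            if ph > phimax:
                phimax = ph
            if strain[s, ci] == 0:
                m0 += 1
            elif strain[s, ci] == 1:
                m1 += 1
    if m_tot == 0:
        phimin = np.nan
        phimax = np.nan
    rec_out[j, REC_T] = t
    rec_out[j, REC_C] = c_tot
    rec_out[j, REC_D] = d_tot
    rec_out[j, REC_Z] = z_tot
    rec_out[j, REC_M] = m_tot
    rec_out[j, REC_M0] = m0
    rec_out[j, REC_M1] = m1
    rec_out[j, REC_PHISUM] = phisum
    rec_out[j, REC_PHIMIN] = phimin
    rec_out[j, REC_PHIMAX] = phimax
    rec_out[j, REC_STOT] = s_tot
    rec_out[j, REC_INPUTS] = cum_in
    rec_out[j, REC_LEACH] = cum_leach
    rec_out[j, REC_RESP] = cum_resp
    rec_out[j, REC_LEACHREC] = cum_leachrec
    rec_out[j, REC_CLIP] = clip_res
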