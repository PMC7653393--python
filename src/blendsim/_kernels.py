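"""Compiled inner loops for the stochastic engines.

These kernels are the hot paths of the Gillespie direct method, the
fixed-step Brownian update and the compartment-Brownian hybrid window
loop.  They are plain translations of the algorithms exposed by
:mod:`blendsim.compartment`, :mod:`blendsim.brownian` and
:mod:`blendsim.hybrid_cb`; the pure-Python paths in those modules
(used with event hooks and in unit tests) define the reference
semantics.

All kernels draw from numba's internal global RNG, which is seeded
explicitly via the ``seed`` argument of each entry point, so a run is
fully reproducible from its seed.

Event-channel order per compartment (shared by total and selection
scans so that the accumulations round identically): left jump, right
jump, order-0 production, order-1 decay, order-2 pair annihilation; a
boundary influx channel (into compartment 0) is scanned first.
"""

import numpy as np
from numba import njit

# status codes returned by the hybrid kernel
OK = 0
FAULT_EMPTY_COMPARTMENT = 1
FAULT_CAPACITY = 2


@njit(cache=True)
def seed_rng(seed):
    """Seed numba's global RNG (used by kernels that take no seed)."""
    np.random.seed(seed)


@njit(cache=True)
def _total_propensity(C, rate_l, rate_r, vol, kappa2, mu, kappa1, influx):
    total = influx
    n = C.shape[0]
    for i in range(n):
        ci = C[i] if C[i] > 0.0 else 0.0
        total += ci * rate_l[i]
        total += ci * rate_r[i]
        total += kappa2 * vol
        total += ci * mu
        if ci > 1.0:
            total += kappa1 * ci * (ci - 1.0) / (2.0 * vol)
    return total


@njit(cache=True)
def ssa_window(C, rate_l, rate_r, vol, kappa2, mu, kappa1, influx,
               t0, t_end, deltaC):
    """Gillespie direct method on a compartment chain until ``t_end``.

    Counts may be real-valued (the PDE-compartment coupler syncs
    non-integer mass into the blending compartments); propensities
    floor at zero and events change counts by integer stoichiometry.
    ``deltaC`` accumulates the net integer count change per compartment.
    Returns the number of events executed.
    """
    n = C.shape[0]
    t = t0
    nev = 0
    while True:
        total = _total_propensity(C, rate_l, rate_r, vol, kappa2, mu,
                                  kappa1, influx)
        if total <= 0.0:
            return nev
        t += np.random.exponential(1.0 / total)
        if t > t_end:
            return nev
        r = np.random.random() * total
        acc = influx
        if r < acc:
            C[0] += 1.0
            deltaC[0] += 1
            nev += 1
            continue
        fired = False
        for i in range(n):
            ci = C[i] if C[i] > 0.0 else 0.0
            acc += ci * rate_l[i]
            if r < acc:
                C[i] -= 1.0
                C[i - 1] += 1.0
                deltaC[i] -= 1
                deltaC[i - 1] += 1
                fired = True
                break
            acc += ci * rate_r[i]
            if r < acc:
                C[i] -= 1.0
                C[i + 1] += 1.0
                deltaC[i] -= 1
                deltaC[i + 1] += 1
                fired = True
                break
            acc += kappa2 * vol
            if r < acc:
                C[i] += 1.0
                deltaC[i] += 1
                fired = True
                break
            acc += ci * mu
            if r < acc:
                C[i] -= 1.0
                deltaC[i] -= 1
                fired = True
                break
            if ci > 1.0:
                acc += kappa1 * ci * (ci - 1.0) / (2.0 * vol)
                if r < acc:
                    C[i] -= 2.0
                    deltaC[i] -= 2
                    fired = True
                    break
        if fired:
            nev += 1
        # identical accumulation order in both scans makes a fall-through
        # impossible up to floating-point ties; treat one as a no-op


@njit(cache=True)
def compartment_run(C0, rate_l, rate_r, vol, kappa2, mu, kappa1, influx,
                    out_times, seed):
    """Run a standalone compartment simulation, recording counts at out_times."""
    np.random.seed(seed)
    n = C0.shape[0]
    C = C0.copy()
    deltaC = np.zeros(n, np.int64)
    out = np.zeros((out_times.shape[0], n))
    t = 0.0
    for k in range(out_times.shape[0]):
        ssa_window(C, rate_l, rate_r, vol, kappa2, mu, kappa1, influx,
                   t, out_times[k], deltaC)
        t = out_times[k]
        out[k, :] = C
    return out


# ---------------------------------------------------------------------------
# Brownian helpers
# ---------------------------------------------------------------------------

@njit(cache=True)
def _reflect_coord(x, lo, hi):
    """Reflect a coordinate into [lo, hi]; returns (x, crossings_at_lo)."""
    nl = 0
    while x < lo or x > hi:
        if x < lo:
            x = 2.0 * lo - x
            nl += 1
        else:
            x = 2.0 * hi - x
    return x, nl


@njit(cache=True)
def _shuffle(idx, m):
    for i in range(m - 1, 0, -1):
        j = np.random.randint(0, i + 1)
        tmp = idx[i]
        idx[i] = idx[j]
        idx[j] = tmp


@njit(cache=True)
def _mark_pairs(pos, elig, m, rho, p_lambda, dim, consumed):
    """lambda-rho rule: each eligible pair closer than rho reacts with
    probability p_lambda; consumed particles leave the pool.  Pairs are
    scanned in randomized order."""
    if m < 2:
        return
    _shuffle(elig, m)
    rho2 = rho * rho
    for ii in range(m):
        ki = elig[ii]
        if consumed[ki]:
            continue
        for jj in range(ii + 1, m):
            kj = elig[jj]
            if consumed[kj]:
                continue
            d2 = (pos[ki, 0] - pos[kj, 0]) ** 2
            if dim == 3:
                d2 += (pos[ki, 1] - pos[kj, 1]) ** 2
                d2 += (pos[ki, 2] - pos[kj, 2]) ** 2
            if d2 < rho2 and np.random.random() < p_lambda:
                consumed[ki] = True
                consumed[kj] = True
                break


# ---------------------------------------------------------------------------
# Compartment-Brownian hybrid: full run
# ---------------------------------------------------------------------------
#
# Particle bookkeeping: positions live in pos[0:n_act].  comp_of[k] is the
# blending-compartment index of particle k (-1 in the pure-Brownian
# region), slot_of[k] its slot in members[comp_of[k]], and
# members[ib, 0:mcount[ib]] lists the particles of blending compartment
# ib.  Removal swaps with the last active particle.

@njit(cache=True)
def _member_remove(k, comp_of, slot_of, members, mcount):
    ib = comp_of[k]
    if ib >= 0:
        s = slot_of[k]
        last = mcount[ib] - 1
        moved = members[ib, last]
        members[ib, s] = moved
        slot_of[moved] = s
        mcount[ib] = last
        comp_of[k] = -1


@njit(cache=True)
def _member_add(k, ib, comp_of, slot_of, members, mcount):
    members[ib, mcount[ib]] = k
    comp_of[k] = ib
    slot_of[k] = mcount[ib]
    mcount[ib] += 1


@njit(cache=True)
def _particle_remove(k, n_act, pos, comp_of, slot_of, members, mcount):
    _member_remove(k, comp_of, slot_of, members, mcount)
    j = n_act - 1
    if j != k:
        pos[k, 0] = pos[j, 0]
        pos[k, 1] = pos[j, 1]
        pos[k, 2] = pos[j, 2]
        ibj = comp_of[j]
        comp_of[k] = ibj
        if ibj >= 0:
            slot_of[k] = slot_of[j]
            members[ibj, slot_of[j]] = k
        comp_of[j] = -1
    else:
        comp_of[k] = -1
    return j


@njit(cache=True)
def _particle_add(x, y, z, n_act, cap, pos, comp_of, slot_of, members,
                  mcount, I1, I2, h, n2):
    if n_act >= cap:
        return -1
    k = n_act
    pos[k, 0] = x
    pos[k, 1] = y
    pos[k, 2] = z
    comp_of[k] = -1
    if x < I2:
        ib = int((x - I1) / h)
        if ib >= n2:
            ib = n2 - 1
        if ib < 0:
            ib = 0
        _member_add(k, ib, comp_of, slot_of, members, mcount)
    return n_act + 1


@njit(cache=True)
def _cb_ssa_window(C, rate_l, rate_r, vol, kappa2, mu, kappa1, influx,
                   t0, t_end, n_c, n2, a, I1, I2, h, Ly, Lz, dim,
                   pos, comp_of, slot_of, members, mcount, n_act, cap):
    """SSA on the [a, I2] chain with immediate particle mirroring.

    Every event touching a blending compartment (index >= n_c) is
    mirrored into the Brownian particles: jumps displace a uniformly
    chosen resident by +-h, interface crossings create/delete a
    particle, reactions create/delete uniformly placed/chosen twins.
    Returns (n_act, status).
    """
    n = C.shape[0]
    t = t0
    while True:
        total = _total_propensity(C, rate_l, rate_r, vol, kappa2, mu,
                                  kappa1, influx)
        if total <= 0.0:
            return n_act, OK
        t += np.random.exponential(1.0 / total)
        if t > t_end:
            return n_act, OK
        r = np.random.random() * total
        acc = influx
        if r < acc:
            C[0] += 1.0       # influx is at the domain boundary, pure region
            continue
        for i in range(n):
            ci = C[i] if C[i] > 0.0 else 0.0
            acc += ci * rate_l[i]
            if r < acc:
                C[i] -= 1.0
                C[i - 1] += 1.0
                if i >= n_c:
                    ib = i - n_c
                    if mcount[ib] <= 0:
                        return n_act, FAULT_EMPTY_COMPARTMENT
                    k = members[ib, np.random.randint(0, mcount[ib])]
                    if i - 1 >= n_c:
                        pos[k, 0] -= h
                        _member_remove(k, comp_of, slot_of, members, mcount)
                        _member_add(k, ib - 1, comp_of, slot_of, members, mcount)
                    else:
                        # left out of the blending region: delete the twin
                        n_act = _particle_remove(k, n_act, pos, comp_of,
                                                 slot_of, members, mcount)
                break
            acc += ci * rate_r[i]
            if r < acc:
                C[i] -= 1.0
                C[i + 1] += 1.0
                if i >= n_c:
                    # within the blending region (right jump out of the
                    # last blending compartment has zero rate: D1(I2)=0)
                    ib = i - n_c
                    if mcount[ib] <= 0:
                        return n_act, FAULT_EMPTY_COMPARTMENT
                    k = members[ib, np.random.randint(0, mcount[ib])]
                    pos[k, 0] += h
                    _member_remove(k, comp_of, slot_of, members, mcount)
                    _member_add(k, ib + 1, comp_of, slot_of, members, mcount)
                elif i + 1 >= n_c:
                    # entry from the pure-compartment region: create a twin
                    # uniformly in the first blending compartment
                    x = I1 + h * np.random.random()
                    y = Ly * np.random.random()
                    z = Lz * np.random.random()
                    n_act = _particle_add(x, y, z, n_act, cap, pos, comp_of,
                                          slot_of, members, mcount,
                                          I1, I2, h, n2)
                    if n_act < 0:
                        return 0, FAULT_CAPACITY
                break
            acc += kappa2 * vol
            if r < acc:
                C[i] += 1.0
                if i >= n_c:
                    ib = i - n_c
                    x = I1 + (ib + np.random.random()) * h
                    y = Ly * np.random.random()
                    z = Lz * np.random.random()
                    n_act = _particle_add(x, y, z, n_act, cap, pos, comp_of,
                                          slot_of, members, mcount,
                                          I1, I2, h, n2)
                    if n_act < 0:
                        return 0, FAULT_CAPACITY
                break
            acc += ci * mu
            if r < acc:
                C[i] -= 1.0
                if i >= n_c:
                    ib = i - n_c
                    if mcount[ib] <= 0:
                        return n_act, FAULT_EMPTY_COMPARTMENT
                    k = members[ib, np.random.randint(0, mcount[ib])]
                    n_act = _particle_remove(k, n_act, pos, comp_of,
                                             slot_of, members, mcount)
                break
            if ci > 1.0:
                acc += kappa1 * ci * (ci - 1.0) / (2.0 * vol)
                if r < acc:
                    C[i] -= 2.0
                    if i >= n_c:
                        ib = i - n_c
                        for _ in range(2):
                            if mcount[ib] <= 0:
                                return n_act, FAULT_EMPTY_COMPARTMENT
                            k = members[ib, np.random.randint(0, mcount[ib])]
                            n_act = _particle_remove(k, n_act, pos, comp_of,
                                                     slot_of, members, mcount)
                    break


@njit(cache=True)
def cb_hybrid_run(C0, pos0, n0,
                  n_c, n2, a, I1, I2, b, h, vol,
                  rate_l, rate_r,
                  D, dim, Ly, Lz, dt,
                  mu, kappa2, kappa1, influx, rho, p_lambda,
                  out_steps, n_windows, cap, seed):
    """Full compartment-Brownian hybrid run.

    Compartment chain with diffusivity ``D1`` on ``[a, I2]`` (rates in
    ``rate_l``/``rate_r``), Brownian particles with ``D2`` on
    ``[I1, b]``.  Each window: (1) SSA with immediate mirroring,
    (2) Euler-Maruyama step + reflecting boundaries + pure-Brownian-
    region reactions, (3) rebinning of the blending counts.

    Returns (comp_out, bhist_out, total_out, nbrow_out, reflects, status)
    where bhist_out bins Brownian positions on [I1, b] at width h.
    """
    np.random.seed(seed)
    n_tot = n_c + n2
    nbin_b = int(round((b - I1) / h))
    n_out = out_steps.shape[0]
    comp_out = np.zeros((n_out, n_tot))
    bhist_out = np.zeros((n_out, nbin_b))
    total_out = np.zeros(n_out)
    nbrow_out = np.zeros(n_out, np.int64)

    C = C0.copy()
    pos = np.zeros((cap, 3))
    pos[:n0, :] = pos0[:n0, :]
    comp_of = np.full(cap, -1, np.int64)
    slot_of = np.zeros(cap, np.int64)
    members = np.zeros((n2, cap), np.int64)
    mcount = np.zeros(n2, np.int64)
    n_act = n0
    # initial binning of blending residents
    for k in range(n_act):
        x = pos[k, 0]
        if x < I2:
            ib = int((x - I1) / h)
            if ib >= n2:
                ib = n2 - 1
            if ib < 0:
                ib = 0
            _member_add(k, ib, comp_of, slot_of, members, mcount)

    slope = D / (I2 - I1)
    VB = (b - I2) * Ly * Lz if dim == 3 else (b - I2)
    reflects = 0
    marked = np.zeros(cap, np.bool_)
    elig = np.zeros(cap, np.int64)
    out_k = 0
    t = 0.0
    for w in range(n_windows):
        t_end = (w + 1) * dt
        n_act, status = _cb_ssa_window(
            C, rate_l, rate_r, vol, kappa2, mu, kappa1, influx,
            t, t_end, n_c, n2, a, I1, I2, h, Ly, Lz, dim,
            pos, comp_of, slot_of, members, mcount, n_act, cap)
        if status != OK:
            return comp_out, bhist_out, total_out, nbrow_out, reflects, status
        t = t_end

        # Euler-Maruyama with drift dD2/dx, then reflection into [I1, b]
        for k in range(n_act):
            x = pos[k, 0]
            if x <= I2:
                Deff = D * (x - I1) / (I2 - I1)
                if Deff < 0.0:
                    Deff = 0.0
                drift = slope * dt
            else:
                Deff = D
                drift = 0.0
            sd = np.sqrt(2.0 * Deff * dt)
            x = x + drift + sd * np.random.normal()
            x, nl = _reflect_coord(x, I1, b)
            reflects += nl
            pos[k, 0] = x
            if dim == 3:
                y = pos[k, 1] + sd * np.random.normal()
                y, _ = _reflect_coord(y, 0.0, Ly)
                pos[k, 1] = y
                z = pos[k, 2] + sd * np.random.normal()
                z, _ = _reflect_coord(z, 0.0, Lz)
                pos[k, 2] = z

        # reactions in the pure-Brownian region (I2, b] only; blending
        # reactions were executed by the compartment paradigm above
        if kappa1 > 0.0 and p_lambda > 0.0:
            m = 0
            for k in range(n_act):
                if pos[k, 0] > I2:
                    elig[m] = k
                    m += 1
                marked[k] = False
            _mark_pairs(pos, elig, m, rho, p_lambda, dim, marked)
            for k in range(n_act - 1, -1, -1):
                if marked[k]:
                    n_act = _particle_remove(k, n_act, pos, comp_of,
                                             slot_of, members, mcount)
        if mu > 0.0:
            p_rm = 1.0 - np.exp(-mu * dt)
            for k in range(n_act - 1, -1, -1):
                if pos[k, 0] > I2 and np.random.random() < p_rm:
                    n_act = _particle_remove(k, n_act, pos, comp_of,
                                             slot_of, members, mcount)
        if kappa2 > 0.0:
            n_new = np.random.poisson(kappa2 * VB * dt)
            for _ in range(n_new):
                x = I2 + (b - I2) * np.random.random()
                y = Ly * np.random.random()
                z = Lz * np.random.random()
                n_act = _particle_add(x, y, z, n_act, cap, pos, comp_of,
                                      slot_of, members, mcount, I1, I2, h, n2)
                if n_act < 0:
                    return comp_out, bhist_out, total_out, nbrow_out, \
                        reflects, FAULT_CAPACITY

        # rebin: blending counts := histogram of Brownian positions
        for ib in range(n2):
            mcount[ib] = 0
        for k in range(n_act):
            x = pos[k, 0]
            if x < I2:
                ib = int((x - I1) / h)
                if ib >= n2:
                    ib = n2 - 1
                if ib < 0:
                    ib = 0
                members[ib, mcount[ib]] = k
                comp_of[k] = ib
                slot_of[k] = mcount[ib]
                mcount[ib] += 1
            else:
                comp_of[k] = -1
        for ib in range(n2):
            C[n_c + ib] = float(mcount[ib])

        if out_k < n_out and out_steps[out_k] == w + 1:
            for i in range(n_tot):
                comp_out[out_k, i] = C[i]
            nb = 0
            for k in range(n_act):
                x = pos[k, 0]
                ib = int((x - I1) / h)
                if ib >= nbin_b:
                    ib = nbin_b - 1
                if ib < 0:
                    ib = 0
                bhist_out[out_k, ib] += 1.0
                if x > I2:
                    nb += 1
            tot = float(n_act)
            for i in range(n_c):
                tot += C[i]
            total_out[out_k] = tot
            nbrow_out[out_k] = nb
            out_k += 1

    return comp_out, bhist_out, total_out, nbrow_out, reflects, OK


# ---------------------------------------------------------------------------
# Pure Brownian full-domain run (ground truth for the 3D bimolecular test)
# ---------------------------------------------------------------------------

@njit(cache=True)
def brownian_run(pos0, n0, a, b, Ly, Lz, D, dim, dt,
                 mu, kappa2, kappa1, rho, p_lambda,
                 hist_width, out_steps, n_windows, cap, seed):
    """Fixed-step Brownian simulation on the whole domain (constant D).

    Records position histograms (bin width ``hist_width`` along x) and
    particle counts at the requested window indices.
    """
    np.random.seed(seed)
    nbin = int(round((b - a) / hist_width))
    n_out = out_steps.shape[0]
    hist_out = np.zeros((n_out, nbin))
    n_out_arr = np.zeros(n_out, np.int64)

    pos = np.zeros((cap, 3))
    pos[:n0, :] = pos0[:n0, :]
    n_act = n0
    sd = np.sqrt(2.0 * D * dt)
    V = (b - a) * Ly * Lz if dim == 3 else (b - a)
    marked = np.zeros(cap, np.bool_)
    elig = np.zeros(cap, np.int64)
    out_k = 0
    for w in range(n_windows):
        for k in range(n_act):
            x = pos[k, 0] + sd * np.random.normal()
            x, _ = _reflect_coord(x, a, b)
            pos[k, 0] = x
            if dim == 3:
                y = pos[k, 1] + sd * np.random.normal()
                y, _ = _reflect_coord(y, 0.0, Ly)
                pos[k, 1] = y
                z = pos[k, 2] + sd * np.random.normal()
                z, _ = _reflect_coord(z, 0.0, Lz)
                pos[k, 2] = z
        if kappa1 > 0.0 and p_lambda > 0.0:
            for k in range(n_act):
                elig[k] = k
                marked[k] = False
            _mark_pairs(pos, elig, n_act, rho, p_lambda, dim, marked)
            for k in range(n_act - 1, -1, -1):
                if marked[k]:
                    j = n_act - 1
                    if j != k:
                        pos[k, 0] = pos[j, 0]
                        pos[k, 1] = pos[j, 1]
                        pos[k, 2] = pos[j, 2]
                    n_act = j
        if mu > 0.0:
            p_rm = 1.0 - np.exp(-mu * dt)
            for k in range(n_act - 1, -1, -1):
                if np.random.random() < p_rm:
                    j = n_act - 1
                    if j != k:
                        pos[k, 0] = pos[j, 0]
                        pos[k, 1] = pos[j, 1]
                        pos[k, 2] = pos[j, 2]
                    n_act = j
        if kappa2 > 0.0:
            n_new = np.random.poisson(kappa2 * V * dt)
            for _ in range(n_new):
                if n_act >= cap:
                    return hist_out, n_out_arr, FAULT_CAPACITY
                pos[n_act, 0] = a + (b - a) * np.random.random()
                pos[n_act, 1] = Ly * np.random.random()
                pos[n_act, 2] = Lz * np.random.random()
                n_act += 1
        if out_k < n_out and out_steps[out_k] == w + 1:
            for k in range(n_act):
                ib = int((pos[k, 0] - a) / hist_width)
                if ib >= nbin:
                    ib = nbin - 1
                if ib < 0:
                    ib = 0
                hist_out[out_k, ib] += 1.0
            n_out_arr[out_k] = n_act
            out_k += 1
    return hist_out, n_out_arr, OK
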