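"""Numba kernels for the event-driven dynamics core.

State layout: ``pos``/``vel`` are (N, 3) arrays; each bead carries its own
last-update time ``tlast`` so positions are advanced lazily. Pair
interactions are encoded as an index matrix ``pair_pot`` into a table of
stepwise potentials: ``pot_bounds[p, :pot_nb[p]]`` are ascending boundary
distances and ``pot_levels[p, s]`` is the energy of shell ``s`` (shell 0 is
inside the innermost boundary; a level of ``WALL`` marks a forbidden region
whose boundary always reflects). The currently occupied shell of every pair
is tracked explicitly in ``shell[i, j]`` so that collisions at boundaries
never suffer from which-side-am-I rounding ambiguity.

Event selection uses a per-bead earliest-event table scanned with argmin,
rather than a heap: every velocity change triggers recomputation of the
affected beads' entries, so the table never holds stale events and the
globally earliest pending collision is always present in the slot of the
pair member that changed velocity most recently.
"""

import numba
import numpy as np

WALL = 1.0e30          # pseudo-energy of a forbidden shell: boundary reflects
_NO_EVENT = 1.0e300
_TEPS = 1.0e-12

KIND_NONE = -2
KIND_HORIZON = -1      # minimum-image may switch: recompute, no dynamics


@numba.njit(cache=True, inline="always")
def _min_image(x, L):
    return x - L * np.rint(x / L)


@numba.njit(cache=True, inline="always")
def collide_radial(v_r, mu, dU):
    """Post-collision radial relative velocity at an energy step.

    A step of height dU transmits when the radial kinetic energy
    0.5*mu*v_r^2 exceeds dU (outgoing speed from energy conservation),
    otherwise the pair reflects elastically. Returns (v_r_new, transmitted).
    """
    if dU >= 0.5 * WALL:
        return -v_r, False                       # forbidden shell: reflect
    arg = v_r * v_r - 2.0 * dU / mu
    if arg > 0.0:
        if v_r > 0.0:
            return np.sqrt(arg), True
        return -np.sqrt(arg), True
    return -v_r, False                           # insufficient radial energy


@numba.njit(cache=True)
def _predict(i, j, t, pos, vel, tlast, L, pair_pot, pot_bounds, pot_nb,
             shell):
    """Earliest future event for pair (i, j) from time t.

    Returns (dt, boundary_index) with boundary_index = KIND_HORIZON for a
    minimum-image refresh event and KIND_NONE when the pair never meets.
    """
    p = pair_pot[i, j]
    dti = t - tlast[i]
    dtj = t - tlast[j]
    rx = _min_image(pos[i, 0] + vel[i, 0] * dti - pos[j, 0] - vel[j, 0] * dtj, L)
    ry = _min_image(pos[i, 1] + vel[i, 1] * dti - pos[j, 1] - vel[j, 1] * dtj, L)
    rz = _min_image(pos[i, 2] + vel[i, 2] * dti - pos[j, 2] - vel[j, 2] * dtj, L)
    vx = vel[i, 0] - vel[j, 0]
    vy = vel[i, 1] - vel[j, 1]
    vz = vel[i, 2] - vel[j, 2]
    r2 = rx * rx + ry * ry + rz * rz
    v2 = vx * vx + vy * vy + vz * vz
    b = rx * vx + ry * vy + rz * vz

    nb = pot_nb[p]
    k = shell[i, j]
    t_best = _NO_EVENT
    b_best = KIND_NONE
    if v2 > 0.0:
        if k > 0 and b < 0.0:  # approaching the inner boundary
            din = pot_bounds[p, k - 1]
            disc = b * b - v2 * (r2 - din * din)
            if disc > 0.0:
                tt = (-b - np.sqrt(disc)) / v2
                if tt > _TEPS:
                    t_best = tt
                    b_best = k - 1
        if k < nb:             # outer boundary is always reachable
            dout = pot_bounds[p, k]
            disc = b * b - v2 * (r2 - dout * dout)
            if disc >= 0.0:
                tt = (-b + np.sqrt(disc)) / v2
                if _TEPS < tt < t_best:
                    t_best = tt
                    b_best = k

    # Minimum-image horizon: if a relative component reaches L/2 before the
    # boundary event, the straight-line prediction stops being valid.
    half = 0.5 * L
    t_h = _NO_EVENT
    for a in range(3):
        va = vel[i, a] - vel[j, a]
        if va > _TEPS:
            ra = rx if a == 0 else (ry if a == 1 else rz)
            th = (half - ra) / va
            if 1.0e-9 < th < t_h:
                t_h = th
        elif va < -_TEPS:
            ra = rx if a == 0 else (ry if a == 1 else rz)
            th = (-half - ra) / va
            if 1.0e-9 < th < t_h:
                t_h = th
    if t_h < t_best:
        return t_h, KIND_HORIZON
    return t_best, b_best


@numba.njit(cache=True)
def _recompute_bead(i, t, pos, vel, tlast, L, pair_pot, pot_bounds, pot_nb,
                    shell, ev_t, ev_j, ev_b):
    N = pos.shape[0]
    best_t = _NO_EVENT
    best_j = -1
    best_b = KIND_NONE
    for j in range(N):
        if j == i:
            continue
        dt, bidx = _predict(i, j, t, pos, vel, tlast, L, pair_pot,
                            pot_bounds, pot_nb, shell)
        if dt < best_t:
            best_t = dt
            best_j = j
            best_b = bidx
    ev_t[i] = t + best_t if best_t < _NO_EVENT else _NO_EVENT
    ev_j[i] = best_j
    ev_b[i] = best_b


@numba.njit(cache=True)
def init_shells(pos, L, pair_pot, pot_bounds, pot_nb, shell):
    """Assign every pair's shell from current minimum-image distances."""
    N = pos.shape[0]
    for i in range(N):
        for j in range(i + 1, N):
            p = pair_pot[i, j]
            dx = _min_image(pos[i, 0] - pos[j, 0], L)
            dy = _min_image(pos[i, 1] - pos[j, 1], L)
            dz = _min_image(pos[i, 2] - pos[j, 2], L)
            d = np.sqrt(dx * dx + dy * dy + dz * dz)
            k = 0
            for m in range(pot_nb[p]):
                if pot_bounds[p, m] < d:
                    k += 1
                else:
                    break
            shell[i, j] = k
            shell[j, i] = k


@numba.njit(cache=True)
def potential_energy(pair_pot, pot_levels, shell):
    """Total potential energy from the pair shell bookkeeping."""
    N = shell.shape[0]
    pe = 0.0
    for i in range(N):
        for j in range(i + 1, N):
            pe += pot_levels[pair_pot[i, j], shell[i, j]]
    return pe


@numba.njit(cache=True)
def kinetic_energy(vel, mass):
    ke = 0.0
    for i in range(vel.shape[0]):
        ke += 0.5 * mass[i] * (vel[i, 0] ** 2 + vel[i, 1] ** 2
                               + vel[i, 2] ** 2)
    return ke


@numba.njit(cache=True)
def run_segment(pos, vel, tlast, mass, t0, t_end,
                L, pair_pot, pot_bounds, pot_nb, pot_levels, shell,
                T, thermo_rate_per_bead,
                sample_interval, next_sample,
                frames_pos, frames_t, frames_pe, frames_ke, frame_count,
                seed, max_events):
    """Advance the system from t0 to t_end, recording frames on the fly.

    Mutates pos/vel/tlast/shell in place. Returns
    (n_collisions, frame_count, next_sample, status); status 0 = ok,
    1 = event budget exhausted, 2 = inconsistent collision state.
    """
    np.random.seed(seed)
    N = pos.shape[0]
    ev_t = np.empty(N)
    ev_j = np.empty(N, dtype=np.int64)
    ev_b = np.empty(N, dtype=np.int64)
    for i in range(N):
        _recompute_bead(i, t0, pos, vel, tlast, L, pair_pot, pot_bounds,
                        pot_nb, shell, ev_t, ev_j, ev_b)

    if thermo_rate_per_bead > 0.0:
        rate = thermo_rate_per_bead * N
        t_thermo = t0 + np.random.exponential(1.0 / rate)
    else:
        rate = 0.0
        t_thermo = _NO_EVENT

    t = t0
    n_coll = 0
    n_events = 0
    while True:
        imin = 0
        tev = ev_t[0]
        for i in range(1, N):
            if ev_t[i] < tev:
                tev = ev_t[i]
                imin = i

        if next_sample <= tev and next_sample <= t_thermo \
                and next_sample <= t_end:
            t = next_sample
            for i in range(N):
                pos[i, 0] += vel[i, 0] * (t - tlast[i])
                pos[i, 1] += vel[i, 1] * (t - tlast[i])
                pos[i, 2] += vel[i, 2] * (t - tlast[i])
                tlast[i] = t
            frames_pos[frame_count] = pos
            frames_t[frame_count] = t
            frames_pe[frame_count] = potential_energy(pair_pot, pot_levels,
                                                      shell)
            frames_ke[frame_count] = kinetic_energy(vel, mass)
            frame_count += 1
            next_sample += sample_interval
            continue

        if t_end <= tev and t_end <= t_thermo:
            for i in range(N):
                pos[i, 0] += vel[i, 0] * (t_end - tlast[i])
                pos[i, 1] += vel[i, 1] * (t_end - tlast[i])
                pos[i, 2] += vel[i, 2] * (t_end - tlast[i])
                tlast[i] = t_end
            return n_coll, frame_count, next_sample, 0

        if t_thermo < tev:
            # Andersen ghost collision: one bead's velocity is redrawn from
            # the Maxwell-Boltzmann distribution at T.
            t = t_thermo
            u = np.random.randint(0, N)
            pos[u, 0] += vel[u, 0] * (t - tlast[u])
            pos[u, 1] += vel[u, 1] * (t - tlast[u])
            pos[u, 2] += vel[u, 2] * (t - tlast[u])
            tlast[u] = t
            s = np.sqrt(T / mass[u])
            vel[u, 0] = s * np.random.normal()
            vel[u, 1] = s * np.random.normal()
            vel[u, 2] = s * np.random.normal()
            _recompute_bead(u, t, pos, vel, tlast, L, pair_pot, pot_bounds,
                            pot_nb, shell, ev_t, ev_j, ev_b)
            for k in range(N):
                if k != u and ev_j[k] == u:
                    _recompute_bead(k, t, pos, vel, tlast, L, pair_pot,
                                    pot_bounds, pot_nb, shell,
                                    ev_t, ev_j, ev_b)
            t_thermo = t + np.random.exponential(1.0 / rate)
            continue

        # pair event
        t = tev
        i = imin
        j = ev_j[i]
        bidx = ev_b[i]
        n_events += 1
        if n_events > max_events:
            return n_coll, frame_count, next_sample, 1

        if bidx == KIND_HORIZON:
            _recompute_bead(i, t, pos, vel, tlast, L, pair_pot, pot_bounds,
                            pot_nb, shell, ev_t, ev_j, ev_b)
            continue

        # advance the two colliding beads to the event time
        for u in (i, j):
            pos[u, 0] += vel[u, 0] * (t - tlast[u])
            pos[u, 1] += vel[u, 1] * (t - tlast[u])
            pos[u, 2] += vel[u, 2] * (t - tlast[u])
            tlast[u] = t

        p = pair_pot[i, j]
        rx = _min_image(pos[i, 0] - pos[j, 0], L)
        ry = _min_image(pos[i, 1] - pos[j, 1], L)
        rz = _min_image(pos[i, 2] - pos[j, 2], L)
        d = np.sqrt(rx * rx + ry * ry + rz * rz)
        rhx = rx / d
        rhy = ry / d
        rhz = rz / d
        v_r = ((vel[i, 0] - vel[j, 0]) * rhx
               + (vel[i, 1] - vel[j, 1]) * rhy
               + (vel[i, 2] - vel[j, 2]) * rhz)
        k = shell[i, j]
        if bidx == k - 1 and v_r < 0.0:
            target = k - 1
        elif bidx == k and v_r > 0.0:
            target = k + 1
        else:
            # rounding produced a stale prediction; recompute and move on
            _recompute_bead(i, t, pos, vel, tlast, L, pair_pot, pot_bounds,
                            pot_nb, shell, ev_t, ev_j, ev_b)
            _recompute_bead(j, t, pos, vel, tlast, L, pair_pot, pot_bounds,
                            pot_nb, shell, ev_t, ev_j, ev_b)
            continue

        mu = mass[i] * mass[j] / (mass[i] + mass[j])
        dU = pot_levels[p, target] - pot_levels[p, k]
        v_r_new, transmitted = collide_radial(v_r, mu, dU)
        if transmitted:
            shell[i, j] = target                 # crossed the energy step
            shell[j, i] = target
        imp = mu * (v_r_new - v_r)
        vel[i, 0] += imp * rhx / mass[i]
        vel[i, 1] += imp * rhy / mass[i]
        vel[i, 2] += imp * rhz / mass[i]
        vel[j, 0] -= imp * rhx / mass[j]
        vel[j, 1] -= imp * rhy / mass[j]
        vel[j, 2] -= imp * rhz / mass[j]
        n_coll += 1

        _recompute_bead(i, t, pos, vel, tlast, L, pair_pot, pot_bounds,
                        pot_nb, shell, ev_t, ev_j, ev_b)
        _recompute_bead(j, t, pos, vel, tlast, L, pair_pot, pot_bounds,
                        pot_nb, shell, ev_t, ev_j, ev_b)
        for kk in range(N):
            if kk != i and kk != j and (ev_j[kk] == i or ev_j[kk] == j):
                _recompute_bead(kk, t, pos, vel, tlast, L, pair_pot,
                                pot_bounds, pot_nb, shell, ev_t, ev_j, ev_b)
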