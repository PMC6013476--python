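"""Numba-compiled trial engine.

One spiking trial is a tight loop over 1 ms timesteps; at desk scale the
experiments need millions of such steps (e.g. 1000 agents x 15 s for the
occupancy analyses), so the loop is compiled.  The mathematics is identical
to the reference implementations in `network` and `plasticity`:

 * EPSPs and the rate filter are differences of exponentials, maintained as
   pairs of leaky accumulators whose step-wise decay reproduces the kernel
   convolution exactly at the sampling times;
 * STDP pairing sums are maintained with exponential pre/post traces
   (the exact double sum over spike pairs, no cutoff);
 * the eligibility trace is stored in a "trial-start frame" (increments are
   multiplied by exp(+t/tau_e) and the whole matrix rescaled once at trial
   end), so its per-step cost is proportional to the number of spikes.

Oracle tests in the suite pin this engine to the reference implementations.
"""

from __future__ import annotations

import numpy as np
from numba import njit

# maze kind codes
OPEN = 0
OBSTACLES = 1
TMAZE = 2

# trial status codes
TIMEOUT = 0
REWARDED = 1
STOPPED_OLD = 2
WRONG_ARM = 3

# T-maze layout constants (must match geometry.py)
_STEM_HALF_W = 0.3
_STEM_Y_LO = -2.0
_STEM_Y_HI = 1.2
_BAR_Y_LO = 1.2
_BAR_Y_HI = 2.0
_X_RIGHT = 1.0
_X_LEFT = -1.0


@njit(cache=True)
def _contains(kind, half, obstacles, x, y):
    if x < -half or x > half or y < -half or y > half:
        return False
    if kind == TMAZE:
        in_stem = (abs(x) <= _STEM_HALF_W) and (y >= _STEM_Y_LO) and (y <= _STEM_Y_HI)
        in_bar = (y >= _BAR_Y_LO) and (y <= _BAR_Y_HI)
        if not (in_stem or in_bar):
            return False
    for i in range(obstacles.shape[0]):
        if obstacles[i, 0] < x < obstacles[i, 1] and obstacles[i, 2] < y < obstacles[i, 3]:
            return False
    return True


@njit(cache=True)
def _bounce_normal(kind, half, obstacles, px, py, cx, cy):
    """Inward unit vector opposing the boundary violated by candidate (cx,cy)."""
    nx = 0.0
    ny = 0.0
    if cx < -half:
        nx += 1.0
    if cx > half:
        nx -= 1.0
    if cy < -half:
        ny += 1.0
    if cy > half:
        ny -= 1.0
    if kind == TMAZE and nx == 0.0 and ny == 0.0:
        if py < _BAR_Y_LO:
            if cx > _STEM_HALF_W:
                nx -= 1.0
            elif cx < -_STEM_HALF_W:
                nx += 1.0
            else:
                ny += 1.0
        else:
            ny += 1.0
    for i in range(obstacles.shape[0]):
        if obstacles[i, 0] < cx < obstacles[i, 1] and obstacles[i, 2] < cy < obstacles[i, 3]:
            d0 = abs(px - obstacles[i, 0])
            d1 = abs(px - obstacles[i, 1])
            d2 = abs(py - obstacles[i, 2])
            d3 = abs(py - obstacles[i, 3])
            m = min(min(d0, d1), min(d2, d3))
            if m == d0:
                nx -= 1.0
            elif m == d1:
                nx += 1.0
            elif m == d2:
                ny -= 1.0
            else:
                ny += 1.0
    norm = np.sqrt(nx * nx + ny * ny)
    if norm == 0.0:
        return 0.0, 0.0
    return nx / norm, ny / norm


@njit(cache=True)
def run_continuous_trial(
    seed,
    # geometry
    maze_kind, half, bounce_d, obstacles, x0, y0,
    # place cells
    centres, sigma, lam_pc,
    # action population
    dirs, thetas, w_lat, eps0, tau_m, tau_s, chi, theta_thr, lam0, delta_u,
    tau_gamma, nu_gamma,
    # synapses
    w, wmask, w_min, w_max,
    # timing
    dt, t_max,
    # reward zones
    has_new_disc, ncx, ncy, nr,
    has_old_disc, ocx, ocy, orr, early_stop,
    tmaze_task,  # 0: none, 1: right-arm rewarded, 2: unrewarded but end on arm entry
    # plasticity
    eta_online, tau_pair, tau_e, a_pp, a_pn,
    # recording
    record_every, traj, acts,
    record_debug, u_rec, pre_rec, post_rec,
):
    """Run one trial of the continuous model, mutating ``w`` online (+ACh).

    Returns (status, t_end, bounces, visited_left, visited_right, elig, occ,
    n_rec) where ``elig`` is the eligibility matrix decayed to t_end and
    ``occ`` the per-cell summed place rates along the trajectory.
    """
    np.random.seed(seed)
    n_pc = centres.shape[0]
    n_a = dirs.shape[0]
    n_steps = int(round(t_max / dt))

    dec_m = np.exp(-dt / tau_m)
    dec_s = np.exp(-dt / tau_s)
    dec_g = np.exp(-dt / tau_gamma)
    dec_n = np.exp(-dt / nu_gamma)
    dec_p = np.exp(-dt / tau_pair)
    kf = eps0 / ((tau_m - tau_s) * 1e3)  # EPSP normalized over ms
    kg = 1.0 / (tau_gamma - nu_gamma)
    grow_e = np.exp(dt / tau_e)

    am_f = np.zeros(n_a)
    as_f = np.zeros(n_a)
    am_l = np.zeros(n_a)
    as_l = np.zeros(n_a)
    refr = np.zeros(n_a)
    rho_a = np.zeros(n_a)
    rho_b = np.zeros(n_a)
    p_tr = np.zeros(n_pc)
    q_tr = np.zeros(n_a)
    elig = np.zeros((n_a, n_pc))
    occ = np.zeros(n_pc)
    rates = np.empty(n_pc)
    u = np.empty(n_a)
    rho = np.empty(n_a)
    allowed = np.ones(n_a, dtype=np.bool_)
    pre_spk = np.zeros(n_pc, dtype=np.int8)
    post_spk = np.zeros(n_a, dtype=np.int8)
    pre_idx = np.empty(n_pc, dtype=np.int64)
    post_idx = np.empty(n_a, dtype=np.int64)

    x = x0
    y = y0
    bounces = 0
    visited_left = False
    visited_right = False
    entered_old = False
    status = TIMEOUT
    t_end = t_max
    n_rec = 0
    e_frame = 1.0  # exp(t/tau_e) lazy frame factor
    inv_sig2 = 1.0 / (sigma * sigma)

    for n in range(n_steps):
        t = n * dt
        # 1. advance linear state to time t
        for j in range(n_a):
            am_f[j] *= dec_m
            as_f[j] *= dec_s
            am_l[j] *= dec_m
            as_l[j] *= dec_s
            refr[j] *= dec_m
            rho_a[j] *= dec_g
            rho_b[j] *= dec_n
            q_tr[j] *= dec_p
        for i in range(n_pc):
            p_tr[i] *= dec_p

        # 2. place-cell rates and spikes
        n_pre = 0
        for i in range(n_pc):
            dx = x - centres[i, 0]
            dy = y - centres[i, 1]
            r = lam_pc * np.exp(-(dx * dx + dy * dy) * inv_sig2)
            rates[i] = r
            occ[i] += r
            if np.random.random() < r * dt:
                pre_spk[i] = 1
                pre_idx[n_pre] = i
                n_pre += 1
            else:
                pre_spk[i] = 0

        # 3. membrane potential, allowed actions, action spikes
        if maze_kind == TMAZE:
            if y < _BAR_Y_LO:
                for j in range(n_a):
                    th = thetas[j]
                    allowed[j] = (th >= 0.25 * np.pi) and (th <= 0.75 * np.pi)
            else:
                for j in range(n_a):
                    th = thetas[j]
                    allowed[j] = (
                        th <= 0.25 * np.pi
                        or th >= 1.75 * np.pi
                        or (0.75 * np.pi <= th <= 1.25 * np.pi)
                    )
        n_post = 0
        for j in range(n_a):
            u[j] = kf * (am_f[j] - as_f[j] + am_l[j] - as_l[j]) + refr[j]
            if record_debug:
                u_rec[n, j] = u[j]
            if allowed[j]:
                lam = lam0 * np.exp((u[j] - theta_thr) / delta_u)
                p = lam * dt
                if p > 1.0:
                    p = 1.0
                if np.random.random() < p:
                    post_spk[j] = 1
                    post_idx[n_post] = j
                    n_post += 1
                else:
                    post_spk[j] = 0
            else:
                post_spk[j] = 0

        # 4. rate estimate and action (spikes this step contribute 0: gamma(0)=0)
        # rho*dt is the estimated spike count per timestep; an action neuron
        # firing once per step contributes a_j/N of displacement per step.
        # N is the number of AVAILABLE action neurons: where the maze
        # restricts the action set (T-maze stem/bar) the average runs over
        # the available ones only.
        ax = 0.0
        ay = 0.0
        n_avail = 0
        for j in range(n_a):
            rho[j] = kg * (rho_a[j] - rho_b[j])
            if allowed[j]:
                n_avail += 1
                ax += rho[j] * dirs[j, 0]
                ay += rho[j] * dirs[j, 1]
        if n_avail > 0:
            ax *= dt / n_avail
            ay *= dt / n_avail

        if record_debug:
            for i in range(n_pc):
                pre_rec[n, i] = pre_spk[i]
            for j in range(n_a):
                post_rec[n, j] = post_spk[j]
        if record_every > 0 and n % record_every == 0 and n_rec < traj.shape[0]:
            traj[n_rec, 0] = x
            traj[n_rec, 1] = y
            acts[n_rec, 0] = ax
            acts[n_rec, 1] = ay
            n_rec += 1

        # 5. move with bounce
        cx = x + ax
        cy = y + ay
        if _contains(maze_kind, half, obstacles, cx, cy):
            x = cx
            y = cy
        else:
            ux, uy = _bounce_normal(maze_kind, half, obstacles, x, y, cx, cy)
            bx = x + bounce_d * ux
            by = y + bounce_d * uy
            if _contains(maze_kind, half, obstacles, bx, by):
                x = bx
                y = by
            bounces += 1

        # 6. plasticity increments from this step's spikes
        e_frame *= grow_e
        if n_post > 0:
            for jj in range(n_post):
                j = post_idx[jj]
                qj = q_tr[j]
                for i in range(n_pc):
                    d_e = a_pp * p_tr[i]
                    d_w = p_tr[i]
                    if pre_spk[i] == 1:
                        d_e += a_pn * qj + 0.5 * (a_pp + a_pn)
                        d_w += qj + 1.0
                    elig[j, i] += e_frame * d_e
                    if eta_online > 0.0 and d_w != 0.0 and wmask[j, i]:
                        nw = w[j, i] - eta_online * d_w
                        if nw < w_min:
                            nw = w_min
                        elif nw > w_max:
                            nw = w_max
                        w[j, i] = nw
        if n_pre > 0:
            for ii in range(n_pre):
                i = pre_idx[ii]
                for j in range(n_a):
                    if post_spk[j] == 1:
                        continue
                    qj = q_tr[j]
                    if qj != 0.0:
                        elig[j, i] += e_frame * a_pn * qj
                        if eta_online > 0.0 and wmask[j, i]:
                            nw = w[j, i] - eta_online * qj
                            if nw < w_min:
                                nw = w_min
                            elif nw > w_max:
                                nw = w_max
                            w[j, i] = nw

        # 7. register this step's spikes in the linear state
        for jj in range(n_post):
            j = post_idx[jj]
            # reset: drop input that arrived before this spike
            am_f[j] = 0.0
            as_f[j] = 0.0
            am_l[j] = 0.0
            as_l[j] = 0.0
            refr[j] = chi
            rho_a[j] += 1.0
            rho_b[j] += 1.0
            q_tr[j] += 1.0
        for ii in range(n_pre):
            i = pre_idx[ii]
            p_tr[i] += 1.0
            for j in range(n_a):
                wji = w[j, i]
                if wji != 0.0:
                    am_f[j] += wji
                    as_f[j] += wji
        for jj in range(n_post):
            j = post_idx[jj]
            for k in range(n_a):
                if k != j:
                    am_l[k] += w_lat[k, j]
                    as_l[k] += w_lat[k, j]

        # 8. reward / termination tests at the post-move position
        t_next = (n + 1) * dt
        if has_new_disc:
            dx = x - ncx
            dy = y - ncy
            if dx * dx + dy * dy <= nr * nr:
                status = REWARDED
                t_end = t_next
                break
        if has_old_disc:
            dx = x - ocx
            dy = y - ocy
            if dx * dx + dy * dy <= orr * orr:
                entered_old = True
                if early_stop:
                    status = STOPPED_OLD
                    t_end = t_next
                    break
        if tmaze_task > 0:
            if x >= _X_RIGHT:
                visited_right = True
                if tmaze_task == 1:
                    status = REWARDED
                else:
                    status = WRONG_ARM
                t_end = t_next
                break
            if x <= _X_LEFT:
                visited_left = True
                status = WRONG_ARM
                t_end = t_next
                break

    # rescale eligibility from the lazy frame to its value at t_end
    scale = np.exp(-t_end / tau_e)
    for j in range(n_a):
        for i in range(n_pc):
            elig[j, i] *= scale

    return (status, t_end, bounces, visited_left, visited_right, entered_old,
            elig, occ, n_rec, x, y)


@njit(cache=True)
def run_discrete_trial(
    seed,
    lam_pc,  # 4000 Hz single place cell
    w, w_lat_val, eps0, tau_m, tau_s, chi, theta_thr, lam0, delta_u,
    tau_gamma, nu_gamma,
    w_min, w_max,
    dt, t_max,
    eta_online, tau_pair, tau_e,
):
    """One radial-maze trial: 5 s of spiking, then winner-take-all arm choice.

    Returns (winner, elig) and mutates ``w`` (shape (n_arms,)) online when
    cholinergic depression is active.  Ties at the end are broken uniformly.
    """
    np.random.seed(seed)
    n_a = w.shape[0]
    n_steps = int(round(t_max / dt))

    dec_m = np.exp(-dt / tau_m)
    dec_s = np.exp(-dt / tau_s)
    dec_g = np.exp(-dt / tau_gamma)
    dec_n = np.exp(-dt / nu_gamma)
    dec_p = np.exp(-dt / tau_pair)
    kf = eps0 / ((tau_m - tau_s) * 1e3)  # EPSP normalized over ms
    kg = 1.0 / (tau_gamma - nu_gamma)
    grow_e = np.exp(dt / tau_e)

    am_f = np.zeros(n_a)
    as_f = np.zeros(n_a)
    am_l = np.zeros(n_a)
    as_l = np.zeros(n_a)
    refr = np.zeros(n_a)
    rho_a = np.zeros(n_a)
    rho_b = np.zeros(n_a)
    p_tr = 0.0
    q_tr = np.zeros(n_a)
    elig = np.zeros(n_a)
    post_spk = np.zeros(n_a, dtype=np.int8)
    e_frame = 1.0

    for n in range(n_steps):
        for j in range(n_a):
            am_f[j] *= dec_m
            as_f[j] *= dec_s
            am_l[j] *= dec_m
            as_l[j] *= dec_s
            refr[j] *= dec_m
            rho_a[j] *= dec_g
            rho_b[j] *= dec_n
            q_tr[j] *= dec_p
        p_tr *= dec_p

        c_pre = np.random.poisson(lam_pc * dt)

        n_post = 0
        for j in range(n_a):
            u = kf * (am_f[j] - as_f[j] + am_l[j] - as_l[j]) + refr[j]
            lam = lam0 * np.exp((u - theta_thr) / delta_u)
            p = lam * dt
            if p > 1.0:
                p = 1.0
            if np.random.random() < p:
                post_spk[j] = 1
                n_post += 1
            else:
                post_spk[j] = 0

        # plasticity (symmetric window; counts pair multiplicatively)
        e_frame *= grow_e
        for j in range(n_a):
            d = post_spk[j] * p_tr + q_tr[j] * c_pre + post_spk[j] * c_pre
            if d != 0.0:
                elig[j] += e_frame * d
                if eta_online > 0.0:
                    nw = w[j] - eta_online * d
                    if nw < w_min:
                        nw = w_min
                    elif nw > w_max:
                        nw = w_max
                    w[j] = nw

        # register spikes
        for j in range(n_a):
            if post_spk[j] == 1:
                am_f[j] = 0.0
                as_f[j] = 0.0
                am_l[j] = 0.0
                as_l[j] = 0.0
                refr[j] = chi
                rho_a[j] += 1.0
                rho_b[j] += 1.0
                q_tr[j] += 1.0
        if c_pre > 0:
            for j in range(n_a):
                am_f[j] += c_pre * w[j]
                as_f[j] += c_pre * w[j]
        for j in range(n_a):
            if post_spk[j] == 1:
                for k in range(n_a):
                    if k != j:
                        am_l[k] += w_lat_val
                        as_l[k] += w_lat_val

    # winner: argmax of filtered rate at T_max, exact ties uniform at random
    best = kg * (rho_a[0] - rho_b[0])
    for j in range(1, n_a):
        v = kg * (rho_a[j] - rho_b[j])
        if v > best:
            best = v
    n_tie = 0
    for j in range(n_a):
        if kg * (rho_a[j] - rho_b[j]) == best:
            n_tie += 1
    pick = int(np.random.random() * n_tie)
    if pick >= n_tie:
        pick = n_tie - 1
    winner = -1
    c = 0
    for j in range(n_a):
        if kg * (rho_a[j] - rho_b[j]) == best:
            if c == pick:
                winner = j
                break
            c += 1

    scale = np.exp(-t_max / tau_e)
    for j in range(n_a):
        elig[j] *= scale
    return winner, elig


@njit(cache=True)
def bee_occupancy(seed, n_steps, half, centres, sigma, lam_pc):
    """Benchmark Exploration over the Environment: i.i.d. uniform positions."""
    np.random.seed(seed)
    n_pc = centres.shape[0]
    occ = np.zeros(n_pc)
    inv_sig2 = 1.0 / (sigma * sigma)
    for n in range(n_steps):
        x = (np.random.random() * 2.0 - 1.0) * half
        y = (np.random.random() * 2.0 - 1.0) * half
        for i in range(n_pc):
            dx = x - centres[i, 0]
            dy = y - centres[i, 1]
            occ[i] += lam_pc * np.exp(-(dx * dx + dy * dy) * inv_sig2)
    return occ


@njit(cache=True)
def bea_occupancy(seed, n_steps, half, bounce_d, speed, centres, sigma, lam_pc):
    """Benchmark Exploration over the Action space: fixed-speed random walk.

    The angle is uniform on [0, 2*pi) each step; the wall bounce rule is the
    same as for the agent.  Starts at the centre of the open field.
    """
    np.random.seed(seed)
    n_pc = centres.shape[0]
    occ = np.zeros(n_pc)
    inv_sig2 = 1.0 / (sigma * sigma)
    x = 0.0
    y = 0.0
    no_obs = np.empty((0, 4))
    for n in range(n_steps):
        for i in range(n_pc):
            dx = x - centres[i, 0]
            dy = y - centres[i, 1]
            occ[i] += lam_pc * np.exp(-(dx * dx + dy * dy) * inv_sig2)
        ang = np.random.random() * 2.0 * np.pi
        cx = x + speed * np.cos(ang)
        cy = y + speed * np.sin(ang)
        if _contains(OPEN, half, no_obs, cx, cy):
            x = cx
            y = cy
        else:
            ux, uy = _bounce_normal(OPEN, half, no_obs, x, y, cx, cy)
            x += bounce_d * ux
            y += bounce_d * uy
    return occ
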