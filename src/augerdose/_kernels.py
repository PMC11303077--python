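"""Numba kernels: electron tracking and on-the-fly dose scoring.

Transport scheme (see docs/methods.md): continuous restricted energy loss
along straight segments, explicit Moller delta rays above the threshold,
and either single elastic scattering events (default) or condensed-history
Gaussian deflections above ``ch_emin``. Each segment's continuous loss is
deposited at a uniformly sampled point on the segment, which is an unbiased
estimator for any volume tally. Electrons at or below the cutoff deposit
their residual energy locally. Energy is conserved exactly per history.

Scoring modes:
  0 sphere    - single sphere of radius ``sphere_r`` centred at the origin
  1 cells     - spherical cells (nucleus / cytoplasm / membrane shells)
  2 radial    - concentric shells of width ``shell_w`` around the origin
  3 none      - no volume scoring (event collection only)
"""

import numpy as np
from numba import njit

_MASK = np.uint64(0xFFFFFFFFFFFFFFFF)
_SM1 = np.uint64(0x9E3779B97F4A7C15)
_SM2 = np.uint64(0xBF58476D1CE4E5B9)
_SM3 = np.uint64(0x94D049BB133111EB)
_INV53 = 1.0 / 9007199254740992.0  # 2^-53

MC2_EV = 510998.95


@njit(cache=True, inline="always")
def _splitmix(z):
    z = (z + _SM1) & _MASK
    z = ((z ^ (z >> np.uint64(30))) * _SM2) & _MASK
    z = ((z ^ (z >> np.uint64(27))) * _SM3) & _MASK
    return z ^ (z >> np.uint64(31))


@njit(cache=True, inline="always")
def _rng_init(st, seed):
    st[0] = _splitmix(seed)
    st[1] = _splitmix(st[0])
    if st[0] == 0 and st[1] == 0:
        st[0] = np.uint64(1)


@njit(cache=True, inline="always")
def _rand(st):
    # xorshift128+
    x = st[0]
    y = st[1]
    st[0] = y
    x ^= (x << np.uint64(23)) & _MASK
    st[1] = x ^ y ^ (x >> np.uint64(17)) ^ (y >> np.uint64(26))
    r = (st[1] + y) & _MASK
    u = float(r >> np.uint64(11)) * _INV53
    if u <= 0.0:
        u = _INV53
    return u


@njit(cache=True, inline="always")
def _interp(log_e0, dlog, table, e_ev):
    x = (np.log(e_ev) - log_e0) / dlog
    n = table.shape[0]
    if x <= 0.0:
        return table[0]
    if x >= n - 1:
        return table[n - 1]
    i = int(x)
    f = x - i
    return table[i] * (1.0 - f) + table[i + 1] * f


@njit(cache=True, inline="always")
def _rotate(ux, uy, uz, mu, phi):
    """Rotate unit vector by polar angle acos(mu), azimuth phi."""
    st = np.sqrt(max(0.0, 1.0 - mu * mu))
    cp = np.cos(phi)
    sp = np.sin(phi)
    if abs(uz) > 0.999999:
        sign = 1.0 if uz > 0.0 else -1.0
        return st * cp, sign * st * sp, sign * mu
    rho = np.sqrt(ux * ux + uy * uy)
    nx = mu * ux + st * (ux * uz * cp - uy * sp) / rho
    ny = mu * uy + st * (uy * uz * cp + ux * sp) / rho
    nz = mu * uz - st * rho * cp
    norm = np.sqrt(nx * nx + ny * ny + nz * nz)
    return nx / norm, ny / norm, nz / norm


@njit(cache=True, inline="always")
def _score(mode, tally, escape, radial, shell_w,
           sphere_r2, centers, r_nuc2, r_in2, r_cell2, r_cell,
           b, src, part, cat, x, y, z, e):
    if e <= 0.0:
        return
    if mode == 0:
        r2 = x * x + y * y + z * z
        if r2 <= sphere_r2:
            tally[b, 0, 0, src, part, cat] += e
        else:
            escape[b, part, cat] += e
    elif mode == 1:
        hit = False
        for t in range(centers.shape[0]):
            dx = x - centers[t, 0]
            if dx > r_cell or dx < -r_cell:
                continue
            dy = y - centers[t, 1]
            if dy > r_cell or dy < -r_cell:
                continue
            dz = z - centers[t, 2]
            r2 = dx * dx + dy * dy + dz * dz
            if r2 > r_cell2:
                continue
            if r2 <= r_nuc2:
                comp = 0
            elif r2 < r_in2:
                comp = 1
            else:
                comp = 2
            tally[b, t, comp, src, part, cat] += e
            hit = True
            break
        if not hit:
            escape[b, part, cat] += e
    elif mode == 2:
        r = np.sqrt(x * x + y * y + z * z)
        idx = int(r / shell_w)
        nb = radial.shape[0] - 1
        if idx < nb:
            radial[idx] += e
        else:
            radial[nb] += e


@njit(cache=True, inline="always")
def _sample_moller_w(st, e, wc):
    """Energy transfer in [wc, e/2] from the Moller DCS (1/W^2 envelope + rejection)."""
    wmax = 0.5 * e
    while True:
        u = _rand(st)
        w = 1.0 / (1.0 / wc - u * (1.0 / wc - 1.0 / wmax))
        r = w / (e - w)
        g = 1.0 + r * r - r
        if _rand(st) * 1.0 <= g:
            return w


@njit(cache=True)
def transport_batch(
    e0, x0, y0, z0, ux0, uy0, uz0, wt, batch, src, part, cat, seeds,
    # physics tables
    log_e0, dlog, s_res, sig_d, sig_el, sig_tr, eta_o, eta_h, p_h, rng_tab,
    # transport settings
    cutoff, wc, f_step, s_max, ch_mode, ch_emin,
    # scoring
    mode, sphere_r, centers, r_nuc, r_in, r_cell, shell_w,
    tally, escape, radial,
    # optional event collection (events.shape[0] == 0 disables)
    events,
):
    """Transport all electrons of a batch; returns number of collected events (-1 on overflow)."""
    n = e0.shape[0]
    cap = 256
    stk_e = np.empty(cap)
    stk_x = np.empty(cap)
    stk_y = np.empty(cap)
    stk_z = np.empty(cap)
    stk_u = np.empty((cap, 3))
    st = np.empty(2, dtype=np.uint64)
    sphere_r2 = sphere_r * sphere_r
    r_nuc2 = r_nuc * r_nuc
    r_in2 = r_in * r_in
    r_cell2 = r_cell * r_cell
    n_ev = 0
    ev_cap = events.shape[0]
    collect = ev_cap > 0

    for i in range(n):
        _rng_init(st, seeds[i])
        b = batch[i]
        s = src[i]
        p = part[i]
        c = cat[i]
        w = wt[i]
        sp = 0
        stk_e[0] = e0[i]
        stk_x[0] = x0[i]
        stk_y[0] = y0[i]
        stk_z[0] = z0[i]
        stk_u[0, 0] = ux0[i]
        stk_u[0, 1] = uy0[i]
        stk_u[0, 2] = uz0[i]
        sp = 1
        while sp > 0:
            sp -= 1
            e = stk_e[sp]
            x = stk_x[sp]
            y = stk_y[sp]
            z = stk_z[sp]
            ux = stk_u[sp, 0]
            uy = stk_u[sp, 1]
            uz = stk_u[sp, 2]
            if e <= cutoff:
                _score(mode, tally, escape, radial, shell_w, sphere_r2, centers,
                       r_nuc2, r_in2, r_cell2, r_cell, b, s, p, c, x, y, z, e * w)
                if collect:
                    if n_ev >= ev_cap:
                        return -1
                    events[n_ev, 0] = x
                    events[n_ev, 1] = y
                    events[n_ev, 2] = z
                    events[n_ev, 3] = e
                    n_ev += 1
                continue
            while e > cutoff:
                sres = _interp(log_e0, dlog, s_res, e)
                sd = _interp(log_e0, dlog, sig_d, e)
                rng_r = _interp(log_e0, dlog, rng_tab, e)
                step = f_step * rng_r
                if step < 1e-5:
                    step = 1e-5
                if s_max > 0.0 and step > s_max:
                    step = s_max
                kind = 0
                if sd > 1e-12:
                    sdist = -np.log(_rand(st)) / sd
                    if sdist < step:
                        step = sdist
                        kind = 1
                single = (ch_mode == 0) or (e < ch_emin)
                if single:
                    sel = _interp(log_e0, dlog, sig_el, e)
                    edist = -np.log(_rand(st)) / sel
                    if edist < step:
                        step = edist
                        kind = 2
                # continuous loss over the step, midpoint-refined
                de = step * sres
                if de > 0.25 * e:
                    step = step * (0.25 * e / de)
                    de = 0.25 * e
                    kind = 0
                emid = e - 0.5 * de
                if emid < cutoff:
                    emid = cutoff
                de = step * _interp(log_e0, dlog, s_res, emid)
                if de > e:
                    de = e
                # deposit at a uniform point along the segment (unbiased)
                t = _rand(st) * step
                _score(mode, tally, escape, radial, shell_w, sphere_r2, centers,
                       r_nuc2, r_in2, r_cell2, r_cell,
                       b, s, p, c, x + ux * t, y + uy * t, z + uz * t, de * w)
                if collect:
                    if n_ev >= ev_cap:
                        return -1
                    events[n_ev, 0] = x + ux * t
                    events[n_ev, 1] = y + uy * t
                    events[n_ev, 2] = z + uz * t
                    events[n_ev, 3] = de
                    n_ev += 1
                x += ux * step
                y += uy * step
                z += uz * step
                e -= de
                if e <= cutoff:
                    _score(mode, tally, escape, radial, shell_w, sphere_r2, centers,
                           r_nuc2, r_in2, r_cell2, r_cell, b, s, p, c, x, y, z, e * w)
                    if collect:
                        if n_ev >= ev_cap:
                            return -1
                        events[n_ev, 0] = x
                        events[n_ev, 1] = y
                        events[n_ev, 2] = z
                        events[n_ev, 3] = e
                        n_ev += 1
                    e = 0.0
                    break
                if kind == 1:
                    # delta ray
                    dw = _sample_moller_w(st, e, wc)
                    e -= dw
                    # secondary direction from free-electron kinematics
                    cs2 = (dw * (e + dw + 2.0 * MC2_EV)) / ((e + dw) * (dw + 2.0 * MC2_EV))
                    if cs2 > 1.0:
                        cs2 = 1.0
                    mu_s = np.sqrt(cs2)
                    phi = 2.0 * np.pi * _rand(st)
                    if sp < cap:
                        sx, sy, sz = _rotate(ux, uy, uz, mu_s, phi)
                        stk_e[sp] = dw
                        stk_x[sp] = x
                        stk_y[sp] = y
                        stk_z[sp] = z
                        stk_u[sp, 0] = sx
                        stk_u[sp, 1] = sy
                        stk_u[sp, 2] = sz
                        sp += 1
                    else:
                        _score(mode, tally, escape, radial, shell_w, sphere_r2, centers,
                               r_nuc2, r_in2, r_cell2, r_cell, b, s, p, c, x, y, z, dw * w)
                elif kind == 2:
                    # single elastic scattering (screened Rutherford)
                    if _rand(st) < _interp(log_e0, dlog, p_h, e):
                        eta = _interp(log_e0, dlog, eta_h, e)
                    else:
                        eta = _interp(log_e0, dlog, eta_o, e)
                    u = _rand(st)
                    mu = 1.0 - 2.0 * eta * u / (1.0 + eta - u)
                    phi = 2.0 * np.pi * _rand(st)
                    ux, uy, uz = _rotate(ux, uy, uz, mu, phi)
                elif ch_mode == 1 and not single:
                    # condensed-history Gaussian deflection over the step
                    str_ = _interp(log_e0, dlog, sig_tr, emid)
                    sigma2 = step * str_
                    theta = np.sqrt(-sigma2 * np.log(_rand(st)))
                    if theta > np.pi:
                        theta = np.pi
                    phi = 2.0 * np.pi * _rand(st)
                    ux, uy, uz = _rotate(ux, uy, uz, np.cos(theta), phi)
    return n_ev


def derive_seeds(base_seed: int, stream: int, n: int) -> np.ndarray:
    """Vectorised counter-based seeds: independent of execution order."""
    def sm(z):
        z = (z + np.uint64(0x9E3779B97F4A7C15)) & _MASK
        z = ((z ^ (z >> np.uint64(30))) * np.uint64(0xBF58476D1CE4E5B9)) & _MASK
        z = ((z ^ (z >> np.uint64(27))) * np.uint64(0x94D049BB133111EB)) & _MASK
        return z ^ (z >> np.uint64(31))

    with np.errstate(over="ignore"):
        root = sm(np.uint64(base_seed & 0x7FFFFFFF))
        root = sm(root ^ np.uint64(stream))
        return sm(root + np.arange(n, dtype=np.uint64))
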