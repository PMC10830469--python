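"""Event-driven numba kernel for the macroscale internal-lysis engine.

All times are integer multiples of the scenario time step (one diffusive hop
per step), which reproduces the synchronous fixed-step semantics exactly: a
scheduled event takes effect at the first step boundary at or after its
scheduled time.  Between events nothing needs stepping except mobile
molecules, so the kernel advances a priority queue instead of every step:

* BOUND molecules sleep until their unbinding time or the breakup of their
  fiber (edge degradation events are queue entries of their own).
* Small-FDP waits (duration 1/k_off) are free diffusion with no possibility
  of binding, so the end-of-wait position is drawn from the exact k-step
  distribution of the reflecting in-plane random walk (axis choice is
  binomial; each 1-D marginal uses the eigendecomposition of the 1-D
  walk-with-holding-at-walls transition matrix).  This is a distribution-
  preserving fast-forward, not an approximation.
* Large-FDP riders hop between adjacent degraded edges at a reduced rate
  (one attempt per ``hop_every`` steps) until their unbinding time.
* UNBOUND molecules are stepped hop by hop until they bind.

Edge degradation is lazy: each edge stores the earliest scheduled lysis time
(the minimum over all lytic initiations); an edge is degraded iff that time
has been reached.
"""

import numpy as np
from numba import njit

INF = np.int64(1) << np.int64(62)

STATE_UNBOUND = 0
STATE_BOUND = 1
STATE_LARGE_FDP = 2
STATE_SMALL_FDP = 3


@njit(inline="always")
def _hpush(ht, hid, n, t, i):
    ht[n] = t
    hid[n] = i
    c = n
    while c > 0:
        p = (c - 1) // 2
        if ht[p] <= ht[c]:
            break
        ht[p], ht[c] = ht[c], ht[p]
        hid[p], hid[c] = hid[c], hid[p]
        c = p
    return n + 1


@njit(inline="always")
def _hpop(ht, hid, n):
    t = ht[0]
    i = hid[0]
    n -= 1
    ht[0] = ht[n]
    hid[0] = hid[n]
    c = 0
    while True:
        l = 2 * c + 1
        if l >= n:
            break
        s = l
        r = l + 1
        if r < n and ht[r] < ht[l]:
            s = r
        if ht[c] <= ht[s]:
            break
        ht[c], ht[s] = ht[s], ht[c]
        hid[c], hid[s] = hid[s], hid[c]
        c = s
    return t, i, n


@njit(inline="always")
def _incident(i, j, nx, ny, nxe, nye, buf):
    c = 0
    if i > 0:
        buf[c] = j * (nx - 1) + i - 1
        c += 1
    if i < nx - 1:
        buf[c] = j * (nx - 1) + i
        c += 1
    if j > 0:
        buf[c] = nxe + (j - 1) * nx + i
        c += 1
    if j < ny - 1:
        buf[c] = nxe + j * nx + i
        c += 1
    buf[c] = nxe + nye + j * nx + i
    return c + 1


@njit(inline="always")
def _endpoints(e, nx, nxe, nye):
    if e < nxe:
        i = e % (nx - 1)
        j = e // (nx - 1)
        a = j * nx + i
        return a, a + 1
    if e < nxe + nye:
        a = e - nxe
        return a, a + nx
    a = e - nxe - nye
    return a, a


@njit(inline="always")
def _move(nodeid, nx, ny):
    # uniform choice of 4 in-plane directions; a move into a wall is a no-op
    i = nodeid % nx
    j = nodeid // nx
    r = np.random.randint(0, 4)
    if r == 0:
        if i < nx - 1:
            i += 1
    elif r == 1:
        if i > 0:
            i -= 1
    elif r == 2:
        if j < ny - 1:
            j += 1
    else:
        if j > 0:
            j -= 1
    return j * nx + i


@njit(inline="always")
def _samp(mode, mean, samples):
    # mode 0: exponential(mean); mode 1: empirical inverse transform with
    # linear interpolation between order statistics
    u = np.random.random()
    if mode == 0:
        return -mean * np.log(1.0 - u)
    n = samples.size
    if n == 1:
        return samples[0]
    idx = u * (n - 1)
    i = int(idx)
    if i >= n - 1:
        return samples[n - 1]
    f = idx - i
    return samples[i] + (samples[i + 1] - samples[i]) * f


@njit
def _ff_1d(pos, m, Q, lam):
    """Sample the position of the 1-D wall-holding walk after m steps."""
    L = Q.shape[0]
    if L == 1 or m == 0:
        return pos
    p = np.zeros(L)
    for k in range(L):
        a = lam[k]
        sgn = 1.0
        if a < 0.0:
            a = -a
            if m % 2 == 1:
                sgn = -1.0
        if a == 0.0:
            continue
        w = sgn * Q[pos, k] * a ** np.float64(m)
        if w != 0.0:
            for jj in range(L):
                p[jj] += w * Q[jj, k]
    tot = 0.0
    for jj in range(L):
        if p[jj] < 0.0:
            p[jj] = 0.0
        tot += p[jj]
    r = np.random.random() * tot
    c = 0.0
    for jj in range(L):
        c += p[jj]
        if r <= c:
            return jj
    return L - 1


@njit(inline="always")
def _ff_walk(nodeid, k, nx, Qx, lx, Qy, ly):
    """Exact fast-forward of k free-diffusion steps in the plane."""
    i = nodeid % nx
    j = nodeid // nx
    kx = np.random.binomial(k, 0.5)
    i2 = _ff_1d(i, kx, Qx, lx)
    j2 = _ff_1d(j, k - kx, Qy, ly)
    return j2 * nx + i2


@njit(cache=False)
def run_kernel(nx, ny, n_tpa, seed, dt, max_steps,
               bind_prob, q, lysis_prob, koff_steps, hop_every,
               u_mode, u_mean, u_samples,
               l_mode, l_mean, l_samples,
               Qx, lx, Qy, ly):
    np.random.seed(seed)
    nxe = (nx - 1) * ny
    nye = nx * (ny - 1)
    n_edges = nxe + nye + nx * ny
    n_nodes = nx * ny

    degrade_step = np.full(n_edges, INF, np.int64)
    degraded = np.zeros(n_edges, np.bool_)
    processed = 0

    node = np.empty(n_tpa, np.int64)
    for m in range(n_tpa):
        node[m] = np.random.randint(0, n_nodes)
    state = np.zeros(n_tpa, np.int64)
    edge = np.full(n_tpa, -1, np.int64)
    unbind_step = np.full(n_tpa, INF, np.int64)
    forced = np.zeros(n_tpa, np.bool_)
    transit_start = np.full(n_tpa, -1, np.int64)
    wake = np.full(n_tpa, -1, np.int64)

    cap = 8 * (n_tpa + n_edges) + 4096
    ht = np.empty(cap, np.int64)
    hid = np.empty(cap, np.int64)
    hn = 0
    for m in range(n_tpa):
        wake[m] = 1
        hn = _hpush(ht, hid, hn, 1, m)

    tcap = 4096
    t_mol = np.empty(tcap, np.int64)
    t_start = np.empty(tcap, np.int64)
    t_dur = np.empty(tcap, np.int64)
    tn = 0

    buf5 = np.empty(5, np.int64)
    ibuf = np.empty(5, np.int64)
    hop_buf = np.empty(10, np.int64)

    n_binds = np.int64(0)
    n_forced = np.int64(0)
    end_step = np.int64(0)
    truncated = False

    while hn > 0:
        t, idx, hn = _hpop(ht, hid, hn)
        if t > max_steps:
            truncated = processed < n_edges
            end_step = max_steps
            break
        if idx >= n_tpa:
            e = idx - n_tpa
            if degraded[e] or degrade_step[e] != t:
                continue  # stale entry: a later push superseded this one
            degraded[e] = True
            processed += 1
            for m in range(n_tpa):
                if state[m] == STATE_BOUND and edge[m] == e:
                    state[m] = STATE_LARGE_FDP
                    transit_start[m] = t
                    nt = unbind_step[m]
                    if t + hop_every < nt:
                        nt = t + hop_every
                    wake[m] = nt
                    if hn >= ht.size - 1:
                        ht2 = np.empty(ht.size * 2, np.int64)
                        hid2 = np.empty(ht.size * 2, np.int64)
                        ht2[:hn] = ht[:hn]
                        hid2[:hn] = hid[:hn]
                        ht, hid = ht2, hid2
                    hn = _hpush(ht, hid, hn, nt, m)
            if processed == n_edges:
                end_step = t
                break
            continue

        m = idx
        if wake[m] != t:
            continue
        s = state[m]
        do_move = False
        do_bind = False

        if s == STATE_BOUND:
            if degraded[edge[m]] or t < unbind_step[m]:
                continue
            edge[m] = -1
            if forced[m]:
                # ejected onto a small FDP: free diffusion, no rebinding
                # until the 1/k_off waiting time has elapsed
                state[m] = STATE_SMALL_FDP
                wake[m] = t + koff_steps
                if hn >= ht.size - 1:
                    ht2 = np.empty(ht.size * 2, np.int64)
                    hid2 = np.empty(ht.size * 2, np.int64)
                    ht2[:hn] = ht[:hn]
                    hid2[:hn] = hid[:hn]
                    ht, hid = ht2, hid2
                hn = _hpush(ht, hid, hn, t + koff_steps, m)
                continue
            state[m] = STATE_UNBOUND
            transit_start[m] = t
            do_move = True
            do_bind = True
        elif s == STATE_UNBOUND:
            do_move = True
            do_bind = True
        elif s == STATE_SMALL_FDP:
            # a transit episode opens only now: the molecule kinetically
            # unbinds from the small FDP and becomes available for rebinding
            node[m] = _ff_walk(node[m], koff_steps, nx, Qx, lx, Qy, ly)
            state[m] = STATE_UNBOUND
            transit_start[m] = t
            do_bind = True  # the fast-forward already covered this step's move
        else:  # STATE_LARGE_FDP
            if t >= unbind_step[m]:
                a, b = _endpoints(edge[m], nx, nxe, nye)
                if b != a and np.random.random() < 0.5:
                    node[m] = b
                else:
                    node[m] = a
                state[m] = STATE_UNBOUND
                edge[m] = -1
                do_move = True
                do_bind = True
            else:
                # hop uniformly to an adjacent degraded edge, if any
                e0 = edge[m]
                a, b = _endpoints(e0, nx, nxe, nye)
                ia = a % nx
                ja = a // nx
                c = _incident(ia, ja, nx, ny, nxe, nye, hop_buf)
                if b != a:
                    ib = b % nx
                    jb = b // nx
                    c += _incident(ib, jb, nx, ny, nxe, nye, hop_buf[c:])
                ncand = 0
                for kk in range(c):
                    e2 = hop_buf[kk]
                    if e2 != e0 and degraded[e2]:
                        hop_buf[ncand] = e2
                        ncand += 1
                if ncand > 0:
                    edge[m] = hop_buf[np.random.randint(0, ncand)]
                nt = unbind_step[m]
                if t + hop_every < nt:
                    nt = t + hop_every
                wake[m] = nt
                if hn >= ht.size - 1:
                    ht2 = np.empty(ht.size * 2, np.int64)
                    hid2 = np.empty(ht.size * 2, np.int64)
                    ht2[:hn] = ht[:hn]
                    hid2[:hn] = hid[:hn]
                    ht, hid = ht2, hid2
                hn = _hpush(ht, hid, hn, nt, m)
                continue

        if do_move:
            node[m] = _move(node[m], nx, ny)
        if do_bind:
            i = node[m] % nx
            j = node[m] // nx
            c = _incident(i, j, nx, ny, nxe, nye, buf5)
            nint = 0
            for kk in range(c):
                e2 = buf5[kk]
                if not degraded[e2] and degrade_step[e2] > t:
                    ibuf[nint] = e2
                    nint += 1
            bound = False
            if nint > 0 and (bind_prob >= 1.0 or np.random.random() < bind_prob):
                e2 = ibuf[np.random.randint(0, nint)]
                tu = _samp(u_mode, u_mean, u_samples)
                tus = np.int64(np.ceil(tu / dt))
                if tus < 1:
                    tus = np.int64(1)
                unbind_step[m] = t + tus
                forced[m] = np.random.random() < q
                state[m] = STATE_BOUND
                edge[m] = e2
                if lysis_prob > 0.0 and np.random.random() < lysis_prob:
                    tl = _samp(l_mode, l_mean, l_samples)
                    tls = np.int64(np.ceil(tl / dt))
                    if tls < 1:
                        tls = np.int64(1)
                    dstep = t + tls
                    if dstep < degrade_step[e2]:
                        degrade_step[e2] = dstep
                        if hn >= ht.size - 1:
                            ht2 = np.empty(ht.size * 2, np.int64)
                            hid2 = np.empty(ht.size * 2, np.int64)
                            ht2[:hn] = ht[:hn]
                            hid2[:hn] = hid[:hn]
                            ht, hid = ht2, hid2
                        hn = _hpush(ht, hid, hn, dstep, n_tpa + e2)
                wake[m] = unbind_step[m]
                if hn >= ht.size - 1:
                    ht2 = np.empty(ht.size * 2, np.int64)
                    hid2 = np.empty(ht.size * 2, np.int64)
                    ht2[:hn] = ht[:hn]
                    hid2[:hn] = hid[:hn]
                    ht, hid = ht2, hid2
                hn = _hpush(ht, hid, hn, unbind_step[m], m)
                if transit_start[m] >= 0:
                    if tn >= t_dur.size:
                        nm = np.empty(tn * 2, np.int64)
                        ns = np.empty(tn * 2, np.int64)
                        nd = np.empty(tn * 2, np.int64)
                        nm[:tn] = t_mol[:tn]
                        ns[:tn] = t_start[:tn]
                        nd[:tn] = t_dur[:tn]
                        t_mol, t_start, t_dur = nm, ns, nd
                    t_mol[tn] = m
                    t_start[tn] = transit_start[m]
                    t_dur[tn] = t - transit_start[m] + 1
                    tn += 1
                    transit_start[m] = -1
                n_binds += 1
                if forced[m]:
                    n_forced += 1
                bound = True
            if not bound:
                wake[m] = t + 1
                if hn >= ht.size - 1:
                    ht2 = np.empty(ht.size * 2, np.int64)
                    hid2 = np.empty(ht.size * 2, np.int64)
                    ht2[:hn] = ht[:hn]
                    hid2[:hn] = hid[:hn]
                    ht, hid = ht2, hid2
                hn = _hpush(ht, hid, hn, t + 1, m)

    if hn == 0 and processed < n_edges:
        truncated = True
        end_step = max_steps

    return (degrade_step, t_mol[:tn].copy(), t_start[:tn].copy(),
            t_dur[:tn].copy(), n_binds, n_forced, end_step, truncated)


def walk_eigensystem(length: int):
    """Eigendecomposition of the 1-D in-plane walk transition matrix
    (holding at walls), used by the exact diffusion fast-forward."""
    if length == 1:
        return np.ones((1, 1)), np.ones(1)
    P = np.zeros((length, length))
    for i in range(length):
        if i > 0:
            P[i, i - 1] = 0.5
        if i < length - 1:
            P[i, i + 1] = 0.5
    P[0, 0] += 0.5
    P[length - 1, length - 1] += 0.5
    lam, Q = np.linalg.eigh(P)
    return np.ascontiguousarray(Q), np.ascontiguousarray(lam)
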