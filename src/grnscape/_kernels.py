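"""JIT-compiled numerical core.

Everything here operates on plain arrays so that numba can compile the
hot loops: steady-state relaxation, fitness evaluation with the
reachability validity rule, the Wang-Landau learning walk, the
fixed-weight entropic measurement walk, quasistatic hysteresis sweeps
and the noisy step-response protocols.  The public modules wrap these in
dataclass-based APIs; nothing outside the package should import from
here directly.

Conventions: ``J`` is the int8 interaction matrix with ``J[i, j]`` the
regulation from gene j onto gene i (graph edge j -> i); gene 0 is the
input.  ``clamp`` is a uint8 mask of silenced genes whose expression is
pinned to 0 (knockouts).
"""

import numpy as np
from numba import njit

__all__ = [
    "relax_kernel",
    "sensitivities_kernel",
    "fitness_kernel",
    "input_reaches_all_kernel",
    "all_reach_kernel",
    "wl_learn_kernel",
    "entropic_kernel",
    "hysteresis_kernel",
    "step_protocol_kernel",
]


@njit(cache=True)
def _sigmoid(x, a, b):
    return 1.0 / (1.0 + np.exp(-a * (x - b)))


@njit(cache=True)
def _to_csr(J):
    """Compact row-wise edge list (regulators per target gene)."""
    n = J.shape[0]
    nnz = 0
    for i in range(n):
        for j in range(n):
            if J[i, j] != 0:
                nnz += 1
    row_ptr = np.empty(n + 1, np.int64)
    col = np.empty(nnz, np.int64)
    val = np.empty(nnz, np.float64)
    p = 0
    for i in range(n):
        row_ptr[i] = p
        for j in range(n):
            if J[i, j] != 0:
                col[p] = j
                val[p] = J[i, j]
                p += 1
    row_ptr[n] = p
    return row_ptr, col, val


@njit(cache=True)
def relax_kernel(J, I, x0, a, b, tol, max_steps, avg_window, clamp):
    """Iterate the expression map to a fixed point or a tail average.

    Returns ``(response, fixed_point, steps)``.  If the max-norm change
    between successive states drops below ``tol`` the final state is the
    response; otherwise the componentwise mean over the last
    ``avg_window`` of ``max_steps`` iterations is returned (limit cycles
    and chaotic attractors are ordinary, flagged outcomes).  The sparse
    regulator list is built once up front so each iteration only touches
    the K existing edges.
    """
    n = J.shape[0]
    row_ptr, col, val = _to_csr(J)
    x = x0.copy()
    xn = np.empty(n)
    acc = np.zeros(n)
    tail_start = max_steps - avg_window
    steps = 0
    for t in range(max_steps):
        diff = 0.0
        for i in range(n):
            if clamp[i] != 0:
                xn[i] = 0.0
            else:
                h = 0.0
                for p in range(row_ptr[i], row_ptr[i + 1]):
                    h += val[p] * x[col[p]]
                if i == 0:
                    h += I
                xn[i] = _sigmoid(h, a, b)
            d = abs(xn[i] - x[i])
            if d > diff:
                diff = d
        for i in range(n):
            x[i] = xn[i]
        steps = t + 1
        if diff < tol:
            return x, True, steps
        if t >= tail_start:
            for i in range(n):
                acc[i] += x[i]
    return acc / avg_window, False, steps


@njit(cache=True)
def sensitivities_kernel(J, a, b, tol, max_steps, avg_window, clamp):
    """Per-gene |response(I=1) - response(I=0)| from the all-0.5 start."""
    n = J.shape[0]
    x0 = np.full(n, 0.5)
    for i in range(n):
        if clamp[i] != 0:
            x0[i] = 0.0
    r0, _, _ = relax_kernel(J, 0.0, x0, a, b, tol, max_steps, avg_window, clamp)
    r1, _, _ = relax_kernel(J, 1.0, x0, a, b, tol, max_steps, avg_window, clamp)
    return np.abs(r1 - r0)


@njit(cache=True)
def input_reaches_all_kernel(J):
    """True iff every gene is reachable from gene 0 along j -> i edges."""
    n = J.shape[0]
    seen = np.zeros(n, np.uint8)
    stack = np.empty(n, np.int64)
    seen[0] = 1
    stack[0] = 0
    top = 1
    count = 1
    while top > 0:
        top -= 1
        u = stack[top]
        for v in range(n):
            if J[v, u] != 0 and seen[v] == 0:
                seen[v] = 1
                stack[top] = v
                top += 1
                count += 1
    return count == n


@njit(cache=True)
def all_reach_kernel(J, target):
    """Per-gene flags: gene g has a directed path to ``target``."""
    n = J.shape[0]
    seen = np.zeros(n, np.uint8)
    stack = np.empty(n, np.int64)
    seen[target] = 1
    stack[0] = target
    top = 1
    while top > 0:
        top -= 1
        u = stack[top]
        for j in range(n):
            if J[u, j] != 0 and seen[j] == 0:
                seen[j] = 1
                stack[top] = j
                top += 1
    return seen


@njit(cache=True)
def fitness_kernel(J, a, b, tol, max_steps, avg_window):
    """Fitness, output gene and validity of an unclamped genotype.

    Output gene = non-input gene of largest sensitivity (ties -> lowest
    index).  Valid iff the input reaches all genes and all genes reach
    the selected output; the fitness is reported either way.
    """
    n = J.shape[0]
    clamp = np.zeros(n, np.uint8)
    s = sensitivities_kernel(J, a, b, tol, max_steps, avg_window, clamp)
    out = 1
    best = s[1]
    for i in range(2, n):
        if s[i] > best:
            best = s[i]
            out = i
    valid = False
    if input_reaches_all_kernel(J):
        reach = all_reach_kernel(J, out)
        ok = True
        for i in range(n):
            if reach[i] == 0:
                ok = False
        valid = ok
    return best, out, valid


@njit(cache=True)
def _bin_of(f, n_bins):
    b = int(f * n_bins)
    if b >= n_bins:
        b = n_bins - 1
    if b < 0:
        b = 0
    return b


@njit(cache=True)
def _propose_inplace(J):
    """Relocate one random edge in place; return undo bookkeeping.

    Picks the r-th existing edge by scan, zeroes it, then places an edge
    with a fresh random sign at a uniformly chosen admissible empty slot
    (off-diagonal, both directions empty after removal).  Returns
    ``(i, j, old_sign, ti, tj)`` so the caller can revert on rejection.
    """
    n = J.shape[0]
    k = 0
    for i in range(n):
        for j in range(n):
            if J[i, j] != 0:
                k += 1
    r = np.random.randint(k)
    src_i = -1
    src_j = -1
    c = 0
    for i in range(n):
        for j in range(n):
            if J[i, j] != 0:
                if c == r:
                    src_i = i
                    src_j = j
                c += 1
    old = J[src_i, src_j]
    J[src_i, src_j] = 0
    nfree = 0
    for i in range(n):
        for j in range(n):
            if i != j and J[i, j] == 0 and J[j, i] == 0:
                nfree += 1
    r = np.random.randint(nfree)
    ti = -1
    tj = -1
    c = 0
    for i in range(n):
        for j in range(n):
            if i != j and J[i, j] == 0 and J[j, i] == 0:
                if c == r:
                    ti = i
                    tj = j
                c += 1
    sign = 1 if np.random.random() < 0.5 else -1
    J[ti, tj] = sign
    return src_i, src_j, old, ti, tj


@njit(cache=True)
def _undo(J, src_i, src_j, old, ti, tj):
    J[ti, tj] = 0
    J[src_i, src_j] = old


@njit(cache=True)
def wl_learn_kernel(
    J,
    f_init,
    n_bins,
    ln_f0,
    ln_f_final,
    flatness,
    check_interval,
    max_moves,
    seed,
    a,
    b,
    tol,
    max_steps,
    avg_window,
):
    """Wang-Landau learning walk over fitness bins.

    ``J`` (a valid genotype, modified in place) performs edge-relocation
    moves; structurally invalid proposals are rejected moves.  Acceptance
    is min(1, exp(lng[old] - lng[new])) on the running log-density-of-
    states estimate ``lng``; after every attempted move the occupied
    bin's ``lng`` gains the modification factor and its histogram one
    count.  When the stage histogram is flat over the bins visited in
    the stage (min >= flatness * mean) the factor halves and the
    histogram resets; the walk stops when the factor drops below
    ``ln_f_final`` or the move budget runs out.

    Returns ``(lng, hist, ever_visited, ln_f, moves_used, converged)``.
    """
    np.random.seed(seed)
    lng = np.zeros(n_bins)
    hist = np.zeros(n_bins, np.int64)
    ever = np.zeros(n_bins, np.uint8)
    b_cur = _bin_of(f_init, n_bins)
    ever[b_cur] = 1
    n_ever = 1
    n_ever_prev = 1
    ln_f = ln_f0
    moves = 0
    converged = False
    while moves < max_moves:
        for _ in range(check_interval):
            moves += 1
            si, sj, old, ti, tj = _propose_inplace(J)
            accept = False
            valid = input_reaches_all_kernel(J)  # cheap pre-check
            if valid:
                f_new, out_new, valid = fitness_kernel(
                    J, a, b, tol, max_steps, avg_window
                )
            if valid:
                b_new = _bin_of(f_new, n_bins)
                if ever[b_new] == 0:
                    # a freshly discovered bin inherits the current bin's
                    # density level instead of starting at zero: the walk
                    # is not trapped there for the thousands of visits it
                    # would take to regrow the global offset, and later
                    # stages refine the initialization as usual
                    lng[b_new] = lng[b_cur]
                    ever[b_new] = 1
                    n_ever += 1
                d = lng[b_cur] - lng[b_new]
                if d >= 0.0 or np.random.random() < np.exp(d):
                    accept = True
            if accept:
                b_cur = b_new
            else:
                _undo(J, si, sj, old, ti, tj)
            lng[b_cur] += ln_f
            hist[b_cur] += 1
        # flatness over every bin seen so far; while the walk is still
        # discovering new reachable bins the factor is held, so frontier
        # expansion proceeds at full penalty strength
        if n_ever > n_ever_prev:
            n_ever_prev = n_ever
            continue
        total = 0
        mn = -1
        for k in range(n_bins):
            if ever[k] != 0:
                total += hist[k]
                if mn < 0 or hist[k] < mn:
                    mn = hist[k]
        if mn >= 0 and mn >= flatness * (total / n_ever):
            ln_f *= 0.5
            for k in range(n_bins):
                hist[k] = 0
            if ln_f < ln_f_final:
                converged = True
                break
    # shift so the minimum visited lng is 0 (offset is arbitrary)
    mn_l = np.inf
    for k in range(n_bins):
        if ever[k] != 0 and lng[k] < mn_l:
            mn_l = lng[k]
    if np.isfinite(mn_l):
        for k in range(n_bins):
            if ever[k] != 0:
                lng[k] -= mn_l
    return lng, hist, ever, ln_f, moves, converged


@njit(cache=True)
def entropic_kernel(
    J,
    f_init,
    lng,
    n_bins,
    n_mcs,
    sample_interval,
    seed,
    store_lo,
    store_hi,
    store_cap,
    a,
    b,
    tol,
    max_steps,
    avg_window,
):
    """Fixed-weight entropic-sampling measurement walk.

    One Monte Carlo step (MCS) is K attempted edge relocations, K the
    edge count.  Every ``sample_interval`` MCS the current fitness is
    recorded; genotypes with fitness in [store_lo, store_hi) are archived
    (up to ``store_cap`` matrices).  Returns the recorded fitness array,
    the per-bin sample histogram, the archive and its fill count.
    """
    np.random.seed(seed)
    n = J.shape[0]
    K = 0
    for i in range(n):
        for j in range(n):
            if J[i, j] != 0:
                K += 1
    n_rec = n_mcs // sample_interval
    fs = np.empty(n_rec)
    outs = np.empty(n_rec, np.int64)
    hist = np.zeros(n_bins, np.int64)
    store = np.zeros((store_cap, n, n), np.int8)
    n_stored = 0
    f_cur = f_init
    out_cur = 0
    b_cur = _bin_of(f_cur, n_bins)
    rec = 0
    for mcs in range(n_mcs):
        for _ in range(K):
            si, sj, old, ti, tj = _propose_inplace(J)
            accept = False
            valid = input_reaches_all_kernel(J)  # cheap pre-check
            if valid:
                f_new, out_new, valid = fitness_kernel(
                    J, a, b, tol, max_steps, avg_window
                )
            if valid:
                b_new = _bin_of(f_new, n_bins)
                d = lng[b_cur] - lng[b_new]
                if d >= 0.0 or np.random.random() < np.exp(d):
                    accept = True
            if accept:
                f_cur = f_new
                out_cur = out_new
                b_cur = b_new
            else:
                _undo(J, si, sj, old, ti, tj)
        if (mcs + 1) % sample_interval == 0:
            fs[rec] = f_cur
            outs[rec] = out_cur
            hist[b_cur] += 1
            rec += 1
            if store_lo <= f_cur < store_hi and n_stored < store_cap:
                for i in range(n):
                    for j in range(n):
                        store[n_stored, i, j] = J[i, j]
                n_stored += 1
    return fs, outs, hist, store, n_stored


@njit(cache=True)
def hysteresis_kernel(J, out, n_grid, a, b, tol, max_steps, avg_window):
    """Quasistatic up and down input sweeps of the output response.

    The upward branch starts from the all-0.5 relaxation at I = 0 and
    carries each steady state to the next grid point; the downward
    branch continues from the upward branch's terminal state at I = 1.
    """
    n = J.shape[0]
    clamp = np.zeros(n, np.uint8)
    up = np.empty(n_grid)
    down = np.empty(n_grid)
    dI = 1.0 / (n_grid - 1)
    x = np.full(n, 0.5)
    for k in range(n_grid):
        x, _, _ = relax_kernel(J, k * dI, x, a, b, tol, max_steps, avg_window, clamp)
        up[k] = x[out]
    for k in range(n_grid - 1, -1, -1):
        x, _, _ = relax_kernel(J, k * dI, x, a, b, tol, max_steps, avg_window, clamp)
        down[k] = x[out]
    return up, down


@njit(cache=True)
def step_protocol_kernel(
    J,
    out,
    levels,
    phase_len,
    input_noise_amp,
    internal_noise_amp,
    seed,
    a,
    b,
    clamp,
):
    """Run the input step schedule and record the output trajectory.

    ``levels`` is the input value per phase (the canonical schedule is
    0 -> 1 -> 0 with 1000-step phases).  Input noise adds one uniform
    [-amp, amp] draw to I per time step; internal noise adds an
    independent uniform draw to each regulating pair's transmitted
    expression per step.  Zero amplitudes draw nothing, so the
    noiseless trajectory is reproduced bit for bit.
    """
    np.random.seed(seed)
    n = J.shape[0]
    n_phases = levels.shape[0]
    traj = np.empty(n_phases * phase_len)
    x = np.full(n, 0.5)
    for i in range(n):
        if clamp[i] != 0:
            x[i] = 0.0
    xn = np.empty(n)
    t = 0
    for p in range(n_phases):
        I0 = levels[p]
        for _ in range(phase_len):
            I = I0
            if input_noise_amp > 0.0:
                I += np.random.uniform(-input_noise_amp, input_noise_amp)
            for i in range(n):
                if clamp[i] != 0:
                    xn[i] = 0.0
                    continue
                h = 0.0
                for j in range(n):
                    Jij = J[i, j]
                    if Jij != 0:
                        xj = x[j]
                        if internal_noise_amp > 0.0:
                            xj += np.random.uniform(
                                -internal_noise_amp, internal_noise_amp
                            )
                        h += Jij * xj
                if i == 0:
                    h += I
                xn[i] = _sigmoid(h, a, b)
            for i in range(n):
                x[i] = xn[i]
            traj[t] = x[out]
            t += 1
    return traj
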