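"""JIT-compiled kernel for the branch-length ARG path.

Same algorithm as the pure-Python core in ``coalescent_engine`` (Hudson
back-in-time coalescent with recombination over discrete sites under
piecewise-constant demography), specialised for the case where only the
per-frequency-class branch lengths are needed.  Falls back silently if
numba is unavailable; results are not bit-identical to the pure-Python
path (different RNG streams) but draw from the same distribution.
"""

from __future__ import annotations

import numpy as np

try:
    from numba import njit

    HAVE_NUMBA = True
except Exception:  # pragma: no cover - numba is normally installed
    HAVE_NUMBA = False

    def njit(*a, **k):
        def wrap(f):
            return f

        return wrap


@njit(cache=True)
def _arg_b_kernel(n, epoch_starts, epoch_sizes, rho, L, seed):  # pragma: no cover
    np.random.seed(seed)
    cap = 4 * n + 64
    masks = np.zeros((cap, L), dtype=np.uint64)
    pops = np.zeros((cap, L), dtype=np.int16)
    lefts = np.full(cap, -1, dtype=np.int64)
    rights = np.full(cap, -1, dtype=np.int64)
    m = n
    for i in range(n):
        one = np.uint64(1) << np.uint64(i)
        for s in range(L):
            masks[i, s] = one
            pops[i, s] = 1
        lefts[i] = 0
        rights[i] = L - 1
    R = np.zeros(n + 1)
    R[1] = float(n * L)
    b_acc = np.zeros(n + 1)
    n_epochs = epoch_starts.shape[0]
    epoch_idx = 0
    t = 0.0
    active = float(n * L)

    while active > 0.0 and m > 1:
        size = epoch_sizes[epoch_idx]
        coal = m * (m - 1) / 2.0 / size
        rec_tot = 0.0
        if rho > 0.0:
            for i in range(m):
                rec_tot += rho * (rights[i] - lefts[i]) / 2.0
        total = coal + rec_tot
        if total <= 0.0:
            break
        dt = np.random.exponential(1.0 / total)
        boundary = np.inf
        if epoch_idx + 1 < n_epochs:
            boundary = epoch_starts[epoch_idx + 1]
        if t + dt > boundary:
            step = boundary - t
            for k in range(1, n):
                b_acc[k] += step * R[k]
            t = boundary
            epoch_idx += 1
            continue
        for k in range(1, n):
            b_acc[k] += dt * R[k]
        t += dt

        if np.random.random() < coal / total:
            i = np.random.randint(0, m)
            j = np.random.randint(0, m - 1)
            if j >= i:
                j += 1
            if i > j:
                i, j = j, i
            for s in range(lefts[i], rights[i] + 1):
                if pops[i, s] > 0:
                    R[pops[i, s]] -= 1.0
            for s in range(lefts[j], rights[j] + 1):
                if pops[j, s] > 0:
                    R[pops[j, s]] -= 1.0
            lo = min(lefts[i], lefts[j])
            hi = max(rights[i], rights[j])
            newleft = np.int64(-1)
            newright = np.int64(-1)
            for s in range(lo, hi + 1):
                p = pops[i, s] + pops[j, s]
                if p == n:  # site MRCA reached: drop it everywhere
                    pops[i, s] = 0
                    masks[i, s] = np.uint64(0)
                elif p > 0:
                    pops[i, s] = p
                    masks[i, s] = masks[i, s] | masks[j, s]
                    R[p] += 1.0
                    if newleft < 0:
                        newleft = s
                    newright = s
            lefts[i] = newleft
            rights[i] = newright
            # remove row j (and row i too if it carries nothing anymore),
            # swapping the last live row in and zeroing the vacated slot
            remove_hi = j
            remove_lo = i if newleft < 0 else -1
            for r in (remove_hi, remove_lo):
                if r < 0:
                    continue
                last = m - 1
                if r != last:
                    for s in range(L):
                        masks[r, s] = masks[last, s]
                        pops[r, s] = pops[last, s]
                    lefts[r] = lefts[last]
                    rights[r] = rights[last]
                for s in range(L):
                    masks[last, s] = np.uint64(0)
                    pops[last, s] = 0
                lefts[last] = -1
                rights[last] = -1
                m = last
            active = 0.0
            for k in range(1, n):
                active += R[k]
        else:
            u = np.random.random() * rec_tot
            pick = 0
            acc = 0.0
            for i in range(m):
                acc += rho * (rights[i] - lefts[i]) / 2.0
                if u < acc:
                    pick = i
                    break
            left = lefts[pick]
            right = rights[pick]
            if right <= left:
                continue
            brk = np.random.randint(left + 1, right + 1)
            if m >= cap:
                new_cap = cap * 2
                masks2 = np.zeros((new_cap, L), dtype=np.uint64)
                pops2 = np.zeros((new_cap, L), dtype=np.int16)
                lefts2 = np.full(new_cap, -1, dtype=np.int64)
                rights2 = np.full(new_cap, -1, dtype=np.int64)
                for r in range(cap):
                    for s in range(L):
                        masks2[r, s] = masks[r, s]
                        pops2[r, s] = pops[r, s]
                    lefts2[r] = lefts[r]
                    rights2[r] = rights[r]
                masks = masks2
                pops = pops2
                lefts = lefts2
                rights = rights2
                cap = new_cap
            newleft = np.int64(-1)
            newright = np.int64(-1)
            for s in range(brk, right + 1):
                masks[m, s] = masks[pick, s]
                pops[m, s] = pops[pick, s]
                if pops[m, s] > 0:
                    if newleft < 0:
                        newleft = s
                    newright = s
                masks[pick, s] = np.uint64(0)
                pops[pick, s] = 0
            lefts[m] = newleft
            rights[m] = newright
            nl = np.int64(-1)
            nr = np.int64(-1)
            for s in range(left, brk):
                if pops[pick, s] > 0:
                    if nl < 0:
                        nl = s
                    nr = s
            lefts[pick] = nl
            rights[pick] = nr
            m += 1
    return b_acc


def arg_branch_lengths(
    n: int,
    epoch_starts: np.ndarray,
    epoch_sizes: np.ndarray,
    rho_per_bp: float,
    L: int,
    seed: int,
) -> np.ndarray:
    """Accumulated per-class branch occupancy (index i = subtending count)."""
    return _arg_b_kernel(
        n,
        np.asarray(epoch_starts, dtype=np.float64),
        np.asarray(epoch_sizes, dtype=np.float64),
        float(rho_per_bp),
        int(L),
        int(seed),
    )
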