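"""Elementary dyad-swap kernels for the data-stream permutation.

An elementary swap picks two events in the same (date, group) block, say
i-j at slot t1 and k-l at slot t2 with all four individuals distinct, and
rewires them to i-l at t1 and k-j at t2 (or the mirror rewiring i-k / j-l,
chosen by coin flip), rejecting proposals that would duplicate an existing
(dyad, slot) event.  Per-individual event counts within each block, the
total event count, and the slot multiset are all invariant.

Two implementations of the same algorithm live here: a numba-compiled
kernel used in production and a pure-python reference that doubles as the
test oracle.  Both consume pre-drawn random arrays, so given the same
draws they must produce identical streams.
"""

from __future__ import annotations

import numpy as np

try:  # pragma: no cover - exercised implicitly
    from numba import njit

    HAVE_NUMBA = True
except Exception:  # pragma: no cover
    HAVE_NUMBA = False

    def njit(*args, **kwargs):
        def wrap(f):
            return f

        if args and callable(args[0]):
            return args[0]
        return wrap


@njit(cache=True)
def _swap_pass_jit(a, b, slot, swappable, block_of, block_ptr, block_idx,
                   occ, n_ind, n_slots_total, e1_pick, u2, coin):
    n_acc = 0
    for s in range(e1_pick.shape[0]):
        e1 = swappable[e1_pick[s]]
        blk = block_of[e1]
        lo = block_ptr[blk]
        hi = block_ptr[blk + 1]
        e2 = block_idx[lo + int(u2[s] * (hi - lo))]
        if e2 == e1:
            continue
        i, j = a[e1], b[e1]
        k, l = a[e2], b[e2]
        if i == k or i == l or j == k or j == l:
            continue
        if coin[s] < 0.5:
            na1, nb1 = (i, l) if i < l else (l, i)
            na2, nb2 = (k, j) if k < j else (j, k)
        else:
            na1, nb1 = (i, k) if i < k else (k, i)
            na2, nb2 = (j, l) if j < l else (l, j)
        old1 = (i * n_ind + j) * n_slots_total + slot[e1]
        old2 = (k * n_ind + l) * n_slots_total + slot[e2]
        new1 = (na1 * n_ind + nb1) * n_slots_total + slot[e1]
        new2 = (na2 * n_ind + nb2) * n_slots_total + slot[e2]
        occ[old1] = 0
        occ[old2] = 0
        if occ[new1] == 0 and occ[new2] == 0:
            occ[new1] = 1
            occ[new2] = 1
            a[e1], b[e1] = na1, nb1
            a[e2], b[e2] = na2, nb2
            n_acc += 1
        else:
            occ[old1] = 1
            occ[old2] = 1
    return n_acc


def _swap_pass_py(a, b, slot, swappable, block_of, block_ptr, block_idx,
                  occ, n_ind, n_slots_total, e1_pick, u2, coin):
    """Pure-python reference implementation (identical semantics)."""
    n_acc = 0
    for s in range(e1_pick.shape[0]):
        e1 = swappable[e1_pick[s]]
        blk = block_of[e1]
        lo = block_ptr[blk]
        hi = block_ptr[blk + 1]
        e2 = block_idx[lo + int(u2[s] * (hi - lo))]
        if e2 == e1:
            continue
        i, j = a[e1], b[e1]
        k, l = a[e2], b[e2]
        if i == k or i == l or j == k or j == l:
            continue
        if coin[s] < 0.5:
            na1, nb1 = (i, l) if i < l else (l, i)
            na2, nb2 = (k, j) if k < j else (j, k)
        else:
            na1, nb1 = (i, k) if i < k else (k, i)
            na2, nb2 = (j, l) if j < l else (l, j)
        old1 = (i * n_ind + j) * n_slots_total + slot[e1]
        old2 = (k * n_ind + l) * n_slots_total + slot[e2]
        new1 = (na1 * n_ind + nb1) * n_slots_total + slot[e1]
        new2 = (na2 * n_ind + nb2) * n_slots_total + slot[e2]
        occ[old1] = 0
        occ[old2] = 0
        if occ[new1] == 0 and occ[new2] == 0:
            occ[new1] = 1
            occ[new2] = 1
            a[e1], b[e1] = na1, nb1
            a[e2], b[e2] = na2, nb2
            n_acc += 1
        else:
            occ[old1] = 1
            occ[old2] = 1
    return n_acc


swap_pass = _swap_pass_jit if HAVE_NUMBA else _swap_pass_py
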