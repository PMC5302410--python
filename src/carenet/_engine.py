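"""Low-level kernels for exhaustive state-space enumeration.

States of the free internal nodes are packed into unsigned integers; for
one control state the full synchronous next-state map ``f`` over all
``2^n_free`` states is materialized once, and attractors/basins are then
recovered by a single linear-time functional-graph traversal instead of
per-state step-by-step simulation.

The kernels are compiled with numba when it is available; without it
they run as plain Python (correct but only usable for small networks).
"""

from __future__ import annotations

import numpy as np

try:  # pragma: no cover - exercised implicitly
    from numba import njit

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    HAVE_NUMBA = False

    def njit(*args, **kwargs):
        if args and callable(args[0]):
            return args[0]

        def wrap(func):
            return func

        return wrap


@njit(cache=False)
def build_transition_map(
    n_free: int,
    out_offsets: np.ndarray,  # int64[n_free+1] slices into out_targets/out_weights
    out_targets: np.ndarray,  # int64[] free-node indices regulated by each free bit
    out_weights: np.ndarray,  # int64[] signs of those regulations
    consts: np.ndarray,       # int64[n_free] signed regulator sum from fixed nodes that are on
    rhs: np.ndarray,          # int64[n_free] n_i - 2*m_i
) -> np.ndarray:
    """Next-state map over all 2^n_free packed states.

    Free internal node ``i`` switches on iff ``2 * r_i > rhs[i]`` where
    ``r_i`` is its signed regulator sum — the exact integer form of the
    strict threshold comparison.  States are visited in gray-code order
    so that each step flips a single source bit and only the regulator
    sums of its targets need updating.
    """
    size = 1 << n_free
    f = np.empty(size, np.uint32)
    r = consts.copy()
    nxt = 0
    for i in range(n_free):
        if 2 * r[i] > rhs[i]:
            nxt |= 1 << i
    f[0] = nxt
    g = 0
    for k in range(1, size):
        b = 0  # index of the bit flipped between gray(k-1) and gray(k)
        kk = k
        while kk & 1 == 0:
            kk >>= 1
            b += 1
        g ^= 1 << b
        delta = 1 if (g >> b) & 1 else -1
        for e in range(out_offsets[b], out_offsets[b + 1]):
            t = out_targets[e]
            r[t] += delta * out_weights[e]
            if 2 * r[t] > rhs[t]:
                nxt |= 1 << t
            else:
                nxt &= ~(1 << t)
        f[g] = nxt
    return f


@njit(cache=False)
def label_basins(f: np.ndarray):
    """Attractor labelling of a functional graph.

    Returns ``(comp, on_cycle, n_attr)`` where ``comp[s]`` is the index
    of the attractor state ``s`` flows into and ``on_cycle[s]`` marks
    states that lie on an attractor cycle.  Runs in O(len(f)).
    """
    n = f.shape[0]
    comp = np.full(n, -1, np.int32)
    mark = np.full(n, -1, np.int64)
    on_cycle = np.zeros(n, np.bool_)
    path = np.empty(n, np.uint32)
    n_attr = 0
    for x in range(n):
        if comp[x] >= 0:
            continue
        y = x
        plen = 0
        while comp[y] < 0 and mark[y] != x:
            mark[y] = x
            path[plen] = y
            plen += 1
            y = f[y]
        if comp[y] >= 0:
            a = comp[y]
        else:
            # y closes a new cycle: walk it once to label its states
            a = n_attr
            n_attr += 1
            z = y
            while True:
                comp[z] = a
                on_cycle[z] = True
                z = f[z]
                if z == y:
                    break
        for k in range(plen):
            comp[path[k]] = a
    return comp, on_cycle, n_attr
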