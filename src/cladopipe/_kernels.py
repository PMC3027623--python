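"""Tight scoring loops, JIT-compiled when numba is available.

Trees arrive as postorder arrays (children before parents, root last).  The
root is the reference leaf, so it is the only node carrying both a state
constraint and children; unordered characters are scored with Hartigan
counts (exact on multifurcations, reduces to Fitch on binary trees) and
ordered characters with a min-plus sweep over states (Wagner costs |i-j|).
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

        def wrap(f):
            return f

        return wrap


INF = 1 << 28


@njit(cache=True)
def steps_kernel(child_ptr, child_idx, leaf_row, umask, uK, omask, oK):
    """Per-character parsimony steps for one tree.

    child_ptr/child_idx: CSR children lists over postorder positions.
    leaf_row[i]: taxon row of node i, or -1 for internal nodes.  The root
    (last position) is a leaf with children.
    umask: (n_taxa, Cu) int64 allowed-state bitmasks, unordered characters.
    omask: (n_taxa, Co) int64 bitmasks, ordered characters.
    """
    n = child_ptr.shape[0] - 1
    Cu = umask.shape[1]
    Co = omask.shape[1]
    out_u = np.zeros(Cu, np.int64)
    out_o = np.zeros(Co, np.int64)

    S = np.zeros(n, np.int64)
    cost = np.zeros(n, np.int64)
    for c in range(Cu):
        K = uK[c]
        for i in range(n):
            lo = child_ptr[i]
            hi = child_ptr[i + 1]
            if hi == lo:
                S[i] = umask[leaf_row[i], c]
                cost[i] = 0
                continue
            allowed = -1
            if i == n - 1 and leaf_row[i] >= 0:
                allowed = umask[leaf_row[i], c]
            maxcount = -1
            smask = 0
            for s in range(K):
                if allowed != -1 and not (allowed >> s) & 1:
                    continue
                cnt = 0
                for k in range(lo, hi):
                    if (S[child_idx[k]] >> s) & 1:
                        cnt += 1
                if cnt > maxcount:
                    maxcount = cnt
                    smask = 1 << s
                elif cnt == maxcount:
                    smask |= 1 << s
            tot = 0
            for k in range(lo, hi):
                tot += cost[child_idx[k]]
            cost[i] = tot + (hi - lo - maxcount)
            S[i] = smask
        out_u[c] = cost[n - 1]

    if Co > 0:
        Kmax = 0
        for c in range(Co):
            if oK[c] > Kmax:
                Kmax = oK[c]
        D = np.zeros((n, Kmax), np.int64)
        E = np.zeros(Kmax, np.int64)
        for c in range(Co):
            K = oK[c]
            for i in range(n):
                lo = child_ptr[i]
                hi = child_ptr[i + 1]
                if hi == lo:
                    m = omask[leaf_row[i], c]
                    for s in range(K):
                        D[i, s] = 0 if (m >> s) & 1 else INF
                    continue
                for s in range(K):
                    D[i, s] = 0
                for k in range(lo, hi):
                    ch = child_idx[k]
                    E[0] = D[ch, 0]
                    for s in range(1, K):
                        e = D[ch, s]
                        if E[s - 1] + 1 < e:
                            e = E[s - 1] + 1
                        E[s] = e
                    for s in range(K - 2, -1, -1):
                        if E[s + 1] + 1 < E[s]:
                            E[s] = E[s + 1] + 1
                    for s in range(K):
                        D[i, s] += E[s]
            best = INF
            root = n - 1
            m = omask[leaf_row[root], c] if leaf_row[root] >= 0 else (1 << K) - 1
            for s in range(K):
                if (m >> s) & 1 and D[root, s] < best:
                    best = D[root, s]
            out_o[c] = best

    return out_u, out_o
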