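"""Exact s-t max-flow / min-cut on int64 capacities (Dinic's algorithm).

Edge costs from the segmentation energy are floats; they are converted to
fixed-point int64 capacities upstream, which requires a solver that genuinely
supports 64-bit capacities (hard-constraint edges are huge).  The kernel is
numba-compiled; edges are traversed in insertion order, so min-cut
tie-breaking is deterministic and reproducible.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def _dinic(n, s, t, indptr, adj, to, cap):
    """Dinic blocking-flow max-flow over a CSR adjacency of edge ids.

    ``adj[indptr[u]:indptr[u+1]]`` lists the ids of edges leaving ``u``;
    edge i and edge i^1 are mutual reverses in ``to``/``cap``.  Returns
    (flow, level); after termination ``level[v] >= 0`` iff v is reachable
    from s in the residual network, i.e. on the source side of a min cut.
    """
    level = np.empty(n, dtype=np.int64)
    it = np.empty(n, dtype=np.int64)
    queue = np.empty(n, dtype=np.int64)
    stack_v = np.empty(n + 1, dtype=np.int64)
    stack_e = np.empty(n + 1, dtype=np.int64)
    INF = np.int64(1) << np.int64(62)
    flow = np.int64(0)

    while True:
        # BFS layering on the residual graph
        for i in range(n):
            level[i] = -1
        level[s] = 0
        qh, qt = 0, 0
        queue[qt] = s
        qt += 1
        while qh < qt:
            u = queue[qh]
            qh += 1
            for p in range(indptr[u], indptr[u + 1]):
                e = adj[p]
                v = to[e]
                if cap[e] > 0 and level[v] < 0:
                    level[v] = level[u] + 1
                    queue[qt] = v
                    qt += 1
        if level[t] < 0:
            return flow, level

        # blocking flow by iterative DFS with current-arc pointers
        for i in range(n):
            it[i] = indptr[i]
        while True:
            depth = 0
            stack_v[0] = s
            found = False
            while depth >= 0:
                u = stack_v[depth]
                if u == t:
                    found = True
                    break
                advanced = False
                p = it[u]
                while p < indptr[u + 1]:
                    e = adj[p]
                    v = to[e]
                    if cap[e] > 0 and level[v] == level[u] + 1:
                        it[u] = p
                        stack_e[depth] = e
                        depth += 1
                        stack_v[depth] = v
                        advanced = True
                        break
                    p += 1
                if not advanced:
                    it[u] = indptr[u + 1]
                    level[u] = -2  # dead end within this phase
                    depth -= 1
            if not found:
                break
            aug = INF
            for d in range(depth):
                e = stack_e[d]
                if cap[e] < aug:
                    aug = cap[e]
            for d in range(depth):
                e = stack_e[d]
                cap[e] -= aug
                cap[e ^ 1] += aug
            flow += aug


def min_cut(
    n_nodes: int,
    source: int,
    sink: int,
    edge_u: np.ndarray,
    edge_v: np.ndarray,
    cap_fwd: np.ndarray,
    cap_bwd: np.ndarray,
) -> tuple[int, np.ndarray]:
    """Max-flow value and boolean source-side mask of a minimum s-t cut.

    Each input edge i is directed u->v with capacity ``cap_fwd[i]`` and its
    reverse v->u with ``cap_bwd[i]`` (0 for pure directed edges).
    """
    edge_u = np.ascontiguousarray(edge_u, dtype=np.int64)
    edge_v = np.ascontiguousarray(edge_v, dtype=np.int64)
    m = edge_u.size
    to = np.empty(2 * m, dtype=np.int64)
    cap = np.empty(2 * m, dtype=np.int64)
    to[0::2] = edge_v
    to[1::2] = edge_u
    cap[0::2] = np.ascontiguousarray(cap_fwd, dtype=np.int64)
    cap[1::2] = np.ascontiguousarray(cap_bwd, dtype=np.int64)
    src = np.empty(2 * m, dtype=np.int64)
    src[0::2] = edge_u
    src[1::2] = edge_v
    # CSR adjacency of edge ids, grouped by source node in insertion order
    adj = np.argsort(src, kind="stable").astype(np.int64)
    counts = np.bincount(src, minlength=n_nodes)
    indptr = np.zeros(n_nodes + 1, dtype=np.int64)
    np.cumsum(counts, out=indptr[1:])
    flow, level = _dinic(
        np.int64(n_nodes), np.int64(source), np.int64(sink), indptr, adj, to, cap
    )
    return int(flow), level >= 0
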