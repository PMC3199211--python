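"""Exact s-t max-flow / min-cut with float capacities (Dinic's algorithm).

Binary submodular pixel-labeling energies reduce to an s-t min-cut on a
graph with one node per pixel plus source/sink terminals.  The solver
works directly on float64 capacities, so the minimum cut — and hence the
MAP labeling — is exact up to floating-point arithmetic, with no integer
quantization.  Dinic's algorithm terminates in at most V phases regardless
of capacity values, so float capacities are safe.

The kernel is JIT-compiled with numba; graphs are stored forward-star
style with paired arcs (arc ``a`` and ``a ^ 1`` are mutual reverses).
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["min_cut_binary"]


@njit(cache=True)
def _dinic(n_nodes, head, nxt, arc_to, cap, s, t):
    level = np.empty(n_nodes, np.int32)
    cur = np.empty(n_nodes, np.int64)
    queue = np.empty(n_nodes, np.int64)
    path = np.empty(n_nodes + 1, np.int64)

    while True:
        # BFS: residual level graph
        for i in range(n_nodes):
            level[i] = -1
        level[s] = 0
        qh, qt = 0, 0
        queue[qt] = s
        qt += 1
        while qh < qt:
            v = queue[qh]
            qh += 1
            a = head[v]
            while a != -1:
                u = arc_to[a]
                if cap[a] > 0.0 and level[u] == -1:
                    level[u] = level[v] + 1
                    queue[qt] = u
                    qt += 1
                a = nxt[a]
        if level[t] == -1:
            break
        for i in range(n_nodes):
            cur[i] = head[i]
        # blocking flow: iterative DFS with current-arc optimization
        v = s
        depth = 0
        while True:
            if v == t:
                # bottleneck along path[0:depth]
                bn = np.inf
                for k in range(depth):
                    if cap[path[k]] < bn:
                        bn = cap[path[k]]
                for k in range(depth):
                    cap[path[k]] -= bn
                    cap[path[k] ^ 1] += bn
                # retreat to the tail of the first saturated arc
                v = s
                depth = 0
                continue
            advanced = False
            a = cur[v]
            while a != -1:
                u = arc_to[a]
                if cap[a] > 0.0 and level[u] == level[v] + 1:
                    path[depth] = a
                    depth += 1
                    v = u
                    advanced = True
                    break
                a = nxt[a]
                cur[v] = a
            if not advanced:
                if v == s:
                    break
                level[v] = -1  # dead end for this phase
                depth -= 1
                v = arc_to[path[depth] ^ 1]
                cur[v] = nxt[cur[v]] if cur[v] != -1 else -1

    # final residual reachability: level != -1 <=> reachable from s
    reach = np.zeros(n_nodes, np.bool_)
    for i in range(n_nodes):
        if level[i] != -1:
            reach[i] = True
    reach[s] = True
    return reach


def min_cut_binary(
    n: int,
    cap_source: np.ndarray,
    cap_sink: np.ndarray,
    edge_u: np.ndarray,
    edge_v: np.ndarray,
    edge_cap: np.ndarray,
) -> np.ndarray:
    """Minimum s-t cut for a binary labeling problem.

    Node ``i`` pays ``cap_source[i]`` when assigned label 1 (its s-arc is
    cut) and ``cap_sink[i]`` when assigned label 0; each undirected edge
    pays ``edge_cap`` when its endpoints are separated.  Returns the
    label-1 indicator array (True = sink side).
    """
    s, t = n, n + 1
    n_nodes = n + 2
    m = 2 * n + edge_u.size  # arc pairs
    arc_to = np.empty(2 * m, np.int64)
    cap = np.empty(2 * m, np.float64)
    frm = np.empty(2 * m, np.int64)

    k = np.arange(n)
    # s -> i pairs (arcs 2j, 2j+1)
    frm[0 : 2 * n : 2] = s
    arc_to[0 : 2 * n : 2] = k
    cap[0 : 2 * n : 2] = cap_source
    frm[1 : 2 * n : 2] = k
    arc_to[1 : 2 * n : 2] = s
    cap[1 : 2 * n : 2] = 0.0
    # i -> t pairs
    o = 2 * n
    frm[o : o + 2 * n : 2] = k
    arc_to[o : o + 2 * n : 2] = t
    cap[o : o + 2 * n : 2] = cap_sink
    frm[o + 1 : o + 2 * n : 2] = t
    arc_to[o + 1 : o + 2 * n : 2] = k
    cap[o + 1 : o + 2 * n : 2] = 0.0
    # undirected pixel edges: symmetric pair
    o = 4 * n
    ne = edge_u.size
    frm[o : o + 2 * ne : 2] = edge_u
    arc_to[o : o + 2 * ne : 2] = edge_v
    cap[o : o + 2 * ne : 2] = edge_cap
    frm[o + 1 : o + 2 * ne : 2] = edge_v
    arc_to[o + 1 : o + 2 * ne : 2] = edge_u
    cap[o + 1 : o + 2 * ne : 2] = edge_cap

    head, nxt = _forward_star(n_nodes, frm)
    reach = _dinic(n_nodes, head, nxt, arc_to, cap, s, t)
    return ~reach[:n]


@njit(cache=True)
def _forward_star(n_nodes, frm):
    n_arcs = frm.size
    head = np.full(n_nodes, -1, np.int64)
    nxt = np.empty(n_arcs, np.int64)
    for a in range(n_arcs - 1, -1, -1):
        nxt[a] = head[frm[a]]
        head[frm[a]] = a
    return head, nxt
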