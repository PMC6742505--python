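"""Numba kernels for max-flow/min-cut on terminal-capacitated CSR graphs.

The graph layout is tuned for binary-MRF problems: every node may carry
residual capacity from the source (``res_src``) and to the sink
(``res_snk``); inter-node arcs are stored twice (both directions) in CSR
form with ``rev`` mapping each arc to its opposite, so residual updates are
O(1).  The source and sink are implicit — augmenting paths are node
sequences whose first node still has source capacity and whose last node
still has sink capacity.

Two access patterns are provided:

* :func:`dinic` — full max-flow (level BFS + blocking flow), used for the
  base solve of every binary move problem.
* :func:`excess_backward_all` / :func:`excess_forward_all` — constrained
  re-solves that reuse the residual state of a finished max-flow.  Fixing a
  node to the sink (resp. source) side only adds capacity on one terminal
  arc, so the min-marginal increase equals the extra flow that can be pushed
  from the source to that node (resp. node to sink) through the residual
  graph.  Each node's augmentation is undone from a change log before the
  next node is processed, which is what makes sweeping all voxels feasible.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = [
    "dinic",
    "reachable_from_source",
    "excess_backward_all",
    "excess_forward_all",
]


@njit(cache=False)
def dinic(indptr, heads, rev, rcap, res_src, res_snk):  # pragma: no cover - jitted
    """Max flow between the implicit terminals; residual arrays are updated
    in place and the pushed flow is returned."""
    n = indptr.shape[0] - 1
    total = np.int64(0)
    level = np.empty(n, np.int32)
    queue = np.empty(n, np.int32)
    itp = np.empty(n, np.int64)
    stack_node = np.empty(n + 2, np.int32)
    stack_arc = np.empty(n + 2, np.int64)

    while True:
        # --- BFS phase: levels from the source side ---
        for i in range(n):
            level[i] = -1
        qh = 0
        qt = 0
        for v in range(n):
            if res_src[v] > 0:
                level[v] = 1
                queue[qt] = v
                qt += 1
        t_level = -1
        while qh < qt:
            u = queue[qh]
            qh += 1
            if t_level != -1 and level[u] + 1 >= t_level:
                continue
            if res_snk[u] > 0:
                t_level = level[u] + 1
                continue
            for e in range(indptr[u], indptr[u + 1]):
                if rcap[e] > 0:
                    w = heads[e]
                    if level[w] < 0:
                        level[w] = level[u] + 1
                        queue[qt] = w
                        qt += 1
        if t_level == -1:
            break

        # --- blocking flow phase ---
        for i in range(n):
            itp[i] = indptr[i]
        for v0 in range(n):
            if res_src[v0] <= 0 or level[v0] != 1:
                continue
            exhausted = False
            while res_src[v0] > 0 and not exhausted:
                top = 0
                stack_node[0] = v0
                while True:
                    u = stack_node[top]
                    if res_snk[u] > 0 and level[u] == t_level - 1:
                        b = res_src[v0]
                        if res_snk[u] < b:
                            b = res_snk[u]
                        for k in range(top):
                            e = stack_arc[k]
                            if rcap[e] < b:
                                b = rcap[e]
                        res_src[v0] -= b
                        res_snk[u] -= b
                        for k in range(top):
                            e = stack_arc[k]
                            rcap[e] -= b
                            rcap[rev[e]] += b
                        total += b
                        break
                    advanced = False
                    e = itp[u]
                    while e < indptr[u + 1]:
                        w = heads[e]
                        if rcap[e] > 0 and level[w] == level[u] + 1 and level[w] < t_level:
                            stack_arc[top] = e
                            top += 1
                            stack_node[top] = w
                            advanced = True
                            break
                        e += 1
                    itp[u] = e
                    if advanced:
                        continue
                    level[u] = -2  # dead end for this phase
                    if top == 0:
                        exhausted = True
                        break
                    top -= 1
                    itp[stack_node[top]] += 1
    return total


@njit(cache=False)
def reachable_from_source(indptr, heads, rcap, res_src):  # pragma: no cover - jitted
    """Nodes reachable from the source in the residual graph (the S side of
    the minimum cut; label 0)."""
    n = indptr.shape[0] - 1
    reach = np.zeros(n, np.uint8)
    queue = np.empty(n, np.int32)
    qt = 0
    for v in range(n):
        if res_src[v] > 0:
            reach[v] = 1
            queue[qt] = v
            qt += 1
    qh = 0
    while qh < qt:
        u = queue[qh]
        qh += 1
        for e in range(indptr[u], indptr[u + 1]):
            if rcap[e] > 0:
                w = heads[e]
                if reach[w] == 0:
                    reach[w] = 1
                    queue[qt] = w
                    qt += 1
    return reach


@njit(cache=False)
def _undo(rcap, res_term, log_arc, log_delta, log_term, log_term_delta, ne, nt):  # pragma: no cover
    for k in range(ne - 1, -1, -1):
        rcap[log_arc[k]] += log_delta[k]
    for k in range(nt - 1, -1, -1):
        res_term[log_term[k]] += log_term_delta[k]


@njit(cache=False)
def excess_backward_all(indptr, heads, rev, rcap, res_src, nodes):  # pragma: no cover - jitted
    """For each query node v: the maximum extra flow the source can push to
    v through the residual graph (== min-marginal increase of fixing v to
    the sink side).  Residual state is restored after each node."""
    n = indptr.shape[0] - 1
    nq = nodes.shape[0]
    out = np.zeros(nq, np.int64)
    down_arc = np.empty(n, np.int64)  # arc u -> (node closer to v)
    visited = np.zeros(n, np.int64)
    stamp = np.int64(0)
    queue = np.empty(n, np.int32)
    cap_log = 4 * rcap.shape[0] + 16
    log_arc = np.empty(cap_log, np.int64)
    log_delta = np.empty(cap_log, np.int64)
    log_term = np.empty(cap_log, np.int64)
    log_term_delta = np.empty(cap_log, np.int64)

    for qi in range(nq):
        v = nodes[qi]
        total = np.int64(0)
        ne = 0
        nt = 0
        overflow = False
        while not overflow:
            stamp += 1
            visited[v] = stamp
            queue[0] = v
            qh = 0
            qt = 1
            hit = np.int64(-1)
            if res_src[v] > 0:
                hit = v
            while qh < qt and hit < 0:
                w = queue[qh]
                qh += 1
                for e in range(indptr[w], indptr[w + 1]):
                    u = heads[e]
                    if visited[u] != stamp and rcap[rev[e]] > 0:
                        visited[u] = stamp
                        down_arc[u] = rev[e]
                        if res_src[u] > 0:
                            hit = u
                            break
                        queue[qt] = u
                        qt += 1
            if hit < 0:
                break
            # bottleneck along hit -> ... -> v
            b = res_src[hit]
            u = hit
            while u != v:
                e = down_arc[u]
                if rcap[e] < b:
                    b = rcap[e]
                u = heads[e]
            # apply + log
            if nt >= cap_log:
                overflow = True
                break
            res_src[hit] -= b
            log_term[nt] = hit
            log_term_delta[nt] = b
            nt += 1
            u = hit
            while u != v:
                e = down_arc[u]
                if ne + 2 > cap_log:
                    overflow = True
                    break
                rcap[e] -= b
                log_arc[ne] = e
                log_delta[ne] = b
                ne += 1
                rcap[rev[e]] += b
                log_arc[ne] = rev[e]
                log_delta[ne] = -b
                ne += 1
                u = heads[e]
            if overflow:
                break
            total += b
        _undo(rcap, res_src, log_arc, log_delta, log_term, log_term_delta, ne, nt)
        out[qi] = np.int64(-1) if overflow else total
    return out


@njit(cache=False)
def excess_forward_all(indptr, heads, rev, rcap, res_snk, nodes):  # pragma: no cover - jitted
    """For each query node v: the maximum extra flow v can push to the sink
    through the residual graph (== min-marginal increase of fixing v to the
    source side)."""
    n = indptr.shape[0] - 1
    nq = nodes.shape[0]
    out = np.zeros(nq, np.int64)
    par_arc = np.empty(n, np.int64)  # arc (node closer to v) -> u
    visited = np.zeros(n, np.int64)
    stamp = np.int64(0)
    queue = np.empty(n, np.int32)
    cap_log = 4 * rcap.shape[0] + 16
    log_arc = np.empty(cap_log, np.int64)
    log_delta = np.empty(cap_log, np.int64)
    log_term = np.empty(cap_log, np.int64)
    log_term_delta = np.empty(cap_log, np.int64)

    for qi in range(nq):
        v = nodes[qi]
        total = np.int64(0)
        ne = 0
        nt = 0
        overflow = False
        while not overflow:
            stamp += 1
            visited[v] = stamp
            queue[0] = v
            qh = 0
            qt = 1
            hit = np.int64(-1)
            if res_snk[v] > 0:
                hit = v
            while qh < qt and hit < 0:
                w = queue[qh]
                qh += 1
                for e in range(indptr[w], indptr[w + 1]):
                    u = heads[e]
                    if visited[u] != stamp and rcap[e] > 0:
                        visited[u] = stamp
                        par_arc[u] = e
                        if res_snk[u] > 0:
                            hit = u
                            break
                        queue[qt] = u
                        qt += 1
            if hit < 0:
                break
            # bottleneck along v -> ... -> hit
            b = res_snk[hit]
            u = hit
            while u != v:
                e = par_arc[u]
                if rcap[e] < b:
                    b = rcap[e]
                u = heads[rev[e]]
            if nt >= cap_log:
                overflow = True
                break
            res_snk[hit] -= b
            log_term[nt] = hit
            log_term_delta[nt] = b
            nt += 1
            u = hit
            while u != v:
                e = par_arc[u]
                if ne + 2 > cap_log:
                    overflow = True
                    break
                rcap[e] -= b
                log_arc[ne] = e
                log_delta[ne] = b
                ne += 1
                rcap[rev[e]] += b
                log_arc[ne] = rev[e]
                log_delta[ne] = -b
                ne += 1
                u = heads[rev[e]]
            if overflow:
                break
            total += b
        _undo(rcap, res_snk, log_arc, log_delta, log_term, log_term_delta, ne, nt)
        out[qi] = np.int64(-1) if overflow else total
    return out
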