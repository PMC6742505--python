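"""Binary-MRF energies as s/t flow networks: construction, max-flow MAP
solves, and constrained re-solves for min-marginals.

A binary pairwise energy E(x) = sum_i E^i(x_i) + sum_ij E^ij(x_i, x_j) is
representable as a cut problem whenever every pairwise term is submodular
(E(0,0) + E(1,1) <= E(0,1) + E(1,0)).  Each term is reparameterised into an
elementary graph: the constant part is absorbed into ``constant_offset``,
the label-dependent remainder goes onto terminal arcs, and the submodularity
surplus e01 + e10 - e00 - e11 becomes the inter-node capacity.  Label 0 is
the source side of the minimum cut, label 1 the sink side; the capacity of
the source arc of a node is therefore the penalty for assigning it label 1,
and vice versa.

Capacities are floats at the API surface but are scaled to int64 before
solving, so flow arithmetic is exact; energies that are dyadic rationals
survive the round trip bit-for-bit.  "Infinite" capacity is a sentinel one
unit larger than the sum of all finite capacities.

Min-marginals (the minimum energy with one node pinned to one label) are
computed either cold — rebuild with an infinite terminal arc and re-solve —
or by reusing the residual state of the base solve: pinning only adds
terminal capacity, so the energy increase equals the extra flow that can be
routed through the residual graph, which is typically a local computation.
Both paths are value-identical by construction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._flow import (
    dinic,
    excess_backward_all,
    excess_forward_all,
    reachable_from_source,
)

__all__ = [
    "SubmodularityError",
    "PairwiseTerm",
    "CutResult",
    "FlowNetwork",
    "elementary_graph",
    "max_flow",
    "solve_constrained",
]

_SUBMODULAR_RTOL = 1e-9


class SubmodularityError(ValueError):
    """Raised for pairwise terms with e00 + e11 > e01 + e10."""

    def __init__(self, margin: float):
        self.margin = margin
        super().__init__(
            f"pairwise term is not submodular: e00 + e11 exceeds e01 + e10 by {margin:.6g}"
        )


@dataclass(frozen=True)
class PairwiseTerm:
    """Energies of one pairwise interaction over the four binary outcomes."""

    e00: float
    e01: float
    e10: float
    e11: float

    @property
    def margin(self) -> float:
        """Submodularity violation (positive means non-submodular)."""
        return (self.e00 + self.e11) - (self.e01 + self.e10)

    @property
    def is_submodular(self) -> bool:
        scale = max(abs(self.e00), abs(self.e01), abs(self.e10), abs(self.e11), 1.0)
        return self.margin <= _SUBMODULAR_RTOL * scale


@dataclass(frozen=True)
class CutResult:
    """Minimum-cut value (excluding the constant offset) and node labels."""

    flow_value: float
    labels: np.ndarray

    def energy(self, constant_offset: float) -> float:
        return self.flow_value + constant_offset


def elementary_graph(term: PairwiseTerm, i: int, j: int) -> dict:
    """Reparameterise one pairwise term into capacity increments.

    Returns the constant offset, the label-1 penalties for nodes ``i`` and
    ``j`` (possibly negative; :meth:`FlowNetwork.add_unary` normalises
    those onto nonnegative terminal arcs) and the i->j capacity.
    """
    if not term.is_submodular:
        raise SubmodularityError(term.margin)
    return {
        "offset": term.e00,
        "unary1_i": term.e10 - term.e00,
        "unary1_j": term.e11 - term.e10,
        "cap_ij": term.e01 + term.e10 - term.e00 - term.e11,
        "i": i,
        "j": j,
    }


class FlowNetwork:
    """Accumulates an energy, then solves it as a min-cut problem."""

    def __init__(self, n_nodes: int):
        if n_nodes < 0:
            raise ValueError("n_nodes must be >= 0")
        self.n_nodes = int(n_nodes)
        self.constant_offset = 0.0
        self._src = np.zeros(self.n_nodes, dtype=float)
        self._snk = np.zeros(self.n_nodes, dtype=float)
        self._ei: list[np.ndarray] = []
        self._ej: list[np.ndarray] = []
        self._cij: list[np.ndarray] = []
        self._cji: list[np.ndarray] = []
        self._pinned: dict[int, int] = {}
        self._built = False
        self._solved = False

    # ---------------- construction ----------------

    def _check_node(self, i: int) -> int:
        i = int(i)
        if not 0 <= i < self.n_nodes:
            raise IndexError(f"node index {i} out of range [0, {self.n_nodes})")
        return i

    def add_unary(self, i: int, e0: float, e1: float) -> None:
        """Add a unary term with energies e0 / e1 for labels 0 / 1."""
        i = self._check_node(i)
        self._invalidate()
        m = min(e0, e1)
        self.constant_offset += m
        self._src[i] += e1 - m  # penalty for label 1 sits on the source arc
        self._snk[i] += e0 - m

    def add_terminal_caps(self, i: int, cap_source: float, cap_sink: float) -> None:
        """Add raw terminal capacities (cap_source penalises label 1)."""
        i = self._check_node(i)
        if cap_source < 0 or cap_sink < 0:
            raise ValueError("terminal capacities must be >= 0")
        self._invalidate()
        self._src[i] += cap_source
        self._snk[i] += cap_sink

    def add_edge(self, i: int, j: int, cap_ij: float, cap_ji: float = 0.0) -> None:
        """Add a raw directed capacity pair between two nodes."""
        i, j = self._check_node(i), self._check_node(j)
        if i == j:
            raise ValueError("self edges are not allowed")
        if cap_ij < 0 or cap_ji < 0:
            raise ValueError("edge capacities must be >= 0")
        self._invalidate()
        self._ei.append(np.array([i], dtype=np.int64))
        self._ej.append(np.array([j], dtype=np.int64))
        self._cij.append(np.array([cap_ij], dtype=float))
        self._cji.append(np.array([cap_ji], dtype=float))

    def add_pairwise(self, i: int, j: int, term: PairwiseTerm) -> None:
        """Add one submodular pairwise term via its elementary graph."""
        inc = elementary_graph(term, self._check_node(i), self._check_node(j))
        self.constant_offset += inc["offset"]
        self.add_unary(i, 0.0, inc["unary1_i"])
        self.add_unary(j, 0.0, inc["unary1_j"])
        cap = max(inc["cap_ij"], 0.0)  # clip tiny negative from float round-off
        if cap > 0.0:
            self.add_edge(i, j, cap, 0.0)

    def add_pairwise_batch(
        self,
        i: np.ndarray,
        j: np.ndarray,
        e00: np.ndarray,
        e01: np.ndarray,
        e10: np.ndarray,
        e11: np.ndarray,
    ) -> None:
        """Vectorised :meth:`add_pairwise` for large move problems."""
        i = np.asarray(i, dtype=np.int64)
        j = np.asarray(j, dtype=np.int64)
        e00, e01 = np.asarray(e00, dtype=float), np.asarray(e01, dtype=float)
        e10, e11 = np.asarray(e10, dtype=float), np.asarray(e11, dtype=float)
        if not (i.shape == j.shape == e00.shape == e01.shape == e10.shape == e11.shape):
            raise ValueError("batch arrays must share a common shape")
        if i.size == 0:
            return
        if i.min() < 0 or j.min() < 0 or i.max() >= self.n_nodes or j.max() >= self.n_nodes:
            raise IndexError("node index out of range in batch")
        margin = (e00 + e11) - (e01 + e10)
        scale = np.maximum.reduce([np.abs(e00), np.abs(e01), np.abs(e10), np.abs(e11)])
        bad = margin > _SUBMODULAR_RTOL * np.maximum(scale, 1.0)
        if np.any(bad):
            raise SubmodularityError(float(margin[bad].max()))
        self._invalidate()
        self.constant_offset += float(e00.sum())
        c1_i = e10 - e00
        c1_j = e11 - e10
        for idx, c1 in ((i, c1_i), (j, c1_j)):
            mneg = np.minimum(c1, 0.0)
            self.constant_offset += float(mneg.sum())
            np.add.at(self._src, idx, c1 - mneg)
            np.add.at(self._snk, idx, -mneg)
        cap = np.clip(e01 + e10 - e00 - e11, 0.0, None)
        self._ei.append(i)
        self._ej.append(j)
        self._cij.append(cap)
        self._cji.append(np.zeros_like(cap))

    def pin(self, i: int, label: int) -> None:
        """Permanently constrain a node to a label via an infinite terminal
        arc (applied when the network is built)."""
        i = self._check_node(i)
        if label not in (0, 1):
            raise ValueError("label must be 0 or 1")
        self._invalidate()
        self._pinned[i] = int(label)

    # ---------------- build & solve ----------------

    def _invalidate(self) -> None:
        self._built = False
        self._solved = False

    def _build(self) -> None:
        if self._built:
            return
        if self._ei:
            ei = np.concatenate(self._ei)
            ej = np.concatenate(self._ej)
            cij = np.concatenate(self._cij)
            cji = np.concatenate(self._cji)
        else:
            ei = ej = np.empty(0, dtype=np.int64)
            cij = cji = np.empty(0, dtype=float)
        total = float(cij.sum() + cji.sum() + self._src.sum() + self._snk.sum())
        scale = 2.0**32
        if total * scale > 2.0**61:
            scale = 2.0 ** np.floor(np.log2(max(2.0**61 / max(total, 1.0), 2.0)))
        self._scale = scale

        cap_int = np.rint(np.concatenate([cij, cji]) * scale).astype(np.int64)
        src_int = np.rint(self._src * scale).astype(np.int64)
        snk_int = np.rint(self._snk * scale).astype(np.int64)
        inf = np.int64(cap_int.sum() + src_int.sum() + snk_int.sum() + 1)
        self._inf = inf
        for node, label in self._pinned.items():
            if label == 0:
                src_int[node] += inf
            else:
                snk_int[node] += inf

        m = ei.size
        tails = np.concatenate([ei, ej])
        heads = np.concatenate([ej, ei])
        order = np.argsort(tails, kind="stable")
        pos = np.empty(2 * m, dtype=np.int64)
        pos[order] = np.arange(2 * m, dtype=np.int64)
        opp = np.concatenate([np.arange(m, 2 * m), np.arange(0, m)]) if m else np.empty(0, np.int64)
        self._heads = heads[order].astype(np.int64)
        self._rev = pos[opp[order]] if m else np.empty(0, np.int64)
        self._cap0 = cap_int[order] if m else np.empty(0, np.int64)
        counts = np.bincount(tails, minlength=self.n_nodes) if m else np.zeros(self.n_nodes, np.int64)
        self._indptr = np.concatenate([[0], np.cumsum(counts)]).astype(np.int64)
        self._src0 = src_int
        self._snk0 = snk_int
        self._built = True

    def solve(self) -> CutResult:
        """Base max-flow solve; keeps the residual state for reuse."""
        if self.n_nodes == 0:
            raise ValueError("cannot solve an empty flow network")
        self._build()
        self._rcap = self._cap0.copy()
        self._rsrc = self._src0.copy()
        self._rsnk = self._snk0.copy()
        flow = dinic(self._indptr, self._heads, self._rev, self._rcap, self._rsrc, self._rsnk)
        reach = reachable_from_source(self._indptr, self._heads, self._rcap, self._rsrc)
        self._flow_int = int(flow)
        self._labels = (reach == 0).astype(np.uint8)
        self._solved = True
        return CutResult(flow_value=self._flow_int / self._scale, labels=self._labels.copy())

    @property
    def min_energy(self) -> float:
        """Minimum energy of the represented MRF (cut value + offset)."""
        if not self._solved:
            self.solve()
        return self._flow_int / self._scale + self.constant_offset

    @property
    def map_labels(self) -> np.ndarray:
        if not self._solved:
            self.solve()
        return self._labels.copy()

    def solve_constrained(self, node: int, label: int, reuse: bool = True) -> float:
        """Minimum energy with ``node`` pinned to ``label`` (min-marginal,
        including the constant offset).

        With ``reuse`` the residual state of the base solve is extended by
        the extra flow enabled by the added terminal capacity; the cold path
        rebuilds and re-solves from scratch.  Both are value-identical.
        """
        node = self._check_node(node)
        if label not in (0, 1):
            raise ValueError("label must be 0 or 1")
        if not self._solved:
            self.solve()
        if reuse:
            q = np.array([node], dtype=np.int64)
            if label == 1:
                extra = excess_backward_all(
                    self._indptr, self._heads, self._rev, self._rcap, self._rsrc, q
                )[0]
            else:
                extra = excess_forward_all(
                    self._indptr, self._heads, self._rev, self._rcap, self._rsnk, q
                )[0]
            if extra < 0:  # change-log overflow; fall back to cold solve
                return self.solve_constrained(node, label, reuse=False)
            return (self._flow_int + int(extra)) / self._scale + self.constant_offset
        # cold path
        rcap = self._cap0.copy()
        rsrc = self._src0.copy()
        rsnk = self._snk0.copy()
        if label == 0:
            rsrc[node] += self._inf
        else:
            rsnk[node] += self._inf
        flow = dinic(self._indptr, self._heads, self._rev, rcap, rsrc, rsnk)
        return int(flow) / self._scale + self.constant_offset

    def min_marginals(self, nodes: np.ndarray | None = None) -> tuple[np.ndarray, np.ndarray]:
        """(psi0, psi1) for the given nodes (default: all), via residual
        reuse.  min(psi0, psi1) equals the unconstrained minimum energy."""
        if not self._solved:
            self.solve()
        if nodes is None:
            nodes = np.arange(self.n_nodes, dtype=np.int64)
        nodes = np.asarray(nodes, dtype=np.int64)
        # The min-marginal at a node's MAP label is the unconstrained
        # minimum; only the opposite label needs a constrained re-solve.
        labels = self._labels[nodes]
        q0 = nodes[labels == 1]  # pin to source side -> push node-to-sink
        q1 = nodes[labels == 0]  # pin to sink side -> push source-to-node
        e0 = np.zeros(nodes.size, dtype=np.int64)
        e1 = np.zeros(nodes.size, dtype=np.int64)
        if q0.size:
            e0[labels == 1] = excess_forward_all(
                self._indptr, self._heads, self._rev, self._rcap, self._rsnk, q0
            )
        if q1.size:
            e1[labels == 0] = excess_backward_all(
                self._indptr, self._heads, self._rev, self._rcap, self._rsrc, q1
            )
        base = self._flow_int / self._scale + self.constant_offset
        psi0 = base + e0 / self._scale
        psi1 = base + e1 / self._scale
        for arr, excess, lab in ((psi0, e0, 0), (psi1, e1, 1)):
            bad = excess < 0
            if np.any(bad):  # change-log overflow; cold-solve the stragglers
                for k in np.nonzero(bad)[0]:
                    arr[k] = self.solve_constrained(int(nodes[k]), lab, reuse=False)
        return psi0, psi1

    def dump_edges(self) -> str:
        """Debug dump: terminal and inter-node capacities as text."""
        self._build()
        lines = [f"# nodes={self.n_nodes} offset={self.constant_offset!r} scale={self._scale}"]
        for v in range(self.n_nodes):
            lines.append(f"t {v} {self._src0[v] / self._scale} {self._snk0[v] / self._scale}")
        for u in range(self.n_nodes):
            for e in range(self._indptr[u], self._indptr[u + 1]):
                lines.append(f"e {u} {self._heads[e]} {self._cap0[e] / self._scale}")
        return "\n".join(lines)


def max_flow(net: FlowNetwork) -> CutResult:
    """Solve the network; flow_value is the minimum cut (offset excluded)."""
    return net.solve()


def solve_constrained(net: FlowNetwork, node: int, label: int, reuse: bool = True) -> float:
    """Min-marginal of ``node`` at ``label`` (offset included)."""
    return net.solve_constrained(node, label, reuse=reuse)
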