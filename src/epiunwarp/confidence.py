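"""Per-voxel confidence of the unwrapping solution from min-marginals.

The max-marginal of assigning label j to voxel v is alpha_{v;j} =
exp(-psi_{v;j}) / Z, where psi_{v;j} is the min-marginal energy (minimum
over all labellings with x_v = j).  The confidence

    omega_{v;j} = exp(-psi_{v;j}) / sum_l exp(-psi_{v;l})

is the normalised max-marginal; the partition function Z cancels, so no
probabilistic normalisation is ever needed.  For a binary move problem the
MAP label's confidence reduces to the logistic of the min-marginal gap,
omega = 1 / (1 + exp(-(psi_other - psi_MAP))), which is used as the
numerically stable form.

One subtlety is specific to phase unwrapping: the move energy depends only
on wrap-count differences, so incrementing *every* voxel in a connected
component is free (E(k + 1) = E(k)) and the raw min-marginals of the
converged move problem are degenerate — flipping any voxel costs nothing
because the whole component can flip along with it.  That global freedom is
pure gauge: it does not change the recovered phase differences and the
reported wrap counts are anyway defined only up to a component-wise
constant.  The confidence problem therefore pins one anchor voxel (the
highest-magnitude voxel of each connected component) to "no move", and
omega_v measures the stability of voxel v's wrap count *relative to its
component*: how much energy it costs to flip v without flipping the anchor.
"""

from __future__ import annotations

from dataclasses import dataclass
import warnings

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components

from .graphcore import FlowNetwork
from .unwrap import UnwrapResult, _edge_arrays

__all__ = [
    "MinMarginalPair",
    "MinMarginals",
    "ConfidenceMap",
    "min_marginals_all",
    "confidence_from_min_marginals",
    "unwrap_confidence",
]


@dataclass(frozen=True)
class MinMarginalPair:
    """Min-marginal energies of one node at its two labels."""

    psi0: float
    psi1: float


class MinMarginals:
    """Min-marginal pairs for every node of a solved binary problem."""

    def __init__(self, psi0: np.ndarray, psi1: np.ndarray):
        self.psi0 = np.asarray(psi0, dtype=float)
        self.psi1 = np.asarray(psi1, dtype=float)
        if self.psi0.shape != self.psi1.shape:
            raise ValueError("psi arrays must have equal shape")

    def __len__(self) -> int:
        return self.psi0.size

    def __getitem__(self, v: int) -> MinMarginalPair:
        return MinMarginalPair(float(self.psi0[v]), float(self.psi1[v]))


@dataclass
class ConfidenceMap:
    """Per-voxel confidence omega in (0, 1] of the MAP wrap counts."""

    omega: np.ndarray
    provenance: str = ""


def min_marginals_all(problem: FlowNetwork) -> MinMarginals:
    """psi_{v;j} for every node and both labels, reusing residual flow.

    Solves the problem first if needed.  For each node, the min-marginal at
    its MAP label equals the unconstrained minimum; the opposite label's
    value is obtained by a constrained re-solve on the shared residual
    graph.
    """
    psi0, psi1 = problem.min_marginals()
    return MinMarginals(psi0, psi1)


def confidence_from_min_marginals(
    pairs: MinMarginals, map_labels: np.ndarray
) -> np.ndarray:
    """Confidence of the MAP label per node: the logistic of the
    min-marginal gap.  Values lie in [0.5, 1] since the MAP label has the
    smaller psi; psi0 == psi1 gives exactly 0.5."""
    map_labels = np.asarray(map_labels)
    psi_map = np.where(map_labels == 0, pairs.psi0, pairs.psi1)
    psi_other = np.where(map_labels == 0, pairs.psi1, pairs.psi0)
    gap = psi_other - psi_map  # >= 0 by MAP optimality
    with np.errstate(over="ignore"):
        return 1.0 / (1.0 + np.exp(-gap))


def _anchored_final_problem(result: UnwrapResult) -> tuple[FlowNetwork, np.ndarray]:
    """Re-build the final move problem with one gauge anchor pinned per
    connected component.  Returns the network and anchor node indices."""
    net = result.final_move_problem
    node_voxels = result.node_voxels
    n = node_voxels.size
    node_of = {}
    gi, gj, w = _edge_arrays(result.unwrapped.shape, result.weights)
    node_of = np.full(int(np.prod(result.unwrapped.shape)), -1, dtype=np.int64)
    node_of[node_voxels] = np.arange(n)
    adj = coo_matrix(
        (np.ones(gi.size), (node_of[gi], node_of[gj])), shape=(n, n)
    )
    n_comp, comp = connected_components(adj, directed=False)
    if result.magnitude is not None:
        quality = result.magnitude.data.ravel()[node_voxels]
    else:
        quality = np.zeros(n)
    # anchor: highest-quality node of each component (lowest index on ties)
    order = np.lexsort((np.arange(n), -quality))
    anchors = np.full(n_comp, -1, dtype=np.int64)
    for idx in order[::-1]:  # reverse so best-quality lands last
        anchors[comp[idx]] = idx
    for a in anchors:
        net.pin(int(a), 0)
    return net, anchors


def unwrap_confidence(
    result: UnwrapResult, outside_value: float = 0.0, stride: int = 1
) -> ConfidenceMap:
    """Confidence volume for a finished unwrapping run.

    Computed on the final (converged) binary move problem, gauge-anchored
    per connected component: at convergence the MAP move is "no change"
    everywhere, and omega_v is the logistic of the energy cost of flipping
    voxel v's wrap count relative to its component anchor.  Low values mark
    voxels where an extra wrap is nearly as cheap as the MAP solution.
    Voxels outside the analysis mask receive ``outside_value``.

    ``stride`` > 1 evaluates the constrained solves on a regular subsample
    of the masked voxels and fills the rest by nearest-neighbour
    propagation — an approximation for very large volumes; the default
    computes every voxel exactly.
    """
    if not result.converged:
        warnings.warn("unwrapping did not converge; confidence computed on the last move problem")
    if stride < 1:
        raise ValueError("stride must be >= 1")
    net, _ = _anchored_final_problem(result)
    net.solve()
    shape = result.unwrapped.shape
    omega = np.full(shape, float(outside_value), dtype=float)
    if stride == 1:
        pairs = min_marginals_all(net)
        omega_nodes = confidence_from_min_marginals(pairs, net.map_labels)
        omega.ravel()[result.node_voxels] = omega_nodes
        return ConfidenceMap(omega=omega, provenance="final-move min-marginals (gauge-anchored)")

    # Strided evaluation + nearest-neighbour fill of the remaining mask.
    from scipy.ndimage import distance_transform_edt

    node_mask3 = np.zeros(shape, dtype=bool)
    node_mask3.ravel()[result.node_voxels] = True
    sub = np.zeros(shape, dtype=bool)
    sub[::stride, ::stride, ::stride] = True
    sel3 = node_mask3 & sub
    node_of = np.full(int(np.prod(shape)), -1, dtype=np.int64)
    node_of[result.node_voxels] = np.arange(result.node_voxels.size)
    q = node_of[np.nonzero(sel3.ravel())[0]]
    psi0, psi1 = net.min_marginals(q)
    omega_q = confidence_from_min_marginals(MinMarginals(psi0, psi1), net.map_labels[q])
    dense = np.zeros(shape, dtype=float)
    dense[sel3] = omega_q
    _, idx = distance_transform_edt(~sel3, return_indices=True)
    filled = dense[tuple(idx)]
    omega[node_mask3] = filled[node_mask3]
    return ConfidenceMap(
        omega=omega,
        provenance=f"final-move min-marginals (gauge-anchored, stride={stride})",
    )
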