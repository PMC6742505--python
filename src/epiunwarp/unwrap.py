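"""Phase unwrapping as MAP inference on a six-neighbourhood pairwise MRF.

The true phase phi_t = phi_w + 2*pi*k is recovered by estimating the
integer wrap-count field k.  Under a hard likelihood (the unwrapped phase
must be congruent to the measurement modulo 2*pi) and a Gaussian smoothness
prior on the true phase, the MAP problem is

    min_k  sum_<i,j> w_ij * (2*pi*(k_i - k_j) + (phi_w,i - phi_w,j))^2

over 6-neighbour pairs <i,j>.  The squared-difference potential is convex,
so every binary "add one wrap" move problem is submodular
(V(t+2*pi) + V(t-2*pi) - 2*V(t) = 8*pi^2 * w >= 0) and solvable exactly by
one graph cut; iterating moves until no binary increment lowers the energy
reaches the global minimum, up to the inherent gauge freedom k -> k + c.

Low-magnitude voxels carry unreliable phase.  Edge weights are the
geometric mean of the two voxels' magnitudes normalised by a high
percentile and clipped to [0, 1]; voxels below ``mask_threshold`` are
excluded from the graph entirely.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .graphcore import FlowNetwork
from .volumes import MagnitudeVolume, PhaseVolume, TWO_PI

__all__ = [
    "UnwrapConfig",
    "EdgeWeights",
    "WrapCountMap",
    "UnwrapResult",
    "pair_weight",
    "edge_weights",
    "energy",
    "binary_move",
    "unwrap",
]

_AXIS_PAIRS = ((1, 0, 0), (0, 1, 0), (0, 0, 1))


@dataclass(frozen=True)
class UnwrapConfig:
    potential: str = "squared"
    quality_weighting: str = "magnitude"
    magnitude_norm_percentile: float = 95.0
    max_iterations: int = 100
    mask_threshold: float = 0.05

    def __post_init__(self) -> None:
        if self.potential != "squared":
            raise ValueError("only the squared-difference potential is supported")
        if self.quality_weighting not in ("none", "magnitude"):
            raise ValueError("quality_weighting must be 'none' or 'magnitude'")
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")
        if not 0.0 <= self.mask_threshold < 1.0:
            raise ValueError("mask_threshold must lie in [0, 1)")


@dataclass
class WrapCountMap:
    """Integer wrap counts k with the wrapped volume they unwrap."""

    k: np.ndarray
    wrapped: PhaseVolume

    def __post_init__(self) -> None:
        self.k = np.asarray(self.k)
        if not np.issubdtype(self.k.dtype, np.integer):
            raise ValueError("wrap counts must be integers")
        if self.k.shape != self.wrapped.shape:
            raise ValueError("wrap-count shape must match the wrapped phase")

    def unwrapped(self) -> PhaseVolume:
        return PhaseVolume(
            self.wrapped.data + TWO_PI * self.k, wrapped=False, geometry=self.wrapped.geometry
        )


@dataclass
class EdgeWeights:
    """Per-face weights of the 6-neighbour graph plus the voxel mask.

    ``axis_weights[a]`` has the volume shape shortened by one along axis
    ``a``; entry p is the weight between voxel p and its +1 neighbour."""

    axis_weights: tuple[np.ndarray, np.ndarray, np.ndarray]
    mask: np.ndarray


@dataclass
class UnwrapResult:
    counts: WrapCountMap
    unwrapped: PhaseVolume
    energy_trace: list[float]
    converged: bool
    final_move_problem: FlowNetwork
    node_voxels: np.ndarray  # flat voxel index per graph node
    weights: EdgeWeights = field(repr=False)
    magnitude: MagnitudeVolume | None = field(default=None, repr=False)


def pair_weight(mag_i, mag_j, config: UnwrapConfig, norm_value: float = 1.0):
    """Edge quality weight in [0, 1] from the two voxels' magnitudes.

    Geometric mean of the magnitudes normalised by ``norm_value`` (the
    configured percentile of the magnitude image) and clipped to [0, 1];
    zero when either voxel falls below the mask threshold.  Monotone
    nondecreasing in both magnitudes.
    """
    if norm_value <= 0:
        raise ValueError("norm_value must be > 0")
    mi = np.clip(np.asarray(mag_i, dtype=float) / norm_value, 0.0, 1.0)
    mj = np.clip(np.asarray(mag_j, dtype=float) / norm_value, 0.0, 1.0)
    w = np.sqrt(mi * mj)
    masked = (mi < config.mask_threshold) | (mj < config.mask_threshold)
    return np.where(masked, 0.0, w) if w.ndim else (0.0 if masked else float(w))


def edge_weights(
    shape: tuple[int, int, int],
    magnitude: MagnitudeVolume | None,
    config: UnwrapConfig,
) -> EdgeWeights:
    """Weights of all 6-neighbour faces and the analysable-voxel mask."""
    if config.quality_weighting == "none" or magnitude is None:
        mask = np.ones(shape, dtype=bool)
        ws = tuple(
            np.ones(tuple(n - d for n, d in zip(shape, ax)), dtype=float) for ax in _AXIS_PAIRS
        )
        return EdgeWeights(axis_weights=ws, mask=mask)
    if magnitude.shape != tuple(shape):
        raise ValueError(f"magnitude shape {magnitude.shape} != phase shape {tuple(shape)}")
    mag = magnitude.data
    norm = float(np.percentile(mag, config.magnitude_norm_percentile))
    if norm <= 0:
        raise ValueError("all voxels are masked out (magnitude quality map is non-positive)")
    mn = np.clip(mag / norm, 0.0, 1.0)
    mask = mn >= config.mask_threshold
    ws = []
    for a in range(3):
        sl_lo = tuple(slice(0, -1) if i == a else slice(None) for i in range(3))
        sl_hi = tuple(slice(1, None) if i == a else slice(None) for i in range(3))
        w = np.sqrt(mn[sl_lo] * mn[sl_hi])
        w[~(mask[sl_lo] & mask[sl_hi])] = 0.0
        ws.append(w)
    return EdgeWeights(axis_weights=tuple(ws), mask=mask)


def _edge_arrays(shape, weights: EdgeWeights):
    """Flat (i, j, w) arrays of all faces with positive weight."""
    flat = np.arange(int(np.prod(shape))).reshape(shape)
    ii, jj, ww = [], [], []
    for a in range(3):
        sl_lo = tuple(slice(0, -1) if i == a else slice(None) for i in range(3))
        sl_hi = tuple(slice(1, None) if i == a else slice(None) for i in range(3))
        w = weights.axis_weights[a]
        keep = w > 0
        ii.append(flat[sl_lo][keep])
        jj.append(flat[sl_hi][keep])
        ww.append(w[keep])
    return np.concatenate(ii), np.concatenate(jj), np.concatenate(ww)


def energy(counts: WrapCountMap, wrapped: PhaseVolume, weights: EdgeWeights) -> float:
    """MRF energy sum_<ij> w * (2*pi*(k_i - k_j) + (phi_i - phi_j))^2.

    Invariant under k -> k + c for any constant integer c, since only count
    differences enter.
    """
    if counts.k.shape != wrapped.shape:
        raise ValueError("count/phase shape mismatch")
    total = 0.0
    for a in range(3):
        sl_lo = tuple(slice(0, -1) if i == a else slice(None) for i in range(3))
        sl_hi = tuple(slice(1, None) if i == a else slice(None) for i in range(3))
        t = TWO_PI * (counts.k[sl_lo] - counts.k[sl_hi]) + (
            wrapped.data[sl_lo] - wrapped.data[sl_hi]
        )
        total += float(np.sum(weights.axis_weights[a] * t * t))
    return total


def _move_network(
    counts: WrapCountMap, wrapped: PhaseVolume, weights: EdgeWeights
) -> tuple[FlowNetwork, np.ndarray]:
    """Build the binary +1-move problem as a flow network over masked voxels.

    Returns the network and the flat voxel index of each node.
    """
    shape = wrapped.shape
    mask_flat = weights.mask.ravel()
    node_voxels = np.nonzero(mask_flat)[0]
    node_of = np.full(mask_flat.size, -1, dtype=np.int64)
    node_of[node_voxels] = np.arange(node_voxels.size)

    net = FlowNetwork(node_voxels.size)
    gi, gj, w = _edge_arrays(shape, weights)
    kf = counts.k.ravel()
    pf = wrapped.data.ravel()
    t = TWO_PI * (kf[gi] - kf[gj]) + (pf[gi] - pf[gj])
    e00 = w * t * t
    e10 = w * (t + TWO_PI) ** 2  # delta_i = 1, delta_j = 0
    e01 = w * (t - TWO_PI) ** 2
    net.add_pairwise_batch(node_of[gi], node_of[gj], e00, e01, e10, e00.copy())
    return net, node_voxels


def binary_move(
    counts: WrapCountMap, wrapped: PhaseVolume, weights: EdgeWeights
) -> tuple[np.ndarray, FlowNetwork, np.ndarray]:
    """Optimal binary increment field delta minimising E(k + delta).

    Returns (delta volume, the solved move network, node voxel indices).
    If no increment lowers the energy the returned delta is all zeros.
    """
    net, node_voxels = _move_network(counts, wrapped, weights)
    current = energy(counts, wrapped, weights)
    tol = 1e-9 * max(1.0, abs(current))
    delta = np.zeros(wrapped.shape, dtype=np.int64)
    if net.n_nodes and net.min_energy < current - tol:
        delta.ravel()[node_voxels] = net.map_labels
    return delta, net, node_voxels


def unwrap(
    wrapped: PhaseVolume,
    magnitude: MagnitudeVolume | None = None,
    config: UnwrapConfig = UnwrapConfig(),
) -> UnwrapResult:
    """Iterated graph-cut unwrapping of a wrapped phase volume.

    Starts from k = 0 and applies optimal +1 binary moves until no move
    lowers the energy (or ``max_iterations`` is reached).  The energy trace
    is strictly decreasing until the final entry.  The returned wrap counts
    are defined up to a global integer offset per connected component of
    the masked graph.
    """
    if not wrapped.wrapped:
        wrapped = wrapped.wrap()
    weights = edge_weights(wrapped.shape, magnitude, config)
    if not weights.mask.any():
        raise ValueError("all voxels are masked out; nothing to unwrap")

    k = np.zeros(wrapped.shape, dtype=np.int64)
    counts = WrapCountMap(k, wrapped)
    trace = [energy(counts, wrapped, weights)]
    converged = False
    net, node_voxels = _move_network(counts, wrapped, weights)
    for _ in range(config.max_iterations):
        current = trace[-1]
        tol = 1e-9 * max(1.0, abs(current))
        if net.n_nodes and net.min_energy < current - tol:
            k.ravel()[node_voxels] += net.map_labels
            counts = WrapCountMap(k, wrapped)
            trace.append(energy(counts, wrapped, weights))
            net, node_voxels = _move_network(counts, wrapped, weights)
        else:
            converged = True
            break

    return UnwrapResult(
        counts=counts,
        unwrapped=counts.unwrapped(),
        energy_trace=trace,
        converged=converged,
        final_move_problem=net,
        node_voxels=node_voxels,
        weights=weights,
        magnitude=magnitude,
    )
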