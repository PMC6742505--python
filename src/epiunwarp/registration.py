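"""Confidence-modulated discrete B-spline registration refinement.

The fieldmap-derived displacement initialises a free-form deformation whose
cubic B-spline control points move only along the phase-encode axis.  Each
control point's data term is SEMI — spatially encoded mutual information: a
normalised mutual information score computed from a *local* joint histogram
in which every voxel's contribution is weighted by a Gaussian kernel
centred on the control point (Parzen-windowed in intensity).  Locality is
what makes the similarity decomposable over control points and hence
optimisable as a multi-label MRF.

The pairwise term regularises the registration's deformation over its full
time course: it penalises the absolute difference, between neighbouring
control points, of the *accumulated registration update* (the projection R
of all refinement applied so far plus the candidate update d) — rather
than only the current iteration's increment.  The fieldmap initialisation
itself is the trusted starting measurement and is not smoothed away by the
penalty.  Per-voxel confidence from the unwrapping stage modulates the
balance: the energy is

    E = - sum_i (1 - sigma_i * lambda) * SEMI_i
        + sum_<ij> w_ij * |(R_i + d_i) - (R_j + d_j)|

with w_ij the mean of sigma*lambda at the two control points, so where the
fieldmap is trusted the registration is discouraged from moving at all,
and where confidence is low the data term takes over.  At sigma*lambda = 1
the refinement is exactly zero and the fieldmap solution is returned
unchanged.  Optimisation is by alpha-expansion: each sweep offers one
candidate displacement to every control point and solves the binary choice
exactly with a graph cut; pairwise terms that violate submodularity for a
particular move have their edge weight zeroed.  Moves that fail to lower
the exactly-recomputed total energy are rolled back, so the energy trace
is non-increasing by construction.

The floating (EPI) image is resampled from the original data at every
evaluation using the full current field, with 1D Jacobian intensity
modulation so distortion-induced pile-up is modelled, not just geometry.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
import warnings

import numpy as np
from scipy.ndimage import map_coordinates

from .graphcore import FlowNetwork
from .volumes import DisplacementFieldPE, Geometry

__all__ = [
    "BSplineGrid",
    "RegConfig",
    "LocalHistogram",
    "dense_field",
    "semi_histogram",
    "semi_data_term",
    "pairwise_cost",
    "project_confidence",
    "register",
]


def cubic_bspline(u: np.ndarray) -> np.ndarray:
    """Cubic B-spline kernel on |u| <= 2 (partition of unity on unit grid)."""
    u = np.abs(np.asarray(u, dtype=float))
    out = np.zeros_like(u)
    m1 = u < 1
    m2 = (u >= 1) & (u < 2)
    out[m1] = (4.0 - 6.0 * u[m1] ** 2 + 3.0 * u[m1] ** 3) / 6.0
    out[m2] = (2.0 - u[m2]) ** 3 / 6.0
    return out


@dataclass
class BSplineGrid:
    """Uniform cubic B-spline grid of PE-only scalar displacements.

    Control point (i, j, k) sits at voxel position ((i-1)*sx, (j-1)*sy,
    (k-1)*sz); the one-voxel-of-spacing margin on every side guarantees the
    basis sums to one over the whole image (so all-equal coefficients
    reproduce that constant exactly).
    """

    image_shape: tuple[int, int, int]
    spacing: tuple[float, float, float]
    pe_axis: int = 1
    coeffs: np.ndarray | None = None

    def __post_init__(self) -> None:
        if any(s <= 0 for s in self.spacing):
            raise ValueError("spacing must be positive")
        n_ctrl = tuple(
            int(np.floor((n - 1) / s)) + 4 for n, s in zip(self.image_shape, self.spacing)
        )
        self.n_ctrl = n_ctrl
        if self.coeffs is None:
            self.coeffs = np.zeros(n_ctrl, dtype=float)
        else:
            self.coeffs = np.asarray(self.coeffs, dtype=float)
            if self.coeffs.shape != n_ctrl:
                raise ValueError(
                    f"coeffs shape {self.coeffs.shape} does not match control grid {n_ctrl}"
                )

    def basis_matrices(self) -> tuple[np.ndarray, ...]:
        """Per-axis (n_vox x n_ctrl) cubic basis matrices."""
        mats = []
        for n, s, nc in zip(self.image_shape, self.spacing, self.n_ctrl):
            x = np.arange(n, dtype=float) / s
            base = np.floor(x).astype(int)
            u = x - base
            B = np.zeros((n, nc), dtype=float)
            w = np.stack(
                [
                    (1.0 - u) ** 3 / 6.0,
                    (3.0 * u**3 - 6.0 * u**2 + 4.0) / 6.0,
                    (-3.0 * u**3 + 3.0 * u**2 + 3.0 * u + 1.0) / 6.0,
                    u**3 / 6.0,
                ],
                axis=1,
            )
            for t in range(4):
                B[np.arange(n), base + t] = w[:, t]
            mats.append(B)
        return tuple(mats)

    def positions(self) -> tuple[np.ndarray, ...]:
        """Control-point voxel coordinates per axis."""
        return tuple(
            (np.arange(nc, dtype=float) - 1.0) * s for nc, s in zip(self.n_ctrl, self.spacing)
        )


def dense_field(grid: BSplineGrid, geometry: Geometry | None = None) -> DisplacementFieldPE:
    """Evaluate the B-spline coefficients into a dense PE displacement."""
    Bx, By, Bz = grid.basis_matrices()
    f = np.tensordot(Bx, grid.coeffs, axes=(1, 0))
    f = np.tensordot(By, f, axes=(1, 1)).transpose(1, 0, 2)
    f = np.tensordot(Bz, f, axes=(1, 2)).transpose(1, 2, 0)
    return DisplacementFieldPE(
        data=f, pe_axis=grid.pe_axis, geometry=geometry or Geometry()
    )


@dataclass(frozen=True)
class RegConfig:
    """Parameters of the discrete registration refinement.

    ``label_step``/``label_range`` define the candidate PE displacements at
    the finest level (coarser levels double the step); ``gamma_sd`` is the
    spatial-encoding Gaussian sd in voxels (defaults to the control-point
    spacing); ``lambda_global`` is the global regularisation weight
    modulated per control point by the projected confidence.
    """

    grid_spacing: float = 5.0
    label_step: float = 0.5
    label_range: float = 10.0
    bins: int = 32
    gamma_sd: float | None = None
    lambda_global: float = 0.5
    max_cycles: int = 5
    levels: int = 2
    refine_range_factor: float = 0.25
    gamma_truncate: float = 3.0

    def __post_init__(self) -> None:
        if self.label_step <= 0:
            raise ValueError("label_step must be > 0")
        if self.label_range < self.label_step:
            raise ValueError("label_range must be >= label_step")
        if not 0.0 < self.lambda_global <= 1.0:
            raise ValueError("lambda_global must lie in (0, 1]")
        if self.bins < 4:
            raise ValueError("need at least 4 intensity bins")
        if self.levels < 1 or self.max_cycles < 1:
            raise ValueError("levels and max_cycles must be >= 1")


@dataclass
class LocalHistogram:
    """Parzen joint histogram of a Gaussian-weighted local region."""

    joint: np.ndarray

    @property
    def total(self) -> float:
        return float(self.joint.sum())

    def nmi(self) -> float:
        """Studholme normalised mutual information (H(R)+H(F))/H(R,F)."""
        p = self.joint / max(self.total, 1e-300)
        pr = p.sum(axis=1)
        pf = p.sum(axis=0)

        def H(q):
            q = q[q > 0]
            return float(-(q * np.log(q)).sum())

        hj = H(p.ravel())
        if hj == 0.0:
            warnings.warn("degenerate single-bin histogram; NMI defined as 2")
            return 2.0
        return (H(pr) + H(pf)) / hj


def _bin_coords(img: np.ndarray, lo: float, hi: float, bins: int) -> tuple[np.ndarray, np.ndarray]:
    """Continuous bin coordinate and 4-tap Parzen weights per voxel.

    Intensities are clamped to [lo, hi] and mapped so the cubic window's
    support stays inside [0, bins-1]."""
    img = np.asarray(img, dtype=float)
    if hi - lo <= 1e-9 * max(abs(hi), abs(lo), 1.0):
        # degenerate intensity range: all mass in a single bin
        taps = np.broadcast_to(np.arange(-1, 3) + 1, img.shape + (4,)).copy()
        w = np.zeros(img.shape + (4,))
        w[..., 1] = 1.0
        return taps, w
    x = np.clip((img - lo) / (hi - lo), 0.0, 1.0)
    b = 1.0 + x * (bins - 3.0 - 2e-6) + 1e-6
    base = np.floor(b).astype(np.int64)
    u = b - base
    w = np.stack(
        [cubic_bspline(u + 1.0), cubic_bspline(u), cubic_bspline(u - 1.0), cubic_bspline(u - 2.0)],
        axis=-1,
    )
    taps = base[..., None] + np.arange(-1, 3)
    return taps, w


def _joint_hist(taps_r, w_r, taps_f, w_f, gamma, bins) -> np.ndarray:
    """Accumulate sum_x w_r w_f Gamma(x) over the 4x4 Parzen tap pairs."""
    flat = np.zeros(bins * bins, dtype=float)
    g = gamma.ravel()
    tr = taps_r.reshape(-1, 4)
    wr = w_r.reshape(-1, 4)
    tf = taps_f.reshape(-1, 4)
    wf = w_f.reshape(-1, 4)
    for a in range(4):
        for b in range(4):
            idx = tr[:, a] * bins + tf[:, b]
            flat += np.bincount(idx, weights=wr[:, a] * wf[:, b] * g, minlength=bins * bins)
    return flat.reshape(bins, bins)


class _SemiEvaluator:
    """Shared state for SEMI evaluations on one image pair and grid."""

    def __init__(self, ref, flt, grid: BSplineGrid, config: RegConfig):
        self.ref = np.asarray(ref, dtype=float)
        self.flt = np.asarray(flt, dtype=float)
        if self.ref.shape != self.flt.shape or self.ref.shape != tuple(grid.image_shape):
            raise ValueError("ref/flt/grid shapes must agree")
        self.grid = grid
        self.config = config
        self.bins = config.bins
        self.gamma_sd = config.gamma_sd if config.gamma_sd is not None else float(
            np.mean(grid.spacing)
        )
        lo_r, hi_r = np.percentile(self.ref, [1, 99])
        lo_f, hi_f = np.percentile(self.flt, [1, 99])
        self.range_r = (float(lo_r), float(max(hi_r, lo_r + 1e-12)))
        self.range_f = (float(lo_f), float(max(hi_f, lo_f + 1e-12)))
        self.taps_r, self.w_r = _bin_coords(self.ref, *self.range_r, self.bins)
        self.pe = grid.pe_axis
        self._axes = [np.arange(n, dtype=float) for n in self.ref.shape]
        self._pos = grid.positions()

    # ---- geometry helpers ----

    def region(self, cp: tuple[int, int, int]):
        """Slices of the Gaussian support box of one control point, clipped
        to the image, or None when the support misses the image."""
        r = self.config.gamma_truncate * self.gamma_sd
        sls = []
        for a in range(3):
            c = self._pos[a][cp[a]]
            lo = int(np.ceil(c - r))
            hi = int(np.floor(c + r)) + 1
            lo, hi = max(lo, 0), min(hi, self.ref.shape[a])
            if lo >= hi:
                return None
            sls.append(slice(lo, hi))
        return tuple(sls)

    def gamma(self, cp, sls) -> np.ndarray:
        d2 = 0.0
        for a, sl in enumerate(sls):
            x = self._axes[a][sl] - self._pos[a][cp[a]]
            shape = [1, 1, 1]
            shape[a] = x.size
            d2 = d2 + (x**2).reshape(shape)
        return np.exp(-0.5 * d2 / self.gamma_sd**2)

    # ---- resampling ----

    def resample(self, disp_pe: np.ndarray, order: int = 1) -> np.ndarray:
        """Floating image pulled through the current total PE field, with
        Jacobian intensity modulation."""
        flt_m = np.moveaxis(self.flt, self.pe, -1)
        d_m = np.moveaxis(disp_pe, self.pe, -1)
        y = np.arange(flt_m.shape[-1], dtype=float)
        coords = list(np.meshgrid(*[np.arange(n, dtype=float) for n in flt_m.shape], indexing="ij"))
        coords[-1] = y + d_m
        out = map_coordinates(flt_m, coords, order=order, mode="constant", cval=0.0)
        jac = np.clip(1.0 + np.gradient(d_m, axis=-1), 0.01, None)
        return np.moveaxis(out * jac, -1, self.pe)

    def resample_box(self, disp_box: np.ndarray, box: tuple[slice, slice, slice]) -> np.ndarray:
        """Resample only the voxels of ``box`` given the PE displacement on
        an equally-shaped box (linear interpolation)."""
        coords = list(
            np.meshgrid(*[np.arange(sl.start, sl.stop, dtype=float) for sl in box], indexing="ij")
        )
        # Jacobian from the box itself; the displacement is unchanged at
        # the box faces along PE (the box covers the basis support).
        if disp_box.shape[self.pe] >= 2:
            jac = np.clip(1.0 + np.gradient(disp_box, axis=self.pe), 0.01, None)
        else:
            jac = np.ones_like(disp_box)
        coords[self.pe] = coords[self.pe] + disp_box
        out = map_coordinates(self.flt, coords, order=1, mode="constant", cval=0.0)
        return out * jac

    # ---- scores ----

    def histogram(self, cp, flt_t: np.ndarray) -> LocalHistogram:
        sls = self.region(cp)
        if sls is None:
            raise ValueError(f"control point {cp} has no support inside the image")
        gamma = self.gamma(cp, sls)
        taps_f, w_f = _bin_coords(flt_t[sls], *self.range_f, self.bins)
        joint = _joint_hist(self.taps_r[sls], self.w_r[sls], taps_f, w_f, gamma, self.bins)
        return LocalHistogram(joint=joint)

    def semi(self, cp, flt_t: np.ndarray) -> float:
        return self.histogram(cp, flt_t).nmi()


def semi_histogram(ref, flt, control_point, grid: BSplineGrid, config: RegConfig) -> LocalHistogram:
    """Local Parzen joint histogram around one control point.

    ``flt`` is the (already transformed) floating image; the histogram
    total equals the Gaussian mass sum_x Gamma_s(x) over the support since
    the Parzen windows sum to one per sample.
    """
    ev = _SemiEvaluator(ref, flt, grid, config)
    return ev.histogram(tuple(control_point), ev.flt)


def semi_data_term(
    ref,
    flt,
    grid: BSplineGrid,
    control_point,
    label: float,
    config: RegConfig,
    base_disp: np.ndarray | None = None,
) -> float:
    """SEMI score of one control point at one candidate displacement.

    The candidate moves only this control point (on top of the grid's
    current coefficients and the optional dense base field); higher is a
    better local match.
    """
    if abs(label) > config.label_range + 1e-9:
        raise ValueError(f"label {label} outside +/-{config.label_range}")
    ev = _SemiEvaluator(ref, flt, grid, config)
    cp = tuple(control_point)
    coeffs = grid.coeffs.copy()
    coeffs[cp] = label
    trial = replace_coeffs(grid, coeffs)
    disp = dense_field(trial).data
    if base_disp is not None:
        disp = disp + base_disp
    return ev.semi(cp, ev.resample(disp))


def replace_coeffs(grid: BSplineGrid, coeffs: np.ndarray) -> BSplineGrid:
    return BSplineGrid(
        image_shape=grid.image_shape, spacing=grid.spacing, pe_axis=grid.pe_axis, coeffs=coeffs
    )


def pairwise_cost(chi_i: float, chi_j: float, current_total_i: float, current_total_j: float) -> float:
    """|(R_i + d_i) - (R_j + d_j)|: absolute difference of total
    displacement (accumulated plus candidate) of two neighbouring control
    points.  Symmetric in (i, j)."""
    return abs((current_total_i + chi_i) - (current_total_j + chi_j))


def project_confidence(conf: np.ndarray, grid: BSplineGrid) -> np.ndarray:
    """Per-control-point confidence: the basis-weighted (convex) average of
    the voxel confidences under each control point's support.  Control
    points without support in the image receive the global mean."""
    conf = np.asarray(conf, dtype=float)
    if conf.shape != tuple(grid.image_shape):
        raise ValueError("confidence must live on the image grid")
    Bx, By, Bz = grid.basis_matrices()
    num = np.einsum("ai,bj,ck,abc->ijk", Bx, By, Bz, conf, optimize=True)
    den = np.einsum("ai,bj,ck,abc->ijk", Bx, By, Bz, np.ones_like(conf), optimize=True)
    sigma = np.where(den > 1e-12, num / np.maximum(den, 1e-12), np.nan)
    finite = np.isfinite(sigma)
    fill = float(np.nanmean(sigma)) if finite.any() else float(conf.mean())
    return np.clip(np.where(finite, sigma, fill), 0.0, 1.0)


@dataclass
class RegistrationResult:
    displacement: DisplacementFieldPE
    energy_trace: list[float]
    grids: list[BSplineGrid] = field(repr=False, default_factory=list)


def _neighbour_pairs(n_ctrl):
    flat = np.arange(int(np.prod(n_ctrl))).reshape(n_ctrl)
    ii, jj = [], []
    for a in range(3):
        sl_lo = tuple(slice(0, -1) if i == a else slice(None) for i in range(3))
        sl_hi = tuple(slice(1, None) if i == a else slice(None) for i in range(3))
        ii.append(flat[sl_lo].ravel())
        jj.append(flat[sl_hi].ravel())
    return np.concatenate(ii), np.concatenate(jj)


def _overlap(a: tuple[slice, ...], b: tuple[slice, ...]) -> tuple[slice, ...] | None:
    out = []
    for sa, sb in zip(a, b):
        lo, hi = max(sa.start, sb.start), min(sa.stop, sb.stop)
        if lo >= hi:
            return None
        out.append(slice(lo, hi))
    return tuple(out)


def _rel(outer: tuple[slice, ...], inner: tuple[slice, ...]) -> tuple[slice, ...]:
    return tuple(slice(i.start - o.start, i.stop - o.start) for o, i in zip(outer, inner))


class _ExpansionEngine:
    """State of one alpha-expansion level: current coefficients, resampled
    floating image, and per-control-point local histograms, all updated
    incrementally as moves are committed."""

    def __init__(self, ev: _SemiEvaluator, data_w, edge_w, pairs, R, base_disp):
        self.ev = ev
        grid = ev.grid
        self.nc = int(np.prod(grid.n_ctrl))
        self.shape = tuple(grid.image_shape)
        self.data_w = data_w
        self.edge_w = edge_w
        self.pairs = pairs
        self.R = R
        self.coeffs = np.zeros(grid.n_ctrl, dtype=float)
        self.Bmats = grid.basis_matrices()
        self.col_rng = []
        for B in self.Bmats:
            nz = B > 0
            any_nz = nz.any(axis=0)
            lo = np.argmax(nz, axis=0)
            hi = B.shape[0] - np.argmax(nz[::-1], axis=0)
            lo[~any_nz] = 0
            hi[~any_nz] = 0
            self.col_rng.append((lo, hi))
        self.regions = []
        self.gammas = []
        for ci in range(self.nc):
            cp = np.unravel_index(ci, grid.n_ctrl)
            sls = ev.region(cp)
            self.regions.append(sls)
            self.gammas.append(ev.gamma(cp, sls) if sls is not None else None)
        self.base_disp = np.asarray(base_disp, dtype=float)
        self.disp = self.base_disp.copy()  # coeffs start at zero
        self.flt_cur = ev.resample(self.disp)
        self.hists = [None] * self.nc
        self.semis = np.zeros(self.nc)
        for ci in range(self.nc):
            if self.regions[ci] is not None:
                self.hists[ci] = self._hist(ci, self.flt_cur)
                self.semis[ci] = LocalHistogram(self.hists[ci]).nmi()

    # ---- helpers ----

    def patch(self, ci: int):
        """Box slices and basis-product values of one control point's
        support, clipped to the image (None when empty)."""
        cp = np.unravel_index(ci, self.ev.grid.n_ctrl)
        sls, cols = [], []
        for a in range(3):
            lo, hi = self.col_rng[a][0][cp[a]], self.col_rng[a][1][cp[a]]
            if lo >= hi:
                return None, None
            sls.append(slice(int(lo), int(hi)))
            cols.append(self.Bmats[a][lo:hi, cp[a]])
        patch = cols[0][:, None, None] * cols[1][None, :, None] * cols[2][None, None, :]
        return tuple(sls), patch

    def _hist(self, ci: int, flt_img: np.ndarray) -> np.ndarray:
        sls = self.regions[ci]
        taps_f, w_f = _bin_coords(flt_img[sls], *self.ev.range_f, self.ev.bins)
        return _joint_hist(
            self.ev.taps_r[sls], self.ev.w_r[sls], taps_f, w_f, self.gammas[ci], self.ev.bins
        )

    def _hist_patchwise(self, ci: int, inter, flt_old_box, flt_new_box) -> np.ndarray:
        """Current histogram of cp ci with the voxels of ``inter`` replaced."""
        H = self.hists[ci].copy()
        sls = self.regions[ci]
        ri = _rel(sls, inter)
        tr = self.ev.taps_r[inter]
        wr = self.ev.w_r[inter]
        g = self.gammas[ci][ri]
        for img, sign in ((flt_old_box, -1.0), (flt_new_box, 1.0)):
            tf, wf = _bin_coords(img, *self.ev.range_f, self.ev.bins)
            H += sign * _joint_hist(tr, wr, tf, wf, g, self.ev.bins)
        return H

    def candidate_semi(self, ci: int, alpha: float) -> float:
        """SEMI of cp ci with only its own coefficient moved to alpha."""
        if self.regions[ci] is None:
            return 0.0
        cp = np.unravel_index(ci, self.ev.grid.n_ctrl)
        dcoef = alpha - self.coeffs[cp]
        if dcoef == 0.0:
            return float(self.semis[ci])
        box, patch = self.patch(ci)
        if box is None:
            return float(self.semis[ci])
        disp_box = self.disp[box] + dcoef * patch
        flt_new_box = self.ev.resample_box(disp_box, box)
        inter = _overlap(box, self.regions[ci])
        if inter is None:
            return float(self.semis[ci])
        rb = _rel(box, inter)
        H = self._hist_patchwise(ci, inter, self.flt_cur[inter], flt_new_box[rb])
        return LocalHistogram(H).nmi()

    def reg_energy(self, coeffs_flat: np.ndarray) -> float:
        T = self.R + coeffs_flat
        return float(np.sum(self.edge_w * np.abs(T[self.pairs[0]] - T[self.pairs[1]])))

    def energy(self) -> float:
        return -float(np.sum(self.data_w * self.semis)) + self.reg_energy(self.coeffs.ravel())

    def try_commit(self, move: np.ndarray, alpha: float, current_energy: float) -> float | None:
        """Apply the expansion move if it lowers the exact total energy;
        returns the new energy on success, None on rollback."""
        moved = np.nonzero(move)[0]
        delta = np.zeros(self.shape, dtype=float)
        boxes = []
        proposal = self.coeffs.copy()
        for ci in moved:
            cp = np.unravel_index(ci, self.ev.grid.n_ctrl)
            d = alpha - proposal[cp]
            proposal[cp] = alpha
            box, patch = self.patch(ci)
            if box is None or d == 0.0:
                continue
            delta[box] += d * patch
            boxes.append(box)
        if not boxes:
            reg = self.reg_energy(proposal.ravel())
            new_energy = -float(np.sum(self.data_w * self.semis)) + reg
            if new_energy < current_energy - 1e-12:
                self.coeffs = proposal
                return new_energy
            return None
        bbox = tuple(
            slice(min(b[a].start for b in boxes), max(b[a].stop for b in boxes)) for a in range(3)
        )
        disp_new = self.disp.copy()
        disp_new[bbox] += delta[bbox]
        flt_new = self.flt_cur.copy()
        flt_new[bbox] = self.ev.resample_box(disp_new[bbox], bbox)
        affected = [
            ci
            for ci in range(self.nc)
            if self.regions[ci] is not None and _overlap(self.regions[ci], bbox) is not None
        ]
        new_semis = self.semis.copy()
        new_hists = {}
        for ci in affected:
            H = self._hist(ci, flt_new)
            new_hists[ci] = H
            new_semis[ci] = LocalHistogram(H).nmi()
        new_energy = -float(np.sum(self.data_w * new_semis)) + self.reg_energy(proposal.ravel())
        if new_energy >= current_energy - 1e-12:
            return None
        self.coeffs = proposal
        self.disp = disp_new
        self.flt_cur = flt_new
        self.semis = new_semis
        for ci, H in new_hists.items():
            self.hists[ci] = H
        return new_energy


def register(
    ref: np.ndarray,
    flt: np.ndarray,
    init: DisplacementFieldPE | None,
    conf: np.ndarray | None,
    config: RegConfig = RegConfig(),
    pe_axis: int | None = None,
) -> RegistrationResult:
    """Refine a PE displacement field by confidence-modulated discrete
    B-spline registration.

    ``ref`` is the undistorted reference (e.g. T1), ``flt`` the distorted
    EPI resampled onto the reference grid; ``init`` the fieldmap-derived
    displacement (zero if None); ``conf`` the unwrapping confidence in
    [0, 1] (zero — fully data-driven — if None, with a warning).
    """
    ref = np.asarray(ref, dtype=float)
    flt = np.asarray(flt, dtype=float)
    if ref.shape != flt.shape:
        raise ValueError(f"shape mismatch: ref {ref.shape} vs flt {flt.shape}")
    if ref.ndim != 3:
        raise ValueError("images must be 3D")
    if init is not None:
        if init.data.shape != ref.shape:
            raise ValueError("init displacement shape mismatch")
        pe = init.pe_axis if pe_axis is None else pe_axis
        base = init.data.astype(float).copy()
    else:
        pe = 1 if pe_axis is None else pe_axis
        base = np.zeros(ref.shape, dtype=float)
    if conf is None:
        warnings.warn("no confidence map supplied; assuming sigma == 0 (fully data-driven)")
        conf = np.zeros(ref.shape, dtype=float)
    conf = np.asarray(conf, dtype=float)
    if conf.shape != ref.shape:
        raise ValueError("confidence shape mismatch")
    if float(np.max(np.abs(ref))) == 0.0 or float(np.max(np.abs(flt))) == 0.0:
        raise ValueError("empty image overlap")

    lam = config.lambda_global
    trace: list[float] = []
    grids: list[BSplineGrid] = []
    init0 = base.copy()  # the fieldmap initialisation is not regularised away

    for level in range(config.levels):
        scale = 2.0 ** (config.levels - 1 - level)
        spacing = tuple([config.grid_spacing * scale] * 3)
        step = config.label_step * scale
        rng_lim = config.label_range if level == 0 else max(
            2 * step, config.label_range * config.refine_range_factor
        )
        labels = np.arange(-rng_lim, rng_lim + step / 2, step)
        grid = BSplineGrid(image_shape=ref.shape, spacing=spacing, pe_axis=pe)
        ev = _SemiEvaluator(ref, flt, grid, config)
        nc = int(np.prod(grid.n_ctrl))
        sigma = np.clip(project_confidence(conf, grid).ravel() * lam, 0.0, 1.0)
        pairs = _neighbour_pairs(grid.n_ctrl)
        edge_w = 0.5 * (sigma[pairs[0]] + sigma[pairs[1]])
        # R: projection of the registration's own accumulated update.
        R = project_confidence_field(base - init0, grid)
        engine = _ExpansionEngine(
            ev,
            data_w=np.where(
                [ev.region(np.unravel_index(ci, grid.n_ctrl)) is not None for ci in range(nc)],
                1.0 - sigma,
                0.0,
            ),
            edge_w=edge_w,
            pairs=pairs,
            R=R,
            base_disp=base,
        )
        energy = engine.energy()
        trace.append(energy)
        for _ in range(config.max_cycles):
            changed = False
            for alpha in labels:
                cf = engine.coeffs.ravel()
                if np.all(cf == alpha):
                    continue
                semi_alpha = np.array(
                    [engine.candidate_semi(ci, float(alpha)) for ci in range(nc)]
                )
                net = FlowNetwork(nc)
                for ci in range(nc):
                    net.add_unary(
                        ci,
                        -engine.data_w[ci] * engine.semis[ci],
                        -engine.data_w[ci] * semi_alpha[ci],
                    )
                Ti0 = R + cf
                Ti1 = R + alpha
                for k in range(pairs[0].size):
                    i, j = int(pairs[0][k]), int(pairs[1][k])
                    w = edge_w[k]
                    if w == 0.0:
                        continue
                    e00 = w * abs(Ti0[i] - Ti0[j])
                    e01 = w * abs(Ti0[i] - Ti1[j])
                    e10 = w * abs(Ti1[i] - Ti0[j])
                    e11 = w * abs(Ti1[i] - Ti1[j])
                    if e00 + e11 > e01 + e10 + 1e-12:
                        continue  # zero the violating edge weight
                    net.add_unary(i, 0.0, e10 - e00)
                    net.add_unary(j, 0.0, e11 - e10)
                    cap = e01 + e10 - e00 - e11
                    if cap > 0:
                        net.add_edge(i, j, cap)
                    net.constant_offset += e00
                move = net.solve().labels.astype(bool) & (cf != alpha)
                if not move.any():
                    continue
                new_energy = engine.try_commit(move, float(alpha), energy)
                if new_energy is not None:
                    energy = new_energy
                    trace.append(energy)
                    changed = True
            if not changed:
                break
        grids.append(replace_coeffs(grid, engine.coeffs))
        base = base + dense_field(grids[-1]).data

    geom = init.geometry if init is not None else Geometry()
    return RegistrationResult(
        displacement=DisplacementFieldPE(
            data=base, pe_axis=pe, pe_sign=init.pe_sign if init is not None else 1, geometry=geom
        ),
        energy_trace=trace,
        grids=grids,
    )


def project_confidence_field(values: np.ndarray, grid: BSplineGrid) -> np.ndarray:
    """Basis-weighted projection of any voxel field onto the control
    points (flattened), as used for R(.) and the confidence weights."""
    Bx, By, Bz = grid.basis_matrices()
    num = np.einsum("ai,bj,ck,abc->ijk", Bx, By, Bz, np.asarray(values, dtype=float), optimize=True)
    den = np.einsum("ai,bj,ck,abc->ijk", Bx, By, Bz, np.ones(grid.image_shape), optimize=True)
    out = np.where(den > 1e-12, num / np.maximum(den, 1e-12), 0.0)
    return out.ravel()
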