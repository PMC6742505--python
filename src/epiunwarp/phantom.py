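"""Synthetic wrapped-phase / fieldmap / EPI phantom generation.

The phantom stands in for a scanner acquisition of a post-resection brain:
a smooth polynomial background field spanning several 2*pi cycles, a few
Gaussian field bumps, and an optional resection cavity whose rim carries a
steep (but sub-pi per voxel step) field ridge and whose core has near-zero
signal magnitude.  Everything downstream (unwrapping, confidence, fieldmap
conversion, distortion correction, registration) is exercised against this
generator, so its smoothness guarantee matters: inside the head mask the
true phase never jumps by pi or more between 6-neighbours, which makes
wrapping the only source of discontinuity in the noise-free wrapped image.

Noise follows the MR phase-noise model: complex channel noise of standard
deviation sigma added to the real and imaginary parts of A*exp(i*phi)
yields uniform phase in pure-noise regions (A = 0) and approximately
Gaussian phase noise of sd sigma/A at high SNR.  A direct Gaussian mode
adds i.i.d. N(0, variance) to the unwrapped phase, which is how the
validation experiments corrupt the ground truth.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter, map_coordinates

from .volumes import (
    Geometry,
    MagnitudeVolume,
    PhaseVolume,
    TWO_PI,
    wrap_to_principal,
)

__all__ = [
    "PhantomSpec",
    "ResectionSpec",
    "NoiseSpec",
    "default_spec",
    "generate_true_phase",
    "generate_magnitude",
    "head_mask",
    "add_phase_noise",
    "wrap_phase",
    "true_wrap_counts",
    "simulate_echo_pair",
    "simulate_distorted_epi",
    "generate_structural",
]


@dataclass(frozen=True)
class ResectionSpec:
    """Resection cavity: ellipsoid with a steep field ridge along its rim.

    The rim ridge is a radial Gaussian of amplitude ``rim_amplitude`` (radians)
    and width ``rim_width`` (voxels).  The worst-case phase slope is about
    rim_amplitude / (rim_width * sqrt(e)) * (mean_radius / min_radius) per
    voxel step, so the smoothness precondition (slope < pi) holds whenever
    rim_amplitude < pi * rim_width * sqrt(e) * min_radius / mean_radius.
    """

    centre: tuple[float, float, float]
    radii: tuple[float, float, float]
    rim_amplitude: float = 2.5
    rim_width: float = 2.5

    def max_rim_amplitude(self) -> float:
        r = np.asarray(self.radii, dtype=float)
        return float(np.pi * self.rim_width * np.sqrt(np.e) * r.min() / r.mean())


@dataclass(frozen=True)
class PhantomSpec:
    grid_shape: tuple[int, int, int] = (64, 64, 32)
    voxel_size: tuple[float, float, float] = (2.5, 2.5, 2.7)
    background_poly_coeffs: dict[tuple[int, int, int], float] = field(default_factory=dict)
    blob_params: tuple[tuple[tuple[float, float, float], float, float], ...] = ()
    resection: ResectionSpec | None = None
    mask_radius: tuple[float, float, float] | None = None
    plateau: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.grid_shape) != 3 or any(int(n) < 8 for n in self.grid_shape):
            raise ValueError(f"grid_shape: all axes must be >= 8 voxels, got {self.grid_shape}")
        if len(self.voxel_size) != 3 or any(v <= 0 for v in self.voxel_size):
            raise ValueError(f"voxel_size: all entries must be > 0, got {self.voxel_size}")
        if self.resection is not None:
            bound = self.resection.max_rim_amplitude()
            if self.resection.rim_amplitude >= bound:
                raise ValueError(
                    "resection: rim_amplitude "
                    f"{self.resection.rim_amplitude:.3g} violates the smoothness bound "
                    f"{bound:.3g} (would create true phase jumps >= pi)"
                )
        if self.plateau < 0:
            raise ValueError(f"plateau: must be >= 0, got {self.plateau}")

    @property
    def geometry(self) -> Geometry:
        return Geometry(voxel_size=tuple(float(v) for v in self.voxel_size))


#: Default background polynomial (normalised coordinates in [-1, 1]), chosen
#: so the in-mask phase range spans well over 2*pi and several wrap fronts
#: cross the head.
DEFAULT_POLY: dict[tuple[int, int, int], float] = {
    (1, 0, 0): 2.6,
    (0, 1, 0): 1.9,
    (0, 0, 1): 1.3,
    (2, 0, 0): 1.6,
    (0, 2, 0): -1.1,
    (0, 0, 2): 0.9,
    (1, 1, 0): 0.7,
}


def default_spec(
    grid_shape: tuple[int, int, int] = (64, 64, 32),
    with_resection: bool = True,
    seed: int = 0,
) -> PhantomSpec:
    """The study-condition phantom: smooth multi-cycle field with resection."""
    nx, ny, nz = grid_shape
    blobs = (
        ((0.62 * nx, 0.60 * ny, 0.55 * nz), 0.13 * min(nx, ny), 2.0),
        ((0.38 * nx, 0.30 * ny, 0.40 * nz), 0.11 * min(nx, ny), -1.6),
        ((0.52 * nx, 0.45 * ny, 0.70 * nz), 0.15 * min(nx, ny), 1.1),
    )
    resection = None
    if with_resection:
        resection = ResectionSpec(
            centre=(0.30 * nx, 0.36 * ny, 0.42 * nz),
            radii=(0.11 * nx, 0.10 * ny, 0.16 * nz),
            rim_amplitude=2.5,
            rim_width=2.5,
        )
    return PhantomSpec(
        grid_shape=grid_shape,
        background_poly_coeffs=dict(DEFAULT_POLY),
        blob_params=blobs,
        resection=resection,
        mask_radius=(0.42 * nx, 0.42 * ny, 0.46 * nz),
        seed=seed,
    )


@dataclass(frozen=True)
class NoiseSpec:
    """Phase-noise model: direct Gaussian on phase, or complex channel noise."""

    mode: str = "phase_gaussian"
    variance: float = 0.0
    sigma_channel: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in ("phase_gaussian", "complex_channel"):
            raise ValueError(f"mode: must be phase_gaussian or complex_channel, got {self.mode!r}")
        if self.variance < 0:
            raise ValueError(f"variance: must be >= 0, got {self.variance}")
        if self.sigma_channel < 0:
            raise ValueError(f"sigma_channel: must be >= 0, got {self.sigma_channel}")


def _grids(spec: PhantomSpec) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    nx, ny, nz = spec.grid_shape
    return np.meshgrid(
        np.arange(nx, dtype=float),
        np.arange(ny, dtype=float),
        np.arange(nz, dtype=float),
        indexing="ij",
    )


def _ellipsoid_rho(
    x: np.ndarray,
    y: np.ndarray,
    z: np.ndarray,
    centre: tuple[float, float, float],
    radii: tuple[float, float, float],
) -> np.ndarray:
    return np.sqrt(
        ((x - centre[0]) / radii[0]) ** 2
        + ((y - centre[1]) / radii[1]) ** 2
        + ((z - centre[2]) / radii[2]) ** 2
    )


def generate_true_phase(spec: PhantomSpec) -> PhaseVolume:
    """Evaluate the noise-free, unwrapped true phase field of the phantom."""
    x, y, z = _grids(spec)
    nx, ny, nz = spec.grid_shape
    # Normalised coordinates in [-1, 1] per axis.
    ux = (x - (nx - 1) / 2.0) / ((nx - 1) / 2.0)
    uy = (y - (ny - 1) / 2.0) / ((ny - 1) / 2.0)
    uz = (z - (nz - 1) / 2.0) / ((nz - 1) / 2.0)

    phase = np.zeros(spec.grid_shape, dtype=float)
    for (px, py, pz), c in spec.background_poly_coeffs.items():
        phase += c * ux**px * uy**py * uz**pz
    for centre, sd, amplitude in spec.blob_params:
        d2 = (x - centre[0]) ** 2 + (y - centre[1]) ** 2 + (z - centre[2]) ** 2
        phase += amplitude * np.exp(-0.5 * d2 / sd**2)
    if spec.resection is not None:
        res = spec.resection
        rho = _ellipsoid_rho(x, y, z, res.centre, res.radii)
        rbar = float(np.mean(res.radii))
        phase += res.rim_amplitude * np.exp(-0.5 * ((rho - 1.0) * rbar / res.rim_width) ** 2)
    return PhaseVolume(phase, wrapped=False, geometry=spec.geometry)


def generate_magnitude(spec: PhantomSpec) -> MagnitudeVolume:
    """Signal magnitude: plateau inside the head, ~zero outside and in the
    resection core, with smooth transition shells."""
    x, y, z = _grids(spec)
    if spec.mask_radius is None:
        mag = np.full(spec.grid_shape, spec.plateau, dtype=float)
    else:
        rho = _ellipsoid_rho(x, y, z, tuple((n - 1) / 2.0 for n in spec.grid_shape), spec.mask_radius)
        # Exactly the plateau for rho <= 1 - edge, exactly 0 for rho >= 1,
        # smoothstep in the shell between.
        edge = 0.12
        t = np.clip((1.0 - rho) / edge, 0.0, 1.0)
        mag = spec.plateau * t * t * (3.0 - 2.0 * t)
    if spec.resection is not None:
        res = spec.resection
        rho = _ellipsoid_rho(x, y, z, res.centre, res.radii)
        # Core suppressed to 2% of the plateau, smooth recovery across the rim.
        t = np.clip((rho - 0.75) / 0.35, 0.0, 1.0)
        suppress = 0.02 + 0.98 * t * t * (3.0 - 2.0 * t)
        mag = mag * suppress
    return MagnitudeVolume(mag, geometry=spec.geometry)


def head_mask(spec: PhantomSpec, threshold: float = 0.05) -> np.ndarray:
    """Boolean mask of analysable voxels (normalised magnitude >= threshold)."""
    mag = generate_magnitude(spec).data
    peak = float(mag.max())
    if peak <= 0:
        raise ValueError("phantom magnitude is identically zero")
    return mag >= threshold * peak


def wrap_phase(phase: PhaseVolume) -> PhaseVolume:
    """Wrap into the principal interval (-pi, pi]; idempotent."""
    return PhaseVolume(wrap_to_principal(phase.data), wrapped=True, geometry=phase.geometry)


def true_wrap_counts(unwrapped: PhaseVolume) -> np.ndarray:
    """Integer field k with unwrapped = wrap(unwrapped) + 2*pi*k."""
    k = np.rint((unwrapped.data - wrap_to_principal(unwrapped.data)) / TWO_PI)
    return k.astype(np.int64)


def add_phase_noise(
    phase: PhaseVolume,
    noise: NoiseSpec,
    magnitude: MagnitudeVolume | None = None,
) -> PhaseVolume:
    """Corrupt a phase volume according to the phase-noise model.

    phase_gaussian: adds i.i.d. N(0, variance) per voxel to the (unwrapped)
    phase; the result stays unwrapped.  complex_channel: adds i.i.d. Gaussian
    noise of sd sigma_channel to the real and imaginary channels of
    A*exp(i*phi) and returns the angle of the noisy complex signal, which is
    by construction wrapped into (-pi, pi].
    """
    rng = np.random.default_rng(noise.seed)
    if noise.mode == "phase_gaussian":
        if noise.variance == 0.0:
            return PhaseVolume(phase.data.copy(), wrapped=phase.wrapped, geometry=phase.geometry)
        noisy = phase.data + rng.normal(0.0, np.sqrt(noise.variance), size=phase.shape)
        return PhaseVolume(noisy, wrapped=False, geometry=phase.geometry)
    # complex_channel
    if magnitude is None:
        raise ValueError("complex_channel noise requires a magnitude volume")
    if magnitude.shape != phase.shape:
        raise ValueError(f"magnitude shape {magnitude.shape} != phase shape {phase.shape}")
    signal = magnitude.data * np.exp(1j * phase.data)
    if noise.sigma_channel > 0.0:
        signal = signal + noise.sigma_channel * (
            rng.standard_normal(phase.shape) + 1j * rng.standard_normal(phase.shape)
        )
    return PhaseVolume(
        wrap_to_principal(np.angle(signal)), wrapped=True, geometry=phase.geometry
    )


def simulate_echo_pair(
    fieldmap_hz: np.ndarray,
    te1: float,
    te2: float,
    base_phase: PhaseVolume | None = None,
    geometry: Geometry | None = None,
) -> tuple[PhaseVolume, PhaseVolume]:
    """Forward model of a dual-echo gradient-echo acquisition.

    The off-resonance field f (Hz) accrues phase 2*pi*f*TE by each echo time,
    on top of an optional echo-independent base phase.  Both echoes are
    returned wrapped; the unwrapped difference is exactly 2*pi*f*(TE2-TE1).
    """
    if not (te2 > te1 > 0):
        raise ValueError(f"echo times must satisfy te2 > te1 > 0, got te1={te1}, te2={te2}")
    fieldmap_hz = np.asarray(fieldmap_hz, dtype=float)
    base = np.zeros_like(fieldmap_hz) if base_phase is None else base_phase.data
    if base.shape != fieldmap_hz.shape:
        raise ValueError("base_phase shape does not match fieldmap shape")
    geom = geometry or (base_phase.geometry if base_phase is not None else Geometry())
    echo1 = wrap_to_principal(base + TWO_PI * fieldmap_hz * te1)
    echo2 = wrap_to_principal(base + TWO_PI * fieldmap_hz * te2)
    return (
        PhaseVolume(echo1, wrapped=True, geometry=geom),
        PhaseVolume(echo2, wrapped=True, geometry=geom),
    )


def _move_pe_last(arr: np.ndarray, pe_axis: int) -> np.ndarray:
    return np.moveaxis(arr, pe_axis, -1)


def simulate_distorted_epi(
    image: np.ndarray,
    disp,
    modulate_jacobian: bool = True,
) -> np.ndarray:
    """Apply the susceptibility forward model to an undistorted image.

    A voxel at PE coordinate y in the true image appears at y' = y + d(y)
    in the distorted EPI.  The distorted image is produced by inverting the
    (assumed monotone) 1D map per PE line and resampling with cubic
    interpolation; with ``modulate_jacobian`` the intensities are scaled by
    dy/dy' so that compressed signal piles up and stretched signal dilutes,
    conserving total intensity.
    """
    image = np.asarray(image, dtype=float)
    d = np.asarray(disp.data, dtype=float)
    pe_axis = int(disp.pe_axis)
    if d.shape != image.shape:
        raise ValueError(f"displacement shape {d.shape} != image shape {image.shape}")
    npe = image.shape[pe_axis]
    if np.max(np.abs(d)) >= npe:
        raise ValueError("displacement exceeds the PE-axis extent")

    dl = _move_pe_last(d, pe_axis).reshape(-1, npe)
    y = np.arange(npe, dtype=float)
    fwd = y[None, :] + dl  # y' = y + d(y), per line
    yinv = np.empty_like(dl)
    outside = 10.0 * npe  # sentinel coordinate -> cubic sampling returns 0
    for i in range(dl.shape[0]):
        line = fwd[i]
        if np.any(np.diff(line) <= 0):
            warnings.warn("non-monotone PE distortion line; using clamped inversion")
            line = np.maximum.accumulate(line + 1e-9 * y)
        yinv[i] = np.interp(y, line, y, left=outside, right=outside)

    shape_moved = _move_pe_last(image, pe_axis).shape
    yinv = yinv.reshape(shape_moved)
    coords = list(np.meshgrid(*[np.arange(n, dtype=float) for n in shape_moved], indexing="ij"))
    coords[-1] = yinv
    sampled = map_coordinates(
        _move_pe_last(image, pe_axis), coords, order=3, mode="constant", cval=0.0
    )
    if modulate_jacobian:
        inside = yinv < npe  # sentinel rows contribute nothing
        jac = np.gradient(np.where(inside, yinv, 0.0), axis=-1)
        sampled = np.where(inside, sampled * np.clip(jac, 0.0, None), 0.0)
    return np.moveaxis(sampled, -1, pe_axis)


def generate_structural(spec: PhantomSpec, texture_sd: float = 0.35, smooth: float = 1.5) -> np.ndarray:
    """A T1-like structural image on the phantom grid: head plateau plus
    smooth, seeded random texture and a few internal structures.

    Used as the reference image in registration experiments; the texture
    gives the local mutual-information data term something to lock on to.
    """
    rng = np.random.default_rng(spec.seed + 7919)
    base = generate_magnitude(spec).data.copy()
    x, y, z = _grids(spec)
    nx, ny, nz = spec.grid_shape
    # Internal "anatomy": a couple of smooth intensity ellipsoids.
    for centre, radii, level in (
        ((0.5 * nx, 0.52 * ny, 0.5 * nz), (0.22 * nx, 0.18 * ny, 0.3 * nz), 0.55),
        ((0.6 * nx, 0.35 * ny, 0.45 * nz), (0.1 * nx, 0.09 * ny, 0.14 * nz), -0.35),
    ):
        rho = _ellipsoid_rho(x, y, z, centre, radii)
        t = np.clip((1.0 - rho) / 0.25, 0.0, 1.0)
        base += level * t * t * (3.0 - 2.0 * t)
    texture = gaussian_filter(rng.standard_normal(spec.grid_shape), smooth)
    texture /= max(texture.std(), 1e-12)
    inside = generate_magnitude(spec).data > 0
    return np.clip(base + texture_sd * texture * inside, 0.0, None)
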