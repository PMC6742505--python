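"""Lightweight 3D volume containers shared by all pipeline stages.

Phase is carried in radians.  A wrapped phase volume is confined to the
principal interval (-pi, pi]; ties at +/-pi map to +pi by convention.
Geometry is minimal on purpose: voxel sizes in mm plus an axis order tag,
enough to write a valid NIfTI header without dragging a full affine through
the numerics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Geometry",
    "PhaseVolume",
    "MagnitudeVolume",
    "DisplacementFieldPE",
    "wrap_to_principal",
]

TWO_PI = 2.0 * np.pi


def wrap_to_principal(values: np.ndarray) -> np.ndarray:
    """Map phase values into the principal interval (-pi, pi].

    The convention is half-open on the left: wrap(pi) == pi and
    wrap(-pi) == pi.  The output is congruent to the input modulo 2*pi to
    machine precision.
    """
    values = np.asarray(values, dtype=float)
    return np.pi - np.mod(np.pi - values, TWO_PI)


@dataclass(frozen=True)
class Geometry:
    """Voxel sizes (mm per axis) and axis-order tag for a 3D grid."""

    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0)
    axis_order: str = "xyz"

    def __post_init__(self) -> None:
        if len(self.voxel_size) != 3 or any(v <= 0 for v in self.voxel_size):
            raise ValueError(f"voxel_size must be three positive floats, got {self.voxel_size}")


def _as_3d(data: np.ndarray, what: str) -> np.ndarray:
    arr = np.asarray(data, dtype=float)
    # Accept trailing singleton dims (e.g. NIfTI 4D with one volume).
    while arr.ndim > 3 and arr.shape[-1] == 1:
        arr = arr[..., 0]
    if arr.ndim != 3:
        raise ValueError(f"{what} must be a 3D scalar field, got shape {data.shape}")
    return arr


@dataclass
class PhaseVolume:
    """3D phase field in radians, wrapped (principal interval) or unwrapped."""

    data: np.ndarray
    wrapped: bool = False
    geometry: Geometry = field(default_factory=Geometry)

    def __post_init__(self) -> None:
        self.data = _as_3d(self.data, "phase")
        if self.wrapped:
            lo, hi = float(self.data.min(initial=0.0)), float(self.data.max(initial=0.0))
            if lo <= -np.pi - 1e-9 or hi > np.pi + 1e-9:
                raise ValueError(
                    f"wrapped phase must lie in (-pi, pi], found range [{lo:.6g}, {hi:.6g}]"
                )

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def wrap(self) -> "PhaseVolume":
        return PhaseVolume(wrap_to_principal(self.data), wrapped=True, geometry=self.geometry)


@dataclass
class DisplacementFieldPE:
    """Scalar per-voxel displacement along the phase-encode axis, in voxels.

    Susceptibility distortion is one-dimensional: off-resonance translates
    voxels only along the low-bandwidth phase-encode (PE) axis.  ``pe_sign``
    records the acquisition's blip polarity.
    """

    data: np.ndarray
    pe_axis: int = 1
    pe_sign: int = 1
    geometry: Geometry = field(default_factory=Geometry)

    def __post_init__(self) -> None:
        self.data = _as_3d(self.data, "displacement")
        if self.pe_axis not in (0, 1, 2):
            raise ValueError(f"pe_axis must be 0, 1 or 2, got {self.pe_axis}")
        if self.pe_sign not in (-1, 1):
            raise ValueError(f"pe_sign must be +/-1, got {self.pe_sign}")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("displacement field must be finite")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape


@dataclass
class MagnitudeVolume:
    """3D nonnegative signal-magnitude field, arbitrary units."""

    data: np.ndarray
    geometry: Geometry = field(default_factory=Geometry)

    def __post_init__(self) -> None:
        self.data = _as_3d(self.data, "magnitude")
        if float(self.data.min(initial=0.0)) < 0:
            raise ValueError("magnitude values must be >= 0")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape
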