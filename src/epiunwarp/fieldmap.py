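"""Dual-echo fieldmap estimation and phase-encode distortion correction.

The B0 off-resonance at a voxel is measured from the phase accrued between
two gradient echoes: f = dPhi / (2*pi * dTE), carried here in Hz (the
gyromagnetic ratio is folded into the Hz representation, the standard
fieldmap convention).  Off-resonance displaces signal along the
low-bandwidth phase-encode axis by delta = f * T_acq voxels, where T_acq is
the effective readout time.  Correction resamples each PE line of the
distorted EPI at y + delta(y) and multiplies by the 1D Jacobian
1 + d(delta)/dy, undoing both the geometric shift and the intensity
pile-up/dilution it causes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import map_coordinates

from .volumes import (
    DisplacementFieldPE,
    Geometry,
    PhaseVolume,
    TWO_PI,
    wrap_to_principal,
)

__all__ = [
    "AcquisitionParams",
    "FieldMapHz",
    "DisplacementFieldPE",
    "phase_difference",
    "fieldmap_from_unwrapped_difference",
    "displacement_from_fieldmap",
    "correct_epi",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class AcquisitionParams:
    """Echo times, effective readout time and PE axis of the acquisition.

    All times in seconds.  ``tacq`` is the effective readout time per PE
    traversal (already divided by any parallel-imaging acceleration).
    """

    te1: float = 0.008
    te2: float = 0.010
    tacq: float = 0.030
    pe_axis: int = 1
    pe_sign: int = 1

    def __post_init__(self) -> None:
        if not (self.te2 > self.te1 > 0):
            raise ValueError(f"echo times must satisfy te2 > te1 > 0, got {self.te1}, {self.te2}")
        if self.tacq <= 0:
            raise ValueError(f"tacq must be > 0, got {self.tacq}")
        if self.pe_axis not in (0, 1, 2):
            raise ValueError(f"pe_axis must be 0, 1 or 2, got {self.pe_axis}")
        if self.pe_sign not in (-1, 1):
            raise ValueError(f"pe_sign must be +/-1, got {self.pe_sign}")

    @property
    def delta_te(self) -> float:
        return self.te2 - self.te1


@dataclass
class FieldMapHz:
    """Per-voxel B0 off-resonance in Hz."""

    data: np.ndarray
    geometry: Geometry = field(default_factory=Geometry)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("fieldmap must be 3D")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape


def phase_difference(echo1: PhaseVolume, echo2: PhaseVolume) -> PhaseVolume:
    """Wrapped phase difference wrap(phi2 - phi1) of two echoes.

    Differencing removes phase contributions common to both echoes
    (coil/object phase), leaving only the off-resonance evolution over
    delta TE.
    """
    if echo1.shape != echo2.shape:
        raise ValueError(f"echo grids differ: {echo1.shape} vs {echo2.shape}")
    return PhaseVolume(
        wrap_to_principal(echo2.data - echo1.data), wrapped=True, geometry=echo1.geometry
    )


def fieldmap_from_unwrapped_difference(
    delta_phi: PhaseVolume, params: AcquisitionParams
) -> FieldMapHz:
    """Off-resonance in Hz from the unwrapped echo phase difference."""
    if delta_phi.wrapped:
        raise ValueError("phase difference must be unwrapped first")
    return FieldMapHz(delta_phi.data / (TWO_PI * params.delta_te), geometry=delta_phi.geometry)


def displacement_from_fieldmap(fmap: FieldMapHz, params: AcquisitionParams) -> DisplacementFieldPE:
    """PE displacement in voxels: delta = pe_sign * f_Hz * T_acq."""
    return DisplacementFieldPE(
        data=params.pe_sign * fmap.data * params.tacq,
        pe_axis=params.pe_axis,
        pe_sign=params.pe_sign,
        geometry=fmap.geometry,
    )


def correct_epi(
    epi: np.ndarray, disp: DisplacementFieldPE, modulate_jacobian: bool = True
) -> np.ndarray:
    """Undistort an EPI volume given the PE displacement field.

    The measured EPI is the distorted image: signal from true PE
    coordinate y was recorded at y + delta(y).  Correction samples the
    distorted image at y + delta(y) with 1D cubic interpolation along the
    PE axis (out-of-field samples are zero) and, with ``modulate_jacobian``,
    multiplies by 1 + d(delta)/dy so that piled-up signal is spread back
    out.  Non-positive Jacobians (folded geometry) are clamped at a small
    positive floor with a logged warning.
    """
    epi = np.asarray(epi, dtype=float)
    d = np.asarray(disp.data, dtype=float)
    if d.shape != epi.shape:
        raise ValueError(f"displacement shape {d.shape} != EPI shape {epi.shape}")
    pe = int(disp.pe_axis)
    npe = epi.shape[pe]

    epi_m = np.moveaxis(epi, pe, -1)
    d_m = np.moveaxis(d, pe, -1)
    y = np.arange(npe, dtype=float)
    sample = y + d_m  # distorted-space coordinate of each true voxel
    coords = list(
        np.meshgrid(*[np.arange(n, dtype=float) for n in epi_m.shape], indexing="ij")
    )
    coords[-1] = sample
    corrected = map_coordinates(epi_m, coords, order=3, mode="constant", cval=0.0)
    if modulate_jacobian:
        jac = 1.0 + np.gradient(d_m, axis=-1)
        if np.any(jac <= 0):
            log.warning(
                "distortion field folds (%d voxels with Jacobian <= 0); clamping",
                int(np.sum(jac <= 0)),
            )
            jac = np.clip(jac, 0.01, None)
        corrected = corrected * jac
    return np.moveaxis(corrected, -1, pe)
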