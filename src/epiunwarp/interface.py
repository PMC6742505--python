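"""NIfTI I/O, phase rescaling, configuration and the end-to-end pipeline.

The pipeline wires the correction stages in acquisition order: wrapped
dual-echo phase -> wrapped difference -> graph-cut unwrapping ->
confidence -> fieldmap (Hz) -> PE displacement -> Jacobian-modulated EPI
correction -> confidence-modulated registration refinement (when an
undistorted structural image is supplied).  All outputs are written
atomically (temp file then rename) together with a JSON run report.

Displacement fields are stored in voxels with the PE axis and sign in a
JSON sidecar, avoiding NIfTI orientation ambiguity for 1D fields.
"""

from __future__ import annotations

import json
import logging
import os
import tempfile
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

from . import __version__
from .confidence import unwrap_confidence
from .fieldmap import (
    AcquisitionParams,
    correct_epi,
    displacement_from_fieldmap,
    fieldmap_from_unwrapped_difference,
    phase_difference,
)
from .registration import RegConfig, register
from .unwrap import UnwrapConfig, unwrap
from .volumes import DisplacementFieldPE, Geometry, MagnitudeVolume, PhaseVolume, wrap_to_principal

__all__ = [
    "read_volume",
    "write_volume",
    "write_sidecar",
    "rescale_phase",
    "PipelineConfig",
    "run_pipeline",
]

log = logging.getLogger(__name__)


def read_volume(path: str | os.PathLike) -> tuple[np.ndarray, Geometry]:
    """Read a 3D NIfTI volume (trailing singleton dims are squeezed)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such volume: {path}")
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.dtype.kind not in "fiu":
        raise ValueError(f"{path}: unsupported voxel dtype {data.dtype} (need scalar volume)")
    data = np.asarray(data, dtype=np.float64)
    while data.ndim > 3 and data.shape[-1] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise ValueError(f"{path}: expected a 3D payload, got shape {data.shape}")
    zooms = img.header.get_zooms()[:3]
    return data, Geometry(voxel_size=tuple(float(z) for z in zooms))


def _atomic_write(path: Path, writer) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    fd, tmp = tempfile.mkstemp(dir=path.parent, suffix="".join(path.suffixes) or ".tmp")
    os.close(fd)
    try:
        writer(tmp)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.remove(tmp)
        raise


def write_volume(data: np.ndarray, geometry: Geometry, path: str | os.PathLike) -> None:
    """Write a 3D volume as float32 NIfTI-1 (atomic)."""
    data = np.asarray(data, dtype=np.float32)
    if data.ndim != 3:
        raise ValueError(f"can only write 3D volumes, got shape {data.shape}")
    affine = np.diag(list(geometry.voxel_size) + [1.0])
    img = nib.Nifti1Image(data, affine)
    img.header.set_zooms(geometry.voxel_size)
    path = Path(path)
    _atomic_write(path, lambda tmp: nib.save(img, tmp))


def write_sidecar(path: str | os.PathLike, payload: dict) -> None:
    """Atomic JSON sidecar write."""
    path = Path(path)
    _atomic_write(path, lambda tmp: Path(tmp).write_text(json.dumps(payload, indent=2)))


def rescale_phase(raw: np.ndarray, convention: str = "radians") -> PhaseVolume:
    """Map a raw scanner phase export into wrapped radians (-pi, pi].

    Conventions: ``radians`` (values must already be in range),
    ``siemens_int`` (stored integers [0, 4095] map linearly onto the
    principal interval) and ``minmax`` (observed range maps linearly).
    """
    raw = np.asarray(raw, dtype=float)
    if convention == "radians":
        eps = 1e-6
        if raw.min() < -np.pi - eps or raw.max() > np.pi + eps:
            raise ValueError(
                f"values in [{raw.min():.3g}, {raw.max():.3g}] are not wrapped radians; "
                "try convention='siemens_int' or 'minmax'"
            )
        return PhaseVolume(wrap_to_principal(raw), wrapped=True)
    if convention == "siemens_int":
        phase = -np.pi + raw / 4095.0 * 2.0 * np.pi
    elif convention == "minmax":
        lo, hi = float(raw.min()), float(raw.max())
        if hi <= lo:
            raise ValueError("minmax rescaling needs a non-degenerate intensity range")
        phase = -np.pi + (raw - lo) / (hi - lo) * 2.0 * np.pi
    else:
        raise ValueError(f"unknown phase convention {convention!r}")
    return PhaseVolume(wrap_to_principal(phase), wrapped=True)


@dataclass
class PipelineConfig:
    """Inputs, acquisition parameters and stage options of a full run."""

    echo1: str = ""
    echo2: str = ""
    magnitude: str = ""
    epi: str = ""
    t1: str = ""  # optional; registration runs only when supplied
    outdir: str = "epiunwarp_out"
    phase_convention: str = "radians"
    acquisition: AcquisitionParams = field(default_factory=AcquisitionParams)
    unwrap: UnwrapConfig = field(default_factory=UnwrapConfig)
    registration: RegConfig = field(default_factory=RegConfig)
    confidence_stride: int = 1
    seed: int = 0
    verbosity: int = 1

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        for key, sub in (
            ("acquisition", AcquisitionParams),
            ("unwrap", UnwrapConfig),
            ("registration", RegConfig),
        ):
            if key in d and isinstance(d[key], dict):
                d[key] = sub(**d[key])
        return cls(**d)

    def to_dict(self) -> dict:
        return asdict(self)


def _rereference_counts(k: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Fix the gauge: subtract the modal in-mask wrap count, so the bulk of
    the volume is treated as on-resonance."""
    vals, cnt = np.unique(k[mask], return_counts=True)
    return k - int(vals[np.argmax(cnt)])


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full correction chain and write all artefacts.

    Returns the run report (also written to ``report.json``): per-stage
    wall times, unwrap energy trace, registration cost trace and output
    paths.  Any stage failure raises with the stage name attached.
    """
    out = Path(config.outdir)
    report: dict = {
        "version": __version__,
        "numpy": np.__version__,
        "seed": config.seed,
        "stages": {},
        "outputs": {},
    }
    timings = report["stages"]

    def stage(name):
        class _T:
            def __enter__(self):
                self.t0 = time.perf_counter()
                log.info("stage %s ...", name)
                return self

            def __exit__(self, et, ev, tb):
                if et is not None:
                    raise RuntimeError(f"pipeline stage '{name}' failed: {ev}") from ev
                timings[name] = round(time.perf_counter() - self.t0, 3)

        return _T()

    with stage("load"):
        e1, geom = read_volume(config.echo1)
        e2, _ = read_volume(config.echo2)
        mag_data, _ = read_volume(config.magnitude)
        echo1 = rescale_phase(e1, config.phase_convention)
        echo2 = rescale_phase(e2, config.phase_convention)
        echo1.geometry = echo2.geometry = geom
        magnitude = MagnitudeVolume(mag_data, geometry=geom)

    with stage("unwrap"):
        dphi = phase_difference(echo1, echo2)
        result = unwrap(dphi, magnitude, config.unwrap)
        k = _rereference_counts(np.asarray(result.counts.k), result.weights.mask)
        unwrapped = PhaseVolume(dphi.data + 2 * np.pi * k, wrapped=False, geometry=geom)
        report["unwrap_energy_trace"] = result.energy_trace
        report["unwrap_converged"] = bool(result.converged)

    with stage("confidence"):
        conf = unwrap_confidence(result, stride=config.confidence_stride)

    with stage("fieldmap"):
        fmap = fieldmap_from_unwrapped_difference(unwrapped, config.acquisition)
        disp = displacement_from_fieldmap(fmap, config.acquisition)

    with stage("correct"):
        epi, _ = read_volume(config.epi)
        corrected = correct_epi(epi, disp, modulate_jacobian=True)

    refined: DisplacementFieldPE | None = None
    if config.t1:
        with stage("register"):
            t1, _ = read_volume(config.t1)
            reg = register(t1, epi, init=disp, conf=conf.omega, config=config.registration)
            refined = reg.displacement
            report["registration_cost_trace"] = reg.energy_trace
            corrected_refined = correct_epi(epi, refined, modulate_jacobian=True)

    with stage("write"):
        outputs = {
            "unwrapped": (unwrapped.data, "unwrapped_phase.nii.gz"),
            "wrap_counts": (k.astype(np.float32), "wrap_counts.nii.gz"),
            "confidence": (conf.omega, "confidence.nii.gz"),
            "fieldmap_hz": (fmap.data, "fieldmap_hz.nii.gz"),
            "displacement": (disp.data, "displacement_vox.nii.gz"),
            "corrected_epi": (corrected, "corrected_epi.nii.gz"),
        }
        if refined is not None:
            outputs["displacement_refined"] = (refined.data, "displacement_refined_vox.nii.gz")
            outputs["corrected_epi_refined"] = (corrected_refined, "corrected_epi_refined.nii.gz")
        for key, (data, name) in outputs.items():
            write_volume(np.asarray(data, dtype=np.float32), geom, out / name)
            report["outputs"][key] = str(out / name)
        write_sidecar(
            out / "displacement_vox.json",
            {
                "pe_axis": config.acquisition.pe_axis,
                "pe_sign": config.acquisition.pe_sign,
                "te1_s": config.acquisition.te1,
                "te2_s": config.acquisition.te2,
                "tacq_s": config.acquisition.tacq,
                "units": "voxels",
            },
        )
        write_sidecar(out / "report.json", report)
    return report
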