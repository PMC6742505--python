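"""Validation statistics: misclassification ratio and tensor-fit residual.

The misclassification ratio (MCR) is the fraction of voxels whose
estimated wrap count is wrong.  Because the unwrapping energy depends only
on wrap-count differences, estimates are defined up to a global integer
offset; the single offset maximising agreement (the mode of the
estimate-truth difference inside the mask) is removed before counting.

The chi-squared residual is the normalised sum of squared fit errors
chi2 = sum (S_m - S_f)^2 / sum S_m^2, as used to score diffusion-tensor
fits on corrected data; provided as a formula utility only.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["MCRReport", "mcr", "chi_squared_residual"]


@dataclass(frozen=True)
class MCRReport:
    """Misclassification ratio after global-offset alignment."""

    mcr: float
    n_masked: int
    global_offset: int


def mcr(k_est: np.ndarray, k_true: np.ndarray, mask: np.ndarray | None = None) -> MCRReport:
    """Fraction of masked voxels with a wrong wrap count, gauge-aligned.

    Removes the global integer offset c that maximises agreement (the mode
    of k_est - k_true within the mask), then counts mismatches.  Invariant
    under global integer shifts of either map.
    """
    k_est = np.asarray(k_est)
    k_true = np.asarray(k_true)
    if k_est.shape != k_true.shape:
        raise ValueError(f"shape mismatch: {k_est.shape} vs {k_true.shape}")
    if mask is None:
        mask = np.ones(k_est.shape, dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != k_est.shape:
        raise ValueError("mask shape mismatch")
    n = int(mask.sum())
    if n == 0:
        raise ValueError("empty mask")
    diff = (k_est.astype(np.int64) - k_true.astype(np.int64))[mask]
    values, counts = np.unique(diff, return_counts=True)
    c = int(values[np.argmax(counts)])
    wrong = int(np.count_nonzero(diff != c))
    return MCRReport(mcr=wrong / n, n_masked=n, global_offset=c)


def chi_squared_residual(s_measured: np.ndarray, s_fitted: np.ndarray) -> float:
    """Normalised sum of squared residuals, sum (S_m - S_f)^2 / sum S_m^2.

    Dimensionless and invariant under common positive rescaling of the
    measured and fitted signals.
    """
    s_m = np.asarray(s_measured, dtype=float).ravel()
    s_f = np.asarray(s_fitted, dtype=float).ravel()
    if s_m.size == 0:
        raise ValueError("need at least one signal")
    if s_m.shape != s_f.shape:
        raise ValueError("measured and fitted signals must have equal length")
    denom = float(np.sum(s_m * s_m))
    if denom == 0.0:
        raise ValueError("all-zero measured signal")
    return float(np.sum((s_m - s_f) ** 2) / denom)
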