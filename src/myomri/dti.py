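"""Diffusion tensor estimation and eigenvalue-derived metrics.

The tensor is fitted per voxel by unweighted linear least squares on the
log-attenuation, ln(S_i / S0) = -b g_i^T D g_i, with the design matrix rows
(gx^2, gy^2, gz^2, 2 gx gy, 2 gx gz, 2 gy gz).  Metrics follow the standard
definitions: eigenvalues sorted descending, ADC = (l1 + l2 + l3)/3, and

    FA = sqrt(3/2) * sqrt(sum (l_i - ADC)^2) / sqrt(sum l_i^2).

Negative eigenvalues arising from noise are retained in the formulas (no
clamping, which would bias ROI means) but counted in the result.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np

from .dixon import largest_slices
from .phantom.build import components_to_tensor
from .phantom.mri import DiffusionVolume


@dataclass
class TensorField:
    components: np.ndarray  # (..., 6): Dxx, Dyy, Dzz, Dxy, Dxz, Dyz in 1e-3 mm^2/s
    s0_map: np.ndarray
    valid_mask: np.ndarray


@dataclass
class DtiMetrics:
    lambda1: np.ndarray
    lambda2: np.ndarray
    lambda3: np.ndarray
    adc: np.ndarray
    fa: np.ndarray
    valid_mask: np.ndarray
    n_negative_eigenvalues: int = 0


def design_matrix(bvals: np.ndarray, bvecs: np.ndarray) -> np.ndarray:
    """Rows b * (gx^2, gy^2, gz^2, 2 gx gy, 2 gx gz, 2 gy gz) for b > 0."""
    g = bvecs
    return bvals[:, None] * np.stack(
        [
            g[:, 0] ** 2,
            g[:, 1] ** 2,
            g[:, 2] ** 2,
            2 * g[:, 0] * g[:, 1],
            2 * g[:, 0] * g[:, 2],
            2 * g[:, 1] * g[:, 2],
        ],
        axis=1,
    )


def fit_tensor(dwi: DiffusionVolume) -> TensorField:
    """Per-voxel linear least-squares tensor fit.

    S0 is the mean of the b=0 volumes.  Voxels with any nonpositive signal
    are flagged invalid.  Components come out in 1e-3 mm^2/s for b given in
    s/mm^2.
    """
    bvals = np.asarray(dwi.bvals, dtype=float)
    bvecs = np.asarray(dwi.bvecs, dtype=float)
    b0 = bvals == 0
    if not b0.any():
        raise ValueError("need at least one b=0 volume")
    dwi_idx = ~b0
    a = design_matrix(bvals[dwi_idx] * 1e-3, bvecs[dwi_idx])  # 1e-3 mm^2/s units
    if np.linalg.matrix_rank(a) < 6:
        raise ValueError(
            "rank-deficient diffusion design: need >= 6 non-collinear directions"
        )

    data = np.asarray(dwi.data, dtype=float)
    shape = data.shape[:-1]
    flat = data.reshape(-1, data.shape[-1])
    s0 = flat[:, b0].mean(axis=1)
    valid = (s0 > 0) & np.all(flat[:, dwi_idx] > 0, axis=1)

    comps = np.full((flat.shape[0], 6), np.nan)
    if valid.any():
        y = -np.log(flat[valid][:, dwi_idx] / s0[valid, None])
        sol, *_ = np.linalg.lstsq(a, y.T, rcond=None)
        comps[valid] = sol.T
    return TensorField(
        components=comps.reshape(shape + (6,)),
        s0_map=s0.reshape(shape),
        valid_mask=valid.reshape(shape),
    )


def tensor_metrics(field: TensorField) -> DtiMetrics:
    """Eigenvalue metrics (l1 >= l2 >= l3, ADC, FA) per voxel."""
    comps = field.components
    shape = comps.shape[:-1]
    flat = comps.reshape(-1, 6)
    valid = field.valid_mask.reshape(-1) & np.all(np.isfinite(flat), axis=1)

    l1 = np.full(flat.shape[0], np.nan)
    l2 = np.full(flat.shape[0], np.nan)
    l3 = np.full(flat.shape[0], np.nan)
    adc = np.full(flat.shape[0], np.nan)
    fa = np.full(flat.shape[0], np.nan)
    n_neg = 0
    if valid.any():
        tensors = components_to_tensor(flat[valid])
        evs = np.linalg.eigvalsh(tensors)[:, ::-1]  # descending
        n_neg = int((evs < 0).sum())
        l1[valid], l2[valid], l3[valid] = evs[:, 0], evs[:, 1], evs[:, 2]
        mean = evs.mean(axis=1)
        adc[valid] = mean
        num = np.sqrt(((evs - mean[:, None]) ** 2).sum(axis=1))
        den = np.sqrt((evs**2).sum(axis=1))
        with np.errstate(invalid="ignore", divide="ignore"):
            fa[valid] = np.sqrt(1.5) * np.where(den > 0, num / den, np.nan)
    return DtiMetrics(
        lambda1=l1.reshape(shape),
        lambda2=l2.reshape(shape),
        lambda3=l3.reshape(shape),
        adc=adc.reshape(shape),
        fa=fa.reshape(shape),
        valid_mask=valid.reshape(shape),
        n_negative_eigenvalues=n_neg,
    )


def fa_from_eigenvalues(eigenvalues: Sequence[float]) -> float:
    """FA of a single eigenvalue triple (used for table-level checks)."""
    ev = np.asarray(eigenvalues, dtype=float)
    mean = ev.mean()
    den = np.sqrt((ev**2).sum())
    return float(np.sqrt(1.5) * np.sqrt(((ev - mean) ** 2).sum()) / den)


def roi_mean_metrics(
    metrics: DtiMetrics,
    roi: np.ndarray,
    n_slices: Optional[int] = 3,
    slices: Optional[Sequence[int]] = None,
) -> dict:
    """ROI means of every metric over the largest ROI slices (default 3)."""
    if not roi.any():
        raise ValueError("empty ROI")
    if slices is None and n_slices is not None:
        slices = largest_slices(roi, n_slices)
    if slices is not None:
        sl = np.zeros_like(roi)
        sl[:, :, list(slices)] = True
        roi = roi & sl
    sel = roi & metrics.valid_mask
    if not sel.any():
        raise ValueError("ROI contains no valid tensor fits")
    return {
        name: float(getattr(metrics, name)[sel].mean())
        for name in ("lambda1", "lambda2", "lambda3", "adc", "fa")
    }
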