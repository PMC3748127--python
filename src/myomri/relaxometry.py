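"""Pixel-wise T2 mapping from multi-echo magnitude data.

The estimator is the log-linear fit the field standard for single-component
muscle T2: ordinary least squares of log S(TE) on TE per voxel,
log S(TE) = log S0 - TE / T2, giving T2 = -1/slope and S0 = exp(intercept).
Voxels with any nonpositive echo, or with a nonnegative slope, are flagged
invalid rather than filled.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np

from .dixon import largest_slices
from .phantom.mri import MultiEchoVolume


@dataclass
class T2MapResult:
    t2_map: np.ndarray  # ms; NaN where invalid
    s0_map: np.ndarray
    r2_map: np.ndarray  # coefficient of determination of the log-linear fit
    valid_mask: np.ndarray


def fit_t2_map(echoes: MultiEchoVolume) -> T2MapResult:
    """OLS of log-signal on echo time, vectorized over all voxels."""
    tes = np.asarray(echoes.echo_times_ms, dtype=float)
    if tes.size < 2 or np.unique(tes).size != tes.size:
        raise ValueError("need at least two distinct echo times")
    data = np.asarray(echoes.data, dtype=float)
    flat = data.reshape(-1, tes.size)
    valid = np.all(flat > 0, axis=1)
    if not valid.any():
        raise ValueError("no voxel has positive signal at every echo")

    logs = np.full_like(flat, np.nan)
    np.log(flat, out=logs, where=flat > 0)
    x = tes - tes.mean()
    sxx = float((x**2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        ymean = logs.mean(axis=1)
        slope = (logs * x).sum(axis=1) / sxx
        intercept = ymean - slope * tes.mean()
        fitted = intercept[:, None] + np.outer(slope, tes)
        ss_res = ((logs - fitted) ** 2).sum(axis=1)
        ss_tot = ((logs - ymean[:, None]) ** 2).sum(axis=1)
        r2 = np.where(ss_tot > 0, 1.0 - ss_res / ss_tot, 1.0)

    valid &= slope < 0  # nonnegative slope: no decay, T2 undefined
    t2 = np.full(flat.shape[0], np.nan)
    t2[valid] = -1.0 / slope[valid]
    s0 = np.full(flat.shape[0], np.nan)
    s0[valid] = np.exp(intercept[valid])
    r2 = np.where(valid, r2, np.nan)

    shape = data.shape[:-1]
    return T2MapResult(
        t2_map=t2.reshape(shape),
        s0_map=s0.reshape(shape),
        r2_map=r2.reshape(shape),
        valid_mask=valid.reshape(shape),
    )


def roi_mean_t2(
    result: T2MapResult,
    roi: np.ndarray,
    n_slices: Optional[int] = 3,
    slices: Optional[Sequence[int]] = None,
) -> float:
    """Mean valid T2 over an ROI, averaged over its largest slices.

    By default the three slices with the largest ROI sections are used,
    matching how regional muscle T2 is reported; pass ``slices`` to override.
    """
    if not roi.any():
        raise ValueError("empty ROI")
    if slices is None and n_slices is not None:
        slices = largest_slices(roi, n_slices)
    if slices is not None:
        sl = np.zeros_like(roi)
        sl[:, :, list(slices)] = True
        roi = roi & sl
    sel = roi & result.valid_mask
    if not sel.any():
        raise ValueError("ROI contains no valid T2 fits")
    return float(result.t2_map[sel].mean())
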