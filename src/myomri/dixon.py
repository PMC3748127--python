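"""Three-point Dixon water-fat separation, fat quantification and anatomy.

The acquisition provides three gradient echoes with water and fat in phase,
opposed, and in phase again.  Writing W and F for the water and fat signal
magnitudes and psi for the static field offset, the echoes are

    S1 = (W + F) e^{i phi1},  S2 = (W - F) e^{i phi2},  S3 = (W + F) e^{i phi3}

with phi_n = 2 pi psi TE_n.  For evenly spaced echoes the field-induced
phase between echo 1 and echo 2 is half of arg(S1* S3), which lets the
opposed echo be demodulated and the pair (W, F) solved algebraically:

    W = (|S1| + S2c) / 2,   F = (|S1| - S2c) / 2

where S2c is the real part of the phase-corrected opposed echo (signed, so
fat-dominated voxels come out with F > W).

Fat percentage per voxel is 100 F / (F + W); anatomy (cross-sectional area
and hindlimb volume) is measured on the water image.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Tuple

import numpy as np
from scipy import ndimage

from .phantom.mri import MultiEchoVolume


@dataclass
class FatWaterResult:
    """Separated maps on the input grid.

    ``water_map``/``fat_map`` are clamped to be nonnegative (``clamped_mask``
    marks affected voxels); ``water_signed``/``fat_signed`` keep the raw
    algebraic solutions, which are the unbiased quantities to average over a
    region when the true fat content is near zero.
    """

    water_map: np.ndarray
    fat_map: np.ndarray
    fat_fraction_map: np.ndarray
    field_phase_map: np.ndarray
    mask: np.ndarray
    water_signed: np.ndarray
    fat_signed: np.ndarray
    clamped_mask: np.ndarray

    @property
    def clamped_fraction(self) -> float:
        m = self.mask
        return float(self.clamped_mask[m].mean()) if m.any() else 0.0


@dataclass
class AnatomyResult:
    """Per-slice cross-sectional areas and the derived hindlimb volume."""

    csa_per_slice_mm2: np.ndarray
    max_csa_mm2: float
    volume_mm3: float
    slices_used: Tuple[int, ...]
    muscle_mask: np.ndarray = field(repr=False, default=None)


def separate_fat_water(
    echoes: MultiEchoVolume, mask_threshold_frac: float = 0.05
) -> FatWaterResult:
    """Algebraic 3-point water/fat separation with field-phase correction.

    The field phase per echo spacing is taken from arg(S1* S3)/2 and assumed
    to lie within (-pi/2, pi/2] per voxel (no spatial unwrapping).
    """
    if echoes.n_echoes != 3:
        raise ValueError(f"expected exactly 3 echoes, got {echoes.n_echoes}")
    if echoes.phase_scheme is None:
        raise ValueError("echo stack carries no water-fat phase scheme metadata")
    if tuple(echoes.phase_scheme) != ("in", "opposed", "in"):
        raise ValueError(
            f"unsupported phase scheme {echoes.phase_scheme}; expected in/opposed/in"
        )
    s1 = echoes.data[..., 0]
    s2 = echoes.data[..., 1]
    s3 = echoes.data[..., 2]

    # field phase accrued over one echo spacing
    dphi = 0.5 * np.angle(s1.conj() * s3)
    # demodulate the opposed echo to the phase of echo 1
    phase1 = np.angle(s1)
    s2c = np.real(s2 * np.exp(-1j * (phase1 + dphi)))

    in_mag = np.abs(s1)
    water_signed = (in_mag + s2c) / 2.0
    fat_signed = (in_mag - s2c) / 2.0
    clamped = (water_signed < 0) | (fat_signed < 0)
    water = np.clip(water_signed, 0.0, None)
    fat = np.clip(fat_signed, 0.0, None)
    total = water + fat
    ff = np.zeros_like(total)
    nz = total > 0
    ff[nz] = fat[nz] / total[nz]

    mask = in_mag > mask_threshold_frac * np.percentile(in_mag, 99)
    return FatWaterResult(
        water_map=water,
        fat_map=fat,
        fat_fraction_map=ff,
        field_phase_map=dphi,
        mask=mask,
        water_signed=water_signed,
        fat_signed=fat_signed,
        clamped_mask=clamped,
    )


def largest_slices(mask: np.ndarray, n: int) -> Tuple[int, ...]:
    """Indices of the n slices with the largest in-mask area (sorted)."""
    areas = mask.reshape(-1, mask.shape[2]).sum(axis=0)
    order = np.argsort(areas)[::-1][:n]
    return tuple(sorted(int(i) for i in order))


def fat_percentage(
    result: FatWaterResult,
    mask: np.ndarray,
    n_slices: Optional[int] = 4,
    clamped: bool = False,
) -> float:
    """Mean fat percentage, 100 F / (F + W), over a muscle mask.

    Averaged over the ``n_slices`` slices with the largest masked sections
    (all slices if None).  By default the signed separation outputs are used:
    truncating negative noise excursions before averaging would bias the
    regional mean upward when the true fat fraction is near zero.
    """
    if not mask.any():
        raise ValueError("empty mask")
    if n_slices is not None:
        keep = largest_slices(mask, n_slices)
        sl = np.zeros_like(mask)
        sl[:, :, list(keep)] = True
        mask = mask & sl
    if clamped:
        f, w = result.fat_map[mask], result.water_map[mask]
    else:
        f, w = result.fat_signed[mask], result.water_signed[mask]
    total = f + w
    good = total > 0
    return float(np.mean(100.0 * f[good] / total[good]))


def measure_anatomy(
    water_map: np.ndarray,
    voxel_dims_mm: Sequence[float],
    n_slices: int = 4,
    threshold_frac: float = 0.5,
) -> AnatomyResult:
    """Segment muscle on the water image and measure CSA and volume.

    The muscle mask thresholds the water image at ``threshold_frac`` of the
    median foreground intensity and keeps the largest connected component
    (subcutaneous fat is dark on the water image and is excluded).  Maximal
    CSA comes from the largest slice; the volume sums the CSAs of the
    ``n_slices`` consecutive largest slices times the slice thickness.
    """
    dx, dy, dz = voxel_dims_mm
    fg = water_map > 0.05 * water_map.max()
    if not fg.any():
        raise ValueError("empty segmentation: water image has no foreground")
    thr = threshold_frac * np.median(water_map[fg])
    mask = water_map > thr
    lab, n = ndimage.label(mask)
    if n == 0:
        raise ValueError("empty segmentation after thresholding")
    sizes = ndimage.sum_labels(np.ones_like(lab), lab, index=np.arange(1, n + 1))
    mask = lab == (1 + int(np.argmax(sizes)))

    csa = mask.reshape(-1, mask.shape[2]).sum(axis=0) * dx * dy
    nz = mask.shape[2]
    n_slices = min(n_slices, nz)
    window_sums = [csa[i : i + n_slices].sum() for i in range(nz - n_slices + 1)]
    best = int(np.argmax(window_sums))
    used = tuple(range(best, best + n_slices))
    return AnatomyResult(
        csa_per_slice_mm2=csa,
        max_csa_mm2=float(csa.max()),
        volume_mm3=float(csa[list(used)].sum() * dz),
        slices_used=used,
        muscle_mask=mask,
    )
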