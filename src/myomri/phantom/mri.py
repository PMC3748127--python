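"""MR signal simulators: three-point Dixon, multi-echo T2, diffusion weighting.

All simulators sample the voxelized ground truth, apply the ideal signal
model, then add independent complex Gaussian noise per receive channel, so
magnitude images are Rician-distributed.  Simulators are pure functions of
(ground truth, acquisition parameters, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence, Tuple

import numpy as np

from .build import GroundTruth, components_to_tensor
from .directions import TWELVE_DIRECTIONS

DIXON_PHASES = ("in", "opposed", "in")
DIXON_TES_MS = (1.5, 1.8, 2.1)
T2_TES_MS = (8.0, 12.0, 16.0, 20.0, 24.0)


@dataclass
class MultiEchoVolume:
    """Echo stack with acquisition metadata.

    ``data`` is complex for Dixon echoes and real magnitude for T2 echoes;
    shape (nx, ny, nz, n_echoes).
    """

    data: np.ndarray
    echo_times_ms: Tuple[float, ...]
    voxel_dims_mm: Tuple[float, float, float]
    phase_scheme: Optional[Tuple[str, ...]] = None
    noise_sigma: float = 0.0
    rng_seed: Optional[int] = None
    meta: Dict = field(default_factory=dict)

    @property
    def n_echoes(self) -> int:
        return self.data.shape[-1]


@dataclass
class DiffusionVolume:
    """Diffusion-weighted stack; one volume per (b-value, direction) pair."""

    data: np.ndarray  # (nx, ny, nz, n_volumes), magnitude
    bvals: np.ndarray  # (n_volumes,) s/mm^2
    bvecs: np.ndarray  # (n_volumes, 3); zero rows for b=0
    voxel_dims_mm: Tuple[float, float, float]
    noise_sigma: float = 0.0
    rng_seed: Optional[int] = None
    meta: Dict = field(default_factory=dict)


def _complex_noise(rng: np.random.Generator, sigma: float, shape) -> np.ndarray:
    if sigma == 0:
        return np.zeros(shape, dtype=complex)
    return sigma * (rng.standard_normal(shape) + 1j * rng.standard_normal(shape))


def simulate_dixon(
    gt: GroundTruth,
    echo_times_ms: Sequence[float] = DIXON_TES_MS,
    phase_scheme: Sequence[str] = DIXON_PHASES,
    noise_sigma: float = 0.0,
    rng_seed: int = 0,
) -> MultiEchoVolume:
    """Three-echo gradient-echo acquisition at idealized water-fat phases.

    Echo n sees S_n = (W + F e^{i theta_n}) e^{i 2 pi psi TE_n} + noise with
    theta = 0, pi, 2 pi for the in/opposed/in scheme, W = rho (1 - FF),
    F = rho FF, and psi the per-voxel static field offset (Hz).  The
    water-fat phase is idealized rather than derived from the literal echo
    spacing; the field-offset phase ramp does use the nominal echo times.
    """
    scheme = tuple(phase_scheme)
    if len(echo_times_ms) != len(scheme):
        raise ValueError("echo_times_ms and phase_scheme must have equal length")
    thetas = []
    n_in = 0
    for ph in scheme:
        if ph == "in":
            thetas.append(2.0 * np.pi * n_in)
            n_in += 1
        elif ph == "opposed":
            thetas.append(np.pi)
        else:
            raise ValueError(f"unknown phase label {ph!r}; expected 'in' or 'opposed'")

    rng = np.random.default_rng(rng_seed)
    water = gt.proton_density * (1.0 - gt.fat_fraction)
    fat = gt.proton_density * gt.fat_fraction
    nx, ny, nz = gt.shape
    data = np.empty((nx, ny, nz, len(scheme)), dtype=complex)
    for n, (te, theta) in enumerate(zip(echo_times_ms, thetas)):
        ramp = np.exp(2j * np.pi * gt.b0_offset_hz * te * 1e-3)
        data[..., n] = (water + fat * np.exp(1j * theta)) * ramp
    data += _complex_noise(rng, noise_sigma, data.shape)
    return MultiEchoVolume(
        data=data,
        echo_times_ms=tuple(float(t) for t in echo_times_ms),
        voxel_dims_mm=gt.voxel_dims_mm,
        phase_scheme=scheme,
        noise_sigma=noise_sigma,
        rng_seed=rng_seed,
    )


def simulate_multiecho_t2(
    gt: GroundTruth,
    echo_times_ms: Sequence[float] = T2_TES_MS,
    noise_sigma: float = 0.0,
    rng_seed: int = 0,
) -> MultiEchoVolume:
    """Spin-echo train: |S0 exp(-TE/T2) + complex noise| per echo (magnitude)."""
    tes = np.asarray(echo_times_ms, dtype=float)
    if np.any(tes <= 0):
        raise ValueError("all echo times must be positive")
    rng = np.random.default_rng(rng_seed)
    muscle = gt.t2_ms > 0
    decay = np.zeros(gt.shape + (tes.size,))
    decay[muscle] = np.exp(-tes[None, :] / gt.t2_ms[muscle, None])
    signal = gt.proton_density[..., None] * decay
    signal = np.abs(signal + _complex_noise(rng, noise_sigma, signal.shape))
    return MultiEchoVolume(
        data=signal,
        echo_times_ms=tuple(tes),
        voxel_dims_mm=gt.voxel_dims_mm,
        noise_sigma=noise_sigma,
        rng_seed=rng_seed,
    )


def simulate_dwi(
    gt: GroundTruth,
    b_s_per_mm2: float = 450.0,
    directions: Optional[np.ndarray] = None,
    n_b0: int = 1,
    noise_sigma: float = 0.0,
    rng_seed: int = 0,
) -> DiffusionVolume:
    """Stejskal-Tanner acquisition: S = S0 exp(-b g^T D g) + noise.

    Fat signal is omitted (fat-suppressed acquisition); S0 is the proton
    density map.  Tensor components are in 1e-3 mm^2/s, so the exponent uses
    b in s/mm^2 scaled accordingly.
    """
    dirs = TWELVE_DIRECTIONS if directions is None else np.asarray(directions, float)
    norms = np.linalg.norm(dirs, axis=1)
    if np.any(np.abs(norms - 1.0) > 1e-8):
        raise ValueError("diffusion directions must be unit-norm")
    rng = np.random.default_rng(rng_seed)
    nvol = n_b0 + dirs.shape[0]
    bvals = np.concatenate([np.zeros(n_b0), np.full(dirs.shape[0], b_s_per_mm2)])
    bvecs = np.vstack([np.zeros((n_b0, 3)), dirs])
    s0 = gt.proton_density
    dten = components_to_tensor(gt.tensor)  # (nx, ny, nz, 3, 3)
    data = np.empty(gt.shape + (nvol,))
    for i in range(nvol):
        if bvals[i] == 0:
            att = np.ones(gt.shape)
        else:
            g = bvecs[i]
            # g^T D g, D in 1e-3 mm^2/s -> exponent b * 1e-3 * quadform
            quad = np.einsum("...ij,i,j->...", dten, g, g)
            att = np.exp(-bvals[i] * 1e-3 * quad)
        vol = s0 * att
        data[..., i] = np.abs(vol + _complex_noise(rng, noise_sigma, vol.shape))
    return DiffusionVolume(
        data=data,
        bvals=bvals,
        bvecs=bvecs,
        voxel_dims_mm=gt.voxel_dims_mm,
        noise_sigma=noise_sigma,
        rng_seed=rng_seed,
    )
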