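"""Rasterize a :class:`PhantomSpec` into a labelled ground-truth volume."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Tuple

import numpy as np

from .spec import Compartment, PhantomSpec

# unique tensor component order used throughout: Dxx, Dyy, Dzz, Dxy, Dxz, Dyz
TENSOR_COMPONENTS = ("dxx", "dyy", "dzz", "dxy", "dxz", "dyz")


def tensor_from_eigensystem(
    eigenvalues: Tuple[float, float, float],
    principal_axis: Tuple[float, float, float],
) -> np.ndarray:
    """Build the symmetric 3x3 diffusion tensor with the given eigenvalues,
    aligning the largest-eigenvalue eigenvector with ``principal_axis``.

    The two secondary eigenvectors span the orthogonal complement; their
    in-plane orientation is chosen deterministically (Gram-Schmidt against
    the least-aligned Cartesian axis) and is irrelevant to the rotationally
    invariant metrics derived downstream.
    """
    v1 = np.asarray(principal_axis, dtype=float)
    v1 = v1 / np.linalg.norm(v1)
    seed_axis = np.eye(3)[np.argmin(np.abs(v1))]
    v2 = seed_axis - v1 * (seed_axis @ v1)
    v2 /= np.linalg.norm(v2)
    v3 = np.cross(v1, v2)
    rot = np.column_stack([v1, v2, v3])
    return rot @ np.diag(eigenvalues) @ rot.T


def tensor_to_components(d: np.ndarray) -> np.ndarray:
    """3x3 symmetric tensor -> 6-vector (Dxx, Dyy, Dzz, Dxy, Dxz, Dyz)."""
    return np.array([d[0, 0], d[1, 1], d[2, 2], d[0, 1], d[0, 2], d[1, 2]])


def components_to_tensor(c: np.ndarray) -> np.ndarray:
    """6-component vector(s) -> full symmetric 3x3 tensor(s); broadcasts."""
    c = np.asarray(c, dtype=float)
    out = np.empty(c.shape[:-1] + (3, 3), dtype=float)
    out[..., 0, 0] = c[..., 0]
    out[..., 1, 1] = c[..., 1]
    out[..., 2, 2] = c[..., 2]
    out[..., 0, 1] = out[..., 1, 0] = c[..., 3]
    out[..., 0, 2] = out[..., 2, 0] = c[..., 4]
    out[..., 1, 2] = out[..., 2, 1] = c[..., 5]
    return out


@dataclass
class GroundTruth:
    """Voxelized truth the simulators sample and the recovery tests compare to.

    Maps are zero in background; ``label_volume`` is 0 in background and the
    compartment label elsewhere.  ``tensor`` holds the 6 unique components
    (Dxx, Dyy, Dzz, Dxy, Dxz, Dyz) in 1e-3 mm^2/s.
    """

    label_volume: np.ndarray  # (nx, ny, nz) int
    proton_density: np.ndarray  # (nx, ny, nz)
    fat_fraction: np.ndarray
    t2_ms: np.ndarray
    tensor: np.ndarray  # (nx, ny, nz, 6)
    b0_offset_hz: np.ndarray
    voxel_dims_mm: Tuple[float, float, float]
    compartments: Dict[int, Compartment] = field(default_factory=dict)

    @property
    def shape(self) -> Tuple[int, int, int]:
        return self.label_volume.shape

    def mask(self, *labels: int) -> np.ndarray:
        """Boolean mask of the given compartment labels (all labels if none)."""
        if not labels:
            return self.label_volume > 0
        return np.isin(self.label_volume, labels)


def build_phantom(spec: PhantomSpec) -> GroundTruth:
    """Rasterize compartments onto the voxel grid and fill the truth maps.

    Voxels are assigned by centre-point inclusion.  Two compartments claiming
    the same voxel is a specification error and is reported with the voxel
    index rather than silently resolved.
    """
    nx, ny, nz = spec.grid
    dx, dy, dz = spec.voxel_dims_mm
    # voxel-centre coordinates, origin at FOV centre
    xs = (np.arange(nx) + 0.5) * dx - spec.fov_mm / 2.0
    ys = (np.arange(ny) + 0.5) * dy - spec.fov_mm / 2.0
    gx, gy = np.meshgrid(xs, ys, indexing="ij")

    labels = np.zeros((nx, ny, nz), dtype=np.int32)
    pd = np.zeros((nx, ny, nz))
    ff = np.zeros((nx, ny, nz))
    t2 = np.zeros((nx, ny, nz))
    b0 = np.zeros((nx, ny, nz))
    tensor = np.zeros((nx, ny, nz, 6))

    for comp in spec.compartments:
        comp_tensor = tensor_to_components(
            tensor_from_eigensystem(
                comp.tensor_eigenvalues_um2_per_ms, comp.principal_axis
            )
        )
        scales = comp.slice_scale if comp.slice_scale is not None else [1.0] * nz
        for k in range(nz):
            inside = comp.geometry.contains(gx, gy, scale=scales[k])
            clash = inside & (labels[:, :, k] > 0)
            if clash.any():
                i, j = np.argwhere(clash)[0]
                raise ValueError(
                    f"compartment {comp.name!r} (label {comp.label}) overlaps "
                    f"label {labels[i, j, k]} at voxel ({i}, {j}, {k})"
                )
            labels[inside, k] = comp.label
            pd[inside, k] = comp.proton_density
            ff[inside, k] = comp.fat_fraction
            t2[inside, k] = comp.t2_ms
            b0[inside, k] = comp.b0_offset_hz
            tensor[inside, k, :] = comp_tensor

    return GroundTruth(
        label_volume=labels,
        proton_density=pd,
        fat_fraction=ff,
        t2_ms=t2,
        tensor=tensor,
        b0_offset_hz=b0,
        voxel_dims_mm=spec.voxel_dims_mm,
        compartments={c.label: c for c in spec.compartments},
    )
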