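"""Phantom specification: geometry and tissue parameters of the digital hindlimb.

The phantom is a stack of axial slices over a square field of view.  Each
compartment (posterior muscle, anterior muscle, subcutaneous fat ring, ...)
is an ellipse or elliptical annulus whose in-plane semi-axes may be scaled
per slice, so that the stack has a well defined "largest" slice the way a
real limb does.  Every compartment carries the per-voxel ground truth the
simulators consume: proton density, fat fraction, T2, a diffusion tensor
(eigenvalues + principal axis) and a static field offset.
"""

from __future__ import annotations

import math
from typing import Literal, Optional, Sequence, Tuple, Union

import numpy as np
from pydantic import BaseModel, ConfigDict, Field, field_validator, model_validator


class Ellipse(BaseModel):
    """Axis-aligned-by-default ellipse, millimetres, origin at FOV centre."""

    kind: Literal["ellipse"] = "ellipse"
    center_mm: Tuple[float, float] = (0.0, 0.0)
    semi_axes_mm: Tuple[float, float]
    rotation_deg: float = 0.0

    @field_validator("semi_axes_mm")
    @classmethod
    def _positive_axes(cls, v: Tuple[float, float]) -> Tuple[float, float]:
        if v[0] <= 0 or v[1] <= 0:
            raise ValueError("ellipse semi-axes must be positive")
        return v

    def contains(self, x: np.ndarray, y: np.ndarray, scale: float = 1.0) -> np.ndarray:
        # `scale` shrinks the whole shape about the FOV centre (tapering limb)
        th = math.radians(self.rotation_deg)
        dx, dy = x - self.center_mm[0] * scale, y - self.center_mm[1] * scale
        u = dx * math.cos(th) + dy * math.sin(th)
        v = -dx * math.sin(th) + dy * math.cos(th)
        a, b = self.semi_axes_mm[0] * scale, self.semi_axes_mm[1] * scale
        return (u / a) ** 2 + (v / b) ** 2 <= 1.0

    def area_mm2(self, scale: float = 1.0) -> float:
        return math.pi * self.semi_axes_mm[0] * self.semi_axes_mm[1] * scale**2

    def max_extent_mm(self) -> float:
        c = math.hypot(*self.center_mm)
        return c + max(self.semi_axes_mm)


class Annulus(BaseModel):
    """Region between two concentric ellipses (e.g. a subcutaneous fat ring)."""

    kind: Literal["annulus"] = "annulus"
    center_mm: Tuple[float, float] = (0.0, 0.0)
    inner_semi_axes_mm: Tuple[float, float]
    outer_semi_axes_mm: Tuple[float, float]
    rotation_deg: float = 0.0

    @model_validator(mode="after")
    def _ordered(self) -> "Annulus":
        ia, oa = self.inner_semi_axes_mm, self.outer_semi_axes_mm
        if min(ia) <= 0 or min(oa) <= 0:
            raise ValueError("annulus semi-axes must be positive")
        if ia[0] >= oa[0] or ia[1] >= oa[1]:
            raise ValueError("annulus inner semi-axes must be smaller than outer")
        return self

    def contains(self, x: np.ndarray, y: np.ndarray, scale: float = 1.0) -> np.ndarray:
        th = math.radians(self.rotation_deg)
        dx, dy = x - self.center_mm[0] * scale, y - self.center_mm[1] * scale
        u = dx * math.cos(th) + dy * math.sin(th)
        v = -dx * math.sin(th) + dy * math.cos(th)
        ia, ib = (s * scale for s in self.inner_semi_axes_mm)
        oa, ob = (s * scale for s in self.outer_semi_axes_mm)
        inside_outer = (u / oa) ** 2 + (v / ob) ** 2 <= 1.0
        inside_inner = (u / ia) ** 2 + (v / ib) ** 2 < 1.0
        return inside_outer & ~inside_inner

    def area_mm2(self, scale: float = 1.0) -> float:
        oa, ob = self.outer_semi_axes_mm
        ia, ib = self.inner_semi_axes_mm
        return math.pi * (oa * ob - ia * ib) * scale**2

    def max_extent_mm(self) -> float:
        c = math.hypot(*self.center_mm)
        return c + max(self.outer_semi_axes_mm)


Geometry = Union[Ellipse, Annulus]


class Compartment(BaseModel):
    """One tissue compartment with its ground-truth MR parameters.

    ``tensor_eigenvalues_um2_per_ms`` are in 1e-3 mm^2/s (= um^2/ms), sorted
    descending; ``principal_axis`` is the eigenvector of the largest
    eigenvalue (muscle fibre direction).
    """

    label: int = Field(gt=0)
    name: str
    geometry: Geometry = Field(discriminator="kind")
    slice_scale: Optional[Sequence[float]] = None
    proton_density: float = Field(default=1.0, gt=0)
    fat_fraction: float = Field(default=0.0, ge=0.0, le=1.0)
    t2_ms: float = Field(default=20.0, gt=0)
    tensor_eigenvalues_um2_per_ms: Tuple[float, float, float] = (1.95, 1.45, 1.07)
    principal_axis: Tuple[float, float, float] = (0.0, 0.0, 1.0)
    b0_offset_hz: float = 0.0

    @field_validator("tensor_eigenvalues_um2_per_ms")
    @classmethod
    def _sorted_positive(cls, v):
        l1, l2, l3 = v
        if not (l1 >= l2 >= l3 > 0):
            raise ValueError("eigenvalues must satisfy l1 >= l2 >= l3 > 0")
        return v

    @field_validator("principal_axis")
    @classmethod
    def _unit(cls, v):
        n = math.sqrt(sum(c * c for c in v))
        if n == 0:
            raise ValueError("principal_axis must be nonzero")
        return tuple(c / n for c in v)


class PhantomSpec(BaseModel):
    """Full phantom description; seeds are mandatory, there is no global RNG."""

    model_config = ConfigDict(validate_assignment=True)

    grid: Tuple[int, int, int] = (128, 128, 7)
    fov_mm: float = Field(default=20.0, gt=0)
    slice_thickness_mm: float = Field(default=1.0, gt=0)
    compartments: Sequence[Compartment]
    noise_sigma: float = Field(default=0.0, ge=0)
    rng_seed: int = 0

    @model_validator(mode="after")
    def _check(self) -> "PhantomSpec":
        nx, ny, nz = self.grid
        if nx * ny * nz <= 0:
            raise ValueError("grid must have positive size")
        labels = [c.label for c in self.compartments]
        if len(set(labels)) != len(labels):
            raise ValueError("compartment labels must be unique")
        half = self.fov_mm / 2.0
        for c in self.compartments:
            scales = c.slice_scale or [1.0]
            if c.slice_scale is not None and len(c.slice_scale) != nz:
                raise ValueError(
                    f"compartment {c.name!r}: slice_scale must have {nz} entries"
                )
            if c.geometry.max_extent_mm() * max(scales) > half:
                raise ValueError(
                    f"compartment {c.name!r} extends beyond the field of view"
                )
        return self

    @property
    def voxel_dims_mm(self) -> Tuple[float, float, float]:
        nx, ny, _ = self.grid
        return (self.fov_mm / nx, self.fov_mm / ny, self.slice_thickness_mm)


# Table-style group presets for the nemaline-myopathy mouse study conditions:
# wild-type vs transgenic alpha-actin(Asp286Gly) hindlimb muscle.
GROUP_PARAMS = {
    "WT": dict(
        fat_fraction=0.0009,
        t2_ms=18.8,
        eigenvalues=(1.95, 1.45, 1.07),
    ),
    "Tg": dict(
        fat_fraction=0.0019,
        t2_ms=19.8,
        eigenvalues=(1.88, 1.34, 1.00),
    ),
}

# Axial profile of the limb: middle slice largest, tapering toward both ends.
# Linear scales; slice areas go as the square.
_SLICE_PROFILE = (0.45, 0.62, 0.866, 1.0, 0.866, 0.62, 0.45)

POSTERIOR_LABEL = 1
ANTERIOR_LABEL = 2
FAT_LABEL = 3


def mouse_hindlimb_spec(
    group: str = "WT",
    *,
    noise_sigma: float = 0.0,
    rng_seed: int = 0,
    principal_axis: Tuple[float, float, float] = (0.0, 0.0, 1.0),
    fat_fraction: Optional[float] = None,
    t2_ms: Optional[float] = None,
    eigenvalues: Optional[Tuple[float, float, float]] = None,
) -> PhantomSpec:
    """Default two-muscle + fat-ring hindlimb phantom for one study group.

    The posterior compartment is the gastrocnemius-region ROI used for T2 and
    DTI statistics; the anterior compartment completes the muscle mask used
    for fat quantification and anatomy.  Muscle truth values default to the
    group means (WT or Tg).
    """
    if group not in GROUP_PARAMS:
        raise ValueError(f"unknown group {group!r}; expected one of {list(GROUP_PARAMS)}")
    p = GROUP_PARAMS[group]
    ff = p["fat_fraction"] if fat_fraction is None else fat_fraction
    t2 = p["t2_ms"] if t2_ms is None else t2_ms
    evs = p["eigenvalues"] if eigenvalues is None else eigenvalues
    prof = list(_SLICE_PROFILE)
    posterior = Compartment(
        label=POSTERIOR_LABEL,
        name="posterior_muscle",
        geometry=Ellipse(center_mm=(0.0, -1.5), semi_axes_mm=(3.8, 2.15)),
        slice_scale=prof,
        proton_density=1.0,
        fat_fraction=ff,
        t2_ms=t2,
        tensor_eigenvalues_um2_per_ms=evs,
        principal_axis=principal_axis,
        b0_offset_hz=8.0,
    )
    anterior = Compartment(
        label=ANTERIOR_LABEL,
        name="anterior_muscle",
        geometry=Ellipse(center_mm=(0.0, 2.3), semi_axes_mm=(2.35, 1.56)),
        slice_scale=prof,
        proton_density=1.0,
        fat_fraction=ff,
        t2_ms=t2,
        tensor_eigenvalues_um2_per_ms=evs,
        principal_axis=principal_axis,
        b0_offset_hz=-5.0,
    )
    fat_ring = Compartment(
        label=FAT_LABEL,
        name="subcutaneous_fat",
        geometry=Annulus(
            center_mm=(0.0, 0.0),
            inner_semi_axes_mm=(6.3, 6.3),
            outer_semi_axes_mm=(7.1, 7.1),
        ),
        slice_scale=prof,
        proton_density=0.9,
        fat_fraction=0.9,
        t2_ms=35.0,
        tensor_eigenvalues_um2_per_ms=(1.0, 0.99, 0.98),
        b0_offset_hz=20.0,
    )
    return PhantomSpec(
        compartments=[posterior, anterior, fat_ring],
        noise_sigma=noise_sigma,
        rng_seed=rng_seed,
    )
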