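"""3D gland reconstruction from per-slice superellipse fits.

A full 3D prostate model is an ordered stack of fitted slice parameter
vectors: at least three annotated slices (base, mid-gland, apex) anchor
the stack, and every intermediate axial plane gets its parameters by
component-wise linear interpolation.  The rotation angle is interpolated
along the shortest arc on the circle so that the +-pi seam never produces
a spurious half-turn.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .superellipse import (
    PARAM_NAMES,
    SliceGrid,
    SuperellipseParams,
    boundary_contour,
    rasterize,
)

__all__ = ["VolumeModel", "BinaryMask3D", "interpolate_params", "build_volume", "export_contours"]


@dataclass
class BinaryMask3D:
    """3D binary mask on a regular grid.

    ``data`` is indexed ``[z, y, x]``; ``spacing`` and ``origin`` are
    (x, y, z) in mm; ``orientation`` is an axis code (RAS by default,
    third axis superior-inferior).
    """

    data: np.ndarray
    spacing: tuple = (1.0, 1.0, 1.0)
    origin: tuple = (0.0, 0.0, 0.0)
    orientation: str = "RAS"

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError("mask data must be 3D")
        vals = np.unique(self.data)
        if not np.all(np.isin(vals, (0, 1))):
            raise ValueError("mask values must be 0/1")
        self.data = self.data.astype(np.uint8)
        if any(s <= 0 for s in self.spacing):
            raise ValueError("spacing must be positive")

    @property
    def volume_mm3(self) -> float:
        return float(self.data.sum()) * float(np.prod(self.spacing))

    def z_coords(self) -> np.ndarray:
        return self.origin[2] + np.arange(self.data.shape[0]) * self.spacing[2]


@dataclass
class VolumeModel:
    """Ordered stack of (z, parameter-vector) pairs defining the gland."""

    entries: list  # [(z_mm, SuperellipseParams)]
    grid: SliceGrid
    z_spacing: float = 2.0
    regions: list | None = None  # optional per-entry base/mid/apex labels

    def __post_init__(self):
        if len(self.entries) < 3:
            raise ValueError("a volume model needs at least 3 annotated slices")
        zs = [z for z, _ in self.entries]
        if not np.all(np.diff(zs) > 0):
            raise ValueError("slice z positions must be strictly increasing")
        for _, p in self.entries:
            p.validate()
        if self.z_spacing <= 0:
            raise ValueError("z spacing must be positive")
        if self.regions is not None:
            if len(self.regions) != len(self.entries):
                raise ValueError("one region label per entry required")
            needed = {"base", "mid", "apex"}
            if not needed <= set(self.regions):
                raise ValueError("model must include base, mid and apex slices")

    @property
    def z_range(self) -> tuple:
        return self.entries[0][0], self.entries[-1][0]


def _wrap_angle(a: float) -> float:
    return float((a + np.pi) % (2 * np.pi) - np.pi)


def interpolate_params(model: VolumeModel, z: float) -> SuperellipseParams:
    """Linearly interpolate the parameter stack at axial position ``z``.

    All components interpolate linearly between the bracketing annotated
    slices except the rotation, which follows the shortest angular arc.
    At an annotated z the stored parameters are returned exactly.
    """
    z_min, z_max = model.z_range
    if not (z_min - 1e-9 <= z <= z_max + 1e-9):
        raise ValueError(f"z={z} outside the annotated range [{z_min}, {z_max}]")
    zs = np.array([e[0] for e in model.entries])
    k = int(np.searchsorted(zs, z, side="right")) - 1
    k = min(max(k, 0), len(zs) - 2)
    z0, p0 = model.entries[k]
    z1, p1 = model.entries[k + 1]
    if abs(z - z0) < 1e-12:
        return p0
    if abs(z - z1) < 1e-12:
        return p1
    f = (z - z0) / (z1 - z0)
    vals = {}
    for name in PARAM_NAMES:
        v0, v1 = getattr(p0, name), getattr(p1, name)
        if name == "r":
            vals[name] = _wrap_angle(v0 + f * _wrap_angle(v1 - v0))
        else:
            vals[name] = (1 - f) * v0 + f * v1
    return SuperellipseParams(**vals).validate()


def build_volume(model: VolumeModel) -> BinaryMask3D:
    """Rasterize the interpolated parameter stack into a 3D binary mask.

    Axial planes are laid at ``z_spacing`` steps across the annotated z
    range (both extreme slices included); the model does not extrapolate
    beyond the base and apex slices.
    """
    z_min, z_max = model.z_range
    n = int(np.floor((z_max - z_min) / model.z_spacing + 1e-9)) + 1
    zs = z_min + np.arange(n) * model.z_spacing
    if zs[-1] < z_max - 1e-9:
        zs = np.append(zs, z_max)
    slices = []
    for z in zs:
        p = interpolate_params(model, z)
        slices.append(rasterize(p, model.grid))
    data = np.stack(slices).astype(np.uint8)
    labels, ncomp = ndimage.label(data)
    if ncomp > 1:  # keep the gland, drop stray voxels from extreme deformations
        sizes = ndimage.sum_labels(data, labels, index=np.arange(1, ncomp + 1))
        data = (labels == 1 + int(np.argmax(sizes))).astype(np.uint8)
    return BinaryMask3D(
        data=data,
        spacing=(model.grid.spacing_x, model.grid.spacing_y, float(model.z_spacing)),
        origin=(model.grid.origin[0], model.grid.origin[1], float(z_min)),
    )


def export_contours(
    model: VolumeModel, n_points_per_slice: int = 12, include_interpolated: bool = False
) -> list:
    """Sample each model slice contour at equal arc length for user editing.

    Returns ``[(z_mm, (n, 2) points), ...]`` with every point lying exactly
    on the model boundary, ready to be written as 3D-Slicer markups for the
    second user iteration.
    """
    if n_points_per_slice < 4:
        raise ValueError("need at least 4 exported points per slice")
    if include_interpolated:
        mask = build_volume(model)
        zs = mask.z_coords()
    else:
        zs = [z for z, _ in model.entries]
    out = []
    for z in zs:
        p = interpolate_params(model, float(z))
        c = boundary_contour(p, n_points_per_slice, equal_arclength=True)
        out.append((float(z), c.vertices))
    return out
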