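"""Synthetic prostate phantoms, simulated annotators, registration pairs.

The phantom family mirrors the anatomy the shape model is built for: a
gland of roughly 40-50 mm axial extent whose axial cross-sections are
deformable superellipses, largest at mid-gland and shrinking toward base
and apex (a tapered ellipsoid), with mild tapering and a posterior
bending at mid-gland standing in for the deformation a transrectal
transducer induces.  Grids use TRUS-like anisotropy (0.5 mm in-plane,
2 mm between slices).  No speckle or intensity texture is simulated: the
segmentation method consumes only points and masks.

Everything is deterministic given the spec's seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .fitting import AnnotatedSlice
from .registration import AffineTransform3D, apply_transform
from .superellipse import SliceGrid, SuperellipseParams, boundary_contour
from .volume import BinaryMask3D, VolumeModel, build_volume, interpolate_params

__all__ = ["PhantomSpec", "generate_phantom", "simulate_annotator", "make_registration_pair"]


def _default_stack() -> list:
    """Five-entry stack spanning 40 mm: tapered, posteriorly bent gland."""
    cx, cy = 32.0, 32.0
    rows = [
        # z,   ax,   ay,   eps,  t,    b
        (0.0, 12.0, 10.0, 2.0, 0.05, 0.000),   # apex
        (10.0, 18.0, 15.0, 2.2, 0.12, 0.006),
        (20.0, 22.0, 18.0, 2.4, 0.20, 0.010),  # mid-gland
        (30.0, 18.5, 15.5, 2.2, 0.12, 0.006),
        (40.0, 13.0, 10.5, 2.0, 0.05, 0.000),  # base
    ]
    return [
        (z, SuperellipseParams(ax=ax, ay=ay, lx=cx, ly=cy, r=0.1, eps=eps, t=t, b=b))
        for z, ax, ay, eps, t, b in rows
    ]


@dataclass
class PhantomSpec:
    """Ground-truth phantom definition plus annotator behavior."""

    stack: list = field(default_factory=_default_stack)
    grid: SliceGrid = field(
        default_factory=lambda: SliceGrid(rows=128, cols=128, spacing_x=0.5, spacing_y=0.5)
    )
    z_spacing: float = 2.0
    seed: int = 0
    annotator_sigma_mm: float = 1.0
    points_per_region: dict = field(default_factory=lambda: {"base": 4, "mid": 10, "apex": 4})

    def __post_init__(self):
        if self.annotator_sigma_mm < 0:
            raise ValueError("annotator noise sigma must be nonnegative")
        mins = {"base": 4, "mid": 6, "apex": 4}
        for region, n in self.points_per_region.items():
            if n < mins[region]:
                raise ValueError(f"{region} needs at least {mins[region]} points")

    def model(self) -> VolumeModel:
        return VolumeModel(entries=list(self.stack), grid=self.grid, z_spacing=self.z_spacing)


def generate_phantom(spec: PhantomSpec) -> tuple:
    """Rasterize the ground-truth stack into a 3D mask.

    Returns ``(BinaryMask3D, VolumeModel)`` -- the dense mask built by
    per-plane parameter interpolation plus the exact generating model.
    """
    model = spec.model()
    return build_volume(model), model


def _region_slices(model: VolumeModel) -> dict:
    """Pick one apex, one mid and one base plane from the model's z range.

    The apex is the inferior extreme, the base the superior extreme, and
    the mid-gland the plane of largest semi-axis product.
    """
    zs = np.array([z for z, _ in model.entries])
    areas = [p.ax * p.ay for _, p in model.entries]
    return {
        "apex": float(zs[0]),
        "mid": float(zs[int(np.argmax(areas))]),
        "base": float(zs[-1]),
    }


def simulate_annotator(
    model: VolumeModel, spec: PhantomSpec, mid_model: str = "bspline"
) -> list:
    """Emulate a physician clicking points on base, mid and apex contours.

    Points are sampled at equal arc length on the true slice contour (with
    a random phase) and jittered with isotropic Gaussian noise of
    ``spec.annotator_sigma_mm``.  Base and apex slices get few points fit
    with the superellipse directly; the mid-gland gets more and, by
    default, the B-spline pathway.
    """
    rng = np.random.default_rng(spec.seed)
    picks = _region_slices(model)
    out = []
    for region in ("base", "mid", "apex"):
        z = picks[region]
        n = spec.points_per_region[region]
        p = interpolate_params(model, z)
        contour = boundary_contour(p, 720, equal_arclength=True)
        phase = rng.integers(0, 720 // n)
        pts = contour.vertices[phase :: 720 // n][:n].copy()
        pts += rng.normal(scale=spec.annotator_sigma_mm, size=pts.shape)
        out.append(
            AnnotatedSlice(
                slice_index=int(round((z - model.z_range[0]) / model.z_spacing)),
                z_mm=z,
                points=pts,
                region=region,
                model=mid_model if region == "mid" else "superellipse",
            )
        )
    return out


def make_registration_pair(
    mask: BinaryMask3D,
    perturbation: AffineTransform3D,
    target_spacing: tuple = (0.8, 0.8, 1.6),
    pad_mm: float = 5.0,
) -> tuple:
    """Build a (fixed, moving, true-transform) triple for registration tests.

    ``moving`` is the input mask resampled under ``perturbation`` onto a
    grid with different spacing and origin, emulating the geometry
    difference between MRI- and TRUS-derived masks.  The returned true
    transform maps moving-frame points to fixed-frame points, so composing
    it with a recovered fixed-to-moving registration transform should give
    the identity.
    """
    size = np.array(mask.data.shape[::-1], dtype=float)
    corners_idx = np.array(
        [[i, j, k] for i in (0, size[0] - 1) for j in (0, size[1] - 1) for k in (0, size[2] - 1)]
    )
    corners = np.asarray(mask.origin) + corners_idx * np.asarray(mask.spacing)
    # moving grid must cover the fixed extent pulled back through the perturbation
    inv = perturbation.inverse()
    moved = inv.apply_points(corners)
    lo = moved.min(axis=0) - pad_mm
    hi = moved.max(axis=0) + pad_mm
    spacing = np.asarray(target_spacing, dtype=float)
    nvox = np.ceil((hi - lo) / spacing).astype(int) + 1
    reference = BinaryMask3D(
        data=np.zeros((int(nvox[2]), int(nvox[1]), int(nvox[0])), dtype=np.uint8),
        spacing=tuple(spacing),
        origin=tuple(lo),
    )
    moving = apply_transform(mask, perturbation, reference)
    return mask, moving, perturbation
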