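"""Segmentation-based MRI-TRUS registration.

Both modalities are reduced to their prostate segmentation masks, which
sidesteps the intensity mismatch between MRI and ultrasound.  Each mask
goes through the same preprocessing chain: crop to the mask bounding box
plus a 10 mm margin, resample to 0.3 mm isotropic voxels (nearest
neighbor for masks), Gaussian smoothing (sigma = 3 voxels), and a signed
Euclidean distance map (negative inside).  Distance maps from the two
modalities then live on the same intensity scale, so the sum of squared
differences (SSD) is a meaningful dissimilarity, minimized by a
regular-step gradient descent over a rigid and then a full affine
transform.  Initialization is either geometric (image centers) or from
matched anatomical landmarks (urethra at base, verumontanum, urethra at
apex) via a least-squares rigid fit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import SimpleITK as sitk
from scipy import ndimage

from .volume import BinaryMask3D

__all__ = [
    "ImageVolume",
    "AffineTransform3D",
    "LandmarkSet",
    "RegistrationResult",
    "crop_voi",
    "resample_isotropic",
    "gaussian_smooth",
    "signed_distance_map",
    "init_center",
    "init_landmarks",
    "ssd",
    "register",
    "apply_transform",
    "preprocess_mask",
]


@dataclass
class ImageVolume:
    """3D scalar image; ``data`` indexed [z, y, x], spacing/origin (x, y, z) mm."""

    data: np.ndarray
    spacing: tuple = (1.0, 1.0, 1.0)
    origin: tuple = (0.0, 0.0, 0.0)
    orientation: str = "RAS"

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 3:
            raise ValueError("volume data must be 3D")
        if any(s <= 0 for s in self.spacing):
            raise ValueError("spacing must be positive")

    def geometric_center(self) -> np.ndarray:
        """Physical center of the voxel lattice (mm), from origin/size/spacing."""
        size = np.array(self.data.shape[::-1], dtype=float)  # (x, y, z)
        return np.asarray(self.origin) + (size - 1) / 2.0 * np.asarray(self.spacing)


def _to_sitk(vol) -> sitk.Image:
    img = sitk.GetImageFromArray(np.asarray(vol.data, dtype=np.float64))
    img.SetSpacing(tuple(float(s) for s in vol.spacing))
    img.SetOrigin(tuple(float(o) for o in vol.origin))
    return img


def _from_sitk(img: sitk.Image, binary: bool):
    arr = sitk.GetArrayFromImage(img)
    kw = dict(spacing=tuple(img.GetSpacing()), origin=tuple(img.GetOrigin()))
    if binary:
        return BinaryMask3D(data=(arr > 0.5).astype(np.uint8), **kw)
    return ImageVolume(data=arr, **kw)


@dataclass
class AffineTransform3D:
    """Affine map ``x -> A (x - c) + c + t`` in physical mm coordinates."""

    matrix: np.ndarray = field(default_factory=lambda: np.eye(3))
    translation: np.ndarray = field(default_factory=lambda: np.zeros(3))
    center: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=float).reshape(3, 3)
        self.translation = np.asarray(self.translation, dtype=float).reshape(3)
        self.center = np.asarray(self.center, dtype=float).reshape(3)
        if abs(np.linalg.det(self.matrix)) < 1e-12:
            raise ValueError("affine matrix must be invertible")

    def to_sitk(self) -> sitk.AffineTransform:
        t = sitk.AffineTransform(3)
        t.SetMatrix(tuple(self.matrix.ravel()))
        t.SetCenter(tuple(self.center))
        t.SetTranslation(tuple(self.translation))
        return t

    @classmethod
    def from_sitk(cls, t: sitk.Transform) -> "AffineTransform3D":
        if isinstance(t, sitk.CompositeTransform):
            t = t.GetNthTransform(t.GetNumberOfTransforms() - 1)
        matrix = np.asarray(t.GetMatrix()).reshape(3, 3)
        return cls(matrix=matrix, translation=t.GetTranslation(), center=t.GetCenter())

    def apply_points(self, points) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        return (pts - self.center) @ self.matrix.T + self.center + self.translation

    def as_matrix4(self) -> np.ndarray:
        m = np.eye(4)
        m[:3, :3] = self.matrix
        m[:3, 3] = self.center + self.translation - self.matrix @ self.center
        return m

    def compose(self, other: "AffineTransform3D") -> "AffineTransform3D":
        """Return the map ``x -> self(other(x))``."""
        m = self.as_matrix4() @ other.as_matrix4()
        return AffineTransform3D(matrix=m[:3, :3], translation=m[:3, 3], center=np.zeros(3))

    def inverse(self) -> "AffineTransform3D":
        m = np.linalg.inv(self.as_matrix4())
        return AffineTransform3D(matrix=m[:3, :3], translation=m[:3, 3], center=np.zeros(3))


@dataclass
class LandmarkSet:
    """Named anatomical fiducials (e.g. UB, VM, UA) in physical mm."""

    points: dict  # name -> (x, y, z)
    frame: str = "RAS"

    def __post_init__(self):
        self.points = {k: np.asarray(v, dtype=float).reshape(3) for k, v in self.points.items()}

    def matched_arrays(self, other: "LandmarkSet") -> tuple:
        names = sorted(set(self.points) & set(other.points))
        if len(names) < 3:
            raise ValueError("landmark initialization needs >= 3 matched fiducials")
        a = np.stack([self.points[n] for n in names])
        b = np.stack([other.points[n] for n in names])
        if np.linalg.matrix_rank(a - a.mean(axis=0)) < 2:
            raise ValueError("landmarks are collinear")
        return a, b


def crop_voi(mask: BinaryMask3D, margin_mm: float = 10.0) -> BinaryMask3D:
    """Crop to the mask's bounding box dilated by ``margin_mm`` per side.

    The crop is clipped to the input extent; no padding is invented and
    every foreground voxel is preserved.
    """
    arr = mask.data.astype(bool)
    if not arr.any():
        raise ValueError("cannot crop an empty mask")
    nz = np.argwhere(arr)  # (z, y, x) indices
    lo_idx, hi_idx = nz.min(axis=0), nz.max(axis=0)
    sampling = np.array([mask.spacing[2], mask.spacing[1], mask.spacing[0]])
    pad = np.ceil(margin_mm / sampling).astype(int)
    lo = np.maximum(lo_idx - pad, 0)
    hi = np.minimum(hi_idx + pad, np.array(arr.shape) - 1)
    sub = arr[lo[0] : hi[0] + 1, lo[1] : hi[1] + 1, lo[2] : hi[2] + 1]
    new_origin = (
        mask.origin[0] + lo[2] * mask.spacing[0],
        mask.origin[1] + lo[1] * mask.spacing[1],
        mask.origin[2] + lo[0] * mask.spacing[2],
    )
    return BinaryMask3D(data=sub.astype(np.uint8), spacing=mask.spacing, origin=new_origin)


def resample_isotropic(vol, res_mm: float = 0.3, mode: str = "nearest"):
    """Resample a volume to isotropic voxels of ``res_mm``.

    Masks should use nearest-neighbor interpolation so values stay binary;
    the physical extent is preserved to within one voxel.
    """
    if res_mm <= 0:
        raise ValueError("resolution must be positive")
    if mode not in ("nearest", "linear"):
        raise ValueError(f"unknown interpolation mode {mode!r}")
    binary = isinstance(vol, BinaryMask3D)
    img = _to_sitk(vol)
    old_size = np.array(img.GetSize(), dtype=float)
    old_spacing = np.array(img.GetSpacing())
    new_size = np.maximum(np.round(old_size * old_spacing / res_mm), 1).astype(int)
    # keep voxel-edge extents aligned: shift the origin by half the spacing change
    new_origin = np.array(img.GetOrigin()) + (res_mm - old_spacing) / 2.0
    interp = sitk.sitkNearestNeighbor if mode == "nearest" else sitk.sitkLinear
    out = sitk.Resample(
        img,
        [int(s) for s in new_size],
        sitk.Transform(),
        interp,
        tuple(new_origin),
        (res_mm, res_mm, res_mm),
        img.GetDirection(),
        0.0,
        img.GetPixelID(),
    )
    return _from_sitk(out, binary=binary)


def gaussian_smooth(mask, sigma: float = 3.0) -> ImageVolume:
    """Smooth a binary mask with a normalized Gaussian, sigma in voxels."""
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    arr = np.asarray(mask.data, dtype=np.float64)
    sm = ndimage.gaussian_filter(arr, sigma=sigma, mode="constant")
    return ImageVolume(data=sm, spacing=mask.spacing, origin=mask.origin)


def signed_distance_map(mask) -> ImageVolume:
    """Signed Euclidean distance (mm) to the mask boundary, negative inside.

    The boundary is the set of foreground voxels with a 6-connected
    background neighbor; every voxel holds the exact Euclidean distance to
    the nearest boundary voxel center, computed with an exact Euclidean
    distance transform and signed negative inside the mask.
    """
    arr = np.asarray(mask.data) > 0.5
    if not arr.any() or arr.all():
        raise ValueError("signed distance needs both foreground and background")
    struct = ndimage.generate_binary_structure(3, 1)
    boundary = arr & ~ndimage.binary_erosion(arr, structure=struct, border_value=0)
    sampling = (mask.spacing[2], mask.spacing[1], mask.spacing[0])  # [z, y, x]
    dist = ndimage.distance_transform_edt(~boundary, sampling=sampling)
    dist[arr] *= -1.0
    return ImageVolume(data=dist, spacing=mask.spacing, origin=mask.origin)


def init_center(fixed, moving) -> AffineTransform3D:
    """Geometric initializer: identity rotation about the moving image's
    center, translated by the vector between the two image centers."""
    cf = ImageVolume.geometric_center(fixed)
    cm = ImageVolume.geometric_center(moving)
    return AffineTransform3D(matrix=np.eye(3), translation=cm - cf, center=cm)


def init_landmarks(fixed_lm: LandmarkSet, moving_lm: LandmarkSet) -> AffineTransform3D:
    """Least-squares rigid transform mapping fixed landmarks onto moving ones.

    Closed-form orthogonal Procrustes (SVD of the cross-covariance with a
    determinant correction), minimizing sum ||T(fixed_i) - moving_i||^2.
    """
    a, b = fixed_lm.matched_arrays(moving_lm)
    ca, cb = a.mean(axis=0), b.mean(axis=0)
    h = (a - ca).T @ (b - cb)
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    return AffineTransform3D(matrix=rot, translation=cb - ca, center=ca)


def ssd(a: ImageVolume, b: ImageVolume) -> float:
    """Sum of squared intensity differences over a common grid."""
    if a.data.shape != b.data.shape:
        raise ValueError("SSD requires identical grids")
    if not (np.allclose(a.spacing, b.spacing) and np.allclose(a.origin, b.origin)):
        raise ValueError("SSD requires identical grids")
    return float(np.sum((a.data - b.data) ** 2))


def preprocess_mask(
    mask: BinaryMask3D,
    margin_mm: float = 10.0,
    res_mm: float = 0.3,
    sigma: float = 3.0,
) -> ImageVolume:
    """Full preprocessing chain: crop -> isotropic resample -> smooth -> SDM."""
    voi = crop_voi(mask, margin_mm=margin_mm)
    iso = resample_isotropic(voi, res_mm=res_mm, mode="nearest")
    smooth = gaussian_smooth(iso, sigma=sigma)
    sdm = signed_distance_map(
        BinaryMask3D(data=(smooth.data >= 0.5).astype(np.uint8), spacing=smooth.spacing,
                     origin=smooth.origin)
    )
    return sdm


@dataclass
class RegistrationResult:
    transform: AffineTransform3D
    final_metric: float
    initial_metric: float
    metric_trace: list
    converged: bool


def _euler_from_affine(t: AffineTransform3D) -> sitk.Euler3DTransform:
    e = sitk.Euler3DTransform()
    e.SetCenter(tuple(t.center))
    e.SetTranslation(tuple(t.translation))
    try:
        e.SetMatrix(tuple(t.matrix.ravel()))
    except RuntimeError:
        e.SetMatrix(tuple(t.matrix.ravel()), 1e-6)
    return e


def register(
    fixed_mask: BinaryMask3D,
    moving_mask: BinaryMask3D,
    init: str = "center",
    landmarks: tuple | None = None,
    margin_mm: float = 10.0,
    res_mm: float = 0.3,
    sigma: float = 3.0,
    learning_rate: float = 1.0,
    max_iterations: int = 200,
    affine_refine: bool = True,
    sampling_fraction: float = 0.05,
    seed: int = 1,
) -> RegistrationResult:
    """Register two segmentation masks through their signed distance maps.

    The returned transform maps fixed-frame points into the moving frame
    (the ITK resampling convention): apply it with :func:`apply_transform`
    to bring the moving mask onto the fixed grid.  Optimization is a
    rigid stage followed by a full affine stage, each a multi-resolution
    regular-step gradient descent on the mean of squared distance-map
    differences; if a stage fails to improve the metric its result is
    discarded in favor of the best transform so far.

    ``sampling_fraction`` controls the seeded random subset of voxels the
    metric is evaluated on during optimization (distance maps are smooth,
    so sparse sampling loses little accuracy and saves most of the cost);
    the reported initial/final metrics always use every voxel.
    """
    if init not in ("center", "landmarks"):
        raise ValueError("init must be 'center' or 'landmarks'")
    if init == "landmarks":
        if landmarks is None:
            raise ValueError("landmark initialization requires landmark sets")
        t0 = init_landmarks(*landmarks)
    fixed_sdm = preprocess_mask(fixed_mask, margin_mm, res_mm, sigma)
    moving_sdm = preprocess_mask(moving_mask, margin_mm, res_mm, sigma)
    if init == "center":
        t0 = init_center(fixed_sdm, moving_sdm)

    f_img = _to_sitk(fixed_sdm)
    m_img = _to_sitk(moving_sdm)

    trace: list = []

    def _make_method(shrink, smooth_sig):
        reg = sitk.ImageRegistrationMethod()
        reg.SetMetricAsMeanSquares()
        reg.SetInterpolator(sitk.sitkLinear)
        reg.SetOptimizerAsRegularStepGradientDescent(
            learningRate=learning_rate,
            minStep=1e-4,
            numberOfIterations=max_iterations,
            relaxationFactor=0.5,
        )
        reg.SetOptimizerScalesFromPhysicalShift()
        if sampling_fraction < 1.0:
            reg.SetMetricSamplingStrategy(reg.RANDOM)
            reg.SetMetricSamplingPercentage(sampling_fraction, seed)
        reg.SetShrinkFactorsPerLevel(shrink)
        reg.SetSmoothingSigmasPerLevel(smooth_sig)
        reg.SmoothingSigmasAreSpecifiedInPhysicalUnitsOff()
        reg.AddCommand(
            sitk.sitkIterationEvent, lambda: trace.append(float(reg.GetMetricValue()))
        )
        return reg

    def _metric_for(transform: sitk.Transform) -> float:
        reg = sitk.ImageRegistrationMethod()
        reg.SetMetricAsMeanSquares()
        reg.SetInterpolator(sitk.sitkLinear)
        reg.SetInitialTransform(transform, inPlace=False)
        return float(reg.MetricEvaluate(f_img, m_img))

    best_t = t0.to_sitk()
    initial_metric = _metric_for(best_t)
    best_metric = initial_metric
    converged = True

    # rigid stage
    rigid = _euler_from_affine(t0)
    reg = _make_method([4, 2, 1], [2, 1, 0])
    reg.SetInitialTransform(rigid, inPlace=True)
    reg.Execute(f_img, m_img)
    m_rigid = _metric_for(rigid)
    if m_rigid <= best_metric:
        best_metric = m_rigid
        best_t = rigid
    else:
        converged = False

    if affine_refine:
        aff = AffineTransform3D.from_sitk(best_t).to_sitk()
        reg = _make_method([2, 1], [1, 0])
        reg.SetInitialTransform(aff, inPlace=True)
        reg.Execute(f_img, m_img)
        m_aff = _metric_for(aff)
        if m_aff <= best_metric:
            best_metric = m_aff
            best_t = aff
        else:
            converged = False

    return RegistrationResult(
        transform=AffineTransform3D.from_sitk(best_t),
        final_metric=best_metric,
        initial_metric=initial_metric,
        metric_trace=trace,
        converged=converged,
    )


def apply_transform(mask, transform: AffineTransform3D, reference) -> BinaryMask3D:
    """Resample ``mask`` onto ``reference``'s grid under ``transform``.

    ``transform`` maps reference-frame (fixed) points into the mask's
    (moving) frame; nearest-neighbor interpolation keeps the output binary.
    """
    img = _to_sitk(mask)
    ref = _to_sitk(reference)
    out = sitk.Resample(img, ref, transform.to_sitk(), sitk.sitkNearestNeighbor, 0.0)
    return _from_sitk(out, binary=True)
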