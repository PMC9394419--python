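"""Deformable superellipse geometry.

A superellipse is the generalized ellipse ``|x/ax|^eps + |y/ay|^eps = 1``:
``eps = 2`` gives an ellipse, smaller values bulge toward a rectangle,
larger values pinch toward a diamond.  The deformable variant adds four
global deformations -- rotation, linear tapering along the y axis,
circular bending along the y axis, and translation -- so that the eight
scalar parameters can reproduce the common axial cross-sections of the
prostate gland, including the narrowing toward the apex and the posterior
indentation induced by a transrectal transducer.

All geometry lives in slice-plane physical millimetres; pixel grids enter
only through :class:`SliceGrid`, which converts between pixel indices and
mm with a pixel-center convention (x = column axis, y = row axis).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage
from shapely import geometry as _sgeom
from shapely.geometry.polygon import orient as _orient

__all__ = [
    "SuperellipseParams",
    "Contour2D",
    "SliceGrid",
    "sample_parametric",
    "inside_outside",
    "apply_deformations",
    "invert_deformations",
    "rasterize",
    "contour_of",
]

PARAM_NAMES = ("ax", "ay", "lx", "ly", "r", "eps", "t", "b")

#: parameters describing intrinsic shape (Gaussian prior applies to these);
#: the remaining four (lx, ly, r and implicitly the pose) get a flat prior.
SHAPE_PARAM_NAMES = ("ax", "ay", "eps", "t", "b")


@dataclass
class SuperellipseParams:
    """The eight-parameter vector of a deformable superellipse.

    Parameters
    ----------
    ax, ay : float
        Semi-axis lengths along x and y, in mm.  Must be positive.
    lx, ly : float
        Translation of the shape center, in mm.
    r : float
        Rotation angle in radians, positive counter-clockwise.
    eps : float
        Squareness exponent (2 = ellipse).  Must be positive.
    t : float
        Linear tapering coefficient along y (dimensionless).  ``|t| < 1``
        keeps the tapering scale factor positive over the shape.
    b : float
        Circular bending curvature along y, in 1/mm.  ``|b| * ay < 1``
        keeps the bending map injective over the shape's extent.
    """

    ax: float
    ay: float
    lx: float = 0.0
    ly: float = 0.0
    r: float = 0.0
    eps: float = 2.0
    t: float = 0.0
    b: float = 0.0

    def validate(self) -> "SuperellipseParams":
        if not np.all(np.isfinite(self.as_array())):
            raise ValueError("superellipse parameters must be finite")
        if self.ax <= 0 or self.ay <= 0:
            raise ValueError(f"semi-axes must be positive (ax={self.ax}, ay={self.ay})")
        if self.eps <= 0:
            raise ValueError(f"squareness exponent must be positive (eps={self.eps})")
        if abs(self.t) >= 1:
            raise ValueError(f"|t| must be < 1 for a positive taper factor (t={self.t})")
        if abs(self.b) * self.ay >= 1:
            raise ValueError(
                f"|b|*ay must be < 1 for an injective bending map (b={self.b}, ay={self.ay})"
            )
        return self

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in PARAM_NAMES], dtype=float)

    @classmethod
    def from_array(cls, vec) -> "SuperellipseParams":
        vec = np.asarray(vec, dtype=float)
        if vec.shape != (8,):
            raise ValueError("parameter vector must have 8 components")
        return cls(**dict(zip(PARAM_NAMES, vec)))

    def replace(self, **kwargs) -> "SuperellipseParams":
        return replace(self, **kwargs)


@dataclass
class Contour2D:
    """A closed planar polygon in slice-plane mm coordinates (CCW)."""

    vertices: np.ndarray
    closed: bool = True

    def __post_init__(self):
        self.vertices = np.asarray(self.vertices, dtype=float)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 2:
            raise ValueError("vertices must be an (n, 2) array")
        if len(self.vertices) < 3:
            raise ValueError("a contour needs at least 3 vertices")

    def ring(self) -> _sgeom.LinearRing:
        return _sgeom.LinearRing(self.vertices)

    def polygon(self) -> _sgeom.Polygon:
        return _sgeom.Polygon(self.vertices)

    @property
    def area(self) -> float:
        return self.polygon().area

    @property
    def perimeter(self) -> float:
        return self.ring().length


@dataclass
class SliceGrid:
    """Pixel grid of one axial slice: shape, mm spacing and mm origin.

    ``origin`` is the mm coordinate of the *center* of pixel (row 0, col 0);
    row index maps to y, column index to x.
    """

    rows: int
    cols: int
    spacing_x: float = 1.0
    spacing_y: float = 1.0
    origin: tuple = (0.0, 0.0)

    def __post_init__(self):
        if self.rows < 1 or self.cols < 1:
            raise ValueError("grid must have at least one pixel")
        if self.spacing_x <= 0 or self.spacing_y <= 0:
            raise ValueError("pixel spacing must be positive")

    def pixel_centers(self):
        """Return (X, Y) mm coordinate arrays of shape (rows, cols)."""
        x = self.origin[0] + np.arange(self.cols) * self.spacing_x
        y = self.origin[1] + np.arange(self.rows) * self.spacing_y
        return np.meshgrid(x, y)

    def mm_to_index(self, points):
        """Map (n, 2) mm points to fractional (row, col) indices."""
        pts = np.asarray(points, dtype=float)
        col = (pts[:, 0] - self.origin[0]) / self.spacing_x
        row = (pts[:, 1] - self.origin[1]) / self.spacing_y
        return np.column_stack([row, col])


def sample_parametric(p: SuperellipseParams, thetas) -> np.ndarray:
    """Sample the centered, undeformed superellipse boundary.

    Implements the parametric form
    ``x = ax * |cos t|^(2/eps) * sign(cos t)``,
    ``y = ay * |sin t|^(2/eps) * sign(sin t)``.
    Deformation parameters of ``p`` are ignored.
    """
    p.validate()
    th = np.asarray(thetas, dtype=float)
    if not np.all(np.isfinite(th)):
        raise ValueError("angles must be finite")
    c, s = np.cos(th), np.sin(th)
    e = 2.0 / p.eps
    x = p.ax * np.abs(c) ** e * np.sign(c)
    y = p.ay * np.abs(s) ** e * np.sign(s)
    return np.column_stack([x, y])


def inside_outside(p: SuperellipseParams, points) -> np.ndarray:
    """Inside-outside function ``f = |x/ax|^eps + |y/ay|^eps``.

    ``f = 1`` on the boundary, ``< 1`` inside, ``> 1`` outside.  Operates
    in the centered, undeformed frame; map measured points back with
    :func:`invert_deformations` first if needed.
    """
    p.validate()
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    return (
        np.abs(pts[..., 0] / p.ax) ** p.eps + np.abs(pts[..., 1] / p.ay) ** p.eps
    )


def _rotate(points, r):
    c, s = np.cos(r), np.sin(r)
    x, y = points[:, 0], points[:, 1]
    return np.column_stack([c * x - s * y, s * x + c * y])


def _taper(points, t, ay):
    # x' = (t*y/ay + 1) * x : linear scaling of the x-extent with height
    x, y = points[:, 0], points[:, 1]
    return np.column_stack([(t * y / ay + 1.0) * x, y])


def _bend_sagitta(y, b):
    # displacement of the x axis along a circular arc of curvature b:
    # the sagitta (1 - sqrt(1 - (b*y)^2)) / b of the arc at height y
    arg = 1.0 - (b * y) ** 2
    if np.any(arg <= 0):
        raise ValueError("point outside the injective range of the bending map")
    return (1.0 - np.sqrt(arg)) / b


def _bend(points, b):
    if b == 0:
        return points
    x, y = points[:, 0], points[:, 1]
    return np.column_stack([x + _bend_sagitta(y, b), y])


def apply_deformations(p: SuperellipseParams, points) -> np.ndarray:
    """Map centered-frame points to the deformed (image) frame.

    The deformations compose in the fixed order rotation -> tapering ->
    bending -> translation.  With all deformation parameters zero the map
    is the identity.
    """
    p.validate()
    pts = np.atleast_2d(np.asarray(points, dtype=float)).copy()
    pts = _rotate(pts, p.r)
    pts = _taper(pts, p.t, p.ay)
    pts = _bend(pts, p.b)
    pts[:, 0] += p.lx
    pts[:, 1] += p.ly
    return pts


def invert_deformations(p: SuperellipseParams, points) -> np.ndarray:
    """Map deformed-frame points back to the centered frame.

    Exactly inverts :func:`apply_deformations` (translation, bending,
    tapering, rotation undone in reverse order).  Raises for points whose
    height lies outside the injective range of the bending arc.
    """
    p.validate()
    pts = np.atleast_2d(np.asarray(points, dtype=float)).copy()
    pts[:, 0] -= p.lx
    pts[:, 1] -= p.ly
    if p.b != 0:
        pts[:, 0] -= _bend_sagitta(pts[:, 1], p.b)
    factor = p.t * pts[:, 1] / p.ay + 1.0
    if np.any(factor <= 0):
        raise ValueError("point outside the injective range of the tapering map")
    pts[:, 0] /= factor
    return _rotate(pts, -p.r)


def _has_holes(mask: np.ndarray) -> bool:
    return bool(np.any(ndimage.binary_fill_holes(mask) & ~mask))


def rasterize(
    p: SuperellipseParams, grid: SliceGrid, max_closing_iter: int = 5
) -> np.ndarray:
    """Rasterize a deformable superellipse to a binary slice mask.

    Builds the set of centered-lattice points with inside-outside value
    <= 1 (lattice supersampled 8x per pixel axis), forward-maps them
    through the deformations, and marks each grid pixel whose estimated
    coverage by mapped points is at least half the pixel area -- for a
    locally straight boundary this coincides with the center-inside rule.
    Each mapped point is weighted by the local area Jacobian of the
    deformation (only the tapering changes area) so that coverage stays
    unbiased where the map expands or shrinks.  Morphological closing
    (3x3 square) repairs any holes the scatter leaves.
    """
    p.validate()
    ss = 8  # supersampling factor per pixel axis
    hx, hy = grid.spacing_x / ss, grid.spacing_y / ss
    nx = int(np.ceil(p.ax / hx)) + ss
    ny = int(np.ceil(p.ay / hy)) + ss
    cx = (np.arange(-nx, nx + 1) + 0.5) * hx
    cy = (np.arange(-ny, ny + 1) + 0.5) * hy
    X, Y = np.meshgrid(cx, cy)
    pts = np.column_stack([X.ravel(), Y.ravel()])
    pts = pts[inside_outside(p, pts) <= 1.0]
    mapped = apply_deformations(p, pts)
    # area Jacobian of rotation->taper->bend->translate: taper only
    y_rot = np.sin(p.r) * pts[:, 0] + np.cos(p.r) * pts[:, 1]
    jac = p.t * y_rot / p.ay + 1.0

    idx = np.rint(grid.mm_to_index(mapped)).astype(int)
    keep = (
        (idx[:, 0] >= 0)
        & (idx[:, 0] < grid.rows)
        & (idx[:, 1] >= 0)
        & (idx[:, 1] < grid.cols)
    )
    if not np.any(keep):
        raise ValueError("shape rasterizes to an empty mask on this grid")
    coverage = np.zeros((grid.rows, grid.cols), dtype=float)
    np.add.at(coverage, (idx[keep, 0], idx[keep, 1]), jac[keep])
    mask = coverage >= ss * ss / 2.0
    if not mask.any():
        raise ValueError("shape rasterizes to an empty mask on this grid")

    kernel = np.ones((3, 3), dtype=bool)
    for _ in range(max_closing_iter):
        if not _has_holes(mask):
            break
        mask = ndimage.binary_closing(mask, structure=kernel)
    # guarantee the hole-free postcondition even for extreme deformations
    mask = ndimage.binary_fill_holes(mask)
    labels, n = ndimage.label(mask)
    if n > 1:
        sizes = ndimage.sum_labels(mask, labels, index=np.arange(1, n + 1))
        mask = labels == (1 + int(np.argmax(sizes)))
    return mask


def contour_of(mask: np.ndarray, grid: SliceGrid | None = None) -> Contour2D:
    """Trace the outer pixel-border polygon of a single-component mask.

    The polygon follows pixel borders (not iso-level interpolation), so a
    3x3 block of unit pixels yields a 3 mm square of perimeter 12 mm.
    Returned in mm coordinates, counter-clockwise.
    """
    mask = np.asarray(mask).astype(bool)
    if not mask.any():
        raise ValueError("cannot trace the contour of an empty mask")
    labels, n = ndimage.label(mask)
    if n != 1:
        raise ValueError(f"mask must have exactly one connected component (got {n})")
    if grid is None:
        grid = SliceGrid(rows=mask.shape[0], cols=mask.shape[1])

    rows, cols = np.nonzero(mask)
    sx, sy = grid.spacing_x, grid.spacing_y
    ox, oy = grid.origin
    boxes = [
        _sgeom.box(
            ox + (c - 0.5) * sx,
            oy + (r - 0.5) * sy,
            ox + (c + 0.5) * sx,
            oy + (r + 0.5) * sy,
        )
        for r, c in zip(rows, cols)
    ]
    from shapely.ops import unary_union

    poly = unary_union(boxes)
    if poly.geom_type != "Polygon":
        poly = max(poly.geoms, key=lambda g: g.area)
    poly = _orient(poly, sign=1.0)  # CCW exterior
    verts = np.asarray(poly.exterior.coords)[:-1]
    return Contour2D(vertices=verts, closed=True)


def boundary_contour(
    p: SuperellipseParams, n_points: int = 180, equal_arclength: bool = False
) -> Contour2D:
    """Dense polygonal approximation of the deformed model boundary.

    Samples the parametric boundary and forward-maps it through the
    deformations.  With ``equal_arclength`` the vertices are re-spaced to
    equal arc length along the deformed curve (used for contour export).
    """
    if n_points < 4:
        raise ValueError("need at least 4 boundary points")
    n_dense = max(n_points, 360) if equal_arclength else n_points
    thetas = np.linspace(0.0, 2.0 * np.pi, n_dense, endpoint=False)
    pts = apply_deformations(p, sample_parametric(p, thetas))
    if equal_arclength:
        closed = np.vstack([pts, pts[:1]])
        seg = np.linalg.norm(np.diff(closed, axis=0), axis=1)
        s = np.concatenate([[0.0], np.cumsum(seg)])
        target = np.linspace(0.0, s[-1], n_points, endpoint=False)
        x = np.interp(target, s, closed[:, 0])
        y = np.interp(target, s, closed[:, 1])
        pts = np.column_stack([x, y])
    return Contour2D(vertices=pts, closed=True)
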