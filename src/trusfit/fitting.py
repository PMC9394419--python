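"""Fitting a deformable superellipse (or B-spline contour) to sparse points.

The fit maximizes a posterior over the parameter vector: a point energy
(sum of squared point-to-boundary distances from the user's clicks to the
model contour) plus an optional Gaussian log-prior over the shape
parameters; pose parameters are box-bounded, playing the role of a uniform
prior.  Because the energy of a rasterized, morphologically closed mask is
piecewise constant in the parameters, the objective evaluated during
optimization uses the analytically deformed boundary polygon -- the exact
curve the rasterization approximates -- which keeps the landscape smooth
enough for a simplex search while describing the same shape.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import shapely
from scipy import interpolate as _interp
from scipy import optimize as _opt

from .superellipse import (
    Contour2D,
    SHAPE_PARAM_NAMES,
    SuperellipseParams,
    boundary_contour,
)

__all__ = [
    "AnnotatedSlice",
    "PriorConfig",
    "FitConfig",
    "FitResult",
    "energy",
    "log_prior",
    "fit_superellipse",
    "fit_bspline_contour",
    "fit_slice",
]

#: recommended minimum point counts per anatomical region
RECOMMENDED_POINTS = {"base": 4, "mid": 6, "apex": 4}
MIN_POINTS = 4


@dataclass
class AnnotatedSlice:
    """User point annotations on one axial slice."""

    slice_index: int
    z_mm: float
    points: np.ndarray
    region: str = "mid"  # base | mid | apex
    model: str = "superellipse"  # superellipse | bspline

    def __post_init__(self):
        self.points = np.atleast_2d(np.asarray(self.points, dtype=float))
        if self.region not in RECOMMENDED_POINTS:
            raise ValueError(f"region must be base/mid/apex, got {self.region!r}")
        if self.model not in ("superellipse", "bspline"):
            raise ValueError(f"model must be superellipse or bspline, got {self.model!r}")
        _check_points(self.points)
        rec = RECOMMENDED_POINTS[self.region]
        if len(self.points) < rec:
            warnings.warn(
                f"{self.region} slice has {len(self.points)} points; "
                f"{rec} are recommended",
                stacklevel=2,
            )


def _check_points(points):
    if len(points) < MIN_POINTS:
        raise ValueError(f"at least {MIN_POINTS} points are required, got {len(points)}")
    if not np.all(np.isfinite(points)):
        raise ValueError("annotation points must be finite")
    if len(np.unique(points.round(9), axis=0)) != len(points):
        raise ValueError("annotation points must be distinct")


@dataclass
class PriorConfig:
    """Gaussian prior over the shape parameters (off by default).

    ``means``/``sigmas`` map parameter names (a subset of ax, ay, eps, t, b)
    to the Gaussian mode and spread.  The published method defines this
    prior but reports no hyperparameters, so none are shipped as defaults.
    """

    enabled: bool = False
    means: dict = field(default_factory=dict)
    sigmas: dict = field(default_factory=dict)
    weight: float = 1.0

    def __post_init__(self):
        if self.enabled:
            if set(self.means) != set(self.sigmas):
                raise ValueError("prior means and sigmas must cover the same parameters")
            bad = set(self.means) - set(SHAPE_PARAM_NAMES)
            if bad:
                raise ValueError(f"prior covers non-shape parameters: {sorted(bad)}")
            if any(s <= 0 for s in self.sigmas.values()):
                raise ValueError("prior sigmas must be positive")
        if self.weight < 0:
            raise ValueError("prior weight must be nonnegative")


@dataclass
class FitConfig:
    """Knobs of the superellipse optimizer."""

    optimizer: str = "nelder-mead"
    multistart: int = 4
    max_iter: int = 2000
    xtol: float = 1e-4
    ftol: float = 1e-6
    seed: int = 0
    squared_distance: bool = True
    n_boundary_points: int = 120
    eps_bounds: tuple = (0.6, 4.0)
    t_max: float = 0.6
    b_ay_max: float = 0.5


@dataclass
class FitResult:
    params: SuperellipseParams
    energy: float
    converged: bool
    n_evals: int


def energy(contour: Contour2D, user_points, squared: bool = True) -> float:
    """Point-to-polygon energy: sum of distances from points to the boundary.

    Each user point contributes its Euclidean distance to the closed
    polygon's boundary (squared by default); zero iff every point lies on
    the boundary.
    """
    pts = np.atleast_2d(np.asarray(user_points, dtype=float))
    if len(pts) < 1:
        raise ValueError("at least one point is required")
    ring = contour.ring()
    if not ring.is_valid or ring.length == 0:
        raise ValueError("degenerate polygon")
    d = shapely.distance(ring, shapely.points(pts))
    return float(np.sum(d**2 if squared else d))


def log_prior(p: SuperellipseParams, prior: PriorConfig) -> float:
    """Gaussian log-prior ``-sum_j (p_j - m_j)^2 / (2 sigma_j^2)`` (<= 0)."""
    if not prior.enabled:
        raise ValueError("log_prior called with a disabled prior")
    total = 0.0
    for name, m in prior.means.items():
        s = prior.sigmas[name]
        total -= (getattr(p, name) - m) ** 2 / (2.0 * s**2)
    return total


def _initial_guess(points: np.ndarray) -> SuperellipseParams:
    """Deterministic, scale-aware initialization from the point cloud.

    Center at the centroid, orientation along the principal axis of the
    points, semi-axes from the max extents along the principal axes,
    eps = 2 (ellipse) and no tapering/bending.
    """
    centroid = points.mean(axis=0)
    centered = points - centroid
    cov = np.cov(centered.T)
    evals, evecs = np.linalg.eigh(cov)
    major = evecs[:, int(np.argmax(evals))]
    r = float(np.arctan2(major[1], major[0]))
    # fold into (-pi/2, pi/2]: a superellipse is symmetric under r -> r + pi
    if r <= -np.pi / 2:
        r += np.pi
    elif r > np.pi / 2:
        r -= np.pi
    c, s = np.cos(r), np.sin(r)
    proj_x = centered @ np.array([c, s])
    proj_y = centered @ np.array([-s, c])
    ax = max(float(np.max(np.abs(proj_x))), 1e-3)
    ay = max(float(np.max(np.abs(proj_y))), 1e-3)
    return SuperellipseParams(ax=ax, ay=ay, lx=centroid[0], ly=centroid[1], r=r)


def fit_superellipse(
    user_points,
    config: FitConfig | None = None,
    prior: PriorConfig | None = None,
) -> FitResult:
    """Fit the eight-parameter deformable superellipse to sparse points.

    Runs a bounded Nelder-Mead simplex search from ``config.multistart``
    deterministic initializations and returns the lowest-energy result.
    The returned energy never exceeds the energy at initialization.
    """
    config = config or FitConfig()
    prior = prior or PriorConfig()
    pts = np.atleast_2d(np.asarray(user_points, dtype=float))
    _check_points(pts)

    p0 = _initial_guess(pts)
    scale = max(p0.ax, p0.ay)
    lo_ax = 0.05 * scale
    hi_ax = 6.0 * scale
    b_cap = config.b_ay_max / max(p0.ay, lo_ax)
    bounds = [
        (lo_ax, hi_ax),  # ax
        (lo_ax, hi_ax),  # ay
        (p0.lx - 2 * scale, p0.lx + 2 * scale),  # lx
        (p0.ly - 2 * scale, p0.ly + 2 * scale),  # ly
        (-np.pi / 2, np.pi / 2),  # r
        config.eps_bounds,  # eps
        (-config.t_max, config.t_max),  # t
        (-b_cap, b_cap),  # b
    ]

    def objective(vec):
        try:
            p = SuperellipseParams.from_array(vec).validate()
            if abs(p.b) * p.ay >= 0.95:
                return 1e9
            contour = boundary_contour(p, config.n_boundary_points)
            e = energy(contour, pts, squared=config.squared_distance)
        except ValueError:
            return 1e9
        if prior.enabled:
            e -= prior.weight * log_prior(p, prior)
        return e

    rng = np.random.default_rng(config.seed)
    starts = [p0.as_array()]
    eps_grid = [1.4, 2.6, 3.2]
    for k in range(1, config.multistart):
        v = p0.as_array().copy()
        v[5] = eps_grid[(k - 1) % len(eps_grid)]
        v[4] += rng.normal(scale=0.1)
        v[0] *= 1.0 + rng.normal(scale=0.05)
        v[1] *= 1.0 + rng.normal(scale=0.05)
        starts.append(v)

    step = np.array(
        [0.15 * scale, 0.15 * scale, 0.08 * scale, 0.08 * scale, 0.15, 0.5, 0.15,
         0.1 / max(p0.ay, lo_ax)]
    )

    best = None
    n_evals = 0
    converged = False
    e_init = objective(np.clip(starts[0], [b[0] for b in bounds], [b[1] for b in bounds]))
    for v0 in starts:
        v0 = np.clip(v0, [b[0] for b in bounds], [b[1] for b in bounds])
        simplex = np.vstack([v0] + [v0 + step * np.eye(8)[i] for i in range(8)])
        simplex = np.clip(simplex, [b[0] for b in bounds], [b[1] for b in bounds])
        res = _opt.minimize(
            objective,
            v0,
            method="Nelder-Mead",
            bounds=bounds,
            options={
                "maxiter": config.max_iter,
                "xatol": config.xtol,
                "fatol": config.ftol,
                "initial_simplex": simplex,
            },
        )
        n_evals += res.nfev
        if best is None or res.fun < best.fun:
            best = res
        converged = converged or bool(res.success)

    if best.fun > e_init:  # simplex never improves past its start, but be safe
        best_params, best_e = p0, e_init
    else:
        best_params, best_e = SuperellipseParams.from_array(best.x).validate(), float(best.fun)
    if prior.enabled:
        # report the pure point energy, not the penalized objective
        best_e = energy(
            boundary_contour(best_params, config.n_boundary_points),
            pts,
            squared=config.squared_distance,
        )
    return FitResult(params=best_params, energy=best_e, converged=converged, n_evals=n_evals)


def _angular_sort(points: np.ndarray) -> np.ndarray:
    """Order scattered boundary clicks angularly about their centroid."""
    centered = points - points.mean(axis=0)
    ang = np.arctan2(centered[:, 1], centered[:, 0])
    rad = np.hypot(centered[:, 0], centered[:, 1])
    order = np.lexsort((rad, ang))
    return points[order]


def fit_bspline_contour(user_points, smoothing: float = 0.0, n_samples: int = 200) -> Contour2D:
    """Closed periodic smoothing B-spline through scattered boundary points.

    Points are sorted angularly about their centroid, then a periodic
    parametric spline (``scipy.interpolate.splprep``) is fitted and sampled
    densely.  Used for irregular mid-gland slices where eight parameters
    are too rigid.
    """
    pts = np.atleast_2d(np.asarray(user_points, dtype=float))
    if len(pts) < 6:
        raise ValueError(f"a B-spline contour needs at least 6 points, got {len(pts)}")
    if not np.all(np.isfinite(pts)):
        raise ValueError("points must be finite")
    centered = pts - pts.mean(axis=0)
    if np.linalg.svd(centered, compute_uv=False)[-1] < 1e-9 * np.abs(centered).max():
        raise ValueError("points are collinear; cannot form a closed contour")
    ordered = _angular_sort(pts)
    closed = np.vstack([ordered, ordered[:1]])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        tck, _ = _interp.splprep([closed[:, 0], closed[:, 1]], s=smoothing, per=True)
    u = np.linspace(0.0, 1.0, max(n_samples, 200) + 1)
    x, y = _interp.splev(u, tck)
    verts = np.column_stack([x, y])[:-1]
    return Contour2D(vertices=verts, closed=True)


@dataclass
class SliceFit:
    params: SuperellipseParams
    contour: Contour2D
    energy: float
    annotated: AnnotatedSlice


def fit_slice(
    sl: AnnotatedSlice,
    config: FitConfig | None = None,
    prior: PriorConfig | None = None,
    bspline_smoothing: float = 0.0,
) -> SliceFit:
    """Fit one annotated slice with the model it requests.

    ``superellipse`` mode fits the deformable superellipse directly to the
    clicks.  ``bspline`` mode first interpolates the clicks with a closed
    B-spline, then fits the superellipse to dense spline samples, so the 3D
    model stays parametric while the in-plane contour honors irregularity.
    """
    config = config or FitConfig()
    if sl.model == "bspline":
        spline = fit_bspline_contour(sl.points, smoothing=bspline_smoothing)
        target = spline.vertices[:: max(1, len(spline.vertices) // 72)]
        res = fit_superellipse(target, config=config, prior=prior)
    else:
        res = fit_superellipse(sl.points, config=config, prior=prior)
    contour = boundary_contour(res.params, config.n_boundary_points)
    return SliceFit(params=res.params, contour=contour, energy=res.energy, annotated=sl)
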