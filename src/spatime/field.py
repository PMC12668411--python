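"""Spatial pseudotime surface and gradient vector field.

Placed cells' pseudotime values are turned into a smooth map of
differentiation progress over the tissue: spatial outliers (cells that are
simultaneously far from their five nearest neighbors — above the 98th
percentile of mean neighbor distance — and discordant with them — above
the 95th percentile of mean absolute pseudotime difference) are removed; a
Gaussian-process regression with an RBF + white-noise kernel provides the
posterior-mean surface on a 200x200 grid; the surface is Gaussian-blurred
(sigma in grid pixels), differentiated with central finite differences,
and masked to the convex hull of the observed points, yielding a
streamline-ready field pointing in the direction of differentiation.

Coordinates are standardized (single isotropic scale) before the GPR so
the kernel's stated initial hyperparameters (length scale 1.0, noise
variance 1e-3) are meaningful regardless of the physical units of the
array; the grid is mapped back to data units.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import shapely
from scipy import ndimage
from scipy.spatial import ConvexHull, QhullError
from sklearn.gaussian_process import GaussianProcessRegressor
from sklearn.gaussian_process.kernels import RBF, WhiteKernel
from sklearn.neighbors import NearestNeighbors

from .config import FieldParams, OutlierParams


def remove_spatial_outliers(
    points: pd.DataFrame, params: OutlierParams | None = None
) -> pd.DataFrame:
    """Drop cells that exceed BOTH the neighbor-distance and the
    pseudotime-discordance percentile thresholds.

    ``points`` needs columns x, y, t. Percentiles are computed over the
    full point set. At most ~2% of points can be removed (the AND of the
    two conditions is bounded by the rarer one).
    """
    params = params or OutlierParams()
    if len(points) < params.k_spatial + 2:
        raise ValueError(
            f"need at least k_spatial + 2 = {params.k_spatial + 2} points"
        )
    xy = points[["x", "y"]].to_numpy(np.float64)
    t = points["t"].to_numpy(np.float64)
    nn = NearestNeighbors(n_neighbors=params.k_spatial + 1).fit(xy)
    dist, idx = nn.kneighbors(xy)
    mean_dist = dist[:, 1:].mean(axis=1)
    mean_dt = np.abs(t[idx[:, 1:]] - t[:, None]).mean(axis=1)
    thr_dist = np.percentile(mean_dist, params.dist_percentile)
    thr_dt = np.percentile(mean_dt, params.dt_percentile)
    outlier = (mean_dist > thr_dist) & (mean_dt > thr_dt)
    return points.loc[~outlier].reset_index(drop=True)


@dataclass
class FieldGrid:
    """Pseudotime surface (and optionally gradients) on a regular grid.

    ``surface[i, j]`` is the value at y=ys[i], x=xs[j] (row = y, column =
    x). ``du``/``dv`` are the x- and y-components of the gradient;
    ``mask`` is True inside the convex hull of the fitted points.
    """

    xs: np.ndarray
    ys: np.ndarray
    surface: np.ndarray
    du: np.ndarray | None = None
    dv: np.ndarray | None = None
    mask: np.ndarray | None = None
    points: np.ndarray | None = None


def fit_pseudotime_surface(
    points: pd.DataFrame, params: FieldParams | None = None
) -> FieldGrid:
    """GPR posterior-mean pseudotime surface on the configured grid.

    The kernel is RBF (initial length scale from ``params``) plus a white
    noise term (initial variance from ``params``); hyperparameters are
    optimized by marginal-likelihood ascent, falling back to the initial
    values with a warning if the optimizer fails.
    """
    params = params or FieldParams()
    if len(points) < 10:
        raise ValueError("need at least 10 points to fit a surface")
    xy = points[["x", "y"]].to_numpy(np.float64)
    t = points["t"].to_numpy(np.float64)

    center = xy.mean(axis=0)
    scale = float(max(xy.std(axis=0).max(), 1e-12))
    z = (xy - center) / scale

    kernel = RBF(length_scale=params.rbf_length_scale,
                 length_scale_bounds=(1e-3, 1e3)) + WhiteKernel(
        noise_level=params.white_noise, noise_level_bounds=(1e-10, 1e1)
    )
    try:
        gpr = GaussianProcessRegressor(
            kernel=kernel, normalize_y=True, random_state=0
        ).fit(z, t)
    except Exception as exc:  # optimizer failure: keep initial values
        warnings.warn(f"GPR optimization failed ({exc}); using initial kernel",
                      stacklevel=2)
        gpr = GaussianProcessRegressor(
            kernel=kernel, normalize_y=True, optimizer=None, random_state=0
        ).fit(z, t)

    (x0, x1), (y0, y1) = _bounds(xy, params.grid_margin)
    ny, nx = params.grid_shape
    xs = np.linspace(x0, x1, nx)
    ys = np.linspace(y0, y1, ny)
    gx, gy = np.meshgrid(xs, ys)
    grid_z = (np.column_stack([gx.ravel(), gy.ravel()]) - center) / scale
    surface = gpr.predict(grid_z).reshape(ny, nx)
    return FieldGrid(xs=xs, ys=ys, surface=surface, points=xy)


def _bounds(xy: np.ndarray, margin: float):
    mins = xy.min(axis=0)
    maxs = xy.max(axis=0)
    pad = (maxs - mins) * margin
    return (mins[0] - pad[0], maxs[0] + pad[0]), (mins[1] - pad[1], maxs[1] + pad[1])


def gradient_field(
    grid: FieldGrid,
    params: FieldParams | None = None,
    points: np.ndarray | None = None,
) -> FieldGrid:
    """Blur the surface, differentiate it, and mask outside the hull.

    By default the surface is convolved with a Gaussian (sigma in grid
    pixels, reflective boundary) before central-difference gradients are
    taken; set ``params.blur_before_gradient`` False to differentiate
    first and blur the components instead. Nodes outside the convex hull
    of the input points are masked (no vectors); hull membership carries a
    half-grid-cell tolerance so that boundary points keep their nearest
    node unmasked.
    """
    params = params or FieldParams()
    pts = points if points is not None else grid.points
    if pts is None:
        raise ValueError("no points available for the hull mask")
    try:
        hull = ConvexHull(pts)
    except QhullError as exc:
        raise ValueError(f"convex hull undefined: {exc}")
    dx = grid.xs[1] - grid.xs[0]
    dy = grid.ys[1] - grid.ys[0]
    hull_poly = shapely.Polygon(pts[hull.vertices]).buffer(0.5 * np.hypot(dx, dy))

    if params.blur_before_gradient and params.blur_sigma > 0:
        smooth = ndimage.gaussian_filter(grid.surface, params.blur_sigma,
                                         mode="reflect")
    else:
        smooth = grid.surface
    dv, du = np.gradient(smooth, grid.ys, grid.xs)  # rows vary with y
    if not params.blur_before_gradient and params.blur_sigma > 0:
        du = ndimage.gaussian_filter(du, params.blur_sigma, mode="reflect")
        dv = ndimage.gaussian_filter(dv, params.blur_sigma, mode="reflect")

    gx, gy = np.meshgrid(grid.xs, grid.ys)
    inside = shapely.contains_xy(hull_poly, gx.ravel(), gy.ravel())
    mask = inside.reshape(grid.surface.shape)
    du = np.where(mask, du, np.nan)
    dv = np.where(mask, dv, np.nan)
    return FieldGrid(
        xs=grid.xs, ys=grid.ys, surface=smooth, du=du, dv=dv, mask=mask, points=pts
    )
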