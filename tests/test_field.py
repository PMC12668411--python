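"""Spatial outlier removal, GPR surface fitting and the gradient field."""

import numpy as np
import pandas as pd
import pytest

from spatime import (
    FieldParams,
    fit_pseudotime_surface,
    gradient_field,
    remove_spatial_outliers,
)
from spatime.field import FieldGrid


def _grid_points(n_side=7, t_fn=None):
    xs, ys = np.meshgrid(np.arange(n_side, dtype=float), np.arange(n_side, dtype=float))
    t = t_fn(xs, ys) if t_fn else np.zeros_like(xs)
    return pd.DataFrame({"x": xs.ravel(), "y": ys.ravel(), "t": t.ravel()})


class TestOutlierRemoval:
    def test_constant_pseudotime_removes_nothing(self):
        pts = _grid_points(7, lambda x, y: np.full_like(x, 0.5))
        assert len(remove_spatial_outliers(pts)) == 49

    def test_removal_bounded_by_distance_percentile(self, rng):
        n = 400
        pts = pd.DataFrame(
            {"x": rng.random(n), "y": rng.random(n), "t": rng.random(n)}
        )
        removed = n - len(remove_spatial_outliers(pts))
        assert removed <= np.ceil(0.02 * n)

    def test_far_discordant_point_removed_concordant_kept(self):
        """A distant cell is an outlier only when its pseudotime disagrees
        with its neighborhood."""
        base = _grid_points(7, lambda x, y: x / 10.0)  # smooth x-gradient
        far_discordant = pd.DataFrame({"x": [30.0], "y": [30.0], "t": [0.9]})
        far_concordant = pd.DataFrame({"x": [30.0], "y": [30.0], "t": [0.55]})
        kept1 = remove_spatial_outliers(pd.concat([base, far_discordant], ignore_index=True))
        assert not ((kept1.x == 30.0) & (kept1.y == 30.0)).any()
        kept2 = remove_spatial_outliers(pd.concat([base, far_concordant], ignore_index=True))
        assert ((kept2.x == 30.0) & (kept2.y == 30.0)).any()

    def test_too_few_points_raises(self):
        with pytest.raises(ValueError, match="points"):
            remove_spatial_outliers(_grid_points(2))


class TestSurfaceFit:
    def test_constant_field_and_grid_shape(self, rng):
        pts = pd.DataFrame(
            {"x": rng.random(50), "y": rng.random(50), "t": np.full(50, 0.5)}
        )
        grid = fit_pseudotime_surface(pts)
        assert grid.surface.shape == (200, 200)
        np.testing.assert_allclose(grid.surface, 0.5, atol=1e-3)

    def test_linear_field_recovered_on_interior(self, rng):
        pts = pd.DataFrame({"x": rng.uniform(0, 10, 400), "y": rng.uniform(0, 10, 400)})
        pts["t"] = 0.1 * pts.x + 0.2 * pts.y
        grid = fit_pseudotime_surface(pts)
        gx, gy = np.meshgrid(grid.xs, grid.ys)
        truth = 0.1 * gx + 0.2 * gy
        interior = (gx > 1) & (gx < 9) & (gy > 1) & (gy < 9)
        rmse = np.sqrt(np.mean((grid.surface - truth)[interior] ** 2))
        assert rmse <= 0.01

    def test_too_few_points_raises(self):
        pts = pd.DataFrame({"x": [0.0, 1.0], "y": [0.0, 1.0], "t": [0.1, 0.2]})
        with pytest.raises(ValueError, match="10 points"):
            fit_pseudotime_surface(pts)


def _radial_field(seed=0, n=300, R=1000.0, noise=0.02):
    rng = np.random.default_rng(seed)
    r = R * np.sqrt(rng.random(n))
    th = rng.random(n) * 2 * np.pi
    t = 1 - r / R + noise * rng.standard_normal(n)
    return pd.DataFrame({"x": r * np.cos(th), "y": r * np.sin(th), "t": t}), R


class TestGradientField:
    def test_plane_gradient_constant_in_interior(self):
        xs = np.linspace(0, 10, 120)
        ys = np.linspace(0, 10, 120)
        gx, gy = np.meshgrid(xs, ys)
        surface = 0.3 * gx + 0.7 * gy
        corners = np.array([[0, 0], [10, 0], [0, 10], [10, 10], [5, 5]], float)
        grid = FieldGrid(xs=xs, ys=ys, surface=surface, points=corners)
        res = gradient_field(grid, FieldParams(blur_sigma=5.0))
        interior = np.zeros_like(surface, bool)
        interior[30:-30, 30:-30] = True
        np.testing.assert_allclose(res.du[interior], 0.3, atol=5e-3)
        np.testing.assert_allclose(res.dv[interior], 0.7, atol=5e-3)

    def test_radial_tissue_gradient_points_inward(self):
        pts, R = _radial_field()
        filtered = remove_spatial_outliers(pts)
        grid = fit_pseudotime_surface(filtered)
        res = gradient_field(grid)
        gx, gy = np.meshgrid(res.xs, res.ys)
        rad = np.hypot(gx, gy)
        mag = np.hypot(res.du, res.dv)
        ok = res.mask & (rad > 0.15 * R) & (rad < 0.8 * R) & (mag > 1e-12)
        cos = (res.du * (-gx / rad) + res.dv * (-gy / rad)) / mag
        ang = np.degrees(np.arccos(np.clip(cos[ok], -1, 1)))
        assert ang.mean() <= 20.0

    def test_mask_contract(self):
        import shapely
        from scipy.spatial import ConvexHull

        pts, _ = _radial_field(seed=1, n=100)
        grid = fit_pseudotime_surface(pts)
        res = gradient_field(grid)
        assert np.isnan(res.du[~res.mask]).all()
        # each input point's nearest grid node is unmasked
        for x, y in res.points:
            i = int(np.argmin(np.abs(res.ys - y)))
            j = int(np.argmin(np.abs(res.xs - x)))
            assert res.mask[i, j]
        # nodes clearly outside the hull (beyond the half-cell boundary
        # tolerance) are all masked
        hull = ConvexHull(res.points)
        poly = shapely.Polygon(res.points[hull.vertices])
        gx, gy = np.meshgrid(res.xs, res.ys)
        cell = np.hypot(res.xs[1] - res.xs[0], res.ys[1] - res.ys[0])
        far_outside = ~shapely.contains_xy(poly.buffer(1.5 * cell), gx.ravel(),
                                           gy.ravel()).reshape(res.mask.shape)
        assert not res.mask[far_outside].any()

    def test_collinear_points_raise(self):
        xs = np.linspace(0, 1, 10)
        grid = FieldGrid(
            xs=xs, ys=xs, surface=np.zeros((10, 10)),
            points=np.column_stack([xs, xs]),
        )
        with pytest.raises(ValueError, match="hull"):
            gradient_field(grid)

    def test_rotation_equivariance(self):
        """Rotating the input points rotates the unmasked gradient field
        (within discretization tolerance)."""
        from scipy.interpolate import RegularGridInterpolator

        pts, R = _radial_field(seed=2, noise=0.0)
        theta = np.deg2rad(30)
        c, s = np.cos(theta), np.sin(theta)
        rot = pts.copy()
        rot["x"] = c * pts.x - s * pts.y
        rot["y"] = s * pts.x + c * pts.y

        res1 = gradient_field(fit_pseudotime_surface(pts))
        res2 = gradient_field(fit_pseudotime_surface(rot))

        def interp(res):
            fill = np.nan
            du = np.where(res.mask, res.du, fill)
            dv = np.where(res.mask, res.dv, fill)
            return (
                RegularGridInterpolator((res.ys, res.xs), du, bounds_error=False),
                RegularGridInterpolator((res.ys, res.xs), dv, bounds_error=False),
            )

        du1, dv1 = interp(res1)
        du2, dv2 = interp(res2)
        rng = np.random.default_rng(3)
        r = 0.6 * R * np.sqrt(rng.random(200))
        th = rng.random(200) * 2 * np.pi
        p = np.column_stack([r * np.cos(th), r * np.sin(th)])
        g1 = np.column_stack([du1(p[:, ::-1]), dv1(p[:, ::-1])])
        p_rot = p @ np.array([[c, s], [-s, c]])  # row-vector rotation
        g2 = np.column_stack([du2(p_rot[:, ::-1]), dv2(p_rot[:, ::-1])])
        g1_rot = g1 @ np.array([[c, s], [-s, c]])
        valid = np.isfinite(g1_rot).all(1) & np.isfinite(g2).all(1)
        valid &= (np.linalg.norm(g1_rot, axis=1) > 1e-6) & (
            np.linalg.norm(g2, axis=1) > 1e-6
        )
        cos_ang = np.sum(g1_rot[valid] * g2[valid], axis=1) / (
            np.linalg.norm(g1_rot[valid], axis=1) * np.linalg.norm(g2[valid], axis=1)
        )
        ang = np.degrees(np.arccos(np.clip(cos_ang, -1, 1)))
        assert np.mean(ang) <= 5.0

    def test_gradient_integrates_to_surface_difference(self):
        """Line-integrating the gradient between two interior nodes
        recovers the blurred-surface difference within 2%."""
        from scipy.interpolate import RegularGridInterpolator

        pts, R = _radial_field(seed=4)
        res = gradient_field(fit_pseudotime_surface(pts))
        fdu = RegularGridInterpolator((res.ys, res.xs), res.du)
        fdv = RegularGridInterpolator((res.ys, res.xs), res.dv)
        fs = RegularGridInterpolator((res.ys, res.xs), res.surface)
        a = np.array([-0.3 * R, -0.2 * R])
        b = np.array([0.35 * R, 0.25 * R])
        ts = np.linspace(0, 1, 2000)
        path = a[None, :] + ts[:, None] * (b - a)[None, :]
        yx = path[:, ::-1]
        integrand = fdu(yx) * (b - a)[0] + fdv(yx) * (b - a)[1]
        integral = float(np.trapezoid(integrand, ts))
        diff = (fs(b[::-1]) - fs(a[::-1])).item()
        assert integral == pytest.approx(diff, rel=0.02)
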