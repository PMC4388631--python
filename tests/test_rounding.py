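"""Ellipsoid constructions: PCA, iterative LP, deep cuts, Lovász pairs."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from fluxhr import (
    Ellipsoid,
    diameter_spectrum,
    lovasz_ellipsoid,
    lp_ellipsoid,
    make_hyperrectangle,
    make_hypercube,
    make_random_polytope,
    min_enclosing_halfellipsoid,
    pca_ellipsoid,
)
from fluxhr.exceptions import (
    DimensionCollapseError,
    EmptyCutError,
    InsufficientDataError,
)


class TestEllipsoid:
    def test_transform_reproduces_shape(self):
        rng = np.random.default_rng(0)
        A = rng.standard_normal((4, 4))
        shape = A @ A.T + 4 * np.eye(4)
        E = Ellipsoid(np.zeros(4), shape)
        np.testing.assert_allclose(E.transform @ E.transform.T, shape,
                                   rtol=1e-8)

    def test_asymmetric_shape_rejected(self):
        with pytest.raises(ValueError, match="symmetric"):
            Ellipsoid(np.zeros(2), np.array([[1.0, 0.5], [0.0, 1.0]]))

    def test_diameters_of_diagonal_shape(self):
        E = Ellipsoid(np.zeros(2), np.diag([1.0, 4.0]))
        np.testing.assert_allclose(diameter_spectrum(E), [2.0, 4.0])
        E = Ellipsoid(np.zeros(3), np.eye(3))
        np.testing.assert_allclose(diameter_spectrum(E), [2.0, 2.0, 2.0])

    def test_diameters_match_extremal_chord_search(self):
        """Random SPD shape: longest/shortest diameters agree with a
        brute-force random-direction extremal chord search within 1%."""
        rng = np.random.default_rng(1)
        A = rng.standard_normal((3, 3))
        E = Ellipsoid(np.zeros(3), A @ A.T + 0.5 * np.eye(3))
        diams = diameter_spectrum(E)
        # chord through the center along u has length 2 sqrt(u^T B u)
        u = rng.standard_normal((200_000, 3))
        u /= np.linalg.norm(u, axis=1, keepdims=True)
        lengths = 2.0 * np.sqrt(np.einsum("ij,jk,ik->i", u, E.shape, u))
        assert lengths.max() == pytest.approx(diams[-1], rel=0.01)
        assert lengths.min() == pytest.approx(diams[0], rel=0.01)

    def test_support_function_is_max_over_boundary(self):
        rng = np.random.default_rng(2)
        E = Ellipsoid([1.0, -2.0], np.diag([4.0, 0.25]))
        g = np.array([0.3, -0.7])
        pts = E.sample_boundary(rng, 50_000)
        assert np.all(pts @ g <= E.support(g) + 1e-12)
        assert (pts @ g).max() == pytest.approx(E.support(g), rel=1e-3)


class TestPcaEllipsoid:
    def test_box_variances_recovered(self):
        """Uniform on [0,a1]x[0,a2] has per-axis variance a_i^2/12."""
        rng = np.random.default_rng(3)
        a = np.array([2.0, 0.5])
        X = rng.random((100_000, 2)) * a
        E = pca_ellipsoid(X)
        np.testing.assert_allclose(np.sort(np.diag(E.shape)),
                                   np.sort(a ** 2 / 12.0), rtol=0.05)
        np.testing.assert_allclose(E.center, a / 2.0, atol=0.01)

    def test_isotropic_cloud_gives_round_ellipsoid(self):
        rng = np.random.default_rng(4)
        E = pca_ellipsoid(rng.standard_normal((50_000, 3)))
        d = diameter_spectrum(E)
        assert d[-1] / d[0] == pytest.approx(1.0, abs=0.05)

    def test_degenerate_cloud_ridge_regularized(self, caplog):
        X = np.ones((10, 2))
        with caplog.at_level("WARNING", logger="fluxhr.rounding"):
            E = pca_ellipsoid(X)
        assert np.all(np.linalg.eigvalsh(E.shape) > 0)
        assert any("ridge" in r.message for r in caplog.records)

    def test_insufficient_points_rejected(self):
        with pytest.raises(InsufficientDataError):
            pca_ellipsoid(np.zeros((3, 3)))

    def test_affine_equivariance(self):
        """PCA of an affinely mapped cloud equals the mapped PCA ellipsoid."""
        rng = np.random.default_rng(5)
        X = rng.random((5_000, 3))
        A = rng.standard_normal((3, 3)) + 2 * np.eye(3)
        b = rng.standard_normal(3)
        E1 = pca_ellipsoid(X @ A.T + b)
        E0 = pca_ellipsoid(X)
        np.testing.assert_allclose(E1.center, A @ E0.center + b, atol=1e-10)
        np.testing.assert_allclose(E1.shape, A @ E0.shape @ A.T, atol=1e-10)


class TestLpEllipsoid:
    def test_box_axes_recovered(self):
        sides = np.array([10.0, 1.0, 0.1])
        poly = make_hyperrectangle(3, axis_lengths=sides)
        E = lp_ellipsoid(poly, seed=0)
        semi, dirs = E.axes()
        np.testing.assert_allclose(np.sort(semi), np.sort(sides / 2), rtol=1e-6)
        # each principal direction aligns with a coordinate axis
        align = np.abs(dirs.T)  # rows: axes of E
        assert np.all(align.max(axis=1) > 1.0 - 1e-6)

    def test_hypercube_axes_equal_by_symmetry(self):
        E = lp_ellipsoid(make_hypercube(2), seed=0)
        semi, _ = E.axes()
        assert semi[0] == pytest.approx(semi[1], rel=1e-6)

    def test_sorted_axis_lengths_proportional_to_sides(self):
        rng_sides = np.array([3.0, 0.2, 7.5, 1.0])
        poly = make_hyperrectangle(4, axis_lengths=rng_sides)
        E = lp_ellipsoid(poly, seed=1)
        semi, _ = E.axes()
        ratio = np.sort(semi) / np.sort(rng_sides)
        np.testing.assert_allclose(ratio, ratio[0], rtol=1e-6)

    def test_flat_polytope_collapses(self):
        """A segment wrongly embedded in 2-D triggers dimension collapse."""
        from fluxhr import Polytope

        G = np.array([[1.0, 0.0], [-1.0, 0.0], [0.0, 1.0], [0.0, -1.0]])
        h = np.array([1.0, 0.0, 0.0, 0.0])  # x in [0,1], y = 0
        seg = Polytope(np.zeros(2), np.eye(2), G, h)
        from fluxhr.exceptions import DegeneratePolytopeError

        with pytest.raises((DimensionCollapseError, DegeneratePolytopeError)):
            lp_ellipsoid(seg)


class TestDeepCut:
    def test_central_cut_of_unit_disk_matches_analytic(self):
        """Keeping x1 <= 0 of the unit disk: minimal enclosing ellipsoid has
        center (-1/3, 0) and semi-axes (2/3, 2/sqrt(3))."""
        E = Ellipsoid.ball([0.0, 0.0], 1.0)
        cut = min_enclosing_halfellipsoid(E, [1.0, 0.0], [0.0, 0.0])
        np.testing.assert_allclose(cut.center, [-1.0 / 3.0, 0.0], atol=1e-12)
        np.testing.assert_allclose(np.sort(cut.axes()[0]),
                                   [2.0 / 3.0, 2.0 / np.sqrt(3.0)], atol=1e-12)

    def test_central_cut_contains_half_disk_grid(self):
        E = Ellipsoid.ball([0.0, 0.0], 1.0)
        cut = min_enclosing_halfellipsoid(E, [1.0, 0.0], [0.0, 0.0])
        xs, ys = np.meshgrid(np.linspace(-1, 0, 60), np.linspace(-1, 1, 120))
        pts = np.column_stack([xs.ravel(), ys.ravel()])
        half = pts[np.linalg.norm(pts, axis=1) <= 1.0]
        for p in half:
            assert cut.contains(p, tol=1e-9)

    def test_central_cut_is_volume_minimal_among_brute_force(self):
        """No axis-aligned candidate ellipsoid containing the half-disk has a
        smaller volume than the deep-cut update (coarse grid search)."""
        E = Ellipsoid.ball([0.0, 0.0], 1.0)
        cut = min_enclosing_halfellipsoid(E, [1.0, 0.0], [0.0, 0.0])
        ref_vol = np.prod(cut.axes()[0])
        ys = np.linspace(-1, 1, 400)
        boundary = np.column_stack([np.zeros_like(ys), ys])
        arc = np.column_stack([-np.abs(np.cos(np.linspace(0, np.pi, 400))),
                               np.sin(np.linspace(0, np.pi, 400))])
        half_pts = np.vstack([boundary, arc])
        for cx in np.linspace(-0.6, 0.0, 25):
            for a in np.linspace(0.4, 1.2, 25):
                for b in np.linspace(0.8, 1.4, 25):
                    if a * b >= ref_vol:
                        continue
                    inside = ((half_pts[:, 0] - cx) / a) ** 2 \
                        + (half_pts[:, 1] / b) ** 2 <= 1 + 1e-12
                    assert not inside.all(), (cx, a, b)

    def test_volume_shrinks_monotonically_with_cut_depth(self):
        E = Ellipsoid.ball(np.zeros(3), 2.0)
        vols = []
        for depth in np.linspace(-0.2, 1.8, 15):  # cut plane moves across E
            cut = min_enclosing_halfellipsoid(E, [1.0, 0.0, 0.0],
                                              [2.0 - depth, 0.0, 0.0])
            vols.append(cut.log_volume())
        diffs = np.diff(vols)
        assert np.all(diffs <= 1e-12)

    def test_shallow_cut_returns_unchanged(self):
        E = Ellipsoid.ball(np.zeros(2), 1.0)
        # half-space x1 <= 0.9 cuts barely; alpha = -0.9 <= -1/2
        out = min_enclosing_halfellipsoid(E, [1.0, 0.0], [0.9, 0.0])
        assert out is E

    def test_empty_cut_raises(self):
        E = Ellipsoid.ball(np.zeros(2), 1.0)
        with pytest.raises(EmptyCutError):
            min_enclosing_halfellipsoid(E, [1.0, 0.0], [-1.5, 0.0])

    def test_one_dimensional_cut_is_exact_interval(self):
        E = Ellipsoid.ball([0.0], 2.0)  # interval [-2, 2]
        cut = min_enclosing_halfellipsoid(E, [1.0], [1.0])
        assert cut.center[0] == pytest.approx(-0.5)
        assert cut.axes()[0][0] == pytest.approx(1.5)

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(st.integers(min_value=0, max_value=10_000))
    def test_cut_always_contains_kept_half(self, seed):
        rng = np.random.default_rng(seed)
        A = rng.standard_normal((3, 3))
        E = Ellipsoid(rng.standard_normal(3), A @ A.T + 0.5 * np.eye(3))
        a = rng.standard_normal(3)
        x0 = E.center + 0.8 * (E.sample_boundary(rng, 1)[0] - E.center)
        cut = min_enclosing_halfellipsoid(E, a, x0)
        pts = E.center + (E.sample_boundary(rng, 2000) - E.center) \
            * rng.random((2000, 1))
        kept = pts[(pts - x0) @ a <= 0]
        for p in kept[:500]:
            assert cut.contains(p, tol=1e-7)
        assert cut.log_volume() <= E.log_volume() + 1e-9


class TestLovaszEllipsoid:
    def _check_pair(self, poly, E, E_inner):
        # inner containment: exact support-function check per constraint
        for g, h in zip(poly.G, poly.h):
            assert E_inner.support(g) <= h + 1e-7 * max(1.0, abs(h))
        # outer containment: every FVA vertex of P lies in E
        from fluxhr import fva

        res = fva(poly)
        for v in np.vstack([res.argmin, res.argmax]):
            assert E.contains(v, tol=1e-6)

    def test_square_pair(self):
        sq = make_hyperrectangle(2, axis_lengths=[2.0, 2.0])
        E, E_inner = lovasz_ellipsoid(sq)
        self._check_pair(sq, E, E_inner)

    def test_ball_polytope_pair(self):
        # regular 16-gon approximating a disk
        from fluxhr import Polytope

        ang = np.linspace(0, 2 * np.pi, 17)[:-1]
        G = np.column_stack([np.cos(ang), np.sin(ang)])
        poly = Polytope(np.zeros(2), np.eye(2), G, np.ones(16))
        E, E_inner = lovasz_ellipsoid(poly)
        self._check_pair(poly, E, E_inner)

    @pytest.mark.parametrize("D,m,seed", [(3, 12, 0), (6, 30, 1), (10, 60, 2)])
    def test_random_polytope_pairs(self, D, m, seed):
        poly = make_random_polytope(D, m, seed=seed)
        E, E_inner = lovasz_ellipsoid(poly)
        self._check_pair(poly, E, E_inner)
        # the default 1/D^{3/2} shrink factor ties the pair together
        np.testing.assert_allclose(E_inner.shape, E.shape / D ** 3, rtol=1e-10)

    def test_matched_start_terminates_immediately(self):
        """If the start ball's 1/D^{3/2} shrinkage already fits inside P, the
        loop terminates without any cut (E stays the start ball)."""
        D = 2
        # box big enough to contain the start ball entirely
        from fluxhr import Polytope

        G = np.vstack([np.eye(D), -np.eye(D)])
        h = np.array([2.0, 2.0, 2.0, 2.0])
        poly = Polytope(np.zeros(D), np.eye(D), G, h)
        E, E_inner = lovasz_ellipsoid(poly)
        lo, hi = poly.bounding_box
        start_radius = 0.5 * np.linalg.norm(hi - lo) * 1.01
        np.testing.assert_allclose(diameter_spectrum(E),
                                   2 * start_radius * np.ones(D), rtol=1e-12)

    def test_endpoint_check_variant_also_sandwiches(self):
        sq = make_hyperrectangle(2, axis_lengths=[3.0, 1.0])
        E, E_inner = lovasz_ellipsoid(sq, endpoint_check=True)
        from fluxhr import fva

        res = fva(sq)
        for v in np.vstack([res.argmin, res.argmax]):
            assert E.contains(v, tol=1e-6)
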