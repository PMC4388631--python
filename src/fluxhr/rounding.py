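"""Matching ellipsoids for rounding a polytope.

Hit-and-run mixes slowly on ill-conditioned polytopes: its autocorrelation
time grows with the sandwiching ratio R/r of circumscribed to inscribed ball
radii, and flux polytopes of metabolic networks are routinely sandwiched at
R/r ~ 1e5.  Drawing HR directions from the surface of an ellipsoid that
matches the polytope is equivalent to an affine change of variables (constant
Jacobian, so uniformity is preserved) and removes the ill-conditioning.

Three constructions are provided:

``pca_ellipsoid``
    the mean-centred covariance of a previous sampling, diagonalized;
``lp_ellipsoid``
    iterative variability analysis: repeatedly find the longest min-to-max
    vertex vector, then recurse in the orthogonal complement;
``lovasz_ellipsoid``
    the shallow/deep-cut ellipsoid method, producing a weak Loewner-John
    pair E_inner <= P <= E with E_inner a 1/D^{3/2} shrinkage of E.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from functools import cached_property

import numpy as np
from scipy import linalg as sla
from scipy.optimize import linprog

from .exceptions import (
    DimensionCollapseError,
    EmptyCutError,
    InsufficientDataError,
    LPSolverError,
    NonConvergenceError,
)
from .polytope import Polytope, find_interior_point, fva

logger = logging.getLogger(__name__)

#: ridge added to a numerically singular covariance, as a fraction of trace/D
PCA_RIDGE_FRACTION = 1.0e-10


@dataclass
class Ellipsoid:
    """{p : (p - center)^T shape^{-1} (p - center) <= 1}.

    ``shape`` is symmetric positive definite; its eigenvectors are the
    ellipsoid axes and the semi-axis lengths are the square roots of its
    eigenvalues.  ``transform`` is any matrix A with A A^T = shape: mapping a
    spherically uniform vector u through A and renormalizing gives the
    direction law used by the rounded hit-and-run (the particular square
    root chosen is irrelevant by spherical symmetry of u).
    """

    center: np.ndarray
    shape: np.ndarray

    def __post_init__(self):
        self.center = np.asarray(self.center, dtype=float).ravel()
        self.shape = np.atleast_2d(np.asarray(self.shape, dtype=float))
        D = self.center.size
        if self.shape.shape != (D, D):
            raise ValueError("shape matrix must be D x D")
        sym_err = np.abs(self.shape - self.shape.T).max()
        scale = max(np.abs(self.shape).max(), 1e-300)
        if sym_err > 1.0e-10 * scale:
            raise ValueError("shape matrix is not symmetric")
        self.shape = 0.5 * (self.shape + self.shape.T)

    @property
    def dim(self) -> int:
        return self.center.size

    @cached_property
    def _eig(self):
        w, V = np.linalg.eigh(self.shape)
        if w[0] <= 0.0:
            raise ValueError("shape matrix is not positive definite")
        return w, V

    @cached_property
    def transform(self) -> np.ndarray:
        """Cholesky factor A with A A^T = shape."""
        return np.linalg.cholesky(self.shape)

    def axes(self):
        """(semi_axis_lengths, directions) sorted by increasing length."""
        w, V = self._eig
        return np.sqrt(w), V

    def diameters(self) -> np.ndarray:
        """Axis diameters 2 sqrt(eigenvalues), sorted increasing."""
        w, _ = self._eig
        return 2.0 * np.sqrt(w)

    def support(self, g) -> float:
        """max over the ellipsoid of g . p  =  g.center + sqrt(g^T shape g)."""
        g = np.asarray(g, dtype=float)
        return float(g @ self.center + math.sqrt(max(g @ self.shape @ g, 0.0)))

    def support_point(self, g) -> np.ndarray:
        """The maximizer of g . p over the ellipsoid."""
        g = np.asarray(g, dtype=float)
        Bg = self.shape @ g
        denom = math.sqrt(max(g @ Bg, 0.0))
        if denom == 0.0:
            return self.center.copy()
        return self.center + Bg / denom

    def contains(self, p, tol: float = 1.0e-9) -> bool:
        d = np.asarray(p, dtype=float) - self.center
        q = d @ np.linalg.solve(self.shape, d)
        return bool(q <= 1.0 + tol)

    def mahalanobis(self, p) -> float:
        d = np.asarray(p, dtype=float) - self.center
        return float(math.sqrt(max(d @ np.linalg.solve(self.shape, d), 0.0)))

    def log_volume(self) -> float:
        """log of the volume up to the (dimension-only) unit-ball constant."""
        w, _ = self._eig
        return 0.5 * float(np.sum(np.log(w)))

    def scaled(self, factor: float) -> "Ellipsoid":
        """Concentric ellipsoid with all semi-axes multiplied by *factor*."""
        return Ellipsoid(self.center.copy(), factor ** 2 * self.shape)

    def sample_boundary(self, rng, n: int = 1) -> np.ndarray:
        """Points on the boundary: image of uniform sphere points under A."""
        u = rng.standard_normal((n, self.dim))
        u /= np.linalg.norm(u, axis=1, keepdims=True)
        return self.center + u @ self.transform.T

    @classmethod
    def ball(cls, center, radius: float) -> "Ellipsoid":
        center = np.asarray(center, dtype=float)
        return cls(center, radius ** 2 * np.eye(center.size))

    @classmethod
    def from_axes(cls, center, semi_axes, directions) -> "Ellipsoid":
        """Build from semi-axis lengths and an orthonormal direction matrix."""
        directions = np.asarray(directions, dtype=float)
        semi_axes = np.asarray(semi_axes, dtype=float)
        shape = (directions * semi_axes ** 2) @ directions.T
        return cls(np.asarray(center, dtype=float), shape)


def diameter_spectrum(ell: Ellipsoid) -> np.ndarray:
    """Sorted axis diameters of an ellipsoid (heterogeneity fingerprint).

    For an ellipsoid the diameters along its principal directions are exactly
    the eigen-decomposition of the shape matrix, so no search is needed.
    """
    return ell.diameters()


# ---------------------------------------------------------------------------
# PCA ellipsoid
# ---------------------------------------------------------------------------

def pca_ellipsoid(chain_or_points) -> Ellipsoid:
    """Ellipsoid from the mean-centred covariance of previous samples.

    Any sampling attempt, even one far from equilibrium, carries information
    about the shape of the space; the closer the chain is to stationarity the
    closer this ellipsoid matches the polytope.  The shape matrix *is* the
    connected covariance (so for uniform samples on a box with sides a_i the
    eigenvalues approach a_i^2 / 12 -- only the relative axis geometry
    matters for direction biasing).

    Raises
    ------
    InsufficientDataError
        With fewer than D + 1 points.
    """
    points = getattr(chain_or_points, "points", chain_or_points)
    X = np.atleast_2d(np.asarray(points, dtype=float))
    T, D = X.shape
    if T < D + 1:
        raise InsufficientDataError(
            f"PCA ellipsoid needs at least D+1 = {D + 1} points, got {T}"
        )
    center = X.mean(axis=0)
    cov = np.cov(X, rowvar=False, ddof=1)
    cov = np.atleast_2d(cov)
    w = np.linalg.eigvalsh(cov)
    if w[0] <= 0.0:
        ridge = PCA_RIDGE_FRACTION * max(np.trace(cov) / D, 1e-300)
        if ridge <= 0.0 or w[0] <= -ridge:
            ridge = abs(w[0]) + max(PCA_RIDGE_FRACTION, 1e-300)
        logger.warning("covariance not positive definite; adding ridge %.3e", ridge)
        cov = cov + ridge * np.eye(D)
    return Ellipsoid(center, cov)


# ---------------------------------------------------------------------------
# LP (iterative variability) ellipsoid
# ---------------------------------------------------------------------------

def _lex_vertex(Gq, hq, i, maximize, pull_target):
    """Canonical optimal point: optimize coordinate i, then pull toward a target.

    Alternate optima make "the min/max vertex" ill-defined (on a box every
    point of a facet is optimal).  A second LP minimizes the l1 distance to
    *pull_target* over the optimal face, which yields a reproducible point
    and, on boxes, axis-aligned min-to-max vectors.
    """
    d = Gq.shape[1]
    c = np.zeros(d)
    c[i] = -1.0 if maximize else 1.0
    res = linprog(c, A_ub=Gq, b_ub=hq, bounds=(None, None), method="highs")
    if not res.success:
        raise LPSolverError(f"axis LP failed (coordinate {i}): {res.message}")
    opt = res.x[i]
    # phase 2: min sum(s), s >= |q - t|, with coordinate i fixed at its optimum
    c2 = np.concatenate([np.zeros(d), np.ones(d)])
    A_ub = np.block([
        [Gq, np.zeros((Gq.shape[0], d))],
        [np.eye(d), -np.eye(d)],
        [-np.eye(d), -np.eye(d)],
    ])
    b_ub = np.concatenate([hq, pull_target, -pull_target])
    A_eq = np.zeros((1, 2 * d))
    A_eq[0, i] = 1.0
    res2 = linprog(c2, A_ub=A_ub, b_ub=b_ub, A_eq=A_eq, b_eq=[opt],
                   bounds=(None, None), method="highs")
    if not res2.success:
        return res.x  # keep the phase-1 vertex if the tie-break LP struggles
    return res2.x[:d]


def lp_ellipsoid(poly: Polytope, seed: int = 0,
                 axis_tol: float = 1.0e-12) -> Ellipsoid:
    """Matching ellipsoid from iterated variability analysis.

    Iteration k ranges every coordinate of the polytope sliced through the
    current center and restricted to the orthogonal complement of the axes
    found so far, takes the longest min-to-max vector as the next axis, and
    recurses until D axes are found.  The center is the midpoint of the first
    axis' endpoints; semi-axes are half the found vectors' lengths.
    """
    D = poly.dim
    x0 = find_interior_point(poly, seed=seed)
    p0 = x0.copy()
    V = np.eye(D)                     # complement basis, D x (D - k)
    axes_dirs = np.zeros((D, D))
    semi = np.zeros(D)
    scale = max(np.abs(poly.h).max(), 1.0)
    for k in range(D):
        Gq = poly.G @ V
        hq = poly.h - poly.G @ p0
        pull = V.T @ (x0 - p0)
        best_vec, best_len = None, -1.0
        for i in range(V.shape[1]):
            q_hi = _lex_vertex(Gq, hq, i, True, pull)
            q_lo = _lex_vertex(Gq, hq, i, False, pull)
            vec = V @ (q_hi - q_lo)
            ln = np.linalg.norm(vec)
            if ln > best_len:
                best_len, best_vec = ln, vec
                best_lo, best_hi = V @ q_lo, V @ q_hi
        if best_len <= axis_tol * scale:
            raise DimensionCollapseError(
                f"axis {k} has negligible length {best_len:.3e}: the polytope "
                f"is not full-dimensional in {D} coordinates"
            )
        if k == 0:
            p0 = p0 + 0.5 * (best_lo + best_hi)
        u = best_vec / best_len
        axes_dirs[:, k] = u
        semi[k] = 0.5 * best_len
        if k < D - 1:
            # orthonormal complement of the axes found so far
            V = sla.null_space(axes_dirs[:, : k + 1].T)
    return Ellipsoid.from_axes(p0, semi, axes_dirs)


# ---------------------------------------------------------------------------
# ellipsoid-method machinery
# ---------------------------------------------------------------------------

def min_enclosing_halfellipsoid(ell: Ellipsoid, cut_normal, cut_point) -> Ellipsoid:
    """Minimal-volume ellipsoid enclosing E intersected with a half-space.

    The kept half-space is {p : a . (p - cut_point) <= 0} with a = cut_normal.
    With cut depth alpha = a . (center - cut_point) / sqrt(a^T B a) the
    standard deep-cut update applies for alpha in (-1/D, 1); alpha <= -1/D
    means the half-space contains E (E is returned unchanged, logged) and
    alpha >= 1 means the intersection is empty.
    """
    a = np.asarray(cut_normal, dtype=float).ravel()
    beta = float(a @ np.asarray(cut_point, dtype=float).ravel())
    return _deep_cut(ell, a, beta)


def _deep_cut(ell: Ellipsoid, a, beta) -> Ellipsoid:
    """Deep-cut update for the half-space {p : a . p <= beta}."""
    n = ell.dim
    B = ell.shape
    c = ell.center
    Ba = B @ a
    aBa = float(a @ Ba)
    if aBa <= 0.0:
        raise EmptyCutError("cut normal lies in the null space of the shape matrix")
    sq = math.sqrt(aBa)
    alpha = (float(a @ c) - beta) / sq
    if alpha >= 1.0:
        raise EmptyCutError(f"cut depth alpha = {alpha:.6f} >= 1: empty intersection")
    if alpha <= -1.0 / n:
        logger.debug("cut too shallow (alpha = %.6f <= -1/D); ellipsoid unchanged",
                     alpha)
        return ell
    if n == 1:
        # interval case: E = [c - r, c + r], keep p <= beta (a > 0) or p >= ...
        r = math.sqrt(B[0, 0])
        lo, hi = c[0] - r, c[0] + r
        if a[0] > 0:
            hi = min(hi, beta / a[0])
        else:
            lo = max(lo, beta / a[0])
        half = 0.5 * (hi - lo)
        return Ellipsoid(np.array([0.5 * (lo + hi)]), np.array([[half ** 2]]))
    b = Ba / sq
    tau = (1.0 + n * alpha) / (n + 1.0)
    sigma = 2.0 * (1.0 + n * alpha) / ((n + 1.0) * (1.0 + alpha))
    delta = n * n * (1.0 - alpha * alpha) / (n * n - 1.0)
    new_center = c - tau * b
    new_shape = delta * (B - sigma * np.outer(b, b))
    new_shape = 0.5 * (new_shape + new_shape.T)
    return Ellipsoid(new_center, new_shape)


def lovasz_ellipsoid(poly: Polytope, shrink: float | None = None,
                     max_iter: int | None = None, tol: float = 1.0e-9,
                     endpoint_check: bool = False):
    """Weak Loewner-John pair by the (shallow-cut) ellipsoid method.

    Starting from the ball enclosing the polytope's bounding box, repeatedly:
    if the center is outside P, cut with the most-violated inequality (a deep
    cut); otherwise shrink E about its center by *shrink* (default
    ``1/D**1.5``) and test whether the shrunken ellipsoid fits inside P by
    exact per-constraint support-function evaluation.  If some constraint is
    violated, cut E through the maximizer of that constraint over the
    shrunken ellipsoid (a shallow cut of depth ``-shrink``).  Terminates when
    E_inner <= P <= E.

    With ``endpoint_check=True`` the inner-containment test instead checks
    only the 2D axis endpoints of the shrunken ellipsoid (a cheaper spot
    check, faithful to the classical formulation but without the exact
    certificate).

    Returns
    -------
    (E, E_inner) : tuple of Ellipsoid
    """
    D = poly.dim
    if shrink is None:
        shrink = 1.0 / D ** 1.5
    if not 0.0 < shrink < 1.0:
        raise ValueError("shrink factor must lie in (0, 1)")
    if max_iter is None:
        max_iter = 50 * D * D

    lo, hi = poly.bounding_box
    center = 0.5 * (lo + hi)
    radius = 0.5 * float(np.linalg.norm(hi - lo)) * 1.01
    if radius == 0.0:
        raise DimensionCollapseError("bounding box has zero diagonal")
    E = Ellipsoid.ball(center, radius)

    G, h = poly.G, poly.h
    hscale = np.maximum(np.abs(h), 1.0)
    prev_logvol = E.log_volume()
    for _ in range(max_iter):
        viol = G @ E.center - h
        worst = int(np.argmax(viol / hscale))
        if viol[worst] > tol * hscale[worst]:
            # center outside P: deep cut with the violated constraint itself
            E = _deep_cut(E, G[worst], h[worst])
        else:
            if endpoint_check:
                inner_ok, cut_row, cut_pt = _endpoint_inner_test(
                    E, shrink, G, h, tol * hscale)
            else:
                inner_ok, cut_row, cut_pt = _support_inner_test(
                    E, shrink, G, h, tol * hscale)
            if inner_ok:
                return E, E.scaled(shrink)
            E = _deep_cut(E, G[cut_row], float(G[cut_row] @ cut_pt))
        logvol = E.log_volume()
        if logvol > prev_logvol + 1e-9:
            raise NonConvergenceError("ellipsoid volume failed to decrease")
        prev_logvol = logvol
    raise NonConvergenceError(
        f"no weak Loewner-John pair after {max_iter} cuts; current outer "
        f"log-volume {prev_logvol:.3f}"
    )


def _support_inner_test(E, shrink, G, h, tols):
    """Exact test E_inner <= P: per-row support sup {g.p : p in E_inner}."""
    Bg = E.shape @ G.T                      # (D, m)
    widths = np.sqrt(np.maximum(np.einsum("ij,ji->i", G, Bg), 0.0))
    margins = G @ E.center + shrink * widths - h
    worst = int(np.argmax(margins / np.maximum(tols, 1e-300)))
    if margins[worst] <= tols[worst]:
        return True, None, None
    g = G[worst]
    cut_pt = E.center + shrink * (E.shape @ g) / max(widths[worst], 1e-300)
    return False, worst, cut_pt


def _endpoint_inner_test(E, shrink, G, h, tols):
    """Spot check: are all axis endpoints of the shrunken ellipsoid in P?"""
    w, V = E._eig
    semi = shrink * np.sqrt(w)
    offsets = V * semi                      # column i = semi[i] * V[:, i]
    endpoints = np.vstack([E.center + offsets.T, E.center - offsets.T])
    viol = endpoints @ G.T - h
    idx = np.unravel_index(np.argmax(viol / np.maximum(tols, 1e-300)), viol.shape)
    if viol[idx] <= tols[idx[1]]:
        return True, None, None
    return False, int(idx[1]), endpoints[idx[0]]
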