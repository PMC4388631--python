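"""Full-dimensional flux polytopes.

The feasible steady states of a metabolic network form the bounded convex set

    P = { v : S v = 0,  vmin <= v <= vmax }.

Because ``S v = 0`` confines v to the null space of S, this set has empty
interior in flux space and a hit-and-run walk on it would be frozen (almost
every chord has zero length).  Everything here therefore works in a
*full-dimensional* parameterisation: an anchor flux vector satisfying
``S anchor = 0``, an orthonormal null-space basis B, and the induced
inequality system ``G p <= h`` so that the polytope is

    { p in R^D : G p <= h },   v = anchor + B p,   D = N - rank(S).

All sampling happens in p-space; fluxes are reconstructed through the affine
map on write-out.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import cached_property

import numpy as np
from scipy import linalg as sla
from scipy.optimize import linprog

from .exceptions import (
    DegenerateChordError,
    DegeneratePolytopeError,
    InfeasibleModelError,
    LPSolverError,
)
from .model_io import StoichiometricModel

#: default tolerance on ||S v||_inf for reconstructed fluxes
EQUALITY_TOL = 1.0e-9
#: default FVA tolerance below which a reaction counts as blocked
BLOCKED_TOL = 1.0e-9
#: chord-width floor, as a fraction of the bounding-box diagonal
CHORD_FLOOR_FRACTION = 1.0e-12


def _solve_lp(c, A_ub, b_ub, A_eq=None, b_eq=None, bounds=(None, None)):
    res = linprog(c, A_ub=A_ub, b_ub=b_ub, A_eq=A_eq, b_eq=b_eq,
                  bounds=bounds, method="highs")
    return res


@dataclass
class FvaResult:
    """Per-variable minima/maxima over a polytope with the optimizing vertices."""

    minimum: np.ndarray          # (n_vars,)
    maximum: np.ndarray          # (n_vars,)
    argmin: np.ndarray           # (n_vars, D) vertices in p-space
    argmax: np.ndarray           # (n_vars, D)
    labels: list | None = None

    @property
    def ranges(self) -> np.ndarray:
        return self.maximum - self.minimum


@dataclass
class Polytope:
    """A bounded full-dimensional polytope {p : G p <= h} with a flux map."""

    anchor: np.ndarray           # (N,) feasible flux vector
    basis: np.ndarray            # (N, D) orthonormal null-space basis
    G: np.ndarray                # (m, D)
    h: np.ndarray                # (m,)
    labels: list | None = None   # surviving reaction ids

    def __post_init__(self):
        self.anchor = np.asarray(self.anchor, dtype=float)
        self.basis = np.atleast_2d(np.asarray(self.basis, dtype=float))
        self.G = np.atleast_2d(np.asarray(self.G, dtype=float))
        self.h = np.asarray(self.h, dtype=float).ravel()
        if self.G.shape[0] != self.h.size:
            raise ValueError("G and h row counts differ")
        if self.G.shape[1] != self.basis.shape[1]:
            raise ValueError("G column count must equal basis column count")

    @property
    def dim(self) -> int:
        """Dimension D of the full-dimensional representation."""
        return self.G.shape[1]

    @property
    def n_constraints(self) -> int:
        return self.G.shape[0]

    # -- geometry ----------------------------------------------------------
    def contains(self, p, tol: float = 1.0e-9) -> bool:
        """True iff ``G p <= h + tol`` elementwise."""
        p = np.asarray(p, dtype=float)
        if p.shape[-1] != self.dim:
            raise ValueError(f"point has dimension {p.shape[-1]}, expected {self.dim}")
        return bool(np.all(self.G @ p <= self.h + tol))

    def contains_all(self, P, tol: float = 1.0e-9) -> bool:
        P = np.atleast_2d(np.asarray(P, dtype=float))
        return bool(np.all(P @ self.G.T <= self.h + tol))

    def chord(self, x, theta):
        """Intersection of the line ``x + lambda theta`` with the polytope.

        Returns ``(lmin, lmax)`` with ``lmin < 0 < lmax`` for interior x.
        Raises :class:`DegenerateChordError` when the chord is narrower than
        the chord-width floor, so a sampler can resample the direction.
        """
        x = np.asarray(x, dtype=float)
        theta = np.asarray(theta, dtype=float)
        gd = self.G @ theta
        slack = self.h - self.G @ x
        lmin, lmax = _chord_from_slack(slack, gd)
        if not np.isfinite(lmin) or not np.isfinite(lmax):
            raise DegenerateChordError("chord unbounded: polytope not bounded "
                                       "along this direction")
        if lmax - lmin < self.chord_floor:
            raise DegenerateChordError(
                f"chord width {lmax - lmin:.3e} below floor {self.chord_floor:.3e}"
            )
        return lmin, lmax

    def to_fluxes(self, P) -> np.ndarray:
        """Map p-space points (T, D) back to flux space (T, N)."""
        P = np.atleast_2d(np.asarray(P, dtype=float))
        return self.anchor + P @ self.basis.T

    # -- cached metrics ----------------------------------------------------
    @cached_property
    def bounding_box(self):
        """(lo, hi) per-coordinate ranges from FVA."""
        res = fva(self)
        return res.minimum.copy(), res.maximum.copy()

    @cached_property
    def bounding_box_diagonal(self) -> float:
        lo, hi = self.bounding_box
        return float(np.linalg.norm(hi - lo))

    @cached_property
    def chord_floor(self) -> float:
        diag = self.bounding_box_diagonal
        return CHORD_FLOOR_FRACTION * (diag if diag > 0 else 1.0)


def _chord_from_slack(slack, gd, eps: float = 1.0e-300):
    """Tightest lambda-interval from per-row ratios slack_i / gd_i."""
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = slack / gd
    pos = gd > eps
    neg = gd < -eps
    lmax = np.min(ratio, where=pos, initial=np.inf)
    lmin = np.max(ratio, where=neg, initial=-np.inf)
    return lmin, lmax


# ---------------------------------------------------------------------------
# construction
# ---------------------------------------------------------------------------

def build_polytope(model: StoichiometricModel) -> Polytope:
    """Reduce a stoichiometric model to its full-dimensional polytope.

    Reactions fixed by their bounds (``lb == ub``) are treated as extra
    equality constraints so that D reflects the dimension actually available
    to the dynamics.  The anchor is an LP-feasible flux vector projected onto
    the equality subspace to machine precision.

    Raises
    ------
    InfeasibleModelError
        If no flux vector satisfies all constraints.
    DegeneratePolytopeError
        If the feasible set is a single point (D = 0).
    """
    S = model.S
    M, N = S.shape
    lb, ub = model.lower_bounds, model.upper_bounds

    fixed = lb == ub
    A_eq = S
    b_eq = np.zeros(M)
    if fixed.any():
        rows = np.zeros((int(fixed.sum()), N))
        rows[np.arange(int(fixed.sum())), np.nonzero(fixed)[0]] = 1.0
        A_eq = np.vstack([S, rows])
        b_eq = np.concatenate([b_eq, lb[fixed]])

    res = _solve_lp(np.zeros(N), None, None, A_eq=A_eq, b_eq=b_eq,
                    bounds=list(zip(lb, ub)))
    if res.status == 2:
        raise InfeasibleModelError(
            f"no feasible steady state: LP reports infeasibility ({res.message})"
        )
    if not res.success:
        raise LPSolverError(f"feasibility LP failed: {res.message}")
    anchor = res.x

    basis = sla.null_space(A_eq)  # rcond: max(M,N) * eps * sigma_max
    D = basis.shape[1]
    if D == 0:
        raise DegeneratePolytopeError(
            "the feasible set is a single point (null space is trivial)"
        )

    # project the LP anchor onto {A_eq v = b_eq} exactly: the HiGHS solution
    # only satisfies equalities to solver tolerance, which is too loose for
    # the steady-state guarantee on exported fluxes.
    correction, *_ = np.linalg.lstsq(A_eq, b_eq - A_eq @ anchor, rcond=None)
    anchor = anchor + correction

    G_rows, h_vals = [], []
    row_tol = max(M, N) * np.finfo(float).eps
    for j in range(N):
        if fixed[j]:
            continue
        row = basis[j, :]
        nrm = np.linalg.norm(row)
        if nrm <= row_tol:
            continue  # flux j is constant over the null space
        if np.isfinite(ub[j]):
            G_rows.append(row / nrm)
            h_vals.append((ub[j] - anchor[j]) / nrm)
        if np.isfinite(lb[j]):
            G_rows.append(-row / nrm)
            h_vals.append((anchor[j] - lb[j]) / nrm)
    if not G_rows:
        raise DegeneratePolytopeError("no finite bounds constrain the null space")
    return Polytope(anchor=anchor, basis=basis, G=np.array(G_rows),
                    h=np.array(h_vals), labels=list(model.reaction_ids))


# ---------------------------------------------------------------------------
# flux variability analysis
# ---------------------------------------------------------------------------

def fva(poly: Polytope, space: str = "coordinates") -> FvaResult:
    """Minimize and maximize each variable over the polytope by LP.

    Parameters
    ----------
    poly : Polytope
    space : {'coordinates', 'fluxes'}
        ``'coordinates'`` ranges each p-space coordinate; ``'fluxes'`` ranges
        each reaction flux ``anchor_j + basis_j . p``.
    """
    D = poly.dim
    if space == "coordinates":
        objectives = np.eye(D)
        offsets = np.zeros(D)
        labels = None
    elif space == "fluxes":
        objectives = poly.basis
        offsets = poly.anchor
        labels = poly.labels
    else:
        raise ValueError(f"unknown space {space!r}")

    n = objectives.shape[0]
    mins = np.empty(n)
    maxs = np.empty(n)
    amin = np.empty((n, D))
    amax = np.empty((n, D))
    for i, c in enumerate(objectives):
        lo, v_lo = _optimize(poly, c, maximize=False, index=i)
        hi, v_hi = _optimize(poly, c, maximize=True, index=i)
        mins[i] = lo + offsets[i]
        maxs[i] = hi + offsets[i]
        amin[i] = v_lo
        amax[i] = v_hi
    return FvaResult(mins, maxs, amin, amax, labels=labels)


def _optimize(poly: Polytope, c, maximize: bool, index: int | None = None):
    sign = -1.0 if maximize else 1.0
    res = _solve_lp(sign * np.asarray(c, dtype=float), poly.G, poly.h)
    if not res.success:
        where = "" if index is None else f" (variable {index})"
        raise LPSolverError(f"FVA LP failed{where}: {res.message}")
    return sign * res.fun, res.x


# ---------------------------------------------------------------------------
# blocked-reaction removal
# ---------------------------------------------------------------------------

def flux_ranges(model: StoichiometricModel):
    """FVA directly on the model constraints {S v = 0, lb <= v <= ub}."""
    S = model.S
    M, N = S.shape
    bounds = list(zip(model.lower_bounds, model.upper_bounds))
    mins = np.empty(N)
    maxs = np.empty(N)
    c = np.zeros(N)
    for j in range(N):
        c[j] = 1.0
        lo = _solve_lp(c, None, None, A_eq=S, b_eq=np.zeros(M), bounds=bounds)
        if lo.status == 2:
            raise InfeasibleModelError("model infeasible during FVA")
        c[j] = -1.0
        hi = _solve_lp(c, None, None, A_eq=S, b_eq=np.zeros(M), bounds=bounds)
        c[j] = 0.0
        if not (lo.success and hi.success):
            raise LPSolverError(f"FVA LP failed for reaction index {j}")
        mins[j], maxs[j] = lo.fun, -hi.fun
    return mins, maxs


def remove_blocked(model: StoichiometricModel,
                   tol: float = BLOCKED_TOL) -> StoichiometricModel:
    """Delete reactions whose flux is pinned to zero everywhere on the polytope.

    A reaction is blocked when its FVA range has width <= *tol* and the range
    sits at zero.  Metabolites that no surviving reaction touches are dropped
    with it.  The operation is idempotent.
    """
    mins, maxs = flux_ranges(model)
    blocked = (maxs - mins <= tol) & (np.abs(maxs) <= tol) & (np.abs(mins) <= tol)
    keep_rxn = ~blocked
    S = model.S[:, keep_rxn]
    keep_met = np.any(S != 0.0, axis=1)
    return StoichiometricModel(
        metabolite_ids=[m for m, k in zip(model.metabolite_ids, keep_met) if k],
        reaction_ids=[r for r, k in zip(model.reaction_ids, keep_rxn) if k],
        S=S[keep_met, :],
        lower_bounds=model.lower_bounds[keep_rxn],
        upper_bounds=model.upper_bounds[keep_rxn],
    )


# ---------------------------------------------------------------------------
# interior points
# ---------------------------------------------------------------------------

def find_interior_point(poly: Polytope, seed: int = 0, retries: int = 20,
                        margin_fraction: float = 1.0e-7) -> np.ndarray:
    """A strictly interior point: midpoint of two LP vertices.

    Maximizes a random objective and its negation, takes the midpoint, and
    retries with a fresh objective if the midpoint hugs a facet.  Falls back
    to the average of all FVA vertices before giving up.
    """
    rng = np.random.default_rng(seed)
    D = poly.dim
    scale = np.maximum(np.abs(poly.h), 1.0)
    margin = margin_fraction * scale

    def _strictly_inside(p):
        return np.all(poly.G @ p <= poly.h - margin)

    for _ in range(retries):
        c = rng.standard_normal(D)
        _, v1 = _optimize(poly, c, maximize=True)
        _, v2 = _optimize(poly, c, maximize=False)
        if np.linalg.norm(v1 - v2) == 0.0:
            continue
        mid = 0.5 * (v1 + v2)
        if _strictly_inside(mid):
            return mid
    res = fva(poly)
    mid = 0.5 * (res.argmin.mean(axis=0) + res.argmax.mean(axis=0))
    if _strictly_inside(mid):
        return mid
    raise DegeneratePolytopeError(
        "could not find a strictly interior point; the polytope is likely "
        "lower-dimensional"
    )


def contains(poly: Polytope, p, tol: float = 1.0e-9) -> bool:
    """Module-level alias for :meth:`Polytope.contains`."""
    return poly.contains(p, tol=tol)


def chord(poly: Polytope, x, theta):
    """Module-level alias for :meth:`Polytope.chord`."""
    return poly.chord(x, theta)
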