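"""Uniform samplers on full-dimensional polytopes.

``hr_sample`` is the workhorse: a hit-and-run Markov chain whose direction
law is either uniform on the sphere (plain HR) or the normalized image of a
sphere point under an ellipsoid transform (rounded HR).  Both leave the
uniform distribution on the polytope invariant -- biasing the direction by a
fixed invertible matrix is an affine change of variables with constant
Jacobian.

``achr_sample`` is the artificially-centered heuristic used by popular flux
samplers: directions point from the running center of mass to a previously
sampled point.  It adapts to elongated shapes but is non-Markovian, so it
carries no uniformity guarantee; it is provided for comparison studies.

``rejection_sample`` is the exact i.i.d. oracle (box proposal + membership
test), practical only in low dimension.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import FrozenDynamicsError, InsufficientDataError
from .polytope import Polytope, _chord_from_slack
from .rounding import Ellipsoid

#: consecutive degenerate-chord resamples tolerated before giving up
RESAMPLE_CAP = 1000
#: refresh the cached constraint products every this many steps (drift control)
_REFRESH_EVERY = 4096


@dataclass
class SampleChain:
    """An ordered matrix of sampled points with provenance metadata."""

    points: np.ndarray           # (T, D), rows ordered by Monte Carlo time
    sampler_id: str              # 'hr', 'hr_rounded', 'achr', 'rejection'
    seed: int
    thinning: int = 1            # MC steps between recorded rows (recorded, not hidden)
    labels: list | None = None
    ellipsoid_ref: str | None = None
    n_resampled: int = 0         # degenerate-chord direction resamples

    def __post_init__(self):
        self.points = np.atleast_2d(np.asarray(self.points, dtype=float))
        if self.points.shape[0] < 1:
            raise ValueError("a chain must contain at least one point")
        if self.thinning < 1:
            raise ValueError("thinning must be >= 1")

    @property
    def n_points(self) -> int:
        return self.points.shape[0]

    @property
    def dim(self) -> int:
        return self.points.shape[1]

    @property
    def mc_steps(self) -> int:
        """Total Monte Carlo steps represented by the chain."""
        return self.n_points * self.thinning


def random_direction(D: int, rng) -> np.ndarray:
    """Uniform unit vector via the Marsaglia construction.

    D independent standard normals, normalized to unit Euclidean length.
    """
    if D < 1:
        raise ValueError("D must be >= 1")
    while True:
        u = rng.standard_normal(D)
        n = np.linalg.norm(u)
        if n > 1.0e-12:
            return u / n


def hr_sample(poly: Polytope, start, n: int, thin: int = 1,
              ellipsoid: Ellipsoid | None = None, seed: int = 0) -> SampleChain:
    """Hit-and-run chain of *n* recorded points (``n * thin`` MC steps).

    Each step draws a direction (sphere-uniform, or ellipsoid-biased when
    *ellipsoid* is given), intersects the line through the current point with
    the polytope, and jumps to a uniform point of the open chord.  The jump
    parameter is nudged inward by the chord-width floor so iterates stay
    strictly interior.  Chords narrower than the floor trigger a direction
    resample (counted on the chain); more than :data:`RESAMPLE_CAP`
    consecutive resamples raise :class:`FrozenDynamicsError`.

    A fixed seed yields a bitwise-identical chain, including the positions of
    any resampled directions (one RNG stream drives everything).
    """
    x = np.array(start, dtype=float)
    D = poly.dim
    if x.shape != (D,):
        raise ValueError(f"start point must have dimension {D}")
    if not poly.contains(x):
        raise ValueError("start point is not inside the polytope")
    A = None
    if ellipsoid is not None:
        A = np.asarray(ellipsoid.transform, dtype=float)
        if A.shape != (D, D):
            raise ValueError("ellipsoid transform must be D x D")
    rng = np.random.default_rng(seed)
    G, h = poly.G, poly.h
    floor = poly.chord_floor
    out = np.empty((n, D))
    gx = G @ x
    n_resampled = 0
    consecutive = 0
    recorded = 0
    step = 0
    while recorded < n:
        u = rng.standard_normal(D)
        if A is not None:
            u = A @ u
        nrm = np.sqrt(u @ u)
        if nrm <= 1.0e-300:
            continue
        u /= nrm
        gd = G @ u
        lmin, lmax = _chord_from_slack(h - gx, gd)
        if lmax - lmin < 3.0 * floor:
            n_resampled += 1
            consecutive += 1
            if consecutive > RESAMPLE_CAP:
                raise FrozenDynamicsError(
                    f"{consecutive} consecutive degenerate chords: dynamics frozen"
                )
            continue
        consecutive = 0
        lam = rng.uniform(lmin + floor, lmax - floor)
        x = x + lam * u
        gx = gx + lam * gd
        step += 1
        if step % _REFRESH_EVERY == 0:
            gx = G @ x
        if step % thin == 0:
            out[recorded] = x
            recorded += 1
    return SampleChain(out, "hr" if A is None else "hr_rounded", seed,
                       thinning=thin, n_resampled=n_resampled,
                       ellipsoid_ref=None if ellipsoid is None else "ellipsoid")


def achr_sample(poly: Polytope, start, n: int, thin: int = 1,
                warmup: int | None = None, seed: int = 0) -> SampleChain:
    """Artificially-centered hit-and-run (comparison baseline, no guarantee).

    After a *warmup* of plain HR steps that seeds the direction pool, each
    direction is ``normalize(random pool point - running center)`` where the
    center is the running mean over every accepted iterate and the pool holds
    the recorded (thinned) points plus the warmup states.  Chord and jump are
    as in :func:`hr_sample`.
    """
    D = poly.dim
    if warmup is None:
        warmup = D + 1
    if warmup < D + 1:
        raise ValueError("warmup must be at least D + 1")
    x = np.array(start, dtype=float)
    if not poly.contains(x):
        raise ValueError("start point is not inside the polytope")
    rng = np.random.default_rng(seed)
    G, h = poly.G, poly.h
    floor = poly.chord_floor
    gx = G @ x
    center = x.copy()
    n_seen = 1
    pool = [x.copy()]
    out = np.empty((n, D))
    n_resampled = 0
    consecutive = 0
    recorded = 0
    step = 0
    while recorded < n:
        if step < warmup:
            u = rng.standard_normal(D)
        else:
            ref = pool[rng.integers(len(pool))]
            u = ref - center
            if np.linalg.norm(u) <= 1.0e-12 * (1.0 + np.linalg.norm(center)):
                u = rng.standard_normal(D)
        nrm = np.linalg.norm(u)
        if nrm <= 1.0e-300:
            continue
        u = u / nrm
        gd = G @ u
        lmin, lmax = _chord_from_slack(h - gx, gd)
        if lmax - lmin < 3.0 * floor:
            n_resampled += 1
            consecutive += 1
            if consecutive > RESAMPLE_CAP:
                raise FrozenDynamicsError(
                    f"{consecutive} consecutive degenerate chords: dynamics frozen"
                )
            continue
        consecutive = 0
        lam = rng.uniform(lmin + floor, lmax - floor)
        x = x + lam * u
        gx = gx + lam * gd
        step += 1
        n_seen += 1
        center += (x - center) / n_seen
        if step % _REFRESH_EVERY == 0:
            gx = G @ x
        if step <= warmup:
            pool.append(x.copy())
        if step % thin == 0:
            out[recorded] = x
            recorded += 1
            pool.append(x.copy())
    return SampleChain(out, "achr", seed, thinning=thin, n_resampled=n_resampled)


def rejection_sample(poly: Polytope, n: int, seed: int = 0,
                     max_dim: int = 10, batch: int = 4096) -> SampleChain:
    """Exact i.i.d. uniform samples by box proposal + membership rejection.

    Serves as the ground-truth oracle in consistency tests; guarded to
    D <= *max_dim* because the acceptance rate collapses exponentially.
    """
    D = poly.dim
    if D > max_dim:
        raise InsufficientDataError(
            f"rejection sampling guarded to D <= {max_dim} (got D = {D})"
        )
    rng = np.random.default_rng(seed)
    lo, hi = poly.bounding_box
    accepted = []
    n_acc = 0
    n_prop = 0
    while n_acc < n:
        props = lo + (hi - lo) * rng.random((batch, D))
        keep = np.all(props @ poly.G.T <= poly.h, axis=1)
        n_prop += batch
        got = props[keep]
        if got.shape[0]:
            accepted.append(got)
            n_acc += got.shape[0]
        if n_prop >= 1e6 and n_acc / n_prop < 1.0e-6:
            raise InsufficientDataError(
                f"rejection acceptance rate {n_acc / n_prop:.2e} below 1e-6"
            )
    points = np.concatenate(accepted, axis=0)[:n]
    chain = SampleChain(points, "rejection", seed, thinning=1)
    chain.acceptance_rate = n_acc / n_prop
    return chain
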