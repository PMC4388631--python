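"""Synthetic polytopes and controlled sampler-comparison experiments.

The generators produce shapes whose per-coordinate marginals are known
analytically (flat on each side of an axis-aligned box), so sampler output
can be scored against exact references: hypercubes probe the dimension
dependence of mixing, hyper-rectangles with sides spanning many decades
reproduce the heterogeneity of flux scales seen in genome-scale metabolic
models, and random half-space polytopes feed the oracle-consistency tests.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import GeneratorError
from .polytope import Polytope, find_interior_point
from .rounding import lovasz_ellipsoid, lp_ellipsoid, pca_ellipsoid
from .samplers import achr_sample, hr_sample
from .diagnostics import DiagnosticsReport, diagnose_chain

#: samplers understood by run_rounding_comparison
KNOWN_SAMPLERS = ("hr", "hr_pca", "hr_lp", "hr_lem", "hr_lp_pca", "hr_lem_pca",
                  "achr")


def make_hypercube(D: int) -> Polytope:
    """The unit cube [0, 1]^D as a full-dimensional polytope."""
    if D < 1:
        raise ValueError("D must be >= 1")
    G = np.vstack([np.eye(D), -np.eye(D)])
    h = np.concatenate([np.ones(D), np.zeros(D)])
    poly = Polytope(anchor=np.zeros(D), basis=np.eye(D), G=G, h=h,
                    labels=[f"x{i}" for i in range(D)])
    poly.sides = np.ones(D)
    return poly


def make_hyperrectangle(D: int, axis_lengths=None, log_range=(-2.0, 5.0),
                        rotate: bool = False, seed: int = 0) -> Polytope:
    """Box [0, a_1] x ... x [0, a_D], optionally randomly rotated.

    Without explicit *axis_lengths* the sides are spaced geometrically
    across ``log_range`` decades (default 1e-2 ... 1e5, the heterogeneity
    regime typical of flux polytopes).  With ``rotate=True`` the box is
    tilted by a seeded random orthogonal matrix, which makes its principal
    directions invisible to coordinate-wise variability analysis.
    """
    if axis_lengths is None:
        if D == 1:
            axis_lengths = np.array([10.0 ** log_range[1]])
        else:
            axis_lengths = np.logspace(log_range[0], log_range[1], D)
    a = np.asarray(axis_lengths, dtype=float)
    if a.shape != (D,) or np.any(a <= 0.0):
        raise ValueError("axis_lengths must be D positive numbers")
    G = np.vstack([np.eye(D), -np.eye(D)])
    h = np.concatenate([a, np.zeros(D)])
    if rotate:
        rng = np.random.default_rng(seed)
        Q, _ = np.linalg.qr(rng.standard_normal((D, D)))
        G = G @ Q.T          # y = Q p  =>  constraints on p = Q^T y
    poly = Polytope(anchor=np.zeros(D), basis=np.eye(D), G=G, h=h,
                    labels=[f"x{i}" for i in range(D)])
    poly.sides = None if rotate else a
    return poly


def make_random_polytope(D: int, n_constraints: int, seed: int = 0,
                         max_retries: int = 50) -> Polytope:
    """Bounded random polytope from unit-normal half-spaces around the origin.

    Normals are uniform on the sphere with offsets in [0.5, 1.5]; instances
    are regenerated until the resulting set is bounded (verified by LP along
    all coordinate directions) and full-dimensional (the origin is interior
    by construction).  Deterministic for a fixed seed.
    """
    if n_constraints < D + 1:
        raise ValueError("need at least D + 1 constraints for boundedness")
    rng = np.random.default_rng(seed)
    for _ in range(max_retries):
        G = rng.standard_normal((n_constraints, D))
        G /= np.linalg.norm(G, axis=1, keepdims=True)
        h = rng.uniform(0.5, 1.5, size=n_constraints)
        poly = Polytope(anchor=np.zeros(D), basis=np.eye(D), G=G, h=h,
                        labels=[f"x{i}" for i in range(D)])
        try:
            lo, hi = poly.bounding_box
        except Exception:
            continue
        if np.all(np.isfinite(lo)) and np.all(np.isfinite(hi)):
            return poly
    raise GeneratorError(
        f"no bounded polytope with {n_constraints} constraints in D={D} "
        f"after {max_retries} attempts"
    )


@dataclass
class BenchmarkSpec:
    """Configuration of one controlled sampler-comparison run."""

    shape: str                        # hypercube | hyperrectangle | random_polytope
    D: int
    step_budget: int
    samplers: list
    axis_lengths: list | None = None
    log_range: tuple = (-2.0, 5.0)
    n_constraints: int | None = None
    seed: int = 0
    thin: int | None = None           # default keeps <= 2e5 recorded points
    bins: int = 100
    pilot_points: int | None = None   # PCA pilot-chain length

    def __post_init__(self):
        if self.D < 1:
            raise ValueError("D must be >= 1")
        if self.step_budget < self.D:
            raise ValueError("step budget must be at least D")
        if not self.samplers:
            raise ValueError("at least one sampler is required")
        unknown = [s for s in self.samplers if s not in KNOWN_SAMPLERS]
        if unknown:
            raise ValueError(f"unknown sampler ids {unknown}; "
                             f"choose from {KNOWN_SAMPLERS}")
        if self.axis_lengths is not None and np.any(
                np.asarray(self.axis_lengths) <= 0):
            raise ValueError("axis lengths must be positive")

    @classmethod
    def from_json(cls, path) -> "BenchmarkSpec":
        with open(path) as fh:
            try:
                data = json.load(fh)
            except json.JSONDecodeError as exc:
                raise ValueError(f"{path}: malformed JSON benchmark spec "
                                 f"({exc})") from exc
        if "log_range" in data:
            data["log_range"] = tuple(data["log_range"])
        return cls(**data)

    def to_json(self, path) -> None:
        data = {k: v for k, v in self.__dict__.items() if v is not None}
        data["log_range"] = list(self.log_range)
        with open(path, "w") as fh:
            json.dump(data, fh, indent=1)

    def build_polytope(self) -> Polytope:
        if self.shape == "hypercube":
            return make_hypercube(self.D)
        if self.shape == "hyperrectangle":
            return make_hyperrectangle(self.D, self.axis_lengths,
                                       self.log_range, seed=self.seed)
        if self.shape == "random_polytope":
            n = self.n_constraints or 3 * self.D
            return make_random_polytope(self.D, n, seed=self.seed)
        raise ValueError(f"unknown shape {self.shape!r}")


def build_rounding_ellipsoid(poly: Polytope, method: str, seed: int = 0,
                             pilot_points: int | None = None,
                             pilot_thin: int = 1):
    """Construct the matching ellipsoid for one preprocessing schedule.

    ``none`` records no ellipsoid; ``pca`` runs an unrounded pilot chain and
    diagonalizes its covariance; ``lp``/``lem`` build the ellipsoid
    geometrically; ``lp_pca``/``lem_pca`` refine the geometric ellipsoid by
    a pilot chain biased with it followed by PCA -- the pilot then explores
    well enough that the covariance is close to stationary.
    """
    method = method.replace("+", "_")
    if pilot_points is None:
        pilot_points = max(2000, 10 * poly.dim)
    if method == "none":
        return None
    if method == "lp":
        return lp_ellipsoid(poly, seed=seed)
    if method == "lem":
        E, _ = lovasz_ellipsoid(poly)
        return E
    if method in ("pca", "lp_pca", "lem_pca"):
        base = None
        if method == "lp_pca":
            base = lp_ellipsoid(poly, seed=seed)
        elif method == "lem_pca":
            base, _ = lovasz_ellipsoid(poly)
        start = find_interior_point(poly, seed=seed)
        pilot = hr_sample(poly, start, n=pilot_points, thin=pilot_thin,
                          ellipsoid=base, seed=seed + 7)
        return pca_ellipsoid(pilot)
    raise ValueError(f"unknown rounding method {method!r}")


def run_rounding_comparison(spec: BenchmarkSpec):
    """Run every requested sampler at the same step budget on the same shape.

    Per-axis KLD against the known flat marginal and integrated
    autocorrelation times are computed for each sampler; preprocessing
    (ellipsoid construction, including any pilot chain) is not charged to
    the sampling budget.

    Returns
    -------
    reports : dict of DiagnosticsReport
    table : pandas.DataFrame
        One row per sampler with tau_max and KLD summaries.
    """
    poly = spec.build_polytope()
    sides = getattr(poly, "sides", None)
    marginals = None if sides is None else np.column_stack(
        [np.zeros(spec.D), sides])
    thin = spec.thin or max(1, spec.step_budget // 200_000)
    n_points = spec.step_budget // thin
    # pilot chains get 5% of the sampling budget (not charged to it)
    pilot = spec.pilot_points or max(2_000, spec.step_budget // 20)
    start = find_interior_point(poly, seed=spec.seed)

    reports = {}
    rows = []
    for sid in spec.samplers:
        if sid == "achr":
            chain = achr_sample(poly, start, n=n_points, thin=thin,
                                seed=spec.seed)
        else:
            method = "none" if sid == "hr" else sid[len("hr_"):]
            ell = build_rounding_ellipsoid(poly, method, seed=spec.seed,
                                           pilot_points=pilot)
            chain = hr_sample(poly, start, n=n_points, thin=thin,
                              ellipsoid=ell, seed=spec.seed)
        report = diagnose_chain(chain, marginal_ranges=marginals,
                                bins=spec.bins)
        report.sampler_id = sid
        reports[sid] = report
        row = {"sampler": sid, **{k: v for k, v in report.summary().items()
                                  if k != "sampler_id"}}
        rows.append(row)
    return reports, pd.DataFrame(rows)
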