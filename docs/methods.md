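# Methods

## The model

A metabolic network with stoichiometric matrix **S** (M metabolites × N
reactions) and flux bounds v<sup>min</sup> ≤ v ≤ v<sup>max</sup> admits the
steady-state set

P = { v ∈ R<sup>N</sup> : S v = 0, v<sup>min</sup> ≤ v ≤ v<sup>max</sup> },

a bounded convex polytope.  Uniform samples from P are the least-committal
description of the network's feasible behaviour and the reference against
which heuristic flux samplers must be judged.

### Full-dimensional reduction

P has empty interior in flux space, so any chord-based Markov chain run in
R<sup>N</sup> is frozen.  `build_polytope` re-parameterizes P as
{ p ∈ R<sup>D</sup> : G p ≤ h } with v = anchor + B p, where B is an
orthonormal basis of the null space of S (augmented with rows for reactions
fixed by their bounds) and D = N − rank(S).  The numerical rank uses the SVD
threshold max(M,N)·eps·σ<sub>max</sub>.  The anchor is an LP-feasible point
re-projected onto {S v = 0} by least squares, because LP solvers meet
equality constraints only to ~1e-9 while the package guarantees
‖S v‖<sub>∞</sub> ≤ 1e-9 on every exported sample with headroom.
Inequality rows are normalized to unit norm.

Blocked reactions (FVA range within 1e-9 of zero — both tolerances
configurable; the choice is an engineering default) are removed first, along
with orphaned metabolites; the operation is idempotent.

## Hit-and-run and rounding

One HR step from x: draw a unit direction θ, intersect the line x + λθ with
the polytope (per-row ratio bounds give [λ<sub>min</sub>, λ<sub>max</sub>]),
draw λ* uniformly on that chord, move.  The chain leaves the uniform law
invariant; its mixing degrades with the sandwiching ratio R/r of the body
(τ ≈ O(D² R²/r²)), and flux polytopes are routinely sandwiched at R/r ≈ 1e5.

Biasing directions as θ = A u/‖A u‖ with u sphere-uniform and A a fixed
invertible matrix is equivalent to running plain HR on A<sup>−1</sup>P — an
affine transformation with constant Jacobian, so uniformity is preserved
exactly while the conditioning of the transformed body can be driven to
O(1).  A is any square root of the matching ellipsoid's shape matrix
(Cholesky here; by spherical symmetry of u the choice of root is
irrelevant).  Three ellipsoid constructions:

- **PCA** (`pca_ellipsoid`): mean and connected covariance of a previous
  (pilot) chain.  Cheap and asymptotically exact, but only as good as the
  pilot: a pilot that never traverses the long axes leaves them
  under-weighted.
- **Iterative LP** (`lp_ellipsoid`): repeatedly range every coordinate over
  the polytope (restricted to the orthogonal complement of axes already
  found, sliced through the current center), take the longest min-to-max
  vertex vector as the next axis.  Degenerate alternate optima are resolved
  by a second LP minimizing the l1 distance to an interior point over the
  optimal face; this canonical choice makes the axes reproducible and, on
  axis-aligned boxes, exactly aligned — so sorted axis lengths are
  proportional to sorted side lengths.  The ellipsoid center is the midpoint
  of the first axis' endpoints (the center convention is ours).
- **Lovász ellipsoid method** (`lovasz_ellipsoid`): start from the ball
  around the FVA bounding box (radius = 1.01 × half-diagonal); while the
  center is outside P, apply a deep cut with the most-violated constraint;
  otherwise shrink by 1/D<sup>3/2</sup> and test E_inner ⊆ P by exact
  per-constraint support-function evaluation (g·c + s·√(gᵀBg) ≤ h), cutting
  through the maximizer of the most-violated constraint when the test fails
  (a shallow cut of depth −1/D<sup>3/2</sup> > −1/D, so volume still
  decreases).  Terminates with a weak Loewner–John pair
  E_inner ⊆ P ⊆ E.  The classical axis-endpoint spot check is available via
  `endpoint_check=True` for fidelity, without the exact certificate.
  Default iteration cap 50·D².  The deep-cut update formulas are the
  standard ones (τ = (1+nα)/(n+1), σ = 2(1+nα)/((n+1)(1+α)),
  δ = n²(1−α²)/(n²−1)), verified in the tests against the analytic central
  cut of the disk and a brute-force volume search; D = 1 is handled as the
  exact interval case.
- **Combined schedules** (`lp+pca`, `lem+pca`): build the geometric
  ellipsoid, run a pilot chain biased by it, then PCA on the pilot.  The
  biased pilot mixes well, so its covariance is close to the stationary one
  — the best schedule observed here, as for the published experiments it
  emulates, *when the base ellipsoid is inexact* (e.g. LEM).  On axis-aligned
  boxes LP is already exact and the PCA step can only add estimation noise.

λ* is drawn from the chord nudged inward by the chord-width floor
(1e-12 × bounding-box diagonal) so iterates stay strictly interior; chords
narrower than the floor trigger a direction resample (counted, one shared
RNG stream, so fixed seed ⇒ bitwise-identical chains), with a cap of 1000
consecutive resamples before a frozen-dynamics error.

### Baselines

`achr_sample` implements artificially-centered hit-and-run: directions from
the running center of mass toward a random previously sampled point.  The
direction pool holds the warmup states plus the recorded (thinned) points,
while the center averages every iterate; storing every iterate, as the
original formulation implies, would need O(T·D) memory (~1 GB at D = 500).
ACHR adapts to elongated bodies but is non-Markovian and carries no
uniformity guarantee; it exists here purely as the comparison baseline.
`rejection_sample` (box proposal + membership) is the exact i.i.d. oracle,
guarded to D ≤ 10.

## Diagnostics

- **Integrated autocorrelation time** (binning/batch means): r(b) =
  b·Var(bin means)/Var(series) over power-of-two bin lengths; τ = r/2 at the
  first b where r changes by < 10% from r(b/2), capped at b = T/20 (the
  thresholds are ours; the method follows the standard batch-means
  construction).  An i.i.d. series gives τ = 1/2; AR(1) gives
  (1+ρ)/(2(1−ρ)), used as the calibration standard.  Estimates that hit the
  cap are flagged *not converged* — on purposely unmixable chains (e.g. an
  unrounded walk on a 7-decade box) the reported value is then a lower
  bound, which is exactly how it is used in the ordering experiments.
  Standard error by delete-one-bin jackknife.  τ is reported in Monte Carlo
  steps (thinning multiplied back in).
- **KS tests**: scipy one- and two-sample Kolmogorov–Smirnov at level 5%,
  on chains subsampled with stride ⌈2τ⌉; fewer than 20 effective samples is
  an error, not a silent pass.
- **KLD (bits)**: histogram plug-in of ∫ P log₂(P/Q) with 100 shared bins
  over the union range and a pseudo-count of 1/2 per bin (both
  configurable).  Against an axis-aligned box the flat reference is used
  analytically (`kld_vs_uniform`).  2<sup>−N·KLD</sup> is the probability
  that N samples of Q pass for P.

## Synthetic benchmark conditions

The generators define the study conditions:

- **Hypercubes** [0,1]^D: the homogeneous control; also the basis of the
  mixing-scaling probe (τ_max vs D on D ∈ {4,8,16,32}, log-log slope).
- **Heterogeneous hyper-rectangles**: sides geometrically spaced across
  decades.  The D = 50 experiment uses 1e-2 … 1e5 (seven decades, the span
  reported for genome-scale flux polytopes) with a 2·10⁶-step budget,
  recorded with thinning 10.
- The **schedule-ordering experiment** uses D = 20 with sides 1e-2 … 1e2
  (four decades — the diameter spread of the small-network ellipsoid) and a
  2·10⁶-step budget per schedule, with pilot chains of 5% of the budget.  The narrower
  span is deliberate: at seven decades a PCA pilot of any desk-scale length
  cannot diffuse across the long axes, so PCA-only rounding is
  indistinguishable from no rounding — the ordering "none worse than PCA
  worse than LP/LEM" is then untestable rather than false.  At four decades
  the pilot resolves part of the spectrum and the full ordering is
  measurable.  The comparison asserts the PCA refinement claim on the LEM
  branch (LEM+PCA ≤ LEM); on axis-aligned boxes LP is exact by construction,
  so refining it cannot help there.
- **Random polytopes**: D+1 or more random unit-normal half-spaces at
  offsets in [0.5, 1.5] around the origin, regenerated until bounded —
  fixtures for the HR-vs-rejection oracle equivalence tests.

What the synthetic shapes do *not* emulate: correlated constraint normals,
the combinatorial facet structure of real stoichiometries, or thermodynamic
(non-convex) restrictions.  Passing these benchmarks certifies the sampler
and the rounding machinery, not any biological conclusion about a specific
network.

## Numerical choices and limitations

- LPs: scipy's HiGHS; any correct LP solver is acceptable by design.
- Equality feasibility 1e-9 on ‖S v‖<sub>∞</sub>; membership tolerance 1e-9;
  PCA ridge 1e-10·trace/D when the pilot covariance is singular (logged).
- Boxes and random shapes are sampled directly in their native coordinates
  (anchor 0, identity basis); model-derived polytopes sample in null-space
  coordinates and reconstruct fluxes on export.
- Chains are stored as text at %.17g, which round-trips IEEE doubles
  bitwise; determinism claims are therefore testable on files, not just in
  memory.
- SBML models are read through cobrapy; exchange bounds are taken as given
  in the file — the package never guesses uptake bounds, so genome-scale
  experiments require the user to state them explicitly.
- Volume computation, vertex enumeration, non-convex (loop-law) constraints
  and multi-chain diagnostics are out of scope.
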