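"""Chain-quality diagnostics.

Integrated autocorrelation times are estimated by the binning (batch-means)
method: group the series into bins of length b and track

    r(b) = b * Var(bin means) / Var(series),

which climbs to the plateau 2 * tau_int as b passes the correlation length.
With the convention used here an i.i.d. series has tau = 1/2, and the
variance of the chain mean is Var * 2 tau / T, so tau is directly the number
of Monte Carlo steps per effectively independent sample.

Sampler agreement is quantified by Kolmogorov-Smirnov tests (on
tau-subsampled chains) and by a histogram plug-in estimate of the
Kullback-Leibler divergence in bits; ``2**(-N * KLD)`` is the probability of
mistaking N samples of one distribution for the other.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import InsufficientDataError

#: relative change in r(b) below which the plateau is declared
PLATEAU_REL_CHANGE = 0.1
#: largest bin length, as a fraction of the series length
BIN_CAP_FRACTION = 1.0 / 20.0
#: default histogram bin count for KLD estimates
DEFAULT_BINS = 100
#: default pseudo-count per histogram bin
DEFAULT_PSEUDOCOUNT = 0.5


@dataclass
class TauEstimate:
    """Integrated autocorrelation time with a jackknife standard error."""

    tau: float
    stderr: float
    converged: bool          # False: no plateau before the bin cap
    anticorrelated: bool     # tau below the i.i.d. value 1/2
    bin_length: int

    def __float__(self):
        return self.tau


def integrated_autocorrelation(series, cap_fraction: float = BIN_CAP_FRACTION,
                               rel_change: float = PLATEAU_REL_CHANGE) -> TauEstimate:
    """Binning estimate of the integrated autocorrelation time (in steps).

    Bin lengths run over powers of two; the plateau is the first b at which
    r(b) changes by less than *rel_change* relative to r(b/2), capped at
    ``T * cap_fraction``.  If no plateau appears the cap estimate is returned
    flagged ``converged=False``.  The standard error is a delete-one-bin
    jackknife at the chosen bin length.
    """
    x = np.asarray(series, dtype=float).ravel()
    T = x.size
    if T < 100:
        raise InsufficientDataError(f"need at least 100 points, got {T}")
    var = x.var(ddof=1)
    if var == 0.0:
        raise InsufficientDataError("constant series: tau is undefined")
    cap = max(2, int(T * cap_fraction))

    def r_of(b):
        nb = T // b
        means = x[: nb * b].reshape(nb, b).mean(axis=1)
        return b * means.var(ddof=1) / var, means

    prev_r, _ = r_of(1)
    b = 2
    chosen = None
    while b <= cap:
        r, means = r_of(b)
        if abs(r - prev_r) < rel_change * max(prev_r, 1.0e-12):
            chosen = (b, r, means)
            break
        prev_r = r
        b *= 2
    converged = chosen is not None
    if not converged:
        b //= 2
        r, means = r_of(b)
        chosen = (b, r, means)
    b, r, means = chosen
    nb = means.size
    # delete-one-bin jackknife on r(b)
    if nb > 2:
        s2 = means.var(ddof=1)
        jack = np.empty(nb)
        total = means.sum()
        ssq = ((means - means.mean()) ** 2).sum()
        for k in range(nb):
            mu_k = (total - means[k]) / (nb - 1)
            ss_k = ssq - (means[k] - means.mean()) ** 2 * nb / (nb - 1)
            jack[k] = b * max(ss_k, 0.0) / (nb - 2) / var
        stderr = math.sqrt(max((nb - 1) * jack.var(ddof=0), 0.0)) / 2.0
    else:
        stderr = float("nan")
    tau = r / 2.0
    return TauEstimate(tau=tau, stderr=stderr, converged=converged,
                       anticorrelated=tau < 0.5, bin_length=b)


def max_autocorrelation(chain, cap_fraction: float = BIN_CAP_FRACTION):
    """Per-coordinate tau (in MC steps) of a chain; returns (tau_max, sorted list).

    Thinning is multiplied back in so that times are reported in Monte Carlo
    steps regardless of how the chain was recorded.  Non-converged
    coordinate estimates propagate their flag.

    Returns
    -------
    tau_max : float
    taus_sorted : ndarray
        Increasing per-coordinate times (for ordered-tau curves).
    estimates : list of TauEstimate
    """
    pts = chain.points
    if pts.shape[0] < 100:
        raise InsufficientDataError("chain too short for tau estimation")
    thin = chain.thinning
    estimates = []
    taus = np.empty(pts.shape[1])
    for j in range(pts.shape[1]):
        est = integrated_autocorrelation(pts[:, j], cap_fraction=cap_fraction)
        est = TauEstimate(tau=est.tau * thin, stderr=est.stderr * thin,
                          converged=est.converged,
                          anticorrelated=est.anticorrelated,
                          bin_length=est.bin_length)
        estimates.append(est)
        taus[j] = est.tau
    order = np.argsort(taus)
    return float(taus.max()), taus[order], estimates


def effective_stride(tau_in_recorded_steps: float) -> int:
    """Subsampling stride giving approximately independent samples."""
    return max(1, math.ceil(2.0 * tau_in_recorded_steps))


def ks_uniformity(samples, reference, tau: float | None = None,
                  alpha: float = 0.05, min_effective: int = 20):
    """Kolmogorov-Smirnov test of *samples* against a reference.

    Parameters
    ----------
    samples : 1-D array
    reference : (a, b) tuple for a one-sample test against Uniform(a, b), or
        a second 1-D sample for a two-sample test.
    tau : float, optional
        Autocorrelation time of *samples* in recorded steps; when given the
        series is subsampled with stride ``ceil(2 tau)`` first.

    Returns
    -------
    (statistic, p_value, reject) : reject is the decision at level *alpha*.
    """
    x = np.asarray(samples, dtype=float).ravel()
    if tau is not None:
        x = x[:: effective_stride(tau)]
    if x.size < min_effective:
        raise InsufficientDataError(
            f"only {x.size} effective samples (< {min_effective})"
        )
    if isinstance(reference, tuple) and len(reference) == 2:
        a, b = reference
        stat, p = stats.kstest(x, "uniform", args=(a, b - a))
    else:
        y = np.asarray(reference, dtype=float).ravel()
        stat, p = stats.ks_2samp(x, y)
    return float(stat), float(p), bool(p < alpha)


# ---------------------------------------------------------------------------
# Kullback-Leibler divergence
# ---------------------------------------------------------------------------

def _histogram_probs(x, edges, pseudo):
    counts, _ = np.histogram(x, bins=edges)
    probs = counts + pseudo
    return probs / probs.sum()


def kld_histogram(q_samples, p_samples, bins: int = DEFAULT_BINS,
                  pseudo: float = DEFAULT_PSEUDOCOUNT) -> float:
    """Histogram plug-in estimate of KLD(Q|P) = integral P log2(P/Q), in bits.

    Both samples are binned on a shared grid spanning the union of their
    ranges, with a pseudo-count per bin to regularize empty cells.  Returns
    ``inf`` when the supports do not overlap at all.
    """
    q = np.asarray(q_samples, dtype=float).ravel()
    p = np.asarray(p_samples, dtype=float).ravel()
    if q.size == 0 or p.size == 0:
        raise InsufficientDataError("empty sample set")
    if min(q.max(), p.max()) < max(q.min(), p.min()):
        return float("inf")
    lo = min(q.min(), p.min())
    hi = max(q.max(), p.max())
    if hi == lo:
        return 0.0
    edges = np.linspace(lo, hi, bins + 1)
    Q = _histogram_probs(q, edges, pseudo)
    P = _histogram_probs(p, edges, pseudo)
    return float(np.sum(P * np.log2(P / Q)))


def kld_vs_uniform(q_samples, low: float, high: float,
                   bins: int = DEFAULT_BINS,
                   pseudo: float = DEFAULT_PSEUDOCOUNT) -> float:
    """KLD(Q|P) in bits where P is the exact flat density on [low, high]."""
    q = np.asarray(q_samples, dtype=float).ravel()
    if q.size == 0:
        raise InsufficientDataError("empty sample set")
    edges = np.linspace(low, high, bins + 1)
    counts, _ = np.histogram(np.clip(q, low, high), bins=edges)
    Q = (counts + pseudo) / (counts.sum() + pseudo * bins)
    P = 1.0 / bins
    return float(np.sum(P * np.log2(P / Q)))


def deception_probability(n_samples: int, kld_bits: float) -> float:
    """Probability of mistaking n samples of Q for P: 2**(-n * KLD)."""
    return float(2.0 ** (-n_samples * kld_bits))


# ---------------------------------------------------------------------------
# scaling probe and report
# ---------------------------------------------------------------------------

@dataclass
class ScalingFit:
    """Power-law fit of tau_max against dimension."""

    exponent: float
    ci_low: float
    ci_high: float
    table: pd.DataFrame

    @property
    def degenerate(self) -> bool:
        return not np.isfinite(self.exponent)


def fit_scaling(dims, taus) -> ScalingFit:
    """Least-squares slope of log tau against log D with a 95% CI."""
    dims = np.asarray(dims, dtype=float)
    taus = np.asarray(taus, dtype=float)
    if dims.size < 3:
        raise InsufficientDataError("need at least 3 dimensions for a fit")
    res = stats.linregress(np.log(dims), np.log(taus))
    tcrit = stats.t.ppf(0.975, dims.size - 2)
    half = tcrit * res.stderr if np.isfinite(res.stderr) else float("inf")
    table = pd.DataFrame({"D": dims, "tau_max": taus})
    return ScalingFit(res.slope, res.slope - half, res.slope + half, table)


def mixing_scaling_probe(dims, steps_per_dim: int | None = None, reps: int = 1,
                         seed: int = 0) -> ScalingFit:
    """Empirical tau_max versus dimension on hypercubes (rounded regime).

    The hypercube is its own matching shape (sandwiching ratio O(1) after
    rounding), so plain HR probes the dimension dependence of mixing alone.
    This is a sanity probe of the polynomial scaling of the mixing time, not
    a proof.
    """
    from .benchmarks import make_hypercube
    from .polytope import find_interior_point
    from .samplers import hr_sample

    dims = list(dims)
    if len(dims) < 3:
        raise InsufficientDataError("need at least 3 dimensions for a fit")
    taus = []
    for i, D in enumerate(dims):
        poly = make_hypercube(D)
        per_rep = []
        for r in range(reps):
            n = steps_per_dim * D if steps_per_dim else max(20000, 1200 * D)
            chain = hr_sample(poly, find_interior_point(poly, seed=seed),
                              n=n, seed=seed + 1000 * i + r)
            tau_max, _, _ = max_autocorrelation(chain)
            per_rep.append(tau_max)
        taus.append(float(np.mean(per_rep)))
    return fit_scaling(dims, taus)


@dataclass
class DiagnosticsReport:
    """Summary of chain quality for one sampler run."""

    sampler_id: str
    taus: np.ndarray                 # per-coordinate, MC steps
    tau_max: float
    converged: np.ndarray            # per-coordinate plateau flags
    ks_stats: np.ndarray | None = None
    ks_pvalues: np.ndarray | None = None
    kld_bits: np.ndarray | None = None
    diameters: np.ndarray | None = None

    def to_frame(self) -> pd.DataFrame:
        data = {"tau": self.taus, "converged": self.converged}
        if self.ks_stats is not None:
            data["ks_stat"] = self.ks_stats
            data["ks_pvalue"] = self.ks_pvalues
        if self.kld_bits is not None:
            data["kld_bits"] = self.kld_bits
        return pd.DataFrame(data)

    def summary(self) -> dict:
        out = {
            "sampler_id": self.sampler_id,
            "tau_max": float(self.tau_max),
            "all_converged": bool(np.all(self.converged)),
        }
        if self.kld_bits is not None:
            out["max_kld_bits"] = float(np.max(self.kld_bits))
            out["mean_kld_bits"] = float(np.mean(self.kld_bits))
        if self.ks_pvalues is not None:
            out["min_ks_pvalue"] = float(np.min(self.ks_pvalues))
        return out


def diagnose_chain(chain, marginal_ranges=None, bins: int = DEFAULT_BINS,
                   alpha: float = 0.05) -> DiagnosticsReport:
    """Full report for one chain.

    Parameters
    ----------
    chain : SampleChain
    marginal_ranges : (D, 2) array, optional
        Analytic flat per-coordinate marginals (axis-aligned boxes); enables
        KS tests and KLD-vs-flat per coordinate.
    """
    tau_max, _, ests = max_autocorrelation(chain)
    taus = np.array([e.tau for e in ests])
    converged = np.array([e.converged for e in ests])
    ks_stats = ks_p = kld = None
    if marginal_ranges is not None:
        rng_arr = np.atleast_2d(np.asarray(marginal_ranges, dtype=float))
        D = chain.dim
        ks_stats = np.empty(D)
        ks_p = np.empty(D)
        kld = np.empty(D)
        for j in range(D):
            a, b = rng_arr[j]
            tau_rec = max(taus[j] / chain.thinning, 0.5)
            try:
                s, p, _ = ks_uniformity(chain.points[:, j], (a, b),
                                        tau=tau_rec, alpha=alpha)
            except InsufficientDataError:
                s, p = float("nan"), float("nan")
            ks_stats[j], ks_p[j] = s, p
            kld[j] = kld_vs_uniform(chain.points[:, j], a, b, bins=bins)
    return DiagnosticsReport(chain.sampler_id, taus, tau_max, converged,
                             ks_stats, ks_p, kld)
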