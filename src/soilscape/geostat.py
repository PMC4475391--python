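"""Trans-Gaussian geostatistics for landscape soil properties.

The workflow implemented here is the classical one for mapping a non-Gaussian
soil or microbial variable observed at a few hundred sites:

1. rank-based normal-score transform to standard-normal scores;
2. empirical (method-of-moments) variogram of the scores;
3. maximum-likelihood fit of a Matérn variogram under a multivariate-normal
   model with unknown constant mean;
4. ordinary kriging in score space, back-transformed through the empirical
   quantile function;
5. leave-one-out cross-validation summarised by standardized squared
   prediction errors (SSPE), whose mean and median are compared with the
   chi-square(1 df) reference values 1 and 0.455 using confidence limits
   obtained by simulating the fitted model.

All distances are planar Euclidean in meters.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy import optimize, special, stats
from scipy.linalg import cho_factor, cho_solve, lu_factor, lu_solve
from scipy.spatial import Delaunay
from scipy.spatial.distance import cdist, pdist, squareform

__all__ = [
    "VariogramModel",
    "NormalScoreMap",
    "EmpiricalVariogram",
    "KrigingResult",
    "CrossValidationReport",
    "normal_score_transform",
    "back_transform",
    "empirical_variogram",
    "matern_correlation",
    "matern_semivariance",
    "fit_variogram_ml",
    "effective_range",
    "ordinary_krige",
    "loo_cross_validate",
    "sspe_confidence_limits",
    "krige_map",
    "chi2_median",
]

_FAMILIES = ("matern", "exponential", "gaussian")

# Median of the chi-square distribution with 1 df: reference value for the
# median SSPE under a correctly specified model.
CHI2_1_MEDIAN = float(stats.chi2.median(1))


# ---------------------------------------------------------------------------
# Variogram model
# ---------------------------------------------------------------------------

@dataclass
class VariogramModel:
    """Isotropic variogram model γ(h) = c0 + c1·(1 − ρ(h)) for h > 0, γ(0)=0.

    Parameters
    ----------
    family : str
        One of ``matern``, ``exponential``, ``gaussian``.
    nugget : float
        Nugget variance c0 (micro-scale + measurement variance), ≥ 0.
    psill : float
        Partial sill c1 (spatially structured variance), ≥ 0.
    phi : float
        Distance parameter in meters, > 0.
    nu : float, optional
        Matérn smoothness; required for ``matern``.  ν = 0.5 is the
        exponential model, ν → ∞ approaches the Gaussian model.
    loglik : float, optional
        Maximized Gaussian log-likelihood when the model was fitted by ML.
    """

    family: str
    nugget: float
    psill: float
    phi: float
    nu: float | None = None
    loglik: float | None = None

    def __post_init__(self) -> None:
        if self.family not in _FAMILIES:
            raise ValueError(f"unknown variogram family {self.family!r}")
        if self.nugget < 0 or self.psill < 0:
            raise ValueError("nugget and partial sill must be non-negative")
        if self.phi <= 0:
            raise ValueError("distance parameter phi must be positive")
        if self.family == "matern":
            if self.nu is None or self.nu <= 0:
                raise ValueError("matern family requires smoothness nu > 0")

    @property
    def sill(self) -> float:
        return self.nugget + self.psill

    def correlation(self, h) -> np.ndarray:
        """Correlation ρ(h) of the spatially structured component."""
        h = np.asarray(h, dtype=float)
        if self.family == "exponential":
            return np.exp(-h / self.phi)
        if self.family == "gaussian":
            return np.exp(-((h / self.phi) ** 2))
        return matern_correlation(h, self.phi, self.nu)

    def semivariance(self, h) -> np.ndarray:
        """γ(h); exactly 0 at h = 0 (the nugget is a discontinuity)."""
        h = np.asarray(h, dtype=float)
        g = self.nugget + self.psill * (1.0 - self.correlation(h))
        return np.where(h > 0, g, 0.0)

    def covariance_matrix(self, sites: np.ndarray) -> np.ndarray:
        """Covariance of observations at `sites` (nugget on the diagonal)."""
        sites = np.asarray(sites, dtype=float)
        D = squareform(pdist(sites))
        K = self.psill * self.correlation(D)
        K[np.diag_indices_from(K)] = self.psill + self.nugget
        return K

    def to_dict(self) -> dict:
        return asdict(self)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def from_dict(cls, d: dict) -> "VariogramModel":
        return cls(**d)

    @classmethod
    def from_json(cls, path) -> "VariogramModel":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def matern_correlation(h, phi: float, nu: float) -> np.ndarray:
    """Matérn correlation ρ(h) = [1/(2^(ν−1)Γ(ν))]·(h/φ)^ν·K_ν(h/φ), ρ(0)=1."""
    h = np.asarray(h, dtype=float)
    u = h / phi
    # closed forms for half-integer smoothness (much faster than kv)
    if nu == 0.5:
        return np.exp(-u)
    if nu == 1.5:
        return (1.0 + u) * np.exp(-u)
    if nu == 2.5:
        return (1.0 + u + u ** 2 / 3.0) * np.exp(-u)
    out = np.ones_like(u)
    pos = u > 0
    up = u[pos]
    r = (2.0 ** (1.0 - nu) / special.gamma(nu)) * (up ** nu) * special.kv(nu, up)
    # K_nu underflows to 0 for large arguments, which is the correct limit.
    out[pos] = np.nan_to_num(r, nan=0.0, posinf=0.0, neginf=0.0)
    return np.clip(out, 0.0, 1.0)


def matern_semivariance(h, model: VariogramModel) -> np.ndarray:
    """Model semivariance γ(h); thin wrapper kept for a functional interface."""
    return model.semivariance(h)


def effective_range(model: VariogramModel, frac: float = 0.95) -> float:
    """Practical range: smallest h with γ(h) − c0 ≥ frac·c1.

    The Matérn model approaches its sill only asymptotically, so the
    conventional 95 %-of-sill distance is used.  Undefined (NaN) for a pure
    nugget model.
    """
    if model.psill <= 0:
        return float("nan")
    target = 1.0 - frac  # solve rho(h) = 1 - frac
    if model.family == "exponential":
        return -model.phi * math.log(target)
    if model.family == "gaussian":
        return model.phi * math.sqrt(-math.log(target))
    lo, hi = 1e-9 * model.phi, model.phi
    while model.correlation(hi) > target:
        hi *= 2.0
        if hi > 1e9 * model.phi:  # pragma: no cover - defensive
            raise RuntimeError("effective range bracketing failed")
    return float(optimize.brentq(lambda h: model.correlation(h) - target, lo, hi))


# ---------------------------------------------------------------------------
# Normal-score transform
# ---------------------------------------------------------------------------

@dataclass
class NormalScoreMap:
    """Monotone empirical map between data values and standard-normal scores.

    Stores the sorted (value, score) pairs of the fitting sample; the back
    transform interpolates linearly between them and clamps scores beyond the
    observed range to the observed minimum/maximum value.
    """

    values: np.ndarray  # sorted ascending
    scores: np.ndarray  # scores of the sorted values (non-decreasing)

    @property
    def n(self) -> int:
        return len(self.values)


def normal_score_transform(values) -> tuple[NormalScoreMap, np.ndarray]:
    """Rank-order (normal-score) transform.

    score_i = Φ⁻¹((r_i − 0.5)/n) with r_i the rank of value i; tied values
    share the mean of their tied ranks, hence the same score.
    """
    values = np.asarray(values, dtype=float)
    if values.ndim != 1 or len(values) < 3:
        raise ValueError("need a 1-D sample with n >= 3")
    if not np.all(np.isfinite(values)):
        raise ValueError("values must be finite")
    if np.ptp(values) == 0:
        raise ValueError("degenerate field: all values identical")
    ranks = stats.rankdata(values, method="average")
    scores = stats.norm.ppf((ranks - 0.5) / len(values))
    order = np.argsort(values, kind="stable")
    nsmap = NormalScoreMap(values=values[order], scores=scores[order])
    return nsmap, scores


def back_transform(nsmap: NormalScoreMap, scores) -> np.ndarray:
    """Map scores back to the original scale.

    Linear interpolation of the empirical quantile function; scores outside
    the observed score range clamp to the observed extremes (a rank transform
    carries no information beyond them).
    """
    scores = np.asarray(scores, dtype=float)
    return np.interp(scores, nsmap.scores, nsmap.values)


# ---------------------------------------------------------------------------
# Empirical variogram
# ---------------------------------------------------------------------------

@dataclass
class EmpiricalVariogram:
    """Method-of-moments variogram: γ̂(h) = Σ (z_i−z_j)² / (2 N(h)) per bin."""

    bin_centers: np.ndarray
    gamma: np.ndarray        # NaN where a bin holds no pair
    counts: np.ndarray
    bin_edges: np.ndarray

    @property
    def max_lag(self) -> float:
        return float(self.bin_edges[-1])


def empirical_variogram(sites, values, max_lag: float | None = None,
                        n_bins: int = 15) -> EmpiricalVariogram:
    sites = np.asarray(sites, dtype=float)
    values = np.asarray(values, dtype=float)
    d = pdist(sites)
    if max_lag is None:
        max_lag = 0.5 * d.max()
    dz2 = pdist(values[:, None], metric="sqeuclidean")
    edges = np.linspace(0.0, max_lag, n_bins + 1)
    idx = np.digitize(d, edges) - 1
    keep = (idx >= 0) & (idx < n_bins)
    counts = np.bincount(idx[keep], minlength=n_bins)
    sums = np.bincount(idx[keep], weights=dz2[keep], minlength=n_bins)
    with np.errstate(invalid="ignore", divide="ignore"):
        gamma = sums / (2.0 * counts)
    gamma[counts == 0] = np.nan
    centers = 0.5 * (edges[:-1] + edges[1:])
    return EmpiricalVariogram(centers, gamma, counts, edges)


# ---------------------------------------------------------------------------
# Maximum-likelihood Matérn fit
# ---------------------------------------------------------------------------

DEFAULT_NU_GRID = (0.25, 0.5, 1.0, 1.5, 2.0, 3.0)


class VariogramFitError(RuntimeError):
    """Raised when no optimizer start converges; carries diagnostics."""


def _profile_negloglik(x: np.ndarray, D: np.ndarray, z: np.ndarray,
                       family: str, nu: float | None) -> float:
    """Negative profile log-likelihood over (log δ, log φ), δ = c0/c1.

    The constant mean μ is profiled by generalized least squares and the
    partial sill c1 analytically, leaving a 2-D search per smoothness value.
    """
    log_delta, log_phi = x
    if abs(log_delta) > 25 or not np.isfinite(log_phi):
        return 1e12
    delta = math.exp(log_delta)
    phi = math.exp(log_phi)
    n = len(z)
    tmp = VariogramModel(family, 0.0, 1.0, phi, nu if family == "matern" else None)
    V = tmp.correlation(D)
    V[np.diag_indices_from(V)] = 1.0 + delta
    try:
        cf = cho_factor(V, lower=True, check_finite=False)
    except np.linalg.LinAlgError:
        return 1e12
    ones = np.ones(n)
    Vi_z = cho_solve(cf, z, check_finite=False)
    Vi_1 = cho_solve(cf, ones, check_finite=False)
    mu = float(ones @ Vi_z) / float(ones @ Vi_1)
    r = z - mu
    quad = float(r @ cho_solve(cf, r, check_finite=False))
    if quad <= 0:
        return 1e12
    c1_hat = quad / n
    logdet = 2.0 * np.sum(np.log(np.diag(cf[0])))
    nll = 0.5 * (n * math.log(2.0 * math.pi * c1_hat) + logdet + n)
    return nll


def _fit_fixed_nu(D: np.ndarray, z: np.ndarray, family: str,
                  nu: float | None, starts) -> tuple[float, float, float, float, float]:
    """Return (nugget, psill, phi, mu-free loglik, nll) for the best start."""
    best = None
    for x0 in starts:
        res = optimize.minimize(_profile_negloglik, x0, args=(D, z, family, nu),
                                method="Nelder-Mead",
                                options={"xatol": 1e-4, "fatol": 1e-6,
                                         "maxiter": 400})
        if best is None or res.fun < best.fun:
            best = res
    if best is None or not np.isfinite(best.fun) or best.fun >= 1e12:
        raise VariogramFitError(
            f"ML variogram fit failed for family={family} nu={nu}: "
            f"no start converged (best objective {None if best is None else best.fun})")
    log_delta, log_phi = best.x
    delta, phi = math.exp(log_delta), math.exp(log_phi)
    # recover profiled c1
    n = len(z)
    tmp = VariogramModel(family, 0.0, 1.0, phi, nu if family == "matern" else None)
    V = tmp.correlation(D)
    V[np.diag_indices_from(V)] = 1.0 + delta
    cf = cho_factor(V, lower=True, check_finite=False)
    ones = np.ones(n)
    mu = float(ones @ cho_solve(cf, z, check_finite=False)) / \
        float(ones @ cho_solve(cf, ones, check_finite=False))
    r = z - mu
    c1 = float(r @ cho_solve(cf, r, check_finite=False)) / n
    c0 = delta * c1
    return c0, c1, phi, -best.fun, best.fun


def fit_variogram_ml(sites, scores, family: str = "matern",
                     fix_nu: float | None = None,
                     nu_grid=DEFAULT_NU_GRID,
                     starts=None) -> VariogramModel:
    """Fit a variogram by Gaussian maximum likelihood.

    Maximizes ℓ = −½[n ln 2π + ln|Σ| + (z−μ1)ᵀΣ⁻¹(z−μ1)] with
    Σ = c1·R(φ,ν) + c0·I; the mean μ and partial sill c1 are profiled out
    analytically and (c0/c1, φ) are optimized in log space from several
    starting points.  For the Matérn family the smoothness ν is, unless fixed,
    optimized over a small grid because the joint likelihood in ν is
    notoriously flat.
    """
    sites = np.asarray(sites, dtype=float)
    z = np.asarray(scores, dtype=float)
    if family not in _FAMILIES:
        raise ValueError(f"unknown family {family!r}")
    D = squareform(pdist(sites))
    if starts is None:
        dmax = D.max()
        starts = [(math.log(d), math.log(p))
                  for d in (0.05, 0.5)
                  for p in (dmax / 30.0, dmax / 8.0, dmax / 3.0)]
    if family == "matern":
        nus = [fix_nu] if fix_nu is not None else list(nu_grid)
    else:
        nus = [None]
    best = None
    errors = []
    for nu in nus:
        try:
            c0, c1, phi, ll, _ = _fit_fixed_nu(D, z, family, nu, starts)
        except VariogramFitError as exc:
            errors.append(str(exc))
            continue
        if best is None or ll > best[3]:
            best = (c0, c1, phi, ll, nu)
    if best is None:
        raise VariogramFitError("; ".join(errors))
    c0, c1, phi, ll, nu = best
    return VariogramModel(family=family, nugget=c0, psill=c1, phi=phi,
                          nu=nu, loglik=ll)


# ---------------------------------------------------------------------------
# Ordinary kriging
# ---------------------------------------------------------------------------

@dataclass
class KrigingResult:
    """Ordinary-kriging predictions at target locations."""

    targets: np.ndarray
    estimate: np.ndarray          # score (transformed) space
    variance: np.ndarray          # kriging variance in score space
    model: VariogramModel
    back_estimate: np.ndarray | None = None  # original scale, if a map was given
    weights: np.ndarray | None = None        # (n_targets, n_sites), optional


def _check_distinct(sites: np.ndarray, tol: float = 1e-9) -> None:
    D = squareform(pdist(sites))
    np.fill_diagonal(D, np.inf)
    i, j = np.unravel_index(np.argmin(D), D.shape)
    if D[i, j] <= tol:
        raise np.linalg.LinAlgError(
            f"duplicate sites {i} and {j} (distance {D[i, j]:g}) make the "
            "kriging system singular")


def ordinary_krige(sites, scores, model: VariogramModel, targets,
                   nsmap: NormalScoreMap | None = None,
                   return_weights: bool = False) -> KrigingResult:
    """Ordinary kriging in semivariance form.

    Solves per target the system [Γ 1; 1ᵀ 0]·[λ; m] = [γ₀; 1] with
    Γ_ij = γ(h_ij), γ₀_i = γ(h_i0); estimate ẑ₀ = λᵀz and variance
    σ₀² = λᵀγ₀ + m.  Weights sum to one by construction.
    """
    sites = np.asarray(sites, dtype=float)
    z = np.asarray(scores, dtype=float)
    targets = np.atleast_2d(np.asarray(targets, dtype=float))
    n = len(sites)
    _check_distinct(sites)
    if n == 1:
        est = np.full(len(targets), z[0])
        var = np.full(len(targets), 0.0)
        w = np.ones((len(targets), 1))
    else:
        G = model.semivariance(squareform(pdist(sites)))
        A = np.zeros((n + 1, n + 1))
        A[:n, :n] = G
        A[:n, n] = 1.0
        A[n, :n] = 1.0
        lu = lu_factor(A)
        g0 = model.semivariance(cdist(targets, sites))  # (m, n)
        B = np.concatenate([g0, np.ones((len(targets), 1))], axis=1)
        sol = lu_solve(lu, B.T).T        # (m, n+1)
        w = sol[:, :n]
        m_lag = sol[:, n]
        est = w @ z
        var = np.einsum("ij,ij->i", w, g0) + m_lag
        var = np.maximum(var, 0.0)
    back = back_transform(nsmap, est) if nsmap is not None else None
    return KrigingResult(targets=targets, estimate=est, variance=var,
                         model=model, back_estimate=back,
                         weights=w if return_weights else None)


# ---------------------------------------------------------------------------
# Leave-one-out cross-validation and the SSPE diagnostic
# ---------------------------------------------------------------------------

@dataclass
class CrossValidationReport:
    """SSPE summary of a leave-one-out cross-validation.

    θ_i = (z_i − ẑ_{−i})² / σ̂²_{−i}; under a correctly specified Gaussian
    model θ ~ χ²(1 df), so mean(θ) ≈ 1 and median(θ) ≈ 0.455.
    """

    theta: np.ndarray
    mean: float
    median: float
    mean_limits: tuple[float, float] | None = None
    median_limits: tuple[float, float] | None = None

    @property
    def verdict(self) -> bool | None:
        """True iff both mean and median fall inside their simulated limits."""
        if self.mean_limits is None or self.median_limits is None:
            return None
        return bool(self.mean_limits[0] <= self.mean <= self.mean_limits[1]
                    and self.median_limits[0] <= self.median
                    <= self.median_limits[1])

    def to_dict(self) -> dict:
        return {
            "theta": self.theta.tolist(),
            "mean": self.mean,
            "median": self.median,
            "mean_limits": list(self.mean_limits) if self.mean_limits else None,
            "median_limits": list(self.median_limits) if self.median_limits else None,
            "verdict": self.verdict,
        }


def _bordered_inverse(sites: np.ndarray, model: VariogramModel) -> np.ndarray:
    """Inverse of the covariance-form OK matrix [[K, 1], [1ᵀ, 0]].

    Its leading n×n block B yields the classical fast leave-one-out
    identities e_i = (B z)_i / B_ii and σ²_{−i} = 1/B_ii.
    """
    n = len(sites)
    K = model.covariance_matrix(sites)
    A = np.zeros((n + 1, n + 1))
    A[:n, :n] = K
    A[:n, n] = 1.0
    A[n, :n] = 1.0
    return np.linalg.inv(A)


def loo_cross_validate(sites, scores, model: VariogramModel) -> CrossValidationReport:
    """Leave-one-out cross-validation with the model held fixed (no refit).

    Each site is predicted by ordinary kriging from all the others; the fixed
    global model is what makes θ_i ~ χ²(1) under a correct model, which is
    the point of the diagnostic.
    """
    sites = np.asarray(sites, dtype=float)
    z = np.asarray(scores, dtype=float)
    if len(sites) < 10:
        raise ValueError("leave-one-out SSPE needs n >= 10 sites")
    _check_distinct(sites)
    n = len(sites)
    Q = _bordered_inverse(sites, model)
    B = Q[:n, :n]
    d = np.diag(B)
    if np.any(d <= 0):
        raise np.linalg.LinAlgError("non-positive LOO kriging variance; "
                                    "check for duplicate sites or an invalid model")
    e = (B @ z) / d
    theta = e ** 2 * d  # e^2 / (1/d)
    return CrossValidationReport(theta=theta, mean=float(theta.mean()),
                                 median=float(np.median(theta)))


def loo_cross_validate_naive(sites, scores, model: VariogramModel) -> CrossValidationReport:
    """Reference LOO implementation: one semivariance-form solve per fold.

    O(n⁴); used to validate the fast bordered-inverse route on small inputs.
    """
    sites = np.asarray(sites, dtype=float)
    z = np.asarray(scores, dtype=float)
    n = len(sites)
    theta = np.empty(n)
    for i in range(n):
        mask = np.arange(n) != i
        res = ordinary_krige(sites[mask], z[mask], model, sites[i:i + 1])
        if res.variance[0] <= 0:
            raise np.linalg.LinAlgError(f"zero kriging variance at fold {i}")
        theta[i] = (z[i] - res.estimate[0]) ** 2 / res.variance[0]
    return CrossValidationReport(theta=theta, mean=float(theta.mean()),
                                 median=float(np.median(theta)))


def sspe_confidence_limits(sites, model: VariogramModel, n_sim: int = 1000,
                           seed: int | None = None,
                           alpha: float = 0.05) -> dict:
    """95 % confidence limits for mean and median SSPE under the fitted model.

    Simulates `n_sim` Gaussian realizations of the model at the data sites,
    runs the leave-one-out SSPE on each, and returns the α/2 and 1−α/2
    percentiles of the simulated mean(θ) and median(θ) distributions.
    """
    sites = np.asarray(sites, dtype=float)
    n = len(sites)
    rng = np.random.default_rng(seed)
    K = model.covariance_matrix(sites)
    L = np.linalg.cholesky(K + 1e-10 * np.trace(K) / n * np.eye(n))
    Z = L @ rng.standard_normal((n, n_sim))
    Q = _bordered_inverse(sites, model)
    B = Q[:n, :n]
    d = np.diag(B)[:, None]
    E = (B @ Z) / d
    theta = E ** 2 * d
    means = theta.mean(axis=0)
    medians = np.median(theta, axis=0)
    lo, hi = 100 * alpha / 2.0, 100 * (1 - alpha / 2.0)
    return {
        "mean_limits": tuple(np.percentile(means, [lo, hi])),
        "median_limits": tuple(np.percentile(medians, [lo, hi])),
        "sim_means": means,
        "sim_medians": medians,
    }


def chi2_median(df: int = 1) -> float:
    """Median of the χ²(df) distribution by root-finding on its CDF."""
    return float(optimize.brentq(lambda x: stats.chi2.cdf(x, df) - 0.5,
                                 1e-12, 100.0, xtol=1e-12))


# ---------------------------------------------------------------------------
# Mapping
# ---------------------------------------------------------------------------

def krige_map(sites, values, model: VariogramModel, resolution: float,
              buffer: float = 0.0, nsmap: NormalScoreMap | None = None,
              scores=None):
    """Krige a variable onto a regular grid over the convex hull of the sites.

    If `scores` is not given the values are normal-score transformed here and
    predictions are back-transformed to the original scale.  Returns a pandas
    DataFrame with columns x, y, estimate (original scale), score_estimate,
    score_variance, restricted to grid nodes inside the (buffered) hull.
    """
    import pandas as pd

    sites = np.asarray(sites, dtype=float)
    constant = None
    if scores is None:
        vals = np.asarray(values, dtype=float)
        if np.ptp(vals) == 0:  # constant field: kriging is the identity
            constant = float(vals[0])
            scores = np.zeros(len(vals))
        else:
            nsmap, scores = normal_score_transform(vals)
    xmin, ymin = sites.min(axis=0) - buffer
    xmax, ymax = sites.max(axis=0) + buffer
    xs = np.arange(xmin, xmax + resolution, resolution)
    ys = np.arange(ymin, ymax + resolution, resolution)
    gx, gy = np.meshgrid(xs, ys)
    pts = np.column_stack([gx.ravel(), gy.ravel()])
    hull = Delaunay(sites)
    inside = hull.find_simplex(pts) >= 0
    if buffer > 0:
        # include near-hull points within the buffer of any site
        near = cdist(pts[~inside], sites).min(axis=1) <= buffer
        idx = np.flatnonzero(~inside)
        inside[idx[near]] = True
    pts = pts[inside]
    res = ordinary_krige(sites, scores, model, pts, nsmap=nsmap)
    est = res.back_estimate if res.back_estimate is not None else res.estimate
    if constant is not None:
        est = np.full(len(pts), constant)
    return pd.DataFrame({
        "x": pts[:, 0],
        "y": pts[:, 1],
        "estimate": est,
        "score_estimate": res.estimate,
        "score_variance": res.variance,
    })
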