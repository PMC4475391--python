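"""PCNM spatial descriptors (Principal Coordinates of Neighbour Matrices).

PCNM eigenvectors are orthogonal spatial patterns derived from the sampling
coordinates alone.  They serve as spatial predictors spanning the coarse to
fine scales the sampling design can perceive: the distance matrix is
truncated at the longest minimum-spanning-tree edge (so the site graph stays
connected), distances beyond the threshold are set to four times it, and a
principal-coordinates analysis of the modified matrix yields the
eigenvectors.  Vectors are screened by a one-sided Moran's I permutation
test, and the characteristic scale of each retained vector is read off a
Gaussian variogram fitted to it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize
from scipy.sparse.csgraph import minimum_spanning_tree
from scipy.spatial.distance import pdist, squareform

from .geostat import EmpiricalVariogram, empirical_variogram

__all__ = [
    "PCNMBasis",
    "pcnm_basis",
    "morans_i",
    "screen_basis",
    "classify_scale",
    "DEFAULT_SCALE_BREAKS",
]

# Scale bands (meters): fine <= 630 < medium <= 800 < coarse
DEFAULT_SCALE_BREAKS = (630.0, 800.0)


@dataclass
class PCNMBasis:
    """PCNM eigenvectors with their spatial diagnostics.

    vectors : (n_sites, k) array, columns centered and unit-norm, ordered by
        decreasing eigenvalue (column 0 = broadest scale).
    eigenvalues : positive eigenvalues of the Gower-centered matrix.
    truncation : threshold distance t (longest MST edge), meters.
    moran_i, moran_p : per-vector Moran's I and permutation p-value
        (filled by :func:`screen_basis`).
    eff_range, scale_class : per-vector Gaussian-variogram effective range
        (meters) and scale label (filled by :func:`classify_scale`).
    """

    vectors: np.ndarray
    eigenvalues: np.ndarray
    truncation: float
    names: list = field(default_factory=list)
    moran_i: np.ndarray | None = None
    moran_p: np.ndarray | None = None
    eff_range: np.ndarray | None = None
    scale_class: list | None = None

    def __post_init__(self) -> None:
        if not self.names:
            self.names = [f"PCNM{i + 1}" for i in range(self.vectors.shape[1])]

    @property
    def k(self) -> int:
        return self.vectors.shape[1]


def _check_distinct(sites: np.ndarray) -> None:
    D = squareform(pdist(sites))
    np.fill_diagonal(D, np.inf)
    i, j = np.unravel_index(np.argmin(D), D.shape)
    if D[i, j] <= 1e-9:
        raise ValueError(f"duplicate sites {i} and {j}")


def truncation_distance(sites) -> float:
    """Longest edge of the minimum spanning tree of the Euclidean site graph."""
    D = squareform(pdist(np.asarray(sites, dtype=float)))
    mst = minimum_spanning_tree(D)
    return float(mst.data.max())


def pcnm_basis(sites, truncation: float | None = None) -> PCNMBasis:
    """Unscreened PCNM basis of a set of site coordinates.

    Distances above the truncation t are replaced by 4t, the squared modified
    distances are Gower-centered (B = −½·J·D*²·J) and eigendecomposed;
    eigenvectors with positive eigenvalue are returned in decreasing
    eigenvalue order, centered and unit-norm.  Signs follow the convention
    that each column's largest-magnitude entry is positive.
    """
    sites = np.asarray(sites, dtype=float)
    n = len(sites)
    if n < 4:
        raise ValueError("PCNM needs at least 4 sites")
    _check_distinct(sites)
    D = squareform(pdist(sites))
    t = truncation_distance(sites) if truncation is None else float(truncation)
    Dstar = np.where(D <= t, D, 4.0 * t)
    np.fill_diagonal(Dstar, 0.0)
    A = -0.5 * Dstar ** 2
    J = np.eye(n) - np.ones((n, n)) / n
    B = J @ A @ J
    B = 0.5 * (B + B.T)
    vals, vecs = np.linalg.eigh(B)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    tol = 1e-8 * max(abs(vals[0]), 1.0)
    keep = vals > tol
    vals, vecs = vals[keep], vecs[:, keep]
    # deterministic sign: largest-magnitude component positive
    for j in range(vecs.shape[1]):
        i = np.argmax(np.abs(vecs[:, j]))
        if vecs[i, j] < 0:
            vecs[:, j] = -vecs[:, j]
    return PCNMBasis(vectors=vecs, eigenvalues=vals, truncation=t)


def morans_i(x, sites, truncation: float | None = None,
             weights: np.ndarray | None = None, n_perm: int = 999,
             seed: int | None = None) -> tuple[float, float]:
    """Moran's I with binary truncated-distance weights and a permutation test.

    I = (n/W)·Σ_ij w_ij (x_i−x̄)(x_j−x̄) / Σ_i (x_i−x̄)², with w_ij = 1 when
    d_ij ≤ t (zero diagonal).  The p-value is one-sided for positive spatial
    autocorrelation, from `n_perm` random permutations of the values:
    p = (1 + #{I_perm ≥ I_obs}) / (n_perm + 1).
    """
    x = np.asarray(x, dtype=float)
    sites = np.asarray(sites, dtype=float)
    n = len(x)
    if len(sites) != n:
        raise ValueError("vector length must match number of sites")
    if weights is None:
        D = squareform(pdist(sites))
        t = truncation_distance(sites) if truncation is None else float(truncation)
        weights = (D <= t).astype(float)
        np.fill_diagonal(weights, 0.0)
    W = weights.sum()
    xc = x - x.mean()
    denom = float(xc @ xc)
    if denom == 0:
        raise ValueError("zero-variance vector: Moran's I undefined")

    def stat(v: np.ndarray) -> float:
        return float(n / W * (v @ weights @ v) / (v @ v))

    i_obs = stat(xc)
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_perm):
        v = rng.permutation(xc)
        if stat(v) >= i_obs:
            exceed += 1
    p = (1.0 + exceed) / (n_perm + 1.0)
    return i_obs, p


def screen_basis(basis: PCNMBasis, sites, alpha: float = 0.001,
                 n_perm: int = 999, seed: int | None = None) -> PCNMBasis:
    """Retain eigenvectors with significant positive spatial autocorrelation.

    Keeps vectors with I above the permutation-null expectation −1/(n−1) and
    one-sided p ≤ `alpha` (0.001 by default; with 999 permutations the
    smallest attainable p is exactly (1+0)/(999+1) = 0.001, so the threshold
    is inclusive).  Moran weights reuse the basis's truncated connectivity.
    """
    sites = np.asarray(sites, dtype=float)
    n = len(sites)
    D = squareform(pdist(sites))
    w = (D <= basis.truncation).astype(float)
    np.fill_diagonal(w, 0.0)
    rng = np.random.default_rng(seed)
    e_null = -1.0 / (n - 1)
    ivals, pvals, keep = [], [], []
    for j in range(basis.k):
        i_j, p_j = morans_i(basis.vectors[:, j], sites, weights=w,
                            n_perm=n_perm,
                            seed=int(rng.integers(0, 2 ** 31 - 1)))
        ivals.append(i_j)
        pvals.append(p_j)
        keep.append(i_j > e_null and p_j <= alpha)
    keep = np.asarray(keep)
    return PCNMBasis(
        vectors=basis.vectors[:, keep],
        eigenvalues=basis.eigenvalues[keep],
        truncation=basis.truncation,
        names=[nm for nm, k in zip(basis.names, keep) if k],
        moran_i=np.asarray(ivals)[keep],
        moran_p=np.asarray(pvals)[keep],
    )


def _gaussian_variogram_range(emp: EmpiricalVariogram) -> float:
    """WLS fit of γ = c0 + c1(1 − exp(−(h/φ)²)); returns the 95 % range φ√ln20.

    Eigenvector variograms oscillate beyond their first maximum (hole
    effect), so only the rising limb up to the first local maximum is fitted
    — the part that carries the pattern's characteristic scale.
    """
    ok = (emp.counts > 0) & np.isfinite(emp.gamma)
    h, g, w = emp.bin_centers[ok], emp.gamma[ok], emp.counts[ok].astype(float)
    if len(h) < 3 or g.max() <= 0:
        raise RuntimeError("too few variogram bins for a Gaussian fit")
    # truncate to the rising limb (keep at least 3 bins)
    cut = len(g)
    for i in range(1, len(g) - 1):
        if g[i + 1] < 0.95 * g[i] and g[i] >= 0.5 * g.max():
            cut = i + 1
            break
    cut = max(cut, 3)
    h, g, w = h[:cut], g[:cut], w[:cut]
    sill0 = float(g[-3:].mean()) if len(g) >= 3 else float(g.mean())
    x0 = np.array([1e-3 * sill0 + 1e-12, max(sill0, 1e-12), h.max() / 3.0])

    def resid(p):
        c0, c1, phi = p
        return np.sqrt(w) * (c0 + c1 * (1 - np.exp(-((h / phi) ** 2))) - g)

    res = optimize.least_squares(
        resid, x0, bounds=([0, 0, 1e-6], [np.inf, np.inf, 100 * h.max()]),
        max_nfev=2000)
    if not res.success or res.x[1] <= 0:
        raise RuntimeError("Gaussian variogram fit did not converge")
    phi = res.x[2]
    return float(phi * np.sqrt(np.log(20.0)))


def classify_scale(basis: PCNMBasis, sites,
                   breaks: tuple[float, float] = DEFAULT_SCALE_BREAKS,
                   max_lag: float | None = None,
                   n_bins: int = 15) -> PCNMBasis:
    """Attach a spatial-scale label to every eigenvector.

    Fits a Gaussian-family variogram to each vector by weighted least squares
    (weights = pair counts) on its empirical variogram and takes the
    95 %-of-sill effective range; vectors are labelled ``fine`` (range ≤
    breaks[0]), ``medium`` (≤ breaks[1]) or ``coarse``, and ``unresolved`` if
    the fit fails.
    """
    sites = np.asarray(sites, dtype=float)
    fine_max, medium_max = breaks
    if not fine_max < medium_max:
        raise ValueError("breaks must be (fine_max, medium_max) increasing")
    ranges, classes = [], []
    for j in range(basis.k):
        emp = empirical_variogram(sites, basis.vectors[:, j],
                                  max_lag=max_lag, n_bins=n_bins)
        try:
            r = _gaussian_variogram_range(emp)
        except RuntimeError:
            ranges.append(float("nan"))
            classes.append("unresolved")
            continue
        ranges.append(r)
        classes.append("fine" if r <= fine_max
                       else "medium" if r <= medium_max else "coarse")
    basis.eff_range = np.asarray(ranges)
    basis.scale_class = classes
    return basis


def scale_label(eff_range: float,
                breaks: tuple[float, float] = DEFAULT_SCALE_BREAKS) -> str:
    """Label an effective range (m) as fine / medium / coarse."""
    if not np.isfinite(eff_range):
        return "unresolved"
    if eff_range <= breaks[0]:
        return "fine"
    return "medium" if eff_range <= breaks[1] else "coarse"
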