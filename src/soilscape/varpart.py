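"""Variance partitioning of microbial responses into soil, management and space.

The responses (microbial biomass, OTU richness, evenness, Shannon index) are
univariate, so redundancy analysis reduces exactly to multiple linear
regression and the adjusted R² (Ezekiel) measures each predictor set's
explained variance on a comparable scale.  Explanatory sets are

* soil — standardized physicochemical variables,
* management — indicator-coded land-management clusters obtained by a factor
  analysis for mixed data (FAMD) followed by Ward clustering,
* space — PCNM eigenvectors selected on the residuals of the environmental
  model.

Unique (marginal) and shared fractions come from inclusion–exclusion over the
adjusted R² of the seven non-empty unions of the three sets; significance of
each unique fraction is assessed by permuting residuals of the reduced model.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage

__all__ = [
    "FAMDResult",
    "ManagementClustering",
    "VarPartResult",
    "standardize",
    "famd",
    "cluster_management",
    "indicator_matrix",
    "adjusted_r2",
    "forward_select",
    "select_spatial_from_residuals",
    "variance_partition",
    "permute_marginal",
]


def standardize(X: pd.DataFrame, ddof: int = 1) -> pd.DataFrame:
    """Center to mean 0 and scale to sd 1 (sample sd by default)."""
    X = pd.DataFrame(X).astype(float)
    sd = X.std(ddof=ddof)
    if (sd == 0).any():
        bad = sd.index[sd == 0].tolist()
        raise ValueError(f"constant columns cannot be standardized: {bad}")
    return (X - X.mean()) / sd


# ---------------------------------------------------------------------------
# Factor analysis for mixed data + management clustering
# ---------------------------------------------------------------------------

@dataclass
class FAMDResult:
    scores: pd.DataFrame        # sites x components (U * S)
    loadings: pd.DataFrame      # processed columns x components (V)
    singular_values: np.ndarray
    explained_variance: np.ndarray  # s^2 / (n - 1)
    columns: list


def famd(quantitative: pd.DataFrame | None,
         categorical: pd.DataFrame | None,
         n_components: int | None = None) -> FAMDResult:
    """Factor analysis for mixed data.

    Quantitative columns are standardized (population sd); each categorical
    level is indicator-coded, scaled by 1/√(level proportion) and centered.
    The combined matrix is decomposed by SVD; scores are U·S, so with purely
    quantitative input the result coincides (up to sign) with standardized
    PCA scores.  Levels with zero occurrences are dropped with a warning.
    """
    import warnings

    blocks, names = [], []
    index = None
    if quantitative is not None and len(quantitative.columns):
        q = pd.DataFrame(quantitative).astype(float)
        index = q.index
        sd = q.std(ddof=0)
        if (sd == 0).any():
            raise ValueError("constant quantitative column in FAMD input")
        blocks.append(((q - q.mean()) / sd).to_numpy())
        names.extend(q.columns.tolist())
    if categorical is not None and len(pd.DataFrame(categorical).columns):
        c = pd.DataFrame(categorical)
        index = c.index if index is None else index
        n = len(c)
        for col in c.columns:
            dummies = pd.get_dummies(c[col].astype("category"))
            empty = dummies.columns[dummies.sum(axis=0) == 0].tolist()
            if empty:
                warnings.warn(f"dropping empty levels {empty} of {col!r}")
                dummies = dummies.drop(columns=empty)
            props = dummies.mean(axis=0).to_numpy()
            Z = dummies.to_numpy(dtype=float) / np.sqrt(props)
            Z = Z - Z.mean(axis=0)
            blocks.append(Z)
            names.extend(f"{col}={lev}" for lev in dummies.columns)
    if not blocks:
        raise ValueError("FAMD needs at least one input column")
    X = np.concatenate(blocks, axis=1)
    n = X.shape[0]
    U, s, Vt = np.linalg.svd(X, full_matrices=False)
    if n_components is not None:
        U, s, Vt = U[:, :n_components], s[:n_components], Vt[:n_components]
    comp = [f"F{i + 1}" for i in range(len(s))]
    return FAMDResult(
        scores=pd.DataFrame(U * s, index=index, columns=comp),
        loadings=pd.DataFrame(Vt.T, index=names, columns=comp),
        singular_values=s,
        explained_variance=s ** 2 / (n - 1),
        columns=names,
    )


@dataclass
class ManagementClustering:
    labels: pd.Series           # cluster id per site, 1..k
    k: int
    scores: pd.DataFrame        # FAMD components used
    linkage_matrix: np.ndarray
    within_inertia: dict = field(default_factory=dict)  # k -> W(k)


def cluster_management(scores: pd.DataFrame, k: int | None = None,
                       n_components: int | None = None,
                       k_max: int = 10) -> ManagementClustering:
    """Ward hierarchical clustering of FAMD scores into management clusters.

    With `k` unset, the number of clusters maximizes the relative loss of
    within-cluster inertia when moving from k−1 to k groups compared with the
    next move, λ(k) = (W(k−1) − W(k)) / (W(k) − W(k+1)) over 2 ≤ k < k_max —
    the elbow where further splitting stops paying.
    """
    S = pd.DataFrame(scores).astype(float)
    if n_components is not None:
        S = S.iloc[:, :n_components]
    X = S.to_numpy()
    n = len(X)
    if k is not None and k > n:
        raise ValueError(f"k={k} exceeds number of sites {n}")
    Z = linkage(X, method="ward")

    def within(kk: int) -> float:
        lab = fcluster(Z, t=kk, criterion="maxclust")
        w = 0.0
        for g in np.unique(lab):
            pts = X[lab == g]
            w += float(((pts - pts.mean(axis=0)) ** 2).sum())
        return w

    inertia = {kk: within(kk) for kk in range(1, min(k_max, n) + 1)}
    if k is None:
        best, best_ratio = 2, -np.inf
        for kk in range(2, min(k_max, n)):
            gain = inertia[kk - 1] - inertia[kk]
            nxt = inertia[kk] - inertia[kk + 1]
            ratio = gain / nxt if nxt > 1e-12 else np.inf
            if ratio > best_ratio:
                best, best_ratio = kk, ratio
        k = best
    labels = pd.Series(fcluster(Z, t=k, criterion="maxclust"),
                       index=S.index, name="management_cluster")
    return ManagementClustering(labels=labels, k=k, scores=S,
                                linkage_matrix=Z, within_inertia=inertia)


def indicator_matrix(labels: pd.Series, drop_reference: bool = True) -> pd.DataFrame:
    """Full-rank indicator coding of cluster labels (first level as reference)."""
    d = pd.get_dummies(pd.Series(labels).astype("category"), prefix="mgmt")
    if drop_reference and d.shape[1] > 1:
        d = d.iloc[:, 1:]
    return d.astype(float)


# ---------------------------------------------------------------------------
# Adjusted R² and stepwise selection
# ---------------------------------------------------------------------------

def _r2(y: np.ndarray, X: np.ndarray | None) -> tuple[float, int, np.ndarray]:
    """R², model rank (excluding intercept) and residuals of OLS with intercept."""
    y = np.asarray(y, dtype=float)
    yc = y - y.mean()
    ss_tot = float(yc @ yc)
    if ss_tot == 0:
        raise ValueError("zero-variance response")
    if X is None or X.size == 0:
        return 0.0, 0, yc
    Xc = X - X.mean(axis=0)
    Q, R = np.linalg.qr(Xc)
    rank = int(np.sum(np.abs(np.diag(R)) > 1e-10 * max(1.0, np.abs(R).max())))
    if rank < Xc.shape[1]:
        # re-orthonormalize on the column space only
        Q = np.linalg.svd(Xc, full_matrices=False)[0][:, :rank]
    else:
        Q = Q[:, :Xc.shape[1]]
    proj = Q.T @ yc
    ss_model = float(proj @ proj)
    resid = yc - Q @ proj
    return ss_model / ss_tot, rank, resid


def adjusted_r2(y, X=None) -> float:
    """Ezekiel-adjusted R²: 1 − (1 − R²)(n − 1)/(n − p − 1).

    With a single response, redundancy analysis reduces to this multiple
    regression; p is the rank of the (centered) predictor matrix, so
    collinear columns do not consume degrees of freedom twice.  Intercept-only
    input returns 0.
    """
    y = np.asarray(y, dtype=float)
    Xa = None if X is None else np.asarray(pd.DataFrame(X), dtype=float)
    r2, p, _ = _r2(y, Xa)
    n = len(y)
    if p == 0:
        return 0.0
    if n <= p + 1:
        raise ValueError(f"adjusted R² undefined: n={n} <= p+1={p + 1}")
    return 1.0 - (1.0 - r2) * (n - 1) / (n - p - 1)


def _aic(n: int, rss: float, p: int) -> float:
    """Gaussian AIC up to a constant: n·ln(RSS/n) + 2p (p = fitted terms)."""
    return n * np.log(max(rss, 1e-300) / n) + 2 * p


def forward_select(y, candidates: pd.DataFrame, alpha: float | None = None,
                   max_vars: int | None = None) -> list:
    """Greedy forward selection maximizing adjusted R² under an AIC guard.

    At each step the candidate giving the largest adjusted-R² increase is
    proposed; selection stops as soon as either the adjusted R² no longer
    increases or the AIC (n·ln(RSS/n) + 2p) no longer decreases — whichever
    triggers first.  Ties break deterministically by column order.  An
    optional `alpha` adds the usual two significance guards of ecological
    forward selection: the model with all candidates must be globally
    significant at `alpha` before any selection starts, and each entering
    variable's partial F-test p-value must fall below `alpha`.  Returns the
    selected column names (possibly empty).
    """
    from scipy import stats as sps

    X = pd.DataFrame(candidates).astype(float)
    y = np.asarray(y, dtype=float)
    n = len(y)
    if alpha is not None and X.shape[1] > 0:
        r2_g, p_g, _ = _r2(y, X.to_numpy())
        if p_g > 0 and n > p_g + 1:
            f_g = (r2_g / p_g) / ((1 - r2_g) / (n - p_g - 1))
            if float(sps.f.sf(f_g, p_g, n - p_g - 1)) >= alpha:
                return []
    selected: list = []
    r2_cur, p_cur, resid = _r2(y, None)
    adj_cur = 0.0
    aic_cur = _aic(n, float(resid @ resid), 1)
    remaining = list(X.columns)
    while remaining and (max_vars is None or len(selected) < max_vars):
        best_col, best_adj = None, adj_cur
        for col in remaining:
            trial = X[selected + [col]].to_numpy()
            r2_t, p_t, _ = _r2(y, trial)
            if p_t <= len(selected):   # collinear with current set
                continue
            if n <= p_t + 1:
                continue
            adj_t = 1.0 - (1.0 - r2_t) * (n - 1) / (n - p_t - 1)
            if adj_t > best_adj + 1e-12:
                best_col, best_adj = col, adj_t
        if best_col is None:
            break
        trial = X[selected + [best_col]].to_numpy()
        r2_t, p_t, resid_t = _r2(y, trial)
        rss_t = float(resid_t @ resid_t)
        aic_t = _aic(n, rss_t, p_t + 1)
        if aic_t >= aic_cur:
            break
        if alpha is not None:
            rss_cur = float(resid @ resid)
            df2 = n - p_t - 1
            f = (rss_cur - rss_t) / (rss_t / df2)
            pval = float(sps.f.sf(f, 1, df2))
            if pval >= alpha:
                break
        selected.append(best_col)
        remaining.remove(best_col)
        adj_cur, aic_cur, resid = best_adj, aic_t, resid_t
    return selected


def select_spatial_from_residuals(y, env_selected: pd.DataFrame | None,
                                  pcnm: pd.DataFrame, **kwargs) -> list:
    """Forward-select PCNM columns on the residuals of the environmental model.

    Residuals of the response on the already-selected environmental columns
    (OLS with intercept) are the new response; a zero-variance residual
    returns an empty selection.
    """
    y = np.asarray(y, dtype=float)
    if env_selected is None or pd.DataFrame(env_selected).shape[1] == 0:
        resid = y - y.mean()
    else:
        Xe = pd.DataFrame(env_selected).astype(float).to_numpy()
        _, _, resid = _r2(y, Xe)
    if float(resid @ resid) <= 1e-12 * len(y):
        return []
    return forward_select(resid, pcnm, **kwargs)


# ---------------------------------------------------------------------------
# Three-set variance partitioning
# ---------------------------------------------------------------------------

_FRACTION_KEYS = ["soil", "management", "space",
                  "soil_management", "soil_space", "management_space",
                  "soil_management_space"]

# membership of each fraction in the marginal R² of each union,
# unknowns ordered as _FRACTION_KEYS = [a, b, c, d, e, f, g]
_UNION_ROWS = {
    ("soil",): [1, 0, 0, 1, 1, 0, 1],
    ("management",): [0, 1, 0, 1, 0, 1, 1],
    ("space",): [0, 0, 1, 0, 1, 1, 1],
    ("soil", "management"): [1, 1, 0, 1, 1, 1, 1],
    ("soil", "space"): [1, 0, 1, 1, 1, 1, 1],
    ("management", "space"): [0, 1, 1, 1, 1, 1, 1],
    ("soil", "management", "space"): [1, 1, 1, 1, 1, 1, 1],
}


@dataclass
class VarPartResult:
    """Unique and shared adjusted-R² fractions for soil / management / space.

    `fractions` holds the seven inclusion–exclusion components (unique
    fractions under the set's own name, shared under joined names); shared
    fractions are reported but carry no significance test — overlap of
    predictor sets cannot be permuted apart.  Slightly negative adjusted
    fractions are reported as computed.
    """

    fractions: dict
    union_r2: dict              # adjusted R² of each of the 7 unions
    total: float                # adjusted R² of the full model
    p_values: dict = field(default_factory=dict)   # unique fractions only
    coefficients: pd.Series | None = None          # standardized, full model
    n_var: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "fractions": self.fractions,
            "union_r2": {"+".join(k): v for k, v in self.union_r2.items()},
            "total": self.total,
            "p_values": self.p_values,
            "coefficients": (None if self.coefficients is None
                             else self.coefficients.to_dict()),
            "n_var": self.n_var,
        }


def _prep_sets(soil, management, space, n: int) -> dict:
    out = {}
    for name, X in (("soil", soil), ("management", management), ("space", space)):
        if X is None:
            out[name] = pd.DataFrame(index=range(n))
        else:
            df = pd.DataFrame(X).astype(float).reset_index(drop=True)
            if len(df) != n:
                raise ValueError(f"set {name!r} has {len(df)} rows, expected {n}")
            out[name] = df
    return out


def variance_partition(y, soil=None, management=None, space=None) -> VarPartResult:
    """Three-set canonical variance partitioning by inclusion–exclusion.

    Computes the adjusted R² of all seven non-empty unions of the sets and
    solves the 7×7 inclusion–exclusion system for the unique fractions
    (a = soil, b = management, c = space), the three pairwise shared
    fractions and the three-way shared fraction.  By construction the
    fractions sum exactly to the full-model adjusted R².  Empty sets
    contribute zero fractions (with a warning).
    """
    import warnings

    y = np.asarray(y, dtype=float)
    n = len(y)
    sets = _prep_sets(soil, management, space, n)
    empty = [k for k, v in sets.items() if v.shape[1] == 0]
    if empty:
        warnings.warn(f"empty explanatory sets: {empty}; their fractions are 0")
    union_r2 = {}
    for combo in _UNION_ROWS:
        cols = [sets[name] for name in combo if sets[name].shape[1] > 0]
        if not cols:
            union_r2[combo] = 0.0
            continue
        X = pd.concat(cols, axis=1).to_numpy()
        union_r2[combo] = adjusted_r2(y, X)
    A = np.array([_UNION_ROWS[c] for c in _UNION_ROWS], dtype=float)
    b = np.array([union_r2[c] for c in _UNION_ROWS])
    frac = np.linalg.solve(A, b)
    fractions = dict(zip(_FRACTION_KEYS, frac.tolist()))
    # components involving an empty set are exactly zero up to solver roundoff
    for name in empty:
        for key in _FRACTION_KEYS:
            if name in key.split("_"):
                fractions[key] = 0.0
    total = union_r2[("soil", "management", "space")]
    # standardized coefficients of the full model
    full_cols = [sets[k] for k in ("soil", "management", "space")
                 if sets[k].shape[1] > 0]
    coefs = None
    if full_cols:
        Xf = pd.concat(full_cols, axis=1)
        Xc = Xf.to_numpy() - Xf.to_numpy().mean(axis=0)
        yc = y - y.mean()
        beta, *_ = np.linalg.lstsq(Xc, yc, rcond=None)
        sdx = Xf.std(ddof=1).to_numpy()
        sdy = y.std(ddof=1)
        coefs = pd.Series(beta * sdx / sdy, index=Xf.columns,
                          name="std_coef")
    return VarPartResult(
        fractions=fractions,
        union_r2=union_r2,
        total=total,
        coefficients=coefs,
        n_var={k: int(sets[k].shape[1]) for k in sets},
    )


def permute_marginal(y, soil=None, management=None, space=None,
                     n_perm: int = 999, seed: int | None = None,
                     result: VarPartResult | None = None) -> dict:
    """Permutation test of each unique fraction (reduced-model residuals).

    For set X the reduced model regresses the response on the two other sets;
    its residuals are permuted, added back to the reduced fit, and X's unique
    fraction recomputed, giving p = (1 + #{perm ≥ observed})/(n_perm + 1).
    Affine transforms of the response leave the p-values unchanged.
    """
    y = np.asarray(y, dtype=float)
    n = len(y)
    sets = _prep_sets(soil, management, space, n)
    if result is None:
        result = variance_partition(y, soil, management, space)
    rng = np.random.default_rng(seed)
    pvals = {}
    names = ("soil", "management", "space")
    for name in names:
        if sets[name].shape[1] == 0:
            continue
        others = [sets[o] for o in names if o != name and sets[o].shape[1] > 0]
        X_red = (pd.concat(others, axis=1).to_numpy()
                 if others else np.empty((n, 0)))
        X_full = np.concatenate([X_red, sets[name].to_numpy()], axis=1)
        obs = result.fractions[name]
        # orthonormal bases for fast projection R²
        def basis(M):
            if M.size == 0:
                return np.empty((n, 0))
            Mc = M - M.mean(axis=0)
            U, s, _ = np.linalg.svd(Mc, full_matrices=False)
            return U[:, s > 1e-10 * max(s[0], 1e-30)]
        Q_red, Q_full = basis(X_red), basis(X_full)
        p_red, p_full = Q_red.shape[1], Q_full.shape[1]
        yc = y - y.mean()
        fit_red = Q_red @ (Q_red.T @ yc)
        resid = yc - fit_red

        def unique_fraction(yv: np.ndarray) -> float:
            yv = yv - yv.mean()
            ss = float(yv @ yv)
            if ss == 0:
                return 0.0
            r2f = float(np.sum((Q_full.T @ yv) ** 2)) / ss
            r2r = float(np.sum((Q_red.T @ yv) ** 2)) / ss
            adjf = 1 - (1 - r2f) * (n - 1) / (n - p_full - 1)
            adjr = 0.0 if p_red == 0 else 1 - (1 - r2r) * (n - 1) / (n - p_red - 1)
            return adjf - adjr

        exceed = 0
        for _ in range(n_perm):
            y_perm = fit_red + rng.permutation(resid)
            if unique_fraction(y_perm) >= obs:
                exceed += 1
        pvals[name] = (1.0 + exceed) / (n_perm + 1.0)
    result.p_values = pvals
    return pvals
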