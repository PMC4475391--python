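"""Synthetic landscapes with known ground truth.

The generator emulates the statistical structure of a surveyed agricultural
landscape: ~248 sites on a 215 m square grid plus 30 random short-distance
infill points (10–100 m from their nearest grid node) over roughly 13 km²;
spatially autocorrelated soil fields (Matérn covariance, effective ranges of
several hundred meters); a patchy categorical land-management mosaic; and
OTU tables whose richness and evenness respond to the simulated drivers.

Every stochastic operation takes an explicit integer seed;
:func:`make_landscape` splits a single master seed into one child stream per
stage (design, fields, land use, responses, OTU table — in that order) so the
whole landscape is reproducible from one integer.

The generator records the quantities a recovery test needs (true variogram
parameters, true coefficients, implied variance fractions) in
:class:`SyntheticTruth`.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dfield

import numpy as np
import pandas as pd

from .geostat import VariogramModel

__all__ = [
    "FieldSpec",
    "LanduseSpec",
    "OTUSpec",
    "ResponseSpec",
    "LandscapeSpec",
    "SyntheticTruth",
    "make_design",
    "simulate_grf",
    "simulate_landuse",
    "simulate_responses",
    "simulate_otu_table",
    "make_landscape",
]

# Cluster frequencies of the six management categories (forest, perennial,
# catch crop, minimum tillage, conventional tillage, mechanical hoeing).
DEFAULT_LANDUSE_FREQS = (44, 7, 22, 57, 104, 33)


@dataclass
class FieldSpec:
    """One spatially autocorrelated soil variable (Gaussian random field)."""

    name: str
    model: VariogramModel          # variogram of the standardized field
    mean: float = 0.0
    sd: float = 1.0

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ValueError("field sd must be non-negative")


@dataclass
class LanduseSpec:
    """Patchy categorical land-management mosaic.

    Categories are obtained by thresholding a smooth auxiliary Gaussian field
    at its empirical quantiles, so they form contiguous patches of
    characteristic size `patch_scale` with (near-)exact requested
    frequencies.
    """

    n_categories: int = 6
    patch_scale: float = 450.0     # meters; 0 => spatially independent labels
    frequencies: tuple = DEFAULT_LANDUSE_FREQS

    def __post_init__(self) -> None:
        if self.n_categories < 1:
            raise ValueError("need at least one category")
        if self.frequencies is not None and len(self.frequencies) != self.n_categories:
            raise ValueError("frequencies length must equal n_categories")


@dataclass
class OTUSpec:
    """Lognormal rank-abundance communities sampled to a fixed read depth.

    Per sample a species pool of size S (monotone in the richness driver) is
    drawn from a global OTU pool; relative abundances follow a lognormal
    rank-abundance curve whose shape parameter σ shrinks with the evenness
    driver (smaller σ => more even community); reads are then a single
    multinomial draw of `reads_per_sample`.
    """

    n_otus: int = 6000             # global pool
    reads_per_sample: int = 10_800
    richness_base: float = 3000.0  # pool size at driver 0
    richness_slope: float = 450.0  # pool size change per driver sd
    sigma_base: float = 2.2        # lognormal shape at driver 0
    sigma_slope: float = 0.25      # decrease per evenness-driver sd
    sigma_bounds: tuple = (0.05, 3.0)


@dataclass
class ResponseSpec:
    """Linear response model: soil + management + spatial residual + noise."""

    field_coefs: dict = dfield(default_factory=dict)  # field name -> beta
    category_effects: tuple | None = None             # one effect per category
    spatial_model: VariogramModel | None = None       # structured residual
    spatial_sd: float = 0.0
    noise_sd: float = 1.0


def _default_field_specs() -> list:
    """Soil variables with effective ranges of several hundred meters."""
    def mat(phi, nu=0.5, c0=0.1, c1=0.9):
        return VariogramModel("matern", c0, c1, phi, nu)
    return [
        FieldSpec("organic_carbon", mat(250.0), mean=30.0, sd=25.0),
        FieldSpec("total_nitrogen", mat(250.0), mean=2.5, sd=1.8),
        FieldSpec("ph", mat(220.0), mean=7.4, sd=0.8),
        FieldSpec("caco3", mat(280.0, nu=1.0), mean=90.0, sd=80.0),
        FieldSpec("clay", mat(230.0), mean=340.0, sd=90.0),
        FieldSpec("sand", mat(200.0), mean=120.0, sd=70.0),
    ]


def _default_response_specs() -> dict:
    return {
        "biomass": ResponseSpec(
            field_coefs={"organic_carbon": 0.8, "clay": 0.2},
            category_effects=(1.5, 0.8, 0.2, -0.3, 0.2, -0.1),
            noise_sd=0.7),
        "richness_driver": ResponseSpec(
            field_coefs={"ph": 0.6, "caco3": 0.3, "clay": -0.3},
            category_effects=(-0.8, -0.4, 0.3, 0.1, 0.3, 0.5),
            noise_sd=0.7),
        "evenness_driver": ResponseSpec(
            field_coefs={"ph": 0.5, "caco3": 0.3, "clay": -0.2},
            category_effects=(-0.9, -0.5, 0.4, 0.1, 0.4, 0.6),
            noise_sd=0.7),
    }


@dataclass
class LandscapeSpec:
    """Full description of a synthetic landscape."""

    n_grid: int = 248
    grid_spacing: float = 215.0
    n_infill: int = 30
    infill_range: tuple = (10.0, 100.0)
    extent: tuple | None = None            # (width, height) m; None = fit grid
    field_specs: list = dfield(default_factory=_default_field_specs)
    landuse: LanduseSpec = dfield(default_factory=LanduseSpec)
    otu: OTUSpec = dfield(default_factory=OTUSpec)
    responses: dict = dfield(default_factory=_default_response_specs)
    cross_corr: float = 0.0                # optional shared latent across fields
    seed: int = 0

    def __post_init__(self) -> None:
        if self.grid_spacing <= 0:
            raise ValueError("grid_spacing must be positive")
        lo, hi = self.infill_range
        if not (0 < lo < hi < self.grid_spacing):
            raise ValueError("infill_range must lie within (0, grid_spacing)")
        if not 0 <= self.cross_corr < 1:
            raise ValueError("cross_corr must be in [0, 1)")


@dataclass
class SyntheticTruth:
    """Ground truth recorded while generating a landscape."""

    field_models: dict                      # field name -> VariogramModel
    response_coefs: dict                    # response -> ResponseSpec
    variance_fractions: dict                # response -> component fractions
    fields: pd.DataFrame | None = None      # realized standardized fields

    def __post_init__(self) -> None:
        for resp, fr in self.variance_fractions.items():
            for k, v in fr.items():
                if not (np.isfinite(v) and -1e-9 <= v <= 1 + 1e-9):
                    raise ValueError(f"fraction {k}={v} of {resp} outside [0,1]")


# ---------------------------------------------------------------------------
# Design
# ---------------------------------------------------------------------------

def make_design(spec: LandscapeSpec) -> pd.DataFrame:
    """Sampling design: a square grid plus short-distance infill points.

    The grid fills rows of ceil(sqrt(n_grid)) columns at `grid_spacing`; each
    infill point is placed at a uniform angle and a uniform distance within
    `infill_range` of a randomly chosen grid node.  Because the maximum
    infill distance is below half the spacing, the chosen node is also the
    nearest one.  Deterministic given ``spec.seed``.
    """
    nx = int(np.ceil(np.sqrt(spec.n_grid)))
    ny = int(np.ceil(spec.n_grid / nx))
    width = (nx - 1) * spec.grid_spacing
    height = (ny - 1) * spec.grid_spacing
    if spec.extent is not None:
        if spec.extent[0] < width or spec.extent[1] < height:
            raise ValueError(
                f"extent {spec.extent} too small for a {nx}x{ny} grid at "
                f"{spec.grid_spacing} m spacing ({width} x {height} m needed)")
    ii = np.arange(spec.n_grid)
    gx = (ii % nx) * spec.grid_spacing
    gy = (ii // nx) * spec.grid_spacing
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 0]))
    xs, ys = [gx], [gy]
    if spec.n_infill > 0:
        node = rng.integers(0, spec.n_grid, spec.n_infill)
        lo, hi = spec.infill_range
        r = rng.uniform(lo, hi, spec.n_infill)
        a = rng.uniform(0, 2 * np.pi, spec.n_infill)
        xs.append(gx[node] + r * np.cos(a))
        ys.append(gy[node] + r * np.sin(a))
    x = np.concatenate(xs)
    y = np.concatenate(ys)
    ids = [f"site_{i + 1:03d}" for i in range(len(x))]
    return pd.DataFrame({"sample_id": ids, "x": x, "y": y}).set_index("sample_id")


# ---------------------------------------------------------------------------
# Random fields, land use, responses, communities
# ---------------------------------------------------------------------------

def simulate_grf(sites, model: VariogramModel, mean: float = 0.0,
                 seed: int | None = None,
                 rng: np.random.Generator | None = None) -> np.ndarray:
    """One realization of a stationary Gaussian random field at `sites`.

    Covariance C(h) = c1·ρ(h) plus an independent nugget c0; implemented by
    Cholesky factorization of the full covariance at the sample sites (suited
    to n up to ~1000).  Escalating diagonal jitter guards against borderline
    positive-definiteness; failure after the largest jitter raises.
    """
    sites = np.asarray(sites, dtype=float)
    if rng is None:
        rng = np.random.default_rng(seed)
    K = model.covariance_matrix(sites)
    n = len(sites)
    scale = max(np.trace(K) / n, 1e-30)
    L = None
    for jitter in (0.0, 1e-12, 1e-10, 1e-8, 1e-6):
        try:
            L = np.linalg.cholesky(K + jitter * scale * np.eye(n))
            break
        except np.linalg.LinAlgError:
            continue
    if L is None:
        raise np.linalg.LinAlgError(
            "covariance not positive definite even after jitter; "
            "check for duplicate sites or invalid parameters")
    return mean + L @ rng.standard_normal(n)


def simulate_landuse(sites, spec: LanduseSpec, seed: int | None = None,
                     rng: np.random.Generator | None = None) -> np.ndarray:
    """Spatially patchy category labels (integers 0..k−1).

    A smooth auxiliary Gaussian field (Gaussian-family correlation with
    length `patch_scale`) is thresholded at its own empirical quantiles, so
    the realized category counts match the requested frequencies to rounding
    while categories form contiguous patches.  `patch_scale` → 0 gives
    spatially independent labels.
    """
    sites = np.asarray(sites, dtype=float)
    n = len(sites)
    if rng is None:
        rng = np.random.default_rng(seed)
    k = spec.n_categories
    if k == 1:
        return np.zeros(n, dtype=int)
    if spec.patch_scale <= 0:
        aux = rng.standard_normal(n)
    else:
        aux_model = VariogramModel("gaussian", 1e-6, 1.0, spec.patch_scale)
        aux = simulate_grf(sites, aux_model, rng=rng)
    freqs = np.asarray(spec.frequencies if spec.frequencies is not None
                       else np.ones(k), dtype=float)
    freqs = freqs / freqs.sum()
    cum = np.cumsum(freqs)[:-1]
    thresholds = np.quantile(aux, cum)
    return np.searchsorted(thresholds, aux, side="right").astype(int)


def _standardize(v: np.ndarray) -> np.ndarray:
    sd = v.std(ddof=1)
    if sd == 0:
        raise ValueError("cannot standardize a constant field")
    return (v - v.mean()) / sd


def simulate_responses(fields: pd.DataFrame, landuse: np.ndarray,
                       specs: dict, sites=None, seed: int | None = None,
                       rng: np.random.Generator | None = None
                       ) -> tuple[pd.DataFrame, dict]:
    """Simulate linear responses and record their implied variance fractions.

    response = Σ β_f · field_f(standardized) + effect[category] + spatially
    structured residual + white noise.  The returned fractions are the sample
    variances of the four components divided by the response's sample
    variance — the ground truth a variance-partitioning recovery test
    compares against (exact when the components are independent).
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    landuse = np.asarray(landuse)
    n = len(fields)
    out = {}
    fractions = {}
    for name, rs in specs.items():
        soil_part = np.zeros(n)
        for fname, beta in rs.field_coefs.items():
            soil_part = soil_part + beta * _standardize(fields[fname].to_numpy())
        mgmt_part = np.zeros(n)
        if rs.category_effects is not None:
            eff = np.asarray(rs.category_effects, dtype=float)
            mgmt_part = eff[landuse]
            mgmt_part = mgmt_part - mgmt_part.mean()
        spat_part = np.zeros(n)
        if rs.spatial_model is not None and rs.spatial_sd > 0:
            if sites is None:
                raise ValueError("spatial residual requested but no sites given")
            spat_part = rs.spatial_sd * _standardize(
                simulate_grf(sites, rs.spatial_model, rng=rng))
        noise = rs.noise_sd * rng.standard_normal(n)
        y = soil_part + mgmt_part + spat_part + noise
        out[name] = y
        tot = y.var(ddof=1)
        fractions[name] = {
            "soil": soil_part.var(ddof=1) / tot,
            "management": mgmt_part.var(ddof=1) / tot,
            "space": spat_part.var(ddof=1) / tot,
            "noise": noise.var(ddof=1) / tot,
        }
    return pd.DataFrame(out, index=fields.index), fractions


def _lognormal_sad(s: int, sigma: float) -> np.ndarray:
    """Deterministic lognormal rank-abundance curve (relative abundances)."""
    from scipy import stats as sps
    q = sps.norm.ppf((np.arange(1, s + 1) - 0.5) / s)
    w = np.exp(sigma * q)
    return w / w.sum()


def simulate_otu_table(richness_driver, evenness_driver, spec: OTUSpec,
                       seed: int | None = None,
                       rng: np.random.Generator | None = None,
                       sample_ids=None) -> pd.DataFrame:
    """OTU count table (samples × OTUs) responding to two per-site drivers.

    Pool size S_i = richness_base + richness_slope·r_i; lognormal shape
    σ_i = sigma_base − sigma_slope·e_i (clipped).  Larger richness driver ⇒
    larger expected rarefied richness; larger evenness driver ⇒ larger
    expected Pielou evenness.  Row sums equal `reads_per_sample` exactly.
    """
    r = np.asarray(richness_driver, dtype=float)
    e = np.asarray(evenness_driver, dtype=float)
    if r.shape != e.shape:
        raise ValueError("driver vectors must have equal length")
    if rng is None:
        rng = np.random.default_rng(seed)
    n = len(r)
    depth = spec.reads_per_sample
    counts = np.zeros((n, spec.n_otus), dtype=np.int64)
    lo, hi = spec.sigma_bounds
    for i in range(n):
        s = int(np.clip(round(spec.richness_base + spec.richness_slope * r[i]),
                        1, spec.n_otus))
        sigma = float(np.clip(spec.sigma_base - spec.sigma_slope * e[i], lo, hi))
        p = _lognormal_sad(s, sigma)
        otus = rng.choice(spec.n_otus, size=s, replace=False)
        counts[i, otus] = rng.multinomial(depth, p)
    ids = (list(sample_ids) if sample_ids is not None
           else [f"site_{i + 1:03d}" for i in range(n)])
    cols = [f"OTU{j + 1:05d}" for j in range(spec.n_otus)]
    df = pd.DataFrame(counts, index=pd.Index(ids, name="sample_id"), columns=cols)
    return df.loc[:, df.sum(axis=0) > 0]


# ---------------------------------------------------------------------------
# Full landscape
# ---------------------------------------------------------------------------

def make_landscape(spec: LandscapeSpec
                   ) -> tuple[pd.DataFrame, pd.DataFrame, SyntheticTruth]:
    """Generate a complete landscape: frame, OTU table and ground truth.

    Child seed streams are spawned from ``spec.seed`` in a fixed order
    (design, fields, land use, responses, OTU table), so each stage is
    individually reproducible.
    """
    frame = make_design(spec)
    sites = frame[["x", "y"]].to_numpy()
    rng_fields = np.random.default_rng(np.random.SeedSequence([spec.seed, 1]))
    rng_landuse = np.random.default_rng(np.random.SeedSequence([spec.seed, 2]))
    rng_resp = np.random.default_rng(np.random.SeedSequence([spec.seed, 3]))
    rng_otu = np.random.default_rng(np.random.SeedSequence([spec.seed, 4]))

    common = None
    if spec.cross_corr > 0:
        common = simulate_grf(sites, spec.field_specs[0].model, rng=rng_fields)
    fields_std = {}
    for fs in spec.field_specs:
        z = simulate_grf(sites, fs.model, rng=rng_fields)
        if common is not None:
            z = (np.sqrt(spec.cross_corr) * common
                 + np.sqrt(1 - spec.cross_corr) * z)
        fields_std[fs.name] = z
        frame[fs.name] = fs.mean + fs.sd * z
    fields_df = pd.DataFrame(fields_std, index=frame.index)

    landuse = simulate_landuse(sites, spec.landuse, rng=rng_landuse)
    frame["land_management"] = landuse

    responses, fractions = simulate_responses(
        fields_df, landuse, spec.responses, sites=sites, rng=rng_resp)
    for col in responses:
        frame[col] = responses[col]

    otu = simulate_otu_table(
        _standardize(responses["richness_driver"].to_numpy()),
        _standardize(responses["evenness_driver"].to_numpy()),
        spec.otu, rng=rng_otu, sample_ids=frame.index)

    truth = SyntheticTruth(
        field_models={fs.name: fs.model for fs in spec.field_specs},
        response_coefs=spec.responses,
        variance_fractions=fractions,
        fields=fields_df,
    )
    return frame, otu, truth
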