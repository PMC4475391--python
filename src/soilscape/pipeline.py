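"""End-to-end orchestration of the landscape analysis.

Stages, in order: fixed-depth rarefaction and diversity metrics from the OTU
table; per-variable trans-Gaussian geostatistics (normal-score transform, ML
Matérn fit, leave-one-out SSPE validation, kriged map); PCNM construction and
Moran screening; environmental and spatial forward selection; three-set
variance partitioning with permutation tests.  A single master seed is split
deterministically per stage so reruns are byte-identical (timestamps are
excluded from the report).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import diversity as dv
from . import geostat as gs
from . import pcnm as pc
from . import varpart as vp
from .io import (read_otu_table, read_sample_frame, write_ascii_grid,
                 write_diversity)

__all__ = ["PipelineConfig", "RunReport", "run_pipeline", "load_config"]


@dataclass
class PipelineConfig:
    """All knobs of the pipeline with their conventional defaults."""

    metadata_path: str | None = None
    otu_path: str | None = None
    output_dir: str = "soilscape_out"
    rarefaction_depth: int = dv.DEFAULT_RAREFACTION_DEPTH   # 10,800 reads
    map_variables: tuple = ()          # metadata columns to krige
    response_variables: tuple = ()     # responses for variance partitioning
    soil_variables: tuple = ()         # explanatory soil columns
    management_column: str = "land_management"
    variogram_family: str = "matern"
    nu_grid: tuple = gs.DEFAULT_NU_GRID
    fix_nu: float | None = None
    cv_n_sim: int = 1000               # SSPE confidence-limit simulations
    pcnm_alpha: float = 0.001          # Moran screening threshold
    pcnm_n_perm: int = 999
    n_perm: int = 999                  # marginal-effect permutations
    scale_breaks: tuple = pc.DEFAULT_SCALE_BREAKS
    map_resolution: float = 100.0      # m
    make_maps: bool = True
    make_plots: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("rarefaction_depth", "cv_n_sim", "pcnm_n_perm", "n_perm"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def load_config(path) -> PipelineConfig:
    """PipelineConfig from a JSON or YAML file."""
    text = Path(path).read_text()
    if str(path).endswith((".yaml", ".yml")):
        import yaml
        doc = yaml.safe_load(text)
    else:
        doc = json.loads(text)
    for key in ("map_variables", "response_variables", "soil_variables",
                "nu_grid", "scale_breaks"):
        if key in doc and isinstance(doc[key], list):
            doc[key] = tuple(doc[key])
    return PipelineConfig(**doc)


@dataclass
class RunReport:
    """Everything a rerun needs to audit: models, verdicts, file paths."""

    config_hash: str
    seed: int
    variables: dict = field(default_factory=dict)   # per mapped variable
    responses: dict = field(default_factory=dict)   # per partitioned response
    pcnm: dict = field(default_factory=dict)
    outputs: list = field(default_factory=list)

    def to_json(self, path) -> None:
        doc = asdict(self)
        for f in self.outputs:
            if not Path(f).exists():
                raise FileNotFoundError(f"claimed output missing: {f}")
        with open(path, "w") as fh:
            json.dump(doc, fh, indent=2, sort_keys=True, default=_json_default)


class PipelineError(RuntimeError):
    pass


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, (np.bool_,)):
        return bool(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    return repr(o)


def _child_seed(master: int, stage: int) -> int:
    return int(np.random.SeedSequence([master, stage]).generate_state(1)[0]
               % (2 ** 31 - 1))


def run_pipeline(config: PipelineConfig,
                 frame: pd.DataFrame | None = None,
                 otu: pd.DataFrame | None = None) -> RunReport:
    """Run the full analysis; inputs from `config` paths or in-memory frames.

    Raises :class:`PipelineError` on inconsistent inputs (e.g. sample ids in
    the metadata without OTU counts or vice versa).
    """
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    report = RunReport(config_hash=config.config_hash(), seed=config.seed)

    if frame is None:
        if config.metadata_path is None:
            raise PipelineError("no metadata: neither a frame nor a path given")
        frame = read_sample_frame(config.metadata_path)
    do_diversity = otu is not None or config.otu_path is not None
    if otu is None and config.otu_path is not None:
        otu = read_otu_table(config.otu_path)

    # ---- diversity ---------------------------------------------------------
    if do_diversity:
        orphans_meta = sorted(set(frame.index) - set(otu.index))
        orphans_otu = sorted(set(otu.index) - set(frame.index))
        if orphans_meta or orphans_otu:
            raise PipelineError(
                f"sample-id mismatch: metadata-only {orphans_meta[:5]}, "
                f"OTU-only {orphans_otu[:5]}")
        otu = otu.loc[frame.index]
        prof = dv.diversity_profile(otu, depth=config.rarefaction_depth,
                                    seed=_child_seed(config.seed, 10))
        div_path = outdir / "diversity.csv"
        write_diversity(prof, div_path)
        report.outputs.append(str(div_path))
        for col in ("richness", "shannon", "evenness"):
            frame[col] = prof[col]

    sites = frame[["x", "y"]].to_numpy(dtype=float)

    # ---- geostatistics per mapped variable ---------------------------------
    for j, var in enumerate(config.map_variables):
        if var not in frame.columns:
            raise PipelineError(f"map variable {var!r} not in the frame")
        values = frame[var].to_numpy(dtype=float)
        nsmap, scores = gs.normal_score_transform(values)
        model = gs.fit_variogram_ml(sites, scores, family=config.variogram_family,
                                    fix_nu=config.fix_nu, nu_grid=config.nu_grid)
        cv = gs.loo_cross_validate(sites, scores, model)
        lim = gs.sspe_confidence_limits(sites, model, n_sim=config.cv_n_sim,
                                        seed=_child_seed(config.seed, 100 + j))
        cv.mean_limits = tuple(lim["mean_limits"])
        cv.median_limits = tuple(lim["median_limits"])
        entry = {
            "model": model.to_dict(),
            "effective_range_m": gs.effective_range(model),
            "cross_validation": cv.to_dict(),
        }
        mpath = outdir / f"variogram_{var}.json"
        with open(mpath, "w") as fh:
            json.dump(entry, fh, indent=2, sort_keys=True, default=_json_default)
        report.outputs.append(str(mpath))
        if config.make_maps:
            grid = gs.krige_map(sites, values, model,
                                resolution=config.map_resolution)
            gpath = outdir / f"map_{var}.csv"
            grid.to_csv(gpath, index=False)
            report.outputs.append(str(gpath))
            apath = outdir / f"map_{var}.asc"
            write_ascii_grid(grid, apath)
            report.outputs.append(str(apath))
            entry["map_csv"] = str(gpath)
        if config.make_plots:
            emp = gs.empirical_variogram(sites, scores)
            from .plots import plot_variogram
            ppath = outdir / f"variogram_{var}.png"
            plot_variogram(emp, model, path=ppath, title=var)
            report.outputs.append(str(ppath))
        report.variables[var] = entry

    # ---- PCNM --------------------------------------------------------------
    basis = pc.pcnm_basis(sites)
    basis = pc.screen_basis(basis, sites, alpha=config.pcnm_alpha,
                            n_perm=config.pcnm_n_perm,
                            seed=_child_seed(config.seed, 20))
    basis = pc.classify_scale(basis, sites, breaks=config.scale_breaks)
    pcnm_df = pd.DataFrame(basis.vectors, index=frame.index, columns=basis.names)
    ppath = outdir / "pcnm_scores.csv"
    pcnm_df.to_csv(ppath)
    report.outputs.append(str(ppath))
    sidecar = {
        "truncation_m": basis.truncation,
        "eigenvalues": basis.eigenvalues.tolist(),
        "moran_i": basis.moran_i.tolist(),
        "moran_p": basis.moran_p.tolist(),
        "effective_range_m": basis.eff_range.tolist(),
        "scale_class": basis.scale_class,
        "names": basis.names,
    }
    spath = outdir / "pcnm_meta.json"
    with open(spath, "w") as fh:
        json.dump(sidecar, fh, indent=2, sort_keys=True, default=_json_default)
    report.outputs.append(str(spath))
    report.pcnm = {"n_retained": basis.k, "truncation_m": basis.truncation}

    # ---- variance partitioning ---------------------------------------------
    results = {}
    if config.response_variables:
        soil = vp.standardize(frame[list(config.soil_variables)]) \
            if config.soil_variables else None
        mgmt = vp.indicator_matrix(frame[config.management_column]) \
            if config.management_column in frame.columns else None
        for i, resp in enumerate(config.response_variables):
            if resp not in frame.columns:
                raise PipelineError(f"response {resp!r} not in the frame")
            y = vp.standardize(frame[[resp]])[resp].to_numpy()
            env_cols = []
            soil_sel = vp.forward_select(y, soil) if soil is not None else []
            if soil_sel:
                env_cols.append(soil[soil_sel])
            if mgmt is not None:
                env_cols.append(mgmt)
            env = pd.concat(env_cols, axis=1) if env_cols else None
            space_sel = vp.select_spatial_from_residuals(y, env, pcnm_df)
            res = vp.variance_partition(
                y,
                soil=soil[soil_sel] if soil_sel else None,
                management=mgmt,
                space=pcnm_df[space_sel] if space_sel else None)
            vp.permute_marginal(
                y,
                soil=soil[soil_sel] if soil_sel else None,
                management=mgmt,
                space=pcnm_df[space_sel] if space_sel else None,
                n_perm=config.n_perm,
                seed=_child_seed(config.seed, 200 + i),
                result=res)
            results[resp] = res
            entry = res.to_dict()
            entry["selected_soil"] = soil_sel
            entry["selected_pcnm"] = space_sel
            entry["pcnm_scales"] = {
                nm: basis.scale_class[basis.names.index(nm)]
                for nm in space_sel}
            report.responses[resp] = entry
            rpath = outdir / f"varpart_{resp}.json"
            with open(rpath, "w") as fh:
                json.dump(entry, fh, indent=2, sort_keys=True, default=_json_default)
            report.outputs.append(str(rpath))
        if config.make_plots and results:
            from .plots import plot_varpart
            vpath = outdir / "varpart.png"
            plot_varpart(results, path=vpath)
            report.outputs.append(str(vpath))

    rpath = outdir / "run_report.json"
    report.to_json(rpath)
    return report
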