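"""End-to-end orchestration: screen -> fit -> summarize -> map.

One :class:`RunConfig` describes a full analysis run: input paths and
column mapping, model terms, priors, chain settings, and IDW options.
:func:`run_pipeline` executes the stages in order, writes every table the
reporting layout needs into the output directory, and records a manifest
(config hash, seed, library versions, per-stage row counts and timings)
sufficient to reproduce the run bit-exactly.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .design import ModelSpec, SmoothSpec, assemble_design, build_mrf_precision, read_edge_list
from .sampler import HyperPriors, MCMCConfig, run_gibbs
from .spatial import hotspot_classify, idw_interpolate, residual_spatial_pattern, spatial_effect_surface
from .summarize import (
    compute_dic, density_estimate, max_autocorrelation,
    residual_diagnostics, smooth_variance_table, summarize, summarize_smooth,
)
from .transform import binned_profile, fit_lambda, yeo_johnson

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline", "load_config"]


class ValidationFailure(ValueError):
    """Configuration or input-data validation failed (CLI exit code 2)."""


@dataclass
class RunConfig:
    """Everything one pipeline run needs.

    ``categorical`` maps column -> reference level; ``smooths`` maps
    column -> optional overrides of degree/n_knots/penalty_order.
    """

    data_csv: str
    adjacency: str | None
    outdir: str
    response: str = "waz"
    categorical: dict = field(default_factory=dict)
    smooths: dict = field(default_factory=dict)
    spatial: str | None = "region"
    lon: str = "lon"
    lat: str = "lat"
    cluster: str | None = "cluster"
    iterations: int = 12000
    burnin: int = 2000
    thin: int = 10
    seed: int = 0
    prior_a: float = 0.001
    prior_b: float = 0.001
    idw_power: float = 2.0
    idw_grid: int = 50
    hotspot_quantile: float = 0.80
    screen_bins: int = 30
    yeo_johnson_screen: bool = True
    plots: bool = False

    def model_spec(self) -> ModelSpec:
        smooths = tuple(
            SmoothSpec(covariate=c, **(opts or {})) for c, opts in self.smooths.items()
        )
        return ModelSpec(
            response=self.response,
            categorical=dict(self.categorical),
            smooths=smooths,
            spatial=self.spatial,
        )


def load_config(path) -> RunConfig:
    """Load a YAML/JSON run configuration file."""
    with open(path) as fh:
        payload = yaml.safe_load(fh)
    try:
        return RunConfig(**payload)
    except TypeError as exc:
        raise ValidationFailure(f"bad configuration: {exc}") from exc


def _config_hash(config: RunConfig) -> str:
    canon = json.dumps(asdict(config), sort_keys=True).encode()
    return hashlib.sha256(canon).hexdigest()


def run_pipeline(config: RunConfig) -> Path:
    """Execute the full workflow and return the output directory.

    Stage order: validation / complete-case filter, nonlinearity
    screening profiles, design assembly, Gibbs sampling, summary tables,
    DIC, chain and residual diagnostics, spatial surfaces and IDW
    hotspots. Partial outputs are retained on failure and the manifest
    marks the failing stage.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config": asdict(config),
        "config_sha256": _config_hash(config),
        "seed": config.seed,
        "versions": {
            "geowaz": __version__,
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
        "stages": {},
    }
    t_all = time.perf_counter()
    stage = "validate"
    try:
        t0 = time.perf_counter()
        spec = config.model_spec()
        data = pd.read_csv(config.data_csv)
        missing = [c for c in spec.columns() if c not in data.columns]
        if missing:
            raise ValidationFailure(f"data is missing model columns: {missing}")
        n_raw = len(data)
        from .design import complete_cases

        data = complete_cases(data, spec.columns())
        manifest["stages"][stage] = {
            "rows_in": n_raw, "rows_out": len(data), "seconds": time.perf_counter() - t0,
        }

        stage = "screen"
        t0 = time.perf_counter()
        if config.yeo_johnson_screen:
            lam = fit_lambda(data[config.response].to_numpy())
            y_screen = yeo_johnson(data[config.response].to_numpy(), lam.lmbda)
            screen_rows = {"response_lambda": lam.lmbda, "response_loglik": lam.loglik}
            for cov in config.smooths:
                prof = binned_profile(data[cov].to_numpy(), y_screen, config.screen_bins)
                prof.to_csv(outdir / f"screen_profile_{cov}.csv", index=False)
            density_estimate(data[config.response].to_numpy()).to_csv(
                outdir / "response_density.csv", index=False
            )
            manifest["stages"][stage] = {**screen_rows, "seconds": time.perf_counter() - t0}

        stage = "design"
        t0 = time.perf_counter()
        structure = None
        if spec.spatial is not None:
            if config.adjacency is None:
                raise ValidationFailure("spatial term requires an adjacency file")
            edges = read_edge_list(config.adjacency)
            regions = sorted(data[spec.spatial].astype(str).unique())
            structure = build_mrf_precision(edges, regions)
        design = assemble_design(data, spec, adjacency=structure, drop_incomplete=False)
        manifest["stages"][stage] = {
            "n_fixed": design.n_fixed,
            "n_penalized_blocks": design.n_penalized_blocks,
            "seconds": time.perf_counter() - t0,
        }

        stage = "gibbs"
        t0 = time.perf_counter()
        priors = HyperPriors(a_tau=config.prior_a, b_tau=config.prior_b,
                             a_sigma=config.prior_a, b_sigma=config.prior_b)
        mcmc = MCMCConfig(iterations=config.iterations, burnin=config.burnin,
                          thin=config.thin, seed=config.seed)
        samples = run_gibbs(design, priors, mcmc)
        samples.save(str(outdir / "samples"))
        manifest["stages"][stage] = {
            "retained_draws": samples.n_draws, "seconds": time.perf_counter() - t0,
        }

        stage = "summaries"
        t0 = time.perf_counter()
        fixed_tab = summarize(samples)
        fixed_tab.to_csv(outdir / "fixed_effects.csv")
        smooth_variance_table(samples).to_csv(outdir / "smooth_variances.csv")
        for cov in config.smooths:
            x = data[cov].to_numpy()
            grid = np.linspace(x.min(), x.max(), 100)
            summarize_smooth(samples, design, cov, grid).to_csv(
                outdir / f"smooth_{cov}.csv", index=False
            )
        dic = compute_dic(samples, design)
        with open(outdir / "dic.json", "w") as fh:
            json.dump(asdict(dic), fh, indent=2)
        manifest["stages"][stage] = {"DIC": dic.DIC, "pD": dic.pD,
                                     "seconds": time.perf_counter() - t0}

        stage = "diagnostics"
        t0 = time.perf_counter()
        scalars = samples.scalar_draws()
        lags = np.arange(0, min(51, samples.n_draws - 1))
        acf = max_autocorrelation(scalars.to_numpy(), lags)
        pd.DataFrame({"lag": lags, "max_autocorrelation": acf}).to_csv(
            outdir / "max_autocorrelation.csv", index=False
        )
        resid = residual_diagnostics(samples, design)
        resid.to_csv(outdir / "residual_diagnostics.csv", index=False)
        manifest["stages"][stage] = {"seconds": time.perf_counter() - t0}

        stage = "spatial"
        t0 = time.perf_counter()
        if design.spatial is not None:
            surface = spatial_effect_surface(samples)
            surface.insert(0, "region", list(design.spatial.regions))
            surface.to_csv(outdir / "spatial_effects.csv", index=False)
            pattern = residual_spatial_pattern(
                resid["residual"].to_numpy(), design.region_index, design.spatial.n_regions
            )
            pattern.insert(0, "region", list(design.spatial.regions))
            pattern.to_csv(outdir / "residual_spatial.csv", index=False)

            # predicted severity per cluster (sign-flipped fit: larger = worse)
            fitted = resid["fitted"].to_numpy()
            cluster_key = data[config.cluster] if config.cluster in data.columns else data[spec.spatial]
            per_cluster = pd.DataFrame({
                "lon": data[config.lon], "lat": data[config.lat],
                "cluster": cluster_key, "severity": -fitted,
            }).groupby("cluster", as_index=False).mean()
            grid_lon = np.linspace(data[config.lon].min(), data[config.lon].max(), config.idw_grid)
            grid_lat = np.linspace(data[config.lat].min(), data[config.lat].max(), config.idw_grid)
            grid = idw_interpolate(per_cluster.rename(columns={"severity": "value"}),
                                   grid_lon, grid_lat, power=config.idw_power)
            flat = grid.to_frame()
            flat["hotspot"] = hotspot_classify(grid, config.hotspot_quantile).ravel()
            flat.to_csv(outdir / "idw_grid.csv", index=False)
        manifest["stages"][stage] = {"seconds": time.perf_counter() - t0}

        if config.plots:
            stage = "plots"
            _render_plots(outdir, config)

        manifest["status"] = "ok"
    except Exception as exc:
        manifest["status"] = "failed"
        manifest["failed_stage"] = stage
        manifest["error"] = f"{type(exc).__name__}: {exc}"
        manifest["total_seconds"] = time.perf_counter() - t_all
        with open(outdir / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2)
        raise
    manifest["total_seconds"] = time.perf_counter() - t_all
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return outdir


def _render_plots(outdir: Path, config: RunConfig) -> None:
    """Render the standard figure set from the exported CSV tables."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    for cov in config.smooths:
        path = outdir / f"smooth_{cov}.csv"
        if not path.exists():
            continue
        tab = pd.read_csv(path)
        fig, ax = plt.subplots(figsize=(5, 3.5))
        ax.fill_between(tab["x"], tab["2.5%"], tab["97.5%"], alpha=0.2, label="95% CI")
        ax.fill_between(tab["x"], tab["10%"], tab["90%"], alpha=0.3, label="80% CI")
        ax.plot(tab["x"], tab["Mean"], lw=1.5)
        ax.set_xlabel(cov)
        ax.set_ylabel("centred effect on WAZ")
        ax.legend(frameon=False, fontsize=8)
        fig.tight_layout()
        fig.savefig(outdir / f"smooth_{cov}.png", dpi=120)
        plt.close(fig)

    dens_path = outdir / "response_density.csv"
    if dens_path.exists():
        dens = pd.read_csv(dens_path)
        fig, ax = plt.subplots(figsize=(5, 3.5))
        ax.fill_between(dens["grid"], dens["histogram"], alpha=0.3, step="mid")
        ax.plot(dens["grid"], dens["kde"], label="KDE")
        ax.plot(dens["grid"], dens["normal"], "--", label="normal fit")
        ax.set_xlabel("WAZ")
        ax.set_ylabel("density")
        ax.legend(frameon=False, fontsize=8)
        fig.tight_layout()
        fig.savefig(outdir / "response_density.png", dpi=120)
        plt.close(fig)

    acf_path = outdir / "max_autocorrelation.csv"
    if acf_path.exists():
        acf = pd.read_csv(acf_path)
        fig, ax = plt.subplots(figsize=(5, 3))
        ax.bar(acf["lag"], acf["max_autocorrelation"], width=0.8)
        ax.set_xlabel("lag")
        ax.set_ylabel("max autocorrelation")
        fig.tight_layout()
        fig.savefig(outdir / "max_autocorrelation.png", dpi=120)
        plt.close(fig)

    resid_path = outdir / "residual_diagnostics.csv"
    if resid_path.exists():
        resid = pd.read_csv(resid_path)
        fig, axes = plt.subplots(1, 2, figsize=(8, 3.2))
        axes[0].scatter(resid["fitted"], resid["residual"], s=4, alpha=0.3)
        axes[0].axhline(0.0, color="k", lw=0.8)
        axes[0].set_xlabel("fitted")
        axes[0].set_ylabel("residual")
        axes[1].scatter(resid["fitted"], resid["sqrt_abs_standardized"], s=4, alpha=0.3)
        axes[1].set_xlabel("fitted")
        axes[1].set_ylabel("sqrt(|standardized residual|)")
        fig.tight_layout()
        fig.savefig(outdir / "residual_plots.png", dpi=120)
        plt.close(fig)

    grid_path = outdir / "idw_grid.csv"
    if grid_path.exists():
        flat = pd.read_csv(grid_path)
        nx_ = flat["lon"].nunique()
        ny_ = flat["lat"].nunique()
        fig, ax = plt.subplots(figsize=(5, 4))
        sc = ax.imshow(
            flat["value"].to_numpy().reshape(ny_, nx_),
            origin="lower", aspect="auto",
            extent=(flat["lon"].min(), flat["lon"].max(), flat["lat"].min(), flat["lat"].max()),
            cmap="viridis",
        )
        fig.colorbar(sc, ax=ax, label="interpolated severity")
        ax.set_xlabel("longitude")
        ax.set_ylabel("latitude")
        fig.tight_layout()
        fig.savefig(outdir / "idw_grid.png", dpi=120)
        plt.close(fig)
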