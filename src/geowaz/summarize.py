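"""Posterior summaries, credible-interval significance, DIC, stepwise
selection, and MCMC/residual diagnostics.

Summary tables mirror the conventional reporting layout for this model
family: posterior mean, SD, and the 2.5/50/97.5% quantiles per parameter,
with a term flagged significant when its 95% credible interval excludes
zero. Smooth-term variances are additionally reported with the min/max
over retained draws. Model comparison uses the deviance information
criterion DIC = Dbar + pD with pD = Dbar - D(theta-bar).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats

from .design import DesignBlocks, ModelSpec, MRFStructure, SmoothSpec, assemble_design
from .sampler import HyperPriors, MCMCConfig, PosteriorSamples, run_gibbs

logger = logging.getLogger(__name__)

__all__ = [
    "DICResult",
    "summarize",
    "summarize_chain",
    "summarize_smooth",
    "smooth_variance_table",
    "flag_significance",
    "compute_dic",
    "stepwise_select",
    "max_autocorrelation",
    "residual_diagnostics",
    "density_estimate",
]

#: default quantile levels: 95% interval, median, and the 80% band edges
DEFAULT_LEVELS = (0.025, 0.10, 0.50, 0.90, 0.975)


def flag_significance(lower: float, upper: float) -> str:
    """Three-class significance from a credible interval.

    ``positive`` if the interval lies above zero, ``negative`` if below,
    ``null`` otherwise (the interval covers zero).
    """
    if lower > 0:
        return "positive"
    if upper < 0:
        return "negative"
    return "null"


def summarize_chain(draws: np.ndarray, levels=DEFAULT_LEVELS) -> dict:
    """Mean/SD/quantile summary of one scalar chain.

    Quantiles use linear interpolation of order statistics, so e.g. the
    median of {1,2,3,4} is 2.5.
    """
    draws = np.asarray(draws, dtype=float)
    if draws.size < 2:
        raise ValueError("need at least 2 retained draws")
    qs = np.quantile(draws, levels)
    row = {"Mean": float(draws.mean()), "SD": float(draws.std(ddof=1))}
    for lv, q in zip(levels, qs):
        row[f"{100 * lv:g}%"] = float(q)
    row["significance"] = flag_significance(row["2.5%"], row["97.5%"])
    return row


def summarize(samples: PosteriorSamples, levels=DEFAULT_LEVELS) -> pd.DataFrame:
    """Posterior summary table over all scalar parameters.

    Rows: fixed effects (intercept first), smooth-term variances
    (``sx(...)`` rows), error variance ``Sigma2``. Columns in reporting
    order: Mean, SD, quantiles, significance flag.
    """
    frame = samples.scalar_draws()
    rows = {name: summarize_chain(frame[name].to_numpy(), levels) for name in frame.columns}
    return pd.DataFrame.from_dict(rows, orient="index")


def summarize_smooth(samples: PosteriorSamples, design: DesignBlocks, label: str,
                     x_grid, levels=DEFAULT_LEVELS) -> pd.DataFrame:
    """Pointwise posterior summary of a centred smooth on a grid.

    Returns one row per grid point with the posterior mean and the 80% and
    95% credible band edges — the standard curve-plot layout.
    """
    draws = samples.smooth_draws(design, label, x_grid)
    out = {"x": np.asarray(x_grid, dtype=float), "Mean": draws.mean(axis=0)}
    for lv in levels:
        out[f"{100 * lv:g}%"] = np.quantile(draws, lv, axis=0)
    return pd.DataFrame(out)


def smooth_variance_table(samples: PosteriorSamples, levels=(0.025, 0.50, 0.975)) -> pd.DataFrame:
    """Smoothing-variance summary with min/max across retained draws."""
    rows = {}
    for label, chain in samples.tau2.items():
        row = summarize_chain(chain, levels)
        row["Min"] = float(chain.min())
        row["Max"] = float(chain.max())
        rows[f"sx({label})"] = row
    rows["Sigma2"] = summarize_chain(samples.sigma2, levels)
    return pd.DataFrame.from_dict(rows, orient="index")


# ---------------------------------------------------------------------------
# DIC


@dataclass(frozen=True)
class DICResult:
    """Deviance information criterion decomposition.

    Dbar is the posterior mean deviance, D_at_mean the deviance at the
    posterior means of eta and sigma^2, pD = Dbar - D_at_mean the
    effective number of parameters, DIC = Dbar + pD.
    """

    Dbar: float
    D_at_mean: float
    pD: float
    DIC: float


def _gaussian_deviance(y: np.ndarray, eta: np.ndarray, sigma2: float) -> float:
    rss = float(np.sum((y - eta) ** 2))
    return y.size * float(np.log(2 * np.pi * sigma2)) + rss / sigma2


def compute_dic(samples: PosteriorSamples, design: DesignBlocks) -> DICResult:
    """DIC of a fitted Gaussian geoadditive model.

    The per-draw deviance is D = n log(2 pi sigma^2) + RSS/sigma^2; the
    plug-in deviance uses the posterior means of eta and sigma^2. pD can be
    negative in pathological cases and is reported as-is with a warning.
    """
    y = design.y
    etas = samples.linear_predictor(design)
    devs = np.array([
        _gaussian_deviance(y, etas[r], samples.sigma2[r]) for r in range(samples.n_draws)
    ])
    dbar = float(devs.mean())
    d_at_mean = _gaussian_deviance(y, etas.mean(axis=0), float(samples.sigma2.mean()))
    pd_ = dbar - d_at_mean
    if pd_ < 0:
        logger.warning("negative effective number of parameters pD=%.3f", pd_)
    return DICResult(Dbar=dbar, D_at_mean=d_at_mean, pD=pd_, DIC=dbar + pd_)


# ---------------------------------------------------------------------------
# stepwise term selection


def _spec_from_terms(response: str, terms) -> ModelSpec:
    categorical = {}
    smooths = []
    spatial = None
    for t in terms:
        if isinstance(t, SmoothSpec):
            smooths.append(t)
        elif t == "spatial":
            spatial = "region"
        elif isinstance(t, tuple) and len(t) == 2:
            categorical[t[0]] = t[1]
        else:
            raise ValueError(f"unrecognized candidate term: {t!r}")
    return ModelSpec(response=response, categorical=categorical,
                     smooths=tuple(smooths), spatial=spatial)


def _term_label(t) -> str:
    if isinstance(t, SmoothSpec):
        return f"s({t.covariate})"
    if t == "spatial":
        return "spatial"
    return t[0]


def stepwise_select(
    data: pd.DataFrame,
    response: str,
    candidates,
    adjacency: MRFStructure | None = None,
    priors: HyperPriors | None = None,
    config: MCMCConfig | None = None,
    max_sweeps: int = 10,
):
    """Greedy forward-backward model search minimizing DIC.

    Candidate terms are :class:`SmoothSpec` objects (penalized smooths),
    ``(column, reference_level)`` tuples (categorical fixed effects), or
    the string ``"spatial"`` (region MRF term; requires ``adjacency``).
    Starting from the intercept-only model, each sweep adds the candidate
    with the largest DIC reduction (strict), then drops any included term
    whose removal does not increase DIC (ties resolve toward the smaller
    model). Deterministic given ``config.seed``: every trial fit uses a
    seed derived from it.

    Returns ``(selected_terms, trace)`` where ``trace`` is an audit trail
    of every model tried (terms, DIC, action).
    """
    priors = priors or HyperPriors()
    config = config or MCMCConfig()
    candidates = list(candidates)
    if not candidates:
        raise ValueError("need at least one candidate term")

    trial = [0]
    cache: dict[frozenset, float] = {}
    trace: list[dict] = []

    def fit_dic(terms) -> float:
        key = frozenset(_term_label(t) for t in terms)
        if key in cache:
            return cache[key]
        spec = _spec_from_terms(response, terms)
        adj = adjacency if spec.spatial else None
        design = assemble_design(data, spec, adjacency=adj)
        cfg = replace(config, seed=config.seed + 1000 * trial[0])
        trial[0] += 1
        samples = run_gibbs(design, priors, cfg)
        dic = compute_dic(samples, design).DIC
        cache[key] = dic
        trace.append({"terms": sorted(key), "DIC": dic, "action": "tried"})
        return dic

    selected: list = []
    current = fit_dic(selected)
    for _ in range(max_sweeps):
        changed = False
        # forward: best strict improvement
        best_term, best_dic = None, current
        for t in candidates:
            if any(_term_label(t) == _term_label(s) for s in selected):
                continue
            dic = fit_dic(selected + [t])
            if dic < best_dic:
                best_term, best_dic = t, dic
        if best_term is not None:
            selected.append(best_term)
            current = best_dic
            trace.append({"terms": sorted(_term_label(t) for t in selected),
                          "DIC": current, "action": f"added {_term_label(best_term)}"})
            changed = True
        # backward: drop anything whose removal does not increase DIC
        for t in list(selected):
            reduced = [s for s in selected if s is not t]
            dic = fit_dic(reduced)
            if dic <= current:  # tie -> smaller model
                selected = reduced
                current = dic
                trace.append({"terms": sorted(_term_label(s) for s in selected),
                              "DIC": current, "action": f"dropped {_term_label(t)}"})
                changed = True
        if not changed:
            break
    return selected, trace


# ---------------------------------------------------------------------------
# diagnostics


def max_autocorrelation(chains, lags) -> np.ndarray:
    """Per-lag maximum sample autocorrelation across all parameters.

    ``chains`` is (draws, parameters); the statistic at lag k is
    ``max_p |acf_p(k)|`` — the curve whose rapid decay indicates a
    well-mixing sampler.
    """
    chains = np.atleast_2d(np.asarray(chains, dtype=float))
    if chains.shape[0] == 1:
        chains = chains.T
    lags = np.asarray(lags, dtype=int)
    n = chains.shape[0]
    if n <= int(lags.max()):
        raise ValueError("chain length must exceed the maximum lag")
    centred = chains - chains.mean(axis=0)
    denom = np.sum(centred**2, axis=0)
    out = np.empty(lags.size)
    for i, k in enumerate(lags):
        if k == 0:
            out[i] = 1.0
            continue
        num = np.sum(centred[:-k] * centred[k:], axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            acf = np.where(denom > 0, num / denom, 0.0)
        out[i] = float(np.max(np.abs(acf)))
    return out


def residual_diagnostics(samples: PosteriorSamples, design: DesignBlocks) -> pd.DataFrame:
    """Residual and scale-location quantities from the posterior-mean fit.

    Columns: fitted eta-hat, residual y - eta-hat, standardized residual
    (scaled by the posterior-mean error SD), and sqrt(|standardized|)
    for the scale-location plot.
    """
    fitted = samples.fitted(design)
    resid = design.y - fitted
    sd = float(np.sqrt(samples.sigma2.mean()))
    std = resid / sd
    return pd.DataFrame({
        "fitted": fitted,
        "residual": resid,
        "standardized": std,
        "sqrt_abs_standardized": np.sqrt(np.abs(std)),
    })


def density_estimate(x, n_grid: int = 256, n_bins: int = 30) -> pd.DataFrame:
    """Histogram + Gaussian-KDE density export for distribution checks.

    Gaussian kernel with Silverman bandwidth, evaluated on a regular grid
    padded by 3 sample SDs, together with the normal density matched to
    the sample mean and variance. Both densities integrate to ~1.
    """
    x = np.asarray(x, dtype=float)
    kde = stats.gaussian_kde(x, bw_method="silverman")
    pad = 3 * x.std(ddof=1)
    grid = np.linspace(x.min() - pad, x.max() + pad, n_grid)
    hist, edges = np.histogram(x, bins=n_bins, density=True)
    centers = 0.5 * (edges[:-1] + edges[1:])
    hist_on_grid = np.interp(grid, centers, hist, left=0.0, right=0.0)
    return pd.DataFrame({
        "grid": grid,
        "kde": kde(grid),
        "normal": stats.norm.pdf(grid, loc=x.mean(), scale=x.std(ddof=1)),
        "histogram": hist_on_grid,
    })
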