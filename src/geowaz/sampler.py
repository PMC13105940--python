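"""Gibbs sampler for the Gaussian geoadditive model.

The model is

    y_i = w_i' gamma + sum_j f_j(x_ij) + f_spat(s_i) + e_i,
    e_i ~ N(0, sigma^2),

with a flat prior on the fixed effects, partially improper Gaussian
smoothness priors ``beta_j | tau_j^2 ~ N(0, tau_j^2 K_j^-)`` on each
penalized block (difference penalty for P-splines, graph Laplacian for the
spatial MRF), and conjugate inverse-gamma hyperpriors on every variance.

All full conditionals are available in closed form, so sampling is a
systematic-scan Gibbs sweep:

* each coefficient block from N(mu, Sigma) with
  Sigma^-1 = B'B/sigma^2 + K/tau^2 and mu = Sigma B' r / sigma^2,
  where r is the partial residual with the block's own contribution
  removed;
* each smoothing variance from IG(a + rank(K)/2, b + beta'K beta/2);
* the error variance from IG(a + n/2, b + RSS/2).

Identifiability: the intrinsic priors are flat along constants, so after
each block draw the coefficients are centred to mean zero and the removed
level is transferred into the intercept, leaving the linear predictor
unchanged.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import linalg

from .design import DesignBlocks

logger = logging.getLogger(__name__)

__all__ = [
    "HyperPriors",
    "MCMCConfig",
    "PosteriorSamples",
    "sample_coefficient_block",
    "sample_smoothing_variance",
    "sample_error_variance",
    "run_gibbs",
]


class NumericalSingularityError(np.linalg.LinAlgError):
    """Full-conditional precision could not be factorized."""


@dataclass(frozen=True)
class HyperPriors:
    """Inverse-gamma shapes/scales for the smoothing and error variances.

    The default IG(0.001, 0.001) for every variance is the conventional
    weakly-informative choice for this model family. ``tau2`` pairs may be
    overridden per term by label.
    """

    a_tau: float = 0.001
    b_tau: float = 0.001
    a_sigma: float = 0.001
    b_sigma: float = 0.001
    per_term: dict = field(default_factory=dict)  # label -> (a, b)

    def __post_init__(self) -> None:
        for v in (self.a_tau, self.b_tau, self.a_sigma, self.b_sigma):
            if v <= 0:
                raise ValueError("inverse-gamma shapes and scales must be > 0")

    def tau_prior(self, label: str) -> tuple[float, float]:
        return self.per_term.get(label, (self.a_tau, self.b_tau))


@dataclass(frozen=True)
class MCMCConfig:
    """Chain run-length configuration (single chain by default)."""

    iterations: int = 12000
    burnin: int = 2000
    thin: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.burnin < self.iterations):
            raise ValueError("need 0 <= burnin < iterations")
        if self.thin < 1:
            raise ValueError("thinning must be >= 1")

    @property
    def n_retained(self) -> int:
        return (self.iterations - self.burnin) // self.thin


@dataclass
class PosteriorSamples:
    """Retained draws from one Gibbs run.

    Arrays are indexed draw-first: ``gamma`` is (R, q), each entry of
    ``betas`` is (R, m_j), ``f_spat`` is (R, S) or None, ``tau2`` maps a
    term label to its (R,) variance chain, ``sigma2`` is (R,).
    """

    gamma: np.ndarray
    fixed_names: tuple[str, ...]
    betas: list[np.ndarray]
    smooth_labels: tuple[str, ...]
    f_spat: np.ndarray | None
    tau2: dict[str, np.ndarray]
    sigma2: np.ndarray
    config: MCMCConfig
    priors: HyperPriors

    @property
    def n_draws(self) -> int:
        return self.sigma2.shape[0]

    def linear_predictor(self, design: DesignBlocks) -> np.ndarray:
        """(R, n) matrix of eta draws on the fitting data."""
        eta = self.gamma @ design.fixed.T
        for sb, beta in zip(design.smooths, self.betas):
            eta += beta @ sb.basis.T
        if self.f_spat is not None:
            eta += self.f_spat[:, design.region_index]
        return eta

    def fitted(self, design: DesignBlocks) -> np.ndarray:
        """Posterior-mean fit eta-hat per observation."""
        return self.linear_predictor(design).mean(axis=0)

    def smooth_draws(self, design: DesignBlocks, label: str, x) -> np.ndarray:
        """(R, len(x)) draws of a centred smooth evaluated at new points."""
        j = self.smooth_labels.index(label)
        Bx = design.smooths[j].evaluate(x)
        return self.betas[j] @ Bx.T

    def scalar_draws(self) -> pd.DataFrame:
        """Fixed effects + variances as a draws-by-parameter table."""
        cols = {name: self.gamma[:, k] for k, name in enumerate(self.fixed_names)}
        for label, chain in self.tau2.items():
            cols[f"sx({label})"] = chain
        cols["Sigma2"] = self.sigma2
        return pd.DataFrame(cols)

    def save(self, path_prefix: str) -> None:
        """Persist draws to <prefix>.csv with a JSON config sidecar."""
        frame = self.scalar_draws()
        for j, label in enumerate(self.smooth_labels):
            for k in range(self.betas[j].shape[1]):
                frame[f"beta[{label}][{k}]"] = self.betas[j][:, k]
        if self.f_spat is not None:
            for s in range(self.f_spat.shape[1]):
                frame[f"f_spat[{s}]"] = self.f_spat[:, s]
        frame.to_csv(f"{path_prefix}.csv", index=False)
        with open(f"{path_prefix}.json", "w") as fh:
            json.dump({"config": asdict(self.config), "priors": asdict(self.priors)}, fh, indent=2)


# ---------------------------------------------------------------------------
# full conditionals


def _draw_gaussian(precision: np.ndarray, linear: np.ndarray, rng) -> np.ndarray:
    """Draw from N(P^-1 h, P^-1) via Cholesky, with a 1e-8 ridge fallback."""
    try:
        L = linalg.cholesky(precision, lower=True)
    except linalg.LinAlgError:
        logger.warning("singular full-conditional precision; applying 1e-8 ridge")
        try:
            L = linalg.cholesky(precision + 1e-8 * np.eye(precision.shape[0]), lower=True)
        except linalg.LinAlgError as exc:
            raise NumericalSingularityError(
                "full-conditional precision is singular even after a 1e-8 ridge; "
                "consider a larger ridge or checking the design for rank deficiency"
            ) from exc
    mu = linalg.cho_solve((L, True), linear)
    z = rng.standard_normal(precision.shape[0])
    return mu + linalg.solve_triangular(L, z, lower=True, trans="T")


def sample_coefficient_block(
    y_partial: np.ndarray,
    B: np.ndarray,
    K: np.ndarray,
    tau2: float,
    sigma2: float,
    rng,
    BtB: np.ndarray | None = None,
    Bty: np.ndarray | None = None,
    center: bool = False,
) -> np.ndarray:
    """Conjugate Gaussian draw of one penalized coefficient block.

    Full conditional: N(mu, Sigma) with Sigma^-1 = B'B/sigma2 + K/tau2 and
    mu = Sigma B' y_partial / sigma2. ``BtB``/``Bty`` may be supplied to
    avoid recomputation inside the Gibbs sweep. With ``center=True`` the
    draw is centred to mean zero (the caller must absorb the level
    elsewhere).
    """
    if tau2 <= 0 or sigma2 <= 0:
        raise ValueError("variances must be strictly positive")
    if BtB is None:
        BtB = B.T @ B
    if Bty is None:
        Bty = B.T @ y_partial
    precision = BtB / sigma2 + K / tau2
    beta = _draw_gaussian(precision, Bty / sigma2, rng)
    if center:
        beta = beta - beta.mean()
    return beta


def sample_smoothing_variance(beta: np.ndarray, K: np.ndarray, a: float, b: float, rng,
                              rank: int | None = None) -> float:
    """Draw tau^2 from IG(a + rank(K)/2, b + beta'K beta/2)."""
    if a <= 0 or b <= 0:
        raise ValueError("inverse-gamma parameters must be > 0")
    if rank is None:
        rank = int(np.linalg.matrix_rank(K))
    if rank == 0:
        return float(1.0 / rng.gamma(a, 1.0 / b))
    quad = float(beta @ K @ beta)
    if quad < 0:
        logger.warning("negative penalty quadratic form %.3e clamped to 0", quad)
        quad = 0.0
    return float(1.0 / rng.gamma(a + rank / 2.0, 1.0 / (b + quad / 2.0)))


def sample_error_variance(residuals: np.ndarray, a: float, b: float, rng) -> float:
    """Draw sigma^2 from IG(a + n/2, b + sum r_i^2 / 2)."""
    residuals = np.asarray(residuals, dtype=float)
    if residuals.size < 1:
        raise ValueError("need at least one residual")
    rss = float(residuals @ residuals)
    return float(1.0 / rng.gamma(a + residuals.size / 2.0, 1.0 / (b + rss / 2.0)))


# ---------------------------------------------------------------------------
# the Gibbs sweep


def run_gibbs(design: DesignBlocks, priors: HyperPriors | None = None,
              config: MCMCConfig | None = None) -> PosteriorSamples:
    """Systematic-scan Gibbs sampler for the assembled geoadditive model.

    Sweep order: fixed effects, each smooth block, the spatial block, each
    smoothing variance, the error variance. Centring (mean-zero blocks with
    the level moved into the intercept) is applied after every block draw.
    Fully reproducible: one master seed spawns one substream per update
    site.
    """
    priors = priors or HyperPriors()
    config = config or MCMCConfig()
    y = design.y
    n = design.n_obs
    W = design.fixed
    WtW = W.T @ W
    Wty_template = W.T  # reused as W' r each sweep

    smooth_labels = tuple(sb.covariate for sb in design.smooths)
    blocks = []
    for sb in design.smooths:
        blocks.append({
            "label": sb.covariate,
            "B": sb.basis,
            "BtB": sb.basis.T @ sb.basis,
            "K": sb.penalty,
            "rank": sb.penalty_rank,
        })
    has_spatial = design.spatial is not None
    if has_spatial:
        S = design.spatial.n_regions
        counts = np.bincount(design.region_index, minlength=S).astype(float)
        blocks.append({
            "label": "spatial",
            "B": None,  # one-hot incidence handled via bincount
            "BtB": np.diag(counts),
            "K": design.spatial.precision,
            "rank": design.spatial.rank,
        })

    # deterministic substreams: one per update site
    ss = np.random.SeedSequence(config.seed)
    children = ss.spawn(len(blocks) + 3)
    rng_gamma = np.random.default_rng(children[0])
    rng_blocks = [np.random.default_rng(c) for c in children[1:1 + len(blocks)]]
    rng_tau = np.random.default_rng(children[-2])
    rng_sigma = np.random.default_rng(children[-1])

    # initial values: OLS fixed effects, zero smooths, variances at 0.1
    gamma, *_ = np.linalg.lstsq(W, y, rcond=None)
    coefs = [np.zeros(b["BtB"].shape[0]) for b in blocks]
    tau2 = {b["label"]: 0.1 for b in blocks}
    sigma2 = 0.1

    fits = [np.zeros(n) for _ in blocks]
    fit_fixed = W @ gamma

    R = config.n_retained
    out_gamma = np.empty((R, design.n_fixed))
    out_betas = [np.empty((R, b["BtB"].shape[0])) for b in blocks]
    out_tau2 = {b["label"]: np.empty(R) for b in blocks}
    out_sigma2 = np.empty(R)

    r_idx = 0
    for it in range(1, config.iterations + 1):
        eta_others = sum(fits)  # all penalized fits

        # fixed effects: flat prior, N(mu, sigma2 (W'W)^-1)
        resid = y - eta_others
        gamma = _draw_gaussian(WtW / sigma2, (Wty_template @ resid) / sigma2, rng_gamma)
        fit_fixed = W @ gamma

        eta = fit_fixed + eta_others
        for k, blk in enumerate(blocks):
            partial = y - eta + fits[k]
            if blk["B"] is not None:
                Bty = blk["B"].T @ partial
            else:
                Bty = np.bincount(design.region_index, weights=partial, minlength=len(coefs[k]))
            beta = sample_coefficient_block(
                partial, blk["B"], blk["K"], tau2[blk["label"]], sigma2,
                rng_blocks[k], BtB=blk["BtB"], Bty=Bty,
            )
            # identifiability: centre the block, move the level to intercept
            level = beta.mean()
            beta -= level
            gamma[0] += level
            fit_fixed += level
            coefs[k] = beta
            new_fit = blk["B"] @ beta if blk["B"] is not None else beta[design.region_index]
            eta += new_fit - fits[k] + level
            fits[k] = new_fit

        for blk, beta in zip(blocks, coefs):
            a, b = priors.tau_prior(blk["label"])
            tau2[blk["label"]] = sample_smoothing_variance(
                beta, blk["K"], a, b, rng_tau, rank=blk["rank"]
            )
        sigma2 = sample_error_variance(y - eta, priors.a_sigma, priors.b_sigma, rng_sigma)

        if not np.isfinite(sigma2) or any(not np.isfinite(v) for v in tau2.values()):
            raise FloatingPointError(
                f"divergent variance draw at iteration {it}: sigma2={sigma2}, tau2={tau2}"
            )

        if it > config.burnin and (it - config.burnin) % config.thin == 0:
            out_gamma[r_idx] = gamma
            for k in range(len(blocks)):
                out_betas[k][r_idx] = coefs[k]
            for label in tau2:
                out_tau2[label][r_idx] = tau2[label]
            out_sigma2[r_idx] = sigma2
            r_idx += 1

    n_smooth = len(design.smooths)
    return PosteriorSamples(
        gamma=out_gamma,
        fixed_names=design.fixed_names,
        betas=out_betas[:n_smooth],
        smooth_labels=smooth_labels,
        f_spat=out_betas[n_smooth] if has_spatial else None,
        tau2=out_tau2,
        sigma2=out_sigma2,
        config=config,
        priors=priors,
    )
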