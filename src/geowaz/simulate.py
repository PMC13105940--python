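"""Synthetic DHS-like data with known ground truth.

The restricted survey micro-data behind the motivating analysis cannot be
redistributed, so this module generates datasets with the same structure:
a two-stage clustered design (children nested in survey clusters nested
in regions), region-level spatial correlation from an intrinsic-MRF draw,
smooth nonlinear covariate effects (including an inverted-U in maternal
BMI), dummy-coded categorical covariates with survey-realistic
frequencies, and Gaussian weight-for-age z-score (WAZ) noise.

Every dataset carries its generating truth (:class:`SimTruth`), so
parameter-recovery of the full pipeline is testable end to end.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .design import MRFStructure, build_mrf_precision, write_edge_list

logger = logging.getLogger(__name__)

__all__ = [
    "SimScenario",
    "SimTruth",
    "default_truth_functions",
    "default_scenario",
    "tiny_scenario",
    "recovery_scenario",
    "lattice_edges",
    "simulate",
    "make_fixture",
]

# covariate distributions of the emulated survey population
CHILD_AGE_RANGE = (0, 59)  # months, uniform over integer months
MOTHER_AGE_DIST = ("truncnorm", 28.0, 7.0, 15.0, 49.0)  # years
MOTHER_BMI_DIST = ("truncnorm", 21.0, 3.5, 12.0, 50.0)  # kg/m^2

#: categorical covariates: {column: (levels, probabilities, {level: true coef})}
#: Reference levels carry coefficient 0. Frequencies for residence,
#: education and diarrhoea follow the emulated survey's published
#: descriptives; the remainder are realistic DHS-like choices.
DEFAULT_CATEGORICALS: dict[str, tuple[tuple, tuple, dict]] = {
    "child_sex": (("male", "female"), (0.5, 0.5), {"female": 0.0837}),
    "residence": (("urban", "rural"), (0.1855, 0.8145), {"rural": -0.0296}),
    "electricity": (("yes", "no"), (0.30, 0.70), {"no": -0.1976}),
    "head_sex": (("male", "female"), (0.75, 0.25), {"female": -0.0521}),
    "diarrhoea": (("no", "yes"), (0.1706, 0.8294), {"yes": 0.2161}),
    "anaemia": (
        ("not_anaemic", "mild", "moderate", "severe"),
        (0.43, 0.29, 0.25, 0.03),
        {"mild": 0.0139, "moderate": 0.2998, "severe": -0.5319},
    ),
    "education": (
        ("no", "primary", "secondary", "higher"),
        (0.6426, 0.2517, 0.0690, 0.0367),
        {"primary": -0.0946, "secondary": 0.1232, "higher": 0.2277},
    ),
}

DEFAULT_INTERCEPT = -1.1037
DEFAULT_SIGMA = float(np.sqrt(1.3511))  # error SD implied by the reported scale
#: default smooth/spatial signal scale: ~0.3 x error SD, large enough that
#: recovery is testable at n ~ 2000 yet subordinate to the noise
DEFAULT_AMPLITUDE = 0.35
DEFAULT_TAU_SPAT = 0.60

# geographic window the unit-square region tiling is mapped onto
LON_WINDOW = (34.0, 46.0)
LAT_WINDOW = (4.0, 14.0)


def _mother_age_rv():
    _, mu, sd, lo, hi = MOTHER_AGE_DIST
    return stats.truncnorm((lo - mu) / sd, (hi - mu) / sd, loc=mu, scale=sd)


def _mother_bmi_rv():
    _, mu, sd, lo, hi = MOTHER_BMI_DIST
    return stats.truncnorm((lo - mu) / sd, (hi - mu) / sd, loc=mu, scale=sd)


def _standardized(base, grid, weights):
    """Centre and unit-scale a curve under a covariate distribution."""
    vals = base(grid)
    w = weights / weights.sum()
    mean = float(np.sum(w * vals))
    sd = float(np.sqrt(np.sum(w * (vals - mean) ** 2)))
    return lambda x, b=base, m=mean, s=sd: (b(np.asarray(x, dtype=float)) - m) / s


def default_truth_functions(amplitude: float = DEFAULT_AMPLITUDE):
    """True smooth effects (f_age, f_mother_age, f_bmi) on WAZ units.

    Shapes follow what is typically seen in child-undernutrition data:

    * child age: WAZ worsens roughly linearly over the first ~10 months,
      then the decline flattens and stabilizes by ~30 months;
    * maternal age: flat between 15 and 35 years, declining afterwards;
    * maternal BMI: inverted U — WAZ peaks at a healthy maternal BMI and
      is lower for both under- and overweight mothers.

    Each curve is centred to mean zero under its covariate distribution
    and scaled so its SD under that distribution equals ``amplitude``.
    """
    age_grid = np.arange(CHILD_AGE_RANGE[0], CHILD_AGE_RANGE[1] + 1, dtype=float)
    age_w = np.ones_like(age_grid)
    f_age = _standardized(lambda t: -(1.0 - np.exp(-t / 7.0)), age_grid, age_w)

    mage_rv = _mother_age_rv()
    mage_grid = np.linspace(15.0, 49.0, 400)
    f_mage = _standardized(
        lambda a: -np.log1p(np.exp((a - 36.0) / 2.5)), mage_grid, mage_rv.pdf(mage_grid)
    )

    bmi_rv = _mother_bmi_rv()
    bmi_grid = np.linspace(12.0, 50.0, 400)
    f_bmi = _standardized(
        lambda b: np.exp(-(((b - 24.0) / 7.0) ** 2)), bmi_grid, bmi_rv.pdf(bmi_grid)
    )

    def scale(f):
        return lambda x, f=f: amplitude * f(x)

    return scale(f_age), scale(f_mage), scale(f_bmi)


def lattice_edges(n_regions: int) -> tuple[list[str], list[tuple[str, str]]]:
    """Region labels and grid-lattice adjacency for ``n_regions`` tiles."""
    if n_regions < 2:
        raise ValueError("need at least 2 regions")
    ncol = int(np.ceil(np.sqrt(n_regions)))
    labels = [f"R{i + 1:02d}" for i in range(n_regions)]
    edges = []
    for i in range(n_regions):
        r, c = divmod(i, ncol)
        if c + 1 < ncol and i + 1 < n_regions:
            edges.append((labels[i], labels[i + 1]))
        if i + ncol < n_regions:
            edges.append((labels[i], labels[i + ncol]))
    return labels, edges


def _region_tiles(labels):
    """Unit-square tiling mapped to the lon/lat window, one tile per region."""
    n = len(labels)
    ncol = int(np.ceil(np.sqrt(n)))
    nrow = int(np.ceil(n / ncol))
    tiles = {}
    for i, lab in enumerate(labels):
        r, c = divmod(i, ncol)
        lon0 = LON_WINDOW[0] + (LON_WINDOW[1] - LON_WINDOW[0]) * c / ncol
        lon1 = LON_WINDOW[0] + (LON_WINDOW[1] - LON_WINDOW[0]) * (c + 1) / ncol
        lat0 = LAT_WINDOW[0] + (LAT_WINDOW[1] - LAT_WINDOW[0]) * r / nrow
        lat1 = LAT_WINDOW[0] + (LAT_WINDOW[1] - LAT_WINDOW[0]) * (r + 1) / nrow
        tiles[lab] = (lon0, lon1, lat0, lat1)
    return tiles


@dataclass(frozen=True)
class SimScenario:
    """Generating conditions for one synthetic survey.

    Defaults emulate the motivating survey: 10,641 children in 645
    clusters across 11 regions, rural share 81.45%, maternal-education
    and diarrhoea frequencies as published, fixed-effect sizes equal to
    the reported posterior means, error SD matching the reported residual
    scale, and smooth/spatial signal scales documented in the methods
    note.
    """

    n: int = 10641
    n_regions: int = 11
    n_clusters: int = 645
    intercept: float = DEFAULT_INTERCEPT
    categoricals: dict = field(default_factory=lambda: dict(DEFAULT_CATEGORICALS))
    amplitude: float = DEFAULT_AMPLITUDE
    tau_spat: float = DEFAULT_TAU_SPAT
    sigma: float = DEFAULT_SIGMA
    edges: tuple | None = None  # None -> lattice adjacency
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError("error SD must be > 0")
        if self.n_regions < 2:
            raise ValueError("need at least 2 regions")
        for name, (levels, probs, coefs) in self.categoricals.items():
            p = np.asarray(probs, dtype=float)
            if (p < 0).any() or (p > 1).any() or abs(p.sum() - 1.0) > 1e-9:
                raise ValueError(f"probabilities of {name!r} must lie in [0,1] and sum to 1")
            unknown = set(coefs) - set(levels)
            if unknown:
                raise ValueError(f"coefficients for unknown levels of {name!r}: {unknown}")

    def adjacency(self) -> MRFStructure:
        if self.edges is None:
            labels, edges = lattice_edges(self.n_regions)
        else:
            labels = [f"R{i + 1:02d}" for i in range(self.n_regions)]
            edges = list(self.edges)
        return build_mrf_precision(edges, labels)


def default_scenario(seed: int = 0, **overrides) -> SimScenario:
    """The survey-scale scenario (10,641 children, 645 clusters, 11 regions)."""
    return SimScenario(seed=seed, **overrides)


def recovery_scenario(seed: int = 0, n: int = 2000) -> SimScenario:
    """Moderate scenario for parameter-recovery studies."""
    return SimScenario(n=n, n_regions=11, n_clusters=110, seed=seed)


def tiny_scenario(seed: int = 0) -> SimScenario:
    """Fits in seconds: 200 children, 4 regions, 20 clusters."""
    return SimScenario(n=200, n_regions=4, n_clusters=20, seed=seed)


@dataclass(frozen=True)
class SimTruth:
    """Ground truth realized for one simulated dataset."""

    scenario: SimScenario
    f_spat: np.ndarray  # per-region spatial effects (per-component sum zero)
    regions: tuple
    eta: np.ndarray  # linear predictor per child
    smooth_grids: dict  # label -> (grid, true centred values)
    truth_functions: dict  # label -> callable


def _draw_mrf(structure: MRFStructure, tau: float, rng) -> np.ndarray:
    """Intrinsic-MRF prior draw on the sum-zero constraint subspace.

    The null space (per-component constants) is set to zero, and the draw
    is rescaled so the empirical SD of the region effects equals ``tau``
    exactly, making the signal scale of a scenario well defined.
    """
    lam, V = np.linalg.eigh(structure.precision)
    pos = lam > 1e-10
    z = rng.standard_normal(int(pos.sum()))
    f = V[:, pos] @ (z / np.sqrt(lam[pos]))
    if structure.n_components > 1:
        logger.warning("adjacency graph has %d components; simulating per component",
                       structure.n_components)
    sd = f.std()
    if sd > 0 and tau > 0:
        f = f * (tau / sd)
    else:
        f = np.zeros_like(f)
    # numerical cleanup of the exact per-component sum-zero constraint
    comp = _component_labels(structure)
    for c in np.unique(comp):
        f[comp == c] -= f[comp == c].mean()
    return f


def _component_labels(structure: MRFStructure) -> np.ndarray:
    import networkx as nx

    g = nx.Graph()
    g.add_nodes_from(structure.regions)
    g.add_edges_from(structure.edges)
    labels = np.zeros(structure.n_regions, dtype=int)
    idx = {r: i for i, r in enumerate(structure.regions)}
    for c, comp in enumerate(nx.connected_components(g)):
        for r in comp:
            labels[idx[r]] = c
    return labels


def simulate(scenario: SimScenario) -> tuple[pd.DataFrame, SimTruth]:
    """Generate one synthetic survey and its ground truth.

    The response is ``waz = eta + N(0, sigma^2)`` exactly, with
    eta = intercept + fixed effects + centred smooths + spatial effect.
    Fully reproducible from ``scenario.seed``.
    """
    rng = np.random.default_rng(np.random.SeedSequence(scenario.seed))
    n = scenario.n
    structure = scenario.adjacency()
    labels = list(structure.regions)

    # two-stage design: clusters assigned to regions round-robin, children
    # to clusters uniformly
    cluster_region = np.array([i % scenario.n_regions for i in range(scenario.n_clusters)])
    child_cluster = rng.integers(0, scenario.n_clusters, size=n)
    region_idx = cluster_region[child_cluster]

    tiles = _region_tiles(labels)
    cluster_lon = np.empty(scenario.n_clusters)
    cluster_lat = np.empty(scenario.n_clusters)
    for c in range(scenario.n_clusters):
        lon0, lon1, lat0, lat1 = tiles[labels[cluster_region[c]]]
        cluster_lon[c] = rng.uniform(lon0, lon1)
        cluster_lat[c] = rng.uniform(lat0, lat1)

    child_age = rng.integers(CHILD_AGE_RANGE[0], CHILD_AGE_RANGE[1] + 1, size=n).astype(float)
    mother_age = _mother_age_rv().rvs(size=n, random_state=rng)
    mother_bmi = _mother_bmi_rv().rvs(size=n, random_state=rng)

    f_age, f_mage, f_bmi = default_truth_functions(scenario.amplitude)
    truth_functions = {
        "child_age_months": f_age,
        "mother_age": f_mage,
        "mother_bmi": f_bmi,
    }

    eta = np.full(n, scenario.intercept)
    data = {
        "child_age_months": child_age,
        "mother_age": mother_age,
        "mother_bmi": mother_bmi,
    }
    for name, (levels, probs, coefs) in scenario.categoricals.items():
        draws = rng.choice(len(levels), size=n, p=np.asarray(probs, dtype=float))
        values = np.asarray(levels, dtype=object)[draws]
        data[name] = values
        effect = np.array([coefs.get(lv, 0.0) for lv in levels])
        eta += effect[draws]

    eta += f_age(child_age) + f_mage(mother_age) + f_bmi(mother_bmi)
    f_spat = _draw_mrf(structure, scenario.tau_spat, rng)
    eta += f_spat[region_idx]

    waz = eta + scenario.sigma * rng.standard_normal(n)

    frame = pd.DataFrame(data)
    frame.insert(0, "waz", waz)
    frame["region"] = np.asarray(labels, dtype=object)[region_idx]
    frame["cluster"] = child_cluster
    frame["lon"] = cluster_lon[child_cluster]
    frame["lat"] = cluster_lat[child_cluster]

    grids = {
        "child_age_months": np.arange(CHILD_AGE_RANGE[0], CHILD_AGE_RANGE[1] + 1, dtype=float),
        "mother_age": np.linspace(15.0, 49.0, 100),
        "mother_bmi": np.linspace(12.0, 50.0, 100),
    }
    smooth_grids = {k: (g, truth_functions[k](g)) for k, g in grids.items()}
    truth = SimTruth(
        scenario=scenario,
        f_spat=f_spat,
        regions=structure.regions,
        eta=eta,
        smooth_grids=smooth_grids,
        truth_functions=truth_functions,
    )
    return frame, truth


_FIXTURE_SIZES = {"tiny": tiny_scenario, "small": recovery_scenario, "survey-scale": default_scenario}


def make_fixture(size: str, outdir, seed: int = 0) -> dict[str, Path]:
    """Write a simulated dataset + adjacency + truth to ``outdir``.

    Sizes: ``tiny`` (200 children / 4 regions), ``small`` (2,000 / 11),
    ``survey-scale`` (10,641 / 11). Regeneration with the same seed is
    byte-identical.
    """
    if size not in _FIXTURE_SIZES:
        raise ValueError(f"size must be one of {sorted(_FIXTURE_SIZES)}")
    scenario = _FIXTURE_SIZES[size](seed=seed)
    frame, truth = simulate(scenario)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "data": outdir / "data.csv",
        "adjacency": outdir / "adjacency.tsv",
        "truth": outdir / "truth.json",
        "scenario": outdir / "scenario.json",
    }
    frame.to_csv(paths["data"], index=False, float_format="%.10g", lineterminator="\n")
    structure = scenario.adjacency()
    write_edge_list(structure.edges, paths["adjacency"])
    truth_payload = {
        "regions": list(truth.regions),
        "f_spat": [round(v, 12) for v in truth.f_spat],
        "smooths": {
            k: {"grid": [round(v, 12) for v in g], "values": [round(v, 12) for v in vals]}
            for k, (g, vals) in truth.smooth_grids.items()
        },
    }
    with open(paths["truth"], "w") as fh:
        json.dump(truth_payload, fh, indent=1)
    scen_payload = {
        "n": scenario.n, "n_regions": scenario.n_regions, "n_clusters": scenario.n_clusters,
        "intercept": scenario.intercept, "amplitude": scenario.amplitude,
        "tau_spat": scenario.tau_spat, "sigma": scenario.sigma, "seed": scenario.seed,
        "size": size,
    }
    with open(paths["scenario"], "w") as fh:
        json.dump(scen_payload, fh, indent=1)
    return paths
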