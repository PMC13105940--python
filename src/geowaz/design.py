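"""Design and penalty matrices for the geoadditive model.

The linear predictor of the geoadditive Gaussian model is

    eta_i = w_i' gamma + sum_j f_j(x_ij) + f_spat(s_i)

with parametric fixed effects ``gamma`` (dummy-coded categoricals plus an
intercept), one penalized B-spline smooth per metrical covariate
(P-splines: B-spline basis + difference penalty on the coefficients), and a
region-level spatial effect with an intrinsic Markov-random-field (MRF)
prior whose precision is the graph Laplacian of the region adjacency.

This module builds every block: basis matrices, difference penalties, the
MRF precision, the one-hot spatial incidence, and the dummy-coded fixed
effects, assembled into a :class:`DesignBlocks` object the sampler consumes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy.interpolate import BSpline

logger = logging.getLogger(__name__)

__all__ = [
    "SmoothSpec",
    "ModelSpec",
    "SplineBasis",
    "MRFStructure",
    "DesignBlocks",
    "build_bspline_basis",
    "build_difference_penalty",
    "build_mrf_precision",
    "assemble_design",
    "complete_cases",
    "read_edge_list",
    "write_edge_list",
    "adjacency_from_polygons",
]


class DegenerateCovariateError(ValueError):
    """Raised when a smooth covariate is constant."""


class CollinearityError(ValueError):
    """Raised when the fixed-effects matrix is rank deficient."""


# ---------------------------------------------------------------------------
# model specification


@dataclass(frozen=True)
class SmoothSpec:
    """One P-spline term: covariate name plus basis/penalty configuration.

    Defaults are the conventional P-spline choices: cubic B-splines on 20
    equidistant knots spanning the observed range, second-order difference
    penalty (random-walk-2 prior on the coefficients).
    """

    covariate: str
    degree: int = 3
    n_knots: int = 20
    penalty_order: int = 2


@dataclass(frozen=True)
class ModelSpec:
    """Terms of the geoadditive model.

    ``categorical`` maps each categorical covariate to its reference level;
    dummy columns are created for every other observed level. ``smooths``
    lists the penalized metrical covariates. ``spatial`` names the region
    column (or None for a non-spatial model).
    """

    response: str
    categorical: dict[str, str] = field(default_factory=dict)
    smooths: tuple[SmoothSpec, ...] = ()
    spatial: str | None = "region"

    def columns(self) -> list[str]:
        cols = [self.response, *self.categorical]
        cols += [s.covariate for s in self.smooths]
        if self.spatial:
            cols.append(self.spatial)
        return cols


# ---------------------------------------------------------------------------
# container types


@dataclass(frozen=True)
class SplineBasis:
    """B-spline basis with its difference penalty.

    ``basis`` is n x m with rows summing to one (partition of unity on the
    covariate range); ``penalty`` is the m x m positive-semidefinite
    difference penalty of order ``penalty_order`` with rank
    ``m - penalty_order``.
    """

    covariate: str
    degree: int
    knots: np.ndarray  # full knot vector incl. exterior knots
    basis: np.ndarray
    penalty: np.ndarray
    penalty_order: int

    @property
    def n_coef(self) -> int:
        return self.basis.shape[1]

    @property
    def penalty_rank(self) -> int:
        return self.n_coef - self.penalty_order

    def evaluate(self, x) -> np.ndarray:
        """Evaluate the basis at new covariate values (clipped to the range)."""
        return _bspline_design(np.asarray(x, dtype=float), self.knots, self.degree)


@dataclass(frozen=True)
class MRFStructure:
    """Intrinsic-MRF precision over regions.

    ``precision`` is the graph Laplacian: diagonal = neighbour counts,
    off-diagonal = -1 for adjacent pairs. Rows sum to zero and the rank is
    S minus the number of connected components, so the quadratic form
    ``b' K b`` equals the sum of squared differences over adjacent pairs.
    """

    regions: tuple
    edges: tuple[tuple, ...]
    precision: np.ndarray
    n_components: int

    @property
    def n_regions(self) -> int:
        return len(self.regions)

    @property
    def rank(self) -> int:
        return self.n_regions - self.n_components

    def index_of(self, labels) -> np.ndarray:
        lookup = {r: i for i, r in enumerate(self.regions)}
        try:
            return np.array([lookup[r] for r in labels], dtype=int)
        except KeyError as exc:
            raise ValueError(f"region not in adjacency structure: {exc}") from exc


@dataclass(frozen=True)
class DesignBlocks:
    """All assembled design blocks, conformable with a response vector.

    eta = W @ gamma + sum_j basis_j @ beta_j + Z_spat @ f_spat
    """

    y: np.ndarray
    fixed: np.ndarray  # n x q, first column = intercept
    fixed_names: tuple[str, ...]
    smooths: tuple[SplineBasis, ...]
    spatial: MRFStructure | None
    region_index: np.ndarray | None  # n, integer codes into spatial.regions

    @property
    def n_obs(self) -> int:
        return self.y.shape[0]

    @property
    def n_fixed(self) -> int:
        return self.fixed.shape[1]

    @property
    def n_penalized_blocks(self) -> int:
        return len(self.smooths) + (1 if self.spatial is not None else 0)

    def spatial_incidence(self) -> np.ndarray:
        """One-hot n x S incidence matrix of observations onto regions."""
        if self.spatial is None:
            raise ValueError("model has no spatial term")
        Z = np.zeros((self.n_obs, self.spatial.n_regions))
        Z[np.arange(self.n_obs), self.region_index] = 1.0
        return Z

    def linear_predictor(self, gamma, betas, f_spat=None) -> np.ndarray:
        eta = self.fixed @ gamma
        for sb, beta in zip(self.smooths, betas):
            eta = eta + sb.basis @ beta
        if f_spat is not None:
            eta = eta + f_spat[self.region_index]
        return eta


# ---------------------------------------------------------------------------
# B-spline basis


def _bspline_design(x: np.ndarray, knots: np.ndarray, degree: int) -> np.ndarray:
    # clip to the base interval so boundary values (and prediction points
    # slightly outside the training range) evaluate cleanly
    lo, hi = knots[degree], knots[-degree - 1]
    xc = np.clip(x, lo, hi)
    return BSpline.design_matrix(xc, knots, degree, extrapolate=False).toarray()


def build_bspline_basis(
    x,
    degree: int = 3,
    n_knots: int = 20,
    penalty_order: int = 2,
    covariate: str = "x",
) -> SplineBasis:
    """Equidistant-knot B-spline basis with a difference penalty.

    ``n_knots`` interior knots are placed equally spaced on
    ``[min(x), max(x)]`` (both endpoints included) and extended by
    ``degree`` knots on each side at the same spacing, yielding
    ``m = n_knots - 1 + degree`` basis functions. Every basis row sums to
    one and entries are nonnegative.
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 1 or x.size < 2:
        raise ValueError("x must be a 1-d array with at least 2 values")
    if degree < 1:
        raise ValueError("degree must be >= 1")
    if n_knots < 2:
        raise ValueError("need at least 2 interior knots")
    lo, hi = float(np.min(x)), float(np.max(x))
    if hi <= lo:
        raise DegenerateCovariateError(f"covariate {covariate!r} is constant")
    step = (hi - lo) / (n_knots - 1)
    knots = lo + step * np.arange(-degree, n_knots + degree)
    B = _bspline_design(x, knots, degree)
    m = B.shape[1]
    K = build_difference_penalty(m, penalty_order)
    return SplineBasis(covariate, degree, knots, B, K, penalty_order)


def build_difference_penalty(m: int, order: int = 2) -> np.ndarray:
    """Penalty K = D'D with D the ``order``-th difference operator.

    K is positive semidefinite with rank ``m - order``; its null space is
    spanned by polynomial coefficient sequences of degree < order, so an
    order-2 penalty leaves linear trends unpenalized (random-walk-2 prior).
    """
    if order < 1:
        raise ValueError("penalty order must be >= 1")
    if m <= order:
        raise ValueError(f"basis size {m} must exceed penalty order {order}")
    D = np.diff(np.eye(m), n=order, axis=0)
    return D.T @ D


# ---------------------------------------------------------------------------
# MRF precision


def build_mrf_precision(
    edges,
    regions,
    connect_islands: bool = False,
    centroids: dict | None = None,
) -> MRFStructure:
    """Graph-Laplacian precision of the intrinsic MRF prior over regions.

    ``edges`` is an iterable of undirected region pairs. Isolated regions
    make the intrinsic prior improper per extra component; with
    ``connect_islands=True`` each island is joined to its nearest region by
    centroid distance (requires ``centroids``) with a logged warning.
    """
    regions = tuple(regions)
    index = {r: i for i, r in enumerate(regions)}
    edge_set: set[tuple] = set()
    for a, b in edges:
        if a not in index or b not in index:
            raise ValueError(f"edge ({a!r}, {b!r}) references unknown region")
        if a == b:
            raise ValueError(f"self-loop on region {a!r}")
        edge_set.add((a, b) if index[a] < index[b] else (b, a))

    graph = nx.Graph()
    graph.add_nodes_from(regions)
    graph.add_edges_from(edge_set)

    islands = [r for r in regions if graph.degree(r) == 0]
    if islands and connect_islands:
        if centroids is None:
            raise ValueError("island connection requires region centroids")
        for r in islands:
            others = [s for s in regions if s != r]
            cx = np.asarray(centroids[r], dtype=float)
            nearest = min(
                others, key=lambda s: float(np.sum((np.asarray(centroids[s]) - cx) ** 2))
            )
            logger.warning("region %r has no neighbours; linking to nearest region %r", r, nearest)
            pair = (r, nearest) if index[r] < index[nearest] else (nearest, r)
            edge_set.add(pair)
            graph.add_edge(*pair)
    elif islands:
        logger.warning("isolated regions (improper per-component prior): %s", islands)

    S = len(regions)
    K = np.zeros((S, S))
    for a, b in edge_set:
        i, j = index[a], index[b]
        K[i, j] -= 1.0
        K[j, i] -= 1.0
        K[i, i] += 1.0
        K[j, j] += 1.0
    n_comp = nx.number_connected_components(graph)
    return MRFStructure(regions, tuple(sorted(edge_set, key=lambda e: (index[e[0]], index[e[1]]))), K, n_comp)


def read_edge_list(path) -> list[tuple[str, str]]:
    """Read a two-column whitespace/comma-delimited region edge list."""
    edges = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.replace(",", " ").split()
            if len(parts) != 2:
                raise ValueError(f"malformed edge line: {line!r}")
            edges.append((parts[0], parts[1]))
    return edges


def write_edge_list(edges, path) -> None:
    with open(path, "w") as fh:
        for a, b in edges:
            fh.write(f"{a}\t{b}\n")


def adjacency_from_polygons(polygons: dict) -> list[tuple]:
    """Derive region adjacency from shapely polygons by shared-boundary test.

    Two regions are neighbours when their geometries intersect in more than
    a point (shared boundary). Returns a sorted edge list so the derived
    adjacency can be written out and reused bit-exactly.
    """
    names = sorted(polygons)
    edges = []
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            inter = polygons[a].intersection(polygons[b])
            if not inter.is_empty and inter.length > 0:
                edges.append((a, b))
    return edges


# ---------------------------------------------------------------------------
# assembly


def complete_cases(data: pd.DataFrame, columns) -> pd.DataFrame:
    """Drop rows with missing values in any model column, logging the count."""
    sub = data[list(columns)]
    keep = sub.notna().all(axis=1)
    dropped = int((~keep).sum())
    if dropped:
        logger.info("complete-case filter dropped %d of %d rows", dropped, len(data))
    if keep.sum() == 0:
        raise ValueError("no complete cases remain")
    return data.loc[keep].reset_index(drop=True)


def _dummy_code(data: pd.DataFrame, categorical: dict[str, str]):
    n = len(data)
    cols = [np.ones(n)]
    names = ["intercept"]
    for var, ref in categorical.items():
        values = data[var].astype(str)
        levels = [lv for lv in pd.unique(values) if lv != str(ref)]
        if str(ref) not in set(values) :
            logger.warning("reference level %r of %r not observed", ref, var)
        for lv in sorted(levels):
            cols.append((values == lv).to_numpy(dtype=float))
            names.append(f"{var}[{lv}]")
    return np.column_stack(cols), tuple(names)


def assemble_design(
    data: pd.DataFrame,
    spec: ModelSpec,
    adjacency: MRFStructure | None = None,
    drop_incomplete: bool = True,
) -> DesignBlocks:
    """Assemble fixed, smooth and spatial blocks against an observation table.

    ``adjacency`` must be supplied when the model spec has a spatial term;
    every observed region label must appear in it.
    """
    missing = [c for c in spec.columns() if c not in data.columns]
    if missing:
        raise ValueError(f"data is missing model columns: {missing}")
    if drop_incomplete:
        data = complete_cases(data, spec.columns())
    y = data[spec.response].to_numpy(dtype=float)

    W, names = _dummy_code(data, spec.categorical)
    rank = np.linalg.matrix_rank(W)
    if rank < W.shape[1]:
        # point at the columns whose removal restores full rank
        offending = []
        keep = list(range(W.shape[1]))
        for j in range(W.shape[1] - 1, 0, -1):
            trial = [k for k in keep if k != j]
            if np.linalg.matrix_rank(W[:, trial]) == rank:
                offending.append(names[j])
                keep = trial
                if len(keep) == rank:
                    break
        raise CollinearityError(f"fixed-effects matrix rank deficient; offending columns: {offending}")

    smooths = tuple(
        build_bspline_basis(
            data[s.covariate].to_numpy(dtype=float),
            degree=s.degree,
            n_knots=s.n_knots,
            penalty_order=s.penalty_order,
            covariate=s.covariate,
        )
        for s in spec.smooths
    )

    region_index = None
    if spec.spatial is not None:
        if adjacency is None:
            raise ValueError("spatial term requires an adjacency structure")
        region_index = adjacency.index_of(data[spec.spatial])
    return DesignBlocks(y, W, names, smooths, adjacency if spec.spatial else None, region_index)
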