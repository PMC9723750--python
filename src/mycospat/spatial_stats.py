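"""Spatial statistics: bivariate pair correlation, kriging, sample selection.

The spatial side of the analysis: classifying plant-species pairs as
aggregated or segregated via the bivariate pair correlation function
g_ij(r) against toroidal-shift null envelopes, interpolating soil
covariates by ordinary kriging under a fitted variogram model, pooling
the nearest background soils around each plant individual, and thinning
conspecific individuals closer than a minimum distance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import lu_factor, lu_solve
from scipy.optimize import least_squares
from scipy.spatial import cKDTree
from scipy.spatial.distance import cdist, pdist, squareform

from .synthetic_forest import OTUTable, PlantCensus

__all__ = [
    "PairCorrelationEstimate",
    "CooccurrenceClass",
    "VariogramModel",
    "bivariate_pcf",
    "classify_cooccurrence",
    "fit_variogram",
    "ordinary_krige",
    "pool_nearest_soils",
    "thin_by_distance",
]


@dataclass
class PairCorrelationEstimate:
    pair: tuple[str, str]
    r: np.ndarray
    g: np.ndarray
    lower: np.ndarray | None
    upper: np.ndarray | None
    n_points: tuple[int, int]
    bandwidth: float
    correction: str = "translation"
    unreliable: np.ndarray | None = None  # r values where kernel support crosses 0


@dataclass
class CooccurrenceClass:
    pair: tuple[str, str]
    cls: str  # aggregated | segregated | none
    statistic: float
    null_quantiles: tuple[float, float]
    rank: int
    n_sim: int
    rule: str = "mean-g over r_range vs toroidal-shift envelope"


@dataclass
class VariogramModel:
    """Semivariogram model gamma(h) = nugget + psill * structure(h / range)."""

    family: str  # spherical | exponential
    nugget: float
    psill: float
    range_m: float

    def __post_init__(self) -> None:
        if self.family not in ("spherical", "exponential"):
            raise ValueError(f"unknown variogram family {self.family!r}")
        if self.nugget < 0 or self.psill < 0 or self.range_m <= 0:
            raise ValueError("require nugget >= 0, psill >= 0, range > 0")

    def __call__(self, h: np.ndarray) -> np.ndarray:
        h = np.asarray(h, dtype=float)
        if self.family == "spherical":
            hr = np.clip(h / self.range_m, 0, 1)
            struct = 1.5 * hr - 0.5 * hr**3
        else:  # exponential with practical range = range_m
            struct = 1 - np.exp(-3 * h / self.range_m)
        gamma = self.nugget + self.psill * struct
        return np.where(h == 0, 0.0, gamma)


def _default_bandwidth(census: PlantCensus, i: str, j: str) -> float:
    """Stoyan's rule of thumb: h = 0.15 / sqrt(lambda), on the denser pattern."""
    lam = max(len(census.points(i)), len(census.points(j))) / census.area
    return 0.15 / np.sqrt(lam)


def bivariate_pcf(
    census: PlantCensus,
    i: str,
    j: str,
    r_grid: np.ndarray | None = None,
    bandwidth: float | None = None,
    correction: str = "translation",
) -> PairCorrelationEstimate:
    """Kernel estimate of the bivariate pair correlation function g_ij(r).

    g_ij(r) = sum over cross pairs of k_h(r - d_pq) e(p, q)
              / (2 pi r lambda_i lambda_j |W|)

    with Epanechnikov kernel k_h and translation edge correction
    e(p, q) = |W| / |W intersect W_(p-q)|.  Values of 1 indicate
    independence; > 1 aggregation at that distance, < 1 segregation.
    Grid points with r <= bandwidth (kernel support crossing zero) are
    flagged as unreliable but kept.
    """
    if correction != "translation":
        raise ValueError("only the translation edge correction is implemented")
    pts_i, pts_j = census.points(i), census.points(j)
    if len(pts_i) < 2 or len(pts_j) < 2:
        raise ValueError(f"both species need >= 2 individuals ({i}: {len(pts_i)}, {j}: {len(pts_j)})")
    w, h_win = census.window
    if r_grid is None:
        r_grid = np.linspace(1.0, min(w, h_win) / 4, 50)
    r_grid = np.asarray(r_grid, dtype=float)
    if (r_grid <= 0).any() or (np.diff(r_grid) <= 0).any():
        raise ValueError("r grid must be strictly increasing and positive")
    if r_grid.max() >= min(w, h_win) / 2:
        raise ValueError("max(r_grid) must be below half the shorter window side")
    if bandwidth is None:
        bandwidth = _default_bandwidth(census, i, j)

    area = census.area
    lam_i = len(pts_i) / area
    lam_j = len(pts_j) / area
    diff = pts_i[:, None, :] - pts_j[None, :, :]  # (ni, nj, 2)
    d = np.hypot(diff[..., 0], diff[..., 1]).ravel()
    # translation correction per pair
    e = area / ((w - np.abs(diff[..., 0])) * (h_win - np.abs(diff[..., 1])))
    e = e.ravel()
    # Epanechnikov kernel, bandwidth h: k(u) = 0.75/h (1 - (u/h)^2), |u| < h
    u = (r_grid[:, None] - d[None, :]) / bandwidth
    k = np.where(np.abs(u) < 1, 0.75 / bandwidth * (1 - u**2), 0.0)
    num = k @ e
    g = num / (2 * np.pi * r_grid * lam_i * lam_j * area)
    unreliable = r_grid <= bandwidth
    return PairCorrelationEstimate(
        (i, j), r_grid, g, None, None, (len(pts_i), len(pts_j)), bandwidth,
        correction, unreliable,
    )


def _toroidal_shift(pts: np.ndarray, window: tuple[float, float], rng) -> np.ndarray:
    w, h = window
    dx, dy = rng.uniform(0, w), rng.uniform(0, h)
    out = pts.copy()
    out[:, 0] = (out[:, 0] + dx) % w
    out[:, 1] = (out[:, 1] + dy) % h
    return out


def classify_cooccurrence(
    census: PlantCensus,
    i: str,
    j: str,
    r_range: tuple[float, float] = (0.0, 30.0),
    n_sim: int = 199,
    alpha: float = 0.05,
    seed: int | np.random.Generator = 0,
    bandwidth: float | None = None,
) -> CooccurrenceClass:
    """Classify a species pair as aggregated, segregated, or neither.

    The summary statistic T is the mean of g_ij(r) over ``r_range``.  A
    null distribution of T is built by toroidally shifting one pattern
    relative to the other ``n_sim`` times (which preserves each pattern's
    own structure while destroying cross-correlation).  The pair is
    aggregated when the observed T exceeds the (1 - alpha) null quantile,
    segregated when it falls below the alpha quantile, and "none"
    otherwise.  The pair is ordered canonically first, so the call is
    symmetric in (i, j) under the same seed.
    """
    if n_sim < 19:
        raise ValueError("n_sim < 19 gives envelopes too coarse for alpha = 0.05")
    i, j = sorted((i, j))
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    lo, hi = r_range
    r_grid = np.linspace(max(lo, 1.0), hi, 30)

    def summary(c: PlantCensus) -> float:
        est = bivariate_pcf(c, i, j, r_grid=r_grid, bandwidth=bandwidth)
        return float(est.g.mean())

    t_obs = summary(census)
    pts_j = census.points(j)
    base_i = census.table[census.table["species"] == i]
    t_null = np.empty(n_sim)
    for s in range(n_sim):
        shifted = _toroidal_shift(pts_j, census.window, rng)
        tbl = pd.concat([
            base_i,
            pd.DataFrame({
                "individual_id": [f"null{k}" for k in range(len(shifted))],
                "species": j, "dbh": 1.0,
                "x": shifted[:, 0], "y": shifted[:, 1],
            }),
        ], ignore_index=True)
        t_null[s] = summary(PlantCensus(tbl, census.window))

    q_lo = float(np.quantile(t_null, alpha))
    q_hi = float(np.quantile(t_null, 1 - alpha))
    rank = int((t_null < t_obs).sum())
    if t_obs > q_hi:
        cls = "aggregated"
    elif t_obs < q_lo:
        cls = "segregated"
    else:
        cls = "none"
    return CooccurrenceClass((i, j), cls, t_obs, (q_lo, q_hi), rank, n_sim)


def empirical_semivariogram(
    points: np.ndarray, values: np.ndarray, n_bins: int = 15, max_lag: float | None = None
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Matheron estimator on distance bins: gamma(h) = mean of (z_i - z_j)^2 / 2.

    Returns (bin centers, semivariances, pair counts); empty bins dropped.
    """
    points = np.asarray(points, dtype=float)
    values = np.asarray(values, dtype=float)
    d = pdist(points)
    dz2 = pdist(values[:, None], metric="sqeuclidean")
    if max_lag is None:
        max_lag = d.max() / 2
    edges = np.linspace(0, max_lag, n_bins + 1)
    centers, gammas, counts = [], [], []
    for b in range(n_bins):
        mask = (d > edges[b]) & (d <= edges[b + 1])
        n = int(mask.sum())
        if n == 0:
            continue
        centers.append((edges[b] + edges[b + 1]) / 2)
        gammas.append(dz2[mask].sum() / (2 * n))
        counts.append(n)
    return np.array(centers), np.array(gammas), np.array(counts)


def fit_variogram(
    points: np.ndarray,
    values: np.ndarray,
    n_bins: int = 15,
    max_lag: float | None = None,
    family: str = "spherical",
) -> VariogramModel:
    """Fit a variogram model to the empirical semivariogram by weighted least squares.

    Weights N(h)/h^2 favour short lags, where kriging accuracy matters
    most.  An all-constant input yields a degenerate pure-nugget-zero
    model with a warning.
    """
    points = np.asarray(points, dtype=float)
    values = np.asarray(values, dtype=float)
    if len(points) < 30:
        raise ValueError("need >= 30 points to fit a variogram")
    if values.std() == 0:
        warnings.warn("all values equal; returning a degenerate pure-nugget model")
        return VariogramModel(family, 0.0, 0.0, 1.0)
    h, gamma, n = empirical_semivariogram(points, values, n_bins, max_lag)
    wts = np.sqrt(n) / h  # residuals scaled by sqrt(N(h))/h -> squared weight N/h^2
    var = values.var()
    h_max = h.max()

    def resid(theta):
        nug, psill, rng_m = theta
        model = VariogramModel(family, max(nug, 0), max(psill, 1e-12), max(rng_m, 1e-6))
        return wts * (model(h) - gamma)

    x0 = np.array([gamma[0] * 0.5, var, h_max / 2])
    sol = least_squares(
        resid, x0, bounds=([0, 1e-12, 1e-6], [var * 3 + 1e-9, var * 5, h_max * 3])
    )
    nug, psill, rng_m = sol.x
    return VariogramModel(family, float(nug), float(psill), float(rng_m))


def ordinary_krige(
    points: np.ndarray,
    values: np.ndarray,
    model: VariogramModel,
    targets: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Ordinary kriging predictions and variances at target locations.

    Solves, per target, the system [Gamma 1; 1' 0][w; mu] = [gamma0; 1];
    the weights sum to one (best linear unbiased predictor) and the
    kriging variance is w'gamma0 + mu.  Duplicate data locations are
    averaged with a warning to keep the system nonsingular.
    """
    points = np.asarray(points, dtype=float)
    values = np.asarray(values, dtype=float)
    targets = np.atleast_2d(np.asarray(targets, dtype=float))

    # deduplicate coincident data points by averaging their values
    uniq, inverse = np.unique(points.round(10), axis=0, return_inverse=True)
    if len(uniq) < len(points):
        warnings.warn(f"averaged {len(points) - len(uniq)} duplicate data location(s)")
        agg = np.zeros(len(uniq))
        cnt = np.zeros(len(uniq))
        np.add.at(agg, inverse, values)
        np.add.at(cnt, inverse, 1)
        points, values = uniq, agg / cnt

    n = len(points)
    gamma_dd = model(squareform(pdist(points)))
    A = np.zeros((n + 1, n + 1))
    A[:n, :n] = gamma_dd
    A[:n, n] = 1.0
    A[n, :n] = 1.0
    lu = lu_factor(A)
    gamma_t0 = model(cdist(points, targets))  # (n, m)
    rhs = np.vstack([gamma_t0, np.ones(targets.shape[0])])
    sol = lu_solve(lu, rhs)
    wsum = sol[:n].sum(axis=0)
    if not np.allclose(wsum, 1.0, atol=1e-10):
        raise RuntimeError("kriging weights do not sum to 1")
    preds = values @ sol[:n]
    variances = np.einsum("im,im->m", sol[:n], gamma_t0) + sol[n]
    variances = np.maximum(variances, 0.0)
    return preds, variances


def pool_nearest_soils(
    individual_xy: np.ndarray,
    soil_table: OTUTable,
    k: int = 3,
) -> pd.Series:
    """Sum the OTU counts of the k nearest background-soil samples.

    With soils rarefied to a common depth, the pooled community has
    exactly k x depth reads (k = 3 at 4100 gives 12,300).  Distance ties
    at the k-th neighbour are broken by sample-id lexicographic order so
    runs are reproducible.
    """
    n_soils = soil_table.counts.shape[0]
    if k > n_soils:
        raise ValueError(f"k = {k} exceeds the {n_soils} available soil samples")
    xy = soil_table.metadata[["x", "y"]].to_numpy(dtype=float)
    d = np.hypot(*(xy - np.asarray(individual_xy, dtype=float)).T)
    order = sorted(range(n_soils), key=lambda m: (round(d[m], 9), str(soil_table.counts.index[m])))
    chosen = soil_table.counts.index[order[:k]]
    return soil_table.counts.loc[chosen].sum(axis=0)


def thin_by_distance(
    individuals: pd.DataFrame,
    min_dist: float = 30.0,
    seed: int | np.random.Generator = 0,
) -> pd.DataFrame:
    """Thin conspecific individuals so no two retained ones are < min_dist apart.

    Individuals closer than ``min_dist`` are linked into proximity
    clusters (connected components of the < min_dist graph); one
    individual per cluster is retained, chosen uniformly at random.
    Prevents nearby conspecifics from sharing the same pooled background
    soils.
    """
    if min_dist <= 0:
        raise ValueError("min_dist must be positive")
    if individuals.empty:
        return individuals.copy()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    xy = individuals[["x", "y"]].to_numpy(dtype=float)
    n = len(xy)
    # union-find over the proximity graph
    parent = list(range(n))

    def find(a):
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    pairs = cKDTree(xy).query_pairs(min_dist, output_type="ndarray")
    # query_pairs uses d <= r; the rule is strict (< min_dist), so filter
    for a, b in pairs:
        if np.hypot(*(xy[a] - xy[b])) < min_dist:
            ra, rb = find(a), find(b)
            if ra != rb:
                parent[ra] = rb
    clusters: dict[int, list[int]] = {}
    for m in range(n):
        clusters.setdefault(find(m), []).append(m)
    keep = sorted(int(rng.choice(members)) for members in clusters.values())
    return individuals.iloc[keep]
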