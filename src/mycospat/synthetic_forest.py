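"""Synthetic forests and root mycobiomes with known ground truth.

Generates marked point patterns of plant individuals (Thomas cluster
processes with planted between-species aggregation or segregation),
spatially autocorrelated soil covariate fields, and OTU count tables in
which host identity, soil environment, and pair-level fungal guild signals
are planted with known strength — so every downstream stage of the
analysis (spatial classification, host-specificity testing, modified
relative abundance, predictive modeling) can be tested for recovery of a
known truth.

The generator emulates the study conditions of a censused 50-ha
(1000 m x 500 m) subtropical forest plot: ~39 host species, root-tip
samples rarefied to 3000 reads and bulk-soil samples to 4100, a minority
of OTUs assignable to the plant-pathogen / ectomycorrhizal / saprotroph
guilds, and spatial pair relationships planted as aggregated, segregated,
or independent.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .community_stats import rarefy

__all__ = [
    "SimulationConfig",
    "PlantCensus",
    "EnvSurfaces",
    "OTUTable",
    "simulate_plant_map",
    "classify_stage",
    "classify_abundance_group",
    "simulate_env_surfaces",
    "simulate_otu_tables",
]

ROOT_DEPTH = 3000
SOIL_DEPTH = 4100


@dataclass
class SimulationConfig:
    """Parameters of one synthetic forest.

    ``pair_relationships`` maps species pairs to "aggregated",
    "segregated", or "independent".  Aggregated pairs share Thomas-process
    parent locations; segregated pairs use hard-core displaced parents.
    ``host_effect`` >= 0 scales the concentration of host-specific fungal
    centroids (0 = one common centroid, no host signal).  ``guild_signal``
    >= 0 plants excess shared pathogens in segregated pairs and excess
    unique ectomycorrhizal OTUs in aggregated pairs.
    """

    window_width_m: float = 1000.0
    window_height_m: float = 500.0
    n_species: int = 39
    individuals_per_species: int = 80
    parents_per_species: int = 25
    cluster_sd_m: float = 12.0
    hardcore_dist_m: float = 60.0
    pair_relationships: dict[tuple[int, int], str] = field(default_factory=dict)
    host_effect: float = 5.0
    guild_signal: float = 4.0
    n_otus: int = 300
    root_depth: int = ROOT_DEPTH
    soil_depth: int = SOIL_DEPTH
    samples_per_species: int = 8
    n_soil_samples: int = 60
    pathogen_fraction: float = 0.10
    ecm_fraction: float = 0.10
    saprotroph_fraction: float = 0.20
    dbh_meanlog: float = 1.5
    dbh_sdlog: float = 0.8
    env_range_m: float = 150.0
    env_sill: float = 1.0
    env_nugget: float = 0.0
    env_grid_m: float = 25.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.window_width_m <= 0 or self.window_height_m <= 0:
            raise ValueError("window dimensions must be positive")
        if self.root_depth < 1 or self.soil_depth < 1:
            raise ValueError("read depths must be >= 1")
        if self.n_species < 1:
            raise ValueError("need at least one species")
        for (i, j), rel in self.pair_relationships.items():
            if rel not in ("aggregated", "segregated", "independent"):
                raise ValueError(f"unknown relationship {rel!r} for pair ({i},{j})")
            for s in (i, j):
                if not (0 <= s < self.n_species):
                    raise ValueError(f"pair ({i},{j}) references invalid species {s}")

    def species_names(self) -> list[str]:
        return [f"sp{i:02d}" for i in range(self.n_species)]


@dataclass
class PlantCensus:
    """Marked point pattern: mapped plant individuals in a rectangular window."""

    table: pd.DataFrame  # columns: individual_id, species, dbh, x, y
    window: tuple[float, float]  # (width, height), origin at (0, 0)

    def __post_init__(self) -> None:
        w, h = self.window
        t = self.table
        if ((t["x"] < 0) | (t["x"] > w) | (t["y"] < 0) | (t["y"] > h)).any():
            raise ValueError("census points outside the window")
        if (t["dbh"] < 1).any():
            raise ValueError("census contains DBH < 1 cm")

    def points(self, species: str) -> np.ndarray:
        sub = self.table[self.table["species"] == species]
        return sub[["x", "y"]].to_numpy(dtype=float)

    def species_list(self) -> list[str]:
        return sorted(self.table["species"].unique())

    @property
    def area(self) -> float:
        return self.window[0] * self.window[1]


@dataclass
class EnvSurfaces:
    """Gridded soil covariate fields with known variogram parameters."""

    grid_xy: np.ndarray  # (n_cells, 2) cell centers
    fields: pd.DataFrame  # one column per covariate, row per cell
    true_range: float
    true_sill: float
    true_nugget: float

    def value_at(self, covariate: str, xy: np.ndarray) -> np.ndarray:
        """Nearest-cell lookup of a covariate at arbitrary coordinates."""
        from scipy.spatial import cKDTree

        _, idx = cKDTree(self.grid_xy).query(np.atleast_2d(xy))
        return self.fields[covariate].to_numpy()[idx]


@dataclass
class OTUTable:
    """Integer count matrix (samples x OTUs) with per-sample metadata."""

    counts: pd.DataFrame
    metadata: pd.DataFrame  # index = sample ids; columns incl. species, x, y, sample_type, dbh

    def __post_init__(self) -> None:
        if not self.counts.index.equals(self.metadata.index):
            raise ValueError("counts and metadata have mismatched sample ids")

    def relative_abundance(self) -> pd.DataFrame:
        tot = self.counts.sum(axis=1)
        return self.counts.div(tot, axis=0)

    def subset_species(self, species: str) -> pd.DataFrame:
        ids = self.metadata.index[self.metadata["species"] == species]
        return self.counts.loc[ids]


def classify_stage(dbh: float) -> str:
    """Developmental stage from diameter at breast height (cm).

    Saplings have DBH <= 5 cm, adults >= 10 cm, juveniles in between;
    the census convention puts both boundaries with the outer classes.
    """
    if dbh < 1:
        raise ValueError(f"DBH {dbh} below census minimum of 1 cm")
    if dbh <= 5:
        return "sapling"
    if dbh >= 10:
        return "adult"
    return "juvenile"


def classify_abundance_group(relative_abundance: float) -> str:
    """Abundance group of a plant species: H (>=1%), M (0.1-1%), L (<=0.1%)."""
    if not (0 < relative_abundance <= 1):
        raise ValueError(f"relative abundance {relative_abundance} outside (0, 1]")
    pct = relative_abundance * 100
    if pct >= 1:
        return "H"
    if pct <= 0.1:
        return "L"
    return "M"


def _aggregation_components(config: SimulationConfig) -> list[set[int]]:
    """Connected components of the aggregated-pair graph (shared parents)."""
    comp = {i: {i} for i in range(config.n_species)}
    for (i, j), rel in config.pair_relationships.items():
        if rel == "aggregated" and comp[i] is not comp[j]:
            merged = comp[i] | comp[j]
            for k in merged:
                comp[k] = merged
    seen: list[set[int]] = []
    for c in comp.values():
        if c not in seen:
            seen.append(c)
    return seen


def simulate_plant_map(config: SimulationConfig) -> PlantCensus:
    """Realize each species as a Thomas cluster process with planted pair structure.

    Species connected by aggregated pairs share one parent point set;
    parent sets of segregated pairs are kept at least ``hardcore_dist_m``
    apart by rejection sampling.  Offspring are Gaussian-displaced around a
    uniformly chosen parent and reflected into the window; DBH is lognormal
    truncated below at 1 cm.
    """
    rng = np.random.default_rng(config.seed)
    w, h = config.window_width_m, config.window_height_m
    comps = _aggregation_components(config)
    comp_of = {s: k for k, c in enumerate(comps) for s in c}

    seg_between: set[tuple[int, int]] = set()
    for (i, j), rel in config.pair_relationships.items():
        if rel == "segregated":
            a, b = comp_of[i], comp_of[j]
            if a == b:
                raise ValueError(
                    f"pair ({i},{j}) is segregated but linked by aggregation"
                )
            seg_between.add((min(a, b), max(a, b)))

    # Parent sets per component, honouring hard-core constraints between
    # components that contain a segregated pair.
    parent_sets: list[np.ndarray] = []
    for k in range(len(comps)):
        constrained = [
            parent_sets[m] for m in range(k)
            if (min(m, k), max(m, k)) in seg_between
        ]
        pts = np.empty((0, 2))
        attempts = 0
        while len(pts) < config.parents_per_species:
            cand = rng.uniform([0, 0], [w, h], size=(1, 2))
            ok = all(
                np.min(np.hypot(*(cand - other).T)) >= config.hardcore_dist_m
                for other in constrained if len(other)
            )
            if ok:
                pts = np.vstack([pts, cand])
            attempts += 1
            if attempts > 10000 * config.parents_per_species:
                raise RuntimeError(
                    "could not place parents under hard-core constraints; "
                    "reduce hardcore_dist_m or parents_per_species"
                )
        parent_sets.append(pts)

    rows = []
    ind = 0
    for s, name in enumerate(config.species_names()):
        parents = parent_sets[comp_of[s]]
        n = config.individuals_per_species
        if n < 1:
            raise ValueError(f"species {name} realized with 0 individuals")
        which = rng.integers(0, len(parents), size=n)
        offsets = rng.normal(0.0, config.cluster_sd_m, size=(n, 2))
        xy = parents[which] + offsets
        # reflect into the window
        xy[:, 0] = np.abs(xy[:, 0]) % (2 * w)
        xy[:, 0] = np.where(xy[:, 0] > w, 2 * w - xy[:, 0], xy[:, 0])
        xy[:, 1] = np.abs(xy[:, 1]) % (2 * h)
        xy[:, 1] = np.where(xy[:, 1] > h, 2 * h - xy[:, 1], xy[:, 1])
        dbh = rng.lognormal(config.dbh_meanlog, config.dbh_sdlog, size=n)
        dbh = np.maximum(dbh, 1.0)
        for k in range(n):
            rows.append((f"ind{ind:05d}", name, dbh[k], xy[k, 0], xy[k, 1]))
            ind += 1
    table = pd.DataFrame(rows, columns=["individual_id", "species", "dbh", "x", "y"])
    return PlantCensus(table, (w, h))


def _spherical_cov(dists: np.ndarray, rng_m: float, sill: float) -> np.ndarray:
    """Spherical covariance: sill * (1 - 1.5 h/a + 0.5 (h/a)^3) for h < a."""
    hr = np.clip(dists / rng_m, 0, 1)
    return sill * (1 - 1.5 * hr + 0.5 * hr**3)


def simulate_env_surfaces(
    config: SimulationConfig, covariates: tuple[str, ...] = ("soil_ph", "soil_n")
) -> EnvSurfaces:
    """Gaussian random fields with a spherical variogram on a regular grid.

    Each covariate is an independent draw with the configured range, sill
    (partial sill of the spherical structure), and nugget, so variogram
    fitting can be checked for parameter recovery against the truth.
    """
    if config.env_sill <= 0 and config.env_nugget <= 0:
        raise ValueError("need positive sill or nugget")
    if config.env_sill < 0 or config.env_range_m <= 0:
        raise ValueError("non-positive sill/range")
    rng = np.random.default_rng(config.seed + 7)
    w, h = config.window_width_m, config.window_height_m
    gx = np.arange(config.env_grid_m / 2, w, config.env_grid_m)
    gy = np.arange(config.env_grid_m / 2, h, config.env_grid_m)
    XX, YY = np.meshgrid(gx, gy)
    grid = np.column_stack([XX.ravel(), YY.ravel()])
    from scipy.spatial.distance import cdist

    d = cdist(grid, grid)
    cov = _spherical_cov(d, config.env_range_m, config.env_sill)
    cov += np.eye(len(grid)) * (config.env_nugget + 1e-10)
    L = np.linalg.cholesky(cov)
    fields = {c: L @ rng.standard_normal(len(grid)) for c in covariates}
    return EnvSurfaces(
        grid, pd.DataFrame(fields), config.env_range_m, config.env_sill,
        config.env_nugget,
    )


def _guild_table(config: SimulationConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Assign guild labels to OTUs; a small fraction gets two labels."""
    otus = [f"otu{k:04d}" for k in range(config.n_otus)]
    n = config.n_otus
    n_path = int(round(config.pathogen_fraction * n))
    n_ecm = int(round(config.ecm_fraction * n))
    n_sap = int(round(config.saprotroph_fraction * n))
    guilds = ["plant pathogen"] * n_path + ["ecm"] * n_ecm + ["saprotroph"] * n_sap
    guilds += [""] * (n - len(guilds))
    # ~2% of assigned OTUs receive a second guild (they are excluded from
    # guild sums downstream, mirroring ambiguous database annotations)
    out = []
    for otu, g in zip(otus, guilds):
        if g and rng.random() < 0.02:
            other = rng.choice([x for x in ("plant pathogen", "ecm", "saprotroph") if x != g])
            g = f"{g}|{other}"
        out.append((otu, g))
    return pd.DataFrame(out, columns=["otu_id", "guild"])


def simulate_otu_tables(
    census: PlantCensus,
    env_fields: EnvSurfaces | None,
    config: SimulationConfig,
) -> tuple[OTUTable, OTUTable, pd.DataFrame]:
    """Generate root-tip and bulk-soil OTU count tables plus a guild table.

    Each host species receives a Dirichlet centroid on the simplex whose
    separation from the common forest centroid is controlled by
    ``host_effect`` (0 collapses all hosts onto one centroid).  Root-tip
    samples are multinomial draws at the root depth around the host
    centroid; soil samples at the soil depth around a common soil centroid
    modulated by the environmental fields.  ``guild_signal`` plants the
    pair-level guild structure: segregated pairs share elevated pathogen
    OTUs, aggregated pairs get elevated ectomycorrhizal OTUs unique to
    each member.
    """
    if census.table.empty:
        raise ValueError("census is empty")
    rng = np.random.default_rng(config.seed + 13)
    n_otus = config.n_otus
    species = config.species_names()
    guilds = _guild_table(config, rng)
    single = guilds["guild"].where(~guilds["guild"].str.contains(r"\|"), "")
    pathogen_ids = np.flatnonzero((single == "plant pathogen").to_numpy())
    ecm_ids = np.flatnonzero((single == "ecm").to_numpy())

    base = rng.dirichlet(np.full(n_otus, 0.8))
    centroids = {}
    for s in species:
        if config.host_effect <= 0:
            centroids[s] = base.copy()
        else:
            # concentration inversely proportional to host_effect: larger
            # effect -> centroids farther from the common one
            conc = np.maximum(base * n_otus * 5.0 / config.host_effect, 1e-3)
            centroids[s] = rng.dirichlet(conc)

    # plant the pair-level guild signal into the centroids
    path_pool = list(pathogen_ids)
    ecm_pool = list(ecm_ids)
    unassigned_pool = list(np.flatnonzero((guilds["guild"] == "").to_numpy()))
    step = config.guild_signal * 0.02
    boost = {s: 0.0 for s in species}
    for (i, j), rel in sorted(config.pair_relationships.items()):
        a, b = species[i], species[j]
        if rel == "segregated" and path_pool:
            # both members recruit the same pathogen -> shared core OTU
            otu = path_pool.pop(0)
            for s in (a, b):
                centroids[s][otu] += step
                boost[s] += step
        elif rel == "aggregated" and len(ecm_pool) >= 2:
            # each member recruits its own mutualist -> unique core OTUs;
            # a jointly elevated unassigned OTU balances the pairwise
            # community overlap against the segregated pairs' shared
            # pathogen, so the planted contrast is in guild identity, not
            # in community distance
            for s in (a, b):
                otu = ecm_pool.pop(0)
                centroids[s][otu] += step
                boost[s] += step
            if unassigned_pool:
                otu = unassigned_pool.pop(0)
                for s in (a, b):
                    centroids[s][otu] += step
                    boost[s] += step
    # Equalize the total planted mass across species with filler boosts on
    # unassigned OTUs, so the guild signal changes guild composition
    # without making the overall community divergence of planted species a
    # shortcut for telling pair classes apart.
    unassigned_ids = np.array(unassigned_pool, dtype=int)
    max_boost = max(boost.values()) if boost else 0.0
    for s in species:
        deficit = max_boost - boost[s]
        if deficit > 1e-12 and len(unassigned_ids):
            k = min(max(1, int(round(deficit / max(step, 1e-9)))), len(unassigned_ids))
            chosen = rng.choice(unassigned_ids, size=k, replace=False)
            centroids[s][chosen] += deficit / k
    for s in species:
        centroids[s] = centroids[s] / centroids[s].sum()

    otu_names = guilds["otu_id"].tolist()
    # root-tip samples: a subset of individuals per species
    root_rows, root_meta = [], []
    for s in species:
        sub = census.table[census.table["species"] == s]
        k = min(config.samples_per_species, len(sub))
        if k < 2:
            warnings.warn(f"species {s} has <2 individuals to sample")
        chosen = sub.iloc[rng.choice(len(sub), size=k, replace=False)]
        for _, row in chosen.iterrows():
            # sequence a deeper raw pool, then rarefy down to the target depth
            pool = rng.multinomial(2 * config.root_depth, centroids[s])
            counts = rarefy(pool, config.root_depth, rng)
            root_rows.append(counts)
            root_meta.append((f"root_{row.individual_id}", s, row.dbh, row.x, row.y, "root"))
    root_counts = pd.DataFrame(
        np.array(root_rows), columns=otu_names,
        index=[m[0] for m in root_meta],
    )
    root_md = pd.DataFrame(
        root_meta, columns=["sample_id", "species", "dbh", "x", "y", "sample_type"]
    ).set_index("sample_id").rename_axis(None)

    # soil samples on random locations, modulated by the environment
    w, h = census.window
    soil_xy = rng.uniform([0, 0], [w, h], size=(config.n_soil_samples, 2))
    soil_centroid = rng.dirichlet(np.full(n_otus, 1.0))
    beta = rng.normal(0, 0.5, size=n_otus)
    soil_rows, soil_meta = [], []
    for k in range(config.n_soil_samples):
        weights = soil_centroid.copy()
        if env_fields is not None:
            z = float(env_fields.value_at(env_fields.fields.columns[0], soil_xy[k])[0])
            weights = weights * np.exp(beta * z)
        weights = weights / weights.sum()
        pool = rng.multinomial(2 * config.soil_depth, weights)
        counts = rarefy(pool, config.soil_depth, rng)
        soil_rows.append(counts)
        soil_meta.append((f"soil{k:04d}", "", np.nan, soil_xy[k, 0], soil_xy[k, 1], "soil"))
    soil_counts = pd.DataFrame(
        np.array(soil_rows), columns=otu_names, index=[m[0] for m in soil_meta]
    )
    soil_md = pd.DataFrame(
        soil_meta, columns=["sample_id", "species", "dbh", "x", "y", "sample_type"]
    ).set_index("sample_id").rename_axis(None)

    return (
        OTUTable(root_counts, root_md),
        OTUTable(soil_counts, soil_md),
        guilds,
    )


def planted_demo_config(
    n_group: int = 6,
    n_independent: int = 3,
    seed: int = 0,
    **overrides,
) -> SimulationConfig:
    """Study-style forest with a rich set of planted pair relationships.

    Two aggregation guilds of ``n_group`` species each (all within-group
    pairs aggregated, sharing parents) plus ``n_independent`` spatially
    independent species; each grouped species is planted segregated from
    one independent species (cycled).  Pathogen and ectomycorrhizal pools
    are sized so every planted pair receives its guild signal.
    """
    n_species = 2 * n_group + n_independent
    rels: dict[tuple[int, int], str] = {}
    for base in (0, n_group):
        for i in range(base, base + n_group):
            for j in range(i + 1, base + n_group):
                rels[(i, j)] = "aggregated"
    for k, i in enumerate(range(2 * n_group)):
        c = 2 * n_group + (k % n_independent)
        rels[(i, c)] = "segregated"
    n_agg = n_group * (n_group - 1)  # both groups combined
    n_otus = overrides.pop("n_otus", 600)
    defaults = dict(
        n_species=n_species,
        n_otus=n_otus,
        parents_per_species=18,
        hardcore_dist_m=50.0,
        pathogen_fraction=max(0.10, 1.4 * (2 * n_group) / n_otus),
        ecm_fraction=max(0.12, 1.4 * 2 * n_agg / n_otus),
        pair_relationships=rels,
        seed=seed,
    )
    defaults.update(overrides)
    return SimulationConfig(**defaults)
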