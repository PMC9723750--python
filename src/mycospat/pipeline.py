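"""End-to-end orchestrator chaining all analysis stages.

Runs, in order: (optional) synthetic-forest generation, spatial
classification of species pairs, kriging-based background-soil
validation, core-OTU definition, host-specificity testing, MRA profiles,
predictive modeling, and guild contrasts.  Writes TSV result tables plus
a JSON run manifest; every stochastic stage draws an independent
substream from the master seed, so a rerun with the same seed reproduces
every output byte-for-byte.
"""

from __future__ import annotations

import itertools
import json
import time
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as mio
from .community_stats import (
    bh_fdr,
    bray_curtis,
    classify_host_specificity,
    cophenetic_distance,
    define_core_otus,
    gower_distance,
    permanova,
)
from .cooccurrence_model import build_features, compare_models, evaluate_predictors
from .mra import compute_mra, guild_contrast, guild_mra, species_relative_abundance, split_shared_unique
from .spatial_stats import (
    classify_cooccurrence,
    fit_variogram,
    ordinary_krige,
    pool_nearest_soils,
    thin_by_distance,
)
from .synthetic_forest import (
    OTUTable,
    PlantCensus,
    SimulationConfig,
    simulate_env_surfaces,
    simulate_otu_tables,
    simulate_plant_map,
)

__all__ = ["PipelineConfig", "run_pipeline", "random_tree", "random_traits"]

DEFAULT_CUTOFFS = tuple(round(0.1 * k, 1) for k in range(1, 10))


@dataclass
class PipelineConfig:
    """Every tunable of the end-to-end analysis, with the study defaults."""

    outdir: str = "results"
    cutoffs: tuple[float, ...] = DEFAULT_CUTOFFS
    mra_cutoffs: tuple[float, ...] = (0.5, 0.9)
    root_depth: int = 3000
    soil_depth: int = 4100
    alpha: float = 0.05
    n_perm: int = 999
    n_sim_envelopes: int = 199
    n_rep: int = 100
    n_trees: int = 1000
    min_dist_m: float = 30.0
    k_nearest_soils: int = 3
    min_replicates: int = 7
    seed: int = 0
    simulation: SimulationConfig | None = None

    def __post_init__(self) -> None:
        for name in ("root_depth", "soil_depth", "n_perm", "n_sim_envelopes",
                     "n_rep", "n_trees", "k_nearest_soils"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if any(not (0 < c <= 1) for c in self.cutoffs):
            raise ValueError("cutoffs must lie in (0, 1]")


def random_tree(species: list[str], rng: np.random.Generator) -> str:
    """Random binary tree with exponential branch lengths, as newick."""
    nodes = [f"{s}:{rng.exponential(1.0):.4f}" for s in species]
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        b = nodes.pop(j)
        a = nodes.pop(i)
        nodes.append(f"({a},{b}):{rng.exponential(1.0):.4f}")
    inner = nodes[0].rsplit(":", 1)[0]
    return inner + ";"


def random_traits(species: list[str], rng: np.random.Generator) -> pd.DataFrame:
    """Synthetic plant trait table: three numeric traits plus one categorical."""
    return pd.DataFrame(
        {
            "leaf_area": rng.lognormal(3, 0.5, len(species)),
            "wood_density": rng.normal(0.6, 0.1, len(species)),
            "max_height": rng.lognormal(2.5, 0.4, len(species)),
            "dispersal": rng.choice(["wind", "animal", "gravity"], len(species)),
        },
        index=species,
    )


def _pairs(species: list[str]) -> list[tuple[str, str]]:
    return list(itertools.combinations(sorted(species), 2))


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full analysis and write result tables plus a manifest.

    Returns the manifest dict.  When ``config.simulation`` is set, all
    inputs are generated synthetically; otherwise the caller must have
    placed census/OTU/guild/trait/tree files in ``outdir/inputs`` in the
    formats written by :mod:`mycospat.io`.
    """
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config": _config_dict(config), "stages": {}, "warnings": []}
    master = np.random.SeedSequence(config.seed)
    streams = {name: np.random.default_rng(s) for name, s in zip(
        ["simulate", "aux", "spatial", "krige", "specificity", "model", "thin"],
        master.spawn(7),
    )}

    def stage(name):
        t0 = time.perf_counter()
        manifest["stages"][name] = {"start": t0}
        return t0

    def done(name, t0, **info):
        manifest["stages"][name].update(
            wall_s=round(time.perf_counter() - t0, 3), **info
        )
        manifest["stages"][name].pop("start")

    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")

        # ---- inputs ------------------------------------------------------
        t0 = stage("inputs")
        if config.simulation is not None:
            sim = config.simulation
            census = simulate_plant_map(sim)
            env = simulate_env_surfaces(sim)
            root, soil, guilds = simulate_otu_tables(census, env, sim)
            mio.write_census(census, out / "census.tsv")
            mio.write_otu_table(root, out / "root_counts.tsv", out / "root_metadata.tsv")
            mio.write_otu_table(soil, out / "soil_counts.tsv", out / "soil_metadata.tsv")
            mio.write_guild_table(guilds, out / "guilds.tsv")
            species = sorted(root.metadata["species"].unique())
            traits = random_traits(species, streams["aux"])
            tree_nwk = random_tree(species, streams["aux"])
            traits.to_csv(out / "traits.tsv", sep="\t")
            (out / "tree.nwk").write_text(tree_nwk + "\n")
        else:
            indir = out / "inputs"
            census = mio.read_census(indir / "census.tsv")
            root = mio.read_otu_table(indir / "root_counts.tsv", indir / "root_metadata.tsv")
            soil = mio.read_otu_table(indir / "soil_counts.tsv", indir / "soil_metadata.tsv")
            guilds = mio.read_guild_table(indir / "guilds.tsv")
            traits = mio.read_trait_table(indir / "traits.tsv")
            tree_nwk = mio.read_newick(indir / "tree.nwk")
            species = sorted(root.metadata["species"].unique())
        census_species = set(census.table["species"].unique())
        missing = sorted(census_species - set(species))
        if missing:
            warnings.warn(f"census species without root samples excluded: {missing}")
        done("inputs", t0, n_species=len(species), n_individuals=len(census.table),
             n_root_samples=len(root.counts), n_soil_samples=len(soil.counts))

        # ---- spatial classification -------------------------------------
        t0 = stage("spatial")
        pair_classes: dict[tuple[str, str], str] = {}
        spatial_rows = []
        for a, b in _pairs(species):
            cc = classify_cooccurrence(
                census, a, b, n_sim=config.n_sim_envelopes, alpha=config.alpha,
                seed=streams["spatial"],
            )
            pair_classes[(a, b)] = cc.cls
            spatial_rows.append({
                "species_a": a, "species_b": b, "class": cc.cls,
                "statistic": cc.statistic, "null_lo": cc.null_quantiles[0],
                "null_hi": cc.null_quantiles[1],
            })
        pd.DataFrame(spatial_rows).to_csv(out / "pair_classes.tsv", sep="\t", index=False)
        done("spatial", t0, n_pairs=len(pair_classes),
             n_aggregated=sum(c == "aggregated" for c in pair_classes.values()),
             n_segregated=sum(c == "segregated" for c in pair_classes.values()))

        # ---- background-soil validation (kriging, pooling, thinning) ----
        t0 = stage("background")
        thinned = {
            s: thin_by_distance(
                census.table[census.table["species"] == s],
                config.min_dist_m, streams["thin"],
            )
            for s in species
        }
        n_thinned = sum(len(v) for v in thinned.values())
        soil_xy = soil.metadata[["x", "y"]].to_numpy(dtype=float)
        krig_rows = []
        if config.simulation is not None and len(soil_xy) < 30:
            warnings.warn(
                f"kriging skipped: only {len(soil_xy)} soil samples (< 30)"
            )
        elif config.simulation is not None:
            env = simulate_env_surfaces(config.simulation)
            for cov in env.fields.columns:
                z = env.value_at(cov, soil_xy)
                model = fit_variogram(soil_xy, z)
                roots_xy = root.metadata[["x", "y"]].to_numpy(dtype=float)
                preds, kvar = ordinary_krige(soil_xy, z, model, roots_xy)
                for sid, p, v in zip(root.metadata.index, preds, kvar):
                    krig_rows.append({"sample_id": sid, "covariate": cov,
                                      "prediction": p, "variance": v})
            pd.DataFrame(krig_rows).to_csv(out / "kriged_env.tsv", sep="\t", index=False)
        pooled_rows = {}
        for sid, row in root.metadata.iterrows():
            pooled = pool_nearest_soils(
                np.array([row.x, row.y]), soil, config.k_nearest_soils
            )
            pooled_rows[sid] = pooled
        pooled_df = pd.DataFrame(pooled_rows).T
        pooled_df.rename_axis("sample_id").to_csv(out / "pooled_soils.tsv", sep="\t")
        done("background", t0, n_thinned=n_thinned, n_kriged=len(krig_rows))

        # ---- core OTUs ---------------------------------------------------
        t0 = stage("core_otus")
        core_sets: dict[tuple[str, float], object] = {}
        core_rows = []
        usable = [
            s for s in species
            if root.subset_species(s).shape[0] >= max(2, config.min_replicates)
        ]
        dropped = sorted(set(species) - set(usable))
        if dropped:
            warnings.warn(
                f"species with < {config.min_replicates} replicates excluded: {dropped}"
            )
        for s in usable:
            tbl = root.subset_species(s)
            for c in config.cutoffs:
                cs = define_core_otus(tbl, c, species=s)
                core_sets[(s, c)] = cs
                core_rows.append({"species": s, "cutoff": c,
                                  "n_core": len(cs.otus), "coverage": cs.coverage})
        pd.DataFrame(core_rows).to_csv(out / "core_otus.tsv", sep="\t", index=False)
        done("core_otus", t0, n_species_usable=len(usable))

        # ---- host specificity -------------------------------------------
        t0 = stage("host_specificity")
        ra = root.relative_abundance()
        raw_p: dict[tuple[str, str], float] = {}
        for a, b in _pairs(usable):
            ids_a = root.metadata.index[root.metadata["species"] == a]
            ids_b = root.metadata.index[root.metadata["species"] == b]
            sub = ra.loc[list(ids_a) + list(ids_b)]
            sub = sub.loc[:, (sub.sum(axis=0) > 0)]
            dm = bray_curtis(sub)
            labels = [a] * len(ids_a) + [b] * len(ids_b)
            res = permanova(dm, labels, n_perm=config.n_perm, seed=streams["specificity"])
            raw_p[(a, b)] = res.p_value
        hs_rows = []
        for s in usable:
            others = [o for o in usable if o != s]
            pv = [raw_p[tuple(sorted((s, o)))] for o in others]
            adj = bh_fdr(pv)
            call = classify_host_specificity(adj, species=s, alpha=config.alpha)
            hs_rows.append({"species": s, "n_significant": call.n_significant,
                            "n_compared": call.n_compared, "call": call.call})
        pd.DataFrame(hs_rows).to_csv(out / "host_specificity.tsv", sep="\t", index=False)
        done("host_specificity", t0, n_tests=len(raw_p))

        # ---- MRA profiles ------------------------------------------------
        t0 = stage("mra")
        sp_ra = {s: species_relative_abundance(root.subset_species(s)) for s in usable}
        profiles: dict[float, dict[tuple[str, str], object]] = {}
        mra_rows = []
        for c in config.mra_cutoffs:
            profiles[c] = {}
            for a, b in _pairs(usable):
                shared, unique = split_shared_unique(core_sets[(a, c)], core_sets[(b, c)])
                prof = compute_mra(sp_ra[a], sp_ra[b], shared, unique,
                                  pair=(a, b), cutoff=c)
                profiles[c][(a, b)] = prof
                for otu, v in prof.shared.items():
                    mra_rows.append({"species_a": a, "species_b": b, "cutoff": c,
                                     "side": "shared", "otu_id": otu, "mra": v})
                for otu, v in prof.unique.items():
                    mra_rows.append({"species_a": a, "species_b": b, "cutoff": c,
                                     "side": "unique", "otu_id": otu, "mra": v})
        pd.DataFrame(mra_rows).to_csv(out / "mra_profiles.tsv", sep="\t", index=False)
        done("mra", t0, n_profiles=sum(len(v) for v in profiles.values()))

        # ---- predictive modeling ----------------------------------------
        t0 = stage("model")
        n_labeled = sum(
            1 for (a, b), c in pair_classes.items()
            if c in ("aggregated", "segregated") and a in usable and b in usable
        )
        model_df = pd.DataFrame()
        if n_labeled >= 10 and len({
            c for c in pair_classes.values() if c != "none"
        }) == 2:
            abund = census.table["species"].value_counts(normalize=True)
            species_abund = {s: float(abund.get(s, 0.0)) for s in usable}
            phylo = cophenetic_distance(tree_nwk)
            trait_d = gower_distance(traits)
            richness = {
                s: float((root.subset_species(s) > 0).any(axis=0).sum()) for s in usable
            }
            pooled_comm = pd.DataFrame(
                {s: root.subset_species(s).sum(axis=0) for s in usable}
            ).T
            usable_classes = {
                p: c for p, c in pair_classes.items()
                if p[0] in usable and p[1] in usable
            }
            tables = {}
            for name in ("RA", "PL", "FT", "RICH", "COMM"):
                tables[name] = build_features(
                    name, usable_classes, species_ra=species_abund, phylo_dist=phylo,
                    trait_dist=trait_d, richness=richness, community=pooled_comm,
                )
            for c in config.mra_cutoffs:
                for side in ("shared", "unique"):
                    tables[f"MRA-{side}-{c}"] = build_features(
                        f"MRA-{side}-{c}", usable_classes,
                        mra_profiles=profiles[c], mra_side=side,
                    )
            results = evaluate_predictors(
                tables, n_rep=config.n_rep,
                seed=int(streams["model"].integers(0, 2**31 - 1)),
                n_trees=config.n_trees,
            )
            model_df = compare_models(results, alpha=config.alpha)
            model_df.to_csv(out / "model_comparison.tsv", sep="\t", index=False)
            auc_rows = []
            for name, r in results.items():
                for k in range(len(r.auc_observed)):
                    auc_rows.append({"predictor_set": name, "repetition": k,
                                     "auc_observed": r.auc_observed[k],
                                     "auc_shuffled": r.auc_shuffled[k]})
            pd.DataFrame(auc_rows).to_csv(out / "auc_values.tsv", sep="\t", index=False)
        else:
            warnings.warn(
                f"modeling skipped: only {n_labeled} labeled pairs or one class"
            )
        done("model", t0, n_labeled_pairs=n_labeled)

        # ---- guild contrasts --------------------------------------------
        t0 = stage("guilds")
        guild_df = pd.DataFrame()
        c0 = config.mra_cutoffs[0]
        summaries = []
        for prof in profiles.get(c0, {}).values():
            summaries.extend(guild_mra(prof, guilds))
        if summaries:
            guild_df = guild_contrast(summaries, pair_classes)
            guild_df.to_csv(out / "guild_contrasts.tsv", sep="\t", index=False)
        done("guilds", t0, n_contrasts=len(guild_df))

    manifest["warnings"] = [str(w.message) for w in caught]
    manifest["seed"] = config.seed
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return manifest


def _config_dict(config: PipelineConfig) -> dict:
    d = asdict(config)
    sim = d.get("simulation")
    if sim and sim.get("pair_relationships"):
        sim["pair_relationships"] = {
            f"{i}-{j}": rel for (i, j), rel in sim["pair_relationships"].items()
        }
    return d
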