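"""Modified relative abundance (MRA) of shared and unique core OTUs.

For a pair of plant species, the core root-associated fungal OTUs are
split into those core to both hosts (shared, candidate "generalists") and
those core to exactly one (unique, candidate "specialists").  Each side
is then renormalized into an MRA profile:

* unique OTU i owned by host X:  MRA_i = RA_X,i / sum over all unique
  OTUs j of RA_owner(j),j  (one pooled denominator across both hosts);
* shared OTU i:  MRA_i = RA_A,i * RA_B,i / sum over shared j of
  RA_A,j * RA_B,j.

Each non-empty side therefore sums to exactly 1.  A high shared MRA
flags a fungus recruited strongly by both hosts when they grow together.
Guild-level summaries sum the MRAs of OTUs assignable to a single
functional guild (plant pathogen, ectomycorrhizal, saprotroph), and the
aggregated-vs-segregated contrast asks whether those guild sums differ
between spatially aggregated and segregated plant pairs.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .community_stats import CoreOTUSet

__all__ = [
    "MRAProfile",
    "GuildMRASummary",
    "species_relative_abundance",
    "split_shared_unique",
    "compute_mra",
    "guild_mra",
    "guild_contrast",
    "parse_guilds",
]

GUILDS = ("plant pathogen", "ecm", "saprotroph")


@dataclass
class MRAProfile:
    pair: tuple[str, str]
    shared: dict[str, float]          # OTU -> MRA (sums to 1 when non-empty)
    unique: dict[str, float]          # OTU -> MRA (sums to 1 when non-empty)
    unique_owner: dict[str, str]      # OTU -> owning species
    cutoff: float
    shared_empty: bool = False
    unique_empty: bool = False
    stage_pair: tuple[str, str] | None = None


@dataclass
class GuildMRASummary:
    pair: tuple[str, str]
    guild: str
    shared_sum: float
    unique_sum: float
    stage_pair: tuple[str, str] | None = None


def species_relative_abundance(
    species_table: pd.DataFrame, method: str = "mean"
) -> pd.Series:
    """Species-level relative abundance of each OTU.

    ``mean`` averages per-sample relative abundances across the species'
    rarefied root-tip samples (the default); ``pooled`` sums counts first
    and normalizes once.  With equal-depth rows the two coincide.
    """
    if method == "mean":
        ra = species_table.div(species_table.sum(axis=1), axis=0)
        return ra.mean(axis=0)
    if method == "pooled":
        tot = species_table.sum(axis=0)
        return tot / tot.sum()
    raise ValueError(f"unknown method {method!r}")


def split_shared_unique(
    core_a: CoreOTUSet, core_b: CoreOTUSet
) -> tuple[frozenset[str], dict[str, str]]:
    """Shared = intersection of the two core sets; unique = symmetric difference.

    Unique OTUs are tagged with the species that owns them.  Both sets
    must come from the same detection-frequency cutoff.
    """
    if not math.isclose(core_a.cutoff, core_b.cutoff):
        raise ValueError(
            f"core sets built at different cutoffs ({core_a.cutoff} vs {core_b.cutoff})"
        )
    shared = core_a.otus & core_b.otus
    unique = {otu: core_a.species for otu in core_a.otus - core_b.otus}
    unique.update({otu: core_b.species for otu in core_b.otus - core_a.otus})
    return frozenset(shared), unique


def compute_mra(
    ra_a: pd.Series,
    ra_b: pd.Series,
    shared: frozenset[str],
    unique: dict[str, str],
    pair: tuple[str, str] = ("A", "B"),
    cutoff: float = 0.5,
    stage_pair: tuple[str, str] | None = None,
) -> MRAProfile:
    """MRA profile of one plant pair from the two hosts' RA vectors.

    An empty side is emitted as an empty dict with its flag set (never
    NaN); a zero denominator on a non-empty side is an error, since it
    means the "core" OTUs carry no reads at all.
    """
    name_a, name_b = pair
    ras = {name_a: ra_a, name_b: ra_b}

    shared_mra: dict[str, float] = {}
    if shared:
        ids = sorted(shared)
        prods = np.array([float(ra_a.get(o, 0.0)) * float(ra_b.get(o, 0.0)) for o in ids])
        denom = prods.sum()
        if denom <= 0:
            raise ValueError("zero denominator for non-empty shared core set")
        shared_mra = dict(zip(ids, prods / denom))

    unique_mra: dict[str, float] = {}
    if unique:
        ids = sorted(unique)
        vals = np.array([float(ras[unique[o]].get(o, 0.0)) for o in ids])
        denom = vals.sum()
        if denom <= 0:
            raise ValueError("zero denominator for non-empty unique core set")
        unique_mra = dict(zip(ids, vals / denom))

    return MRAProfile(
        pair, shared_mra, unique_mra, dict(unique), cutoff,
        shared_empty=not shared, unique_empty=not unique, stage_pair=stage_pair,
    )


def parse_guilds(guild_table: pd.DataFrame) -> tuple[dict[str, str], set[str]]:
    """Map OTU -> single guild label; OTUs with multiple labels are excluded.

    The guild table has columns (otu_id, guild); multi-guild entries are
    joined by "|".  Returns the single-guild mapping and the set of
    excluded multi-guild OTUs.
    """
    single: dict[str, str] = {}
    excluded: set[str] = set()
    for _, row in guild_table.iterrows():
        raw = str(row["guild"]) if pd.notna(row["guild"]) else ""
        labels = [g for g in raw.split("|") if g]
        if len(labels) == 1:
            single[str(row["otu_id"])] = labels[0]
        elif len(labels) > 1:
            excluded.add(str(row["otu_id"]))
    return single, excluded


def guild_mra(
    profile: MRAProfile, guild_table: pd.DataFrame, guilds: tuple[str, ...] = GUILDS
) -> list[GuildMRASummary]:
    """Per-guild sums of MRAs on each side of a pair's profile.

    OTUs with multiple guild assignments are excluded before summation;
    unassigned OTUs contribute to no guild.
    """
    single, _excluded = parse_guilds(guild_table)
    out = []
    for g in guilds:
        s_sum = sum(v for o, v in profile.shared.items() if single.get(o) == g)
        u_sum = sum(v for o, v in profile.unique.items() if single.get(o) == g)
        out.append(GuildMRASummary(profile.pair, g, s_sum, u_sum, profile.stage_pair))
    return out


def guild_contrast(
    summaries: list[GuildMRASummary],
    pair_classes: dict[tuple[str, str], str],
    stage_pairs: bool = False,
) -> pd.DataFrame:
    """Wilcoxon rank-sum contrasts of guild MRA sums: aggregated vs segregated pairs.

    One two-sided test per (guild x side x stage-pair) stratum, with
    effect size r = |Z| / sqrt(N) from the normal approximation of the
    rank-sum statistic.  Strata with a class absent or fewer than two
    pairs per class are skipped with a warning.
    """
    rows = []
    df = pd.DataFrame([
        {
            "pair": s.pair, "guild": s.guild, "shared": s.shared_sum,
            "unique": s.unique_sum,
            "stage_pair": "-".join(s.stage_pair) if s.stage_pair else "all",
            "cls": pair_classes.get(s.pair, pair_classes.get((s.pair[1], s.pair[0]), "none")),
        }
        for s in summaries
    ])
    df = df[df["cls"].isin(["aggregated", "segregated"])]
    strata = df["stage_pair"].unique() if stage_pairs else ["all"]
    for stage in strata:
        sub = df if not stage_pairs else df[df["stage_pair"] == stage]
        for guild in sub["guild"].unique():
            gsub = sub[sub["guild"] == guild]
            for side in ("shared", "unique"):
                a = gsub.loc[gsub["cls"] == "aggregated", side].to_numpy()
                s = gsub.loc[gsub["cls"] == "segregated", side].to_numpy()
                if len(a) < 2 or len(s) < 2:
                    warnings.warn(
                        f"stratum ({guild}, {side}, {stage}) skipped: "
                        f"{len(a)} aggregated vs {len(s)} segregated"
                    )
                    continue
                n = len(a) + len(s)
                if np.all(np.concatenate([a, s]) == np.concatenate([a, s])[0]):
                    stat, p, z = float(len(a) * len(s) / 2), 1.0, 0.0
                else:
                    res = stats.mannwhitneyu(a, s, alternative="two-sided")
                    stat, p = float(res.statistic), float(res.pvalue)
                    # normal-approximation Z for the effect size r = |Z|/sqrt(N)
                    mu = len(a) * len(s) / 2
                    combined = np.concatenate([a, s])
                    _, tie_counts = np.unique(combined, return_counts=True)
                    tie_term = (tie_counts**3 - tie_counts).sum()
                    sigma2 = len(a) * len(s) / 12 * (n + 1 - tie_term / (n * (n - 1)))
                    z = (stat - mu) / np.sqrt(sigma2) if sigma2 > 0 else 0.0
                rows.append({
                    "guild": guild, "side": side, "stage_pair": stage,
                    "n_aggregated": len(a), "n_segregated": len(s),
                    "mean_aggregated": float(a.mean()), "mean_segregated": float(s.mean()),
                    "statistic": stat, "p_value": p,
                    "effect_size_r": abs(float(z)) / np.sqrt(n),
                })
    return pd.DataFrame(rows)
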