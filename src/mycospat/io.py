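"""Plain-text readers and writers for every pipeline input and output.

All tables are TSV with header rows; trees are newick; configuration is a
single YAML file.  Every writer round-trips losslessly through its reader.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .synthetic_forest import OTUTable, PlantCensus

CENSUS_COLUMNS = ["individual_id", "species", "dbh", "x", "y"]
META_COLUMNS = ["species", "dbh", "x", "y", "sample_type"]


def write_census(census: PlantCensus, path: str | Path) -> None:
    path = Path(path)
    df = census.table[CENSUS_COLUMNS].copy()
    with open(path, "w") as fh:
        fh.write(f"# window\t{census.window[0]}\t{census.window[1]}\n")
        df.to_csv(fh, sep="\t", index=False)


def read_census(path: str | Path) -> PlantCensus:
    path = Path(path)
    with open(path) as fh:
        first = fh.readline().strip().split("\t")
        if first[0] != "# window":
            raise ValueError(f"{path} missing '# window' header line")
        window = (float(first[1]), float(first[2]))
        df = pd.read_csv(fh, sep="\t")
    return PlantCensus(df[CENSUS_COLUMNS], window)


def write_otu_table(table: OTUTable, counts_path: str | Path, meta_path: str | Path) -> None:
    table.counts.rename_axis("sample_id").to_csv(counts_path, sep="\t")
    table.metadata.rename_axis("sample_id").to_csv(meta_path, sep="\t")


def read_otu_table(counts_path: str | Path, meta_path: str | Path) -> OTUTable:
    counts = pd.read_csv(counts_path, sep="\t", index_col="sample_id").rename_axis(None)
    meta = pd.read_csv(meta_path, sep="\t", index_col="sample_id").rename_axis(None)
    meta["species"] = meta["species"].fillna("").astype(str)
    return OTUTable(counts, meta)


def write_guild_table(guilds: pd.DataFrame, path: str | Path) -> None:
    guilds[["otu_id", "guild"]].to_csv(path, sep="\t", index=False)


def read_guild_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"otu_id": str})
    df["guild"] = df["guild"].fillna("")
    return df[["otu_id", "guild"]]


def read_trait_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def read_newick(path: str | Path) -> str:
    return Path(path).read_text().strip()
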