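"""Plain-CSV readers and writers for the pipeline's tables.

All interchange is delimited text: a tree table (``plot_id, lon, lat,
species, dbh_cm, status``), a species trait table with one value column and
one provenance column per trait, a taxonomy table, a per-plot climate table
and a two-column synonym map.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .datatypes import CLIMATE_VARS, TRAITS, TraitTable

__all__ = [
    "read_trait_table",
    "write_trait_table",
    "read_taxonomy",
    "read_trees",
    "read_climate",
    "read_synonym_map",
]

_FLOAT_FMT = "%.10g"


def write_trait_table(table: TraitTable, path: str | Path) -> None:
    """One row per species: value columns plus ``<trait>_provenance`` columns."""
    out = table.values.copy()
    for t in TRAITS:
        out[f"{t}_provenance"] = table.provenance[t]
    out.to_csv(path, float_format=_FLOAT_FMT)


def read_trait_table(path: str | Path) -> TraitTable:
    df = pd.read_csv(path, index_col="species")
    values = df[list(TRAITS)].astype(float)
    prov_cols = [f"{t}_provenance" for t in TRAITS]
    if all(c in df.columns for c in prov_cols):
        prov = df[prov_cols].copy()
        prov.columns = list(TRAITS)
    else:
        prov = values.where(values.isna(), "observed").where(values.notna())
    return TraitTable(values, prov.where(values.notna()))


def read_taxonomy(path: str | Path) -> pd.DataFrame:
    tax = pd.read_csv(path)
    required = {"species", "genus", "family"}
    missing = required - set(tax.columns)
    if missing:
        raise ValueError(f"taxonomy file lacks columns {sorted(missing)}")
    return tax


def read_trees(path: str | Path) -> pd.DataFrame:
    trees = pd.read_csv(
        path,
        dtype={"plot_id": str, "species": str, "status": str},
    )
    required = {"plot_id", "lon", "lat", "species", "dbh_cm", "status"}
    missing = required - set(trees.columns)
    if missing:
        raise ValueError(f"tree file lacks columns {sorted(missing)}")
    if not np.isfinite(trees[["lon", "lat"]].to_numpy()).all():
        raise ValueError("non-finite coordinates in tree table")
    if (trees["dbh_cm"] <= 0).any():
        raise ValueError("nonpositive dbh in tree table")
    return trees


def read_climate(path: str | Path) -> pd.DataFrame:
    clim = pd.read_csv(path, dtype={"plot_id": str})
    required = {"plot_id", "lon", "lat", *CLIMATE_VARS}
    missing = required - set(clim.columns)
    if missing:
        raise ValueError(f"climate file lacks columns {sorted(missing)}")
    return clim


def read_synonym_map(path: str | Path) -> dict[str, str]:
    """Two-column CSV ``raw,canonical`` -> dict."""
    df = pd.read_csv(path)
    if df.shape[1] < 2:
        raise ValueError("synonym map needs two columns (raw, canonical)")
    return dict(zip(df.iloc[:, 0].astype(str), df.iloc[:, 1].astype(str)))
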