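"""From tree records to grid-cell communities and their weighted mean traits.

A *community* is the pooled sample of living trees (DBH strictly above the
inventory threshold, 12.7 cm by default) falling in one lon/lat grid cell.
Species abundance is measured as the species' share of the community's total
basal area, pooled over all the cell's plots; the community-weighted mean
(CWM) of a trait is the share-weighted average of the species' transformed
trait values.  Communities are labelled by the functional group (broadleaved
deciduous/evergreen, needleleaved conifer) holding a strict majority (>50%)
of basal area; ties and pluralities below one half are excluded.
"""

from __future__ import annotations

import logging
import math

import numpy as np
import pandas as pd

from .datatypes import (
    FUNCTIONAL_GROUPS,
    LOG_TRAITS,
    NEGATIVE_TRAITS,
    TRAITS,
    TraitTable,
)

__all__ = [
    "filter_trees",
    "assign_grid",
    "basal_area",
    "transform_traits",
    "assemble_communities",
    "classify_functional_type",
    "cwm_matrix",
    "min_plot_filter",
    "TraitTransformError",
]

logger = logging.getLogger(__name__)


class TraitTransformError(ValueError):
    """A raw trait value violates the sign convention of its transform."""


def filter_trees(
    trees: pd.DataFrame, min_dbh: float = 12.7, status: str = "living"
) -> pd.DataFrame:
    """Keep living trees with DBH strictly greater than ``min_dbh`` (cm)."""
    alive = trees["status"] == status
    big = trees["dbh_cm"] > min_dbh
    kept = trees[alive & big]
    logger.info(
        "filter_trees: removed %d dead/non-%s and %d sub-threshold of %d trees",
        int((~alive).sum()), status, int((alive & ~big).sum()), len(trees),
    )
    return kept.copy()


def assign_grid(trees: pd.DataFrame, resolution: float = 0.25) -> pd.Series:
    """Half-open grid-cell ids ``"x|y"`` with x = floor(lon/res), y = floor(lat/res).

    A coordinate exactly on a boundary belongs to the upper cell's lower
    edge (half-open convention ``[x, x + res)``).
    """
    if resolution <= 0:
        raise ValueError("resolution must be positive")
    x = np.floor(trees["lon"].to_numpy() / resolution).astype(np.int64)
    y = np.floor(trees["lat"].to_numpy() / resolution).astype(np.int64)
    return pd.Series(
        [f"{a}|{b}" for a, b in zip(x, y)], index=trees.index, name="cell_id"
    )


def cell_centres(cell_ids: pd.Index | pd.Series, resolution: float = 0.25) -> pd.DataFrame:
    """Lon/lat of cell centres for mapping output."""
    parts = [c.split("|") for c in cell_ids]
    x = np.array([int(p[0]) for p in parts])
    y = np.array([int(p[1]) for p in parts])
    return pd.DataFrame(
        {"lon": (x + 0.5) * resolution, "lat": (y + 0.5) * resolution},
        index=pd.Index(cell_ids, name="cell_id"),
    )


def basal_area(dbh_cm) -> np.ndarray | float:
    """Stem cross-section at breast height in m^2: pi * (dbh_cm / 200)^2."""
    dbh = np.asarray(dbh_cm, dtype=float)
    if np.any(dbh <= 0):
        raise ValueError("dbh must be positive")
    out = math.pi * (dbh / 200.0) ** 2
    return float(out) if out.ndim == 0 else out


def transform_traits(values: pd.DataFrame | pd.Series):
    """Transform raw traits for CWM/ordination.

    N, Ks, LS, LMA, Slope -> ln(x); P50, TLP -> ln(-x); WD unchanged.
    Missing cells pass through as NaN.

    Raises
    ------
    TraitTransformError
        naming species and trait on a zero or wrong-signed input.
    """
    row = isinstance(values, pd.Series)
    df = values.to_frame().T if row else values
    out = df.copy().astype(float)
    for t in df.columns:
        if t not in TRAITS:
            raise ValueError(f"unknown trait column {t!r}")
        col = df[t]
        if t in NEGATIVE_TRAITS:
            bad = col.index[col.ge(0) & col.notna()]
            if len(bad):
                raise TraitTransformError(
                    f"trait {t} must be negative; offending species: "
                    f"{list(bad[:5])}"
                )
            out[t] = np.log(-col)
        elif t in LOG_TRAITS:
            bad = col.index[col.le(0) & col.notna()]
            if len(bad):
                raise TraitTransformError(
                    f"trait {t} must be positive; offending species: "
                    f"{list(bad[:5])}"
                )
            out[t] = np.log(col)
        # WD: identity
    return out.iloc[0] if row else out


def assemble_communities(
    trees: pd.DataFrame,
    taxonomy: pd.DataFrame,
    resolution: float = 0.25,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pool (already filtered) trees into grid-cell communities.

    Returns
    -------
    cells : DataFrame indexed by cell_id
        ``lon, lat`` (cell centre), ``plot_count, total_ba``, one
        ``share_<G>`` column per functional group, ``dominant_type``
        (``"excluded"`` when no group exceeds one half).
    abundance : DataFrame
        Tidy per-(cell, species) basal area and share.
    """
    t = trees.copy()
    t["cell_id"] = assign_grid(t, resolution)
    t["ba"] = basal_area(t["dbh_cm"].to_numpy())
    tax = taxonomy.set_index("species") if "species" in taxonomy.columns else taxonomy
    t["functional_group"] = t["species"].map(tax["functional_group"])
    if t["functional_group"].isna().any():
        missing = sorted(t.loc[t["functional_group"].isna(), "species"].unique())
        raise ValueError(f"species missing functional group: {missing[:5]}")

    abundance = (
        t.groupby(["cell_id", "species"], as_index=False)["ba"].sum()
        .rename(columns={"ba": "basal_area"})
    )
    total = abundance.groupby("cell_id")["basal_area"].transform("sum")
    abundance["share"] = abundance["basal_area"] / total

    cells = t.groupby("cell_id").agg(
        plot_count=("plot_id", "nunique"), total_ba=("ba", "sum")
    )
    group_ba = (
        t.pivot_table(index="cell_id", columns="functional_group",
                      values="ba", aggfunc="sum", fill_value=0.0)
        .reindex(columns=list(FUNCTIONAL_GROUPS), fill_value=0.0)
    )
    group_share = group_ba.div(group_ba.sum(axis=1), axis=0)
    for g in FUNCTIONAL_GROUPS:
        cells[f"share_{g}"] = group_share[g]
    cells["dominant_type"] = classify_functional_type(group_share)
    centres = cell_centres(cells.index, resolution)
    cells.insert(0, "lat", centres["lat"])
    cells.insert(0, "lon", centres["lon"])
    n_excl = int((cells["dominant_type"] == "excluded").sum())
    logger.info(
        "assemble_communities: %d cells, %d excluded by the >50%% dominance rule",
        len(cells), n_excl,
    )
    return cells, abundance


def classify_functional_type(group_shares: pd.DataFrame) -> pd.Series:
    """Majority functional type per community; strict > 0.5, else excluded."""
    shares = group_shares.reindex(columns=list(FUNCTIONAL_GROUPS), fill_value=0.0)
    winner = shares.idxmax(axis=1)
    top = shares.max(axis=1)
    return winner.where(top > 0.5, "excluded").rename("dominant_type")


def cwm_matrix(
    abundance: pd.DataFrame,
    traits: TraitTable | pd.DataFrame,
) -> tuple[pd.DataFrame, pd.DataFrame, list[str]]:
    """Community-weighted means of transformed traits.

    Parameters
    ----------
    abundance : tidy per-(cell_id, species) shares from
        :func:`assemble_communities`.
    traits : complete raw-scale species trait table (post-imputation).

    Returns ``(cwm_transformed, cwm_raw, excluded_cells)``: communities with
    any member species lacking a complete trait row are excluded and listed.
    """
    values = traits.values if isinstance(traits, TraitTable) else traits
    transformed = transform_traits(values)

    known = abundance["species"].isin(values.index)
    complete_species = values.dropna().index
    ok_species = abundance["species"].isin(complete_species)
    bad_cells = sorted(abundance.loc[~(known & ok_species), "cell_id"].unique())
    if bad_cells:
        logger.info(
            "cwm_matrix: excluding %d communities with trait-less species",
            len(bad_cells),
        )
    ab = abundance[~abundance["cell_id"].isin(bad_cells)]

    share = ab.pivot_table(index="cell_id", columns="species", values="share",
                           fill_value=0.0)
    cwm_t = pd.DataFrame(
        share.to_numpy() @ transformed.loc[share.columns].to_numpy(),
        index=share.index, columns=list(TRAITS),
    )
    cwm_r = pd.DataFrame(
        share.to_numpy() @ values.loc[share.columns].to_numpy(),
        index=share.index, columns=list(TRAITS),
    )
    return cwm_t, cwm_r, bad_cells


def min_plot_filter(cells: pd.DataFrame, min_plots: int = 1) -> pd.DataFrame:
    """Drop communities with fewer than ``min_plots`` plots (sensitivity runs)."""
    kept = cells[cells["plot_count"] >= min_plots]
    logger.info(
        "min_plot_filter: dropped %d of %d communities (min_plots=%d)",
        len(cells) - len(kept), len(cells), min_plots,
    )
    return kept.copy()
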