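"""Species-trait matching, hierarchical gap-filling and masking validation.

Trait coverage in compiled species-trait tables is sparse (hydraulic traits
especially), so missing species x trait cells are filled by a three-level
hierarchy:

1. median of *observed* trait values across congeneric species;
2. else, median of observed values across confamilial species;
3. else, a taxonomic-distance weighted k-nearest-neighbour imputation
   (:func:`phylo_impute`) standing in for tree-based phylogenetic imputers.

Observed cells are never overwritten; every filled cell carries a provenance
code.  :func:`masking_validation` measures imputation skill by repeatedly
hiding a fraction of the observed cells, re-running the chain, and scoring
z-transformed predictions against the held-out observations.
"""

from __future__ import annotations

import logging
import re
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .datatypes import TRAITS, TraitTable, ValidationReport

__all__ = [
    "CanonicalisationError",
    "TraitImputationError",
    "canonicalise_names",
    "species_median",
    "gapfill_hierarchy",
    "phylo_impute",
    "HierarchicalTraitImputer",
    "masking_validation",
]

logger = logging.getLogger(__name__)

GAPFILL_METHODS = ("genus_family_phylo", "genus_phylo", "phylo_only")


class CanonicalisationError(ValueError):
    """Two raw names resolve to conflicting canonical targets."""


class TraitImputationError(ValueError):
    """A trait cannot be imputed (e.g. no observed donor anywhere)."""


def _normalise(name: str) -> str:
    parts = re.sub(r"\s+", " ", name.strip()).split(" ")
    if not parts or parts == [""]:
        raise ValueError("empty species name")
    head = parts[0].capitalize()
    rest = [p.lower() for p in parts[1:]]
    return " ".join([head, *rest])


def canonicalise_names(
    raw_names: Iterable[str],
    synonym_map: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Deterministically canonicalise species names.

    Trims and collapses whitespace, capitalises the genus epithet and
    lower-cases the rest, then applies the user-supplied synonym map (keys
    are matched after the same normalisation).  Names absent from the map
    pass through unchanged and are flagged ``mapped=False``.

    Returns a DataFrame with columns ``raw, canonical, mapped``.

    Raises
    ------
    CanonicalisationError
        If two raw spellings of the same normalised name are mapped to
        different canonical targets by the synonym map.
    """
    syn_norm: dict[str, str] = {}
    conflicts: dict[str, set[str]] = {}
    if synonym_map:
        for k, v in synonym_map.items():
            nk, nv = _normalise(k), _normalise(v)
            if nk in syn_norm and syn_norm[nk] != nv:
                conflicts.setdefault(nk, {syn_norm[nk]}).add(nv)
            syn_norm[nk] = nv
    if conflicts:
        raise CanonicalisationError(
            f"conflicting synonym targets: {sorted(conflicts.items())}"
        )

    rows = []
    for raw in raw_names:
        norm = _normalise(raw)
        mapped = norm in syn_norm
        rows.append({"raw": raw, "canonical": syn_norm.get(norm, norm),
                     "mapped": mapped})
    return pd.DataFrame(rows)


def species_median(observations: pd.DataFrame) -> TraitTable:
    """Per-species medians of raw trait observations.

    ``observations`` is tidy with columns ``species, trait, value`` (one row
    per measurement).  Cells with at least one observation get the median and
    provenance ``observed``; species/trait combinations without observations
    stay missing.
    """
    obs = observations.copy()
    unknown = set(obs["trait"]) - set(TRAITS)
    if unknown:
        raise ValueError(f"unknown traits in observations: {sorted(unknown)}")
    values = (
        obs.pivot_table(index="species", columns="trait", values="value",
                        aggfunc="median")
        .reindex(columns=list(TRAITS))
        .rename_axis(index="species", columns=None)
        .sort_index()
    )
    provenance = values.where(values.isna(), "observed").where(values.notna())
    return TraitTable(values, provenance)


def _check_taxonomy(table: TraitTable, taxonomy: pd.DataFrame) -> pd.DataFrame:
    tax = taxonomy.set_index("species") if "species" in taxonomy.columns else taxonomy
    missing = table.species.difference(tax.index)
    if len(missing):
        raise ValueError(
            f"taxonomy does not cover {len(missing)} species, "
            f"e.g. {list(missing[:3])}"
        )
    return tax.loc[table.species]


def gapfill_hierarchy(
    table: TraitTable,
    taxonomy: pd.DataFrame,
    include_family: bool = True,
) -> TraitTable:
    """Fill missing cells with genus medians, then family medians.

    Medians are taken over *observed* species values only (cells whose
    provenance is ``observed``), so imputations never cascade.  Observed
    cells are untouched; remaining gaps are left for :func:`phylo_impute`.
    """
    tax = _check_taxonomy(table, taxonomy)
    values = table.values.copy()
    prov = table.provenance.copy()
    observed = prov == "observed"
    obs_values = values.where(observed)

    levels = [("genus", "genus_median")]
    if include_family:
        levels.append(("family", "family_median"))
    for level, code in levels:
        groups = tax[level]
        medians = obs_values.groupby(groups.to_numpy()).median()
        for t in TRAITS:
            fill = groups.map(medians[t])
            target = values[t].isna() & fill.notna()
            values.loc[target, t] = fill[target]
            prov.loc[target, t] = code
    return TraitTable(values, prov)


def phylo_impute(
    table: TraitTable,
    taxonomy: pd.DataFrame,
    k: int = 5,
    seed: int = 0,
) -> TraitTable:
    """Taxonomic-distance weighted k-NN imputation of the remaining gaps.

    For each still-missing cell the donors are species with an *observed*
    value for that trait, ranked by taxonomic distance d (1 = same genus,
    2 = same family, 3 = otherwise); ties at equal d are broken by Euclidean
    distance over shared z-scored observed traits, and residual ties by a
    seeded random permutation.  The imputed value is the 1/d-weighted mean
    of the k nearest donors.

    Raises
    ------
    TraitImputationError
        If a trait that needs imputing has no observed value anywhere.
    """
    tax = _check_taxonomy(table, taxonomy)
    values = table.values.copy()
    prov = table.provenance.copy()
    observed = prov == "observed"
    obs_values = values.where(observed)

    mu = obs_values.mean()
    sd = obs_values.std(ddof=1).replace(0.0, 1.0)
    z = ((obs_values - mu) / sd).to_numpy()  # NaN where not observed

    genus = tax["genus"].to_numpy()
    family = tax["family"].to_numpy()
    species = table.species.to_numpy()
    rng = np.random.default_rng(seed)
    jitter = rng.permutation(len(species))  # residual tie-break order

    obs_np = observed.to_numpy()
    val_np = values.to_numpy()

    for j, t in enumerate(TRAITS):
        missing_rows = np.flatnonzero(np.isnan(val_np[:, j]))
        if missing_rows.size == 0:
            continue
        donors = np.flatnonzero(obs_np[:, j])
        if donors.size == 0:
            raise TraitImputationError(
                f"trait {t} has no observed values; cannot impute"
            )
        for i in missing_rows:
            d = np.full(donors.size, 3.0)
            d[family[donors] == family[i]] = 2.0
            d[genus[donors] == genus[i]] = 1.0
            # shared z-scored traits (excluding the target trait)
            zi = z[i].copy()
            zi[j] = np.nan
            diff = z[donors] - zi
            shared = ~np.isnan(diff)
            with np.errstate(invalid="ignore"):
                eu = np.sqrt(np.nansum(diff**2, axis=1) / shared.sum(axis=1))
            eu[shared.sum(axis=1) == 0] = np.inf
            order = np.lexsort((jitter[donors], eu, d))
            top = donors[order[: min(k, donors.size)]]
            dd = d[order[: min(k, donors.size)]]
            w = 1.0 / dd
            val_np[i, j] = float(np.sum(w * val_np[top, j]) / np.sum(w))
            prov.iloc[i, j] = "phylo_imputed"

    values = pd.DataFrame(val_np, index=table.species, columns=list(TRAITS))
    return TraitTable(values, prov)


class HierarchicalTraitImputer(BaseEstimator, TransformerMixin):
    """Sklearn-style transformer running the full gap-fill chain.

    Parameters
    ----------
    taxonomy : DataFrame
        Columns ``species, genus, family`` (``functional_group`` ignored).
    method : str
        ``genus_family_phylo`` (default), ``genus_phylo`` (skip family
        medians) or ``phylo_only``.
    k : int
        Neighbour count for the taxonomic k-NN step.
    random_state : int
        Seed for residual tie-breaking in the k-NN step.
    """

    def __init__(self, taxonomy: pd.DataFrame | None = None,
                 method: str = "genus_family_phylo", k: int = 5,
                 random_state: int = 0):
        self.taxonomy = taxonomy
        self.method = method
        self.k = k
        self.random_state = random_state

    def _as_table(self, X) -> TraitTable:
        if isinstance(X, TraitTable):
            return X.copy()
        values = pd.DataFrame(X).reindex(columns=list(TRAITS))
        prov = values.where(values.isna(), "observed").where(values.notna())
        return TraitTable(values, prov)

    def fit(self, X, y=None):
        if self.method not in GAPFILL_METHODS:
            raise ValueError(
                f"method must be one of {GAPFILL_METHODS}, got {self.method!r}"
            )
        if self.taxonomy is None:
            raise ValueError("taxonomy is required")
        table = self._as_table(X)
        _check_taxonomy(table, self.taxonomy)
        self.n_features_in_ = len(TRAITS)
        self.feature_names_in_ = np.asarray(TRAITS, dtype=object)
        return self

    def transform(self, X) -> TraitTable:
        table = self._as_table(X)
        if self.method == "genus_family_phylo":
            table = gapfill_hierarchy(table, self.taxonomy, include_family=True)
        elif self.method == "genus_phylo":
            table = gapfill_hierarchy(table, self.taxonomy, include_family=False)
        table = phylo_impute(table, self.taxonomy, k=self.k,
                             seed=self.random_state)
        return table

    def fit_transform(self, X, y=None, **fit_params) -> TraitTable:
        return self.fit(X, y).transform(X)


def masking_validation(
    table: TraitTable,
    taxonomy: pd.DataFrame,
    proportions: Sequence[float] = (0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8),
    reps: int = 100,
    seed: int = 0,
    method: str = "genus_family_phylo",
    k: int = 5,
) -> ValidationReport:
    """Hold-out validation of the gap-fill chain.

    Per replicate and masking proportion p, a fraction p of each trait's
    *observed* species (uniform at random, per trait) has its value hidden;
    the full chain then re-fills the table and predictions at the masked
    cells are compared to the held-out observations.  Both are z-transformed
    with the full observed distribution's mean and sd so replicates share a
    scale; R2 is the squared Pearson correlation and RMSE the root mean
    squared error on the z scale.

    Traits whose masking would leave fewer than 2 species unmasked, or whose
    masked set is too small to correlate, are skipped and logged.
    """
    if any(not 0.0 < p < 1.0 for p in proportions):
        raise ValueError("proportions must lie strictly in (0, 1)")
    observed = table.provenance == "observed"
    obs_values = table.values.where(observed)
    mu = obs_values.mean()
    sd = obs_values.std(ddof=1)

    rng = np.random.default_rng(seed)
    obs_idx = {t: np.flatnonzero(observed[t].to_numpy()) for t in TRAITS}

    records, skipped = [], []
    for p in proportions:
        for r in range(reps):
            masked_values = obs_values.copy()
            masked_cells: dict[str, np.ndarray] = {}
            for t in TRAITS:
                idx = obs_idx[t]
                n_mask = int(round(p * idx.size))
                if idx.size - n_mask < 2:
                    skipped.append(
                        {"trait": t, "proportion": p, "replicate": r,
                         "reason": "fewer than 2 species left unmasked"}
                    )
                    continue
                sel = rng.choice(idx, size=n_mask, replace=False)
                masked_cells[t] = sel
                masked_values.iloc[sel, masked_values.columns.get_loc(t)] = np.nan

            imp = HierarchicalTraitImputer(
                taxonomy=taxonomy, method=method, k=k,
                random_state=int(rng.integers(2**31 - 1)),
            )
            filled = imp.fit_transform(masked_values)

            for t, sel in masked_cells.items():
                truth_z = (obs_values[t].iloc[sel] - mu[t]) / sd[t]
                pred_z = (filled.values[t].iloc[sel] - mu[t]) / sd[t]
                ok = pred_z.notna()
                if ok.sum() < 2 or truth_z[ok].std() == 0 or pred_z[ok].std() == 0:
                    skipped.append(
                        {"trait": t, "proportion": p, "replicate": r,
                         "reason": "degenerate masked set"}
                    )
                    continue
                rho = float(np.corrcoef(truth_z[ok], pred_z[ok])[0, 1])
                rmse = float(np.sqrt(np.mean((truth_z[ok] - pred_z[ok]) ** 2)))
                records.append(
                    {"trait": t, "proportion": p, "replicate": r,
                     "r2": rho**2, "rmse": rmse}
                )
    if skipped:
        logger.info("masking_validation skipped %d trait-replicates", len(skipped))
    return ValidationReport(
        records=pd.DataFrame(records,
                             columns=["trait", "proportion", "replicate",
                                      "r2", "rmse"]),
        skipped=pd.DataFrame(skipped,
                             columns=["trait", "proportion", "replicate",
                                      "reason"]),
    )
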