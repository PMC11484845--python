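"""Config-driven orchestration of the full analysis and sensitivity suite.

``run_main`` drives: data loading (or synthesis) -> name canonicalisation ->
trait gap-filling -> tree filtering -> grid-cell communities -> CWM matrix ->
scaled PCA + correlations -> climate aggregation -> LMG bootstrap, univariate
regressions and aridity divergence.  Every filter step's exclusion count is
recorded in a machine-readable manifest; a single seed fans out to per-stage
child seeds, so one config reproduces every output byte for byte.

``run_sensitivity`` reruns the ordination under alternative gap-fill
methods, grid resolutions and the minimum-plot filter, plus a species-level
PCA, and reports pairwise Procrustes congruence against the baseline.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .climate_importance import (
    aggregate_climate,
    aridity_divergence,
    bootstrap_importance,
    univariate_regressions,
)
from .community import (
    assemble_communities,
    cwm_matrix,
    filter_trees,
    min_plot_filter,
    transform_traits,
)
from .datatypes import CLIMATE_VARS, TRAITS, TraitTable
from .io import (
    _FLOAT_FMT,
    read_climate,
    read_synonym_map,
    read_taxonomy,
    read_trait_table,
    read_trees,
    write_trait_table,
)
from .ordination import ScaledPCA, correlation_matrix, procrustes_compare
from .synthetic_data import SynthConfig, generate_dataset
from .trait_assembly import GAPFILL_METHODS, HierarchicalTraitImputer, canonicalise_names

__all__ = ["RunConfig", "run_main", "run_sensitivity"]

logger = logging.getLogger(__name__)

_PKG_VERSION = "0.1.0"


class PipelineError(RuntimeError):
    """A pipeline stage failed; the stage is named in the message."""


@dataclass
class RunConfig:
    """Inputs and knobs for one analysis run.

    Exactly one input source: either ``synthetic=True`` (with ``synth``
    holding the generator conditions) or the four CSV paths.
    """

    synthetic: bool = True
    synth: SynthConfig = field(default_factory=SynthConfig)
    trees_path: str | None = None
    traits_path: str | None = None
    taxonomy_path: str | None = None
    climate_path: str | None = None
    synonym_map_path: str | None = None

    resolution: float = 0.25
    gapfill_method: str = "genus_family_phylo"
    knn_k: int = 5
    min_plots: int = 1
    min_dbh: float = 12.7
    n_components: int = 2
    n_boot: int = 1000
    n_perm: int = 999
    n_ai_bins: int = 5
    masking_proportions: tuple[float, ...] = (0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8)
    masking_reps: int = 100
    seed: int = 0
    output_dir: str = "results"

    def __post_init__(self) -> None:
        if self.resolution <= 0:
            raise ValueError("resolution must be positive")
        if self.gapfill_method not in GAPFILL_METHODS:
            raise ValueError(
                f"gapfill_method must be one of {GAPFILL_METHODS}"
            )
        paths = (self.trees_path, self.traits_path, self.taxonomy_path)
        if self.synthetic and any(p is not None for p in paths):
            raise ValueError("choose either synthetic input or CSV paths")
        if not self.synthetic and any(p is None for p in paths):
            raise ValueError(
                "CSV input needs trees_path, traits_path and taxonomy_path"
            )
        # synthetic data inherit the run seed unless set explicitly
        if self.synthetic and self.synth.seed != self.seed:
            self.synth = dataclasses.replace(self.synth, seed=self.seed)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        synth_raw = raw.pop("synth", None)
        cfg = cls(**{k: v for k, v in raw.items() if k != "synth"})
        if synth_raw:
            if "latent_loadings" in synth_raw:
                synth_raw["latent_loadings"] = {
                    k: tuple(v) for k, v in synth_raw["latent_loadings"].items()
                }
            cfg.synth = dataclasses.replace(
                SynthConfig(**synth_raw),
            )
            cfg.synth = dataclasses.replace(cfg.synth, seed=cfg.seed)
        return cfg

    def stage_seed(self, stage: int) -> int:
        """Child seed for one stochastic stage (below 2^31)."""
        ss = np.random.SeedSequence(entropy=int(self.seed),
                                    spawn_key=(100 + stage,))
        return int(ss.generate_state(1)[0] % (2**31 - 1))

    def digest(self) -> str:
        def enc(o):
            if dataclasses.is_dataclass(o) and not isinstance(o, type):
                return dataclasses.asdict(o)
            if isinstance(o, tuple):
                return list(o)
            raise TypeError(type(o))

        fields = dataclasses.asdict(self)
        fields.pop("output_dir", None)  # where results land is not what they are
        payload = json.dumps(fields, default=enc, sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _load_inputs(config: RunConfig) -> dict:
    if config.synthetic:
        return generate_dataset(config.synth)
    trees = read_trees(config.trees_path)
    traits = read_trait_table(config.traits_path)
    taxonomy = read_taxonomy(config.taxonomy_path)
    climate = read_climate(config.climate_path) if config.climate_path else None
    synonyms = (
        read_synonym_map(config.synonym_map_path)
        if config.synonym_map_path
        else None
    )
    mapping = canonicalise_names(trees["species"], synonyms)
    trees = trees.assign(
        species=trees["species"].map(
            dict(zip(mapping["raw"], mapping["canonical"]))
        )
    )
    tmap = canonicalise_names(traits.species, synonyms)
    ren = dict(zip(tmap["raw"], tmap["canonical"]))
    traits = TraitTable(
        traits.values.rename(index=ren), traits.provenance.rename(index=ren)
    )
    tax_map = canonicalise_names(taxonomy["species"], synonyms)
    taxonomy = taxonomy.assign(
        species=taxonomy["species"].map(
            dict(zip(tax_map["raw"], tax_map["canonical"]))
        )
    )
    return {
        "taxonomy": taxonomy,
        "traits": traits,
        "trees": trees,
        "climate": climate,
        "truth": None,
    }


def _ordination_pipeline(
    trees_kept: pd.DataFrame,
    taxonomy: pd.DataFrame,
    filled: TraitTable,
    resolution: float,
    min_plots: int,
    n_components: int,
) -> dict:
    """Communities -> CWM -> PCA for one (resolution, min_plots) setting."""
    cells, abundance = assemble_communities(trees_kept, taxonomy, resolution)
    n_cells_all = len(cells)
    cells = cells[cells["dominant_type"] != "excluded"]
    n_excl_dom = n_cells_all - len(cells)
    cells_before_minplot = len(cells)
    if min_plots > 1:
        cells = min_plot_filter(cells, min_plots)
    n_excl_minplot = cells_before_minplot - len(cells)

    abundance = abundance[abundance["cell_id"].isin(cells.index)]
    cwm_t, cwm_r, bad_cells = cwm_matrix(abundance, filled)
    cells = cells.loc[cwm_t.index]

    est = ScaledPCA(n_components=n_components).fit(cwm_t)
    summary = est.summary(cwm_t)
    return {
        "cells": cells,
        "abundance": abundance,
        "cwm_transformed": cwm_t,
        "cwm_raw": cwm_r,
        "estimator": est,
        "ordination": summary,
        "counts": {
            "cells_total": n_cells_all,
            "cells_excluded_dominance": n_excl_dom,
            "cells_excluded_min_plots": n_excl_minplot,
            "cells_excluded_missing_traits": len(bad_cells),
            "n_communities": len(cwm_t),
        },
    }


def run_main(config: RunConfig, write: bool = True) -> dict:
    """Execute the full analysis; returns the result bundle.

    With ``write=True`` all tables are written as CSV under
    ``config.output_dir`` together with ``manifest.json``.
    """
    counts: dict[str, int] = {}
    try:
        data = _load_inputs(config)
    except Exception as e:  # noqa: BLE001
        raise PipelineError(f"input stage failed: {e}") from e
    trees, taxonomy, traits = data["trees"], data["taxonomy"], data["traits"]

    try:
        imputer = HierarchicalTraitImputer(
            taxonomy=taxonomy,
            method=config.gapfill_method,
            k=config.knn_k,
            random_state=config.stage_seed(1),
        )
        filled = imputer.fit_transform(traits)
    except Exception as e:  # noqa: BLE001
        raise PipelineError(f"trait gap-fill stage failed: {e}") from e

    try:
        counts["trees_total"] = len(trees)
        alive = trees["status"] == "living"
        big = trees["dbh_cm"] > config.min_dbh
        counts["trees_removed_dead"] = int((~alive).sum())
        counts["trees_removed_subthreshold"] = int((alive & ~big).sum())
        trees_kept = filter_trees(trees, config.min_dbh)
        counts["trees_kept"] = len(trees_kept)

        ordn = _ordination_pipeline(
            trees_kept, taxonomy, filled, config.resolution,
            config.min_plots, config.n_components,
        )
        counts.update(ordn["counts"])
    except PipelineError:
        raise
    except Exception as e:  # noqa: BLE001
        raise PipelineError(f"community/ordination stage failed: {e}") from e

    cwm_t = ordn["cwm_transformed"]
    corr_r, corr_p = correlation_matrix(cwm_t)
    scores = ordn["ordination"].scores
    cells = ordn["cells"]
    scores_map = cells[["lon", "lat"]].join(scores)

    bundle: dict = {
        "config": config,
        "taxonomy": taxonomy,
        "traits_raw": traits,
        "traits_filled": filled,
        "trees_kept": trees_kept,
        "truth": data.get("truth"),
        **{k: v for k, v in ordn.items() if k != "counts"},
        "correlation_r": corr_r,
        "correlation_p": corr_p,
        "scores_map": scores_map,
    }

    climate = data.get("climate")
    if climate is not None:
        try:
            cell_climate = aggregate_climate(climate, config.resolution)
            joined = scores.join(cell_climate, how="left")
            has_climate = joined[list(CLIMATE_VARS)].notna().all(axis=1)
            counts["cells_missing_climate"] = int((~has_climate).sum())
            joined = joined[has_climate]
            counts["n_communities_climate"] = len(joined)

            X = joined[list(CLIMATE_VARS)]
            importance = {
                pc: bootstrap_importance(
                    X, joined[pc], n_boot=config.n_boot,
                    seed=config.stage_seed(2 + i), response=pc,
                )
                for i, pc in enumerate(scores.columns)
            }
            univariate = univariate_regressions(X, joined[scores.columns])
            div_bins, div_trend = aridity_divergence(
                joined[scores.columns], joined["AI"], n_bins=config.n_ai_bins
            )
            bundle.update(
                cell_climate=cell_climate,
                importance=importance,
                univariate=univariate,
                divergence_bins=div_bins,
                divergence_trend=div_trend,
            )
        except Exception as e:  # noqa: BLE001
            raise PipelineError(f"climate importance stage failed: {e}") from e

    bundle["counts"] = counts
    manifest = {
        "package_version": _PKG_VERSION,
        "seed": config.seed,
        "config_digest": config.digest(),
        "config": json.loads(
            json.dumps(
                {k: v for k, v in dataclasses.asdict(config).items()
                 if k != "output_dir"},
                default=lambda o: list(o) if isinstance(o, tuple) else str(o),
            )
        ),
        "counts": counts,
    }
    bundle["manifest"] = manifest

    if write:
        _write_bundle(bundle, Path(config.output_dir))
    return bundle


def _write_bundle(bundle: dict, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)

    def w(df: pd.DataFrame, name: str, index: bool = True) -> None:
        df.to_csv(outdir / name, float_format=_FLOAT_FMT, index=index)

    write_trait_table(bundle["traits_filled"], outdir / "traits_filled.csv")
    w(bundle["cells"], "communities.csv")
    w(bundle["cwm_transformed"], "cwm_transformed.csv")
    w(bundle["cwm_raw"], "cwm_raw.csv")
    ordn = bundle["ordination"]
    w(ordn.loadings, "loadings.csv")
    w(
        pd.DataFrame(
            {
                "component": [f"PC{i + 1}" for i in range(len(ordn.explained_pct))],
                "eigenvalue": ordn.eigenvalues[: len(ordn.explained_pct)],
                "explained_pct": ordn.explained_pct,
            }
        ),
        "explained_variance.csv",
        index=False,
    )
    w(ordn.contributions, "contributions.csv")
    w(bundle["scores_map"], "scores_map.csv")
    w(bundle["correlation_r"], "correlation_r.csv")
    w(bundle["correlation_p"], "correlation_p.csv")
    if "importance" in bundle:
        rows = []
        for pc, res in bundle["importance"].items():
            tab = res.table().reset_index()
            tab.insert(0, "response", pc)
            tab["r_squared"] = res.r_squared
            rows.append(tab)
            w(res.draws, f"importance_draws_{pc}.csv", index=False)
        w(pd.concat(rows, ignore_index=True), "importance.csv", index=False)
        w(bundle["univariate"], "univariate_regressions.csv", index=False)
        w(bundle["divergence_bins"], "divergence_bins.csv", index=False)
        w(bundle["divergence_trend"], "divergence_trend.csv", index=False)
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(bundle["manifest"], fh, indent=2, sort_keys=True)
        fh.write("\n")


def run_sensitivity(config: RunConfig, write: bool = True) -> pd.DataFrame:
    """Procrustes congruence of the ordination under analysis variants.

    Variants: the three gap-fill methods, coarser/finer grids (0.1 and 0.5
    degrees), the <`min_plots`=3 community filter, and a species-level PCA
    of the filled trait table.  Each variant's two-axis loadings are
    compared to the baseline by a permutation Procrustes test.
    """
    base = run_main(config, write=False)
    base_loadings = base["ordination"].loadings
    filled = base["traits_filled"]
    taxonomy = base["taxonomy"]
    trees_kept = base["trees_kept"]
    traits_input = base["traits_raw"]

    comparisons: list[tuple[str, pd.DataFrame]] = []

    for method in GAPFILL_METHODS:
        if method == config.gapfill_method:
            continue
        imputer = HierarchicalTraitImputer(
            taxonomy=taxonomy, method=method, k=config.knn_k,
            random_state=config.stage_seed(1),
        )
        refilled = imputer.fit_transform(traits_input)
        ordn = _ordination_pipeline(
            trees_kept, taxonomy, refilled, config.resolution,
            config.min_plots, config.n_components,
        )
        comparisons.append((f"gapfill:{method}", ordn["ordination"].loadings))

    for res in (0.1, 0.5):
        ordn = _ordination_pipeline(
            trees_kept, taxonomy, filled, res, config.min_plots,
            config.n_components,
        )
        comparisons.append((f"grid:{res}", ordn["ordination"].loadings))

    ordn = _ordination_pipeline(
        trees_kept, taxonomy, filled, config.resolution, 3,
        config.n_components,
    )
    comparisons.append(("min_plots:3", ordn["ordination"].loadings))

    species_t = transform_traits(filled.values)
    sp_est = ScaledPCA(n_components=config.n_components).fit(species_t)
    comparisons.append(("species_level", sp_est.loadings_))

    rows = []
    for i, (name, loadings) in enumerate(comparisons):
        res = procrustes_compare(
            base_loadings, loadings, n_perm=config.n_perm,
            seed=config.stage_seed(50 + i),
        )
        rows.append(
            {
                "comparison": name,
                "m2": res.m2,
                "p_value": res.p_value,
                "n_perm": res.n_permutations,
            }
        )
    table = pd.DataFrame(rows)
    if write:
        outdir = Path(config.output_dir)
        outdir.mkdir(parents=True, exist_ok=True)
        table.to_csv(outdir / "sensitivity_procrustes.csv", index=False,
                     float_format=_FLOAT_FMT)
    return table
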