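"""Synthetic taxonomy, trait, inventory and climate data with known truth.

The generator emulates the statistical structure the downstream analysis
assumes, so that axis recovery, driver recovery and divergence recovery are
well-posed tests:

* a nested taxonomy (families > genera > species) carrying phylogenetic
  trait signal as family- and genus-level random intercepts;
* species traits produced by a two-factor linear latent model on the
  transformed trait scale — axis 1 is the acquisitive-conservative
  spectrum, axis 2 the isohydricity spectrum — with per-trait signed
  loadings, so the species trait correlation matrix converges to the
  analytic ``diag(s) (L L' + diag(sigma2)) diag(s)`` correlation;
* inventory plots on a climate gradient where species are sampled with
  Gaussian niche weights centred on a climate-dependent optimum along
  axis 1 (and optionally axis 2), with niche breadth *increasing* as the
  aridity index falls — drier communities admit a wider range of water
  stress strategies;
* tree diameters from a shifted log-normal above the 12.7 cm inventory
  threshold, plus configurable fractions of dead and sub-threshold stems
  to exercise the downstream filters.

One trait value is emitted per species (no intraspecific variation).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .datatypes import (
    CLIMATE_VARS,
    FUNCTIONAL_GROUPS,
    LOG_TRAITS,
    NEGATIVE_TRAITS,
    TRAITS,
    TraitTable,
)

__all__ = [
    "SynthConfig",
    "SynthTruth",
    "generate_taxonomy",
    "generate_traits",
    "generate_inventory",
    "generate_dataset",
    "true_cwm_axes",
]

# Default signed loadings of the 8 traits on (axis1, axis2), on the
# transformed scale (ln for all but WD; P50 and TLP sign-flipped before the
# log, so e.g. a higher ln(-TLP) column value means a *more negative* raw
# turgor loss point, i.e. more anisohydric).  Axis 1 carries the five
# acquisitive-conservative / hydraulic-efficiency traits, axis 2 the three
# stomatal-regulation traits.
DEFAULT_LATENT_LOADINGS: dict[str, tuple[float, float]] = {
    "N": (0.80, 0.0),
    "Ks": (0.80, 0.0),
    "LS": (0.70, 0.0),
    "LMA": (-0.70, 0.0),
    "P50": (-0.70, 0.0),
    "Slope": (0.0, 0.60),
    "TLP": (0.0, 0.80),
    "WD": (0.0, 0.60),
}

# Per-trait location and scale applied on the transformed scale; affine per
# column, hence invisible to correlation-based ordination.  Locations put the
# back-transformed traits in realistic ranges (N ~ 15 mg/g, LMA ~ 100 g/m2,
# P50 ~ -3 MPa, TLP ~ -2 MPa, WD ~ 0.6 g/cm3).
DEFAULT_TRAIT_MEANS: dict[str, float] = {
    "N": math.log(15.0),
    "Ks": math.log(2.0),
    "LS": math.log(3000.0),
    "LMA": math.log(100.0),
    "P50": math.log(3.0),
    "Slope": math.log(50.0),
    "TLP": math.log(2.0),
    "WD": 0.60,
}
DEFAULT_TRAIT_SCALES: dict[str, float] = {
    "N": 0.30,
    "Ks": 0.45,
    "LS": 0.40,
    "LMA": 0.30,
    "P50": 0.35,
    "Slope": 0.40,
    "TLP": 0.25,
    "WD": 0.08,
}

DEFAULT_CLIMATE_GRADIENT: dict[str, tuple[float, float]] = {
    "MAT": (2.0, 18.0),
    "MAP": (300.0, 1500.0),
    "Summer_T": (12.0, 28.0),
    "Summer_P": (40.0, 300.0),
    "AI": (0.2, 2.0),
}

_WD_FLOOR = 0.05  # g cm-3, positivity floor for the identity-scale trait


class SynthConfigError(ValueError):
    """Raised for inconsistent generator configurations."""


@dataclass
class SynthConfig:
    """Conditions for the synthetic study system.

    Defaults give 10 x 4 x 5 = 200 species over 2000 plots of ~30 trees on a
    0.25-degree-compatible lon/lat window, with 30% missingness per trait,
    10% dead stems and 5% sub-threshold stems.
    """

    n_families: int = 10
    genera_per_family: int = 4
    species_per_genus: int = 5
    latent_loadings: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_LATENT_LOADINGS)
    )
    phylo_sd_family: float = 0.30
    phylo_sd_genus: float = 0.30
    residual_sd: float = 0.20
    trait_means: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_TRAIT_MEANS)
    )
    trait_scales: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_TRAIT_SCALES)
    )
    allow_uncoupled_traits: bool = False
    axis_phylo_corr: float = 0.6  # intra-family correlation of axis scores
    group_axis1_separation: float = 1.5  # BD/BE/NC centre spacing on axis 1

    n_plots: int = 2000
    trees_per_plot: int = 30
    lon_range: tuple[float, float] = (0.0, 8.0)
    lat_range: tuple[float, float] = (43.0, 47.0)
    climate_gradient: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_CLIMATE_GRADIENT)
    )
    climate_axis1_effect: float = 1.2  # Summer_T -> axis-1 optimum (per sd)
    climate_axis2_effect: float = 0.0  # MAT -> axis-2 optimum (per sd)
    niche_breadth_base: float = 0.35
    niche_breadth_aridity_slope: float = 0.90
    dead_fraction: float = 0.10
    subthreshold_fraction: float = 0.05
    dbh_lognorm_mean: float = math.log(8.0)  # cm above threshold
    dbh_lognorm_sigma: float = 0.70
    min_dbh: float = 12.7

    missing_fraction: float | Mapping[str, float] = 0.30
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_families", "genera_per_family", "species_per_genus",
                     "n_plots", "trees_per_plot"):
            if getattr(self, name) < 1:
                raise SynthConfigError(f"{name} must be >= 1")
        for t, frac in self.missing_by_trait().items():
            if not 0.0 <= frac < 1.0:
                raise SynthConfigError(
                    f"missing_fraction for {t} must be in [0, 1), got {frac}"
                )
        if set(self.latent_loadings) != set(TRAITS):
            raise SynthConfigError("latent_loadings must cover the 8 traits")
        if not 0.0 <= self.axis_phylo_corr < 1.0:
            raise SynthConfigError("axis_phylo_corr must be in [0, 1)")
        for sd_name in ("phylo_sd_family", "phylo_sd_genus", "residual_sd"):
            if getattr(self, sd_name) < 0:
                raise SynthConfigError(f"{sd_name} must be nonnegative")

    def missing_by_trait(self) -> dict[str, float]:
        if isinstance(self.missing_fraction, Mapping):
            return {t: float(self.missing_fraction.get(t, 0.0)) for t in TRAITS}
        return {t: float(self.missing_fraction) for t in TRAITS}

    @property
    def n_species(self) -> int:
        return self.n_families * self.genera_per_family * self.species_per_genus

    def loading_matrix(self) -> np.ndarray:
        return np.array([self.latent_loadings[t] for t in TRAITS], dtype=float)

    def rng(self, stage: int) -> np.random.Generator:
        """Stage-keyed child generator so stages stay decoupled."""
        return np.random.default_rng(np.random.SeedSequence(
            entropy=int(self.seed), spawn_key=(int(stage),)
        ))


@dataclass
class SynthTruth:
    """Ground truth stored alongside the generated data for recovery tests."""

    axes: pd.DataFrame  # species-indexed, columns axis1/axis2
    loadings: pd.DataFrame  # traits x (axis1, axis2), the planted L
    transformed_traits: pd.DataFrame  # species x traits, transformed scale, complete
    plot_expected_cwm: pd.DataFrame | None = None  # plot-indexed axis1/axis2
    climate_effects: dict[str, float] = field(default_factory=dict)


def generate_taxonomy(config: SynthConfig) -> pd.DataFrame:
    """Build a balanced species -> genus -> family taxonomy.

    Returns a DataFrame with columns ``species, genus, family,
    functional_group``; species names are binomial-style with the genus as
    the first epithet, functional groups cycle over genera so every group is
    represented.
    """
    rows = []
    for f in range(config.n_families):
        family = f"Famula{f + 1:02d}aceae"
        group = FUNCTIONAL_GROUPS[f % len(FUNCTIONAL_GROUPS)]
        for g in range(config.genera_per_family):
            genus = f"Genusia{f + 1:02d}x{g + 1:02d}"

            for s in range(config.species_per_genus):
                rows.append(
                    {
                        "species": f"{genus} specia{s + 1:02d}",
                        "genus": genus,
                        "family": family,
                        "functional_group": group,
                    }
                )
    tax = pd.DataFrame(rows)
    assert tax["species"].is_unique
    return tax


def _back_transform(trait: str, y: np.ndarray) -> np.ndarray:
    if trait in NEGATIVE_TRAITS:
        return -np.exp(y)
    if trait in LOG_TRAITS:
        return np.exp(y)
    return np.maximum(y, _WD_FLOOR)  # WD, identity scale


def generate_traits(
    taxonomy: pd.DataFrame, config: SynthConfig
) -> tuple[TraitTable, SynthTruth]:
    """Draw species traits from the two-axis latent model, then mask MCAR.

    On the transformed scale each trait is ``mu_t + s_t * (L_t1 a1 + L_t2 a2
    + u_family + u_genus + eps)`` with standard-normal species axis scores
    ``a1, a2`` and independent nested intercepts.  Raw-scale traits are
    recovered by inverting the community-module transforms (exp, negated exp,
    identity for WD), and missingness is applied completely at random per
    trait at the configured fraction.
    """
    L = config.loading_matrix()
    if not config.allow_uncoupled_traits:
        dead_rows = [TRAITS[i] for i in range(len(TRAITS))
                     if np.allclose(L[i], 0.0)]
        if dead_rows:
            raise SynthConfigError(
                "traits coupled to neither axis: "
                f"{dead_rows}; set allow_uncoupled_traits=True to permit"
            )

    rng = config.rng(1)
    species = taxonomy["species"].to_numpy()
    n = len(species)

    fam_codes, fam_idx = np.unique(taxonomy["family"], return_inverse=True)
    gen_codes, gen_idx = np.unique(taxonomy["genus"], return_inverse=True)
    # Axis scores carry phylogenetic signal (family random component) and a
    # functional-group contrast along axis 1: broadleaved deciduous families
    # sit on the acquisitive side, conifers on the conservative side.  The
    # result is rescaled by its theoretical sd so marginals stay ~N(0, 1).
    rho = config.axis_phylo_corr
    sep = config.group_axis1_separation
    group_of_family = (
        taxonomy.drop_duplicates("family").set_index("family")["functional_group"]
    )
    offset_map = {"BD": sep, "BE": 0.0, "NC": -sep}
    offsets = np.array(
        [offset_map[group_of_family[f]] for f in fam_codes]
    )
    fam_axes = rng.standard_normal((len(fam_codes), 2))
    axes = math.sqrt(rho) * fam_axes[fam_idx] + math.sqrt(1.0 - rho) * (
        rng.standard_normal((n, 2))
    )
    axes[:, 0] += offsets[fam_idx]
    # across-group variance of the offsets under the balanced group cycle
    off_var = float(np.mean((np.array(list(offset_map.values()))) ** 2))
    axes[:, 0] /= math.sqrt(1.0 + off_var)

    fam_eff = rng.normal(0.0, config.phylo_sd_family, (len(fam_codes), 8))
    gen_eff = rng.normal(0.0, config.phylo_sd_genus, (len(gen_codes), 8))
    resid = rng.normal(0.0, config.residual_sd, (n, 8))

    latent = axes @ L.T + fam_eff[fam_idx] + gen_eff[gen_idx] + resid
    mu = np.array([config.trait_means[t] for t in TRAITS])
    sc = np.array([config.trait_scales[t] for t in TRAITS])
    transformed = mu + sc * latent

    raw = np.column_stack(
        [_back_transform(t, transformed[:, j]) for j, t in enumerate(TRAITS)]
    )
    values = pd.DataFrame(raw, index=pd.Index(species, name="species"),
                          columns=list(TRAITS))

    mask = np.zeros((n, 8), dtype=bool)
    fractions = config.missing_by_trait()
    for j, t in enumerate(TRAITS):
        mask[:, j] = rng.random(n) < fractions[t]
    values = values.mask(mask)
    provenance = values.where(values.isna(), "observed").where(values.notna())

    truth = SynthTruth(
        axes=pd.DataFrame(axes, index=values.index, columns=["axis1", "axis2"]),
        loadings=pd.DataFrame(L, index=list(TRAITS), columns=["axis1", "axis2"]),
        transformed_traits=pd.DataFrame(
            transformed, index=values.index, columns=list(TRAITS)
        ),
    )
    return TraitTable(values, provenance), truth


def _range_z(x: np.ndarray, lo: float, hi: float) -> np.ndarray:
    """Standardise by the uniform-gradient moments (deterministic truth)."""
    mean = 0.5 * (lo + hi)
    sd = (hi - lo) / math.sqrt(12.0)
    return (x - mean) / sd


def generate_inventory(
    taxonomy: pd.DataFrame, truth: SynthTruth, config: SynthConfig
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Place plots on a climate gradient and fill them with filtered trees.

    Species enter a plot with probability proportional to a Gaussian niche
    weight ``exp(-(a1 - mu1(climate))^2 / (2 w(AI)^2))`` (times the matching
    axis-2 factor when a climate -> axis-2 effect is configured); the niche
    breadth ``w`` widens linearly as the aridity index decreases.  Returns
    ``(trees, climate)``; ``truth`` is updated in place with per-plot
    expected CWM axis positions and the planted climate effect sizes.
    """
    rng = config.rng(2)
    g = config.climate_gradient
    n_plots = config.n_plots

    lon = rng.uniform(*config.lon_range, n_plots)
    lat = rng.uniform(*config.lat_range, n_plots)
    t_lon = (lon - config.lon_range[0]) / (config.lon_range[1] - config.lon_range[0])
    t_lat = (lat - config.lat_range[0]) / (config.lat_range[1] - config.lat_range[0])

    st_lo, st_hi = g["Summer_T"]
    mat_lo, mat_hi = g["MAT"]
    ai_lo, ai_hi = g["AI"]
    summer_t = st_lo + (st_hi - st_lo) * t_lon + rng.normal(0, 0.3, n_plots)
    mat = mat_lo + (mat_hi - mat_lo) * t_lat + rng.normal(0, 0.3, n_plots)
    # wetter (higher AI) at the cool end of the summer-temperature gradient
    ai = np.exp(
        math.log(ai_hi) + (math.log(ai_lo) - math.log(ai_hi)) * t_lon
        + rng.normal(0, 0.2, n_plots)
    )
    ai_frac = np.clip((ai - ai_lo) / (ai_hi - ai_lo), 0.0, 1.0)
    map_lo, map_hi = g["MAP"]
    mapr = np.clip(
        map_lo + (map_hi - map_lo) * ai_frac + rng.normal(0, 40.0, n_plots),
        50.0, None,
    )
    sp_lo, sp_hi = g["Summer_P"]
    summer_p = np.clip(
        sp_lo + (sp_hi - sp_lo) * ai_frac + rng.normal(0, 15.0, n_plots),
        5.0, None,
    )

    width = config.niche_breadth_base + config.niche_breadth_aridity_slope * (
        1.0 - ai_frac
    )
    if np.any(width <= 0):
        raise SynthConfigError(
            "niche breadth nonpositive on the gradient; check "
            "niche_breadth_base / niche_breadth_aridity_slope"
        )

    mu1 = config.climate_axis1_effect * _range_z(summer_t, st_lo, st_hi)
    mu2 = config.climate_axis2_effect * _range_z(mat, mat_lo, mat_hi)

    a1 = truth.axes["axis1"].to_numpy()
    a2 = truth.axes["axis2"].to_numpy()
    species = truth.axes.index.to_numpy()
    n_sp = len(species)

    plot_ids = np.array([f"P{i + 1:06d}" for i in range(n_plots)])
    n_trees = config.trees_per_plot

    # niche weights: plots x species
    logw = -((a1[None, :] - mu1[:, None]) ** 2) / (2.0 * width[:, None] ** 2)
    if config.climate_axis2_effect != 0.0:
        logw = logw - ((a2[None, :] - mu2[:, None]) ** 2) / (
            2.0 * width[:, None] ** 2
        )
    probs = np.exp(logw - logw.max(axis=1, keepdims=True))
    probs /= probs.sum(axis=1, keepdims=True)

    exp_cwm1 = probs @ a1
    exp_cwm2 = probs @ a2

    # species draws per tree, vectorised via inverse-CDF sampling
    cum = np.cumsum(probs, axis=1)
    u = rng.random((n_plots, n_trees))
    sp_idx = np.empty((n_plots, n_trees), dtype=np.int64)
    for i in range(n_plots):
        sp_idx[i] = np.searchsorted(cum[i], u[i], side="right")
    sp_idx = np.minimum(sp_idx, n_sp - 1)

    total = n_plots * n_trees
    dbh = config.min_dbh + rng.lognormal(
        config.dbh_lognorm_mean, config.dbh_lognorm_sigma, total
    )
    sub = rng.random(total) < config.subthreshold_fraction
    dbh[sub] = rng.uniform(5.0, config.min_dbh, sub.sum())
    dead = rng.random(total) < config.dead_fraction
    status = np.where(dead, "dead", "living")

    trees = pd.DataFrame(
        {
            "plot_id": np.repeat(plot_ids, n_trees),
            "lon": np.repeat(lon, n_trees),
            "lat": np.repeat(lat, n_trees),
            "species": species[sp_idx.ravel()],
            "dbh_cm": dbh,
            "status": status,
        }
    )
    climate = pd.DataFrame(
        {
            "plot_id": plot_ids,
            "lon": lon,
            "lat": lat,
            "MAT": mat,
            "MAP": mapr,
            "Summer_T": summer_t,
            "Summer_P": summer_p,
            "AI": ai,
        }
    )

    truth.plot_expected_cwm = pd.DataFrame(
        {"axis1": exp_cwm1, "axis2": exp_cwm2},
        index=pd.Index(plot_ids, name="plot_id"),
    )
    truth.climate_effects = {
        "Summer_T->axis1": config.climate_axis1_effect,
        "MAT->axis2": config.climate_axis2_effect,
    }
    return trees, climate


def generate_dataset(config: SynthConfig) -> dict:
    """Run all three generator stages; returns a dict of tables plus truth."""
    taxonomy = generate_taxonomy(config)
    traits, truth = generate_traits(taxonomy, config)
    trees, climate = generate_inventory(taxonomy, truth, config)
    return {
        "taxonomy": taxonomy,
        "traits": traits,
        "truth": truth,
        "trees": trees,
        "climate": climate,
    }


def true_cwm_axes(
    trees: pd.DataFrame, truth: SynthTruth, resolution: float = 0.25
) -> pd.DataFrame:
    """Realised basal-area-weighted CWM of the *true* axis scores per cell.

    Computed directly from the generator's species axis positions and the
    (already filtered) tree table, before any trait inference; the reference
    configuration for axis-recovery tests.
    """
    from .community import assign_grid, basal_area

    t = trees.copy()
    t["cell_id"] = assign_grid(t, resolution)
    t["ba"] = basal_area(t["dbh_cm"].to_numpy())
    t = t.join(truth.axes, on="species")
    w = t.groupby("cell_id")["ba"].transform("sum")
    t["w1"] = t["ba"] * t["axis1"] / w
    t["w2"] = t["ba"] * t["axis2"] / w
    out = t.groupby("cell_id")[["w1", "w2"]].sum()
    out.columns = ["axis1", "axis2"]
    return out
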