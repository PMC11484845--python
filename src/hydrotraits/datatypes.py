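"""Shared domain types and trait/climate naming conventions.

Trait columns follow the eight water-stress-related traits usually analysed
together in forest functional biogeography:

====== ======================================== ====================
name   meaning                                  units
====== ======================================== ====================
N      leaf nitrogen content                    mg g-1
Ks     max xylem conductivity per sapwood area  kg m-1 s-1 MPa-1
LS     leaf area to sapwood area ratio          mm2 mm-2
LMA    leaf mass per area                       g m-2
P50    xylem water potential at 50% cond. loss  MPa (negative)
Slope  embolism vulnerability curve slope       % MPa-1
TLP    leaf turgor loss point                   MPa (negative)
WD     wood density                             g cm-3
====== ======================================== ====================

P50 and TLP are water potentials and must be negative on the raw scale;
before log transformation they are multiplied by -1.  Wood density is the
only trait analysed untransformed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: canonical trait column order
TRAITS: tuple[str, ...] = ("N", "Ks", "LS", "LMA", "P50", "Slope", "TLP", "WD")

#: traits that are log-transformed before CWM calculation (all but WD)
LOG_TRAITS: tuple[str, ...] = ("N", "Ks", "LS", "LMA", "P50", "Slope", "TLP")

#: traits stored as negative water potentials (sign-flipped before the log)
NEGATIVE_TRAITS: tuple[str, ...] = ("P50", "TLP")

#: climate variables, per plot and aggregated per grid cell
CLIMATE_VARS: tuple[str, ...] = ("MAT", "MAP", "Summer_T", "Summer_P", "AI")

#: broadleaved deciduous / broadleaved evergreen / needleleaved conifer
FUNCTIONAL_GROUPS: tuple[str, ...] = ("BD", "BE", "NC")

#: provenance codes for trait cells, in fill order
PROVENANCE_CODES: tuple[str, ...] = (
    "observed",
    "genus_median",
    "family_median",
    "phylo_imputed",
)


class TraitTableError(ValueError):
    """Raised when a trait table violates its sign/positivity contract."""


@dataclass
class TraitTable:
    """Species x trait values with a parallel per-cell provenance table.

    ``values`` is a species-indexed DataFrame with the eight trait columns
    (NaN = missing); ``provenance`` has the same shape and holds one of the
    :data:`PROVENANCE_CODES` wherever a value is present and NaN elsewhere.
    """

    values: pd.DataFrame
    provenance: pd.DataFrame

    def __post_init__(self) -> None:
        if list(self.values.columns) != list(TRAITS):
            self.values = self.values.reindex(columns=list(TRAITS))
        if list(self.provenance.columns) != list(TRAITS):
            self.provenance = self.provenance.reindex(columns=list(TRAITS))
        self.provenance = self.provenance.astype(object)
        if not self.values.index.equals(self.provenance.index):
            raise TraitTableError("values and provenance must share an index")
        has_val = self.values.notna()
        has_prov = self.provenance.notna()
        if not has_val.equals(has_prov):
            raise TraitTableError("provenance present iff value present")

    def validate_signs(self) -> None:
        """Check the sign conventions (P50/TLP <= 0, other traits > 0)."""
        v = self.values
        for t in NEGATIVE_TRAITS:
            bad = v.index[v[t].gt(0)]
            if len(bad):
                raise TraitTableError(
                    f"{t} must be nonpositive; positive for {list(bad[:5])}"
                )
        for t in ("N", "Ks", "LS", "LMA", "Slope", "WD"):
            bad = v.index[v[t].le(0)]
            if len(bad):
                raise TraitTableError(
                    f"{t} must be positive; nonpositive for {list(bad[:5])}"
                )

    @property
    def species(self) -> pd.Index:
        return self.values.index

    def n_missing(self) -> pd.Series:
        return self.values.isna().sum()

    def provenance_counts(self) -> pd.DataFrame:
        """Per-trait counts of each provenance code (partition of filled cells)."""
        out = {}
        for code in PROVENANCE_CODES:
            out[code] = (self.provenance == code).sum()
        return pd.DataFrame(out)

    def copy(self) -> "TraitTable":
        return TraitTable(self.values.copy(), self.provenance.copy())


@dataclass
class ValidationReport:
    """Tidy masking-validation results: one row per (trait, proportion, replicate).

    Columns: ``trait, proportion, replicate, r2, rmse``.  ``r2`` is the squared
    Pearson correlation of z-transformed predicted vs observed values and
    ``rmse`` the root mean squared error on the same z scale.
    """

    records: pd.DataFrame
    skipped: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(
            columns=["trait", "proportion", "replicate", "reason"]
        )
    )

    def means(self) -> pd.DataFrame:
        """Mean R2 and RMSE per (trait, proportion) over replicates."""
        return (
            self.records.groupby(["trait", "proportion"], as_index=False)[
                ["r2", "rmse"]
            ].mean()
        )


@dataclass
class OrdinationSummary:
    """Loadings, explained-variance shares, contributions and scores of a PCA."""

    loadings: pd.DataFrame  # traits x components (unit eigenvectors, signed)
    eigenvalues: np.ndarray  # all p eigenvalues of the correlation matrix
    explained_pct: np.ndarray  # per retained component, percent of total
    contributions: pd.DataFrame  # traits x components, percent, sums to 100
    scores: pd.DataFrame  # observations x components
    means: pd.Series
    sds: pd.Series
    sign_flips: np.ndarray  # +-1 applied per component by the sign convention


@dataclass
class ProcrustesResult:
    """Symmetric Procrustes superimposition of two loading configurations."""

    m2: float  # residual dissimilarity in [0, 1]
    rotation: np.ndarray
    scale: float
    p_value: float
    n_permutations: int
    scaling: bool  # whether the optimal dilation was applied


@dataclass
class ImportanceResult:
    """LMG relative-importance decomposition with bootstrap intervals."""

    response: str
    shares: pd.Series  # point-estimate LMG share per regressor
    r_squared: float
    boot_mean: pd.Series
    ci_low: pd.Series
    ci_high: pd.Series
    draws: pd.DataFrame  # n_boot x regressors, for violin plots
    n_obs: int
    n_boot: int
    ci_level: tuple[float, float] = (2.5, 97.5)

    def table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "share": self.shares,
                "boot_mean": self.boot_mean,
                "ci_lo": self.ci_low,
                "ci_hi": self.ci_high,
            }
        ).rename_axis("variable")
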