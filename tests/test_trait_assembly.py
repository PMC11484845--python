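"""Name canonicalisation, medians, hierarchical gap-fill and its validation."""

import numpy as np
import pandas as pd
import pytest

from conftest import make_trait_table
from hydrotraits import (
    HierarchicalTraitImputer,
    SynthConfig,
    canonicalise_names,
    gapfill_hierarchy,
    generate_taxonomy,
    generate_traits,
    masking_validation,
    phylo_impute,
    species_median,
)
from hydrotraits.datatypes import TRAITS
from hydrotraits.trait_assembly import CanonicalisationError, TraitImputationError


class TestCanonicaliseNames:
    def test_whitespace_and_case_normalisation(self):
        out = canonicalise_names(["  quercus Robur ", "FAGUS   SYLVATICA"])
        assert list(out["canonical"]) == ["Quercus robur", "Fagus sylvatica"]

    def test_unmapped_name_flagged_and_unchanged(self):
        out = canonicalise_names(["Picea abies"], {"Abies alba": "Abies x"})
        assert out.loc[0, "canonical"] == "Picea abies"
        assert not out.loc[0, "mapped"]

    def test_synonym_merge_pools_observations_by_median(self):
        """Rows of a synonym are pooled into the target before the median."""
        obs = pd.DataFrame(
            {
                "species": ["Alpha oldname", "Alpha oldname", "Alpha target"],
                "trait": ["WD", "WD", "WD"],
                "value": [0.2, 0.4, 0.9],
            }
        )
        mapping = canonicalise_names(
            obs["species"], {"Alpha oldname": "Alpha target"}
        )
        obs["species"] = obs["species"].map(
            dict(zip(mapping["raw"], mapping["canonical"]))
        )
        table = species_median(obs)
        # pooled {0.2, 0.4, 0.9} -> median 0.4, computed by hand
        assert table.values.loc["Alpha target", "WD"] == pytest.approx(0.4)

    def test_conflicting_synonym_targets_raise(self):
        with pytest.raises(CanonicalisationError):
            canonicalise_names(
                ["Alpha x"], {"alpha  X": "Alpha y", "Alpha x": "Alpha z"}
            )


class TestSpeciesMedian:
    @pytest.mark.parametrize(
        "values,expected",
        [([2.0, 4.0, 9.0], 4.0), ([2.0, 4.0], 3.0)],
    )
    def test_median_of_observations(self, values, expected):
        obs = pd.DataFrame(
            {"species": "Alpha sp1", "trait": "LMA", "value": values}
        )
        table = species_median(obs)
        assert table.values.loc["Alpha sp1", "LMA"] == expected
        assert table.provenance.loc["Alpha sp1", "LMA"] == "observed"

    def test_no_observations_leave_cell_missing(self):
        obs = pd.DataFrame(
            {"species": ["Alpha sp1"], "trait": ["LMA"], "value": [10.0]}
        )
        table = species_median(obs)
        assert np.isnan(table.values.loc["Alpha sp1", "WD"])
        assert pd.isna(table.provenance.loc["Alpha sp1", "WD"])


class TestGapfillHierarchy:
    def test_genus_median_fill(self, toy_taxonomy):
        table = make_trait_table(
            {
                "Alpha sp1": {"WD": 0.5},
                "Alpha sp2": {"WD": 0.7},
                "Alpha sp3": {},
                "Beta sp1": {"WD": 0.4},
                "Beta sp2": {"WD": 0.6},
                "Gamma sp1": {"WD": 0.9},
                "Gamma sp2": {},
            }
        )
        out = gapfill_hierarchy(table, toy_taxonomy)
        # congeneric medians {0.5, 0.7} -> 0.6
        assert out.values.loc["Alpha sp3", "WD"] == pytest.approx(0.6)
        assert out.provenance.loc["Alpha sp3", "WD"] == "genus_median"

    def test_family_fallback_when_genus_empty(self, toy_taxonomy):
        table = make_trait_table(
            {
                "Alpha sp1": {"WD": 0.4},
                "Alpha sp2": {"WD": 0.6},
                "Alpha sp3": {"WD": 0.8},
                "Beta sp1": {},
                "Beta sp2": {},
                "Gamma sp1": {"WD": 0.9},
                "Gamma sp2": {},
            }
        )
        out = gapfill_hierarchy(table, toy_taxonomy)
        # genus Beta empty; confamilial observed {0.4, 0.6, 0.8} -> 0.6
        assert out.values.loc["Beta sp1", "WD"] == pytest.approx(0.6)
        assert out.provenance.loc["Beta sp1", "WD"] == "family_median"
        # other family untouched by Famone's values
        assert np.isnan(out.values.loc["Gamma sp2", "WD"]) or (
            out.provenance.loc["Gamma sp2", "WD"] != "family_median"
            or out.values.loc["Gamma sp2", "WD"] == pytest.approx(0.9)
        )

    def test_full_genus_coverage_leaves_nothing_for_phylo(self):
        """MCAR at 0.3 with every genus observed -> chain ends at genus/family."""
        cfg = SynthConfig(seed=13, missing_fraction=0.3)
        tax = generate_taxonomy(cfg)
        table, _ = generate_traits(tax, cfg)
        out = gapfill_hierarchy(table, tax)
        # enumerate remaining-missing cells: each needs an all-missing genus
        # AND an all-missing family for that trait
        observed = table.provenance == "observed"
        joined = observed.join(tax.set_index("species")[["genus", "family"]])
        for t in TRAITS:
            fam_any = joined.groupby("family")[t].any()
            expect_missing = ~joined["family"].map(fam_any)
            actual_missing = out.values[t].isna()
            assert actual_missing.equals(expect_missing.astype(bool))

    def test_idempotence(self, toy_taxonomy):
        table = make_trait_table(
            {
                "Alpha sp1": {"WD": 0.5, "N": 12.0},
                "Alpha sp2": {"WD": 0.7},
                "Alpha sp3": {},
                "Beta sp1": {"N": 20.0},
                "Beta sp2": {},
                "Gamma sp1": {"WD": 0.9, "N": 15.0},
                "Gamma sp2": {},
            }
        )
        once = gapfill_hierarchy(table, toy_taxonomy)
        twice = gapfill_hierarchy(once, toy_taxonomy)
        pd.testing.assert_frame_equal(once.values, twice.values)
        pd.testing.assert_frame_equal(once.provenance, twice.provenance)


class TestPhyloImpute:
    @staticmethod
    def _with_background(wd_by_species, seed=0):
        """All non-WD traits observed (randomised) so only WD needs imputing."""
        rng = np.random.default_rng(seed)
        rows = {}
        for sp, wd in wd_by_species.items():
            r = {t: float(rng.uniform(1, 5)) for t in TRAITS if t != "WD"}
            r["P50"], r["TLP"] = -r["P50"], -r["TLP"]
            if wd is not None:
                r["WD"] = wd
            rows[sp] = r
        return make_trait_table(rows)

    def test_constant_neighbourhood_returns_the_constant(self, toy_taxonomy):
        table = self._with_background(
            {
                "Alpha sp1": 0.5, "Alpha sp2": 0.5, "Alpha sp3": None,
                "Beta sp1": 0.5, "Beta sp2": 0.5,
                "Gamma sp1": 0.5, "Gamma sp2": 0.5,
            }
        )
        out = phylo_impute(table, toy_taxonomy, k=5)
        assert out.values.loc["Alpha sp3", "WD"] == pytest.approx(0.5)
        assert out.provenance.loc["Alpha sp3", "WD"] == "phylo_imputed"

    def test_distance_weighted_mean_hand_example(self, toy_taxonomy):
        """Donors at d=1 (value 0) and d=3 (value 4), k=2:
        (0/1 + 4/3) / (1 + 1/3) = 1.0."""
        table = self._with_background(
            {
                "Alpha sp1": 0.0,    # same genus, d=1
                "Alpha sp2": None,
                "Alpha sp3": None,
                "Beta sp1": None,    # same family but no value
                "Beta sp2": None,
                "Gamma sp1": 4.0,    # other family, d=3
                "Gamma sp2": None,
            }
        )
        out = phylo_impute(table, toy_taxonomy, k=2)
        assert out.values.loc["Alpha sp2", "WD"] == pytest.approx(1.0)

    def test_trait_without_any_observation_raises(self):
        tax = pd.DataFrame(
            {
                "species": ["Alpha sp1", "Alpha sp2"],
                "genus": ["Alpha", "Alpha"],
                "family": ["Famone", "Famone"],
                "functional_group": ["BD", "BD"],
            }
        )
        # N is observed for no species at all -> a hard, named error
        table = make_trait_table({"Alpha sp1": {"WD": 0.5}, "Alpha sp2": {}})
        with pytest.raises(TraitImputationError, match="N"):
            phylo_impute(table, tax)


class TestImputerChain:
    def test_observed_cells_never_modified(self, small_dataset):
        table = small_dataset["traits"]
        imp = HierarchicalTraitImputer(taxonomy=small_dataset["taxonomy"])
        filled = imp.fit_transform(table)
        observed = table.provenance == "observed"
        before = table.values.where(observed)
        after = filled.values.where(observed)
        pd.testing.assert_frame_equal(before, after)

    def test_provenance_partitions_filled_cells(self, small_dataset):
        table = small_dataset["traits"]
        imp = HierarchicalTraitImputer(taxonomy=small_dataset["taxonomy"])
        filled = imp.fit_transform(table)
        counts = filled.provenance_counts()
        assert (counts.sum(axis=1) == filled.values.notna().sum()).all()
        assert filled.values.notna().all().all()  # chain completes the table

    def test_sklearn_params_roundtrip(self, small_dataset):
        imp = HierarchicalTraitImputer(
            taxonomy=small_dataset["taxonomy"], method="genus_phylo", k=3
        )
        params = imp.get_params()
        assert params["method"] == "genus_phylo" and params["k"] == 3
        imp.set_params(k=7)
        assert imp.k == 7

    def test_unknown_method_rejected(self, small_dataset):
        imp = HierarchicalTraitImputer(
            taxonomy=small_dataset["taxonomy"], method="nope"
        )
        with pytest.raises(ValueError, match="method"):
            imp.fit(small_dataset["traits"])

    def test_genus_signal_beats_global_mean_imputation(self):
        """With strong genus-level signal, the chain's RMSE is below the
        global-mean oracle's RMSE on the same masked cells."""
        cfg = SynthConfig(
            seed=17, phylo_sd_genus=1.0, phylo_sd_family=0.3,
            residual_sd=0.15, missing_fraction=0.0,
        )
        tax = generate_taxonomy(cfg)
        table, _ = generate_traits(tax, cfg)
        rng = np.random.default_rng(0)
        masked = table.values.copy()
        hidden = {}
        for t in TRAITS:
            sel = rng.choice(len(masked), size=60, replace=False)
            hidden[t] = sel
            masked.iloc[sel, masked.columns.get_loc(t)] = np.nan
        imp = HierarchicalTraitImputer(taxonomy=tax)
        filled = imp.fit_transform(masked)
        err_chain, err_global = [], []
        for t, sel in hidden.items():
            truth = table.values[t].iloc[sel]
            err_chain.extend((filled.values[t].iloc[sel] - truth) ** 2)
            err_global.extend((masked[t].mean() - truth) ** 2)
        assert np.sqrt(np.mean(err_chain)) < np.sqrt(np.mean(err_global))


class TestMaskingValidation:
    def _perfect_table_and_taxonomy(self):
        """Genus-constant traits: the genus median recovers exactly."""
        rows, tax = {}, []
        rng = np.random.default_rng(3)
        for g in range(6):
            value = {t: float(rng.uniform(1, 5)) for t in TRAITS}
            value["P50"] = -value["P50"]
            value["TLP"] = -value["TLP"]
            for s in range(5):
                name = f"Genus{g} sp{s}"
                rows[name] = dict(value)
                tax.append(
                    {"species": name, "genus": f"Genus{g}",
                     "family": "Famone", "functional_group": "BD"}
                )
        return make_trait_table(rows), pd.DataFrame(tax)

    def test_perfect_imputation_scores_r2_one_rmse_zero(self):
        table, tax = self._perfect_table_and_taxonomy()
        report = masking_validation(
            table, tax, proportions=(0.2, 0.4), reps=3, seed=1
        )
        assert (report.records["r2"] > 1 - 1e-9).all()
        assert (report.records["rmse"] < 1e-9).all()

    def test_uninformative_taxonomy_scores_near_zero_r2(self):
        """One genus, random values: prediction is the pooled median ->
        essentially no skill (R2 near its permutation-null level)."""
        rng = np.random.default_rng(5)
        rows = {}
        for i in range(40):
            r = {t: float(rng.uniform(1, 5)) for t in TRAITS}
            r["P50"], r["TLP"] = -r["P50"], -r["TLP"]
            r["WD"] = float(rng.uniform(0.3, 0.9))
            rows[f"Mono sp{i}"] = r
        tax = pd.DataFrame(
            {
                "species": list(rows),
                "genus": "Mono",
                "family": "Famone",
                "functional_group": "BD",
            }
        )
        report = masking_validation(
            make_trait_table(rows), tax, proportions=(0.5,), reps=30, seed=2
        )
        wd = report.records[report.records["trait"] == "WD"]
        assert wd["r2"].mean() < 0.15

    def test_invalid_proportion_rejected(self, small_dataset):
        with pytest.raises(ValueError):
            masking_validation(
                small_dataset["traits"], small_dataset["taxonomy"],
                proportions=(0.0, 0.5), reps=1,
            )

    def test_report_shape_and_skip_logging(self, small_dataset):
        report = masking_validation(
            small_dataset["traits"], small_dataset["taxonomy"],
            proportions=(0.3, 0.6), reps=2, seed=11,
        )
        assert set(report.records.columns) == {
            "trait", "proportion", "replicate", "r2", "rmse"
        }
        assert (report.records["rmse"] >= 0).all()
        assert (report.records["r2"] <= 1).all()
        means = report.means()
        assert set(means["proportion"]) == {0.3, 0.6}
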