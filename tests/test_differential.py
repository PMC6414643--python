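"""Differential statistics: t-tests, BH adjustment, collapsing, model API."""

import numpy as np
import pandas as pd
import pytest

from combedit import (
    DifferentialEditingModel,
    NO_EDIT,
    benjamini_hochberg,
    build_matrix,
    overall_editing_level,
    pattern_ttest,
    percent_of_edited,
    site_collapse,
)
from combedit.differential import fold_change, sig_label
from combedit.quantify import PatternMatrix
from conftest import stepup_bh_oracle


def _matrix(values_by_pattern, genotypes=("WT", "WT", "WT", "LoxP", "LoxP", "LoxP")):
    libs = [f"lib{i}" for i in range(len(genotypes))]
    rpkm_df = pd.DataFrame(values_by_pattern, index=libs, dtype=float).T
    totals = pd.Series(1_000_000, index=libs)
    counts = (rpkm_df * 209 * totals / 1e9).round().astype(int)
    return PatternMatrix(counts, rpkm_df, pd.Series(dict(zip(libs, genotypes))), totals, 209)


class TestBenjaminiHochberg:
    def test_textbook_example(self):
        adjusted = benjamini_hochberg([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(adjusted, [0.04, 0.04, 0.04, 0.04])

    def test_matches_stepup_oracle_on_random_vectors(self):
        rng = np.random.default_rng(99)
        for _ in range(200):
            m = rng.integers(1, 120)
            p = rng.random(m) ** rng.uniform(0.5, 3)
            assert np.allclose(benjamini_hochberg(p), stepup_bh_oracle(p)), p

    def test_adjusted_at_least_raw_and_in_unit_interval(self):
        rng = np.random.default_rng(5)
        p = rng.random(50)
        adj = benjamini_hochberg(p)
        assert np.all(adj >= p - 1e-12)
        assert np.all((0 <= adj) & (adj <= 1))


class TestFoldChangeAndLabels:
    def test_printed_fold_change(self):
        assert round(fold_change(2631, 535), 1) == 4.9

    def test_zero_denominator_is_nan_not_inf(self):
        assert np.isnan(fold_change(5.0, 0.0))

    @pytest.mark.parametrize(
        "p, label",
        [(0.2, "ns"), (0.04, "*"), (0.009, "**"), (0.0009, "***"), (0.00009, "****")],
    )
    def test_sig_labels(self, p, label):
        assert sig_label(p) == label


class TestPatternTtest:
    def test_identical_groups_are_null(self):
        m = _matrix({"D": [10, 12, 14, 10, 12, 14], NO_EDIT: [5, 5, 5, 5, 5, 5]})
        table = pattern_ttest(m, ("WT", "LoxP"))
        assert table.loc["D", "fold_change"] == pytest.approx(1.0)
        assert table.loc["D", "p_value"] == pytest.approx(1.0)
        # constant and equal in both groups -> p = 1 by convention
        assert table.loc[NO_EDIT, "p_value"] == 1.0
        assert table.loc[NO_EDIT, "sig"] == "ns"

    def test_clear_separation_is_significant(self):
        m = _matrix({"D": [100, 101, 99, 10, 11, 9], "CD": [50, 51, 49, 50, 49, 51]})
        table = pattern_ttest(m, ("WT", "LoxP"))
        assert table.loc["D", "fold_change"] == pytest.approx(10, rel=0.05)
        assert table.loc["D", "p_bh"] < 0.001
        assert table.loc["CD", "p_value"] > 0.05

    def test_requires_two_libraries_per_group(self):
        m = _matrix({"D": [1, 2]}, genotypes=("WT", "LoxP"))
        with pytest.raises(ValueError, match=">=2"):
            pattern_ttest(m, ("WT", "LoxP"))

    def test_welch_option_differs_under_heteroscedasticity(self):
        m = _matrix({"D": [100, 200, 300, 149, 150, 151]})
        student = pattern_ttest(m, ("WT", "LoxP"))
        welch = pattern_ttest(m, ("WT", "LoxP"), equal_var=False)
        assert student.loc["D", "p_value"] != welch.loc["D", "p_value"]


class TestPercentages:
    def test_single_edited_pattern_is_100(self):
        pct = percent_of_edited(pd.Series({"D": 42.0, NO_EDIT: 17.0}))
        assert pct["D"] == 100.0
        assert np.isnan(pct[NO_EDIT])

    def test_no_edited_patterns_rejected(self):
        with pytest.raises(ValueError, match="no edited"):
            percent_of_edited(pd.Series({NO_EDIT: 1.0}))

    def test_sums_to_100_over_edited(self):
        m = _matrix({
            "D": [100, 110, 90, 80, 85, 75],
            "CD": [30, 32, 28, 20, 22, 18],
            "AD": [10, 11, 9, 12, 13, 11],
            NO_EDIT: [60, 62, 58, 70, 72, 68],
        })
        table = pattern_ttest(m, ("WT", "LoxP"))
        for col in ("pct_WT", "pct_LoxP"):
            assert table[col].dropna().sum() == pytest.approx(100.0)


class TestSiteCollapse:
    def test_single_pattern_matrix(self):
        m = _matrix({"ABD": [10, 12, 8, 10, 12, 8]})
        table = site_collapse(m, ("WT", "LoxP"))
        assert table.loc["A", "mean_WT"] == table.loc["B", "mean_WT"] == table.loc["D", "mean_WT"]
        assert table.loc["C", "mean_WT"] == 0.0
        assert np.isnan(table.loc["C", "fold_change"])  # 0/0 -> NA, not inf

    def test_site_mean_is_superset_sum(self):
        m = _matrix({
            "D": [100, 100, 100, 100, 100, 100],
            "CD": [30, 30, 30, 30, 30, 30],
            "ACD": [10, 10, 10, 10, 10, 10],
        })
        table = site_collapse(m, ("WT", "LoxP"))
        assert table.loc["D", "mean_WT"] == pytest.approx(140.0)
        assert table.loc["C", "mean_WT"] == pytest.approx(40.0)
        assert table.loc["A", "mean_WT"] == pytest.approx(10.0)

    def test_percentages_can_exceed_100_total(self):
        m = _matrix({
            "ABD": [50, 50, 50, 50, 50, 50],
            "AD": [50, 50, 50, 50, 50, 50],
        })
        table = site_collapse(m, ("WT", "LoxP"))
        # A and D each appear in both patterns: 100% each; sites co-occur
        assert table.loc["A", "pct_WT"] == pytest.approx(100.0)
        assert table["pct_WT"].sum() > 100.0

    def test_printed_site_fold_change(self):
        # group means as published for site A: 148907 vs 100311 -> 1.5
        noise = np.array([0.9, 1.0, 1.1])
        m = _matrix({
            "AD": list(148907 * noise) + list(100311 * noise),
        })
        table = site_collapse(m, ("WT", "LoxP"))
        assert round(table.loc["A", "fold_change"], 1) == 1.5


class TestOverallEditingLevel:
    def test_all_noedit(self):
        m = _matrix({NO_EDIT: [10, 10, 10, 10, 10, 10]})
        level = overall_editing_level(m, ("WT", "LoxP"))
        assert level.pct_edited_group1 == 0.0

    def test_fully_edited(self):
        m = _matrix({NO_EDIT: [0, 0, 0, 0, 0, 0], "D": [10, 10, 10, 10, 10, 10]})
        level = overall_editing_level(m, ("WT", "LoxP"))
        assert level.pct_edited_group1 == 100.0

    def test_noedit_required(self):
        m = _matrix({"D": [10, 10, 10, 10, 10, 10]})
        with pytest.raises(ValueError, match="NoEdit"):
            overall_editing_level(m, ("WT", "LoxP"))

    def test_level_matches_mixture(self):
        m = _matrix({NO_EDIT: [40, 40, 40, 40, 40, 40], "D": [60, 60, 60, 60, 60, 60]})
        level = overall_editing_level(m, ("WT", "LoxP"))
        assert level.pct_edited_group1 == pytest.approx(60.0)
        assert level.difference == pytest.approx(0.0)


class TestModelResults:
    def _counts_matrix(self):
        rng = np.random.default_rng(3)
        counts = {}
        genotypes = {}
        totals = {}
        for g, base in (("WT", 1.0), ("LoxP", 0.6)):
            for i in range(3):
                lib = f"{g}{i}"
                counts[lib] = {
                    NO_EDIT: rng.poisson(4000),
                    "D": rng.poisson(6000 * base),
                    "CD": rng.poisson(900 * base),
                    "rare": 1,
                }
                genotypes[lib] = g
                totals[lib] = 20_000
        # "rare" is not a valid label set member but build_matrix is agnostic;
        # use a real label instead
        for lib in counts:
            counts[lib]["AD"] = counts[lib].pop("rare")
        return build_matrix(counts, genotypes, totals)

    def test_fit_filters_and_reports(self):
        model = DifferentialEditingModel(self._counts_matrix(), ("WT", "LoxP"))
        results = model.fit(min_mean_rpkm=10.0)
        assert "D" in results.patterns.index
        assert results.editing_level is not None
        assert len(results.sites) == 11
        text = results.summary()
        assert "WT" in text and "overall editing level" in text

    def test_infinite_threshold_rejected(self):
        model = DifferentialEditingModel(self._counts_matrix(), ("WT", "LoxP"))
        with pytest.raises(ValueError, match="no patterns survive"):
            model.fit(min_mean_rpkm=float("inf"))

    def test_grouping_inferred_and_validated(self):
        matrix = self._counts_matrix()
        model = DifferentialEditingModel(matrix)
        assert set(model.grouping) == {"WT", "LoxP"}
        with pytest.raises(ValueError, match="unknown genotype"):
            DifferentialEditingModel(matrix, ("WT", "Nope"))

    def test_results_export(self, tmp_path):
        results = DifferentialEditingModel(self._counts_matrix(), ("WT", "LoxP")).fit()
        results.to_dir(tmp_path / "out")
        assert (tmp_path / "out" / "pattern_differential.tsv").exists()
        assert (tmp_path / "out" / "site_contribution.tsv").exists()
        assert (tmp_path / "out" / "differential.json").exists()
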