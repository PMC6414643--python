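"""Genotype comparison of editing-pattern expression.

The statistic is deliberately plain: for each pattern (row of the filtered
RPKM matrix) a two-sided Student's t-test between the two genotype groups,
Benjamini-Hochberg step-up adjustment across all tested patterns jointly,
and the WT/LoxP fold change of group means.  Three views are produced:

* per-pattern differential table (fold change, p, pBH, significance stars,
  percent of edited expression per group);
* single-site collapsing — for each of the 11 sites, the per-library sum
  of RPKM over all patterns containing that site, compared the same way
  (its own BH family of 11 tests);
* overall editing level — the percentage of total (edited + NoEdit) mean
  expression that is edited, per group.

Percentages use the edited-only denominator: a pattern's (or site's) group
mean divided by the summed group mean of all edited patterns, x100.

The model/results pair wraps these into a statsmodels-style interface:
``DifferentialEditingModel(matrix).fit()`` returns
:class:`DifferentialEditingResults` carrying all three tables plus
``summary()`` and file export.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .quantify import PatternMatrix, filter_by_mean_rpkm
from .reference import CANONICAL_ORDER, NO_EDIT, pattern_contains_site

#: GraphPad-style significance stars on raw p-values.
SIG_THRESHOLDS = ((1e-4, "****"), (1e-3, "***"), (1e-2, "**"), (5e-2, "*"))


def sig_label(p: float) -> str:
    for threshold, stars in SIG_THRESHOLDS:
        if p < threshold:
            return stars
    return "ns"


def benjamini_hochberg(p_values) -> np.ndarray:
    """BH step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def fold_change(mean1: float, mean2: float) -> float:
    """Group-1 over group-2 mean; NaN (never infinity) for a zero denominator."""
    if mean2 == 0:
        return float("nan")
    return mean1 / mean2


def _ttest_rows(values1: pd.DataFrame, values2: pd.DataFrame, equal_var: bool) -> np.ndarray:
    """Row-wise two-sided t-test p-values with the zero-variance convention:
    both groups constant and equal -> p = 1; constant but different -> p = 0."""
    import warnings

    with warnings.catch_warnings():
        # constant rows are handled explicitly below
        warnings.simplefilter("ignore", RuntimeWarning)
        p = sps.ttest_ind(values1, values2, axis=1, equal_var=equal_var).pvalue
    v1 = values1.var(axis=1, ddof=1).to_numpy()
    v2 = values2.var(axis=1, ddof=1).to_numpy()
    m1 = values1.mean(axis=1).to_numpy()
    m2 = values2.mean(axis=1).to_numpy()
    degenerate = (v1 == 0) & (v2 == 0)
    p = np.where(degenerate & (m1 == m2), 1.0, p)
    p = np.where(degenerate & (m1 != m2), 0.0, p)
    return p


def percent_of_edited(mean_rpkm: pd.Series) -> pd.Series:
    """Each edited pattern's share of total edited mean expression (%).

    ``NoEdit`` is excluded from both numerator set and denominator; its
    entry (if present) is returned as NaN.
    """
    edited = mean_rpkm.drop(index=NO_EDIT, errors="ignore")
    if edited.empty:
        raise ValueError("no edited patterns in matrix")
    denominator = edited.sum()
    pct = mean_rpkm / denominator * 100.0
    if NO_EDIT in pct.index:
        pct.loc[NO_EDIT] = np.nan
    return pct


def pattern_ttest(
    matrix: PatternMatrix,
    grouping: tuple[str, str],
    equal_var: bool = True,
) -> pd.DataFrame:
    """Per-pattern differential table over a (filtered) matrix.

    Columns: mean_<g1>, mean_<g2>, fold_change (g1/g2), p_value, sig, p_bh,
    pct_<g1>, pct_<g2>.  The BH family is all rows tested together.
    """
    g1, g2 = grouping
    libs1 = matrix.group_libraries(g1)
    libs2 = matrix.group_libraries(g2)
    if len(libs1) < 2 or len(libs2) < 2:
        raise ValueError("need >=2 libraries per genotype for a t-test")
    values1, values2 = matrix.rpkm[libs1], matrix.rpkm[libs2]
    mean1, mean2 = values1.mean(axis=1), values2.mean(axis=1)
    p = _ttest_rows(values1, values2, equal_var)
    table = pd.DataFrame(
        {
            f"mean_{g1}": mean1,
            f"mean_{g2}": mean2,
            "fold_change": [fold_change(a, b) for a, b in zip(mean1, mean2)],
            "p_value": p,
            "sig": [sig_label(x) for x in p],
            "p_bh": benjamini_hochberg(p),
            f"pct_{g1}": percent_of_edited(mean1),
            f"pct_{g2}": percent_of_edited(mean2),
        },
        index=matrix.counts.index,
    )
    return table.sort_values(f"mean_{g1}", ascending=False)


def site_collapse(
    matrix: PatternMatrix,
    grouping: tuple[str, str],
    site_labels: tuple[str, ...] = CANONICAL_ORDER,
    equal_var: bool = True,
) -> pd.DataFrame:
    """Single-site contribution table.

    For each site, the per-library collapsed value is the sum of RPKM over
    every pattern containing that site; group means, fold change and
    Student's t-test follow, BH-adjusted across the sites (their own
    family).  Percentages use the edited-only denominator.
    """
    g1, g2 = grouping
    libs1 = matrix.group_libraries(g1)
    libs2 = matrix.group_libraries(g2)
    collapsed = pd.DataFrame(
        {
            site: matrix.rpkm[[pattern_contains_site(p, site) for p in matrix.patterns]].sum(axis=0)
            for site in site_labels
        }
    ).T  # sites x libraries
    values1, values2 = collapsed[libs1], collapsed[libs2]
    mean1, mean2 = values1.mean(axis=1), values2.mean(axis=1)
    p = _ttest_rows(values1, values2, equal_var)
    edited_total1 = matrix.group_mean_rpkm(g1).drop(index=NO_EDIT, errors="ignore").sum()
    edited_total2 = matrix.group_mean_rpkm(g2).drop(index=NO_EDIT, errors="ignore").sum()
    return pd.DataFrame(
        {
            f"mean_{g1}": mean1,
            f"mean_{g2}": mean2,
            "fold_change": [fold_change(a, b) for a, b in zip(mean1, mean2)],
            "p_value": p,
            "sig": [sig_label(x) for x in p],
            "p_bh": benjamini_hochberg(p),
            f"pct_{g1}": mean1 / edited_total1 * 100.0,
            f"pct_{g2}": mean2 / edited_total2 * 100.0,
        },
        index=pd.Index(site_labels, name="site"),
    )


@dataclass(frozen=True)
class EditingLevelSummary:
    """Percent of total mean expression (edited + NoEdit) that is edited."""

    group1: str
    group2: str
    pct_edited_group1: float
    pct_edited_group2: float

    @property
    def difference(self) -> float:
        return self.pct_edited_group1 - self.pct_edited_group2


def overall_editing_level(
    matrix: PatternMatrix, grouping: tuple[str, str]
) -> EditingLevelSummary:
    """Overall per-genotype editing level from group-mean RPKM values."""
    if NO_EDIT not in matrix.counts.index:
        raise ValueError("matrix must include the NoEdit pattern")
    pcts = []
    for genotype in grouping:
        means = matrix.group_mean_rpkm(genotype)
        total = means.sum()
        edited = means.drop(index=NO_EDIT).sum()
        pcts.append(edited / total * 100.0 if total > 0 else float("nan"))
    return EditingLevelSummary(grouping[0], grouping[1], pcts[0], pcts[1])


# ------------------------------------------------------------ model/results

class DifferentialEditingModel:
    """Differential editing-pattern expression between two genotypes.

    Parameters
    ----------
    matrix
        Pattern x library RPKM/count matrix (see ``quantify.build_matrix``).
    grouping
        (group1, group2) genotype labels; fold changes are group1 / group2.
    equal_var
        Student's equal-variance t-test by default; set False for Welch.
    """

    def __init__(
        self,
        matrix: PatternMatrix,
        grouping: tuple[str, str] | None = None,
        equal_var: bool = True,
    ):
        if grouping is None:
            groups = list(dict.fromkeys(matrix.genotypes))
            if len(groups) != 2:
                raise ValueError(f"two genotypes required, found {groups!r}")
            grouping = (groups[0], groups[1])
        for genotype in grouping:
            matrix.group_libraries(genotype)  # validates labels
        self.matrix = matrix
        self.grouping = tuple(grouping)
        self.equal_var = equal_var

    @classmethod
    def from_counts(
        cls,
        pattern_counts,
        genotypes,
        total_mapped,
        contig_length: int = 209,
        **kwargs,
    ) -> "DifferentialEditingModel":
        from .quantify import build_matrix

        return cls(build_matrix(pattern_counts, genotypes, total_mapped, contig_length), **kwargs)

    def fit(self, min_mean_rpkm: float | None = 10.0) -> "DifferentialEditingResults":
        """Apply the expression filter and compute all three result tables."""
        matrix = self.matrix
        if min_mean_rpkm is not None:
            matrix = filter_by_mean_rpkm(matrix, min_mean_rpkm, self.grouping)
        if matrix.counts.empty:
            raise ValueError("no patterns survive filter")
        patterns = pattern_ttest(matrix, self.grouping, self.equal_var)
        sites = site_collapse(matrix, self.grouping, equal_var=self.equal_var)
        level = (
            overall_editing_level(matrix, self.grouping)
            if NO_EDIT in matrix.counts.index
            else None
        )
        return DifferentialEditingResults(self, matrix, patterns, sites, level)


@dataclass
class DifferentialEditingResults:
    """Fitted differential-editing tables with reporting helpers."""

    model: DifferentialEditingModel
    filtered_matrix: PatternMatrix
    patterns: pd.DataFrame
    sites: pd.DataFrame
    editing_level: EditingLevelSummary | None

    @property
    def significant_patterns(self) -> pd.DataFrame:
        return self.patterns[self.patterns["p_value"] < 0.05]

    def summary(self, top: int = 10) -> str:
        g1, g2 = self.model.grouping
        lines = [
            "Differential editing-pattern expression",
            "=" * 46,
            f"groups: {g1} (numerator) vs {g2}; "
            f"{len(self.filtered_matrix.libraries)} libraries, "
            f"{len(self.filtered_matrix.patterns)} patterns tested",
        ]
        if self.editing_level is not None:
            lines.append(
                f"overall editing level: {g1} {self.editing_level.pct_edited_group1:.1f}%"
                f" | {g2} {self.editing_level.pct_edited_group2:.1f}%"
                f" (difference {self.editing_level.difference:+.1f} points)"
            )
        ranked = self.patterns.assign(
            _score=np.abs(np.log(self.patterns["fold_change"].replace(0, np.nan)))
        ).sort_values("_score", ascending=False)
        lines.append(f"top patterns by |log fold change| (of {len(self.patterns)}):")
        show = ranked.head(top).drop(columns="_score")
        lines.append(show.to_string(float_format=lambda v: f"{v:.4g}"))
        lines.append("single-site contributions:")
        lines.append(self.sites.to_string(float_format=lambda v: f"{v:.4g}"))
        return "\n".join(lines)

    def to_dir(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.patterns.rename_axis("pattern").to_csv(outdir / "pattern_differential.tsv", sep="\t")
        self.sites.to_csv(outdir / "site_contribution.tsv", sep="\t")
        bundle = {
            "grouping": list(self.model.grouping),
            "n_patterns_tested": int(len(self.patterns)),
            "n_significant_raw": int((self.patterns["p_value"] < 0.05).sum()),
            "editing_level": (
                None
                if self.editing_level is None
                else {
                    self.editing_level.group1: self.editing_level.pct_edited_group1,
                    self.editing_level.group2: self.editing_level.pct_edited_group2,
                }
            ),
        }
        with open(outdir / "differential.json", "w") as fh:
            json.dump(bundle, fh, indent=2)
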