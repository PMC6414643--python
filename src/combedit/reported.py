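"""Published summary statistics for the mouse choroid-plexus 5-Ht2cr
amplicon study design (two genotypes, six biological replicates each).

These tables hold the study's printed group-level numbers: the average
splice-variant read counts per genotype, the per-pattern mean RPKM values
with fold changes and t-test results for the 21 differentially expressed
editing patterns, and the single-site collapsed values for all 11 sites.

They serve two purposes:

* worked-example inputs — the differential module can be fed these group
  means to re-derive the printed fold changes and percentages;
* simulator calibration — :func:`combedit.simulate.reported_profile_pair`
  turns the mean RPKM columns into genotype pattern distributions whose
  built-in ratios equal the printed fold changes.

Values are stored as printed (including their printed precision, which the
consistency helpers below use); nothing here is recomputed.
"""

from __future__ import annotations

import pandas as pd

#: Genotype labels used throughout: wild type and the Snord115-expressing line.
GROUP_WT = "WT"
GROUP_LOXP = "LoxP"

# --------------------------------------------------------------- splicing
# Average per-library read counts for the two splice contigs, per genotype.
SPLICE_SUMMARY = pd.DataFrame(
    {
        "genotype": [GROUP_LOXP, GROUP_WT],
        "mapped_reads": [6_493_463, 5_569_933],
        "full_reads": [2_942_551, 2_516_839],
        "truncated_reads": [3_550_911, 3_053_094],
        "pct_full": [45.3, 45.2],
        "pct_truncated": [54.7, 54.8],
    }
).set_index("genotype")

# ----------------------------------------------------- per-pattern results
# The 21 editing patterns with significant genotype differences.  Numeric
# columns are kept as printed strings so downstream checks know the printed
# precision; use PATTERN_DIFFERENTIAL for a float view.
_PATTERN_ROWS = [
    # pattern, mean WT, mean LoxP, fold change, p, sig, pBH, WT %, LoxP %
    ("CD",     "126959", "104482", "1.2",  "0.0009",   "***",  "0.021",  "12.6",    "11.8"),
    ("AD",     "44104.5", "33894", "1.3",  "0.0013",   "**",   "0.0185", "4.4",     "3.8"),
    ("ABD",    "32223",  "18402",  "1.75", "6.52E-05", "****", "0.0072", "3.2",     "2.1"),
    ("ED",     "23259",  "19153",  "1.2",  "0.03068",  "*",    "0.179",  "2.3",     "2.17"),
    ("ACD",    "19010",  "14490",  "1.3",  "0.0043",   "**",   "0.053",  "1.9",     "1.6"),
    ("ABCD",   "12761",  "5132",   "2.5",  "0.00027",  "***",  "0.0099", "1.3",     "0.58"),
    ("E",      "11309",  "17713",  "0.64", "0.0062",   "**",   "0.0627", "1.1",     "2"),
    ("AC",     "5546",   "3450",   "1.6",  "0.00095",  "***",  "0.0175", "0.55",    "0.3"),
    ("AECD",   "3544",   "1277",   "2.8",  "0.0098",   "**",   "0.09",   "0.35",    "0.14"),
    ("BCD",    "2631",   "535",    "4.9",  "0.024",    "*",    "0.156",  "0.26",    "0.06"),
    ("CDH",    "262",    "79",     "3.3",  "0.019",    "*",    "0.1288", "0.026",   "0.009"),
    ("1AD",    "64.5",   "44",     "1.46", "0.037",    "*",    "0.1973", "0.006",   "0.005"),
    ("ADG",    "61.5",   "46",     "1.34", "0.044",    "*",    "0.2218", "0.006",   "0.0052"),
    ("ABDG",   "44",     "25",     "1.8",  "0.029",    "*",    "0.1792", "0.004",   "0.0028"),
    ("1ABD",   "35.5",   "22",     "1.6",  "0.012",    "*",    "0.0867", "0.0035",  "0.0025"),
    ("ABCDG",  "24.6",   "8",      "3.2",  "0.0013",   "**",   "0.0185", "0.002",   "0.00087"),
    ("ABCDF",  "21",     "6.5",    "3.2",  "0.00016",  "***",  "0.009",  "0.002",   "0.0007"),
    ("3ABCD",  "19.5",   "7",      "2.9",  "0.005",    "**",   "0.0554", "0.0019",  "0.00076"),
    ("1ABCD",  "19",     "4",      "5",    "0.0003",   "***",  "0.0087", "0.00185", "0.0004"),
    ("ABCDH",  "12",     "3",      "3.6",  "0.0112",   "*",    "0.0867", "0.0012",  "0.0004"),
    ("3AC",    "11",     "5",      "2.33", "0.01",     "*",    "0.0867", "0.001",   "0.00056"),
]

_PATTERN_COLUMNS = [
    "pattern", "mean_wt", "mean_loxp", "fold_change",
    "p_value", "sig", "p_bh", "pct_wt", "pct_loxp",
]

PATTERN_DIFFERENTIAL_PRINTED = pd.DataFrame(
    _PATTERN_ROWS, columns=_PATTERN_COLUMNS
).set_index("pattern")

PATTERN_DIFFERENTIAL = PATTERN_DIFFERENTIAL_PRINTED.drop(columns="sig").astype(float)
PATTERN_DIFFERENTIAL["sig"] = PATTERN_DIFFERENTIAL_PRINTED["sig"]

# ----------------------------------------------------- per-site collapsing
# Single-site contribution: mean RPKM summed over all patterns containing
# the site, per genotype.  'no' in sig means not significant; the adjusted
# p-values were reported for the four significant sites only.
_SITE_ROWS = [
    ("1", "2275",   "2225",   "1",   "0.67",     "no",   None,     "0.2",  "0.22"),
    ("2", "4129",   "3295",   "1.3", "0.14",     "no",   None,     "0.4",  "0.43"),
    ("3", "2119",   "2078",   "1",   "0.8",      "no",   None,     "0.2",  "0.2"),
    ("A", "148907", "100311", "1.5", "0.000057", "****", "0.0006", "14.7", "11.3"),
    ("B", "66074",  "37479",  "1.8", "0.0003",   "***",  "0.001",  "6.5",  "4.2"),
    ("C", "234736", "190987", "1.2", "0.0004",   "***",  "0.0016", "23.2", "21.6"),
    ("D", "904161", "782103", "1.2", "0.006",    "**",   "0.016",  "89.5", "88.4"),
    ("E", "51944",  "45946",  "1.1", "0.15",     "no",   None,     "5.1",  "5.2"),
    ("F", "1877",   "1891",   "1",   "0.94",     "no",   None,     "0.2",  "0.2"),
    ("G", "3242",   "2378",   "1.4", "0.14",     "no",   None,     "0.3",  "0.23"),
    ("H", "1940",   "1878",   "1",   "0.84",     "no",   None,     "0.2",  "0.26"),
]

SITE_CONTRIBUTION_PRINTED = pd.DataFrame(
    _SITE_ROWS,
    columns=["site", "mean_wt", "mean_loxp", "fold_change",
             "p_value", "sig", "p_bh", "pct_wt", "pct_loxp"],
).set_index("site")

SITE_CONTRIBUTION = SITE_CONTRIBUTION_PRINTED.drop(columns="sig").astype(float)
SITE_CONTRIBUTION["sig"] = SITE_CONTRIBUTION_PRINTED["sig"]

#: Overall editing level (percent of transcript-level expression that is
#: edited), as reported per genotype.
OVERALL_EDITING_PCT = {GROUP_WT: 69.0, GROUP_LOXP: 64.0}

#: Most prevalent edited isoform: single D-site editing, ~61% of all edited
#: transcripts in wild type.
D_ONLY_SHARE_OF_EDITED_WT = 0.61


def edited_total_mean_rpkm(group: str) -> float:
    """Implied per-genotype total mean RPKM over all *edited* patterns.

    The single-site table reports both the D-site collapsed mean RPKM and
    the percentage that value represents of all edited expression, so the
    edited-total denominator is their quotient.
    """
    row = SITE_CONTRIBUTION.loc["D"]
    mean = row["mean_wt"] if group == GROUP_WT else row["mean_loxp"]
    pct = row["pct_wt"] if group == GROUP_WT else row["pct_loxp"]
    return float(mean) / (float(pct) / 100.0)


# ------------------------------------------------ printed-precision helpers

def printed_decimals(printed: str) -> int:
    """Number of decimal places carried by a printed numeral (0 for '1.2E3'
    style scientific notation, where the helper falls back to exactness)."""
    s = printed.strip()
    if "e" in s.lower():
        return 0
    if "." not in s:
        return 0
    return len(s.split(".")[1])


def printed_halfwidth(printed: str) -> float:
    """Half of one unit in the last printed digit (the rounding radius)."""
    return 0.5 * 10.0 ** (-printed_decimals(printed))


def consistent_with_printed(computed: float, printed: str) -> bool:
    """Whether ``computed`` rounds to the printed numeral (within one half
    unit in the last printed place, with a small float guard)."""
    return abs(computed - float(printed)) <= printed_halfwidth(printed) + 1e-12


def ratio_interval(numer: str, denom: str) -> tuple[float, float]:
    """Interval of quotients compatible with two printed (rounded) means."""
    n, d = float(numer), float(denom)
    hn, hd = printed_halfwidth(numer), printed_halfwidth(denom)
    lo = (n - hn) / (d + hd)
    hi = (n + hn) / (d - hd) if d - hd > 0 else float("inf")
    return lo, hi
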