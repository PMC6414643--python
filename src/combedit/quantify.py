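"""RPKM matrices, expression filtering and splice-isoform summaries.

Pattern abundances are normalized exactly as

    RPKM = reads / sequence_length * (1e9 / total_mapped)

with ``sequence_length`` the full-length contig length (every editing
pattern lives on the 209 nt contig) and ``total_mapped`` the library's
mapped reads over *both* splice contigs.  No pseudocounts.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
import yaml

from .reads import LibraryStats
from .reference import pattern_sort_key


def rpkm(reads: float, sequence_length: int, total_mapped: int) -> float:
    """Reads per kilobase of contig per million mapped reads."""
    if sequence_length <= 0:
        raise ValueError("sequence_length must be > 0")
    if total_mapped <= 0:
        raise ValueError("empty library: total_mapped must be > 0")
    return reads / sequence_length * (1e9 / total_mapped)


@dataclass
class PatternMatrix:
    """Libraries x editing-patterns table of counts and RPKM values.

    ``counts`` and ``rpkm`` are pattern-indexed DataFrames with one column
    per library; ``genotypes`` and ``total_mapped`` are library-indexed.
    """

    counts: pd.DataFrame
    rpkm: pd.DataFrame
    genotypes: pd.Series
    total_mapped: pd.Series
    contig_length: int

    @property
    def libraries(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def patterns(self) -> list[str]:
        return list(self.counts.index)

    def group_libraries(self, genotype: str) -> list[str]:
        libs = [lib for lib in self.libraries if self.genotypes[lib] == genotype]
        if not libs:
            raise ValueError(f"unknown genotype label {genotype!r}")
        return libs

    def group_mean_rpkm(self, genotype: str) -> pd.Series:
        return self.rpkm[self.group_libraries(genotype)].mean(axis=1)

    # ------------------------------------------------------------------ I/O
    def to_dir(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.counts.rename_axis("pattern").to_csv(outdir / "counts.tsv", sep="\t")
        self.rpkm.rename_axis("pattern").to_csv(outdir / "rpkm.tsv", sep="\t")
        meta = pd.DataFrame(
            {"genotype": self.genotypes, "total_mapped": self.total_mapped}
        ).rename_axis("library")
        meta.to_csv(outdir / "libraries.tsv", sep="\t")
        with open(outdir / "matrix.yaml", "w") as fh:
            yaml.safe_dump({"contig_length": self.contig_length}, fh)

    @classmethod
    def from_dir(cls, indir: str | Path) -> "PatternMatrix":
        indir = Path(indir)
        counts = pd.read_csv(indir / "counts.tsv", sep="\t", index_col="pattern")
        rpkm_df = pd.read_csv(indir / "rpkm.tsv", sep="\t", index_col="pattern")
        meta = pd.read_csv(indir / "libraries.tsv", sep="\t", index_col="library")
        with open(indir / "matrix.yaml") as fh:
            extra = yaml.safe_load(fh)
        return cls(
            counts=counts,
            rpkm=rpkm_df,
            genotypes=meta["genotype"],
            total_mapped=meta["total_mapped"],
            contig_length=int(extra["contig_length"]),
        )


def build_matrix(
    pattern_counts: Mapping[str, Mapping[str, int]] | Iterable[tuple[str, Mapping[str, int]]],
    genotypes: Mapping[str, str],
    total_mapped: Mapping[str, int],
    contig_length: int = 209,
) -> PatternMatrix:
    """Assemble per-library pattern-count tables into a :class:`PatternMatrix`.

    ``pattern_counts`` maps library id -> {pattern -> count} (or an iterable
    of such pairs; duplicate library ids are rejected).  Patterns absent
    from a library get count 0.
    """
    items = list(pattern_counts.items()) if isinstance(pattern_counts, Mapping) else list(pattern_counts)
    libs = [lib for lib, _ in items]
    if len(set(libs)) != len(libs):
        raise ValueError("duplicate library IDs in pattern_counts")
    if not libs:
        raise ValueError("at least one library required")
    for lib in libs:
        if lib not in genotypes:
            raise ValueError(f"library {lib!r} missing from genotypes")
        if lib not in total_mapped:
            raise ValueError(f"library {lib!r} missing from total_mapped")

    counts = (
        pd.DataFrame({lib: pd.Series(dict(table), dtype=float) for lib, table in items})
        .fillna(0.0)
        .astype(int)
    )
    counts = counts.loc[sorted(counts.index, key=pattern_sort_key)]
    counts.index.name = "pattern"
    totals = pd.Series({lib: int(total_mapped[lib]) for lib in libs})
    if (totals <= 0).any():
        raise ValueError("empty library: total_mapped must be > 0")
    rpkm_df = counts / contig_length * (1e9 / totals)
    return PatternMatrix(
        counts=counts,
        rpkm=rpkm_df,
        genotypes=pd.Series({lib: genotypes[lib] for lib in libs}),
        total_mapped=totals,
        contig_length=contig_length,
    )


def filter_by_mean_rpkm(
    matrix: PatternMatrix,
    threshold: float = 10.0,
    grouping: tuple[str, str] | None = None,
) -> PatternMatrix:
    """Keep patterns whose mean RPKM reaches ``threshold`` (inclusive) in
    *either* genotype group; NoEdit is treated like any other pattern."""
    if grouping is None:
        groups = list(dict.fromkeys(matrix.genotypes))
        if len(groups) != 2:
            raise ValueError(f"grouping required: found genotypes {groups!r}")
        grouping = (groups[0], groups[1])
    keep = pd.Series(False, index=matrix.counts.index)
    for genotype in grouping:
        keep |= matrix.group_mean_rpkm(genotype) >= threshold
    return PatternMatrix(
        counts=matrix.counts[keep],
        rpkm=matrix.rpkm[keep],
        genotypes=matrix.genotypes,
        total_mapped=matrix.total_mapped,
        contig_length=matrix.contig_length,
    )


def splice_summary(
    stats: Mapping[str, LibraryStats] | Iterable[LibraryStats],
    genotypes: Mapping[str, str],
) -> pd.DataFrame:
    """Per-genotype splice-variant summary: average mapped / full / truncated
    read counts and the percentage each isoform represents of mapped reads.

    Percentages are kept at full precision; round to one decimal for
    display, which is the conventional reporting precision.
    """
    stats_list = list(stats.values()) if isinstance(stats, Mapping) else list(stats)
    rows = []
    for s in stats_list:
        rows.append(
            {
                "library": s.library_id,
                "genotype": genotypes[s.library_id],
                "mapped_reads": s.mapped_reads,
                "full_reads": s.full_reads,
                "truncated_reads": s.truncated_reads,
            }
        )
    per_lib = pd.DataFrame(rows).set_index("library")
    grouped = per_lib.groupby("genotype")[["mapped_reads", "full_reads", "truncated_reads"]].mean()
    grouped["pct_full"] = grouped["full_reads"] / grouped["mapped_reads"] * 100.0
    grouped["pct_truncated"] = grouped["truncated_reads"] / grouped["mapped_reads"] * 100.0
    return grouped


def library_totals(stats: Mapping[str, LibraryStats]) -> dict[str, int]:
    """Mapped-read totals (both contigs) for RPKM denominators."""
    return {lib: s.mapped_reads for lib, s in stats.items()}
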