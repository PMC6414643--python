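"""End-to-end conveniences tying simulator, classifier, caller and matrix.

These run the same stages the CLI orchestrates, but in memory — useful for
simulation studies (parameter recovery, calibration) where writing FASTQ
to disk adds nothing.
"""

from __future__ import annotations

import pandas as pd

from .calling import call_library
from .quantify import PatternMatrix, build_matrix
from .reads import LibraryStats, classify_reads
from .reference import AmpliconReference
from .simulate import SimDesign, library_seed, simulate_library


def quantify_simulated_design(
    ref: AmpliconReference,
    design: SimDesign,
    policy: str = "strict",
    keep_truth: bool = False,
) -> tuple[PatternMatrix, dict[str, LibraryStats], pd.DataFrame | None]:
    """Simulate a design and quantify it through the full read pipeline.

    Each library is generated (per-library seed derived from the design
    seed), classified read by read against the two contigs, pattern-called
    and assembled into a :class:`PatternMatrix`.  Returns the matrix, the
    per-library stats and (optionally) the pooled truth table.
    """
    profiles = {p.name: p for p in design.genotypes}
    counts: dict = {}
    genotypes: dict[str, str] = {}
    totals: dict[str, int] = {}
    stats: dict[str, LibraryStats] = {}
    truths = []
    for index, (lib_id, genotype) in enumerate(design.library_ids()):
        reads, truth = simulate_library(
            ref,
            profiles[genotype],
            design.reads_per_library,
            error_rate=design.per_base_error_rate,
            seed=library_seed(design.seed, index),
            library_id=lib_id,
        )
        observations, lib_stats = classify_reads(reads, ref, lib_id)
        pattern_counts, rejections = call_library(observations, ref.site_map, policy)
        lib_stats.discarded_ambiguous_base = rejections.get("non_AG_base", 0)
        counts[lib_id] = pattern_counts
        genotypes[lib_id] = genotype
        totals[lib_id] = lib_stats.mapped_reads
        stats[lib_id] = lib_stats
        if keep_truth:
            truth["genotype"] = genotype
            truths.append(truth)
    matrix = build_matrix(counts, genotypes, totals, contig_length=len(ref.full_contig))
    truth_df = pd.concat(truths, ignore_index=True) if truths else None
    return matrix, stats, truth_df
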