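"""Read ingestion: splice-contig assignment and per-site base extraction.

Two entry points produce the same ``ReadObservation`` stream:

* :func:`read_alignments` walks existing SAM/BAM alignments (CIGAR-aware,
  mapping-quality filtered) against the two splice contigs;
* :func:`classify_raw_reads` aligns raw FASTQ/FASTA reads itself — each
  read is globally aligned (edlib, Needleman-Wunsch) against both contigs
  in both orientations and assigned to the closer one.  The two contigs
  differ by a 95 nt block, so assignment is unambiguous far above any
  realistic error rate; exact ties are left unassigned.

Full-contig observations carry the base call at every editing site plus
flags for incomplete site coverage and indels inside the site window.
Reads flagged either way stay in the mapped/splice tallies (they are real
amplicon molecules) but are rejected later by the pattern caller, whose
unit of counting is the complete joint pattern.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator

import edlib
import numpy as np
import pysam
from Bio.SeqIO.FastaIO import SimpleFastaParser
from Bio.SeqIO.QualityIO import FastqGeneralIterator

from .reference import AmpliconReference, ReferenceError

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

#: Default mapping-quality floor for alignment input ("high mapping
#: quality" read filtering); conventional high-confidence threshold.
DEFAULT_MIN_MAPQ = 30

#: Reads farther than this edit distance from both contigs are unassigned.
DEFAULT_MAX_EDIT_DISTANCE = 60

# Hamming fast path: a read of exactly contig length within this many
# substitutions of that contig cannot be closer to the other contig (the
# contigs differ by a 95 nt block), so the full alignment is skipped.
_FAST_HAMMING_MAX = 25


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class ReadObservation:
    """One read's contig assignment and (for full-contig reads) site calls."""

    read_id: str
    library_id: str
    contig: str  # "full" | "truncated" | "unassigned"
    mapq: int | None = None
    site_bases: dict[str, str] | None = None
    covered_all_sites: bool = False
    has_indel_in_window: bool = False
    edit_distance: int | None = None


@dataclass
class LibraryStats:
    """Per-library accounting; every input read lands in exactly one tally."""

    library_id: str
    total_reads: int = 0
    mapped_reads: int = 0
    full_reads: int = 0
    truncated_reads: int = 0
    unassigned_reads: int = 0
    discarded_by_mapq: int = 0
    discarded_unmapped: int = 0
    flagged_partial_coverage: int = 0
    flagged_indel_in_window: int = 0
    discarded_ambiguous_base: int = 0

    def check(self) -> None:
        assert self.mapped_reads == self.full_reads + self.truncated_reads
        assert (
            self.total_reads
            == self.mapped_reads
            + self.unassigned_reads
            + self.discarded_by_mapq
            + self.discarded_unmapped
        )


def _walk_aligned_pairs(
    pairs: Iterable[tuple[int | None, int | None]],
    query: str,
    positions: dict[str, int],
    window: tuple[int, int],
) -> tuple[dict[str, str], bool, bool]:
    """Extract per-site query bases from (query_pos, ref_pos) pairs and flag
    indels inside the half-open reference ``window``."""
    w0, w1 = window
    wanted = {pos: label for label, pos in positions.items()}
    site_bases: dict[str, str] = {}
    has_indel = False
    prev_ref: int | None = None
    for qpos, rpos in pairs:
        if rpos is None:
            # insertion in the read; attribute it to the gap after prev_ref
            if prev_ref is not None and w0 - 1 <= prev_ref < w1:
                has_indel = True
            continue
        if qpos is None:
            if w0 <= rpos < w1:
                has_indel = True
        elif rpos in wanted:
            site_bases[wanted[rpos]] = query[qpos].upper()
        prev_ref = rpos
    covered = len(site_bases) == len(positions)
    return site_bases, covered, has_indel


def read_alignments(
    path: str | Path,
    ref: AmpliconReference,
    min_mapq: int = DEFAULT_MIN_MAPQ,
    library_id: str | None = None,
) -> tuple[list[ReadObservation], LibraryStats]:
    """Ingest a SAM/BAM file aligned against the two splice contigs.

    Unmapped, secondary and supplementary records are excluded from the
    mapped tally; reads below ``min_mapq`` are counted as discarded.
    """
    path = Path(path)
    library_id = library_id or path.stem
    stats = LibraryStats(library_id)
    observations: list[ReadObservation] = []
    positions = ref.site_positions
    window = ref.site_map.window()

    with pysam.AlignmentFile(str(path), check_sq=False) as af:
        names = set(af.references or ())
        if not {ref.full_id, ref.truncated_id} <= names:
            raise ReferenceError(
                f"{path}: alignment targets {sorted(names)!r} do not include "
                f"{ref.full_id!r} and {ref.truncated_id!r}"
            )
        for aln in af:
            if aln.is_secondary or aln.is_supplementary:
                continue
            stats.total_reads += 1
            if aln.is_unmapped:
                stats.discarded_unmapped += 1
                continue
            if aln.mapping_quality < min_mapq:
                stats.discarded_by_mapq += 1
                continue
            stats.mapped_reads += 1
            if aln.reference_name == ref.truncated_id:
                stats.truncated_reads += 1
                observations.append(
                    ReadObservation(aln.query_name, library_id, "truncated", aln.mapping_quality)
                )
                continue
            stats.full_reads += 1
            query = aln.query_sequence or ""
            try:
                pairs = aln.get_aligned_pairs()
            except ValueError:  # malformed CIGAR
                observations.append(
                    ReadObservation(aln.query_name, library_id, "full", aln.mapping_quality)
                )
                stats.flagged_partial_coverage += 1
                continue
            site_bases, covered, has_indel = _walk_aligned_pairs(pairs, query, positions, window)
            if not covered:
                stats.flagged_partial_coverage += 1
            if has_indel:
                stats.flagged_indel_in_window += 1
            observations.append(
                ReadObservation(
                    aln.query_name,
                    library_id,
                    "full",
                    aln.mapping_quality,
                    site_bases=site_bases if covered else None,
                    covered_all_sites=covered,
                    has_indel_in_window=has_indel,
                )
            )
    stats.check()
    return observations, stats


# ------------------------------------------------------- raw classification

def _iter_reads(path: Path) -> Iterator[tuple[str, str]]:
    with open(path) as fh:
        first = fh.read(1)
        fh.seek(0)
        if first == "@":
            for title, seq, _qual in FastqGeneralIterator(fh):
                yield title.split()[0], seq.upper()
        elif first == ">":
            for title, seq in SimpleFastaParser(fh):
                yield title.split()[0], seq.upper()
        elif first == "":
            return
        else:
            raise ValueError(f"{path}: not FASTA or FASTQ (starts with {first!r})")


class _Classifier:
    """Two-contig global-alignment classifier with memoized verdicts."""

    def __init__(
        self,
        ref: AmpliconReference,
        max_edit_distance: int = DEFAULT_MAX_EDIT_DISTANCE,
        memo_limit: int = 200_000,
    ):
        self.ref = ref
        self.max_edit_distance = max_edit_distance
        self.positions = ref.site_positions
        self.window = ref.site_map.window()
        self._full_arr = np.frombuffer(ref.full_contig.encode(), dtype=np.uint8)
        self._tr_arr = np.frombuffer(ref.truncated_contig.encode(), dtype=np.uint8)
        self._memo: dict[str, tuple] = {}
        self._memo_limit = memo_limit

    def classify(self, seq: str) -> tuple[str, dict[str, str] | None, bool, bool, int | None]:
        """Return (contig, site_bases, covered_all_sites, has_indel, distance)."""
        hit = self._memo.get(seq)
        if hit is None:
            hit = self._classify_uncached(seq)
            if len(self._memo) < self._memo_limit:
                self._memo[seq] = hit
        return hit

    def _classify_uncached(self, seq: str):
        n = len(seq)
        if n == len(self.ref.full_contig):
            arr = np.frombuffer(seq.encode(), dtype=np.uint8)
            hd = int((arr != self._full_arr).sum())
            if hd <= _FAST_HAMMING_MAX:
                bases = {label: seq[pos] for label, pos in self.positions.items()}
                return "full", bases, True, False, hd
        if n == len(self.ref.truncated_contig):
            arr = np.frombuffer(seq.encode(), dtype=np.uint8)
            hd = int((arr != self._tr_arr).sum())
            if hd <= _FAST_HAMMING_MAX:
                return "truncated", None, False, False, hd
        return self._classify_aligned(seq)

    def _classify_aligned(self, seq: str):
        rc = reverse_complement(seq)
        candidates = []  # (distance, contig, oriented_seq, target)
        for oriented in (seq, rc):
            for contig, target in (("full", self.ref.full_contig), ("truncated", self.ref.truncated_contig)):
                res = edlib.align(oriented, target, mode="NW", task="distance")
                candidates.append((res["editDistance"], contig, oriented, target))
        candidates.sort(key=lambda c: c[0])
        best = candidates[0]
        if best[0] > self.max_edit_distance:
            return "unassigned", None, False, False, best[0]
        runner_up = next((c for c in candidates[1:] if c[1] != best[1]), None)
        if runner_up is not None and runner_up[0] == best[0]:
            return "unassigned", None, False, False, best[0]  # contig tie
        distance, contig, oriented, target = best
        if contig == "truncated":
            return "truncated", None, False, False, distance
        res = edlib.align(oriented, target, mode="NW", task="path")
        pairs = _cigar_to_pairs(res["cigar"])
        site_bases, covered, has_indel = _walk_aligned_pairs(
            pairs, oriented, self.positions, self.window
        )
        return "full", site_bases if covered else None, covered, has_indel, distance


def _cigar_to_pairs(cigar: str) -> list[tuple[int | None, int | None]]:
    """Expand an edlib NW CIGAR (=/X/I/D, query vs target) into
    (query_pos, target_pos) pairs, SAM-style."""
    pairs: list[tuple[int | None, int | None]] = []
    qpos = tpos = 0
    count = ""
    for char in cigar:
        if char.isdigit():
            count += char
            continue
        n = int(count)
        count = ""
        if char in "=XM":
            for _ in range(n):
                pairs.append((qpos, tpos))
                qpos += 1
                tpos += 1
        elif char == "I":  # consumes query only
            for _ in range(n):
                pairs.append((qpos, None))
                qpos += 1
        elif char == "D":  # consumes target only
            for _ in range(n):
                pairs.append((None, tpos))
                tpos += 1
        else:
            raise ValueError(f"unsupported CIGAR op {char!r}")
    return pairs


def classify_raw_reads(
    path: str | Path,
    ref: AmpliconReference,
    library_id: str | None = None,
    max_edit_distance: int = DEFAULT_MAX_EDIT_DISTANCE,
) -> tuple[list[ReadObservation], LibraryStats]:
    """Classify raw FASTQ/FASTA amplicon reads against the two contigs.

    An empty file yields an empty stream with zeroed stats.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    library_id = library_id or path.stem.removesuffix(".fastq").removesuffix(".fasta")
    return classify_reads(_iter_reads(path), ref, library_id, max_edit_distance)


def classify_reads(
    reads: Iterable[tuple[str, str]],
    ref: AmpliconReference,
    library_id: str = "lib",
    max_edit_distance: int = DEFAULT_MAX_EDIT_DISTANCE,
) -> tuple[list[ReadObservation], LibraryStats]:
    """Classify an in-memory stream of ``(read_id, sequence)`` pairs."""
    stats = LibraryStats(library_id)
    observations: list[ReadObservation] = []
    classifier = _Classifier(ref, max_edit_distance)
    for read_id, seq in reads:
        stats.total_reads += 1
        contig, site_bases, covered, has_indel, distance = classifier.classify(seq)
        if contig == "unassigned":
            stats.unassigned_reads += 1
            observations.append(
                ReadObservation(read_id, library_id, "unassigned", edit_distance=distance)
            )
            continue
        stats.mapped_reads += 1
        if contig == "truncated":
            stats.truncated_reads += 1
            observations.append(
                ReadObservation(read_id, library_id, "truncated", edit_distance=distance)
            )
            continue
        stats.full_reads += 1
        if not covered:
            stats.flagged_partial_coverage += 1
        if has_indel:
            stats.flagged_indel_in_window += 1
        observations.append(
            ReadObservation(
                read_id,
                library_id,
                "full",
                site_bases=site_bases,
                covered_all_sites=covered,
                has_indel_in_window=has_indel,
                edit_distance=distance,
            )
        )
    stats.check()
    return observations, stats
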