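"""Per-read editing-pattern calling.

A full-contig read covering all 11 sites is reduced to one joint editing
pattern: 'G' at a site means edited, 'A' unedited.  Because a single
miscalled site corrupts the whole combinatorial pattern, the default
policy rejects any read showing a non-A/G base (C, T or N) at a site; the
"lenient" policy instead treats such sites as unedited and keeps the read.
Truncated-contig reads never reach the caller — exon Vb is absent, so they
carry no editing information.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable

from .reads import ReadObservation
from .reference import SiteMap, make_pattern_label

REJECT_NONE = "none"
REJECT_NON_AG = "non_AG_base"
REJECT_PARTIAL = "partial_coverage"
REJECT_INDEL = "indel"

POLICIES = ("strict", "lenient")


@dataclass(frozen=True)
class PatternCall:
    """Outcome of calling one read; ``pattern`` is None iff rejected."""

    read_id: str
    pattern: str | None
    n_edited: int = 0
    rejected_reason: str = REJECT_NONE

    @property
    def accepted(self) -> bool:
        return self.rejected_reason == REJECT_NONE


def call_pattern(
    obs: ReadObservation, site_map: SiteMap, policy: str = "strict"
) -> PatternCall:
    """Call the joint editing pattern of one full-contig observation.

    Observations on other contigs are a caller error; incomplete coverage
    or an indel in the site window yields an explicit rejection.
    """
    if policy not in POLICIES:
        raise ValueError(f"unknown policy {policy!r}; expected one of {POLICIES}")
    if obs.contig != "full":
        raise ValueError(
            f"read {obs.read_id}: pattern calling requires a full-contig read, got {obs.contig!r}"
        )
    if obs.has_indel_in_window:
        return PatternCall(obs.read_id, None, rejected_reason=REJECT_INDEL)
    if not obs.covered_all_sites or obs.site_bases is None:
        return PatternCall(obs.read_id, None, rejected_reason=REJECT_PARTIAL)

    edited = set()
    for label in site_map.labels:
        base = obs.site_bases.get(label)
        if base is None:
            return PatternCall(obs.read_id, None, rejected_reason=REJECT_PARTIAL)
        if base == "G":
            edited.add(label)
        elif base != "A":
            if policy == "strict":
                return PatternCall(obs.read_id, None, rejected_reason=REJECT_NON_AG)
            # lenient: non-A/G treated as unedited
    return PatternCall(
        obs.read_id, make_pattern_label(edited, site_map), n_edited=len(edited)
    )


def count_patterns(
    calls: Iterable[PatternCall], library_id: str | None = None
) -> tuple[Counter, Counter]:
    """Histogram accepted calls by pattern; tally rejections separately.

    Returns ``(pattern_counts, rejection_counts)``; the sum of pattern
    counts equals the number of accepted calls.
    """
    patterns: Counter = Counter()
    rejections: Counter = Counter()
    for call in calls:
        if call.accepted:
            patterns[call.pattern] += 1
        else:
            rejections[call.rejected_reason] += 1
    return patterns, rejections


def call_library(
    observations: Iterable[ReadObservation],
    site_map: SiteMap,
    policy: str = "strict",
) -> tuple[Counter, Counter]:
    """Call and histogram every full-contig observation of a library."""
    calls = (
        call_pattern(obs, site_map, policy)
        for obs in observations
        if obs.contig == "full"
    )
    return count_patterns(calls)
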