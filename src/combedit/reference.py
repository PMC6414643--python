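"""Amplicon reference model: splice contigs, editing-site map, pattern labels.

The amplicon spans the serotonin-receptor 2C (5-Ht2cr) pre-mRNA region from
exon IV to exon VI.  Two splice products are possible: the full-length
message retaining the alternatively spliced exon Vb (209 nt contig) and a
truncated message that skips it (114 nt contig).  Eleven A-to-I editing
sites, conventionally labelled 1, 2, 3, A, B, E, C, D, F, G and H in their
5'->3' genomic order, lie in a <=30 nt window inside exon Vb; inosine is
read as G by RT and sequencing, so an edited site appears as an A->G call.

Every downstream stage identifies a read's joint editing state by a
*pattern label*: the concatenation of the edited site labels in canonical
order (e.g. ``"ABD"``), or ``"NoEdit"`` for the fully unedited read.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

#: Canonical site order: genomic 5'->3'.  Note E precedes C and D.
CANONICAL_ORDER: tuple[str, ...] = ("1", "2", "3", "A", "B", "E", "C", "D", "F", "G", "H")

_ORDER_INDEX = {label: i for i, label in enumerate(CANONICAL_ORDER)}

#: Label used for the fully unedited pattern.
NO_EDIT = "NoEdit"

#: Contig identifiers used in FASTA references and SAM/BAM headers.
FULL_ID = "5-Ht2cr"
TRUNCATED_ID = "5-Ht2cr-tr"

# Synthetic default contigs.  The real exon IV-VI amplicon sequence is not
# bundled; this stand-in pair reproduces its architecture: a 209 nt
# full-length contig whose 95 nt exon Vb block (positions 60-154) carries
# the 11 editing sites in a 30 nt window, and a 114 nt truncated contig
# equal to the full contig with that block spliced out.
_SYNTHETIC_FULL = (
    "TCTCTACATCCCCCGATCACGGGCTTTACTTGCTGCTTACATACGTAAATTACGTGCTTG"
    "GGGGATCAGGGGCCTATGACCATAGAAATAAAGAAAGAAAATAGATTGGAGGGTGAAACTTCCTTTATAAAAAAGGTGATGGTCCCGCAAC"
    "GACGAGTCACAATACCCATGCGCATCAATGCGAACGGAGACAATGTAAGCCTGGGCGT"
)
_SYNTHETIC_SITES = {
    "1": 75, "2": 78, "3": 81, "A": 85, "B": 86, "E": 89,
    "C": 91, "D": 93, "F": 97, "G": 100, "H": 104,
}
_SYNTHETIC_DONOR = 60
_SYNTHETIC_VB_END = 155


class ReferenceError(ValueError):
    """Raised for an inconsistent reference, site map or pattern label."""


@dataclass(frozen=True)
class EditingSite:
    """One A-to-I editing site on the full-length contig (0-based offset)."""

    label: str
    position: int

    def __post_init__(self) -> None:
        if self.label not in _ORDER_INDEX:
            raise ReferenceError(f"unknown editing-site label {self.label!r}")
        if self.position < 0:
            raise ReferenceError(f"site {self.label}: negative position {self.position}")


@dataclass(frozen=True)
class SiteMap:
    """The ordered collection of the 11 editing sites.

    Sites are stored in canonical (genomic) order; positions must be
    strictly increasing and span at most ``max_window`` nucleotides.
    """

    sites: tuple[EditingSite, ...]
    max_window: int = 30

    @classmethod
    def from_positions(cls, positions: Mapping[str, int], max_window: int = 30) -> "SiteMap":
        ordered = tuple(
            EditingSite(label, positions[label])
            for label in CANONICAL_ORDER
            if label in positions
        )
        missing = set(positions) - set(CANONICAL_ORDER)
        if missing:
            raise ReferenceError(f"unknown editing-site label(s) {sorted(missing)!r}")
        return cls(ordered, max_window=max_window)

    def __post_init__(self) -> None:
        labels = [s.label for s in self.sites]
        if len(set(labels)) != len(labels):
            raise ReferenceError("duplicate site labels in site map")
        order = [_ORDER_INDEX[l] for l in labels]
        if order != sorted(order):
            raise ReferenceError("site map labels not in canonical order")

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(s.label for s in self.sites)

    @property
    def positions(self) -> dict[str, int]:
        return {s.label: s.position for s in self.sites}

    def window(self) -> tuple[int, int]:
        """Half-open reference interval [start, end) spanning all sites."""
        pos = [s.position for s in self.sites]
        return min(pos), max(pos) + 1

    def violations(self) -> list[str]:
        out = []
        pos = [s.position for s in self.sites]
        if any(b <= a for a, b in zip(pos, pos[1:])):
            out.append("non-monotonic site map")
        if pos and (max(pos) - min(pos) + 1) > self.max_window:
            out.append(
                f"site window spans {max(pos) - min(pos) + 1} nt "
                f"(limit {self.max_window})"
            )
        return out


@dataclass(frozen=True)
class AmpliconReference:
    """The two splice-variant contigs plus the editing-site map.

    ``full_contig`` retains exon Vb and carries the editing sites;
    ``truncated_contig`` equals the full contig with the alternatively
    spliced block removed, i.e. ``full[:donor] + full[vb_end:]``.
    """

    full_contig: str
    truncated_contig: str
    site_map: SiteMap
    splice_donor_offset: int
    full_id: str = FULL_ID
    truncated_id: str = TRUNCATED_ID

    @classmethod
    def default(cls) -> "AmpliconReference":
        """The bundled synthetic 209/114 nt reference pair."""
        full = _SYNTHETIC_FULL
        truncated = full[:_SYNTHETIC_DONOR] + full[_SYNTHETIC_VB_END:]
        return cls(
            full_contig=full,
            truncated_contig=truncated,
            site_map=SiteMap.from_positions(_SYNTHETIC_SITES),
            splice_donor_offset=_SYNTHETIC_DONOR,
        )

    @property
    def site_positions(self) -> dict[str, int]:
        return self.site_map.positions

    def violations(self) -> list[str]:
        out = list(self.site_map.violations())
        n = len(self.full_contig)
        for site in self.site_map.sites:
            if site.position >= n:
                out.append(f"site {site.label} position {site.position} beyond contig end {n}")
            elif self.full_contig[site.position] != "A":
                out.append(
                    f"site {site.label}: reference base "
                    f"{self.full_contig[site.position]!r} at position {site.position}, expected 'A'"
                )
        if self.site_map.sites and self.site_map.sites[0].position < self.splice_donor_offset:
            out.append("editing sites overlap the shared prefix retained in the truncated contig")
        if not (0 <= self.splice_donor_offset <= n):
            out.append("splice donor offset outside the full contig")
        return out

    # ---------------------------------------------------------------- I/O
    def to_fasta(self, path: str | Path) -> None:
        records = [
            SeqRecord(Seq(self.full_contig), id=self.full_id, description=""),
            SeqRecord(Seq(self.truncated_contig), id=self.truncated_id, description=""),
        ]
        SeqIO.write(records, str(path), "fasta")

    def site_map_to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("label\tposition\tref_base\n")
            for site in self.site_map.sites:
                fh.write(f"{site.label}\t{site.position}\t{self.full_contig[site.position]}\n")

    @classmethod
    def from_fasta(
        cls,
        fasta_path: str | Path,
        site_tsv_path: str | Path,
        splice_donor_offset: int,
        full_id: str = FULL_ID,
        truncated_id: str = TRUNCATED_ID,
    ) -> "AmpliconReference":
        seqs = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(fasta_path), "fasta")}
        for required in (full_id, truncated_id):
            if required not in seqs:
                raise ReferenceError(
                    f"contig {required!r} missing from {fasta_path}; found {sorted(seqs)!r}"
                )
        positions: dict[str, int] = {}
        with open(site_tsv_path) as fh:
            header = fh.readline()
            if not header.startswith("label"):
                raise ReferenceError(f"{site_tsv_path}: expected header 'label\\tposition\\tref_base'")
            for line in fh:
                if not line.strip():
                    continue
                label, pos, _base = line.rstrip("\n").split("\t")[:3]
                positions[label] = int(pos)
        return cls(
            full_contig=seqs[full_id],
            truncated_contig=seqs[truncated_id],
            site_map=SiteMap.from_positions(positions),
            splice_donor_offset=splice_donor_offset,
            full_id=full_id,
            truncated_id=truncated_id,
        )


@dataclass
class ValidationReport:
    """Outcome of :func:`validate_reference`; empty ``violations`` means valid."""

    violations: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.violations


def validate_reference(ref: AmpliconReference) -> ValidationReport:
    """Check contig/site-map consistency and the A-base identity at each site."""
    return ValidationReport(ref.violations())


# ------------------------------------------------------------------ labels

def make_pattern_label(edited_sites: Iterable[str], site_map: SiteMap | None = None) -> str:
    """Canonical label for a set of edited sites: member labels joined in
    canonical order; the empty set maps to ``"NoEdit"``.
    """
    allowed = set(site_map.labels) if site_map is not None else set(CANONICAL_ORDER)
    edited = set(edited_sites)
    for label in edited:
        if label not in allowed:
            raise ReferenceError(f"unknown editing-site label {label!r}")
    if not edited:
        return NO_EDIT
    return "".join(sorted(edited, key=_ORDER_INDEX.__getitem__))


def parse_pattern_label(label: str, site_map: SiteMap | None = None) -> frozenset[str]:
    """Inverse of :func:`make_pattern_label`; rejects unknown or repeated sites."""
    if label == NO_EDIT:
        return frozenset()
    allowed = set(site_map.labels) if site_map is not None else set(CANONICAL_ORDER)
    seen: set[str] = set()
    for char in label:
        if char not in allowed:
            raise ReferenceError(f"unknown editing-site label {char!r} in pattern {label!r}")
        if char in seen:
            raise ReferenceError(f"repeated site {char!r} in pattern {label!r}")
        seen.add(char)
    return frozenset(seen)


def all_pattern_labels(site_map: SiteMap | None = None) -> list[str]:
    """Every possible pattern label (2^11 = 2048 for the default map),
    ``"NoEdit"`` first, then by increasing pattern size in canonical order."""
    labels = site_map.labels if site_map is not None else CANONICAL_ORDER
    out = [NO_EDIT]
    for k in range(1, len(labels) + 1):
        for combo in itertools.combinations(labels, k):
            out.append("".join(combo))
    return out


def pattern_sort_key(label: str) -> tuple:
    """Deterministic ordering: NoEdit first, then by size, then canonical order."""
    if label == NO_EDIT:
        return (0, ())
    return (1, len(label), tuple(_ORDER_INDEX.get(c, 99) for c in label))


def pattern_contains_site(label: str, site: str) -> bool:
    """Whether a pattern label includes ``site`` among its edited sites."""
    return label != NO_EDIT and site in label
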