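"""Core domain types shared across the pipeline.

All genomic coordinates are 0-based half-open; GTF is the only 1-based
surface (converted at the I/O boundary). An intron is stored by its
genomic (left, right) = (end of upstream exon, start of downstream exon)
regardless of strand; biological donor/acceptor roles are resolved by
strand where they matter.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Optional, Sequence, Tuple

DNA_ALPHABET = frozenset("ACGTN")

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (N-safe)."""
    return seq.translate(_COMPLEMENT)[::-1]


class IsoatlasError(Exception):
    """Base class for package errors."""


class ParameterError(IsoatlasError, ValueError):
    """Invalid user-supplied parameter."""


class FormatError(IsoatlasError, ValueError):
    """Malformed input file content."""


class CoordinateError(IsoatlasError, ValueError):
    """Coordinates fall outside the reference."""


class ContractError(IsoatlasError, RuntimeError):
    """An internal precondition between stages was violated."""


class CapacityError(IsoatlasError, ValueError):
    """The genome cannot hold the requested gene layout."""


@dataclass(frozen=True)
class GenomeRef:
    """A reference genome held in memory as uppercase contig strings."""

    contigs: dict

    def __post_init__(self):
        for name, seq in self.contigs.items():
            if not name:
                raise ParameterError("contig names must be non-empty")
            if len(seq) < 1:
                raise ParameterError(f"contig {name!r} is empty")
            if set(seq) - DNA_ALPHABET:
                bad = sorted(set(seq) - DNA_ALPHABET)
                raise ParameterError(f"contig {name!r} has non-ACGTN characters: {bad}")

    def __getitem__(self, name: str) -> str:
        return self.contigs[name]

    def __contains__(self, name: str) -> bool:
        return name in self.contigs

    def fetch(self, contig: str, start: int, end: int) -> str:
        """Slice [start, end) of a contig, with bounds checking."""
        if contig not in self.contigs:
            raise CoordinateError(f"unknown contig {contig!r}")
        seq = self.contigs[contig]
        if start < 0 or end > len(seq) or start > end:
            raise CoordinateError(
                f"window [{start},{end}) outside contig {contig!r} of length {len(seq)}"
            )
        return seq[start:end]


@dataclass(frozen=True)
class TranscriptModel:
    """A strand-aware exon chain on a contig.

    ``exons`` are sorted, non-overlapping, non-adjacent (start, end) pairs in
    0-based half-open genomic coordinates. ``coverage`` and ``identity`` are
    aligner-reported query fractions, defaulting to 1.0 for truth-derived
    models.
    """

    id: str
    contig: str
    strand: str
    exons: Tuple[Tuple[int, int], ...]
    source: str = "unknown"
    coverage: float = 1.0
    identity: float = 1.0

    def __post_init__(self):
        if self.strand not in ("+", "-"):
            raise ParameterError(f"{self.id}: strand must be '+' or '-'")
        if not self.exons:
            raise ParameterError(f"{self.id}: transcript has no exons")
        exons = tuple(tuple(e) for e in self.exons)
        object.__setattr__(self, "exons", exons)
        prev_end = None
        for s, e in exons:
            if s >= e:
                raise FormatError(f"{self.id}: exon ({s},{e}) has start >= end")
            if prev_end is not None and s < prev_end:
                raise FormatError(f"{self.id}: exons overlap or are unsorted at ({s},{e})")
            if prev_end is not None and s == prev_end:
                raise FormatError(f"{self.id}: adjacent exons at {s} (zero-length intron)")
            prev_end = e

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    @property
    def introns(self) -> Tuple[Tuple[int, int], ...]:
        """Genomic (left, right) intron intervals between consecutive exons."""
        return tuple(
            (self.exons[i][1], self.exons[i + 1][0]) for i in range(len(self.exons) - 1)
        )

    @property
    def intron_chain(self) -> Tuple[Tuple[int, int], ...]:
        return self.introns

    @property
    def length(self) -> int:
        """Spliced (mature transcript) length in nt."""
        return sum(e - s for s, e in self.exons)

    @property
    def three_prime(self) -> int:
        """Genomic coordinate of the 3' terminus (half-open end on '+', start on '-')."""
        return self.end if self.strand == "+" else self.start

    @property
    def five_prime(self) -> int:
        return self.start if self.strand == "+" else self.end

    def spliced_sequence(self, genome: GenomeRef) -> str:
        """Mature transcript sequence in transcript (sense) orientation."""
        seq = "".join(genome.fetch(self.contig, s, e) for s, e in self.exons)
        return seq if self.strand == "+" else revcomp(seq)

    def with_(self, **kwargs) -> "TranscriptModel":
        return replace(self, **kwargs)


MOTIF_CLASSES = ("GT-AG", "GC-AG", "AT-AC", "other")


def classify_motif(motif: str) -> str:
    """Map a 4-char intron boundary motif (transcript orientation) to its class."""
    if motif[:2] == "GT" and motif[2:] == "AG":
        return "GT-AG"
    if motif[:2] == "GC" and motif[2:] == "AG":
        return "GC-AG"
    if motif[:2] == "AT" and motif[2:] == "AC":
        return "AT-AC"
    return "other"


@dataclass(frozen=True)
class Junction:
    """One intron: genomic (donor, acceptor) interval plus motif and support.

    ``donor`` is the first intron base and ``acceptor`` one past the last
    intron base in genomic orientation. ``motif`` is the first two plus last
    two intron bases in transcript orientation.
    """

    contig: str
    strand: str
    donor: int
    acceptor: int
    motif: str = "NNNN"
    motif_class: str = "other"
    sr_support: int = 0

    def __post_init__(self):
        if self.donor >= self.acceptor:
            raise FormatError(
                f"junction ({self.donor},{self.acceptor}) has donor >= acceptor"
            )
        if self.sr_support < 0:
            raise ParameterError("sr_support must be >= 0")

    @property
    def key(self) -> Tuple[str, int, int, str]:
        return (self.contig, self.donor, self.acceptor, self.strand)


@dataclass
class ASEvent:
    """A typed alternative-splicing variant between two isoforms of a locus.

    ``inclusion_junctions`` / ``exclusion_junctions`` are sets of genomic
    (contig, donor, acceptor) keys; strand handled at the locus level. For IR
    the inclusion (retaining) form has no junction across the variant intron
    and is quantified from intron-body coverage.
    """

    event_id: str
    type: str
    locus_id: str
    contig: str
    strand: str
    flank_left: int
    flank_right: int
    variant: Tuple[int, ...]
    inclusion_junctions: frozenset
    exclusion_junctions: frozenset
    isoform_inclusion: str
    isoform_exclusion: str

    def __post_init__(self):
        if self.type not in ("IR", "ES", "AA", "AD", "MX"):
            raise ParameterError(f"unknown AS type {self.type!r}")
        if self.inclusion_junctions & self.exclusion_junctions:
            raise ContractError(
                f"{self.event_id}: inclusion and exclusion junction sets overlap"
            )


@dataclass(frozen=True)
class PolyASite:
    """A clustered poly(A) cleavage position with FLnc read support."""

    gene_id: str
    contig: str
    strand: str
    position: int
    support: int
    internal_priming: bool = False

    def __post_init__(self):
        if self.support < 1:
            raise ParameterError("poly(A) site support must be >= 1")


def exonic_overlap(a: TranscriptModel, b: TranscriptModel) -> int:
    """Total exonic overlap in bp between two models (0 if different contigs)."""
    if a.contig != b.contig:
        return 0
    total = 0
    for s1, e1 in a.exons:
        for s2, e2 in b.exons:
            total += max(0, min(e1, e2) - max(s1, s2))
    return total
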