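"""ORF detection, representative selection, Markov coding-potential scoring
and non-coding RNA flagging.

ORFs are complete ATG..stop spans scanned over the three sense reading
frames (full-length reads are already oriented); an ORF is retained when it
encodes at least ``min_aa`` (default 100) amino acids. A transcript's
representative ORF is the 5'-most (ties to the longest); a locus's
representative isoform is the one with the longest ORF. Loci with no
retained ORF are non-coding candidates: lncRNA when longer than 200 nt,
short-ncRNA otherwise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

from .models import ContractError, ParameterError, revcomp

_STOPS = {"TAA", "TAG", "TGA"}
LNCRNA_MIN_NT = 200
DEFAULT_MIN_AA = 100


@dataclass(frozen=True)
class OrfRecord:
    """One complete ORF on a transcript (0-based half-open transcript
    coordinates; ``end`` is one past the stop codon)."""

    transcript_id: str
    frame: int
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self):
        if (self.end - self.start) % 3 != 0:
            raise ParameterError("ORF span must be a multiple of 3")

    @property
    def aa_length(self) -> int:
        return (self.end - self.start) // 3 - 1


@dataclass(frozen=True)
class NcrnaFlag:
    locus_id: str
    length_nt: int
    category: str  # coding | lncRNA-candidate | short-ncRNA-candidate


def find_orfs(seq: str, transcript_id: str = "", min_aa: int = DEFAULT_MIN_AA,
              both_strands: bool = False) -> List[OrfRecord]:
    """Complete ORFs (ATG..in-frame stop) in the three sense frames.

    Overlapping ORFs sharing a stop resolve to the 5'-most ATG. With
    ``both_strands`` the reverse complement is scanned too (for unoriented
    input); coordinates then refer to the scanned strand. Sorted by start.
    """
    seq = seq.upper()
    orfs = list(_scan_strand(seq, transcript_id, min_aa, "+"))
    if both_strands:
        orfs.extend(_scan_strand(revcomp(seq), transcript_id, min_aa, "-"))
    return sorted(orfs, key=lambda o: (o.start, -(o.end - o.start), o.strand))


def _scan_strand(seq, transcript_id, min_aa, strand):
    n = len(seq)
    for frame in range(3):
        start: Optional[int] = None
        for i in range(frame, n - 2, 3):
            codon = seq[i:i + 3]
            if start is None:
                if codon == "ATG":
                    start = i
            elif codon in _STOPS:
                aa = (i + 3 - start) // 3 - 1
                if aa >= min_aa:
                    yield OrfRecord(transcript_id=transcript_id, frame=frame,
                                    start=start, end=i + 3, strand=strand)
                start = None


def representative_orf(orfs: Sequence[OrfRecord]) -> OrfRecord:
    """The transcript's representative: 5'-most start, ties to the longest."""
    if not orfs:
        raise ContractError("representative_orf needs a non-empty ORF list")
    return min(orfs, key=lambda o: (o.start, -(o.end - o.start)))


def locus_representative(orfs_by_isoform: Dict[str, Sequence[OrfRecord]]) -> str:
    """Isoform id whose longest ORF is maximal (ties to lexicographically
    smaller id)."""
    best_id, best_aa = None, -1
    for iso_id in sorted(orfs_by_isoform):
        orfs = orfs_by_isoform[iso_id]
        if not orfs:
            continue
        aa = max(o.aa_length for o in orfs)
        if aa > best_aa:
            best_id, best_aa = iso_id, aa
    if best_id is None:
        raise ContractError("no isoform has a retained ORF")
    return best_id


# ---------------------------------------------------------------------------
# Markov coding-potential score
# ---------------------------------------------------------------------------

@dataclass
class MarkovModel:
    """Fixed-order nucleotide Markov chain with add-one smoothing.

    ``transitions[context][base]`` are log probabilities; contexts shorter
    than ``order`` (used for a sequence's first bases) fall back to
    lower-order chains trained on the same data.
    """

    order: int
    log_probs: Dict[str, Dict[str, float]]

    def log_likelihood(self, seq: str) -> float:
        total = 0.0
        for i in range(len(seq)):
            ctx = seq[max(0, i - self.order):i]
            table = self.log_probs.get(ctx)
            while table is None and ctx:
                ctx = ctx[1:]
                table = self.log_probs.get(ctx)
            if table is None:
                table = self.log_probs[""]
            total += table.get(seq[i], math.log(0.25))
        return total


def train_markov(seqs: Sequence[str], order: int = 5) -> MarkovModel:
    """Train an order-``order`` Markov chain (with all lower-order fallback
    tables) by add-one-smoothed counting."""
    if order < 0:
        raise ParameterError("order must be >= 0")
    counts: Dict[str, Dict[str, int]] = {}
    for seq in seqs:
        seq = seq.upper()
        for k in range(order + 1):
            for i in range(len(seq)):
                if i < k:
                    continue
                ctx = seq[i - k:i]
                counts.setdefault(ctx, {}).setdefault(seq[i], 0)
                counts[ctx][seq[i]] += 1
    log_probs: Dict[str, Dict[str, float]] = {}
    for ctx, table in counts.items():
        total = sum(table.values()) + 4  # add-one over ACGT
        log_probs[ctx] = {
            b: math.log((table.get(b, 0) + 1) / total) for b in "ACGT"
        }
    if "" not in log_probs:
        log_probs[""] = {b: math.log(0.25) for b in "ACGT"}
    return MarkovModel(order=order, log_probs=log_probs)


def markov_score(seq: str, orf: OrfRecord, coding: MarkovModel,
                 background: MarkovModel) -> float:
    """Log-likelihood ratio (base e) of the ORF sequence under the coding vs
    background models."""
    sub = seq[orf.start:orf.end].upper()
    if len(sub) < coding.order + 1:
        raise ParameterError("ORF shorter than model order + 1")
    return coding.log_likelihood(sub) - background.log_likelihood(sub)


# ---------------------------------------------------------------------------
# ncRNA flagging
# ---------------------------------------------------------------------------

def flag_ncrna(locus_lengths: Dict[str, int],
               retained_orfs_by_locus: Dict[str, bool]) -> List[NcrnaFlag]:
    """One flag per locus using its longest isoform length.

    Coding when any isoform has a retained ORF; otherwise lncRNA candidate
    (> 200 nt) or short-ncRNA candidate (<= 200 nt).
    """
    flags = []
    for locus_id in sorted(locus_lengths):
        length = locus_lengths[locus_id]
        if retained_orfs_by_locus.get(locus_id, False):
            cat = "coding"
        elif length > LNCRNA_MIN_NT:
            cat = "lncRNA-candidate"
        else:
            cat = "short-ncRNA-candidate"
        flags.append(NcrnaFlag(locus_id=locus_id, length_nt=length, category=cat))
    return flags


def translate(seq: str) -> str:
    """Standard-code translation of a CDS (stops as '*')."""
    from Bio.Seq import Seq

    return str(Seq(seq).translate())
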