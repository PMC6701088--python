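"""Readers and writers for FASTA, GTF, BED12, SAM spliced alignments and
STAR-style SJ tab files.

One coordinate convention everywhere: internal coordinates are 0-based
half-open; GTF (1-based closed) and SJ tab intron first/last columns
(1-based inclusive) are converted at this boundary and nowhere else.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import gffutils
import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .models import (
    FormatError,
    GenomeRef,
    TranscriptModel,
)

logger = logging.getLogger(__name__)

SJKey = Tuple[str, int, int, str]  # (contig, donor, acceptor, strand); strand '.' = undetermined


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path) -> Dict[str, str]:
    """Read a FASTA file into an ordered dict of id -> uppercase sequence."""
    records = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        records[rec.id] = str(rec.seq).upper()
    return records


def write_fasta(path, records: Dict[str, str], width: int = 70) -> None:
    seqrecs = [SeqRecord(Seq(s), id=name, description="") for name, s in records.items()]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(seqrecs)


def read_genome(path) -> GenomeRef:
    return GenomeRef(read_fasta(path))


def write_genome(path, genome: GenomeRef) -> None:
    write_fasta(path, genome.contigs)


# ---------------------------------------------------------------------------
# GTF
# ---------------------------------------------------------------------------

def read_gtf(path) -> List[TranscriptModel]:
    """Read exon features from a GTF into transcript models.

    GTF 1-based closed intervals become 0-based half-open. Exons are grouped
    by ``transcript_id`` and sorted; model invariants (sorted, non-overlapping
    exons) are enforced and violations raise :class:`FormatError` naming the
    transcript.
    """
    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )
    grouped: Dict[str, dict] = {}
    for feat in db.features_of_type("exon"):
        tid = feat.attributes.get("transcript_id", [None])[0]
        if tid is None:
            raise FormatError(f"exon at {feat.seqid}:{feat.start} lacks transcript_id")
        entry = grouped.setdefault(
            tid, {"contig": feat.seqid, "strand": feat.strand, "exons": []}
        )
        if entry["contig"] != feat.seqid or entry["strand"] != feat.strand:
            raise FormatError(f"transcript {tid!r} spans contigs or strands")
        entry["exons"].append((feat.start - 1, feat.end))  # to 0-based half-open
    models = []
    for tid, entry in grouped.items():
        exons = tuple(sorted(entry["exons"]))
        try:
            models.append(
                TranscriptModel(
                    id=tid,
                    contig=entry["contig"],
                    strand=entry["strand"],
                    exons=exons,
                    source="annotated",
                )
            )
        except FormatError as exc:
            raise FormatError(f"invalid transcript {tid!r} in {path}: {exc}") from exc
    return models


def write_gtf(path, models: Sequence[TranscriptModel], gene_ids: Optional[Dict[str, str]] = None) -> None:
    """Write transcript and exon features (GTF 2.2 attribute dialect).

    ``gene_ids`` optionally maps transcript id -> gene/locus id; transcripts
    absent from the map use their own id as gene_id.
    """
    gene_ids = gene_ids or {}
    with open(path, "w") as fh:
        for m in models:
            gid = gene_ids.get(m.id, m.id)
            attrs = f'gene_id "{gid}"; transcript_id "{m.id}";'
            fh.write(
                "\t".join(
                    [m.contig, m.source, "transcript", str(m.start + 1), str(m.end),
                     ".", m.strand, ".", attrs]
                )
                + "\n"
            )
            for s, e in m.exons:
                fh.write(
                    "\t".join(
                        [m.contig, m.source, "exon", str(s + 1), str(e), ".", m.strand,
                         ".", attrs]
                    )
                    + "\n"
                )


# ---------------------------------------------------------------------------
# BED12
# ---------------------------------------------------------------------------

def read_bed12(path) -> List[TranscriptModel]:
    models = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 12:
                raise FormatError(f"{path}:{lineno}: BED12 needs 12 columns, got {len(fields)}")
            try:
                chrom = fields[0]
                chrom_start = int(fields[1])
                name = fields[3]
                strand = fields[5]
                block_count = int(fields[9])
                sizes = [int(x) for x in fields[10].rstrip(",").split(",")]
                starts = [int(x) for x in fields[11].rstrip(",").split(",")]
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
            if len(sizes) != block_count or len(starts) != block_count:
                raise FormatError(f"{path}:{lineno}: block count mismatch")
            exons = tuple(
                (chrom_start + st, chrom_start + st + sz) for st, sz in zip(starts, sizes)
            )
            try:
                models.append(
                    TranscriptModel(id=name, contig=chrom, strand=strand, exons=exons,
                                    source="bed12")
                )
            except FormatError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
    return models


def write_bed12(path, models: Sequence[TranscriptModel]) -> None:
    with open(path, "w") as fh:
        for m in models:
            sizes = ",".join(str(e - s) for s, e in m.exons)
            starts = ",".join(str(s - m.start) for s, e in m.exons)
            fh.write(
                "\t".join(
                    [m.contig, str(m.start), str(m.end), m.id, "0", m.strand,
                     str(m.start), str(m.end), "0", str(len(m.exons)), sizes, starts]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# SAM spliced alignments
# ---------------------------------------------------------------------------

_REF_CONSUMING = {0, 2, 3}  # M, D, N
_SUPPORTED_OPS = {0, 1, 2, 3, 4}  # M, I, D, N, S


def read_alignments_with_stats(path):
    """Read spliced alignments (SAM or BED12 by extension) into models.

    Returns ``(models, stats)`` where stats counts skipped unmapped records.
    SAM N operations become introns; soft clips are discarded; unsupported
    CIGAR ops raise :class:`FormatError`.
    """
    path = str(path)
    if path.endswith((".bed", ".bed12")):
        return read_bed12(path), {"skipped_unmapped": 0}
    models = []
    skipped = 0
    with pysam.AlignmentFile(path, "r", check_sq=False) as sam:
        for rec in sam:
            if rec.is_unmapped:
                skipped += 1
                continue
            exons = []
            pos = rec.reference_start
            cur_start = None
            for op, length in rec.cigartuples:
                if op not in _SUPPORTED_OPS:
                    raise FormatError(
                        f"read {rec.query_name!r}: unsupported CIGAR op code {op}"
                    )
                if op in (1, 4):  # I, S: consume query only
                    continue
                if op == 3:  # N: intron
                    if cur_start is not None:
                        exons.append((cur_start, pos))
                        cur_start = None
                    pos += length
                    continue
                if cur_start is None:
                    cur_start = pos
                pos += length
            if cur_start is not None:
                exons.append((cur_start, pos))
            coverage = float(rec.get_tag("XC")) if rec.has_tag("XC") else 1.0
            identity = float(rec.get_tag("XI")) if rec.has_tag("XI") else 1.0
            models.append(
                TranscriptModel(
                    id=rec.query_name,
                    contig=rec.reference_name,
                    strand="-" if rec.is_reverse else "+",
                    exons=tuple(exons),
                    source="aligned",
                    coverage=coverage,
                    identity=identity,
                )
            )
    if skipped:
        logger.info("skipped %d unmapped records in %s", skipped, path)
    return models, {"skipped_unmapped": skipped}


def read_alignments(path) -> List[TranscriptModel]:
    return read_alignments_with_stats(path)[0]


def write_sam(path, models: Sequence[TranscriptModel], contig_lengths: Dict[str, int],
              sequences: Optional[Dict[str, str]] = None) -> None:
    """Write models as headerful SAM records with N-CIGAR introns.

    Query coverage/identity are carried in XC/XI tags so they survive a
    round trip through :func:`read_alignments`.
    """
    header = {
        "HD": {"VN": "1.6", "SO": "unknown"},
        "SQ": [{"SN": name, "LN": length} for name, length in contig_lengths.items()],
    }
    refs = list(contig_lengths)
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for m in models:
            rec = pysam.AlignedSegment(out.header)
            rec.query_name = m.id
            rec.reference_id = refs.index(m.contig)
            rec.reference_start = m.start
            rec.mapping_quality = 60
            rec.flag = 16 if m.strand == "-" else 0
            cigar = []
            for i, (s, e) in enumerate(m.exons):
                if i:
                    cigar.append((3, s - m.exons[i - 1][1]))
                cigar.append((0, e - s))
            rec.cigartuples = cigar
            if sequences and m.id in sequences:
                rec.query_sequence = sequences[m.id]
            rec.set_tag("XC", m.coverage)
            rec.set_tag("XI", m.identity)
            out.write(rec)


# ---------------------------------------------------------------------------
# SJ tab (STAR SJ.out.tab dialect)
# ---------------------------------------------------------------------------

_STRAND_CODE_TO_CHAR = {0: ".", 1: "+", 2: "-"}
_STRAND_CHAR_TO_CODE = {".": 0, "+": 1, "-": 2}


def read_sj_tab(path) -> Dict[SJKey, int]:
    """Read an SJ tab file into a (contig, donor, acceptor, strand) -> unique
    read count map.

    Columns: contig, intron first base (1-based), intron last base (1-based,
    inclusive), strand code 0/1/2, motif code, annotated flag, unique reads,
    multi reads, max overhang. Only uniquely mapped read counts (column 7)
    are kept.
    """
    support: Dict[SJKey, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise FormatError(f"{path}:{lineno}: expected 9 columns, got {len(fields)}")
            try:
                contig = fields[0]
                first = int(fields[1])
                last = int(fields[2])
                strand_code = int(fields[3])
                unique = int(fields[6])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
            if first > last:
                raise FormatError(f"{path}:{lineno}: intron first base > last base")
            if strand_code not in _STRAND_CODE_TO_CHAR:
                raise FormatError(f"{path}:{lineno}: strand code must be 0/1/2")
            key = (contig, first - 1, last, _STRAND_CODE_TO_CHAR[strand_code])
            support[key] = support.get(key, 0) + unique
    return support


def write_sj_tab(path, rows: Dict[SJKey, int], motif_codes: Optional[Dict[SJKey, int]] = None) -> None:
    motif_codes = motif_codes or {}
    with open(path, "w") as fh:
        for (contig, donor, acceptor, strand), unique in sorted(rows.items()):
            fh.write(
                "\t".join(
                    str(x)
                    for x in [
                        contig, donor + 1, acceptor, _STRAND_CHAR_TO_CODE[strand],
                        motif_codes.get((contig, donor, acceptor, strand), 0),
                        0, unique, 0, 50,
                    ]
                )
                + "\n"
            )
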