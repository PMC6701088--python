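"""Synthetic transcriptome generator with machine-readable ground truth.

Emulates the statistical structure of a pooled-tissue long-read isoform
sequencing experiment on a plant genome: multi-isoform gene loci carrying
planted alternative-splicing events with an intron-retention-dominant type
mix, full-length reads with barcoded primers, poly(A) tails and random 5'
truncation, short-read splice-junction count tables at controlled PSI, and
poly(A) cleavage sites with an AATAAA signal planted a fixed distance
upstream.

Every source of randomness flows from ``SimParams.seed``; identical
parameters give byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .models import (
    CapacityError,
    GenomeRef,
    ParameterError,
    TranscriptModel,
    revcomp,
)

# Five-type AS mix: IR/AA/AD from the reported event-type frequencies
# (IR 68.85%, AA 15.64%, AD 9.31%); ES and MX split the remainder equally.
DEFAULT_AS_MIX = {"IR": 0.6885, "AA": 0.1564, "AD": 0.0931, "ES": 0.031, "MX": 0.031}

# Overall junction-class frequencies 84.65 / 1.52 / 0.40 / 13.43 (%)
# imply a 15.35% non-canonical fraction with the conditional mix below.
DEFAULT_NONCANONICAL_FRAC = 0.1535
DEFAULT_NONCANONICAL_MIX = {"GC-AG": 0.099, "AT-AC": 0.026, "other": 0.875}

# Fixed 30-mer detection primers (the study's barcoded primers are not
# published; these are arbitrary non-self-complementary 30-mers).
DEFAULT_PRIMER5 = "AAGCAGTGGTATCAACGCAGAGTACATGGG"
DEFAULT_PRIMER3 = "GTACTCTGCGTTGATACCACTGCTTCCGAT"

_OTHER_MOTIF_PAIRS = (("TT", "GG"), ("CA", "TG"), ("AC", "CC"), ("GA", "TA"))
_STOP_CODONS = ("TAA", "TAG", "TGA")


@dataclass
class SimParams:
    """Generator configuration. Proportions must each sum to 1."""

    seed: int = 0
    n_genes: int = 30
    contig_lengths: Tuple[int, ...] = (400_000,)
    gc: float = 0.42
    isoform_dist: Dict[int, float] = field(
        default_factory=lambda: {1: 0.49, 2: 0.35, 3: 0.16}
    )
    as_mix: Dict[str, float] = field(default_factory=lambda: dict(DEFAULT_AS_MIX))
    frac_noncanonical: float = DEFAULT_NONCANONICAL_FRAC
    noncanonical_mix: Dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_NONCANONICAL_MIX)
    )
    fl_depth: int = 10
    max_trunc_frac: float = 0.3
    nfl_frac: float = 0.27
    error_rate: float = 0.0
    primer5: str = DEFAULT_PRIMER5
    primer3: str = DEFAULT_PRIMER3
    polya_len: int = 30
    polya_signal_offset: int = 25
    signal_frac: float = 1.0
    apa_frac: float = 0.5
    apa_shift: int = 180
    coding_frac: float = 0.9
    sj_depth: int = 60
    sj_samples: Tuple[str, ...] = ("leaf", "seed_5h", "seed_15h", "seed_30h")
    psi_low: float = 0.1
    psi_high: float = 0.9
    n_exons_range: Tuple[int, int] = (5, 8)
    exon_len_range: Tuple[int, int] = (120, 250)
    intron_len_range: Tuple[int, int] = (250, 500)
    mx_exon_len: int = 100
    gene_spacing: int = 500
    p_strand_flip: float = 0.5

    def __post_init__(self):
        for name, dist in (("as_mix", self.as_mix), ("isoform_dist", self.isoform_dist),
                           ("noncanonical_mix", self.noncanonical_mix)):
            total = sum(dist.values())
            if abs(total - 1.0) > 1e-9:
                raise ParameterError(f"{name} proportions sum to {total}, not 1")
            if any(v < 0 for v in dist.values()):
                raise ParameterError(f"{name} has negative proportions")
        if any(n <= 0 for n in self.contig_lengths):
            raise ParameterError("contig lengths must be positive")
        if not 0.0 <= self.gc <= 1.0:
            raise ParameterError("gc must lie in [0, 1]")
        for name in ("n_genes", "fl_depth", "polya_len", "sj_depth", "apa_shift",
                     "polya_signal_offset"):
            if getattr(self, name) < 0:
                raise ParameterError(f"{name} must be >= 0")
        if not 0 <= self.psi_low <= self.psi_high <= 1:
            raise ParameterError("psi bounds must satisfy 0 <= low <= high <= 1")
        if not self.primer5 or not self.primer3:
            raise ParameterError("primer sequences must be non-empty")


@dataclass
class TruthTable:
    """Ground truth for everything the generator planted.

    ``events.inclusion_junctions``/``exclusion_junctions`` are serialized as
    ``donor-acceptor`` pairs joined by ';' (all on the gene's contig).
    """

    genes: pd.DataFrame
    events: pd.DataFrame
    polya: pd.DataFrame
    junction_classes: pd.DataFrame
    reads: pd.DataFrame = field(default_factory=pd.DataFrame)
    psi: pd.DataFrame = field(default_factory=pd.DataFrame)

    def event_junction_sets(self, event_id: str):
        row = self.events.set_index("event_id").loc[event_id]
        return (_parse_juncset(row["inclusion_junctions"], row["contig"]),
                _parse_juncset(row["exclusion_junctions"], row["contig"]))

    def save(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.genes.to_csv(outdir / "truth_genes.csv", index=False)
        self.events.to_csv(outdir / "truth_events.csv", index=False)
        self.polya.to_csv(outdir / "truth_polya.csv", index=False)
        self.junction_classes.to_csv(outdir / "truth_junctions.csv", index=False)
        if len(self.reads):
            self.reads.to_csv(outdir / "truth_reads.csv", index=False)
        if len(self.psi):
            self.psi.to_csv(outdir / "truth_psi.csv")


def _fmt_juncset(juncs) -> str:
    return ";".join(f"{d}-{a}" for d, a in sorted(juncs))


def _parse_juncset(text: str, contig: str):
    if not text or (isinstance(text, float) and np.isnan(text)):
        return frozenset()
    out = set()
    for tok in str(text).split(";"):
        d, a = tok.split("-")
        out.add((contig, int(d), int(a)))
    return frozenset(out)


# ---------------------------------------------------------------------------
# Genome
# ---------------------------------------------------------------------------

def make_genome(params: SimParams) -> GenomeRef:
    """Random genome with the requested contig lengths and GC content."""
    rng = np.random.default_rng(params.seed)
    p_gc = params.gc / 2.0
    p_at = (1.0 - params.gc) / 2.0
    contigs = {}
    for i, length in enumerate(params.contig_lengths):
        bases = rng.choice(np.array(list("ACGT")), size=length,
                           p=[p_at, p_gc, p_gc, p_at])
        contigs[f"contig_{i + 1}"] = "".join(bases)
    return GenomeRef(contigs)


# ---------------------------------------------------------------------------
# Gene planting
# ---------------------------------------------------------------------------

def _sample_dist(rng, dist: Dict) -> object:
    keys = sorted(dist, key=str)
    probs = np.array([dist[k] for k in keys], dtype=float)
    return keys[rng.choice(len(keys), p=probs / probs.sum())]


def _plant(buf: list, start: int, seq: str) -> None:
    buf[start:start + len(seq)] = list(seq)


def _plant_intron_motif(buf, strand, d, a, cls, rng) -> None:
    if cls == "GT-AG":
        five, three = "GT", "AG"
    elif cls == "GC-AG":
        five, three = "GC", "AG"
    elif cls == "AT-AC":
        five, three = "AT", "AC"
    else:
        five, three = _OTHER_MOTIF_PAIRS[rng.integers(len(_OTHER_MOTIF_PAIRS))]
    if strand == "+":
        _plant(buf, d, five)
        _plant(buf, a - 2, three)
    else:
        _plant(buf, a - 2, revcomp(five))
        _plant(buf, d, revcomp(three))


def _transcript_to_genomic(exons, strand):
    """Map of transcript position -> genomic position (transcript orientation)."""
    positions = []
    for s, e in exons:
        positions.extend(range(s, e))
    if strand == "-":
        positions = positions[::-1]
    return positions


def _random_codons(rng, n: int) -> str:
    bases = "ACGT"
    out = []
    while len(out) < n:
        codon = "".join(bases[i] for i in rng.integers(0, 4, size=3))
        if codon not in _STOP_CODONS:
            out.append(codon)
    return "".join(out)


def _plant_polya_signal(buf, strand, cleave, offset, hexamer="AATAAA") -> None:
    """Place the signal so its 3'-most base sits ``offset`` nt upstream of the
    cleavage position in transcript orientation (offset 25 on '+' puts the
    hexamer at genomic cleavage-30..cleavage-25 inclusive)."""
    w = len(hexamer)
    if strand == "+":
        _plant(buf, cleave - offset - w + 1, hexamer)
    else:
        # transcript runs right-to-left; distance-u base sits at cleave+u-1
        _plant(buf, cleave + offset - 1, revcomp(hexamer))


def _plant_end_bias(buf, strand, cleave, rng) -> None:
    """U-rich upstream / A-rich downstream composition around a cleavage
    site, rejection-sampled to stay below the internal-priming thresholds."""
    up = "".join(rng.choice(list("ACGT"), size=10, p=[0.2, 0.15, 0.15, 0.5]))
    for _ in range(50):
        down = "".join(rng.choice(list("ACGT"), size=15, p=[0.45, 0.19, 0.18, 0.18]))
        if strand == "+":
            window = down + "".join(buf[cleave + 15: cleave + 20])
        else:
            window = down + revcomp("".join(buf[max(0, cleave - 20): cleave - 15]))
        if window.count("A") <= 10 and "A" * 7 not in window:
            break
    if strand == "+":
        _plant(buf, cleave - 10, up)                 # 3' UTR tail, sense == genomic
        _plant(buf, cleave, down)                    # downstream of cleavage
    else:
        _plant(buf, cleave, revcomp(up))             # sense tail maps rightward
        _plant(buf, cleave - 15, revcomp(down))      # downstream maps leftward


def plant_genes(genome: GenomeRef, params: SimParams):
    """Plant non-overlapping gene loci with AS events and poly(A) signals.

    Mutates ``genome.contigs`` in place (sequence is stamped with splice
    motifs, coding regions, poly(A) signals and end-composition bias) and
    returns ``(annotation, truth)``.
    """
    rng = np.random.default_rng(params.seed + 1)
    contig_names = list(genome.contigs)
    buffers = {name: list(genome.contigs[name]) for name in contig_names}

    annotation: List[TranscriptModel] = []
    gene_rows, event_rows, polya_rows, junc_rows = [], [], [], []
    contig_idx, cursor = 0, 200
    ev_counter = 0

    for g in range(params.n_genes):
        gid = f"gene_{g + 1:05d}"
        strand = "+" if rng.random() < 0.5 else "-"
        k = int(_sample_dist(rng, params.isoform_dist))
        n_events = min(k - 1, 2)
        ev_types = [str(_sample_dist(rng, params.as_mix)) for _ in range(n_events)]
        slots = [1, 3][:n_events]

        n_exons = int(rng.integers(params.n_exons_range[0], params.n_exons_range[1] + 1))
        exon_lens = rng.integers(params.exon_len_range[0], params.exon_len_range[1] + 1,
                                 size=n_exons)
        intron_lens = rng.integers(params.intron_len_range[0],
                                   params.intron_len_range[1] + 1, size=n_exons - 1)
        for slot, etype in zip(slots, ev_types):
            if etype == "MX":
                intron_lens[slot] = max(intron_lens[slot], params.mx_exon_len + 120)

        # Base exon chain in gene-relative coordinates.
        rel_exons = []
        pos = 0
        for i in range(n_exons):
            rel_exons.append((pos, pos + int(exon_lens[i])))
            pos += int(exon_lens[i])
            if i < n_exons - 1:
                pos += int(intron_lens[i])
        gene_span = pos + params.apa_shift + 120

        contig = contig_names[contig_idx]
        while cursor + gene_span + params.gene_spacing > len(buffers[contig]):
            contig_idx += 1
            if contig_idx >= len(contig_names):
                raise CapacityError(
                    f"genome too small for {params.n_genes} genes "
                    f"(failed at gene {g + 1})"
                )
            contig = contig_names[contig_idx]
            cursor = 200
        offset = cursor
        cursor += gene_span + params.gene_spacing
        buf = buffers[contig]

        base_exons = tuple((s + offset, e + offset) for s, e in rel_exons)

        # Variant isoforms, one planted event each.
        isoforms: List[Tuple[str, Tuple[Tuple[int, int], ...]]] = []
        base_id = f"{gid}.i1"
        isoforms.append((base_id, base_exons))
        extra_motifs: List[Tuple[int, int]] = []  # introns created by variants

        for v, (slot, etype) in enumerate(zip(slots, ev_types), start=2):
            iso_id = f"{gid}.i{v}"
            exons = list(base_exons)
            d = base_exons[slot][1]            # intron <slot> left boundary
            a = base_exons[slot + 1][0]        # intron <slot> right boundary
            ev_counter += 1
            eid = f"as_{ev_counter:05d}"
            if etype == "IR":
                exons[slot] = (base_exons[slot][0], base_exons[slot + 1][1])
                del exons[slot + 1]
                inc_j, exc_j = frozenset(), frozenset({(d, a)})
                iso_inc, iso_exc = iso_id, base_id
                variant = (d, a)
            elif etype == "ES":
                prev_d = base_exons[slot - 1][1]
                del exons[slot]
                inc_j = frozenset({(prev_d, base_exons[slot][0]), (d, a)})
                exc_j = frozenset({(prev_d, a)})
                iso_inc, iso_exc = base_id, iso_id
                variant = base_exons[slot]
            elif etype in ("AA", "AD"):
                delta = 30
                vary_right = (etype == "AA") == (strand == "+")
                if vary_right:
                    new_a = a + delta
                    exons[slot + 1] = (new_a, base_exons[slot + 1][1])
                    inc_j, exc_j = frozenset({(d, a)}), frozenset({(d, new_a)})
                    variant = (d, a, new_a)
                    extra_motifs.append((d, new_a))
                else:
                    new_d = d - delta
                    exons[slot] = (base_exons[slot][0], new_d)
                    inc_j, exc_j = frozenset({(d, a)}), frozenset({(new_d, a)})
                    variant = (new_d, d, a)
                    extra_motifs.append((new_d, a))
                iso_inc, iso_exc = base_id, iso_id
            else:  # MX
                prev_d = base_exons[slot - 1][1]
                x_s, x_e = base_exons[slot]
                y_s = d + 40
                y_e = y_s + params.mx_exon_len
                exons[slot] = (y_s, y_e)
                inc_j = frozenset({(prev_d, x_s), (x_e, a)})
                exc_j = frozenset({(prev_d, y_s), (y_e, a)})
                iso_inc, iso_exc = base_id, iso_id
                variant = (x_s, x_e, y_s, y_e)
                extra_motifs.extend([(prev_d, y_s), (y_e, a)])
            isoforms.append((iso_id, tuple(exons)))
            event_rows.append(dict(
                event_id=eid, gene_id=gid, type=etype, contig=contig, strand=strand,
                variant=",".join(map(str, variant)),
                inclusion_junctions=_fmt_juncset(inc_j),
                exclusion_junctions=_fmt_juncset(exc_j),
                isoform_inclusion=iso_inc, isoform_exclusion=iso_exc,
            ))

        # Optional APA isoform: identical chain, 3' exon extended well past
        # both the collapse tolerance and the site-cluster window so truth
        # stays unambiguous at both the model and the site level.
        has_apa = rng.random() < params.apa_frac
        if has_apa:
            iso_id = f"{gid}.apa"
            exons = list(base_exons)
            if strand == "+":
                s, e = exons[-1]
                exons[-1] = (s, e + params.apa_shift)
            else:
                s, e = exons[0]
                exons[0] = (max(0, s - params.apa_shift), e)
            isoforms.append((iso_id, tuple(exons)))

        # Intron motif classes: constitutive introns draw from the
        # non-canonical mix; introns flanking a planted event stay GT-AG so
        # event truth is independent of junction-class truth.
        base_introns = [(base_exons[i][1], base_exons[i + 1][0])
                        for i in range(n_exons - 1)]
        blocked = set()
        for slot in slots:
            blocked.update({slot - 1, slot, slot + 1})
        intron_cls = {}
        for i, (d, a) in enumerate(base_introns):
            if i not in blocked and rng.random() < params.frac_noncanonical:
                cls = str(_sample_dist(rng, params.noncanonical_mix))
            else:
                cls = "GT-AG"
            intron_cls[(d, a)] = cls
        for d, a in extra_motifs:
            intron_cls[(d, a)] = "GT-AG"

        # Coding region on the base isoform (sense orientation), ending well
        # clear of the 3' UTR where poly(A) features are planted. Planted
        # before splice motifs: a variant boundary inside a base exon may
        # overwrite two CDS bases, so coding truth is per-gene presence, not
        # exact ORF coordinates.
        coding = rng.random() < params.coding_frac
        if coding:
            tmap = _transcript_to_genomic(base_exons, strand)
            L = len(tmap)
            cds_start = 30
            n_codons = (L - 90 - cds_start) // 3 - 2
            cds = "ATG" + _random_codons(rng, n_codons) + "TAA"
            for i, base in enumerate(cds):
                gpos = tmap[cds_start + i]
                buf[gpos] = base if strand == "+" else revcomp(base)

        for (d, a), cls in sorted(intron_cls.items()):
            _plant_intron_motif(buf, strand, d, a, cls, rng)
            junc_rows.append(dict(contig=contig, donor=d, acceptor=a, strand=strand,
                                  motif_class=cls))

        # Poly(A) sites: one per distinct isoform 3' end.
        seen_ends = {}
        for iso_id, exons in isoforms:
            model = TranscriptModel(id=iso_id, contig=contig, strand=strand,
                                    exons=exons, source="truth")
            cleave = model.three_prime
            if cleave not in seen_ends:
                with_signal = rng.random() < params.signal_frac
                if with_signal:
                    _plant_polya_signal(buf, strand, cleave,
                                        params.polya_signal_offset)
                _plant_end_bias(buf, strand, cleave, rng)
                seen_ends[cleave] = with_signal
                polya_rows.append(dict(
                    gene_id=gid, contig=contig, strand=strand, position=cleave,
                    signal=with_signal,
                    signal_offset=params.polya_signal_offset if with_signal else -1,
                ))

        for iso_id, exons in isoforms:
            annotation.append(TranscriptModel(id=iso_id, contig=contig, strand=strand,
                                              exons=exons, source="truth"))
        gene_rows.append(dict(
            gene_id=gid, contig=contig, strand=strand,
            start=min(e[0][0] for _, e in isoforms),
            end=max(e[-1][1] for _, e in isoforms),
            n_isoforms=len(isoforms), coding=coding, n_events=n_events,
            n_polya_sites=len(seen_ends),
        ))

    for name in contig_names:
        genome.contigs[name] = "".join(buffers[name])

    events = pd.DataFrame(event_rows, columns=[
        "event_id", "gene_id", "type", "contig", "strand", "variant",
        "inclusion_junctions", "exclusion_junctions", "isoform_inclusion",
        "isoform_exclusion"])
    psi = _draw_psi(events, params)
    truth = TruthTable(
        genes=pd.DataFrame(gene_rows),
        events=events,
        polya=pd.DataFrame(polya_rows, columns=["gene_id", "contig", "strand",
                                                "position", "signal", "signal_offset"]),
        junction_classes=pd.DataFrame(junc_rows, columns=["contig", "donor", "acceptor",
                                                          "strand", "motif_class"]),
        psi=psi,
    )
    return annotation, truth


def _draw_psi(events: pd.DataFrame, params: SimParams) -> pd.DataFrame:
    rng = np.random.default_rng(params.seed + 2)
    if not len(events):
        return pd.DataFrame(columns=list(params.sj_samples))
    vals = rng.uniform(params.psi_low, params.psi_high,
                       size=(len(events), len(params.sj_samples)))
    return pd.DataFrame(vals, index=list(events["event_id"]),
                        columns=list(params.sj_samples))


# ---------------------------------------------------------------------------
# Full-length reads
# ---------------------------------------------------------------------------

def simulate_fl_reads(annotation: Sequence[TranscriptModel], truth: TruthTable,
                      params: SimParams, genome: GenomeRef):
    """Simulate FL reads from every isoform at fixed depth.

    A full-length read is 5' primer + (possibly 5'-truncated) transcript +
    poly(A) + reverse-complemented 3' primer, randomly strand-flipped. An
    nFL read omits exactly one of those three elements; the truth table
    records which. Truncation never consumes the 5'-most exon, so the
    read's intron chain equals its source isoform's.

    Returns ``(reads, truth)`` where reads is an ordered id -> sequence dict
    and ``truth.reads`` has been filled in.
    """
    if not annotation:
        raise ParameterError("annotation is empty")
    rng = np.random.default_rng(params.seed + 3)
    reads: Dict[str, str] = {}
    read_rows = []
    p3rc = revcomp(params.primer3)
    for model in annotation:
        transcript = model.spliced_sequence(genome)
        first_exon = model.exons[0] if model.strand == "+" else model.exons[-1]
        first_len = first_exon[1] - first_exon[0]
        cap = min(int(params.max_trunc_frac * len(transcript)), max(0, first_len - 20))
        for n in range(params.fl_depth):
            rid = f"read_{model.id}_{n:04d}"
            trunc = int(rng.integers(0, cap + 1)) if cap > 0 else 0
            insert = transcript[trunc:]
            missing = "none"
            if rng.random() < params.nfl_frac:
                missing = ("5p", "3p", "polya")[rng.integers(3)]
            parts = []
            if missing != "5p":
                parts.append(params.primer5)
            parts.append(insert)
            if missing != "polya":
                parts.append("A" * params.polya_len)
            if missing != "3p":
                parts.append(p3rc)
            seq = "".join(parts)
            if params.error_rate > 0:
                seq = _add_errors(seq, params.error_rate, rng)
            flipped = rng.random() < params.p_strand_flip
            if flipped:
                seq = revcomp(seq)
            reads[rid] = seq
            read_rows.append(dict(
                read_id=rid, isoform_id=model.id,
                gene_id=model.id.rsplit(".", 1)[0],
                category="FLnc" if missing == "none" else "nFL",
                missing=missing, read_strand="-" if flipped else "+",
                truncation=trunc,
            ))
    truth.reads = pd.DataFrame(read_rows, columns=[
        "read_id", "isoform_id", "gene_id", "category", "missing",
        "read_strand", "truncation"])
    return reads, truth


def _add_errors(seq: str, rate: float, rng) -> str:
    arr = np.array(list(seq))
    mask = rng.random(len(arr)) < rate
    if mask.any():
        subs = rng.choice(list("ACGT"), size=int(mask.sum()))
        arr[mask] = subs
    return "".join(arr)


def truth_alignments(truth: TruthTable, annotation: Sequence[TranscriptModel],
                     flnc_only: bool = False) -> List[TranscriptModel]:
    """Aligner stand-in: the genomic exon chain of each simulated read.

    Each read aligns to its source isoform with its 5' truncation applied to
    the 5'-most exon; coverage and identity are 1.0 (error-free reads).
    """
    by_id = {m.id: m for m in annotation}
    models = []
    for row in truth.reads.itertuples():
        if flnc_only and row.category != "FLnc":
            continue
        iso = by_id[row.isoform_id]
        exons = list(iso.exons)
        t = int(row.truncation)
        if t > 0:
            if iso.strand == "+":
                s, e = exons[0]
                exons[0] = (s + t, e)
            else:
                s, e = exons[-1]
                exons[-1] = (s, e - t)
        models.append(TranscriptModel(id=row.read_id, contig=iso.contig,
                                      strand=iso.strand, exons=tuple(exons),
                                      source="aligned"))
    return models


# ---------------------------------------------------------------------------
# Short-read junction counts
# ---------------------------------------------------------------------------

def simulate_sj_counts(annotation: Sequence[TranscriptModel], truth: TruthTable,
                       params: SimParams):
    """Per-sample junction count tables at the truth PSI.

    For each AS event, inclusion reads are Binomial(depth, PSI) and exclusion
    reads take the remainder; constitutive junctions get the full depth. IR
    inclusion (intron retention) has no junction, so its evidence goes to a
    per-sample intron-coverage table instead.

    Returns ``(sj_tables, intron_cov)``: two dicts keyed by sample name; sj
    values map (contig, donor, acceptor, strand) -> unique count, intron-cov
    values map (contig, donor, acceptor) -> retention count.
    """
    rng = np.random.default_rng(params.seed + 4)
    if len(truth.psi):
        bad = truth.psi.values
        if np.any((bad < 0) | (bad > 1)):
            raise ParameterError("truth PSI values must lie in [0, 1]")
    constitutive = {}
    for m in annotation:
        for d, a in m.introns:
            constitutive[(m.contig, d, a, m.strand)] = params.sj_depth

    sj_tables, cov_tables = {}, {}
    events = truth.events
    for sample in params.sj_samples:
        rows = dict(constitutive)
        cov = {}
        for ev in events.itertuples():
            psi = float(truth.psi.loc[ev.event_id, sample])
            depth = params.sj_depth
            inc = int(rng.binomial(depth, psi))
            exc = depth - inc
            inc_j = _parse_juncset(ev.inclusion_junctions, ev.contig)
            exc_j = _parse_juncset(ev.exclusion_junctions, ev.contig)
            for contig, d, a in inc_j:
                rows[(contig, d, a, ev.strand)] = inc
            for contig, d, a in exc_j:
                rows[(contig, d, a, ev.strand)] = exc
            if ev.type == "IR":
                (contig, d, a), = exc_j
                cov[(contig, d, a)] = inc
        sj_tables[sample] = rows
        cov_tables[sample] = cov
    return sj_tables, cov_tables


def write_intron_coverage(path, cov: Dict[Tuple[str, int, int], int]) -> None:
    with open(path, "w") as fh:
        fh.write("contig\tdonor\tacceptor\tcount\n")
        for (contig, d, a), n in sorted(cov.items()):
            fh.write(f"{contig}\t{d}\t{a}\t{n}\n")


def read_intron_coverage(path) -> Dict[Tuple[str, int, int], int]:
    out = {}
    with open(path) as fh:
        header = fh.readline()
        for line in fh:
            contig, d, a, n = line.rstrip("\n").split("\t")
            out[(contig, int(d), int(a))] = int(n)
    return out


# ---------------------------------------------------------------------------
# Dataset writer (demo / CLI surface)
# ---------------------------------------------------------------------------

def generate_dataset(outdir, params: SimParams):
    """Generate and write a complete synthetic dataset with truth tables.

    Writes genome FASTA, annotation GTF, reads FASTA, per-read alignments
    (BED12), per-sample SJ tab and intron-coverage files, and truth CSVs.
    Returns ``(genome, annotation, truth, reads, paths)``.
    """
    from . import io_formats

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    genome = make_genome(params)
    annotation, truth = plant_genes(genome, params)
    reads, truth = simulate_fl_reads(annotation, truth, params, genome)
    sj_tables, cov_tables = simulate_sj_counts(annotation, truth, params)
    alignments = truth_alignments(truth, annotation)

    paths = {
        "genome": outdir / "genome.fasta",
        "annotation": outdir / "annotation.gtf",
        "reads": outdir / "reads.fasta",
        "alignments": outdir / "alignments.bed",
    }
    io_formats.write_genome(paths["genome"], genome)
    io_formats.write_gtf(paths["annotation"], annotation,
                         gene_ids={m.id: m.id.rsplit(".", 1)[0] for m in annotation})
    io_formats.write_fasta(paths["reads"], reads)
    io_formats.write_bed12(paths["alignments"], alignments)
    paths["sj"] = []
    paths["intron_cov"] = []
    for sample in params.sj_samples:
        sj_path = outdir / f"SJ_{sample}.tab"
        io_formats.write_sj_tab(sj_path, sj_tables[sample])
        paths["sj"].append(sj_path)
        cov_path = outdir / f"intron_coverage_{sample}.tsv"
        write_intron_coverage(cov_path, cov_tables[sample])
        paths["intron_cov"].append(cov_path)
    truth.save(outdir)
    return genome, annotation, truth, reads, paths
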