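"""Splice-junction extraction, motif classification, short-read validation
and false-junction filtering.

A junction's motif is the first two plus last two intron bases in transcript
orientation; GT-AG is canonical, GC-AG and AT-AC are minor non-canonical
classes. A junction is presumed false only when its motif is not GT-AG AND
no short-read sample supports it: unsupported canonical junctions are
retained (they may simply be expressed in unsampled tissues), while
unsupported non-canonical junctions mark their isoforms for removal.
"""

from __future__ import annotations

from typing import Dict, Iterable, List, Sequence, Set, Tuple

import pandas as pd

from .collapse import IsoformCluster
from .models import (
    ContractError,
    GenomeRef,
    Junction,
    TranscriptModel,
    classify_motif,
    revcomp,
)


def extract_junctions(models: Sequence[TranscriptModel],
                      genome: GenomeRef) -> List[Junction]:
    """One Junction per distinct (contig, donor, acceptor, strand), with the
    motif read from the genome in transcript orientation."""
    seen = {}
    for m in models:
        for d, a in m.introns:
            key = (m.contig, d, a, m.strand)
            if key in seen:
                continue
            left = genome.fetch(m.contig, d, d + 2)
            right = genome.fetch(m.contig, a - 2, a)
            motif = left + right if m.strand == "+" else revcomp(right) + revcomp(left)
            seen[key] = Junction(contig=m.contig, strand=m.strand, donor=d,
                                 acceptor=a, motif=motif,
                                 motif_class=classify_motif(motif))
    return [seen[k] for k in sorted(seen)]


def attach_support(junctions: Sequence[Junction],
                   sj_maps: Sequence[Dict[Tuple[str, int, int, str], int]]) -> List[Junction]:
    """Sum unique-read support over samples for each junction.

    SJ rows with undetermined strand ('.') match either strand at the same
    coordinates.
    """
    merged: Dict[Tuple[str, int, int, str], int] = {}
    for sj in sj_maps:
        for key, n in sj.items():
            merged[key] = merged.get(key, 0) + n
    out = []
    for j in junctions:
        support = merged.get((j.contig, j.donor, j.acceptor, j.strand), 0)
        support += merged.get((j.contig, j.donor, j.acceptor, "."), 0)
        out.append(Junction(contig=j.contig, strand=j.strand, donor=j.donor,
                            acceptor=j.acceptor, motif=j.motif,
                            motif_class=j.motif_class, sr_support=support))
    return out


def is_false_junction(j: Junction, min_support: int = 1) -> bool:
    return j.motif_class != "GT-AG" and j.sr_support < min_support


def filter_isoforms(clusters: Sequence[IsoformCluster],
                    junctions: Sequence[Junction],
                    min_support: int = 1):
    """Remove isoforms containing at least one false junction.

    Returns ``(kept, removed, report)`` where the report counts junctions per
    motif class (total, supported, false) plus isoforms removed.
    """
    by_key = {(j.contig, j.donor, j.acceptor, j.strand): j for j in junctions}
    kept, removed = [], []
    for c in clusters:
        m = c.representative
        false_found = False
        for d, a in m.introns:
            j = by_key.get((m.contig, d, a, m.strand))
            if j is None:
                raise ContractError(
                    f"cluster {c.cluster_id}: junction ({m.contig},{d},{a},{m.strand}) "
                    "not in the junction set"
                )
            if is_false_junction(j, min_support):
                false_found = True
        (removed if false_found else kept).append(c)

    rows = []
    for cls in ("GT-AG", "GC-AG", "AT-AC", "other"):
        of_class = [j for j in junctions if j.motif_class == cls]
        rows.append(dict(
            motif_class=cls,
            total=len(of_class),
            supported=sum(j.sr_support >= min_support for j in of_class),
            false=sum(is_false_junction(j, min_support) for j in of_class),
        ))
    report = pd.DataFrame(rows)
    report.attrs["isoforms_kept"] = len(kept)
    report.attrs["isoforms_removed"] = len(removed)
    return kept, removed, report


def junction_table(junctions: Sequence[Junction]) -> pd.DataFrame:
    return pd.DataFrame(
        [dict(contig=j.contig, donor=j.donor, acceptor=j.acceptor, strand=j.strand,
              motif=j.motif, motif_class=j.motif_class, sr_support=j.sr_support)
         for j in junctions]
    )
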