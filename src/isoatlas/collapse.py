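"""Collapse of aligned full-length isoforms into non-redundant transcript
models, locus assignment, and rarefaction curves.

Multi-exon alignments merge when their intron chains are identical and their
3' ends lie within a tolerance (5' differences, the signature of degraded
full-length reads, are ignored); single-exon alignments merge on reciprocal
overlap. Loci are connected components of same-strand exonic overlap.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .models import (
    ContractError,
    ParameterError,
    TranscriptModel,
    exonic_overlap,
)


@dataclass
class CollapseParams:
    """Alignment filtering and collapse thresholds.

    ``min_coverage``/``min_identity`` follow the reference-based collapse
    settings (-c 0.8 -i 0.7); comparisons are inclusive (>=). ``tol3`` is the
    3'-end tolerance in nt for merging identical intron chains.
    """

    min_coverage: float = 0.8
    min_identity: float = 0.7
    ignore_5prime: bool = True
    tol3: int = 100
    single_exon_overlap: float = 0.5

    def __post_init__(self):
        if not 0 < self.min_coverage <= 1 or not 0 < self.min_identity <= 1:
            raise ParameterError("coverage/identity thresholds must lie in (0, 1]")
        if self.tol3 < 0:
            raise ParameterError("tol3 must be >= 0")
        if not 0 < self.single_exon_overlap <= 1:
            raise ParameterError("single_exon_overlap must lie in (0, 1]")


@dataclass
class IsoformCluster:
    """A non-redundant isoform: representative model plus its member reads."""

    cluster_id: str
    representative: TranscriptModel
    members: Tuple[str, ...]

    @property
    def fl_count(self) -> int:
        return len(self.members)


@dataclass
class Locus:
    """A transcript locus: same-strand clusters connected by exonic overlap."""

    locus_id: str
    contig: str
    strand: str
    clusters: Tuple[IsoformCluster, ...]

    @property
    def n_isoforms(self) -> int:
        return len(self.clusters)


def filter_alignments(aligned: Sequence[TranscriptModel], params: CollapseParams):
    """Keep alignments with coverage >= c and identity >= i.

    Returns ``(kept, stats)``; models must carry coverage/identity metadata.
    """
    kept, n_cov, n_ident = [], 0, 0
    for m in aligned:
        if m.coverage is None or m.identity is None:
            raise ContractError(f"{m.id}: alignment lacks coverage/identity metadata")
        if m.coverage < params.min_coverage:
            n_cov += 1
        elif m.identity < params.min_identity:
            n_ident += 1
        else:
            kept.append(m)
    return kept, {"discarded_low_coverage": n_cov, "discarded_low_identity": n_ident}


class _UnionFind:
    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i: int, j: int) -> None:
        ri, rj = self.find(i), self.find(j)
        if ri != rj:
            self.parent[max(ri, rj)] = min(ri, rj)


def _three_prime_end(m: TranscriptModel) -> int:
    return m.end if m.strand == "+" else m.start


def collapse_isoforms(aligned: Sequence[TranscriptModel],
                      params: Optional[CollapseParams] = None) -> List[IsoformCluster]:
    """Collapse alignments into non-redundant isoform clusters.

    Multi-exon models merge iff intron chains are identical and 3' ends are
    within ``tol3`` (single-linkage along sorted 3' ends); 5' ends are
    ignored. Single-exon models merge iff same strand and reciprocal overlap
    >= ``single_exon_overlap``. The representative takes the widest genomic
    span of the members. Output order is deterministic (contig, start, id).
    """
    params = params or CollapseParams()
    groups: Dict[Tuple, List[TranscriptModel]] = {}
    singles: Dict[Tuple[str, str], List[TranscriptModel]] = {}
    for m in aligned:
        if len(m.exons) > 1:
            groups.setdefault((m.contig, m.strand, m.introns), []).append(m)
        else:
            singles.setdefault((m.contig, m.strand), []).append(m)

    raw_clusters: List[List[TranscriptModel]] = []
    for key in groups:
        members = sorted(groups[key], key=_three_prime_end)
        chain: List[TranscriptModel] = []
        prev_end = None
        for m in members:
            e3 = _three_prime_end(m)
            if prev_end is not None and e3 - prev_end > params.tol3:
                raw_clusters.append(chain)
                chain = []
            chain.append(m)
            prev_end = e3
        if chain:
            raw_clusters.append(chain)

    for (contig, strand), members in singles.items():
        members = sorted(members, key=lambda m: (m.start, m.end, m.id))
        uf = _UnionFind(len(members))
        for i in range(len(members)):
            for j in range(i + 1, len(members)):
                a, b = members[i], members[j]
                if b.start >= a.end:
                    break
                ov = min(a.end, b.end) - max(a.start, b.start)
                if ov >= params.single_exon_overlap * (a.end - a.start) and \
                   ov >= params.single_exon_overlap * (b.end - b.start):
                    uf.union(i, j)
        comp: Dict[int, List[TranscriptModel]] = {}
        for i, m in enumerate(members):
            comp.setdefault(uf.find(i), []).append(m)
        raw_clusters.extend(comp.values())

    reps = []
    for members in raw_clusters:
        first = members[0]
        start = min(m.start for m in members)
        end = max(m.end for m in members)
        if len(first.exons) == 1:
            exons = ((start, end),)
        else:
            exons = tuple(
                [(start, first.introns[0][0])]
                + [(first.introns[i][1], first.introns[i + 1][0])
                   for i in range(len(first.introns) - 1)]
                + [(first.introns[-1][1], end)]
            )
        rep = TranscriptModel(id="", contig=first.contig, strand=first.strand,
                              exons=exons, source="collapsed")
        reps.append((rep, tuple(sorted(m.id for m in members))))

    reps.sort(key=lambda rm: (rm[0].contig, rm[0].start, rm[0].end, rm[1]))
    clusters = []
    for i, (rep, member_ids) in enumerate(reps, 1):
        cid = f"iso_{i:05d}"
        clusters.append(IsoformCluster(cluster_id=cid,
                                       representative=rep.with_(id=cid),
                                       members=member_ids))
    return clusters


def assign_loci(clusters: Sequence[IsoformCluster]) -> List[Locus]:
    """Group clusters into loci: connected components under same-strand
    exonic overlap (>= 1 bp), transitively closed. Locus ids are stable under
    input order (sorted by contig, start, cluster id)."""
    ordered = sorted(clusters,
                     key=lambda c: (c.representative.contig, c.representative.start,
                                    c.representative.end, c.cluster_id))
    uf = _UnionFind(len(ordered))
    for i in range(len(ordered)):
        a = ordered[i].representative
        for j in range(i + 1, len(ordered)):
            b = ordered[j].representative
            if b.contig != a.contig or b.start >= a.end:
                break
            if b.strand == a.strand and exonic_overlap(a, b) >= 1:
                uf.union(i, j)
    comps: Dict[int, List[IsoformCluster]] = {}
    for i, c in enumerate(ordered):
        comps.setdefault(uf.find(i), []).append(c)
    loci = []
    for n, root in enumerate(sorted(comps), 1):
        members = comps[root]
        rep = members[0].representative
        loci.append(Locus(locus_id=f"locus_{n:05d}", contig=rep.contig,
                          strand=rep.strand, clusters=tuple(members)))
    return loci


def cluster_membership(clusters: Sequence[IsoformCluster]) -> Dict[str, str]:
    """read/member id -> cluster id."""
    out = {}
    for c in clusters:
        for m in c.members:
            out[m] = c.cluster_id
    return out


def locus_membership(loci: Sequence[Locus]) -> Dict[str, str]:
    """cluster id -> locus id."""
    return {c.cluster_id: l.locus_id for l in loci for c in l.clusters}


def rarefaction(read_to_cluster: Dict[str, str],
                subsample_fractions: Sequence[float],
                reps: int = 50,
                seed: int = 0,
                cluster_to_locus: Optional[Dict[str, str]] = None) -> pd.DataFrame:
    """Discovery-saturation curves by read subsampling without replacement.

    Returns a table with the mean and SD of distinct isoform clusters (and
    loci, when ``cluster_to_locus`` is given) per subsample fraction.
    """
    if not read_to_cluster:
        raise ParameterError("read_to_cluster map is empty")
    for f in subsample_fractions:
        if not 0 < f <= 1:
            raise ParameterError(f"subsample fraction {f} outside (0, 1]")
    rng = np.random.default_rng(seed)
    reads = sorted(read_to_cluster)
    clusters = np.array([read_to_cluster[r] for r in reads])
    loci = (np.array([cluster_to_locus[c] for c in clusters])
            if cluster_to_locus is not None else clusters)
    n = len(reads)
    rows = []
    for f in subsample_fractions:
        k = max(1, int(round(f * n)))
        nc, nl = [], []
        for _ in range(reps):
            idx = rng.choice(n, size=k, replace=False)
            nc.append(len(set(clusters[idx])))
            nl.append(len(set(loci[idx])))
        rows.append(dict(fraction=f, n_reads=k,
                         mean_clusters=float(np.mean(nc)), sd_clusters=float(np.std(nc)),
                         mean_loci=float(np.mean(nl)), sd_loci=float(np.std(nl))))
    return pd.DataFrame(rows)
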