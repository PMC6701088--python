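"""Poly(A) cleavage-site calling from full-length read 3' ends, internal
priming filtering, per-gene APA summaries, flanking nucleotide composition,
and poly(A)-signal motif discovery (exhaustive hexamer count or a
one-occurrence-per-sequence EM, a single-motif MEME-style model).

Cleavage position convention: the 0-based genomic coordinate one past the
last transcribed base on '+', and of the first (genomically lowest)
transcribed base on '-'. The upstream distance of a motif is measured from
its 3'-most base to the cleavage site, so the canonical AATAAA signal
"about 25 nt upstream" has offset 25.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .models import CoordinateError, GenomeRef, ParameterError, PolyASite, revcomp

_BASES = "ACGT"
_BASE_IDX = {b: i for i, b in enumerate(_BASES)}


# ---------------------------------------------------------------------------
# Site calling
# ---------------------------------------------------------------------------

def _downstream_window(genome: GenomeRef, contig: str, strand: str, pos: int,
                       size: int = 20) -> str:
    """Sense-orientation sequence immediately downstream of a cleavage site."""
    length = len(genome[contig])
    if strand == "+":
        return genome.fetch(contig, pos, min(length, pos + size))
    return revcomp(genome.fetch(contig, max(0, pos - size), pos))


def _is_internal_priming(window: str, min_a: int = 12, min_run: int = 8) -> bool:
    return window.count("A") >= min_a or "A" * min_run in window


def call_sites(flnc_ends: Sequence[Tuple[str, str, str, int]],
               genome: GenomeRef,
               cluster_window: int = 24,
               min_support: int = 1) -> List[PolyASite]:
    """Cluster FLnc read 3' ends into poly(A) sites per gene.

    ``flnc_ends`` holds (gene id, contig, strand, genomic 3' position)
    tuples. Ends cluster by single linkage with gap <= ``cluster_window``;
    the site position is the modal end (ties break to the most distal 3'
    position, strand-aware), support is the cluster size, and sites backed
    by fewer than ``min_support`` reads are dropped. A site is flagged as
    internal priming when the 20 nt immediately downstream contain >= 12 A's
    or a run of >= 8 A's (genomic A-tract rather than a true tail).
    """
    grouped: Dict[Tuple[str, str, str], List[int]] = {}
    for gene_id, contig, strand, pos in flnc_ends:
        if contig not in genome:
            raise CoordinateError(f"unknown contig {contig!r}")
        grouped.setdefault((gene_id, contig, strand), []).append(pos)

    sites = []
    for (gene_id, contig, strand), ends in sorted(grouped.items()):
        ends = sorted(ends)
        clusters: List[List[int]] = [[ends[0]]]
        for pos in ends[1:]:
            if pos - clusters[-1][-1] <= cluster_window:
                clusters[-1].append(pos)
            else:
                clusters.append([pos])
        for members in clusters:
            if len(members) < min_support:
                continue
            counts: Dict[int, int] = {}
            for pos in members:
                counts[pos] = counts.get(pos, 0) + 1
            best = max(counts.values())
            modal = [p for p, c in counts.items() if c == best]
            # most distal 3' = largest coordinate on '+', smallest on '-'
            position = max(modal) if strand == "+" else min(modal)
            window = _downstream_window(genome, contig, strand, position)
            sites.append(PolyASite(
                gene_id=gene_id, contig=contig, strand=strand, position=position,
                support=len(members),
                internal_priming=_is_internal_priming(window),
            ))
    return sites


def apa_summary(sites: Sequence[PolyASite],
                exclude_internal_priming: bool = True) -> dict:
    """Per-gene poly(A)-site counts and the APA summary.

    Genes with >= 2 sites are flagged APA. ``mean_sites_per_gene`` is the
    mean over genes with >= 1 site; ``sites_per_gene_ratio`` is the raw
    total-sites / total-genes division (the two need not agree and both are
    reported).
    """
    used = [s for s in sites if not (exclude_internal_priming and s.internal_priming)]
    per_gene: Dict[str, int] = {}
    for s in used:
        per_gene[s.gene_id] = per_gene.get(s.gene_id, 0) + 1
    counts = pd.Series(per_gene, dtype=int)
    dist = {}
    for bucket in ("1", "2", "3", "4", ">=5"):
        if bucket == ">=5":
            dist[bucket] = int((counts >= 5).sum())
        else:
            dist[bucket] = int((counts == int(bucket)).sum())
    n_genes = len(counts)
    total = int(counts.sum()) if n_genes else 0
    return dict(
        per_gene=per_gene,
        n_genes_with_site=n_genes,
        n_sites=total,
        n_apa_genes=int((counts >= 2).sum()) if n_genes else 0,
        distribution=dist,
        mean_sites_per_gene=float(counts.mean()) if n_genes else float("nan"),
        sites_per_gene_ratio=(total / n_genes) if n_genes else float("nan"),
    )


# ---------------------------------------------------------------------------
# Nucleotide profile
# ---------------------------------------------------------------------------

def nucleotide_profile(sites: Sequence[PolyASite], genome: GenomeRef,
                       flank: int = 50):
    """4 x (2*flank+1) base-frequency matrix around cleavage sites.

    Column ``flank`` (profile position 0) is the first base downstream of
    the cleavage; negative positions are the transcript's 3' end. Sites too
    close to a contig edge are skipped and counted. Returns ``(profile,
    n_skipped)`` with the profile as a DataFrame indexed by base.
    """
    if flank < 1:
        raise ParameterError("flank must be >= 1")
    width = 2 * flank + 1
    counts = np.zeros((4, width))
    skipped = 0
    for s in sites:
        length = len(genome[s.contig])
        if s.strand == "+":
            lo, hi = s.position - flank, s.position + flank + 1
            if lo < 0 or hi > length:
                skipped += 1
                continue
            seq = genome.fetch(s.contig, lo, hi)
        else:
            lo, hi = s.position - 1 - flank, s.position + flank
            if lo < 0 or hi > length:
                skipped += 1
                continue
            seq = revcomp(genome.fetch(s.contig, lo, hi))
        for i, base in enumerate(seq):
            if base in _BASE_IDX:
                counts[_BASE_IDX[base], i] += 1
    sums = counts.sum(axis=0)
    sums[sums == 0] = 1.0
    profile = pd.DataFrame(counts / sums, index=list(_BASES),
                           columns=np.arange(-flank, flank + 1))
    return profile, skipped


def upstream_sequences(sites: Sequence[PolyASite], genome: GenomeRef,
                       length: int = 50) -> List[str]:
    """Sense-orientation sequence of the ``length`` nt ending at each
    cleavage site (the poly(A)-signal search window)."""
    out = []
    for s in sites:
        if s.strand == "+":
            if s.position - length < 0:
                continue
            out.append(genome.fetch(s.contig, s.position - length, s.position))
        else:
            if s.position + length > len(genome[s.contig]):
                continue
            out.append(revcomp(genome.fetch(s.contig, s.position, s.position + length)))
    return out


# ---------------------------------------------------------------------------
# Signal motif discovery
# ---------------------------------------------------------------------------

@dataclass
class PWMotif:
    """A position weight matrix with per-sequence best offsets.

    ``offsets`` report the distance from the motif's 3'-most base to the
    cleavage site (sequence end), one entry per input sequence.
    """

    width: int
    matrix: np.ndarray          # 4 x width, columns sum to 1
    offsets: List[int]
    consensus: str
    log_likelihood: float = float("nan")

    def __post_init__(self):
        if self.width < 4:
            raise ParameterError("motif width must be >= 4")
        if not np.allclose(self.matrix.sum(axis=0), 1.0, atol=1e-9):
            raise ParameterError("PWM columns must sum to 1")


def _offsets_from_starts(starts: Sequence[int], L: int, width: int) -> List[int]:
    return [L - j - width + 1 for j in starts]


def find_signal_motif(upstream_seqs: Sequence[str], width: int = 6,
                      mode: str = "hexamer-count", seed: int = 0,
                      n_restarts: int = 5, max_iter: int = 50,
                      tol: float = 1e-6) -> Tuple[PWMotif, Dict[int, int]]:
    """Find the dominant upstream motif and its offset histogram.

    ``hexamer-count`` exhaustively counts all w-mers and returns the most
    frequent as a 0/1-sharpened PWM with each sequence's best (first, 5'-most)
    occurrence offset. ``em`` fits a one-occurrence-per-sequence finite
    mixture over offsets by expectation-maximization against a uniform
    background, with seeded restarts, keeping the highest-likelihood fit; the
    EM log likelihood is non-decreasing over iterations by construction.
    """
    if not upstream_seqs:
        raise ParameterError("no upstream sequences supplied")
    L_min = min(len(s) for s in upstream_seqs)
    if width > L_min:
        raise ParameterError(f"width {width} exceeds shortest sequence ({L_min})")
    if mode == "hexamer-count":
        return _motif_by_count(upstream_seqs, width)
    if mode == "em":
        return _motif_by_em(upstream_seqs, width, seed=seed, n_restarts=n_restarts,
                            max_iter=max_iter, tol=tol)
    raise ParameterError(f"unknown mode {mode!r}")


def _motif_by_count(seqs: Sequence[str], width: int):
    counts: Dict[str, int] = {}
    for s in seqs:
        for j in range(len(s) - width + 1):
            w = s[j:j + width]
            if set(w) <= set(_BASES):
                counts[w] = counts.get(w, 0) + 1
    best = max(sorted(counts), key=lambda w: counts[w])
    matrix = np.full((4, width), 1e-12)
    for i, base in enumerate(best):
        matrix[_BASE_IDX[base], i] = 1.0
    matrix /= matrix.sum(axis=0, keepdims=True)
    offsets = []
    for s in seqs:
        j = s.find(best)
        if j >= 0:
            offsets.append(len(s) - j - width + 1)
    hist: Dict[int, int] = {}
    for o in offsets:
        hist[o] = hist.get(o, 0) + 1
    motif = PWMotif(width=width, matrix=matrix, offsets=offsets, consensus=best)
    return motif, hist


def _motif_by_em(seqs: Sequence[str], width: int, seed: int, n_restarts: int,
                 max_iter: int, tol: float):
    rng = np.random.default_rng(seed)
    # precompute, per sequence, the (n_positions x width) matrix of window
    # base codes used by every E step
    windows = []
    for s in seqs:
        x = np.array([_BASE_IDX.get(b, 0) for b in s], dtype=np.intp)
        windows.append(np.lib.stride_tricks.sliding_window_view(x, width))
    col = np.arange(width)
    best_fit = None
    for _ in range(max(1, n_restarts)):
        pwm = rng.dirichlet(np.ones(4) * 2.0, size=width).T  # 4 x width
        prev_ll = -np.inf
        resp = None
        for _ in range(max_iter):
            pwm, ll, resp = _em_step(windows, pwm, width, col)
            assert ll >= prev_ll - 1e-6, "EM log-likelihood decreased"
            if ll - prev_ll < tol:
                prev_ll = ll
                break
            prev_ll = ll
        if best_fit is None or prev_ll > best_fit[1]:
            best_fit = (pwm, prev_ll, resp)
    pwm, ll, resp = best_fit
    starts = [int(np.argmax(r)) for r in resp]
    offsets = [len(s) - j - width + 1 for s, j in zip(seqs, starts)]
    hist: Dict[int, int] = {}
    for o in offsets:
        hist[o] = hist.get(o, 0) + 1
    consensus = "".join(_BASES[i] for i in np.argmax(pwm, axis=0))
    motif = PWMotif(width=width, matrix=pwm, offsets=offsets, consensus=consensus,
                    log_likelihood=ll)
    return motif, hist


def _em_step(windows, pwm, width, col):
    """One EM iteration over all sequences.

    Returns (updated pwm, log-likelihood under the incoming pwm,
    responsibilities). The observed-data log-likelihood of this
    uniform-prior, one-occurrence-per-sequence mixture is non-decreasing
    across iterations (standard EM guarantee; the tiny pseudocount keeps the
    M step interior).
    """
    log_pwm = np.log(pwm + 1e-300)
    log_bg = np.log(0.25)
    new_counts = np.full((4, width), 1e-3)
    total_ll = 0.0
    responsibilities = []
    for w in windows:
        n_pos = w.shape[0]
        scores = log_pwm[w, col].sum(axis=1) - width * log_bg
        m = scores.max()
        probs = np.exp(scores - m)
        z = probs.sum()
        probs /= z
        total_ll += m + np.log(z) - np.log(n_pos) + (w.shape[0] + width - 1) * log_bg
        responsibilities.append(probs)
        np.add.at(new_counts, (w, np.broadcast_to(col, w.shape)), probs[:, None])
    new_pwm = new_counts / new_counts.sum(axis=0, keepdims=True)
    return new_pwm, total_ll, responsibilities
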