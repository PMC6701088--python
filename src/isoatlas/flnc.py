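"""Full-length non-chimeric (FLnc) read classification.

A read is FLnc when the 5' primer, the 3' primer and a poly(A) tail are all
found in one consistent orientation; a read lacking any one of them, or
carrying an internal (chimeric) primer hit, is non-full-length (nFL). The
oriented insert is the sequence between the 5' primer and the poly(A) run,
reported in transcript orientation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import edlib

from .models import ParameterError, revcomp


@dataclass
class FlncResult:
    read_id: str
    category: str               # "FLnc" | "nFL"
    strand: str                 # detected read orientation, '+' or '-'
    insert: str                 # primer/poly(A)-trimmed sequence, sense orientation
    polya_len: int
    found_primer5: bool
    found_primer3: bool
    found_polya: bool
    chimeric: bool = False


def _best_hit(pattern: str, target: str, max_edits: int) -> Optional[Tuple[int, int, int]]:
    """Best infix alignment of pattern in target with <= max_edits edits.

    Returns (start, end_exclusive, edits) or None.
    """
    if not target:
        return None
    res = edlib.align(pattern, target, mode="HW", task="locations", k=max_edits)
    if res["editDistance"] < 0 or not res["locations"]:
        return None
    start, end = res["locations"][0]
    return start, end + 1, res["editDistance"]


def _polya_run(seq: str, anchor: int, max_nona_per10: int = 1) -> Tuple[int, int]:
    """Length and start of the A-run ending just before ``anchor``.

    Walks 5' from ``anchor`` allowing at most one non-A per ten bases of run
    (tail heterogeneity tolerance); trailing (5'-most) non-A bases are not
    counted as part of the run.
    """
    i = anchor - 1
    run = 0
    non_a = 0
    last_good = anchor
    while i >= 0:
        if seq[i] == "A":
            run = anchor - i
            last_good = i
        else:
            non_a += 1
            if non_a > max(1, (anchor - i) // 10) * max_nona_per10:
                break
        i -= 1
    return anchor - last_good, last_good


def classify_read(read_id: str, seq: str, primer5: str, primer3: str,
                  min_polya: int = 20, max_edits: int = 3,
                  window: int = 100) -> FlncResult:
    """Classify one read as FLnc or nFL and extract the oriented insert.

    Both orientations are searched; a primer hit is an alignment within the
    terminal ``window`` with at most ``max_edits`` edits. The poly(A) tail is
    a run of >= ``min_polya`` A's immediately 5' of the 3'-primer hit (or at
    the read end when the 3' primer is absent). Primer hits in the read
    interior mark the read chimeric, hence nFL.
    """
    if not primer5 or not primer3:
        raise ParameterError("primers must be non-empty")
    if min_polya < 1:
        raise ParameterError("min_polya must be >= 1")

    p3rc = revcomp(primer3)
    best = None
    for strand in ("+", "-"):
        s = seq if strand == "+" else revcomp(seq)
        w = min(window, len(s))
        hit5 = _best_hit(primer5, s[:w], max_edits)
        tail_off = max(0, len(s) - w)
        hit3 = _best_hit(p3rc, s[tail_off:], max_edits)
        insert_start = hit5[1] if hit5 else 0
        anchor = tail_off + hit3[0] if hit3 else len(s)
        polya_len, polya_start = _polya_run(s, anchor)
        has_polya = polya_len >= min_polya
        # chimera scan: primer occurrences strictly inside the insert region
        interior = s[insert_start + 10: max(insert_start + 10, polya_start - 10)]
        chimeric = bool(
            _best_hit(primer5, interior, max_edits)
            or _best_hit(p3rc, interior, max_edits)
        )
        n_found = sum((hit5 is not None, hit3 is not None, has_polya))
        insert_end = polya_start if has_polya else anchor
        insert = s[insert_start:insert_end]
        cand = dict(strand=strand, found5=hit5 is not None, found3=hit3 is not None,
                    polya=has_polya, polya_len=polya_len if has_polya else 0,
                    insert=insert, chimeric=chimeric, n=n_found)
        if best is None or cand["n"] > best["n"]:
            best = cand

    full = best["found5"] and best["found3"] and best["polya"]
    category = "FLnc" if (full and not best["chimeric"] and best["insert"]) else "nFL"
    return FlncResult(
        read_id=read_id,
        category=category,
        strand=best["strand"],
        insert=best["insert"],
        polya_len=best["polya_len"],
        found_primer5=best["found5"],
        found_primer3=best["found3"],
        found_polya=best["polya"],
        chimeric=best["chimeric"],
    )


def classify_reads(reads: Dict[str, str], primer5: str, primer3: str,
                   min_polya: int = 20, max_edits: int = 3,
                   window: int = 100) -> List[FlncResult]:
    return [
        classify_read(rid, seq, primer5, primer3, min_polya=min_polya,
                      max_edits=max_edits, window=window)
        for rid, seq in reads.items()
    ]


def results_to_table(results: Sequence[FlncResult]):
    import pandas as pd

    return pd.DataFrame(
        [
            dict(read_id=r.read_id, category=r.category, strand=r.strand,
                 insert_length=len(r.insert), polya_len=r.polya_len,
                 found_primer5=r.found_primer5, found_primer3=r.found_primer3,
                 found_polya=r.found_polya, chimeric=r.chimeric)
            for r in results
        ]
    )
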