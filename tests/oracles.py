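"""Independent reference implementations used to check the package.

These deliberately take different algorithmic routes from the library:
the AS-event oracle works on exonic coverage bitmaps instead of intron-set
difference regions; the Bayes-factor oracle integrates the two marginal
likelihoods numerically; the rarefaction oracle evaluates the closed-form
hypergeometric expectation.
"""

from __future__ import annotations

import math
from typing import Dict, List, Sequence, Set, Tuple

import numpy as np
from scipy import integrate


# ---------------------------------------------------------------------------
# Brute-force AS event enumeration (coverage-bitmap route)
# ---------------------------------------------------------------------------

def _coverage(exons) -> Set[int]:
    cov = set()
    for s, e in exons:
        cov.update(range(s, e))
    return cov


def _intervals(points: Set[int]) -> List[Tuple[int, int]]:
    out = []
    for p in sorted(points):
        if out and p == out[-1][1]:
            out[-1] = (out[-1][0], p + 1)
        else:
            out.append((p, p + 1))
    return out


def _introns(exons) -> List[Tuple[int, int]]:
    return [(exons[i][1], exons[i + 1][0]) for i in range(len(exons) - 1)]


def brute_force_pair_events(exons_a, exons_b, strand: str):
    """All five-type events between two exon chains, as a set of
    (type, variant) tuples, via exonic-coverage symmetric difference."""
    cov_a, cov_b = _coverage(exons_a), _coverage(exons_b)
    lo = max(exons_a[0][0], exons_b[0][0])
    hi = min(exons_a[-1][1], exons_b[-1][1])
    shared = set(range(lo, hi))
    diff = ((cov_a ^ cov_b) & shared)
    if not diff:
        return set()
    intervals = _intervals(diff)
    introns_a, introns_b = _introns(exons_a), _introns(exons_b)

    # bubble grouping: intervals connected when one intron (of either
    # isoform) touches both (closed-interval overlap)
    n = len(intervals)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            i = parent[i]
        return i

    def touches(iv, intron):
        return iv[0] <= intron[1] and intron[0] <= iv[1]

    for intron in introns_a + introns_b:
        hits = [i for i, iv in enumerate(intervals) if touches(iv, intron)]
        for i in hits[1:]:
            ri, rj = find(hits[0]), find(i)
            if ri != rj:
                parent[rj] = ri
    bubbles: Dict[int, List[Tuple[int, int]]] = {}
    for i, iv in enumerate(intervals):
        bubbles.setdefault(find(i), []).append(iv)

    events = set()
    for ivs in bubbles.values():
        ev = _classify_bubble(ivs, exons_a, exons_b, cov_a, cov_b,
                              introns_a, introns_b, strand)
        if ev is not None:
            events.add(ev)
    return events


def _classify_bubble(ivs, exons_a, exons_b, cov_a, cov_b, introns_a, introns_b,
                     strand):
    ivs = sorted(ivs)
    set_a, set_b = set(introns_a), set(introns_b)
    exoset_a, exoset_b = set(exons_a), set(exons_b)

    if len(ivs) == 1:
        lo, hi = ivs[0]
        in_a = lo in cov_a
        # IR: the interval is exactly an intron of the non-covering isoform
        # and the covering isoform is exonic one base beyond both sides
        cov_side = cov_a if in_a else cov_b
        other_introns = set_b if in_a else set_a
        if (lo, hi) in other_introns and (lo - 1) in cov_side and hi in cov_side:
            return ("IR", (lo, hi))
        # ES: interval is an exon of one isoform whose flanking introns'
        # outer boundaries form one intron of the other
        exoset = exoset_a if in_a else exoset_b
        my_introns = set_a if in_a else set_b
        their_introns = set_b if in_a else set_a
        if (lo, hi) in exoset:
            donors = [d for d, a in my_introns if a == lo]
            acceptors = [a for d, a in my_introns if d == hi]
            for d in donors:
                for a in acceptors:
                    if (d, a) in their_introns:
                        return ("ES", (lo, hi))
        # AA / AD: interval flanked by two introns sharing one boundary
        for d1, a1 in set_a:
            for d2, a2 in set_b:
                if d1 == d2 and {min(a1, a2), max(a1, a2)} == {lo, hi}:
                    return (("AA" if strand == "+" else "AD"), (d1, lo, hi))
                if a1 == a2 and {min(d1, d2), max(d1, d2)} == {lo, hi}:
                    return (("AD" if strand == "+" else "AA"), (lo, hi, a1))
        return None

    if len(ivs) == 2:
        (s1, e1), (s2, e2) = ivs
        x_in_a = s1 in cov_a
        y_in_a = s2 in cov_a
        if x_in_a == y_in_a:
            return None
        x_exons, y_exons = (exoset_a, exoset_b) if x_in_a else (exoset_b, exoset_a)
        x_introns, y_introns = (set_a, set_b) if x_in_a else (set_b, set_a)
        if (s1, e1) not in x_exons or (s2, e2) not in y_exons:
            return None
        # shared outer boundaries
        d_x = [d for d, a in x_introns if a == s1]
        a_x = [a for d, a in x_introns if d == e1]
        d_y = [d for d, a in y_introns if a == s2]
        a_y = [a for d, a in y_introns if d == e2]
        for d in d_x:
            for a in a_x:
                if d in d_y and a in a_y:
                    return ("MX", (s1, e1, s2, e2))
        return None
    return None


def brute_force_locus_events(models) -> Set[Tuple[str, tuple]]:
    """(type, variant) pairs over all isoform pairs of one locus."""
    out = set()
    for i in range(len(models)):
        for j in range(i + 1, len(models)):
            out |= brute_force_pair_events(models[i].exons, models[j].exons,
                                           models[i].strand)
    return out


# ---------------------------------------------------------------------------
# Bayes-factor quadrature
# ---------------------------------------------------------------------------

def _log_beta_integral(a: int, b: int) -> float:
    """log of the integral of p^a (1-p)^b over [0,1] by scaled quadrature."""
    if a + b == 0:
        return 0.0
    mode = a / (a + b) if (a + b) else 0.5
    mode = min(max(mode, 1e-12), 1 - 1e-12)
    log_m = a * math.log(mode) + b * math.log(1 - mode)

    def f(p):
        if p <= 0 or p >= 1:
            return 0.0
        return math.exp(a * math.log(p) + b * math.log(1 - p) - log_m)

    val, _ = integrate.quad(f, 0.0, 1.0, limit=200)
    return log_m + math.log(val)


def bayes_factor_quadrature(na_inc, na_exc, nb_inc, nb_exc) -> float:
    log_bf = (
        _log_beta_integral(na_inc, na_exc)
        + _log_beta_integral(nb_inc, nb_exc)
        - _log_beta_integral(na_inc + nb_inc, na_exc + nb_exc)
    )
    return math.exp(log_bf)


# ---------------------------------------------------------------------------
# Rarefaction expectation
# ---------------------------------------------------------------------------

def expected_distinct(group_sizes: Sequence[int], k: int) -> float:
    """Closed-form E[#distinct groups] for a size-k subsample without
    replacement from groups of the given sizes."""
    n = sum(group_sizes)
    total = 0.0
    for size in group_sizes:
        total += 1.0 - (math.comb(n - size, k) / math.comb(n, k)
                        if n - size >= k else 0.0)
    return total
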