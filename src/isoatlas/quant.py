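"""PSI estimation, Bayes-factor differential splicing, and FPKM.

Percent-spliced-in is inferred from junction-spanning short-read counts
under a Beta-binomial model with a uniform Beta(1,1) prior: the posterior
for an event with n_inc inclusion and n_exc exclusion reads is
Beta(n_inc+1, n_exc+1). Differential splicing between two samples is scored
by the Bayes factor of independent per-sample PSIs against a shared PSI,
which has the closed form

    BF = B(nA_inc+1, nA_exc+1) * B(nB_inc+1, nB_exc+1)
         / B(nA_inc+nB_inc+1, nA_exc+nB_exc+1)

(B the Beta function), computed in log space. Presence and differential
calls reproduce the published filter set: an event is present in a sample
when n_inc >= 1, n_exc >= 1, n_inc+n_exc >= 10 and the 95% credible
interval is no wider than 0.2; a differential call additionally needs
|dPSI| >= 0.20 and BF >= 10.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.special import betaln
from scipy.stats import beta as beta_dist

from .models import ASEvent, ContractError, ParameterError

# Published presence / differential filter thresholds
MIN_INC = 1
MIN_EXC = 1
MIN_SUM = 10
MAX_CI_WIDTH = 0.2
MIN_DELTA_PSI = 0.20
MIN_BAYES_FACTOR = 10.0
CI_LEVEL = 0.95


@dataclass
class PsiEstimate:
    event_id: str
    sample: str
    n_inc: int
    n_exc: int
    psi_mean: float
    ci_low: float
    ci_high: float
    present: bool


@dataclass
class DiffEvent:
    event_id: str
    sample_a: str
    sample_b: str
    delta_psi: float
    bayes_factor: float
    passes: bool


def count_event_reads(event: ASEvent, sj: Dict[Tuple[str, int, int, str], int],
                      intron_coverage: Optional[Dict[Tuple[str, int, int], int]] = None
                      ) -> Tuple[int, int]:
    """Sum junction support over an event's inclusion and exclusion sets.

    Junction keys match on exact coordinates; rows with undetermined strand
    match either strand. For IR the inclusion (retained) form spans no
    junction, so its evidence comes from ``intron_coverage`` when supplied
    (else 0 — a documented limitation of junction-only counting).
    """
    def support(key3):
        contig, d, a = key3
        total = 0
        for strand in (event.strand, "."):
            total += sj.get((contig, d, a, strand), 0)
        return total

    n_exc = sum(support(k) for k in event.exclusion_junctions)
    if event.type == "IR":
        n_inc = 0
        if intron_coverage:
            n_inc = sum(intron_coverage.get(k, 0) for k in event.exclusion_junctions)
    else:
        n_inc = sum(support(k) for k in event.inclusion_junctions)
    return n_inc, n_exc


def estimate_psi(n_inc: int, n_exc: int, event_id: str = "", sample: str = "") -> PsiEstimate:
    """Beta(n_inc+1, n_exc+1) posterior summary of PSI."""
    if n_inc < 0 or n_exc < 0:
        raise ParameterError("counts must be >= 0")
    a, b = n_inc + 1, n_exc + 1
    mean = a / (a + b)
    alpha = (1 - CI_LEVEL) / 2
    lo = float(beta_dist.ppf(alpha, a, b))
    hi = float(beta_dist.ppf(1 - alpha, a, b))
    present = (
        n_inc >= MIN_INC
        and n_exc >= MIN_EXC
        and n_inc + n_exc >= MIN_SUM
        and (hi - lo) <= MAX_CI_WIDTH
    )
    return PsiEstimate(event_id=event_id, sample=sample, n_inc=n_inc, n_exc=n_exc,
                       psi_mean=mean, ci_low=lo, ci_high=hi, present=present)


def log_bayes_factor(na_inc: int, na_exc: int, nb_inc: int, nb_exc: int) -> float:
    """Natural-log Bayes factor of independent vs shared PSI."""
    for n in (na_inc, na_exc, nb_inc, nb_exc):
        if n < 0:
            raise ParameterError("counts must be >= 0")
    return (
        betaln(na_inc + 1, na_exc + 1)
        + betaln(nb_inc + 1, nb_exc + 1)
        - betaln(na_inc + nb_inc + 1, na_exc + nb_exc + 1)
    )


def bayes_factor(na_inc: int, na_exc: int, nb_inc: int, nb_exc: int) -> float:
    return float(np.exp(log_bayes_factor(na_inc, na_exc, nb_inc, nb_exc)))


def call_differential(ps_a: PsiEstimate, ps_b: PsiEstimate) -> DiffEvent:
    """Differential AS call between two samples of one event.

    Passes when both samples meet the count filters (n_inc >= 1, n_exc >= 1,
    sum >= 10), |dPSI| >= 0.20 and BF >= 10.
    """
    if ps_a.event_id != ps_b.event_id:
        raise ContractError(
            f"event id mismatch: {ps_a.event_id!r} vs {ps_b.event_id!r}"
        )
    delta = ps_a.psi_mean - ps_b.psi_mean
    bf = bayes_factor(ps_a.n_inc, ps_a.n_exc, ps_b.n_inc, ps_b.n_exc)

    def count_ok(ps):
        return (ps.n_inc >= MIN_INC and ps.n_exc >= MIN_EXC
                and ps.n_inc + ps.n_exc >= MIN_SUM)

    passes = (count_ok(ps_a) and count_ok(ps_b)
              and abs(delta) >= MIN_DELTA_PSI and bf >= MIN_BAYES_FACTOR)
    return DiffEvent(event_id=ps_a.event_id, sample_a=ps_a.sample,
                     sample_b=ps_b.sample, delta_psi=delta, bayes_factor=bf,
                     passes=passes)


def fpkm(fragments: float, effective_length_nt: float,
         total_mapped_fragments: float) -> float:
    """Fragments per kilobase of transcript per million mapped fragments."""
    if effective_length_nt <= 0 or total_mapped_fragments <= 0:
        raise ParameterError("effective length and total fragments must be > 0")
    if fragments < 0:
        raise ParameterError("fragment count must be >= 0")
    return fragments / ((effective_length_nt / 1000.0)
                        * (total_mapped_fragments / 1e6))


@dataclass
class ExpressionRecord:
    gene_id: str
    fragments: float
    effective_length_nt: float
    fpkm: float
    expressed: bool


def expression_record(gene_id: str, fragments: float, effective_length_nt: float,
                      total_mapped_fragments: float,
                      min_fpkm: float = 1.0) -> ExpressionRecord:
    value = fpkm(fragments, effective_length_nt, total_mapped_fragments)
    return ExpressionRecord(gene_id=gene_id, fragments=fragments,
                            effective_length_nt=effective_length_nt,
                            fpkm=value, expressed=value >= min_fpkm)


# ---------------------------------------------------------------------------
# Table-level drivers
# ---------------------------------------------------------------------------

def psi_table(events: Sequence[ASEvent],
              sj_by_sample: Dict[str, Dict[Tuple[str, int, int, str], int]],
              intron_cov_by_sample: Optional[Dict[str, Dict]] = None) -> pd.DataFrame:
    """Per-event, per-sample PSI estimates as a tidy table."""
    rows = []
    for ev in events:
        for sample, sj in sj_by_sample.items():
            cov = (intron_cov_by_sample or {}).get(sample)
            n_inc, n_exc = count_event_reads(ev, sj, cov)
            ps = estimate_psi(n_inc, n_exc, event_id=ev.event_id, sample=sample)
            rows.append(dict(event_id=ev.event_id, type=ev.type, sample=sample,
                             n_inc=n_inc, n_exc=n_exc, psi_mean=ps.psi_mean,
                             ci_low=ps.ci_low, ci_high=ps.ci_high,
                             present=ps.present))
    return pd.DataFrame(rows)


def differential_table(psi: pd.DataFrame, sample_a: str, sample_b: str) -> pd.DataFrame:
    """Pairwise differential AS calls between two samples of a PSI table."""
    rows = []
    pa = psi[psi["sample"] == sample_a].set_index("event_id")
    pb = psi[psi["sample"] == sample_b].set_index("event_id")
    for event_id in pa.index.intersection(pb.index):
        ra, rb = pa.loc[event_id], pb.loc[event_id]
        ps_a = estimate_psi(int(ra.n_inc), int(ra.n_exc), event_id, sample_a)
        ps_b = estimate_psi(int(rb.n_inc), int(rb.n_exc), event_id, sample_b)
        d = call_differential(ps_a, ps_b)
        rows.append(dict(event_id=event_id, sample_a=sample_a, sample_b=sample_b,
                         delta_psi=d.delta_psi, bayes_factor=d.bayes_factor,
                         passes=d.passes))
    return pd.DataFrame(rows)
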