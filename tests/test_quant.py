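import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import integrate
from scipy.stats import beta as beta_dist

from isoatlas.models import ASEvent, ContractError, ParameterError
from isoatlas.quant import (
    bayes_factor,
    call_differential,
    count_event_reads,
    estimate_psi,
    expression_record,
    fpkm,
    log_bayes_factor,
    psi_table,
)

from oracles import bayes_factor_quadrature


def _event(etype="ES", inc=(("c", 100, 200), ("c", 250, 400)),
           exc=(("c", 100, 400),)):
    return ASEvent(event_id="e1", type=etype, locus_id="L", contig="c",
                   strand="+", flank_left=100, flank_right=400, variant=(200, 250),
                   inclusion_junctions=frozenset(inc),
                   exclusion_junctions=frozenset(exc),
                   isoform_inclusion="a", isoform_exclusion="b")


class TestCountEventReads:
    def test_es_sums_inclusion_junctions(self):
        sj = {("c", 100, 200, "+"): 12, ("c", 250, 400, "+"): 8,
              ("c", 100, 400, "+"): 30}
        assert count_event_reads(_event(), sj) == (20, 30)

    def test_absent_event_counts_zero(self):
        assert count_event_reads(_event(), {}) == (0, 0)

    def test_ir_uses_intron_coverage(self):
        ev = _event(etype="IR", inc=(), exc=(("c", 100, 400),))
        sj = {("c", 100, 400, "+"): 25}
        assert count_event_reads(ev, sj) == (0, 25)
        assert count_event_reads(ev, sj, {("c", 100, 400): 40}) == (40, 25)

    def test_undetermined_strand_rows_counted(self):
        sj = {("c", 100, 200, "."): 5, ("c", 250, 400, "+"): 5,
              ("c", 100, 400, "."): 9}
        assert count_event_reads(_event(), sj) == (10, 9)


class TestEstimatePsi:
    def test_uniform_posterior_with_no_data(self):
        ps = estimate_psi(0, 0)
        assert ps.psi_mean == 0.5
        assert ps.ci_low == pytest.approx(0.025, abs=1e-9)
        assert ps.ci_high == pytest.approx(0.975, abs=1e-9)
        assert not ps.present

    def test_posterior_mean_closed_form(self):
        assert estimate_psi(30, 10).psi_mean == pytest.approx(31 / 42)

    def test_ci_matches_quadrature(self):
        """Central 95% interval endpoints for (30,10) agree with numerical
        quadrature of the Beta density to 1e-6."""
        ps = estimate_psi(30, 10)
        for endpoint, mass in ((ps.ci_low, 0.025), (ps.ci_high, 0.975)):
            got, _ = integrate.quad(lambda p: beta_dist.pdf(p, 31, 11), 0, endpoint)
            assert got == pytest.approx(mass, abs=1e-6)

    @pytest.mark.parametrize("n_inc,n_exc,present", [
        (5, 5, False),     # sum < 10
        (0, 60, False),    # inclusion filter
        (60, 0, False),    # exclusion filter
        (50, 50, True),
        (6, 4, False),     # sum = 10 but CI wider than 0.2
        (200, 200, True),
    ])
    def test_presence_filter(self, n_inc, n_exc, present):
        assert estimate_psi(n_inc, n_exc).present is present

    def test_negative_counts_rejected(self):
        with pytest.raises(ParameterError):
            estimate_psi(-1, 5)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.integers(0, 300), st.integers(0, 300))
    def test_mean_within_interval(self, n_inc, n_exc):
        ps = estimate_psi(n_inc, n_exc)
        assert 0.0 <= ps.ci_low <= ps.psi_mean <= ps.ci_high <= 1.0


class TestBayesFactor:
    def test_balanced_counts_favor_shared(self):
        assert bayes_factor(5, 5, 5, 5) == pytest.approx(0.505, abs=0.001)

    def test_no_data_is_one(self):
        assert bayes_factor(0, 0, 0, 0) == pytest.approx(1.0)

    def test_opposed_counts_far_exceed_threshold(self):
        assert bayes_factor(50, 0, 0, 50) > 1e20

    def test_symmetric_in_samples(self, rng):
        for _ in range(50):
            a, b, c, d = (int(x) for x in rng.integers(0, 100, 4))
            assert log_bayes_factor(a, b, c, d) == \
                pytest.approx(log_bayes_factor(c, d, a, b), rel=1e-12)

    def test_matches_quadrature_oracle(self, rng):
        """Closed-form log-space BF matches numerical double-integral to
        1e-6 relative on 100 random count tuples <= 200."""
        for _ in range(100):
            a, b, c, d = (int(x) for x in rng.integers(0, 201, 4))
            got = bayes_factor(a, b, c, d)
            ref = bayes_factor_quadrature(a, b, c, d)
            assert got == pytest.approx(ref, rel=1e-6)


class TestCallDifferential:
    def test_strong_shift_passes(self):
        d = call_differential(estimate_psi(40, 10, "e", "A"),
                              estimate_psi(10, 40, "e", "B"))
        assert d.delta_psi == pytest.approx(0.5769, abs=1e-3)
        assert d.bayes_factor > 10
        assert d.passes

    def test_no_shift_fails(self):
        d = call_differential(estimate_psi(25, 25, "e", "A"),
                              estimate_psi(25, 25, "e", "B"))
        assert d.delta_psi == 0
        assert not d.passes

    def test_low_count_sample_blocks_call(self):
        d = call_differential(estimate_psi(4, 4, "e", "A"),
                              estimate_psi(40, 2, "e", "B"))
        assert not d.passes

    def test_mismatched_event_ids_rejected(self):
        with pytest.raises(ContractError):
            call_differential(estimate_psi(5, 5, "e1", "A"),
                              estimate_psi(5, 5, "e2", "B"))


class TestFpkm:
    @pytest.mark.parametrize("frags,length,total,expected", [
        (10, 1000, 1e6, 10.0),
        (0, 500, 1e6, 0.0),
        (5, 500, 2e6, 5.0),
    ])
    def test_closed_form(self, frags, length, total, expected):
        assert fpkm(frags, length, total) == pytest.approx(expected)

    def test_zero_length_rejected(self):
        with pytest.raises(ParameterError):
            fpkm(10, 0, 1e6)

    def test_expression_threshold(self):
        assert expression_record("g", 10, 1000, 1e7).expressed  # fpkm = 1.0
        assert not expression_record("g", 9, 1000, 1e7).expressed


class TestStatisticalProperties:
    """Smaller-n versions of the inference-quality checks (the acceptance
    suite runs the full replication counts)."""

    def test_psi_rmse_small(self, rng):
        depth = 100
        errs = []
        for true_psi in (0.2, 0.5, 0.8):
            n_inc = rng.binomial(depth, true_psi, size=100)
            errs.extend((((n + 1) / (depth + 2)) - true_psi) for n in n_inc)
        rmse = float(np.sqrt(np.mean(np.square(errs))))
        assert rmse <= 0.06

    def test_null_fpr_small(self, rng):
        depth = 100
        false = 0
        for _ in range(200):
            a = int(rng.binomial(depth, 0.5))
            b = int(rng.binomial(depth, 0.5))
            d = call_differential(estimate_psi(a, depth - a, "e", "A"),
                                  estimate_psi(b, depth - b, "e", "B"))
            false += d.passes
        assert false / 200 <= 0.05


def test_psi_table_from_synthetic_counts(dataset):
    """Pipeline-level PSI estimates track the generator's truth PSI."""
    from isoatlas.simulate import _parse_juncset

    truth = dataset["truth"]
    events = []
    for r in truth.events.itertuples():
        events.append(ASEvent(
            event_id=r.event_id, type=r.type, locus_id=r.gene_id,
            contig=r.contig, strand=r.strand, flank_left=0, flank_right=0,
            variant=tuple(int(x) for x in r.variant.split(",")),
            inclusion_junctions=_parse_juncset(r.inclusion_junctions, r.contig),
            exclusion_junctions=_parse_juncset(r.exclusion_junctions, r.contig),
            isoform_inclusion=r.isoform_inclusion,
            isoform_exclusion=r.isoform_exclusion))
    table = psi_table(events, dataset["sj"], dataset["intron_cov"])
    merged = 0
    for row in table.itertuples():
        true_psi = truth.psi.loc[row.event_id, row.sample]
        if row.type == "ES" or row.type == "MX":
            # inclusion support is summed over two junctions; the estimate
            # tracks the count ratio, not raw PSI — just bound it
            assert 0 <= row.psi_mean <= 1
        else:
            assert abs(row.psi_mean - true_psi) < 0.25
            merged += 1
    assert merged > 0
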