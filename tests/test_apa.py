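import numpy as np
import pytest

from isoatlas.apa import (
    PWMotif,
    apa_summary,
    call_sites,
    find_signal_motif,
    nucleotide_profile,
    upstream_sequences,
)
from isoatlas.models import CoordinateError, GenomeRef, ParameterError, PolyASite


@pytest.fixture
def flat_genome():
    return GenomeRef({"c": "C" * 5000})


class TestCallSites:
    def test_modal_position_within_cluster(self, flat_genome):
        ends = ([("g", "c", "+", 1000)] * 4 + [("g", "c", "+", 1001)] * 3
                + [("g", "c", "+", 1002)] * 3)
        (site,) = call_sites(ends, flat_genome)
        assert site.position == 1000
        assert site.support == 10

    def test_modal_tie_breaks_to_distal(self, flat_genome):
        ends = [("g", "c", "+", 1000)] * 3 + [("g", "c", "+", 1005)] * 3
        (site,) = call_sites(ends, flat_genome)
        assert site.position == 1005
        minus = [("g", "c", "-", 1000)] * 3 + [("g", "c", "-", 1005)] * 3
        (site,) = call_sites(minus, flat_genome)
        assert site.position == 1000  # distal 3' is genomically lower on '-'

    def test_gap_beyond_window_splits(self, flat_genome):
        ends = [("g", "c", "+", 1000), ("g", "c", "+", 1050)]
        assert len(call_sites(ends, flat_genome, cluster_window=24)) == 2
        assert len(call_sites(ends, flat_genome, cluster_window=50)) == 1

    def test_internal_priming_flag(self):
        seq = list("C" * 3000)
        seq[1000:1015] = "A" * 15
        genome = GenomeRef({"c": "".join(seq)})
        (site,) = call_sites([("g", "c", "+", 1000)], genome)
        assert site.internal_priming

    def test_min_support_drops_small_clusters(self, flat_genome):
        ends = [("g", "c", "+", 1000)] * 3 + [("g", "c", "+", 2000)]
        sites = call_sites(ends, flat_genome, min_support=2)
        assert [s.position for s in sites] == [1000]

    def test_order_invariance(self, flat_genome, rng):
        ends = [("g", "c", "+", int(p))
                for p in rng.integers(500, 4000, size=60)]
        a = call_sites(ends, flat_genome)
        b = call_sites(ends[::-1], flat_genome)
        assert [(s.position, s.support) for s in a] == \
               [(s.position, s.support) for s in b]

    def test_support_conservation(self, flat_genome, rng):
        ends = [("g", "c", "+", int(p))
                for p in rng.integers(500, 4000, size=80)]
        sites = call_sites(ends, flat_genome, min_support=1)
        assert sum(s.support for s in sites) == 80

    def test_unknown_contig_rejected(self, flat_genome):
        with pytest.raises(CoordinateError):
            call_sites([("g", "nope", "+", 10)], flat_genome)

    def test_planted_sites_recovered_exactly(self, dataset):
        from isoatlas.simulate import truth_alignments

        truth = dataset["truth"]
        ann = {m.id: m for m in dataset["annotation"]}
        aligned = truth_alignments(truth, dataset["annotation"], flnc_only=True)
        src = dict(zip(truth.reads.read_id, truth.reads.isoform_id))
        ends = [(src[m.id].rsplit(".", 1)[0], m.contig, m.strand, m.three_prime)
                for m in aligned]
        sites = call_sites(ends, dataset["genome"])
        got = {(s.gene_id, s.position) for s in sites}
        observed_iso = set(truth.reads[truth.reads.category == "FLnc"].isoform_id)
        expected = {(i.rsplit(".", 1)[0], ann[i].three_prime)
                    for i in observed_iso}
        assert got == expected


class TestSummary:
    def _sites(self, counts):
        sites = []
        for gene, n in counts.items():
            for k in range(n):
                sites.append(PolyASite(gene_id=gene, contig="c", strand="+",
                                       position=1000 + 500 * k, support=2))
        return sites

    def test_counts_and_mean(self):
        s = apa_summary(self._sites({"g1": 1, "g2": 2, "g3": 5}))
        assert s["n_apa_genes"] == 2
        assert s["mean_sites_per_gene"] == pytest.approx(8 / 3)
        assert s["distribution"] == {"1": 1, "2": 1, "3": 0, "4": 0, ">=5": 1}

    def test_all_single_site_means_no_apa(self):
        s = apa_summary(self._sites({"g1": 1, "g2": 1}))
        assert s["n_apa_genes"] == 0

    def test_empty_input(self):
        s = apa_summary([])
        assert s["n_sites"] == 0 and s["n_apa_genes"] == 0

    def test_internal_priming_excluded(self):
        sites = self._sites({"g1": 2})
        flagged = PolyASite(gene_id="g1", contig="c", strand="+", position=9000,
                            support=3, internal_priming=True)
        s = apa_summary(sites + [flagged])
        assert s["per_gene"]["g1"] == 2


class TestProfile:
    def test_single_site_gives_indicator_columns(self):
        seq = "ACGT" * 1000
        genome = GenomeRef({"c": seq})
        site = PolyASite(gene_id="g", contig="c", strand="+", position=2000,
                         support=1)
        profile, skipped = nucleotide_profile([site], genome, flank=5)
        assert skipped == 0
        assert np.allclose(profile.sum(axis=0), 1.0)
        # position 0 is the first downstream base = seq[2000]
        assert profile.loc[seq[2000], 0] == 1.0
        assert profile.loc[seq[1999], -1] == 1.0

    def test_downstream_a_bias_reproduced(self, dataset):
        """The generator's planted composition bias (U-rich upstream, A-rich
        downstream) shows in the profile (oracle: direct counting)."""
        truth = dataset["truth"]
        sites = [PolyASite(gene_id=r.gene_id, contig=r.contig, strand=r.strand,
                           position=r.position, support=1)
                 for r in truth.polya.itertuples()]
        profile, _ = nucleotide_profile(sites, dataset["genome"], flank=10)
        a_down = profile.loc["A", 1:10].mean()
        a_up = profile.loc["A", -10:-1].mean()
        t_up = profile.loc["T", -10:-1].mean()
        t_down = profile.loc["T", 1:10].mean()
        assert a_down > a_up
        assert t_up > t_down

    def test_edge_sites_skipped_with_count(self):
        genome = GenomeRef({"c": "A" * 100})
        site = PolyASite(gene_id="g", contig="c", strand="+", position=3,
                         support=1)
        profile, skipped = nucleotide_profile([site], genome, flank=10)
        assert skipped == 1


class TestSignalMotif:
    def _planted(self, rng, n=60, L=50, offset=25):
        seqs = []
        for _ in range(n):
            s = list(rng.choice(list("ACGT"), size=L, p=[0.2, 0.3, 0.3, 0.2]))
            start = L - offset - 5  # 3'-most base lands at distance `offset`
            s[start:start + 6] = "AATAAA"
            seqs.append("".join(s))
        return seqs

    def test_hexamer_count_recovers_planted_signal(self, rng):
        seqs = self._planted(rng)
        motif, hist = find_signal_motif(seqs, 6, mode="hexamer-count")
        assert motif.consensus == "AATAAA"
        assert max(hist, key=hist.get) == 25

    def test_em_recovers_planted_signal(self, rng):
        seqs = self._planted(rng)
        motif, hist = find_signal_motif(seqs, 6, mode="em", seed=1)
        assert motif.consensus == "AATAAA"
        assert abs(max(hist, key=hist.get) - 25) <= 2

    def test_em_seeded_determinism(self, rng):
        seqs = self._planted(rng, n=30)
        m1, _ = find_signal_motif(seqs, 6, mode="em", seed=3)
        m2, _ = find_signal_motif(seqs, 6, mode="em", seed=3)
        assert np.array_equal(m1.matrix, m2.matrix)

    def test_width_equal_length_is_degenerate(self):
        seqs = ["AATAAA", "AATAAA", "AACAAA"]
        motif, hist = find_signal_motif(seqs, 6, mode="hexamer-count")
        assert hist == {1: 2}  # single possible placement
        assert motif.consensus == "AATAAA"

    def test_width_longer_than_sequences_rejected(self):
        with pytest.raises(ParameterError):
            find_signal_motif(["ACGTA"], 6)

    def test_pwm_columns_sum_to_one(self, rng):
        seqs = self._planted(rng, n=20)
        motif, _ = find_signal_motif(seqs, 6, mode="em", seed=0)
        assert np.allclose(motif.matrix.sum(axis=0), 1.0)


def test_upstream_sequences_end_at_cleavage(dataset):
    """The planted hexamer appears in the upstream window exactly at the
    configured offset for every signal-bearing site, both strands."""
    truth = dataset["truth"]
    sites = [PolyASite(gene_id=r.gene_id, contig=r.contig, strand=r.strand,
                       position=r.position, support=1)
             for r in truth.polya.itertuples() if r.signal]
    seqs = upstream_sequences(sites, dataset["genome"], length=50)
    assert len(seqs) == len(sites)
    for s in seqs:
        j = s.find("AATAAA")
        assert 50 - j - 6 + 1 == 25
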