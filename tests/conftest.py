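import numpy as np
import pytest

from isoatlas.simulate import (
    SimParams,
    make_genome,
    plant_genes,
    simulate_fl_reads,
    simulate_sj_counts,
    truth_alignments,
)


@pytest.fixture(scope="session")
def sim_params():
    return SimParams(seed=7, n_genes=20, contig_lengths=(400_000,))


@pytest.fixture(scope="session")
def dataset(sim_params):
    """One mid-sized synthetic dataset shared across test modules."""
    genome = make_genome(sim_params)
    annotation, truth = plant_genes(genome, sim_params)
    reads, truth = simulate_fl_reads(annotation, truth, sim_params, genome)
    sj, cov = simulate_sj_counts(annotation, truth, sim_params)
    return dict(params=sim_params, genome=genome, annotation=annotation,
                truth=truth, reads=reads, sj=sj, intron_cov=cov)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


def random_locus(rng, max_isoforms=4, max_exons=6, grid=10, span=600):
    """Random same-strand exon chains on a coarse coordinate grid (so that
    shared splice boundaries arise often), for oracle-equivalence checks."""
    from isoatlas.models import TranscriptModel

    strand = "+" if rng.random() < 0.5 else "-"
    n_iso = int(rng.integers(2, max_isoforms + 1))
    models = []
    for i in range(n_iso):
        n_exons = int(rng.integers(1, max_exons + 1))
        # 2*n_exons distinct grid points, sorted, as exon boundaries
        points = rng.choice(span // grid, size=2 * n_exons, replace=False)
        bounds = sorted(int(p) * grid for p in points)
        exons = tuple((bounds[2 * k], bounds[2 * k + 1]) for k in range(n_exons))
        models.append(TranscriptModel(id=f"iso{i}", contig="c", strand=strand,
                                      exons=exons, source="test"))
    return models
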