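"""End-to-end pipeline: FLnc classification -> alignment filtering ->
isoform collapse -> junction QC -> AS cataloguing -> APA -> PSI /
differential splicing -> ORF / ncRNA flagging.

Each stage writes its outputs before the next starts; a run manifest
records the funnel counts (reads -> FLnc -> non-redundant isoforms ->
filtered isoforms -> loci -> events) plus per-stage parameters.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import pandas as pd
import yaml

from . import apa as apa_mod
from . import collapse as collapse_mod
from . import events as events_mod
from . import flnc as flnc_mod
from . import io_formats
from . import junctions as junctions_mod
from . import orf as orf_mod
from . import quant as quant_mod
from .models import ParameterError
from .simulate import (
    DEFAULT_PRIMER3,
    DEFAULT_PRIMER5,
    SimParams,
    generate_dataset,
    read_intron_coverage,
)


@dataclass
class PipelineConfig:
    """Paths and per-stage parameters for one pipeline run."""

    genome: str
    reads: str
    alignments: str
    sj_tables: List[str]
    outdir: str
    intron_coverage: List[str] = field(default_factory=list)
    primer5: str = DEFAULT_PRIMER5
    primer3: str = DEFAULT_PRIMER3
    min_polya: int = 20
    max_edits: int = 3
    collapse: collapse_mod.CollapseParams = field(default_factory=collapse_mod.CollapseParams)
    junction_min_support: int = 1
    apa_cluster_window: int = 24
    apa_min_support: int = 1
    orf_min_aa: int = 100
    diff_samples: Optional[Tuple[str, str]] = None
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        if "collapse" in raw and isinstance(raw["collapse"], dict):
            raw["collapse"] = collapse_mod.CollapseParams(**raw["collapse"])
        if "diff_samples" in raw and raw["diff_samples"] is not None:
            raw["diff_samples"] = tuple(raw["diff_samples"])
        return cls(**raw)

    def validate(self) -> None:
        for name in ("genome", "reads", "alignments"):
            p = getattr(self, name)
            if not Path(p).exists():
                raise ParameterError(f"{name} path does not exist: {p}")
        for p in list(self.sj_tables) + list(self.intron_coverage):
            if not Path(p).exists():
                raise ParameterError(f"input path does not exist: {p}")


def _sample_name(path) -> str:
    stem = Path(path).stem
    for prefix in ("SJ_", "intron_coverage_"):
        if stem.startswith(prefix):
            return stem[len(prefix):]
    return stem


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages and return the run manifest."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"stages": {}, "parameters": {
        "junction_min_support": config.junction_min_support,
        "apa_cluster_window": config.apa_cluster_window,
        "orf_min_aa": config.orf_min_aa,
        "collapse": asdict(config.collapse),
        "seed": config.seed,
    }}

    # --- FLnc classification -------------------------------------------------
    reads = io_formats.read_fasta(config.reads)
    results = flnc_mod.classify_reads(reads, config.primer5, config.primer3,
                                      min_polya=config.min_polya,
                                      max_edits=config.max_edits)
    report = flnc_mod.results_to_table(results)
    report.to_csv(outdir / "flnc_report.tsv", sep="\t", index=False)
    flnc_ids = {r.read_id for r in results if r.category == "FLnc"}
    io_formats.write_fasta(outdir / "flnc.fasta",
                           {r.read_id: r.insert for r in results
                            if r.category == "FLnc"})
    manifest["stages"]["flnc"] = {
        "n_reads": len(reads), "n_flnc": len(flnc_ids),
        "n_nfl": len(reads) - len(flnc_ids),
    }

    # --- Collapse ------------------------------------------------------------
    aligned, align_stats = io_formats.read_alignments_with_stats(config.alignments)
    aligned = [m for m in aligned if m.id in flnc_ids]
    kept_alignments, filt_stats = collapse_mod.filter_alignments(aligned, config.collapse)
    clusters = collapse_mod.collapse_isoforms(kept_alignments, config.collapse)
    abundance = pd.DataFrame(
        [dict(cluster_id=c.cluster_id, fl_count=c.fl_count) for c in clusters]
    )
    abundance.to_csv(outdir / "abundance.tsv", sep="\t", index=False)
    manifest["stages"]["collapse"] = {
        "n_aligned_flnc": len(aligned), **align_stats, **filt_stats,
        "n_clusters": len(clusters),
    }

    # --- Junction QC ---------------------------------------------------------
    genome = io_formats.read_genome(config.genome)
    sj_by_sample = {_sample_name(p): io_formats.read_sj_tab(p)
                    for p in config.sj_tables}
    reps = [c.representative for c in clusters]
    juncs = junctions_mod.extract_junctions(reps, genome)
    juncs = junctions_mod.attach_support(juncs, list(sj_by_sample.values()))
    kept, removed, jreport = junctions_mod.filter_isoforms(
        clusters, juncs, min_support=config.junction_min_support)
    junctions_mod.junction_table(juncs).to_csv(outdir / "junctions.tsv", sep="\t",
                                               index=False)
    jreport.to_csv(outdir / "junction_filter_report.tsv", sep="\t", index=False)
    manifest["stages"]["junction_qc"] = {
        "n_junctions": len(juncs),
        "n_isoforms_kept": len(kept), "n_isoforms_removed": len(removed),
    }

    # --- Loci + AS catalog ---------------------------------------------------
    loci = collapse_mod.assign_loci(kept)
    locus_of = collapse_mod.locus_membership(loci)
    io_formats.write_gtf(outdir / "collapsed.gtf",
                         [c.representative for c in kept],
                         gene_ids={c.cluster_id: locus_of[c.cluster_id]
                                   for c in kept})
    pd.DataFrame(
        [dict(locus_id=l.locus_id, contig=l.contig, strand=l.strand,
              n_isoforms=l.n_isoforms) for l in loci]
    ).to_csv(outdir / "loci.tsv", sep="\t", index=False)
    as_events = events_mod.detect_all_events(loci)
    events_mod.events_table(as_events).to_csv(outdir / "events.tsv", sep="\t",
                                              index=False)
    summary = events_mod.summarize_types(as_events)
    summary.to_csv(outdir / "events_summary.tsv", sep="\t", index=False)
    manifest["stages"]["as_catalog"] = {
        "n_loci": len(loci), "n_events": len(as_events),
        "type_counts": {row["type"]: int(row["count"])
                        for _, row in summary.iterrows() if row["type"] != "total"},
        "isoform_histogram": events_mod.isoform_histogram(loci),
    }

    # --- APA -----------------------------------------------------------------
    read_cluster = collapse_mod.cluster_membership(kept)
    by_id = {m.id: m for m in aligned}
    flnc_ends = []
    for read_id, cluster_id in read_cluster.items():
        m = by_id.get(read_id)
        if m is None:
            continue
        flnc_ends.append((locus_of[cluster_id], m.contig, m.strand, m.three_prime))
    sites = apa_mod.call_sites(flnc_ends, genome,
                               cluster_window=config.apa_cluster_window,
                               min_support=config.apa_min_support)
    apa_summary = apa_mod.apa_summary(sites)
    pd.DataFrame(
        [dict(gene_id=s.gene_id, contig=s.contig, strand=s.strand,
              position=s.position, support=s.support,
              internal_priming=s.internal_priming) for s in sites]
    ).to_csv(outdir / "polya_sites.tsv", sep="\t", index=False)
    profile, n_skipped = apa_mod.nucleotide_profile(sites, genome, flank=50)
    profile.to_csv(outdir / "polya_profile.csv")
    upstream = apa_mod.upstream_sequences(sites, genome, length=50)
    motif, offsets = apa_mod.find_signal_motif(upstream, width=6,
                                               mode="hexamer-count")
    manifest["stages"]["apa"] = {
        "n_sites": len(sites),
        "n_internal_priming": sum(s.internal_priming for s in sites),
        "n_genes_with_site": apa_summary["n_genes_with_site"],
        "n_apa_genes": apa_summary["n_apa_genes"],
        "mean_sites_per_gene": apa_summary["mean_sites_per_gene"],
        "signal_consensus": motif.consensus,
        "signal_modal_offset": (max(offsets, key=offsets.get) if offsets else None),
    }

    # --- PSI / differential --------------------------------------------------
    cov_by_sample = {_sample_name(p): read_intron_coverage(p)
                     for p in config.intron_coverage}
    psi = quant_mod.psi_table(as_events, sj_by_sample, cov_by_sample or None)
    psi.to_csv(outdir / "psi.tsv", sep="\t", index=False)
    diff_pair = config.diff_samples or tuple(sorted(sj_by_sample))[:2]
    diff = pd.DataFrame()
    if len(diff_pair) == 2 and len(psi):
        diff = quant_mod.differential_table(psi, diff_pair[0], diff_pair[1])
        diff.to_csv(outdir / "differential.tsv", sep="\t", index=False)
    manifest["stages"]["splice_quant"] = {
        "n_psi_rows": len(psi),
        "n_present": int(psi["present"].sum()) if len(psi) else 0,
        "diff_pair": list(diff_pair),
        "n_differential": int(diff["passes"].sum()) if len(diff) else 0,
    }

    # --- ORF / ncRNA ---------------------------------------------------------
    orf_rows = []
    orfs_by_locus: Dict[str, Dict[str, list]] = {}
    lengths_by_locus: Dict[str, int] = {}
    peptides = {}
    for c in kept:
        m = c.representative
        seq = m.spliced_sequence(genome)
        locus_id = locus_of[c.cluster_id]
        lengths_by_locus[locus_id] = max(lengths_by_locus.get(locus_id, 0), len(seq))
        orfs = orf_mod.find_orfs(seq, transcript_id=c.cluster_id,
                                 min_aa=config.orf_min_aa)
        orfs_by_locus.setdefault(locus_id, {})[c.cluster_id] = orfs
        for o in orfs:
            orf_rows.append(dict(transcript_id=c.cluster_id, locus_id=locus_id,
                                 frame=o.frame, start=o.start, end=o.end,
                                 aa_length=o.aa_length))
        if orfs:
            rep = orf_mod.representative_orf(orfs)
            peptides[c.cluster_id] = orf_mod.translate(seq[rep.start:rep.end - 3])
    pd.DataFrame(orf_rows).to_csv(outdir / "orfs.tsv", sep="\t", index=False)
    if peptides:
        io_formats.write_fasta(outdir / "peptides.fasta", peptides)
    has_orf = {locus_id: any(orfs for orfs in by_iso.values())
               for locus_id, by_iso in orfs_by_locus.items()}
    flags = orf_mod.flag_ncrna(lengths_by_locus, has_orf)
    pd.DataFrame([dict(locus_id=f.locus_id, length_nt=f.length_nt,
                       category=f.category) for f in flags]
                 ).to_csv(outdir / "ncrna_flags.tsv", sep="\t", index=False)
    manifest["stages"]["orf_ncrna"] = {
        "n_coding_loci": sum(f.category == "coding" for f in flags),
        "n_lncrna_candidates": sum(f.category == "lncRNA-candidate" for f in flags),
        "n_short_ncrna_candidates": sum(f.category == "short-ncRNA-candidate"
                                        for f in flags),
    }

    manifest["funnel"] = {
        "reads": manifest["stages"]["flnc"]["n_reads"],
        "flnc": manifest["stages"]["flnc"]["n_flnc"],
        "non_redundant_isoforms": manifest["stages"]["collapse"]["n_clusters"],
        "filtered_isoforms": manifest["stages"]["junction_qc"]["n_isoforms_kept"],
        "loci": manifest["stages"]["as_catalog"]["n_loci"],
        "as_events": manifest["stages"]["as_catalog"]["n_events"],
        "polya_sites": manifest["stages"]["apa"]["n_sites"],
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return manifest


def run_demo(outdir, seed: int = 0, n_genes: int = 30) -> dict:
    """Generate the packaged synthetic fixture and run the full pipeline.

    Returns the manifest extended with the truth-table expectations for the
    funnel counts.
    """
    outdir = Path(outdir)
    data_dir = outdir / "data"
    params = SimParams(seed=seed, n_genes=n_genes)
    genome, annotation, truth, reads, paths = generate_dataset(data_dir, params)
    config = PipelineConfig(
        genome=str(paths["genome"]),
        reads=str(paths["reads"]),
        alignments=str(paths["alignments"]),
        sj_tables=[str(p) for p in paths["sj"]],
        intron_coverage=[str(p) for p in paths["intron_cov"]],
        outdir=str(outdir / "results"),
        primer5=params.primer5,
        primer3=params.primer3,
        seed=seed,
    )
    manifest = run_pipeline(config)

    flnc_reads = truth.reads[truth.reads.category == "FLnc"]
    observed_isoforms = set(flnc_reads.isoform_id)
    iso_three_prime = {m.id: m.three_prime for m in annotation}
    expected_sites = {
        (m.id.rsplit(".", 1)[0], iso_three_prime[m.id])
        for m in annotation if m.id in observed_isoforms
    }
    manifest["truth_expectations"] = {
        "reads": int(len(truth.reads)),
        "flnc": int((truth.reads.category == "FLnc").sum()),
        "non_redundant_isoforms": len(observed_isoforms),
        "filtered_isoforms": len(observed_isoforms),
        "loci": int(truth.genes.gene_id.nunique()),
        "as_events": int(len(truth.events)),
        "polya_sites": len(expected_sites),
    }
    with open(Path(config.outdir) / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return manifest
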