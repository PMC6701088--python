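# isoatlas

Reconstruction and splicing analysis of full-length transcriptomes from
long-read isoform sequencing (PacBio Iso-Seq-style) data, aimed at plant
genomes and other species where a close relative's genome serves as the
mapping reference. The package provides the complete post-alignment
analysis chain as a tested Python library plus a thin `isoatlas` CLI:

1. **FLnc classification** — a circular-consensus read is full-length
   non-chimeric (FLnc) when it carries the 5' primer, the 3' primer and a
   poly(A) tail in one consistent orientation; anything missing one of the
   three, or with an internal primer hit, is non-full-length (nFL).
2. **Isoform collapse** — aligned FLnc reads with identical intron chains
   merge into non-redundant isoforms (coverage ≥ 0.8, identity ≥ 0.7;
   5' differences ignored, 3' ends merged within a 100 nt tolerance), and
   same-strand isoforms connected by exonic overlap form transcript loci.
3. **Splice-junction QC** — junction motifs (canonical GT-AG; non-canonical
   GC-AG, AT-AC, other) are read from the genome and validated against
   short-read junction tables (STAR `SJ.out.tab` dialect); a junction is
   presumed false only when it is non-canonical *and* unsupported, and
   isoforms containing false junctions are removed.
4. **AS event catalog** — pairwise isoform comparison within each locus
   classifies the five major alternative-splicing types: intron retention
   (IR), exon skipping (ES), alternative acceptor (AA), alternative donor
   (AD) and mutually exclusive exons (MX), deduplicated by coordinates.
5. **APA analysis** — FLnc read 3' ends cluster into poly(A) cleavage
   sites (24 nt single-linkage window, internal-priming filter), with
   per-gene alternative-polyadenylation summaries, flanking nucleotide
   composition, and discovery of the upstream AAUAAA signal by exhaustive
   hexamer counting or a single-motif EM.
6. **PSI / differential splicing** — percent-spliced-in per event and
   sample from junction counts under a Beta-binomial model
   (posterior Beta(n_inc+1, n_exc+1)), with MISO-style presence filters
   (n_inc ≥ 1, n_exc ≥ 1, sum ≥ 10, 95% CI width ≤ 0.2) and differential
   calls by |ΔΨ| ≥ 0.20 and Bayes factor ≥ 10, where

   BF = B(n_inc^A+1, n_exc^A+1) · B(n_inc^B+1, n_exc^B+1) /
        B(n_inc^A+n_inc^B+1, n_exc^A+n_exc^B+1).

7. **ORF / lncRNA flags** — complete ATG..stop ORFs of ≥ 100 aa in the
   three sense frames, 5'-most representative per transcript, longest-ORF
   locus representative, an optional 5th-order Markov coding-potential
   score, and lncRNA (> 200 nt, no retained ORF) / short-ncRNA candidates.

A first-class synthetic-data generator (`isoatlas.simulate`) builds
genomes, gene models with planted AS events at an IR-dominant type mix,
full-length reads with primers, poly(A) tails and random 5' truncation,
and junction-count tables at controlled PSI — all with machine-readable
ground truth, so every stage is tested against planted truth end to end.

## Worked example

```
$ python examples/02_collapse_and_events.py
590 FLnc alignments -> 83 non-redundant isoforms in 40 loci (23 events planted)
 type  count  proportion
   IR     17    0.739130
   ES      1    0.043478
   AA      3    0.130435
   AD      1    0.043478
   MX      1    0.043478
total     23    1.000000
loci by isoform count: {'2': 17, '3': 10, '1': 11, '4': 2}
```

590 error-free FLnc alignments collapse to exactly the 83 planted isoforms
in 40 loci; all 23 planted events come back with the correct type, and the
type proportions track the IR-dominant mix the generator plants. Similarly:

```
$ python examples/04_apa_signal.py
60 poly(A) sites in 40 genes; 20 genes with alternative polyadenylation
mean sites/gene 1.50; distribution {'1': 20, '2': 20, '3': 0, '4': 0, '>=5': 0}
dominant upstream hexamer: AATAAA, modal distance 25 nt upstream of cleavage
A frequency downstream 0.39 vs upstream 0.21 (T upstream 0.50)
```

Every planted cleavage site is recovered at its exact position, the
AATAAA signal sits 25 nt upstream of cleavage, and the profile shows the
canonical U-rich upstream / A-rich downstream bias. The other examples
cover FLnc classification (`01`) and PSI/Bayes-factor differential
splicing (`03`).

The full pipeline runs from a shell:

```
isoatlas demo --out demo_run --seed 1        # synthetic fixture + pipeline
isoatlas run --config config.yaml            # your own inputs
```

`isoatlas demo` prints the manifest funnel (reads → FLnc → non-redundant
isoforms → filtered isoforms → loci → events) next to the truth-table
expectations; on error-free synthetic data they agree exactly.

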