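# Methods

This note documents the models, conventions, parameters and limitations of
the isoatlas pipeline, and what passing its synthetic-truth tests does and
does not establish about real data.

## Coordinates and core objects

All internal coordinates are 0-based half-open; GTF (1-based closed) and
SJ-tab intron columns (1-based inclusive) are converted at the I/O boundary
and nowhere else. An intron is keyed by its genomic (left, right) ends
regardless of strand; donor/acceptor *roles* are resolved by strand at use
sites (a shared genomic left boundary is a shared donor on `+` but a shared
acceptor on `-`). A transcript's 3' terminus is the half-open exon-chain
end on `+` and the chain start on `-`; upstream distances are measured from
a feature's 3'-most base to that position, so a signal "25 nt upstream"
occupies genomic `cleavage-30 .. cleavage-25` (inclusive) on `+`.

## FLnc classification

A primer hit is an infix alignment (edlib) within a 100 nt terminal window
with at most 3 edits for the default 30-mer primers. The poly(A) tail is a
run of ≥ 20 A's immediately 5' of the 3'-primer hit, tolerating one non-A
per ten bases of run (tail heterogeneity). Both read orientations are
scored and the one with more elements found wins (ties to forward). A
primer hit in the read interior marks the read chimeric and therefore nFL,
even if all three terminal elements are present. The vendor software this
stage stands in for does not publish its thresholds; all of these are
config surface.

## Collapse

Multi-exon alignments merge iff their intron chains are identical and
their strand-aware 3' ends lie within `tol3` (single-linkage along sorted
3' ends); 5' ends are ignored entirely, reflecting 5'-truncated full-length
reads. `tol3 = 100` nt keeps genuine alternative-polyadenylation isoforms
separable at the model level while absorbing small 3' scatter; APA proper
is called from raw read ends, not collapsed models. Single-exon alignments
merge on reciprocal overlap ≥ 0.5. The representative takes the widest
genomic span of its members; threshold comparisons (coverage ≥ 0.8,
identity ≥ 0.7) are inclusive. Loci are connected components of
same-strand exonic overlap (≥ 1 bp, transitively closed) — an exonic
rather than shared-junction criterion so single-exon genes join loci too.
Aligner-reported coverage/identity are trusted; truth-derived alignments
default to 1.0.

## Junction QC

Motifs are the first two plus last two intron bases in transcript
orientation; classes GT-AG, GC-AG, AT-AC, other. The filter removes an
isoform only when it contains a junction that is simultaneously
non-canonical and short-read-unsupported (default: ≥ 1 uniquely mapped
read in any sample counts as support). Canonical GT-AG junctions are never
removed for lack of support: absence of coverage in the sampled tissues is
weak evidence against a junction that carries the canonical motif
(tissue-specific expression), while a non-canonical motif without
independent support is best explained as alignment error. The per-class
report (total / supported / false) lets users audit stricter policies.
Junction equality is exact; a ±n nt wobble window exists as config and
defaults to 0 because synthetic truth needs none.

## AS event classification

Events are detected pairwise within a locus on *difference regions*
("bubbles"): the introns private to each isoform of a pair are grouped by
closed-interval overlap, and each group is classified against exactly one
of five structural predicates (IR, ES, AA, AD, MX). Region-level
classification is what prevents an MX bubble from also surfacing as
spurious AA and AD (its four introns pairwise share single boundaries).
Events are deduplicated across pairs by (type, variant coordinates).
Decisions taken where the published five-code taxonomy leaves room:

- Transcript 5'/3' end differences never create events; an AA/AD candidate
  whose alternative segment is not fully exonic in the shorter-intron
  isoform (i.e. the other isoform simply ends inside the intron) is
  rejected as an end artifact.
- MX requires the two alternative exons strictly separated; a zero-length
  gap (touching exons sharing a boundary coordinate) is left as a complex
  event.
- Structures matching none of the five predicates are not emitted; the
  summary covers the five major types only.
- The IR *inclusion* form is the retaining isoform; the MX inclusion form
  is the one using the genomically upstream exon. Both conventions matter
  only for PSI orientation and are fixed here.

An independently coded brute-force enumerator (exonic coverage bitmaps,
symmetric difference, interval merging) agrees with the implementation on
thousands of random loci; the acceptance suite runs 500.

## APA

Cleavage sites: per gene, read 3' ends cluster by single linkage with gap
≤ 24 nt; the site is the modal end (ties to the most distal 3' position),
support is cluster size. Internal priming: ≥ 12 A's or an 8-run in the
20 nt immediately downstream (genomic, sense orientation) — evidence the
oligo-dT primed on a genomic A-tract. The upstream motif search window is
50 nt, comfortably containing the ~25 nt canonical signal position. The
clustering and priming thresholds follow common practice for long-read APA
callers and are config-exposed. The per-gene summary reports both the mean
over genes with ≥ 1 site and the raw total-sites/total-genes ratio — the
two definitions differ and both are printed rather than adjudicated.

Motif discovery offers an exhaustive hexamer count (sharpened 0/1 PWM,
first occurrence per sequence) and a one-occurrence-per-sequence EM
(uniform background, ≤ 50 iterations or Δlog-likelihood < 1e-6, 5 seeded
restarts, best fit by likelihood). The EM observed-data log-likelihood is
asserted non-decreasing every iteration. Offsets report the distance from
the motif's 3'-most base to the cleavage site.

## PSI and differential splicing

The full generative-read-model MCMC used by MISO-class tools is replaced
by a junction-count Beta-binomial model: PSI posterior Beta(n_inc+1,
n_exc+1), point estimate the posterior mean, central 95% credible interval
(the published filters name a CI without a level; 95% is the convention).
Because inclusion and exclusion evidence are both single-junction counts,
effective-length correction cancels and is omitted. The Bayes factor of
independent vs shared PSI has the closed Beta-function form and is
computed in log space; it matches numerical quadrature to ~1e-12 relative.
Presence filters (n_inc ≥ 1, n_exc ≥ 1, n_inc+n_exc ≥ 10, CI width ≤ 0.2)
and differential filters (per-sample counts, |ΔΨ| ≥ 0.20, BF ≥ 10) are
reproduced exactly; no multiple-testing correction is applied, matching
filter-based calling. For ES/MX events the inclusion count sums two
junctions, so the PSI point estimate tracks the junction-count ratio
rather than the molar isoform fraction — a documented property of
junction-only counting. IR inclusion evidence needs intron-body coverage,
which SJ tables lack; an intron-coverage TSV is accepted (the generator
emits one), else IR events count zero inclusion and fail presence filters.

Measured under the model's own assumptions (depth 100, 500 replicates per
true PSI in 0.1..0.9): RMSE ≈ 0.043, CI coverage ≈ 94%, null
false-positive rate of the full differential filter ≈ 0.3–0.5% over 1000
null pairs, power ≈ 100% at ΔΨ = 0.4. These are recomputed, not quoted, by
`scripts/acceptance.py`.

## ORF and ncRNA rules

ORFs are complete ATG..in-frame-stop spans in the three sense frames
(full-length reads are oriented; `both_strands` exists for unoriented
input); within a frame, overlapping ORFs resolve to the 5'-most ATG per
stop. Retention requires ≥ 100 aa, where aa = span/3 − 1 (stop excluded).
No 3'-partial ORFs are reported: a full-length transcript should contain
its complete CDS. The transcript representative is the 5'-most ORF (ties
to longest); the locus representative is the isoform with the longest ORF
(ties to lexicographically smaller id). External coding-potential
classifiers are replaced by the ORF rule plus an optional log-likelihood
ratio between two 5th-order add-one-smoothed nucleotide Markov chains
(coding vs background), trained from labeled sets; score ≤ 0 supports
non-coding. Loci with no retained ORF are lncRNA candidates when the
longest isoform exceeds 200 nt, short-ncRNA candidates otherwise.

## Synthetic data generator

The generator defines the study conditions the tests run under:

- **AS-type mix** defaults to IR 68.85%, AA 15.64%, AD 9.31%, with ES and
  MX splitting the remaining 6.2% equally — the IR-dominant mix typical of
  plant transcriptomes.
- **Junction classes**: 15.35% of constitutive introns are non-canonical,
  split to reproduce overall frequencies of 84.65% GT-AG, 1.52% GC-AG,
  0.40% AT-AC, 13.43% other. Introns flanking a planted event stay GT-AG
  so event truth is independent of junction-class truth.
- **Genes** are non-overlapping, on one uniformly chosen strand, with 5–8
  exons (120–250 nt) and introns of 250–500 nt; per-gene isoform counts
  follow {1: 0.49, 2: 0.35, 3: 0.16} (about half of loci multi-isoform).
  Each extra isoform realizes one planted event at its own slot, slots
  separated by two exons so cross-pair comparisons cannot create novel
  structures.
- **Reads**: depth 10 per isoform, 27% nFL (each nFL read omits exactly
  one of 5' primer / 3' primer / poly(A)), poly(A) length 30, random
  strand flip at 0.5, 5' truncation uniform up to 30% of transcript length
  but capped so the 5'-most exon survives — the collapse contract merges
  only identical intron chains, and real 5'-degraded reads that lose whole
  junctions would found new (shorter) chains rather than collapse errors.
  Reads are error-free by default (error correction is outside the
  pipeline's scope); a uniform substitution rate exists as a parameter.
- **Poly(A)**: every distinct isoform 3' end is a cleavage site; 50% of
  genes gain an APA isoform whose last exon extends 180 nt (beyond both
  `tol3` = 100 and the 24 nt site window, keeping model-level and
  site-level truth unambiguous). Sites carry an AATAAA signal ending 25 nt
  upstream of cleavage (all sites by default, configurable), plus a
  planted U-rich upstream / A-rich downstream composition bias
  rejection-sampled to stay below the internal-priming thresholds.
- **Coding**: 90% of genes carry a planted stop-free CDS on the base
  isoform covering most of the transcript. Splice-motif planting wins
  conflicts with CDS letters at variant boundaries, so coding truth is
  per-gene presence rather than exact ORF coordinates.
- **Junction counts**: constitutive junctions get the full per-sample
  depth (60); event junctions split Binomial(depth, PSI) against the
  remainder, with true PSI uniform on [0.1, 0.9] per event and sample.
  No overdispersion — the simplest model consistent with the inference
  stage's likelihood. IR retention evidence goes to a separate
  intron-coverage table.
- The study-scale accession data behind the published counts are not
  required or downloaded; desk-scale problem sizes (tens to hundreds of
  genes, depth 10–100) keep the full suite under ten seconds while
  exercising every code path.

What passing these tests shows: the algorithms implement their definitions
exactly (classification, collapse, event typing, site calling are perfect
on error-free truth) and the inference stage is calibrated under its own
model. What they do not show: robustness to alignment error, to 5'
degradation that destroys junctions, to overdispersed junction counts, to
internal-priming artifacts in reads, or to chimeric molecules — real-data
effects the generator deliberately omits (listed as its non-goals).

## Numerical and degenerate-input choices

Empty inputs return empty outputs except where a contract forbids them
(`representative_orf`, `rarefaction` on an empty map). Parsers reject
coordinate inversions rather than repairing them. Ties: modal poly(A)
position → most distal 3'; representative ORF → longest; locus
representative → smaller id; FLnc orientation → forward. The EM uses a
1e-3 pseudocount to keep the M step interior; Beta quantiles come from
scipy. All randomness in the generator, the EM restarts and rarefaction
flows from explicit integer seeds; fixed seeds give byte-identical output
files.
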