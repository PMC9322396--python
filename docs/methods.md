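# Methods

`hrp` annotates NB-LRR (nucleotide-binding, leucine-rich-repeat) resistance
gene models directly in a genome assembly with a two-pass procedure: a
protein domain search (PDS) over the predicted proteome seeds a set of
full-length R-proteins, which are then used as queries for spliced,
codon-aware homology prediction on the genomic DNA. This note describes the
models and numerical choices behind each stage, what the synthetic
benchmark does and does not emulate, and the known limitations.

## Domain detection and classification

Proteins are scanned with three detectors:

* **Profile scan.** Position-specific scoring matrices (log-odds bits over
  the 20 amino acids, uniform background, pseudocount 1.0 x background) for
  the NB, TIR, Rx-N coiled-coil and RPW8 domains, built at load time from
  small seed alignments shipped with the package. The scan is an ungapped
  sliding window; windows at or above the per-profile bit threshold are
  merged greedily by score into non-overlapping hits. Thresholds are fixed
  in the bundled metadata at 45% (NB) or 40% (TIR/Rx-N/RPW8) of the
  consensus self-score — far enough above the random-window distribution
  (which sits hundreds of bits lower) that false positives were not
  observed in 10^4 random proteins, while homologs down to ~65-70% identity
  still clear them. These profiles are the package's own; the Pfam
  accessions carried in the metadata (NB: PF00931, TIR: PF01582, Rx-N:
  PF18052) label what each profile stands for, nothing more.
* **LRR repeats.** The leucine-rich repeat array is detected as tandem
  8-residue frames with hydrophobic anchors (L/I/V/F) at positions
  0, 3, 5, 7. A frame matches when at least 3 of the 4 anchors are
  hydrophobic **and** at most one non-anchor position is; a hit requires at
  least `min_repeats` (default 3) consecutive tiled frames. The non-anchor
  condition is what separates periodic from merely hydrophobic sequence: a
  shuffled LRR region keeps its ~50% hydrophobic composition, and anchors
  alone would match it in well over 5% of shuffles, while the two-sided
  rule keeps the shuffle null below 5%.
* **Coiled coil.** A 21-residue sliding window scored as the geometric mean
  of per-residue heptad propensities (bundled table; core positions a/d vs
  other positions, best of the 7 registers), mapped through a logistic to a
  probability. Windows above 0.5 merge into one hit. This is a deliberately
  simple stand-in for a full coiled-coil predictor, tuned to be quiet:
  ideal heptads score > 0.9, random proteins essentially never fire.

Hits assemble into an ordered architecture (same-kind overlaps keep the
higher score; Rx-N and coiled-coil evidence collapse to a single CC token
at the earliest start). Classification is a pure function of the ordered
kind list: a protein is **full-length** when an NB is followed by an LRR;
the label is CNL / TNL / RNL by the earliest of CC / TIR / RPW8 preceding
the NB, or NL when no N-terminal domain is recognized. Anything else is a
partial label joining the ordered kinds ("TIR-NB", "NB", "LRR", ...). The
complete 326-row truth table over every ordered arrangement of the five
domain kinds is committed under `tests/data/` and checked in the suite.

## Motif discovery and rescue

NB-domain regions of the pass-1 full-length proteins are decomposed into up
to 19 motifs of width 4-7 by a ZOOPS ("zero or one occurrence per
sequence") EM with sequential site erasure. Initialization is deterministic
(most frequent exact word, ties lexicographic), convergence at
log-likelihood improvement < 1e-4 or 50 iterations, pseudocount 0.01 x
background per cell. Width is chosen by log-likelihood ratio minus a
BIC-style penalty of 0.5 x 19 x ln(n) per column; without the penalty a
weakly conserved flanking column routinely inflates the accepted width by
one. Background frequencies are estimated from the input set itself.

Motif scanning reports an **exact** p-value per window: the log-odds are
rescaled to integers at 1/100-bit precision and the null score distribution
is built by staged convolution of the per-column distributions under the
background; the observed score is rescaled identically, so the width-1
p-value of a single-residue motif is exactly that residue's background
frequency. Per-protein evidence is combined with the QFAST product rule
(q = prod p_i, combined p = q * sum_{k<n} (-ln q)^k / k!) scaled by the
database size.

A proteome entry is **rescued** when at least 3 distinct motifs have
best-hit p < 1e-5 and the combined E-value is at most 10. With 19 motifs
and ~300-window proteins, a 1e-4 per-motif cutoff lets roughly 2% of
random proteins through the 3-motif rule; 1e-5 brings the null rescue rate
under 1% while true NB regions sit at p ~ 1e-9 per motif. Both values are
configurable.

## Spliced homology prediction

Each full-length pass-1 protein without internal stops is a query.
(Pseudoprotein queries are excluded deliberately: a fused two-gene protein
aligns colinearly across *any* adjacent paralog pair and would manufacture
chimeric two-gene models across every cluster.)

1. **Seeding.** Exact amino-acid 4-mers between query and all six
   translated frames seed ungapped X-drop extensions (drop 20) under
   BLOSUM62; segments under 50 are discarded and contained segments on a
   diagonal merged.
2. **Chaining.** Colinear same-strand HSPs are chained by dynamic
   programming. A join costs `15 + gap/64` (the intron cost shape, below)
   and requires a subject gap of at most `max_intron`; chain footprints are
   capped at the maximum gene span.
3. **Spliced alignment.** The query is aligned codon-aware against a
   genomic window around each chain (local, BLOSUM62; affine gaps open 11 /
   extend 1). Introns are permitted only between codons, at GT...AG
   boundaries, with length in [40, `max_intron`], each costing
   `intron_open + intron_per_nt x length` = 15 + length/64 score units. All
   scores are multiples of 1/64, so float32 dynamic programming is exact
   and the traceback can use exact comparisons.

Three numerical choices here deserve their rationale:

* **Intron length cap (`max_intron` = 2200).** In tandem R-gene clusters a
  spliced aligner can "hop" the intergenic gap and stitch the
  better-matching copy of each exon from two adjacent paralogs into one
  chimeric model. Such a hop must traverse at least one gene body plus the
  intergenic gap — under the benchmark's conditions (introns 40-2000 nt,
  cluster spacing 1-5 kb) that is >= ~2.4 kb — so a cap modestly above the
  realistic intron range excludes chimeras structurally while keeping every
  legitimate intron reachable. The cap is a config knob for genomes with
  longer introns.
* **Intron cost shape (open 15 + length/64).** The cost must stay below the
  affine-gap cost of deleting the intron as codons (11 + length/3), or
  short introns would be absorbed into exons; and it must stay well below
  the value of a diverged distal exon (~100-300 score units), or models
  fragment at long introns. A flat cost satisfying both would make chance
  joins of unrelated segments across multi-kb gaps profitable; the shallow
  per-nt component preserves the E-value calibration on random sequence.
* **Two scores per candidate.** The DP path score (gaps and intron costs
  included) drives the Karlin-Altschul E-value, E = K m n exp(-lambda S)
  with the standard ungapped BLOSUM62 constants lambda = 0.3176, K = 0.134
  and n = both strands of the assembly; candidates with E > 0.01 are
  dropped. The reported protein-level score excludes intron costs, so the
  translation of a predicted model re-aligns to its query at exactly that
  score (verified in the suite with an independent aligner).

Chains are pooled across queries; per overlapping genomic region (same
strand) only the best few chains (default 6, at most 2 per query) are
spliced-aligned. Overlap counting is against individually accepted chain
footprints, never merged regions, so one low-scoring chain straddling two
gene loci cannot weld them into a single region and starve both of
alignment slots.

## Filtering, reconciliation, reporting

Predicted models spanning **strictly more than** 20 kb are removed.
Same-strand models overlapping by >= 1 bp are clustered single-linkage and
each cluster keeps the model encoding the longest protein (ties: higher
score, then smaller start); opposite-strand overlaps are kept. Surviving
models are re-translated, re-annotated with the domain detectors, and
flagged `pseudogene=true` when the coding sequence contains internal stops
or a frameshift — pseudogenes with complete architecture stay in the
output.

Pass-1 loci (full-length, partial, or motif-rescued) that no pass-2 model
overlaps are appended unchanged, with provenance `PDS` or `motif-rescue`;
everything from the homology pass carries `homology-pass`. This guarantees
the conservation property — the homology pass may re-model but never
silently drops a pass-1 locus — while letting pass 2 win wherever it
produced a model (which is what resolves fused and split annotation
defects: the fused protein's locus is re-modelled as two genes by clean
queries, a split gene's two halves are covered by one full model).

The report mirrors the standard class layout: full-length counts per
CNL/TNL/RNL/NL, partial counts per joined label, pseudogene count, and
per-gene records with exactly one provenance each.

## Model-set and proteome comparison

`match_models` pairs models on the same assembly by same-strand CDS overlap
and reports the per-pair shared fraction (shared coding bases / union of
coding bases), structure identity (identical exon boundary sets), and the
aggregate shared-CDS percentage over matched pairs. `rbh_pairs` estimates
gene correspondences between two proteomes as reciprocal best hits under
ungapped BLOSUM62 scoring with a normalized confidence (best score /
self-score of the smaller protein; the default threshold of 1 maps to a
0.25 cutoff). This is a simplification of full ortholog clustering —
in-paralog expansion is out of scope, and the normalized confidence is not
numerically comparable to external tools' internal scores.

## The synthetic benchmark

The generator emulates the conditions that defeat automated R-gene
annotation: a 500-kb assembly with 30 full-length NB-LRR genes (23 CNL,
5 TNL, 1 RNL, 1 NL — a CNL-dominated mix typical of real repertoires) in
tandem clusters of 1-4 genes spaced 1-5 kb apart, each gene carrying 1-3
phase-0 GT...AG introns of 40-2000 nt, plus intronless TE-like decoy ORFs
and ordinary background genes. Proteins are assembled from the same
consensus blocks that underlie the bundled profiles (NB fixed at 200
residues, the average NB domain length; >= 5 LRR units) and mutated to
identities drawn from U(0.82, 0.95); inside the LRR array substitutions
preserve the hydrophobic periodicity (anchors stay hydrophobic, non-anchors
non-hydrophobic). Every generated protein is verified closed-loop against
the package's own classifiers, and every truth model re-translates from the
genome to exactly the generated protein.

The defective "automated" annotation derives from the truth by logged
defects only: 10 genes omitted, one adjacent same-strand pair fused into a
single model, one multi-exon gene split into two partial models, and
optionally a gene whose NB region is degraded below the profile threshold
(mutating only the C-terminal half, so motif content in the intact half
still rescues it).

What passing on this benchmark does **not** show: real NB-LRR divergence is
not uniform point substitution (no indels within domains here, no domain
shuffling, no nested TE insertions inside introns); intergenic DNA is
i.i.d. random rather than repeat-laden; introns are phase-0 only, matching
the aligner's documented simplification; and the bundled profiles are
synthetic stand-ins, not Pfam/SUPERFAMILY models, so absolute bit
thresholds do not transfer to real proteomes. The pipeline's *procedural*
properties — defect resolution, overlap filtering, conservation of pass-1
loci, E-value calibration on random sequence — are what the benchmark
exercises.

## Problem sizes and determinism

Default problem sizes (the benchmark genome of 500 kb with ~50 genes, 20
random 100-kb genomes for the null, 50 sequences for motif recovery) run
the whole acceptance computation in a few minutes on one core. Every stage
is deterministic given the inputs and seeds: generator output is
bit-identical per seed, EM initialization is derandomized, and repeated
pipeline runs produce byte-identical reports.

## Known limitations

* Introns are phase-0 only and must be canonical GT...AG with length within
  `[min_intron, max_intron]`; non-canonical splice sites and frameshift-
  tolerant alignment are out of scope.
* Ungapped Karlin-Altschul constants are applied to a mildly gapped/spliced
  score; the E-values are calibrated (random genomes yield none to few
  candidates at E <= 0.01) but are not exact gapped statistics.
* The coiled-coil and LRR detectors are synthetic-calibrated heuristics;
  on real proteomes a profile-HMM scanner would replace them.
* Chromosome-scale assemblies are out of scope: the k-mer index and the
  per-window DP are designed for desk-scale (sub-Mb) experiments.
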