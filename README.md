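# hrp — full-length homology-based NB-LRR resistance gene prediction

Plant disease resistance (R) genes of the NB-LRR class — proteins carrying
a nucleotide-binding (NB-ARC) domain followed by leucine-rich repeats, with
a coiled-coil (CNL), TIR (TNL) or RPW8 (RNL) N-terminus — sit in clusters
of tandemly duplicated paralogs that automated genome annotation handles
badly: repeat masking hides them, and the models that do get produced are
often missing, fused or split. The conventional remedy, a protein
domain search (PDS) over the predicted proteome, can only find what the
annotation already contains.

`hrp` implements a two-pass alternative for people annotating plant
genomes or mining R-gene alleles across accessions:

1. **Pass 1 (PDS).** Scan the predicted proteome with bundled PSSMs
   (NB, TIR, Rx-N/CC, RPW8), an LRR repeat detector and a coiled-coil
   heuristic; classify every protein (CNL/TNL/RNL/NL or a partial label).
   NB regions of full-length hits are decomposed into short motifs
   (ZOOPS EM, up to 19 motifs of width 4–7) which rescue proteins whose
   domain scores fell below threshold — scan p-values are exact, computed
   by convolution of the integer-rescaled score distributions, and
   combined with the QFAST product rule
   `p_comb = q · Σ_{k<n} (−ln q)^k / k!`, `q = Π p_i`.
2. **Pass 2 (homology).** Every full-length protein becomes a query for
   spliced gene prediction directly on the assembly: translated 4-mer
   seeding in six frames, X-drop extension under BLOSUM62, colinear HSP
   chaining, then codon-aware local alignment with GT…AG introns between
   codons. Significance is Karlin–Altschul, `E = K·m·n·e^{−λS}`
   (λ = 0.3176, K = 0.134 for ungapped BLOSUM62), cutoff `E ≤ 0.01`.
   Models spanning > 20 kb are dropped; same-strand overlapping models are
   resolved to the one encoding the longest protein; everything surviving
   is re-translated, re-annotated, classified, and flagged as a pseudogene
   when internal stops or a frameshift are present.

A synthetic-data generator (`hrp.synth`) builds genomes with known truth —
clustered intron-containing NB-LRR paralogs, TE-like decoy ORFs, and a
deliberately defective annotation (omitted / fused / split / weakened
models) — so the whole pipeline is testable offline.

## Worked example

Simulate a 200-kb genome carrying ten full-length NB-LRR genes (eight CNL,
two TNL) whose automated annotation omits three genes, fuses one adjacent
pair and splits one gene, then re-annotate it:

```bash
hrp simulate --spec demo_spec.yaml --seed 42 --out demo
# wrote genome (200000 bp), 21 truth models, 18 defective models to demo
hrp run --genome demo/genome.fa --proteome demo/proteome.faa \
        --gff demo/defective.gff3 --out demo/out
```

The run prints the class summary:

```json
{
 "full_length": {"CNL": 8, "TNL": 2, "RNL": 0, "NL": 0},
 "total_full_length": 10,
 "partial": {},
 "total_partial": 0,
 "pseudogenes": 0,
 "total": 10
}
```

All ten implanted genes are recovered as full-length models — including
the three the annotation omitted, the fused pair (now two models) and the
split gene (now one model) — and none of the TE decoys is called. The
per-gene table (`demo/out/report.tsv`) records each model's locus, class
and provenance:

```
id        seqid    start   end     strand  class  full_length  pseudogene  provenance
HRP_0011  chr_syn  5690    9786    +       CNL    1            0           homology-pass
HRP_0018  chr_syn  13961   18264   +       CNL    1            0           homology-pass
HRP_0017  chr_syn  52266   54778   +       CNL    1            0           homology-pass
...
```

Outputs also include `hrp.gff3` (gene/mRNA/CDS models), `hrp_proteins.faa`
(predicted proteins), `report.json` and the discovered motifs in MEME
minimal text format.

Other commands: `hrp mine --query fom2.faa --genome assembly.fa --out dir`
(single-query allele mining), `hrp pds` (proteome classification only),
`hrp compare` (two GFF3 model sets: shared-CDS fraction and intron–exon
structure identity), `hrp simulate` (synthetic benchmarks). The same
functionality is available as a library (`hrp.pipeline.run_hrp`,
`hrp.pipeline.mine_alleles`, `hrp.compare`, `hrp.synth`).

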