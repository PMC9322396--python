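{
 "NB": {
  "alignment": "nb.fasta",
  "accession": "PF00931",
  "threshold": 352.2
 },
 "TIR": {
  "alignment": "tir.fasta",
  "accession": "PF01582",
  "threshold": 187.8
 },
 "CC_RXN": {
  "alignment": "cc_rxn.fasta",
  "accession": "PF18052",
  "threshold": 70.2
 },
 "RPW8": {
  "alignment": "rpw8.fasta",
  "accession": "HRP-RPW8",
  "threshold": 140.4
 }
}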