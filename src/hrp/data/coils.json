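{
 "core": {
  "A": 2.2,
  "C": 0.8,
  "D": 0.3,
  "E": 0.6,
  "F": 3.0,
  "G": 0.1,
  "H": 0.6,
  "I": 5.0,
  "K": 0.6,
  "L": 8.0,
  "M": 4.0,
  "N": 0.4,
  "P": 0.01,
  "Q": 0.8,
  "R": 0.6,
  "S": 0.5,
  "T": 0.5,
  "V": 4.0,
  "W": 1.0,
  "Y": 1.5,
  "X": 0.5,
  "*": 0.01
 },
 "other": {
  "A": 1.6,
  "C": 0.4,
  "D": 1.2,
  "E": 2.4,
  "F": 0.4,
  "G": 0.3,
  "H": 0.8,
  "I": 0.5,
  "K": 2.2,
  "L": 0.9,
  "M": 0.8,
  "N": 1.0,
  "P": 0.02,
  "Q": 2.0,
  "R": 1.8,
  "S": 0.9,
  "T": 0.8,
  "V": 0.5,
  "W": 0.3,
  "Y": 0.5,
  "X": 0.5,
  "*": 0.01
 }
}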