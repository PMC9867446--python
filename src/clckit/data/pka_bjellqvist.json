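{
 "negative": {
  "C": 9.0,
  "Cterm": 3.55,
  "D": 4.05,
  "E": 4.45,
  "Y": 10.0
 },
 "positive": {
  "H": 5.98,
  "K": 10.0,
  "Nterm": 7.5,
  "R": 12.0
 }
}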