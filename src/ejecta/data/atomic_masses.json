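{
  "_comment": "IUPAC conventional standard atomic weights, rounded to 3 decimals (amu).",
  "H": 1.008,
  "C": 12.011,
  "N": 14.007,
  "O": 15.999,
  "S": 32.06,
  "P": 30.974
}
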