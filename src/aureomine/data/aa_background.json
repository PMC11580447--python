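{
  "A": 0.0787945, "C": 0.0151600, "D": 0.0535222, "E": 0.0668298,
  "F": 0.0397062, "G": 0.0695071, "H": 0.0229198, "I": 0.0590092,
  "K": 0.0594422, "L": 0.0963728, "M": 0.0237718, "N": 0.0414064,
  "P": 0.0482904, "Q": 0.0395639, "R": 0.0540978, "S": 0.0683364,
  "T": 0.0540687, "V": 0.0673417, "W": 0.0114135, "Y": 0.0304133
}
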