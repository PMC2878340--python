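{
  "comment": "Unified DNA nearest-neighbor parameters (Allawi & SantaLucia 1997; SantaLucia 1998 PNAS 95:1460). dH in kcal/mol, dS in cal/(mol K), per 5'->3' dinucleotide stack of one strand.",
  "stacks": {
    "AA": [-7.9, -22.2],
    "AT": [-7.2, -20.4],
    "TA": [-7.2, -21.3],
    "CA": [-8.5, -22.7],
    "GT": [-8.4, -22.4],
    "CT": [-7.8, -21.0],
    "GA": [-8.2, -22.2],
    "CG": [-10.6, -27.2],
    "GC": [-9.8, -24.4],
    "GG": [-8.0, -19.9],
    "TT": [-7.9, -22.2],
    "TG": [-8.5, -22.7],
    "AC": [-8.4, -22.4],
    "AG": [-7.8, -21.0],
    "TC": [-8.2, -22.2],
    "CC": [-8.0, -19.9]
  },
  "init_at": [2.3, 4.1],
  "init_gc": [0.1, -2.8]
}
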