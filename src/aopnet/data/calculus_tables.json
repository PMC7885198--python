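{
  "comment": "Default categorical weight-of-evidence calculus. strength: convincingness x reliability -> argument strength (symmetric 3x3). combine: same-direction combination of two strengths (symmetric 5x5). oppose: Against-magnitude (row) vs For-magnitude (column) -> signed result; '0' is Balanced, a leading '-' means Against.",
  "grades": ["Small", "Medium", "Large"],
  "strength_levels": ["VL", "L", "M", "H", "VH"],
  "strength": {
    "Large":  {"Large": "VH", "Medium": "H",  "Small": "M"},
    "Medium": {"Large": "H",  "Medium": "M",  "Small": "L"},
    "Small":  {"Large": "M",  "Medium": "L",  "Small": "VL"}
  },
  "combine": {
    "VH": {"VH": "VH", "H": "VH", "M": "VH", "L": "VH", "VL": "VH"},
    "H":  {"VH": "VH", "H": "VH", "M": "VH", "L": "H",  "VL": "H"},
    "M":  {"VH": "VH", "H": "VH", "M": "H",  "L": "H",  "VL": "M"},
    "L":  {"VH": "VH", "H": "H",  "M": "H",  "L": "M",  "VL": "M"},
    "VL": {"VH": "VH", "H": "H",  "M": "M",  "L": "M",  "VL": "L"}
  },
  "oppose": {
    "VH": {"VH": "0",  "H": "-H", "M": "-VH", "L": "-VH", "VL": "-VH"},
    "H":  {"VH": "H",  "H": "0",  "M": "-M",  "L": "-M",  "VL": "-H"},
    "M":  {"VH": "VH", "H": "M",  "M": "0",   "L": "-VL", "VL": "-L"},
    "L":  {"VH": "VH", "H": "M",  "M": "VL",  "L": "0",   "VL": "-VL"},
    "VL": {"VH": "VH", "H": "H",  "M": "L",   "L": "VL",  "VL": "0"}
  }
}
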