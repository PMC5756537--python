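{
  "name": "pipette",
  "temperature_K": 310.15,
  "pH": 7.2,
  "components": [
    {"chemical": "caesium aspartate", "mM": 135},
    {"chemical": "CsCl", "mM": 30},
    {"chemical": "TEA-chloride", "mM": 20},
    {"chemical": "MgCl2", "mM": 2.0},
    {"chemical": "Tris-ATP", "mM": 5.0},
    {"chemical": "Na2-GTP", "mM": 0.1},
    {"chemical": "EGTA", "mM": 5.0},
    {"chemical": "Hepes", "mM": 5.0}
  ]
}
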