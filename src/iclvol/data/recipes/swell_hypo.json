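{
  "name": "swell_hypo",
  "temperature_K": 310.15,
  "pH": 7.4,
  "components": [
    {"chemical": "NaCl", "mM": 90},
    {"chemical": "KCl", "mM": 5.4},
    {"chemical": "CaCl2", "mM": 1.8},
    {"chemical": "MgCl2", "mM": 0.5},
    {"chemical": "NaH2PO4", "mM": 0.33},
    {"chemical": "glucose", "mM": 5.5},
    {"chemical": "Hepes", "mM": 5.0}
  ]
}
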