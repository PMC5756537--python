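{
  "name": "bath_iso",
  "temperature_K": 310.15,
  "pH": 7.4,
  "components": [
    {"chemical": "mannitol", "mM": 150},
    {"chemical": "NaCl", "mM": 100},
    {"chemical": "MgCl2", "mM": 2.0},
    {"chemical": "BaCl2", "mM": 2.0},
    {"chemical": "GdCl3", "mM": 0.03},
    {"chemical": "glucose", "mM": 5.5},
    {"chemical": "Hepes", "mM": 10}
  ]
}
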