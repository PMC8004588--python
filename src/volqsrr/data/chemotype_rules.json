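[
  {
    "name": "E-caryophyllene + caryophyllene oxide",
    "markers": {"E-caryophyllene": [15.6, 45.8], "caryophyllene oxide": [5.0, 100.0]},
    "priority": 1
  },
  {
    "name": "E-caryophyllene",
    "markers": {"E-caryophyllene": [15.6, 45.8]},
    "priority": 2
  },
  {
    "name": "beta-bisabolene",
    "markers": {"beta-bisabolene": [13.1, 28.3]},
    "priority": 3
  },
  {
    "name": "alpha-pinene",
    "markers": {"alpha-pinene": [21.5, 28.9]},
    "priority": 4
  },
  {
    "name": "beta-farnesene",
    "markers": {"beta-farnesene": [20.2, 24.2]},
    "priority": 5
  }
]
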