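{
  "comment": "Tunnel starting-point residues (chain:resnum) of the three ranked E-region binding sites.",
  "site1": [
    ["N", 48], ["N", 49], ["N", 50], ["N", 51],
    ["P", 19], ["P", 20], ["P", 21], ["P", 22],
    ["O", 81], ["O", 83], ["O", 84], ["O", 85], ["O", 86],
    ["Q", 48], ["Q", 49], ["Q", 50], ["Q", 51],
    ["S", 19], ["S", 20], ["S", 21], ["S", 22],
    ["R", 81], ["R", 83], ["R", 84], ["R", 85], ["R", 86]
  ],
  "site2": [
    ["O", 76], ["O", 78], ["O", 79],
    ["Q", 54], ["Q", 57], ["Q", 60], ["Q", 61],
    ["S", 26], ["S", 29], ["S", 30], ["S", 33], ["S", 34]
  ],
  "site3": [
    ["N", 54], ["N", 57], ["N", 60], ["N", 61],
    ["P", 26], ["P", 29], ["P", 30], ["P", 33],
    ["O", 64],
    ["R", 76], ["R", 78], ["R", 79]
  ]
}
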