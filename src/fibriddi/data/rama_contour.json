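{
  "comment": "Coarse polygonal Ramachandran contour table, general case (Gly/Pro lumped in). Polygons are closed (phi, psi) vertex lists in degrees. 'favored' polygons are strict subsets of 'allowed' ones.",
  "favored": {
    "beta": [[-170.0, 80.0], [-45.0, 80.0], [-45.0, 178.0], [-170.0, 178.0]],
    "beta-wrap": [[-170.0, -180.0], [-45.0, -180.0], [-45.0, -170.0], [-170.0, -170.0]],
    "alpha": [[-160.0, -70.0], [-45.0, -70.0], [-45.0, -5.0], [-160.0, -5.0]],
    "left-handed": [[30.0, 0.0], [90.0, 0.0], [90.0, 80.0], [30.0, 80.0]]
  },
  "allowed": {
    "beta": [[-180.0, 60.0], [-20.0, 60.0], [-20.0, 180.0], [-180.0, 180.0]],
    "beta-wrap": [[-180.0, -180.0], [-20.0, -180.0], [-20.0, -150.0], [-180.0, -150.0]],
    "alpha": [[-180.0, -90.0], [-20.0, -90.0], [-20.0, 60.0], [-180.0, 60.0]],
    "left-handed": [[20.0, -30.0], [110.0, -30.0], [110.0, 100.0], [20.0, 100.0]]
  }
}
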