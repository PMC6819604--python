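{
 "compositions": [
  [
   0.041666666666666664,
   0.20833333333333334,
   0.041666666666666664,
   0.20833333333333334,
   0.16666666666666666,
   0.3333333333333333
  ],
  [
   0.08333333333333333,
   0.16666666666666666,
   0.16666666666666666,
   0.08333333333333333,
   0.16666666666666666,
   0.3333333333333333
  ],
  [
   0.125,
   0.125,
   0.20833333333333334,
   0.041666666666666664,
   0.16666666666666666,
   0.3333333333333333
  ],
  [
   0.16666666666666666,
   0.08333333333333333,
   0.125,
   0.125,
   0.16666666666666666,
   0.3333333333333333
  ],
  [
   0.20833333333333334,
   0.041666666666666664,
   0.041666666666666664,
   0.20833333333333334,
   0.16666666666666666,
   0.3333333333333333
  ]
 ],
 "ordering": [
  1,
  2,
  3,
  4,
  5
 ],
 "progression_features": [
  "inc",
  "dec",
  "bump",
  "dip"
 ],
 "trajectories": {}
}
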