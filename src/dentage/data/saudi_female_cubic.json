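{
 "name": "saudi_female_cubic",
 "sex": "female",
 "variant": "poly",
 "coefficients": {
  "b0": -8.2685196546024,
  "b1": 0.7571223721081531,
  "b2": -0.013256109491418639,
  "b3": 7.78170035903497e-05
 },
 "coverage": {
  "score": [
   27.2,
   100.0
  ]
 },
 "provenance": "least-squares cubic refit from the published Saudi prediction table; published rounded coefficients retained as metadata",
 "published_coefficients": {
  "b0": -8.269,
  "b1": 0.757,
  "b2": -0.013,
  "b3": 7.782e-05
 }
}
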