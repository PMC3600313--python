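{
 "name": "saudi_male_cubic",
 "sex": "male",
 "variant": "poly",
 "coefficients": {
  "b0": -7.423826855433168,
  "b1": 0.7410385143100273,
  "b2": -0.01315701157795654,
  "b3": 7.862837054784212e-05
 },
 "coverage": {
  "score": [
   25.8,
   98.8
  ]
 },
 "provenance": "least-squares cubic refit from the published Saudi prediction table; published rounded coefficients retained as metadata",
 "published_coefficients": {
  "b0": -7.424,
  "b1": 0.741,
  "b2": -0.013,
  "b3": 7.863e-05
 }
}
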