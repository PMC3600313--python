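{
 "name": "demo_alemran_male",
 "sex": "male",
 "variant": "table",
 "pairs": [
  [
   0.0,
   2.65
  ],
  [
   5.0,
   2.98625
  ],
  [
   10.0,
   3.345
  ],
  [
   15.0,
   3.72625
  ],
  [
   20.0,
   4.13
  ],
  [
   25.0,
   4.55625
  ],
  [
   30.0,
   5.005
  ],
  [
   35.0,
   5.47625
  ],
  [
   40.0,
   5.97
  ],
  [
   45.0,
   6.48625
  ],
  [
   50.0,
   7.025
  ],
  [
   55.0,
   7.58625
  ],
  [
   60.0,
   8.17
  ],
  [
   65.0,
   8.77625
  ],
  [
   70.0,
   9.405
  ],
  [
   75.0,
   10.05625
  ],
  [
   80.0,
   10.73
  ],
  [
   85.0,
   11.42625
  ],
  [
   90.0,
   12.145
  ],
  [
   95.0,
   12.88625
  ],
  [
   100.0,
   13.65
  ]
 ],
 "provenance": "synthetic demo values; placeholder, not the published standard",
 "coverage": {
  "age": [
   7.5,
   17.0
  ]
 }
}
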