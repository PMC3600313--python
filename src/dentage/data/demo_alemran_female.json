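{
 "name": "demo_alemran_female",
 "sex": "female",
 "variant": "table",
 "pairs": [
  [
   0.0,
   2.65
  ],
  [
   5.0,
   3.00125
  ],
  [
   10.0,
   3.375
  ],
  [
   15.0,
   3.77125
  ],
  [
   20.0,
   4.19
  ],
  [
   25.0,
   4.63125
  ],
  [
   30.0,
   5.095
  ],
  [
   35.0,
   5.58125
  ],
  [
   40.0,
   6.09
  ],
  [
   45.0,
   6.62125
  ],
  [
   50.0,
   7.175
  ],
  [
   55.0,
   7.75125
  ],
  [
   60.0,
   8.35
  ],
  [
   65.0,
   8.97125
  ],
  [
   70.0,
   9.615
  ],
  [
   75.0,
   10.28125
  ],
  [
   80.0,
   10.97
  ],
  [
   85.0,
   11.68125
  ],
  [
   90.0,
   12.415
  ],
  [
   95.0,
   13.17125
  ],
  [
   100.0,
   13.95
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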