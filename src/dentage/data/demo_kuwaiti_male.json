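{
 "name": "demo_kuwaiti_male",
 "sex": "male",
 "variant": "table",
 "pairs": [
  [
   0.0,
   2.55
  ],
  [
   5.0,
   2.88625
  ],
  [
   10.0,
   3.245
  ],
  [
   15.0,
   3.62625
  ],
  [
   20.0,
   4.03
  ],
  [
   25.0,
   4.45625
  ],
  [
   30.0,
   4.905
  ],
  [
   35.0,
   5.37625
  ],
  [
   40.0,
   5.87
  ],
  [
   45.0,
   6.38625
  ],
  [
   50.0,
   6.925
  ],
  [
   55.0,
   7.48625
  ],
  [
   60.0,
   8.07
  ],
  [
   65.0,
   8.67625
  ],
  [
   70.0,
   9.305
  ],
  [
   75.0,
   9.95625
  ],
  [
   80.0,
   10.63
  ],
  [
   85.0,
   11.32625
  ],
  [
   90.0,
   12.045
  ],
  [
   95.0,
   12.78625
  ],
  [
   100.0,
   13.55
  ]
 ],
 "provenance": "synthetic demo values; placeholder, not the published standard"
}
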