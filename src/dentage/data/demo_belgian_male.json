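{
 "name": "demo_belgian_male",
 "sex": "male",
 "variant": "table",
 "pairs": [
  [
   0.0,
   4.4
  ],
  [
   5.0,
   4.73625
  ],
  [
   10.0,
   5.095
  ],
  [
   15.0,
   5.47625
  ],
  [
   20.0,
   5.88
  ],
  [
   25.0,
   6.30625
  ],
  [
   30.0,
   6.755
  ],
  [
   35.0,
   7.22625
  ],
  [
   40.0,
   7.72
  ],
  [
   45.0,
   8.23625
  ],
  [
   50.0,
   8.775
  ],
  [
   55.0,
   9.33625
  ],
  [
   60.0,
   9.92
  ],
  [
   65.0,
   10.52625
  ],
  [
   70.0,
   11.155
  ],
  [
   75.0,
   11.80625
  ],
  [
   80.0,
   12.48
  ],
  [
   85.0,
   13.17625
  ],
  [
   90.0,
   13.895
  ],
  [
   95.0,
   14.63625
  ],
  [
   100.0,
   15.4
  ]
 ],
 "provenance": "synthetic demo values; placeholder, not the published standard"
}
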