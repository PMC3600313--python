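{
 "name": "demo_french_canadian_male",
 "sex": "male",
 "variant": "table",
 "pairs": [
  [
   0.0,
   3.0
  ],
  [
   5.0,
   3.33625
  ],
  [
   10.0,
   3.695
  ],
  [
   15.0,
   4.07625
  ],
  [
   20.0,
   4.48
  ],
  [
   25.0,
   4.90625
  ],
  [
   30.0,
   5.355
  ],
  [
   35.0,
   5.82625
  ],
  [
   40.0,
   6.32
  ],
  [
   45.0,
   6.83625
  ],
  [
   50.0,
   7.375
  ],
  [
   55.0,
   7.93625
  ],
  [
   60.0,
   8.52
  ],
  [
   65.0,
   9.12625
  ],
  [
   70.0,
   9.755
  ],
  [
   75.0,
   10.40625
  ],
  [
   80.0,
   11.08
  ],
  [
   85.0,
   11.77625
  ],
  [
   90.0,
   12.495
  ],
  [
   95.0,
   13.23625
  ],
  [
   100.0,
   14.0
  ]
 ],
 "provenance": "synthetic demo values; placeholder, not the published standard"
}
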