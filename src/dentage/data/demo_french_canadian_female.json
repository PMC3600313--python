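{
 "name": "demo_french_canadian_female",
 "sex": "female",
 "variant": "table",
 "pairs": [
  [
   0.0,
   3.0
  ],
  [
   5.0,
   3.35125
  ],
  [
   10.0,
   3.725
  ],
  [
   15.0,
   4.12125
  ],
  [
   20.0,
   4.54
  ],
  [
   25.0,
   4.98125
  ],
  [
   30.0,
   5.445
  ],
  [
   35.0,
   5.93125
  ],
  [
   40.0,
   6.44
  ],
  [
   45.0,
   6.97125
  ],
  [
   50.0,
   7.525
  ],
  [
   55.0,
   8.10125
  ],
  [
   60.0,
   8.7
  ],
  [
   65.0,
   9.32125
  ],
  [
   70.0,
   9.965
  ],
  [
   75.0,
   10.63125
  ],
  [
   80.0,
   11.32
  ],
  [
   85.0,
   12.03125
  ],
  [
   90.0,
   12.765
  ],
  [
   95.0,
   13.52125
  ],
  [
   100.0,
   14.3
  ]
 ],
 "provenance": "synthetic demo values; placeholder, not the published standard"
}
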