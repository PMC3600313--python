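{
 "name": "demo_kuwaiti_female",
 "sex": "female",
 "variant": "table",
 "pairs": [
  [
   0.0,
   2.55
  ],
  [
   5.0,
   2.90125
  ],
  [
   10.0,
   3.275
  ],
  [
   15.0,
   3.67125
  ],
  [
   20.0,
   4.09
  ],
  [
   25.0,
   4.53125
  ],
  [
   30.0,
   4.995
  ],
  [
   35.0,
   5.48125
  ],
  [
   40.0,
   5.99
  ],
  [
   45.0,
   6.52125
  ],
  [
   50.0,
   7.075
  ],
  [
   55.0,
   7.65125
  ],
  [
   60.0,
   8.25
  ],
  [
   65.0,
   8.87125
  ],
  [
   70.0,
   9.515
  ],
  [
   75.0,
   10.18125
  ],
  [
   80.0,
   10.87
  ],
  [
   85.0,
   11.58125
  ],
  [
   90.0,
   12.315
  ],
  [
   95.0,
   13.07125
  ],
  [
   100.0,
   13.85
  ]
 ],
 "provenance": "synthetic demo values; placeholder, not the published standard"
}
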