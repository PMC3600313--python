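{
 "name": "demo_belgian_female",
 "sex": "female",
 "variant": "table",
 "pairs": [
  [
   0.0,
   4.4
  ],
  [
   5.0,
   4.75125
  ],
  [
   10.0,
   5.125
  ],
  [
   15.0,
   5.52125
  ],
  [
   20.0,
   5.94
  ],
  [
   25.0,
   6.38125
  ],
  [
   30.0,
   6.845
  ],
  [
   35.0,
   7.33125
  ],
  [
   40.0,
   7.84
  ],
  [
   45.0,
   8.37125
  ],
  [
   50.0,
   8.925
  ],
  [
   55.0,
   9.50125
  ],
  [
   60.0,
   10.1
  ],
  [
   65.0,
   10.72125
  ],
  [
   70.0,
   11.365
  ],
  [
   75.0,
   12.03125
  ],
  [
   80.0,
   12.72
  ],
  [
   85.0,
   13.43125
  ],
  [
   90.0,
   14.165
  ],
  [
   95.0,
   14.92125
  ],
  [
   100.0,
   15.7
  ]
 ],
 "provenance": "synthetic demo values; placeholder, not the published standard"
}
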