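{
 "name": "saudi_female",
 "sex": "female",
 "variant": "table",
 "pairs": [
  [
   27.2,
   4.08377
  ],
  [
   27.4,
   4.12524
  ],
  [
   30.2,
   4.64983
  ],
  [
   30.3,
   4.66671
  ],
  [
   33.6,
   5.15701
  ],
  [
   35.1,
   5.3399
  ],
  [
   35.9,
   5.42803
  ],
  [
   39.4,
   5.74337
  ],
  [
   45.2,
   6.05669
  ],
  [
   47.9,
   6.13495
  ],
  [
   50.8,
   6.18559
  ],
  [
   52.0,
   6.19902
  ],
  [
   59.4,
   6.24147
  ],
  [
   60.5,
   6.2489
  ],
  [
   61.2,
   6.25469
  ],
  [
   63.6,
   6.28319
  ],
  [
   63.7,
   6.28473
  ],
  [
   64.5,
   6.29826
  ],
  [
   65.0,
   6.30787
  ],
  [
   65.5,
   6.31843
  ],
  [
   67.8,
   6.38106
  ],
  [
   67.9,
   6.38436
  ],
  [
   71.3,
   6.53046
  ],
  [
   72.0,
   6.56966
  ],
  [
   77.2,
   6.98061
  ],
  [
   79.3,
   7.21594
  ],
  [
   79.6,
   7.25324
  ],
  [
   79.9,
   7.29151
  ],
  [
   81.4,
   7.49764
  ],
  [
   82.1,
   7.60258
  ],
  [
   82.7,
   7.69714
  ],
  [
   82.9,
   7.72963
  ],
  [
   85.0,
   8.10086
  ],
  [
   86.3,
   8.35951
  ],
  [
   87.1,
   8.53019
  ],
  [
   87.2,
   8.55216
  ],
  [
   87.4,
   8.59652
  ],
  [
   88.1,
   8.75631
  ],
  [
   88.3,
   8.80327
  ],
  [
   88.4,
   8.82697
  ],
  [
   89.1,
   8.99705
  ],
  [
   89.3,
   9.04699
  ],
  [
   89.5,
   9.09754
  ],
  [
   90.5,
   9.35954
  ],
  [
   91.5,
   9.63728
  ],
  [
   91.7,
   9.69475
  ],
  [
   92.2,
   9.84131
  ],
  [
   92.9,
   10.05345
  ],
  [
   93.7,
   10.30601
  ],
  [
   94.0,
   10.40356
  ],
  [
   94.2,
   10.46946
  ],
  [
   94.4,
   10.53605
  ],
  [
   95.0,
   10.74007
  ],
  [
   95.3,
   10.84448
  ],
  [
   95.7,
   10.98622
  ],
  [
   96.0,
   11.09443
  ],
  [
   96.1,
   11.13086
  ],
  [
   96.3,
   11.20428
  ],
  [
   96.8,
   11.39107
  ],
  [
   97.1,
   11.50539
  ],
  [
   98.6,
   12.10261
  ],
  [
   98.9,
   12.22728
  ],
  [
   100.0,
   12.69963
  ]
 ],
 "provenance": "published Saudi prediction table (calibration study, 2013)"
}
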