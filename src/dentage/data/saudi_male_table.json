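{
 "name": "saudi_male",
 "sex": "male",
 "variant": "table",
 "pairs": [
  [
   25.8,
   4.28746
  ],
  [
   27.5,
   4.63997
  ],
  [
   28.6,
   4.84737
  ],
  [
   30.2,
   5.12152
  ],
  [
   31.4,
   5.30676
  ],
  [
   32.9,
   5.51512
  ],
  [
   43.4,
   6.38282
  ],
  [
   45.1,
   6.4484
  ],
  [
   49.0,
   6.54762
  ],
  [
   50.3,
   6.56851
  ],
  [
   52.0,
   6.58939
  ],
  [
   52.1,
   6.59044
  ],
  [
   52.2,
   6.59147
  ],
  [
   52.8,
   6.5973
  ],
  [
   53.9,
   6.60675
  ],
  [
   56.8,
   6.62817
  ],
  [
   58.9,
   6.64555
  ],
  [
   60.8,
   6.66675
  ],
  [
   65.0,
   6.74862
  ],
  [
   67.0,
   6.81243
  ],
  [
   67.5,
   6.83155
  ],
  [
   67.6,
   6.83554
  ],
  [
   67.7,
   6.83958
  ],
  [
   71.7,
   7.05245
  ],
  [
   73.0,
   7.14604
  ],
  [
   74.0,
   7.22733
  ],
  [
   75.6,
   7.37547
  ],
  [
   77.6,
   7.59454
  ],
  [
   77.7,
   7.60654
  ],
  [
   77.9,
   7.63085
  ],
  [
   79.4,
   7.8268
  ],
  [
   81.3,
   8.11119
  ],
  [
   81.5,
   8.1436
  ],
  [
   82.1,
   8.24375
  ],
  [
   83.5,
   8.49501
  ],
  [
   83.6,
   8.51392
  ],
  [
   84.5,
   8.69009
  ],
  [
   84.9,
   8.77189
  ],
  [
   85.6,
   8.92035
  ],
  [
   85.8,
   8.96403
  ],
  [
   85.9,
   8.98608
  ],
  [
   86.0,
   9.00827
  ],
  [
   87.3,
   9.30993
  ],
  [
   87.9,
   9.45756
  ],
  [
   89.6,
   9.90584
  ],
  [
   90.3,
   10.10369
  ],
  [
   90.4,
   10.1326
  ],
  [
   90.5,
   10.16168
  ],
  [
   91.4,
   10.43079
  ],
  [
   91.6,
   10.49243
  ],
  [
   92.4,
   10.74578
  ],
  [
   93.1,
   10.97653
  ],
  [
   93.4,
   11.07805
  ],
  [
   93.5,
   11.11225
  ],
  [
   93.8,
   11.21591
  ],
  [
   94.1,
   11.32118
  ],
  [
   94.5,
   11.46407
  ],
  [
   94.7,
   11.53661
  ],
  [
   95.3,
   11.75866
  ],
  [
   96.1,
   12.06518
  ],
  [
   96.2,
   12.10434
  ],
  [
   97.0,
   12.42458
  ],
  [
   98.8,
   13.19098
  ]
 ],
 "provenance": "published Saudi prediction table (calibration study, 2013)"
}
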