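{
 "provenance": "printed cohort summary tables of the 2013 Saudi calibration study; group rows give n and mean (sd) of DA-CA in years",
 "table1": {
  "male": {
   "groups": [
    {"group": "4.00-4.99", "n": 7, "ca_mean": 4.62, "ca_sd": 0.23, "da_mean": 5.37, "da_sd": 0.26, "diff_mean": 0.75, "diff_sd": 0.18, "ci": [0.58, 0.93], "p": 0.0},
    {"group": "5.00-5.99", "n": 12, "ca_mean": 5.77, "ca_sd": 0.1, "da_mean": 6.6, "da_sd": 0.8, "diff_mean": 0.83, "diff_sd": 0.79, "ci": [0.33, 1.33], "p": 0.004},
    {"group": "6.00-6.99", "n": 26, "ca_mean": 6.46, "ca_sd": 0.22, "da_mean": 7.5, "da_sd": 0.35, "diff_mean": 1.04, "diff_sd": 0.35, "ci": [0.9, 1.18], "p": 0.0},
    {"group": "7.00-7.99", "n": 28, "ca_mean": 7.43, "ca_sd": 0.25, "da_mean": 8.08, "da_sd": 0.46, "diff_mean": 0.66, "diff_sd": 0.42, "ci": [0.5, 0.82], "p": 0.0},
    {"group": "8.00-8.99", "n": 26, "ca_mean": 8.4, "ca_sd": 0.24, "da_mean": 9.1, "da_sd": 0.83, "diff_mean": 0.7, "diff_sd": 0.98, "ci": [0.29, 1.09], "p": 0.058},
    {"group": "9.00-9.99", "n": 30, "ca_mean": 9.43, "ca_sd": 0.31, "da_mean": 10.4, "da_sd": 0.98, "diff_mean": 0.97, "diff_sd": 0.85, "ci": [0.65, 1.28], "p": 0.0},
    {"group": "10.00-10.99", "n": 30, "ca_mean": 10.54, "ca_sd": 0.33, "da_mean": 11.76, "da_sd": 0.51, "diff_mean": 1.21, "diff_sd": 0.56, "ci": [1.0, 1.42], "p": 0.0},
    {"group": "11.00-11.99", "n": 16, "ca_mean": 11.37, "ca_sd": 0.17, "da_mean": 11.55, "da_sd": 1.09, "diff_mean": 0.17, "diff_sd": 1.05, "ci": [-0.38, 0.73], "p": 0.523},
    {"group": "12.00-12.99", "n": 30, "ca_mean": 12.4, "ca_sd": 0.31, "da_mean": 13.1, "da_sd": 1.27, "diff_mean": 0.69, "diff_sd": 1.18, "ci": [0.25, 1.14], "p": 0.003},
    {"group": "13.00-13.99", "n": 12, "ca_mean": 13.62, "ca_sd": 0.3, "da_mean": 13.5, "da_sd": 0.81, "diff_mean": -0.12, "diff_sd": 0.69, "ci": [-0.56, 0.32], "p": 0.557}
   ],
   "total": {"n": 217, "ca_mean": 9.27, "ca_sd": 2.43, "da_mean": 10.04, "da_sd": 2.44, "diff_mean": 0.76, "diff_sd": 0.85, "ci": [0.65, 0.88], "p": 0.0}
  },
  "female": {
   "groups": [
    {"group": "4.00-4.99", "n": 9, "ca_mean": 4.66, "ca_sd": 0.14, "da_mean": 5.57, "da_sd": 0.68, "diff_mean": 0.9, "diff_sd": 0.72, "ci": [0.34, 1.46], "p": 0.006},
    {"group": "5.00-5.99", "n": 20, "ca_mean": 5.63, "ca_sd": 0.34, "da_mean": 6.9, "da_sd": 0.77, "diff_mean": 1.26, "diff_sd": 0.66, "ci": [0.95, 1.58], "p": 0.0},
    {"group": "6.00-6.99", "n": 22, "ca_mean": 6.35, "ca_sd": 0.28, "da_mean": 7.49, "da_sd": 0.25, "diff_mean": 1.13, "diff_sd": 0.45, "ci": [0.93, 1.33], "p": 0.0},
    {"group": "7.00-7.99", "n": 40, "ca_mean": 7.41, "ca_sd": 0.29, "da_mean": 8.4, "da_sd": 0.83, "diff_mean": 0.98, "diff_sd": 0.69, "ci": [0.76, 1.2], "p": 0.0},
    {"group": "8.00-8.99", "n": 38, "ca_mean": 8.38, "ca_sd": 0.3, "da_mean": 8.8, "da_sd": 0.75, "diff_mean": 0.42, "diff_sd": 0.69, "ci": [0.19, 0.65], "p": 0.001},
    {"group": "9.00-9.99", "n": 24, "ca_mean": 9.42, "ca_sd": 0.3, "da_mean": 9.78, "da_sd": 0.82, "diff_mean": 0.36, "diff_sd": 0.83, "ci": [0.01, 0.71], "p": 0.044},
    {"group": "10.00-10.99", "n": 24, "ca_mean": 10.53, "ca_sd": 0.35, "da_mean": 11.59, "da_sd": 0.61, "diff_mean": 1.05, "diff_sd": 0.7, "ci": [0.75, 1.35], "p": 0.0},
    {"group": "11.00-11.99", "n": 6, "ca_mean": 11.36, "ca_sd": 0.12, "da_mean": 11.9, "da_sd": 0.46, "diff_mean": 0.53, "diff_sd": 0.42, "ci": [0.09, 0.97], "p": 0.026},
    {"group": "12.00-12.99", "n": 12, "ca_mean": 12.45, "ca_sd": 0.26, "da_mean": 13.2, "da_sd": 1.15, "diff_mean": 0.74, "diff_sd": 1.05, "ci": [0.07, 1.41], "p": 0.033},
    {"group": "13.00-13.99", "n": 10, "ca_mean": 13.32, "ca_sd": 0.3, "da_mean": 14.4, "da_sd": 1.17, "diff_mean": 1.08, "diff_sd": 1.06, "ci": [0.31, 1.84], "p": 0.011}
   ],
   "total": {"n": 205, "ca_mean": 8.48, "ca_sd": 2.27, "da_mean": 9.31, "da_sd": 2.3, "diff_mean": 0.83, "diff_sd": 0.78, "ci": [0.72, 0.94], "p": 0.0}
  },
  "combined_total": {"n": 422, "ca_mean": 8.89, "ca_sd": 2.38, "da_mean": 9.69, "da_sd": 2.4, "diff_mean": 0.8, "diff_sd": 0.82, "ci": [0.72, 0.87], "p": 0.0}
 },
 "by_standard": {
  "male": {
   "groups": [
    {"group": "4-5", "n": 7, "french_canadian": [0.75, 0.18], "belgian": [-1.26, 0.53], "kuwaiti": [0.03, 0.17], "saudi": null},
    {"group": "5-6", "n": 12, "french_canadian": [0.82, 0.78], "belgian": [0.11, 1.67], "kuwaiti": [0.04, 0.79], "saudi": null},
    {"group": "6-7", "n": 26, "french_canadian": [1.04, 0.35], "belgian": [1.57, 0.96], "kuwaiti": [0.51, 0.7], "saudi": null},
    {"group": "7-8", "n": 28, "french_canadian": [0.66, 0.42], "belgian": [2.11, 1.01], "kuwaiti": [0.6, 0.69], "saudi": [1.68, 0.0]},
    {"group": "8-9", "n": 26, "french_canadian": [0.69, 0.98], "belgian": [2.81, 1.33], "kuwaiti": [0.85, 0.92], "saudi": [1.22, 0.77]},
    {"group": "9-10", "n": 30, "french_canadian": [0.97, 0.84], "belgian": [3.23, 0.82], "kuwaiti": [0.83, 0.57], "saudi": [0.95, 0.68]},
    {"group": "10-11", "n": 30, "french_canadian": [1.21, 0.56], "belgian": [3.05, 0.48], "kuwaiti": [0.6, 0.48], "saudi": [0.8, 0.43]},
    {"group": "11-12", "n": 16, "french_canadian": [0.17, 1.05], "belgian": [2.14, 0.65], "kuwaiti": [-0.39, 0.62], "saudi": [-0.19, 0.67]},
    {"group": "12-13", "n": 30, "french_canadian": [0.69, 1.18], "belgian": [1.91, 0.53], "kuwaiti": [-0.2, 1.15], "saudi": [-0.19, 0.88]},
    {"group": "13-14", "n": 12, "french_canadian": [-0.12, 0.69], "belgian": [1.2, 0.86], "kuwaiti": [-1.51, 0.63], "saudi": [-1.22, 0.41]}
   ],
   "totals": {
    "french_canadian": {"mean": 0.76, "sd": 0.85, "n": 217},
    "belgian": {"mean": 2.12, "sd": 1.36, "n": 217},
    "kuwaiti": {"mean": 0.3, "sd": 0.96, "n": 217},
    "saudi": {"mean": 0.4, "sd": 1.0, "n": 138}
   },
   "subset_means": {"kuwaiti": 0.3, "saudi": 0.39, "french_canadian": 0.76, "belgian": 2.12}
  },
  "female": {
   "groups": [
    {"group": "4-5", "n": 9, "french_canadian": [0.9, 0.72], "belgian": [-0.36, 1.41], "kuwaiti": [0.62, 0.52], "saudi": null},
    {"group": "5-6", "n": 20, "french_canadian": [1.26, 0.66], "belgian": [1.38, 1.36], "kuwaiti": [0.95, 0.69], "saudi": null},
    {"group": "6-7", "n": 22, "french_canadian": [1.13, 0.45], "belgian": [1.96, 0.85], "kuwaiti": [0.92, 0.62], "saudi": null},
    {"group": "7-8", "n": 40, "french_canadian": [0.98, 0.65], "belgian": [2.82, 1.22], "kuwaiti": [1.24, 0.82], "saudi": [1.51, 0.57]},
    {"group": "8-9", "n": 38, "french_canadian": [0.42, 0.69], "belgian": [2.73, 0.83], "kuwaiti": [0.76, 0.53], "saudi": [0.9, 0.57]},
    {"group": "9-10", "n": 24, "french_canadian": [0.36, 0.83], "belgian": [2.95, 1.02], "kuwaiti": [0.56, 0.67], "saudi": [0.6, 0.65]},
    {"group": "10-11", "n": 24, "french_canadian": [1.05, 0.7], "belgian": [3.28, 0.68], "kuwaiti": [0.5, 0.9], "saudi": [0.76, 0.56]},
    {"group": "11-12", "n": 6, "french_canadian": [0.53, 0.42], "belgian": [2.68, 0.04], "kuwaiti": [0.15, 0.34], "saudi": [0.17, 0.27]},
    {"group": "12-13", "n": 12, "french_canadian": [0.74, 1.05], "belgian": [2.03, 0.47], "kuwaiti": [0.25, 1.35], "saudi": [-0.09, 0.98]},
    {"group": "13-14", "n": 10, "french_canadian": [1.08, 1.06], "belgian": [1.79, 0.41], "kuwaiti": [-0.15, 1.34], "saudi": [0.88, 1.43]}
   ],
   "totals": {
    "french_canadian": {"mean": 0.83, "sd": 0.78, "n": 205},
    "belgian": {"mean": 2.4, "sd": 1.26, "n": 205},
    "kuwaiti": {"mean": 0.74, "sd": 0.85, "n": 205},
    "saudi": {"mean": 0.84, "sd": 0.84, "n": 132}
   },
   "subset_means": {"kuwaiti": 0.74, "french_canadian": 0.83, "saudi": 0.84, "belgian": 2.4}
  }
 }
}
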