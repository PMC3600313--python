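{
 "sex": "female",
 "provenance": "synthetic demo weight table (placeholder, not literature values)",
 "weights": {
  "I1": {
   "0": 0.0,
   "A": 0.75,
   "B": 1.875,
   "C": 3.25,
   "D": 4.875,
   "E": 6.75,
   "F": 8.75,
   "G": 10.625,
   "H": 12.5
  },
  "I2": {
   "0": 0.0,
   "A": 0.75,
   "B": 1.875,
   "C": 3.25,
   "D": 4.875,
   "E": 6.75,
   "F": 8.75,
   "G": 10.625,
   "H": 12.5
  },
  "C": {
   "0": 0.0,
   "A": 0.81,
   "B": 2.025,
   "C": 3.51,
   "D": 5.265,
   "E": 7.29,
   "F": 9.45,
   "G": 11.475,
   "H": 13.5
  },
  "PM1": {
   "0": 0.0,
   "A": 0.93,
   "B": 2.325,
   "C": 4.03,
   "D": 6.045,
   "E": 8.37,
   "F": 10.85,
   "G": 13.175,
   "H": 15.5
  },
  "PM2": {
   "0": 0.0,
   "A": 0.93,
   "B": 2.325,
   "C": 4.03,
   "D": 6.045,
   "E": 8.37,
   "F": 10.85,
   "G": 13.175,
   "H": 15.5
  },
  "M1": {
   "0": 0.0,
   "A": 0.93,
   "B": 2.325,
   "C": 4.03,
   "D": 6.045,
   "E": 8.37,
   "F": 10.85,
   "G": 13.175,
   "H": 15.5
  },
  "M2": {
   "0": 0.0,
   "A": 0.9,
   "B": 2.25,
   "C": 3.9,
   "D": 5.85,
   "E": 8.1,
   "F": 10.5,
   "G": 12.75,
   "H": 15.0
  }
 }
}
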