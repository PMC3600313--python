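{
 "sex": "male",
 "provenance": "synthetic demo weight table (placeholder, not literature values)",
 "weights": {
  "I1": {
   "0": 0.0,
   "A": 0.6,
   "B": 1.56,
   "C": 2.76,
   "D": 4.2,
   "E": 6.0,
   "F": 7.92,
   "G": 9.96,
   "H": 12.0
  },
  "I2": {
   "0": 0.0,
   "A": 0.65,
   "B": 1.69,
   "C": 2.99,
   "D": 4.55,
   "E": 6.5,
   "F": 8.58,
   "G": 10.79,
   "H": 13.0
  },
  "C": {
   "0": 0.0,
   "A": 0.7,
   "B": 1.82,
   "C": 3.22,
   "D": 4.9,
   "E": 7.0,
   "F": 9.24,
   "G": 11.62,
   "H": 14.0
  },
  "PM1": {
   "0": 0.0,
   "A": 0.75,
   "B": 1.95,
   "C": 3.45,
   "D": 5.25,
   "E": 7.5,
   "F": 9.9,
   "G": 12.45,
   "H": 15.0
  },
  "PM2": {
   "0": 0.0,
   "A": 0.8,
   "B": 2.08,
   "C": 3.68,
   "D": 5.6,
   "E": 8.0,
   "F": 10.56,
   "G": 13.28,
   "H": 16.0
  },
  "M1": {
   "0": 0.0,
   "A": 0.75,
   "B": 1.95,
   "C": 3.45,
   "D": 5.25,
   "E": 7.5,
   "F": 9.9,
   "G": 12.45,
   "H": 15.0
  },
  "M2": {
   "0": 0.0,
   "A": 0.75,
   "B": 1.95,
   "C": 3.45,
   "D": 5.25,
   "E": 7.5,
   "F": 9.9,
   "G": 12.45,
   "H": 15.0
  }
 }
}
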