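{
  "_comment": "Literature-reported spectral-clustering group memberships of the 25 odorants (see odorants.csv for the compound numbering), one partition per spectroscopy: IR (6 groups, silhouette-selected k=6), Raman (6 groups, k=6), VDOS (5 groups, k=5).",
  "IR": {
    "A": [11, 16, 19, 23],
    "B": [1, 2, 4, 5, 6, 7, 9, 10, 13, 14, 24],
    "C": [15, 20],
    "D": [3, 18, 25],
    "E": [17, 21, 22],
    "F": [8, 12]
  },
  "Raman": {
    "A'": [3, 8, 16, 18, 23],
    "B'": [6, 14, 17, 19, 21, 22],
    "C'": [15, 20],
    "D'": [1, 2, 7, 12],
    "E'": [25],
    "F'": [4, 5, 9, 10, 11, 13, 24]
  },
  "VDOS": {
    "A''": [16, 18, 23],
    "B''": [3, 8, 12],
    "C''": [15, 20],
    "D''": [1, 2, 4, 5, 6, 7, 9, 10, 11, 13, 14, 17, 19, 21, 22, 24],
    "E''": [25]
  }
}
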