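{
  "description": "Published source-comparison summary: incidence-factor means and global indices per supplier at each scale and averaged over both (values rounded to 2 decimals as printed).",
  "rows": ["dimensions", "compressibility", "flowability", "lubricity_stability", "lubricity_dosage", "IP", "PP", "IGC"],
  "pilot": {
    "Glenmarck": {"dimensions": 4.82, "compressibility": 3.72, "flowability": 3.3, "lubricity_stability": 9.85, "lubricity_dosage": 5.87, "IP": 0.42, "PP": 5.18, "IGC": 4.93},
    "USV": {"dimensions": 3.01, "compressibility": 4.8, "flowability": 3.01, "lubricity_stability": 9.8, "lubricity_dosage": 9.1, "IP": 0.58, "PP": 5.6, "IGC": 5.33},
    "UQUIFA": {"dimensions": 2.48, "compressibility": 2.24, "flowability": 3.4, "lubricity_stability": 9.71, "lubricity_dosage": 2.79, "IP": 0.25, "PP": 3.91, "IGC": 3.72}
  },
  "industrial": {
    "Glenmarck": {"dimensions": 4.84, "compressibility": 3.75, "flowability": 3.35, "lubricity_stability": 9.85, "lubricity_dosage": 5.9, "IP": 0.42, "PP": 5.21, "IGC": 4.96},
    "USV": {"dimensions": 3.06, "compressibility": 5.02, "flowability": 3.0, "lubricity_stability": 9.81, "lubricity_dosage": 9.33, "IP": 0.58, "PP": 5.7, "IGC": 5.43},
    "UQUIFA": {"dimensions": 2.46, "compressibility": 2.34, "flowability": 3.45, "lubricity_stability": 9.76, "lubricity_dosage": 2.86, "IP": 0.25, "PP": 3.96, "IGC": 3.77}
  },
  "average": {
    "Glenmarck": {"dimensions": 4.83, "compressibility": 3.73, "flowability": 3.33, "lubricity_stability": 9.85, "lubricity_dosage": 5.89, "IP": 0.42, "PP": 5.19, "IGC": 4.94},
    "USV": {"dimensions": 3.03, "compressibility": 4.91, "flowability": 3.0, "lubricity_stability": 9.8, "lubricity_dosage": 9.22, "IP": 0.58, "PP": 5.65, "IGC": 5.38},
    "UQUIFA": {"dimensions": 2.47, "compressibility": 2.29, "flowability": 3.42, "lubricity_stability": 9.74, "lubricity_dosage": 2.82, "IP": 0.25, "PP": 3.93, "IGC": 3.75}
  }
}
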