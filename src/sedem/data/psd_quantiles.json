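{
  "description": "Published laser-diffraction particle-size quantiles (volume-weighted, micrometres) and distribution-breadth ratio F' = D90/D10 per supplier.",
  "columns": ["D10", "D50", "D90", "Fprime"],
  "sources": {
    "Glenmarck": [13.053, 59.635, 163.493, 12.525],
    "USV": [4.715, 13.396, 51.339, 10.888],
    "UQUIFA": [2.813, 8.865, 30.443, 10.822]
  }
}
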