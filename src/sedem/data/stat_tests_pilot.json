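{
  "description": "Published batch-reproducibility tests on the pilot-scale replicate radii: Brown-Forsythe (median-centred Levene) p-value, one-way ANOVA F-ratio and p-value, grouped by batch within each source. null = not testable (all values identical).",
  "columns": ["levene_p", "anova_F", "anova_p"],
  "sources": {
    "Glenmarck": {
      "Da": [0.5787, 0.01, 0.9934],
      "Dc": [0.9796, 1.19, 0.3676],
      "Ie": [0.4394, 1.74, 0.2529],
      "IC": [0.6607, 3.02, 0.1236],
      "Icd": [0.3422, 1.39, 0.3184],
      "IH": [0.6493, 2.73, 0.1438],
      "alpha": [0.4561, 2.47, 0.1649],
      "t": [null, null, null],
      "HR": [0.2506, 2.7, 0.1454],
      "H": [1.0, 0.33, 0.729],
      "Pf": [0.6631, 4.74, 0.0582],
      "Itheta": [0.9055, 0.14, 0.8752],
      "PP": [0.4996, 0.04, 0.959],
      "IGC": [0.4996, 0.04, 0.959]
    },
    "USV": {
      "Da": [0.6164, 1.03, 0.4114],
      "Dc": [0.822, 0.97, 0.4317],
      "Ie": [0.6907, 1.83, 0.2401],
      "IC": [0.6452, 1.6, 0.2779],
      "Icd": [null, null, null],
      "IH": [0.0192, 1.6, 0.2783],
      "alpha": [0.7526, 1.71, 0.2589],
      "t": [null, null, null],
      "HR": [0.3694, 0.45, 0.6589],
      "H": [0.1537, 2.38, 0.1729],
      "Pf": [0.8115, 1.65, 0.268],
      "Itheta": [0.9077, 2.27, 0.1846],
      "PP": [0.6293, 0.18, 0.8389],
      "IGC": [0.6293, 0.18, 0.8389]
    },
    "UQUIFA": {
      "Da": [0.9302, 2.97, 0.1267],
      "Dc": [0.946, 0.66, 0.5524],
      "Ie": [0.6047, 0.91, 0.4512],
      "IC": [0.7681, 0.61, 0.5728],
      "Icd": [null, null, null],
      "IH": [0.7767, 0.61, 0.5728],
      "alpha": [0.6188, 1.87, 0.2331],
      "t": [null, null, null],
      "HR": [0.8418, 0.17, 0.8487],
      "H": [0.5748, 0.2, 0.8249],
      "Pf": [0.9751, 1.41, 0.3149],
      "Itheta": [0.822, 2.01, 0.2143],
      "PP": [0.439, 0.23, 0.7989],
      "IGC": [0.439, 0.23, 0.7989]
    }
  }
}
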