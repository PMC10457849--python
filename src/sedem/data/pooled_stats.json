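{
  "description": "Published pooled descriptive statistics of the nine (pilot, industrial) or eighteen (pooled) replicate radii per source: [mean, variance (n-1), standard deviation (n-1), CV%]. CV is null where the mean is zero.",
  "stat_order": ["mean", "variance", "sd", "cv_pct"],
  "pilot": {
    "Glenmarck": {
      "Da": [4.1767, 0.0038, 0.0616, 1.4759],
      "Dc": [5.4589, 0.0071, 0.084, 1.5393],
      "Ie": [4.6871, 0.0498, 0.2232, 4.763],
      "IC": [4.6966, 0.0365, 0.1912, 4.0702],
      "Icd": [1.7767, 0.0338, 0.1839, 10.3527],
      "IH": [8.4646, 0.0066, 0.0812, 0.9599],
      "alpha": [1.4387, 0.0758, 0.2753, 19.1339],
      "t": [0.0, 0.0, 0.0, null],
      "HR": [9.7052, 0.0087, 0.0933, 0.961],
      "H": [9.9928, 0.0, 0.0044, 0.0441],
      "Pf": [7.675, 0.0217, 0.1472, 1.9173],
      "Itheta": [4.0667, 0.1869, 0.4323, 10.6301],
      "PP": [5.1782, 0.0011, 0.0338, 0.6527],
      "IGC": [4.9297, 0.001, 0.0322, 0.6527]
    },
    "USV": {
      "Da": [2.5356, 0.003, 0.0548, 2.1612],
      "Dc": [3.4844, 0.0097, 0.0985, 2.8269],
      "Ie": [8.9466, 0.1772, 0.4209, 4.7046],
      "IC": [5.4425, 0.0577, 0.2401, 4.4119],
      "Icd": [0.0, 0.0, 0.0, 0.0],
      "IH": [8.129, 0.0134, 0.1159, 1.4255],
      "alpha": [0.8913, 0.066, 0.2568, 28.8146],
      "t": [0.0, 0.0, 0.0, null],
      "HR": [9.6142, 0.0026, 0.0507, 0.527],
      "H": [9.9904, 0.0002, 0.0152, 0.1524],
      "Pf": [9.3496, 0.0192, 0.1384, 1.4802],
      "Itheta": [8.85, 0.3063, 0.5534, 6.2531],
      "PP": [5.6028, 0.0037, 0.0611, 1.0904],
      "IGC": [5.3339, 0.0034, 0.0582, 1.0904]
    },
    "UQUIFA": {
      "Da": [2.32, 0.0019, 0.0433, 1.8664],
      "Dc": [2.6378, 0.0035, 0.0595, 2.257],
      "Ie": [4.3239, 0.2645, 0.5143, 11.8939],
      "IC": [2.4062, 0.0771, 0.2777, 11.5428],
      "Icd": [0.0, 0.0, 0.0, 0.0],
      "IH": [9.3149, 0.0079, 0.0887, 0.9525],
      "alpha": [0.8706, 0.1319, 0.3632, 41.7191],
      "t": [0.0, 0.0, 0.0, null],
      "HR": [9.434, 0.1429, 0.378, 4.0072],
      "H": [9.9775, 0.0001, 0.0084, 0.0843],
      "Pf": [3.1572, 0.1623, 0.4029, 12.7616],
      "Itheta": [2.4278, 0.0526, 0.2293, 9.444],
      "PP": [3.9058, 0.0023, 0.0483, 1.2372],
      "IGC": [3.7184, 0.0021, 0.046, 1.2372]
    }
  },
  "industrial": {
    "Glenmarck": {
      "Da": [4.2022, 0.0014, 0.038, 0.9044],
      "Dc": [5.4798, 0.0048, 0.0692, 1.2637],
      "Ie": [4.6226, 0.0326, 0.1805, 3.9054],
      "IC": [4.6615, 0.0284, 0.1686, 3.6175],
      "Icd": [1.9572, 0.0226, 0.1502, 7.6747],
      "IH": [8.4798, 0.0051, 0.0713, 0.8403],
      "alpha": [1.5681, 0.1422, 0.3771, 24.0471],
      "t": [0.0, 0.0, 0.0, null],
      "HR": [9.7051, 0.0054, 0.0737, 0.7591],
      "H": [9.9929, 0.0, 0.0042, 0.0416],
      "Pf": [7.6316, 0.0286, 0.1692, 2.2166],
      "Itheta": [4.1722, 0.0744, 0.2728, 6.5396],
      "PP": [5.2061, 0.0004, 0.0211, 0.4044],
      "IGC": [4.9562, 0.0004, 0.02, 0.4044]
    },
    "USV": {
      "Da": [2.5544, 0.0027, 0.0522, 2.0446],
      "Dc": [3.5556, 0.0054, 0.0735, 2.0673],
      "Ie": [9.4257, 0.2931, 0.5414, 5.7434],
      "IC": [5.6291, 0.0677, 0.2602, 4.6221],
      "Icd": [0.0, 0.0, 0.0, 0.0],
      "IH": [8.0395, 0.0159, 0.126, 1.5667],
      "alpha": [0.9672, 0.051, 0.2259, 23.3535],
      "t": [0.0, 0.0, 0.0, null],
      "HR": [9.6291, 0.0026, 0.0508, 0.5271],
      "H": [9.9823, 0.0003, 0.0161, 0.1617],
      "Pf": [9.4299, 0.0073, 0.0852, 0.9033],
      "Itheta": [9.2389, 0.2436, 0.4936, 5.3423],
      "PP": [5.7043, 0.0049, 0.07, 1.2279],
      "IGC": [5.4305, 0.0044, 0.0667, 1.2279]
    },
    "UQUIFA": {
      "Da": [2.2967, 0.0016, 0.0406, 1.7687],
      "Dc": [2.6244, 0.0029, 0.0536, 2.044],
      "Ie": [4.5299, 0.1599, 0.3998, 8.8265],
      "IC": [2.4959, 0.0452, 0.2125, 8.5151],
      "Icd": [0.0, 0.0, 0.0, 0.0],
      "IH": [9.2863, 0.005, 0.0705, 0.7595],
      "alpha": [1.0722, 0.0809, 0.2844, 26.5214],
      "t": [0.0, 0.0, 0.0, null],
      "HR": [9.5498, 0.0388, 0.197, 2.0625],
      "H": [9.9793, 0.0001, 0.0084, 0.0841],
      "Pf": [3.3907, 0.0712, 0.2667, 7.8669],
      "Itheta": [2.3206, 0.119, 0.345, 14.8681],
      "PP": [3.9621, 0.0045, 0.0672, 1.6971],
      "IGC": [3.772, 0.0041, 0.064, 1.6971]
    }
  },
  "pooled": {
    "Glenmarck": {
      "Da": [4.1894, 0.0026, 0.0514, 1.2266],
      "Dc": [5.4693, 0.0057, 0.0755, 1.3798],
      "Ie": [4.6549, 0.0399, 0.1997, 4.2907],
      "IC": [4.679, 0.0309, 0.1758, 3.7571],
      "Icd": [1.8669, 0.0352, 0.1875, 10.0448],
      "IH": [8.4722, 0.0056, 0.0745, 0.8798],
      "alpha": [1.5034, 0.107, 0.3271, 21.7591],
      "t": [0.0, 0.0, 0.0, null],
      "HR": [9.7052, 0.0066, 0.0815, 0.8401],
      "H": [9.9928, 0.0, 0.0042, 0.0416],
      "Pf": [7.6533, 0.0242, 0.1554, 2.0307],
      "Itheta": [4.1194, 0.1259, 0.3549, 8.6142],
      "PP": [5.1922, 0.001, 0.0308, 0.5941],
      "IGC": [4.9429, 0.0009, 0.0294, 0.5941]
    },
    "USV": {
      "Da": [2.545, 0.0028, 0.0528, 2.0759],
      "Dc": [3.52, 0.0084, 0.0919, 2.611],
      "Ie": [9.1861, 0.282, 0.5311, 5.7812],
      "IC": [5.5358, 0.0682, 0.2612, 4.7177],
      "Icd": [0.0, 0.0, 0.0, 0.0],
      "IH": [8.0842, 0.0159, 0.1261, 1.56],
      "alpha": [0.9292, 0.0566, 0.2378, 25.5959],
      "t": [0.0, 0.0, 0.0, null],
      "HR": [9.6217, 0.0025, 0.0498, 0.5174],
      "H": [9.9864, 0.0002, 0.0158, 0.158],
      "Pf": [9.3898, 0.0141, 0.1189, 1.2662],
      "Itheta": [9.0444, 0.2988, 0.5466, 6.0437],
      "PP": [5.6536, 0.0068, 0.0824, 1.4578],
      "IGC": [5.3822, 0.0062, 0.0785, 1.4578]
    },
    "UQUIFA": {
      "Da": [2.3083, 0.0018, 0.0425, 1.8395],
      "Dc": [2.6311, 0.0031, 0.0554, 2.1056],
      "Ie": [4.4269, 0.2109, 0.4593, 10.3744],
      "IC": [2.4511, 0.0597, 0.2443, 9.9675],
      "Icd": [0.0, 0.0, 0.0, 0.0],
      "IH": [9.3006, 0.0063, 0.0791, 0.8509],
      "alpha": [0.9714, 0.1109, 0.333, 34.2803],
      "t": [0.0, 0.0, 0.0, null],
      "HR": [9.4919, 0.0891, 0.2984, 3.144],
      "H": [9.9784, 0.0001, 0.0082, 0.0822],
      "Pf": [3.274, 0.1243, 0.3526, 10.7691],
      "Itheta": [2.3742, 0.0838, 0.2895, 12.1931],
      "PP": [3.934, 0.0041, 0.0638, 1.6209],
      "IGC": [3.7452, 0.0037, 0.0607, 1.6209]
    }
  }
}
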