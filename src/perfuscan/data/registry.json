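{
  "perfusates": [
    {
      "name": "232H",
      "nature": "lipophilic",
      "mu20": 2.9, "A_visc": -0.11, "B_visc": -0.0003, "rse_visc": 0.0055,
      "T1_23": 729.6, "A_T1": 24.8, "B_T1": 0.53, "rse_T1": 7.2,
      "T2_23": 233.6, "A_T2": 2.7, "B_T2": -0.04, "rse_T2": 9.7
    },
    {
      "name": "240H",
      "nature": "lipophilic",
      "mu20": 3.7, "A_visc": -0.14, "B_visc": 0.002, "rse_visc": 0.0084,
      "T1_23": 597.0, "A_T1": 20.6, "B_T1": 0.43, "rse_T1": 4.6,
      "T2_23": 223.0, "A_T2": 4.3, "B_T2": 0.04, "rse_T2": 6.5
    },
    {
      "name": "250H",
      "nature": "lipophilic",
      "mu20": 3.7, "A_visc": -0.10, "B_visc": 0.005, "rse_visc": 0.0071,
      "T1_23": 611.5, "A_T1": 21.4, "B_T1": 0.46, "rse_T1": 4.6,
      "T2_23": 229.0, "A_T2": 5.9, "B_T2": 0.10, "rse_T2": 7.0
    },
    {
      "name": "PEG200",
      "nature": "hygroscopic",
      "mu20": 64.5, "A_visc": -3.22, "B_visc": 0.243, "rse_visc": 0.54,
      "T1_23": 216.2, "A_T1": 9.5, "B_T1": 0.24, "rse_T1": 3.4,
      "T2_23": 139.4, "A_T2": 6.7, "B_T2": 0.15, "rse_T2": 1.0
    },
    {
      "name": "PEG400",
      "nature": "hygroscopic",
      "mu20": 128.7, "A_visc": -0.11, "B_visc": 1.072, "rse_visc": 1.16,
      "T1_23": 201.9, "A_T1": 8.1, "B_T1": 0.20, "rse_T1": 3.2,
      "T2_23": 123.5, "A_T2": 6.8, "B_T2": 0.15, "rse_T2": 1.6
    },
    {
      "name": "Silicon oil",
      "nature": "lipophilic",
      "mu20": 97.3, "A_visc": -2.00, "B_visc": 0.053, "rse_visc": 0.16,
      "T1_23": 999.4, "A_T1": 14.1, "B_T1": 0.27, "rse_T1": 10.7,
      "T2_23": 545.5, "A_T2": 15.1, "B_T2": 0.32, "rse_T2": 15.5
    },
    {
      "name": "Paraffin oil",
      "nature": "lipophilic",
      "mu20": 32.2, "A_visc": -1.54, "B_visc": 0.097, "rse_visc": 0.11,
      "T1_23": 206.7, "A_T1": 4.9, "B_T1": 0.12, "rse_T1": 2.7,
      "T2_23": 144.3, "A_T2": 4.8, "B_T2": 0.09, "rse_T2": 2.4
    },
    {
      "name": "Angiofil",
      "nature": "lipophilic",
      "mu20": 91.4, "A_visc": -5.51, "B_visc": 0.318, "rse_visc": 0.86,
      "T1_23": 214.8, "A_T1": 3.5, "B_T1": 0.08, "rse_T1": 3.5,
      "T2_23": 157.7, "A_T2": 5.4, "B_T2": 0.10, "rse_T2": 4.8
    },
    {
      "name": "Paraffin oil + Angiofil (6%)",
      "nature": "lipophilic",
      "mu20": 32.5, "A_visc": -1.62, "B_visc": 0.094, "rse_visc": 0.15,
      "T1_23": 205.5, "A_T1": 4.7, "B_T1": 0.11, "rse_T1": 2.7,
      "T2_23": 144.1, "A_T2": 4.4, "B_T2": 0.07, "rse_T2": 2.4
    }
  ],
  "cadaver_perfusate_temp": {
    "reference_temperature": 31.6,
    "intercept": 28.4,
    "A": 0.835,
    "B": 0.014,
    "rse": 0.8778,
    "coeff_se": [0.06, 0.003]
  }
}
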