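{
  "schema_version": 1,
  "name": "Mu-DM",
  "theta": null,
  "provenance": {
    "source": "published probe sets and hazard ratios for the decitabine-deregulated prognostic genes; beta = ln(HR); expression cutpoints and theta were not published"
  },
  "probes": [
    {
      "probe_id": "203708_at",
      "cutpoint": null,
      "beta": -1.6928195213731514,
      "p_adj": 0.016,
      "gene": "PDE4B"
    },
    {
      "probe_id": "225629_s_at",
      "cutpoint": null,
      "beta": -1.0613165039244128,
      "p_adj": 0.051,
      "gene": "ZBTB4"
    },
    {
      "probe_id": "217492_s_at",
      "cutpoint": null,
      "beta": -1.0272222925814367,
      "p_adj": 0.049,
      "gene": "PTENP1"
    },
    {
      "probe_id": "202917_s_at",
      "cutpoint": null,
      "beta": -1.0133524447172864,
      "p_adj": 0.034,
      "gene": "S100A8"
    },
    {
      "probe_id": "215210_s_at",
      "cutpoint": null,
      "beta": -0.9038682118755978,
      "p_adj": 0.049,
      "gene": "DLST"
    },
    {
      "probe_id": "219684_at",
      "cutpoint": null,
      "beta": 1.640548907459153,
      "p_adj": 0.046,
      "gene": "RTP4"
    },
    {
      "probe_id": "224701_at",
      "cutpoint": null,
      "beta": 1.4124493185967417,
      "p_adj": 0.002,
      "gene": "PARP14"
    },
    {
      "probe_id": "217503_at",
      "cutpoint": null,
      "beta": 1.3339478807476814,
      "p_adj": 0.01,
      "gene": "STK17B"
    },
    {
      "probe_id": "222848_at",
      "cutpoint": null,
      "beta": 1.319887428922292,
      "p_adj": 0.007,
      "gene": "CENPK"
    },
    {
      "probe_id": "223271_s_at",
      "cutpoint": null,
      "beta": 1.303184454396884,
      "p_adj": 0.007,
      "gene": "CTDSPL2"
    },
    {
      "probe_id": "228351_at",
      "cutpoint": null,
      "beta": 1.2900587532390648,
      "p_adj": 0.046,
      "gene": "HEATR1"
    },
    {
      "probe_id": "204709_s_at",
      "cutpoint": null,
      "beta": 1.2669476034873244,
      "p_adj": 0.012,
      "gene": "KIF23"
    },
    {
      "probe_id": "213647_at",
      "cutpoint": null,
      "beta": 1.2632789102233435,
      "p_adj": 0.009,
      "gene": "DNA2"
    },
    {
      "probe_id": "219211_at",
      "cutpoint": null,
      "beta": 1.144222799920162,
      "p_adj": 0.02,
      "gene": "USP18"
    },
    {
      "probe_id": "212416_at",
      "cutpoint": null,
      "beta": 1.0922588146959344,
      "p_adj": 0.048,
      "gene": "SCAMP1"
    },
    {
      "probe_id": "212577_at",
      "cutpoint": null,
      "beta": 1.023170093501251,
      "p_adj": 0.024,
      "gene": "SMCHD1"
    },
    {
      "probe_id": "208901_s_at",
      "cutpoint": null,
      "beta": 1.0126912261604704,
      "p_adj": 0.026,
      "gene": "TOP1"
    },
    {
      "probe_id": "224227_s_at",
      "cutpoint": null,
      "beta": 0.9973175705165285,
      "p_adj": 0.041,
      "gene": "BDP1"
    },
    {
      "probe_id": "242625_at",
      "cutpoint": null,
      "beta": 0.9936220748104786,
      "p_adj": 0.049,
      "gene": "RSAD2"
    },
    {
      "probe_id": "213742_at",
      "cutpoint": null,
      "beta": 0.9597332897169919,
      "p_adj": 0.036,
      "gene": "SRSF11"
    },
    {
      "probe_id": "218585_s_at",
      "cutpoint": null,
      "beta": 0.9485642924244507,
      "p_adj": 0.036,
      "gene": "DTL"
    },
    {
      "probe_id": "228006_at",
      "cutpoint": null,
      "beta": 0.9477893989335261,
      "p_adj": 0.045,
      "gene": "PTEN"
    },
    {
      "probe_id": "225647_s_at",
      "cutpoint": null,
      "beta": 0.9376607576103475,
      "p_adj": 0.045,
      "gene": "CTSC"
    },
    {
      "probe_id": "243213_at",
      "cutpoint": null,
      "beta": 0.9313763692921958,
      "p_adj": 0.046,
      "gene": "STAT3"
    },
    {
      "probe_id": "226942_at",
      "cutpoint": null,
      "beta": 0.8679404709331084,
      "p_adj": 0.047,
      "gene": "PHF20L1"
    }
  ]
}
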