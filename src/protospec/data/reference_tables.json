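{
  "compositions": {
    "CVDF": {
      "ash_pct": 0.56,
      "pct_C": 48.5,
      "pct_N": 5.2,
      "mole_fractions": {
        "aliphatic": 0.31,
        "NR": 0.06,
        "OR": 0.16,
        "Ar": 0.23,
        "PhOY": 0.12,
        "COY": 0.11
      },
      "cmc_g_per_L": 2.76
    },
    "CVT230": {
      "ash_pct": 0.81,
      "pct_C": 52.5,
      "pct_N": 5.2,
      "mole_fractions": {
        "aliphatic": 0.28,
        "NR": 0.07,
        "OR": 0.02,
        "Ar": 0.22,
        "PhOY": 0.11,
        "COY": 0.11
      },
      "cmc_g_per_L": 4.2
    },
    "FORSUD": {
      "ash_pct": 0.01,
      "pct_C": 57.5,
      "pct_N": 8.8,
      "mole_fractions": {
        "aliphatic": 0.43,
        "NR": 0.09,
        "OR": 0.15,
        "Ar": 0.15,
        "PhOY": 0.06,
        "COY": 0.13
      },
      "cmc_g_per_L": 1.02
    }
  },
  "models": {
    "CVDF": {
      "Model I": {
        "sites": [
          {"id": "Hcvdf1", "logbeta": [5.69, 9.83], "conc_mmol_per_g": 3.0}
        ],
        "sigma_fit_reported": 2.14
      },
      "Model II": {
        "sites": [
          {"id": "Hcvdf1", "logbeta": [5.42, 9.41], "conc_mmol_per_g": 2.6},
          {"id": "Hcvdf2", "logbeta": [7.78], "conc_mmol_per_g": 0.8},
          {"id": "Hcvdf3", "logbeta": [10.23], "conc_mmol_per_g": 0.9}
        ],
        "sigma_fit_reported": 2.55
      },
      "Model III": {
        "sites": [
          {"id": "Hcvdf1", "logbeta": [4.34], "conc_mmol_per_g": 1.70},
          {"id": "Hcvdf2", "logbeta": [6.03], "conc_mmol_per_g": 1.0},
          {"id": "Hcvdf3", "logbeta": [8.33], "conc_mmol_per_g": 0.7},
          {"id": "Hcvdf4", "logbeta": [10.40], "conc_mmol_per_g": 0.9}
        ],
        "sigma_fit_reported": 1.73
      }
    },
    "CVT230": {
      "Model I": {
        "sites": [
          {"id": "Hcvt1", "logbeta": [5.29, 8.86], "conc_mmol_per_g": 3.0}
        ],
        "sigma_fit_reported": 2.43
      },
      "Model II": {
        "sites": [
          {"id": "Hcvt1", "logbeta": [5.10, 8.61], "conc_mmol_per_g": 2.70},
          {"id": "Hcvt2", "logbeta": [7.58], "conc_mmol_per_g": 0.8},
          {"id": "Hcvt3", "logbeta": [9.97], "conc_mmol_per_g": 1.3}
        ],
        "sigma_fit_reported": 3.03
      },
      "Model III": {
        "sites": [
          {"id": "Hcvt1", "logbeta": [3.87], "conc_mmol_per_g": 1.76},
          {"id": "Hcvt2", "logbeta": [5.76], "conc_mmol_per_g": 1.07},
          {"id": "Hcvt3", "logbeta": [8.26], "conc_mmol_per_g": 0.71},
          {"id": "Hcvt4", "logbeta": [10.16], "conc_mmol_per_g": 1.2}
        ],
        "sigma_fit_reported": 1.75
      }
    },
    "FORSUD": {
      "Model I": {
        "sites": [
          {"id": "Hforsud1", "logbeta": [6.12, 10.32], "conc_mmol_per_g": 1.61}
        ],
        "sigma_fit_reported": 1.66
      },
      "Model II": {
        "sites": [
          {"id": "Hforsud1", "logbeta": [6.37, 10.65], "conc_mmol_per_g": 1.67},
          {"id": "Hforsud2", "logbeta": [9.34], "conc_mmol_per_g": 1.602}
        ],
        "sigma_fit_reported": 1.80
      },
      "Model III": {
        "sites": [
          {"id": "Hforsud1", "logbeta": [4.50], "conc_mmol_per_g": 1.015},
          {"id": "Hforsud2", "logbeta": [6.77], "conc_mmol_per_g": 0.67},
          {"id": "Hforsud3", "logbeta": [9.37], "conc_mmol_per_g": 1.58}
        ],
        "sigma_fit_reported": 1.43
      }
    }
  }
}
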