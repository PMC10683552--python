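{
  "E": {
    "C": 20.0,
    "gK": 8.0,
    "gL": 2.0,
    "gCa": 4.0,
    "gKCa": 0.25,
    "vK": -84.0,
    "vL": -60.0,
    "vCa": 120.0,
    "k1": 10.0,
    "v1": -1.2,
    "v2": 18.0,
    "v3": 12.0,
    "v4": 17.0,
    "phi": 0.23,
    "eps": 0.005,
    "mu": 0.19,
    "kCa": 1.0
  },
  "GA": {
    "C": 20.0,
    "gK": 8.0,
    "gL": 2.0,
    "gCa": 4.0,
    "gKCa": 0.25,
    "vK": -84.0,
    "vL": -60.0,
    "vCa": 120.0,
    "k1": 10.0,
    "v1": -1.2,
    "v2": 18.0,
    "v3": 12.0,
    "v4": 17.0,
    "phi": 0.23,
    "eps": 0.005,
    "mu": 0.19,
    "kCa": 1.0
  },
  "GL": {
    "C": 20.0,
    "gK": 8.0,
    "gL": 2.0,
    "gCa": 4.0,
    "gKCa": 0.25,
    "vK": -84.0,
    "vL": -60.0,
    "vCa": 120.0,
    "k1": 10.0,
    "v1": -1.2,
    "v2": 18.0,
    "v3": 12.0,
    "v4": 17.0,
    "phi": 0.23,
    "eps": 0.005,
    "mu": 0.19,
    "kCa": 1.0
  },
  "M": {
    "C": 1.0,
    "gK": 8.0,
    "gL": 2.0,
    "gCa": 4.0,
    "gKCa": 0.3,
    "vK": -84.0,
    "vL": -60.0,
    "vCa": 120.0,
    "k1": 10.0,
    "v1": -1.2,
    "v2": 18.0,
    "v3": 12.0,
    "v4": 17.0,
    "phi": 0.23,
    "eps": 0.005,
    "mu": 0.19,
    "kCa": 0.9
  },
  "kin_E": {
    "alpha": 15.0,
    "beta": 0.1,
    "theta_s": 0.0,
    "sigma_s": 4.0
  },
  "kin_GA": {
    "alpha": 4.0,
    "beta": 0.08,
    "theta_s": 0.0,
    "sigma_s": 4.0
  },
  "kin_GL": {
    "alpha": 8.0,
    "beta": 0.08,
    "theta_s": 0.0,
    "sigma_s": 4.0
  },
  "connections": {
    "gE_GA": 0.3,
    "vE_GA": 40.0,
    "gE_GL": 0.3,
    "vE_GL": 40.0,
    "gGA_GL": 0.4,
    "vGA_GL": -50.0,
    "gE_M": 0.24,
    "vE_M": 40.0,
    "gGA_M": 0.4,
    "gGL_M": 0.2,
    "vG_M": -50.0,
    "gM_M": 0.1,
    "vM_M": -50.0,
    "sM_const": 0.029
  },
  "modulation": {
    "D1_M": 0.015,
    "D1_GL": 0.25,
    "gI_max": 15.0,
    "k2": 10.0,
    "rho": 10000.0,
    "gI_law": "relaxation"
  },
  "IE0": 43.9,
  "IGA0": 36.0,
  "IGL0": 36.0,
  "IM0": 19.5,
  "status": "subordinate"
}
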