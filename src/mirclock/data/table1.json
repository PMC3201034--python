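{
  "comment": "Basal rate constants of the miR-206-mediated circadian clock model. Units: h^-1, nM, nM*h^-1 or nM^-1*h^-1 as appropriate; Hill exponents dimensionless. k_sB/k_sC are multiples of the protein-synthesis scale k_stot and V_sB/V_sC multiples of the transcription scale v_stot; they are resolved to absolute values on load. The four shipped sets differ only in C3, the miR-206/Clock-mRNA silencing-complex formation rate.",
  "base": {
    "k1": 0.4,
    "k2": 0.2,
    "k3": 0.55,
    "k4": 0.1,
    "k5": 2.0,
    "k6": 1.0,
    "d1": 3.6,
    "d2": 0.9,
    "d3": 4.0,
    "d4": 0.9,
    "d5": 4.0,
    "d6": 0.9,
    "K_IB": 0.8,
    "K_I": 2.0,
    "K_AM": 2.0,
    "K_AC": 0.8,
    "k_dmb": 0.01,
    "k_dmc": 0.12,
    "k_dnc": 0.5,
    "k_dn1": 0.01,
    "k_dn2": 0.01,
    "k_dn3": 0.01,
    "k_dn4": 0.01,
    "k_dn5": 0.01,
    "k_dn6": 0.01,
    "K_d1": 0.3,
    "K_d2": 0.3,
    "K_d3": 0.3,
    "K_d4": 0.3,
    "K_dp1": 0.3,
    "K_dp2": 0.3,
    "K_dp3": 0.3,
    "K_p1": 0.1,
    "K_p2": 0.1,
    "K_p3": 0.1,
    "K_vd": 0.1,
    "K_1": 1.5,
    "K_2": 2.0,
    "K_3": 1.5,
    "K_4": 2.0,
    "K_mB": 0.4,
    "K_mC": 0.1,
    "K_m": 0.2,
    "k_stot": 1.0,
    "k_sB": "1.0*k_stot",
    "k_sC": "0.3*k_stot",
    "k_s": 2.0,
    "m1": 4.0,
    "m2": 4.0,
    "n1": 4.0,
    "n2": 4.0,
    "V_1B": 1.0,
    "V_2B": 0.1,
    "V_3B": 1.0,
    "V_4B": 0.2,
    "V_1C": 1.0,
    "V_2C": 0.5,
    "V_1": 6.0,
    "V_2": 3.0,
    "V_3": 6.0,
    "V_4": 3.0,
    "V_dBC": 1.0,
    "V_dBN": 1.0,
    "V_dCC": 0.1,
    "V_dIN": 0.6,
    "V_mB": 0.3,
    "V_mC": 0.12,
    "V_d": 1.5,
    "v_stot": 1.0,
    "V_sB": "0.28*v_stot",
    "V_sC": "0.95*v_stot",
    "V_sM": 1.0,
    "V_s": 0.5,
    "V_m": 0.3,
    "C1": 0.01,
    "C2": 0.01,
    "C3": 1.0,
    "C4": 0.6
  },
  "sets": {
    "Set1": {"C3": 0.0},
    "Set2": {"C3": 0.5},
    "Set3": {"C3": 1.0},
    "Set4": {"C3": 1.5}
  }
}
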