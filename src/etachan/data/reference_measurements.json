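{
  "version": 1,
  "description": "Published single-channel CRC measurements for adult muscle-type nicotinic AChRs: agonist series at wild-type binding sites and agonist/binding-site-mutant combinations. Concentration-response parameters (EC50, PO^max) were measured at +70 mV on an eS450W background (plus the listed extra backgrounds that scale L0); equilibrium constants, coupling constant c and efficiency eta were derived from them. Used by the reference-check command to validate the closed-form inversion against tabulated values.",
  "ach_reference": {
    "kdc_uM": 174.0,
    "kdo_nM": 29.0,
    "dg_la_kcal_mol": -5.1,
    "dg_ha_kcal_mol": -10.2,
    "pomax_approx": 0.96,
    "L0_-100mV": 7.4e-07
  },
  "agonist_eta_class_means": [0.32, 0.41, 0.45, 0.51, 0.55],
  "agonist_eta_class_sds": [0.035, 0.005, 0.014, 0.008, 0.015],
  "agonists": [
    {"label": "BzTMA", "ec50_uM": 1070, "ec50_sem": 200, "pomax": 0.60, "pomax_sem": 0.05,
     "kdc_uM": 930, "kdc_sem": 112.0, "kdo_nM": 650, "kdo_sem": 90, "c": 1424, "c_sem": 18.0,
     "eta": 0.51, "eta_sem": 0.01, "n": 3, "extra_backgrounds": []},
    {"label": "Dec", "ec50_uM": 190, "ec50_sem": 20, "pomax": 0.79, "pomax_sem": 0.03,
     "kdc_uM": 90, "kdc_sem": 7.0, "kdo_nM": 140, "kdo_sem": 10, "c": 643, "c_sem": 21,
     "eta": 0.41, "eta_sem": 0.01, "n": 4, "extra_backgrounds": ["eL269F"]},
    {"label": "SCh", "ec50_uM": 20, "ec50_sem": 3, "pomax": 0.84, "pomax_sem": 0.02,
     "kdc_uM": 50, "kdc_sem": 4.0, "kdo_nM": 20, "kdo_sem": 1, "c": 3177, "c_sem": 118,
     "eta": 0.45, "eta_sem": 0.01, "n": 3, "extra_backgrounds": []},
    {"label": "BzTEA", "ec50_uM": 2, "ec50_sem": 0.1, "pomax": 0.85, "pomax_sem": 0.02,
     "kdc_uM": 0.80, "kdc_sem": 0.3, "kdo_nM": 3, "kdo_sem": 2, "c": 316, "c_sem": 14,
     "eta": 0.29, "eta_sem": 0.00, "n": 3, "extra_backgrounds": ["eL269F", "eE181W"]},
    {"label": "TriMA", "ec50_uM": 16000, "ec50_sem": 1200, "pomax": 0.78, "pomax_sem": 0.03,
     "kdc_uM": 7720, "kdc_sem": 316.0, "kdo_nM": 12580, "kdo_sem": 670, "c": 615, "c_sem": 18,
     "eta": 0.57, "eta_sem": 0.01, "n": 4, "extra_backgrounds": ["eL269F"]}
  ],
  "mutants": [
    {"mutation": "D200A", "agonist": "ACh", "ec50_uM": 110, "ec50_sem": 10, "pomax": 0.80, "pomax_sem": 0.02,
     "kdc_uM": 52, "kdc_sem": 3, "kdo_nM": 150, "kdo_sem": 5, "c": 338, "c_sem": 12,
     "eta": 0.37, "eta_sem": 0.00, "n": 3, "eta_wt": 0.50, "extra_backgrounds": []},
    {"mutation": "D200A", "agonist": "CCh", "ec50_uM": 320, "ec50_sem": 70, "pomax": 0.45, "pomax_sem": 0.02,
     "kdc_uM": 138, "kdc_sem": 18, "kdo_nM": 900, "kdo_sem": 94, "c": 153, "c_sem": 3,
     "eta": 0.36, "eta_sem": 0.00, "n": 4, "eta_wt": 0.52, "extra_backgrounds": []},
    {"mutation": "D200A", "agonist": "TMA", "ec50_uM": 13350, "ec50_sem": 2970, "pomax": 0.37, "pomax_sem": 0.03,
     "kdc_uM": 5683, "kdc_sem": 740, "kdo_nM": 4382, "kdo_sem": 890, "c": 130, "c_sem": 5,
     "eta": 0.48, "eta_sem": 0.02, "n": 5, "eta_wt": 0.54, "extra_backgrounds": [],
     "suspect": "tabulated KdO is internally inconsistent with the same row's c and eta (both consistent with 43820 nM); likely a printing error, excluded from checks"},
    {"mutation": "D200A", "agonist": "Ebt", "ec50_uM": 110, "ec50_sem": 20, "pomax": 0.50, "pomax_sem": 0.03,
     "kdc_uM": 47, "kdc_sem": 5, "kdo_nM": 680, "kdo_sem": 47, "c": 69, "c_sem": 2,
     "eta": 0.30, "eta_sem": 0.00, "n": 3, "eta_wt": 0.41, "extra_backgrounds": ["eL269F"]},
    {"mutation": "D200A", "agonist": "Ebx", "ec50_uM": 60, "ec50_sem": 20, "pomax": 0.49, "pomax_sem": 0.03,
     "kdc_uM": 26, "kdc_sem": 5, "kdo_nM": 390, "kdo_sem": 58, "c": 67, "c_sem": 3,
     "eta": 0.29, "eta_sem": 0.01, "n": 3, "eta_wt": 0.46, "extra_backgrounds": ["eL269F"]},
    {"mutation": "K145A", "agonist": "ACh", "ec50_uM": 110, "ec50_sem": 10, "pomax": 0.95, "pomax_sem": 0.06,
     "kdc_uM": 83, "kdc_sem": 5, "kdo_nM": 50, "kdo_sem": 3, "c": 1672, "c_sem": 82,
     "eta": 0.44, "eta_sem": 0.00, "n": 3, "extra_backgrounds": []},
    {"mutation": "K145A", "agonist": "CCh", "ec50_uM": 380, "ec50_sem": 30, "pomax": 0.53, "pomax_sem": 0.01,
     "kdc_uM": 165, "kdc_sem": 8, "kdo_nM": 400, "kdo_sem": 15, "c": 411, "c_sem": 5,
     "eta": 0.41, "eta_sem": 0.00, "n": 4, "extra_backgrounds": []},
    {"mutation": "K145A", "agonist": "TMA", "ec50_uM": 2200, "ec50_sem": 590, "pomax": 0.19, "pomax_sem": 0.01,
     "kdc_uM": 922, "kdc_sem": 125, "kdo_nM": 5010, "kdo_sem": 712, "c": 184, "c_sem": 3,
     "eta": 0.43, "eta_sem": 0.01, "n": 3, "extra_backgrounds": []},
    {"mutation": "K145A", "agonist": "Ebt", "ec50_uM": 40, "ec50_sem": 4, "pomax": 0.81, "pomax_sem": 0.04,
     "kdc_uM": 20, "kdc_sem": 2, "kdo_nM": 20, "kdo_sem": 2, "c": 792, "c_sem": 52,
     "eta": 0.38, "eta_sem": 0.00, "n": 3, "extra_backgrounds": []},
    {"mutation": "K145A", "agonist": "Ebx", "ec50_uM": 40, "ec50_sem": 3, "pomax": 0.83, "pomax_sem": 0.01,
     "kdc_uM": 20, "kdc_sem": 1, "kdo_nM": 20, "kdo_sem": 1, "c": 847, "c_sem": 17,
     "eta": 0.38, "eta_sem": 0.00, "n": 3, "extra_backgrounds": []},
    {"mutation": "G153S", "agonist": "Ebt", "ec50_uM": 2, "ec50_sem": 0.5, "pomax": 0.65, "pomax_sem": 0.01,
     "kdc_uM": 2, "kdc_sem": 0.3, "kdo_nM": 7, "kdo_sem": 1, "c": 313, "c_sem": 4,
     "eta": 0.31, "eta_sem": 0.01, "n": 4, "extra_backgrounds": []}
  ]
}
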