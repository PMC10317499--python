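{
  "version": 1,
  "RT_kcal_per_mol": 0.59,
  "temperature_C": 23,
  "standard_state_M": 1.0,
  "e_fold_mV": 60.0,
  "L0": {
    "wt_-100mV": 7.4e-07,
    "wt_+70mV_eS450W": 5.2e-07
  },
  "L0_reference_voltage_mV": -100.0,
  "background_folds": {
    "eS450W": 1.0,
    "eL269F": 179.0,
    "eE181W": 5.5,
    "dV269A": 250.0
  },
  "notes": {
    "eS450W": "M4 epsilon-subunit substitution engineered to compensate exactly for the effect of depolarizing from -100 mV to +70 mV on unliganded gating; its fold entry is therefore 1.0 relative to the depolarization-compensated reference L0.",
    "L0_+70mV": "The unliganded gating constant used for +70 mV recordings carrying eS450W is stored as an explicit measured constant (5.2e-7) rather than derived from the e-fold/60 mV voltage rule, because the rule applied to 7.4e-7 at -100 mV gives 4.49e-7 at -70 mV; the published constant evidently derives from an unrounded rule."
  }
}
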