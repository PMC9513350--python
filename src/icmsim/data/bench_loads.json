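{
  "version": 1,
  "comment": "Bench model circuits for the electrode-electrolyte interface: Rs in series with Rp||Cp. Only |Z| at 1 kHz is known for the physical circuits (33.7 kOhm for a metal intracortical microelectrode model, 325 kOhm for a small-surface-area variant, both with Rs ~ 1 kOhm). Cp was fixed at a realistic double-layer value per model and Rp solved by root-finding so that |Z|(1 kHz) matches; regenerate with icmsim.electrode_load.fit_parallel_resistance.",
  "models": {
    "metal_33k7": {
      "r_series_ohm": 1000.0,
      "r_parallel_ohm": 35982.17622646484,
      "c_parallel_f": 2e-09,
      "v_limit_v": 2.42
    },
    "small_tip_325k": {
      "r_series_ohm": 1000.0,
      "r_parallel_ohm": 354847.17544003687,
      "c_parallel_f": 2e-10,
      "v_limit_v": 2.42
    }
  }
}
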