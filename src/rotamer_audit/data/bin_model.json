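{
  "halfwidth": 30.0,
  "generic_modes": {"p": 65.0, "t": 180.0, "m": -65.0},
  "pro_modes": {"Cγ Endo": 30.0, "Cγ Exo": -30.0},
  "comment": "p centred at +65 by mirror symmetry with the printed m interval [-95, -35]; t wraps across +/-180 (|chi| >= 150). Off = outside every bin."
}
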