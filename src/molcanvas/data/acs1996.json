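{
  "bond_length": 14.4,
  "bond_width": 0.6,
  "bond_double_gap": 0.18,
  "atom_font_family": "Helvetica",
  "atom_font_size": 10.0,
  "atom_color": "#000000",
  "element_color_scheme": "mono",
  "show_carbon_labels": false,
  "show_implicit_h": true,
  "lone_pair_size": 3.0,
  "label_buffer": 2.0,
  "dash_length": 2.5,
  "dash_spacing": 2.5,
  "background": "#ffffff",
  "margin": 10.0
}
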