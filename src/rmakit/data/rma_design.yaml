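# Reference eight-channel resonant microphone array design.
# Geometry dimensions in mm (converted to SI on load); layer thicknesses in um.
units:
  geometry: mm
  layer_thickness: um
cantilevers:
  # no, design frequency (Hz), outline length l, outline width c,
  # narrow length l_n, per-beam narrow width c_n
  - {no: 1, f_design: 253, l: 3.6, c: 2.3, l_n: 0.9, c_n: 0.13}
  - {no: 2, f_design: 308, l: 3.4, c: 2.3, l_n: 0.8, c_n: 0.14}
  - {no: 3, f_design: 367, l: 3.2, c: 2.2, l_n: 0.7, c_n: 0.15}
  - {no: 4, f_design: 429, l: 2.6, c: 2.6, l_n: 0.8, c_n: 0.115}
  - {no: 5, f_design: 495, l: 2.6, c: 2.6, l_n: 0.7, c_n: 0.15}
  - {no: 6, f_design: 565, l: 2.5, c: 2.5, l_n: 0.7, c_n: 0.17}
  - {no: 7, f_design: 639, l: 2.4, c: 2.4, l_n: 0.75, c_n: 0.18}
  - {no: 8, f_design: 717, l: 2.3, c: 2.3, l_n: 0.7, c_n: 0.185}
n_support_beams: 2
layers:
  # Stack bottom-up. The electrode/insulator/piezo layers sit only on the
  # narrow support beams (narrow_only); the plate is bare device-layer Si.
  # E in GPa, density in kg/m^3. Si constants are the (110) single-crystal
  # values; thin-film constants are standard handbook values.
  - {name: Si device layer, thickness: 5.0, E: 169, rho: 2329}
  - {name: Al ground electrode, thickness: 0.2, E: 70, rho: 2700, narrow_only: true}
  - {name: SiN insulator, thickness: 0.1, E: 250, rho: 3100, narrow_only: true}
  - {name: Piezoelectric ZnO, thickness: 0.5, E: 140, rho: 5606, narrow_only: true,
     d31: 5.43e-12, relative_permittivity: 10.9}
  - {name: SiN insulator, thickness: 0.1, E: 250, rho: 3100, narrow_only: true}
  - {name: Al top electrode, thickness: 0.2, E: 70, rho: 2700, narrow_only: true}
mel_band:
  # Array band endpoints on the Mel grid (Hz): the realised design spans
  # 253-717; the target wheeze band is 200-800.
  design: [253, 717]
  wheeze: [200, 800]
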