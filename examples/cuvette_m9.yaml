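# Cuvette settling assay in plain M9 buffer: inputs for `taxisort estimate`.
# Quantities may carry unit suffixes; bare numbers are read as SI.
fluid:
  density: "1.0 g/mL"
  viscosity: "1.0 mPa*s"
  label: m9
worm:
  volume: "5.96e-12 m3"
  density: "1.08 g/mL"
  stokes_radius: "0.37 mm"
behavior:
  thrust: "0.81 nN"
  mode: random_reorient
  reorientation_time: "4.65 s"
measurements:
  settling_speed: "0.52 mm/s"   # passive (taxis-deficient) strain
  directed_speed: "0.64 mm/s"   # downward-swimming (competent) strain
g: "9.81 m/s2"
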