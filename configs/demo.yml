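# Demo configuration for the full pipeline:
#   silkfric run-all --config configs/demo.yml
# Builds the published composite (2 crystal units of 5x5 polyalanine strands,
# 7 bundles x 8 amorphous chains), measures the SASA contact area, generates
# the synthetic pulling campaign over 0.02-20 m/s, extracts and fits the
# friction dataset, and sweeps the viscous-film slider.
seed: 1
outdir: silkfric_out

builder:
  n_units: 2
  strands_per_sheet: 5
  sheets_per_unit: 5
  polyala_length: 8
  n_bundles: 7
  chains_per_bundle: 8
  unit_gap: 3.0

probe_radius: 0.14        # nm, water probe
sasa_points: 960
contact_threshold: 0.01   # nm^2 buried area per contacting residue

velocities: [0.02, 0.05, 0.2, 0.5, 2.0, 5.0, 20.0]
protocol:
  spring_k: 830.0         # pN/nm per bundle spring
  n_springs: 7
  n_replicas: 4
  temperature: 300.0
truth:
  bond_params: interface  # preset: U_bond = 8.4 kT, ma = 1.32 nm
  xi_water_res: 1.0e-12   # Ns/m per residue

fit_modes: [fix_Ubond, fix_ma]

slider_velocities: [0.01, 0.1, 1.0, 5.0]
slider_duration: 2.0e-10  # s
crystal_card:
  youngs_modulus: 25.0    # GPa
  poisson: 0.3
  yield_stress: 2.0
  tangent_modulus: 2.5
  hardening_mix: 0.5
amorphous_card:
  bulk_modulus: 4.0       # GPa
  G0: 1.5
  Ginf: 0.15
  beta: 1.0e+9             # 1/s
film_card:
  eta: 200.0              # Ns/m^2
  h: 0.5                  # nm
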