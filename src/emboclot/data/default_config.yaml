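# Reference configuration for the canonical clot-in-tube setup.
# Units are embedded in the key names; all lengths SI (meters).
geometry:
  D_m: 0.0127      # tube inner diameter
  h_m: 0.0026      # clot height above the tube bottom
  L_m: 0.0138      # maximum streamwise chord (at the tube bottom)
fluid:
  nu_m2_s: 1.0e-6  # kinematic viscosity (phosphate-buffered saline, 20 C)
  rho_kg_m3: 1000.0
constitutive:
  eta_p_Pa_s: 2.1e4  # polymeric viscosity (fitted to stress relaxation)
  lambda_s: 6.0      # relaxation timescale (fitted to stress relaxation)
  epsilon: 0.01      # bulk extensibility parameter
  zeta: 0.0          # affine network deformation
adhesion:
  n_stations: 16
  h_b_m: 70.0e-6     # bond-layer (wall-normal) thickness
  phi: 0.8           # fraction of drag applied at the leading edge
  failure_cap: 148.4131591025766  # e^5; replace via calibration
criterion:
  displacement_fraction: 0.05
  window_timescales: 10.0
seed: 0
output_dir: emboclot-out
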