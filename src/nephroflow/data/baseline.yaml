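# Baseline calibration fixture for the lumped human-kidney model.
#
# All constants of the healthy baseline live here: boundary conditions,
# systemic constants, the prescribed node pressures used by the continuity
# calibration, the vessel geometry for the Poiseuille fit, and the external
# reference column for the baseline-flow comparison. The pressure profile,
# geometry and reference column are SYNTHETIC reconstructions from standard
# human renal physiology, constrained to the documented scalar anchors
# (MAP 90, 13 mmHg heart-to-arteriole drop, GFR 120 mL/min, R_GB 1e7,
# pi 30 mmHg, R_b 2.78e6).
# The efferent pressure E is stored at full precision: it is the unique
# value (given the other pressures) at which the feedback relations
# reproduce the continuity-derived afferent resistance exactly, so that
# the calibrated model's closed-loop solve returns the prescribed profile
# as an exact fixed point.
name: baseline

constants:
  map_mmHg: 90.0
  ureter_pressure_mmHg: 0.0
  venous_pressure_mmHg: 3.0
  venous_sodium_meq_per_ml: 0.140
  cardiac_output_ml_min: 5500.0
  kidney_flow_fraction: 0.1
  plasma_fraction: 0.55
  nephron_scale: 2.0e+6
  oncotic_pressure_mmHg: 30.0
  filtration_resistance: 1.0e+7       # R_GB, mmHg*s/mL
  baseline_afferent_resistance: 2.78e+6  # R_b, mmHg*s/mL
  heart_to_arteriole_drop_mmHg: 13.0
  gfr_target_ml_min: 120.0
  resistance_unit: 1.0e+7

# Prescribed pressures (mmHg) for the continuity (method-2) calibration.
# Monotone along both chains; A = 90 - 13; G - B = 40 gives the 10 mmHg net
# filtration pressure implied by GFR 120 with R_GB = 1e7 and pi = 30.
pressures_mmHg:
  H: 90.0
  A: 77.0
  G: 47.0
  B: 7.0
  P: 6.0
  N: 5.0
  K: 4.0
  D: 3.0
  E: 13.84031299368565
  V: 3.0
  U: 0.0

# Synthetic per-segment vessel geometry (cm) with per-segment effective
# viscosity (mmHg*s) back-computed so the Poiseuille resistance at unit
# scalings plays the role of the "from the literature, before optimization"
# column. AG is the feedback-free afferent arteriole (target R_b).
geometry:
  HA:      {length_cm: 1.0,  radius_cm: 2.0e-3,  viscosity_mmHg_s: 9.7207627232e-06}
  AG:      {length_cm: 0.03, radius_cm: 1.0e-3,  viscosity_mmHg_s: 5.4585172356e-05}
  GE:      {length_cm: 0.03, radius_cm: 0.9e-3,  viscosity_mmHg_s: 1.5501769666e-04}
  EV:      {length_cm: 1.0,  radius_cm: 2.0e-3,  viscosity_mmHg_s: 1.3481902580e-05}
  BP:      {length_cm: 0.05, radius_cm: 1.25e-3, viscosity_mmHg_s: 2.4927187803e-05}
  PN:      {length_cm: 1.4,  radius_cm: 1.25e-3, viscosity_mmHg_s: 5.4785028139e-06}
  NK:      {length_cm: 1.0,  radius_cm: 0.75e-3, viscosity_mmHg_s: 3.8231521175e-07}
  KD:      {length_cm: 1.0,  radius_cm: 1.0e-3,  viscosity_mmHg_s: 2.6582707069e-06}
  DU:      {length_cm: 2.0,  radius_cm: 1.0e-3,  viscosity_mmHg_s: 1.3049692561e-04}

scaling_bounds: [0.7, 1.2]

# Synthetic reference column for the baseline-flow comparison: canonical
# textbook normals of the classical whole-kidney model this lumped model's
# reabsorption relations derive from (GFR 125 mL/min, effective RPF 660
# mL/min, urine 1 mL/min, urinary sodium 0.1 mEq/min ~ 144 mEq/day), with
# loop and distal deliveries propagated from GFR 125 through that model's
# own reabsorption fractions.
reference_flows:
  renal_plasma_flow_ml_min: 660.0
  gfr_ml_min: 125.0
  loop_inflow_ml_min: 31.25
  distal_inflow_ml_min: 20.703125
  urine_flow_ml_min: 1.0
  filtered_sodium_meq_min: 17.5
  distal_sodium_delivery_meq_min: 0.875
  urinary_sodium_meq_min: 0.1
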