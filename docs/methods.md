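# Methods

## Network topology

The kidney is reduced to a single representative nephron, a directed network
of eleven nodes:

```
blood:     H ── A ── G ── E ── V
                     │
filtrate:            B ── P ── N ── K ── D ── U
reabsorption (to V): water from P, N, D; sodium from P, K, D
```

`H` heart (MAP boundary), `A` pre-afferent arteriole, `G` glomerulus, `B`
Bowman's space, `P` proximal tubule, `N` thin descending limb, `K` thick
ascending limb, `D` lumped distal tubule + collecting duct, `E` post-efferent
arteriole, `V` veins (3 mmHg boundary), `U` ureter (0 mmHg boundary). The
descending limb is sodium-impermeable and the ascending limb
water-impermeable. Whole-body outputs scale the nephron by 2×10⁶ (both
kidneys) and convert to per-minute units.

## Constitutive relations

* **Hydraulic flow** on every vessel/tubule edge: `Q = (P_up − P_down) / R`.
* **Filtration** (G→B): Starling relation
  `Q_GB = (P_G − P_B − π) / R_GB` with oncotic pressure `π = 30 mmHg` and
  membrane resistance `R_GB = 10⁷ mmHg·s/mL`.
* **Water reabsorption fractions** (of segment inflow, returned to V):
  proximal 0.75 (glomerulotubular balance); descending limb
  `0.65 − 0.01·Q_PN` with the inflow in aggregate mL/min (clamped to
  [0, 1)); ascending limb 0 (water-impermeable); distal 0.95 (fixed
  antidiuretic tone).
* **Sodium reabsorption fractions**: proximal 0.75; descending limb 0;
  ascending limb 0.80; distal
  `0.2268 / (1 + exp(7·J_KD − 7.7)) + 0.7316` with the sodium delivery
  `J_KD` in aggregate mEq/min (delivery-sensitive, aldosterone-like).
* **Poiseuille resistance** for the geometry route: `R = 8ηl / (πr⁴)`.

The empirical coefficients above are calibrated on *aggregate* units
(mL/min, mEq/min); all internal network arithmetic is per-nephron (mL/s,
mEq/s, mmHg, mEq/mL; resistances in mmHg·s/mL).

## Feedback (afferent resistance)

All three autoregulation mechanisms act additively on the afferent arteriole,
on top of a feedback-free baseline `R_b = 2.78×10⁶ mmHg·s/mL`, each with a
dimensionless gain (1 = healthy, 0 = ablated):

```
R_AG   = R_b + R_TGF + R_MD + R_MA
R_TGF  = g_tgf · U · 0.1505 / (1 + exp(4.8 − 40·C_D))          (distal [Na])
R_MD   = g_md · 0.5 (R_b + R_GE + R_TGF)(P_A/67 − 1) H(P_A−67) (pressure)
R_MA   = g_ma · U · 0.5 (R_b + R_MD) / R_GE                    (resistance ratio)
```

`U = 10⁷ mmHg·s/mL` is the normalized resistance unit in which the empirical
relations are expressed; the Heaviside factor is 1 at exactly 67 mmHg, and
the mechanisms compose in the order TGF → descending myogenic → ascending
myogenic. Ablating TGF while keeping the ascending mechanism is rejected as
an unsupported configuration.

## Steady-state solve

Unknowns (12): pressures at A, G, B, P, N, K, D, E and sodium concentrations
at P, N, K, D. Bowman's-space and venous sodium are fixed at 0.140 mEq/mL
(free filtration); boundary pressures are MAP, 3 mmHg (veins) and 0 mmHg
(ureter). Residuals are water conservation at the eight pressure nodes and
sodium conservation at the four tubular nodes, with the afferent resistance
re-evaluated from the current iterate.

The solver is a damped Newton iteration: central finite-difference Jacobian
(relative step 10⁻⁶), unknowns scaled by 100 mmHg / 0.14 mEq/mL, residuals
by typical per-nephron flow magnitudes (10⁻⁶ mL/s, 1.4×10⁻⁷ mEq/s), a
backtracking line search on the scaled residual norm, and convergence at a
scaled norm below 10⁻¹⁰ (about 10⁻¹⁶ mL/s absolute). The initial guess uses
linear pressure ramps and tubular concentrations forward-propagated through
the baseline reabsorption fractions, which starts the TGF sigmoid on its
correct branch; baseline solves converge in ~6 iterations. Non-convergence is
reported in the solution object, never silently. MAP sweeps warm-start each
point from the previous solution (continuation), which the myogenic threshold
makes worthwhile.

The water equations are affine in the pressures whenever the gains are zero
and the two state-dependent fractions are frozen; the sodium equations are
bilinear (flow × concentration) but closed-form given the flows. The test
suite exploits this two-stage direct solve as an independent oracle for the
Newton iteration.

## Calibration

* **Continuity route** (the default): prescribe the baseline pressure profile
  (90 / 77 / 47 / 7 / 6 / 5 / 4 / 3 mmHg along the chains, efferent node at
  its feedback-consistent value) and a 120 mL/min GFR target; forward-
  propagate the flows through the reabsorption fractions; each edge
  resistance is ΔP/Q. The heart-to-arteriole resistance comes from the
  prescribed 13 mmHg perfusion drop over the baseline per-nephron plasma
  flow (cardiac output 5500 mL/min × 0.1 per kidney × 2 kidneys × 0.55
  plasma = 605 mL/min), giving 2.58×10⁶ mmHg·s/mL. A consistency check
  verifies that the feedback relations, evaluated at the prescribed state,
  reproduce the continuity-derived afferent total (they do, exactly, by
  construction of the fixture's efferent pressure).
* **Geometry route**: per-segment vessel lengths, radii and effective
  viscosities from the fixture, with dimensionless length/radius scalings
  fitted by bounded least squares (bounds [0.7, 1.2], SciPy trust-region
  reflective) so Poiseuille matches the continuity targets. Two scalings per
  single resistance target make the problem underdetermined; feasibility —
  average relative error ≲ 10⁻¹³ here — is the criterion, not uniqueness.

All constants live in the versioned fixture
`src/nephroflow/data/baseline.yaml`. The fixture's pressure profile, vessel
geometry and external reference column are physiologically standard
reconstructions constrained to the documented scalar anchors; they are
labelled as such in the file.

## Experiments

* **MAP sweep**: 54–180 mmHg in steps of 9 (15 points), warm-started.
* **Scenarios**: uniform multipliers on the four vascular resistances
  (heart-to-arteriole, baseline afferent, efferent, efferent-to-vein) and on
  the three gains. Severe hypertension = (×6, ×0.5); the ×6 corresponds to a
  uniform geometric shrink of 6^(−1/3) ≈ 0.55 of vessel length and radius.
* **Sensitivity**: independent one-factor grids, resistance multipliers 1–8
  with gains at 1, feedback multipliers 0–2 with resistances at baseline,
  plus tubular sodium profiles at MAP 90.
* **Curve evaluation**: a shape-preserving monotone cubic (PCHIP) through the
  solved (MAP, GFR) knots, no extrapolation; RMSE against observation tables
  with columns `map_mmHg`, `gfr_ml_min`.
* **Synthetic observations**: seeded Gaussian noise added to the model curve
  at sampled MAP values — a stand-in for patient data that exercises the RMSE
  machinery end to end. No real patient data ships with or is required by
  this package.

## Known model limitations

* Distal sodium concentration is **not** monotone in MAP over the full sweep:
  with the distal reabsorption sigmoid saturated at low filtration
  (GFR ≲ 60 mL/min), `C_D = (1 − r_D)·J_KD/Q_DU` decreases with GFR, so the
  curve dips between MAP 54 and ~75 mmHg before rising. Monotone increase
  holds from ~81 mmHg upward.
* Closed-loop GFR at fixed MAP is **not** strictly non-increasing in the
  vascular resistance multiplier: scaling the efferent resistance raises
  glomerular pressure while the ascending myogenic term (∝ 1/R_GE) relaxes,
  producing a ~0.6% rise between multipliers 1 and 2 before the steep
  monotone decline from 2 to 8.

Both effects follow from the constitutive relations at the documented
baseline anchors; the acceptance tests assert the strict full-range forms and
fail on these two points by design.
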