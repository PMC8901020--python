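# nephroflow

A closed-loop, steady-state mechanistic model of human kidney hemodynamics:
mean arterial pressure (MAP) in, glomerular filtration rate (GFR) out.

## The model in one paragraph

One representative nephron is modeled as a lumped hydraulic network of eleven
anatomical nodes — heart, pre-afferent arteriole, glomerulus, Bowman's space,
proximal tubule, the two limbs of the loop of Henle, a lumped distal
tubule/collecting duct, post-efferent arteriole, veins, and ureter — and
scaled by 2×10⁶ to the whole body. Flow through each vessel follows Ohm's-law
hydraulics (Q = ΔP/R); filtration across the glomerular membrane follows the
Starling relation with a 30 mmHg oncotic pressure opposing a fixed
10⁷ mmHg·s/mL membrane resistance. Water and sodium are returned to the blood
along the tubule by segment-specific reabsorption fractions (proximal
glomerulotubular balance, flow-dependent descending-limb water uptake, a
constant thick-ascending-limb sodium fraction, and delivery-dependent
sigmoidal distal sodium reabsorption). The loop is closed by three
autoregulation mechanisms that all act on the afferent arteriolar resistance:
tubuloglomerular feedback (sensing distal sodium concentration), a descending
myogenic response (sensing arteriolar pressure above a 67 mmHg threshold),
and an ascending myogenic response (sensing the afferent/efferent resistance
ratio). The steady state is the root of the 12 nodewise water- and
sodium-conservation equations, found by a damped Newton iteration.

Calibration is by construction, not regression: edge resistances are read off
as ΔP/Q from a prescribed physiological pressure profile and a 120 mL/min GFR
target (the "continuity" method), and a bounded least-squares fit then finds
per-segment length/radius scaling factors so that Poiseuille's law applied to
vessel geometry reproduces the same resistances. The calibrated closed-loop
model returns the prescribed pressure profile as an exact fixed point.

## Worked example

```python
>>> from nephroflow import KidneyModel
>>> model = KidneyModel.from_fixture()   # calibrate from the packaged baseline
>>> sol = model.solve()                  # closed-loop steady state at MAP 90
>>> print(sol.summary())
Steady-state kidney solution
============================
converged: True  (residual 4.730e-17, 6 Newton iterations)
MAP 90.0 mmHg | gains (TGF 1, MD 1, MA 1)

GFR           120.0 mL/min
RPF           605.0 mL/min
urine flow     0.98 mL/min
urine [Na]     63.1 mEq/L

node   P (mmHg)   C_Na (mEq/L)
  A      77.000          -
  G      47.000          -
  B       7.000      140.0
  P       6.000      140.0
  N       5.000      215.4
  K       4.000       43.1
  D       3.000       63.1
  E      13.840          -

afferent resistance (mmHg*s/mL): total 5.95e+06 = base 2.78e+06 + TGF 1.401e+05 + MD 8.302e+05 + MA 2.2e+06
```

Autoregulation flattens the GFR–MAP curve; with the feedback loop open
(all gains zero) filtration tracks pressure almost linearly:

```python
>>> from nephroflow import FeedbackGains, SweepSpec
>>> closed = model.sweep()                                        # MAP 54..180
>>> open_ = model.sweep(SweepSpec(gains=FeedbackGains.open_loop()))
>>> for m, gc, go in zip(closed.map_values[4:11:3],
...                      closed.gfr_values[4:11:3], open_.gfr_values[4:11:3]):
...     print(f"MAP {m:5.0f}  closed {gc:7.2f}  open {go:7.2f}")
MAP    90  closed  120.00  open  173.71
MAP   117  closed  138.61  open  255.53
MAP   144  closed  148.71  open  347.84
```

Disease scenarios multiply vascular resistances and feedback gains:

```python
>>> from nephroflow import SEVERE_HYPERTENSION
>>> round(model.with_scenario(SEVERE_HYPERTENSION).solve().gfr, 1)
90.7
```

The same experiments are available from the command line:

```bash
nephroflow solve --map 90
nephroflow sweep --open-loop --out sweep.csv
nephroflow calibrate
nephroflow sensitivity --resistance-alphas 1,2,4,6,8
nephroflow make-synth --seed 7 --n 200 --out obs.csv
nephroflow fit-obs --observations obs.csv
```

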