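# emboclot

Reduced-order, desk-scale modeling of **blood-clot embolization in a tube**:
when does a clot adhering to the wall of a tube detach (embolize) under the
drag of turbulent flow?

The package is aimed at researchers in thrombosis biomechanics and
computational hemodynamics who want the constitutive, geometric and
threshold-analysis machinery of a clot-embolization study without running
3D multiphase CFD. It provides:

* the **Phan-Thien–Tanner (PTT) viscoelastic model** for the clot's
  polymeric (fibrin-network) stress τ, with the exponential destruction
  function

  f(τ) = exp( ε λ tr(τ) / η_p ),

  where λ is the relaxation time, η_p the polymeric viscosity
  (G = η_p/λ is the small-strain elastic modulus) and ε the
  extensibility parameter — large fiber strain λ tr(τ)/η_p collapses the
  stress, emulating breakage of the fibrin/platelet network;
* a **stress-relaxation compression test** simulator (10% strain over 1 s,
  30 s hold, homogeneous incompressible uniaxial closure) and a
  statsmodels-style fitting interface recovering (η_p, λ) from measured
  or synthetic curves;
* the **clot-in-tube geometry** — the intersection of the tube interior
  with a spanwise-oriented cylinder — with adaptive-quadrature volume,
  frontal (projected) area and wall contact area, each cross-checked by
  Monte-Carlo oracles;
* **turbulent pipe-flow loading**: Reynolds numbers, transit timescale
  T = D/U, wall units, the log-law reference profile, the drag
  coefficient C_D = 2F_D/(ρAU²), and a drag-vs-flow-rate law
  F_D = c·Q^p fitted to the packaged drag table of the reference
  simulations;
* a **reduced-order detachment model**: the clot as a chain of stations
  anchored by PTT tether bonds with a wall-specific extensibility ε_w,
  the embolization criterion (leading-edge displacement ≥ 5% of the clot
  length within 10 transit timescales), multiplicative-bisection
  **threshold bracketing** with geometric-mean summaries, and the scaling
  quantity Π = ε_wt λ F_D / (η_p A_c);
* a **synthetic embolization cohort** generator (truncated normal
  moment-matched to the experimental 5.1 ± 1.1 LPM on [2.3, 7.5] LPM)
  mapped through the drag law to per-sample embolization drag forces.

## Worked example

```python
from emboclot import (PTTParameters, ClotGeometry, CompressionProtocol,
                      EmbolizationCriterion, StressRelaxationModel,
                      synth_relaxation_curve)
from emboclot.pipeflow import DragLawModel, load_drag_table
from emboclot.embolization import calibrate_adhesion, threshold_table

params = PTTParameters(eta_p=2.1e4, lambda_relax=6.0, epsilon=0.01)
clot = ClotGeometry(height=0.0026, chord_length=0.0138)  # meters
print(round(clot.volume() * 1e9, 1))        # 158.6  (µL)
print(round(clot.contact_area() * 1e6, 1))  # 130.3  (mm², wall patch)

# recover constitutive parameters from a noisy synthetic relaxation curve
protocol = CompressionProtocol()
curve = synth_relaxation_curve(params, protocol, noise_sd_fraction=0.05,
                               seed=1, n_samples=81)
print(StressRelaxationModel(curve, protocol).fit().summary())
#   eta_p  [Pa s]          2.098e+04
#   lambda [s]                 5.936
#   modulus G [Pa]              3534
#   R^2                       0.9979

# drag law and embolization thresholds across the five flow conditions
drag = DragLawModel(load_drag_table()).fit()     # F = c Q^p, p = 2.081
criterion = EmbolizationCriterion()
adhesion, _ = calibrate_adhesion(clot, params, criterion, drag.predict)
print(threshold_table([1.9, 2.8, 4.2, 6.3, 10.0], clot, params,
                      adhesion, criterion, drag.predict).to_string())
```

The threshold table printed by the last call:

```
 Q_LPM  eps_no  eps_yes  eps_geomean    F_D_N     Pi
   1.9   21.08    26.16        23.49 0.000281 0.0145
   2.8    8.89    11.03         9.90 0.000629 0.0137
   4.2    3.75     4.65         4.18 0.001464 0.0134
   6.3    1.58     1.96         1.76 0.003403 0.0131
  10.0    0.67     0.83         0.74 0.008903 0.0145
```

Read it as: at 4.2 LPM the clot stays attached for wall extensibility
ε_w = 3.75 but detaches at 4.65, so the threshold (geometric mean) is
≈ 4.2 — inside the reference bracket [3, 5] used for calibration. The
threshold decreases monotonically with flow rate (stronger drag needs a
weaker wall to resist it), while Π = ε_wt λ F_D / (η_p A_c) stays flat
at ≈ 0.013–0.015: the wall stress scales with F_D/A_c, so threshold ×
drag is approximately conserved.

A command-line interface mirrors these workflows
(`emboclot geometry`, `emboclot pipeflow-table --Q 1.9`,
`emboclot drag-fit --eval 2.3,7.5`, `emboclot threshold --Q 4.2`,
`emboclot cohort --n 32 --map`, …); every command writes JSON artifacts
plus a provenance stub (config hash, seed, library versions).

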