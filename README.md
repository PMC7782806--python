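# dropforge

Design automation for microfluidic flow-focusing droplet generators.

Droplet microfluidics compartmentalizes reactions into picoliter drops for
single-cell assays, enzyme screens and digital diagnostics — but getting a
device that produces, say, 50 μm droplets at 150 Hz normally takes
expertise and several fabricate-test-revise cycles, because no reliable
closed-form model maps a geometry and flow condition to its performance.
`dropforge` replaces that loop with a predictive stack and its inversion:

* **Performance prediction** — a regime classifier (dripping vs jetting)
  plus four per-regime neural-network regressors predict droplet diameter
  D and generation rate F from the eight design parameters: orifice width
  Or, five geometric ratios normalized to Or, capillary number Ca, and
  flow-rate ratio ϕ = Q_c/Q_d. Conservation of mass, (π/6)·D³·F = Q_d,
  ties the two regressors together through the "inferred diameter"
  D_inf = 10⁶·(6·Q_w/(π·F))^{1/3}, a built-in consistency check.
* **Inverse design** — given a desired (D, F), a greedy
  coordinate-perturbation search over the design space minimizes
  C = |D_des − D_pred| + |F_des − F_pred| + |D_des − D_inf|,
  seeded from the closest observed data points, honoring per-parameter
  constraints, and returning a geometry plus pump settings (Q_c in ml/h,
  Q_d in μl/min).
* **Tolerance analysis** — Sobol variance-based sensitivity over a
  fabrication-tolerance hypercube, principal-parameter heatmap grids, and
  flow-adjustment maps for correcting deviations at the pumps.
* **Single-cell planning** — Poisson loading statistics
  P(λ, k) = e^{−λ}λ^k/k! and the inlet concentration
  C_cells = 60·F·λ/Q_w that delivers a target mean occupancy λ.
* **Transfer learning** — adapt a trained stack to a new fluid pair from
  tens of observations by freezing the early network layers.
* **Synthetic surrogate** — an analytic pseudo-physics with the right
  qualitative shape (smooth, monotone, regime-switched, mass-conserving)
  generates data-sets so the entire stack is testable without a lab.

See `docs/methods.md` for the models, estimators and design choices.

## Worked example

```python
from dropforge.design import DesignSpec, search
from dropforge.synthetic import (SurrogateParams, SurrogatePredictor,
                                 generate_dataset, surrogate_truth)

params = SurrogateParams()
records = generate_dataset(600, params, seed=1)     # synthetic observations
predictor = SurrogatePredictor(params)

spec = DesignSpec(desired_diameter_um=50.0, desired_rate_hz=150.0,
                  constraints={"aspect_ratio": 1.0, "water_inlet_ratio": 2.0})
result = search(predictor, spec, records)
print(result.status, result.to_dict()["dispersed_rate_ul_min"])
truth = surrogate_truth(result.design, params)
print(truth.diameter_um, truth.rate_hz)
```

Running this (it is `examples/03_inverse_design.py`) prints:

```
status: converged after 6 iterations
pump settings: Q_c = 0.689 ml/h, Q_d = 0.580 μl/min
delivered (surrogate truth): 49.8 μm at 150 Hz (0.5% / 0.1% off the request)
```

i.e. the search found a constrained geometry (shallowest allowed channel,
narrowest allowed water inlet) whose true performance is within 0.5% in
diameter and 0.1% in rate of the request. The other scripts in
`examples/` walk through physics arithmetic, training and evaluation,
tolerance analysis, encapsulation planning, and transfer learning, each
printing the numbers it computes and what they mean.

A command-line interface wraps the same library:

```bash
dropforge synth --n 600 --seed 1 --out data.csv
dropforge train data.csv --out run/ --seed 0 --viscosity 0.0572 --sigma 0.005
dropforge design run/stack --dataset data.csv --spec spec.json
dropforge encapsulate --rate 167 --qw 0.52 --lam 0.05
```

## Data

The CSV schema is one row per observation:
`orifice_width_um, aspect_ratio, orifice_length_ratio, water_inlet_ratio,
oil_inlet_ratio, outlet_ratio, capillary_number, flow_rate_ratio, regime,
diameter_um, rate_hz[, polydispersity]`. The published 998-point
experimental data-set (downloadable from dafdcad.org) follows this schema;
place it at `data/droplet_dataset.csv` to enable the optional
reproduction tests. The package never downloads anything itself.

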