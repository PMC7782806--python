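# Methods

## The problem

A flow-focusing droplet generator pinches a dispersed aqueous phase into
monodisperse droplets with a continuous oil phase at a narrow orifice. Its
performance — generation regime (dripping vs jetting), droplet diameter D
(μm) and generation rate F (Hz) — is governed by eight design parameters:
the orifice width Or (μm), five geometric parameters expressed as
dimensionless multiples of Or (channel depth H/Or, orifice length, water
inlet W_d/Or, oil inlet W_c/Or, outlet), and the flow condition given by
the capillary number Ca and the flow-rate ratio ϕ = Q_c/Q_d. No reliable
closed-form or CFD route exists from these parameters to performance, so
this package predicts performance with learned models and inverts that
prediction to automate design.

## Closed-form backbone

Three relations are exact and anchor everything else:

* **Conservation of mass**: (π/6)·D³·F = Q_d. Given any two of
  {D, F, Q_d}, the third follows. The "inferred diameter"
  D_inf = 10⁶·(6·Q_w/(π·F))^{1/3} back-computed from a predicted rate is
  therefore a consistency check on the diameter prediction.
* **Flow conversion**: Q_c = Ca·σ·H·W_c / (μ_c·W_d·[1/Or − 1/(2·W_c)]),
  Q_d = Q_c/ϕ, converting the dimensionless flow condition into pump
  settings for a given geometry and fluid pair (viscosity μ_c, interfacial
  tension σ). σ has no default anywhere in the package: it is a required
  configuration value, because assuming one silently would corrupt every
  downstream flow rate.
* **Error propagation**: at fixed Q_d, F ∝ D⁻³, so a fractional diameter
  error ε_d maps to a rate error ε_f = 1 − (1+ε_d)⁻³ ≈ 3·ε_d − 6·ε_d².
  The ratio ε_f/ε_d is strictly decreasing in ε_d and tends to 3 as the
  perturbation vanishes (from below for growing droplets, from above for
  shrinking ones).

All computation is SI internally (lengths m, flows m³/s); μm, ml/h and
μl/min appear only at I/O boundaries, so unit conversions happen exactly
once per quantity.

## Predictive stack

Prediction is a two-stage pipeline: a binary regime classifier followed by
per-regime diameter and rate regressors (four regressors total). The
classifier trains on all observations; the regressors only on the bounded
performance window 25–250 μm × 5–500 Hz (inclusive endpoints) where data
density supports regression. Keeping independent diameter and rate models,
rather than deriving one from the other, is deliberate: their disagreement
(via D_inf) flags regions where at least one model is unreliable.

Networks are fully connected with three hidden ReLU layers — widths
[32, 32, 16] for regression and [64, 32, 16] for classification — trained
full-batch with Adam (learning rate 10⁻², cap 5000 epochs), early stopping
on a 15% validation carve-out with patience 300, and optional dropout
(default 0). The widths and rates are tool choices; alternatives can be
explored with the built-in grid search (`hyper_search`), which scores
candidates by k-fold cross-validation or a train/holdout split and
persists the full leaderboard. Features are min–max scaled to [0, 1] using
statistics fitted on the training data and stored with the model.
Regression targets are fitted in log space (min–max scaled log-values):
both outcomes are positive with approximately multiplicative noise, and
the exponential inverse guarantees positive predictions.

The implementation keeps explicit per-layer numpy weight arrays so that
transfer learning can freeze the first layers of a pre-trained network and
optionally append fresh layers — operations needed below that high-level
estimators do not expose. Training is deterministic given the seed.

Each trained stack stores its held-out mean absolute error per model.
These "validation tolerances" are not cosmetic: the inverse-design seed
acceptance compares candidate deviations against them, so a stack that
knows itself to be accurate demands more of a seed than a sloppy one.
Predictions outside ~[0.5×, 2×] of the training outcome range raise an
extrapolation warning; design points outside the training parameter ranges
are refused with the offending parameter named.

Persistence is a directory with a JSON manifest (schema version,
architectures, normalization statistics, tolerances, bounds, fluid
properties, provenance) plus an `.npz` weight file whose SHA-256 digest is
checked at load time.

## Inverse design

Given a desired diameter (and optionally rate), the data-set is ranked by
a fitness — Euclidean distance in performance space with diameter scaled
by 1/250 μm and rate by 1/500 Hz — after applying constraints: interval
constraints exclude records; fixed-value constraints project the record's
parameter onto the fixed value (exact matches essentially never occur in
continuous data). If the top seed's observed *and* predicted performance
both sit within the stack's validation tolerances, it is returned as-is.

Otherwise a greedy coordinate-perturbation descent minimizes

C = |D_des − D_pred| + |F_des − F_pred| + |D_des − D_inf|.

Each iteration perturbs every free parameter by ±one normalized step
(default 0.05 of the global range), predicts the up-to-16 candidates, and
moves to the cost argmin if it improves; after three consecutive
non-improving iterations (step halved each time) the search declares
convergence. The cost trace is non-increasing by construction, all
iterates respect constraints and bounds, and ties break deterministically
by parameter index.

Two design choices here were genuinely open. First, the unweighted sum of
a μm term and a Hz term makes the rate term dominate axis-aligned moves in
regions where dF/dD is steep (dF ≈ −3F/D·dD), and a single greedy path can
stall several percent away from an achievable design. The search therefore
descends from the top five fitness-ranked seeds and returns the
lowest-final-cost run; the ranking exists precisely to order alternative
starting basins, and five starts cost well under a second. Second, the
step-halving budget resets after every improving move (consecutive-stall
semantics), matching standard compass-search practice. In diameter-only
mode the rate term is dropped but the D_inf redundancy term is kept.

## Tolerance analysis

Fabrication and pumps deliver a design only to within a tolerance t
(multiplicative, per parameter: the hypercube [p(1−t), p(1+t)], clipped at
hard floors such as the 75 μm minimum orifice). Sensitivity of predicted
diameter and rate over that hypercube is estimated with the pick-freeze
(Saltelli) scheme on a scrambled Sobol' sequence (default 1024 base
samples per block, plus two cross-blocks per parameter): first-order
indices from
mean(f_B·(f_{AB_i} − f_A))/Var, total-effect from
mean((f_A − f_{AB_i})²)/(2·Var), and second-order interactions from the
closed two-parameter variance minus the first-order terms. The estimators
are validated in the tests against closed-form variance shares of an
additive linear response and against a brute-force double-loop Monte-Carlo
oracle.

The parameter with the largest total-effect index (ties broken by
parameter order) is the "principal" parameter per output; it is tabulated
against every other parameter over the levels {−t, 0, +t} in 3×3 grids
whose center cell is exactly the nominal prediction. The flow-adjustment
map predicts performance over a grid of (Q_c, Q_d) spanning ±2t (default
21×21), recovering Ca and ϕ from each flow pair by inverting the flow
conversion; cells whose implied condition leaves the stack's supported
ranges are flagged invalid rather than extrapolated.

## Transfer learning

To support a new fluid pair from tens rather than hundreds of
observations, the pre-trained regressors are fine-tuned with their first
two layers frozen (loaded without the ability to be retrained); for
strongly shifted fluids one layer is frozen and fresh hidden layers are
appended before the output head. Normalization statistics and target
scales are inherited from the pre-trained stack so the frozen feature
representation stays meaningful. The paired evaluation protocol splits the
small set into four non-overlapping folds and trains both the fine-tuned
and a from-scratch network of identical architecture on each 3-fold
train-set, scoring on the held-out fold until every fold has been the test
set once.

## Single-cell encapsulation

Cell capture is Poisson: P(λ, k) = e^{−λ}·λ^k/k! with λ the mean cells
per droplet, kept at 0.05–0.1 (default 0.05) so single-cell events
dominate multi-cell events at the price of ~95% empty droplets. The inlet
concentration delivering a target λ for a device generating F Hz from
Q_w μl/min is C_cells = 60·F·λ/Q_w (cells/μl). The pmf is evaluated
through scipy's log-space implementation (stable to λ = 10, k = 100), and
expected occupancy tables report the residual mass beyond the truncation.

## Synthetic surrogate

The surrogate generator exists so every module is testable without
experimental data. Its diameter law
D = k0·Or·(c0 + c1·ϕ^{−c2})·Ca^{−c3}·aspect^{c4} (defaults k0 = 0.3,
c0 = 0.6, c1 = 1.8, c2 = 0.4, c3 = 0.25, c4 = 0.2) is *not* a physical
model — the coefficients are arbitrary — but it has the right shape:
smooth, monotone decreasing in Ca and ϕ, proportional to orifice width.
The regime boundary is monotone in Ca (jetting iff Ca > 0.12·ϕ^{−0.1});
the rate follows from conservation of mass with Q_d from the flow
conversion (σ = 0.005 N/m, μ_c = 0.0572 Pa·s); measurement noise is
multiplicative log-normal on the diameter (sd 0.05, a typical measurement
CV) with the rate recomputed from the noisy diameter so every record
conserves mass exactly. Sampling ranges: Or 75–300 μm, aspect 1–3, water
inlet 2–4, other ratios 1–4, Ca 0.02–0.8 (log-uniform, placing both
regimes well inside the sample), ϕ 2–40. With these defaults roughly
two-thirds of generated records land inside the bounded performance
window — the rate spans orders of magnitude over the Ca range, so a
substantial out-of-window fraction is intrinsic to the law — and both
regimes hold well over 20% share. The property-shifted variant scales
c0–c3 by a factor (default 1.25), producing systematically larger
droplets at matched inputs, as a stand-in for a fluid-property change.

What passing against the surrogate shows: the pipeline machinery —
training, routing, inversion, sensitivity, transfer — behaves correctly
on data with the right structure. What it does not show: accuracy on real
devices, where noise is not purely multiplicative, regime boundaries are
fuzzy, and the diameter law is not a separable power law.

## Problem sizes and numerical choices

Default experiment sizes, chosen to keep a full run on one CPU core in
minutes: 600 training records (the regression pools after bound-filtering
and splitting are then ≈90 dripping / ≈240 jetting); 200 noise-free
records for unseen-point evaluation; a 3×3 grid of design requests
(D ∈ {50, 100, 150} μm × F ∈ {50, 150, 300} Hz); ten 36-point shifted sets
for the transfer comparison (lighter training config: 1500 epochs,
patience 100); and a 1000-record pool for the data-reduction endpoint
comparison (sizes 50 vs 325, five repetitions, jetting diameter — the
dripping pool is too small for 325-point sub-samples at these defaults).
Degenerate inputs are handled explicitly: zero-width normalization maps to
0.5 with a warning, zero output variance yields zero sensitivity indices
with a warning, tolerance boxes clip at hard floors with a warning, and a
regime with fewer than 30 bounded records refuses regressor training and
points to transfer learning.

## Known limitations

Only dripping and jetting are modeled (no squeezing or tip-streaming); the
greedy search is local by design (no global optimizer); uncertainty is
reported only as repeated-session standard deviations; the surrogate is a
test harness, not physics; and the fitness and model-tolerance constants
of seeding reconstruct a published behavior whose exact constants are not
public, so they are documented choices rather than reproductions.
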