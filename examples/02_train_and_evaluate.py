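"""Train the predictive stack on synthetic observations and evaluate it.

Generates 600 surrogate observations (the built-in pseudo-physics with 5%
multiplicative measurement noise), trains the regime classifier on all of
them and the four per-regime regressors on the bounded 25–250 μm /
5–500 Hz window, then reports held-out metrics.
"""

from dropforge.dataset import split_train_test
from dropforge.predictor import TrainingConfig, evaluate, train_stack
from dropforge.synthetic import SurrogateParams, generate_dataset

params = SurrogateParams()
records = generate_dataset(600, params, seed=1)
stack = train_stack(records, TrainingConfig(seed=0), fluids=params.fluids)

_, test = split_train_test(records, 0.2, seed=0)
report = evaluate(stack, test)
print(f"regime classifier accuracy: {report.classifier_accuracy:.3f}")
for (regime, target), m in sorted(report.per_model.items()):
    unit = "μm" if target == "diameter" else "Hz"
    print(f"{regime:>9} {target:>8}: MAE {m.mae:6.2f} {unit}  "
          f"MAPE {m.mape:5.1f}%  R² {m.r2:.3f}")
# The held-out MAEs double as the stack's validation tolerances: the
# inverse-design seed acceptance compares candidate deviations against them.
print("stored tolerances:",
      {f"{r}/{t}": round(v, 2) for (r, t), v in stack.tolerances.items()})
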