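"""The predictive stack: regime classifier + four per-regime regressors.

Performance prediction is a two-step pipeline: first classify the
generation regime (dripping vs jetting) from the eight design parameters,
then predict droplet diameter and generation rate with the regressors
trained for that regime. The classifier is trained on all observations;
the regressors only on the bounded performance window (25–250 μm,
5–500 Hz) where data density supports regression.

Each trained stack carries its min–max normalization statistics, the
per-model held-out mean absolute errors (the "validation tolerances" the
inverse-design seed acceptance uses), feature bounds, and provenance
metadata, and can be persisted to a directory and reloaded bit-stably.

Transfer learning: a pre-trained stack's early layers can be frozen and
its late layers fine-tuned on a small data-set for a new fluid pair
(:func:`fine_tune`), optionally appending fresh layers for strongly
shifted fluids.
"""

from __future__ import annotations

import copy
import hashlib
import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from sklearn.metrics import mean_absolute_error, mean_squared_error, r2_score
from sklearn.model_selection import KFold

from . import physics
from .dataset import (
    DIAMETER_RANGE_UM,
    RATE_RANGE_HZ,
    NormalizationStats,
    ObservationRecord,
    bound_filter,
    normalize_features,
    split_train_test,
)
from .nn import MLP, extend_network
from .physics import (
    DRIPPING,
    FEATURE_NAMES,
    JETTING,
    REGIMES,
    DesignPoint,
    FluidPair,
    Performance,
)

__all__ = [
    "TrainingConfig",
    "PredictorStack",
    "MetricValues",
    "MetricsReport",
    "HyperSearchSpec",
    "ValidityError",
    "ExtrapolationWarning",
    "train_stack",
    "predict",
    "evaluate",
    "repeated_sessions",
    "data_reduction_experiment",
    "hyper_search",
    "save_stack",
    "load_stack",
    "fine_tune",
]

STACK_FORMAT_VERSION = "dropforge-stack-1"
TARGETS = ("diameter", "rate")
MIN_REGIME_RECORDS = 30


class ValidityError(ValueError):
    """A design point falls outside the stack's supported parameter bounds."""


class ExtrapolationWarning(UserWarning):
    """Predicted performance far outside the training outcome range."""


@dataclass(frozen=True)
class TrainingConfig:
    """Hyperparameters for training the stack.

    Depth is three or four hidden layers with rectified-linear activations,
    trained with the Adam optimizer, optional dropout, and early stopping —
    widths and rates are tool choices.
    """

    regressor_hidden: tuple[int, ...] = (32, 32, 16)
    classifier_hidden: tuple[int, ...] = (64, 32, 16)
    learning_rate: float = 1e-2
    dropout: float = 0.0
    epochs: int = 5000
    patience: int = 300
    val_fraction: float = 0.15
    test_fraction: float = 0.2
    repetitions: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        for hidden in (self.regressor_hidden, self.classifier_hidden):
            if len(hidden) not in (3, 4):
                raise ValueError("hidden layer count must be 3 or 4")
        for frac in (self.val_fraction, self.test_fraction):
            if not 0 < frac < 1:
                raise ValueError("fractions must be in (0, 1)")


@dataclass
class _TargetScale:
    """Min–max scaling of log-targets.

    Diameter and rate are positive with roughly multiplicative noise, so
    the regressors fit log-values scaled to [0, 1]; predictions are
    exponentiated back, which also guarantees positive outputs.
    """

    lo: float  # min/max of the raw training targets
    hi: float

    def transform(self, y: np.ndarray) -> np.ndarray:
        y = np.asarray(y, dtype=float)
        width = np.log(self.hi) - np.log(self.lo)
        if width <= 0:
            return np.full_like(y, 0.5)
        return (np.log(y) - np.log(self.lo)) / width

    def inverse(self, z: np.ndarray) -> np.ndarray:
        z = np.asarray(z, dtype=float)
        width = np.log(self.hi) - np.log(self.lo)
        return np.exp(z * width + np.log(self.lo)) if width > 0 else \
            np.full_like(z, self.lo)


@dataclass
class PredictorStack:
    """Trained classifier + per-regime regressors with their statistics."""

    classifier: MLP
    regressors: dict  # (regime, target) -> MLP
    norm_stats: NormalizationStats
    target_scales: dict  # (regime, target) -> _TargetScale
    tolerances: dict  # (regime, target) -> held-out MAE
    classifier_accuracy: float
    feature_bounds: np.ndarray  # (8, 2) training min/max per parameter
    outcome_ranges: dict  # target -> (min, max) over training outcomes
    fluids: FluidPair
    provenance: dict = field(default_factory=dict)
    diameter_validity_um: tuple[float, float] = DIAMETER_RANGE_UM
    rate_validity_hz: tuple[float, float] = RATE_RANGE_HZ

    def tolerance(self, target: str, regime: str) -> float:
        return self.tolerances[(regime, target)]

    def predict(self, design: DesignPoint) -> Performance:
        return predict(self, design)


def _design_matrix(records: list[ObservationRecord]) -> np.ndarray:
    return np.array([r.design.to_vector() for r in records], dtype=float)


def _check_bounds(stack: PredictorStack, design: DesignPoint) -> None:
    vec = np.asarray(design.to_vector(), dtype=float)
    lo, hi = stack.feature_bounds[:, 0], stack.feature_bounds[:, 1]
    rel = 1e-9 * np.maximum(np.abs(lo), np.abs(hi))
    for i, name in enumerate(FEATURE_NAMES):
        if vec[i] < lo[i] - rel[i] or vec[i] > hi[i] + rel[i]:
            raise ValidityError(
                f"{name}={vec[i]:g} outside supported range "
                f"[{lo[i]:g}, {hi[i]:g}]"
            )


def train_stack(
    records: list[ObservationRecord],
    config: TrainingConfig | None = None,
    fluids: FluidPair | None = None,
) -> PredictorStack:
    """Train the full predictive stack on an observation data-set.

    The classifier sees every record; the four regressors see the
    bound-filtered records of their regime. A held-out split (the config's
    ``test_fraction``) provides each model's validation MAE, stored as the
    stack's tolerances. Training is reproducible given the config seed.
    ``fluids`` supplies μ_c and σ for converting (Ca, ϕ) to flow rates at
    prediction time; there is no silent default for σ.
    """
    config = config or TrainingConfig()
    if fluids is None:
        raise ValueError("fluids (μ_c and σ) must be provided; no silent default")

    x_all, norm_stats = normalize_features(records)
    y_regime = np.array(
        [1.0 if r.outcome.regime == JETTING else 0.0 for r in records])

    train_recs, test_recs = split_train_test(
        records, test_fraction=config.test_fraction, seed=config.seed)

    # --- classifier: all records ---------------------------------------
    x_train = norm_stats.transform(_design_matrix(train_recs))
    y_train = np.array(
        [1.0 if r.outcome.regime == JETTING else 0.0 for r in train_recs])
    x_test = norm_stats.transform(_design_matrix(test_recs))
    y_test = np.array(
        [1.0 if r.outcome.regime == JETTING else 0.0 for r in test_recs])
    classifier = MLP([8, *config.classifier_hidden, 1],
                     task="classification", seed=config.seed)
    classifier.fit(x_train, y_train, epochs=config.epochs,
                   learning_rate=config.learning_rate, dropout=config.dropout,
                   patience=config.patience, val_fraction=config.val_fraction,
                   seed=config.seed)
    acc = float(np.mean((classifier.predict(x_test)[:, 0] >= 0.5) == (y_test >= 0.5)))

    # --- regressors: bounded window, per regime -------------------------
    regressors: dict = {}
    target_scales: dict = {}
    tolerances: dict = {}
    bounded_train = bound_filter(train_recs)
    bounded_test = bound_filter(test_recs)
    for regime in REGIMES:
        regime_train = [r for r in bounded_train if r.outcome.regime == regime]
        regime_test = [r for r in bounded_test if r.outcome.regime == regime]
        if len(regime_train) < MIN_REGIME_RECORDS:
            raise ValueError(
                f"regime '{regime}' has {len(regime_train)} bounded training "
                f"records (< {MIN_REGIME_RECORDS}); train on more data or use "
                f"transfer learning (fine_tune) from a pre-trained stack"
            )
        xr = norm_stats.transform(_design_matrix(regime_train))
        xt = norm_stats.transform(_design_matrix(regime_test))
        for target in TARGETS:
            getter = (lambda r: r.outcome.diameter_um) if target == "diameter" \
                else (lambda r: r.outcome.rate_hz)
            y = np.array([getter(r) for r in regime_train])
            scale = _TargetScale(float(y.min()), float(y.max()))
            model_offset = 1 + REGIMES.index(regime) * len(TARGETS) \
                + TARGETS.index(target)
            net = MLP([8, *config.regressor_hidden, 1], task="regression",
                      seed=config.seed + model_offset)
            net.fit(xr, scale.transform(y), epochs=config.epochs,
                    learning_rate=config.learning_rate, dropout=config.dropout,
                    patience=config.patience, val_fraction=config.val_fraction,
                    seed=config.seed)
            regressors[(regime, target)] = net
            target_scales[(regime, target)] = scale
            if regime_test:
                y_true = np.array([getter(r) for r in regime_test])
                y_pred = scale.inverse(net.predict(xt)[:, 0])
                tolerances[(regime, target)] = float(
                    mean_absolute_error(y_true, y_pred))
            else:
                tolerances[(regime, target)] = float("nan")

    x_mat = _design_matrix(records)
    diameters = np.array([r.outcome.diameter_um for r in bound_filter(records)])
    rates = np.array([r.outcome.rate_hz for r in bound_filter(records)])
    return PredictorStack(
        classifier=classifier,
        regressors=regressors,
        norm_stats=norm_stats,
        target_scales=target_scales,
        tolerances=tolerances,
        classifier_accuracy=acc,
        feature_bounds=np.column_stack([x_mat.min(axis=0), x_mat.max(axis=0)]),
        outcome_ranges={
            "diameter": (float(diameters.min()), float(diameters.max())),
            "rate": (float(rates.min()), float(rates.max())),
        },
        fluids=fluids,
        provenance={
            "seed": config.seed,
            "n_records": len(records),
            "data_fingerprint": hashlib.sha256(
                np.ascontiguousarray(x_all).tobytes()).hexdigest()[:16],
        },
    )


def predict(stack: PredictorStack, design: DesignPoint) -> Performance:
    """Predict regime, diameter, rate, and the mass-conservation check.

    The inferred diameter is back-computed from the predicted rate and the
    dispersed flow rate (from the flow condition, geometry and fluid pair),
    so that disagreement between the two regressors is visible. Raises
    :class:`ValidityError` for out-of-bounds design points; warns with
    :class:`ExtrapolationWarning` when a prediction leaves ~[0.5×, 2×] of
    the training outcome range.
    """
    _check_bounds(stack, design)
    z = stack.norm_stats.transform(
        np.asarray(design.to_vector(), dtype=float)[None, :])
    p_jet = float(stack.classifier.predict(z)[0, 0])
    regime = JETTING if p_jet >= 0.5 else DRIPPING
    out = {}
    for target in TARGETS:
        net = stack.regressors[(regime, target)]
        scale = stack.target_scales[(regime, target)]
        value = float(scale.inverse(net.predict(z)[0, 0]))
        lo, hi = stack.outcome_ranges[target]
        if not 0.5 * lo <= value <= 2.0 * hi:
            warnings.warn(
                f"predicted {target} {value:g} outside ~[0.5×, 2×] the "
                f"training range [{lo:g}, {hi:g}]", ExtrapolationWarning)
        out[target] = max(value, 1e-6)  # keep physical positivity
    flow = physics.flow_rates_from_dimensionless(
        design.flow, design.geometry, stack.fluids)
    d_inf = physics.infer_diameter(flow.dispersed_rate, out["rate"])
    return Performance(
        regime=regime,
        diameter_um=out["diameter"],
        rate_hz=out["rate"],
        inferred_diameter_um=d_inf,
    )


@dataclass(frozen=True)
class MetricValues:
    r2: float
    rmse: float
    mape: float
    mae: float


@dataclass(frozen=True)
class MetricsReport:
    """Per-model metrics, optionally aggregated over repeated sessions."""

    per_model: dict  # (regime, target) -> MetricValues | (mean, sd) dict
    classifier_accuracy: float | tuple[float, float]
    n_sessions: int = 1


def _metrics(y_true: np.ndarray, y_pred: np.ndarray) -> MetricValues:
    nonzero = y_true != 0
    if not np.all(nonzero):
        warnings.warn("zero-valued truth excluded from MAPE")
    mape = float(np.mean(
        np.abs((y_true[nonzero] - y_pred[nonzero]) / y_true[nonzero])) * 100.0)
    return MetricValues(
        r2=float(r2_score(y_true, y_pred)),
        rmse=float(np.sqrt(mean_squared_error(y_true, y_pred))),
        mape=mape,
        mae=float(mean_absolute_error(y_true, y_pred)),
    )


def evaluate(stack: PredictorStack, test_records: list[ObservationRecord]
             ) -> MetricsReport:
    """R², RMSE, MAPE and MAE per regime and target, plus classifier accuracy.

    Regime-specific regressors are scored on the test records whose observed
    regime matches (the regressor pipeline's ground-truth routing); the
    classifier on all test records.
    """
    if not test_records:
        raise ValueError("test set must be nonempty")
    x = stack.norm_stats.transform(_design_matrix(test_records))
    y_true_regime = np.array(
        [1.0 if r.outcome.regime == JETTING else 0.0 for r in test_records])
    pred_regime = (stack.classifier.predict(x)[:, 0] >= 0.5).astype(float)
    accuracy = float(np.mean(pred_regime == y_true_regime))

    per_model = {}
    for regime in REGIMES:
        idx = [i for i, r in enumerate(test_records) if r.outcome.regime == regime]
        if not idx:
            continue
        xr = x[idx]
        for target in TARGETS:
            getter = (lambda r: r.outcome.diameter_um) if target == "diameter" \
                else (lambda r: r.outcome.rate_hz)
            y_true = np.array([getter(test_records[i]) for i in idx])
            net = stack.regressors[(regime, target)]
            scale = stack.target_scales[(regime, target)]
            y_pred = scale.inverse(net.predict(xr)[:, 0])
            per_model[(regime, target)] = _metrics(y_true, y_pred)
    return MetricsReport(per_model=per_model, classifier_accuracy=accuracy)


def repeated_sessions(
    records: list[ObservationRecord],
    config: TrainingConfig | None = None,
    fluids: FluidPair | None = None,
    n_sessions: int | None = None,
) -> MetricsReport:
    """Train/test over several random splits; report mean ± sd per metric.

    Each session redraws the 80/20 split (seed + session index), retrains
    the full stack, and evaluates on its held-out records.
    """
    config = config or TrainingConfig()
    n_sessions = n_sessions or config.repetitions
    if n_sessions < 2:
        raise ValueError("need ≥ 2 sessions for a mean ± sd report")
    metric_names = ("r2", "rmse", "mape", "mae")
    collected: dict = {}
    accs = []
    for s in range(n_sessions):
        cfg = TrainingConfig(**{**asdict(config), "seed": config.seed + s})
        _, test = split_train_test(records, config.test_fraction, seed=cfg.seed)
        stack = train_stack(records, cfg, fluids=fluids)
        report = evaluate(stack, test)
        accs.append(report.classifier_accuracy)
        for key, vals in report.per_model.items():
            for m in metric_names:
                collected.setdefault((key, m), []).append(getattr(vals, m))
    per_model = {}
    for regime in REGIMES:
        for target in TARGETS:
            key = (regime, target)
            if (key, "mae") in collected:
                per_model[key] = {
                    m: (float(np.mean(collected[(key, m)])),
                        float(np.std(collected[(key, m)], ddof=1)))
                    for m in metric_names
                }
    return MetricsReport(
        per_model=per_model,
        classifier_accuracy=(float(np.mean(accs)), float(np.std(accs, ddof=1))),
        n_sessions=n_sessions,
    )


def data_reduction_experiment(
    records: list[ObservationRecord],
    sizes: tuple[int, ...] = (50, 100, 150, 200, 250, 300, 325),
    repetitions: int = 10,
    seed: int = 0,
    config: TrainingConfig | None = None,
    regimes: tuple[str, ...] = REGIMES,
    targets: tuple[str, ...] = TARGETS,
) -> dict:
    """Accuracy vs training-set size, per regime.

    A fixed 20% test split is drawn once; for each sub-sample size and
    repetition, that many records are drawn from the bounded per-regime
    train pool, a regressor is trained, and all four metrics are computed
    on the fixed test split. Sizes exceeding the pool are skipped with a
    warning. Returns ``{(regime, target, size): {metric: (mean, sd)}}``.
    """
    config = config or TrainingConfig()
    train_recs, test_recs = split_train_test(records, 0.2, seed=seed)
    bounded_train = bound_filter(train_recs)
    bounded_test = bound_filter(test_recs)
    x_stats = normalize_features(records)[1]
    rng = np.random.default_rng(seed)
    curves: dict = {}
    for regime in regimes:
        pool = [r for r in bounded_train if r.outcome.regime == regime]
        test = [r for r in bounded_test if r.outcome.regime == regime]
        x_test = x_stats.transform(_design_matrix(test))
        for target in targets:
            getter = (lambda r: r.outcome.diameter_um) if target == "diameter" \
                else (lambda r: r.outcome.rate_hz)
            y_test = np.array([getter(r) for r in test])
            for size in sizes:
                if size > len(pool):
                    warnings.warn(
                        f"size {size} exceeds {regime} pool ({len(pool)}); skipped")
                    continue
                runs = {m: [] for m in ("r2", "rmse", "mape", "mae")}
                for rep in range(repetitions):
                    sub_idx = rng.choice(len(pool), size=size, replace=False)
                    sub = [pool[i] for i in sub_idx]
                    x = x_stats.transform(_design_matrix(sub))
                    y = np.array([getter(r) for r in sub])
                    scale = _TargetScale(float(y.min()), float(y.max()))
                    net = MLP([8, *config.regressor_hidden, 1],
                              task="regression", seed=seed + rep)
                    net.fit(x, scale.transform(y), epochs=config.epochs,
                            learning_rate=config.learning_rate,
                            patience=config.patience,
                            val_fraction=config.val_fraction, seed=seed + rep)
                    y_pred = scale.inverse(net.predict(x_test)[:, 0])
                    vals = _metrics(y_test, y_pred)
                    for m in runs:
                        runs[m].append(getattr(vals, m))
                curves[(regime, target, size)] = {
                    m: (float(np.mean(v)),
                        float(np.std(v, ddof=1)) if len(v) > 1 else 0.0)
                    for m, v in runs.items()
                }
    return curves


@dataclass(frozen=True)
class HyperSearchSpec:
    """Grid and validation protocol for the hyperparameter search."""

    hidden_grid: tuple[tuple[int, ...], ...] = ((32, 32, 16), (64, 32, 16))
    dropout_grid: tuple[float, ...] = (0.0,)
    learning_rate_grid: tuple[float, ...] = (1e-2,)
    epochs_grid: tuple[int, ...] = (5000,)
    validation: str = "kfold"  # or "holdout"
    n_folds: int = 4
    metric: str = "mae"
    test_fraction: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if not (self.hidden_grid and self.dropout_grid and self.learning_rate_grid):
            raise ValueError("grids must be nonempty")
        if self.validation == "kfold" and self.n_folds < 2:
            raise ValueError("need ≥ 2 folds")


def hyper_search(
    records: list[ObservationRecord],
    spec: HyperSearchSpec | None = None,
    target: str = "diameter",
) -> tuple[TrainingConfig, list[dict]]:
    """Grid search over network hyperparameters for one regression target.

    Each candidate is scored by the spec's validation method (k-fold CV or
    a single train/holdout split) on the bounded data-set. Returns the best
    config and the full leaderboard sorted by score (error metric:
    ascending). All candidates failing (non-finite scores) raises.
    """
    spec = spec or HyperSearchSpec()
    bounded = bound_filter(records)
    x = _design_matrix(bounded)
    stats = normalize_features(bounded)[1]
    x = stats.transform(x)
    getter = (lambda r: r.outcome.diameter_um) if target == "diameter" \
        else (lambda r: r.outcome.rate_hz)
    y = np.array([getter(r) for r in bounded])

    def score_candidate(hidden, dropout, lr, epochs) -> float:
        def one(train_idx, val_idx) -> float:
            scale = _TargetScale(float(y[train_idx].min()), float(y[train_idx].max()))
            net = MLP([8, *hidden, 1], task="regression", seed=spec.seed)
            net.fit(x[train_idx], scale.transform(y[train_idx]), epochs=epochs,
                    learning_rate=lr, dropout=dropout, seed=spec.seed)
            pred = scale.inverse(net.predict(x[val_idx])[:, 0])
            return float(mean_absolute_error(y[val_idx], pred))
        if spec.validation == "kfold":
            folds = KFold(n_splits=spec.n_folds, shuffle=True,
                          random_state=spec.seed)
            return float(np.mean([one(tr, va) for tr, va in folds.split(x)]))
        n_test = max(1, int(round(len(x) * spec.test_fraction)))
        perm = np.random.default_rng(spec.seed).permutation(len(x))
        return one(perm[n_test:], perm[:n_test])

    leaderboard = []
    for hidden in spec.hidden_grid:
        for dropout in spec.dropout_grid:
            for lr in spec.learning_rate_grid:
                for epochs in spec.epochs_grid:
                    score = score_candidate(hidden, dropout, lr, epochs)
                    leaderboard.append({
                        "hidden": tuple(hidden), "dropout": dropout,
                        "learning_rate": lr, "epochs": epochs, "score": score,
                    })
    if not any(np.isfinite(c["score"]) for c in leaderboard):
        raise RuntimeError(
            "all candidates failed to converge: "
            + "; ".join(f"{c['hidden']}→{c['score']}" for c in leaderboard))
    leaderboard.sort(key=lambda c: (c["score"], c["hidden"]))
    best = leaderboard[0]
    best_config = TrainingConfig(
        regressor_hidden=best["hidden"],
        learning_rate=best["learning_rate"],
        dropout=best["dropout"],
        epochs=best["epochs"],
        seed=spec.seed,
    )
    return best_config, leaderboard


# --------------------------------------------------------------------- #
# Persistence

def _model_key(regime: str, target: str) -> str:
    return f"{regime}_{target}"


def save_stack(stack: PredictorStack, path) -> None:
    """Persist a stack: JSON manifest + portable npz weight arrays.

    The manifest stores the schema version, architectures, normalization
    statistics, tolerances, bounds, fluids and provenance, plus a SHA-256
    digest of the weight file so tampering is detected at load time.
    """
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    arrays: dict[str, np.ndarray] = {}
    nets = {"classifier": stack.classifier}
    nets.update({_model_key(r, t): net for (r, t), net in stack.regressors.items()})
    for name, net in nets.items():
        for i, (w, b) in enumerate(zip(net.weights, net.biases)):
            arrays[f"{name}_w{i}"] = w
            arrays[f"{name}_b{i}"] = b
    weights_path = path / "weights.npz"
    np.savez(weights_path, **arrays)
    digest = hashlib.sha256(weights_path.read_bytes()).hexdigest()
    manifest = {
        "format_version": STACK_FORMAT_VERSION,
        "weights_sha256": digest,
        "classifier": stack.classifier.to_dict(),
        "regressors": {
            _model_key(r, t): net.to_dict()
            for (r, t), net in stack.regressors.items()
        },
        "norm_stats": {
            "feature_names": list(stack.norm_stats.feature_names),
            "minima": stack.norm_stats.minima.tolist(),
            "maxima": stack.norm_stats.maxima.tolist(),
        },
        "target_scales": {
            _model_key(r, t): [s.lo, s.hi]
            for (r, t), s in stack.target_scales.items()
        },
        "tolerances": {
            _model_key(r, t): v for (r, t), v in stack.tolerances.items()},
        "classifier_accuracy": stack.classifier_accuracy,
        "feature_bounds": stack.feature_bounds.tolist(),
        "outcome_ranges": {k: list(v) for k, v in stack.outcome_ranges.items()},
        "fluids": {
            "continuous_viscosity": stack.fluids.continuous_viscosity,
            "interfacial_tension": stack.fluids.interfacial_tension,
            "continuous_label": stack.fluids.continuous_label,
            "dispersed_label": stack.fluids.dispersed_label,
        },
        "provenance": stack.provenance,
        "diameter_validity_um": list(stack.diameter_validity_um),
        "rate_validity_hz": list(stack.rate_validity_hz),
    }
    (path / "manifest.json").write_text(json.dumps(manifest, indent=2))


def load_stack(path) -> PredictorStack:
    """Load a persisted stack; verifies schema version and weight integrity."""
    path = Path(path)
    manifest = json.loads((path / "manifest.json").read_text())
    if manifest.get("format_version") != STACK_FORMAT_VERSION:
        raise ValueError(
            f"unsupported stack format {manifest.get('format_version')!r}; "
            f"expected {STACK_FORMAT_VERSION!r}")
    weights_path = path / "weights.npz"
    digest = hashlib.sha256(weights_path.read_bytes()).hexdigest()
    if digest != manifest["weights_sha256"]:
        raise ValueError("weight file integrity check failed (digest mismatch)")
    arrays = np.load(weights_path)

    def restore(name: str, meta: dict) -> MLP:
        net = MLP.from_dict(meta)
        net.weights = [arrays[f"{name}_w{i}"] for i in range(net.n_layers)]
        net.biases = [arrays[f"{name}_b{i}"] for i in range(net.n_layers)]
        return net

    classifier = restore("classifier", manifest["classifier"])
    regressors = {}
    target_scales = {}
    tolerances = {}
    for key, meta in manifest["regressors"].items():
        regime, target = key.split("_", 1)
        regressors[(regime, target)] = restore(key, meta)
        lo, hi = manifest["target_scales"][key]
        target_scales[(regime, target)] = _TargetScale(lo, hi)
        tolerances[(regime, target)] = manifest["tolerances"][key]
    fl = manifest["fluids"]
    return PredictorStack(
        classifier=classifier,
        regressors=regressors,
        norm_stats=NormalizationStats(
            feature_names=tuple(manifest["norm_stats"]["feature_names"]),
            minima=np.array(manifest["norm_stats"]["minima"]),
            maxima=np.array(manifest["norm_stats"]["maxima"]),
        ),
        target_scales=target_scales,
        tolerances=tolerances,
        classifier_accuracy=manifest["classifier_accuracy"],
        feature_bounds=np.array(manifest["feature_bounds"]),
        outcome_ranges={k: tuple(v) for k, v in manifest["outcome_ranges"].items()},
        fluids=FluidPair(
            continuous_viscosity=fl["continuous_viscosity"],
            interfacial_tension=fl["interfacial_tension"],
            continuous_label=fl["continuous_label"],
            dispersed_label=fl["dispersed_label"],
        ),
        provenance=manifest["provenance"],
        diameter_validity_um=tuple(manifest["diameter_validity_um"]),
        rate_validity_hz=tuple(manifest["rate_validity_hz"]),
    )


def fine_tune(
    pretrained: PredictorStack,
    small_records: list[ObservationRecord],
    frozen_layers: int = 2,
    config: TrainingConfig | None = None,
    add_layers: tuple[int, ...] = (),
    targets: tuple[str, ...] = TARGETS,
) -> PredictorStack:
    """Adapt a pre-trained stack to a small data-set for new fluids.

    The first ``frozen_layers`` weight layers of each regressor are loaded
    without the ability to be retrained; the remaining layers are updated
    on the new records. For strongly shifted fluid properties, pass
    ``add_layers`` to append freshly initialized hidden layers before the
    output head (then typically with ``frozen_layers=1``). Regimes absent
    from ``small_records`` keep their pre-trained regressors. Normalization
    statistics and target scales are inherited from the pre-trained stack
    so the frozen feature representation stays meaningful.
    """
    config = config or TrainingConfig()
    depth = pretrained.regressors[(DRIPPING, "diameter")].n_layers
    if frozen_layers >= depth + len(add_layers):
        raise ValueError(f"frozen_layers={frozen_layers} must be < network depth")
    new_stack = copy.deepcopy(pretrained)
    bounded = bound_filter(small_records)
    for regime in REGIMES:
        regime_recs = [r for r in bounded if r.outcome.regime == regime]
        if not regime_recs:
            continue
        x = pretrained.norm_stats.transform(_design_matrix(regime_recs))
        for target in targets:
            getter = (lambda r: r.outcome.diameter_um) if target == "diameter" \
                else (lambda r: r.outcome.rate_hz)
            y = np.array([getter(r) for r in regime_recs])
            scale = pretrained.target_scales[(regime, target)]
            net = copy.deepcopy(pretrained.regressors[(regime, target)])
            if add_layers:
                net = extend_network(net, list(add_layers), seed=config.seed)
            net.fit(x, scale.transform(y), epochs=config.epochs,
                    learning_rate=config.learning_rate, dropout=config.dropout,
                    patience=config.patience, val_fraction=config.val_fraction,
                    frozen_layers=frozen_layers, seed=config.seed)
            new_stack.regressors[(regime, target)] = net
    new_stack.provenance = dict(pretrained.provenance)
    new_stack.provenance.update({
        "fine_tuned": True,
        "frozen_layers": frozen_layers,
        "n_small_records": len(small_records),
    })
    return new_stack


def transfer_experiment(
    pretrained: PredictorStack,
    small_records: list[ObservationRecord],
    frozen_layers: int = 2,
    add_layers: tuple[int, ...] = (),
    config: TrainingConfig | None = None,
    n_folds: int = 4,
    seed: int = 0,
    target: str = "diameter",
) -> dict:
    """Paired fine-tuned vs scratch-trained comparison on a small data-set.

    The small set is split into ``n_folds`` non-overlapping folds; for each
    fold, both a fine-tuned copy of the pre-trained regressors and
    freshly initialized networks of the same architecture are trained on
    the remaining folds and scored (MAE on ``target``) on the held-out
    fold, rotating until every fold served as the test set once. Both arms
    share the pre-trained normalization so the comparison isolates the
    value of the transferred weights. Returns per-fold MAEs and the mean
    for each arm.
    """
    config = config or TrainingConfig()
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(small_records))
    folds = np.array_split(order, n_folds)
    tuned_maes, scratch_maes = [], []
    for k in range(n_folds):
        test = [small_records[i] for i in folds[k]]
        train = [small_records[i] for j, fold in enumerate(folds) if j != k
                 for i in fold]
        tuned = fine_tune(pretrained, train, frozen_layers=frozen_layers,
                          config=config, add_layers=add_layers,
                          targets=(target,))
        scratch = copy.deepcopy(pretrained)
        for key, net in scratch.regressors.items():
            scratch.regressors[key] = MLP(net.layer_sizes, task=net.task,
                                          seed=config.seed + 17)
        scratch = fine_tune(scratch, train, frozen_layers=0, config=config,
                            targets=(target,))

        def fold_mae(stack: PredictorStack) -> float:
            getter = (lambda r: r.outcome.diameter_um) if target == "diameter" \
                else (lambda r: r.outcome.rate_hz)
            errors = []
            for r in test:
                regime = r.outcome.regime  # ground-truth routing
                z = stack.norm_stats.transform(
                    np.asarray(r.design.to_vector(), dtype=float)[None, :])
                net = stack.regressors[(regime, target)]
                scale = stack.target_scales[(regime, target)]
                pred = float(scale.inverse(net.predict(z)[0, 0]))
                errors.append(abs(pred - getter(r)))
            return float(np.mean(errors))

        tuned_maes.append(fold_mae(tuned))
        scratch_maes.append(fold_mae(scratch))
    return {
        "fine_tuned_mae": tuned_maes,
        "scratch_mae": scratch_maes,
        "fine_tuned_mean": float(np.mean(tuned_maes)),
        "scratch_mean": float(np.mean(scratch_maes)),
        "fine_tuned_wins": bool(np.mean(tuned_maes) < np.mean(scratch_maes)),
    }
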