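"""Tolerance analysis: how fabrication and pump variability move performance.

Micro-milling and syringe pumps deliver a design only to within a
tolerance. Given a nominal design and a user tolerance (a fraction, e.g.
0.1 for ±10% per parameter), this module quantifies the consequences:

* variance-based (Sobol) sensitivity of predicted diameter and rate over
  the tolerance hypercube, using quasi-Monte-Carlo (Sobol' sequence)
  pick-freeze sampling — first-order variances Var_{X_i}(E[Y|X_i]),
  second-order interaction variances, and the total-effect index;
* a "tolerance grid": the principal (highest total-effect) parameter is
  perturbed jointly with every other parameter over {−tol, 0, +tol} and
  the predicted performance tabulated for heatmap display;
* a flow-adjustment map: predicted performance over a grid of continuous
  and dispersed flow rates around the design point (±2× tolerance), to
  guide operators correcting observed deviations at the pump.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.stats import qmc

from . import physics
from .physics import (
    FEATURE_NAMES,
    JETTING,
    MIN_ORIFICE_UM,
    DesignPoint,
    Performance,
)

__all__ = [
    "SensitivityResult",
    "ToleranceReport",
    "FlowAdjustmentMap",
    "sample_hypercube",
    "sobol_indices",
    "principal_parameter",
    "tolerance_grid",
    "flow_adjustment_map",
    "diameter_response",
    "rate_response",
]

# Hard floors a tolerance perturbation may not cross (fabrication/tool limits).
_HARD_LOWER = {
    "orifice_width_um": MIN_ORIFICE_UM,
    "aspect_ratio": 1.0,
    "water_inlet_ratio": 2.0,
}


@dataclass(frozen=True)
class SensitivityResult:
    """Variance decomposition of one output over the tolerance hypercube."""

    output: str  # "diameter" or "rate"
    parameter_names: tuple[str, ...]
    first_order: np.ndarray  # S_i, fraction of output variance
    second_order: np.ndarray  # S_ij, (8, 8) symmetric, zero diagonal
    total_effect: np.ndarray  # ST_i
    n_samples: int
    tolerance: float


@dataclass(frozen=True)
class ToleranceReport:
    """Principal-parameter heatmap grids around a nominal design."""

    principal: dict  # output -> parameter name
    grids: dict  # (output, other_param) -> (3, 3) predictions; rows: principal
    levels: tuple[float, float, float]  # multiplicative level factors
    nominal: Performance
    tolerance: float
    model_tolerances: dict  # (regime, target) -> validation MAE annotation


@dataclass(frozen=True)
class FlowAdjustmentMap:
    """Predicted performance over a (Q_c, Q_d) grid around the design."""

    qc_ml_h: np.ndarray  # grid axis, ml/h
    qd_ul_min: np.ndarray  # grid axis, μl/min
    diameter_um: np.ndarray  # (len(qc), len(qd))
    rate_hz: np.ndarray
    valid: np.ndarray  # False where the implied flow condition left bounds


def _tolerance_box(design: DesignPoint, tolerance_fraction: float
                   ) -> tuple[np.ndarray, np.ndarray]:
    nominal = np.asarray(design.to_vector(), dtype=float)
    lo = nominal * (1.0 - tolerance_fraction)
    hi = nominal * (1.0 + tolerance_fraction)
    clipped = []
    for i, name in enumerate(FEATURE_NAMES):
        floor = _HARD_LOWER.get(name)
        if floor is not None and lo[i] < floor:
            lo[i] = floor
            clipped.append(name)
    if clipped:
        warnings.warn(
            "tolerance box clipped at hard lower bound(s): " + ", ".join(clipped))
    return lo, hi


def sample_hypercube(
    design: DesignPoint, tolerance_fraction: float, n: int, seed: int = 0
) -> np.ndarray:
    """Low-discrepancy samples over the multiplicative tolerance box.

    Each parameter p spans [p·(1−tol), p·(1+tol)], clipped at hard
    fabrication floors (with a warning). Deterministic for a fixed seed;
    tolerance 0 returns the nominal design n times.
    """
    if not 0 <= tolerance_fraction < 0.5:
        raise ValueError("tolerance_fraction must be in [0, 0.5)")
    lo, hi = _tolerance_box(design, tolerance_fraction)
    sampler = qmc.Sobol(d=len(FEATURE_NAMES), scramble=True, rng=seed)
    unit = sampler.random(n)
    return lo + unit * (hi - lo)  # qmc.scale rejects zero-width (tol=0) boxes


def diameter_response(stack):
    """Vectorized diameter prediction over raw design-parameter matrices."""
    return _stack_response(stack, "diameter")


def rate_response(stack):
    """Vectorized rate prediction over raw design-parameter matrices."""
    return _stack_response(stack, "rate")


def _stack_response(stack, target: str):
    def f(x: np.ndarray) -> np.ndarray:
        z = stack.norm_stats.transform(np.atleast_2d(np.asarray(x, dtype=float)))
        jet = stack.classifier.predict(z)[:, 0] >= 0.5
        out = np.empty(len(z))
        for regime, mask in (("dripping", ~jet), ("jetting", jet)):
            if not mask.any():
                continue
            net = stack.regressors[(regime, target)]
            scale = stack.target_scales[(regime, target)]
            out[mask] = scale.inverse(net.predict(z[mask])[:, 0])
        return out
    return f


def sobol_indices(
    response_function,
    design: DesignPoint,
    tolerance_fraction: float,
    n: int = 1024,
    seed: int = 0,
    output: str = "response",
) -> SensitivityResult:
    """Pick-freeze (Saltelli) estimates of Sobol sensitivity indices.

    Two independent quasi-random sample blocks A and B are drawn over the
    tolerance hypercube; cross blocks AB_i (A with column i from B) and
    BA_i give the standard estimators: first-order
    S_i = mean(f_B·(f_{AB_i} − f_A))/Var, total-effect
    ST_i = mean((f_A − f_{AB_i})²)/(2·Var), and second-order interactions
    from the closed (i, j) variance minus the two first-order terms.
    ``response_function`` maps an (m, 8) parameter matrix to m outputs.
    Zero output variance yields all-zero indices with a warning.
    """
    d = len(FEATURE_NAMES)
    lo, hi = _tolerance_box(design, tolerance_fraction)
    sampler = qmc.Sobol(d=2 * d, scramble=True, rng=seed)
    unit = sampler.random(n)
    a = lo + unit[:, :d] * (hi - lo)
    b = lo + unit[:, d:] * (hi - lo)
    f_a = np.asarray(response_function(a), dtype=float)
    f_b = np.asarray(response_function(b), dtype=float)
    all_f = np.concatenate([f_a, f_b])
    variance = float(np.var(all_f))
    if variance == 0.0:
        warnings.warn("zero output variance over the hypercube; indices set to 0")
        zeros = np.zeros(d)
        return SensitivityResult(output=output,
                                 parameter_names=FEATURE_NAMES,
                                 first_order=zeros,
                                 second_order=np.zeros((d, d)),
                                 total_effect=zeros.copy(),
                                 n_samples=n, tolerance=tolerance_fraction)

    f_ab = np.empty((d, n))
    f_ba = np.empty((d, n))
    for i in range(d):
        ab_i = a.copy()
        ab_i[:, i] = b[:, i]
        f_ab[i] = response_function(ab_i)
        ba_i = b.copy()
        ba_i[:, i] = a[:, i]
        f_ba[i] = response_function(ba_i)

    first = np.array([
        float(np.mean(f_b * (f_ab[i] - f_a))) / variance for i in range(d)])
    total = np.array([
        0.5 * float(np.mean((f_a - f_ab[i]) ** 2)) / variance for i in range(d)])
    f0_sq = float(np.mean(f_a) * np.mean(f_b))
    second = np.zeros((d, d))
    for i in range(d):
        for j in range(i + 1, d):
            closed_ij = (float(np.mean(f_ba[i] * f_ab[j])) - f0_sq) / variance
            s_ij = closed_ij - first[i] - first[j]
            second[i, j] = second[j, i] = s_ij
    return SensitivityResult(output=output,
                             parameter_names=FEATURE_NAMES,
                             first_order=first,
                             second_order=second,
                             total_effect=np.maximum(total, 0.0),
                             n_samples=n, tolerance=tolerance_fraction)


def principal_parameter(result: SensitivityResult) -> str:
    """Parameter with the highest total-effect index (first index on ties)."""
    return result.parameter_names[int(np.argmax(result.total_effect))]


def _predict_quiet(stack, design: DesignPoint) -> Performance:
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return stack.predict(design)


def tolerance_grid(
    stack, design: DesignPoint, tolerance_fraction: float,
    n_sensitivity: int = 1024, seed: int = 0,
) -> ToleranceReport:
    """Heatmap grids: principal parameter × every other parameter.

    For each output, the principal parameter (highest total-effect index
    over the tolerance hypercube) and each other parameter are jointly set
    to the three levels {−tol, 0, +tol} (multiplicative, clipped at hard
    floors) and the stack's prediction recorded in a 3×3 grid whose center
    cell is exactly the nominal prediction. The stack's per-model
    validation MAEs are attached as the per-cell error annotation.
    """
    nominal_vec = np.asarray(design.to_vector(), dtype=float)
    lo, hi = _tolerance_box(design, tolerance_fraction)
    nominal_perf = _predict_quiet(stack, design)
    levels = (1.0 - tolerance_fraction, 1.0, 1.0 + tolerance_fraction)

    principal = {}
    for output, response in (("diameter", diameter_response(stack)),
                             ("rate", rate_response(stack))):
        sens = sobol_indices(response, design, tolerance_fraction,
                             n=n_sensitivity, seed=seed, output=output)
        principal[output] = principal_parameter(sens)

    def level_value(index: int, level_pos: int) -> float:
        return (lo[index], nominal_vec[index], hi[index])[level_pos]

    grids = {}
    for output in ("diameter", "rate"):
        p_idx = FEATURE_NAMES.index(principal[output])
        for other in FEATURE_NAMES:
            if other == principal[output]:
                continue
            o_idx = FEATURE_NAMES.index(other)
            grid = np.empty((3, 3))
            for r in range(3):
                for c in range(3):
                    vec = nominal_vec.copy()
                    vec[p_idx] = level_value(p_idx, r)
                    vec[o_idx] = level_value(o_idx, c)
                    if r == 1 and c == 1:
                        perf = nominal_perf
                    else:
                        perf = _predict_quiet(stack, DesignPoint.from_vector(vec))
                    grid[r, c] = (perf.diameter_um if output == "diameter"
                                  else perf.rate_hz)
            grids[(output, other)] = grid
    return ToleranceReport(
        principal=principal, grids=grids, levels=levels,
        nominal=nominal_perf, tolerance=tolerance_fraction,
        model_tolerances=dict(stack.tolerances),
    )


def flow_adjustment_map(
    stack, design: DesignPoint, tolerance_fraction: float, resolution: int = 21
) -> FlowAdjustmentMap:
    """Predicted performance over (Q_c, Q_d) varied ±2× the tolerance.

    Each grid cell's flow pair is converted back to the dimensionless flow
    condition (Ca from Q_c through the geometry and fluids, ϕ = Q_c/Q_d)
    and predicted; cells whose implied condition leaves the stack's
    supported parameter bounds are flagged invalid (NaN predictions).
    """
    from . import units
    from .predictor import ValidityError  # local import avoids a cycle

    nominal = physics.flow_rates_from_dimensionless(
        design.flow, design.geometry, stack.fluids)
    span = 2.0 * tolerance_fraction
    qc_values = nominal.continuous_rate * np.linspace(1 - span, 1 + span, resolution)
    qd_values = nominal.dispersed_rate * np.linspace(1 - span, 1 + span, resolution)
    diameter = np.full((resolution, resolution), np.nan)
    rate = np.full((resolution, resolution), np.nan)
    valid = np.zeros((resolution, resolution), dtype=bool)
    for i, q_c in enumerate(qc_values):
        ca = physics.capillary_number_from_rates(q_c, design.geometry, stack.fluids)
        for j, q_d in enumerate(qd_values):
            phi = q_c / q_d
            try:
                point = DesignPoint(
                    geometry=design.geometry,
                    flow=physics.FlowCondition(capillary_number=ca,
                                               flow_rate_ratio=phi),
                )
                perf = _predict_quiet(stack, point)
            except (ValidityError, physics.DomainError, ValueError):
                continue
            diameter[i, j] = perf.diameter_um
            rate[i, j] = perf.rate_hz
            valid[i, j] = True
    return FlowAdjustmentMap(
        qc_ml_h=np.array([units.m3s_to_ml_h(q) for q in qc_values]),
        qd_ul_min=np.array([units.m3s_to_ul_min(q) for q in qd_values]),
        diameter_um=diameter,
        rate_hz=rate,
        valid=valid,
    )
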