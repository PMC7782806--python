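"""Inverse design: from a desired performance to a geometry and flow rates.

The design-automation engine works backwards through the predictive stack.
Given a desired droplet diameter (and optionally rate), it first ranks the
observation data-set by closeness of observed performance to the request
and takes the best record as a seed; if both the seed's observed and
predicted performance already sit within the predictive models' validation
tolerances, the seed is returned outright. Otherwise a greedy
coordinate-perturbation descent runs: each of the eight design parameters
is increased and decreased by a shared normalized step (16 candidate
devices per iteration), each candidate's performance is predicted, and a
cost

    C = |D_des − D_pred| + |F_des − F_pred| + |D_des − D_inf|

is minimized, where D_inf is the diameter inferred from the predicted rate
and dispersed flow by conservation of mass. The D_inf term is a redundancy
penalty: where the two regressors disagree, at least one is unreliable and
the search is steered away. Per-parameter constraints (fixed values or
intervals) are honored at every iterate.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np

from . import physics, units
from .dataset import DIAMETER_RANGE_UM, RATE_RANGE_HZ, ObservationRecord
from .physics import FEATURE_NAMES, DesignPoint, FlowCondition, Performance

__all__ = [
    "DesignSpec",
    "DesignResult",
    "ConstraintInfeasibleError",
    "cost",
    "rank_seed_candidates",
    "accept_seed",
    "neighborhood",
    "search",
]

SEED_ACCEPTED = "seed-accepted"
CONVERGED = "converged"
ITERATION_CAPPED = "iteration-capped"

_PERF_SCALE_D = DIAMETER_RANGE_UM[1]  # 250 μm
_PERF_SCALE_F = RATE_RANGE_HZ[1]  # 500 Hz


class ConstraintInfeasibleError(ValueError):
    """No data-set record (or design) satisfies the given constraints."""


@dataclass(frozen=True)
class DesignSpec:
    """User-specified desired performance and optional constraints.

    ``constraints`` maps a design-parameter name to either a fixed value or
    a ``(lo, hi)`` interval. ``desired_rate_hz=None`` selects diameter-only
    mode (the rate term is dropped from the cost; the inferred-diameter
    redundancy term is kept).
    """

    desired_diameter_um: float
    desired_rate_hz: float | None = None
    constraints: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        dlo, dhi = DIAMETER_RANGE_UM
        if not dlo <= self.desired_diameter_um <= dhi:
            raise ValueError(
                f"desired diameter must be within [{dlo}, {dhi}] μm")
        if self.desired_rate_hz is not None:
            flo, fhi = RATE_RANGE_HZ
            if not flo <= self.desired_rate_hz <= fhi:
                raise ValueError(f"desired rate must be within [{flo}, {fhi}] Hz")
        for name in self.constraints:
            if name not in FEATURE_NAMES:
                raise ValueError(f"unknown design parameter {name!r}")

    def constraint_box(self, global_bounds: np.ndarray) -> np.ndarray:
        """Feasible (lo, hi) per parameter: global bounds ∩ constraints."""
        box = np.array(global_bounds, dtype=float)
        for i, name in enumerate(FEATURE_NAMES):
            if name not in self.constraints:
                continue
            c = self.constraints[name]
            lo, hi = (c, c) if np.isscalar(c) else (c[0], c[1])
            if hi < box[i, 0] or lo > box[i, 1]:
                raise ConstraintInfeasibleError(
                    f"constraint on {name} ([{lo}, {hi}]) lies outside the "
                    f"supported range [{box[i, 0]:g}, {box[i, 1]:g}]")
            box[i, 0] = max(box[i, 0], lo)
            box[i, 1] = min(box[i, 1], hi)
        return box

    def fixed_parameters(self) -> set[str]:
        return {name for name, c in self.constraints.items() if np.isscalar(c)}


@dataclass
class DesignResult:
    """Proposed design with flow rates, prediction, and descent trace."""

    design: DesignPoint
    flow: FlowCondition  # Q_c, Q_d populated
    predicted: Performance
    cost_trace: list[float]
    status: str
    iterations: int

    def to_dict(self) -> dict:
        vec = [float(v) for v in self.design.to_vector()]
        g = self.design.geometry
        return {
            "design_parameters": dict(zip(FEATURE_NAMES, vec)),
            "absolute_lengths_um": {
                "orifice_width": g.orifice_width_um,
                "channel_depth": g.aspect_ratio * g.orifice_width_um,
                "orifice_length": g.orifice_length_ratio * g.orifice_width_um,
                "water_inlet": g.water_inlet_ratio * g.orifice_width_um,
                "oil_inlet": g.oil_inlet_ratio * g.orifice_width_um,
                "outlet": g.outlet_ratio * g.orifice_width_um,
            },
            "continuous_rate_ml_h": units.m3s_to_ml_h(self.flow.continuous_rate),
            "dispersed_rate_ul_min": units.m3s_to_ul_min(self.flow.dispersed_rate),
            "predicted": {
                "regime": self.predicted.regime,
                "diameter_um": self.predicted.diameter_um,
                "rate_hz": self.predicted.rate_hz,
                "inferred_diameter_um": self.predicted.inferred_diameter_um,
            },
            "cost_trace": [float(c) for c in self.cost_trace],
            "status": self.status,
            "iterations": self.iterations,
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)


def cost(spec: DesignSpec, predicted: Performance,
         dispersed_rate_m3s: float) -> float:
    """Design-automation cost: performance mismatch + redundancy penalty."""
    d_inf = predicted.inferred_diameter_um
    if d_inf is None:
        d_inf = physics.infer_diameter(dispersed_rate_m3s, predicted.rate_hz)
    c = abs(spec.desired_diameter_um - predicted.diameter_um)
    if spec.desired_rate_hz is not None:
        c += abs(spec.desired_rate_hz - predicted.rate_hz)
    c += abs(spec.desired_diameter_um - d_inf)
    return c


def _fitness(spec: DesignSpec, outcome: Performance) -> float:
    """Scaled Euclidean distance of an observed performance to the request."""
    dd = (spec.desired_diameter_um - outcome.diameter_um) / _PERF_SCALE_D
    if spec.desired_rate_hz is None:
        return abs(dd)
    df = (spec.desired_rate_hz - outcome.rate_hz) / _PERF_SCALE_F
    return float(np.hypot(dd, df))


def _project_record(record: ObservationRecord, spec: DesignSpec
                    ) -> ObservationRecord:
    """Snap fixed-value-constrained parameters of a record's design."""
    fixed = spec.fixed_parameters()
    if not fixed:
        return record
    vec = list(record.design.to_vector())
    for i, name in enumerate(FEATURE_NAMES):
        if name in fixed:
            vec[i] = float(spec.constraints[name])
    return ObservationRecord(design=DesignPoint.from_vector(vec),
                             outcome=record.outcome)


def rank_seed_candidates(records: list[ObservationRecord], spec: DesignSpec
                         ) -> list[ObservationRecord]:
    """Rank data-set records by performance closeness, constraint-aware.

    Records violating interval constraints are excluded; fixed-value
    constraints are applied by projecting the record's parameter onto the
    fixed value (exact matches would almost never occur in a continuous
    data-set). The first element is the search seed.
    """
    if not records:
        raise ValueError("data-set must be nonempty")
    kept = []
    for r in records:
        vec = r.design.to_vector()
        ok = True
        for i, name in enumerate(FEATURE_NAMES):
            c = spec.constraints.get(name)
            if c is None or np.isscalar(c):
                continue
            if not c[0] <= vec[i] <= c[1]:
                ok = False
                break
        if ok:
            kept.append(r)
    if not kept:
        raise ConstraintInfeasibleError(
            "no data-set record satisfies the interval constraints")
    kept.sort(key=lambda r: _fitness(spec, r.outcome))
    return [_project_record(r, spec) for r in kept]


def accept_seed(spec: DesignSpec, record: ObservationRecord, stack) -> bool:
    """Seed acceptance: observed AND predicted deviations within tolerances.

    Deviations are compared (inclusively) against the stack's stored
    per-model validation MAEs for the predicted regime.
    """
    predicted = stack.predict(record.design)
    tol_d = stack.tolerance("diameter", predicted.regime)
    tol_f = stack.tolerance("rate", predicted.regime)
    checks = [
        abs(record.outcome.diameter_um - spec.desired_diameter_um) <= tol_d,
        abs(predicted.diameter_um - spec.desired_diameter_um) <= tol_d,
    ]
    if spec.desired_rate_hz is not None:
        checks += [
            abs(record.outcome.rate_hz - spec.desired_rate_hz) <= tol_f,
            abs(predicted.rate_hz - spec.desired_rate_hz) <= tol_f,
        ]
    return all(checks)


def neighborhood(
    design: DesignPoint,
    step: float,
    bounds: np.ndarray,
    constraints: dict | None = None,
) -> list[DesignPoint]:
    """±step perturbations of each free parameter, in normalized coordinates.

    ``step`` is a fraction of each parameter's global range (``bounds``,
    shape (8, 2)). Candidates are clipped to the bounds and to interval
    constraints; fixed-value-constrained parameters are not perturbed, and
    clipped duplicates (including the unperturbed point) are dropped — so
    an unconstrained interior point yields exactly 16 candidates.
    """
    if step <= 0:
        raise ValueError("step must be > 0")
    spec_like = DesignSpec(desired_diameter_um=DIAMETER_RANGE_UM[0],
                           constraints=constraints or {})
    box = spec_like.constraint_box(bounds)
    fixed = spec_like.fixed_parameters()
    vec = np.asarray(design.to_vector(), dtype=float)
    widths = bounds[:, 1] - bounds[:, 0]
    out: list[DesignPoint] = []
    seen = {tuple(np.round(vec, 12))}
    for i, name in enumerate(FEATURE_NAMES):
        if name in fixed or widths[i] == 0:
            continue
        for sign in (+1.0, -1.0):
            candidate = vec.copy()
            candidate[i] = np.clip(candidate[i] + sign * step * widths[i],
                                   box[i, 0], box[i, 1])
            key = tuple(np.round(candidate, 12))
            if key in seen:
                continue
            seen.add(key)
            out.append(DesignPoint.from_vector(candidate))
    return out


def search(
    stack,
    spec: DesignSpec,
    records: list[ObservationRecord],
    step: float = 0.05,
    max_iterations: int = 500,
    n_starts: int = 5,
) -> DesignResult:
    """Greedy coordinate-perturbation descent from the best data-set seeds.

    If the top-ranked record already satisfies the seed-acceptance test it
    is returned outright. Otherwise a descent runs from each of the top
    ``n_starts`` ranked seeds and the lowest-final-cost run wins (the cost
    landscape has narrow valleys where a single greedy path can stall; the
    fitness ranking supplies naturally ordered alternative basins). Within
    a descent, every neighborhood candidate is predicted and the cost
    argmin taken if it improves; when no candidate improves, the step is
    halved (up to three consecutive times) before declaring convergence.
    Each run's cost trace is non-increasing by construction; ties are
    broken deterministically by candidate order (lowest parameter index,
    positive perturbation first) and, across starts, by seed rank.
    """
    ranked = rank_seed_candidates(records, spec)

    def predict_quiet(design: DesignPoint):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            return stack.predict(design)

    def evaluate(design: DesignPoint) -> tuple[float, Performance, FlowCondition]:
        flow = physics.flow_rates_from_dimensionless(
            design.flow, design.geometry, stack.fluids)
        perf = predict_quiet(design)
        return cost(spec, perf, flow.dispersed_rate), perf, flow

    def within_tolerance(perf: Performance) -> bool:
        ok = abs(perf.diameter_um - spec.desired_diameter_um) <= \
            stack.tolerance("diameter", perf.regime)
        if spec.desired_rate_hz is not None:
            ok = ok and abs(perf.rate_hz - spec.desired_rate_hz) <= \
                stack.tolerance("rate", perf.regime)
        return ok

    top = ranked[0]
    top_cost, top_perf, top_flow = evaluate(top.design)
    if accept_seed(spec, top, stack):
        return DesignResult(design=top.design, flow=top_flow,
                            predicted=top_perf, cost_trace=[top_cost],
                            status=SEED_ACCEPTED, iterations=0)

    bounds = stack.feature_bounds

    def descend(seed: ObservationRecord) -> DesignResult:
        current = seed.design
        current_cost, current_perf, current_flow = evaluate(current)
        trace = [current_cost]
        local_step = step
        halvings = 0
        iterations = 0
        status = CONVERGED
        while iterations < max_iterations:
            if within_tolerance(current_perf):
                break
            iterations += 1
            best = None
            for candidate in neighborhood(current, local_step, bounds,
                                          spec.constraints):
                try:
                    c, perf, flow = evaluate(candidate)
                except (physics.DomainError, ValueError):
                    continue
                if best is None or c < best[0]:
                    best = (c, candidate, perf, flow)
            if best is not None and best[0] < current_cost - 1e-12:
                current_cost, current, current_perf, current_flow = best
                trace.append(current_cost)
                halvings = 0  # fresh halving budget after every improvement
            elif halvings < 3:
                local_step /= 2.0
                halvings += 1
            else:
                break
        else:
            status = ITERATION_CAPPED
        return DesignResult(design=current, flow=current_flow,
                            predicted=current_perf, cost_trace=trace,
                            status=status, iterations=iterations)

    results = [descend(seed) for seed in ranked[:max(1, n_starts)]]
    return min(results, key=lambda r: r.cost_trace[-1])
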