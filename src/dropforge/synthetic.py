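"""Surrogate ground-truth physics and data-set generator.

Real droplet-generation data requires fabricated devices and imaging; this
module provides an analytic stand-in with the right qualitative shape so
that every other module is testable without any experimental data:

* droplet diameter falls smoothly and monotonically with capillary number
  and flow-rate ratio, and scales with the orifice width;
* the dripping→jetting transition is a monotone boundary in capillary
  number (jetting at high Ca);
* generation rate is tied to diameter through conservation of mass, with
  the dispersed flow obtained from the geometry and flow condition;
* measurement noise is multiplicative (log-normal) on the diameter, with
  the rate recomputed from the noisy diameter so mass stays conserved.

The surrogate law is NOT a claim about droplet physics — its coefficients
are arbitrary, chosen once so that default sampling lands mostly inside
the 25–250 μm / 5–500 Hz performance window.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from . import physics
from .dataset import ObservationRecord
from .physics import (
    DRIPPING,
    FEATURE_NAMES,
    JETTING,
    DesignPoint,
    FluidPair,
    Performance,
)

__all__ = [
    "SurrogateParams",
    "SurrogatePredictor",
    "surrogate_truth",
    "generate_dataset",
    "generate_shifted_dataset",
    "DEFAULT_RANGES",
]

#: Default sampling ranges per design parameter (lo, hi); Ca is log-uniform.
DEFAULT_RANGES: dict[str, tuple[float, float]] = {
    "orifice_width_um": (75.0, 300.0),
    "aspect_ratio": (1.0, 3.0),
    "orifice_length_ratio": (1.0, 4.0),
    "water_inlet_ratio": (2.0, 4.0),
    "oil_inlet_ratio": (1.0, 4.0),
    "outlet_ratio": (1.0, 4.0),
    "capillary_number": (0.02, 0.8),
    "flow_rate_ratio": (2.0, 40.0),
}


@dataclass(frozen=True)
class SurrogateParams:
    """Coefficients of the surrogate diameter law and sampling setup.

    Diameter (μm): D = k0·Or·(c0 + c1·ϕ^−c2)·Ca^−c3·aspect^c4.
    Regime: jetting iff Ca > threshold·ϕ^−0.1.
    Rate: F = Q_d/(πD³/6), with Q_d from the geometry/flow-condition
    conversion using the default fluid pair below.
    """

    k0: float = 0.3
    c0: float = 0.6
    c1: float = 1.8
    c2: float = 0.4
    c3: float = 0.25
    c4: float = 0.2
    regime_threshold: float = 0.12
    noise_sd: float = 0.05  # multiplicative (log-normal) diameter noise, fraction
    interfacial_tension: float = 0.005  # N/m
    continuous_viscosity: float = 0.0572  # Pa·s (NF 350 mineral oil)
    ranges: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_RANGES))

    def __post_init__(self) -> None:
        if not 0.0 <= self.noise_sd <= 0.2:
            raise ValueError("noise_sd must be in [0, 0.2]")

    @property
    def fluids(self) -> FluidPair:
        return FluidPair(
            continuous_viscosity=self.continuous_viscosity,
            interfacial_tension=self.interfacial_tension,
            continuous_label="surrogate oil",
            dispersed_label="surrogate water",
        )


def surrogate_truth(design: DesignPoint, params: SurrogateParams | None = None
                    ) -> Performance:
    """Noise-free surrogate performance for a design point."""
    params = params or SurrogateParams()
    g, fl = design.geometry, design.flow
    ca, phi = fl.capillary_number, fl.flow_rate_ratio
    diameter_um = (params.k0 * g.orifice_width_um
                   * (params.c0 + params.c1 * phi ** (-params.c2))
                   * ca ** (-params.c3)
                   * g.aspect_ratio ** params.c4)
    flow = physics.flow_rates_from_dimensionless(fl, g, params.fluids)
    rate_hz = flow.dispersed_rate / (
        (math.pi / 6.0) * (diameter_um * 1e-6) ** 3)
    regime = JETTING if ca > params.regime_threshold * phi ** (-0.1) else DRIPPING
    return Performance(regime=regime, diameter_um=diameter_um, rate_hz=rate_hz)


def _sample_designs(n: int, params: SurrogateParams, rng: np.random.Generator
                    ) -> list[DesignPoint]:
    cols = {}
    for name in FEATURE_NAMES:
        lo, hi = params.ranges[name]
        if name == "capillary_number":  # log-uniform: regimes on both sides
            cols[name] = np.exp(rng.uniform(np.log(lo), np.log(hi), size=n))
        else:
            cols[name] = rng.uniform(lo, hi, size=n)
    return [
        DesignPoint.from_vector([cols[name][i] for name in FEATURE_NAMES])
        for i in range(n)
    ]


def generate_dataset(
    n: int, params: SurrogateParams | None = None, seed: int = 0
) -> list[ObservationRecord]:
    """Sample ``n`` observation records from the surrogate.

    Design points are drawn uniformly over the configured ranges (capillary
    number log-uniformly). Multiplicative log-normal noise of fractional sd
    ``params.noise_sd`` perturbs the diameter; the rate is then recomputed
    from the noisy diameter at the design's dispersed flow, so every record
    satisfies conservation of mass exactly. Regime labels are noise-free.
    """
    if n < 1:
        raise ValueError("n must be ≥ 1")
    params = params or SurrogateParams()
    rng = np.random.default_rng(seed)
    records = []
    for design in _sample_designs(n, params, rng):
        truth = surrogate_truth(design, params)
        if params.noise_sd > 0:
            factor = math.exp(rng.normal(0.0, params.noise_sd))
        else:
            factor = 1.0
        diameter = truth.diameter_um * factor
        q_d = physics.flow_rates_from_dimensionless(
            design.flow, design.geometry, params.fluids).dispersed_rate
        rate = q_d / ((math.pi / 6.0) * (diameter * 1e-6) ** 3)
        records.append(ObservationRecord(
            design=design,
            outcome=Performance(regime=truth.regime, diameter_um=diameter,
                                rate_hz=rate),
        ))
    return records


def generate_shifted_dataset(
    n: int,
    params: SurrogateParams | None = None,
    shift_factor: float = 1.25,
    seed: int = 0,
) -> list[ObservationRecord]:
    """Sample from a property-shifted surrogate (c0..c3 scaled).

    Emulates swapping the fluid pair: the diameter law's coefficients c0–c3
    are multiplied by ``shift_factor``, producing systematically larger
    droplets at matched inputs for factors > 1. Used to exercise the
    transfer-learning protocol on a small data-set.
    """
    base = params or SurrogateParams()
    shifted = SurrogateParams(
        k0=base.k0,
        c0=base.c0 * shift_factor,
        c1=base.c1 * shift_factor,
        c2=base.c2 * shift_factor,
        c3=base.c3 * shift_factor,
        c4=base.c4,
        regime_threshold=base.regime_threshold,
        noise_sd=base.noise_sd,
        interfacial_tension=base.interfacial_tension,
        continuous_viscosity=base.continuous_viscosity,
        ranges=dict(base.ranges),
    )
    return generate_dataset(n, shifted, seed=seed)


class SurrogatePredictor:
    """The surrogate wrapped in the predictor interface.

    Serves as a "perfect predictor" in tests and benchmarks: regimes,
    diameters and rates come straight from :func:`surrogate_truth`, the
    inferred diameter from conservation of mass, and the validation
    tolerances are small constants standing in for held-out errors.
    """

    def __init__(self, params: SurrogateParams | None = None,
                 diameter_tolerance_um: float = 1.0,
                 rate_tolerance_hz: float = 2.0):
        self.params = params or SurrogateParams()
        self.fluids = self.params.fluids
        self._tol_d = diameter_tolerance_um
        self._tol_f = rate_tolerance_hz
        lo = [self.params.ranges[name][0] for name in FEATURE_NAMES]
        hi = [self.params.ranges[name][1] for name in FEATURE_NAMES]
        self.feature_bounds = np.column_stack([lo, hi]).astype(float)

    def tolerance(self, target: str, regime: str) -> float:
        return self._tol_d if target == "diameter" else self._tol_f

    def predict(self, design: DesignPoint) -> Performance:
        truth = surrogate_truth(design, self.params)
        q_d = physics.flow_rates_from_dimensionless(
            design.flow, design.geometry, self.fluids).dispersed_rate
        return Performance(
            regime=truth.regime,
            diameter_um=truth.diameter_um,
            rate_hz=truth.rate_hz,
            inferred_diameter_um=physics.infer_diameter(q_d, truth.rate_hz),
        )
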