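"""Closed-form physics of flow-focusing droplet generation.

A flow-focusing droplet generator pinches a dispersed phase (water) into
monodisperse droplets with a continuous phase (oil) at a narrow orifice.
Three quantities are linked exactly by conservation of mass: droplet
diameter D, generation rate F, and dispersed-phase flow rate Q_d,

    (π/6)·D³·F = Q_d.

Given any two, the third follows. This module provides that relation, its
inverse (the "inferred diameter" used as a redundancy check between
independently trained diameter and rate predictors), the conversion from
the dimensionless flow condition (capillary number Ca, flow-rate ratio
ϕ = Q_c/Q_d) to absolute flow rates for a given geometry and fluid pair,
and the first-order error propagation showing that a fractional diameter
error ε_d maps to a rate error ε_f ≈ 3·ε_d.

All functions operate in SI internally; see :mod:`dropforge.units`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from . import units

__all__ = [
    "FluidPair",
    "Geometry",
    "FlowCondition",
    "DesignPoint",
    "Performance",
    "ErrorPropagation",
    "FEATURE_NAMES",
    "MIN_ORIFICE_UM",
    "dispersed_rate_from",
    "infer_diameter",
    "flow_rates_from_dimensionless",
    "capillary_number_from_rates",
    "propagate_diameter_error",
]

#: Minimum fabricable orifice width in μm (milling feature-size floor).
MIN_ORIFICE_UM = 75.0

#: Canonical ordering of the eight design parameters, matching the CSV schema.
FEATURE_NAMES = (
    "orifice_width_um",
    "aspect_ratio",
    "orifice_length_ratio",
    "water_inlet_ratio",
    "oil_inlet_ratio",
    "outlet_ratio",
    "capillary_number",
    "flow_rate_ratio",
)

DRIPPING = "dripping"
JETTING = "jetting"
REGIMES = (DRIPPING, JETTING)


class DomainError(ValueError):
    """Raised when a physical quantity is outside its admissible domain."""


@dataclass(frozen=True)
class FluidPair:
    """Continuous/dispersed fluid combination.

    Parameters
    ----------
    continuous_viscosity : float
        Dynamic viscosity μ_c of the continuous (oil) phase, Pa·s.
    interfacial_tension : float
        Interfacial tension σ between the phases, N/m. There is no default:
        σ is a required configuration value.
    continuous_label, dispersed_label : str
        Free-text phase descriptions.
    """

    continuous_viscosity: float
    interfacial_tension: float
    continuous_label: str = "mineral oil"
    dispersed_label: str = "DI water"

    def __post_init__(self) -> None:
        if self.continuous_viscosity <= 0:
            raise DomainError("continuous_viscosity must be > 0 Pa·s")
        if self.interfacial_tension <= 0:
            raise DomainError("interfacial_tension must be > 0 N/m")


@dataclass(frozen=True)
class Geometry:
    """Flow-focusing geometry, stored in the model's native normalized form.

    ``orifice_width_um`` is absolute (μm); the five other parameters are
    dimensionless multiples of the orifice width: channel depth
    (``aspect_ratio`` = H/Or), orifice length, water-inlet width (W_d/Or),
    oil-inlet width (W_c/Or), and outlet width. Absolute lengths are derived
    on demand via the ``*_m`` properties.
    """

    orifice_width_um: float
    aspect_ratio: float
    orifice_length_ratio: float
    water_inlet_ratio: float
    oil_inlet_ratio: float
    outlet_ratio: float

    def __post_init__(self) -> None:
        if self.orifice_width_um < MIN_ORIFICE_UM:
            raise DomainError(
                f"orifice_width_um={self.orifice_width_um} below the "
                f"{MIN_ORIFICE_UM} μm fabrication floor"
            )
        for name in ("aspect_ratio", "orifice_length_ratio", "water_inlet_ratio",
                     "oil_inlet_ratio", "outlet_ratio"):
            if getattr(self, name) <= 0:
                raise DomainError(f"{name} must be > 0")
        # Tool-level lowest allowable constraint values.
        if self.aspect_ratio < 1.0:
            raise DomainError("aspect_ratio must be ≥ 1")
        if self.water_inlet_ratio < 2.0:
            raise DomainError("water_inlet_ratio must be ≥ 2")

    @property
    def orifice_width_m(self) -> float:
        return units.um_to_m(self.orifice_width_um)

    @property
    def channel_depth_m(self) -> float:
        return self.aspect_ratio * self.orifice_width_m

    @property
    def water_inlet_m(self) -> float:
        return self.water_inlet_ratio * self.orifice_width_m

    @property
    def oil_inlet_m(self) -> float:
        return self.oil_inlet_ratio * self.orifice_width_m


@dataclass
class FlowCondition:
    """Flow condition in dimensionless (Ca, ϕ) and/or absolute (Q_c, Q_d) form.

    ``continuous_rate`` and ``dispersed_rate`` are stored in m³/s.
    When all of ϕ, Q_c, Q_d are populated they must satisfy Q_d·ϕ = Q_c.
    """

    capillary_number: float
    flow_rate_ratio: float
    continuous_rate: float | None = None
    dispersed_rate: float | None = None

    def __post_init__(self) -> None:
        if self.capillary_number <= 0:
            raise DomainError("capillary_number must be > 0")
        if self.flow_rate_ratio <= 0:
            raise DomainError("flow_rate_ratio must be > 0")
        for name in ("continuous_rate", "dispersed_rate"):
            v = getattr(self, name)
            if v is not None and v <= 0:
                raise DomainError(f"{name} must be > 0 m³/s")
        if self.continuous_rate is not None and self.dispersed_rate is not None:
            if not math.isclose(self.dispersed_rate * self.flow_rate_ratio,
                                self.continuous_rate, rel_tol=1e-9):
                raise DomainError("Q_d·ϕ must equal Q_c (relative 1e-9)")

    @property
    def continuous_rate_ml_h(self) -> float | None:
        if self.continuous_rate is None:
            return None
        return units.m3s_to_ml_h(self.continuous_rate)

    @property
    def dispersed_rate_ul_min(self) -> float | None:
        if self.dispersed_rate is None:
            return None
        return units.m3s_to_ul_min(self.dispersed_rate)


@dataclass(frozen=True)
class DesignPoint:
    """The eight design parameters fed to the predictive models."""

    geometry: Geometry
    flow: FlowCondition

    def to_vector(self) -> tuple[float, ...]:
        """Parameters in :data:`FEATURE_NAMES` order."""
        g, f = self.geometry, self.flow
        return (g.orifice_width_um, g.aspect_ratio, g.orifice_length_ratio,
                g.water_inlet_ratio, g.oil_inlet_ratio, g.outlet_ratio,
                f.capillary_number, f.flow_rate_ratio)

    @staticmethod
    def from_vector(vec) -> "DesignPoint":
        (orifice, aspect, olen, water, oil, outlet, ca, phi) = (
            float(v) for v in vec)
        return DesignPoint(
            geometry=Geometry(orifice, aspect, olen, water, oil, outlet),
            flow=FlowCondition(capillary_number=ca, flow_rate_ratio=phi),
        )


@dataclass
class Performance:
    """Observed or predicted droplet-generation performance."""

    regime: str
    diameter_um: float
    rate_hz: float
    inferred_diameter_um: float | None = None
    polydispersity: float | None = None

    def __post_init__(self) -> None:
        regime = self.regime.lower()
        if regime not in REGIMES:
            raise DomainError(f"regime must be one of {REGIMES}, got {self.regime!r}")
        object.__setattr__(self, "regime", regime)
        if self.diameter_um <= 0:
            raise DomainError("diameter_um must be > 0")
        if self.rate_hz <= 0:
            raise DomainError("rate_hz must be > 0")


@dataclass(frozen=True)
class ErrorPropagation:
    """Exact and first-order propagated diameter→rate errors.

    ``eps_d`` = δ/D; ``eps_f_exact`` = 1 − D³/(D+δ)³; ``eps_f_approx`` = 3·ε_d.
    ``delta_um`` / ``delta_f_hz`` are the corresponding absolute errors.
    """

    delta_um: float
    delta_f_hz: float
    eps_d: float
    eps_f_exact: float
    eps_f_approx: float


def dispersed_rate_from(diameter_um: float, rate_hz: float) -> float:
    """Dispersed-phase flow rate Q_d = (π/6)·D³·F by conservation of mass.

    Parameters are the droplet diameter in μm and the generation rate in Hz;
    the returned flow is in m³/s.
    """
    if diameter_um <= 0 or rate_hz <= 0:
        raise DomainError("diameter and rate must be > 0")
    d_m = units.um_to_m(diameter_um)
    return (math.pi / 6.0) * d_m**3 * rate_hz


def infer_diameter(dispersed_rate_m3s: float, rate_hz: float) -> float:
    """Inferred droplet diameter (μm) from Q_d (m³/s) and rate F (Hz).

    D_inf = 1e6·(6·Q_w/(π·F))^(1/3); the exact algebraic inverse of
    :func:`dispersed_rate_from`. Used as the redundancy term cross-checking
    the diameter regressor against the rate regressor.
    """
    if dispersed_rate_m3s <= 0 or rate_hz <= 0:
        raise DomainError("dispersed rate and rate must be > 0")
    d_m = (6.0 * dispersed_rate_m3s / (math.pi * rate_hz)) ** (1.0 / 3.0)
    return units.m_to_um(d_m)


def flow_rates_from_dimensionless(
    flow: FlowCondition, geometry: Geometry, fluids: FluidPair
) -> FlowCondition:
    """Convert a (Ca, ϕ) flow condition into absolute flow rates.

    Q_c = Ca·σ·H·W_c / (μ_c·W_d·[1/Or − 1/(2·W_c)]),  Q_d = Q_c/ϕ,

    with the channel depth H, oil-inlet width W_c, water-inlet width W_d and
    orifice width Or in m, so that both flows come out in m³/s. The bracket
    is positive whenever the oil inlet is wider than half the orifice.
    """
    if fluids is None:
        raise DomainError("fluid properties (μ_c, σ) are required")
    orifice = geometry.orifice_width_m
    w_c = geometry.oil_inlet_m
    w_d = geometry.water_inlet_m
    depth = geometry.channel_depth_m
    bracket = 1.0 / orifice - 1.0 / (2.0 * w_c)
    if bracket <= 0:
        raise DomainError(
            "degenerate geometry: 1/Or − 1/(2·W_c) ≤ 0 "
            "(oil inlet must exceed half the orifice width)"
        )
    q_c = (flow.capillary_number * fluids.interfacial_tension * depth * w_c) / (
        fluids.continuous_viscosity * w_d * bracket
    )
    q_d = q_c / flow.flow_rate_ratio
    return FlowCondition(
        capillary_number=flow.capillary_number,
        flow_rate_ratio=flow.flow_rate_ratio,
        continuous_rate=q_c,
        dispersed_rate=q_d,
    )


def capillary_number_from_rates(
    continuous_rate_m3s: float, geometry: Geometry, fluids: FluidPair
) -> float:
    """Invert the flow-rate conversion: Ca implied by Q_c for a geometry."""
    if continuous_rate_m3s <= 0:
        raise DomainError("continuous rate must be > 0")
    bracket = 1.0 / geometry.orifice_width_m - 1.0 / (2.0 * geometry.oil_inlet_m)
    if bracket <= 0:
        raise DomainError("degenerate geometry: 1/Or − 1/(2·W_c) ≤ 0")
    return (continuous_rate_m3s * fluids.continuous_viscosity * geometry.water_inlet_m
            * bracket) / (fluids.interfacial_tension * geometry.channel_depth_m
                          * geometry.oil_inlet_m)


def propagate_diameter_error(
    diameter_um: float, delta_um: float, dispersed_rate_m3s: float
) -> ErrorPropagation:
    """Propagate a diameter error δ into the generation-rate error.

    At fixed Q_d, F ∝ 1/D³, so the exact fractional rate error is
    ε_f = 1 − D³/(D+δ)³ and its first-order (Taylor) approximation is 3·ε_d
    with ε_d = δ/D. The ratio ε_f/ε_d approaches 3 as δ/D → 0.
    """
    if diameter_um <= 0:
        raise DomainError("diameter must be > 0")
    if delta_um <= -diameter_um:
        raise DomainError("delta must exceed −diameter (D+δ must stay positive)")
    eps_d = delta_um / diameter_um
    eps_f_exact = 1.0 - 1.0 / (1.0 + eps_d) ** 3
    eps_f_approx = 3.0 * eps_d
    rate_nominal = dispersed_rate_m3s / (
        (math.pi / 6.0) * units.um_to_m(diameter_um) ** 3
    )
    rate_perturbed = dispersed_rate_m3s / (
        (math.pi / 6.0) * units.um_to_m(diameter_um + delta_um) ** 3
    )
    return ErrorPropagation(
        delta_um=delta_um,
        delta_f_hz=rate_nominal - rate_perturbed,
        eps_d=eps_d,
        eps_f_exact=eps_f_exact,
        eps_f_approx=eps_f_approx,
    )
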