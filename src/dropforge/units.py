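"""Unit conversions for flow and length quantities.

All internal computation in this package uses SI units (lengths in m,
volumetric flows in m³/s). The conversions below are applied only at I/O
boundaries: droplet diameters are displayed in μm, continuous-phase (oil)
flow rates in ml/h, and dispersed-phase (water) flow rates in μl/min,
following the conventions of the droplet-microfluidics literature.
"""

M_PER_UM = 1e-6
UM_PER_M = 1e6

# 1 μl/min = 1e-9 m³ / 60 s
M3S_PER_UL_MIN = 1e-9 / 60.0
# 1 ml/h = 1e-6 m³ / 3600 s
M3S_PER_ML_H = 1e-6 / 3600.0


def um_to_m(value_um: float) -> float:
    return value_um * M_PER_UM


def m_to_um(value_m: float) -> float:
    return value_m * UM_PER_M


def ul_min_to_m3s(value: float) -> float:
    return value * M3S_PER_UL_MIN


def m3s_to_ul_min(value: float) -> float:
    return value / M3S_PER_UL_MIN


def ml_h_to_m3s(value: float) -> float:
    return value * M3S_PER_ML_H


def m3s_to_ml_h(value: float) -> float:
    return value / M3S_PER_ML_H
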