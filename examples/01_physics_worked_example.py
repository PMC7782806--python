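"""Conservation-of-mass arithmetic on a real operating point.

A flow-focusing device running 0.52 μl/min of dispersed phase at 167
droplets per second must, by mass conservation, produce droplets of a
specific diameter — no model needed. The same relation propagates a
diameter prediction error into roughly three times the rate error.
"""

from dropforge import physics, units

q_w = units.ul_min_to_m3s(0.52)  # dispersed (water) flow, m³/s
diameter = physics.infer_diameter(q_w, 167.0)
print(f"inferred droplet diameter: {diameter:.1f} μm")
# → 46.3 μm: each of the 167 droplets per second carries 1/167th of the flow.

q_c = units.ml_h_to_m3s(0.312)  # continuous (oil) flow at flow-rate ratio 10
print(f"dispersed flow at ratio 10: {units.m3s_to_ul_min(q_c / 10):.2f} μl/min")
# → 0.52 μl/min: the dimensionless flow condition fixes both pump settings.

ep = physics.propagate_diameter_error(100.0, 1.0, physics.dispersed_rate_from(100.0, 100.0))
print(f"1% diameter error → {100 * ep.eps_f_exact:.1f}% rate error "
      f"(first-order: {100 * ep.eps_f_approx:.1f}%)")
# → ≈3%: rate scales with 1/D³, so small diameter errors triple in the rate.
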