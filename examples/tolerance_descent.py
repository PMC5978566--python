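"""Measure a detection threshold with the tolerance-descent procedure.

The distance tolerance starts above the induced error and is lowered in
0.1 mm steps until failing pixels first appear; with equality passing and
no noise, a 1.5 mm edge shift is first flagged one grid step below, at
1.4 mm, so the noise-free sensitivity is bounded by the sweep step.
"""

import episense as ep

pitch = ep.DEFAULT_PITCH_MM * 2
panel = (384, 512)

nominal = ep.open_field(10.0, 10.0)
errant, _ = ep.inject_error(nominal, None, "jaw_shift", jaw="X2", shift_mm=1.0)
baseline = ep.render_image(nominal, pitch_mm=pitch, panel_shape=panel)
fraction = ep.render_image(errant, pitch_mm=pitch, panel_shape=panel)

sweep = ep.sweep_dta(baseline, fraction, start_mm=2.0, step_mm=0.1, induced_mm=1.5)

print("tolerance  failing pixels")
for tolerance, n_fail in sweep.trace:
    print(f"  {tolerance:4.1f} mm   {n_fail}")
print(f"detection threshold : {sweep.detection_threshold} mm")
print(f"induced (detector)  : {sweep.induced_magnitude} mm")
print(f"sensitivity         : {sweep.sensitivity:.1f} mm (<= one sweep step, noise-free)")
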