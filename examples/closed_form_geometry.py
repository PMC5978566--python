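"""How induced machine errors appear on the portal image, analytically.

Length errors set at the isocenter are magnified by sdd/sad = 1.5 on a
panel at 150 cm; a collimator rotation tilts every field edge by half the
field side times tan(angle); a vertical couch error only changes the
apparent size of the irradiated region, by diameter * v / SAD.
"""

import episense as ep

geom = ep.PlaneGeometry()  # SAD 100 cm, SDD 150 cm
print(f"magnification sdd/sad = {geom.magnification}")

for shift in (1.0, 2.0, 3.0, 4.0):
    print(f"jaw opened {shift:.0f} mm at isocenter -> edge moves {shift * geom.magnification:.1f} mm on the image")

for theta in (1.0, 2.0, 3.0):
    dev = ep.collimator_edge_deviation(150.0, theta)
    print(f"collimator rotated {theta:.0f} deg on the 15 cm image field -> max edge deviation {dev:.1f} mm")

for v in (4.0, 10.0):
    out = ep.vertical_couch_apparent_shift(100.0, v, 1000.0)
    print(
        f"couch {v:.0f} mm too high under a 10 cm dose region -> "
        f"diameter change {out['diameter_change_mm']:.1f} mm, edge shift {out['edge_shift_mm']:.1f} mm"
    )

print(f"3 mm vertical error seen by a lateral beam: {ep.oblique_couch_projection(3.0, 90.0):.1f} mm in-image")
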