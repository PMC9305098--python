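"""Shared physical constants and frame conventions.

The en-face angiography frame and the trajectory model must agree on a
single degrees-to-millimeters conversion; both import it from here.
"""

#: Physical width of the normalized en-face angiography frame (mm).
TARGET_MM = 4.11

#: Pixel width of the normalized en-face angiography frame.
TARGET_PX = 960

#: Angular field of view of the en-face scan (degrees).
FIELD_DEG = 15.0

#: Retinal scale: TARGET_MM of tissue spans FIELD_DEG of visual angle.
MM_PER_DEG = TARGET_MM / FIELD_DEG  # = 0.274 mm/deg

#: Diameter of the circumpapillary ring scan (mm).
RING_DIAMETER_MM = 3.5

#: Radius of the ring scan expressed in degrees of visual angle.
RING_RADIUS_DEG = (RING_DIAMETER_MM / 2.0) / MM_PER_DEG
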