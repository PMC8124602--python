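"""Unit conventions.

Labels are expressed in kg (weight) and cm (body sizes); depth images are in
mm. The single cm<->mm conversion used across the package lives here so the
factor of 10 cannot drift between modules.
"""

#: Default camera-to-platform distance (mm).
CAMERA_DISTANCE_MM = 1650.0


def cm_to_mm(x):
    """Convert centimetres to millimetres."""
    return x * 10.0


def mm_to_cm(x):
    """Convert millimetres to centimetres."""
    return x / 10.0
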