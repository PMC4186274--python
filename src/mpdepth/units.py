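"""Unit conventions and conversion constants.

Every quantity in this package carries a fixed unit convention:

- viewing distance ``f`` and depth ``d``: centimetres
- retinal image velocity ``dtheta`` and pursuit velocity ``dalpha``: deg/s
  (unless a :class:`~mpdepth.geometry.TransducerModel` says radians)
- binocular disparity ``delta``: arcmin
- head translation speed ``v``: cm/s
- logarithms in the plane fit: natural logs
"""

import math

DEG_PER_RAD = 180.0 / math.pi
ARCMIN_PER_DEG = 60.0
ARCMIN_PER_RAD = DEG_PER_RAD * ARCMIN_PER_DEG

#: Default inter-ocular distance (cm); standard adult value.
DEFAULT_INTEROCULAR_CM = 6.5

#: Default monitor pixel pitch (mm per pixel).
DEFAULT_PIXEL_PITCH_MM = 0.244


def arcmin_to_rad(delta_arcmin: float) -> float:
    """Convert a disparity from arcmin to radians."""
    return delta_arcmin / ARCMIN_PER_RAD


def rad_to_arcmin(delta_rad: float) -> float:
    """Convert an angle from radians to arcmin."""
    return delta_rad * ARCMIN_PER_RAD
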