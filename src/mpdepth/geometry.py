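"""Closed-form depth laws and unit conversions for motion parallax.

Motion parallax couples the retinal image velocity of a non-fixated point
(``dtheta``, deg/s) to the compensatory pursuit eye rotation (``dalpha``,
deg/s) that keeps the fixated point stable. The exact geometry gives relative
depth as

    d/f = (dtheta/dalpha) * 1 / (1 - dtheta/dalpha)        (motion/pursuit law)

which for the small ratios used here is well approximated by the
motion/pursuit ratio itself, d/f ~ dtheta/dalpha. Perceived depth, however,
is strongly foreshortened relative to this geometry; the empirical
motion/pursuit ratio models it with power-law transducers on the two rate
signals,

    d_mp = k * f * dtheta**r / dalpha**e

with fitted exponents r (retinal motion) and e (pursuit) and a scaling
constant k whose value depends on the angular unit. Binocular comparison
stimuli are converted between disparity and depth by the distance-square law
d = f**2 * delta / i.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from enum import Enum

import numpy as np

from .units import (
    ARCMIN_PER_RAD,
    DEFAULT_INTEROCULAR_CM,
    DEFAULT_PIXEL_PITCH_MM,
    DEG_PER_RAD,
    arcmin_to_rad,
)

__all__ = [
    "AngleUnit",
    "HeadState",
    "Direction",
    "StimulusCondition",
    "DisparityStimulus",
    "TransducerModel",
    "JohnstonScaling",
    "exact_relative_depth",
    "approx_depth",
    "disparity_to_depth",
    "depth_to_disparity",
    "empirical_depth",
    "rescale_model",
    "johnston_ratio",
    "head_speed_to_pursuit_rate",
    "pixel_to_angle",
    "pursuit_fraction",
]


class AngleUnit(str, Enum):
    DEGREE = "degree"
    RADIAN = "radian"


class HeadState(str, Enum):
    STATIONARY = "stationary"
    TRANSLATING = "translating"


class Direction(str, Enum):
    LEFT = "left"
    RIGHT = "right"


@dataclass(frozen=True)
class StimulusCondition:
    """One motion-parallax stimulus.

    Parameters
    ----------
    f : float
        Viewing distance, cm. Must be positive.
    dtheta : float
        Peak retinal image velocity, deg/s. Must be positive and smaller
        than ``dalpha`` (ratio in (0, 1)).
    dalpha : float
        Pursuit / compensatory eye rotation velocity, deg/s. Positive.
    head_state : HeadState
        Whether the observer's head is stationary or laterally translating.
    direction : Direction
        Direction of stimulus (or head) translation. The two directions are
        pooled in analysis.
    """

    f: float
    dtheta: float
    dalpha: float
    head_state: HeadState = HeadState.STATIONARY
    direction: Direction = Direction.LEFT

    def __post_init__(self) -> None:
        if self.f <= 0:
            raise ValueError(f"viewing distance f must be > 0 cm, got {self.f}")
        if self.dalpha <= 0:
            raise ValueError(f"dalpha must be > 0 deg/s, got {self.dalpha}")
        if self.dtheta < 0:
            raise ValueError(f"dtheta must be >= 0 deg/s, got {self.dtheta}")
        if self.dtheta / self.dalpha >= 1:
            raise ValueError(
                "motion/pursuit ratio dtheta/dalpha must be < 1 "
                f"(got {self.dtheta / self.dalpha:.3g})"
            )

    @property
    def ratio(self) -> float:
        """Motion/pursuit ratio dtheta/dalpha (dimensionless)."""
        return self.dtheta / self.dalpha


@dataclass(frozen=True)
class DisparityStimulus:
    """A static binocular-disparity stimulus.

    delta is the peak disparity in arcmin, f the viewing distance in cm and
    i the inter-ocular distance in cm.
    """

    delta: float
    f: float
    i: float = DEFAULT_INTEROCULAR_CM

    def __post_init__(self) -> None:
        if self.delta < 0:
            raise ValueError(f"disparity must be >= 0 arcmin, got {self.delta}")
        if self.f <= 0:
            raise ValueError(f"viewing distance f must be > 0 cm, got {self.f}")
        if self.i <= 0:
            raise ValueError(f"inter-ocular distance must be > 0 cm, got {self.i}")


@dataclass(frozen=True)
class TransducerModel:
    """Power-law transducer parameters of the empirical motion/pursuit ratio.

    ``r`` and ``e`` are the dimensionless exponents on the retinal-motion and
    pursuit signals; ``k`` is the scaling constant, whose numerical value
    depends on the angular unit in which the rates are expressed
    (``angle_unit``). The defaults are the values fitted to group depth
    matches with rates in deg/s.
    """

    r: float = 0.416
    e: float = 0.192
    k: float = 0.0313
    angle_unit: AngleUnit = AngleUnit.DEGREE

    def __post_init__(self) -> None:
        if self.k <= 0:
            raise ValueError(f"scaling constant k must be > 0, got {self.k}")
        if not (math.isfinite(self.r) and math.isfinite(self.e)):
            raise ValueError("exponents r and e must be finite")


#: Transducer parameters after the hypothetical stereo-distortion correction.
ADJUSTED_TRANSDUCER = TransducerModel(r=0.428, e=0.148, k=0.0444)


@dataclass(frozen=True)
class JohnstonScaling:
    """Linear model of stereo depth distortion vs viewing distance.

    perceived/veridical = a - b*f, extrapolated from depth-constancy data at
    two short viewing distances. With the default coefficients the ratio
    exceeds 1 at near distances (stereo depth over-estimated) and crosses 1
    near 92 cm.
    """

    a: float = 2.015
    b: float = 0.011


def exact_relative_depth(dtheta, dalpha):
    """Exact relative depth d/f from the motion/pursuit law.

    d/f = (dtheta/dalpha) / (1 - dtheta/dalpha). Valid for ratios in [0, 1);
    a ratio >= 1 has no solution (the point would be at infinite depth or
    behind the observer).

    Accepts scalars or arrays; rates may be in any consistent angular unit.
    """
    dtheta = np.asarray(dtheta, dtype=float)
    dalpha = np.asarray(dalpha, dtype=float)
    if np.any(dalpha <= 0):
        raise ValueError("dalpha must be > 0")
    ratio = dtheta / dalpha
    if np.any(ratio < 0) or np.any(ratio >= 1):
        raise ValueError("motion/pursuit ratio must lie in [0, 1)")
    out = ratio / (1.0 - ratio)
    return out.item() if out.ndim == 0 else out


def approx_depth(cond: StimulusCondition) -> float:
    """First-order geometric depth prediction d = (dtheta/dalpha) * f, cm.

    This is the default geometric benchmark against which perceived depth is
    compared; it converges to the exact law as the ratio goes to zero.
    """
    return cond.ratio * cond.f


def disparity_to_depth(stim: DisparityStimulus) -> float:
    """Depth (cm) of a disparity stimulus by the distance-square law.

    d = f**2 * delta_rad / i, with delta converted from arcmin to radians.
    """
    return stim.f**2 * arcmin_to_rad(stim.delta) / stim.i


def depth_to_disparity(depth_cm, f, i=DEFAULT_INTEROCULAR_CM):
    """Disparity (arcmin) depicting ``depth_cm`` at distance ``f``.

    Inverse of :func:`disparity_to_depth`: delta = d * i / f**2.
    """
    f = np.asarray(f, dtype=float)
    if np.any(f <= 0) or i <= 0:
        raise ValueError("f and i must be > 0 cm")
    out = np.asarray(depth_cm, dtype=float) * i / f**2 * ARCMIN_PER_RAD
    return out.item() if out.ndim == 0 else out


def empirical_depth(cond: StimulusCondition, model: TransducerModel | None = None) -> float:
    """Perceived depth d_mp (cm) from the empirical motion/pursuit ratio.

    d_mp = k * f * dtheta**r / dalpha**e. Rates must be expressed in
    ``model.angle_unit`` (the package convention is deg/s, matching the
    default k).
    """
    if model is None:
        model = TransducerModel()
    if cond.dtheta <= 0 or cond.dalpha <= 0:
        raise ValueError("empirical depth requires strictly positive rates")
    return model.k * cond.f * cond.dtheta**model.r / cond.dalpha**model.e


def rescale_model(
    model: TransducerModel,
    c: float,
    new_unit: AngleUnit | None = None,
) -> TransducerModel:
    """Re-express a transducer model after multiplying all rates by ``c``.

    If rates are converted as rate' = c * rate (e.g. c = pi/180 for
    degree -> radian), the exponents are unchanged and k' = k / c**(r - e),
    so that predicted depths are invariant. ``new_unit`` optionally records
    the unit of the converted rates.
    """
    if c <= 0:
        raise ValueError(f"conversion factor must be > 0, got {c}")
    k_new = model.k / c ** (model.r - model.e)
    unit = new_unit if new_unit is not None else model.angle_unit
    return replace(model, k=k_new, angle_unit=unit)


def johnston_ratio(f, js: JohnstonScaling | None = None):
    """Perceived/veridical stereo depth ratio a - b*f at distance ``f`` (cm).

    Values <= 0 indicate ``f`` outside the calibrated range; the caller
    decides how to treat them.
    """
    if js is None:
        js = JohnstonScaling()
    f = np.asarray(f, dtype=float)
    if np.any(f <= 0):
        raise ValueError("f must be > 0 cm")
    out = js.a - js.b * f
    return out.item() if out.ndim == 0 else out


def head_speed_to_pursuit_rate(v, f):
    """Compensatory eye rotation rate (deg/s) for head speed v (cm/s) at f (cm).

    Small-angle conversion dalpha = (v / f) * (180 / pi): an observer fixating
    a point at distance f while translating at v must rotate the eye at this
    rate to keep the point foveated.
    """
    f = np.asarray(f, dtype=float)
    if np.any(f <= 0):
        raise ValueError("f must be > 0 cm")
    out = np.asarray(v, dtype=float) / f * DEG_PER_RAD
    return out.item() if out.ndim == 0 else out


def pixel_to_angle(n_pixels, f, pitch_mm=DEFAULT_PIXEL_PITCH_MM):
    """Visual angle (arcmin) subtended by ``n_pixels`` at distance f (cm).

    Small-angle: angle = n * pitch / f, with pitch converted from mm to cm.
    With the default 0.244 mm pitch one pixel subtends 2.33 arcmin at 36 cm,
    1.55 at 54 cm and 1.17 at 72 cm.
    """
    f = np.asarray(f, dtype=float)
    n_pixels = np.asarray(n_pixels, dtype=float)
    if np.any(f <= 0) or pitch_mm <= 0 or np.any(n_pixels < 0):
        raise ValueError("pixel count must be >= 0; pitch and f must be > 0")
    out = n_pixels * (pitch_mm / 10.0) / f * ARCMIN_PER_RAD
    return out.item() if out.ndim == 0 else out


def pursuit_fraction(pursuit_equiv, total):
    """Pursuit-equivalent eye speed as a percentage of the total eye speed."""
    total = np.asarray(total, dtype=float)
    if np.any(total <= 0):
        raise ValueError("total eye speed must be > 0")
    out = 100.0 * np.asarray(pursuit_equiv, dtype=float) / total
    return out.item() if out.ndim == 0 else out
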