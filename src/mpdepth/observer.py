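"""Synthetic 2IFC depth-matching observer.

Generates trial-level data with the statistical structure the analysis
pipeline assumes, so that every downstream stage (aggregation, psychometric
fitting, depth conversion, plane fitting) can be exercised without external
data. On each simulated trial the observer forms a noisy internal depth
estimate of the motion parallax stimulus from the empirical motion/pursuit
ratio and a noisy internal depth estimate of the stereo comparison from the
distance-square law, and reports "stereo deeper" when the latter exceeds the
former. Internal noise is multiplicative lognormal with unit mean, a
Weber-like model for a strictly positive magnitude.

Three session types are emulated:

- head-stationary sessions over a grid of (dtheta, dalpha) pairs at three
  viewing distances (13 psychometric functions x 9 disparity levels per
  condition);
- head-translating sessions where the compensatory eye movement is pursuit
  plus tVOR, but only the pursuit fraction drives perceived depth;
- depth-constancy control sessions comparing a fixed-disparity stimulus at
  one distance against a variable-disparity stimulus at the other.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .geometry import (
    DisparityStimulus,
    JohnstonScaling,
    TransducerModel,
    disparity_to_depth,
    head_speed_to_pursuit_rate,
    johnston_ratio,
    pixel_to_angle,
)
from .units import ARCMIN_PER_RAD, DEFAULT_INTEROCULAR_CM, DEFAULT_PIXEL_PITCH_MM

__all__ = [
    "SimulationConfig",
    "STATIONARY_GRID",
    "TRANSLATING_GRID",
    "build_stimulus_grid",
    "simulate_trials",
    "simulate_head_translation_session",
    "simulate_depth_constancy_control",
    "lognormal_noise",
]

# Head-stationary conditions: condition -> (f_cm, [(ratio, dalpha_deg_s), ...]).
# The grid interpolates the published ranges (ratios 0.042-0.25, dalpha
# 1.1-11.57 deg/s, dtheta 0.14-1.65 deg/s) and includes every published
# anchor value; 13 pairs per condition, 52 in total. The 4.95 deg/s pursuit
# speed appears in both 36 cm conditions as a replication.
STATIONARY_GRID: dict[str, tuple[float, list[tuple[float, float]]]] = {
    "S36A": (36.0, [(r, 4.95) for r in (0.042, 0.083, 0.125, 0.167, 0.25)]
                   + [(r, 6.6) for r in (0.042, 0.083, 0.167, 0.25)]
                   + [(r, 11.57) for r in (0.042, 0.083, 0.125, 0.142)]),
    "S36B": (36.0, [(r, 1.1) for r in (0.13, 0.167, 0.2, 0.25)]
                   + [(r, 2.75) for r in (0.083, 0.125, 0.167, 0.25)]
                   + [(r, 4.95) for r in (0.042, 0.083, 0.125, 0.167, 0.25)]),
    "S54": (54.0, [(r, 2.2) for r in (0.083, 0.125, 0.167, 0.25)]
                  + [(r, 4.4) for r in (0.042, 0.083, 0.167, 0.25)]
                  + [(r, 8.8) for r in (0.042, 0.083, 0.125, 0.167, 0.1875)]),
    "S72": (72.0, [(r, 4.15) for r in (0.042, 0.083, 0.167, 0.25)]
                  + [(r, 4.98) for r in (0.042, 0.083, 0.167, 0.25)]
                  + [(r, 5.81) for r in (0.042, 0.083, 0.125, 0.167, 0.25)]),
}

_TRANSLATING_RATIOS = [0.042, 0.06, 0.083, 0.1, 0.115, 0.13, 0.142,
                       0.155, 0.167, 0.19, 0.21, 0.23, 0.25]

# Head-translating conditions: condition -> (f_cm, mean and SD of the head
# translation speed in cm/s, 13 nominal motion/pursuit ratios).
TRANSLATING_GRID: dict[str, tuple[float, float, float, list[float]]] = {
    "T36": (36.0, 11.0, 0.9, list(_TRANSLATING_RATIOS)),
    "T72": (72.0, 12.1, 1.2, list(_TRANSLATING_RATIOS)),
}


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for the synthetic observer.

    Defaults reproduce the emulated experiment's scale: 13 psychometric
    functions x 9 disparity levels (1-9 pixels) per condition, 20 blocks,
    7 concordant observers; internal-depth noise CV 0.15 (placing fitted
    sigmas in the 1-3 arcmin range); only 40% of the head-translation
    compensatory eye movement (the pursuit component) drives depth.
    """

    true_model: TransducerModel = field(default_factory=TransducerModel)
    noise_cv: float = 0.15
    pursuit_gain: float = 0.4
    johnston_distortion: bool = False
    johnston: JohnstonScaling = field(default_factory=JohnstonScaling)
    i: float = DEFAULT_INTEROCULAR_CM
    pixel_pitch_mm: float = DEFAULT_PIXEL_PITCH_MM
    disparity_pixels: tuple[int, ...] = tuple(range(1, 10))
    n_blocks: int = 20
    n_observers: int = 7
    stationary_grid: dict = field(default_factory=lambda: dict(STATIONARY_GRID))
    translating_grid: dict = field(default_factory=lambda: dict(TRANSLATING_GRID))

    def __post_init__(self) -> None:
        if self.noise_cv < 0:
            raise ValueError(f"noise_cv must be >= 0, got {self.noise_cv}")
        if not 0 < self.pursuit_gain <= 1:
            raise ValueError(f"pursuit_gain must be in (0, 1], got {self.pursuit_gain}")
        for cid, (f, pairs) in self.stationary_grid.items():
            for ratio, dalpha in pairs:
                if not 0 < ratio < 1:
                    raise ValueError(f"{cid}: ratio {ratio} outside (0, 1)")
                if dalpha <= 0:
                    raise ValueError(f"{cid}: dalpha {dalpha} must be > 0")
        for cid, (f, _, _, ratios) in self.translating_grid.items():
            for ratio in ratios:
                if not 0 < ratio < 1:
                    raise ValueError(f"{cid}: ratio {ratio} outside (0, 1)")


def lognormal_noise(rng: np.random.Generator, cv: float, size) -> np.ndarray:
    """Unit-mean multiplicative lognormal noise with coefficient of variation cv."""
    if cv == 0:
        return np.ones(size)
    s2 = np.log1p(cv * cv)
    return rng.lognormal(mean=-0.5 * s2, sigma=np.sqrt(s2), size=size)


def build_stimulus_grid(config: SimulationConfig | None = None) -> pd.DataFrame:
    """Expand the configured conditions into a trial-type table.

    One row per (condition, stimulus pair, disparity level); with the default
    configuration each condition contributes 13 x 9 = 117 trial types (one
    block's worth of trials). Head-translating rows carry the nominal total
    eye speed implied by the mean head speed.
    """
    config = config or SimulationConfig()
    rows = []
    pixels = np.asarray(config.disparity_pixels)
    for cid, (f, pairs) in config.stationary_grid.items():
        arcmin = pixel_to_angle(pixels, f, config.pixel_pitch_mm)
        for ratio, dalpha in pairs:
            for px, am in zip(pixels, arcmin):
                rows.append((cid, f, "stationary", ratio * dalpha, dalpha,
                             ratio, np.nan, int(px), am))
    for cid, (f, v_mean, _v_sd, ratios) in config.translating_grid.items():
        arcmin = pixel_to_angle(pixels, f, config.pixel_pitch_mm)
        total = head_speed_to_pursuit_rate(v_mean, f)
        for ratio in ratios:
            for px, am in zip(pixels, arcmin):
                rows.append((cid, f, "translating", ratio * total, total,
                             ratio, v_mean, int(px), am))
    return pd.DataFrame(
        rows,
        columns=["condition_id", "f_cm", "head_state", "dtheta_deg_s",
                 "dalpha_deg_s", "ratio", "head_speed_cm_s",
                 "disparity_pixels", "disparity_arcmin"],
    )


def _assemble_session(grid: pd.DataFrame, config: SimulationConfig) -> pd.DataFrame:
    """Tile the trial-type grid over observers and blocks."""
    frames = []
    for obs in range(1, config.n_observers + 1):
        for block in range(1, config.n_blocks + 1):
            t = grid.copy()
            t["observer_id"] = f"O{obs}"
            t["block"] = block
            t["direction"] = "left" if block % 2 == 1 else "right"
            frames.append(t)
    return pd.concat(frames, ignore_index=True)


def _internal_stereo_depth(trials: pd.DataFrame, config: SimulationConfig,
                           rng: np.random.Generator) -> np.ndarray:
    d = trials["f_cm"].to_numpy() ** 2 \
        * (trials["disparity_arcmin"].to_numpy() / ARCMIN_PER_RAD) / config.i
    if config.johnston_distortion:
        d = d * johnston_ratio(trials["f_cm"].to_numpy(), config.johnston)
    return d * lognormal_noise(rng, config.noise_cv, len(trials))


def simulate_trials(grid: pd.DataFrame | None = None,
                    config: SimulationConfig | None = None,
                    seed: int = 0) -> pd.DataFrame:
    """Simulate head-stationary 2IFC sessions over the stationary grid.

    Internal parallax depth is ``empirical_depth(condition, true_model)``
    times lognormal noise; internal stereo depth is the distance-square-law
    depth (optionally Johnston-distorted) times independent lognormal noise.
    The response is "stereo deeper" iff the stereo internal depth exceeds
    the parallax internal depth. Identical (config, seed) give identical
    trial streams.
    """
    config = config or SimulationConfig()
    if grid is None:
        grid = build_stimulus_grid(config)
    grid = grid[grid["head_state"] == "stationary"]
    if grid.empty:
        raise ValueError("no head-stationary trial types in grid")
    rng = np.random.default_rng(seed)
    trials = _assemble_session(grid, config)

    m = config.true_model
    d_mp = m.k * trials["f_cm"].to_numpy() \
        * trials["dtheta_deg_s"].to_numpy() ** m.r \
        / trials["dalpha_deg_s"].to_numpy() ** m.e
    internal_mp = d_mp * lognormal_noise(rng, config.noise_cv, len(trials))
    internal_stereo = _internal_stereo_depth(trials, config, rng)
    trials["response_stereo_deeper"] = internal_stereo > internal_mp
    return _finalize(trials)


def simulate_head_translation_session(grid: pd.DataFrame | None = None,
                                      config: SimulationConfig | None = None,
                                      seed: int = 0) -> pd.DataFrame:
    """Simulate head-translating 2IFC sessions.

    The per-trial head speed is drawn from a truncated normal around the
    configured mean; the stimulus program holds each trial's nominal
    motion/pursuit ratio regardless of the drawn speed. The total
    compensatory eye speed is ``head_speed_to_pursuit_rate(v, f)``, but only
    the pursuit fraction ``g = pursuit_gain`` of it feeds the depth
    mechanism: perceived depth equals that of a head-stationary stimulus at
    the same motion/pursuit ratio with dalpha = g * total.
    """
    config = config or SimulationConfig()
    if grid is None:
        grid = build_stimulus_grid(config)
    grid = grid[grid["head_state"] == "translating"]
    if grid.empty:
        raise ValueError("no head-translating trial types in grid")
    rng = np.random.default_rng(seed)
    trials = _assemble_session(grid, config)

    speed_mean = trials["head_speed_cm_s"].to_numpy()
    sd_by_cond = {cid: spec[2] for cid, spec in config.translating_grid.items()}
    speed_sd = trials["condition_id"].map(sd_by_cond).to_numpy(dtype=float)
    v = rng.normal(speed_mean, speed_sd)
    v = np.clip(v, 0.05 * speed_mean, None)  # truncated positive
    trials["head_speed_cm_s"] = v

    total = head_speed_to_pursuit_rate(v, trials["f_cm"].to_numpy())
    dalpha_eff = config.pursuit_gain * total
    dtheta_eff = trials["ratio"].to_numpy() * dalpha_eff
    m = config.true_model
    d_mp = m.k * trials["f_cm"].to_numpy() * dtheta_eff ** m.r / dalpha_eff ** m.e
    internal_mp = d_mp * lognormal_noise(rng, config.noise_cv, len(trials))
    internal_stereo = _internal_stereo_depth(trials, config, rng)
    trials["response_stereo_deeper"] = internal_stereo > internal_mp
    return _finalize(trials)


def _finalize(trials: pd.DataFrame) -> pd.DataFrame:
    cols = ["observer_id", "condition_id", "f_cm", "dtheta_deg_s",
            "dalpha_deg_s", "head_state", "direction", "head_speed_cm_s",
            "disparity_pixels", "disparity_arcmin", "response_stereo_deeper",
            "block"]
    return trials[cols].reset_index(drop=True)


# -- depth-constancy control ------------------------------------------------

#: (fixed f, fixed disparity arcmin, variable f, variable disparity range)
CONTROL_CONDITIONS = {
    "C_fix36": (36.0, 23.3, 72.0, (1.2, 11.7)),
    "C_fix72": (72.0, 4.66, 36.0, (9.3, 28.0)),
}

OBSERVER_MODELS = ("perfect_constancy", "disparity_matcher", "distance_misestimate")


def simulate_depth_constancy_control(config: SimulationConfig | None = None,
                                     observer_model: str = "perfect_constancy",
                                     misestimate: float = 0.10,
                                     n_levels: int = 9,
                                     n_reps_per_block: int = 10,
                                     n_blocks: int = 2,
                                     n_observers: int = 9,
                                     conditions: dict | None = None,
                                     seed: int = 0) -> pd.DataFrame:
    """Simulate the two-distance depth-constancy control sessions.

    A fixed-disparity stereo stimulus at one distance is compared against a
    variable-disparity stimulus at the other (method of constant stimuli,
    default 9 levels x 10 repeats x 2 blocks per condition). Observer models:

    - ``perfect_constancy``: internal depths follow the distance-square law
      at each stimulus's true distance; the PSE lands where the two depths
      are equal, i.e. delta_fixed * (f_fixed / f_variable)**2.
    - ``disparity_matcher``: the observer compares raw disparities, ignoring
      distance, producing a (f_fixed/f_variable)**2-fold depth mismatch.
    - ``distance_misestimate``: the variable stimulus's distance is
      mis-perceived by ``misestimate`` (over-estimated when near, under-
      estimated when far), shifting the PSE by the squared factor.
    """
    config = config or SimulationConfig()
    if observer_model not in OBSERVER_MODELS:
        raise ValueError(f"unknown observer_model {observer_model!r}; "
                         f"choose from {OBSERVER_MODELS}")
    rng = np.random.default_rng(seed)
    rows = []
    conditions = conditions if conditions is not None else CONTROL_CONDITIONS
    for cid, (f_fix, delta_fix, f_var, (lo, hi)) in conditions.items():
        levels = np.linspace(lo, hi, n_levels)
        for obs in range(1, n_observers + 1):
            for block in range(1, n_blocks + 1):
                deltas = np.tile(levels, n_reps_per_block)
                n = len(deltas)
                if observer_model == "disparity_matcher":
                    int_fix = delta_fix * lognormal_noise(rng, config.noise_cv, n)
                    int_var = deltas * lognormal_noise(rng, config.noise_cv, n)
                else:
                    f_var_perceived = f_var
                    if observer_model == "distance_misestimate":
                        factor = 1 + misestimate if f_var < f_fix else 1 - misestimate
                        f_var_perceived = f_var * factor
                    d_fix = disparity_to_depth(
                        DisparityStimulus(delta_fix, f_fix, config.i))
                    d_var = f_var_perceived**2 \
                        * (deltas / ARCMIN_PER_RAD) / config.i
                    int_fix = d_fix * lognormal_noise(rng, config.noise_cv, n)
                    int_var = d_var * lognormal_noise(rng, config.noise_cv, n)
                resp = int_var > int_fix
                for dlt, r in zip(deltas, resp):
                    rows.append((f"O{obs}", cid, f_fix, delta_fix, f_var,
                                 dlt, bool(r), block))
    return pd.DataFrame(
        rows,
        columns=["observer_id", "condition_id", "f_fixed_cm",
                 "delta_fixed_arcmin", "f_variable_cm", "disparity_arcmin",
                 "response_variable_deeper", "block"],
    )
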