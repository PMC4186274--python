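"""End-to-end analysis pipeline: simulate -> aggregate -> fit -> report.

Stages mirror the emulated study's analysis: per-condition psychometric
functions are fitted to pooled 2IFC responses, their PSEs are converted to
perceived-depth matches through the distance-square law, the head-stationary
matches feed the log-space plane fit of the empirical motion/pursuit ratio
(plus its stereo-distortion-adjusted refit), head-translating matches are
reduced to pursuit-equivalent eye speeds, and the depth-constancy control
sessions are summarized as normalized depth matches. An observer whose PSEs
sit more than 3 SD from the group means across most functions is excluded
before the group analysis.

Unit conventions (fixed package-wide): cm, deg/s, arcmin, natural logs.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .geometry import (
    DisparityStimulus,
    JohnstonScaling,
    TransducerModel,
    disparity_to_depth,
)
from .observer import (
    SimulationConfig,
    build_stimulus_grid,
    simulate_depth_constancy_control,
    simulate_head_translation_session,
    simulate_trials,
)
from .psychometrics import (
    FUNCTION_KEYS,
    PsychometricCumulativeNormal,
    aggregate_trials,
)
from .transducer import (
    PlaneFitResult,
    fit_empirical_mpr,
    johnston_adjust_and_refit,
)

logger = logging.getLogger("mpdepth")

__all__ = [
    "TRIAL_COLUMNS",
    "read_trials",
    "write_trials",
    "per_observer_pses",
    "exclude_outlier_observers",
    "fit_depth_matches",
    "pursuit_fraction_table",
    "analyze_constancy",
    "run_full_pipeline",
    "PipelineReport",
]

TRIAL_COLUMNS = [
    "observer_id", "condition_id", "f_cm", "dtheta_deg_s", "dalpha_deg_s",
    "head_state", "direction", "head_speed_cm_s", "disparity_pixels",
    "disparity_arcmin", "response_stereo_deeper", "block",
]

_HEAD_STATES = {"stationary", "translating"}
_DIRECTIONS = {"left", "right"}


def write_trials(trials: pd.DataFrame, path, provenance: dict | None = None) -> None:
    """Write a trial table as CSV with provenance recorded in '#' header lines."""
    path = Path(path)
    with path.open("w") as fh:
        for key, value in (provenance or {}).items():
            fh.write(f"# {key}={value}\n")
        trials.to_csv(fh, index=False)


def read_trials(path) -> tuple[pd.DataFrame, dict]:
    """Read and validate a trial CSV; returns (trials, provenance).

    Validation errors cite the 1-based file line of the offending row.
    """
    path = Path(path)
    provenance: dict[str, str] = {}
    n_comment = 0
    with path.open() as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            n_comment += 1
            body = line[1:].strip()
            if "=" in body:
                key, _, value = body.partition("=")
                provenance[key.strip()] = value.strip()
    trials = pd.read_csv(path, comment="#")
    if trials.empty:
        raise ValueError(f"{path}: no trial rows")
    missing = [c for c in TRIAL_COLUMNS if c not in trials.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s) {missing}")

    # file line of data row i: comments + header + 1-based offset
    def line_of(idx: int) -> int:
        return n_comment + 2 + int(idx)

    bad = trials.index[~trials["head_state"].isin(_HEAD_STATES)]
    if len(bad):
        raise ValueError(
            f"{path} line {line_of(bad[0])}: unknown head_state "
            f"{trials.loc[bad[0], 'head_state']!r}"
        )
    bad = trials.index[~trials["direction"].isin(_DIRECTIONS)]
    if len(bad):
        raise ValueError(
            f"{path} line {line_of(bad[0])}: unknown direction "
            f"{trials.loc[bad[0], 'direction']!r}"
        )
    for col in ("f_cm", "dtheta_deg_s", "dalpha_deg_s"):
        bad = trials.index[trials[col] <= 0]
        if len(bad):
            raise ValueError(
                f"{path} line {line_of(bad[0])}: non-positive {col} "
                f"({trials.loc[bad[0], col]})"
            )
    needs_speed = trials["head_state"] == "translating"
    bad = trials.index[needs_speed & trials["head_speed_cm_s"].isna()]
    if len(bad):
        raise ValueError(
            f"{path} line {line_of(bad[0])}: translating trial lacks head_speed_cm_s"
        )
    trials["response_stereo_deeper"] = trials["response_stereo_deeper"].astype(bool)
    return trials[TRIAL_COLUMNS], provenance


def per_observer_pses(trials: pd.DataFrame, method: str = "ls") -> pd.DataFrame:
    """Fit one psychometric function per observer per condition function.

    Returns one row per (observer, function) with pse/sigma/convergence.
    """
    rows = []
    for (obs, *key), sub in trials.groupby(["observer_id"] + FUNCTION_KEYS):
        agg = aggregate_trials(sub)
        est = PsychometricCumulativeNormal(method=method)
        est.fit(agg["disparity_arcmin"], agg["proportion"],
                sample_weight=agg["n_trials"])
        rows.append((obs, *key, est.pse_, est.sigma_, est.converged_,
                     est.extrapolated_))
    return pd.DataFrame(
        rows,
        columns=["observer_id"] + FUNCTION_KEYS
        + ["pse_arcmin", "sigma_arcmin", "converged", "extrapolated"],
    )


def exclude_outlier_observers(
    pse_table: pd.DataFrame,
    z_threshold: float = 3.0,
    fraction_threshold: float = 0.5,
) -> tuple[list[str], dict]:
    """Flag observers whose PSEs deviate > ``z_threshold`` SD from group means.

    Group mean and SD for each psychometric function are computed leave-one-
    out (over the other observers): with the candidate included, a sample z
    can never exceed (n-1)/sqrt(n), which is below 3 for any realistic panel
    size, and the rule would be vacuous. An observer is excluded when the
    fraction of its functions exceeding the threshold (strict inequality) is
    greater than ``fraction_threshold``. Returns (kept observer ids, report).
    With fewer than 3 observers the rule is skipped with a warning.
    """
    observers = sorted(pse_table["observer_id"].unique())
    if len(observers) < 3:
        logger.warning("outlier rule skipped: only %d observers", len(observers))
        return observers, {"skipped": True, "excluded": []}

    t = pse_table.dropna(subset=["pse_arcmin"]).copy()
    flags = []
    for _, sub in t.groupby(FUNCTION_KEYS):
        pse = sub["pse_arcmin"].to_numpy()
        n = pse.size
        if n < 3:
            continue
        total, total_sq = pse.sum(), (pse**2).sum()
        loo_mean = (total - pse) / (n - 1)
        loo_var = (total_sq - pse**2 - (n - 1) * loo_mean**2) / (n - 2)
        loo_sd = np.sqrt(np.maximum(loo_var, 0))
        with np.errstate(invalid="ignore", divide="ignore"):
            z = (pse - loo_mean) / loo_sd
        flags.append(pd.DataFrame(
            {"observer_id": sub["observer_id"].to_numpy(),
             "flagged": np.abs(z) > z_threshold}))
    if not flags:
        return observers, {"skipped": True, "excluded": []}
    flagged = pd.concat(flags, ignore_index=True)

    frac = (flagged.groupby("observer_id")["flagged"].mean()
            .reindex(observers, fill_value=0.0))
    excluded = sorted(frac[frac > fraction_threshold].index)
    kept = [o for o in observers if o not in excluded]
    report = {
        "skipped": False,
        "excluded": excluded,
        "flagged_fraction": frac.to_dict(),
        "z_threshold": z_threshold,
        "fraction_threshold": fraction_threshold,
    }
    if excluded:
        logger.info("excluded observer(s) %s (>%.1f SD on majority of functions)",
                    excluded, z_threshold)
    return kept, report


def fit_depth_matches(
    trials: pd.DataFrame,
    i: float,
    method: str = "ls",
    group_average: bool = True,
) -> pd.DataFrame:
    """Fit psychometric functions and convert PSEs to depth matches.

    With ``group_average=True`` one function is fitted per condition function
    to the proportions pooled over observers; otherwise per-observer fits are
    made and their d_mp estimates averaged (with SE). Unconverged fits yield
    NaN depth and are flagged.
    """
    if group_average:
        agg = aggregate_trials(trials)
        rows = []
        for key, sub in agg.groupby(FUNCTION_KEYS):
            est = PsychometricCumulativeNormal(method=method)
            est.fit(sub["disparity_arcmin"], sub["proportion"],
                    sample_weight=sub["n_trials"])
            f = key[FUNCTION_KEYS.index("f_cm")]
            d_mp = (disparity_to_depth(DisparityStimulus(est.pse_, f, i))
                    if est.converged_ and est.pse_ > 0 else np.nan)
            thr = (disparity_to_depth(DisparityStimulus(est.sigma_, f, i))
                   if est.converged_ else np.nan)
            rows.append((*key, est.pse_, est.sigma_, est.converged_,
                         est.extrapolated_, d_mp, np.nan, thr))
        out = pd.DataFrame(
            rows,
            columns=FUNCTION_KEYS + ["pse_arcmin", "sigma_arcmin", "converged",
                                     "extrapolated", "d_mp_cm", "d_mp_se_cm",
                                     "depth_threshold_cm"],
        )
        return out

    per_obs = per_observer_pses(trials, method=method)
    per_obs = per_obs[per_obs["converged"] & (per_obs["pse_arcmin"] > 0)].copy()
    per_obs["d_mp_cm"] = [
        disparity_to_depth(DisparityStimulus(p, f, i))
        for p, f in zip(per_obs["pse_arcmin"], per_obs["f_cm"])
    ]
    g = per_obs.groupby(FUNCTION_KEYS)
    out = g.agg(
        pse_arcmin=("pse_arcmin", "mean"),
        sigma_arcmin=("sigma_arcmin", "mean"),
        d_mp_cm=("d_mp_cm", "mean"),
        d_mp_se_cm=("d_mp_cm", "sem"),
        n_observers=("observer_id", "nunique"),
    ).reset_index()
    out["converged"] = True
    return out


def pursuit_fraction_table(
    translating_matches: pd.DataFrame, model: TransducerModel
) -> pd.DataFrame:
    """Reduce head-translating depth matches to pursuit-equivalent eye speeds.

    For each function the head-stationary pursuit speed that would produce
    the same d_mp at the same motion/pursuit ratio is solved from the fitted
    model, d_mp = k f (ratio * da)^r / da^e  =>  da = (d_mp / (k f
    ratio^r))^(1/(r-e)), and expressed as a percentage of the total
    (pursuit + tVOR) eye speed of the stimulus.
    """
    t = translating_matches.dropna(subset=["d_mp_cm"]).copy()
    ratio = t["dtheta_deg_s"] / t["dalpha_deg_s"]
    base = t["d_mp_cm"] / (model.k * t["f_cm"] * ratio**model.r)
    t["dalpha_equivalent_deg_s"] = base ** (1.0 / (model.r - model.e))
    t["dalpha_total_deg_s"] = t["dalpha_deg_s"]
    t["pursuit_fraction_pct"] = (
        100.0 * t["dalpha_equivalent_deg_s"] / t["dalpha_total_deg_s"]
    )
    return t[FUNCTION_KEYS + ["d_mp_cm", "dalpha_equivalent_deg_s",
                              "dalpha_total_deg_s", "pursuit_fraction_pct"]]


def analyze_constancy(control_trials: pd.DataFrame, i: float,
                      method: str = "ls") -> pd.DataFrame:
    """Summarize depth-constancy control sessions as normalized depth matches.

    Per condition, a cumulative normal is fitted to the pooled proportion of
    "variable deeper" responses vs variable disparity; the PSE is converted
    to depth at the variable distance and divided by the fixed stimulus's
    depth. Perfect constancy gives a normalized match of 1.
    """
    rows = []
    for cid, sub in control_trials.groupby("condition_id"):
        agg = (sub.groupby("disparity_arcmin", as_index=False)
               .agg(n_trials=("response_variable_deeper", "size"),
                    n_deeper=("response_variable_deeper", "sum")))
        agg["proportion"] = agg["n_deeper"] / agg["n_trials"]
        est = PsychometricCumulativeNormal(method=method)
        est.fit(agg["disparity_arcmin"], agg["proportion"],
                sample_weight=agg["n_trials"])
        f_fix = sub["f_fixed_cm"].iloc[0]
        f_var = sub["f_variable_cm"].iloc[0]
        delta_fix = sub["delta_fixed_arcmin"].iloc[0]
        d_fix = disparity_to_depth(DisparityStimulus(delta_fix, f_fix, i))
        d_match = disparity_to_depth(DisparityStimulus(est.pse_, f_var, i))
        expected_pse = delta_fix * (f_fix / f_var) ** 2
        thr = disparity_to_depth(DisparityStimulus(est.sigma_, f_var, i))
        rows.append((cid, f_fix, delta_fix, f_var, est.pse_, expected_pse,
                     est.sigma_, d_fix, d_match, d_match / d_fix, thr,
                     est.converged_))
    return pd.DataFrame(
        rows,
        columns=["condition_id", "f_fixed_cm", "delta_fixed_arcmin",
                 "f_variable_cm", "pse_arcmin", "expected_pse_arcmin",
                 "sigma_arcmin", "depth_fixed_cm", "depth_match_cm",
                 "normalized_match", "depth_threshold_cm", "converged"],
    )


@dataclass
class PipelineReport:
    """Full-session analysis report. All depths cm, rates deg/s, PSEs arcmin;
    the transducer k is tagged with its angle unit."""

    seed: int
    config: SimulationConfig
    exclusions: dict
    depth_matches: pd.DataFrame
    plane_fit: PlaneFitResult
    model: TransducerModel
    adjusted_fit: PlaneFitResult
    adjusted_model: TransducerModel
    pursuit_fractions: pd.DataFrame
    constancy: pd.DataFrame
    foreshortening: pd.DataFrame = field(repr=False, default=None)

    def to_dict(self) -> dict:
        def fit_dict(fit: PlaneFitResult, model: TransducerModel) -> dict:
            return {
                "intercept_ln": fit.intercept,
                "coef_log_dtheta": fit.coef_log_dtheta,
                "coef_log_dalpha": fit.coef_log_dalpha,
                "r_squared": fit.r_squared,
                "n_points": fit.n_points,
                "n_excluded": fit.n_excluded,
                "model": {"r": model.r, "e": model.e, "k": model.k,
                          "angle_unit": model.angle_unit.value},
            }

        return {
            "seed": self.seed,
            "units": {"depth": "cm", "rates": "deg/s", "disparity": "arcmin",
                      "logs": "natural"},
            "exclusions": self.exclusions,
            "plane_fit": fit_dict(self.plane_fit, self.model),
            "adjusted_plane_fit": fit_dict(self.adjusted_fit, self.adjusted_model),
            "depth_matches": self.depth_matches.to_dict(orient="records"),
            "pursuit_fractions": self.pursuit_fractions.to_dict(orient="records"),
            "constancy": self.constancy.to_dict(orient="records"),
        }

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2, default=float))


def run_full_pipeline(
    config: SimulationConfig | None = None,
    seed: int = 0,
    method: str = "ls",
    group_average: bool = True,
    apply_exclusion: bool = True,
) -> PipelineReport:
    """Run simulate -> aggregate -> fit -> convert -> plane-fit -> report.

    Deterministic given (config, seed): sub-stage seeds are derived from
    ``seed`` with a SeedSequence.
    """
    config = config or SimulationConfig()
    s_stat, s_trans, s_ctrl = (
        int(s) % (2**31) for s in np.random.SeedSequence(seed).generate_state(3)
    )
    grid = build_stimulus_grid(config)
    stationary = simulate_trials(grid, config, seed=s_stat)
    translating = simulate_head_translation_session(grid, config, seed=s_trans)
    trials = pd.concat([stationary, translating], ignore_index=True)
    logger.info("simulated %d trials (%d stationary, %d translating)",
                len(trials), len(stationary), len(translating))

    if apply_exclusion and trials["observer_id"].nunique() >= 3:
        pses = per_observer_pses(trials, method=method)
        kept, exclusions = exclude_outlier_observers(pses)
        trials = trials[trials["observer_id"].isin(kept)]
    else:
        exclusions = {"skipped": True, "excluded": []}

    matches = fit_depth_matches(trials, i=config.i, method=method,
                                group_average=group_average)
    logger.info("fitted %d psychometric functions (%d converged)",
                len(matches), int(matches["converged"].sum()))

    stat_matches = matches[matches["head_state"] == "stationary"].dropna(
        subset=["d_mp_cm"])
    plane_fit, model = fit_empirical_mpr(stat_matches)
    adj_fit, adj_model = johnston_adjust_and_refit(stat_matches, config.johnston)
    logger.info("plane fit: r=%.3f e=%.3f k=%.4f r2=%.3f (n=%d)",
                model.r, model.e, model.k, plane_fit.r_squared,
                plane_fit.n_points)

    trans_matches = matches[matches["head_state"] == "translating"]
    fractions = pursuit_fraction_table(trans_matches, model)

    control = simulate_depth_constancy_control(config, seed=s_ctrl)
    constancy = analyze_constancy(control, i=config.i, method=method)
    logger.info("control normalized matches: %s",
                np.round(constancy["normalized_match"].to_numpy(), 3))

    from .transducer import predict_depth_surface

    fore = predict_depth_surface(
        model,
        stat_matches[["dtheta_deg_s", "dalpha_deg_s", "f_cm"]].drop_duplicates(),
    )

    return PipelineReport(
        seed=seed,
        config=config,
        exclusions=exclusions,
        depth_matches=matches,
        plane_fit=plane_fit,
        model=model,
        adjusted_fit=adj_fit,
        adjusted_model=adj_model,
        pursuit_fractions=fractions,
        constancy=constancy,
        foreshortening=fore,
    )
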