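# Methods

## Model and conventions

Depth from motion parallax is modelled through three relations:

1. **Motion/pursuit law (exact geometry).** For retinal image velocity dθ
   and compensatory pursuit velocity dα, relative depth is
   d/f = (dθ/dα)/(1 − dθ/dα). The first-order form d/f ≈ dθ/dα is used as
   the default geometric prediction; its relative error equals the ratio
   itself, below 1% over the stimulus range used here (ratios ≤ 0.25 give
   errors ≤ 25% of depth only at the top of the range; at the small depths
   involved both forms are reported by `predict_depth_surface`). Ratios ≥ 1
   are a domain error: the task measures peak-to-trough depth magnitude, so
   only unsigned magnitudes are modelled.
2. **Distance-square law.** A disparity δ (arcmin, converted to radians
   internally) at viewing distance f (cm) with inter-ocular distance i (cm)
   depicts depth d = f²δ/i. The default i = 6.5 cm is the standard adult
   value; it reproduces the printed control depths (23.3′ @ 36 cm → 1.35 cm,
   4.66′ @ 72 cm → 1.08 cm) and is overridable everywhere.
3. **Empirical motion/pursuit ratio.** Perceived depth follows
   d_mp = k·f·dθ^r/dα^e with power-law transducers on the two rate signals.
   With rates in deg/s the reference parameters are r = 0.416, e = 0.192,
   k = 0.0313. k is unit-dependent: converting rates by a factor c changes
   k by c^(e−r) (π/180 gives k ≈ 0.0775 with the rounded exponents), while
   r and e are invariant; `TransducerModel` therefore records its angle
   unit. Note d_mp increases with dθ at fixed dα, increases with dα along
   fixed-ratio lines (because r > e), and decreases with dα at fixed dθ.

Units are fixed package-wide: cm, deg/s, arcmin, natural logs.

## Psychometric estimation

Responses ("comparison stereo stimulus deeper") are pooled over blocks and
left/right directions per disparity level, and a two-parameter cumulative
normal Φ((δ − PSE)/σ) is fitted by unweighted nonlinear least squares on the
proportions (`scipy.optimize.curve_fit`, initial PSE from the interpolated
50% crossing, σ bounded positive). A binomial probit GLM on the counts is
available behind `method="probit"` as a robustness option. No lapse or guess
rates are modelled, matching the two-parameter summary being emulated. Flat
proportion profiles are flagged unconverged; a PSE outside the fitted level
range is flagged extrapolated. The PSE converts to a depth match d_mp via
the distance-square law; σ converts the same way to a depth-discrimination
threshold.

## Plane fit

The transducer fit is unweighted OLS of ln(d_mp/f) on [1, ln dθ, ln dα]
(statsmodels; an SE-weighted variant sits behind `weighted=True`). The
emulated analysis pooled condition-level mean depth matches without stated
weights, so unweighted is the default. Exported parameters are
r = coefficient on ln dθ, e = −coefficient on ln dα, k = exp(intercept).
Non-positive d_mp values carry no log-space information and are excluded
with a count; a design whose ln dθ and ln dα are collinear (single
motion/pursuit ratio) is rejected by a rank check.

The stereo-distortion ("Johnston-adjusted") refit multiplies each d_mp by
a − b·f (defaults a = 2.015, b = 0.011 cm⁻¹, a linear extrapolation of
reported stereo depth-constancy failures; unity near f = 92 cm with these
rounded coefficients) before refitting. Because f co-varies with dα across
conditions, this distance-dependent scaling moves the exponents, not just k.

## Synthetic observer

The generator's defaults are the study conditions, not tuning knobs:

- **Grid.** Four head-stationary conditions (two at 36 cm with overlapping
  pursuit-speed ranges sharing the 4.95 deg/s replication, one each at 54
  and 72 cm) and two head-translating conditions (36, 72 cm), each with 13
  (dθ, dα) stimuli × 9 disparity levels (1–9 pixels at 0.244 mm/pixel),
  i.e. 117 trial types per block; 20 blocks; 7 concordant observers. The
  exact 13 stimulus pairs per condition were never published; the defaults
  interpolate the published ranges (ratios 0.042–0.25, dα 1.1–11.57 deg/s,
  dθ 0.14–1.65 deg/s) and include every published anchor value.
- **Response model.** Internal parallax depth = d_mp(model)·ε₁ and internal
  stereo depth = (f²δ/i)·ε₂ (optionally Johnston-distorted), with ε
  unit-mean multiplicative lognormal, independent across the two intervals
  (2IFC independence; no inter-trial learning). Depth is positive and
  roughly Weber-like, hence the multiplicative noise. The default CV of
  0.15 places fitted σ in the 1–3 arcmin range characteristic of this task.
  The response is "stereo deeper" iff the stereo internal depth is larger;
  the induced psychometric function is therefore a probit in log disparity
  whose exact 50% point is δ = d_mp·i/f².
- **Head translation.** Per-trial head speed is drawn normal (means 11.0
  and 12.1 cm/s at 36 and 72 cm, SDs 0.9 and 1.2, truncated positive); the
  stimulus program holds the nominal motion/pursuit ratio regardless of the
  drawn speed. The total compensatory eye speed is (v/f)·(180/π), but only
  the pursuit fraction g (default 0.4; tVOR supplies the rest) drives
  depth: internal depth equals that of a head-stationary stimulus at the
  same ratio with dα = g·total. This choice — rather than pairing the raw
  retinal dθ with a scaled dα — is what makes the downstream
  pursuit-fraction analysis recover g: solving
  d_mp = k·f·(ratio·dα_eq)^r/dα_eq^e for the equivalent stationary eye
  speed gives dα_eq = g·total exactly, i.e. a recovered fraction of 100·g%.
- **Constancy control.** Fixed 23.3′ @ 36 cm vs variable 1.2–11.7′ @ 72 cm,
  and fixed 4.66′ @ 72 cm vs variable 9.3–28′ @ 36 cm; 9 levels × 10
  repeats × 2 blocks × 9 observers. Observer models: `perfect_constancy`
  (distance-square depths at the true distances), `disparity_matcher`
  (compares raw disparities — saturates within the study's variable ranges
  and would match only at the fixed disparity itself), and
  `distance_misestimate(p)` (variable distance misperceived by ±p,
  over-estimated when near, shifting the PSE by the squared factor).

Everything is driven by `numpy.random.Generator` seeds; identical
(config, seed) produce byte-identical trial CSVs.

### What the generator does not emulate

Ocular-motor dynamics (pursuit latency and gain curves, fixation error),
stimulus rendering (dot density, cross-talk), criterion drift, lapses, and
between-observer parameter heterogeneity. Passing recovery tests therefore
shows the analysis chain is unbiased under the assumed response model at
the study's scale — not that real observers satisfy that model.

## Numerical choices and caveats

- Psychometric fits are nearly unbiased where the generating function is a
  cumulative normal in linear disparity (PSE bias < 2%, σ bias < 10% at 20
  trials/level over 500 replicates). Under the lognormal response model the
  true function is log-symmetric, and fitting a linear cumulative normal
  leaves a small asymptotic PSE bias (≈ +1.1% at the control conditions'
  level placement); control normalized matches consequently scatter around
  ≈1.01 rather than 1.000, and tests of "near-perfect constancy" average
  over replicate sessions.
- The outlier-observer rule (">3 SD from the group means") uses
  leave-one-out group statistics: with the candidate included, a sample z
  cannot exceed (n−1)/√n ≈ 2.47 for n = 8, and the rule would never fire.
  An observer is excluded when more than half of its functions exceed 3 SD
  (strict inequality at the boundary); both thresholds are configurable.
- End-to-end recovery at the default scale (10 seeds) returns r and e
  within ±0.01 and k within a few percent — comfortably inside the ±0.05 /
  ±20% bounds asserted in the tests. Plane r² at noise CV 0.15 is ≈0.997;
  pushing r² down to the ≈0.875 regime of noisier empirical data requires
  CV ≈ 0.35 (recorded, not asserted, since the empirical noise level is
  unknown).
- The 52 condition-level depth matches behind the published plane fit were
  distributed only inside a proprietary interactive notebook; the package
  provides the plain-CSV import path for a user transcription, and the fit
  machinery is validated on synthetic tables instead.
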