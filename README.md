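# mpdepth

Tools for analysing perceived depth from **motion parallax** measured with a
two-interval forced-choice (2IFC) depth-matching task against binocular
disparity, including a synthetic observer that generates complete sessions
for validation.

## The problem

A laterally translating observer who keeps fixating a point at viewing
distance *f* rotates the eye at rate *dα* while a non-fixated point at depth
*d* slides across the retina at rate *dθ*. Geometry ties the two rates to
relative depth (the motion/pursuit law):

    d/f = (dθ/dα) · 1 / (1 − dθ/dα)   ≈   dθ/dα        (small ratios)

Perceived depth, however, is strongly foreshortened relative to this
geometry. When perceived parallax depth is measured by finding the binocular
disparity δ whose stereo depth (distance-square law, *d* = *f*²δ/*i* with
inter-ocular distance *i*) matches it, the matches follow a power law in the
two rate signals — the *empirical* motion/pursuit ratio:

    d_mp = k · f · dθ^r / dα^e

with transducer exponents *r* (retinal motion) and *e* (pursuit) and a
scaling constant *k* that depends on the angular unit. In natural-log space
this is a plane, `ln(d_mp/f) = ln k + r·ln dθ − e·ln dα`, so ordinary least
squares recovers (*r*, *e*, *k*) directly. The package implements:

- `geometry` — the exact and approximate depth laws, disparity↔depth
  conversion, unit rescaling of *k*, head-speed→eye-rotation conversion,
  pixel→arcmin conversion, stereo-distortion (depth-constancy) scaling;
- `psychometrics` — 2IFC aggregation and a scikit-learn-style
  `PsychometricCumulativeNormal` estimator for PSE/σ, plus conversion of
  PSEs to depth matches and of σ to depth-discrimination thresholds;
- `observer` — a seeded synthetic observer emulating head-stationary,
  head-translating (pursuit + tVOR) and depth-constancy control sessions;
- `transducer` — the `MotionPursuitPlaneFit` estimator (log-space OLS) and
  its stereo-distortion-adjusted refit;
- `pipeline` / `cli` — trial CSV I/O, the >3 SD outlier-observer rule, and
  the full simulate → fit → report orchestration (`mpdepth` console script).

## Worked example

```sh
$ mpdepth run-all --seed 2 --out report.json
recovered transducer: r=0.424 e=0.202 k=0.0324 (degree); plane r2=0.997; mean pursuit fraction 38.0%
```

The run simulates the default study (six conditions, 13 psychometric
functions × 9 disparity levels each, 20 blocks, 7 observers, internal-depth
noise CV 0.15, generating transducer r=0.416, e=0.192, k=0.0313 in deg/s
units), fits a cumulative normal to each function, converts PSEs to depth
matches and refits the log-space plane. The recovered exponents sit within
a few hundredths of the generating values and the plane is nearly exact
(r² = 0.997) at this noise level. The pursuit fraction — the head-stationary
eye speed equivalent to each head-translating condition, as a percentage of
the total compensatory eye speed — recovers the configured 40% pursuit gain.

The depth-constancy control compares a fixed-disparity stimulus at one
distance against a variable one at the other:

```sh
$ mpdepth control --seed 2 --out control.csv
C_fix36: PSE 5.86 arcmin, normalized match 1.006
C_fix72: PSE 18.90 arcmin, normalized match 1.014
```

A normalized match of 1 is perfect depth constancy: the fixed 23.3-arcmin
stimulus at 36 cm (1.35 cm of depth) is matched by ≈5.8 arcmin at 72 cm,
the quarter disparity that depicts the same depth after distance-square
scaling.

Library use mirrors scikit-learn:

```python
from mpdepth import MotionPursuitPlaneFit
est = MotionPursuitPlaneFit().fit(X, d_mp)   # X columns: dtheta, dalpha, f
est.r_, est.e_, est.k_, est.r_squared_
```

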