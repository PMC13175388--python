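# fpboundary

First-passage estimation of time-varying threshold (boundary) functions from
functional trajectories.

## The problem

In many biomedical and environmental settings an event is triggered the first
time a subject's trajectory X_i(t) reaches a critical level — a biomarker
exceeding a risk threshold, a country's incidence rate entering a
high-incidence regime.  When the critical level itself evolves smoothly over
time, the event time is a first-passage time over a *boundary function* Q(t):

    T_i = inf{ t : X_i(t) >= Q(t) }.

If trajectories are continuous and cross without overshoot, the observed
crossing pair (T_i, X_i(T_i)) sits on the boundary: X_i(T_i) = Q(T_i).  The
crossing pairs therefore anchor the boundary at the observed transition
points, and smoothing them recovers Q(t).  This package is for statisticians
and epidemiologists who want to reconstruct such boundaries from crossing
events rather than assume a fixed cutoff.

## The estimator

The boundary is represented in a clamped cubic B-spline basis,
Q(t) = Σ_k β_k φ_k(t), and fitted to the n crossing pairs by penalized least
squares:

    β̂_λ = argmin_β  Σ_i ( X_i(T_i) − Σ_k β_k φ_k(T_i) )² + λ βᵀSβ
         = (ΦᵀΦ + λS)⁻¹ Φᵀ𝐗,

where S is a roughness penalty (the exact curvature penalty ∫(Q″)², or a
second-order coefficient-difference penalty) and the smoothing parameter λ is
selected by generalized cross-validation,
GCV(λ) = n·RSS(λ) / (n − tr H_λ)², or by K-fold cross-validation.  A LOESS
smoother (local linear, tricube weights) estimates the same conditional mean
E[X(T) | T = t] as a descriptive alternative, and a classical hinge
(continuous piecewise-linear) threshold regression with grid-searched kink is
included as the fixed-threshold baseline.

The package also ships:

* a Monte Carlo harness with three scenario families (linear, logistic and
  parabolic trajectories against quadratic, linear and kinked boundaries)
  reporting average MSE, its SD and censoring proportions;
* a panel pipeline for country-by-year incidence data: a time-varying
  benchmark defined as the smoothed cross-sectional p-quantile, first-passage
  classification with left-censoring (units above the benchmark at the first
  observed year), reconstruction of the conditional crossing-level curve
  Q*(t) = E[X(T) | T = t], quantile-level sensitivity analysis, and bootstrap
  confidence bands from resampling countries with replacement;
* a synthetic incidence-panel generator for experimentation, emulating
  heterogeneous country levels with catch-up growth.

## Worked example

Reconstructing a declining boundary q(t) = −0.8t + 0.9 from the crossings of
200 noisy logistic trajectories (`examples/02_boundary_from_crossings.py`):

```
$ python examples/02_boundary_from_crossings.py
200 crossings observed (right-censored: 0)
GCV selected lambda = 0.0316228 (edf = 2.21, rss = 0.1463)
penalized spline MSE vs truth on the crossing range: 0.000979
LOESS (span 0.5) MSE vs truth on the crossing range: 0.001062
```

Every trajectory crosses (no censoring); GCV picks a strong penalty (the
boundary is a line, so ~2 effective degrees of freedom suffice) and both the
penalized spline and LOESS reconstruct the boundary to ≈0.001 mean squared
error — about (0.03)² pointwise — on the range where crossings occur.

The panel pipeline on a synthetic 40-country incidence panel
(`examples/04_incidence_panel_pipeline.py`):

```
$ python examples/04_incidence_panel_pipeline.py
panel: 40 countries x 19 years
crossed: 12, left-censored: 14, never crossed: 14
benchmark smoothing lambda = 0.501187, boundary lambda = 0.000125893
Q* on the crossing range:
  1998.0:  24.61
  ...
  2013.8:  34.14
95% bootstrap band mean width: 2.23 (1 of 200 replicates skipped)
```

Twelve countries enter the upper-incidence regime during the window and
anchor the Q* curve; the 14 countries already above the 0.65-quantile
benchmark in 1998 are left-censored and excluded from the regression.

The other examples cover crossing detection (`01`), the Monte Carlo study
(`03`) and the hinge baseline (`05`).  A thin CLI exposes the same
functionality (`fpboundary synth|simulate|estimate|apply --help`).

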