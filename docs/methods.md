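# Methods

This note documents the models, defaults and numerical choices behind
`fluogrowth`, and what the synthetic-data generator does and does not
emulate.

## Growth and reporter model

Each condition (a set of strains sharing a well) is integrated as a
Lotka–Volterra competitive logistic system. For strain *i* with maximum
specific growth rate `r_i` (h⁻¹), inoculum `x0_i` (OD-equivalent), shared
carrying capacity `K` (OD-equivalent) and competition matrix `alpha`
(`alpha_ii = 1`):

    dX_i/dt = r_i X_i (1 − load_i / K) − delta_i X_i · [exhausted_i]
    load_i  = Σ_j alpha_ij X_j

`delta_i` is a lysis rate applied only after strain *i* perceives resource
exhaustion. Exhaustion is a **latched** switch that trips when
`load_i ≥ 0.99 K`: a purely instantaneous indicator would chatter (lysis
pulls the load back below threshold, growth pushes it up again), whereas
consumed resources do not return; latching makes the switch crisp and the
post-exhaustion dynamics well defined. `K = 0` (no nutrients) is treated as
exhausted-from-start with zero growth.

Reporter expression uses the standard two-stage maturation picture: protein
is produced in a dark state `D` at rate `s_i` per unit biomass and matures
into the detected pool `F` at rate `m_i`:

    dD_i/dt = s_i X⁺_i − m_i D_i,      dF_i/dt = m_i D_i

`X⁺_i` is the production biomass: identical to `X_i` before exhaustion and
held at its exhaustion value afterwards. This deliberately decouples the
detected signal from lysis — fluorescent protein already made does not
disappear when cells lyse in the well — and reproduces the two qualitative
signatures the model exists for: fluorescence lags OD (maturation), and the
late-phase OD decline is not mirrored by the signal, which is non-decreasing
throughout. Holding `X⁺` constant (rather than letting it re-grow as lysis
frees "capacity") is a simplification; it slightly overstates late signal
production for large `delta`.

OD is modeled as proportional to biomass with no Beer–Lambert saturation;
the simulated densities stay ≤ 1.2, where plate readers are close to linear.

### Integration

Classical fixed-step RK4 with step `min(0.01 h, grid spacing)`; each grid
interval is subdivided evenly so grid points are hit exactly. At `r = 1 h⁻¹`
this reproduces the single-strain logistic closed form to ~1e-10 relative
(tested at 1e-6). Non-finite states raise an integration error. The
exhaustion latch is evaluated between RK4 steps, so the switch position is
resolved to one step (≤ 0.01 h).

## Measurement model

Per well and timepoint, with one seeded `numpy` generator driving every
draw in a fixed well-major, channel-minor order (so equal seeds give
bit-identical plates):

- OD read: `od_blank + (Σ_i X_i) · (1 + od_cv·ε)`
- fluorescence read: `autofluorescence_channel + F_strain · (1 + fluo_cv·ε)`
- blank wells: `baseline · (1 + cv·ε)`; empty wells read 0.
- CFU samples: `round(conversion · X_i · exp(σZ − σ²/2))` (mean-1 lognormal
  error), emulating dilution plating from flask cultures.

Defaults (versioned in `defaults.yaml`, not code): `r = 1.0 h⁻¹`,
`x0 = 0.005` (an OD 0.05 culture diluted 1:10 into the well), `K = 1.2` at
full medium strength, `s = 2300 A.U.·OD⁻¹·h⁻¹` and `m = 0.5 h⁻¹` (signal
near 3.5e4 A.U. by 20 h at full strength), `od_cv = 0.05`,
`fluo_cv = 0.01`, medium baselines `od_blank = 0.04` and autofluorescence
120–150 A.U. The OD coefficient of variation deliberately exceeds the
fluorescence one — replicate scatter of OD traces in plates is much larger
than that of reporter signals — and this asymmetry is what the calibration
stage's behaviour under noise probes.

What the generator does **not** emulate: evaporation and edge effects,
aggregation/flock optics, oxygen limitation, spectral crosstalk between
fluorescence channels, autofluorescent strains, or instrument drift.
Passing tests therefore demonstrate correctness of the analysis chain under
a clean, well-mixed, linear-response instrument model — not robustness to
those real-world artifacts.

## Analysis conventions

- **Blank correction** subtracts the arithmetic mean of the blank wells,
  by default per timepoint (background can drift), optionally as one grand
  mean. Negative corrected values are retained — clamping would bias AUC
  upward. Corrected channels are flagged and re-correction raises.
- **AUC** is the linear trapezoid over the observed window, first to last
  finite timepoint, no baseline anchoring; missing reads are dropped with
  their timepoints (the interpolant bridges the gap). Because fitness is a
  ratio of identically computed AUCs, any common baseline convention
  cancels. No parametric (logistic/Gompertz) curve fitting and no
  lag/growth-rate estimation is provided.
- **Calibration** fits are OLS (`scipy.stats.linregress`) or a Huber
  M-estimator via IRLS: tuning constant 1.345 on residuals standardized by
  the normal-consistent MAD (re-estimated each iteration), at most 50
  iterations, convergence 1e-8 on the coefficients, convergence failure is
  an error carrying the iteration count. A full MM-estimator
  (S-start/bisquare) is intentionally out of scope: on clean growth data
  robust and least-squares fits coincide, which the tests assert. Adjusted
  R² is `1 − (1−R²)(n−1)/(n−2)` (for Huber, R² is computed with the final
  weights); the slope p-value comes from its t statistic. Table-style CFU
  correlations are computed on log10 counts; non-positive counts are an
  error, not silently dropped.
- **Fitness** ratios divide each condition replicate's AUC by the
  *monoculture mean* AUC of the same strain and reporter channel; the
  monoculture group therefore self-normalizes to exactly 1. Fitness is only
  defined on fluorescence channels — OD cannot attribute growth to a strain
  in coculture. ANOVA uses the classical between/within decomposition;
  all-identical-constant input returns F = 0, p = 1 instead of NaN.
  Post-hoc tests are pooled-variance t tests of each condition against the
  monoculture (reference-vs-each, matching how competition assays are
  reported), Bonferroni-multiplied by the number of comparisons; an
  all-pairs mode widens the family and multiplier.
- **Imaging** uses exact (histogram-free) intermeans thresholding on raw
  gray values — for 8-bit images this differs from 256-bin IsoData by less
  than one gray level, without binning dialects; iteration stops when the
  threshold moves < 0.5 intensity units. Opening uses a 3×3 cross, one
  iteration; components are 8-connected; both are configurable. Cells are
  relabeled in raster-scan order for deterministic output. Background is
  the median fluorescence over the inverted mask; intensities are first
  scaled by `reference_exposure / exposure` (linear exposure response, no
  offset). Manual mask adjustment is not reproduced; an integer (dy, dx)
  mask offset is available instead.

## Problem sizes and determinism

The shipped experiment designs are the package's reference conditions: the
isogenic competition uses 10 monoculture + 10 coculture wells on a 48-h,
15-min grid; the dilution series uses 12 strengths × 4 wells on a 20-h,
15-min grid; image fixtures plant 10–20 cells on 400×400 px at 0.1 µm/px.
These sizes exercise every code path while keeping a full suite run under a
minute. All stochastic tests and scripts take explicit seeds; same-seed
runs are byte-identical end to end.

## Known limitations

- The isogenic-competition relative AUC settles near 0.515 rather than
  exactly 0.5: before resources bind, the focal strain grows identically in
  mono- and coculture, so the early part of the signal does not halve. This
  is a property of the assay definition, not an artifact.
- Under the default low fluorescence noise, which of the nine calibration
  cells is *best* is decided by sub-1e-3 curvature differences and is not a
  stable statistic; what is stable (and tested) is that AUC(OD) — the
  response metric that integrates out the noisier channel — anchors the
  best-correlated pair, and that all nine cells sit above r = 0.99.
- The Huber fit guards the zero-residual case (perfect fits fall back to
  OLS weights) but, like any M-estimator with MAD scale, is unreliable when
  more than half the points are outliers.
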