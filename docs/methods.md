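# Methods

## The five-step pathway model

The pathway is a chain of five activation/deactivation cycles driven by a
fold-input R, with the inactive precursor pools held at 1 (the active forms
are assumed to be a small fraction of large total pools). Every forward and
reverse rate carries a multiplicative factor `eps_i = exp(z·CV)` with `z`
standard normal — ten factors per cell, one per regulator. Two conventions
matter:

* **Lognormal noise uses σ(ln eps) = CV exactly**, not the
  `sqrt(ln(1+CV²))` that would make the real-space CV exact. For CV ≤ 0.4
  the two differ by under 4%, and the closed-form noise-propagation results
  (`CV_total = CV·√N`, the fIDL and aHC formulas) are exact in log-space
  under this convention.
* **Sign-grouped covariation** draws one factor for all five activating
  rates and one for all five deactivating rates. The output log-variance is
  then `(5·CV)² + (5·CV)² = 50·CV²` instead of `10·CV²`: maximal
  covariation multiplies the effective noise by √5.

Because every step is linear, the steady state has the closed form
`A* = R·Πeps_odd/Πeps_even`, which serves as both the fast path for
population simulation (5,000 cells is the default population, configurable)
and the oracle against which the integrator is checked. The trajectory
integrator is adaptive Runge–Kutta 4/5 (rtol 1e-8, atol 1e-10) on a default
horizon of t = 15. Equilibrium is never assumed: the slowest relaxation
rate equals the smallest deactivating multiplier, so for strongly perturbed
draws t = 15 leaves relative residuals up to ~1e-3. `simulate_trajectory`
therefore accepts `ensure_converged=True`, which extends the integration in
horizon-sized chunks until the output is within a stated tolerance of the
closed form. Trajectories start from the basal (R = 1) steady state of the
cell's own rate draw, so a run shows the response to a step in stimulus;
the initial condition is an explicit argument for anyone wanting zero
starts.

## Detection limit and mutual information

The fIDL detection criterion matches the 95th percentile of the basal
log-output distribution to the 5th percentile of the stimulated one
(empirical quantiles, linear interpolation). Both distributions have the
same shape for the linear model — stimulation only shifts the log-output —
so the simulated fIDL reduces to a quantile ratio of a single basal sample;
for non-scale-equivariant models (the saturating variant) the limit is
found by bisection on ln R to 1e-4. The analytic form
`exp(2·Φ⁻¹(acc)·CV·√N)` follows from the matched-quantile criterion with
Gaussian log-outputs; the factor 2 reflects equal noise in the basal and
stimulated distributions.

Mutual information is the naive plug-in estimate from a 2-D histogram of
(log2 R, log2 A*) with 0.05-unit bins, empty bins contributing zero, and no
bias correction. The bias is material — of order 1 bit for 10⁴ samples at
the default binning — which is one reason the detection limit, not MI, is
the headline analog metric: a saturating output transform
(`10·y/(y+9)` applied to the y4 drive) changes MI by several tenths of a
bit while moving the quantile-matched fIDL by only a few percent. The input
distribution for MI experiments is log2-uniform over a configurable range
(no canonical range exists; 2⁰–2⁶ is the default in the experiment
runner).

## Binary activation and Hill fitting

A cell activates when its steady-state output exceeds a threshold (default
10; the fitted steepness is insensitive to the choice provided the
threshold is well above basal relative to the total noise — the test suite
checks 5/10/20 agree within 15%). Dose–response curves use a 30-point
log-spaced grid over R ∈ [1, 100], bracketing the default threshold
symmetrically in log space. With 5,000 cells per dose the Monte-Carlo
standard error of a fraction is at most 0.7 percentage points.

Hill fits minimize squared error of `f(R) = R^h/(k^h + R^h)` by
Levenberg–Marquardt-style nonlinear least squares with k initialized at the
grid point nearest half-activation and h at 2, h bounded in (0, 100].
Saturated points (fraction 0 or 1) are retained — they carry steepness
information. If the least-squares routine fails on step-like data, h is
recovered by a profile grid search, and fits that hit the steepness bound
are flagged `step_like`.

Because the fraction-activated curve of the linear model is a probit in
ln R (a lognormal threshold crossing), not a Hill function, the fitted h on
the default grid runs ~7% above the midpoint-slope equivalent
`4·φ(0)/CV_total`: at 10% CV the fit gives h ≈ 5.4 where the calibrated
analytic form `β/(CV·√N)` with β = 1.4 gives 4.4. Both are reported; the
analytic β is kept at its conventional 1.4 for the closed-form trade-off
expressions, and the regression of *fitted* coefficients on `1/(CV·√N)`
over CV ∈ [0.1, 0.4] yields a slope near 1.7. The co-dependency product
`log2(fIDL)·aHC = α·β/ln 2 ≈ 6.64` with α = 2·Φ⁻¹(0.95) and β = 1.4 is
verified constant across CV and N to machine precision.

For partial covariation the effective total CV is the standard
error-propagation form with `n_cov` perfectly correlated components:
`CV·√(N − N_cov + N_cov²)` — a reconstruction (the shared terms add
linearly, the rest in quadrature), reducing correctly to `CV·√N` at
N_cov ∈ {0, 1} and `CV·N` at N_cov = N.

## The MAPK/ERK cascade

The cascade couples RasGTP (input) → Raf → MEK → ERK with two-site
distributive phosphorylation of MEK and ERK, four phosphatases (one per
cycle group), and negative feedback from doubly phosphorylated ERK (ppERK)
onto Raf activation. The packaged rate set
(`src/sigvar/data/mapk_rates.yaml`) is authored for this package (the
architecture follows the classical negative-feedback ERK cascade models;
no published constant set is reproduced) and is tuned for a specific
qualitative regime:

* upstream tiers respond gradedly (rate laws far from saturation), so the
  cell-to-cell MEK and ERK totals shift the activation point;
* the ERK-tier phosphatases operate near saturation, giving a sharp
  switch between an OFF state near zero ppERK and an ON plateau, so that
  with 15% CV on MEK/ERK totals and 10% on the input the terminal-ppERK
  histogram at intermediate doses is genuinely bimodal;
* the feedback is first-order with a large inhibition constant. Strong
  feedback combined with deep zero-order ultrasensitivity turns this
  architecture into a relaxation oscillator (terminal readouts then
  depend on the phase at the end of the run); the weak-feedback regime
  keeps terminal ppERK monotone in dose while leaving the feedback loop
  intact.

Cells are classified by terminal-time ppERK against a threshold of 17
(model units; the ON plateau is ~70–95 and OFF ~0), not by peak ppERK.
Doses are specified in log2 units with a default 24-point grid over
2⁹–2¹³, bracketing the activation window. Every downstream claim about
this module is ordinal — monotone dose–response, bimodality at an
intermediate dose, covariation giving a shallower fitted Hill curve than
independent noise at matched CVs, active cells having higher median MEK
and ERK — so the conclusions survive substitution of the parameter set.
`fold_error_at_fraction` interpolates the curve piecewise-linearly in
(log2 dose, log10 fraction) and reports
`fraction(R*·1.1)/fraction(R*)` at a target fraction (default 1%),
approaching `1.1^h` for Hill-like tails.

## Measurement statistics

* **Correction factors.** Each reference peptide is median-normalized
  across samples; a sample's factor is the median of its normalized
  reference values, and all its abundances are divided by it. A single
  pass leaves residual factors of a few percent (dividing shifts the
  column medians), so the pass is iterated to its fixed point, making the
  correction exactly idempotent; the reported factor is the per-sample
  product over iterations and differs from the single-pass value only in
  the third decimal. Only the designated reference set (default: the 22
  non-cycling of 26 proteins) drives the factor; cyclin-like proteins are
  excluded.
* **CVs** use the n−1 standard deviation (small batches of 5–10 make the
  denominator material, and unbiasedness of the variance is conventional).
  Bootstrap CIs are percentile intervals (2.5–97.5) from 2,000 resamples
  with replacement.
* **Covariation** is pairwise Pearson correlation with two-sided
  t-distribution p-values (df = n−2), Benjamini–Hochberg step-up over the
  unique unordered pairs, significance at adjusted p < 0.05.
  Zero-variance columns are reported undefined and excluded from the
  multiplicity count. Correlations are computed on corrected abundances
  by default (run them on the raw table to opt out). The Fig-style
  extremes comparison uses a two-sided Wilcoxon rank-sum test — the
  choice of test is this package's, labeled as such — and notch
  half-widths `1.58·IQR/√n`.
* **Gating and normalization.** The 2N (G0/G1) mode is the lowest
  substantial peak of a Gaussian KDE of integrated DNA stain; the gate is
  mode·[1−w, 1+w] with w = 0.25 by default (explicit and configurable,
  since by-eye histogram gating is not reproducible). Cells beyond a
  350-pixel radius from the field center are dropped. Concentration is
  antibody intensity over the total-protein mass stain, which removes a
  common cell-volume factor exactly.
* **FRET activity** is the trapezoidal area under the ratio curve from
  stimulus time to trace end, with no baseline subtraction by default
  (subtracting the pre-stimulus baseline is an easy extension); the
  active/inactive threshold sits at the density minimum between the two
  largest modes of a Silverman-bandwidth KDE of the scores and fails
  loudly on unimodal data.

## Synthetic data

The egg generator produces
`value = mean·profile(t)·exp(b)·calib·exp(tech)` with `b` drawn from a
planted correlated normal (per-protein log-sd = biological CV, defaults
5–15% with planted MEK–ERK and MCM5–MCM7 correlations of 0.7), a
per-sample lognormal calibration factor (default 5%) and independent
technical noise. Default designs mirror the pipeline's target studies:
5 eggs × 5 timepoints; 2 timepoints × 6 batches × 10 eggs; and a
technical-replicate mode that zeroes biological variance (a mixed lysate
split into 30 aliquots), which is the only design under which calibration
and technical noise are separable. Cyclin-like proteins follow a fixed
piecewise mid-cycle-peak/late-degradation profile (qualitative shape
only). The cell generator composes intensity = mass × concentration ×
noise, a 2N/4N DNA mixture, uniform positions for the radius filter, and
an activation probability logistic in ln(MEK·ERK), with saturating-rise
FRET traces per class sampled every 2 minutes.

What the generators deliberately omit: absolute abundances of any real
protein panel, missing values and detection limits, heavy-tailed or
multiplicative-drift batch effects, cell-cycle–expression coupling beyond
the fixed cyclin profile, and image-level artifacts (segmentation errors,
uneven illumination beyond the radius cut). Passing recovery tests
therefore demonstrates the statistical pipeline is correct and calibrated
on its stated noise model, not that real measurements obey that model.

## Problem sizes and numerical conventions

Population simulations default to 5,000 cells per dose (closed-form
steady states, so cost is negligible); Monte-Carlo detection limits use
10⁵–10⁶ cells; MAPK population analyses use 120–500 ODE cells per
condition, sizes at which every ordinal comparison in the test suite is
stable across seeds. Correlated draws use Cholesky factorization with an
eigenvalue fallback for PSD-but-singular matrices (PSD checked with 1e-10
tolerance). Quantiles follow numpy's default (type-7) convention. The
0·log 0 = 0 convention applies throughout the MI estimator.

## Known limitations

The analytic fIDL/aHC formulas assume Gaussian log-outputs, exact for the
linear pathway only; the MAPK parameter set is one point in a large
qualitative regime and supports ordinal claims only; the plug-in MI
estimator is biased upward and is included for comparison, not inference;
the correction factor assumes reference peptides are not co-regulated in a
common direction; and the bimodal threshold finder requires genuinely
bimodal scores — unimodal intermediates (partial activation) are out of
scope by design.
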