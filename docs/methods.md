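# Methods

## Model

For every ordered pair of spin systems (response y, predictor x) the package
fits, by ordinary least squares over the pairwise-complete samples,

    δ_y = a·δ_x + b,    a = Σ(x−x̄)(y−ȳ) / Σ(x−x̄)²,   b = ȳ − a·x̄,

and records R² (squared Pearson correlation, clamped to [0, 1]), RMSE
(√(SSres/n); the denominator is configurable via `rmse_ddof`, default 0),
rRMSE = 100·RMSE/ȳ in percent, the training max-|residual| envelope, and the
slope standard error (classical, with n−2 residual degrees of freedom). rRMSE
is computed on raw (uncentered) shifts, so an RMSE of 1e-4 ppm on a ~1 ppm
signal reads as ~0.01 %. Column mean-centering exists as a presentation
utility only and is never applied before fitting.

Models with fewer than `min_n = 50` paired samples are recorded but flagged
*unstable* and excluded from predictor selection and map building. The
default reflects that pairs of scarce metabolites (ethanol with
3-hydroxybutyrate) co-occur in only a few dozen spectra, too few for the
slope to be trusted.

## Prediction maps

A prediction map is a directed spanning tree over the panel, rooted at an
anchor system; each non-root node carries the fitted model from its parent.
Two constructions exist:

* the fixed published 16-system serum/plasma map: valine –CH₃ anchors the
  amino acids (alanine, leucine, isoleucine, tyrosine, glycine directly;
  phenylalanine via tyrosine; histidine via glycine); leucine bridges to
  lactate, which anchors the carboxylic acids and the glucose anomeric
  proton; leucine also predicts ethanol, which predicts acetone, with
  pyruvate→acetone as a per-sample alternate when ethanol is undetected;
* a minimum-total-weight spanning arborescence (weight = |rRMSE| or RMSE)
  over the stable models, computed by the classic Chu-Liu/Edmonds
  cycle-contraction algorithm. The implementation is in-package because the
  construction must be bit-reproducible: ties in (possibly
  contraction-adjusted) weight break by higher R², then by lexicographic
  (predictor, response). With `class_guided=True` a response may only be
  predicted from its own chemical-class group (amino acids; carboxylic
  acids + sugars; alcohols + ketones) or from designated bridge systems,
  reproducing the sub-map-then-join strategy.

Binding a map to a fitted model matrix attaches coefficients and computes
two chained error estimates per node along its root path: a quadrature
estimate √(Σ (gain·RMSE)²) assuming independent edge errors, and a
conservative envelope Σ gain·max|resid|, where gain is the product of
downstream slopes (all ≈ 1 here). The envelope is what prediction results
expose as `est_error`.

## Prediction modes

*Semi-automated*: each response is predicted from its predictor's observed
shift in that sample; if the primary predictor is missing and an alternate
edge exists, the alternate is used (logged); otherwise the value is marked
unavailable. *Automated*: only the anchor's observed shift enters; the map
is traversed in topological order and each node uses its parent's
*predicted* value — algebraically a composition of affine maps, which the
tests verify to 1e-12 ppm. Chaining operates on unrounded values; reported
shifts are rounded to the recording precision (4 decimals). Predictions are
never clamped to the training range; extrapolation is the user's
responsibility (the underlying δ–pH relations are only locally linear).

Validation compares rounded predictions with observed shifts per system and
reports max-|error| and RMSE in ppm and in linewidth units. The linewidth
constant defaults to Δv½ = 0.001 ppm, the usual serum/plasma peak width at
600 MHz (so the common ~0.05 ppm drift range is ~50 linewidths); it is
configurable for other field strengths.

## Synthetic data generator

The generator encodes the method's own generative assumption: shifts co-vary
through shared latent matrix effects. Per sample j, factor values f_j are
drawn (standard normal, unit variance), and

    δ_ij = μ_i + Σ_f L_if·f_jf + ε_ij,   ε_ij ~ N(0, σ_i²),

followed by per-system Bernoulli detection (missing completely at random)
and rounding to 4 decimals, so quantization error (sd ≈ 2.9e-5 ppm) is part
of the simulated measurement. The serum-like panel loads every system on one
dominant global factor (scale 0.008 ppm × a per-system sensitivity in
[0.9, 1.1]) plus a weak class factor (2.5e-4 ppm; amino acids, carboxylic
acids + glucose, ethanol + acetone), with measurement noise σ = 6e-5 ppm.
These values give column ranges ≈ 0.05 ppm, within-class R² ≈ 0.9999 with
single-edge RMSE ≈ 1e-4 ppm, and cross-class R² ≈ 0.998 — cross-class bridge
models are nearly as good as within-class ones, as real serum data show,
while within-class predictors remain strictly best. Histidine additionally
loads on a small factor shared with glycine (2e-4 ppm) and on an
idiosyncratic factor (1.408e-3 ppm), putting its best model near R² ≈ 0.97;
that idiosyncratic factor is drawn from a unit-variance *uniform* law rather
than a normal one, because the pH-like effect it represents is range-bounded
— with Gaussian tails the simulated histidine worst case would exceed the
~3-linewidth envelope real data show. Ethanol's detection probability is
157/940; 3-hydroxybutyrate's is 0.25, chosen so the ethanol↔3HB overlap
(~39 samples) falls below `min_n` and those models are flagged unstable.

What the generator does *not* emulate: the irregular/multimodal marginal
shift distributions of real cohorts (only second moments matter for linear
models), assignment errors, peak-overlap biases, cohort-level batch
structure, and any nonlinearity of δ–pH response outside the ~0.05 ppm
range. Passing tests therefore demonstrate correctness of the machinery and
plausibility of the error budget, not real-data performance; the real-data
figures require the public serum cohort and are covered by an optional
integration test that runs only when a locally assembled shift table is
present under `data/external/`.

### Parameter recovery

`recovery_report` compares fitted slopes with the generative truth. Because
the predictor is observed with noise and quantization, OLS consistently
estimates the *population* slope cov(y,x)/var(x) — the latent sensitivity
ratio s_y/s_x attenuated by var-ratio ≈ 1 − (σ_x² + q²)/s_x², with q² the
rounding-error variance (10^-2p/12). The report lists both quantities
(the ratio only where loading vectors are proportional, i.e. genuinely
same-factor pairs) and a z-score (fitted − population)/SE. Z-scores of pairs
sharing a system are strongly correlated — near-collinear predictors make
the pairs almost interchangeable — so the fraction of |z| ≤ 2 over a panel
is a much noisier statistic than its ~620-pair count suggests (effective
sample ≈ tens, sd ≈ 1.5 points around the nominal 95.45 %).

## Numerical choices and degenerate inputs

* Ingest rounding is half-even: exact decimal semantics for text input (via
  the `decimal` module), binary-correct formatting for float input; values
  are canonicalized so write→read round-trips are bit-identical.
* A constant predictor raises a degenerate-predictor error; a constant
  response yields a model flagged unusable (R² undefined). Tables keep at
  least one present value per retained column; all-missing columns are
  dropped with a warning on read.
* Peak positions are taken at the sampled maximum (no interpolation): at
  >65k points over ~20 ppm the grid spacing (~3e-4 ppm) is already below the
  reported precision. Peak prominence thresholds are relative to the window
  maximum so crowded and sparse regions behave comparably.
* Multiplet positions are the arithmetic mean of the supplied component
  ppms; resolving partially overlapped multiplets (J-coupling arithmetic,
  J-resolved projections) is up to the caller — only visible components
  should be passed.
* Calibration is a rigid axis shift; shifts > 0.5 ppm warn (probable wrong
  reference) but are applied.
* JCAMP-DX support covers the plain-numeric (AFFN/fixed) XYDATA form only;
  compressed encodings are rejected with a clear error. Vendor raw
  directories are out of scope — convert to ppm/intensity text first.

## Problem sizes

Simulated cohorts default to 940 training and 1,052 validation samples — the
sizes of the serum and plasma-EDTA cohorts the method was developed on — and
16 spin systems; a full fit (240 OLS models) takes well under a second, and
the complete acceptance run a few seconds.

## Known limitations

* The maps apply only to spectra acquired and prepared under one consistent
  protocol; coefficients are matrix- and SOP-specific.
* Histidine is predicted 2–6× worse than the rest of the panel (its shift
  has a strong idiosyncratic pH component); on simulated data its max error
  is ~3 linewidths vs ≤1.5 for all other systems.
* Missing predictors degrade semi-automated coverage; only acetone has an
  alternate edge in the published map.
* No assignment scoring: the tool predicts positions, it does not decide
  which observed peak is which metabolite.
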