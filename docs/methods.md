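# Methods

## Problem setting

A THz-TDS transmission measurement of a pellet pressed from analyte powder and
HDPE binder yields an absorbance spectrum a(ω) = log10|R(ω)| − log10|S(ω)|,
with S and R the Fourier magnitudes of the sample and blank-reference field
traces. The regression target is the dimensionless mass-ratio vector
y ∈ Δ² (three analytes summing to one; the binder is excluded from the
ratio). The package evaluates combinations of normalization, dimensionality
reduction and prediction models for this calibration task.

## Frequency-grid convention

The acquisition band "0.3–3.0 THz at 5 GHz resolution" and a 540-feature
input vector are reconciled by the half-open convention (0.3, 3.0]: points
0.305, 0.310, …, 3.000 THz. Both bounds and the resolution are configurable;
every container validates uniform spacing.

Time-domain ingestion applies a centered, edge-truncated moving average
(default window 2000 samples on a 4001-sample trace — kept as the documented
default although unusually wide; the instrument convention is not
recoverable) before a DTFT evaluated exactly at the grid frequencies.
Reference compensation is log-domain subtraction, the standard absorbance
definition; amplitude-domain subtraction is not offered.

## Synthetic-data generator

The generator emulates the measurement design, not the chemistry:

* **Design**: each ternary-diagram edge carries 10 points at t = k/10,
  k = 0…9 — half-open, so cycling the three edges visits each vertex exactly
  once (30 unitary/binary samples → 180 replicate spectra always in
  training). Each median (vertex → opposite-edge midpoint) carries 10
  strictly interior points at t = k/11, k = 1…10, which by construction
  avoids the centroid (t = 2/3) and the edge points; 20 further compositions
  are drawn uniformly from the open simplex interior. 80 samples × 6
  replicates = 480 spectra. Degenerate user spacings that collide (e.g.
  2-point medians, which all hit the centroid) raise an error listing the
  collisions rather than silently deduplicating.
* **Pure spectra**: 5 Lorentzian peaks per compound plus a broadband slope.
  Centers sit in the literature-reported feature ranges for caffeine, quinic
  acid and nicotinic acid, with the most discriminating peaks in 2.0–3.0 THz;
  the numbers are documented generator constants, not spectroscopic claims.
* **Mixing**: Beer–Lambert linear combination Σ y_c s_c(ω) plus an optional
  pairwise departure β Σ_{c<c'} y_c y_c' g_{cc'}(ω) with
  g_{cc'} = (s_c + s_c')/2. The cross term deliberately lives in the span of
  the pure spectra (oscillator-strength redistribution): a cross term outside
  that span would leave y exactly linearly recoverable from the spectrum and
  no linearity probe could detect the nonlinearity. With g in the span the
  spectrum→composition inverse is genuinely quadratic. β defaults to 0 (the
  linear world); the linearity study uses β = 0.5, at which the distortion
  z_c = y_c + (β/2)·y_c(1−y_c) peaks at ~0.06 absolute — a clear but not
  overwhelming departure.
* **Nuisances**: per-replicate scattering baseline ξ_r·Q_ext(ω) with ξ_r ~
  U(0.05, 0.15); multiplicative thickness jitter of 5% relative s.d.
  (pellets of 0.850–0.950 mm vary by about that much); sharp positive
  artifacts at 20 documented atmospheric water lines (amplitude 0.02 a.u. —
  residual absorption under imperfect nitrogen purging); i.i.d. Gaussian
  noise of 0.01 a.u. per point, roughly 2–3% of a typical peak. Negative
  assembled absorbance is clipped at zero with a warning; replicate draws are
  consumed in a fixed order so one seed reproduces the dataset bit-exactly.

What a green test on this generator does **not** establish: recovery of the
instrument study's numeric RMSEP values (those require the measured spectra),
realistic inter-batch particle-size variation (the baseline shape Q_ext is
fixed here — see Limitations), or spectroscopic fidelity of the component
libraries.

## Mie baseline removal

Q_ext is computed from the Mie series for a homogeneous sphere
(Bohren–Huffman logarithmic-derivative downward recursion, truncation
N = ceil(x + 4x^(1/3) + 2), size parameter x = 2πrf·n_med/c). Defaults
r = 30 μm and n = 1.54 describe a typical HDPE powder scale; both are
explicitly overridable because they are assumptions, not measurements.

The removal objective — pin the baseline to the spectral troughs without
exceeding them on the valid set Ω — is solved two ways, which must agree:

* a linear program in (ξ, slack) with penalty weight M = 1e9 (HiGHS), the
  fidelity route;
* the closed form ξ* = max(0, min_{Ω, Q>0} a/Q_ext), its exact large-M limit,
  used as the oracle and as the fast path inside the evaluation loop.

ξ is constrained nonnegative (a negative scattering baseline is unphysical);
a spectrum dipping below zero on Ω yields ξ = 0 with a warning. Ω excludes
frequencies ≤ 0.55 THz and closed ±25 GHz bands around each water line; band
edges landing exactly on grid points are excluded. In single-factor mode the
shared ξ is the minimum of the per-spectrum fits over the *training* block
and is applied to held-out spectra as well; multifactor fits each spectrum
individually; the concatenation variant additionally returns the per-spectrum
ξ for appending as a feature after dimensionality reduction.

## Evaluation design

Ternary samples are shuffled by seed and dealt round-robin into k = 5 folds
with all 6 replicates of a sample kept together — fold test sets of exactly
60 spectra. Splitting replicates would leak near-duplicate spectra between
training and test. Unitary and binary samples (order ≤ 2) are pinned to every
training set: they are the extrema bounding the interpolation. Every stage
(normalization, baseline fit, reducer, model) is fitted per fold on the
training block only; normalization statistics are per-feature (per-spectrum
normalization would erase the concentration scale that is the target).

The headline metric is pooled RMSE over all held-out residuals and all three
analytes jointly (per-fold and per-analyte values are also reported); pooling
rather than averaging fold RMSEs keeps the identity
RMSEP² · N = Σ_folds RMSEP_f² · n_f exact.

The preprocessing-effect report subtracts, for each configuration using a
technique, the RMSEP of the configuration identical except for that stage
bypassed; only exact matched pairs enter a cell, and cells without pairs are
absent, never imputed. The linearity probe runs tanh- and identity-activation
single-hidden-layer MLPs (no preprocessing) on identical folds and seeds;
sklearn's regressor fixes the output layer to identity, so the toggle acts on
the hidden layer only — the identity model remains exactly affine, preserving
the linear/nonlinear contrast.

## Numerical choices

* MLP fits use lbfgs with 3 seeded restarts, keeping the lowest training
  loss: small tanh networks on 540 raw features occasionally land in
  saturated local optima, and a diverged fit would measure the optimizer, not
  the data.
* SVR and gradient boosting are natively single-output and train one
  regressor per analyte (recorded on the TrainedModel); PLSR and MLP predict
  all three jointly. "Prescale" PLSR standardizes X internally.
* The CNN is a NumPy 1-D conv net — entry convolution, one residual block
  (two convolutions + skip), sigmoid activations, global average pooling,
  full-batch Adam — because no deep-learning framework is assumed. Its
  topology is an interpretation and it is excluded from acceptance gating.
* Gradient boosting maps the reported tree parameters onto
  sklearn's GradientBoostingRegressor (colsample→max_features,
  min-child-weight→min_samples_leaf); the 10,000-round setting is scaled to
  300 rounds by default for desk-scale runs and is available via the
  hyperparameter table.
* Reducer seeds and the pipeline seed are recorded in the fitted state; one
  root seed makes an entire EvalResult reproducible bit-for-bit.
* Out-of-sample transforms for LLE/modified-LLE (neighbor-weight
  reconstruction) and isomap (kernel embedding) use scikit-learn's
  extensions, since held-out folds must be projected with training-fitted
  states.

## Known limitations

* The simulated baseline has a fixed spectral shape (one Q_ext for all
  spectra, scaled by ξ_r). A rank-1 additive nuisance uncorrelated with the
  target is exactly annihilable by a linear model in 540 dimensions, so
  baseline removal improves linear calibrations here only modestly (~15–20%
  under measurement noise) — real pellets, with particle-size variation
  changing the baseline *shape*, benefit far more. Simulating a size
  distribution per replicate would close this gap but is out of scope.
* Water-line artifacts use a documented default line list; the instrument's
  effective line set depends on purge quality and is configurable.
* The component libraries are caricatures adequate for pipeline validation,
  not spectroscopy.
* The full combinatorial search of the original study (millions of
  combinations) is supported in structure (declarative grids) but default
  grids are small.
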