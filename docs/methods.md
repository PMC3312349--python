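# Methods

## Estimation model

The object under study is a nonnegative biomass surface b(i,j) on a
grid, analysed as a probability measure μ = b / Σb. The estimator is
the moment (box-counting) method: for dyadic box sides ε the partition
function X_q(ε) = Σ (box mass)^q is computed by exact tiling, and the
mass exponents K(q) are ordinary least-squares slopes of log X_q on
log ε. Dimensions follow as D(q) = K(q)/(q−1); the q = 1 case uses the
entropy sums Y(ε) = Σ mass·log(mass), whose slope on log ε is D(1)
directly. Natural logarithms are used throughout the regressions —
slopes of log–log fits are base-invariant, and the entropy route to
D(1) is likewise a ratio of natural-log quantities.

Per-q goodness of fit (R²) and the slope standard error are recorded.
The box sizes at successive ε are nested, so the residuals are not
independent; R² is reported as a descriptive index of scaling quality,
not as the basis of a test.

### Defaults and their rationale

- **q grid**: −5 … 5 in steps of 0.5. The range covers dense-region
  (q > 0) and sparse-region (q < 0) behavior symmetrically; 0.5 steps
  give smooth spectra at trivial cost.
- **box sizes**: dyadic, ε = 2, 4, …, side/2. ε = 1 is dominated by
  pixel-level noise; ε = side yields a single box with no information.
  Dyadic tiling is exact (no partial boxes), which is also why
  non-dyadic inputs are center-cropped to the largest power-of-2
  square first.
- **zero-mass boxes** are excluded from the sums. For q > 0 this
  changes nothing; for q ≤ 0 it keeps X_q finite on fields with empty
  regions. On gradient-transformed or cascade inputs all boxes carry
  mass, so the rule only guards pathological inputs.
- **constant response** (e.g. X_1 ≡ 1 at q = 1): the scaling fit is a
  perfect zero-slope line and R² is reported as 1 rather than left 0/0.

## Stationarity and the gradient transform

Box-counting moment scaling assumes broad-sense stationarity. The
pipeline assesses it from the radially averaged 2-D periodogram: the
mean is removed, power is averaged over log-spaced radial bins
(geometric ratio 2^¼), and the exponent β is the negative slope of
log power on log wavenumber, fitted from the second-lowest bin (the
lowest leaks DC/trend power) up to half the Nyquist frequency (the top
octave is alias-dominated). Surfaces with β > 1 are nonstationary and
are replaced by the magnitude of their local first differences before
normalization — the standard absolute-gradient transform. Forward
differences are used, with backward differences on the last row/column
so dyadic dimensions are preserved; whether forward, central or
absolute-increment differences are used changes estimates negligibly
on the fields this package targets, and the forward/backward scheme is
the one that keeps the tiling exact. Constant surfaces, whose spectrum
is identically zero, skip the check and go straight to normalization
(yielding the flat spectrum D(q) ≡ 2).

The gradient policy is `auto` (fire iff β > 1) with `always`/`never`
overrides. Note that multiplicative-cascade fields themselves have
β ≈ 1.3–1.7, so under `auto` they are gradient-transformed like real
biomass surfaces; when the goal is to verify the estimator against the
cascade's closed-form spectrum, the cascade already *is* the measure
and `never` is the appropriate policy. Verification code and tests do
exactly that.

## The cascade oracle

A quadrant multiplicative cascade with weights (w₁…w₄) has the exact
spectrum D(q) = −log₂(Σ wᵢ^q)/(q−1), with the base-2 entropy
−Σ wᵢ log₂ wᵢ at q = 1. Three modes are generated:

- **deterministic** — weights assigned to quadrants in fixed reading
  order; useful for hand enumeration.
- **microcanonical** (default) — the four weights are randomly
  permuted at every subdivision. Mass is conserved exactly, and the
  multiset of box masses at every dyadic scale is *identical* to the
  deterministic cascade's, so the estimated spectrum equals the closed
  form to machine precision. A corollary worth knowing: analysed
  without the gradient transform, all microcanonical realizations of
  the same weights give *identical* spectra — replicate variability in
  simulations comes from the full pipeline (the gradient transform
  responds to the spatial arrangement, which does vary).
- **canonical** — each subdivision multiplies the weights by i.i.d.
  log-normal factors (σ = 0.2 by default) renormalized to sum 1. This
  breaks exact scale symmetry the way real data do while keeping all
  cells positive, so negative-q moments exist; scaling fits remain
  excellent (R² ≳ 0.999 at σ = 0.2) but no longer perfect.

Fractional-Brownian-type surfaces for the stationarity tests are
synthesized spectrally: Fourier amplitudes ∝ k^(−β/2) with complex
Gaussian phases, inverse-transformed and shifted to be nonnegative.

## Statistical layer

- **Group comparison**: per q, the Welch (unequal-variance) two-sample
  t between the groups' D(q) values, averaged over the q grid
  (including the q = 1 entry). Significance by permutation of whole
  plates with group sizes preserved; two-sided p with the add-one
  convention, p = (1 + #{|T*| ≥ |T_obs|})/(n_perm + 1), so p ≥
  1/(n_perm+1) and the test is exact under exchangeability. Default
  n_perm = 10 000. Pairwise tables are Holm-adjusted (step-down
  Bonferroni, via statsmodels). With g plates per group the number of
  distinct splits is C(2g, g); at g = 5 that is 252, so raw p-values
  floor near 0.008 — detecting pairs at stringent adjusted thresholds
  requires more replicates per group, not more permutations.
- **Randomization envelope**: n_rep (default 1000) uniform pixel
  shuffles, each re-analysed with the identical pipeline (gradient
  decision frozen to the observed field's); per-q percentile bounds at
  α/2 and 1−α/2 (default α = 0.01). The observed curve escaping the
  band anywhere flags a non-random spatial arrangement. A caveat
  learned from simulation: for strongly heavy-tailed value
  distributions the *shuffled* measure itself scales anomalously at
  large positive q, so the discrimination comes from the bulk of the q
  grid rather than any single preselected q. Constant fields produce a
  degenerate band equal to the observed curve and are never flagged.
- **Diversity**: Shannon H in bits (base 2); Kendall tau-b with tie
  handling (scipy); quantile regression of H on D(1) by pinball-loss
  linear fits (statsmodels QuantReg) at levels 0.1 … 0.9, with
  asymptotic (kernel sandwich) or pair-bootstrap slope standard
  errors. H is the response because the upper conditional quantiles
  are read as the minimum diversity to expect at a given D(1).

## Synthetic succession

`generate_succession_series` emulates a maturing community on
replicate plates: cascade weights interpolate linearly from
(0.55, 0.25, 0.15, 0.05) to uniform — moving along a straight line
toward the uniform vector can only increase the weight entropy, so the
theoretical D(1) rises monotonically from 1.601 to 2 — while community
evenness in a geometric-series (niche-preemption) abundance model
declines from 0.85 by 0.07 per week, driving Shannon H down. Defaults:
6 weeks × 5 plates, 512×512 plates (levels 9), a 20-species pool
sampled with 500 individuals (observed richness then ranges roughly
10–20 and H roughly 1.9–3.8 bits, a realistic microscope-count
regime). Every plate and community is seeded deterministically from
(master seed, week, plate), so one integer reproduces the series.

What the generator does **not** emulate: imaging noise and optical
artifacts, the grayscale-to-biomass calibration curve (the pipeline
accepts a configurable monotone calibration, defaulting to identity),
within-week ecological heterogeneity beyond cascade randomness, and
any actual growth/colonization mechanism. Passing tests therefore
demonstrate correctness of the estimators and inference on fields with
known scaling structure — not robustness to real imaging pipelines.

## Verification problem sizes

Identities and oracle agreement are checked on 256–512 px fields
(estimates there are exact to ~1e-15 for microcanonical cascades);
permutation-test calibration uses 200 null simulations of 10 plates at
64 px with 999 permutations; envelope behavior uses 200 shuffles at
256 px and 20 i.i.d. control seeds. These sizes give sampling error
well below the tolerances being checked while keeping the whole
verification suite runnable in a few minutes.

## Known limitations

- Negative-q estimates amplify the sparsest boxes and carry several
  times the error of positive-q estimates; tolerances reflect that.
- The scaling-range choice (dyadic, interior scales) is a convention;
  fields whose self-similarity holds only over a sub-range need the
  box sizes set explicitly.
- The envelope's per-q bands are pointwise; with 21 q values the
  family-wise false-flag rate exceeds α slightly (empirically ~2–5%
  at α = 0.01 thanks to the strong dependence of D(q) across q).
- Images are assumed single-channel; color handling and illumination
  correction are out of scope.
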