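# Methods

This note documents the models, estimators, numerical choices and known
limitations of the `ctt` toolkit, and states exactly what the synthetic
data emulate — hence what passing tests do and do not establish about real
recordings.

## Data model

All analyses operate on a `PatternSet`: an observations × units matrix of
activity values with per-observation condition, run/chunk and (optionally)
time-bin and trial labels, and per-unit identifiers.  Volumetric data use
0-based C-order linear voxel indexes as unit ids and carry the source
NIfTI shape/affine; time windows are half-open `[start, end)` on 0-based
bin indexes.  These two conventions are enforced everywhere.

## Synthetic data generator

The simulator is the reference implementation of the data-generating
process CTT assumes, not a fixture: localizer trials are noisy
realizations of K fixed condition templates; main-task trials are weighted
template mixtures plus noise.

- **Templates.** K i.i.d. standard-Gaussian V-vectors are mixed through
  the Cholesky factor of the K×K equicorrelation matrix with off-diagonal
  `template_corr`, giving the exact population pairwise correlation by
  construction; each template is then standardized to zero mean and unit
  variance across units (which leaves between-template sample correlations
  unchanged).  `template_corr` must exceed −1/(K−1) to keep the
  correlation matrix positive definite.
- **Noise.** Gaussian with stationary covariance
  Σ = σ²[(1−ρ)I + ρS], where S is a squared-exponential kernel
  exp(−d²/2ℓ²) over unit index (1-D) or voxel coordinates (3-D) with
  length scale ℓ = 2 units.  diag(Σ) = σ² for every ρ, so per-unit noise
  variance is σ² regardless of smoothness.  In volume mode the covariance
  is defined over the ROI voxels only; out-of-ROI voxels receive
  independent N(0, σ²) noise (a full-grid V×V covariance would be
  needlessly expensive and carries no signal).
- **Modes.** `pattern` (plain matrices); `volume` (templates occupy only an
  axis-aligned `roi_box` of the grid, everything else pure noise); `epoch`
  (each trial sampled at `n_time_bins` bins, the template mixture active
  only inside a boxcar `active_window`, zero outside — no hemodynamic or
  ERP response shape is imposed, since none is part of the method).
- **Baseline shifts.** An optional scalar offset per main-task chunk,
  drawn N(0, `baseline_shift_sd`), added to every unit.  Correlation-based
  indexes are invariant to it; Euclidean distances inflate — the
  documented robustness contrast between the two metric families.
- **Reproducibility.** One seed per dataset; truth, each localizer run and
  each main chunk draw from named, non-overlapping branches of the seed
  tree (`SeedSequence` spawn keys), so regenerating one part never replays
  another's noise, and identical specs give bit-identical data.
- **Balance.** Trials per condition must divide evenly over runs/chunks;
  the generator refuses unbalanced designs rather than silently
  approximating them.

What the generator does **not** emulate: hemodynamic convolution and
autocorrelated scanner noise, physiological/motion artifacts,
non-stationary noise, inter-subject anatomical variability, or realistic
effect-size distributions.  Passing tests therefore establish the
estimators' statistical properties (bias, calibration, recovery) under a
clean Gaussian process — they do not certify performance on any particular
real dataset.

## Extraction

- **GLM.** Plain ordinary least squares per run, B = (XᵀX)⁻¹XᵀY, with
  t = B/SE from the residual variance and diag((XᵀX)⁻¹); one regressor per
  condition (run-wise) or per trial (trial-wise).  No HRF convolution,
  prewhitening or nuisance modeling — designs come in ready-made (boxcar
  construction from BIDS-style events tables is provided).  Rank-deficient
  designs are refused, naming the dependent columns.
- **Univariate noise normalization** divides each unit by its residual SD
  (equivalent to replacing betas by t values up to a common design
  factor); per-run residual SDs are used, matching run-wise GLMs.
- **Multivariate noise normalization** whitens patterns with Σ̂^(−1/2)
  where Σ̂ = (1−γ)S + γ·diag(S) shrinks the empirical residual covariance
  toward its diagonal; γ defaults to the analytic optimal intensity
  (Ledoit–Wolf/Schäfer–Strimmer estimator over the off-diagonal entries),
  overridable.  γ = 1 reduces exactly to univariate normalization — the
  diagonal case computes the whitener and applies it with the same
  arithmetic as the univariate path, so the equality is bit-exact, a
  property the tests assert.
- **Supertrials** average seeded random groups of k trials within each
  condition × run cell (leftover trials smaller than k are discarded);
  k = 1 is the identity.  Random grouping was chosen over consecutive
  grouping to avoid confounding with slow drifts; the literature has no
  consensus here.
- **Temporal smoothing** is a centered moving average within each trial;
  edge bins use truncated windows (no padding — we do not invent data at
  epoch borders).
- **PCA** is fitted on the training set only (localizer by default, to
  keep main-task information out of the projection) and retains the
  minimal number of components whose cumulative explained-variance ratio
  reaches the requested fraction (default 0.99).

All extraction operations are pure and append a provenance record
(operation + parameters) to the returned container.

## Templates

Canonical templates are arithmetic condition means (per run and then
across runs when run-wise estimates are kept; those estimates feed the
correlationability diagnostic and the fully crossed cv estimator).
Exemplars may be retained for classifier training.  Support selection
(ROI mask, time window with optional collapse) commutes with template
estimation, which the tests assert.  Data-driven peak-discriminability
bin selection is deliberately not provided: selecting the support on the
same data that is later tested invites circularity; use theoretically
informed windows or the temporal-generalization matrix instead.

## Tracking estimators

- **Polarity.** Every metric is tagged higher-is-more-active
  (correlations, betas, semi-partial r, classifier d) or
  lower-is-more-active (distances).  `relative_activation` folds polarity
  so a positive relative index always means the target template is more
  active; Pearson values are Fisher-z transformed before subtraction
  (variance stabilization before any averaging).
- **Cross-validated distances.** With main-task chunk means ȳ_c, the
  estimator averages ⟨T − ȳ_c, T − ȳ_c'⟩ over ordered chunk pairs c ≠ c'.
  With the template held fixed this removes the main-task noise bias but
  retains the template's own noise contribution V·σ_T² (documented, not
  corrected — the correct handling of template noise within CTT is an
  open research question).  Setting `cross_template_runs=True` (requires
  run-wise template estimates) additionally crosses template runs r ≠ r',
  averaging ⟨T_r − ȳ_c, T_{r'} − ȳ_{c'}⟩, which is unbiased for the true
  squared distance: this is the estimator the bias audit uses.  Negative
  values are genuine outcomes and are reported, never clipped (clipping
  would bias group statistics); their count is flagged in metadata.
- **Cross-validated correlation.** No canonical formula exists; this
  package uses mean over ordered chunk pairs of
  ⟨T̃, ỹ_c⟩ / (‖T̃‖ · √⟨ỹ_c, ỹ_c'⟩) on unit-centered vectors — the
  cross-chunk inner product in the denominator estimates the signal
  variance without its noise inflation, so the index is not attenuated
  toward zero by main-task noise.  Pairs whose cross-chunk inner product
  is not positive are dropped and counted; this is one admissible reading
  and is labeled as such.
- **Regression partitioning.** Pattern and templates are centered across
  units before the no-intercept fit, removing the global-mean component
  that reflects general rather than content-specific activation.  Signed
  semi-partial correlations come from the R²-difference formula and are
  verified against a residualization oracle to 1e−10.  Collinear templates
  (condition number > 1e8) are refused.
- **Classifier tracking.** Linear discriminant with shrinkage-regularized
  pooled within-class covariance (same diagonal-target shrinkage as the
  noise model, default intensity 0.1).  Each observation receives one
  signed distance to each condition's one-vs-rest hyperplane (midpoint
  between the class mean and the mean of the remaining class means);
  prediction is the argmax of d with ties broken by lowest condition
  index.

## Mapping

The searchlight enumerates integer offsets with ‖δ‖ ≤ radius
(lexicographic order; radius in voxels internally, millimeters converted
via the affine at the CLI), truncates spheres at the mask boundary and
skips centers with fewer than `min_voxels` (default 12) in-mask voxels
(NaN in the output map).  Radius-0 spheres with correlation metrics are
refused outright (one voxel has no variance).  The per-center scalar is
the mean (or median) relative index over main observations — restricted to
a designated main condition when the design mixes target- and
baseline-active trials, since averaging over both would cancel.  Template
estimation inside each sphere uses sphere-local data only; when
multivariate normalization is used in a searchlight, the noise model
should likewise be sphere-local.

The temporal driver estimates templates per localizer bin and tracks them
on each main bin: the time-resolved output is the t = t' diagonal of the
full generalization matrix (an exact identity, asserted).  A symmetric
"matched" scalar (mean same-condition correlation between localizer and
main bin means) is provided for generalization matrices; with Pearson it
makes the matrix transpose-covariant under swapping the two datasets.

## Inference

- **Wilcoxon signed-rank** (scipy backend): zeros dropped and counted,
  exact sign-enumeration null for n ≤ 25 without ties, normal
  approximation with continuity correction otherwise.  The one-sample form
  is only appropriate for bias-controlled (cross-validated) indexes;
  naive indexes call for the paired form against a baseline template.
- **Permutation nulls.** Group level: sign flipping of per-subject
  relative indexes (exchangeable under the no-effect null); with n ≤ 12
  subjects the full 2ⁿ enumeration replaces sampling — the test is then
  exact, RNG-free and bit-reproducible, with p = #{null ≥ obs}/2ⁿ (the
  identity flip is part of the null).  Subject level: trial-label
  shuffling with the target-minus-baseline mean difference.  Sampled nulls
  use the add-one rule (1 + #{null ≥ obs})/(1 + n_perm), so p ≥
  1/(n_perm+1) always.
- **Cluster correction.** Observed and null maps are thresholded (default:
  the per-unit 95th percentile of the permutation null, i.e. uncorrected
  p < 0.05), contiguous suprathreshold units labeled (1-D adjacency for
  time; 6-connectivity default in 3-D, 18/26 available), and the maximum
  cluster statistic per null map forms the FWE null.  The default cluster
  statistic is **size** (member count).  Because sizes are small integers,
  the attainable significance levels are discrete and the test is mildly
  conservative at nominal α = 0.05 on short maps (measured type-I rates of
  2–3% on 20-bin null simulations) — valid FWE control, at some cost in
  power.  A **mass** statistic (summed threshold exceedance) with a
  continuous null is available for designs where that discreteness bites.
- **FDR**: Benjamini–Hochberg step-up (statsmodels backend).
- Tests are one-sided by default (relative activation is a directional
  hypothesis); two-sided is a flag away.

## Diagnostics

SNR is the mean of one template's activation-index distribution divided by
its sample SD (n−1) — the "t value linked to the similarity measurement"
reading of index reliability; this interpretation is a documented choice,
as the quantity is not defined operationally in the literature that names
it.  Entropy is Shannon entropy in bits over an equal-width 16-bin
histogram of template values (bin count overridable; constant templates
return 0 with a warning).  Correlationability is the Fisher-z-averaged
mean pairwise correlation among run-wise estimates of the same condition's
template; run-wise estimates (rather than trial exemplars) are the
default because they match how canonical templates are estimated.

The bias audit simulates a main condition that expresses exactly its own
template, with one localizer trial per run and one main trial per chunk at
the same noise level, so template estimates and chunk patterns each carry
one full noise draw.  The naive squared Euclidean distance, averaged over
(template-run, chunk) pairs, then has analytic expectation 2·Σ_v Var_v =
2Vσ² although the true distance is zero; the fully crossed cv estimator is
unbiased around zero.  With t trials averaged per run/chunk the analytic
expectation generalizes to Vσ²(1/t_loc + 1/t_main), which the report uses.

## Problem sizes

Simulation sizes used by the test suite and the acceptance script, chosen
to estimate each quantity with comfortable Monte-Carlo precision: bias
audit V = 200, σ = 0.5, 20 chunks, 1000 repetitions; weight recovery
V = 300, 40 trials, σ = 0.2, plus 100 simulated subjects for the
relative-index sign rate; type-I calibration 200 experiments × 10 subjects
× 20 time bins with exhaustive 2¹⁰ sign flips; searchlight 20³ grid with a
5³ signal box at radius 2; temporal contrasts 40 seeded runs of 15-bin
epochs.  The packaged demo runs 8 subjects at 60 units.

## Known limitations

Within-region comparisons only (no cross-region pattern mapping); no
surface-based searchlights; no HRF/ERP forward modeling; trial-wise GLM is
one-regressor-per-trial on a shared design (no iterative single-trial
variants); no threshold-free cluster enhancement or random-field theory;
classifier tracking is linear only.  The cross-validated correlation
definition and the SNR reading above are documented choices where the
method leaves the formula open.
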