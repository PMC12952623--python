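# Methods

## Twin variance-component model

The engine fits univariate twin models by full maximum likelihood.  Each
pair contributes a bivariate-normal log-density with a single free mean
shared across twins and zygosities and an exchangeable covariance; the
off-diagonal is a² + c² (MZ) vs a²/2 + c² (DZ) under ACE, a² + d² vs
a²/2 + d²/4 under ADE, and the AE/E submodels drop terms.  Parameters are
path coefficients (a, c, e optimized unconstrained and squared), which
enforces non-negative variance components without constrained optimization.
The likelihood is evaluated from per-zygosity sufficient statistics
(n, Σ(x₁+x₂), Σ(x₁²+x₂²), Σx₁x₂), so a fit costs the same at 16 pairs as at
40 000 — this is what makes the replicate-heavy calibration suites cheap.

Numerical choices:

* Optimizer: L-BFGS-B with three starts — Falconer-derived
  (a² = 2(r_MZ − r_DZ), c² = 2r_DZ − r_MZ, e² = 1 − r_MZ, clipped into
  (0, 1)), an equal split, and an E-dominant start.  Termination at
  gradient/ftol defaults (gtol 1e-8, ftol 1e-12); non-convergence of all
  starts raises rather than returning silently.
* The E model is closed form (grand mean, mean squared deviation) and is
  computed analytically.
* A floor of 1e-8 on e² keeps the likelihood bounded when the ML solution
  sits on the e → 0 boundary (e.g. a phenotype fully determined by shared
  factors); away from the boundary its effect is below the optimizer's
  termination tolerance.
* Phenotypes are z-standardized cohort-wide before fitting; the AE additive
  fraction is invariant to sign flips and affine rescaling, and raw
  (r_MZ, r_DZ) are always carried through so "near zero or negative"
  heritability patterns stay visible.
* Model family: ADE iff r_MZ > 2·r_DZ with the boundary going to ACE —
  equality is the purely additive pattern, and C (unlike D) can absorb any
  residual shared similarity.  A CE model is not fitted.
* Significance of A: χ² = 2(logL_AE − logL_E) against χ²(1).  Because a²
  is tested on the boundary of its space, the χ²(1) reference is
  conservative (empirical size ≈ 0.01–0.03 at α = 0.05 in the calibration
  suite); the ½χ²(0) + ½χ²(1) boundary mixture is available via
  `boundary_mixture=True` and is the less conservative choice.
* Multiple testing: Bonferroni by default (α = 0.05, configurable; the
  analyses this package mirrors quote both 0.05 and 0.03),
  Benjamini–Hochberg optional.  Both delegate to
  `statsmodels.stats.multitest`.
* The intraclass correlation is the one-way random-effects ANOVA form for
  groups of two, (MSB − MSW)/(MSB + MSW), clipped to [−1, 1] — the standard
  twin-literature estimator, chosen for its hand-computable oracle.
* MZ-vs-DZ similarity per edge is compared by Fisher r-to-z,
  z = (atanh r_MZ − atanh r_DZ)/√(1/(n_MZ−3) + 1/(n_DZ−3)).  This is an
  explicit stand-in: the analyses this package reimplements do not state
  their test for that comparison.

## Connectivity phenotypes

Static FC is the Pearson correlation of the condition's pooled frames,
computed per run (runs are standardized separately) and combined across runs
by a frame-weighted average of the correlation matrices.  Partial
correlation is available behind a flag: Ledoit–Wolf shrinkage of the
covariance toward a scaled identity, pseudo-inverse, then the standardized
negated off-diagonal of the precision matrix.  Pearson is the default; the
partial variant exists because the source analyses mention both without
resolving which was used where, and the discrepancy is surfaced as
configuration rather than silently resolved.

Dynamic FC uses a rectangular sliding window, default 18 s → round(18/0.72)
= 25 frames, step 3 frames (the step unit is frames because steps are
applied to the sampled series; 3 frames = 2.16 s).  Windows are laid out
inside each task block — never across a block boundary — and pooled across
the condition's blocks and runs; each window is re-standardized before the
correlation, so a window matrix is exactly the static estimator restricted
to the window's frames (the suite asserts bit-identity).  Per-edge summaries
are the arithmetic mean and the unbiased (n−1) variance across windows.
Windows containing a zero-variance ROI segment are dropped with a logged
count; a zero-variance ROI over a whole condition is a hard error naming the
ROI.  Frame membership of a block is half-open [onset, onset+duration) in
seconds, frame time = index × TR, with an optional hemodynamic lag shift
(default 0 s — no lag correction is applied unless asked for).  No Fisher
r-to-z transform is applied by default; a flag applies atanh to static FC
and the dynamic mean (not the variance).

All genetic modelling operates on the 2-back − 0-back differential
phenotype, formed elementwise per subject and edge after both condition
tables exist; subject or edge mismatches are errors, not joins.

## Dynamic states

Windowed ROI matrices are averaged within Yeo-7 network blocks (diagonal =
mean of distinct within-network pairs, off-diagonal = mean of all
cross-network pairs).  The clustering feature vector contains both the
within-network diagonal and the upper off-diagonal entries (28 features for
the full 7-network set): the state contrasts of interest are within-network,
which requires the diagonal — this inclusion is an interpretation, flagged
here because the source description ("upper-triangular elements") is
ambiguous about the diagonal.  Networks represented by a single ROI have no
within-network value and that feature is dropped.  Features are z-scored
over the pooled windows of all subjects and clustered by a single k-means
model (k-means++ initialization, n_init restarts, fixed seed) across
subjects.  States are relabeled by ascending group-mean occupancy, so State
1 is always the transient state regardless of the k-means seed.

Occupancy is the fraction of a subject's windows in a state; dwell is the
mean length of maximal consecutive runs, in windows, with no conversion to
seconds and no deduplication of overlapping windows; the transition count
(number of label changes) is included as a third temporal metric so that
state-switching behaviour can be tested for heritability.  State-1-vs-2
contrasts are paired t-tests per network and for the between-network mean;
subjects missing a state are excluded from the contrast, and zero-variance
difference vectors are reported as degenerate rather than producing
infinite t statistics.

## The synthetic cohort generator

The generator exists to provide ground truth, at two levels.

**Phenotype level.**  Per pair, additive factors are bivariate standard
normal correlated 1.0 (MZ) / 0.5 (DZ) (dominance: 1.0 / 0.25), one shared
environment draw per pair, independent unique draws per twin; the phenotype
is the path-weighted sum, so marginal variance is 1 and the expected twin
correlations are r_MZ = a² + c², r_DZ = a²/2 + c².  This level is exact by
construction and is the basis for all quantitative recovery targets.

**Time-series level.**  Block-design two-condition series: frames are drawn
from the covariance of a planted regime (a 2-state Markov chain with
configurable stay probabilities, started from its stationary distribution;
`switch_every` sets the chain cadence in frames — per-frame by default, or
one analysis-window per step so that regime boundaries align with
non-overlapping windows in recovery experiments).  Regime covariances are
network-block correlation matrices (within-network r, between-network r,
optional per-network boosts), eigenvalue-clipped at 1e-6 and rescaled to
unit diagonal whenever repair is needed.  Heritable condition effects are
per-pair ACE-structured increments added to named target edges' correlations
during 2-back frames only; increments pushing |r| past 0.99 are clipped and
counted in the recorded ground truth.  One global seed is split into
substreams (phenotype draws, state chains, noise) via `SeedSequence`, making
every output byte-identical across reruns.

What this generator does **not** emulate: hemodynamic-response convolution,
1/f and physiological noise spectra, motion artifacts, spatial structure, or
any mechanistic account of how genetic variation enters BOLD.  Passing tests
therefore demonstrate that the estimators recover what the generative model
plants — calibration, consistency, and correctness of the machinery — not
that real task-fMRI heritability takes any particular value.  For that
reason the quantitative recovery anchors (the reported top-edge additive
fractions 0.328, 0.303, 0.436) are exercised through the phenotype-level
generator, where truth is exact; the time-series level backs qualitative
end-to-end checks (a planted heritable edge rises into the top static edges;
planted regimes are recovered with adjusted Rand ≥ 0.9).

Default study conditions mirror the motivating cohort: 134 MZ + 78 DZ pairs,
TR 0.72 s, two runs of eight 25 s task blocks (four per condition) with
2.5 s cues and a mid-run fixation block.  The default end-to-end
configuration is scaled to 20 MZ + 12 DZ pairs and 12 ROIs (two per network
across six of the Yeo-7 systems) — chosen so the full pipeline, including
the per-edge genetic scan over three measures, remains a desk-scale
computation while every stage still runs on realistic structure.  The
planted-state recovery experiment uses 20 subjects with 300 non-overlapping
windows each, enough that the occupancy comparison against the chain's
stationary distribution has a sampling error (≈ 0.02) comfortably inside
the ±0.05 check.

## Known limitations

* No sex-limitation, age moderation, bivariate genetic models, or extended
  pedigrees; no CE model.
* Real-data ingestion is plain-text TSV/CSV (one converter step away from
  CIFTI workflows, which are out of scope).
* The two-state k-means framework cannot express gradual state transitions;
  dwell in overlapping-window units inherits the windowing's smoothing.
* The Fisher r-to-z MZ/DZ comparison treats intraclass correlations as
  ordinary correlations, which is approximate for small pair counts.
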