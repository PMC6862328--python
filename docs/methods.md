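# Methods

`methsignal` treats differential DNA methylation as a signal-detection
problem. Statistically significant methylation changes arise spontaneously
in healthy individuals; a site-level test against a control group therefore
does not, by itself, distinguish a disease- or treatment-induced change
from natural background variation. The package separates the two in three
steps: (1) measure every individual — control and treatment alike — against
a common reference; (2) model each individual's genome-wide background
divergence distribution and keep only sites in its extreme tail; (3)
estimate the divergence cutoff that best discriminates treatment-origin
from control-origin candidate sites, and validate the discrimination with
a cross-validated classifier.

## Divergence of methylation levels

At a cytosine with methylated/unmethylated read counts (n_mC, n_uC), the
methylation level is the posterior mean under a beta prior. The default is
the uniform prior, p̂ = (n_mC + 1)/(n_mC + n_uC + 2), which is defined even
at zero coverage and never touches 0 or 1. Optionally a beta prior is
fitted per sample by least squares between the beta CDF and the empirical
CDF of the sample's own crude levels (initialized at method-of-moments
estimates); its shape parameters then act as pseudo-counts.

Each sample is compared site-by-site with a *reference individual* pooled
from control-process samples that are excluded from the analyzed control
group (counts summed per site by default; mean/median offered). Measuring
control and treatment samples against the same origin is what makes their
divergence distributions comparable. Two statistics are recorded per site:

* the signed total-variation distance tv = p̂_sample − p̂_ref (its absolute
  value |TV| is the Manhattan distance on the two-point space (p, 1−p));
* the coverage-weighted Hellinger divergence
  H = w[(√p_c − √p_t)² + (√(1−p_c) − √(1−p_t))²] with
  w = 2 m_c m_t/(m_c + m_t) and m = coverage + 1 for each party.

Sites must reach a minimum coverage (default 10) in both parties; nothing
is imputed. The records satisfy |TV| ≤ 2·√(H/w).

Under the null of a common level, a second-order expansion of the
Hellinger kernel gives H → ½·χ²(1): the Hellinger chi-square test (HCT)
therefore uses 2H as its χ²(1) statistic, which restores the nominal
type-I error (0.05 ± 0.01 empirically under a binomial null at coverage
≥ 30). Using H itself against χ²(1) would be conservative by a factor of
~10 at α = 0.05.

## Background distribution and critical values

The genome-wide distribution of H within one sample is summarized by its
ECDF and fitted, by nonlinear least squares over the (H, ECDF) points,
with four candidate models: Weibull and gamma CDFs, each with and without
a location parameter (bounded trust-region optimization; Weibull
initialized from the log-log linearization of the CDF, gamma from method
of moments; location starts at 0 and is bounded by the smallest
observation). ECDFs beyond 500,000 points are thinned to a deterministic
every-k-th subsample (≥100,000 points) before fitting. The best model is
the lowest AIC computed from the Gaussian RSS over the ECDF points, with
ties broken by fewer parameters and then higher R². Model selection
between Weibull and gamma is only moderately sharp for sub-exponential
shapes (the two CDFs nearly coincide there); critical values are
insensitive to which of the two wins because both fit the upper tail.

The per-sample critical value H(α) is the model's (1−α) quantile (closed
form for Weibull, incomplete-gamma inversion for gamma; α = 0.05 by
default). Fitting is done per individual — including treatment
individuals, whose distributions mix background with signal — so critical
values are an individual property, not a group property.

## Potential DMPs and the optimal cutoff

A site is a *potential DMP* (pDMP) for a sample if its H strictly exceeds
that sample's H(α) **and** its |TV| reaches the empirical background
quantile cutoff, by default the 95% quantile (TV95) of |TV| pooled over
the control group's tracks (a pooled-both-groups option exists). Potential
DMPs inherit the group label of their sample — control individuals
produce pDMPs too, and keeping them is the point of the method.

The final DMP call applies an optimal H cutoff, estimated three ways:

* **Youden**: the threshold over observed H values maximizing
  J = sensitivity + specificity − 1 with treatment as the positive class
  (ties resolved to the smallest threshold). Cheap and reproducible, but on
  *perfectly* separated groups the maximizing threshold excludes every
  control pDMP, leaving a single-class DMP set on which the downstream
  classifier cannot train — the pipeline fails loudly in that case.
* **Classifier posterior** (used by the benchmark experiments): candidate
  cutoffs are 50 evenly spaced quantiles of pDMP H between q0.05 and
  q0.995; each candidate's induced DMP set is scored by a small Monte
  Carlo CV of the origin classifier, and the candidate with the best mean
  accuracy (kappa as tie-break, then the smaller cutoff) wins. Candidates
  that leave fewer than 5 DMPs in either class are skipped. This method
  keeps both classes in the final set by construction.
* **Gamma mixture**: a two-component gamma mixture fitted to pDMP H by EM
  (2-means on log H initialization; weighted gamma M-steps via Newton on
  the profile shape equation; tolerance 1e−8 on the relative
  log-likelihood change, max 500 iterations). The cutoff is the smallest H
  at which the posterior of the higher-mean component reaches ½ (grid
  bracket + root refinement). Components separated by less than 2 pooled
  standard deviations are flagged degenerate: overlapping gamma components
  drift without a stable optimum, so the cutoff is reported but marked
  unstable.

DMPs are the pDMPs with H strictly above the cutoff, both groups retained.

## Origin classification and Monte Carlo cross-validation

Each DMP contributes four predictors: |TV|, H, the relative chromosome
position pos/length, and log₂ of the tail probability of the site's own H
under its sample's fitted background model (floored at log₂ 1e−300; a
constant-per-sample variant evaluating the tail at H(α) is available
behind a switch). The label is the group of origin (CT/TT, TT positive).

Model families: plain logistic regression (no scaling, no PCA) and
standardized-PCA variants feeding logistic, LDA or QDA models (all four
principal components by default). QDA carries a small covariance shrinkage
(reg_param 1e−3): within one group the first, second and fourth predictors
are deterministic or near-deterministic transforms of one another, so
small DMP classes are rank-deficient in the PCA basis.

Performance is estimated by Monte Carlo cross-validation: 999 stratified
random 60/40 train/test splits; per split the indicator panel (accuracy,
Cohen's kappa, sensitivity, specificity, PPV, NPV, detection rate, FDR) is
computed on the held-out part; the report carries means and 2.5/97.5%
percentile bootstrap intervals across splits plus the pooled confusion
matrix. Splits are stratified to keep both classes in every test set; the
positive class is treatment, the posterior threshold is fixed at 0.5.

For external validation, per-sample background models and critical values
are re-fitted (they are individual properties) while every group-level
decision — TV95, the optimal cutoff, the trained classifier — is frozen
from training.

## The count simulator

The generator emulates bisulfite count data with a known truth:

* **Coverage**: negative binomial with mean 30 and dispersion 4.5
  (variance μ + μ²/θ), floored at 10 by rejection resampling (clamping
  would pile mass at exactly 10). 30× is a standard whole-genome bisulfite
  target depth; θ = 4.5 gives the strong overdispersion typical of
  bisulfite libraries.
* **Background levels**: one latent level per site drawn from
  beta(0.09, 0.5) — a strongly bimodal, mostly-unmethylated methylome
  (mean ≈ 0.15) — shared by every individual of a group, so that
  between-individual variation enters through coverage and count noise.
  Reference individuals are control-process draws sharing the control
  levels. The latent profile is the *population*; an explicit
  `population_seed` lets independent datasets (external cohorts) sample
  new individuals from the same populations.
* **Treatment effect**: the treatment methylome is a quantile-preserved
  perturbation of the control methylome — at each site the treatment
  latent level is the same quantile of a beta whose mean is shifted up at
  fixed concentration. Under this comonotone coupling the genome-wide mean
  absolute latent difference E|p_t − p_c| equals the mean shift exactly,
  so the three benchmark effect sizes (0.0356, 0.1332, 0.1845) are
  calibrated precisely; the calibration routine still verifies the
  realized mean by Monte Carlo within 2%. Independent draws could not
  reach the small effect sizes at all (two independent draws from any
  diffuse beta differ by ≈0.24 on average), which is why the coupled
  design was adopted. The effect is applied genome-wide, matching a
  single genome-wide effect-size summary.
* **Counts**: k ~ Binomial(coverage, latent level); posterior level
  p* = (a + k)/(a + b + coverage) under the group's own beta as the
  conjugate prior; methylated reads = round(coverage · p*). Counts always
  sum to the coverage.

What the generator does **not** emulate: chromosomal autocorrelation of
methylation, cytosine context (CG/CHG/CHH), inter-individual biological
variation beyond count noise, read-level error, or subpopulation structure
among patients. Consequently the benchmark results certify the machinery —
calibration of the background model, threshold estimation, classifier
performance under a homogeneous population — not performance on real
cohorts, where individual heterogeneity widens the background |TV|
distribution well beyond count noise. In particular, the pooled background
TV95 in the mild scenario is ≈0.16 here, whereas noisier backgrounds with
inter-individual variation can reach ≈0.35; adding a per-individual
overdispersion knob would close that gap but would have to be calibrated
against the very quantity being validated, so it was deliberately left
out.

## Numerical and design choices

* Strict ">" at both the critical-value and optimal-cutoff filters;
  boundary sites are excluded.
* Quantiles are linear-interpolation (type-7) throughout.
* Duplicate sites in input are an error, not a merge: corrupt input fails
  loudly.
* Reference pooling defaults to summed counts (preserves all reads and
  gives the natural counts centroid); mean/median round half-up.
* All randomness flows from explicit seeds through
  `numpy.random.SeedSequence`; reruns with the same configuration are
  byte-identical, including written artifacts.
* Benchmark problem sizes: the packaged experiment protocols default to
  100,000 sites per sample (`scripts/acceptance.py`), and the test suite
  runs the same protocols at 20,000 sites; both sizes give
  indistinguishable classifier indicators because the DMP sets scale
  proportionally.

## Known limitations

* The Weibull-vs-gamma model choice is unstable for sub-exponential
  shapes; only the fitted tail matters downstream.
* The Youden cutoff is unusable on perfectly separated groups (see above);
  the classifier-posterior method is the robust default for benchmark-like
  data.
* The Fisher exact comparator pools replicates per group into one 2×2
  table per site; it is a baseline, not a calibrated reproduction of any
  specific published tool.
* `predict_external` assumes the external cohort is measured against the
  training reference (or a compatible one supplied explicitly); divergence
  tracks measured against a different origin are not comparable.
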