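# Methods

## Growth laws and their calculus

Cumulative height (m) and DBH (cm) trajectories are modelled with four
three-parameter saturating laws — Gompertz `a·exp(−b·c^t)` (with
`0 < c < 1`), Chapman–Richards `a·(1 − e^{−bt})^c`, logistic
`Asym/(1 + exp((xmid − t)/scal))` and asymptotic regression
`a + (b − a)·exp(−e^c·t)` — with time `t` in years from planting, `t ≥ 0`.
The Chapman–Richards form here is the printed three-parameter one, not the
four-parameter generalized logistic that also carries the "Richards" name;
it is sigmoid for `c > 1` and has a one-sided derivative singularity at
exactly `t = 0` when `c < 1` (the evaluator returns the one-sided limit,
`±inf` where divergent, and downstream curvature code raises a named error
rather than propagating non-finite values).

First and second time derivatives, the inflection time (time of maximum
growth rate) and the plateau are all closed-form:

* logistic `t* = xmid`; Gompertz `t* = ln b / (−ln c)` (interior only when
  `b > 1`); Chapman–Richards `t* = ln c / b` for `c > 1`; the asymptotic law
  and Chapman–Richards with `c ≤ 1` have no interior inflection and report
  `None` rather than raising.

The analytic derivatives are validated in the test suite against central
finite differences (step `1e-5`; the second derivative is differenced from
the analytic first derivative to avoid cancellation) at relative tolerance
`1e-4` with an absolute floor of `1e-6 × plateau` for points where the
derivative itself vanishes.

## Fitting

Each series (≥ 4 points; the trial schedule {1, 2, 3, 5, 6, 7, 9, 10, 11}
years — gaps are data, never imputed) is fitted by unweighted nonlinear
least squares (`scipy.optimize.least_squares`, Levenberg–Marquardt in a
transformed parameter space). Positivity and interval constraints are
enforced by smooth reparameterization (log for positive parameters, logit
for the Gompertz shape `c ∈ (0,1)`, `a = b + e^z` for the asymptotic law's
`a > b`), keeping the solver unconstrained. Self-start heuristics: plateau
`1.05 × max` (for the logistic additionally corrected by the estimated
headroom of the last observation), rate/shape from crude two-point
log-linearizations. Non-convergence triggers up to 10 restarts with seeded
multiplicative lognormal jitter (sd 0.3) of the initial vector; the best SSE
is kept and the result is never worse than the self-start. Convergence
tolerances: `ftol = 1e-10`, `xtol = gtol = 1e-12`, 2000 function
evaluations per start.

The likelihood is independent Gaussian with the variance concentrated out:
`σ̂² = SSE/n` (floored at `1e-12` so perfect fits stay finite) and
`log L = −(n/2)(ln 2πσ̂² + 1)`. Information criteria use the full-likelihood
convention with `k = 3 + 1` (σ counted): `AIC = n ln 2πσ̂² + n + 2k`,
`BIC = n ln 2πσ̂² + n + k ln n` — the same constants as R's `AIC()` on an
`nls` fit, which matters only when comparing values across implementations,
never for ranking. σ̂² is per series; no pooling across clones during
per-clone fitting, and no autocorrelated residual structure (observations a
year apart on a tree are treated as independent given the curve — a known
simplification).

## Model selection

For one trait, each of the five metrics (AIC, BIC, R², RMSE, MAE) is
compared between all six law pairs by a paired two-sided t-test across
clones (the clone is the pairing unit), Holm-adjusted within metric. A
zero-variance nonzero-mean difference vector (e.g. a constant AIC offset) is
reported as `p = 0` with a `constant_difference` flag — infinitely strong
evidence in the paired-t model — rather than crashing. The winner is the law
with the best mean AIC among laws never significantly worse than any other
law on AIC; ties break by mean BIC, then mean RMSE, then the fixed order
(gompertz, richard, logistic, asymptotic). The full reasoning is emitted as
a `decision_trace`. Tukey-HSD-style simultaneous comparison would be a
reasonable alternative; the paired-t + Holm choice assumes least about the
metric distributions.

## Trajectory likelihood-ratio test

For a SNP with `G` usable genotype classes (classes below `min_class_size`,
default 3, are excluded; fewer than two usable classes marks the SNP
untestable, as with monomorphic loci), the null model fits one curve to all
member clones' observations pooled and the alternative fits one curve per
class. `LR = −2(log L0 − log L1)` is referred to `χ²` with
`df = 3(G − 1)`.

The residual-variance convention is the one genuinely open design choice.
The default (`sigma_mode="pooled"`) shares a single σ̂² across classes in
the alternative (`σ̂₁² = Σ_g SSE_g / n`), so the alternative has exactly
`3(G − 1)` extra free parameters and the χ² reference with that df is
asymptotically exact; simulation at the package's study conditions
(24 clones, 12/12 classes, 2% noise, 500 replicates) gives a 5.0% rejection
rate at nominal α = 0.05 with uniform p-values. The alternative
(`sigma_mode="per_class"`) lets every class concentrate its own σ̂²; that
adds `G − 1` further variance parameters, so it must be paired with
`count_sigma_df=True` (`df = 4(G − 1)`) to stay calibrated — referring the
per-class-σ statistic to `df = 3(G − 1)` rejects ≈10% of true nulls at
the 5% level for `G = 2`. Both options are exposed; the calibrated pooled
default is used everywhere unless asked otherwise.

Classes whose fitted trajectories are practically identical (e.g. a dominant
locus where heterozygote and one homozygote coincide) can be merged before
testing: greedy pairwise merging by normalized L2 distance between predicted
curves over the observation window (mean squared difference divided by the
squared mean plateau), refitting after each merge, while the distance is
strictly below a threshold (`0` disables merging). The merge history is kept
on the classing object.

Supporting statistics: minor-allele frequency by direct allele counting;
per-year single-time association as a one-way fixed-effects GLM
(statsmodels OLS with genotype as a categorical factor — identical to
one-way ANOVA, no kinship/structure covariates, defensible for a small panel
of unrelated clones); genotype-count χ² against a Mendelian ratio (1:2:1 or
1:1 by default). A joint test of genotype effects on the fitted parameter
vectors is provided as a one-way MANOVA with Wilks' Λ computed from the
within/between scatter matrices; the primary p-value uses Rao's F
transformation, which is exact for one-dimensional input (reducing exactly
to the GLM F-test) and for two groups, with Bartlett's χ² approximation also
reported. No mixed-model machinery: with ~24 unrelated clones a kinship
correction is neither estimable nor needed. p-values are reported raw across
SNPs by default; Benjamini–Hochberg is available by flag.

## Ontogenetic staging

The phase boundary between rapid and reduced growth is the maximizer of the
curvature `κ(t) = |y''|/(1 + y'²)^{3/2}` of the fitted curve on the
decelerating limb (`t` past the inflection; the guard can be disabled, and a
search window lying entirely on the accelerating limb is answered but
flagged). The argmax is located on a 0.01-year grid and refined by bounded
golden-section search (`xatol = 1e-6`), which is deterministic and agrees
with a brute-force `1e-4`-step scan to well under 0.01 years in the tests.

κ is not unit-invariant: measuring height in cm instead of m moves the
argmax. The default computes on raw trait/age units (height m, DBH cm,
years), matching common field practice; `normalize="minmax"` rescales both
axes to `[0, 1]` over the search window first, giving a unit-free boundary.
Two consequences, fixed as numeric regression fixtures in the tests: in raw
units a 20% larger plateau (same rate/shape) transitions *later*
(t_mc 14.14 → 15.05 years for Chapman–Richards (30, 0.2, 2) vs (36, 0.2, 2)),
i.e. better-performing genotypes enjoy a longer rapid phase; in normalized
mode the boundary is amplitude-invariant, and rescaling the time axis
(halving `b` with a correspondingly doubled window) exactly doubles `t_mc`.
Boundaries beyond the last measured age are legitimate (saturating curves
are extrapolated there) and stamped with an `extrapolated` flag.

## Synthetic trial data

The generator emulates a clonal field trial: 24 clones, 20 biallelic SNPs
with MAF evenly spread over [0.08, 0.44] drawn iid at Hardy–Weinberg
genotype frequencies, Chapman–Richards trajectories with defaults height
`(a, b, c) = (28 m, 0.18, 1.6)` and DBH `(33 cm, 0.22, 1.3)` — chosen once
as plausible values for a fast-growing poplar stand reaching ~24 m and
~28 cm at 11 years, not estimates of any real trial — and iid Gaussian
measurement noise with sd defaulting to 1.5% of the plateau, the regime in
which growth-curve R² across clones stays above 0.995. Three of the default
SNPs carry effects (plateau and rate QTLs, additive and dominant). Effects
act multiplicatively on curve parameters — parameter = base ×
(1 + effect)^dose after dominance coding — so genotype classes diverge
progressively with age, which is exactly the alternative the trajectory LR
test is built to detect (and why single-year tests at early ages miss such
loci). Each clone has 3 ramets whose measurements are averaged to the clone
mean (ramet-level output by flag); simulated measurements are floored at
0.01 trait units since physical measurements are positive. Everything is a
pure function of configuration + seed.

What the generator does **not** emulate: spatial block effects, linkage
disequilibrium between SNPs, pedigree structure, age-dependent
(heteroscedastic or autocorrelated) measurement error, and genotype ×
environment interaction. Passing tests therefore demonstrate correctness and
calibration of the statistical machinery under its own assumptions, not
robustness of the method to real field data.

## Problem sizes and numerical choices

Simulation-based checks use 24-clone panels: 500 replicates for null
calibration of the LR test (binomial 95% band around α = 0.05), 40 per
effect size for the power curve over {0, 5, 10, 20}% plateau effects, and
20 replicate datasets for model-selection recovery; the acceptance script
uses 200/50/10 for the same quantities. Degenerate inputs are handled
explicitly: constant series are non-fittable; zero total variance makes R²
undefined (error); all-missing SNPs and monomorphic SNPs are errors and
untestable sentinels respectively; expected genotype counts of zero are
errors. Ties in the model-selection winner rule are broken deterministically
as described above, and staging is bit-deterministic for identical inputs.

## Known limitations

* The plateau of a saturating curve observed to only ~80% of its asymptote
  is weakly identified: at 2% measurement noise individual Chapman–Richards
  plateau estimates can stray ~30% high while remaining genuine ML optima;
  aggregate (mean/median) recovery stays within a few percent.
* The LR test's χ² reference is asymptotic in the number of observations per
  class; very small classes (below the default minimum of 3 clones ×
  9 ages) are excluded rather than tested.
* Raw-unit curvature staging depends on the measurement units; use the
  normalized mode when comparing boundaries across traits.
* Independent-Gaussian residuals understate within-clone serial correlation;
  LR p-values should be read as approximate for real repeated measures.
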