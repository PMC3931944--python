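# Methods

## Model family

All models are Gaussian multi-kernel mixed models for replicated
multi-environment trial records,

    y_ijk = mu + sum_t u_t(i,j) + eps_ijk,
    u_t ~ N(0, K_t sigma2_t),   eps ~ N(0, I sigma2_eps),

with i indexing environments (location-by-year combinations), j lines
and k replicates. The family contains seven members distinguished only
by which random terms enter: `EL`, `EG`, `ELW`, `EGW`, `EGW-GxE`,
`EGW-GxW` and `EGW-GxWGxE`. Terms and kernels:

* **E**, **L** — exchangeable environment and line main effects;
  record-level kernels are the incidence products Z Z' (1 when two
  records share the entity, else 0).
* **G** — genomic values. The genomic relationship matrix is
  G = X_s X_s' / p with markers centered and divided by their
  population SD (default), or the allele-frequency scaling
  G_jj' = p^-1 sum_m (x_jm - 2 theta_m)(x_j'm - 2 theta_m) /
  (2 theta_m (1 - theta_m)) via `scaling="freq"`. Both describe twice
  the realized kinship when markers segregate independently; the SD
  scaling is the default because it applies unchanged to ECs and gives
  a unit diagonal mean exactly, so variance parameters stay on the
  trait scale. The two scalings coincide only under Hardy-Weinberg
  genotype proportions; data may depart from that, and the package
  deliberately exposes both rather than reconciling them.
* **W** — EC-driven environment effects; Omega = W_s W_s' / Q from
  standardized ECs is the exact environmental analogue of G. EC rows
  may be keyed by environment or by environment-by-line (key
  `env::line`); both keyings are supported because EC tables in
  practice come in both shapes, and the record-incidence map is
  inferred from the kernel's labels.
* **GxW**, **GxE** — interactions. A first-order multiplicative
  reaction norm multiplies a random genetic score (linear in markers)
  by a random environmental score (linear in ECs); with independent,
  zero-mean IID coefficients the covariance of the product process is
  the Hadamard product of the factor covariances. Hence
  cov(GxW) = [Z_g G Z_g'] o [Z_E Omega Z_E'] and
  cov(GxE) = [Z_g G Z_g'] o [Z_E Z_E']. The explicit alternative —
  one regression column per marker-EC pair — needs p*Q columns
  (162,860 at p = 2,395, Q = 68) and is retained only as a brute-force
  test oracle (`khatri_rao_oracle`), which must agree with the
  Hadamard construction to 1e-10 by the algebraic identity
  (XX') o (WW') = C C' with C the row-wise Khatri-Rao product.

Record-level kernels inside `make_model` are kept in factored form
B (with B B' = K): entity kernels are eigen-factored once (J x J or
I x I), factors are expanded to records by row indexing, and Hadamard
products are factored by the row-wise Khatri-Rao product. No dense
record-by-record matrix is formed during model fitting; the dense
kernel operations exist alongside for validation and are tested to
agree with the factored path.

## Quality control

Markers: drop when minor allele frequency min(theta, 1-theta) < 3 %
(theta = mean of non-missing calls / 2) or when more than 10 % of calls
are missing; remaining missing calls are imputed with 2 theta_m, which
preserves each marker's mean. Filtering precedes imputation so both
statistics are computed on observed calls only.

ECs: drop a covariate when more than 30 % of its rows equal its modal
value (interpreted as "repeated values": the rule targets
near-constant covariates) or when more than 0.2 % of values fall
outside mean +/- 4 SD, with mean and SD computed on all rows
(population divisor). Surviving columns are centered and scaled to
unit population variance; the population divisor (n, not n-1) makes
trace(G)/J and trace(Omega)/rows equal 1 exactly.

## Sampler

Each term is reparameterized through its kernel factor, u = B alpha
with alpha ~ N(0, I sigma2_t); eigenpairs below 1e-8 of the largest
eigenvalue are truncated (numerical rank control). Per Gibbs sweep,
each term's coefficient block is updated jointly: with
B'B = U D U' precomputed once per fit, the rotated coefficients have a
diagonal-precision Gaussian full conditional, so one block update costs
two matrix-vector products. Variances are drawn from conjugate
scaled-inverse-chi-square full conditionals
(S_t + alpha'alpha) / chi2(df_t + rank_t), the residual analogously
over observed records, and the intercept from its flat-prior Gaussian
conditional.

Priors follow the convention of Bayesian genomic-prediction software:
df = 5 for every variance, and scales set by an R-squared partition in
which the residual receives half the response variance and the
remainder is split equally among the random terms,
S = var(y) * R2 * (df + 2), putting each prior mode at its partitioned
share. Sampler defaults are 12,000 iterations, 2,000 burn-in, thinning
5; short exploratory chains are adequate for prediction tasks, long
chains are advisable for variance reporting. Point estimates are
posterior means throughout.

Records with a missing response are excluded from the likelihood and
their linear predictors accumulated as predictions — the single
mechanism serving both cross-validation designs. Correctness of the
sampler is checked against the closed-form generalized-least-squares /
BLUP solution with fixed variances (agreement to < 0.02 mean absolute
error at 20,000 draws) and by single-kernel variance recovery within
posterior uncertainty.

## Variance reporting

Because the environment main effect is a nuisance when the question is
ranking lines within environments, each fitted component (including
the residual) is reported as a percentage of the total variance minus
the E variance, to one decimal; percentages sum to 100 +/- rounding.

## Cross-validation and accuracy

CV1 assigns whole lines to folds (held-out lines have no record
anywhere: the new-variety problem); CV2 assigns individual records
(the incomplete-trial problem). Units are shuffled by seed and dealt
round-robin, so fold sizes differ by at most one; ten folds by
default. The same partition serves every model in a run.

The target of prediction is within-environment performance: records
and predictions are both corrected by the comprehensive model's
environment-level prediction for the same fold,
eta_ij = mu + E_i + w_ij (posterior means). The intercept is included
in eta deliberately: it is fold-specific (each fold's training mean
shifts with the held-out units), and leaving it in the predictions
injects a shared cross-fold artifact that produces a spurious nonzero
pooled correlation even when markers and ECs carry no signal; since a
truly constant offset cannot affect a Pearson correlation, including
mu in eta removes the artifact and nothing else. With it, the CV1
correlation of the `EL` model on null data is statistically
indistinguishable from zero, as theory demands.

Accuracy is the Pearson correlation of the pooled corrected vectors
(not a per-fold average), with two 95 % intervals: the large-sample
formula rho +/- 1.96 sqrt((1 - rho^2)/(n - 2)) with n the pooled record
count, and a percentile bootstrap resampling record pairs 10,000 times
(degenerate resamples are redrawn and counted). The percentile grid
cuts both vectors into four classes at their own empirical 20/50/80
percentiles — ties broken by stable ordinal rank — and reports the
conditional distribution of observed classes given predicted classes;
columns sum to one.

## Synthetic trial networks

The generator draws from exactly the process the comprehensive model
assumes: markers Binomial(2, theta_m) with theta_m ~ U(0.1, 0.5)
(monomorphic columns redrawn), environment-level ECs Gaussian with
AR(1) correlation 0.3 across covariates, kernels rebuilt from the QC'd
tables exactly as in an analysis run, and every effect drawn through
the kernel's eigenfactorization. Interaction effects are drawn from
the Hadamard-product covariance directly (exact and simple); the
product-of-two-scores construction — identical covariance,
non-Gaussian draws — is available as `interaction_mode="scores"` for
cross-checks. The phenotype equals the sum of stored components
exactly, which `truth_check` verifies along with realized-vs-nominal
component variances.

Default conditions mirror a wheat grain-yield trial network at desk
scale: 60 lines, 30 environments, 2 replicates, 500 markers, 20 ECs,
trait mean 92.5 quintals/ha, and a variance profile in which the
environment effect dominates (sigma2 = 148.6), marker and EC main
effects are moderate (12.7, 19.8), interactions smaller (GxW 5.0,
GxE 3.9) and the residual is 14.9. What the generator does **not**
emulate: linkage disequilibrium (markers are independent, so genomic
relationships between simulated lines are weaker than in real breeding
panels and CV1 accuracies are conservative), selection or population
structure, EC derivation from weather series, and non-Gaussian trait
noise. Passing tests on these simulations therefore validate the
machinery and its statistical properties, not field performance.

## Numerical choices and limitations

* Kernels are validated on construction: symmetry to 1e-10 and minimum
  eigenvalue >= -1e-8 times the maximum (Gram matrices should be PSD;
  true negatives indicate a construction bug and raise rather than
  being clipped).
* Record ordering is the phenotype-table order everywhere; record
  labels are carried by kernels and checked in Hadamard products.
* Eigen-truncation threshold 1e-8 (relative) in all factorizations.
* The explicit-contrast oracle refuses above 200,000 contrasts by
  default (memory guard); it exists for testing, not analysis.
* **Environment-level identifiability.** The E and W variances are
  both environment-level quantities and must be separated from as many
  observations as there are environments. With a few dozen
  environments the realized variance of a single EC-kernel draw
  deviates from its nominal value by 50 % or more routinely, and the
  weakly identified sigma2_W is attracted toward its prior mean. At
  the default simulation scale (30 environments) the comprehensive
  model recovers G, GxW, GxE and the residual well, E with moderate
  shrinkage, and W poorly — a property of the design dimension, not of
  the estimator; the corresponding recovery test documents this and
  fails on the W component. Reliable separation of E from W needs
  environment counts in the hundreds, as in the real networks this
  methodology targets.
* Test and acceptance runs use deliberately scaled-down networks
  (hundreds to a few thousand records, chains of 1,500-12,000
  iterations), chosen as the package's own compromise between
  statistical resolution and turnaround.
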