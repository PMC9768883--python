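# Methods

## The problem

Region-averaged cortical thickness (one value per atlas region, in mm) is
spatially dependent: neighbouring regions on the cortical sheet co-vary, and
distant but functionally coupled regions co-vary too.  Comparing patient
groups region by region ignores that structure and inflates type-I error,
while a full 68x68 residual covariance is poorly identified from a few dozen
subjects.  `corticospec` implements a fully Bayesian spectral compromise:
project the data onto spherical harmonics, model the residual covariance
with a small parametric family (nugget + Matérn plus optional low-frequency
subject random effects), and let spatially varying covariate effects be
estimated jointly with that covariance.

## Spatial model

For subject i at region centroid v on the unit sphere,

    Y_i(v) = sum_{k=0}^{p} X_ik B_k(v) + sum_{j=1}^{J} Z_j(v) gamma_ij + E_i(v)

* `X_i` — intercept, centred age (years), male sex, and two diagnosis
  dummies (left and right temporal-lobe epilepsy; healthy controls are the
  baseline).
* `B_k(v)` — spatially varying coefficient surfaces (mm per covariate unit).
* `Z_j` — the first J real spherical-harmonic basis functions;
  `gamma_i ~ N(0, Sigma)` are subject-level amplitudes giving long-range,
  nonstationary residual covariance.
* `E_i` — small-scale residual, mean-zero Gaussian with

      Cov[E(v), E(v')] = sigma^2 1(v = v') + tau^2 M_nu(3 d(v,v') / phi),

  `M_nu` the Matérn correlation with the modified Bessel function of the
  second kind, `d` the **chordal** distance between unit vectors (chordal
  guarantees positive definiteness for every smoothness nu), and the factor
  `3/phi` making `phi` a range: correlation ~0.05 at distance `phi` when
  nu = 1/2.

## Spectral transform

The basis columns are real spherical harmonics, ordered by degree l, then
order m (real part before imaginary part), with three scalings:

* `sqrt(2)` on the m > 0 real/imaginary pairs, so the real representation is
  an isometry of the conjugate-symmetric complex coefficients;
* the Schmidt semi-normalisation `sqrt((l-m)!/(l+m)!)` on m > 0 — without
  it the unnormalised `P_l^m` spread over nine orders of magnitude by
  l = m = 7, destroying both the conditioning of the transform and the
  premise that coefficient variances depend only on the degree;
* `1/sqrt(2l+1)` from the truncated expansion, so the (0,0) column is
  identically 1 and a constant field has its value as the single
  coefficient.

At L = 7 the 68 regions map to exactly (7+1)^2 = 64 real coefficients.  The
forward transform is a least-squares fit at the scattered centroids; when
the evaluation matrix is rank-deficient or has condition number above 1e10
a ridge of `1e-8 * trace(A'A)/cols` is added, otherwise the solve is exact,
which keeps the forward/inverse round trip at machine precision on
general-position points.  All 68 regions live on a single sphere with
left-hemisphere centroids at longitudes [0, pi) and right at [pi, 2pi); a
per-hemisphere two-sphere layout would be equally defensible but the joint
68 -> 64 reduction requires the single sphere.

## Spectral-domain likelihood and the residual variance profile

After the transform the model treats coefficients as independent across
frequencies omega, with the random-effect term present only on the retained
set L (the first J columns, where `Z~` restricted to L is the identity):

    Y~_i(omega) ~ N( sum_k X_ik B~_k(omega) + [omega in L] gamma_i,omega ,
                     lambda_res(omega) )

Two variance families appear:

* **Latent coefficient surfaces** `B~_k(omega)` use the degree-only Matérn
  spectral density

      lambda(l | theta_k) = sigma_k^2 + tau_k^2 * c * (alpha^2 + l(l+1))^-(nu_k+1),

  alpha = 3/phi_k, with c normalising the discrete spectrum
  `sum_l (2l+1) c (...) = 1` over degrees 0..50 so that the spatial-variance
  parameter keeps its units.  This acts as a smoothness prior: high-degree
  coefficients of the coefficient surfaces are shrunk hard.

* **Residuals** live in the spatial domain and pass through the same
  least-squares transform as the data, so their spectral variance is taken
  as the exact diagonal of the propagated covariance,

      lambda_res(omega) = v * [ (1-p) w_omega + p s_omega(phi, nu) ],

  with `w = diag(A+ A+')` (the nugget propagation, `A+` the transform
  pseudo-inverse) and `s = diag(A+ R(phi, nu) A+')`.  "Independent"
  residual structure means independent in the spatial domain and reduces to
  `v * w`.  This choice matters: at 68 scattered centroids the transform has
  condition number ~1.5e3 and the true spectral residual variance is
  hump-shaped in degree (three orders of magnitude between l = 0 and
  l = 5).  A degree-only monotone density cannot represent that; fitted
  that way, the sampler absorbs transform-amplified noise into the
  coefficient surfaces and the spatial credible intervals balloon to
  1-2 mm for 0.15 mm effects.  With the propagated diagonal the intervals
  are honest (~0.15 mm) and frequentist coverage of the 90% intervals sits
  at the nominal rate.  The off-diagonal covariance induced by the
  transform is still neglected; that approximation is the price of the
  per-frequency factorised likelihood.

## Priors

With epsilon = 0.1 throughout:

* `B~_k(omega) ~ N(beta_k,omega, lambda(omega | theta_k))` on the retained
  set (prior mean 0 off it); the intercept's prior means have
  `beta_0j ~ N(0, delta_0^2)`, `delta_0^2 ~ InvGamma(eps, eps)`.
* Slope prior means: Gaussian option `beta_kj ~ N(0, delta_k^2)`;
  horseshoe option `beta_kj ~ N(0, delta_kj^2)`,
  `delta_kj ~ half-Cauchy(delta_k)` via the inverse-gamma scale-mixture
  augmentation so every update stays conjugate.
* `Sigma ~ InvWishart(J + eps, (nu3/(J+eps)) I_J)`; the scale parameter nu3
  gets its own InvGamma(eps, eps) hyperprior.  Its full conditional is a
  generalized inverse Gaussian and is sampled exactly
  (`scipy.stats.geninvgauss`).
* Matérn blocks (residual theta; intercept process theta_0; one shared
  slope process theta_1): total variance ~ InvGamma(eps, eps) (conjugate);
  spatial-proportion logit r ~ N(0, 1); log range ~ N(0, 1/eps^2);
  log smoothness ~ N(-2, 1).

The three-block structure (one residual, one intercept-process, one shared
slope-process) mirrors the three subscript families in the prior stack.
The nonstationary flag removes both nonstationary components together —
the random effects gamma and the `Z~ beta` prior-mean term — which keeps
the stationary configuration fully conjugate and lets the
frozen-variance configuration be checked against its exact closed-form
posterior.

## Sampler

Gibbs updates in closed form for: the per-column coefficient vectors
(joint multivariate-normal across covariates), the random effects (one
shared precision across subjects), Sigma (inverse-Wishart via Bartlett),
nu3 (GIG), all beta and variance scales, and each block's total variance.
The (r, log phi, log nu) triples use joint Gaussian random-walk Metropolis,
step size adapted every 50 burn-in iterations toward 25-45% acceptance and
frozen afterwards (adaptation only during burn-in preserves ergodicity).
Proposals whose spectral profile overflows to non-finite values are
rejected outright.  Retained draws number exactly
`(iterations - burn_in) // thinning`; identical configs and seeds give
bit-identical output.  The desk default is 5,000/1,000/4; the published
schedule (100,000/10,000/10) ships as the `paper` preset.

Degenerate inputs: a non-PD inverse-Wishart draw is retried with a logged
jitter; zero posterior sd at any region raises an error naming the region;
a non-finite data value aborts before sampling.

## Inference outputs

Posterior z-scores are the ratio of posterior mean to posterior sd of each
coefficient surface, region by region, after inverse-transforming every
retained draw.  For group contrasts the hypotheses are one-sided
("thinning"): H0 B_k(v) >= 0 vs H1 B_k(v) < 0; the posterior null
probability is the fraction of retained draws >= 0.  The Bayesian FDR rule
sorts regions by null probability and rejects the largest prefix whose
running mean stays at or below q (default 0.01), reporting the largest
z-score among rejected regions as the data-dependent threshold.  On null
simulations the realised false-rejection rate (falsely rejected regions out
of 68) sits at the target q within Monte-Carlo noise; the
false-discovery proportion among rejected regions is controlled in
posterior expectation, not per dataset, so occasional null datasets with a
handful of rejections are expected.

## Model comparison

Leave-one-out cross-validation refits the model without each subject and
predicts their 68 regional values by the posterior predictive mean —
covariates times posterior-mean coefficient surfaces, random effects at
their prior mean of zero so nothing subject-specific leaks.  The grid
crosses residual structure x fixed-effect prior x nonstationary x
J in {4, 9}, 16 configurations in the published row order.

An empirical caution from our synthetic experiments: at desk scale
(10-40 subjects, 68 regions) the LOOCV differences between residual
structures are smaller than Monte-Carlo noise, and the nonstationary
configurations typically *lose* the comparison even on data generated with
strong random effects, because with `Z~` restricted to the retained set
each gamma_ij is informed by a single observation and is confounded with
the fixed-effect surfaces there.  The grid is therefore reported as a
descriptive experiment; treat small MSE differences as noise.

## Synthetic cohort generator

The generator is the package's study stand-in (the original MRI cohort is
not redistributable), reproducing the published design: 68 Desikan regions
(34 per hemisphere, Fibonacci-lattice centroids with seeded jitter,
minimum chordal separation > 0.05), 53 subjects in groups of 20/19/14 with
the published sex counts (10/10, 11/8, 10/4) and ages affinely matched to
the published group means and SDs (27.95 +/- 6.32, 32.10 +/- 8.47,
28.28 +/- 6.28) — which reproduces the published chi-square (1.56, df 2)
and ANOVA (F = 1.92, df 2, 50) exactly to print precision.

Default generative parameters, chosen once to resemble the published
thickness tables: baseline surface 2.7 mm with smooth low-degree variation
(published regional means run ~2.4-3.8 mm); age slope about -0.01 mm/year;
negligible sex effect; a left-TLE effect surface peaking at -0.15 mm over
cingulate/frontal targets and a right-TLE effect at the right entorhinal
area (published group differences are 0.02-0.16 mm); residual nugget sd
0.07 mm and Matérn sd 0.14 mm, range 0.5, smoothness 1 (regional SDs in
the published tables are 0.1-0.5 mm); random-effect sd 0.05 on the first
nine harmonics.

What the generator does **not** emulate: measurement pipeline artefacts
(segmentation errors, site effects), non-Gaussian heavy tails, disease
duration or seizure-frequency covariates, and any vertex-level structure
below the regional average.  Passing tests therefore demonstrate
correctness of the statistical machinery under the stated model, not
robustness to real-data violations of it.

## Validation battery and problem sizes

`corticospec.validation` (used by `tests/test_acceptance.py` and
`scripts/acceptance.py`) runs: the demographic worked examples; the
68 -> 64 spectral dimension; a Gibbs-vs-closed-form check (m = 20, 16
coefficients, frozen variances, 4,000 retained draws); coverage of 90%
credible intervals over 50 replicate cohorts (m = 40, 68 regions, 2,000
iterations per fit); Bayesian-FDR null calibration over 50 replicates
(m = 30); the Matérn sampling check (20,000 draws at 30 points, judged
with a multiplicity-aware criterion — 465 simultaneous covariance entries
make "every entry within 3 SE" fail by chance alone); the transform round
trip at 64 points; and classifier checks (the six-point AUC equals 2/3 by
pair enumeration, label-permutation null AUC near 0.5, LOOCV determinism).
These sizes keep the whole battery within minutes on one CPU while leaving
each check statistically meaningful.

## Known limitations

* The per-frequency factorised likelihood ignores off-diagonal covariance
  induced by the scattered-point transform; variances are exact on the
  diagonal only.
* The spectral density attributed to the original analysis is not printed
  in the source material; ours is the standard sphere SPDE analogue plus
  the transform propagation described above.
* Desk-scale schedules (a few thousand iterations) are adequate for the
  synthetic cohorts here; real analyses should use the `paper` preset and
  check acceptance rates and traces.
* LOOCV model ranking at these sample sizes is noise-dominated; see above.
* The MLP benchmark selects regions on the same data it classifies
  (as in the original design); its AUCs are optimistic and serve only to
  compare region-selection routes under identical conditions.
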