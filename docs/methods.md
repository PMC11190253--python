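# Methods

## Generating model

Each simulated study draws `n` subjects. Subject cell membership
(marker `M` in {0,1}, treatment `T` in {0,1}) is multinomial with
probabilities `(p_00, p_10, p_01, p_11)` determined uniquely by the marker
prevalence `p_M`, the treated fraction `p_T`, and the marker-treatment odds
ratio `OR_MT` via the Plackett construction: for `OR_MT != 1`, `p_11` is the
admissible root of

    OR_MT * (p_M - p_11) * (p_T - p_11) = p_11 * (1 - p_M - p_T + p_11),

and `p_11 = p_M * p_T` under independence. The construction is verified in
tests by round-tripping margins and odds ratio to 1e-8 over a random sweep.

Latent event times are exponential by inverse transform,

    t_e = -log(U) / (lambda_e * exp(bM*M + bT*T + bI*M*T)),   U ~ Uniform(0,1),

with the baseline rate calibrated so the cumulative baseline incidence by
the administrative horizon `t_end = 5` years equals `p_e`:
`lambda_e = -log(1 - p_e) / t_end`. Censoring times are exponential with
rate `lambda_c = -log(1 - p_c) / t_end` independent of `M` and `T`
(non-differential); `p_c = 0` means no random censoring (`t_c = +inf`).
A subject is an event at `t_e` if `t_e <= min(t_c, t_end)`, otherwise
censored at `min(t_c, t_end)`. Uniform draws are taken on the open unit
interval so all times are strictly positive; the only tied observed times
are administrative-censoring ties at `t_end`, which are unproblematic for
the partial likelihood (censored subjects remain in the risk set at their
censoring time).

Replicate streams: each (scenario, replicate) pair owns a PCG64 generator
seeded from `SeedSequence((master_seed, sha256(scenario_key)[:4],
replicate_index))`. Replicates are therefore bit-reproducible individually,
across processes, and independent of execution order. Draw order within a
replicate is fixed: cells, event uniforms, censoring uniforms.

Defaults follow the study conditions: `N = 10000` replicates per condition,
`p_T = 0.5`, `p_e = 0.2`, `t_end = 5`, `HR_T = 1` (qualitative
interactions), with the grid sweeping `n` in 200..1000, `p_M` in
{0.25, 0.5, 0.75}, `p_c` in {0.2, 0.5}, `OR_MT` in {0.5, 1, 2}, `HR_M` in
{0.6, 0.8, 1, 3, 6} and `HR_I` in {0.25, 0.5, 0.75, 1}. The five
study-derived presets carry the published design parameters unchanged.

## Eligibility and convergence accounting

A replicate with more than one empty marker-treatment *event* cell is
ineligible and never fitted (the eligibility rule counts events, not
subjects). Eligible replicates are fitted by both methods in both
parametrizations; every fit carries its own convergence flag. Summary
denominators:

- converged-only mode: `N_c` = eligible replicates whose fit converged; PL
  coverage additionally conditions on both profile bounds having converged,
  and PL power on a computable likelihood-ratio statistic at zero (both
  counts are reported separately).
- sensitivity mode: non-converged fits count as covering the truth and not
  rejecting, with denominator `N_eligible`.

## Estimation

The Cox partial log-likelihood uses Breslow risk sets (no event-time ties
occur under the generator, where Breslow and Efron coincide). The Firth
objective adds `0.5 * log det I(beta)`; its modified score uses the
analytic derivative of the information — per event with risk-set mean `m`
and covariance `V`,

    dV[b,c]/dbeta[a] = S3[a,b,c]/S0 - m[a]*S2[b,c]/S0 - V[a,b]*m[c] - m[b]*V[a,c],

where `S0, S1, S2, S3` are the eta-weighted risk-set moment sums. The
analytic form is validated against central finite differences in tests.

Solver: Newton–Raphson from `beta = 0`, at most `maxiter = 1000` iterations.
The increment is rescaled so its largest coordinate moves at most
`maxstep = 0.01`; rescaling (rather than clipping each coordinate
independently) preserves the ascent direction — coordinate-wise clipping
distorts the Newton direction, inflates iteration counts severalfold, and
spuriously flags slow-converging finite-MLE fits as non-converged. Because
the unpenalized information only approximates the penalized Hessian, a step
that fails to increase the objective is halved up to five times before being
accepted; without this the Firth iteration can oscillate around its optimum
indefinitely. A fit converges iff the maximum absolute (modified) score
drops below `tol = 1e-6` in fewer than `maxiter` iterations, so the
"iterations < maxiter" convergence convention coincides with score
convergence; a singular information matrix at any iterate flags
non-convergence (never an exception). Under monotone likelihood the
standard fit walks at most `maxiter * maxstep = 10` log-HR units and is
flagged non-converged; the Firth fit reaches its finite optimum.

Covariance is the inverse observed information at the final estimate (for
Firth fits too, as is conventional for penalized Cox models). Wald
intervals and p-values use the normal reference. Profile-likelihood bounds
are the roots of `2*[l*(b_hat) - l*_profile(b)] = chi2(1, 1-alpha)`, located
by outward geometric bracketing from the estimate (initial step = one SE)
and Brent root-finding to 1e-8 on `b`; a bound with no bracket within 50
log-HR units of the estimate, or whose inner profile maximization fails, is
flagged non-converged. The "PL" significance decision is the (penalized)
likelihood-ratio test of `bI = 0` against chi-square(1) — equivalent to
asking whether the PL interval excludes zero — with the null profile fit
started from zero like every primary fit. Inner profile fits during
bound root-finding warm-start from the outer solution; the profiled
objective is concave with a unique maximum, so this changes iteration
counts only, not values.

The subgroup parametrization is a unit-determinant linear recoding of the
interaction parametrization, so maximized partial likelihoods coincide and,
for the MPLE, `exp(b_high - b_low) = exp(bI)` exactly. The Firth penalty is
not reparametrization-invariant in general; for this particular recoding
`log det I` shifts by `2*log|det B| = 0`, so the two penalized fits agree up
to solver tolerance — tests report this agreement without asserting exact
invariance.

## Performance measures

Per coefficient and method: bias (absolute; relative in % when the truth is
nonzero — relative bias is never computed at truth zero), model SE
(root-mean of variance estimates) vs empirical SE (across-replicate SD,
divisor `N_c - 1`) summarized as `100*(ModSE/EmpSE - 1)`, coverage of 95%
Wald and PL intervals (closed intervals), and the rejection rate of the
`bI = 0` test at `alpha = 0.05` (`p <= alpha` rejects; labelled type I error
when `HR_I = 1`, power otherwise). Every rate carries a binomial
Monte-Carlo SE and the SE-ratio a leave-one-out jackknife SE, so
comparisons against published full-scale values can use the combined
`3*sqrt(se_ours^2 + se_published^2)` tolerance; near-boundary rates in such
comparisons floor `p(1-p)` at `1/(4n)` to keep tolerances positive.

## Problem sizes used in tests and reproduction runs

The published tables aggregate 10000 replicates per condition. The package
reproduces table cells at 2000 replicates (binomial MC SE about one
percentage point on a 50% rate), which is the default for
`scripts/acceptance.py` power targets; the convergence-count target runs the
full 10000 replicates. The null-calibration check uses 2000 replicates at
n = 2000, and large-sample parameter recovery averages 20 replicates of
n = 1e5 (the mean's MC SE, ~0.007 on the interaction coefficient, makes the
0.02 recovery tolerance a consistency check rather than a coin flip).
`analysis/` drivers default to 300–400 replicates with correspondingly wider
tolerances.

## What the generator does and does not emulate

It emulates: unbalanced and correlated marker-treatment allocation,
proportional-hazards effects on an exponential baseline, non-differential
random censoring calibrated to an observed censoring fraction, and
administrative end-of-study censoring. It does not emulate: non-exponential
baselines or time-varying effects, informative censoring, covariates beyond
`M` and `T` (no confounder adjustment, as in the emulated analyses),
staggered accrual, or measurement error in the marker. Passing tests
therefore certify the estimator and the Monte-Carlo machinery under these
idealized conditions, not robustness of the conclusions to violations of
them.

## Known limitations

- The multinomial cell construction follows the Plackett family; other
  copulas with the same margins/odds ratio would differ in higher-order
  structure (irrelevant here, since only cell probabilities enter).
- Profile bounds are declared non-converged beyond 50 log-HR units from the
  estimate; HRs beyond that range are numerically meaningless anyway.
- The convergence bookkeeping of a reference R implementation can differ at
  the margin (fits needing almost exactly the iteration budget); observed
  convergence fractions agree with published counts within Monte-Carlo
  tolerance but are not guaranteed replicate-for-replicate identical.
- No multiple-testing adjustment across scenarios; no figure generation.
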