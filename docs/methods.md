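# Methods

## Model

`leaky_telegraph` implements a two-state (telegraph) model of gene
expression with promoter leakage and auto-regulatory feedback.  The
promoter switches between two activity states D0 and D1, and a single
product species P is synthesized in *both* states:

    D0 --gamma1--> D1            D1 --gamma0--> D0
    D1 + P --f--> D0 + P         (catalytic feedback; P is not consumed)
    D1 --lambda1--> D1 + P       D0 --lambda0--> D0 + P
    P --d--> 0

Transcription and translation are collapsed into a single synthesis
step, which is the standard reduction when the protein lifetime is much
longer than the mRNA lifetime.  Which state is "ON" is set by the
synthesis rates: with `lambda1 >> lambda0`, D1 is ON, `lambda0` is the
leakage rate and the feedback (which pushes D1 toward D0 at rate `f`
per product molecule) is negative; with `lambda0 >> lambda1` the
labeling mirrors and the same reaction acts as positive feedback.  A
tie (`lambda1 == lambda0`, `f == 0`) is constitutive expression: the
promoter state is irrelevant and the stationary law is Poisson.

All analysis is done in time units of the product lifetime: every rate
is divided by `d` (`normalize`), so `d = 1` throughout.

## Stationary distribution (analytic path)

With the derived constants

    lam   = lambda1 - lambda0          R     = lam - f*lambda0
    Q     = R/(f+1)^2                  alpha = 1 + lam*gamma1/R
    beta  = 1 + (lam+gamma0+gamma1)/(f+1) - R/(f+1)^2
    g     = (lam+gamma1+gamma0)/gamma1 - R/(gamma1*(f+1))
    A     = exp(-lambda0) / (g * 1F1(alpha-1, beta-1; f*Q))

the stationary probability of n molecules is the finite binomial
mixture

    P(n) = (g*A/n!) * sum_{m=0}^n C(n,m) lambda0^(n-m) [(f+1)Q]^m
           * (alpha-1)_m/(beta-1)_m * 1F1(alpha+m-1, beta+m-1; -Q).

Numerical choices:

- **Log-space accumulation with sign tracking.**  The summand spans
  hundreds of orders of magnitude (`lambda0^(n-m)` with leakage up to
  ~40 and n up to a few hundred).  Binomials and Pochhammer ratios are
  accumulated as log-magnitude plus sign, combined per n with a signed
  log-sum-exp.  In the `lam > 0` regime every factor is positive once
  the 1F1 terms are routed through Kummer's transformation, so there
  is no cancellation across m and the result is accurate to ~1e-11 TV
  against the brute-force solver.
- **Stable 1F1.**  `hyp1f1_stable` evaluates Kummer's function to >= 10
  significant digits: negative arguments go through the transformation
  `1F1(a,b;-x) = exp(-x) 1F1(b-a,b;x)` (positive-term series when
  `b > a > 0`); arguments beyond |z| = 10, negative first parameters,
  or any nonfinite fixed-precision result fall back to mpmath at >= 40
  digits.  The pmf series always uses the arbitrary-precision signed-log
  route (`log_hyp1f1`).
- **Truncation.**  `n_max = ceil(mean + 10*sigma)` with a floor of 50,
  from the generating-function moments; this captures all but ~1e-8 of
  the mass in the regimes studied.  The pmf is renormalized after
  truncation and the pre-normalization residual recorded
  (`renorm_residual`); it is below 1e-6 for every supported regime.
- **Degenerate parameters.**  As `R -> 0`, alpha diverges; the analytic
  path is refused for `|R| <= 1e-10 * max(lambda1, lambda0, 1)` and
  callers are directed to the CME solver.  The constitutive case
  (`lambda1 == lambda0`, `f == 0`) bypasses the series and returns the
  Poisson closed form.
- **Positive-feedback regime (`lam < 0`).**  The domain of validity of
  the closed form is not established there, and the series alternates
  with catastrophic cancellation.  `stationary_pmf` computes both the
  analytic attempt and the CME solution, keeps the analytic result only
  if they agree to TV <= 1e-6, and otherwise returns the CME marginal
  (`source = "cme-fallback"`, logged).  The generating-function
  *moments*, by contrast, were verified to agree with the oracle to
  machine precision also for `lam < 0`, so `moments` stays analytic in
  every nondegenerate regime.

## Moments and noise

The factorial-moment derivatives of the generating function at z = 1,

    G'(1)  = lambda0 + lam * F2/(g*F1)
    G''(1) = [g*lambda0^2*F1 + 2*lam*lambda0*F2
              + lam*(lam*gamma1+R)/(lam+gamma1+gamma0+f+1-R/(1+f)) * F3]/(g*F1)

with `F1 = 1F1(alpha-1,beta-1;fQ)`, `F2 = 1F1(alpha,beta;fQ)`,
`F3 = 1F1(alpha+1,beta+1;fQ)`, give mean `<n> = G'(1)`, variance
`G''(1) + G'(1) - G'(1)^2` and noise intensity (squared coefficient of
variation) `eta^2 = var/<n>^2`.  The prefactor `A*exp(lambda0)` cancels
algebraically and is never formed in floating point.  At `f = 0` all
F's are 1 and the mean reduces exactly to the occupancy-weighted
synthesis rate `(lambda0*gamma0 + lambda1*gamma1)/(gamma0+gamma1)`.

## Brute-force oracle (truncated CME)

The chemical master equation on `{(D0,n),(D1,n) : 0 <= n <= N}` with
*reflecting* truncation (synthesis suppressed out of n = N) is a proper
stochastic generator, so its null space is a probability vector.  It is
found by replacing one balance row with the normalization constraint
and doing a sparse direct solve -- deterministic and exact to solver
tolerance, with no eigen-iteration.  N starts at
`max(50, ceil(nu + 10*sqrt(nu)))`, `nu = max(lambda0, lambda1)` (an
upper bound on the mean), and doubles (at most three times) until the
boundary mass is below 1e-8.  This solver is implemented independently
of the analytic path and is the ground truth for every analytic result,
including the `lam < 0` routing above.

## Stochastic simulation

Exact Gillespie direct method (numba-compiled), recording each event's
time, promoter state, copy number and reaction channel; runs are
bit-reproducible from their seed.  The chain starts at (D0, n = 0) and
estimators discard a default burn-in of 10% of the horizon; the default
horizon is 1e5 lifetimes.  Stationary histograms weight each copy-number
level by occupancy *time*, not event counts.

Two refined schemes probe the model's simplifying assumptions:

- **slow_binding** makes the feedback transition pass through an
  explicit TF-DNA complex: `D1 + P -> D0B` at `f` per molecule
  sequesters one product molecule, and `D0B -> D0 + P` releases it at
  `k_off` (default 10).  The complex transcribes at the leak rate, and
  spontaneous gamma0/gamma1 switching is untouched.  This construction
  was chosen so that the fast-dissociation limit provably collapses to
  the baseline network (the sequestered interval vanishes), which is
  verified as a test at `k_off = 500`.
- **two_stage** resolves transcription and translation:
  `Ds -> Ds + M` at `lambda_s`, `M -> M + P` at `k_p`, `M -> 0` at
  `d_m`, with feedback carried by the protein.  Defaults `d_m = 5`,
  `k_p = 5` (in units of `d`) encode an mRNA turning over five times
  faster than the protein with a translational burst size of one, which
  keeps the mean protein level comparable to the baseline model.

Both variants are checked qualitatively only (noise reduction and
unimodalization under increasing leakage, fast-binding reduction); their
quantitative behavior depends on `k_off`, `k_p`, `d_m`, which are
exposed, not fitted.

## Burst kinetics

Bursts are delimited by the promoter state: a burst is one complete ON
dwell period, its size the number of synthesis events fired during it
(counted from the reaction-channel log, so interleaved degradation does
not bias it), and `<BF> = 1/tau_OFF`, `<BS> = k_transcription*tau_ON`.
Incomplete first/last dwell intervals are discarded.  Without feedback
the dwells are exponential and the closed forms are `<BF> = gamma1`,
`<BS> = lambda1/gamma0` (D1 ON) or the gamma0/gamma1-mirrored pair
(D0 ON); `theoretical_burst` refuses `f != 0`, where no closed form
holds and only the empirical estimator applies.  Estimators require at
least 10 complete ON periods.

## Mode counting

A mode is a strict local maximum of the pmf (support boundaries count),
after discarding indices below `1e-4` of the peak mass -- suppressing
spurious tail modes from floating-point ripple -- and merging plateaus
that agree within `1e-12`, reported at their leftmost index (so
Poisson(5), with P(4) = P(5), has one mode at 4).  Since no formal peak
definition is canonical, this convention is committed and deterministic.
In the `lam < 0` regime mode counting always runs on the oracle-routed
pmf, never on an unvalidated analytic series.

## Scans

- **Noise vs. leakage** (free or fixed mean).  In fixed-mean mode a
  compensating parameter (`gamma1` down, `gamma0` up, `f` up, or the
  majority synthesis rate down) is re-solved at each grid point by
  bracketed Brent root finding on the analytic mean (1e-8 relative on
  the achieved mean); the fixed mean defaults to the base set's mean at
  zero leakage, making the scan origin the common anchor of all four
  compensation curves.  Infeasible points (no nonnegative compensating
  value reaches the target) are recorded as gaps, not errors.  Every
  10th analytic row is re-verified against the CME oracle at 1e-6
  relative tolerance.
- **Modality vs. leakage** reports the mode count and locations per
  grid point, with the computation path flagged.
- **Burst vs. leakage** aggregates the empirical burst statistics over
  independent seeds (default 8) with standard errors across seeds;
  trend statements use endpoint differences against 3-s.e. bands, with
  no multiple-testing correction (the scans are exploratory and
  documented as such).

## Problem sizes and reproducibility

Default experiment sizes -- simulation horizon 1e5 lifetimes for
histogram comparisons, 2e4 lifetimes and 4-8 seeds per point for burst
scans, 20-50 point leakage grids -- were chosen so each run gives
thousands of effective samples (TV sampling error well below the 0.02
comparison threshold; thousands of complete bursts per point) while a
full scan completes in seconds.  All randomness flows from explicit
integer seeds; identical seeds give bit-identical trajectories and scan
tables.

## Known limitations

- The closed-form distribution is only used where it is validated
  against the oracle; in the positive-feedback labeling it is, in
  practice, always replaced by the oracle result.
- Time-dependent distributions, multi-state promoters (> 2 states),
  mRNA-protein joint laws, parameter inference from data and
  tau-leaping/hybrid acceleration are out of scope.
- Mode claims are made on analytic/oracle pmfs only; simulated
  histograms are not smoothed for mode counting.
- The synthetic trajectories emulate a well-mixed single cell with
  constant rates; extrinsic noise, cell division and dosage effects are
  not modeled, so tests passing here speak to the mathematics of the
  model, not to any particular experimental system.
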