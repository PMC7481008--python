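# Methods

This note documents the statistical models implemented in `mdinfer`,
the numerical choices behind them, what the synthetic-data generators do
and do not emulate, and the known limitations.

## Bayesian single-exponential kinetics

A set of trajectories started from one configuration is modelled as a
homogeneous Poisson process: each trajectory waits an Exp(k) time before
transitioning, and a trajectory of length `T` that never transitions is
a right-censored observation (type-I censoring, exactly at the fixed
trajectory length).  The likelihood depends on the data only through the
sufficient statistics `n` (observed transitions) and `Θ` (total
exposure: event times of transitioning trajectories plus full lengths of
censored ones): `l(k|D) = k^n e^{-kΘ}`.

Posteriors are kept analytic as Gamma distributions — Gamma(n+1, Θ) for
the uniform prior, Gamma(n, Θ) for the Jeffreys prior `p(k) ∝ 1/k` —
rather than on a grid; grids would only be needed for plotting.  The
Jeffreys posterior is improper at `n = 0` and the constructor refuses
it, directing the caller to the uniform prior, which supports inference
with zero observed events.  Credible intervals are central equal-tailed
by default; a highest-posterior-density variant is available
(`method="hpd"`), and for shape ≤ 1 the HPD interval is the one-sided
`[0, q_level]`.

### Model comparison

The odds ratio for "two distinct rate processes generated datasets 1
and 2" versus "one shared process" is the closed-form marginal-
likelihood ratio

```
BF = (2/π) · (n/Θ) / (n₁²/Θ₁² + n₂²/Θ₂²)
     · (n₁! n₂! / n!) · Θ^{n+1} / (Θ₁^{n₁+1} Θ₂^{n₂+1})
```

with `n = n₁+n₂`, `Θ = Θ₁+Θ₂`.  It is evaluated in log space with
log-Gamma functions in place of factorials, so large counts cannot
overflow, and it is symmetric under swapping the datasets.  Either
dataset may contain zero events (the uniform-prior branch); the ratio is
undefined only when no events exist at all.  Interpretation follows the
Jeffreys scale with thresholds 1/3 and 3.

## Frequentist kinetics

The survival curve is the simple censored survival fraction (no
Kaplan–Meier machinery: with fixed-length runs the at-risk set only
changes at events).  The exponential time constant comes from nonlinear
least squares of `exp(-t/τ)` against the curve, evaluated at plotting
positions `1 − (i−½)/N` so the last event does not pin the curve at
exactly zero, which no exponential can reach.  The censored maximum-
likelihood estimate `τ̂ = Θ/n` is always computed alongside, and the fit
is flagged when the two disagree by more than two approximate standard
errors (`τ/√n`).  The half-life is `t½ = τ ln 2` identically.

Bootstrap SEs resample trajectories with replacement (default 1000
resamples); resamples without any event cannot be fit and are redrawn
and counted, and when the redraw fraction exceeds its budget (default
one half) the routine refuses and recommends the Bayesian estimator —
the frequentist fit has no answer for event-free data.

`rate_vs_sample_size` draws subsets *without* replacement within a
resample, independently across resamples, estimates `τ̂ = Θ/n` per
subset, and fits the log–log slope of the SE against the subset size.
For i.i.d. transition-time pools the slope is −1/2; a small residual
steepening (≈ −0.51) arises from subsetting a finite pool without
replacement (the finite-population correction shrinks the SE at the
largest subset sizes).  Heavily censored pools steepen the slope further
at small N because the ratio estimator `Θ/n` inherits variance from the
random event count.

Endstate classification uses strict proximity; ties count as "no
transition", the conservative choice for a transition census.
Conclusion-pattern probabilities are products of per-condition empirical
transition frequencies (or of one pooled frequency under the shared-
probability hypothesis); the `2^B` probabilities sum to one by
construction.  Whether a product-of-frequencies model exactly describes
any particular historical tally is not knowable from the tally itself;
the model is the natural one for "draw one trajectory per condition
independently" and is documented as such.

## Free energies from work values

Sign convention: the forward work drives A→B, the reverse work drives
B→A, so a consistent pair has `W_f ≈ +ΔG`, `W_r ≈ −ΔG`.  The estimator
solves the Bennett acceptance-ratio equation — the maximum-likelihood
estimator implied by the Crooks fluctuation theorem —

```
Σ_F f(M + β(W_f − ΔG)) = Σ_R f(−M + β(W_r + ΔG)),   M = ln(n_F/n_R)
```

with `f` the logistic function, by bracketed Brent root finding
(expanding the bracket until a sign change; tolerance 1e-12).  The
equation is monotone in ΔG, so the root is unique.  Standard errors are
bootstrap over work values (default 1000 resamples, both directions
resampled independently).  When the forward and mirrored-reverse work
distributions are separated by more than 50 kT the estimate carries a
low-overlap flag: the equation still has a root, but it is dominated by
the extreme tails and should not be trusted.

## Potentials of mean force from umbrella sampling

Windows hold a reaction-coordinate series under a harmonic restraint
`½K(x−c)²` (K in kJ/mol per squared coordinate unit) and an optional
leading equilibration fraction to discard.  The unrestrained part of the
potential is common to all windows and cancels from the reweighting
denominators, so only the biases enter.  The window free energies solve
the standard multistate self-consistency; numerically the solver
iterates the fixed-point update and switches to damped Newton steps on
the convex multistate objective (the Hessian is a K×K matrix, cheap for
tens of windows), stopping when the largest relative change of any
window free energy per fixed-point sweep falls below 1e-8 (at most 10⁴
iterations; non-convergence raises with the residual).  Boltzmann
factors are computed once with a per-sample offset so no entry can
under- or overflow, making each sweep a single matrix–vector product.

The PMF is `−kT log` of the unbiased-weight histogram, by default on 50
uniform bins.  Two guards protect the histogram: bins visited by fewer
than 10 raw samples are dropped, and the default coordinate range stops
two restrained standard deviations beyond the outermost window centers.
Both address the same pathology: outside the windowed region the
unbiased weights grow like `exp(+bias)`, so a near-empty edge bin can
acquire a strongly downward-biased free energy, and the min-zero
alignment would then shift the entire profile by that one bin's error.
An explicit `coord_range` and `min_bin_count` override both defaults.
Profiles are aligned so the minimum bin is exactly zero.

Bin standard errors are relative to the reference (minimum) bin and
come from ten contiguous block replicates of every window's series —
blocks much longer than the sampler's correlation time act as
near-independent repeats and automatically include the reference-bin
covariance.  Bins that too few blocks visit fall back to a multinomial
counting error with the effective sample count deflated by the windows'
mean statistical inefficiency.  A flat profile aligned to min-zero sits
at its noise floor by construction, so flatness checks in the test suite
measure deviation about the profile's mean level, not about zero.

Periodic coordinates (dihedrals) are supported via a `periodic` flag
that applies minimum-image distances in the bias and the binning;
default non-periodic.  `profile_convergence` re-estimates the profile
from leading data fractions; its per-fraction errors come from disjoint
contiguous blocks within the fraction, standing in for the independent
repeats a production study would use.  `neighbor_overlap` reports the
shared histogram area of adjacent windows; values of 0.3 and above
indicate comfortable overlap for the reweighting.

## Autocorrelation and replicate statistics

The ACF uses the FFT-based estimator; the integrated autocorrelation
time truncates the sum at the first non-positive value (initial-positive-
sequence style), giving `τ_int = ½ + Σρ` in sampling-interval units and
`g = 2τ_int`.  A fixed-lag truncation can be had by choosing `max_lag`.
Constant series are rejected rather than returning 0/0.

Replicate summaries report mean, `SE = SD/√n` and a confidence interval
using the Student-t quantile by default; a normal-quantile variant is
provided for comparison with conventions that assume normality from a
handful of repeats (at n = 3 the t interval is substantially wider — the
honest choice).  Single values are refused with an explicit "N = 1"
message: one number has no error bar.  The trend test across ordered
conditions combines per-condition CIs, a one-way ANOVA, and the
least-squares slope of value versus condition index; a trend is declared
only when the slope CI excludes zero, and any single-replicate condition
causes refusal.

## Solvent observables

MSD uses the FFT decomposition of the time-origin-averaged squared
displacement, averaged over particles, with D from the least-squares
slope over 10–50% of the maximal lag by default (short lags are
ballistic-free here but the window avoids the poorly averaged long-lag
tail; it is configurable and reported).  Chunked estimates (default 5
chunks) give a spread.  Wrapped coordinates are refused outright when a
single-step displacement exceeds half the box — no unwrapping heuristic
is applied; unwrapping is the caller's responsibility.

The finite-size correction is `ξ k_B T/(6πηL)` with ξ = 2.837297 for a
cubic box; `k_B` is fixed at 1.380649e-23 J/K and conversions are
centralized, with D reported in nm²/ps and convertible to 10⁻⁵ cm²/s.
The box-size extrapolation is the stated simple weighted average of
uncorrected coefficients — deliberately approximate, as documented in
its docstring.

RDFs divide shell-binned pair counts by the shell volume and a reference
density computed over an explicit normalization volume (the box, or a
sphere of fixed radius — default 4.25 nm — which makes differently sized
boxes comparable) minus an explicit excluded volume.  Because the
normalization enters as a pure prefactor, mis-stating the excluded
volume rescales g(r) by exactly `(V − v_stated)/(V − v_true)`; the
ideal-gas and excluded-sphere generators make both directions of that
identity testable.

## Synthetic data: what it emulates

Each generator draws from the closed-form model its estimator assumes:
exponential waiting times with type-I censoring; Gaussian work pairs
offset by the dissipated work `βσ²/2` so the Crooks relation holds
exactly with crossing at the true ΔG; Metropolis Monte Carlo Boltzmann
samples of a quartic double well `U(x) = a(x²−1)²` (barrier `a` in kT,
wells at ±1 — the minimal two-conformer model) under harmonic
restraints, with step sizes adapted toward 40% acceptance during a 10%
burn-in that is then discarded; stationary AR(1) series; independent
Gaussian random walks in a periodic box (per-step variance `2D·dt` per
dimension, wrapped and unwrapped coordinates both emitted); Poisson-
number uniform point configurations with a central excluded sphere; and
i.i.d. Gaussian replicate values.  Default study conditions follow the
documented designs: 1 µs trajectory censoring, 20-replicate ΔG designs,
13 windows with ≈ 0.25-unit restrained widths over [−1.5, 1.5], 1000
bootstrap resamples, 95% intervals, 4.25 nm RDF normalization radius.

What passing these tests shows is that the estimators are correct for
data matching their model assumptions, at realistic sizes.  What it
does not show: robustness to multi-exponential kinetics, to
non-Gaussian (e.g. bimodal) work distributions, to reaction coordinates
with hidden orthogonal slow modes, to anomalous diffusion, or to force-
field error — none of which the generators emulate, and the first three
of which are the common failure modes in real applications.

Reproducibility: every generator consumes a single integer seed through
one `numpy` Generator and draws vectorized, so outputs are byte-stable
across runs and independent of any iteration order.

## Known limitations

- Rates are reported in the dataset's declared time unit; no unit
  conversion is ever silent (pooling datasets with different units is an
  error).
- The PMF bin errors are replicate-style approximations, not the full
  asymptotic multistate covariance; for few windows with poor overlap
  they can be optimistic.
- The bootstrap half-life SE inherits the survival-fit's bias at very
  small `n`; the module points to the Bayesian estimator whenever
  resampling starts failing.
- The MC umbrella sampler is exact for the 1-D model potential but is
  not a stand-in for molecular sampling problems (no metastability
  beyond the double well, no kinetic trapping across windows).
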