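# Methods

## The model

`greymarkov` fits short, strictly positive annual incidence series — the
motivating case is a rural maternal mortality rate (MMR, deaths per 100,000
live births) declining over roughly a decade — with the grey model GM(1,1)
and two extensions: a metabolic (rolling-window) refit chain and a
Markov-chain correction of the fluctuation around the grey trend.

### GM(1,1)

Given x(0)(1..n), the accumulated generating operation (AGO) forms
x(1)(k) = Σ_{i≤k} x(0)(i).  The whitenization equation

    dx(1)/dt + a·x(1) = u

has the time response

    x̂(1)(k+1) = (x(0)(1) − u/a)·e^{−ak} + u/a,

and inverse AGO (first differences) returns fitted values x̂(0) on the
original scale, with x̂(0)(1) = x(0)(1) by construction.  The developing
coefficient `a` and control variable `u` are estimated by ordinary least
squares on the grey difference equation x(0)(k) + a·z(1)(k) = u, k = 2..n,
where z(1)(k) is the mean of adjacent AGO values — design rows
[−z(1)(k), 1], response x(0)(k).  This is the universal GM(1,1) estimation
convention; the estimate is computed with `numpy.linalg.lstsq` and is
cross-checked in the tests against a hand-written closed-form 2×2
normal-equations solve.

Assumptions: the level series is positive and roughly exponential-plus-
constant; n is small (the model is designed for n ≈ 10); there are no
covariates.  |a| classifies how far ahead the model may be trusted
(defaults: ≤ 0.3 medium-long-term, ≤ 0.5 short-term, ≤ 1 caution, > 1
unsuitable; configurable).

Numerical choices: for |a| < 1e−8 the time response uses its analytic
linear limit x(0)(1) + u·k, so a constant series is fitted exactly (a = 0,
u = c) without dividing by a.  Fitting requires n ≥ 4 (two parameters from
n − 1 equations plus two residual degrees of freedom).  Indexing is 1-based
over the fitting window; calendar years are carried as labels only.

A caveat worth knowing: OLS on data generated from the *continuous* time
response recovers `a` only up to an O(a²) discretisation bias (≈ 0.05%
relative at a ≈ 0.08), because the difference equation and the exponential
solution are not identical at unit steps.  Data satisfying the difference
equation exactly refit to machine precision; the tests exercise both.

### Metabolic chain

A metabolic step drops the window's oldest observation, appends a new value
— the actual observation or the model's own one-step forecast — and refits
from scratch.  The default seeds each step with the previous model's
forecast, so a chain can extend past the end of the data; the
`source="actual"` mode consumes observed values instead.  Both are exposed
and neither is privileged; the forecast-seeded mode is the default because
it is the self-contained construction.

### Markov correction

States are defined on the ratio y(k) = actual/fitted — not on |error| —
because the revision multiplies the grey forecast by a ratio-interval
midpoint, so the state space must bracket 1.  The partition is either K
equal-width intervals spanning the observed ratio range (default K = 3) or
user-supplied custom boundaries (how expert-chosen unequal intervals are
reproduced).  Intervals are lower-inclusive, upper-exclusive, last interval
closed; out-of-range ratios at forecast time are clamped to the nearest
state with a warning.

One-step transition probabilities are row-normalised pair counts; rows with
no observed transitions remain all-zero, are flagged, and fall back to the
marginal state frequencies when used as a forecast source.  m-step matrices
are matrix powers of the one-step matrix (Chapman–Kolmogorov), the dominant
grey–Markov convention; direct lag-m counting is available as
`m_step_method="empirical"`.

The Markov-property check is the likelihood-ratio chi-square statistic

    2·|Σ_ij f_ij·ln(p_ij / p_.j)|,   df = (K − 1)²,

with marginals p_.j taken as state frequencies over the whole sequence.
The summed quantity is non-negative by construction (each row's empirical
distribution maximises that row's log-likelihood), so the absolute value
guards rounding only.  A per-cell absolute value — a form that also
circulates in the applied literature — was deliberately not used: it makes
the statistic first-order in the deviations, so it grows like √n under
independence and rejects almost surely at moderate n, destroying the test's
size.  The implemented form holds its nominal level (empirical type-I
≈ 0.06 at alpha = 0.05, n = 50, K = 3, by simulation in the tests).
Rejection means consecutive states are dependent, i.e. the sequence is
*suitable* for Markov correction.

State forecasting takes the three most recent states with transfer steps
m = 1, 2, 3, sums the corresponding rows of P(m), and predicts the argmax
state; ties break toward the higher-index (larger-ratio) state and are
flagged.  The revision of a grey forecast x̂ with predicted state
[Q1, Q2] is 0.5·(Q1 + Q2)·x̂, which always lies in [Q1·x̂, Q2·x̂].

In-sample hybrid fitted values revise each window year's grey fitted value
by the midpoint of *its own* assigned state's interval — the natural
in-sample analogue of the forecast revision.  This is what the hybrid
ARE/C/P diagnostics are computed on.

### Diagnostics

Per-point relative error |actual − fitted|/actual and its mean (ARE);
post-test ratio C = sd(residuals)/sd(original); small-error probability
P = fraction of residual deviations from their mean below c·Sx.  Both
standard deviations are population (divide-by-n), the grey-theory
convention, applied consistently to numerator and denominator.  The
constant c defaults to 0.6745, the probable-error multiplier of the normal
distribution; 0.6475, a variant seen in print, can be passed explicitly and
is flagged in the report.  Grades combine C and P as the worse of the two
classes: good (C ≤ 0.35, P ≥ 0.95), qualified (≤ 0.50, ≥ 0.80), barely
qualified (≤ 0.65, ≥ 0.70), else unqualified; boundaries belong to the
better class.  ARE is computed on absolute relative errors.

## The synthetic generator

`GeneratorConfig` emulates the MMR study shape: n = 13 years from 2005,
initial rate x0 = 63.0, exponential decay 0.095/year toward a floor of
15.0, so the noise-free trend runs from 63.0 to about 20 — matching the
published endpoints of the real series, which is not redistributable and is
only partially printed.  Fluctuation is multiplicative on the ratio scale:
a hidden K-state Markov chain (default K = 3, stay-probability 0.5,
uniform moves otherwise) picks a ratio interval each year from K
equal-width intervals on [1 − K·σ, 1 + K·σ] (σ = `noise_sd`, default 0.02,
i.e. ratios within ±6%), and the observed value is trend × a uniform draw
from that interval.  Ratio-scale noise is chosen because the Markov
correction operates on actual/fitted ratios, giving the hybrid model a
recoverable structure.  The generator returns the true trend and hidden
states alongside the observations, so recovery tests need no external
oracle.

What the generator does *not* emulate: reporting artefacts,
re-classification of rural/urban areas over time, undercounting, or any
covariate structure.  Passing tests therefore demonstrate that the
machinery recovers the structure it assumes — exponential trend with
state-structured ratio fluctuation — not that real MMR series satisfy that
assumption.

Problem sizes used by the test-suite and the acceptance script — 10-year
fitting windows, 3-step chains, 200 replicates for distributional
properties, 2000 replicates of length-50 sequences for the test's size —
are chosen so every stochastic claim is a stable rate while the whole suite
runs in seconds.

## Design choices made where the design was open

- **Estimation method**: the OLS-on-difference-equation convention, stated
  explicitly since grey publications often omit it.
- **Sign convention**: the time response is written with e^{−ak} and `a`
  estimated directly; for a declining series a > 0.  Published grey
  expressions sometimes print −a with a positive exponent; this package
  fixes one convention and documents it rather than matching any one
  printing.
- **Markov statistic form**: likelihood-ratio, not per-cell absolute value
  (see above).
- **Hybrid in-sample construction**: own-state midpoint revision per window
  year.
- **Tie-break**: higher-index state, flagged.
- **CSV formatting**: 4 decimal places everywhere, making identical run
  configurations byte-identical — golden-file tests stay stable.

## Known limitations

- GM(1,1) represents exponential-plus-constant levels only; series with
  turning points need the metabolic or hybrid variants, and even those only
  track, not explain.
- The state partition is estimated in-sample from as few as 10 ratios;
  with K = 3 some transition rows routinely rest on 2–3 counts, so the
  transition matrix is noisy and the property test has modest power.
- Forecast-time ratios can leave the in-sample partition; they are clamped
  with a warning rather than extrapolated.
- The diagnostics assume a non-constant original series (Sx > 0); constant
  actuals raise rather than returning C = 0/0.
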