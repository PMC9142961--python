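# Methods

This note records the models, numerical choices, and defaults behind
`alphachain`, and what the synthetic generators do and do not emulate.

## Decay-chain model

The ²²⁵Ac chain is modelled as a strictly serial parent→daughter list
with per-link branching fractions in (0, 1].  Internal units are minutes
and kBq; converters live at the boundary (`alphachain.units`).

Half-life defaults (packaged in `data/ac225_chain.yaml`): ²²⁵Ac 9.9 d,
²²¹Fr 5 min, ²¹⁷At 32.3 ms, ²¹³Bi 45.6 min.  The 5-min value for ²²¹Fr is
a common rounding; users preferring the 4.8-min literature value can
supply their own chain file — at the ≥ 24 h delays used for the
delayed-window assay the difference is far below counting error.  The
²¹³Bi branching (²¹³Po/²⁰⁹Tl) is collapsed to a single effective link to
the stable terminus because no counting window downstream of ²¹³Bi is
used.

By default ²¹⁷At is treated as in instantaneous equilibrium with ²²¹Fr:
its half-life is more than six orders of magnitude below any counting
interval, and carrying λ ≈ 1.3 × 10³ /min through the closed form costs
conditioning for no observable effect (the collapsed and full chains
agree to < 1 × 10⁻⁶ relative on every slower member).  The full
four-member chain remains available (`ac225_chain(full=True)`) and is
what the validation against the stiff-ODE oracle uses.

Activities follow the distinct-λ Bateman closed form evaluated in atom
space (N = A/λ).  When any two decay constants agree to within 1 × 10⁻⁹
relative, the solver switches to `scipy.linalg.expm` of the chain's
lower-bidiagonal rate matrix — the exact limit of the closed form, never
a division by ~0.  Atom conservation (members plus a λ = 0 terminus
carried through the same formula) holds to 1 × 10⁻⁹ relative on random
chains; against a Radau integration of the chain ODEs at rtol 10⁻¹¹ the
closed form agrees to ~10⁻¹² relative over 0–14 days.

Equilibrium ratios use A_d/A_p = Π_links b·λ_d/(λ_d − λ_p); a daughter
whose λ does not exceed the parent's has no transient equilibrium and
raises `EquilibriumError` explicitly.

A useful identity exploited throughout: the state with all daughters at
their asymptotic ratios is exactly the −λ_parent eigenvector of the
chain, so a supported daughter decays exactly with the parent's λ.  This
is asserted against the Bateman solution in the tests.

## Counting model and reduction

The reduction is relative: standards (three aliquots of 1% of the
injected dose) are counted simultaneously with samples, so detector
efficiency and decay cancel and no explicit decay correction to
injection time is applied in the default path.  Window names ("Fr221"
170–270 keV, "Bi213" 380–520 keV) are matched by name; the keV ranges
are metadata.  Background is an optional subtraction; net counts below
zero floor at 0 with a warning, and %IA/g values are never clamped.

The delayed ²²⁵Ac assay requires the record to start ≥ 24 h
(configurable) after dissection; at ten ²¹³Bi half-lives the surviving
free-daughter fraction is 2⁻¹⁰ ≈ 0.098%, so by 24 h (≈ 31.6 half-lives)
it is negligible.  An equilibrium-ratio correction λ_Fr/(λ_Fr − λ_Ac)
(≈ 1.00035) is applied by default in the record-level API; the
cohort-level reduction disables it because its standards are themselves
²²⁵Ac aliquots with daughters in equilibrium, where the factor cancels.

## One-phase ²¹³Bi fit and decomposition

Traces are converted to rates at bin midpoints (an exact
integral-over-bin expectation is easy to add but midpoints are used
consistently by generator and fit, so the round trip is exact at the
noiseless limit).  The fit minimizes Poisson-weighted squared residuals
(weights 1/var, var = counts/Δt²; empty bins floored at one count).

k defaults to fixed at ln 2/45.6 min: the decay constant is physical, and
fixing it reduces variance.  The free-k mode reproduces the behavior of
generic curve-fitting software and flags fits whose k deviates > 20%
from the physical value.  With k fixed the model is linear in the two
amplitudes and is solved by bounded linear least squares (plateau ≥ 0,
free component unconstrained — blood shows genuine deficits and negative
values are reported, never clamped).

The plateau is modelled as decaying with λ(²²⁵Ac) across the trace
(default).  The plain constant-plateau model is selectable; on a 12-h
trace of a pure-equilibrium sample it absorbs the parent's decay,
1 − e^(−λ_Ac·720 min) ≈ 3.4%, into the free term, which is the documented
bias bound of that variant.  With the correction on, the recovered free
component of an equilibrium sample is zero to < 0.5%.

The decomposition takes the supported level preferentially from the
late (≥ 10 × 45.6 min; protocol default 24 h) equilibrium record counted
against its own simultaneous standards, falling back to the fitted
plateau (flagged).  A_t0 = A_free + A_supported holds identically by
construction.  The standard error of A_free combines the fit covariance,
the equilibrium record's Poisson error, and both standards runs; over
200 Poisson replicates of the kidney- and blood-like scenarios the 95%
interval covers the true free component at ~95%.

Traces are fitted in count-rate space and converted to %IA/g at the end;
whether normalization precedes or follows fitting is mathematically
immaterial for the relative method, and rate space keeps the Poisson
weights exact.

## Synthetic generators

All randomness flows through `numpy.random.default_rng(seed)`; equal
seeds give identical tables.

*Counting traces.*  Expected bin counts are ε·Δt·[A_free(t₀)·e^(−λ_Bi·τ)
+ A_sup(t₀)·e^(−λ_Ac·τ)] + background, with A_free(t₀) = (R − 1)·A_sup(t₀)
parameterized by the redistribution ratio R (kidney-like R > 1,
blood-like R < 1).  Counts are Poisson draws.  Defaults: 5-min bins over
720 min (the protocol states only "approximately 12 h"), window
efficiencies 0.20–0.25 (plausible NaI well-counter photopeak values),
background 1 count/min — none of these are stated by the protocol, so
all are configurable, and the relative reduction cancels the efficiency
anyway.

*Biodistribution cohorts.*  Inter-animal uptake and organ masses are
lognormal (uptake must be positive and the study reports mean ± SD
only), parameterized by arithmetic mean and cv.  Cohorts of five animals
at days 1/3/7 with a 50 kBq injected activity mirror the study design;
mass-balanced truth sets reduce to organ %IA summing to 100 within
counting error.

*Therapy cohorts.*  Tumors follow piecewise-exponential volume
trajectories from a lognormal initial volume (median 82.9 mm³ at the
day-21 randomization, the study's reported median).  Control and
low-dose arms grow with doubling times 31.9 and 67.8 days (the reported
group values used as simulation truth); effective arms shrink after
treatment and regrow slowly late in the study — the study shows but does
not parameterize regrowth, so the change-points are this package's
choice.  Caliper noise is multiplicative lognormal per radius, default
cv 5% (no noise model is stated).  Measurements are twice weekly
(3/4-day alternation) and stop at the first reading at or past the 2-cm³
endpoint.  Note an internal tension in the source numbers: a 31.9-day
doubling time from 82.9 mm³ does not reach 2 cm³ by day 150, so
simulated control medians are censored rather than matching the reported
99-day control median; the generator keeps the stated parameters rather
than tuning toward the median.

What the generators do **not** emulate: antibody pharmacokinetics
(uptake values are endpoints, not compartment solutions), spectral
crosstalk between windows, dead time, ulceration/clinical events (input
flags, emitted with probability 0 by default), and weight-loss
trajectories (weights are stable by default; the weight rules are
exercised with hand-built series in tests).  Passing round-trip tests
therefore demonstrates correctness of the analysis arithmetic under the
stated statistical assumptions, not fidelity to animal biology.

## Efficacy and survival

Doubling time uses log-linear OLS of ln V on day rather than a nonlinear
exponential fit: identical on noiseless data, stabler under
multiplicative noise, and the estimator is not otherwise specified.
Animals need ≥ 3 positive volumes; non-positive slopes mark the animal
excluded ("tumor size decreased over time") instead of erroring, and
excluded counts are carried into the group summaries.

The acute weight rule (>15% within 2 days) is evaluated on a daily grid
with linear interpolation between weigh-ins, comparing each day to the
interpolated weight two days earlier; baseline for the chronic rule is
the first recorded weight.  The earliest crossing wins; ties break by a
fixed cause priority (volume, ulceration, acute, chronic, clinical).
Censoring is at study end (day 150 post-inoculation; time origin is the
inoculation day, an injection-day origin is a parameter away).

Kaplan–Meier estimation and the log-rank test delegate to lifelines;
medians that never reach S ≤ 0.5 are reported as "not reached" / ">150"
rather than as a number.  Tests validate the KM curve against the
empirical survivor function, the log-rank statistic against a direct
risk-table computation, its p-value against a 10,000-shuffle permutation
oracle, and its size (rejection rate 3–7% at α = 0.05 over 2,000
identical-hazard replicates).

## Statistics

Auto mode for two-group comparisons runs Levene's test (mean-centered;
Brown–Forsythe selectable) and chooses pooled vs Welch at p ≥ 0.05,
recording the choice — it never switches silently.  Pairwise p-values
are unadjusted by default (Holm available), α = 0.05 two-sided.  The
zero-variance and all-identical degenerate cases return the p = 1
convention with a note rather than NaN.  A summary-statistic entry point
(`two_group_test_from_stats`) supports checks against published
mean ± SD tables.

## Problem sizes

Defaults used by the test and acceptance runs: 144-bin (12 h) traces,
cohorts of 5 animals × 3 timepoints, therapy groups of 10, 200 Poisson
replicates for interval calibration, 2,000 replicates for test size,
10,000 permutations for the log-rank oracle.  These sizes give Monte
Carlo errors comfortably below the assertion tolerances while keeping a
full run in the low minutes on a single CPU.

## Known limitations

- Serial chains only (branching reduces flux but all flux stays on the
  chain); adequate for the collapsed ²²⁵Ac chain, not for general decay
  networks.
- No spectral unmixing or dead-time correction; windows are assumed
  clean.
- The one-phase fit assumes the sample is sealed after dissection (no
  biological washout during the 12-h count).
- Survival analysis treats measurement days as exact event times; no
  interval-censoring machinery.
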