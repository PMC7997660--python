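# Methods

## Polymer mechanics

Tether extension is modelled as the sum of independent contributions from
every dsDNA base pair and ssDNA nucleotide (superposition), each following
the extensible worm-like chain in the Marko–Siggia interpolation with an
additive enthalpic term:

    xi(F) = h · (1 − ½·sqrt(kBT/(F·P)) + F/S).

Defaults: dsDNA P = 50 nm, h = 0.34 nm/bp; ssDNA P = 1.0 nm,
h = 0.59 nm/nt; S = 1000 pN for both; kBT = 4.11 pN·nm (298 K),
configurable.  The interpolation formula itself is a choice — published
force–extension work at these forces (7–12 pN) also uses Odijk or
higher-order interpolations, which differ from Marko–Siggia by a few
percent in xi_ss; the Marko–Siggia form is the most common default and is
applied identically to both species.  Unwinding one base pair releases two
nucleotides, so base pairs unwound = Δx / (2·xi_ss(F)).  The conversion is
real-valued on purpose; discretisation into steps belongs to step
detection.

## Four-state switch kinetics

States: low-processivity (initial), high-processivity, dissociated,
past-threshold (>25 bp; absorbing, as is dissociation).  Rates: k1
(low→high, linear in ssDNA-binding-protein concentration), k−1, k2
(threshold crossing from high), k_off (dissociation from low), k′off
(dissociation from high; 0 in the reference model).  The closed-form
crossing probability and its eigenvalues are written in the grouped
parameterisation A = k2 + k′off, B = k_off, C = k−1 + k2 + k′off, D = k2,
k = k1([c]); the eigenvalue expression is exactly the eigen-decomposition
of the transient 2×2 generator block, which the unit tests verify
against `numpy.linalg.eigvals` and against stiff ODE integration of the
master equations (max |Δ| < 1e−8 over [0, 200] s for all published
parameter sets).

Numerical choices:

* Repeated eigenvalue λ+ ≈ λ− (within 1e−9 relative): the L'Hôpital limit
  k·D·[(1 − e^{−λt}) − λ t e^{−λt}]/λ² is used; the generic expression is
  indeterminate there.
* λ → 0 factors are evaluated with `expm1` so small-rate limits are exact.
* `solve_states` uses the matrix exponential of the full 4×4 generator —
  an implementation independent of the scalar closed form, so the two
  cross-check each other.

## Global fitting

The data are per-molecule first threshold-crossing times grouped by
concentration, with censoring (dissociation or end of observation).  Two
losses are implemented:

* **`method='mle'` (default)** — interval-censored maximum likelihood: a
  molecule crossing at t contributes the first-passage density
  k D (e^{−λ+t} − e^{−λ−t})/(λ− − λ+); a censored molecule contributes
  1 − P_>25(t_max).  Optimised with L-BFGS-B under non-negativity bounds.
* **`method='curves'`** — weighted least squares of the empirical
  fraction-crossed step curves on a time grid, each point weighted by its
  binomial variance (floored at 1/(4n) to avoid infinite weight at 0/1).

The likelihood is the default because, in recovery experiments at the
realistic scale of 100 molecules per concentration, the curve loss leaves
k−1 essentially undetermined (median relative bias of −60 to −80%, with
frequent boundary estimates at 0, driven by the heavy correlation between
neighbouring points of a step-function curve), while the MLE keeps the
median bias of k2, k_off and k−1 within ~10%.  Both estimators agree at
large n.

Shared parameters: A, B, C (and D where free) across concentrations, one k
per concentration.  The default constraint k′off = 0 sets A = D (four
parameter kinds); `koff_prime_free=True` fits A, B, C, D independently, in
which case k′off = A − D may come out negative — useful as a diagnostic
that dissociation from the high state is not needed.

Confidence intervals are parametric bootstrap (default 200 resamples):
datasets are resimulated from the fitted rates at the original sample
sizes and refitted with the same loss; intervals are the symmetric
normal-theory form, estimate ± z·(bootstrap SE).  Percentile intervals
were measured to undercover k2 slightly at these sample sizes, and the
symmetric form matches how such rate constants are conventionally
reported.

The k1-vs-concentration line is inverse-variance weighted least squares
(weights from bootstrap SEs when available); concentrations are nanomolar
at interfaces, converted to molar internally so the slope is in M⁻¹ s⁻¹.
Derived models: predicted high-processivity burst fraction
= P_>25(τ_low) with τ_low = 7 s (the mean low-processivity burst
duration), and mean burst duration = τ_low (1 − P∞) + τ_high P∞ with
P∞ = kD/(kA + BC).

## Synthetic traces

The generator is two-layered.  A Gillespie path of the switch scheme
decides each unwinding attempt's outcome: the attempt's low-state window
(walk to a stall target plus stall dwell) is handed to the kinetics, and
the attempt becomes a high-processivity burst exactly when the path
reaches the crossed state within that window — so the simulated
high-burst fraction equals the model's crossing probability by
construction, closing the loop that the burst-analysis tests check.  The
stepping layer renders 1 bp steps (forward/backstep mix 0.62/0.20 within
the unwinding phase, rezipping as −3 bp backslides at 25 events/s, overall
step-type fractions ≈ 0.62/0.20/0.18 matching the reported 19–25%
backsteps and 18–19% backslides), a position-dependent slowdown in the
GC-rich stall region 10–15 bp (rate factor 0.15 in the low state — bursts
stall there — and 0.60 in the high state, which traverses it), base
forward rate 9 steps/s giving ~4.5 bp/s net off-stall speed, a stall dwell
of mean 2 s so low bursts last ~7 s, occasional −5/+5 release/recapture
step pairs (0.05 s⁻¹), and 5 ± 1 attempts per molecule.  Transient melting
is a Poisson process of rate k_on·c (k_on = 1.2×10⁸ M⁻¹ s⁻¹ default)
rendered as rectangular +5 bp pulses with exponential 20 ms lifetimes;
i.i.d. Gaussian noise (0.3 bp default) is added after point-sampling the
piecewise-constant path at the acquisition rate (89, 100 or 267 Hz).
First-passage datasets use an observation window of 60 s, matching the
span over which fraction-crossed curves are experimentally displayed.

Every injected step, melting pulse (with a `resolvable` flag, see below)
and burst (with its category and kinetic window) is returned in an
injection log, which is the ground-truth oracle for the detector tests.

What the generator does **not** emulate: bead–trap Brownian dynamics and
force-feedback artefacts, drift, sequence-derived base-pairing energies
(the stall is phenomenological), partial melting amplitudes, correlated
(non-white) noise, and tether rupture.  Passing detector tests therefore
demonstrate correctness of the algorithms under the stated statistical
structure, not robustness to every instrumental artefact of real traces.

## Step detection

Iterative chi-square step placement in the style of Kerssemakers et al.:
the single step that maximally reduces the residual sum of squares is
placed greedily (per-segment best splits are cached, so each placement is
linear in trace length); after each placement a counter-fit with steps at
the centres of the current plateaus is evaluated, and the quality ratio
S(N) = chi²_counter/chi²_fit is recorded.  The accepted step count is the
interior peak of S(N), subject to S ≥ 1.2 (configurable).  On featureless
noise S(N) creeps upward monotonically toward the expansion frontier, so a
peak at the frontier is rejected — this yields zero steps on flat noisy
traces while recovering ≥ 90% of 1 bp steps at 0.3 bp r.m.s. noise.  An
exact fit (zero residual) is accepted outright.  Expansion is capped at
n/4 steps and stops once S has clearly declined past its peak.

Melting events during unwinding are adjacent step pairs: a forward step
> 2 bp followed by a backward step > 2 bp within five sample points
(56 ms at 89 Hz).  Chains such as (+3, +3, −3) resolve by first match in
time order; paired steps are removed from the enzyme step pool.  On
enzyme-free hairpins, events are contiguous excursions > 4 bp above the
baseline (trace median) lasting at most 0.2 s (10× the characteristic
lifetime; both configurable).  Backsteps are steps in [−2, 0) bp,
backslides < −2 bp; adjacent ~5 bp backward/forward pairs are counted
separately as release/recapture events.

## Melting on-rate

The basic estimator is k_on = 1/(mean inter-event time × c) with the
exponential-rate standard error k_on/√n.  Two detection biases are
corrected when the sampling interval is supplied: (i) sub-sample
censoring — an event shorter than the distance to the next sample instant
leaves no sample; for exponential lifetimes the number of samples covered
by detected events is geometric with ratio e^{−dt/θ}, which yields θ and
the resolvable fraction (θ/dt)(1 − e^{−dt/θ}) (≈ 0.77 at 20 ms lifetime
and 89 Hz); (ii) merging — overlapping events are detected as one
excursion, so detected events are busy periods of an M/G/∞ process
arriving at rate λe^{−λθ}, inverted by fixed-point iteration (a ~2%
effect at 1.2 s⁻¹).  With both corrections the recovered on-rate is
unbiased in simulation; detector recall is likewise quoted against
resolvable events, since events that span no sample instant are absent
from the data by construction.

## Event alignment and densities

Melting and reannealing transitions are aligned independently at t_melt
and t_anneal (time zero) and at the pre-melt baseline (position zero),
using the full-bandwidth trace; the control variant repeats the alignment
at random time points paired with points 0.06 s later (the melt-search
window).  Probability densities of the aligned clouds use a direct sum of
axis-aligned 2D Gaussian kernels, bandwidths per axis by Silverman's rule
(σ·n^{−1/6}), normalised on the evaluation grid.

## Burst analysis

Traces are masked (melting spans replaced by linear interpolation),
smoothed by robust local quadratic regression — 51-point window, tricube
distance weights, two bisquare reweighting passes; the robust pass is
skipped when the fit is already essentially exact, which keeps noiseless
piecewise-linear inputs intact — and segmented by hysteresis turning-point
detection with a 5 bp threshold: each valley→peak→valley triple with both
flanks exceeding 5 bp is one burst.  A final descending excursion that
returns to baseline and stays (rezip followed by dissociation) is closed
at its first return to within 1 bp of the post-peak minimum; trailing
rises without a closing retraction are flagged incomplete and excluded
from duration statistics.  Processivity is the maximum smoothed position
in the burst; the 25 bp threshold splits low/high.  Unwinding portions:
high bursts — start to maximum; stalling low bursts (≥ 10 bp) — start to
the last point above 10 bp; small bursts (< 10 bp) — the first 75% of the
duration.  Velocities are slopes of straight-line fits over
half-overlapping 50-point windows, aggregated into 2 bp position bins
with s.e.m.  Summary tables reproduce the bookkeeping identities
n_low + n_high = n_bursts and fraction_high = n_high/n_bursts on any
input.

## Problem sizes

The test-suite and acceptance computations run at desk scale: 100
molecules per concentration (five concentrations) for global-fit recovery,
1500 Gillespie paths per parameter set for the simulation-equivalence
check, 40 point-fit replicates for median-bias estimates and 20
bootstrap-equipped replicates (60 resamples each) for CI coverage, 150–200
simulated molecules for burst-count recovery, and 300–500 s of bare-hairpin
trace for melting statistics.  The library default of 200 bootstrap
resamples is used for standalone fits.

## Known limitations

* k−1 is weakly identified at realistic sample sizes (its likelihood is
  flat when k_off·k−1 is small); expect wide intervals.
* The simulator's stall phenomenology is parameterised, not derived from
  sequence thermodynamics; positions and rates in the stall region encode
  observed behaviour, not base-pairing energetics.
* Step detection assumes piecewise-constant signals; smoothly ramping
  segments (high rates at high bandwidth) are not decomposed into steps.
* No force-ramp analysis, hidden-Markov step inference, drift correction,
  or instrument (bead/trap) dynamics.
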