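# Methods

## The kinetic model

`opencomplex` analyses the two-level extension signal of a magnetic-tweezers
assay in which a single supercoiled DNA tether carries a bacterial promoter.
Opening of the promoter by the RNA polymerase holoenzyme (core + sigma70)
unwinds ~10 bp, which linking-number conservation converts into a writhe
change and hence an extension jump; the tether therefore toggles between a
closed-state level (CS: free promoter and the closed complex RP_C) and an
open-state level (OS: the intermediate open complex RP_I and the stable open
complex RP_O).  The promoter cycle is a continuous-time Markov chain

    R + P  <=[k1[R] / k-1]=>  RP_C  --[k2]-->  RP_I  <=[k3 / k-3]=>  RP_O

with dissociation from RP_I at rate `k5` (and, in the general model, from
RP_O at `k4`).  All rates are s^-1 except `k1` (nM^-1 s^-1); holoenzyme is
in pseudo-first-order excess at concentration `[R]` (nM).

A dwell in either observable level is a first passage of the chain
restricted to that level's states, so its density is phase-type,
`f(t) = pi0' exp(Q t) a`.  For the accepted dissociation model (`k4 = 0`,
dissociation only via RP_I) the OS density is exactly the two-exponential
mixture `p+ k+ e^{-k+ t} + p- k- e^{-k- t}`, with the closed-form
correspondence

    k5  = p+ k+ + p- k-
    k3  = p+ p- (k+ - k-)^2 / k5
    k-3 = k+ k- / k5

and its inverse through the eigenvalues of the 2x2 generator.  The inverse
is evaluated with cancellation-free root formulas (shifted discriminant
`u^2 + 4 k3 k-3`, product form for the small root), which keeps the round
trip exact to ~1e-11 over the rate decades the assay probes (~0.01-10
s^-1); far outside that range the weight `p-` saturates in double
precision.  A repeated eigenvalue (the Erlang boundary, measure zero) falls
back to the single-exponential limit.  Errors on the derived rates are
propagated to first order with central finite differences (relative step
1e-6) from the one-SD bootstrap errors of `(k+, k-, p-)`.

The model ladder used to discriminate dissociation pathways (reversed
pathway; two parallel pathways; dissociation from RP_O starting from either
open state; dissociation from RP_I under three closing assumptions) is
exposed through `build_scheme`, and `pdf_shape` classifies each candidate by
its density at the origin: a scheme whose start state has no direct
absorption gives `f(0+) = 0` (a gamma-like peaked density), which the
measured, monotonically decaying dwell histograms rule out.  Note that for
the "dissociation from RP_O" model this mathematical classification ties the
peaked shape to the RP_I start and the decaying double-exponential to the
RP_O start; the shape reported here is the derived one.  The two-pathway
model needs a start-state mixing weight that the rate table does not carry;
`build_scheme` takes it as an explicit `mix_weight` argument.

## Synthetic traces

No public single-molecule traces exist for this assay, so the `simulate`
module is a first-class generator emulating the acquisition chain: exact
Gillespie simulation of the chain above, rendered at 58 Hz with states
{R+P, RP_C} at the closed level and {RP_I, RP_O} at `z_CS - jump` (73 nm
for positive, 42 nm for negative supercoiling -- the two open complexes
render at the same level, as no bubble-size difference is observable),
plus optional linear drift, i.i.d. Gaussian tracking noise, and 10-point
block averaging.  Defaults:

| parameter | default | why |
|---|---|---|
| `f_s` | 58 Hz | camera acquisition rate of the assay |
| `decimate` | 10 | the preprocessing applied before change-point analysis |
| `noise_sd` | 25 nm | gives the 73 nm jump SNR ~ 9 after decimation, visually consistent with published traces; the true amplitude is not stated |
| `jump_pos` / `jump_neg` | 73 / 42 nm | measured jump magnitudes |
| `drift_rate` | 0 nm/s | drift characteristics are unknown; non-zero drift is supported and removed by a robust line fit |

The canonical kinetic fixture mimics the reference (potassium-acetate-like)
condition: `K_D = 17 nM` (`k1 = 0.3 nM^-1 s^-1`, `k-1 = 5.1 s^-1`),
`k2 = 0.45 s^-1`, and an OS mixture `(k+ = 0.3, k- = 0.03, p- = 0.5)`,
i.e. `k5 = 0.165`, `k3 = 0.1105`, `k-3 = 0.0545 s^-1`, at 5 nM holoenzyme.
These sit inside the observed order of magnitude (closed-state exit
~0.01-0.1 s^-1, open-state exits ~0.01-1 s^-1) and were fixed by an
identifiability analysis: with a 10x separation of the mixture rates the
derived rates are estimable to a few percent from a few thousand dwells,
whereas a 5x separation leaves the RP_I->RP_O rate uncertain to ~17% at
2500 dwells.  Binding and dissociation (`k-1 + k1[R] ~ 6.6 s^-1`) are fast
against `k2`, so the closed-state dwell is effectively single-exponential.

What the generator does *not* emulate: bead Brownian dynamics and camera
point-spread physics (noise is white by construction), torque dependence of
the rates, plectoneme dynamics beyond the level mapping, and tether-to-
tether heterogeneity.  Passing recovery tests therefore validate the
statistical chain -- segmentation, truncated MLE, conversions -- under
idealized noise, not robustness to correlated bead motion.

The generator truth for the observable closed-state exit rate is defined as
the reciprocal mean first passage of the binding chain,
`1 / E[T(R+P -> RP_I)]`.  The rapid-pre-equilibration expression
`k_open = k2 [R]/(K_D + [R])` differs from it by the direct binding time
`1/(k1 [R])`, about 6% at the fixture condition and more at low
concentration, so synthetic concentration series for testing the binding
fit are generated from the hyperbolic law itself rather than from
trajectories.

## Segmentation

Transitions are found by offline bottom-up change-point detection with an
L1 (least-absolute-deviation) cost: start from a fine partition, repeatedly
merge the adjacent pair with the smallest cost increase, and stop when the
smallest increase exceeds a penalty.  Two implementation choices matter:

* **Penalty scale.**  The cost is computed on a median-centred,
  MAD-standardized copy of the signal, so the penalty is scale-free and a
  useful range is ~0.2-5 (default 1.0); on raw nanometre data the same
  numbers would be meaningless.  Standardization also makes segmentation
  invariant to offsets and gain, and the standardized signal is quantized
  at 1e-6 so the greedy merge order is stable under float-level input
  perturbations.
* **Initial partition.**  `detect_changepoints` defaults to 2-sample
  initial segments (the classical n/2 partition).  The pipeline, however,
  runs with `min_size = 1`: a 2-sample event is representable in an n/2
  partition only when it aligns with the partition grid, so roughly half of
  all 2-sample closed-state gaps are otherwise invisible, and each missed
  gap falsely fuses two open dwells.  At the assay's SNR (a 9-sigma jump) a
  single-sample excursion is still detected reliably and false positives
  are negligible (~4.6-sigma single-sample threshold).

Segments are classified by exact length-weighted 1-D 2-means on their
medians; the lower-extension cluster is the open state.  If the two cluster
centres are closer than 3 noise SDs the trace is treated as having no
resolvable open level (all CS).  Adjacent same-label segments are merged.
Linear drift above 0.5 nm/s is removed by a Theil-Sen fit (on <= ~500
subsampled points) before detection.

Dwell durations are segment lengths over the effective sampling rate; the
first and last dwell of each trace are censored and never fitted.  The
pipeline keeps every detected dwell (`segment.t_min = 0`) -- a detected
short dwell is a real level excursion that correctly terminates its
neighbours -- and instead truncates the *likelihood* at
`fit.t_min = 0.776 s` (~4.5 effective samples at 5.8 Hz), above the scale
where detection is complete.  Dwells shorter than the resolution that
survive to extraction with a nonzero `t_min` are discarded with their
neighbours merged (the behaviour of `extract_dwells` for callers who want a
hard floor).  The quality metrics are the overlapping Allan deviation
(octave-spaced averaging times; white noise decays as tau^-1/2) and an
autocorrelation time estimated as the 1/e crossing of the FFT
autocorrelation -- a stand-in for reading the correlation time off the
Allan minimum, validated only on synthetic noise.

## Dwell-time fitting

Single-exponential fits are closed form under left truncation:
`k = 1/(mean(tau) - t_min)`.  The two-exponential mixture is maximized by
L-BFGS-B in `(ln k+, ln k-, logit p-)` with the density renormalized on
`[t_min, inf)`; 8 stratified restarts (quantile-derived rate scales x
weights {0.2, 0.5, 0.8}, plus log-normal jitter) guard against local
optima, and `k+ >= k-` is restored by relabeling.  On single-exponential
data the mixture optimum is a ridge (`k+ = k-` at any weight, or a
vanishing weight); both ends describe the same density and BIC
(`m ln N - 2 ln L`, m = 1 or 3) then selects the single model.  Bootstrap
errors are one-SD spreads over resampled refits (default 1000 replicates,
warm-started at the point estimate); replicates that fail to converge are
dropped and counted, and more than 20% failures raises.

## Dependence fits

* Concentration: weighted least squares of `k_open = k2 [R]/(K_D + [R])`;
  flat series are flagged unidentifiable (relative SD of K_D above 1, or
  K_D collapsed far below the lowest probed concentration).
* Temperature: `ln k` vs `1/T` linear fits with the gas constant
  1.98720425e-3 kcal/(mol K); energies are reported in kcal/mol with a
  kJ/mol echo (x 4.184), and negative activation energies are permitted
  (they flag a hidden stable intermediate).  The non-monotonic
  `k_open(T)` law (Arrhenius forms for k2 and K_D inside the binding
  expression) is fitted in a reference-temperature parametrization
  (`k2_ref`, `KD_ref` at the median data temperature) to avoid the
  astronomically scaled attempt prefactors, by multi-start
  Levenberg-Marquardt on log-rate residuals; both parametrizations are
  reported.  Unweighted by default.
* Salt: the sensitivity `S` is defined as the log-log slope
  `d ln k / d ln [salt]` (the underlying studies do not define it
  explicitly).

## Population simulation

The deterministic module integrates `dp/dt = W p` for the four species
fractions via the eigendecomposition of the fixed generator (exact for a
linear system; `expm` fallback for defective generators), from the all-free
initial condition.  The steady state is the normalized null vector of `W`,
with a reducibility check, and `summarize` reports the equilibrium free-
promoter fraction, the RP_O/RP_I ratio, and the RP_I peak time.  The
stochastic cross-check averages vectorized Gillespie trajectories of the
same generator.  The published per-temperature population figures depend on
supplementary rate tables that are not available, so the module ships with
the canonical fixture rates instead and those printed values are not
reproduced.

## Geometry

Bubble size and bent length follow from linking-number arithmetic:
`n = pitch (J_pos + J_neg)/(2 dz)` and `L_bend = (J_pos - J_neg)/2` with
`dz = 60 nm/turn` and `pitch = 10.5 bp/turn`; rounding is to the nearest
unit, half away from zero.  Rotation-curve apices are located by a parabola
fit to the points within 90% of the maximal extension (the centring rule of
the underlying experiments is not stated); an apex within 1% of the scanned
range boundary is rejected.  The synthetic rotation curves use a quadratic
cap wide enough that the 90% window stays parabolic, matched to 60 nm/turn
linear wings.

## Validation problem sizes

The test suite validates the chain at the following scales, chosen so the
whole suite runs in about a minute: conversion round trips over 1e4 random
rate triples; 1e5 stochastic first-passage samples against the analytic
mixture (KS < 0.01); an end-to-end ensemble of 36 traces x 4800 s
(~6000 dwells per state) recovering `(k5, k3, k-3, k_open)` within 15%;
BIC operating characteristics over 200 replicates x 2000 dwells; and 1e4
Gillespie trajectories against the population ODE (2% pointwise).

## Known limitations

* Dwells shorter than ~1 effective sample (~0.17 s at the default
  decimation) are irreducibly invisible; the truncated likelihood accounts
  for the missing short dwells but not for the rare dwell fusions they
  cause (<2% of events at the fixture rates).
* The mixture fit assumes exactly one intermediate open state; more states
  produce higher-order phase-type densities that this package only
  simulates, not fits.
* Censoring is handled by exclusion, not by a censored likelihood; with
  dwells much longer than the trace length the fits would be biased.
* The salt-sensitivity definition and the Allan-based correlation-time
  estimator are package choices where the source procedures are
  underspecified.
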