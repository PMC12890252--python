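# Methods

## The refilling model and its integration

The core state variable is the expected per-site occupancy ρ(t) of N
independent release sites, dρ/dt = k₁(1 − ρ) − b₁ρ between APs.  Release
is an instantaneous multiplicative event: at each AP time, ρ ← (1 − p_v)ρ
and the drop ×N is the expected quantal content of that EPSC.  Treating
release as a delta event rather than a rate over a time step keeps the
per-AP amplitude independent of the integrator step.  Integration is
forward Euler, default step 1 ms; the step must not exceed the smallest
inter-AP interval.  The initial condition defaults to the resting
steady state ρ = k₁/(k₁ + b₁) and is configurable.  Euler's global
error for the relaxation problem is O(h(k₁+b₁)²t·e^(−(k₁+b₁)t)), about
10⁻⁵ in occupancy at h = 10 µs for the reference rate regime (k₁+b₁ =
23/s); the tests compare against the closed-form exponential at that
accuracy, and halving the step changes per-AP amplitudes by well under
0.5% at h ≤ 1 ms.

Two stochastic dialects are provided because the closed-form two-pulse
failure analysis assumes a one-transition-per-interval scheme that is
not identical to the exact two-state Markov propagator:

- `continuous-time`: exact propagator per inter-AP interval,
  P(1→1) = p_∞ + (1−p_∞)e^(−(k₁+b₁)Δt), P(0→1) = p_∞(1−e^(−(k₁+b₁)Δt)).
  Physically exact for constant rates; used by the EPSC-train generator.
- `per-interval-BF`: a docked site undocks with B = 1 − e^(−b₁Δt), an
  empty site docks with F = 1 − e^(−k₁Δt), and a site that undocks
  within the interval is not refilled in that interval (sites emptied
  by release at the AP itself are part of the empty pool and may
  refill).  This is the Monte-Carlo oracle for the failure analysis.

The two dialects differ at order (BΔt)(FΔt); at Δt = 20 ms and the
reference rates the difference in joint outcome probabilities is below
the Monte-Carlo resolution used in the tests (3 SE at 10⁶ trials), but
the distinction matters for exact agreement with the combinatorial
formulas.

## The calcium sensor

Synaptotagmin-7 is a chain of n sequential Ca²⁺-binding steps with
forward rate (n−j)·k_on·[Ca] out of state Sⱼ and backward rate
(j+1)·k_off·bʲ into it.  The cooperativity factor b multiplies
successive unbinding rates geometrically (the allosteric-sensor
convention); the factor could alternatively scale binding rates, and
the chain is written so that the rate rule is a single local function
(`_chain_rates`) if that variant is ever needed.  Defaults: n = 5
(two to three Ca²⁺ ions on each C2 domain; configurable 2–6),
k_on = 7 /µM/s, k_off = 10 /s, b = 0.35, K₁,max = 300 /s, k₁,b = 6.9 /s.
Only the fully bound fraction drives docking, k₁ = k₁,b + K₁,max·sₙ.
With b = 1 the chain has the binomial equilibrium
Binomial(n, c/(c + k_off/k_on)), which the integrator reproduces to
1e-9 — the main correctness anchor for the master-equation code.

The Ca²⁺ waveform is a peak-scaled Gaussian (peak 40 µM, center
0.25 ms after the AP, σ = 0.085 ms — the normalized-Gaussian form has
density units, so the peak is fixed physically) plus a residual
1 µM·e^(−t/50 ms), superposed linearly across APs with no saturation.
The resting term defaults to 0 so that the sensor is fully unbound at
rest; the measured resting concentration (0.05 µM) can be supplied but
at 50 nM the equilibrium fully-bound fraction is negligible
(≪ 10⁻⁴ of K₁,max), so the choice does not affect train simulations.

Integration uses a two-timescale grid: 5 µs steps within ±2 ms of each
AP (to resolve the 85 µs Gaussian), 1 ms elsewhere; binding chain and
pool share the grid.  Against a uniformly fine 1 µs grid the per-pulse
amplitudes agree within 1% (tested at 40 Hz).  The binding chain starts
in S₀; no published initial condition exists for the train simulations
and the resting drive is negligible, so the ground state is the natural
choice.

## Failure analysis

`predict_joint` implements the exact sums over (n₀, n₁, n₂): binomial
P(n₀) at occupancy p_occ, binomial release P(n₁|n₀) with p_v, the
B/F double-binomial refilling kernel P(n₂|n₁), and the second-pulse
failure factor (1−p_v)^n₂, with the failure mass split by whether the
first pulse released anything.  Success entries come from the exact
marginal P(F₁) = Σ P(n₀)(1−p_v)^n₀ — which equals (1 − p_v·p_occ)^N —
so the four outputs sum to 1 by construction.  Binomial terms are
computed in log space (gammaln), giving headroom to N ≈ 20.  An
independent brute-force enumeration with plain integer combinadics
backs the tests, as does the per-interval-BF Monte-Carlo dialect.

The cost is the sum of squared errors over the four outcome
combinations with p_r pinned to the observed first-pulse failure rate.
When only the two failure rates are recorded, the observed success
mass is split pro rata to the model prediction, making the success
residuals zero and the cost a function of the failure pattern alone;
pinning P(F₁) then forces e₀₁ = −e₀₀.  A full observed 4-vector can be
supplied instead.  Optimization is a deterministic 5×5 grid of
L-BFGS-B starts over the bounded box (default k₁ ∈ [4, 8] /s,
p_v ∈ [0.8, 1]); boundary optima are flagged.  Note that with the
pro-rata split and only the printed failure rates as input, the cost
has a near-zero minimum at k₁ ≈ 4.47/s (the model can match P₀₀ = 6.2%
exactly); a nonzero minimum cost arises only when observed success
frequencies constrain the fit as well.

## Quantal analysis

The MPFA variance model is Var = qĪ(1 + CV_QS²) − Ī²/N — the standard
intra-site-variability form with inter-site variability set to zero
(one parabola).  CV_QS defaults to 0.2.  The fit is unweighted least
squares in (q, N) (optional weights accepted); N is declared
unidentifiable when its covariance is unbounded or when the largest
mean stays below 20% of the fitted capacity Nq, i.e. when all points
sit on the rising limb.  Quantal size from asynchronous events uses
1- vs 2-component Gaussian mixtures (deterministic quantile-based
initialization, BIC selection) and reports the lowest-mean component,
which absorbs the single-quantum peak while the second catches double
events.  Train summaries: PPR = A₂/A₁, steady-state EPSC = mean of the
last five normalized amplitudes, efficacy = EPSC_ss × frequency;
k_STF is fitted as A(t) = a_ss − (a_ss − 1)e^(−k·(t−t₁)).

## Calcium buffering

κ_B for a sweep is the linearized binding ratio between resting
calcium (default 0.05 µM) and the transient peak.  The extrapolation
fits τ and 1/A linearly against κ_B; both lines have x-intercept
−(1 + κ_S), and the two κ_S estimates (decay-based and
amplitude-based) are reported separately rather than averaged, since
they answer slightly different questions and need not coincide in
data.  Derived: A_Ca = 1/intercept(1/A), τ_Ca = intercept(τ),
γ = 1/slope(τ), Δ[Ca]_T = 1/slope(1/A); the identities
Δ[Ca]_T = A_Ca(1 + κ_S) and γτ_Ca = 1 + κ_S hold exactly for every
fit.  τ is kept in seconds internally and reported in ms.

## Synthetic data

The generators define the study conditions for all closure tests.
EPSC trains: per-site continuous-time simulation; each released quantum
draws Normal(q, q·CV_QS) truncated at zero (truncation bias is
negligible at CV ≤ 0.3) plus additive recording noise; defaults q =
25 pA, CV_QS = 0.2, N = 6, k₁ = 6.9/s, b₁ = 16.1/s, p_v = 1.  Paired
trials use the per-interval-BF dialect to match the combinatorics, with
success threshold q/2.  Asynchronous events are truncated normals at
the measured quantal statistics (24 pA, CV 0.25).  Line scans: the
buffering load and the transient peak determine each other (κ_B depends
on the peak), so the generator solves the pair by fixed-point iteration
before rendering the two channels through the inverse calibration with
per-sample multiplicative noise; defaults emulate the measured bouton
(κ_S = 96.4, A_Ca = 1.16 µM, τ_Ca = 43 ms, rest 50 nM, indicator
K_d = 2.3 µM at 150/250/500 µM).  The scan rate (640 lines/s) places
the onset exactly on a sample so that noise-free closure tests are not
biased by peak-sampling offset.  All generators are driven by a single
seed and are byte-reproducible.

What the generators do not emulate: EPSC waveform kinetics (amplitudes
only), correlated recording noise, rundown and series-resistance drift,
multivesicular lateral interactions, spatial calcium gradients and
buffer diffusion, and photobleaching.  Passing closure tests therefore
demonstrate correctness of the estimators under the stated statistical
model, not robustness to those real-data features.

## Problem sizes

Monte-Carlo checks use 10⁵ trials (moment convergence, 3-SE criterion)
and 10⁶ trials (joint failure frequencies); MPFA recovery uses 100
trials/point for the noisy-design check and 10⁴ trials/point for the
bias check.  These sizes put the sampling error comfortably below the
assertion tolerances while keeping the default suite under a minute.

## Known limitations

- Single-pool, one-step priming only; no loose/tight two-state priming
  cascade, no site-clearance or endocytic limit — at 20–40 Hz the
  sensor model therefore overshoots late-train amplitudes relative to
  recordings of this synapse type (steady-state ≈ 3× baseline here).
- Euler integration: accuracy is first-order in the step; the defaults
  are chosen for the reference rate regime and should be re-examined
  for rate constants beyond ~10³/s.
- The Gaussian-mixture quantal fit assumes at most two components and
  well-separated peaks.
- `fit_transient` estimates the amplitude from the peak sample; for
  slow sampling relative to the decay this underestimates the true
  amplitude by ~Δt_sample/(2τ).
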