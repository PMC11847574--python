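# Methods

## Generative model

An evoked response under release-probability condition *k* is modelled
as the outcome of *n* independent Bernoulli release sites with common
probability *pₖ*. Conditional on *j* successful releases the amplitude
is the sum of *j* iid uniquantal gamma variables — exactly a
Gamma(*j*γ, λ) — and the recorded failure (j = 0) amplitude is Gaussian
baseline noise with SD ε. The composite amplitude density is therefore

    Q(x | k) = B(0; n, pₖ) N(x | 0, ε) + Σ_{j=1..n} B(j; n, pₖ) G(x | jγ, λ)

with quantal size q = γλ (the uniquantal mean), uniquantal coefficient
of variation v = 1/√γ, and the mean-response relation μᵢ = n pᵢ q which
makes pᵢ = μᵢ/(n q) and λ = q/γ latent rather than free.

Model assumptions worth keeping in mind:

* all sites share one *p* per condition and one uniquantal distribution
  (no site heterogeneity, no intrasite variance decomposition);
* amplitudes are analysed as positive magnitudes (loaders flip inward
  currents), because the gamma density has support (0, ∞);
* the noise Gaussian enters the *failure* component only. A real
  recording adds noise to successful sweeps too; since ε is typically
  several-fold smaller than q this is a deliberate approximation of the
  composite model, with consequences quantified below.

## Likelihood

The log-likelihood sums, over conditions, a per-condition weight term
−log(s.e.(xᵢ)·√2π) — a Gaussian evaluated at zero deviation whose role
is to weight conditions by how well their mean is determined — plus
log Q(x|k) for every sweep amplitude. The weight term uses the unbiased
(n−1) sample SD. Parameter points whose implied pᵢ = μᵢ/(n q) falls
outside [0, 1] have zero likelihood (−∞ log-likelihood), not an
exception; with the q-grid construction below this excises a contiguous
low-q region for each n.

All products are accumulated in log space (log-gamma via `gammaln`,
mixtures via logsumexp in the scalar path): with 50+ sweeps a direct
density product underflows double precision.

## Discrete-grid exact inference

Because *n* is discrete, Hamiltonian samplers do not apply and
random-walk Metropolis mixes poorly; with only two continuous
parameters, exact enumeration is cheaper and deterministic. The grid:

| axis | support | spacing | default resolution |
| --- | --- | --- | --- |
| n | 1 .. n_max | integers | n_max = 12 (operator-set; 10 used in the recovery studies) |
| q | [min μᵢ/(n_max·p_max), max μᵢ/p_min] | log-uniform, endpoints inclusive | 128 |
| γ | [1/v_max², 1/v_min²] | log-uniform | 64 |

with defaults v ∈ [0.05, 1.0] and tractable release probability
p ∈ [0.04, 0.96]. Priors follow Jeffreys' rule: Zipf f(n) ∝ 1/n and
uniform in log q and log γ, normalized jointly over the grid.

The posterior is prior × exp(ℒ + L), normalized by its grid sum, where
the offset L is the negative mean of the finite log-likelihood values —
a centring device for 64-bit exponentiation. The implementation applies
an additional internal max-shift before exponentiating, which cancels
in the normalization but makes the result immune to overflow on very
wide grids; consequently the posterior is exactly invariant to any
constant added to L.

The grid evaluation is vectorised over (sweep × q × γ) blocks per
(n, condition); it agrees with the scalar per-point log-likelihood to
~1e−13 and with an independent brute-force no-logarithm Bayes
computation to better than 1e−10 wherever that oracle retains normal
(non-subnormal) float64 precision.

Marginals are sums over the complementary axes. Point estimates are
half-quantiles: for the discrete *n*, the smallest n whose cumulative
marginal reaches 0.5 (deterministic, and conservative under the Zipf
prior); for log q and log γ, the median interpolated linearly on the
cumulative grid and exponentiated. p̂ᵢ = μᵢ/(n̂ q̂) is reported as-is
even when it exceeds 1 — with a warning flag — as a diagnostic of model
misfit rather than clipped.

## Simulator

`simulate_observations` forward-samples the physical recording: per
sweep j ~ Binomial(n, p), amplitude = Gamma(jγ, λ) + N(0, ε), with the
noise added to *every* sweep (as an amplifier does), not only failures.
It can report the true ε ("known" mode) or an estimate from simulated
stimulus-free sweeps ("estimated" mode). A single seeded
`numpy.random.Generator` drives everything, so output is bit-identical
given the seed.

Two exact moment identities hold for the simulated sweeps and are used
as oracles: mean = npq, and variance = n[pγλ² + p(1−p)q²] + ε². For the
*composite model density* the corresponding variance is
n[pγλ² + p(1−p)q²] + B(0;n,p)·ε², since there the noise enters failures
only — the two expressions differ by (1−B₀)ε², which is exactly the
simulator-vs-model approximation noted above.

`simulate_event_train` lays difference-of-exponential synaptic kernels
(defaults 0.3 ms rise, 3 ms decay — a glycinergic IPSC scale at
near-physiological temperature) at Poisson times on Gaussian noise and
returns the planted ground truth, as a fixture source for the detection
and kinetics code. What these simulations do **not** emulate: correlated
(filtered) recording noise, series-resistance filtering, baseline drift,
short-term plasticity within trains, or Ca²⁺-cooperativity linking mM
concentrations to p. Passing tests therefore demonstrate correctness of
the estimators under the stated model, not robustness to every artifact
of real recordings.

## Identifiability of n at realistic sweep counts

With the reference recovery design (n = 5, q = 0.1, v = 0.3, ε = 0.02,
p = {0.3, 0.7}, 150 sweeps/condition, n_max = 10) the posterior median
q̂ is essentially unbiased (median bias a few percent), but the marginal
posterior over *n* honestly spreads over {4, 5, 6}: the exact-n half-
quantile lands on 5 in roughly 45% of seeded replicates. This is a
property of the information in the data, not of the algorithm — when
data are drawn exactly from the composite model (noise on failures
only), the posterior concentrates entirely on the true n at 3000
sweeps/condition in every replicate tested, and with physically
simulated noise the residual model mismatch (the (1−B₀)ε² term) plus
n–q trade-off along the μ = npq ridge keeps neighbouring n plausible at
150 sweeps. For this reason the marginal over n is always reported
alongside the point estimate.

## Derived electrophysiological measures

* Driving-force conductance σ = I/(V_reversal − V_cell); pA/mV gives nS.
  Scaled conductance expresses σ as a percentage of the cell's resting
  conductance, removing cell-size dependence.
* IPSP correction to rest: IPSP × (V_rest − V_reversal)/(V_membrane −
  V_reversal), the linear driving-force extrapolation (defaults: rest
  −60 mV, Cl⁻ reversal −75 mV).
* I–V slope conductance is a least-squares line fit of I against V;
  recurrent-inhibition strength is the difference between the slope
  conductance during a 200-Hz train steady state and at rest (negative
  differences are flagged, not suppressed).
* Stimulus-artifact removal fits a single or double exponential to the
  artifact tail by least squares (double initialised from the single
  fit, amplitudes and time constants bounded; a non-convergent double
  fit falls back to the single) and subtracts its forward extrapolation
  from a copy of the trace.
* Kinetics: amplitude is peak minus local baseline; rise and decay times
  run between two amplitude fractions with linear interpolation between
  samples — 10–90% for evoked responses, 20–80% for small spontaneous
  events where baseline noise makes the extreme fractions unreliable.
* Onset latency is the first post-stimulus point where the trace
  derivative exceeds 5× the SD of the baseline derivative; a flat or
  sub-threshold trace returns a no-response signal rather than raising.
  Jitter (SD of latencies) is meaningful within one cell only.
* Mini/asynchronous event detection: candidate peaks ≥ 1.5× the
  caller-supplied baseline noise SD (the window that defines the noise
  is the caller's, so the threshold is not defined by its own
  detections), grouped so that maxima not separated by a return below
  threshold count as one event; amplitude is read off a 0.5 ms
  boxcar-smoothed copy against a 2 ms pre-event baseline (configurable),
  and events are kept only if the 20–80% rise exceeds 0.1 ms and the
  decay 0.5 ms — the waveform criterion that rejects noise excursions,
  which rise and fall within a sample or two. On seeded pure noise the
  false-positive rate is below 1 per 10 s at the default settings.

## Nested-data statistics

* ICC(1,1): one-way random-effects intraclass correlation from ANOVA
  mean squares, (MSB − MSW)/(MSB + (k−1)MSW), with the standard
  unbalanced correction k₀ = (N − Σnᵢ²/N)/(a−1). The (k−1) denominator
  is the standard Shrout–Fleiss form; a variant with "k+1" circulates in
  print but is inconsistent with the scale it is interpreted on (it
  cannot reach 1 when MSW → 0), so (k−1) is used. Labels: poor ≤ 0.50 <
  moderate ≤ 0.75 < good ≤ 0.90 < excellent.
* Effect sizes: mean difference and Hedges' g = (mean_case −
  mean_control)/pooled SD (pooled with the (n₁−1)+(n₂−1) denominator; no
  small-sample correction factor, matching the hand-checked examples).
  Percentile bootstrap (default 10,000 replicas, 95% CI from the
  2.5/97.5 percentiles) rather than BCa, reporting the full resampling
  distributions; a comparison is "meaningful" when its CI excludes 0.
  Replicas with zero pooled SD are dropped and counted. Measured
  coverage of the mean-difference CI at n = 30 per group is ~93%,
  the usual mild undercoverage of percentile intervals at this n.
* Hierarchical (two-level) bootstrap: per replica, resample units
  (cells) with replacement at the group's unit count, then k events per
  sampled unit with replacement, k being the group's maximum
  events-per-unit; effect sizes are computed on the pooled resampled
  events. Every unit gets equal expected weight regardless of how many
  events it contributed, which is the point: pooling raw events would
  let a single over-sampled cell dominate. Within-cell paired resampling
  is available as an option for latency/jitter comparisons.
* Routing: ICC ≤ 0.50 → treat observations as independent; ICC > 0.50
  with ≥ 20 observations per unit → hierarchical bootstrap; ICC > 0.50
  with sparse units → a linear mixed model is recommended (routing only;
  fitting an LMM is out of scope and belongs to a dedicated fitter).

## Problem sizes and numerical choices

The validation studies use sizes chosen to make their Monte Carlo error
small relative to what they assert: oracle equivalence on a 4 × 16 × 8
grid with 50 sweeps (the largest size at which the no-logarithm oracle
retains full precision); density quadrature to 1e−6 absolute; moment
identities at 5,000 sweeps (3 SE bands); recovery over 20 replicates of
the reference design; CI coverage over 4,000 outer replications of
1,000-replica bootstraps (MC error ~0.4% against a ±3-point band). All
stochastic stages consume explicit seeds and are bit-reproducible;
command-line runs write a manifest (package version, command, seed,
resolved configuration) sufficient to reproduce outputs exactly.

## Known limitations

* The uniquantal family is gamma only; Gaussian or log-normal quanta,
  per-site p heterogeneity and intrasite variance are out of scope.
* The composite model's noise-on-failures-only approximation slightly
  inflates n̂ uncertainty on physically realistic data (quantified
  above); q̂ is robust to it.
* Event detection assumes a caller-declared polarity and a reasonably
  stationary baseline; it does not deconvolve overlapping events closer
  than the grouping criterion allows.
* No proprietary acquisition formats: sweeps and amplitude tables are
  plain CSV with JSON sidecars.
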