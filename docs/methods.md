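# Methods

## Model class

All stages assume a time-homogeneous, Markovian, one-dimensional Langevin
equation for the observed variable (a single MEG channel's signal x, or the
derived evidence z):

    dz/dt = P_G(z) + P_H(z) Γ(t),     ⟨Γ(t)Γ(t′)⟩ = δ(t−t′),

interpreted in the Itô sense. P_G (drift) and P_H (noise amplitude) are
polynomials; coefficient vectors are stored highest degree first. Two
degree sets are treated as first-class model families: the leaky
stochastic accumulator (LSA, G=1/H=0 — Ornstein–Uhlenbeck drift az+b with
constant noise) and a nonlinear generalization (G=3/H=2) whose
state-dependent noise amplitude permits spectral exponents other than the
Brownian α=2 that every constant-noise accumulator produces.

## Kramers–Moyal reconstruction

Drift and diffusion are the τ→0 rates of the conditional increment
moments. The estimator:

1. bins the observed state range [min, max] into 100 equal bins
   (`n_bins`);
2. for each lag τ = 1/fs … 10/fs (10 values) computes per-bin means
   A1(x, τ) = ⟨x(t+τ)−x(t)⟩ and A2(x, τ) = ⟨(x(t+τ)−x(t))²⟩, where the
   base sample x(t) selects the bin. Within trial-structured data no pair
   (t, t+τ) straddles a trial boundary, and the final max-lag samples of
   each trial contribute no base points ("right boundary" rule);
3. extrapolates each bin's A(τ) to τ=0 with a zero-intercept least-squares
   polynomial c₁τ + c₂τ² and reports the linear coefficient c₁ as the
   rate. The zero intercept enforces A(0)=0 identically and the quadratic
   term removes O(τ²) finite-lag bias exactly for polynomial moments;
4. fits g to D¹ and h to √D² by count-weighted least squares over valid
   bins.

Numerical safeguards: a bin is valid only with ≥ 10 pairs at every lag
(`MIN_BIN_COUNT`; low-occupancy tail bins otherwise dominate the fits);
negative extrapolated D² (finite-sample noise in a nonnegative rate) is
clamped to 0 and the bin is excluded from the h fit; if a fitted h(z)
touches zero anywhere on the supported state range the model is flagged in
its provenance and simulation clamps h at ε = 10⁻⁶ model units so the SDE
stays well defined.

Three modes combine trials:

- **concatenated** — one moment field from all trials jointly (shared
  bins over the global range). Statistically the best-behaved mode: on a
  10⁵-sample Ornstein–Uhlenbeck series all three LSA parameters are
  recovered with ≲ 1% bias (replicate-calibrated spread ~14% on the slope
  at that length, shrinking as 1/√N).
- **single_trial** — one field and one polynomial fit per trial, each
  binned over that trial's own range.
- **pooled** — per-trial fields whose (bin, D¹) and (bin, √D²) points are
  pooled into one count-weighted fit; the estimator used for behavioral
  models, where one equation must describe the whole trial ensemble.

**Known limitation — finite-trial conditioning bias.** Per-trial binning
conditions each moment on events that involve the trial's own future: the
trial's min–max range (which defines the bins) and the bin-occupancy
threshold both depend on samples after t, so the selection correlates with
the increments being averaged. For 750-sample trials this flattens the
estimated drift substantially (OU slope −0.29 is estimated near −0.10 by
the pooled mode at 60×750 samples; the same data concatenated give −0.28).
The single-trial and pooled modes reproduce this procedure deliberately —
it is the estimator a per-trial analysis implies — and the recovery tests
freeze their tolerances from 20-replicate calibrations of exactly this
behavior (|bias| + 5 SD: slope ±0.46, intercept ±1.25, noise ±0.16 for the
OU benchmark). Concatenated mode should be preferred whenever a single
equation for the ensemble is acceptable.

Scale handling: estimation runs in native units; an optional multiplicative
`scale` (e.g. 10¹³ to map Tesla-scale signals onto order-one evidence) is
applied at the reader boundary and recorded in model provenance.
Windowing is a half-open crop [start, end) in seconds relative to the
event; the pipeline's behavioral window is −3…0 s, clipped with a warning
to the epoch extent (−2.5…0 s for default 3-s epochs).

## First-passage simulation

Euler–Maruyama with constant Δt (default 2⁻⁸ s) from z(0)=0, Itô
increments z′ = z + P_G(z)Δt + max(P_H(z), ε)·√Δt·N(0,1). Two crossing
criteria are exposed:

- **band** (default): first step with |z−β| < 0.01. With noise amplitudes
  of order 1 and Δt = 2⁻⁸ the per-step increment (~h/16 ≈ 0.11) is much
  wider than the 0.02 band, so paths frequently jump the band and are
  detected on a later revisit; the band rule therefore reports
  systematically longer waiting times than the continuous-time first
  passage, and its bias grows with Δt.
- **upcross**: first step with z ≥ β, the conventional absorbing-bound
  rule. Its Δt sensitivity is the ordinary Euler overshoot bias: halving
  Δt from 2⁻⁸ moves the LSA benchmark's mean waiting time by ~1.3%.

Runs not crossing by t_max (default 60 s; inverse-Gaussian tail mass
beyond it is ~10⁻⁴ for the parameter ranges of interest) are censored:
counted, excluded from fitting. Each run consumes an independent
counter-based substream keyed by (seed, run index), so single runs are
reproducible and extending n_runs never reshuffles existing runs. The
same applies to the data generator, keyed by (seed, subject, channel,
trial). The two inner loops are JIT-compiled when numba is importable;
the pure-Python fallback consumes the identical random stream and returns
identical results.

## Waiting-time statistics

Inverse-Gaussian density ρ(w; μ, λ) = [λ/(2πw³)]^{1/2}
exp{−λ(w−μ)²/(2μ²w)}. Fitting uses the closed-form MLE (μ̂ = mean,
λ̂ = n/Σ(1/wᵢ − 1/μ̂)); a histogram least-squares fit is provided as a
diagnostic only. The threshold scan simulates each β on the grid (default
2.0…8.0, step 0.1), fits (μ(β), λ(β)), and minimizes the Euclidean
distance E(β) to the target (M, L); grid points where every run censors
or the fit degenerates are excluded. By default each grid point draws
independent noise substreams; `share_noise=True` reuses the same
substreams across the grid for variance-reduced, run-by-run monotone
comparisons.

**Selection noise at the argmin.** With N_T = 100 runs per grid point the
batch spread of μ̂ is ~σ_batch ≈ √(μ³/λ)/10 (≈ 0.9 s for μ ≈ 9–11) and of
λ̂ ≈ λ√(2/100). Minimizing E over ~60 grid points then selects, in part,
favorable noise: the reported (μ(β₀), λ(β₀)) are biased toward the target
by one to two batch-SDs relative to the converged values at that β. Any
single reported batch should be read with those error bars; increasing
N_T or re-simulating the winning β with fresh streams removes the
selection component.

The L2 distance between fitted densities is computed by adaptive
quadrature over (0, 50] s (absolute tolerance 10⁻⁸; the densities involved
are below 10⁻¹² beyond 50 s) and satisfies the metric axioms on the IG
family to quadrature tolerance.

## Channel selection

The event-related field (ERF) is the pointwise trial mean. The readiness
weight W locates the ERF maximum within ±0.2 s of the event (inclusive
window, 101 samples at 250 Hz; first occurrence wins ties) and averages
the ERF over ±0.1 s around that peak (51 samples, truncated at epoch
edges). Channels are ranked by signed W (magnetometer polarity is
orientation-dependent, so an absolute-value variant is available) with
ties broken by channel order, and the top k (default 5) feed the
behavioral reconstruction.

## Spectral exponent

Welch PSD (Hann taper, 256-sample segments, 50% overlap, constant
detrend); α is the negative slope of log₁₀ power vs log₁₀ frequency over
the fit band (default 0.5–40 Hz; the package's own validation uses
1–40 Hz). Series shorter than one segment are rejected rather than
padded. At 10⁵ samples white noise fits to α = 0 and a random walk to
α = 2, each within ±0.1.

## Synthetic data generator

The generator emulates the statistical skeleton of event-aligned
magnetometer epochs: per-subject sets of n_trials × n_channels trials
(default 60 trials, 750 samples at 250 Hz, event at 2.5 s), each trial an
independent Euler–Maruyama path of the ground-truth equation at one step
per sample, mapped to Tesla by amplitude_scale (default 10⁻¹³, so
order-one dynamics appear as ~100 fT) and per-channel gains. Options:
shared noise streams across channels (gain tests), an additive
deterministic ramp-and-collapse event template (linear rise to the event,
0.5 s decay — a minimal readiness-field surrogate), and arbitrary epoch
geometry. One Euler step per sample is intentional: the generator's role
is to produce data with the assumed Markovian structure at the recording
resolution, not to be a high-accuracy SDE solver.

What it does not emulate — and what passing tests therefore do not
certify about recorded MEG: 1/f background superimposed on the dynamics,
oscillatory (narrowband) activity, artifacts (ocular, cardiac, muscular),
inter-channel field spread from common sources, non-Markovian memory, or
nonstationarity across a session. Recovery results certify the estimator
chain under its own model assumptions.

## Problem sizes used by the test suite

Tests run the chain at sizes chosen to keep the whole suite in a few
minutes while leaving Monte-Carlo margins quantifiable: recovery tests
use 60×750-sample datasets, 10⁵–2×10⁶-sample series for consistency and
round-trip checks (the 2×10⁶ length keeps the OU slope's replicate spread
under the 10% assertion band), 3×10⁶ samples for the cubic
leading-coefficient check, 100-run batches (20 replicates) for
first-passage reproduction, and 10⁴-run batches for converged simulation
values. Pipeline tests use scaled-down protocols (25–30 trials, coarse β
grids, 40–60 runs per point) exercising every stage.

## Known limitations

- The per-trial (single_trial/pooled) estimator bias discussed above.
- The band crossing rule's Δt-dependent detection delay; use upcross for
  convergence studies.
- E(β) argmin selection noise at small N_T.
- The IG MLE ignores censoring (censored runs are dropped, not
  likelihood-weighted); with t_max = 60 s and the default parameter
  ranges the censored fraction is negligible, but heavy censoring would
  bias μ̂ downward.
- Reconstruction assumes stationary Markovian dynamics with polynomial
  coefficients; no Markovianity test is performed and non-polynomial
  functional forms are out of scope.
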