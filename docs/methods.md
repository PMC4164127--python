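# Methods

## Model

A TAFC decision is modelled as two sequential neuronal populations, each
accumulating noisy evidence by a drift diffusion until an absorbing
threshold fires a pulse and the accumulator renews. The holding time
between pulses — the interpulse interval (IPI) — is the observable
first-passage time. Its law is taken to be **ex-Wald**: the convolution
of a Wald (inverse-Gaussian) first-passage time with drift *v*, noise
scale *s* and threshold *θ*, and an independent exponential stage with
rate *γ* capturing residual, non-diffusive latency. The CDF is

    H(t | v, s, θ, γ) = F(t | v, s, θ) − F(t | k, s, θ) · exp(−γt + θ(v − k)/s²),
    k = √(v² − 2γs²),

with F the Wald CDF

    F(t | v, s, θ) = Φ((vt − θ)/(s√t)) + exp(2θv/s²) · Φ(−(vt + θ)/(s√t)).

Only the real-*k* branch (v² ≥ 2γs²) is implemented; parameter sets
outside it are rejected. The exp·Φ products are evaluated in log-space
(`scipy.special.log_ndtr`), since for θv/s² ≳ 350 the factors overflow
and underflow separately while their product stays below 1. At the
boundary k = 0 the zero-drift Wald CDF 2Φ(−θ/(s√t)) is used as the
limit.

Time is measured in samples (1 sample = `dt` seconds, default 0.05);
fitted rates are "per sample" and converted with `dt` only on spectral
axes.

## Coding and count reconstruction

The likelihood series y is pulse-coded by strict thresholding
(bit = 1 iff y > δ). IPIs are the lengths of maximal zero runs
terminated by a pulse; the trailing run is censored (no terminating
pulse) and dropped, zero-length gaps between adjacent pulses are dropped
(a zero holding time is not a renewal interval), and the leading run
counts when pulse-terminated. The infomax initialization δ₀ is the
series mean: for a near-symmetric unimodal series this nearly balances
the binary code and hence nearly maximizes its entropy.

By the renewal CLT, the accumulated count N(t) of a renewal process with
interval mean μ and SD σ is asymptotically Normal(t/μ, t·σ²/μ³);
population count series are averages of `n_pop` (default 50) such
Gaussians per time point. The activity rate is N(t)/t — the simplest
definition whose stationary value is the renewal rate 1/μ. Recoding a
count series at threshold θ scans its increments, emitting a pulse and
resetting whenever the accumulated increment reaches θ.

## Layer fitting

Parameters are estimated by matching the ex-Wald CDF to the empirical
IPI CDF at Hazen plotting positions (i − ½)/n, minimizing the RMSE —
CDF matching avoids any binning choice for integer-valued intervals.
Two numerical choices matter:

- **De-rounding.** An interval recorded as j whole samples corresponds
  to a continuous passage time in (j − 1, j]; the c ties at j are spread
  uniformly over that bin before comparison. Evaluating the model CDF at
  the raw integers instead biases the fitted mean upward by about half a
  sample and leaves a sawtooth floor in the objective that drowns the
  shape information.
- **Unit-drift normalization.** The Wald CDF is exactly invariant under
  a common rescaling of (v, s, θ): holding times identify only the
  first-passage mean μ_w = θ/v, the shape λ = θ²/s², and γ. The search
  therefore runs over (μ_w, λ, γ) in log-space — a coarse grid of 8
  log-spaced points per parameter spanning a factor 3 around
  moment-based initial guesses, then Nelder-Mead — and reports
  parameters with the drift pinned at v = 1 evidence unit per sample:
  θ = μ_w, s = θ/√λ. Under this convention θ inherits the
  well-determined first-passage mean while the statistically fragile
  shape estimate lands in s. Estimating s "freely" is not meaningful:
  the objective is perfectly flat along the scaling ridge.

The moment initialization splits the interval variance evenly between
the diffusion and exponential stages (1/γ₀ = σ/√2, clipped to
[0.05μ, 0.8μ]; μ_w0 = μ − 1/γ₀; λ₀ = μ_w0³/var_w with a 1/12 variance
floor for near-degenerate integer samples — the rounding variance of a
uniform offset). The real-k constraint is γ ≤ λ/(2μ_w²) in identifiable
coordinates; the optimizer clips violations back with a small penalty
and the returned fit is flagged when it ends on the boundary.

The backward procedure fits the choice layer (layer 2) on IPI(δ₀),
reconstructs N₂ from those interval moments, recodes N₂ at the fitted
θ₂, fits the valuation layer (layer 1) on IPI(θ₂), and reconstructs N₁.
The result is δ₀-dependent by design and bit-reproducible given the
seed; each stochastic stage consumes a child of one `SeedSequence`.

## LN-cascade gain

The transfer function T_Nz = P_Nz/P_NN is a Welch estimate (segment
length 32, Hann taper, 50% overlap — suitable defaults for ~100-sample
series) with the binary output mean-centered so its DC mass does not
dominate the ratio; zero-power bins are regularized by
ε = 10⁻¹² × max P_NN and flagged. The raw filter C is the inverse DFT
of T_Nz. Bussgang's theorem for Gaussian input gives the correction
α = Cov(X, g(X))/Var(X) with X = C∗N, and the gain series is
z(t) = logistic((C′∗N)(t)) with C′ = C/α, using the full linear
convolution truncated to the series length and applied to the raw
(uncentered) input. Band powers integrate the Welch spectrum of the
mean-removed gain over delta (0.5–4 Hz), theta (4–8), alpha (8–12) and
beta (12 Hz–Nyquist); at the default 20 Hz sampling the Nyquist
frequency is 10 Hz, so the beta band is absent and alpha is truncated —
`dt` is configurable for faster-sampled inputs.

## Surrogates and screening

iAAFT surrogates iterate spectrum imposition and rank remapping onto the
original values (max 100 iterations, relative spectrum-change tolerance
1e-8), ending on the remap so every surrogate is an exact permutation of
the source. Gaussian noise with SD equal to c × SD(source) (c = 1 by
default) perturbs 30 randomly chosen positions; probability-valued
series are clipped to [0, 1] and the clip is flagged. Members are kept
"realistic-structured" by a Wald–Wolfowitz runs test (median
dichotomization, ties dropped, normal approximation with continuity
correction, two-sided, α = 0.05); an ensemble with fewer accepted
members than the target (default 40 of 100) warns rather than fails.
The continuity correction makes the test mildly conservative — its
empirical size at series length 100 is ≈3–4% rather than 5% — which
only makes the screening stricter.

## Synchrony

Instantaneous phases come from the analytic signal of the mean-removed
rate series, wrapped to (−π, π]. Phase locking per trailing window of 6
samples is the centered correntropy coefficient

    η = u(φ₁, φ₂) / √(u(φ₁,φ₁) · u(φ₂,φ₂)),
    u(x, y) = mean_i κ(x_i − y_i) − mean_{ij} κ(x_i − y_j),

with a Gaussian kernel whose width defaults to Silverman's rule on the
pooled window. η is clipped to [−1, 1] against rounding; constant
windows raise an error (zero self-correntropy).

Distances D = |η − η_sur| against a single seeded surrogate-pair profile
are fitted by a two-parameter Weibull via profile likelihood (1-D root
solve for the shape, closed-form scale; shape capped at 50 and flagged
for degenerate all-equal samples). The critical value at level α is the
upper-α quantile a·(−ln α)^(1/b); windows with D above it are reported
as synchronization times, indexed by the window's last sample (1-based).
The test statistic is mean(D)/SE(D); its p-value is a seeded parametric
bootstrap — statistics resampled from the fitted Weibull, the observed
value referred two-sided to the bootstrap distribution recentered at its
own mean. This is a pragmatic reference distribution: for a nonnegative
distance variable "mean = 0" is degenerate, so the p-value measures
departure from the typical Weibull-sample statistic, not from zero.

## Synthetic data

The generator emulates the study conditions: 100 samples at 50 ms, a
logistic preference trend consolidating in the last third of the trial
(the likelihood is conditioned on the finally chosen image), AR(1) noise
with coefficient 0.8, affine rescaling to mean 0.66 and SD 0.095, and a
clip to [0.01, 0.99] (≈3.5σ away, essentially never binding). Across
seeds the realized mean/SD calibrate to the targets within 0.02, and the
runs test rejects independence for >99% of seeds, so surrogate screening
has structure to detect. What the generator does **not** emulate: gaze
physiology (saccade kinematics, fixation durations), between-subject
heterogeneity, and any genuine coupling between the two layers beyond
what the pipeline itself induces — so passing tests demonstrate the
estimators' correctness and calibration on renewal/AR-style data, not
neurobiological validity on real eye-tracking series.

## Problem sizes and budgets

Default test and acceptance sizes: 10⁵–10⁶ draws for distribution
oracles, 2000 intervals × 10 replicates for recovery, 512-sample AR(1)
series for surrogate checks, 1000 replications for test-size estimates,
and a 100-sample, 20-surrogate end-to-end pipeline. These sizes keep
every Monte-Carlo tolerance at 3 standard errors or better while the
whole suite runs in well under a minute.

## Known limitations

- The imaginary-k regime (v² < 2γs²) of the ex-Wald is rejected, not
  implemented; heavy exponential stages relative to the drift are
  outside the model.
- The ex-Wald shape (λ) carries most of the estimation variance; under
  the unit-drift convention this appears as ±20% wobble in s at 2000
  intervals.
- The reinforcement feedback that would adapt the valuation threshold
  over trials is not modelled (no update rule is specified); the
  pipeline is a single-trial, feed-forward estimate.
- The bootstrap p-value of the sync test is not comparable across
  different window counts and is not a test against literal zero mean
  distance (see above).
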