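# Methods

## Forward model for TCSPC decays

A decay histogram is modeled as the discrete causal convolution of the
multi-exponential emission law `d(t) = Σᵢ αᵢ exp(−t/τᵢ)` with the measured
IRF normalized to unit sum, evaluated on the channel grid (default 0–50 ns
in 0.05 ns channels; the window covers five times the longest default
lifetime so tails reach the baseline). Working on the data grid with the
sampled IRF is the convention of vendor TCSPC software and keeps generator
and fit exactly consistent. The plain discrete convolution is first-order
accurate against the continuous integral — the exponential's kink at t = 0
enters at full weight — which in fitting is absorbed by the IRF shift
parameter. `convolve_model(..., edge="trapezoid")` half-weights the two
endpoint samples of each convolution sum; on strongly oversampled grids this
is second-order accurate (verified at < 10⁻⁶ of peak against the closed-form
Gaussian⊗exponential expression at 100× oversampling) and is the right mode
for sub-channel IRF work. It must not be used with a delta-like IRF, whose
kink needs full weight.

## Estimator and global fit

The default objective is Neyman-weighted least squares,
`Σ (obs − model)² / max(obs, 1)`, the common practical choice for Poisson
histograms with moderate counts; `weighting="poisson"` switches to Poisson
deviance residuals for low-count work. Amplitudes are constrained
non-negative by default (all physical species emit; a flag allows negative
amplitudes for excited-state-reaction spectra). Global fits share one
lifetime set across wavelengths and profile the per-curve amplitudes out by
weighted NNLS at each trial point (variable projection), leaving a 4-D
nonlinear problem (three lifetimes + one global IRF shift of at most ±5
channels; per-wavelength color shift is deliberately not modeled). Without a
user initialization, eight deterministic log-spaced lifetime windows
spanning 0.05–20 ns seed a multistart and the best objective wins.
Lifetimes may instead be fixed to externally determined values
(`fix_taus`), reproducing the linked-lifetime workflow in which one
lifetime set is imposed on a family of related samples. Over-parameterized
fits are flagged when a component's intensity contribution `Σ_λ αᵢ(λ)τᵢ`
collapses below 10⁻³ of the largest or two lifetimes come within a factor
1.25. Lifetime uncertainties come from the Gauss–Newton covariance of the
profiled objective.

## Decay-associated spectra and rates

`DASᵢ(λ) = I(λ)·αᵢ(λ)τᵢ / Σⱼ αⱼ(λ)τⱼ` partitions the steady-state spectrum
exactly; wavelengths where every αᵢτᵢ vanishes are reported as undefined
bins rather than silently zeroed. Species amplitudes use trapezoidal
quadrature on the native wavelength grid (spectra are smooth at 10 nm
spacing). The average lifetime is the amplitude-weighted mean
`ΣAᵢτᵢ/ΣAᵢ`: it reproduces the published table values from their printed
inputs (3.48 vs 3.47 ns; 5.37 vs 5.35 ns — second-decimal differences trace
to the table's own rounding of the amplitudes), whereas the
intensity-weighted alternative `ΣAᵢτᵢ²/ΣAᵢτᵢ` (~8 ns for the single strand)
is grossly inconsistent with it. Rates are reported in 10⁷ s⁻¹ with
`k_r + k_nr = 1/τ_av` exact by construction; the nm→eV conversion uses
1239.84193 eV·nm. Charge-transfer sign convention: positive means electron
density lost by the designated donor fragment upon excitation.

## Melting curves

The two-state model is a Boltzmann sigmoid between linear baselines,
parameterized directly by the midpoint T_m and a width in °C — no van't
Hoff enthalpy is assumed beyond the curve shape. Initial guesses: T_m at
the steepest point of a 5-point moving average (edge-padded smoothing is
avoided because zero padding fakes a steep edge at the boundaries),
baselines from the first/last 10% of points. A fit is refused
(`NoTransitionError`) when the baseline-corrected transition amplitude is
below five times the baseline noise. The derivative estimator smooths with
a user-sized odd moving average, takes the extremum of dF/dT, and refuses
boundary extrema and near-constant derivatives (pure baselines). Both raw
and affine-normalized (fraction-unfolded-like) entry points exist; T_m is
affine-invariant so they agree.

## Stacking angles and block bootstrap

The stacking angle is `arccos(|n_a·n_b|/‖n_a‖‖n_b‖)` with each normal a
cross product of two ring-atom difference vectors. The absolute dot product
folds the angle into [0°, 90°]: ring normals have no preferred orientation
and reported stacking means (~10°) only make sense unsigned. Which atoms
span each plane is explicit user input (`RingSpec`); defaults take the 1st,
3rd and 5th atoms of the listed ring, well separated around a six-membered
ring.

τ_int uses the biased FFT autocorrelation with the initial-positive-sequence
cutoff (sum to the lag before the first negative autocorrelation; for AR(1)
with φ = 0.9 this recovers the analytic (1+φ)/(1−φ)·dt = 19·dt within a few
percent at n = 10⁵). The moving-block bootstrap draws ⌈n/L⌉ overlapping
blocks of length L = ⌈5·τ_int/dt⌉ (clamped to [1, n/2]) uniformly with
replacement — non-circular, truncating the concatenation to n — and
recomputes the 1°-bin histogram per replica; bands are percentile intervals
(BCa is not attempted; plain percentile matches the stated 95% bands).
Coverage is assessed on bins whose true expected count is at least 5:
essentially empty bins get zero-width intervals and no meaningful per-bin
coverage notion. Under those terms the measured mean per-bin coverage for
AR(1) series (φ = 0.9, n = 20 000, 50 series, 1000 replicas) is ≈ 93–95%.

## Synthetic data: what it emulates and what it does not

The generators reproduce the *statistical structure* of the measurements:
Poisson counting noise on reconvolved tri-exponential decays (default
lifetimes 0.61/2.35/10.00 ns; each curve scaled so its noiseless peak hits
`peak_counts`, emulating fixed-peak acquisition), Gaussian component
emission bands whose τ-weighted sum is the steady-state spectrum, Gaussian
noise on sigmoidal melting curves over 15–95 °C in 0.5 °C steps, and a
stationary AR(1) angle process (marginal N(mean, sd²), lag-k
autocorrelation φᵏ) reflected at 0° and 90°. The IRF is a discretized
Gaussian (default FWHM 0.5 ns, consistent with a sub-ns instrument; the
true instrument shape is not public) and is supplied noise-free. Real data
additionally contain IRF counting noise and drift, background/scatter,
color shift of the detection chain, non-two-state melting intermediates,
and non-Markovian angle dynamics with transient spikes; passing tests
therefore demonstrate estimator correctness under the stated noise models,
not robustness to every instrumental artifact. Channel width, time window
and peak counts of the original instrument are unpublished; the defaults
are field conventions.

## Problem sizes and numerical choices

Statistical tests use 25 synthetic datasets for lifetime/DAS recovery
(medians are reported; at peak 10⁴ counts the median lifetime error is
< 1%), 100–200 seeds for melting recovery, n = 10⁵ for autocorrelation
checks, and 50 series × 1000 replicas (n = 20 000 each) for bootstrap
coverage — sizes chosen so every check is statistically meaningful while
the full suite runs in well under a minute of simulation time.
Optimizer tolerances are 10⁻¹² (ftol/xtol/gtol) so noiseless fits recover
parameters to ≥ 6 digits; ties between multistart solutions are broken
toward the first (lower-complexity) start by requiring strict improvement.
Degenerate inputs fail loudly: non-uniform time grids, negative counts,
constant angle series, collinear ring atoms, melting curves without a
transition, and series shorter than two bootstrap blocks all raise typed
errors.

## Known limitations

- No lifetime distributions, anisotropy, or time-resolved emission-spectrum
  reconstruction beyond the DAS partition.
- No van't Hoff thermodynamics or multi-transition melting deconvolution.
- The per-wavelength IRF color shift is not modeled; one global shift only.
- The Poisson-deviance option profiles amplitudes with reweighted NNLS
  rather than an exact inner MLE solve (adequate at these count levels).
- Published MD-derived mean angles (10.0–11.1°) require the original
  trajectories; they are emulated by the AR(1) generator, not reproduced.
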