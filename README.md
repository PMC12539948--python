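# duplexdyn

Analysis pipeline for probing epigenetically modified DNA duplexes with the
fluorescent adenine analogue 2-aminopurine (2Ap). 2Ap emission is strongly
quenched by base stacking, so its photophysics — lifetimes, quantum yield,
radiative and non-radiative rates — report on the local conformation around
modified cytosines (5-methyl-C, 5-hydroxymethyl-C). `duplexdyn` implements
the four quantitative stages such a study needs, end to end:

1. **TCSPC reconvolution fitting** (`duplexdyn.tcspc`). A measured decay is
   the instrument response function (IRF) convolved with
   `I(t) = Σᵢ αᵢ exp(−t/τᵢ)`. Fits run on single curves or *globally* across
   an emission-wavelength series with one shared lifetime set τᵢ and
   per-wavelength amplitudes αᵢ(λ), using variable projection: amplitudes are
   profiled out by weighted non-negative least squares at each trial lifetime
   set, so the nonlinear search covers only the lifetimes and a sub-channel
   IRF shift.
2. **Decay-associated spectra and rate decomposition**
   (`duplexdyn.photophysics`). The steady-state spectrum is partitioned as
   `DASᵢ(λ) = I(λ)·αᵢ(λ)τᵢ / Σⱼ αⱼ(λ)τⱼ`, giving species amplitudes
   `Aᵢ = ∫DASᵢ/∫I`, fractional intensities `fᵢ = Aᵢτᵢ/Σⱼ Aⱼτⱼ`, the
   amplitude-weighted mean lifetime `τ_av = ΣAᵢτᵢ/ΣAᵢ`, and the rate split
   `k_r = Φ/τ_av`, `k_nr = (1−Φ)/τ_av`. Relative quantum yields
   (`Φ_f = Φ_r·(I_f/I_r)(A_r/A_f)(n_f/n_r)²`), Stokes shifts and fragment
   charge-transfer amounts are included.
3. **Melting curves** (`duplexdyn.melting`). Two-state Boltzmann sigmoid
   with linear baselines fitted to fluorescence-vs-temperature data; returns
   T_m with its standard error, plus a smoothed-derivative cross-check.
4. **Stacking dynamics** (`duplexdyn.stacking`). Stacking angles from
   ring-plane normals (cross products of ring-atom vectors, folded to
   [0°, 90°]), 1°-bin histograms, integrated autocorrelation times τ_int,
   and a moving-block bootstrap (block length 5·τ_int, 1000 replicas) giving
   per-bin 95% confidence bands that respect the serial correlation of MD
   trajectories.

`duplexdyn.synthetic` generates every input with known ground truth
(tri-exponential decays with Poisson noise, component emission bands,
sigmoidal melting curves, AR(1) angle series, two-ring coordinate frames),
which is how the whole pipeline is tested without any measured data.

## Worked example

```
$ duplexdyn simulate --kind decays --seed 11 --out data
$ duplexdyn fit --decays data/decays.csv --irf data/irf.csv --components 3 --global --out fit.json
lifetimes [ns]: 0.606, 2.317, 9.909  chi2_red(pooled)=1.029
$ duplexdyn das --fit fit.json --spectrum data/spectrum.csv --qy 0.0059 --out row.csv
A_i = 0.215, 0.308, 0.478  tau_av = 5.58 ns  k_r = 0.11  k_nr = 17.83 (1e7/s)
```

The simulated duplex decays (true lifetimes 0.61, 2.35, 10.00 ns, peak 10⁴
counts, 12 emission wavelengths) are refit globally: the shared lifetimes
come back within ~1%, the pooled reduced χ² near 1 says the noise model is
consistent, and the decay-associated summary splits the emission into a
strongly stacked short-lived species and two less-stacked longer-lived ones.
With the supplied quantum yield the non-radiative rate k_nr ≈ 17.8×10⁷ s⁻¹
dominates k_r — the signature of charge-transfer quenching in the duplex.

```
$ duplexdyn simulate --kind melt --seed 11 --tm 59.5 --out data
$ duplexdyn melt --curve data/melt.csv --out tm.json
Tm = 59.49 +/- 0.03 C
$ duplexdyn simulate --kind angles --seed 11 --phi 0.9 --n-frames 20000 --out data
$ duplexdyn stack --angles data/angles.csv --dt-ps 1 --bootstrap 1000 --seed 7 --out hist.csv
n = 20000 frames, tau_int = 16.2 ps, block length = 82, mean angle = 10.05 deg
```

A full run (simulate → fit → das → melt → stack) is driven by a YAML config:

```
$ duplexdyn run --config cfg.yaml
wrote 10 artifacts to runout
```

Reruns with the same config and seed are byte-identical.

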