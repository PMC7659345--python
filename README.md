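# photophys

Quantitative analysis toolkit for the biophysical characterization of
microbial rhodopsins — in particular light-gated cation channels
(channelrhodopsins) studied by flash photolysis and whole-cell patch clamp.
It is aimed at spectroscopists and electrophysiologists who have the raw
numbers (ΔA matrices, I–V tables, dose–response and decay traces, pH-series
spectra) and want reproducible, scriptable fits instead of one-off
spreadsheet analysis.

## What it computes

**Photocycle kinetics** (`photophys.photocycle`). A transient-absorption
surface ΔA(λ, t) is modelled globally as a sum of exponentials with shared
lifetimes,

    ΔA(λ, t) = Σᵢ DASᵢ(λ) · exp(−t/τᵢ),

fitted by variable projection (nonlinear search over log τ only; the
decay-associated spectra DAS solved exactly by linear least squares at each
iterate). The number of components is incremented until the weighted
residual SD stops improving. Interpreting the components as an irreversible
sequential chain K → L → N → ground, the DAS are transformed via the
Bateman solution of the chain into evolution-associated difference spectra
(EAS) and compartment concentration profiles, and into absolute
intermediate spectra given the ground-state spectrum and the photoexcited
fraction. Quasilogarithmic compression condenses uniformly digitized
traces to ~100 points per time decade before fitting.

**Ion selectivity** (`photophys.ephys`). Photocurrent I–V families recorded
under ion substitution are fitted jointly with the Goldman–Hodgkin–Katz
flux equation,

    I(V) = offset + scale · Σ_S (P_S/P_Na) · z_S² u · ([S]ᵢₙ − [S]ₒᵤₜ e^(−z_S u)) / (1 − e^(−z_S u)),   u = VF/RT,

yielding permeability ratios P_K⁺/P_Na⁺, P_H⁺/P_Na⁺ (fitted in log₁₀
space), reversal potentials by bisection, Ca²⁺-block dose–response fits
I(C) = I_max/(1 + (C/K)ⁿ), single-exponential channel-closing kinetics
(τ_off), and flux-normalized action spectra.

**Spectroscopic pKa** (`photophys.titration`). The absorption maximum of
the retinal band, extracted from 280 nm-normalized pH-series spectra, is
fitted with the single-site Henderson–Hasselbalch sigmoid
λ(pH) = λ_base + Δλ/(1 + 10^(pH−pKa)) to give the Schiff-base counterion
pKa and the acid-induced red-shift Δλ.

**Synthetic data** (`photophys.synthetic`). Seeded generators produce every
input modality from known ground truth (sequential photocycle with Gaussian
intermediate bands, GHK-shaped I–V families, Hill block curves,
monoexponential decays, single-pKa titrations), so each fit can be
validated as a parameter-recovery problem.

## Worked example

Simulate the default three-intermediate photocycle fixture (bands at
540/460/560 nm on a 500 nm ground state, lifetimes 5·10⁻⁵/0.3/1.5 s, 1%
noise) and run the full global analysis:

```sh
photophys simulate --kind tas --seed 7 --out demo
photophys fit-tas demo/tas.csv --n-max 5 --tol 0.05
```

which prints (abridged):

```yaml
n_components: 3
lifetimes_s:
- 5.011519260767121e-05
- 0.2993447970381171
- 1.5035577254940033
weighted_residual_sd: 0.0012251032789323013
sd_trace:
  1: 0.03923883385625534
  2: 0.016885850709797156
  3: 0.0012251032789323013
  4: 0.0012229416047029068
intermediate_peaks_nm:
- 540.092169924649
- 459.90930904017017
- 559.767105259621
converged: true
```

Model selection accepts three exponentials (adding a fourth improves the
residual SD by < 5%), the recovered lifetimes match the generating
5·10⁻⁵/0.3/1.5 s within a fraction of a percent, and the reconstructed
intermediate spectra peak within 0.3 nm of the generating 540/460/560 nm
bands. The other pipelines work the same way, e.g.:

```sh
photophys simulate --kind iv --seed 1 --out demo
photophys fit-iv demo/iv.csv --conditions demo/conditions.yaml --free-ions K
photophys simulate --kind decay --seed 1 --out demo
photophys fit-decay demo/decay.csv --light-off-ms 0
```

The same pipelines are available as plain functions
(`photophys.photocycle.select_model`, `photophys.ephys.fit_permeability_ratios`,
`photophys.titration.fit_henderson_hasselbalch`, …) for notebook use.

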