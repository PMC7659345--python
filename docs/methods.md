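# Methods

## Photocycle model

The transient-absorption analysis assumes a strictly irreversible,
sequential first-order chain of spectrally distinct intermediates,

    K → L → N → ground,   rates kⱼ = 1/τⱼ ordered fastest first,

with unit population delivered to the first compartment by the actinic
flash. The populations are the closed-form Bateman solutions

    cⱼ(t) = Σᵢ b_ji e^(−kᵢ t),  b_ji = (Π_{m<j} k_m) / (Π_{m≤j, m≠i}(k_m − k_i)),

so the measured surface is exactly a sum of exponentials and a global
multiexponential fit is the natural estimator. Real photocycles can
contain spectral equilibria between late intermediates (e.g. an L ⇌ N
equilibrium); the chain approximation folds such an equilibrium into a
single effective compartment and the two spectra then mix. This is a
deliberate modelling choice — resolving back-reactions from a single
flash-photolysis surface is ill-posed without additional constraints — and
a known limitation: EAS of compartments linked by a fast equilibrium are
weighted averages, not pure species spectra.

Instrument response is ignored. The generators place the earliest delay at
10 ns and the fastest fixture lifetime at 50 µs, three orders of magnitude
above a ~50 ns detection bandwidth, so convolution with the instrument
response would change nothing resolvable here. Analyses of data with
sub-microsecond intermediates would need an IRF term this package does not
provide.

### Variable projection

`fit_global_exponentials` searches only over log₁₀ τ (positivity for free;
photocycle lifetimes span ~9 decades) with scipy's Levenberg–Marquardt
least squares; at each iterate the DAS are the exact weighted
linear-least-squares amplitudes. This separable formulation has n
nonlinear parameters instead of n·(1 + n_λ) and is verified in the tests
against a brute-force joint fit of all amplitudes and lifetimes on small
instances (agreement to 1e−6 relative). Initial lifetimes default to n
values log-spaced across the observed time range; weights default to 1 and
per-point weights are honored everywhere. Adjacent fitted lifetimes with a
ratio below 1.05 flag the result as degenerate; a non-converged optimizer
flags the result rather than failing silently.

`weighted_residual_sd = sqrt(SSE_w / (N − n − n·n_λ))`. Model selection
increments n until the relative SD improvement falls below a threshold,
default 5% (exposed as `rel_improvement_tol` / `--tol`): on the default
fixture the SD drops ~2.3× from n=2 to n=3 and by ~0.2% from n=3 to n=4, so
the decision is insensitive to that default over a wide range.

### DAS → EAS

With compartments ordered fastest first, DASᵢ(λ) = Σⱼ b_ji·EASⱼ(λ); the
EAS solve this n×n triangular-structured system per wavelength. Nearly
equal rates make the system ill-conditioned; a condition number above 1e8
(or a rate ratio within 5%) attaches a warning to the result instead of
refusing, since the reconstruction identity still holds numerically.
Absolute intermediate spectra are ground + EAS/excited_fraction. The
photoexcited fraction cannot be inferred from the ΔA surface itself (it is
perfectly confounded with the EAS amplitudes) and is therefore a required
user parameter.

### Quasilog compression

Uniformly digitized traces are averaged inside time bins log-spaced at
`points_per_decade` (default 100) per decade; bin times are the mean of
member times, empty bins are dropped. Peak localization in spectra uses
the discrete maximum refined by the parabola through its two neighbours,
which recovers sub-grid peak positions (≤ 1 nm error for a 35 nm-wide
Gaussian sampled every 10 nm, verified against a fine-grid oracle).

## GHK electrodiffusion

Currents use the constant-field flux equation per ion with concentrations
(not activities — activity coefficients for the mixed solutions are not
available), a shared `scale` (pA) absorbing channel count and absolute
reference permeability, and an optional voltage-independent `offset` (pA)
motivated by the possibility of a pump-like component visible as non-zero
current under symmetric solutions at 0 mV; the offset term is off by
default and both variants are supported. Temperature defaults to 295 K
(room temperature), configurable. At |z·u| < 1e−6 the flux term switches
to its second-order Taylor expansion z([S]ᵢₙ−[S]ₒᵤₜ) + z²u([S]ᵢₙ+[S]ₒᵤₜ)/2,
making I(V) continuous and smooth through 0 mV (checked by finite
differences in the tests).

Divalents (Mg²⁺, Ca²⁺) are carried in the sum with z = 2 but default
relative permeability 0, consistent with a channel impermeable to Ca²⁺;
calcium inhibition is modelled as a multiplicative Hill-type block of the
monovalent current, not as a Ca²⁺ flux term. Whether the block reflects
pore occlusion or surface-charge screening is not distinguishable from a
dose–response curve and is not modelled.

Reversal potentials come from bracketing bisection (Brent) on [−200, 200]
mV to 0.01 mV; for monovalent-only compositions the closed-form GHK
voltage equation serves as an independent oracle in the tests (1000 random
compositions). Ratio fitting (`fit_permeability_ratios`) optimizes
{log₁₀ scale, log₁₀ ratio per free ion, optional offset} jointly across
all curves; log-space ratios are essential for protons, whose ratio spans
≥ 4 orders of magnitude. An ion with zero concentration in every
condition is rejected as unidentifiable.

The Ca²⁺ block fit reports both the fixed-n = 1 (Michaelis-type, single
site) and free-Hill variants, with the free Hill coefficient bounded to
[0.3, 4]; the data behind an "inflection point" estimate do not
discriminate the two functional forms. Off-kinetics fitting uses a plain
three-parameter exponential (baseline, amplitude, log τ) on t ≥ light-off
and warns when the trace covers less than 3τ.

## Titration

Only a single-pKa sigmoid is fitted (no Hill exponent on the titration),
parameterized with the acid limb at λ_base + Δλ — a red-shift at low pH, as
counterion protonation produces. λmax extraction windows default to
400–650 nm to isolate the retinal band from the 280 nm aromatic band used
for normalization. Fitting λmax positions (rather than absorbance ratios
or basis-spectrum decomposition) is the implemented interpretation of
"absorption maximum vs pH"; isosbestic analysis is out of scope.

## Synthetic generators and what passing tests show

The generators emulate the study conditions with the published estimates
as generating truths:

| quantity | generating truth | noise | recovery demanded |
|---|---|---|---|
| τ_off | 155 ms (i0 −50 pA, 1 ms/pt, 1 s) | 1 pA additive (2% of amplitude) | mean of 20 seeds within 5% |
| P_K⁺/P_Na⁺ | 0.5 (110 mM Na/K compositions) | 5% multiplicative | mean of 20 seeds within 10% |
| P_H⁺/P_Na⁺ | 10⁴·⁵ (pipette pH 5.0, arginine) | none | log₁₀ in [4, 5] |
| K_Ca²⁺ | 2.2 mM, n = 1, i_max 60 pA | 5% multiplicative | mean of 20 seeds within 15% |
| pKa / Δλ | 4.8 (λ_base 500 nm) and 3.5 (507 nm), Δλ 30 nm | 0.5 nm on λmax | pKa ±0.2, Δλ ±2 nm, λ_base ±1 nm |
| photocycle | bands 540/460/560 nm, σ 35 nm, ground 500 nm, τ = 5·10⁻⁵/0.3/1.5 s, excited fraction 0.2 | additive, 1% of max ΔA | n = 3 selected; slowest τ ±10%; peaks ±3 nm |

Only the band maxima, the slowest lifetime, the selectivity/block/closing
constants and the pKa values are published quantities; the two faster
photocycle lifetimes, band widths and amplitudes, the excited fraction,
and all noise levels are declared fixture constants chosen to be
realistic (1% of full scale for a 25-pulse-averaged ΔA surface, 5%
point-to-point scatter for whole-cell currents, half a nanometre on a
λmax read from a 2 nm-sampled spectrum). Grids default to 120 log-spaced
delays over 10 ns–10 s, 330–700 nm in 10 nm steps, and −80…+80 mV in
20 mV steps. Every generator call takes one explicit integer seed; the
same seed is bit-reproducible and noiseless generation is exactly
inverted by the corresponding fit (tested).

Noise semantics differ by modality on purpose: the ΔA generator adds
Gaussian noise scaled to the surface maximum (detector-limited noise does
not shrink with the signal), while the current/dose generators apply
per-point multiplicative scatter plus optional additive pA noise
(amplitude variability dominates patch-clamp repeats).

What the generators do **not** emulate — and hence what passing recovery
tests cannot certify about real recordings: shot noise and detector
nonlinearity, instrument response convolution, baseline drift, liquid
junction potentials, series-resistance and space-clamp errors, rundown,
cell-to-cell expression variability, and any state-dependent (photocycle-
coupled) conductance. The acceptance numbers demonstrate that the
estimators are unbiased and precise under the stated model, not that the
model captures every systematic error of the instruments.

## Numerical choices

- Exponential-sum and sigmoid fits run scipy least squares with tight
  tolerances (1e−12); positivity-constrained scalars (lifetimes, scale,
  K_half, τ_off) are optimized in log₁₀ space.
- Ties/degeneracies: collapsing lifetimes flag rather than fail; rate ties
  in the chain transform warn about conditioning; an λmax on a window edge
  is returned flagged rather than refined.
- Delimited output uses 17 significant digits, so write → read round-trips
  are exact at double precision.
- Acceptance-script problem sizes (20 seeds per stochastic recovery, one
  fixture surface for the global analysis) keep the full run at a few
  seconds while leaving seed-to-seed scatter well inside the demanded
  tolerances.
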