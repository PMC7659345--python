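"""Seeded generators for every input modality, with known ground truth.

The raw recordings behind a rhodopsin characterization — flash-photolysis
ΔA surfaces, whole-cell I–V families, blocker dose–response tables,
photocurrent-off traces, pH-series spectra — are emulated here from their
generating models, so that every fitting routine in this package can be
exercised as a parameter-recovery problem with the truth attached to the
generated object.

Conventions: one explicit integer seed per generator call (via
:class:`NoiseSpec`); noiseless generation is exactly invertible by the
corresponding fit.  The transient-absorption generator treats its relative
noise as a fraction of the surface maximum (detector-style additive noise);
the electrophysiology generators treat it as per-point multiplicative
scatter.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .ephys import (
    DecayTrace,
    DoseResponseCurve,
    IonSpecies,
    IVCurve,
    RecordingConditions,
    ghk_current,
)
from .photocycle import Spectrum, TransientDataset, chain_concentrations
from .titration import TitrationSeries, henderson_hasselbalch

__all__ = [
    "GaussianBand",
    "PhotocycleSpec",
    "NoiseSpec",
    "default_photocycle_spec",
    "default_time_grid",
    "default_wavelength_grid",
    "gen_transient_dataset",
    "standard_na_conditions",
    "gen_iv_dataset",
    "gen_dose_response",
    "gen_decay_trace",
    "gen_titration",
    "gen_titration_points",
]


@dataclass
class GaussianBand:
    """A Gaussian absorption band: A(λ) = amplitude·exp(−(λ−center)²/2σ²)."""

    center: float     # nm
    width: float      # Gaussian sigma, nm
    amplitude: float  # AU

    def __post_init__(self) -> None:
        if self.width <= 0:
            raise ValueError("band width must be positive")
        if self.amplitude < 0:
            raise ValueError("band amplitude must be >= 0")

    def __call__(self, wavelengths: np.ndarray) -> np.ndarray:
        wl = np.asarray(wavelengths, dtype=float)
        return self.amplitude * np.exp(-((wl - self.center) ** 2) / (2 * self.width**2))


@dataclass
class PhotocycleSpec:
    """Ground truth for a sequential photocycle: one Gaussian band per
    kinetic compartment, lifetimes strictly increasing (fastest first)."""

    ground: GaussianBand
    intermediates: list[GaussianBand]
    lifetimes: list[float]       # s, strictly increasing
    excited_fraction: float = 0.2

    def __post_init__(self) -> None:
        if len(self.intermediates) != len(self.lifetimes):
            raise ValueError("one lifetime per intermediate required")
        if not self.lifetimes:
            raise ValueError("at least one intermediate required")
        lt = np.asarray(self.lifetimes, dtype=float)
        if np.any(lt <= 0) or np.any(np.diff(lt) <= 0):
            raise ValueError("lifetimes must be positive and strictly increasing")
        if not 0 < self.excited_fraction <= 1:
            raise ValueError("excited_fraction must be in (0, 1]")


@dataclass
class NoiseSpec:
    """Gaussian noise description; sd_additive in signal units, sd_relative
    dimensionless.  All randomness flows from the integer seed."""

    sd_additive: float = 0.0
    sd_relative: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sd_additive < 0 or self.sd_relative < 0:
            raise ValueError("noise standard deviations must be >= 0")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


NOISELESS = NoiseSpec()


# ---------------------------------------------------------------------------
# transient absorption


def default_photocycle_spec() -> PhotocycleSpec:
    """Three-intermediate fixture: K-, L-, N-like bands at 540/460/560 nm
    on a 500 nm ground state, slowest compartment living 1.5 s.

    The two faster lifetimes and all band widths/amplitudes are declared
    fixture constants, not measured quantities.
    """
    sigma = 35.0
    return PhotocycleSpec(
        ground=GaussianBand(500.0, sigma, 1.0),
        intermediates=[
            GaussianBand(540.0, sigma, 1.0),
            GaussianBand(460.0, sigma, 1.0),
            GaussianBand(560.0, sigma, 1.0),
        ],
        lifetimes=[5e-5, 0.3, 1.5],
        excited_fraction=0.2,
    )


def default_time_grid() -> np.ndarray:
    """120 points log-spaced from 10 ns to 10 s."""
    return np.logspace(-8, 1, 120)


def default_wavelength_grid() -> np.ndarray:
    """330–700 nm in 10 nm steps."""
    return np.arange(330.0, 701.0, 10.0)


def gen_transient_dataset(
    spec: PhotocycleSpec,
    times: np.ndarray | None = None,
    wavelengths: np.ndarray | None = None,
    noise: NoiseSpec = NOISELESS,
) -> TransientDataset:
    """Synthesize a ΔA(λ, t) surface from a sequential photocycle.

    ΔA(λ, t) = excited_fraction · Σⱼ cⱼ(t)·(εⱼ(λ) − ε_ground(λ)) with the
    cⱼ the populations of the irreversible chain (c₁(0) = 1).  Noise is
    additive Gaussian with sd = sd_additive + sd_relative·max|ΔA|.  The
    generating spec and the noiseless concentration profiles are stored on
    the returned dataset (``truth`` attribute) for recovery tests.
    """
    t = default_time_grid() if times is None else np.asarray(times, dtype=float)
    wl = (
        default_wavelength_grid()
        if wavelengths is None
        else np.asarray(wavelengths, dtype=float)
    )
    if t.size == 0 or wl.size == 0:
        raise ValueError("empty time or wavelength grid")
    if np.any(t <= 0):
        raise ValueError("times must be positive")

    rates = 1.0 / np.asarray(spec.lifetimes, dtype=float)
    conc = chain_concentrations(rates, t)  # (n, n_t)
    eps_ground = spec.ground(wl)
    diff = np.array([band(wl) - eps_ground for band in spec.intermediates])  # (n, n_wl)
    clean = spec.excited_fraction * (diff.T @ conc)  # (n_wl, n_t)

    sd = noise.sd_additive + noise.sd_relative * np.max(np.abs(clean), initial=0.0)
    delta_a = clean if sd == 0 else clean + noise.rng().normal(0.0, sd, clean.shape)
    truth = {"spec": spec, "concentrations": conc, "noise_sd": sd}
    return TransientDataset(t, wl, delta_a, truth=truth)


# ---------------------------------------------------------------------------
# electrophysiology


def standard_na_conditions(
    na_out: float = 110.0,
    na_in: float = 110.0,
    temperature: float = 295.0,
) -> RecordingConditions:
    """Standard whole-cell composition: NaCl-based bath and pipette with
    2 mM Mg²⁺ carried as impermeant divalent."""
    return RecordingConditions(
        ions=[
            IonSpecies("Na", 1, na_in, na_out, rel_permeability=1.0),
            IonSpecies("Mg", 2, 2.0, 2.0, rel_permeability=0.0),
        ],
        temperature=temperature,
    )


def gen_iv_dataset(
    conditions: list[RecordingConditions],
    ratios: dict[str, float],
    scale: float = 1.0,
    offset: float = 0.0,
    voltages: np.ndarray | None = None,
    noise: NoiseSpec = NOISELESS,
) -> list[IVCurve]:
    """GHK-model I–V curves under a family of ionic conditions.

    ``ratios`` maps ion names to the true permeability ratios applied to
    every condition (other ions keep the ratio already set in the
    condition).  Noise: per-point multiplicative N(0, sd_relative) plus
    additive N(0, sd_additive) pA; each curve draws an independent stream
    spawned from the seed.
    """
    v = (
        np.arange(-80.0, 81.0, 20.0)
        if voltages is None
        else np.asarray(voltages, dtype=float)
    )
    import copy as _copy

    ss = np.random.SeedSequence(noise.seed)
    children = ss.spawn(len(conditions))
    curves = []
    for cond, child in zip(conditions, children):
        cond = _copy.deepcopy(cond)
        for ion in cond.ions:
            if ion.name in ratios:
                ion.rel_permeability = ratios[ion.name]
        clean = ghk_current(v, cond, scale, offset)
        rng = np.random.default_rng(child)
        i = clean.copy()
        if noise.sd_relative > 0:
            i = i * (1.0 + rng.normal(0.0, noise.sd_relative, i.shape))
        if noise.sd_additive > 0:
            i = i + rng.normal(0.0, noise.sd_additive, i.shape)
        curves.append(
            IVCurve(
                v.copy(),
                i,
                conditions=cond,
                truth={"ratios": dict(ratios), "scale": scale, "offset": offset},
            )
        )
    return curves


def gen_dose_response(
    i_max: float,
    k_half: float,
    hill_n: float,
    concentrations: np.ndarray,
    noise: NoiseSpec = NOISELESS,
    voltage: float = 80.0,
) -> DoseResponseCurve:
    """Hill-type block curve I(C) = i_max/(1 + (C/k_half)^hill_n) + noise."""
    if k_half <= 0 or hill_n <= 0:
        raise ValueError("k_half and hill_n must be positive")
    c = np.asarray(concentrations, dtype=float)
    clean = i_max / (1.0 + (c / k_half) ** hill_n)
    rng = noise.rng()
    i = clean.copy()
    if noise.sd_relative > 0:
        i = i * (1.0 + rng.normal(0.0, noise.sd_relative, i.shape))
    if noise.sd_additive > 0:
        i = i + rng.normal(0.0, noise.sd_additive, i.shape)
    return DoseResponseCurve(
        c, i, voltage=voltage,
        truth={"i_max": i_max, "k_half": k_half, "hill_n": hill_n},
    )


def gen_decay_trace(
    tau: float,
    i0: float,
    baseline: float = 0.0,
    dt: float = 1.0,
    duration: float = 1000.0,
    noise: NoiseSpec = NOISELESS,
) -> DecayTrace:
    """Monoexponential off-trace I(t) = baseline + i0·exp(−t/τ) + noise,
    times in ms starting at 0."""
    if tau <= 0 or dt <= 0 or duration <= 0:
        raise ValueError("tau, dt and duration must be positive")
    t = np.arange(0.0, duration + dt / 2, dt)
    clean = baseline + i0 * np.exp(-t / tau)
    rng = noise.rng()
    i = clean.copy()
    if noise.sd_relative > 0:
        i = i * (1.0 + rng.normal(0.0, noise.sd_relative, i.shape))
    if noise.sd_additive > 0:
        i = i + rng.normal(0.0, noise.sd_additive, i.shape)
    return DecayTrace(t, i, truth={"tau": tau, "i0": i0, "baseline": baseline})


# ---------------------------------------------------------------------------
# titration


def gen_titration(
    pka: float,
    lambda_base: float,
    delta_lambda: float,
    ph_values: np.ndarray,
    band_width: float = 35.0,
    noise: NoiseSpec = NOISELESS,
    wavelengths: np.ndarray | None = None,
) -> TitrationSeries:
    """pH series of spectra whose retinal band follows the titration sigmoid.

    Each spectrum holds a unit-amplitude Gaussian retinal band centered at
    λ(pH) = lambda_base + delta_lambda/(1 + 10^(pH − pKa)) plus a fixed
    aromatic protein band at 280 nm for normalization; noise (sd_additive
    AU + sd_relative of the band amplitude) is additive on the absorbances.
    """
    wl = (
        np.arange(250.0, 701.0, 2.0)
        if wavelengths is None
        else np.asarray(wavelengths, dtype=float)
    )
    ph = np.asarray(ph_values, dtype=float)
    rng = noise.rng()
    entries: list[tuple[float, Spectrum]] = []
    protein = GaussianBand(280.0, 20.0, 2.0)
    for p in ph:
        center = float(henderson_hasselbalch(np.array(p), pka, lambda_base, delta_lambda))
        retinal = GaussianBand(center, band_width, 1.0)
        a = retinal(wl) + protein(wl)
        sd = noise.sd_additive + noise.sd_relative * 1.0
        if sd > 0:
            a = a + rng.normal(0.0, sd, a.shape)
        entries.append((float(p), Spectrum(wl.copy(), a)))
    series = TitrationSeries(entries)
    series.truth = {"pka": pka, "lambda_base": lambda_base, "delta_lambda": delta_lambda}
    return series


def gen_titration_points(
    pka: float,
    lambda_base: float,
    delta_lambda: float,
    ph_values: np.ndarray,
    noise: NoiseSpec = NOISELESS,
) -> TitrationSeries:
    """(pH, λmax) titration points with Gaussian noise (sd_additive, nm)
    directly on the extracted maxima."""
    ph = np.asarray(ph_values, dtype=float)
    centers = henderson_hasselbalch(ph, pka, lambda_base, delta_lambda)
    rng = noise.rng()
    if noise.sd_additive > 0:
        centers = centers + rng.normal(0.0, noise.sd_additive, centers.shape)
    series = TitrationSeries([(float(p), float(c)) for p, c in zip(ph, centers)])
    series.truth = {"pka": pka, "lambda_base": lambda_base, "delta_lambda": delta_lambda}
    return series
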