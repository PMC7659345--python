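"""Spectroscopic pKa determination from pH-series absorption spectra.

Protonation of the retinal Schiff-base counterion red-shifts the visible
absorption band of a microbial rhodopsin.  Tracking the band maximum λmax
across a pH series and fitting the single-protonation-site sigmoid

    λ(pH) = λ_base + Δλ / (1 + 10^(pH − pKa))

(the Henderson–Hasselbalch form: λ_base is the alkaline asymptote, λ_base+Δλ
the acid asymptote) yields the counterion pKa.  Spectra are normalized at
the 280 nm aromatic protein band so that concentration differences between
pH points cancel.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

from .photocycle import Spectrum, find_lambda_max

__all__ = [
    "TitrationSeries",
    "PkaFit",
    "henderson_hasselbalch",
    "normalize_at_280",
    "extract_lambda_max_series",
    "fit_henderson_hasselbalch",
]

DEFAULT_WINDOW = (400.0, 650.0)  # nm; isolates the retinal band from 280 nm


@dataclass
class TitrationSeries:
    """pH-indexed spectra, or pre-extracted (pH, λmax) points."""

    entries: list[tuple[float, Spectrum]] | list[tuple[float, float]]
    truth: dict | None = None  # generating parameters, when synthetic

    def __post_init__(self) -> None:
        phs = [ph for ph, _ in self.entries]
        if len(set(phs)) != len(phs):
            raise ValueError("pH values must be distinct")

    @property
    def holds_spectra(self) -> bool:
        return bool(self.entries) and isinstance(self.entries[0][1], Spectrum)


@dataclass
class PkaFit:
    """Single-pKa Henderson–Hasselbalch fit of λmax vs pH."""

    pka: float           # pH units
    lambda_base: float   # nm, alkaline asymptote
    delta_lambda: float  # nm, acid-induced red-shift
    residual_sd: float   # nm
    extrapolated: bool = False  # pKa outside the sampled pH range ± 1

    def predict(self, ph: np.ndarray) -> np.ndarray:
        return henderson_hasselbalch(np.asarray(ph, dtype=float),
                                     self.pka, self.lambda_base, self.delta_lambda)


def henderson_hasselbalch(
    ph: np.ndarray, pka: float, lambda_base: float, delta_lambda: float
) -> np.ndarray:
    """λ(pH) = lambda_base + delta_lambda / (1 + 10^(pH − pKa))."""
    return lambda_base + delta_lambda / (1.0 + 10.0 ** (ph - pka))


def normalize_at_280(spectrum: Spectrum) -> Spectrum:
    """Divide a spectrum by its (interpolated) absorbance at 280 nm."""
    wl = spectrum.wavelengths
    if not (wl[0] <= 280.0 <= wl[-1]):
        raise ValueError("280 nm outside the spectral range")
    a280 = float(np.interp(280.0, wl, spectrum.values))
    if a280 <= 0:
        raise ValueError(f"non-positive absorbance at 280 nm ({a280:.3g})")
    return Spectrum(wl.copy(), spectrum.values / a280)


def extract_lambda_max_series(
    series: TitrationSeries,
    window: tuple[float, float] = DEFAULT_WINDOW,
) -> list[tuple[float, float]]:
    """(pH, λmax) points from a titration series.

    Spectra are 280 nm-normalized and their maxima located inside ``window``
    (which must exclude the protein band); entries that already hold λmax
    values pass through unchanged.
    """
    if not series.holds_spectra:
        return [(float(ph), float(lm)) for ph, lm in series.entries]
    out = []
    for ph, spec in series.entries:
        lm = find_lambda_max(normalize_at_280(spec), window)
        out.append((float(ph), lm.wavelength))
    return out


def fit_henderson_hasselbalch(points: list[tuple[float, float]]) -> PkaFit:
    """Least-squares fit of the single-pKa sigmoid to (pH, λmax) points."""
    if len(points) < 4:
        raise ValueError("need at least 4 (pH, lambda_max) points")
    ph = np.array([p for p, _ in points], dtype=float)
    lam = np.array([l for _, l in points], dtype=float)
    if ph.max() - ph.min() < 1.0:
        raise ValueError("pH range must span at least 1 unit")
    span = lam.max() - lam.min()
    if span < 1e-3:
        raise ValueError("lambda_max is flat across the series: no titration signal")

    order = np.argsort(ph)
    base0 = lam[order][-1]          # alkaline asymptote
    delta0 = lam[order][0] - base0  # acid red-shift
    pka0 = float(np.median(ph))
    popt, _ = curve_fit(
        lambda p, pka, base, delta: henderson_hasselbalch(p, pka, base, delta),
        ph, lam, p0=[pka0, base0, delta0], maxfev=20000,
    )
    pka, base, delta = (float(v) for v in popt)
    resid = lam - henderson_hasselbalch(ph, pka, base, delta)
    sd = float(np.sqrt(np.sum(resid**2) / max(ph.size - 3, 1)))
    extrapolated = not (ph.min() - 1.0 <= pka <= ph.max() + 1.0)
    return PkaFit(pka, base, delta, sd, extrapolated)
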