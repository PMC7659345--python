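"""Global kinetic analysis of flash-photolysis transient-absorption data.

A rhodopsin photocycle probed by transient absorption yields a matrix of
absorbance changes ΔA(λ, t).  Under a global multiexponential model

    ΔA(λ, t) = Σᵢ DASᵢ(λ) · exp(−t / τᵢ)

the lifetimes τᵢ are shared across wavelengths while the amplitudes — the
decay-associated spectra (DAS) — are wavelength-resolved.  The fit uses
variable projection: the nonlinear search runs over the (log) lifetimes
only, with the DAS solved by linear least squares at every iterate.

Assuming the intermediates form a single irreversible chain ordered fastest
first (K → L → N → ground), the DAS are a known linear transform (Bateman
coefficients) of the evolution-associated difference spectra (EAS) of the
kinetic compartments; :func:`das_to_eas` inverts that transform and also
returns the compartment concentration profiles.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np
from scipy.optimize import least_squares

__all__ = [
    "TransientDataset",
    "GlobalFitResult",
    "SequentialScheme",
    "Spectrum",
    "LambdaMax",
    "quasilog_compress",
    "fit_global_exponentials",
    "select_model",
    "das_to_eas",
    "intermediate_spectra",
    "find_lambda_max",
    "bateman_coefficients",
    "chain_concentrations",
]

#: adjacent-lifetime ratio below which a fit is flagged degenerate
DEGENERACY_RATIO = 1.05


@dataclass
class Spectrum:
    """A single absorption (or difference) spectrum on a wavelength grid."""

    wavelengths: np.ndarray  # nm, strictly increasing
    values: np.ndarray       # AU

    def __post_init__(self) -> None:
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.wavelengths.shape != self.values.shape:
            raise ValueError("wavelengths and values must have equal length")
        if self.wavelengths.size and np.any(np.diff(self.wavelengths) <= 0):
            raise ValueError("wavelengths must be strictly increasing")


@dataclass
class TransientDataset:
    """ΔA(λ, t) matrix with optional per-point weights.

    ``delta_a`` has shape ``(len(wavelengths), len(times))`` — one row per
    wavelength, one column per delay time.  ``weights`` (same shape) scale
    the residuals in the global fit; they default to 1.
    """

    times: np.ndarray        # s, strictly increasing
    wavelengths: np.ndarray  # nm, strictly increasing
    delta_a: np.ndarray      # AU, shape (n_wl, n_t)
    weights: np.ndarray | None = None
    truth: object | None = None  # generating parameters, when synthetic

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.delta_a = np.asarray(self.delta_a, dtype=float)
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(np.diff(self.wavelengths) <= 0):
            raise ValueError("wavelengths must be strictly increasing")
        if self.delta_a.shape != (self.wavelengths.size, self.times.size):
            raise ValueError(
                f"delta_a shape {self.delta_a.shape} does not match "
                f"(n_wavelengths={self.wavelengths.size}, n_times={self.times.size})"
            )
        if not np.all(np.isfinite(self.delta_a)):
            raise ValueError("delta_a contains non-finite entries")
        if self.weights is None:
            self.weights = np.ones_like(self.delta_a)
        else:
            self.weights = np.asarray(self.weights, dtype=float)
            if self.weights.shape != self.delta_a.shape:
                raise ValueError("weights must match delta_a shape")
            if np.any(self.weights < 0):
                raise ValueError("weights must be non-negative")


@dataclass
class GlobalFitResult:
    """Outcome of a global multiexponential fit."""

    n_components: int
    lifetimes: np.ndarray          # s, strictly increasing
    das: np.ndarray                # (n_components, n_wl), AU
    wavelengths: np.ndarray        # nm
    weighted_residual_sd: float    # AU
    converged: bool
    degenerate: bool = False       # adjacent lifetimes closer than 5%
    sd_trace: dict[int, float] = field(default_factory=dict)  # model selection

    def model(self, times: np.ndarray) -> np.ndarray:
        """Reconstruct ΔA_model(λ, t) = Σᵢ DASᵢ(λ)·exp(−t/τᵢ)."""
        t = np.asarray(times, dtype=float)
        decays = np.exp(-t[None, :] / self.lifetimes[:, None])  # (n, n_t)
        return self.das.T @ decays


@dataclass
class SequentialScheme:
    """Irreversible sequential-chain interpretation of a global fit."""

    rates: np.ndarray           # s⁻¹, decreasing (fastest compartment first)
    bateman: np.ndarray         # lower-triangular coefficients b[j, i]
    eas: np.ndarray             # (n, n_wl) evolution-associated difference spectra
    concentrations: np.ndarray  # (n, n_t) compartment populations
    times: np.ndarray           # s, grid of the concentration profiles
    wavelengths: np.ndarray     # nm
    condition_warning: str | None = None


class LambdaMax(NamedTuple):
    """Refined spectral-maximum position; ``at_edge`` flags an unreliable
    maximum sitting on the boundary of the search window."""

    wavelength: float  # nm
    at_edge: bool

    def __float__(self) -> float:  # allows float(find_lambda_max(...))
        return self.wavelength


# ---------------------------------------------------------------------------
# sequential-chain kinetics


def bateman_coefficients(rates: Sequence[float]) -> np.ndarray:
    """Coefficients of the irreversible first-order chain 1 → 2 → … → n.

    With unit population in compartment 1 at t = 0, the populations are

        cⱼ(t) = Σᵢ b[j, i] · exp(−kᵢ t),
        b[j, i] = (Π_{m<j} k_m) / (Π_{m≤j, m≠i} (k_m − k_i))   for i ≤ j,

    the classic closed-form solution for a radioactive-decay-style chain.
    Requires pairwise-distinct rates.
    """
    k = np.asarray(rates, dtype=float)
    n = k.size
    if n == 0:
        raise ValueError("at least one rate required")
    if np.any(k <= 0):
        raise ValueError("rates must be positive")
    b = np.zeros((n, n))
    for j in range(n):
        prefactor = np.prod(k[:j])  # empty product = 1 for j = 0
        for i in range(j + 1):
            denom = 1.0
            for m in range(j + 1):
                if m != i:
                    denom *= k[m] - k[i]
            if denom == 0.0:
                raise ValueError("Bateman coefficients undefined for equal rates")
            b[j, i] = prefactor / denom
    return b


def chain_concentrations(rates: Sequence[float], times: np.ndarray) -> np.ndarray:
    """Population profiles cⱼ(t) of the irreversible chain, shape (n, n_t)."""
    k = np.asarray(rates, dtype=float)
    t = np.asarray(times, dtype=float)
    b = bateman_coefficients(k)
    decays = np.exp(-np.outer(k, t))  # (n, n_t)
    return b @ decays


# ---------------------------------------------------------------------------
# data compression


def quasilog_compress(
    times: np.ndarray,
    values: np.ndarray,
    points_per_decade: int,
) -> tuple[np.ndarray, np.ndarray]:
    """Bin uniformly sampled traces into log-spaced time bins.

    Flash-photolysis transients are digitized linearly (tens of thousands of
    points) but evolve over many decades; averaging within bins log-spaced at
    ``points_per_decade`` per decade equalizes information density and
    reduces the data to ~10² points per decade of delay time.

    ``values`` may be 1-D (one trace) or 2-D with time on the last axis.
    Each output time is the mean of the input times in its bin, each output
    value the mean of the corresponding samples; empty bins are dropped.
    """
    t = np.asarray(times, dtype=float)
    v = np.asarray(values, dtype=float)
    if t.ndim != 1 or t.size == 0:
        raise ValueError("times must be a non-empty 1-D array")
    if np.any(t <= 0):
        raise ValueError("times must be strictly positive (log binning)")
    if np.any(np.diff(t) <= 0):
        raise ValueError("times must be strictly increasing")
    if points_per_decade < 1:
        raise ValueError("points_per_decade must be >= 1")
    if v.shape[-1] != t.size:
        raise ValueError("last axis of values must match times")

    lo, hi = np.log10(t[0]), np.log10(t[-1])
    n_bins = max(1, int(np.ceil((hi - lo) * points_per_decade)))
    edges = np.logspace(lo, hi, n_bins + 1)
    # right-closed last bin so t[-1] is kept
    idx = np.clip(np.searchsorted(edges, t, side="right") - 1, 0, n_bins - 1)

    counts = np.bincount(idx, minlength=n_bins)
    keep = counts > 0
    t_out = np.bincount(idx, weights=t, minlength=n_bins)[keep] / counts[keep]
    if v.ndim == 1:
        v_out = np.bincount(idx, weights=v, minlength=n_bins)[keep] / counts[keep]
    else:
        rows = [
            np.bincount(idx, weights=row, minlength=n_bins)[keep] / counts[keep]
            for row in v.reshape(-1, t.size)
        ]
        v_out = np.array(rows).reshape(v.shape[:-1] + (int(keep.sum()),))
    return t_out, v_out


def compress_dataset(data: TransientDataset, points_per_decade: int) -> TransientDataset:
    """Apply :func:`quasilog_compress` to every wavelength trace of a dataset."""
    t_out, a_out = quasilog_compress(data.times, data.delta_a, points_per_decade)
    _, w_out = quasilog_compress(data.times, data.weights, points_per_decade)
    return TransientDataset(t_out, data.wavelengths, a_out, w_out, truth=data.truth)


# ---------------------------------------------------------------------------
# global multiexponential fitting (variable projection)


def _solve_das(
    log10_tau: np.ndarray,
    times: np.ndarray,
    y: np.ndarray,
    w: np.ndarray,
    uniform_weights: bool,
) -> tuple[np.ndarray, np.ndarray]:
    """Amplitudes by (weighted) linear least squares at fixed lifetimes.

    Returns (das, weighted residual matrix), with ``y``/``w`` of shape
    (n_t, n_wl) and das of shape (n, n_wl).
    """
    tau = 10.0 ** log10_tau
    e = np.exp(-times[:, None] / tau[None, :])  # (n_t, n)
    if uniform_weights:
        das, *_ = np.linalg.lstsq(e, y)
        resid = (y - e @ das) * w
    else:
        das = np.empty((tau.size, y.shape[1]))
        for j in range(y.shape[1]):
            wj = w[:, j]
            aj, *_ = np.linalg.lstsq(e * wj[:, None], y[:, j] * wj)
            das[:, j] = aj
        resid = (y - e @ das) * w
    return das, resid


def fit_global_exponentials(
    data: TransientDataset,
    n: int,
    initial_lifetimes: Sequence[float] | str = "auto",
) -> GlobalFitResult:
    """Fit ΔA(λ, t) = Σᵢ DASᵢ(λ)·exp(−t/τᵢ) with shared lifetimes.

    The nonlinear search runs over log₁₀ τ (positivity for free, and the
    lifetimes of a photocycle span many decades); at each iterate the DAS
    are the exact weighted linear-least-squares solution, so only ``n``
    nonlinear parameters remain (variable projection).

    ``initial_lifetimes='auto'`` seeds the search with ``n`` lifetimes
    log-spaced over the observed time range.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    n_wl, n_t = data.delta_a.shape
    n_params = n + n * n_wl
    n_points = n_wl * n_t
    if n_params > n_points:
        raise ValueError(f"model has {n_params} parameters but only {n_points} points")

    y = data.delta_a.T.copy()   # (n_t, n_wl)
    w = data.weights.T.copy()
    uniform = np.allclose(w, w.flat[0])

    if isinstance(initial_lifetimes, str):
        if initial_lifetimes != "auto":
            raise ValueError("initial_lifetimes must be a sequence or 'auto'")
        x0 = np.linspace(
            np.log10(data.times[0] * 3.0), np.log10(data.times[-1] / 3.0), n
        )
    else:
        x0 = np.log10(np.asarray(initial_lifetimes, dtype=float))
        if x0.size != n:
            raise ValueError("initial_lifetimes length must equal n")

    def residuals(x: np.ndarray) -> np.ndarray:
        _, r = _solve_das(x, data.times, y, w, uniform)
        return r.ravel()

    sol = least_squares(residuals, x0, method="lm" if n_points > n else "trf",
                        xtol=1e-12, ftol=1e-12, gtol=1e-12, max_nfev=400 * n)
    order = np.argsort(sol.x)
    log_tau = sol.x[order]
    das, resid = _solve_das(log_tau, data.times, y, w, uniform)

    dof = max(n_points - n_params, 1)
    sd = float(np.sqrt(np.sum(resid**2) / dof))
    tau = 10.0 ** log_tau
    degenerate = bool(n > 1 and np.any(tau[1:] / tau[:-1] < DEGENERACY_RATIO))
    converged = bool(sol.status > 0)
    if not converged:
        warnings.warn("global exponential fit did not converge", RuntimeWarning)
    if degenerate:
        warnings.warn(
            "nearly collapsing lifetimes (ratio < 1.05); fit flagged degenerate",
            RuntimeWarning,
        )
    return GlobalFitResult(
        n_components=n,
        lifetimes=tau,
        das=das,
        wavelengths=data.wavelengths.copy(),
        weighted_residual_sd=sd,
        converged=converged,
        degenerate=degenerate,
    )


def select_model(
    data: TransientDataset,
    n_max: int,
    rel_improvement_tol: float = 0.05,
    initial_lifetimes: str | Sequence[float] = "auto",
) -> GlobalFitResult:
    """Increment the number of exponentials until the weighted residual SD
    stops improving.

    Fits n = 1, 2, … and accepts n as soon as the relative SD improvement
    from n to n+1 falls below ``rel_improvement_tol`` (or n_max is reached).
    The SD-vs-n trace is attached to the returned fit for reporting.
    """
    if n_max < 1:
        raise ValueError("n_max must be >= 1")
    sd_trace: dict[int, float] = {}
    fits: dict[int, GlobalFitResult] = {}
    accepted = None
    for n in range(1, n_max + 1):
        fits[n] = fit_global_exponentials(data, n, initial_lifetimes)
        sd_trace[n] = fits[n].weighted_residual_sd
        if n > 1:
            prev = sd_trace[n - 1]
            improvement = (prev - sd_trace[n]) / prev if prev > 0 else 0.0
            if improvement < rel_improvement_tol:
                accepted = fits[n - 1]
                break
    if accepted is None:
        accepted = fits[n_max]
    accepted.sd_trace = sd_trace
    return accepted


# ---------------------------------------------------------------------------
# DAS → EAS transform and intermediate spectra


def das_to_eas(fit: GlobalFitResult, times: np.ndarray | None = None) -> SequentialScheme:
    """Interpret a global fit as an irreversible sequential chain.

    With compartments ordered fastest first (rates kᵢ = 1/τᵢ, decreasing)
    and unit initial population in the first, the multiexponential model and
    the chain model are related per wavelength by DAS = Mᵀ·EAS where M holds
    the Bateman coefficients; this solves that linear system for the EAS and
    emits the compartment concentration profiles.
    """
    tau = np.asarray(fit.lifetimes, dtype=float)
    if np.any(np.diff(tau) <= 0):
        raise ValueError("lifetimes must be distinct and increasing")
    rates = 1.0 / tau  # decreasing: fastest compartment first
    b = bateman_coefficients(rates)
    # DAS_i(λ) = Σ_j b[j, i] · EAS_j(λ)  →  solve bᵀ · EAS = DAS
    m = b.T
    cond = np.linalg.cond(m)
    warning = None
    if cond > 1e8 or np.any(rates[:-1] / rates[1:] < DEGENERACY_RATIO):
        warning = (
            f"nearly equal chain rates (condition number {cond:.2g}); "
            "EAS may be poorly determined"
        )
        warnings.warn(warning, RuntimeWarning)
    eas = np.linalg.solve(m, fit.das)
    t = np.asarray(times, dtype=float) if times is not None else None
    if t is None:
        # a default grid spanning the fitted dynamics
        t = np.logspace(np.log10(tau[0] / 100), np.log10(tau[-1] * 10), 200)
    conc = b @ np.exp(-np.outer(rates, t))
    return SequentialScheme(
        rates=rates,
        bateman=b,
        eas=eas,
        concentrations=conc,
        times=t,
        wavelengths=fit.wavelengths.copy(),
        condition_warning=warning,
    )


def intermediate_spectra(
    scheme: SequentialScheme,
    ground: Spectrum,
    excited_fraction: float,
) -> list[Spectrum]:
    """Absolute absorption spectra of the chain intermediates.

    The EAS are difference spectra of the full sample, of which only a
    fraction was photoexcited; the absolute spectrum of intermediate j is
    ground + EASⱼ / excited_fraction, with the ground spectrum linearly
    interpolated onto the dataset's wavelength grid.
    """
    if not 0 < excited_fraction <= 1:
        raise ValueError("excited_fraction must be in (0, 1]")
    wl = scheme.wavelengths
    if wl[0] < ground.wavelengths[0] or wl[-1] > ground.wavelengths[-1]:
        raise ValueError("ground spectrum does not cover the dataset wavelength range")
    g = np.interp(wl, ground.wavelengths, ground.values)
    return [Spectrum(wl.copy(), g + row / excited_fraction) for row in scheme.eas]


def find_lambda_max(
    spectrum: Spectrum,
    window: tuple[float, float] | str = "full",
) -> LambdaMax:
    """Locate the spectral maximum, refined by parabolic interpolation.

    Finds the discrete maximum inside ``window`` (nm range, or "full") and
    refines it with the vertex of the parabola through the three surrounding
    points — recovering sub-grid peak positions from coarsely sampled
    spectra.  A maximum on the window edge is returned as-is with
    ``at_edge=True``.
    """
    wl, v = spectrum.wavelengths, spectrum.values
    if isinstance(window, str):
        if window != "full":
            raise ValueError("window must be a (lo, hi) pair or 'full'")
        mask = np.ones_like(wl, dtype=bool)
    else:
        lo, hi = window
        mask = (wl >= lo) & (wl <= hi)
    if mask.sum() < 3:
        raise ValueError("need at least 3 points in the window")
    wl, v = wl[mask], v[mask]
    i = int(np.argmax(v))
    if i == 0 or i == wl.size - 1:
        return LambdaMax(float(wl[i]), at_edge=True)
    x0, x1, x2 = wl[i - 1], wl[i], wl[i + 1]
    y0, y1, y2 = v[i - 1], v[i], v[i + 1]
    denom = (x0 - x1) * (x0 - x2) * (x1 - x2)
    a = (x2 * (y1 - y0) + x1 * (y0 - y2) + x0 * (y2 - y1)) / denom
    bq = (x2**2 * (y0 - y1) + x1**2 * (y2 - y0) + x0**2 * (y1 - y2)) / denom
    if a == 0:
        return LambdaMax(float(x1), at_edge=False)
    return LambdaMax(float(-bq / (2 * a)), at_edge=False)
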