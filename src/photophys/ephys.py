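"""Whole-cell photocurrent analysis: GHK electrodiffusion, ion selectivity,
divalent block, channel-closing kinetics, action spectra.

The constant-field (Goldman–Hodgkin–Katz) flux model describes the current
carried by each permeant ion S through a passively conducting channel:

    I_S(V) = P_S · z_S² · u · ([S]_in − [S]_out · e^{−z_S u}) / (1 − e^{−z_S u}),
    u = V·F/(R·T)

Permeabilities enter only as ratios to a reference ion (here Na⁺), with a
single scale factor absorbing channel count, absolute permeability and
geometry.  Permeability ratios are inferred by jointly least-squares fitting
I–V families recorded under ion substitution.  Sign convention: inward
current negative, depolarizing voltages positive.
"""

from __future__ import annotations

import copy
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import brentq, curve_fit, least_squares

from .photocycle import LambdaMax, Spectrum, find_lambda_max

__all__ = [
    "FARADAY",
    "GAS_CONSTANT",
    "IonSpecies",
    "RecordingConditions",
    "IVCurve",
    "PermeabilityFit",
    "DoseResponseCurve",
    "BlockFit",
    "DecayTrace",
    "NoReversalError",
    "ghk_current",
    "ghk_voltage",
    "reversal_potential",
    "fit_permeability_ratios",
    "fit_ca_block",
    "fit_tau_off",
    "action_spectrum",
]

FARADAY = 96485.33212  # C/mol
GAS_CONSTANT = 8.31446261815324  # J/(mol K)


class NoReversalError(ValueError):
    """Total current does not change sign on the search interval."""


@dataclass
class IonSpecies:
    """One ionic species with pipette/bath concentrations and permeability
    relative to the reference ion."""

    name: str
    z: int                       # signed valence (±1, ±2)
    conc_in: float               # pipette, mM
    conc_out: float              # bath, mM
    rel_permeability: float = 0.0  # P_X / P_reference

    def __post_init__(self) -> None:
        if self.z == 0:
            raise ValueError("charge must be non-zero")
        if self.conc_in < 0 or self.conc_out < 0:
            raise ValueError(f"negative concentration for {self.name}")
        if self.rel_permeability < 0:
            raise ValueError("relative permeability must be >= 0")


@dataclass
class RecordingConditions:
    """Full ionic composition of one recording, plus temperature (K)."""

    ions: list[IonSpecies]
    temperature: float = 295.0  # room temperature

    def __post_init__(self) -> None:
        if self.temperature <= 0:
            raise ValueError("temperature must be positive (kelvin)")
        refs = [ion for ion in self.ions if ion.rel_permeability == 1.0]
        if len(refs) != 1:
            raise ValueError(
                "exactly one reference ion with rel_permeability == 1 required, "
                f"found {len(refs)}"
            )

    @property
    def reference_ion(self) -> IonSpecies:
        return next(ion for ion in self.ions if ion.rel_permeability == 1.0)

    def ion(self, name: str) -> IonSpecies:
        for ion in self.ions:
            if ion.name == name:
                return ion
        raise KeyError(name)

    def thermal_voltage_mv(self) -> float:
        """RT/F in mV."""
        return GAS_CONSTANT * self.temperature / FARADAY * 1e3


@dataclass
class IVCurve:
    """Measured current–voltage points under one ionic condition."""

    voltages: np.ndarray  # mV, strictly increasing
    currents: np.ndarray  # pA
    conditions: RecordingConditions = None
    sem: np.ndarray | None = None
    truth: dict | None = None  # generating parameters, when synthetic

    def __post_init__(self) -> None:
        self.voltages = np.asarray(self.voltages, dtype=float)
        self.currents = np.asarray(self.currents, dtype=float)
        if self.voltages.shape != self.currents.shape:
            raise ValueError("voltages and currents must have equal length")
        if np.any(np.diff(self.voltages) <= 0):
            raise ValueError("voltages must be strictly increasing")
        if self.sem is not None:
            self.sem = np.asarray(self.sem, dtype=float)
            if self.sem.shape != self.voltages.shape:
                raise ValueError("sem must match voltages length")


@dataclass
class PermeabilityFit:
    """Joint GHK fit across I–V curves."""

    log10_ratios: dict[str, float]     # per fitted (non-reference) ion
    scale: float                       # pA, lumps N·P_ref and geometry
    offset: float                      # pA, voltage-independent component
    reversal_potential: float          # mV, first curve's conditions at the optimum
    residual_sd: float                 # pA
    per_curve_residuals: list[np.ndarray] = field(default_factory=list)

    def ratio(self, name: str) -> float:
        return 10.0 ** self.log10_ratios[name]


@dataclass
class DoseResponseCurve:
    """Photocurrent vs blocker concentration at a fixed holding voltage."""

    concentrations: np.ndarray  # mM, strictly increasing
    currents: np.ndarray        # pA
    voltage: float = 80.0       # mV
    truth: dict | None = None

    def __post_init__(self) -> None:
        self.concentrations = np.asarray(self.concentrations, dtype=float)
        self.currents = np.asarray(self.currents, dtype=float)
        if self.concentrations.shape != self.currents.shape:
            raise ValueError("concentrations and currents must have equal length")
        if np.any(self.concentrations < 0):
            raise ValueError("concentrations must be >= 0")
        if np.any(np.diff(self.concentrations) <= 0):
            raise ValueError("concentrations must be strictly increasing")


@dataclass
class BlockFit:
    """Hill-type inhibition fit I(C) = i_max / (1 + (C/k_half)^hill_n)."""

    i_max: float    # pA, unblocked current
    k_half: float   # mM, half-inhibition concentration
    hill_n: float
    residual_sd: float = np.nan

    def predict(self, concentrations: np.ndarray) -> np.ndarray:
        c = np.asarray(concentrations, dtype=float)
        return self.i_max / (1.0 + (c / self.k_half) ** self.hill_n)


@dataclass
class DecayTrace:
    """Photocurrent relaxation after the light is switched off."""

    times: np.ndarray     # ms, strictly increasing
    currents: np.ndarray  # pA
    truth: dict | None = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.currents = np.asarray(self.currents, dtype=float)
        if self.times.shape != self.currents.shape:
            raise ValueError("times and currents must have equal length")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")


# ---------------------------------------------------------------------------
# GHK model


def _ghk_flux_term(z: int, u: np.ndarray, c_in: float, c_out: float) -> np.ndarray:
    """z²·u·(c_in − c_out·e^{−zu})/(1 − e^{−zu}), with the analytic small-u
    limit z·(c_in − c_out) + z²·u·(c_in + c_out)/2 so the current is
    continuous through V = 0."""
    zu = z * u
    small = np.abs(zu) < 1e-6
    out = np.empty_like(u)
    with np.errstate(over="ignore", invalid="ignore"):
        ezu = np.exp(-zu[~small])
        out[~small] = z * z * u[~small] * (c_in - c_out * ezu) / (1.0 - ezu)
    out[small] = z * (c_in - c_out) + z * z * u[small] * (c_in + c_out) / 2.0
    return out


def ghk_current(
    v: float | np.ndarray,
    conditions: RecordingConditions,
    scale: float = 1.0,
    offset: float = 0.0,
    per_ion: bool = False,
):
    """Total GHK current (pA) at membrane voltage ``v`` (mV).

    I(V) = offset + scale · Σ_S r_S · z_S²·u·([S]_in − [S]_out e^{−z_S u})
    / (1 − e^{−z_S u}) with u = VF/RT.  With ``per_ion=True`` also returns
    the scaled contribution of each species (offset excluded).
    """
    v_arr = np.atleast_1d(np.asarray(v, dtype=float))
    if not np.all(np.isfinite(v_arr)):
        raise ValueError("voltage must be finite")
    u = v_arr / conditions.thermal_voltage_mv()
    total = np.zeros_like(u)
    parts: dict[str, np.ndarray] = {}
    for ion in conditions.ions:
        term = ion.rel_permeability * _ghk_flux_term(ion.z, u, ion.conc_in, ion.conc_out)
        parts[ion.name] = scale * term
        total += term
    total = offset + scale * total
    if np.isscalar(v) or np.ndim(v) == 0:
        total = float(total[0])
        parts = {k: float(p[0]) for k, p in parts.items()}
    if per_ion:
        return total, parts
    return total


def ghk_voltage(conditions: RecordingConditions) -> float:
    """Closed-form GHK (zero-current) voltage for monovalent ions, mV.

    U_rev = (RT/F)·ln[(Σ_cat P[out] + Σ_an P[in]) / (Σ_cat P[in] + Σ_an P[out])].
    Only valid when every permeant ion is monovalent.
    """
    num = den = 0.0
    for ion in conditions.ions:
        if ion.rel_permeability == 0:
            continue
        if abs(ion.z) != 1:
            raise ValueError("closed-form GHK voltage requires monovalent ions")
        if ion.z == 1:
            num += ion.rel_permeability * ion.conc_out
            den += ion.rel_permeability * ion.conc_in
        else:
            num += ion.rel_permeability * ion.conc_in
            den += ion.rel_permeability * ion.conc_out
    if num <= 0 or den <= 0:
        raise NoReversalError("one-sided permeant concentrations: no finite reversal")
    return conditions.thermal_voltage_mv() * np.log(num / den)


def reversal_potential(
    conditions: RecordingConditions,
    scale: float = 1.0,
    offset: float = 0.0,
    bracket: tuple[float, float] = (-200.0, 200.0),
) -> float:
    """Zero-current voltage (mV) of the GHK total current, to 0.01 mV."""

    def f(v: float) -> float:
        return ghk_current(v, conditions, scale, offset)

    lo, hi = bracket
    f_lo, f_hi = f(lo), f(hi)
    if f_lo == 0.0:
        return lo
    if f_hi == 0.0:
        return hi
    if np.sign(f_lo) == np.sign(f_hi):
        raise NoReversalError(
            f"current does not change sign on [{lo}, {hi}] mV "
            f"(I({lo}) = {f_lo:.3g}, I({hi}) = {f_hi:.3g} pA)"
        )
    return float(brentq(f, lo, hi, xtol=0.005))


# ---------------------------------------------------------------------------
# permeability-ratio fitting


def fit_permeability_ratios(
    curves: Sequence[IVCurve],
    free_ions: Sequence[str],
    fit_offset: bool = False,
) -> PermeabilityFit:
    """Jointly fit permeability ratios to a family of I–V curves.

    Minimizes the summed squared current error over {scale, log₁₀ ratio per
    free ion, optional offset} across all curves simultaneously; ratios of
    ions not listed in ``free_ions`` stay fixed at their values in each
    curve's conditions.  Ratios are optimized in log space because proton
    ratios span several orders of magnitude.
    """
    if not curves:
        raise ValueError("at least one IV curve required")
    free_ions = list(free_ions)
    for name in free_ions:
        present = any(
            ion.name == name and (ion.conc_in > 0 or ion.conc_out > 0)
            for c in curves
            for ion in c.conditions.ions
        )
        if not present:
            raise ValueError(
                f"ion {name!r} has zero concentration in every condition: "
                "its permeability ratio is unidentifiable"
            )

    def build_conditions(curve: IVCurve, log10_r: np.ndarray) -> RecordingConditions:
        cond = copy.deepcopy(curve.conditions)
        for name, lr in zip(free_ions, log10_r):
            for ion in cond.ions:
                if ion.name == name:
                    ion.rel_permeability = 10.0 ** lr
        return cond

    # initial scale from the amplitude ratio of data to the unit-scale model
    cond0 = build_conditions(curves[0], np.zeros(len(free_ions)))
    model0 = ghk_current(curves[0].voltages, cond0)
    denom = np.max(np.abs(model0))
    scale0 = np.max(np.abs(curves[0].currents)) / denom if denom > 0 else 1.0

    n_free = len(free_ions)
    x0 = np.concatenate([[np.log10(max(scale0, 1e-12))], np.zeros(n_free),
                         [0.0] if fit_offset else []])

    def unpack(x: np.ndarray):
        scale = 10.0 ** x[0]
        log10_r = x[1 : 1 + n_free]
        offset = x[1 + n_free] if fit_offset else 0.0
        return scale, log10_r, offset

    def residuals(x: np.ndarray) -> np.ndarray:
        scale, log10_r, offset = unpack(x)
        res = []
        for curve in curves:
            cond = build_conditions(curve, log10_r)
            model = ghk_current(curve.voltages, cond, scale, offset)
            res.append(model - curve.currents)
        return np.concatenate(res)

    sol = least_squares(residuals, x0, xtol=1e-12, ftol=1e-12, gtol=1e-12)
    scale, log10_r, offset = unpack(sol.x)
    res = residuals(sol.x)
    n_points = res.size
    n_params = 1 + n_free + (1 if fit_offset else 0)
    sd = float(np.sqrt(np.sum(res**2) / max(n_points - n_params, 1)))
    per_curve = []
    start = 0
    for curve in curves:
        per_curve.append(res[start : start + curve.voltages.size])
        start += curve.voltages.size
    try:
        u_rev = reversal_potential(build_conditions(curves[0], log10_r), scale, offset)
    except NoReversalError:
        u_rev = np.nan
    return PermeabilityFit(
        log10_ratios={name: float(lr) for name, lr in zip(free_ions, log10_r)},
        scale=float(scale),
        offset=float(offset),
        reversal_potential=u_rev,
        residual_sd=sd,
        per_curve_residuals=per_curve,
    )


# ---------------------------------------------------------------------------
# Ca²⁺ block, off-kinetics, action spectrum


def fit_ca_block(
    curve: DoseResponseCurve,
    fix_hill_n: float | str = "free",
    hill_bounds: tuple[float, float] = (0.3, 4.0),
) -> BlockFit:
    """Fit the divalent-block dose–response I(C) = i_max/(1 + (C/k_half)^n).

    ``fix_hill_n=1`` gives the Michaelis-type single-site inhibition; "free"
    fits the Hill coefficient within ``hill_bounds``.
    """
    c, i = curve.concentrations, curve.currents
    if c.size < 4:
        raise ValueError("need at least 4 concentrations")
    # inhibition curves lose current magnitude with concentration
    mag = np.abs(i) / np.max(np.abs(i))
    if np.polyfit(c, mag, 1)[0] > 0 and mag[-1] > mag[0]:
        raise ValueError(
            "current magnitude increases with concentration: not an inhibition curve"
        )

    i_max0 = i[np.argmin(c)]
    k0 = float(np.median(c[c > 0])) if np.any(c > 0) else 1.0
    if isinstance(fix_hill_n, str):
        if fix_hill_n != "free":
            raise ValueError("fix_hill_n must be a number or 'free'")

        def model(cc, i_max, log_k, n):
            return i_max / (1.0 + (cc / 10.0**log_k) ** n)

        popt, _ = curve_fit(
            model, c, i, p0=[i_max0, np.log10(k0), 1.0],
            bounds=([-np.inf, -np.inf, hill_bounds[0]], [np.inf, np.inf, hill_bounds[1]]),
            maxfev=20000,
        )
        i_max, k_half, hill_n = popt[0], 10.0 ** popt[1], popt[2]
    else:
        n_fixed = float(fix_hill_n)

        def model(cc, i_max, log_k):
            return i_max / (1.0 + (cc / 10.0**log_k) ** n_fixed)

        popt, _ = curve_fit(model, c, i, p0=[i_max0, np.log10(k0)], maxfev=20000)
        i_max, k_half, hill_n = popt[0], 10.0 ** popt[1], n_fixed

    fit = BlockFit(float(i_max), float(k_half), float(hill_n))
    resid = i - fit.predict(c)
    dof = max(c.size - (2 if not isinstance(fix_hill_n, str) else 3), 1)
    fit.residual_sd = float(np.sqrt(np.sum(resid**2) / dof))
    return fit


def fit_tau_off(
    trace: DecayTrace,
    t_light_off: float = 0.0,
) -> tuple[float, float, float]:
    """Single-exponential fit of the photocurrent decay after light off.

    Fits I(t) = baseline + i0·exp(−(t − t_light_off)/τ) on t ≥ t_light_off
    and returns (tau_ms, i0_pA, baseline_pA).  Warns when the trace covers
    less than 3τ past light-off (tau then poorly constrained).
    """
    mask = trace.times >= t_light_off
    t = trace.times[mask] - t_light_off
    i = trace.currents[mask]
    if t.size < 4:
        raise ValueError("too few points after light-off")

    tail = i[-max(t.size // 10, 1):]
    baseline0 = float(np.mean(tail))
    i0_0 = float(i[0] - baseline0)
    if abs(i0_0) <= 3 * max(np.std(tail), 1e-12) or abs(i0_0) < 0.05 * np.max(np.abs(i) + 1e-12):
        raise ValueError("trace does not decay: no resolvable exponential amplitude")
    tau0 = max((t[-1] - t[0]) / 5.0, (t[1] - t[0]))

    def model(tt, log_tau, i0, baseline):
        return baseline + i0 * np.exp(-tt / 10.0**log_tau)

    popt, _ = curve_fit(model, t, i, p0=[np.log10(tau0), i0_0, baseline0], maxfev=20000)
    tau = 10.0 ** popt[0]
    if t[-1] < 3 * tau:
        warnings.warn(
            f"trace extends only {t[-1]/tau:.1f}*tau past light-off; "
            "tau poorly constrained",
            RuntimeWarning,
        )
    return float(tau), float(popt[1]), float(popt[2])


def action_spectrum(
    wavelengths: np.ndarray,
    responses: np.ndarray,
    photon_flux: np.ndarray,
) -> tuple[Spectrum, LambdaMax]:
    """Flux-corrected, max-normalized photoresponse spectrum and its peak.

    In the linear (sub-saturating) regime the photoresponse scales with
    photon flux, so dividing by the per-wavelength flux converts a recording
    made at unequal fluxes into the equal-flux action spectrum.
    """
    wl = np.asarray(wavelengths, dtype=float)
    resp = np.asarray(responses, dtype=float)
    flux = np.asarray(photon_flux, dtype=float)
    if not (wl.shape == resp.shape == flux.shape):
        raise ValueError("wavelengths, responses and photon_flux must have equal length")
    if np.any(flux <= 0):
        raise ValueError("photon fluxes must be positive")
    corrected = resp / flux
    peak_val = np.max(np.abs(corrected))
    if peak_val == 0:
        raise ValueError("all responses are zero")
    spec = Spectrum(wl, corrected / peak_val)
    return spec, find_lambda_max(spec)
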