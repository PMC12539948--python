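"""Decay-associated spectra and photophysical rate decomposition.

Given a global lifetime analysis (shared lifetimes tau_i, per-wavelength
amplitudes alpha_i(lambda)) and the steady-state emission spectrum I(lambda),
the decay-associated spectrum of component i is

    DAS_i(lambda) = I(lambda) * alpha_i(lambda) tau_i / sum_j alpha_j(lambda) tau_j,

so the component spectra partition the steady-state emission exactly.  From
the DAS follow the species amplitudes A_i (DAS area over total emission
area), the fractional intensities f_i = A_i tau_i / sum_j A_j tau_j, the
amplitude-weighted average lifetime tau_av = sum A_i tau_i / sum A_i, and the
radiative / non-radiative rate split k_r = QY / tau_av,
k_nr = (1 - QY) / tau_av.  Small spectro-arithmetic utilities (relative
quantum yield against a reference fluorophore, Stokes shift in eV, fragment
charge-transfer amount) live here as well.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .tcspc import GlobalFitResult

__all__ = [
    "DASet",
    "PhotophysicsSummary",
    "QYInputs",
    "FragmentCharges",
    "PhotophysicsError",
    "build_das",
    "species_amplitudes",
    "fractional_intensities",
    "average_lifetime",
    "rate_constants",
    "relative_qy",
    "stokes_shift",
    "ct_amount",
    "summarize",
    "EV_NM",
]

EV_NM = 1239.84193  # photon energy (eV) times wavelength (nm)


class PhotophysicsError(ValueError):
    """Invalid photophysics input."""


@dataclass
class DASet:
    """Decay-associated spectra partitioning the steady-state emission.

    ``das`` has shape (n_components, n_wl); rows sum to ``steady_state`` at
    every wavelength by construction.  ``undefined`` marks wavelengths where
    all amplitude-lifetime products vanish and the split is meaningless.
    """

    wavelengths: np.ndarray
    das: np.ndarray
    steady_state: np.ndarray
    lifetimes: np.ndarray
    undefined: np.ndarray | None = None


@dataclass
class PhotophysicsSummary:
    """One row of a decay-associated photophysics table."""

    lifetimes: np.ndarray  # ns
    amplitudes: np.ndarray  # A_i, sum to 1
    fractional: np.ndarray  # f_i, sum to 1
    tau_av: float  # ns
    qy: float
    k_r: float  # 1e7 s^-1
    k_nr: float  # 1e7 s^-1


@dataclass(frozen=True)
class QYInputs:
    """Relative quantum-yield determination against a reference fluorophore.

    I: integrated emission area; A: absorbance at the excitation wavelength;
    n: solvent refractive index; suffix f = sample, r = reference;
    phi_r: reference quantum yield.
    """

    i_f: float
    i_r: float
    a_f: float
    a_r: float
    n_f: float = 1.333
    n_r: float = 1.333
    phi_r: float = 0.68

    def __post_init__(self) -> None:
        vals = (self.i_f, self.i_r, self.a_f, self.a_r, self.n_f, self.n_r, self.phi_r)
        if any(v <= 0 for v in vals):
            raise PhotophysicsError("all quantum-yield inputs must be positive")
        if self.a_f >= 3.0 or self.a_r >= 3.0:
            raise PhotophysicsError("absorbance must be < 3 for a meaningful yield")


@dataclass
class FragmentCharges:
    """Per-atom charges (a.u.) in ground and excited state with a fragment mask.

    ``mask`` assigns each atom to "donor", "acceptor" or "other".
    """

    ground: np.ndarray
    excited: np.ndarray
    mask: Sequence[str]

    def __post_init__(self) -> None:
        self.ground = np.asarray(self.ground, dtype=float)
        self.excited = np.asarray(self.excited, dtype=float)
        if not (self.ground.size == self.excited.size == len(self.mask)):
            raise PhotophysicsError("charge lists and mask must have equal length")
        bad = set(self.mask) - {"donor", "acceptor", "other"}
        if bad:
            raise PhotophysicsError(f"unknown fragment labels: {sorted(bad)}")


def build_das(
    fit: GlobalFitResult,
    steady_state_wl: np.ndarray,
    steady_state_i: np.ndarray,
) -> DASet:
    """Distribute the steady-state spectrum over the lifetime components.

    The steady-state spectrum is linearly interpolated onto the fit's
    wavelength grid (which must lie within its range).  Wavelengths where
    sum_j alpha_j tau_j = 0 are reported as undefined bins (NaN DAS).
    """
    wl = np.asarray(fit.wavelengths, dtype=float)
    ss_wl = np.asarray(steady_state_wl, dtype=float)
    ss_i = np.asarray(steady_state_i, dtype=float)
    if wl.min() < ss_wl.min() - 1e-9 or wl.max() > ss_wl.max() + 1e-9:
        raise PhotophysicsError(
            "fit wavelengths extend beyond the steady-state spectrum"
        )
    intensity = np.interp(wl, ss_wl, ss_i)
    weights = fit.alphas * fit.taus[None, :]  # (n_wl, k)
    denom = weights.sum(axis=1)
    undefined = denom <= 0
    with np.errstate(invalid="ignore", divide="ignore"):
        das = (intensity[:, None] * weights / denom[:, None]).T
    das[:, undefined] = np.nan
    return DASet(
        wavelengths=wl,
        das=das,
        steady_state=intensity,
        lifetimes=fit.taus.copy(),
        undefined=undefined if undefined.any() else None,
    )


def species_amplitudes(das: DASet) -> np.ndarray:
    """A_i = area(DAS_i) / area(I), trapezoidal quadrature; sums to 1."""
    total = float(np.trapezoid(das.steady_state, das.wavelengths))
    if total <= 0:
        raise PhotophysicsError("steady-state spectrum has zero area")
    return np.trapezoid(np.nan_to_num(das.das), das.wavelengths, axis=1) / total


def fractional_intensities(
    amplitudes: Sequence[float], taus: Sequence[float]
) -> np.ndarray:
    """f_i = A_i tau_i / sum_j A_j tau_j; invariant to rescaling of A."""
    a = np.asarray(amplitudes, dtype=float)
    t = np.asarray(taus, dtype=float)
    if a.shape != t.shape:
        raise PhotophysicsError("amplitudes and lifetimes must have equal length")
    if np.any(a < 0) or np.any(t <= 0):
        raise PhotophysicsError("amplitudes must be >= 0 and lifetimes > 0")
    denom = float(np.sum(a * t))
    if denom <= 0:
        raise PhotophysicsError("all-zero amplitude-lifetime products")
    return a * t / denom


def average_lifetime(amplitudes: Sequence[float], taus: Sequence[float]) -> float:
    """Amplitude-weighted mean lifetime sum A_i tau_i / sum A_i (ns)."""
    a = np.asarray(amplitudes, dtype=float)
    t = np.asarray(taus, dtype=float)
    s = float(a.sum())
    if s <= 0:
        raise PhotophysicsError("amplitudes sum to zero")
    return float(np.sum(a * t) / s)


def rate_constants(qy: float, tau_av: float) -> tuple[float, float]:
    """(k_r, k_nr) in 1e7 s^-1 from the quantum yield and tau_av in ns.

    k_r = QY / tau_av and k_nr = (1 - QY) / tau_av; their sum is the total
    depopulation rate 1/tau_av.
    """
    if not 0.0 <= qy <= 1.0:
        raise PhotophysicsError("quantum yield must lie in [0, 1]")
    if tau_av <= 0:
        raise PhotophysicsError("tau_av must be positive")
    per_ns_to_1e7 = 100.0  # 1/ns = 1e9 s^-1 = 100 x 1e7 s^-1
    k_r = qy / tau_av * per_ns_to_1e7
    k_nr = (1.0 - qy) / tau_av * per_ns_to_1e7
    return k_r, k_nr


def relative_qy(inputs: QYInputs) -> float:
    """phi_f = phi_r (I_f/I_r)(A_r/A_f)(n_f/n_r)^2."""
    return (
        inputs.phi_r
        * (inputs.i_f / inputs.i_r)
        * (inputs.a_r / inputs.a_f)
        * (inputs.n_f / inputs.n_r) ** 2
    )


def stokes_shift(lambda_abs: float, lambda_em: float) -> float:
    """Absorption-emission energy gap in eV; negative values are allowed
    (anti-Stokes) but usually indicate swapped inputs."""
    if lambda_abs <= 0 or lambda_em <= 0:
        raise PhotophysicsError("wavelengths must be positive")
    return EV_NM * (1.0 / lambda_abs - 1.0 / lambda_em)


def ct_amount(charges: FragmentCharges) -> float:
    """Charge transferred by the donor fragment upon excitation (a.u.).

    Positive = electron density lost by the donor in the excited state,
    computed as the donor-atom sum of (q_excited - q_ground).
    """
    mask = np.asarray([m == "donor" for m in charges.mask])
    return float(np.sum((charges.excited - charges.ground)[mask]))


def summarize(
    fit: GlobalFitResult,
    steady_state_wl: np.ndarray,
    steady_state_i: np.ndarray,
    qy: float,
) -> PhotophysicsSummary:
    """Full decay-associated summary: DAS -> A_i -> f_i -> tau_av -> rates."""
    das = build_das(fit, steady_state_wl, steady_state_i)
    amps = species_amplitudes(das)
    fracs = fractional_intensities(amps, das.lifetimes)
    tau_av = average_lifetime(amps, das.lifetimes)
    k_r, k_nr = rate_constants(qy, tau_av)
    return PhotophysicsSummary(
        lifetimes=das.lifetimes.copy(),
        amplitudes=amps,
        fractional=fracs,
        tau_av=tau_av,
        qy=qy,
        k_r=k_r,
        k_nr=k_nr,
    )
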