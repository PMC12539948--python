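"""Two-state thermal melting analysis of DNA duplexes.

A duplex-to-single-strand transition monitored through a fluorescent base
produces a sigmoidal fluorescence-vs-temperature curve: the probe is quenched
by stacking in the duplex and brightens as the helix melts.  The canonical
two-state model fitted here is a Boltzmann sigmoid riding on linear folded and
unfolded baselines,

    F(T) = L(T) + [U(T) - L(T)] / (1 + exp((Tm - T) / w)),

with L and U linear in T.  ``Tm`` is the transition midpoint and ``w`` its
width in degrees C.  A smoothed-derivative estimator is provided as an
independent cross-check: the midpoint is read off as the extremum of dF/dT.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit
from scipy.special import expit

__all__ = [
    "MeltingCurve",
    "MeltingFit",
    "MeltingError",
    "NoTransitionError",
    "fit_melting",
    "tm_derivative",
    "normalize_curve",
]


class MeltingError(ValueError):
    """Invalid melting-curve input."""


class NoTransitionError(RuntimeError):
    """The signal shows no resolvable two-state transition."""


@dataclass
class MeltingCurve:
    """Temperature-fluorescence record (temps degC strictly increasing)."""

    temps: np.ndarray
    fluorescence: np.ndarray

    def __post_init__(self) -> None:
        self.temps = np.asarray(self.temps, dtype=float)
        self.fluorescence = np.asarray(self.fluorescence, dtype=float)
        if self.temps.size < 10:
            raise MeltingError("melting curve needs at least 10 points")
        if self.temps.shape != self.fluorescence.shape:
            raise MeltingError("temps and fluorescence must have equal length")
        if np.any(np.diff(self.temps) <= 0):
            raise MeltingError("temperatures must be strictly increasing")
        if self.temps[0] < 0.0 or self.temps[-1] > 110.0:
            raise MeltingError("temperatures outside the 0-110 degC range")


@dataclass
class MeltingFit:
    tm: float
    width: float
    lower_baseline: tuple[float, float]  # intercept, slope
    upper_baseline: tuple[float, float]
    tm_stderr: float
    method: str
    residual_sd: float = float("nan")


def melting_model(
    T: np.ndarray,
    tm: float,
    width: float,
    bl0: float,
    bl1: float,
    bu0: float,
    bu1: float,
) -> np.ndarray:
    """Boltzmann sigmoid between linear baselines; overflow-safe."""
    L = bl0 + bl1 * T
    U = bu0 + bu1 * T
    return L + (U - L) * expit((T - tm) / width)


def _baseline(T: np.ndarray, F: np.ndarray) -> tuple[float, float, float]:
    """Linear fit returning (intercept, slope, residual sd)."""
    coeff = np.polyfit(T, F, 1)
    resid = F - np.polyval(coeff, T)
    sd = float(np.std(resid, ddof=min(2, resid.size - 1)))
    return float(coeff[1]), float(coeff[0]), sd


def _initial_guess(curve: MeltingCurve):
    T, F = curve.temps, curve.fluorescence
    n = T.size
    m = max(3, n // 10)
    bl0, bl1, sd_lo = _baseline(T[:m], F[:m])
    bu0, bu1, sd_hi = _baseline(T[-m:], F[-m:])
    # steepest point of a lightly smoothed signal locates the transition;
    # 'valid' convolution avoids zero-padding spikes at the curve edges
    w = min(5, n if n % 2 else n - 1)
    smooth = np.convolve(F, np.ones(w) / w, mode="valid")
    Ts = T[w // 2 : w // 2 + smooth.size]
    dF = np.gradient(smooth, Ts)
    tm0 = float(Ts[np.argmax(np.abs(dF))])
    noise = 0.5 * (sd_lo + sd_hi)
    amp = abs((bu0 + bu1 * tm0) - (bl0 + bl1 * tm0))
    return (tm0, 2.0, bl0, bl1, bu0, bu1), amp, noise


def fit_melting(curve: MeltingCurve, normalize: bool = False) -> MeltingFit:
    """Least-squares two-state sigmoid fit; returns Tm with its standard error.

    Raises :class:`NoTransitionError` when the baseline-corrected transition
    amplitude does not exceed five times the baseline noise (nothing to fit),
    and on optimizer failure.  With ``normalize=True`` the curve is first
    mapped to an approximate fraction-unfolded scale; Tm is unchanged by this
    affine transform, so the flag only affects the reported baselines.
    """
    if normalize:
        curve = normalize_curve(curve)
    T, F = curve.temps, curve.fluorescence
    p0, amp, noise = _initial_guess(curve)
    span = float(F.max() - F.min())
    if noise > 0 and span < 5.0 * noise:
        raise NoTransitionError("signal range below 5x the baseline noise")
    if amp < max(5.0 * noise, 1e-6 * span):
        raise NoTransitionError("signal is consistent with a single linear baseline")
    lb = [T[0], 1e-4, -np.inf, -np.inf, -np.inf, -np.inf]
    ub = [T[-1], (T[-1] - T[0]), np.inf, np.inf, np.inf, np.inf]
    p0 = (min(max(p0[0], T[0]), T[-1]), *p0[1:])
    try:
        popt, pcov = curve_fit(
            melting_model, T, F, p0=p0, bounds=(lb, ub), maxfev=20000
        )
    except RuntimeError as exc:  # pragma: no cover - rare
        raise NoTransitionError(f"melting fit did not converge: {exc}") from exc
    resid = F - melting_model(T, *popt)
    return MeltingFit(
        tm=float(popt[0]),
        width=float(popt[1]),
        lower_baseline=(float(popt[2]), float(popt[3])),
        upper_baseline=(float(popt[4]), float(popt[5])),
        tm_stderr=float(np.sqrt(max(pcov[0, 0], 0.0))),
        method="sigmoid",
        residual_sd=float(np.std(resid, ddof=min(6, resid.size - 1))),
    )


def tm_derivative(curve: MeltingCurve, smooth_window: int = 5) -> float:
    """Midpoint from the extremum of the smoothed derivative dF/dT.

    ``smooth_window`` is an odd moving-average length in points.  Raises
    :class:`NoTransitionError` when the extremum falls on the first or last
    usable point, which signals a boundary artefact rather than a transition.
    """
    if smooth_window < 3 or smooth_window % 2 == 0:
        raise MeltingError("smooth_window must be odd and >= 3")
    T, F = curve.temps, curve.fluorescence
    if smooth_window >= T.size:
        raise MeltingError("smooth_window larger than the curve")
    kernel = np.ones(smooth_window) / smooth_window
    smooth = np.convolve(F, kernel, mode="valid")
    Ts = T[smooth_window // 2 : smooth_window // 2 + smooth.size]
    dF = np.gradient(smooth, Ts)
    mag = np.abs(dF)
    idx = int(np.argmax(mag))
    if idx in (0, dF.size - 1):
        raise NoTransitionError("derivative extremum at the curve boundary")
    # a near-constant derivative (pure baseline) has no localized extremum
    if mag[idx] < 2.0 * np.median(mag):
        raise NoTransitionError("no localized derivative extremum (baseline-only signal)")
    return float(Ts[idx])


def normalize_curve(curve: MeltingCurve) -> MeltingCurve:
    """Affine rescale of the fluorescence axis to [0, 1] (fraction-like)."""
    F = curve.fluorescence
    span = F.max() - F.min()
    if span <= 0:
        raise MeltingError("flat signal cannot be normalized")
    return MeltingCurve(curve.temps.copy(), (F - F.min()) / span)
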