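"""Synthetic measurement generators with known ground truth.

Every input consumed by the analysis pipeline can be produced here with
known parameters, which makes the downstream estimators testable end to end:

* multi-wavelength TCSPC decay histograms — tri-exponential decays convolved
  with a sub-nanosecond Gaussian IRF and Poisson counting noise, emulating a
  fluorescent-base-labeled duplex measured across its emission band;
* the matching steady-state spectrum, which for a multi-exponential emitter
  is I(lambda) = sum_i alpha_i(lambda) * tau_i up to a constant;
* sigmoidal two-state melting curves over 15-95 degC;
* stationary AR(1) stacking-angle series with tunable mean, spread and
  picosecond-scale autocorrelation, reflected into [0, 90] deg; and
* toy two-ring coordinate frames whose inter-plane dihedral follows a
  prescribed schedule — a geometry oracle for the stacking-angle code.

All generators take explicit integer seeds and are bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy.signal import lfilter
from scipy.special import expit

from .melting import MeltingCurve
from .stacking import AngleSeries, TrajectoryFrames, fold_angle
from .tcspc import DecayDataset, convolve_model

__all__ = [
    "DecayModelSpec",
    "IRFSpec",
    "MeltingModelSpec",
    "AngleProcessSpec",
    "SyntheticError",
    "default_time_grid",
    "gaussian_bands",
    "gen_decay_dataset",
    "gen_melting_curve",
    "gen_angle_series",
    "gen_ring_frames",
    "duplex_decay_spec",
    "DEFAULT_LIFETIMES_NS",
]

# Lifetime triple characteristic of the probe in these duplexes (ns):
# strongly stacked / partially stacked / extrahelical-like populations.
DEFAULT_LIFETIMES_NS = (0.61, 2.35, 10.00)


class SyntheticError(ValueError):
    """Invalid generator specification."""


def default_time_grid(t_max: float = 50.0, dt: float = 0.05) -> np.ndarray:
    """Channel centers 0..t_max ns; the window covers 5x the longest default
    lifetime so tails decay into the baseline."""
    n = int(round(t_max / dt))
    return dt * np.arange(n)


@dataclass(frozen=True)
class IRFSpec:
    """Gaussian instrument response: FWHM and peak position t0, both ns."""

    fwhm: float = 0.5
    t0: float = 2.0
    shape: str = "gaussian"

    def __post_init__(self) -> None:
        if self.fwhm <= 0:
            raise SyntheticError("IRF fwhm must be positive")
        if self.shape != "gaussian":
            raise SyntheticError(f"unsupported IRF shape {self.shape!r}")

    def discretize(self, grid: np.ndarray) -> np.ndarray:
        """Non-negative samples on the grid, normalized to unit sum."""
        grid = np.asarray(grid, dtype=float)
        sigma = self.fwhm / (2.0 * np.sqrt(2.0 * np.log(2.0)))
        y = np.exp(-0.5 * ((grid - self.t0) / sigma) ** 2)
        s = y.sum()
        if s <= 0:
            raise SyntheticError("IRF has no support on the time grid")
        return y / s


@dataclass
class DecayModelSpec:
    """Ground truth for a multi-wavelength decay dataset.

    ``amplitude_spectra`` holds the per-component amplitude bands
    alpha_i(lambda): an array of shape (n_components, n_wavelengths) or a
    sequence of callables evaluated on ``wavelengths``.  Lifetimes are in ns,
    strictly increasing; bands are non-negative and dimensionless.
    """

    lifetimes: Sequence[float]
    amplitude_spectra: np.ndarray | Sequence[Callable[[np.ndarray], np.ndarray]]
    wavelengths: np.ndarray
    time_grid: np.ndarray = field(default_factory=default_time_grid)
    peak_counts: float = 1e4

    def __post_init__(self) -> None:
        self.lifetimes = np.asarray(self.lifetimes, dtype=float)
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.time_grid = np.asarray(self.time_grid, dtype=float)
        if np.any(self.lifetimes <= 0) or np.any(np.diff(self.lifetimes) <= 0):
            raise SyntheticError("lifetimes must be positive and strictly increasing")
        if np.any(np.diff(self.wavelengths) <= 0):
            raise SyntheticError("wavelengths must be strictly increasing")
        steps = np.diff(self.time_grid)
        if steps.size == 0 or steps[0] <= 0 or not np.allclose(steps, steps[0]):
            raise SyntheticError("time grid must be uniform and increasing")
        if self.peak_counts <= 0:
            raise SyntheticError("peak_counts must be positive")
        if callable(getattr(self.amplitude_spectra, "__iter__", None)) and not isinstance(
            self.amplitude_spectra, np.ndarray
        ):
            spectra = list(self.amplitude_spectra)
            if spectra and callable(spectra[0]):
                self.amplitude_spectra = np.vstack(
                    [np.asarray(f(self.wavelengths), dtype=float) for f in spectra]
                )
            else:
                self.amplitude_spectra = np.asarray(spectra, dtype=float)
        else:
            self.amplitude_spectra = np.asarray(self.amplitude_spectra, dtype=float)
        expected = (self.lifetimes.size, self.wavelengths.size)
        if self.amplitude_spectra.shape != expected:
            raise SyntheticError(
                f"amplitude_spectra shape {self.amplitude_spectra.shape} != {expected}"
            )
        if np.any(self.amplitude_spectra < 0):
            raise SyntheticError("amplitude spectra must be non-negative")

    def steady_state(self) -> np.ndarray:
        """Noiseless steady-state spectrum sum_i alpha_i(lambda) * tau_i."""
        return self.amplitude_spectra.T @ self.lifetimes


def gaussian_bands(
    centers: Sequence[float], widths: Sequence[float], heights: Sequence[float]
) -> list[Callable[[np.ndarray], np.ndarray]]:
    """Per-component Gaussian emission bands alpha_i(lambda) (nm)."""

    def make(c: float, w: float, h: float) -> Callable[[np.ndarray], np.ndarray]:
        return lambda wl: h * np.exp(-0.5 * ((np.asarray(wl) - c) / w) ** 2)

    return [make(c, w, h) for c, w, h in zip(centers, widths, heights, strict=True)]


def duplex_decay_spec(
    peak_counts: float = 1e4,
    wavelengths: np.ndarray | None = None,
    time_grid: np.ndarray | None = None,
) -> DecayModelSpec:
    """Study-condition dataset spec: lifetimes (0.61, 2.35, 10.00) ns across
    a 320-430 nm emission grid at 10 nm intervals, Gaussian component bands
    with the long-lifetime band on the red edge."""
    if wavelengths is None:
        wavelengths = np.arange(320.0, 431.0, 10.0)
    if time_grid is None:
        time_grid = default_time_grid()
    taus = np.asarray(DEFAULT_LIFETIMES_NS)
    # heights ~ A_i / tau_i give DAS-area amplitudes near the duplex values
    target_A = np.array([0.24, 0.31, 0.45])
    bands = gaussian_bands(
        centers=(360.0, 372.0, 382.0),
        widths=(22.0, 24.0, 26.0),
        heights=tuple(target_A / taus),
    )
    return DecayModelSpec(
        lifetimes=taus,
        amplitude_spectra=bands,
        wavelengths=wavelengths,
        time_grid=time_grid,
        peak_counts=peak_counts,
    )


def gen_decay_dataset(
    spec: DecayModelSpec,
    irf: IRFSpec,
    seed: int,
    noise: bool = True,
) -> DecayDataset:
    """Simulate a multi-wavelength TCSPC dataset.

    Each curve is the reconvolved multi-exponential model scaled so its
    noiseless maximum equals ``peak_counts`` (curves are acquired to a fixed
    peak count, as in standard TCSPC practice), then Poisson-sampled.  The
    exact steady-state spectrum and the generator parameters travel with the
    dataset as ground truth.
    """
    rng = np.random.default_rng(seed)
    irf_counts = irf.discretize(spec.time_grid)
    n_wl = spec.wavelengths.size
    counts = np.empty((n_wl, spec.time_grid.size))
    scales = np.empty(n_wl)
    for j in range(n_wl):
        model = convolve_model(
            spec.lifetimes, spec.amplitude_spectra[:, j], irf_counts, spec.time_grid
        )
        peak = model.max()
        if peak <= 0:
            raise SyntheticError(
                f"zero model at wavelength {spec.wavelengths[j]:g} nm"
            )
        scales[j] = spec.peak_counts / peak
        noiseless = scales[j] * model
        counts[j] = rng.poisson(noiseless) if noise else noiseless
    return DecayDataset(
        wavelengths=spec.wavelengths.copy(),
        time_grid=spec.time_grid.copy(),
        counts=counts,
        irf=irf_counts,
        steady_state=spec.steady_state(),
        metadata={"excitation_nm": 291.0, "sample": "synthetic duplex"},
        truth={
            "lifetimes": np.asarray(spec.lifetimes).copy(),
            "amplitude_spectra": spec.amplitude_spectra.copy(),
            "scales": scales,
            "irf": irf,
            "seed": seed,
        },
    )


@dataclass(frozen=True)
class MeltingModelSpec:
    """Two-state melting-curve truth.

    ``lower_baseline``/``upper_baseline`` are (intercept, slope) in a.u. and
    a.u./degC; ``noise_sd`` is relative to the transition amplitude at Tm.
    The fluorescence rises through the transition (the probe is quenched in
    the duplex and brightens on melting).
    """

    tm: float = 59.5
    width: float = 2.0
    lower_baseline: tuple[float, float] = (0.05, 0.0005)
    upper_baseline: tuple[float, float] = (1.0, 0.001)
    noise_sd: float = 0.01
    temp_grid: np.ndarray = field(
        default_factory=lambda: np.arange(15.0, 95.0 + 0.25, 0.5)
    )

    def __post_init__(self) -> None:
        if self.width <= 0:
            raise SyntheticError("width must be positive")
        tg = np.asarray(self.temp_grid, dtype=float)
        object.__setattr__(self, "temp_grid", tg)
        if np.any(np.diff(tg) <= 0):
            raise SyntheticError("temperature grid must be strictly increasing")
        if not tg[0] < self.tm < tg[-1]:
            raise SyntheticError("tm must lie inside the temperature grid")


def gen_melting_curve(spec: MeltingModelSpec, seed: int) -> MeltingCurve:
    """Sigmoidal melting curve with Gaussian noise scaled to the amplitude."""
    rng = np.random.default_rng(seed)
    T = spec.temp_grid
    bl0, bl1 = spec.lower_baseline
    bu0, bu1 = spec.upper_baseline
    L = bl0 + bl1 * T
    U = bu0 + bu1 * T
    F = L + (U - L) * expit((T - spec.tm) / spec.width)
    amp = abs((bu0 + bu1 * spec.tm) - (bl0 + bl1 * spec.tm))
    if spec.noise_sd > 0:
        F = F + rng.normal(0.0, spec.noise_sd * amp, size=T.size)
    return MeltingCurve(temps=T.copy(), fluorescence=F)


@dataclass(frozen=True)
class AngleProcessSpec:
    """Stationary AR(1) emulation of a stacking-angle trajectory.

    ``mean``/``sd`` in degrees, ``phi`` the lag-1 autocorrelation (|phi| < 1),
    ``dt`` the frame spacing in ps.  Values outside [0, 90] are reflected at
    the boundaries, preserving continuity of the process.
    """

    mean: float = 10.0
    sd: float = 4.0
    phi: float = 0.9
    n: int = 100_000
    dt: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.mean <= 90.0:
            raise SyntheticError("mean must lie in [0, 90] degrees")
        if self.sd <= 0:
            raise SyntheticError("sd must be positive")
        if not abs(self.phi) < 1.0:
            raise SyntheticError("|phi| must be < 1 for stationarity")
        if self.n < 1 or self.dt <= 0:
            raise SyntheticError("n must be >= 1 and dt > 0")


def gen_angle_series(spec: AngleProcessSpec) -> AngleSeries:
    """AR(1) angle series x_t = mean + phi (x_{t-1} - mean) + eps_t.

    Innovations have variance sd^2 (1 - phi^2) so the marginal is
    N(mean, sd^2) before reflection; lag-k autocorrelation is phi^k.
    """
    rng = np.random.default_rng(spec.seed)
    e = rng.normal(0.0, spec.sd * np.sqrt(1.0 - spec.phi**2), size=spec.n)
    e[0] = rng.normal(0.0, spec.sd)  # stationary start
    y = lfilter([1.0], [1.0, -spec.phi], e)
    return AngleSeries(dt=spec.dt, angles=fold_angle(spec.mean + y))


def _hexagon(radius: float = 1.39) -> np.ndarray:
    ang = np.deg2rad(60.0 * np.arange(6))
    return np.column_stack([radius * np.cos(ang), radius * np.sin(ang), np.zeros(6)])


def gen_ring_frames(
    angle_schedule: Sequence[float],
    noise_sd: float = 0.0,
    seed: int = 0,
    dt: float = 1.0,
    separation: float = 3.4,
) -> TrajectoryFrames:
    """Frames of two six-atom rings with programmed inter-plane dihedrals.

    Ring A (carbons) lies in the xy plane; ring B (nitrogens) is the same
    hexagon rigidly rotated about the x axis by the scheduled angle and
    displaced by ``separation`` Angstrom along z — the rise between stacked
    bases.  Optional isotropic Gaussian coordinate noise perturbs every atom.
    """
    schedule = np.asarray(angle_schedule, dtype=float)
    if schedule.size and (schedule.min() < 0.0 or schedule.max() > 90.0):
        raise SyntheticError("scheduled angles must lie in [0, 90] degrees")
    rng = np.random.default_rng(seed)
    base = _hexagon()
    frames = np.empty((schedule.size, 12, 3))
    for i, theta in enumerate(np.deg2rad(schedule)):
        rot = np.array(
            [
                [1.0, 0.0, 0.0],
                [0.0, np.cos(theta), -np.sin(theta)],
                [0.0, np.sin(theta), np.cos(theta)],
            ]
        )
        ring_b = base @ rot.T + np.array([0.0, 0.0, separation])
        frames[i, :6] = base
        frames[i, 6:] = ring_b
    if noise_sd > 0:
        frames = frames + rng.normal(0.0, noise_sd, size=frames.shape)
    return TrajectoryFrames(
        elements=["C"] * 6 + ["N"] * 6, coords=frames, dt=dt
    )
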