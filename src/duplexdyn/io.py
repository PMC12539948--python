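"""File formats: long-format CSV tables, multi-frame XYZ, JSON fit reports.

All numeric columns are written with round-trip-safe formatting (17
significant digits) so writer/reader pairs reproduce values exactly.
Comment lines starting with ``#`` are skipped on read; unknown extra columns
are accepted with a logged warning.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .melting import MeltingCurve
from .stacking import AngleHistogram, AngleSeries, TrajectoryFrames
from .tcspc import DecayDataset, GlobalFitResult

__all__ = [
    "SchemaError",
    "XYZParseError",
    "read_table",
    "write_decay_dataset",
    "read_decay_dataset",
    "write_melting_curve",
    "read_melting_curve",
    "write_angle_series",
    "read_angle_series",
    "write_histogram",
    "write_fit_json",
    "read_fit_json",
    "write_xyz_frames",
    "read_xyz_frames",
    "write_summary_csv",
]

logger = logging.getLogger("duplexdyn")

_FMT = "%.17g"


class SchemaError(ValueError):
    """A table is missing a required column or holds a non-numeric cell."""


class XYZParseError(ValueError):
    """Malformed multi-frame XYZ file."""


def read_table(path: str | Path, required: Sequence[str]) -> pd.DataFrame:
    """CSV with a header; returns the required columns as floats.

    The header is matched order-insensitively; extra columns are ignored with
    a warning; a missing column or a non-numeric cell raises
    :class:`SchemaError` naming the offender (and its row for cells).
    """
    path = Path(path)
    df = pd.read_csv(
        path, comment="#", skip_blank_lines=True, float_precision="round_trip"
    )
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path.name}: missing column(s) {missing}")
    extra = [c for c in df.columns if c not in required]
    if extra:
        logger.warning("%s: ignoring unknown column(s) %s", path.name, extra)
    out = {}
    for col in required:
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = vals.isna() & df[col].notna()
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise SchemaError(
                f"{path.name}: non-numeric value {df[col].iloc[row]!r} "
                f"in column {col!r}, row {row}"
            )
        out[col] = vals.to_numpy(dtype=float)
    return pd.DataFrame(out)


def _write_csv(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, index=False, float_format=_FMT)


# --- decay datasets ---------------------------------------------------------


def write_decay_dataset(
    dataset: DecayDataset,
    decays_path: str | Path,
    irf_path: str | Path,
    spectrum_path: str | Path | None = None,
) -> None:
    """Long-format decay CSV (wavelength_nm, time_ns, counts) + IRF CSV
    (time_ns, counts) and optionally a spectrum CSV (wavelength_nm, intensity)."""
    n_wl, n_t = dataset.counts.shape
    _write_csv(
        pd.DataFrame(
            {
                "wavelength_nm": np.repeat(dataset.wavelengths, n_t),
                "time_ns": np.tile(dataset.time_grid, n_wl),
                "counts": dataset.counts.ravel(),
            }
        ),
        decays_path,
    )
    _write_csv(
        pd.DataFrame({"time_ns": dataset.time_grid, "counts": dataset.irf}),
        irf_path,
    )
    if spectrum_path is not None and dataset.steady_state is not None:
        _write_csv(
            pd.DataFrame(
                {
                    "wavelength_nm": dataset.wavelengths,
                    "intensity": dataset.steady_state,
                }
            ),
            spectrum_path,
        )


def read_decay_dataset(
    decays_path: str | Path,
    irf_path: str | Path,
    spectrum_path: str | Path | None = None,
) -> DecayDataset:
    dec = read_table(decays_path, ["wavelength_nm", "time_ns", "counts"])
    irf = read_table(irf_path, ["time_ns", "counts"])
    wavelengths = np.unique(dec["wavelength_nm"].to_numpy())
    grid = irf["time_ns"].to_numpy()
    counts = np.empty((wavelengths.size, grid.size))
    for j, wl in enumerate(wavelengths):
        sub = dec[dec["wavelength_nm"] == wl]
        if len(sub) != grid.size:
            raise SchemaError(
                f"wavelength {wl:g} nm has {len(sub)} channels, expected {grid.size}"
            )
        counts[j] = sub["counts"].to_numpy()
    steady = None
    if spectrum_path is not None:
        spec = read_table(spectrum_path, ["wavelength_nm", "intensity"])
        steady = np.interp(
            wavelengths,
            spec["wavelength_nm"].to_numpy(),
            spec["intensity"].to_numpy(),
        )
    return DecayDataset(
        wavelengths=wavelengths,
        time_grid=grid,
        counts=counts,
        irf=irf["counts"].to_numpy(),
        steady_state=steady,
    )


def read_spectrum(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    spec = read_table(path, ["wavelength_nm", "intensity"])
    return spec["wavelength_nm"].to_numpy(), spec["intensity"].to_numpy()


# --- melting curves ---------------------------------------------------------


def write_melting_curve(curve: MeltingCurve, path: str | Path) -> None:
    _write_csv(
        pd.DataFrame({"temp_C": curve.temps, "fluorescence": curve.fluorescence}),
        path,
    )


def read_melting_curve(path: str | Path) -> MeltingCurve:
    df = read_table(path, ["temp_C", "fluorescence"])
    return MeltingCurve(df["temp_C"].to_numpy(), df["fluorescence"].to_numpy())


# --- angle series / histograms ---------------------------------------------


def write_angle_series(series: AngleSeries, path: str | Path) -> None:
    _write_csv(
        pd.DataFrame(
            {"frame": np.arange(series.n), "angle_deg": series.angles}
        ),
        path,
    )


def read_angle_series(path: str | Path, dt: float = 1.0) -> AngleSeries:
    df = read_table(path, ["frame", "angle_deg"])
    return AngleSeries(dt=dt, angles=df["angle_deg"].to_numpy())


def write_histogram(hist: AngleHistogram, path: str | Path) -> None:
    data = {
        "bin_lo": hist.bin_edges[:-1],
        "bin_hi": hist.bin_edges[1:],
        "density": hist.density,
    }
    if hist.ci_low is not None:
        data["ci_lo"] = hist.ci_low
        data["ci_hi"] = hist.ci_high
    _write_csv(pd.DataFrame(data), path)


# --- fit reports ------------------------------------------------------------


def write_fit_json(fit: GlobalFitResult, path: str | Path) -> None:
    """Flat JSON report: lifetimes, per-wavelength amplitudes, diagnostics."""
    report = {
        "lifetimes_ns": fit.taus.tolist(),
        "tau_stderr_ns": None if fit.tau_stderr is None else fit.tau_stderr.tolist(),
        "irf_shift_ns": fit.shift,
        "wavelengths_nm": fit.wavelengths.tolist(),
        "amplitudes": fit.alphas.tolist(),
        "chi2_reduced": fit.chi2_reduced.tolist(),
        "chi2_reduced_pooled": fit.chi2_reduced_pooled,
        "objective": fit.objective,
        "success": fit.success,
        "flags": list(fit.flags),
    }
    Path(path).write_text(json.dumps(report, indent=2) + "\n")


def read_fit_json(path: str | Path) -> GlobalFitResult:
    d = json.loads(Path(path).read_text())
    return GlobalFitResult(
        taus=np.asarray(d["lifetimes_ns"], dtype=float),
        alphas=np.asarray(d["amplitudes"], dtype=float),
        shift=float(d["irf_shift_ns"]),
        wavelengths=np.asarray(d["wavelengths_nm"], dtype=float),
        chi2_reduced=np.asarray(d["chi2_reduced"], dtype=float),
        chi2_reduced_pooled=float(d["chi2_reduced_pooled"]),
        residuals=[],
        tau_stderr=(
            None
            if d.get("tau_stderr_ns") is None
            else np.asarray(d["tau_stderr_ns"], dtype=float)
        ),
        success=bool(d["success"]),
        message="loaded from file",
        objective=float(d["objective"]),
        flags=list(d.get("flags", [])),
    )


# --- summary table ----------------------------------------------------------


def write_summary_csv(summary, path: str | Path, label: str = "sample") -> None:
    """Single-row photophysics table: tau1..k, A1..k, f1..k, tau_av, rates, QY."""
    row: dict[str, object] = {"sample": label}
    for i, (t, a, f) in enumerate(
        zip(summary.lifetimes, summary.amplitudes, summary.fractional), start=1
    ):
        row[f"tau{i}_ns"] = t
        row[f"A{i}"] = a
        row[f"f{i}"] = f
    row["tau_av_ns"] = summary.tau_av
    row["k_r_1e7_s"] = summary.k_r
    row["k_nr_1e7_s"] = summary.k_nr
    row["QY"] = summary.qy
    _write_csv(pd.DataFrame([row]), path)


# --- multi-frame XYZ --------------------------------------------------------


def write_xyz_frames(frames: TrajectoryFrames, path: str | Path) -> None:
    lines: list[str] = []
    for i in range(frames.n_frames):
        lines.append(str(len(frames.elements)))
        lines.append(f"frame {i}")
        for el, (x, y, z) in zip(frames.elements, frames.coords[i]):
            lines.append(f"{el} {x:.17g} {y:.17g} {z:.17g}")
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


def read_xyz_frames(path: str | Path, dt: float = 1.0) -> TrajectoryFrames:
    """Standard multi-frame XYZ; an empty file yields zero frames.

    Raises :class:`XYZParseError` (naming the frame) when an atom-count line
    is not an integer, a frame is truncated, or an atom line is malformed.
    """
    text = Path(path).read_text()
    lines = text.splitlines()
    pos = 0
    elements: list[str] | None = None
    coords: list[np.ndarray] = []
    frame = 0
    while pos < len(lines):
        if not lines[pos].strip():
            pos += 1
            continue
        try:
            natoms = int(lines[pos].strip())
        except ValueError as exc:
            raise XYZParseError(
                f"frame {frame}: expected an atom count, got {lines[pos]!r}"
            ) from exc
        pos += 2  # skip comment line
        els: list[str] = []
        xyz = np.empty((natoms, 3))
        for a in range(natoms):
            if pos >= len(lines):
                raise XYZParseError(
                    f"frame {frame}: truncated (expected {natoms} atoms, got {a})"
                )
            parts = lines[pos].split()
            if len(parts) != 4:
                raise XYZParseError(
                    f"frame {frame}: malformed atom line {lines[pos]!r} "
                    f"(expected {natoms} atoms, got {a})"
                )
            try:
                xyz[a] = [float(p) for p in parts[1:]]
            except ValueError as exc:
                raise XYZParseError(
                    f"frame {frame}: non-numeric coordinate in {lines[pos]!r}"
                ) from exc
            els.append(parts[0])
            pos += 1
        if elements is None:
            elements = els
        coords.append(xyz)
        frame += 1
    if not coords:
        return TrajectoryFrames(elements=[], coords=np.empty((0, 0, 3)), dt=dt)
    return TrajectoryFrames(elements=elements or [], coords=np.stack(coords), dt=dt)
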