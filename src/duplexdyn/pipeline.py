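"""End-to-end pipeline: simulate -> fit -> das -> melt -> stack.

A run is described by a strict nested configuration (YAML on disk): unknown
keys are rejected by name so that a config always means what it says, every
stage seed is recorded in the run log, and two runs with the same config
produce byte-identical artifacts.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np
import yaml

from . import io as dio
from . import photophysics, synthetic
from .melting import fit_melting
from .stacking import block_bootstrap_histogram, integrated_act
from .tcspc import fit_global

__all__ = ["ConfigError", "RunConfig", "run_pipeline", "load_config"]


class ConfigError(ValueError):
    """Invalid or inconsistent run configuration."""


_SCHEMA: dict[str, dict[str, type | tuple]] = {
    "simulate": {
        "enabled": bool,
        "peak_counts": (int, float),
        "irf_fwhm_ns": (int, float),
        "melting_tm": (int, float),
        "melting_width": (int, float),
        "melting_noise": (int, float),
        "angle_mean": (int, float),
        "angle_sd": (int, float),
        "angle_phi": (int, float),
        "angle_n": int,
        "angle_dt_ps": (int, float),
    },
    "fit": {"enabled": bool, "components": int},
    "das": {"enabled": bool, "qy": (int, float)},
    "melt": {"enabled": bool, "method": str},
    "stack": {"enabled": bool, "replicas": int, "ci_level": (int, float)},
}
_TOP = {"output_dir": str, "seed": int, **{k: dict for k in _SCHEMA}}

_DEFAULTS: dict[str, dict] = {
    "simulate": {
        "enabled": True,
        "peak_counts": 1e4,
        "irf_fwhm_ns": 0.5,
        "melting_tm": 59.5,
        "melting_width": 2.0,
        "melting_noise": 0.01,
        "angle_mean": 10.0,
        "angle_sd": 4.0,
        "angle_phi": 0.9,
        "angle_n": 100_000,
        "angle_dt_ps": 1.0,
    },
    "fit": {"enabled": True, "components": 3},
    "das": {"enabled": True, "qy": 0.0059},
    "melt": {"enabled": True, "method": "sigmoid"},
    "stack": {"enabled": True, "replicas": 1000, "ci_level": 0.95},
}


@dataclass
class RunConfig:
    output_dir: Path
    seed: int = 1
    stages: dict = dc_field(default_factory=dict)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        unknown = set(raw) - set(_TOP)
        if unknown:
            raise ConfigError(f"unknown config key(s): {sorted(unknown)}")
        if "output_dir" not in raw:
            raise ConfigError("config must set output_dir")
        seed = raw.get("seed", 1)
        if not isinstance(seed, int):
            raise ConfigError("seed must be an integer")
        stages = {}
        for stage, schema in _SCHEMA.items():
            block = dict(_DEFAULTS[stage])
            user = raw.get(stage, {})
            if not isinstance(user, dict):
                raise ConfigError(f"stage {stage!r} must be a mapping")
            bad = set(user) - set(schema)
            if bad:
                raise ConfigError(f"unknown key(s) in stage {stage!r}: {sorted(bad)}")
            for key, val in user.items():
                expected = schema[key]
                ok = isinstance(val, expected)
                if isinstance(val, bool) and expected is not bool:
                    ok = False  # bools are ints in Python; reject for numerics
                if not ok:
                    raise ConfigError(
                        f"{stage}.{key}: expected {expected}, got {type(val).__name__}"
                    )
                block[key] = val
            stages[stage] = block
        cfg = cls(output_dir=Path(raw["output_dir"]), seed=seed, stages=stages)
        cfg.validate_dependencies()
        return cfg

    def validate_dependencies(self) -> None:
        s = self.stages
        if s["fit"]["enabled"] and not s["simulate"]["enabled"]:
            raise ConfigError("stage 'fit' requires stage 'simulate'")
        if s["das"]["enabled"] and not s["fit"]["enabled"]:
            raise ConfigError("stage 'das' requires stage 'fit'")
        if s["melt"]["enabled"] and not s["simulate"]["enabled"]:
            raise ConfigError("stage 'melt' requires stage 'simulate'")
        if s["stack"]["enabled"] and not s["simulate"]["enabled"]:
            raise ConfigError("stage 'stack' requires stage 'simulate'")
        if not 1 <= s["fit"]["components"] <= 4:
            raise ConfigError("fit.components must be in 1..4")
        if not 0 < s["stack"]["ci_level"] < 1:
            raise ConfigError("stack.ci_level must be in (0, 1)")
        if s["melt"]["method"] not in ("sigmoid", "derivative"):
            raise ConfigError("melt.method must be 'sigmoid' or 'derivative'")

    def config_hash(self) -> str:
        blob = json.dumps(
            {"output_dir": str(self.output_dir), "seed": self.seed, **self.stages},
            sort_keys=True,
        )
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def load_config(path: str | Path) -> RunConfig:
    raw = yaml.safe_load(Path(path).read_text())
    if not isinstance(raw, dict):
        raise ConfigError("config file must hold a mapping")
    return RunConfig.from_dict(raw)


def run_pipeline(config: RunConfig) -> dict:
    """Execute the enabled stages in dependency order; returns the run log.

    Artifacts written to ``output_dir``: decays/irf/spectrum CSVs, fit.json,
    das.csv, summary.csv, melt.csv, tm.json, angles.csv, hist.csv, run.json.
    Reruns with the same config are byte-identical.
    """
    out = config.output_dir
    out.mkdir(parents=True, exist_ok=True)
    s = config.stages
    # stage seeds derived once from the master seed, all below 2**31
    ss = np.random.SeedSequence(config.seed)
    seed_decay, seed_melt, seed_angle, seed_boot = (
        int(x) for x in ss.generate_state(4) % (2**31)
    )
    log: dict = {
        "seed": config.seed,
        "stage_seeds": {
            "decay": seed_decay,
            "melting": seed_melt,
            "angles": seed_angle,
            "bootstrap": seed_boot,
        },
        "config_hash": config.config_hash(),
        "artifacts": [],
    }

    dataset = None
    if s["simulate"]["enabled"]:
        spec = synthetic.duplex_decay_spec(peak_counts=s["simulate"]["peak_counts"])
        irf = synthetic.IRFSpec(fwhm=s["simulate"]["irf_fwhm_ns"])
        dataset = synthetic.gen_decay_dataset(spec, irf, seed=seed_decay)
        dio.write_decay_dataset(
            dataset, out / "decays.csv", out / "irf.csv", out / "spectrum.csv"
        )
        log["artifacts"] += ["decays.csv", "irf.csv", "spectrum.csv"]

        mspec = synthetic.MeltingModelSpec(
            tm=s["simulate"]["melting_tm"],
            width=s["simulate"]["melting_width"],
            noise_sd=s["simulate"]["melting_noise"],
        )
        curve = synthetic.gen_melting_curve(mspec, seed=seed_melt)
        dio.write_melting_curve(curve, out / "melt.csv")
        log["artifacts"].append("melt.csv")

        aspec = synthetic.AngleProcessSpec(
            mean=s["simulate"]["angle_mean"],
            sd=s["simulate"]["angle_sd"],
            phi=s["simulate"]["angle_phi"],
            n=s["simulate"]["angle_n"],
            dt=s["simulate"]["angle_dt_ps"],
            seed=seed_angle,
        )
        series = synthetic.gen_angle_series(aspec)
        dio.write_angle_series(series, out / "angles.csv")
        log["artifacts"].append("angles.csv")

    fit = None
    if s["fit"]["enabled"]:
        assert dataset is not None
        fit = fit_global(dataset, n_components=s["fit"]["components"])
        dio.write_fit_json(fit, out / "fit.json")
        log["artifacts"].append("fit.json")
        log["fit"] = {
            "lifetimes_ns": fit.taus.tolist(),
            "chi2_reduced_pooled": fit.chi2_reduced_pooled,
        }

    if s["das"]["enabled"]:
        assert fit is not None and dataset is not None
        summary = photophysics.summarize(
            fit, dataset.wavelengths, dataset.steady_state, qy=s["das"]["qy"]
        )
        das = photophysics.build_das(fit, dataset.wavelengths, dataset.steady_state)
        import pandas as pd

        das_df = pd.DataFrame({"wavelength_nm": das.wavelengths})
        for i in range(das.das.shape[0]):
            das_df[f"das{i + 1}"] = das.das[i]
        das_df["steady_state"] = das.steady_state
        das_df.to_csv(out / "das.csv", index=False, float_format="%.17g")
        dio.write_summary_csv(summary, out / "summary.csv", label="synthetic duplex")
        log["artifacts"] += ["das.csv", "summary.csv"]
        log["das"] = {
            "A": summary.amplitudes.tolist(),
            "tau_av_ns": summary.tau_av,
            "k_nr_1e7": summary.k_nr,
        }

    if s["melt"]["enabled"]:
        curve = dio.read_melting_curve(out / "melt.csv")
        if s["melt"]["method"] == "sigmoid":
            mfit = fit_melting(curve)
            tm_report = {
                "tm_C": mfit.tm,
                "tm_stderr_C": mfit.tm_stderr,
                "width_C": mfit.width,
                "method": mfit.method,
            }
        else:
            from .melting import tm_derivative

            tm_report = {"tm_C": tm_derivative(curve), "method": "derivative"}
        (out / "tm.json").write_text(json.dumps(tm_report, indent=2) + "\n")
        log["artifacts"].append("tm.json")
        log["melt"] = tm_report

    if s["stack"]["enabled"]:
        series = dio.read_angle_series(
            out / "angles.csv", dt=s["simulate"]["angle_dt_ps"]
        )
        act = integrated_act(series)
        hist = block_bootstrap_histogram(
            series,
            n_replicas=s["stack"]["replicas"],
            level=s["stack"]["ci_level"],
            seed=seed_boot,
            block_length=act.block_length,
        )
        dio.write_histogram(hist, out / "hist.csv")
        log["artifacts"].append("hist.csv")
        log["stack"] = {
            "tau_int_ps": act.tau_int,
            "block_length": act.block_length,
        }

    (out / "run.json").write_text(json.dumps(log, indent=2, sort_keys=True) + "\n")
    return log
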