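"""End-to-end run: simulate -> metrics -> kinetics -> distribution fits.

A run is fully determined by a :class:`RunConfig` (plain key=value text
file); it writes the ensemble, metrics and kinetics tables, one fit JSON
per observable, and a machine-readable summary with built-in
parameter-recovery checks.  Summaries contain no timestamps or paths, so
two runs from the same config and seed are byte-identical.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Optional

import numpy as np
import pandas as pd

from . import distfit, io, synth
from .errors import BindscapeError, ConfigError
from .kinetics import kinetics_for_profile
from .landscape import ROOM_TEMPERATURE, LandscapeParams
from .spectrum import compute_metrics, stratify_profile

log = logging.getLogger("bindscape")

__all__ = ["RunConfig", "default_config", "load_config", "run_pipeline"]


@dataclass(frozen=True)
class RunConfig:
    """Everything a pipeline run needs; serializable to key=value text."""

    ensemble: synth.EnsembleSpec = field(default_factory=synth.EnsembleSpec)
    temperature: float = ROOM_TEMPERATURE
    bin_width: float = 0.5
    diffusion: float = 1.0
    exclusion_radius: float = 1.0
    fit_bins: Optional[int] = None
    fit_center_window: float = 1.5
    fit_tail_fraction: float = 0.2
    seed: int = 0


def default_config(seed: int = 0) -> RunConfig:
    spec = synth.EnsembleSpec(seed=seed)
    return RunConfig(ensemble=spec, seed=seed)


_SCALAR_KEYS = {
    "temperature": float,
    "bin_width": float,
    "diffusion": float,
    "exclusion_radius": float,
    "fit_bins": int,
    "fit_center_window": float,
    "fit_tail_fraction": float,
    "seed": int,
}

_ENSEMBLE_KEYS = {
    "num_ligands": int,
    "states_per_ligand": int,
    "gap_mean": float,
    "gap_sd": float,
    "rmsd_native": float,
    "rmsd_max": float,
    "energy_rmsd_slope": float,
    "rmsd_noise_sd": float,
    "seed": int,
}

_LANDSCAPE_KEYS = {
    "mean_energy": float,
    "roughness": float,
    "temperature": float,
    "num_states": int,
    "entropy": float,
    "cutoff_free_energy": float,
    "time_prefactor": float,
}


def load_config(path) -> RunConfig:
    """Parse a key=value config file with dotted sections.

    Example::

        seed = 7
        temperature = 0.593
        ensemble.num_ligands = 720
        ensemble.landscape.roughness = 2.0

    Unknown keys raise :class:`ConfigError` naming the key.
    """
    scalars: Dict[str, object] = {}
    ens: Dict[str, object] = {}
    land: Dict[str, object] = {}
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), 1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ConfigError(f"{path}:{lineno}: expected key = value, got {raw!r}")
        key, value = (part.strip() for part in line.split("=", 1))
        if key in _SCALAR_KEYS:
            scalars[key] = _SCALAR_KEYS[key](value)
        elif key.startswith("ensemble.landscape."):
            sub = key[len("ensemble.landscape."):]
            if sub not in _LANDSCAPE_KEYS:
                raise ConfigError(f"unknown config key {key!r}")
            land[sub] = _LANDSCAPE_KEYS[sub](value)
        elif key.startswith("ensemble."):
            sub = key[len("ensemble."):]
            if sub not in _ENSEMBLE_KEYS:
                raise ConfigError(f"unknown config key {key!r}")
            ens[sub] = _ENSEMBLE_KEYS[sub](value)
        else:
            raise ConfigError(f"unknown config key {key!r}")
    base_spec = synth.EnsembleSpec()
    landscape = (
        LandscapeParams(**land) if land else base_spec.landscape
    )
    if "seed" in scalars and "seed" not in ens:
        ens["seed"] = scalars["seed"]
    spec = dataclasses.replace(base_spec, landscape=landscape, **ens)
    return RunConfig(ensemble=spec, **scalars)


def config_to_dict(config: RunConfig) -> dict:
    """Flat, JSON-friendly echo of the config (for summary provenance)."""
    spec = config.ensemble
    land = spec.landscape
    out = {k: getattr(config, k) for k in _SCALAR_KEYS}
    out.update({f"ensemble.{k}": getattr(spec, k) for k in _ENSEMBLE_KEYS})
    out.update(
        {f"ensemble.landscape.{k}": getattr(land, k) for k in _LANDSCAPE_KEYS}
    )
    return out


def _fit_summary(values: np.ndarray, config: RunConfig, name: str) -> dict:
    fit = distfit.fit_composite(
        values,
        n_bins=config.fit_bins,
        center_window_sigmas=config.fit_center_window,
        variable_name=name,
    )
    return fit.summary()


def run_pipeline(config: RunConfig, outdir) -> dict:
    """Run the full analysis; returns the summary dict it also writes.

    Stages: simulate the spectra, compute per-ligand metrics, build the
    stratified profiles and their on/off MFPTs, fit the composite model
    to affinity, log K, ISR and the log kinetic times, and check that the
    fits recover the generating parameters.  A stage failure is recorded
    in the summary (``failed_stage``) and reflected in the return value.
    """
    out = io.ensure_dir(outdir)
    summary: dict = {"config": config_to_dict(config), "checks": {}, "failed_stage": None}
    t = config.temperature
    spec = config.ensemble
    try:
        stage = "simulate"
        t0 = time.perf_counter()
        spectra = synth.generate_ensemble(spec)
        frame = synth.ensemble_to_frame(spectra)
        io.write_tsv(frame, out / "ensemble.tsv")
        log.info("simulate: %d ligands in %.2fs", len(spectra), time.perf_counter() - t0)

        stage = "metrics"
        t0 = time.perf_counter()
        rows = [
            compute_metrics(sp, t, exclusion_radius=config.exclusion_radius)
            for sp in spectra
        ]
        metrics = pd.DataFrame(
            {
                "ligand_id": [m.ligand_id for m in rows],
                "F_n": [m.F_n for m in rows],
                "F_mean": [m.F_mean for m in rows],
                "dF": [m.dF for m in rows],
                "F_un": [m.F_un for m in rows],
                "affinity": [m.affinity for m in rows],
                "logK": [m.logK for m in rows],
                "ISR": [m.isr for m in rows],
            }
        )
        io.write_tsv(metrics, out / "metrics.tsv")
        log.info("metrics: %d ligands in %.2fs", len(rows), time.perf_counter() - t0)

        stage = "kinetics"
        t0 = time.perf_counter()
        kin_rows = []
        for sp in spectra:
            profile = stratify_profile(sp, t, config.bin_width, D=config.diffusion)
            res = kinetics_for_profile(profile, t)
            kin_rows.append(
                (sp.ligand_id, res.tau_on, res.tau_off, res.barrier_on, res.barrier_off)
            )
        kin = pd.DataFrame(
            kin_rows, columns=["ligand_id", "tau_on", "tau_off", "barrier_on", "barrier_off"]
        )
        io.write_tsv(kin, out / "kinetics.tsv")
        log.info("kinetics: %d ligands in %.2fs", len(kin_rows), time.perf_counter() - t0)

        stage = "fitdist"
        t0 = time.perf_counter()
        fits = {
            "affinity": _fit_summary(metrics["affinity"].to_numpy(), config, "affinity"),
            "logK": _fit_summary(metrics["logK"].to_numpy(), config, "logK"),
            "isr": _fit_summary(metrics["ISR"].to_numpy(), config, "ISR"),
            "log_tau": {
                "log_tau_on": _fit_summary(
                    np.log(kin["tau_on"].to_numpy()), config, "log_tau_on"
                ),
                "log_tau_off": _fit_summary(
                    np.log(kin["tau_off"].to_numpy()), config, "log_tau_off"
                ),
            },
        }
        for name, payload in fits.items():
            (out / f"fit_{name}.json").write_text(
                json.dumps(payload, indent=2, sort_keys=True) + "\n"
            )
        # landscape-level recovery: an analytic-law ensemble of the same
        # size must return the nominal roughness from the composite fit
        rem = synth.sample_rem_ensemble(
            dataclasses.replace(spec.landscape, temperature=t),
            spec.num_ligands,
            seed=spec.seed + 1,
        )
        rem_fit_aff = _fit_summary(rem["affinity"].to_numpy(), config, "rem_affinity")
        rem_fit_logk = _fit_summary(rem["logK"].to_numpy(), config, "rem_logK")
        (out / "fit_rem_affinity.json").write_text(
            json.dumps(rem_fit_aff, indent=2, sort_keys=True) + "\n"
        )
        log.info("fitdist: %.2fs", time.perf_counter() - t0)

        stage = "checks"
        dE = spec.landscape.roughness
        pooled_sd = float(
            frame.loc[frame["is_native"] == 0, "energy_kcal_mol"].std(ddof=0)
        )
        rec_sigma_aff = rem_fit_aff["center"]["sigma"]
        rec_sigma_logk = rem_fit_logk["center"]["sigma"]
        checks = {
            "pooled_nonnative_sd": {
                "value": pooled_sd,
                "expected": dE,
                "tolerance_rel": 0.05,
                "passed": bool(abs(pooled_sd - dE) <= 0.05 * dE),
            },
            "recovered_affinity_sigma": {
                "value": rec_sigma_aff,
                "expected": dE,
                "tolerance_rel": 0.05,
                "passed": bool(abs(rec_sigma_aff - dE) <= 0.05 * dE),
            },
            "recovered_logK_sigma": {
                "value": rec_sigma_logk,
                "expected": dE / t,
                "tolerance_rel": 0.05,
                "passed": bool(abs(rec_sigma_logk - dE / t) <= 0.05 * dE / t),
            },
        }
        summary["checks"] = checks
        summary["fits"] = fits
        summary["rem_recovery"] = {"affinity": rem_fit_aff, "logK": rem_fit_logk}
        summary["n_ligands"] = int(spec.num_ligands)
        summary["passed"] = bool(all(c["passed"] for c in checks.values()))
    except BindscapeError as exc:
        summary["failed_stage"] = stage
        summary["error"] = str(exc)
        summary["passed"] = False
        log.error("stage %s failed: %s", stage, exc)

    (Path(out) / "summary.json").write_text(
        json.dumps(summary, indent=2, sort_keys=True) + "\n"
    )
    return summary
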