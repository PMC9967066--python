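"""End-to-end pipeline: YAML config -> simulate -> fit -> report.

One YAML document configures a full synthetic vaping experiment:
chamber scenario, puff schedule, source distribution, simulation and
noise settings.  :func:`run_pipeline` executes

    simulate -> instrument ceiling -> decay fit -> emissions -> size modes

and writes all CSV artifacts plus a JSON manifest recording the seed,
config hash and package version.  Runs are idempotent for a fixed seed.
Validation failures raise :class:`ConfigError` naming the offending
field path, and no partial artifact directory is left behind (artifacts
are staged in a temporary directory and moved into place atomically).
"""

from __future__ import annotations

import hashlib
import json
import shutil
import tempfile
from pathlib import Path
from typing import Any

import numpy as np
import yaml

from . import __version__
from .chamber import (
    ChamberScenario,
    NoiseSpec,
    SourceSpec,
    apply_instrument,
    simulate_chamber,
)
from .decay import fit_decay, pick_decay_window
from .emissions import (
    MassConversionSpec,
    default_emission_window,
    emission_factor,
    number_to_mass,
    total_emission,
)
from .grids import SizeGrid, composite_grid
from .puffs import PuffProfile, PuffSchedule, regular_schedule
from .series import ConcSeries
from .sizedist import LognormalMode, fit_modes, modes_to_csv, normalize


class ConfigError(ValueError):
    """Invalid pipeline configuration; message names the field path."""


def _require(cfg: dict, key: str, path: str) -> Any:
    if key not in cfg:
        raise ConfigError(f"missing required field: {path}.{key}")
    return cfg[key]


def _num(value: Any, path: str) -> float:
    """Coerce a YAML scalar to float (YAML 1.1 reads '4.92e10' as text)."""
    if value is None:
        raise ConfigError(f"missing numeric value at {path}")
    try:
        return float(value)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"{path}: not a number: {value!r}") from exc


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ConfigError("config must be a YAML mapping")
    return cfg


def _build_scenario(cfg: dict) -> ChamberScenario:
    sc = _require(cfg, "scenario", "$")
    try:
        eags = sc.get("dilution_flow_eags_lpm")
        chamber_flow = sc.get("dilution_flow_chamber_lpm")
        return ChamberScenario(
            volume_Vc_m3=_num(_require(sc, "volume_Vc_m3", "$.scenario"), "$.scenario.volume_Vc_m3"),
            ach=_num(sc.get("ach", 0.0), "$.scenario.ach"),
            label=sc.get("label", "static"),
            dilution_flow_eags_lpm=None if eags is None else _num(eags, "$.scenario.dilution_flow_eags_lpm"),
            dilution_flow_chamber_lpm=None if chamber_flow is None else _num(chamber_flow, "$.scenario.dilution_flow_chamber_lpm"),
        )
    except ValueError as exc:
        raise ConfigError(f"$.scenario: {exc}") from exc


def _build_schedule(cfg: dict) -> PuffSchedule:
    sc = _require(cfg, "schedule", "$")
    prof_cfg = sc.get("profile", {})
    try:
        profile = PuffProfile(
            volume_mL=_num(prof_cfg.get("volume_mL", 55.0), "$.schedule.profile.volume_mL"),
            duration_s=_num(prof_cfg.get("duration_s", 3.0), "$.schedule.profile.duration_s"),
        )
        if "puff_times_s" in sc:
            return PuffSchedule(np.asarray(sc["puff_times_s"], dtype=float), profile)
        return regular_schedule(
            n_puffs=int(_require(sc, "n_puffs", "$.schedule")),
            interval_s=_num(_require(sc, "interval_s", "$.schedule"), "$.schedule.interval_s"),
            start_s=_num(sc.get("start_s", 0.0), "$.schedule.start_s"),
            profile=profile,
        )
    except ValueError as exc:
        raise ConfigError(f"$.schedule: {exc}") from exc


def _build_source(cfg: dict) -> SourceSpec:
    sc = _require(cfg, "source", "$")
    modes_cfg = _require(sc, "modes", "$.source")
    try:
        modes = tuple(
            LognormalMode(
                _num(m.get("weight", 1.0), f"$.source.modes[{i}].weight"),
                _num(_require(m, "gmd_nm", f"$.source.modes[{i}]"), f"$.source.modes[{i}].gmd_nm"),
                _num(m.get("gsd", 1.6), f"$.source.modes[{i}].gsd"),
            )
            for i, m in enumerate(modes_cfg)
        )
        return SourceSpec(modes, _num(_require(sc, "number_per_puff", "$.source"), "$.source.number_per_puff"))
    except ConfigError:
        raise
    except ValueError as exc:
        raise ConfigError(f"$.source: {exc}") from exc


def apply_ops_ceiling(series: ConcSeries, ceiling_per_cm3: float) -> ConcSeries:
    """Clip only the optical-sizer channels (bins above 300 nm)."""
    split = int(np.searchsorted(series.grid.bin_edges, 300.0 * (1 + 1e-12)))
    if split >= series.grid.bin_edges.size - 1:
        return series.copy()
    ops_grid = SizeGrid(series.grid.bin_edges[split:])
    ops_part = ConcSeries(
        series.times, ops_grid, series.conc[:, split:], series.saturated[:, split:]
    )
    clipped = apply_instrument(ops_part, ceiling_per_cm3)
    out = series.copy()
    out.conc[:, split:] = clipped.conc
    out.saturated[:, split:] = clipped.saturated
    return out


def run_pipeline(config: str | Path | dict, out_dir: str | Path, seed: int | None = None) -> dict:
    """Execute the full pipeline described by a config; return the manifest.

    ``seed`` overrides the config's seed when given; the config must
    carry one otherwise (simulation requires an explicit seed).
    """
    if isinstance(config, (str, Path)):
        cfg = load_config(config)
        cfg_bytes = Path(config).read_bytes()
    else:
        cfg = config
        cfg_bytes = yaml.safe_dump(cfg, sort_keys=True).encode()

    if seed is None:
        seed = cfg.get("seed")
    if seed is None:
        raise ConfigError("missing required field: $.seed (simulation seed is mandatory)")
    seed = int(seed)

    scenario = _build_scenario(cfg)
    schedule = _build_schedule(cfg)
    source = _build_source(cfg)
    sim = cfg.get("simulation", {})
    noise_cfg = sim.get("noise")
    try:
        noise = (
            NoiseSpec(gsd=_num(noise_cfg.get("gsd", 1.05), "$.simulation.noise.gsd"), poisson=bool(noise_cfg.get("poisson", False)))
            if noise_cfg
            else None
        )
    except ValueError as exc:
        raise ConfigError(f"$.simulation.noise: {exc}") from exc

    series = simulate_chamber(
        scenario,
        schedule,
        source,
        beta_dep_per_s=_num(sim.get("beta_dep_per_s", 0.0), "$.simulation.beta_dep_per_s"),
        dt_s=_num(sim.get("dt_s", 10.0), "$.simulation.dt_s"),
        t_end_s=None if sim.get("t_end_s") is None else _num(sim.get("t_end_s"), "$.simulation.t_end_s"),
        grid=composite_grid(),
        noise=noise,
        seed=seed,
    )
    ceiling = _num(cfg.get("instrument", {}).get("ops_ceiling_per_cm3", 3000.0), "$.instrument.ops_ceiling_per_cm3")
    series = apply_ops_ceiling(series, ceiling)

    lag_s = cfg.get("decay", {}).get("lag_s", 120.0)
    window = pick_decay_window(series, schedule, lag_s=lag_s)
    decay_fit = fit_decay(series, window)

    ewin = default_emission_window(series, schedule.puff_times_s, lag_s=lag_s)
    beta_for_tp = max(decay_fit.beta_per_s, 0.0)
    per_bin_tp = total_emission(series, scenario, beta_for_tp, ewin, per_bin=True)
    tp_number = float(np.sum(per_bin_tp))
    mass_spec = MassConversionSpec(
        density_g_cm3=cfg.get("mass", {}).get("density_g_cm3", 1.0)
    )
    tp_mass = number_to_mass(np.clip(per_bin_tp, 0, None), series.grid, mass_spec)
    result = emission_factor(
        tp_number,
        schedule.n_puffs,
        dilution_factor=scenario.dilution_factor,
        beta_used_per_s=decay_fit.beta_per_s,
        scenario_label=scenario.label,
        tp_mass_ug=tp_mass,
    )

    dist = normalize(np.clip(per_bin_tp, 0, None), series.grid)
    n_modes = cfg.get("size_fit", {}).get("n_modes", "auto")
    mode_fit = fit_modes(dist, n_modes)

    out_dir = Path(out_dir)
    out_dir.parent.mkdir(parents=True, exist_ok=True)
    manifest = {
        "package_version": __version__,
        "seed": seed,
        "config_sha256": hashlib.sha256(cfg_bytes).hexdigest(),
        "scenario": scenario.label,
        "n_puffs": schedule.n_puffs,
        "dilution_factor": scenario.dilution_factor,
        "beta_per_s": decay_fit.beta_per_s,
        "artifacts": [
            "series.csv",
            "series_saturation.csv",
            "decay_fit.csv",
            "emissions.csv",
            "distribution.csv",
            "size_modes.csv",
            "manifest.json",
        ],
    }
    tmp = Path(tempfile.mkdtemp(prefix=".pipeline-", dir=out_dir.parent))
    try:
        series.to_csv(tmp / "series.csv", tmp / "series_saturation.csv")
        decay_fit.to_frame().to_csv(tmp / "decay_fit.csv", index=False, float_format="%.17g")
        result.to_frame(device=cfg.get("device", {}).get("device_type", "")).to_csv(
            tmp / "emissions.csv", index=False, float_format="%.17g"
        )
        dist.to_csv(tmp / "distribution.csv")
        modes_to_csv(mode_fit, tmp / "size_modes.csv")
        (tmp / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
        if out_dir.exists():
            shutil.rmtree(out_dir)
        tmp.rename(out_dir)
    finally:
        if tmp.exists():
            shutil.rmtree(tmp, ignore_errors=True)
    return manifest
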