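"""Run configuration, pipeline orchestration, and provenance.

A RunConfig drives the full analysis chain (read → superpose → RMSF/RMSD/
DCCM [→ ΔDCCM → features]; dipole → ACF → spectrum → peaks) and every run
emits a manifest recording inputs, parameters, seeds, and content hashes of
the outputs, so identical configs produce hash-identical artifacts.
Defaults mirror the study conditions: 5 fs sampling, 0.25 display cutoff,
300 K.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import correlation, spectroscopy, structure_io, superposition

__all__ = ["RunConfig", "ConfigError", "load_config", "run_pipeline"]

logger = logging.getLogger(__name__)


class ConfigError(ValueError):
    pass


@dataclass
class RunConfig:
    """Parameters for one end-to-end analysis run (YAML-serializable)."""

    topology: str | None = None         # reference PDB
    trajectory: str | None = None       # multi-frame XYZ
    trajectory_modified: str | None = None  # optional second system for ΔDCCM
    dipole: str | None = None           # CSV: t_fs, mu_x, mu_y, mu_z
    selection: str = "CA"               # "CA" or "all"
    timestep: float = 5.0               # fs
    temperature: float = 300.0          # K
    cutoff: float = 0.25                # |C| display threshold
    band: tuple[float, float] | None = None  # peak-search band, cm⁻¹
    max_lag_fraction: float = 0.25
    zero_padding: int = 4
    seed: int = 0
    output_dir: str = "azidyn_out"

    def validate(self) -> None:
        if self.timestep <= 0:
            raise ConfigError("timestep must be > 0 fs")
        if self.temperature <= 0:
            raise ConfigError("temperature must be > 0 K")
        if self.cutoff < 0:
            raise ConfigError("cutoff must be >= 0")
        if not 0 < self.max_lag_fraction <= 1:
            raise ConfigError("max_lag_fraction must be in (0, 1]")
        if self.trajectory is not None and self.topology is None:
            raise ConfigError("a trajectory requires a topology PDB")
        if self.trajectory is None and self.dipole is None:
            raise ConfigError("nothing to do: no trajectory and no dipole input")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def load_config(path: str | Path) -> RunConfig:
    raw = yaml.safe_load(Path(path).read_text()) or {}
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")
    if "band" in raw and raw["band"] is not None:
        raw["band"] = tuple(raw["band"])
    return RunConfig(**raw)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _selector(expr: str):
    if expr == "CA":
        return structure_io.is_calpha
    if expr == "all":
        return lambda atom: True
    return structure_io.name_is(*expr.split(","))


def _analyse_system(
    config: RunConfig, traj_path: str, outdir: Path, tag: str
) -> tuple[correlation.CorrelationMatrix, list[Path]]:
    structure = structure_io.read_pdb(config.topology)
    traj = structure_io.read_xyz_trajectory(traj_path, timestep=config.timestep)
    sel = structure_io.select_atoms(structure, _selector(config.selection))
    resnums = structure_io.residue_numbers(structure, sel)
    logger.info("stage superpose [%s]: %d frames, %d selected atoms",
                tag, traj.n_frames, sel.size)
    fitted = superposition.superpose_trajectory(traj, structure, sel)

    outputs: list[Path] = []
    rmsd = superposition.compute_rmsd_series(fitted, structure, sel, superpose=False)
    p = outdir / f"rmsd_{tag}.csv"
    pd.DataFrame({"time_fs": rmsd.time, "rmsd_A": rmsd.rmsd}).to_csv(p, index=False)
    outputs.append(p)

    rmsf = superposition.compute_rmsf(fitted, sel, residue_numbers=resnums)
    p = outdir / f"rmsf_{tag}.csv"
    pd.DataFrame(
        {"residue": rmsf.residue_numbers, "rmsf_A": rmsf.rmsf}
    ).to_csv(p, index=False)
    outputs.append(p)

    dccm = correlation.compute_dccm(fitted, sel, residue_numbers=resnums, label=tag)
    p = outdir / f"dccm_{tag}.csv"
    correlation.save_matrix_csv(dccm, p)
    outputs.append(p)
    return dccm, outputs


def run_pipeline(config: RunConfig) -> dict:
    """Execute all configured stages; return (and write) the manifest."""
    config.validate()
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    outputs: list[Path] = []

    try:
        if config.trajectory is not None:
            dccm_wt, produced = _analyse_system(
                config, config.trajectory, outdir, "wt"
            )
            outputs.extend(produced)
            if config.trajectory_modified is not None:
                dccm_mod, produced = _analyse_system(
                    config, config.trajectory_modified, outdir, "mod"
                )
                outputs.extend(produced)
                delta = correlation.compute_delta_dccm(dccm_mod, dccm_wt)
                p = outdir / "ddccm.csv"
                resnums = delta.residue_numbers
                pd.DataFrame(delta.values, index=resnums, columns=resnums).to_csv(
                    p, index_label="residue"
                )
                outputs.append(p)
                blocks = correlation.extract_feature_blocks(delta, config.cutoff)
                p = outdir / "features.json"
                p.write_text(
                    json.dumps(
                        [dataclasses.asdict(b) for b in blocks], indent=2
                    )
                )
                outputs.append(p)

        if config.dipole is not None:
            df = pd.read_csv(config.dipole)
            series = spectroscopy.DipoleSeries(
                values=df.iloc[:, 1:4].to_numpy(dtype=float),
                timestep=float(df.iloc[1, 0] - df.iloc[0, 0]),
                source=str(config.dipole),
            )
            span = (series.n_samples - 1) * series.timestep
            acf = spectroscopy.dipole_acf(
                series, max_lag=config.max_lag_fraction * span
            )
            spec = spectroscopy.ir_spectrum(
                acf,
                spectroscopy.SpectrumParams(
                    temperature=config.temperature,
                    zero_padding=config.zero_padding,
                ),
            )
            p = outdir / "spectrum.csv"
            pd.DataFrame(
                {"wavenumber_cm-1": spec.wavenumbers, "intensity": spec.intensity}
            ).to_csv(p, index=False)
            outputs.append(p)
            if config.band is not None:
                nu_max, fwhm = spectroscopy.peak_metrics(spec, config.band)
                p = outdir / "peaks.json"
                p.write_text(
                    json.dumps(
                        {"peak_cm-1": nu_max, "fwhm_cm-1": fwhm,
                         "band": list(config.band)},
                        indent=2,
                    )
                )
                outputs.append(p)
    except Exception as exc:
        raise ConfigError(f"pipeline aborted: {exc}") from exc

    manifest = {
        "config": _jsonable(config.to_dict()),
        "outputs": {str(p.name): _sha256(p) for p in outputs},
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj
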