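"""Configuration files, matrix/trajectory serialization and run manifests.

All quantities are minutes and cells/mL internally; configuration files may
give durations with explicit unit suffixes ("60 days", "7 years").  Every
file write is atomic (temp file + rename) so interrupted runs never leave
truncated outputs, and every CLI run writes a manifest with the resolved
configuration, seeds and content digests of its inputs and outputs.
"""

from __future__ import annotations

import dataclasses
import datetime
import hashlib
import json
import os
import tempfile
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .compatibility import CompatibilityMatrix, validate_alpha
from .dynamics import (
    FULL_SPREAD_THRESHOLD,
    MINUTES_PER_DAY,
    MINUTES_PER_HOUR,
    MINUTES_PER_YEAR,
    SimulationConfig,
    Trajectory,
)
from .errors import ConfigurationError, InvalidInputError
from .experiments import ALL_MECHANISMS, DEFAULT_GAMMAS
from .rate_calibration import CalibrationScaling, EndpointExperiment

__all__ = [
    "RunSettings",
    "parse_duration",
    "load_config",
    "atomic_write_text",
    "write_matrix",
    "read_matrix",
    "write_trajectory",
    "read_trajectory",
    "write_json",
    "read_experiments_csv",
    "build_manifest",
    "file_digest",
]

_DURATION_UNITS = {
    "min": 1.0,
    "minute": 1.0,
    "minutes": 1.0,
    "h": MINUTES_PER_HOUR,
    "hr": MINUTES_PER_HOUR,
    "hour": MINUTES_PER_HOUR,
    "hours": MINUTES_PER_HOUR,
    "d": MINUTES_PER_DAY,
    "day": MINUTES_PER_DAY,
    "days": MINUTES_PER_DAY,
    "y": MINUTES_PER_YEAR,
    "yr": MINUTES_PER_YEAR,
    "year": MINUTES_PER_YEAR,
    "years": MINUTES_PER_YEAR,
}


def parse_duration(value: float | int | str) -> float:
    """Duration in minutes from a number (minutes) or '<number> <unit>' string."""
    if isinstance(value, (int, float)) and not isinstance(value, bool):
        return float(value)
    if isinstance(value, str):
        parts = value.strip().split()
        if len(parts) == 2 and parts[1].lower() in _DURATION_UNITS:
            try:
                return float(parts[0]) * _DURATION_UNITS[parts[1].lower()]
            except ValueError:
                pass
        if len(parts) == 1:
            try:
                return float(parts[0])
            except ValueError:
                pass
    raise ConfigurationError(
        f"cannot parse duration {value!r}; use minutes or '<number> <min|h|day|year>'"
    )


@dataclass
class RunSettings:
    """Fully resolved run configuration: simulation + mechanism parameters."""

    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    gammas: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_GAMMAS))
    enabled: tuple[str, ...] = ALL_MECHANISMS
    spc_fraction: float = 0.15
    p_transformable: float = 0.01
    n_modules: int | None = None
    vesicle_participation: float = 1.0
    threshold: float = FULL_SPREAD_THRESHOLD
    seed: int = 0

    def to_dict(self) -> dict[str, Any]:
        out = dataclasses.asdict(self)
        out["simulation"] = dataclasses.asdict(self.simulation)
        out["enabled"] = list(self.enabled)
        return out


_SIM_KEYS = {
    "n_species",
    "total_time",
    "n_steps",
    "fitness",
    "fitness_unit",
    "per_species_density",
    "initial_species",
    "initial_fraction",
    "record_every",
}
_GAMMA_KEYS = {f"gamma_{m}" for m in ALL_MECHANISMS}
_OTHER_KEYS = {
    "mechanisms",
    "seed",
    "threshold",
    "spc_fraction",
    "p_transformable",
    "n_modules",
    "vesicle_participation",
}


def load_config(path: str | Path | None) -> RunSettings:
    """Load a YAML configuration file, filling defaults and rejecting unknown keys.

    An absent path or empty file yields the default study conditions: 100
    species at 1e4 cells/mL, 1e4 timesteps, fitness 0.02 per day, initial
    fraction 1e-4 in one species, the four calibrated rate constants, and all
    mechanisms enabled over a 60-day horizon.
    """
    raw: dict[str, Any] = {}
    if path is not None:
        text = Path(path).read_text()
        loaded = yaml.safe_load(text)
        if loaded is None:
            loaded = {}
        if not isinstance(loaded, dict):
            raise ConfigurationError("config file must be a mapping of keys to values")
        raw = loaded
    unknown = set(raw) - _SIM_KEYS - _GAMMA_KEYS - _OTHER_KEYS
    if unknown:
        raise ConfigurationError(f"unknown configuration keys: {sorted(unknown)}")

    def coerce(key: str, value: Any, kind: type) -> Any:
        # YAML 1.1 reads exponent forms like 1.0e5 (no sign) as strings
        try:
            return kind(value)
        except (TypeError, ValueError) as exc:
            raise ConfigurationError(f"field {key!r}: cannot read {value!r}") from exc

    sim_kwargs: dict[str, Any] = {}
    if "total_time" in raw:
        sim_kwargs["total_time"] = parse_duration(raw["total_time"])
    if "fitness_unit" in raw:
        sim_kwargs["fitness_input_unit"] = str(raw["fitness_unit"])
    for key, kind in (
        ("n_species", int), ("n_steps", int), ("fitness", float),
        ("per_species_density", float), ("initial_species", int),
        ("initial_fraction", float), ("record_every", int),
    ):
        if key in raw:
            sim_kwargs[key] = coerce(key, raw[key], kind)
    seed = coerce("seed", raw.get("seed", 0), int)
    simulation = SimulationConfig(rng_seed=seed, **sim_kwargs)

    gammas = dict(DEFAULT_GAMMAS)
    for key in _GAMMA_KEYS & set(raw):
        gammas[key.removeprefix("gamma_")] = coerce(key, raw[key], float)

    enabled = tuple(raw.get("mechanisms", ALL_MECHANISMS))
    bad = set(enabled) - set(ALL_MECHANISMS)
    if bad:
        raise ConfigurationError(f"unknown mechanisms: {sorted(bad)}")

    return RunSettings(
        simulation=simulation,
        gammas=gammas,
        enabled=enabled,
        spc_fraction=coerce("spc_fraction", raw.get("spc_fraction", 0.15), float),
        p_transformable=coerce(
            "p_transformable", raw.get("p_transformable", 0.01), float
        ),
        n_modules=(
            None if raw.get("n_modules") is None
            else coerce("n_modules", raw["n_modules"], int)
        ),
        vesicle_participation=coerce(
            "vesicle_participation", raw.get("vesicle_participation", 1.0), float
        ),
        threshold=coerce("threshold", raw.get("threshold", FULL_SPREAD_THRESHOLD), float),
        seed=seed,
    )


def atomic_write_text(path: str | Path, text: str) -> None:
    """Write text via a temp file and rename, never leaving partial output."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fd, tmp = tempfile.mkstemp(dir=path.parent, prefix=f".{path.name}.", suffix=".tmp")
    try:
        with os.fdopen(fd, "w") as fh:
            fh.write(text)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def write_json(path: str | Path, obj: Any) -> None:
    atomic_write_text(path, json.dumps(obj, indent=2, sort_keys=True) + "\n")


def _sidecar(path: Path) -> Path:
    return path.with_name(path.stem + ".meta.json")


def write_matrix(
    matrix: CompatibilityMatrix,
    path: str | Path,
    metadata: Mapping[str, Any] | None = None,
) -> None:
    """Serialize a compatibility matrix as CSV with species-id headers.

    Rows are donors, columns recipients, full float precision.  Generator
    metadata (mechanism, seed, parameters, and for transduction the module
    partition and phage-set sizes) goes to a ``<name>.meta.json`` sidecar.
    """
    path = Path(path)
    frame = pd.DataFrame(
        matrix.entries, index=matrix.species_ids, columns=matrix.species_ids
    )
    # default float formatting is the shortest round-trippable repr
    atomic_write_text(path, frame.to_csv())
    meta: dict[str, Any] = {"mechanism": matrix.mechanism, "n_species": matrix.n}
    if matrix.network is not None:
        meta["module_of"] = matrix.network.module_of.tolist()
        meta["phage_count"] = matrix.network.phage_count.tolist()
        meta["n_modules"] = matrix.network.n_modules
    if metadata:
        meta.update(metadata)
    write_json(_sidecar(path), meta)


def read_matrix(path: str | Path) -> CompatibilityMatrix:
    """Read a compatibility matrix CSV, validating shape and entry range."""
    path = Path(path)
    try:
        frame = pd.read_csv(path, index_col=0, float_precision="round_trip")
    except (pd.errors.ParserError, ValueError) as exc:
        raise InvalidInputError(f"malformed matrix file {path}: {exc}") from exc
    entries = frame.to_numpy(dtype=float)
    if entries.ndim != 2 or entries.shape[0] != entries.shape[1]:
        raise InvalidInputError(
            f"matrix in {path} is not square: shape {entries.shape}"
        )
    mechanism = "unknown"
    sidecar = _sidecar(path)
    if sidecar.exists():
        mechanism = json.loads(sidecar.read_text()).get("mechanism", "unknown")
    matrix = CompatibilityMatrix(
        mechanism, entries, species_ids=[str(s) for s in frame.index]
    )
    report = validate_alpha(matrix)
    if not report.passed:
        raise InvalidInputError(
            f"matrix in {path} failed validation: {report.violations[0]}"
        )
    return matrix


def write_trajectory(
    trajectory: Trajectory,
    csv_path: str | Path,
    summary_path: str | Path | None = None,
) -> None:
    """Write a trajectory as long-format CSV plus a JSON summary.

    The CSV has columns ``time_min, species_id, plasmid_fraction``; the
    summary carries the full-spread time (or null), the enabled mechanisms
    and the configuration echo.
    """
    if trajectory.n_records == 0:
        raise InvalidInputError("cannot write an empty trajectory")
    csv_path = Path(csv_path)
    n = trajectory.fractions.shape[1]
    species = [f"sp{i + 1}" for i in range(n)]
    frame = pd.DataFrame(
        {
            "time_min": np.repeat(trajectory.times, n),
            "species_id": np.tile(species, trajectory.n_records),
            "plasmid_fraction": trajectory.fractions.ravel(),
        }
    )
    atomic_write_text(csv_path, frame.to_csv(index=False))
    if summary_path is not None:
        write_json(
            summary_path,
            {
                "full_spread_time_min": trajectory.full_spread_time,
                "enabled_mechanisms": list(trajectory.enabled_mechanisms),
                "cap_events": trajectory.cap_events,
                "n_records": trajectory.n_records,
                "config": dataclasses.asdict(trajectory.config),
            },
        )


def read_trajectory(csv_path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    """Read a long-format trajectory CSV back to (times, fractions) arrays."""
    frame = pd.read_csv(csv_path, float_precision="round_trip")
    times = frame["time_min"].unique()
    n = frame["species_id"].nunique()
    fractions = frame["plasmid_fraction"].to_numpy().reshape(len(times), n)
    return times, fractions


def read_experiments_csv(
    path: str | Path,
) -> list[tuple[EndpointExperiment, CalibrationScaling]]:
    """Read end-point calibration experiments from a delimited text table.

    Expected columns: ``label, V0, R0, R1, dt_min`` and optionally
    ``vector_per_donor`` and ``recipient_efficiency`` (default 1).
    """
    frame = pd.read_csv(path)
    required = {"label", "V0", "R0", "R1", "dt_min"}
    missing = required - set(frame.columns)
    if missing:
        raise InvalidInputError(f"experiments file missing columns: {sorted(missing)}")
    out = []
    for row in frame.itertuples(index=False):
        exp = EndpointExperiment(
            vector_conc_initial=float(row.V0),
            recipient_conc_initial=float(row.R0),
            recipient_conc_final=float(row.R1),
            duration=float(row.dt_min),
            label=str(row.label),
        )
        scaling = CalibrationScaling(
            vector_per_donor=float(getattr(row, "vector_per_donor", 1.0)),
            recipient_efficiency=float(getattr(row, "recipient_efficiency", 1.0)),
        )
        out.append((exp, scaling))
    return out


def file_digest(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def build_manifest(
    command: str,
    settings: RunSettings | None,
    seeds: Sequence[int],
    inputs: Sequence[str | Path] = (),
    outputs: Sequence[str | Path] = (),
    extra: Mapping[str, Any] | None = None,
) -> dict[str, Any]:
    """Assemble a reproducibility manifest for one CLI run."""
    from . import __version__

    manifest: dict[str, Any] = {
        "tool": "hgtsim",
        "version": __version__,
        "created_utc": datetime.datetime.now(datetime.timezone.utc).isoformat(),
        "command": command,
        "seeds": list(seeds),
        "inputs": {str(p): file_digest(p) for p in inputs},
        "outputs": {str(p): file_digest(p) for p in outputs},
    }
    if settings is not None:
        manifest["settings"] = settings.to_dict()
    if extra:
        manifest.update(extra)
    return manifest
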