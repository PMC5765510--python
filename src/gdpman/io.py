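"""CSV and config I/O plus run manifests.

Progress curves travel as tidy UTF-8 CSV with columns ``time_min``,
``species``, ``concentration_M``, ``replicate`` — the shape of a
chromatography-derived concentration table. Floats are serialised with
shortest-round-trip repr so write/read is bit-exact. Model and experiment
definitions use nested YAML; every CLI run writes a JSON manifest recording
command, configs, seeds, package version, timestamps and output checksums.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .datasets import TimeSeriesDataset
from .exceptions import ParseError, ValidationError
from .model import CascadeModel, RateParameters
from .simulate import ExperimentDesign

__all__ = [
    "write_timeseries_csv",
    "read_timeseries_csv",
    "design_to_dict",
    "design_from_dict",
    "load_config",
    "save_config",
    "model_from_config",
    "design_from_config",
    "RunManifest",
]

_COLUMNS = ("time_min", "species", "concentration_M", "replicate")


def write_timeseries_csv(dataset: TimeSeriesDataset, path) -> None:
    """Write a dataset as tidy CSV (one row per time/species/replicate)."""
    rows = []
    for i, t in enumerate(dataset.times):
        for j, sp in enumerate(dataset.species):
            for r in range(dataset.n_replicates):
                rows.append((repr(float(t)), sp,
                             repr(float(dataset.values[i, j, r])), r + 1))
    frame = pd.DataFrame(rows, columns=_COLUMNS)
    frame.to_csv(path, index=False)


def read_timeseries_csv(
    path,
    design: ExperimentDesign | None = None,
    variant: str = "cascade",
    model: CascadeModel | None = None,
) -> TimeSeriesDataset:
    """Read a tidy progress-curve CSV back into a dataset.

    If ``design`` is omitted a minimal design is reconstructed from the
    file (sample times, replicate count, t=0 concentrations). When a
    ``model`` is supplied, species names are validated against its state
    space. Schema violations raise :class:`ParseError` with the offending
    row number (1-based, excluding the header).
    """
    try:
        frame = pd.read_csv(path, dtype=str, encoding="utf-8")
    except Exception as exc:
        raise ParseError(f"cannot read {path}: {exc}") from exc
    missing = [c for c in _COLUMNS if c not in frame.columns]
    if missing:
        raise ParseError(f"{path}: missing required column(s) {missing}")

    def _numeric(column, cast):
        try:
            return frame[column].map(cast).to_numpy()
        except (TypeError, ValueError):
            for i, raw in enumerate(frame[column]):
                try:
                    cast(raw)
                except (TypeError, ValueError):
                    raise ParseError(
                        f"{path}: non-numeric {column!r} value {raw!r} "
                        f"at row {i + 1}"
                    ) from None
            raise  # pragma: no cover

    times = _numeric("time_min", float)
    conc = _numeric("concentration_M", float)
    reps = _numeric("replicate", int)
    neg = np.flatnonzero(conc < 0)
    if neg.size:
        raise ParseError(
            f"{path}: negative concentration {conc[neg[0]]!r} at row "
            f"{int(neg[0]) + 1}"
        )
    species_col = frame["species"].to_numpy()
    if model is not None:
        for i, sp in enumerate(species_col):
            try:
                model.species_index(sp)
            except KeyError:
                raise ParseError(
                    f"{path}: unknown species {sp!r} at row {i + 1}"
                ) from None

    keys = {}
    for i, key in enumerate(zip(times, species_col, reps)):
        if key in keys:
            raise ParseError(
                f"{path}: duplicate (time, species, replicate) = {key} at "
                f"row {i + 1} (first at row {keys[key] + 1})"
            )
        keys[key] = i

    unique_times = np.unique(times)
    species = tuple(dict.fromkeys(species_col))  # preserve file order
    n_reps = int(reps.max())
    values = np.full((unique_times.size, len(species), n_reps), np.nan)
    t_ix = {t: i for i, t in enumerate(unique_times)}
    s_ix = {s: j for j, s in enumerate(species)}
    for t, sp, r, c in zip(times, species_col, reps, conc):
        values[t_ix[t], s_ix[sp], r - 1] = c
    if np.isnan(values).any():
        raise ParseError(f"{path}: incomplete time x species x replicate grid")

    if design is None:
        initial = {
            sp: float(values[0, s_ix[sp], :].mean()) for sp in species
            if sp in CascadeModel("cascade").species_names
        }
        design = ExperimentDesign(
            initial_concentrations=initial,
            enzyme_loadings={},
            t_end=float(unique_times[-1]) if unique_times[-1] > 0 else 1.0,
            sample_times=tuple(unique_times),
            replicates=n_reps,
            observed_species=species,
            name=Path(path).stem,
        )
    return TimeSeriesDataset(
        design=design,
        variant=variant,
        times=unique_times,
        species=species,
        values=values,
    )


# -- config ---------------------------------------------------------------


def design_to_dict(design: ExperimentDesign) -> dict:
    return {
        "name": design.name,
        "initial_concentrations": {k: float(v) for k, v in
                                   design.initial_concentrations.items()},
        "enzyme_loadings": {k: float(v) for k, v in
                            design.enzyme_loadings.items()},
        "t_end": float(design.t_end),
        "sample_times": [float(t) for t in design.sample_times],
        "metadata": dict(design.metadata),
        "replicates": int(design.replicates),
        "observed_species": (
            list(design.observed_species) if design.observed_species else None
        ),
    }


def design_from_dict(data: Mapping) -> ExperimentDesign:
    try:
        kwargs = dict(
            initial_concentrations=dict(data["initial_concentrations"]),
            enzyme_loadings=dict(data.get("enzyme_loadings", {})),
            t_end=float(data.get("t_end", 240.0)),
            sample_times=data.get("sample_times"),
            replicates=int(data.get("replicates", 1)),
            observed_species=(
                tuple(data["observed_species"])
                if data.get("observed_species")
                else None
            ),
            name=str(data.get("name", "")),
        )
        if data.get("metadata"):
            kwargs["metadata"] = dict(data["metadata"])
        return ExperimentDesign(**kwargs)
    except KeyError as exc:
        raise ParseError(f"design config missing key {exc}") from exc


def load_config(path) -> dict:
    with open(path, "r", encoding="utf-8") as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict):
        raise ParseError(f"{path}: config must be a mapping")
    return data


def save_config(data: Mapping, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(dict(data), fh, sort_keys=False)


def model_from_config(config: Mapping) -> CascadeModel:
    """Build a model from a config mapping with keys ``variant``,
    ``ppa_mode`` and ``parameters`` (k1..k7, Keq1..Keq3, *_opt)."""
    params = RateParameters().replace(**dict(config.get("parameters", {})))
    return CascadeModel(
        variant=config.get("variant", "cascade"),
        parameters=params,
        ppa_mode=config.get("ppa_mode", "fast_kinetic"),
        disabled_reactions=tuple(config.get("disabled_reactions", ())),
    )


def design_from_config(config: Mapping) -> ExperimentDesign:
    if "design" in config:
        config = config["design"]
    return design_from_dict(config)


# -- manifests ------------------------------------------------------------


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclass
class RunManifest:
    """Provenance record written once per CLI run."""

    command: str
    config_paths: list = field(default_factory=list)
    seed: int | None = None
    package_version: str = ""
    started: str = ""
    finished: str = ""
    outputs: dict = field(default_factory=dict)
    status: str = "running"
    failed_stage: str | None = None

    @classmethod
    def start(cls, command: str, config_paths=(), seed=None) -> "RunManifest":
        from . import __version__

        return cls(
            command=command,
            config_paths=[str(p) for p in config_paths],
            seed=seed,
            package_version=__version__,
            started=datetime.now(timezone.utc).isoformat(),
        )

    def add_output(self, path) -> None:
        p = Path(path)
        self.outputs[str(p)] = _sha256(p)

    def finish(self, status: str = "ok", failed_stage: str | None = None) -> None:
        self.finished = datetime.now(timezone.utc).isoformat()
        self.status = status
        self.failed_stage = failed_stage

    def verify_outputs(self) -> bool:
        return all(
            Path(p).exists() and _sha256(Path(p)) == digest
            for p, digest in self.outputs.items()
        )

    def write(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2)
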