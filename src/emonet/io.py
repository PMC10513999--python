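"""Reading and writing networks, schedules, configs, trajectories and data.

Formats are deliberately plain text:

* network JSON — ``{"labels": [...], "weights": [[...]], "thresholds": [...],
  "coding": "spin"|"binary"}`` (floats round-trip losslessly via repr);
* network CSV pair — edge list (``from,to,weight``) + node list
  (``label,threshold``);
* trajectory CSV — long format with columns ``run, sweep, field, intensity``
  plus optional per-component state columns, with schedule/config in a JSON
  sidecar;
* data CSV — header of component labels, one 0/1 (or ordinal) row per
  observation.

Every loader enforces the type invariants and raises
:class:`ValidationError` messages that name the violated invariant.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .dynamics import EventSchedule, SimulationConfig, TrajectoryEnsemble
from .network import ComponentNetwork, NetworkValidationError
from .synthesis import BinaryDataMatrix

__all__ = [
    "ValidationError",
    "network_to_json",
    "network_from_json",
    "write_network_json",
    "read_network_json",
    "write_network_csv",
    "read_network_csv",
    "write_schedule_json",
    "read_schedule_json",
    "write_config_json",
    "read_config_json",
    "write_trajectories_csv",
    "read_trajectories_csv",
    "write_data_csv",
    "read_data_csv",
    "validate_and_load",
]


class ValidationError(ValueError):
    """A file failed schema or invariant validation; the message names why."""


def _require(d: dict, key: str, where: str):
    if key not in d:
        raise ValidationError(f"missing field {key!r} in {where}")
    return d[key]


def network_to_json(net: ComponentNetwork) -> dict:
    return {
        "labels": list(net.labels),
        "weights": [[float(v) for v in row] for row in net.weights],
        "thresholds": [float(v) for v in net.thresholds],
        "coding": net.coding,
    }


def network_from_json(obj: dict, where: str = "network JSON") -> ComponentNetwork:
    labels = _require(obj, "labels", where)
    weights = _require(obj, "weights", where)
    thresholds = _require(obj, "thresholds", where)
    coding = obj.get("coding", "spin")
    try:
        return ComponentNetwork(tuple(labels), np.array(weights, dtype=float),
                                np.array(thresholds, dtype=float), coding=coding)
    except NetworkValidationError as err:
        raise ValidationError(f"{where}: {err}") from err
    except (TypeError, ValueError) as err:
        raise ValidationError(f"{where}: malformed numeric content ({err})") from err


def write_network_json(net: ComponentNetwork, path) -> None:
    Path(path).write_text(json.dumps(network_to_json(net), indent=2) + "\n")


def read_network_json(path) -> ComponentNetwork:
    try:
        obj = json.loads(Path(path).read_text())
    except json.JSONDecodeError as err:
        raise ValidationError(f"{path}: not valid JSON ({err})") from err
    return network_from_json(obj, where=str(path))


def write_network_csv(net: ComponentNetwork, edges_path, nodes_path) -> None:
    """Write the edge-list / node-list CSV pair (zero edges omitted)."""
    iu = np.triu_indices(net.n, k=1)
    rows = [
        {"from": net.labels[i], "to": net.labels[j], "weight": float(net.weights[i, j])}
        for i, j in zip(*iu)
        if net.weights[i, j] != 0.0
    ]
    fmt = lambda v: repr(float(v))  # full precision, lossless on re-read
    pd.DataFrame(rows, columns=["from", "to", "weight"]).to_csv(
        edges_path, index=False, float_format=fmt
    )
    pd.DataFrame(
        {"label": list(net.labels), "threshold": [float(v) for v in net.thresholds]}
    ).to_csv(nodes_path, index=False, float_format=fmt)


def read_network_csv(edges_path, nodes_path, coding: str = "spin") -> ComponentNetwork:
    nodes = pd.read_csv(nodes_path, float_precision="round_trip")
    for col in ("label", "threshold"):
        if col not in nodes.columns:
            raise ValidationError(f"{nodes_path}: missing column {col!r}")
    labels = [str(x) for x in nodes["label"]]
    index = {lab: i for i, lab in enumerate(labels)}
    n = len(labels)
    w = np.zeros((n, n))
    edges = pd.read_csv(edges_path, float_precision="round_trip")
    for col in ("from", "to", "weight"):
        if col not in edges.columns:
            raise ValidationError(f"{edges_path}: missing column {col!r}")
    for _, row in edges.iterrows():
        a, b = str(row["from"]), str(row["to"])
        if a not in index or b not in index:
            raise ValidationError(f"{edges_path}: edge references unknown label {a!r} or {b!r}")
        i, j = index[a], index[b]
        if i == j:
            raise ValidationError(f"{edges_path}: self-loop on {a!r}")
        w[i, j] = w[j, i] = float(row["weight"])
    try:
        return ComponentNetwork(tuple(labels), w, nodes["threshold"].to_numpy(float),
                                coding=coding)
    except NetworkValidationError as err:
        raise ValidationError(f"{edges_path}/{nodes_path}: {err}") from err


def write_schedule_json(schedule: EventSchedule, path) -> None:
    Path(path).write_text(json.dumps(dataclasses.asdict(schedule), indent=2) + "\n")


def read_schedule_json(path) -> EventSchedule:
    obj = json.loads(Path(path).read_text())
    known = {f.name for f in dataclasses.fields(EventSchedule)}
    unknown = set(obj) - known
    if unknown:
        raise ValidationError(f"{path}: unknown schedule fields {sorted(unknown)}")
    try:
        return EventSchedule(**obj)
    except (TypeError, ValueError) as err:
        raise ValidationError(f"{path}: {err}") from err


def write_config_json(config: SimulationConfig, path) -> None:
    Path(path).write_text(json.dumps(dataclasses.asdict(config), indent=2) + "\n")


def read_config_json(path) -> SimulationConfig:
    obj = json.loads(Path(path).read_text())
    known = {f.name for f in dataclasses.fields(SimulationConfig)}
    unknown = set(obj) - known
    if unknown:
        raise ValidationError(f"{path}: unknown config fields {sorted(unknown)}")
    try:
        return SimulationConfig(**obj)
    except (TypeError, ValueError) as err:
        raise ValidationError(f"{path}: {err}") from err


def write_trajectories_csv(
    ens: TrajectoryEnsemble, path, include_states: bool = False
) -> None:
    """Long-format trajectory CSV + a ``<path>.meta.json`` sidecar.

    The sidecar stores the schedule and config so an ensemble reloaded from
    disk carries its full provenance.
    """
    runs, sweeps = ens.intensity.shape
    run_idx = np.repeat(np.arange(runs), sweeps)
    sweep_idx = np.tile(np.arange(sweeps), runs)
    frame = pd.DataFrame(
        {
            "run": run_idx,
            "sweep": sweep_idx,
            "field": np.tile(ens.field, runs),
            "intensity": ens.intensity.ravel(),
        }
    )
    if include_states and ens.states is not None:
        n = ens.states.shape[2]
        for j in range(n):
            frame[f"s_{j}"] = ens.states[:, :, j].ravel()
    frame.to_csv(path, index=False)
    meta = {
        "schedule": dataclasses.asdict(ens.schedule),
        "config": dataclasses.asdict(ens.config),
    }
    Path(str(path) + ".meta.json").write_text(json.dumps(meta, indent=2) + "\n")


def read_trajectories_csv(path) -> TrajectoryEnsemble:
    """Rebuild a (possibly intensity-only) ensemble from CSV + sidecar.

    If the sidecar is missing, the schedule is inferred from the field
    column (baseline = leading zeros, hold = sweeps at peak, fade = the
    remaining nonzero stretch) and a placeholder config is attached.
    """
    frame = pd.read_csv(path, float_precision="round_trip")
    for col in ("run", "sweep", "field", "intensity"):
        if col not in frame.columns:
            raise ValidationError(f"{path}: missing column {col!r}")
    runs = int(frame["run"].max()) + 1
    sweeps = int(frame["sweep"].max()) + 1
    if len(frame) != runs * sweeps:
        raise ValidationError(f"{path}: incomplete run x sweep grid")
    frame = frame.sort_values(["run", "sweep"])
    intensity = frame["intensity"].to_numpy(float).reshape(runs, sweeps)
    field = frame["field"].to_numpy(float)[:sweeps]
    meta_path = Path(str(path) + ".meta.json")
    if meta_path.exists():
        meta = json.loads(meta_path.read_text())
        schedule = EventSchedule(**meta["schedule"])
        config = SimulationConfig(**meta["config"])
    else:
        schedule = _infer_schedule(field)
        config = SimulationConfig(runs=runs)
    state_cols = sorted(
        (c for c in frame.columns if c.startswith("s_")), key=lambda c: int(c[2:])
    )
    states = None
    if state_cols:
        states = (
            frame[state_cols].to_numpy(np.int8).reshape(runs, sweeps, len(state_cols))
        )
    return TrajectoryEnsemble(
        intensity=intensity, field=field, schedule=schedule, config=config, states=states
    )


def _infer_schedule(field: np.ndarray) -> EventSchedule:
    nz = np.nonzero(field)[0]
    if nz.size == 0:
        return EventSchedule(
            baseline_sweeps=len(field), amplitude=0.0, hold_sweeps=0,
            fade_sweeps=0, post_sweeps=0,
        )
    baseline = int(nz[0])
    amplitude = float(field.max())
    hold = int(np.sum(field == amplitude))
    fade = int(nz[-1] + 1 - baseline - hold)
    post = int(len(field) - nz[-1] - 1)
    return EventSchedule(
        baseline_sweeps=baseline, amplitude=amplitude, hold_sweeps=hold,
        fade_sweeps=max(fade, 0), post_sweeps=post,
    )


def write_data_csv(data: BinaryDataMatrix, path) -> None:
    data.to_frame().to_csv(path, index=False)


def read_data_csv(path) -> BinaryDataMatrix:
    frame = pd.read_csv(path)
    if frame.shape[1] < 1 or frame.shape[0] < 1:
        raise ValidationError(f"{path}: empty data matrix")
    values = frame.to_numpy()
    if not np.isfinite(values.astype(float)).all():
        raise ValidationError(f"{path}: data contain non-finite entries")
    if not np.isin(values, (0, 1)).all():
        raise ValidationError(f"{path}: data entries must be 0/1 (binarize first)")
    return BinaryDataMatrix(values.astype(np.int8), frame.columns)


_LOADERS = {
    "network": read_network_json,
    "schedule": read_schedule_json,
    "config": read_config_json,
    "trajectories": read_trajectories_csv,
    "data": read_data_csv,
}


def validate_and_load(path, format: str):
    """Parse and validate a file of the given format into its typed object."""
    if format not in _LOADERS:
        raise ValidationError(
            f"unknown format {format!r}; expected one of {sorted(_LOADERS)}"
        )
    p = Path(path)
    if not p.exists():
        raise ValidationError(f"{path}: file does not exist")
    return _LOADERS[format](p)
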