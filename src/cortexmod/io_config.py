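"""Configuration loading, seed management, result writers and run provenance."""

from __future__ import annotations

import dataclasses
import datetime
import hashlib
import json
import zlib
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__ as _version
from .rate_network import RateModelParams, ParameterError
from .spiking_network import SimulationProtocol, SpikeTrainSet, SpikingModelParams

__all__ = [
    "ConfigError",
    "RunManifest",
    "derive_seed",
    "load_config",
    "write_activity_curve",
    "read_activity_curve",
    "write_raster",
    "read_raster",
    "write_summary",
    "read_summary",
    "write_manifest",
]

_SCHEMA_VERSION = 1


class ConfigError(ValueError):
    """A configuration file failed validation."""


def derive_seed(root_seed: int, stage: str, *indices: int) -> int:
    """Deterministic per-stage seed below 2**31.

    Seeds are derived from (root seed, stage name, grid/seed indices) so
    sweep points are independent, reproducible and parallelizable.
    """
    entropy = [int(root_seed) & 0x7FFFFFFF, zlib.crc32(stage.encode())]
    entropy.extend(int(i) & 0x7FFFFFFF for i in indices)
    return int(np.random.SeedSequence(entropy).generate_state(1)[0] % (2**31))


_PROTOCOL_FIELDS = {f.name for f in dataclasses.fields(SimulationProtocol)}
_RATE_FIELDS = {f.name for f in dataclasses.fields(RateModelParams)}
_SPIKING_FIELDS = {f.name for f in dataclasses.fields(SpikingModelParams)}


def load_config(path, kind: str = "rate"):
    """Load and validate a flat YAML configuration.

    Keys mirror the parameter dataclass field names; omitted fields take the
    standard defaults.  For ``kind='spiking'`` protocol keys (drive/relax/
    measure durations and Poisson settings) may appear in the same mapping
    and a ``(SpikingModelParams, SimulationProtocol)`` pair is returned; for
    ``kind='rate'`` a :class:`RateModelParams` is returned.

    Unknown keys and invariant violations raise :class:`ConfigError` naming
    the offending field.
    """
    path = Path(path)
    try:
        raw = yaml.safe_load(path.read_text())
    except yaml.YAMLError as err:
        raise ConfigError(f"{path}: not valid YAML: {err}") from err
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: expected a flat key-value mapping")
    if kind == "rate":
        unknown = set(raw) - _RATE_FIELDS
        if unknown:
            raise ConfigError(f"{path}: unknown keys {sorted(unknown)}")
        try:
            return RateModelParams(**raw)
        except ParameterError as err:
            raise ConfigError(f"{path}: {err}") from err
    if kind == "spiking":
        unknown = set(raw) - _SPIKING_FIELDS - _PROTOCOL_FIELDS
        if unknown:
            raise ConfigError(f"{path}: unknown keys {sorted(unknown)}")
        p_kwargs = {k: v for k, v in raw.items() if k in _SPIKING_FIELDS}
        proto_kwargs = {k: v for k, v in raw.items() if k in _PROTOCOL_FIELDS}
        try:
            return (
                SpikingModelParams(**p_kwargs),
                SimulationProtocol(**proto_kwargs),
            )
        except ParameterError as err:
            raise ConfigError(f"{path}: {err}") from err
    raise ConfigError(f"unknown config kind {kind!r}")


def write_activity_curve(curve, path) -> None:
    """Write an activity curve as CSV
    (``swept_value,module_id,activity,normalized,se``)."""
    from .experiments import ActivityCurve  # local import to avoid cycle

    assert isinstance(curve, ActivityCurve)
    rows = []
    for k, x in enumerate(curve.swept_values):
        for m in range(curve.n_modules):
            rows.append(
                {
                    "swept_value": x,
                    "module_id": m,
                    "activity": curve.activity[k, m],
                    "normalized": curve.normalized[k, m],
                    "se": curve.se[k],
                }
            )
    df = pd.DataFrame(rows)
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(f"# cortexmod activity curve v{_SCHEMA_VERSION} "
                 f"model={curve.model} swept={curve.swept_variable}\n")
        df.to_csv(fh, index=False)


def read_activity_curve(path):
    """Read back a curve written by :func:`write_activity_curve`."""
    from .experiments import ActivityCurve

    path = Path(path)
    with open(path) as fh:
        header = fh.readline()
        df = pd.read_csv(fh)
    model, swept = "", ""
    for token in header.strip().split():
        if token.startswith("model="):
            model = token[6:]
        elif token.startswith("swept="):
            swept = token[6:]
    swept_values = df["swept_value"].unique()
    n_mod = df["module_id"].nunique()
    activity = df.pivot(
        index="swept_value", columns="module_id", values="activity"
    ).loc[swept_values].to_numpy()
    normalized = df.pivot(
        index="swept_value", columns="module_id", values="normalized"
    ).loc[swept_values].to_numpy()
    se = df.groupby("swept_value", sort=False)["se"].first().loc[swept_values]
    return ActivityCurve(
        swept_values=np.asarray(swept_values, dtype=float),
        activity=activity.reshape(-1, n_mod),
        normalized=normalized.reshape(-1, n_mod),
        se=se.to_numpy(),
        swept_variable=swept,
        model=model,
    )


def write_raster(spikes: SpikeTrainSet, module_of, path) -> None:
    """Write spikes as CSV ``neuron_id,module_id,spike_time_ms`` (one row per
    spike; header-only file for a silent run)."""
    module_of = np.asarray(module_of)
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df = pd.DataFrame(
        {
            "neuron_id": spikes.neuron_ids.astype(int),
            "module_id": module_of[spikes.neuron_ids]
            if spikes.n_spikes
            else np.empty(0, int),
            "spike_time_ms": spikes.times,
        }
    )
    df.to_csv(path, index=False)


def read_raster(path, t_window=(0.0, float("inf"))) -> SpikeTrainSet:
    df = pd.read_csv(path)
    return SpikeTrainSet(
        neuron_ids=df["neuron_id"].to_numpy(dtype=np.int64),
        times=df["spike_time_ms"].to_numpy(dtype=float),
        t_window=tuple(t_window),
    )


def write_summary(summary, path) -> None:
    """Write a decrease summary (or any dataclass) as JSON."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    payload = (
        dataclasses.asdict(summary)
        if dataclasses.is_dataclass(summary)
        else dict(summary)
    )
    payload["schema_version"] = _SCHEMA_VERSION
    path.write_text(json.dumps(payload, indent=2, sort_keys=True))


def read_summary(path) -> dict:
    payload = json.loads(Path(path).read_text())
    payload.pop("schema_version", None)
    return payload


@dataclass(frozen=True)
class RunManifest:
    """Provenance record written alongside every result file set.

    Re-running with the recorded parameters and root seed reproduces
    deterministic outputs bit-exactly and stochastic summaries
    statistically.
    """

    run_id: str
    params: dict
    root_seed: int
    derived_seeds: dict
    software_version: str
    created_at: str

    @staticmethod
    def create(params, root_seed: int, derived_seeds: dict | None = None):
        pdict = (
            dataclasses.asdict(params)
            if dataclasses.is_dataclass(params)
            else dict(params)
        )
        digest = hashlib.sha1(
            json.dumps(
                {"params": pdict, "seed": root_seed}, sort_keys=True, default=str
            ).encode()
        ).hexdigest()[:12]
        return RunManifest(
            run_id=digest,
            params=pdict,
            root_seed=int(root_seed),
            derived_seeds=dict(derived_seeds or {}),
            software_version=_version,
            created_at=datetime.datetime.now(datetime.timezone.utc).isoformat(),
        )


def write_manifest(manifest: RunManifest, path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(
        json.dumps(dataclasses.asdict(manifest), indent=2, sort_keys=True, default=str)
    )
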