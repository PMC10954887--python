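"""On-disk formats: tidy CSV tables, JSON manifests, structured run logs.

Rasters are CSV with header ``neuron_id,population,time_ms``; voltage
traces and phase series are CSV with a ``time_ms`` column plus one column
per interneuron; every run directory carries a JSON manifest with the
full config, seeds and a config hash so it can be regenerated exactly.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .config import NetworkConfig
from .network import SpikeRaster, VoltageTraces
from .phase import PhaseSeries

__all__ = [
    "write_raster_csv",
    "read_raster_csv",
    "write_traces_csv",
    "write_phases_csv",
    "write_manifest",
    "setup_logging",
]


def setup_logging(level: int = logging.INFO) -> None:
    logging.basicConfig(
        level=level, format="%(asctime)s %(name)s %(levelname)s %(message)s"
    )


def write_raster_csv(raster: SpikeRaster, path: str | Path) -> None:
    pd.DataFrame(
        {
            "neuron_id": raster.neuron_id,
            "population": raster.population,
            "time_ms": raster.time_ms,
        }
    ).to_csv(path, index=False)


def read_raster_csv(path: str | Path, duration: float | None = None) -> SpikeRaster:
    df = pd.read_csv(path)
    return SpikeRaster(
        neuron_id=df["neuron_id"].to_numpy(),
        time_ms=df["time_ms"].to_numpy(float),
        population=df["population"].to_numpy(object),
        duration=float(duration if duration is not None else df["time_ms"].max()),
    )


def write_traces_csv(traces: VoltageTraces, path: str | Path) -> None:
    df = pd.DataFrame(traces.v, columns=[f"n{int(i)}" for i in traces.neuron_ids])
    df.insert(0, "time_ms", traces.time_ms)
    df.to_csv(path, index=False, float_format="%.4f")


def write_phases_csv(phases: PhaseSeries, path: str | Path) -> None:
    """Phase CSV plus a JSON sidecar with the filter provenance."""
    df = pd.DataFrame(
        phases.phases, columns=[f"n{int(i)}" for i in phases.neuron_ids]
    )
    df.insert(0, "time_ms", phases.time_ms)
    df.insert(1, "valid", phases.valid.astype(int))
    df.to_csv(path, index=False, float_format="%.6f")
    sidecar = Path(path).with_suffix(".filter.json")
    spec = phases.filter_spec
    sidecar.write_text(
        json.dumps(
            {
                "order": spec.order,
                "cutoff_hz": spec.cutoff_hz,
                "sampling_rate_hz": spec.sampling_rate_hz,
                "zero_phase": spec.zero_phase,
            },
            indent=2,
        )
        + "\n"
    )


def write_manifest(
    config: NetworkConfig, path: str | Path, extra: dict | None = None
) -> dict:
    manifest = {
        "config": config.to_dict(),
        "config_hash": config.config_hash(),
        **(extra or {}),
    }
    Path(path).write_text(json.dumps(manifest, indent=2, default=_jsonable) + "\n")
    return manifest


def _jsonable(x):
    if isinstance(x, (np.integer,)):
        return int(x)
    if isinstance(x, (np.floating,)):
        return float(x)
    if isinstance(x, np.ndarray):
        return x.tolist()
    raise TypeError(f"not JSON serializable: {type(x)}")
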