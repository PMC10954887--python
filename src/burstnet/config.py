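"""Declarative network configuration.

A :class:`NetworkConfig` fully determines one simulation: populations
(sizes, Izhikevich parameters, external drive), probabilistic synapse
groups, the integration settings, and the two seeds (topology wiring and
initial-condition jitter) that make a run exactly reproducible.
Configs round-trip through JSON and can be loaded from TOML.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal

__all__ = [
    "NeuronModelParams",
    "PopulationSpec",
    "SynapseSpec",
    "NetworkConfig",
    "ConfigurationError",
    "PYRAMIDAL_PARAMS",
    "FAST_SPIKING_PARAMS",
    "default_network_config",
]

SPIKE_THRESHOLD_MV = 30.0


class ConfigurationError(ValueError):
    """Raised when a configuration field is out of its valid range."""


def _finite(x: float) -> bool:
    try:
        return abs(float(x)) < float("inf")
    except (TypeError, ValueError):
        return False


@dataclass(frozen=True)
class NeuronModelParams:
    """Izhikevich single-neuron parameters (a, b, c, d).

    ``a`` sets the recovery-variable time scale, ``b`` its coupling to the
    membrane potential, ``c`` the post-spike reset potential (mV) and ``d``
    the post-spike recovery increment.
    """

    a: float
    b: float
    c: float
    d: float

    def __post_init__(self) -> None:
        for name in ("a", "b", "c", "d"):
            val = getattr(self, name)
            if not _finite(val):
                raise ConfigurationError(f"NeuronModelParams.{name} must be finite, got {val!r}")
        if self.c >= SPIKE_THRESHOLD_MV:
            raise ConfigurationError(
                f"reset potential c={self.c} must lie below the spike threshold "
                f"{SPIKE_THRESHOLD_MV} mV"
            )


#: Regular-spiking pyramidal cell (slow excitatory driver).
PYRAMIDAL_PARAMS = NeuronModelParams(a=0.02, b=0.2, c=-65.0, d=8.0)
#: Fast-spiking inhibitory interneuron.
FAST_SPIKING_PARAMS = NeuronModelParams(a=0.1, b=0.2, c=-65.0, d=2.0)

PopulationLabel = Literal["pyramidal", "fast_spiking"]


@dataclass(frozen=True)
class PopulationSpec:
    label: str
    size: int
    params: NeuronModelParams
    i_ext: float = 0.0

    def __post_init__(self) -> None:
        if self.label not in ("pyramidal", "fast_spiking"):
            raise ConfigurationError(f"unknown population label {self.label!r}")
        if self.size < 1:
            raise ConfigurationError(f"population {self.label}: size must be >= 1")
        if self.label == "fast_spiking" and self.i_ext != 0.0:
            raise ConfigurationError("fast_spiking population must have i_ext = 0")


@dataclass(frozen=True)
class SynapseSpec:
    """One probabilistic synapse group (e.g. E->I with p=0.7, w=+0.3)."""

    source: str
    target: str
    connection_probability: float
    weight: float
    coupling_mode: str = "voltage_kick"

    def __post_init__(self) -> None:
        p = self.connection_probability
        if not (0.0 <= p <= 1.0):
            raise ConfigurationError(
                f"synapse {self.source}->{self.target}: connection_probability={p} "
                "outside [0, 1]"
            )
        if self.coupling_mode not in ("voltage_kick", "current_pulse"):
            raise ConfigurationError(f"unknown coupling_mode {self.coupling_mode!r}")
        if self.source == "pyramidal" and self.weight < 0:
            raise ConfigurationError("excitatory (pyramidal-source) weight must be > 0")
        if self.source == "fast_spiking" and self.weight > 0:
            raise ConfigurationError("inhibitory (fast_spiking-source) weight must be < 0")


@dataclass(frozen=True)
class NetworkConfig:
    populations: tuple[PopulationSpec, ...]
    synapses: tuple[SynapseSpec, ...]
    dt: float = 0.1  # ms
    duration: float = 10_000.0  # ms
    seed_topology: int = 0
    seed_init: int = 0
    init_jitter_mv: float = 2.0  # uniform (0, jitter) added to v0 = c
    record_decimation: int = 1  # keep every k-th voltage sample

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ConfigurationError(f"dt must be > 0, got {self.dt}")
        if self.duration < self.dt:
            raise ConfigurationError("duration must be >= dt")
        if self.init_jitter_mv < 0:
            raise ConfigurationError("init_jitter_mv must be >= 0")
        if self.record_decimation < 1:
            raise ConfigurationError("record_decimation must be >= 1")
        labels = [p.label for p in self.populations]
        if len(set(labels)) != len(labels):
            raise ConfigurationError("duplicate population labels")
        for s in self.synapses:
            if s.source not in labels or s.target not in labels:
                raise ConfigurationError(
                    f"synapse {s.source}->{s.target} references unknown population"
                )

    # -- convenience accessors -------------------------------------------------

    def population(self, label: str) -> PopulationSpec:
        for p in self.populations:
            if p.label == label:
                return p
        raise KeyError(label)

    @property
    def n_total(self) -> int:
        return sum(p.size for p in self.populations)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(self.to_dict(), indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text

    def config_hash(self) -> str:
        """Stable short hash identifying this exact configuration."""
        canon = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(canon.encode()).hexdigest()[:12]

    @classmethod
    def from_dict(cls, d: dict) -> "NetworkConfig":
        pops = tuple(
            PopulationSpec(
                label=p["label"],
                size=int(p["size"]),
                params=NeuronModelParams(**p["params"]),
                i_ext=float(p.get("i_ext", 0.0)),
            )
            for p in d["populations"]
        )
        syns = tuple(
            SynapseSpec(
                source=s["source"],
                target=s["target"],
                connection_probability=float(s["connection_probability"]),
                weight=float(s["weight"]),
                coupling_mode=s.get("coupling_mode", "voltage_kick"),
            )
            for s in d["synapses"]
        )
        kwargs = {
            k: d[k]
            for k in (
                "dt",
                "duration",
                "seed_topology",
                "seed_init",
                "init_jitter_mv",
                "record_decimation",
            )
            if k in d
        }
        return cls(populations=pops, synapses=syns, **kwargs)

    @classmethod
    def from_file(cls, path: str | Path) -> "NetworkConfig":
        path = Path(path)
        if path.suffix == ".toml":
            import tomllib

            d = tomllib.loads(path.read_text())
        else:
            d = json.loads(path.read_text())
        # allow a top-level [network] table in experiment config files
        if "network" in d and "populations" not in d:
            d = d["network"]
        return cls.from_dict(d)


def default_network_config(
    i_ext: float = 5.0,
    p_ei: float = 0.7,
    p_ii: float = 0.4,
    w_exc: float = 0.3,
    w_inh: float = -0.3,
    n_pyramidal: int = 100,
    n_fast_spiking: int = 50,
    duration: float = 10_000.0,
    dt: float = 0.1,
    seed_topology: int = 0,
    seed_init: int = 0,
    **kwargs,
) -> NetworkConfig:
    """Representative two-population network: 100 pyramidal cells driving 50
    fast-spiking interneurons (E->I) with recurrent inhibition (I->I)."""
    return NetworkConfig(
        populations=(
            PopulationSpec("pyramidal", n_pyramidal, PYRAMIDAL_PARAMS, i_ext=i_ext),
            PopulationSpec("fast_spiking", n_fast_spiking, FAST_SPIKING_PARAMS, i_ext=0.0),
        ),
        synapses=(
            SynapseSpec("pyramidal", "fast_spiking", p_ei, w_exc),
            SynapseSpec("fast_spiking", "fast_spiking", p_ii, w_inh),
        ),
        duration=duration,
        dt=dt,
        seed_topology=seed_topology,
        seed_init=seed_init,
        **kwargs,
    )
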