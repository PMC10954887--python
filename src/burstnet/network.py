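"""Two-population pulse-coupled Izhikevich network: wiring, integration,
and population firing statistics.

The membrane model is the standard two-variable quadratic
integrate-and-reset form

    dv/dt = 0.04 v^2 + 5 v + 140 - u + I_ext + I_syn
    du/dt = a (b v - u),        if v >= 30 mV: v <- c, u <- u + d

integrated with forward Euler at a fixed step (0.1 ms by default).
Synapses are instantaneous pulses: each presynaptic spike adds its signed
weight (+0.3 excitatory / -0.3 inhibitory by default) to the postsynaptic
membrane potential at the next step.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import sparse

from . import _core
from .config import ConfigurationError, NetworkConfig, NeuronModelParams

__all__ = [
    "Adjacency",
    "SimState",
    "SpikeRaster",
    "VoltageTraces",
    "IntegrationError",
    "UndefinedFrequencyError",
    "build_network",
    "euler_step",
    "deliver_spikes",
    "simulate",
    "population_frequency",
    "fi_curve",
]

logger = logging.getLogger("burstnet")

SPIKE_THRESHOLD_MV = _core.V_THRESH


class IntegrationError(RuntimeError):
    pass


class UndefinedFrequencyError(ValueError):
    """Not enough spikes to define a population frequency."""


@dataclass
class Adjacency:
    """Realized directed edge sets, concatenated over all populations.

    Neurons are indexed globally in config population order. ``matrix`` is
    a CSR matrix with matrix[i, j] = summed weight of edges i -> j.
    """

    matrix: sparse.csr_matrix
    offsets: dict[str, int]  # population label -> first global index
    sizes: dict[str, int]
    edge_counts: dict[tuple[str, str], int]

    def global_indices(self, label: str) -> np.ndarray:
        o = self.offsets[label]
        return np.arange(o, o + self.sizes[label])


@dataclass
class SimState:
    v: np.ndarray
    u: np.ndarray
    t: float


@dataclass
class SpikeRaster:
    neuron_id: np.ndarray  # global ids, int
    time_ms: np.ndarray  # non-decreasing
    population: np.ndarray  # label per spike (object/str array)
    duration: float

    def for_population(self, label: str) -> "SpikeRaster":
        m = self.population == label
        return SpikeRaster(self.neuron_id[m], self.time_ms[m], self.population[m], self.duration)

    def spike_times_of(self, neuron: int) -> np.ndarray:
        return self.time_ms[self.neuron_id == neuron]

    def __len__(self) -> int:
        return self.neuron_id.size


@dataclass
class VoltageTraces:
    time_ms: np.ndarray  # (T,)
    v: np.ndarray  # (T, n_channels)
    neuron_ids: np.ndarray  # global ids of recorded neurons
    dt_ms: float  # sampling interval of the recording

    @property
    def sampling_rate_hz(self) -> float:
        return 1000.0 / self.dt_ms


def build_network(config: NetworkConfig) -> Adjacency:
    """Realize the probabilistic wiring of ``config``.

    Each ordered (source, target) pair across a synapse group is an edge
    independently with the group's probability; self-edges are excluded.
    Deterministic given ``config.seed_topology``.
    """
    rng = np.random.default_rng(config.seed_topology)
    offsets: dict[str, int] = {}
    sizes: dict[str, int] = {}
    off = 0
    for p in config.populations:
        offsets[p.label] = off
        sizes[p.label] = p.size
        off += p.size
    n = off

    rows: list[np.ndarray] = []
    cols: list[np.ndarray] = []
    vals: list[np.ndarray] = []
    edge_counts: dict[tuple[str, str], int] = {}
    for syn in config.synapses:
        ns, nt = sizes[syn.source], sizes[syn.target]
        mask = rng.random((ns, nt)) < syn.connection_probability
        if syn.source == syn.target:
            np.fill_diagonal(mask, False)
        r, c = np.nonzero(mask)
        rows.append(r + offsets[syn.source])
        cols.append(c + offsets[syn.target])
        vals.append(np.full(r.size, syn.weight))
        edge_counts[(syn.source, syn.target)] = int(r.size)

    if rows:
        mat = sparse.csr_matrix(
            (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
            shape=(n, n),
        )
    else:
        mat = sparse.csr_matrix((n, n))
    return Adjacency(matrix=mat, offsets=offsets, sizes=sizes, edge_counts=edge_counts)


def euler_step(
    v: np.ndarray,
    u: np.ndarray,
    params: NeuronModelParams | tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray],
    i_input: np.ndarray | float,
    dt: float,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """One forward-Euler step; returns (v', u', spiked mask) after reset.

    Reference (pure numpy) implementation of the kernel's update rule for a
    synapse-free input current; used directly for isolated neurons and as
    the oracle the compiled kernel is checked against.
    """
    if isinstance(params, NeuronModelParams):
        a, b, c, d = params.a, params.b, params.c, params.d
    else:
        a, b, c, d = params
    v = np.asarray(v, dtype=float)
    u = np.asarray(u, dtype=float)
    dv = 0.04 * v * v + 5.0 * v + 140.0 - u + i_input
    du = a * (b * v - u)
    v_new = v + dt * dv
    u_new = u + dt * du
    if not (np.all(np.isfinite(v_new)) and np.all(np.isfinite(u_new))):
        bad = int(np.flatnonzero(~np.isfinite(np.atleast_1d(v_new + u_new)))[0])
        raise IntegrationError(f"non-finite state at neuron {bad}")
    spiked = v_new >= SPIKE_THRESHOLD_MV
    v_new = np.where(spiked, c, v_new)
    u_new = np.where(spiked, u_new + d, u_new)
    return v_new, u_new, spiked


def deliver_spikes(
    spiked: np.ndarray, adjacency: Adjacency, mode: str = "voltage_kick", dt: float = 0.1
) -> np.ndarray:
    """Per-neuron synaptic drive at the next step from spikes at this one.

    voltage_kick: the returned vector is a membrane-potential increment
    (sum of presynaptic weights). current_pulse: the same quantity divided
    by dt, i.e. a one-step current whose time integral equals the weight.
    """
    spiked = np.asarray(spiked, dtype=float)
    kick = spiked @ adjacency.matrix  # sum_i w_ij over spiking i
    kick = np.asarray(kick).ravel()
    if mode == "current_pulse":
        return kick / dt
    if mode != "voltage_kick":
        raise ConfigurationError(f"unknown coupling_mode {mode!r}")
    return kick


def _initial_state(config: NetworkConfig) -> tuple[np.ndarray, np.ndarray]:
    rng = np.random.default_rng(config.seed_init)
    v0 = np.empty(config.n_total)
    b = np.empty(config.n_total)
    off = 0
    for p in config.populations:
        v0[off : off + p.size] = p.params.c + config.init_jitter_mv * rng.random(p.size)
        b[off : off + p.size] = p.params.b
        off += p.size
    return v0, b * v0


def _param_arrays(config: NetworkConfig) -> tuple[np.ndarray, ...]:
    n = config.n_total
    a = np.empty(n)
    b = np.empty(n)
    c = np.empty(n)
    d = np.empty(n)
    i_ext = np.empty(n)
    off = 0
    for p in config.populations:
        sl = slice(off, off + p.size)
        a[sl], b[sl], c[sl], d[sl] = p.params.a, p.params.b, p.params.c, p.params.d
        i_ext[sl] = p.i_ext
        off += p.size
    return a, b, c, d, i_ext


def simulate(
    config: NetworkConfig,
    adjacency: Adjacency | None = None,
    perturbation: tuple[float, np.ndarray, float] | None = None,
    record_population: str = "fast_spiking",
) -> tuple[SpikeRaster, VoltageTraces]:
    """Integrate ``config`` for its full duration.

    Deterministic given (seed_topology, seed_init). ``perturbation`` is an
    optional one-off exogenous spike volley ``(t_ms, global_targets,
    weight)``: each target's membrane potential is incremented by
    ``weight`` at the step containing ``t_ms``.

    Voltage recording is peak-preserving: each stored sample is the
    maximum of the threshold-clipped membrane potential (min(v, 30 mV))
    over its decimation window, so spikes appear in the traces as +30 mV
    deflections and survive decimation. No recorded sample exceeds 30 mV.
    """
    if adjacency is None:
        adjacency = build_network(config)
    a, b, c, d, i_ext = _param_arrays(config)
    v0, u0 = _initial_state(config)
    n_steps = int(round(config.duration / config.dt))
    stride = config.record_decimation

    labels = [p.label for p in config.populations]
    rec_ids = (
        adjacency.global_indices(record_population)
        if record_population in labels
        else np.arange(config.n_total)
    )
    n_rec_samples = n_steps // stride
    rec_out = np.empty((n_rec_samples, rec_ids.size))

    if perturbation is None:
        pert_step, pert_targets, pert_weight = -1, np.empty(0, dtype=np.int64), 0.0
    else:
        t_ms, targets, pert_weight = perturbation
        pert_step = int(round(t_ms / config.dt))
        pert_targets = np.asarray(targets, dtype=np.int64)
        if pert_step < 0 or pert_step >= n_steps:
            raise ConfigurationError("perturbation time outside the simulation")

    # generous spike buffer: ~1.2 kHz sustained average per neuron
    cap = max(10_000, int(config.n_total * config.duration * 1.2))
    spike_id = np.empty(cap, dtype=np.int64)
    spike_step = np.empty(cap, dtype=np.int64)

    mode = config.synapses[0].coupling_mode if config.synapses else "voltage_kick"
    csr = adjacency.matrix
    status, n_spk, where_step, where_neuron = _core.euler_run(
        v0,
        u0,
        a,
        b,
        c,
        d,
        i_ext,
        csr.indptr.astype(np.int64),
        csr.indices.astype(np.int64),
        csr.data.astype(np.float64),
        config.dt,
        n_steps,
        rec_ids.astype(np.int64),
        stride,
        rec_out,
        pert_step,
        pert_targets,
        float(pert_weight),
        spike_id,
        spike_step,
        mode == "current_pulse",
    )
    if status == _core.STATUS_NONFINITE:
        raise IntegrationError(
            f"non-finite membrane state at t={where_step * config.dt:.1f} ms, "
            f"neuron {where_neuron}"
        )
    if status == _core.STATUS_OVERFLOW:
        raise IntegrationError("spike buffer exhausted (pathological firing rate)")

    pop_of = np.empty(config.n_total, dtype=object)
    off = 0
    for p in config.populations:
        pop_of[off : off + p.size] = p.label
        off += p.size

    sid = spike_id[:n_spk]
    times = (spike_step[:n_spk] + 1) * config.dt
    raster = SpikeRaster(
        neuron_id=sid.copy(),
        time_ms=times,
        population=pop_of[sid],
        duration=config.duration,
    )
    traces = VoltageTraces(
        time_ms=(np.arange(1, n_rec_samples + 1) * stride) * config.dt,
        v=rec_out,
        neuron_ids=rec_ids,
        dt_ms=config.dt * stride,
    )
    logger.info(
        "simulate config=%s seeds=(%d,%d) edges=%s spikes=%d",
        config.config_hash(),
        config.seed_topology,
        config.seed_init,
        adjacency.edge_counts,
        n_spk,
    )
    return raster, traces


def population_frequency(
    raster: SpikeRaster, population: str = "pyramidal", transient_ms: float = 500.0
) -> float:
    """Inverse of the mean interspike interval pooled over the population (Hz).

    The first ``transient_ms`` of spikes is discarded before pooling.
    """
    sub = raster.for_population(population)
    keep = sub.time_ms >= transient_ms
    ids, times = sub.neuron_id[keep], sub.time_ms[keep]
    isis: list[np.ndarray] = []
    for nid in np.unique(ids):
        t = np.sort(times[ids == nid])
        if t.size >= 2:
            isis.append(np.diff(t))
    if not isis:
        raise UndefinedFrequencyError(
            f"population {population!r}: no neuron has >= 2 spikes after {transient_ms} ms"
        )
    return 1000.0 / float(np.mean(np.concatenate(isis)))


def fi_curve(
    params: NeuronModelParams,
    i_values: np.ndarray,
    duration: float = 2000.0,
    dt: float = 0.1,
    transient_ms: float = 500.0,
) -> np.ndarray:
    """Steady-state firing frequency (Hz) of one isolated neuron per input
    current. Subthreshold currents give 0 Hz."""
    i_values = np.atleast_1d(np.asarray(i_values, dtype=float))
    n_steps = int(round(duration / dt))
    # integrate all currents as one bank of independent neurons
    v = np.full(i_values.size, params.c + 1.0)
    u = params.b * v
    spike_times: list[list[float]] = [[] for _ in i_values]
    for step in range(n_steps):
        v, u, spiked = euler_step(v, u, params, i_values, dt)
        if spiked.any():
            t = (step + 1) * dt
            for j in np.flatnonzero(spiked):
                spike_times[j].append(t)
    out = np.empty(i_values.size)
    for k, st in enumerate(spike_times):
        t = np.asarray(st)
        t = t[t >= transient_ms]
        out[k] = 1000.0 / float(np.mean(np.diff(t))) if t.size >= 2 else 0.0
    return out
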