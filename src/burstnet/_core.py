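"""Forward-Euler integration kernel for pulse-coupled Izhikevich networks.

The kernel is deliberately minimal: everything stochastic (wiring, initial
conditions, perturbation targets) is drawn by the caller and passed in as
plain arrays, so a run is a pure function of its inputs.

Spike timing/delivery convention: a spike detected at step k (after the
Euler update, v >= 30 mV) resets the neuron at step k and is delivered to
its targets during step k+1. The per-spike increment w is added to the
postsynaptic membrane potential after that step's Euler derivative update
(voltage_kick), which is numerically the same as injecting a one-step
current of w/dt (current_pulse) under forward Euler -- the unit-area
reading of an instantaneous (Dirac) pulse.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["euler_run", "STATUS_OK", "STATUS_NONFINITE", "STATUS_OVERFLOW"]

STATUS_OK = 0
STATUS_NONFINITE = 1  # non-finite membrane state; offending step/neuron reported
STATUS_OVERFLOW = 2  # spike buffer exhausted

V_THRESH = 30.0


@njit(cache=True)
def euler_run(
    v,
    u,
    a,
    b,
    c,
    d,
    i_ext,
    indptr,
    indices,
    weights,
    dt,
    n_steps,
    rec_ids,
    rec_stride,
    rec_out,
    pert_step,
    pert_targets,
    pert_weight,
    spike_id,
    spike_step,
    current_pulse,
):  # pragma: no cover - exercised via network.simulate
    """Integrate the network in place; returns (status, n_spikes, where).

    ``where`` is (step, neuron) of the first non-finite state when
    status == STATUS_NONFINITE, else (-1, -1).
    """
    n = v.size
    kick = np.zeros(n)
    kick_next = np.zeros(n)
    n_spk = 0
    cap = spike_id.size
    n_rec = rec_ids.size
    rec_acc = np.full(n_rec, -1.0e300)
    spiked_now = np.zeros(n, dtype=np.bool_)

    for k in range(n_steps):
        # exogenous single-spike perturbation, delivered like any other spike
        if k == pert_step:
            for t in range(pert_targets.size):
                kick[pert_targets[t]] += pert_weight

        for j in range(n):
            vo = v[j]
            uo = u[j]
            dv = 0.04 * vo * vo + 5.0 * vo + 140.0 - uo + i_ext[j]
            du = a[j] * (b[j] * vo - uo)
            if current_pulse:
                v[j] = vo + dt * (dv + kick[j] / dt)
            else:
                v[j] = vo + dt * dv + kick[j]
            u[j] = uo + dt * du
            kick_next[j] = 0.0

        for j in range(n):
            if not (np.isfinite(v[j]) and np.isfinite(u[j])):
                return STATUS_NONFINITE, n_spk, k, j
            if v[j] >= V_THRESH:
                if n_spk >= cap:
                    return STATUS_OVERFLOW, n_spk, k, j
                spike_id[n_spk] = j
                spike_step[n_spk] = k
                n_spk += 1
                v[j] = c[j]
                u[j] += d[j]
                for e in range(indptr[j], indptr[j + 1]):
                    kick_next[indices[e]] += weights[e]
                spiked_now[j] = True

        tmp = kick
        kick = kick_next
        kick_next = tmp

        # peak-preserving recording: running max of min(v, 30) over the
        # stride window, so spike deflections survive decimation
        for m in range(n_rec):
            j = rec_ids[m]
            val = V_THRESH if spiked_now[j] else v[j]
            if val > rec_acc[m]:
                rec_acc[m] = val
        for j in range(n):
            spiked_now[j] = False
        if (k + 1) % rec_stride == 0:
            r = k // rec_stride
            if r < rec_out.shape[0]:
                for m in range(n_rec):
                    rec_out[r, m] = rec_acc[m]
                    rec_acc[m] = -1.0e300

    return STATUS_OK, n_spk, -1, -1
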