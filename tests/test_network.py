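"""Simulator unit tests: wiring, integration, reset, firing statistics."""

import numpy as np
import pytest
from scipy import stats

from burstnet import (
    FAST_SPIKING_PARAMS,
    PYRAMIDAL_PARAMS,
    ConfigurationError,
    NeuronModelParams,
    default_network_config,
)
from burstnet.network import (
    UndefinedFrequencyError,
    build_network,
    deliver_spikes,
    euler_step,
    fi_curve,
    population_frequency,
    simulate,
)
from burstnet.network import SpikeRaster


def _raster(ids, times, pop="pyramidal", duration=1000.0):
    ids = np.asarray(ids)
    return SpikeRaster(
        neuron_id=ids,
        time_ms=np.asarray(times, float),
        population=np.full(ids.size, pop, dtype=object),
        duration=duration,
    )


class TestBuildNetwork:
    def test_complete_bipartite_edge_count(self):
        cfg = default_network_config(p_ei=1.0, p_ii=0.0)
        adj = build_network(cfg)
        assert adj.edge_counts[("pyramidal", "fast_spiking")] == 100 * 50
        assert adj.edge_counts[("fast_spiking", "fast_spiking")] == 0

    def test_zero_probability_zero_edges(self):
        cfg = default_network_config(p_ei=0.0, p_ii=0.0)
        adj = build_network(cfg)
        assert adj.matrix.nnz == 0

    def test_recurrent_edge_count_binomial_and_deterministic(self):
        # I-I with p=0.4 over 50*49 ordered pairs (self-edges excluded)
        cfg = default_network_config(p_ei=0.0, p_ii=0.4, seed_topology=77)
        n_pairs = 50 * 49
        lo, hi = stats.binom.ppf([0.0005, 0.9995], n_pairs, 0.4)
        count = build_network(cfg).edge_counts[("fast_spiking", "fast_spiking")]
        assert lo <= count <= hi
        again = build_network(cfg)
        assert (again.matrix != build_network(cfg).matrix).nnz == 0

    def test_no_self_edges(self):
        cfg = default_network_config(p_ei=0.0, p_ii=1.0)
        mat = build_network(cfg).matrix
        assert np.all(mat.diagonal() == 0.0)

    def test_invalid_probability_rejected(self):
        with pytest.raises(ConfigurationError):
            default_network_config(p_ei=1.5)


class TestEulerStep:
    def test_resting_fixed_point_is_stationary(self):
        # (v, u) = (-70, -14) is a root of 0.04 v^2 + 4.8 v + 140 with u = b v
        v, u = np.array([-70.0]), np.array([-14.0])
        v2, u2, spiked = euler_step(v, u, PYRAMIDAL_PARAMS, 0.0, 0.1)
        assert v2[0] == pytest.approx(-70.0, abs=1e-12)
        assert u2[0] == pytest.approx(-14.0, abs=1e-12)
        assert not spiked[0]

    def test_single_step_from_reset_potential(self):
        # direct substitution: dv = 169 - 325 + 140 + 13 = -3 -> v' = -65.3
        v2, u2, _ = euler_step(np.array([-65.0]), np.array([-13.0]), PYRAMIDAL_PARAMS, 0.0, 0.1)
        assert v2[0] == pytest.approx(-65.3, abs=1e-12)
        assert u2[0] == pytest.approx(-13.0, abs=1e-12)

    def test_threshold_crossing_resets_and_increments(self):
        v, u = np.array([31.0]), np.array([5.0])
        v2, u2, spiked = euler_step(v, u, PYRAMIDAL_PARAMS, 0.0, 0.1)
        assert spiked[0]
        assert v2[0] == -65.0
        u_pre = u[0] + 0.1 * PYRAMIDAL_PARAMS.a * (PYRAMIDAL_PARAMS.b * v[0] - u[0])
        assert u2[0] == pytest.approx(u_pre + 8.0)

    def test_fixed_point_holds_over_one_second(self):
        v, u = np.array([-70.0]), np.array([-14.0])
        for _ in range(10_000):
            v, u, _ = euler_step(v, u, PYRAMIDAL_PARAMS, 0.0, 0.1)
        assert abs(v[0] + 70.0) < 1e-9
        assert abs(u[0] + 14.0) < 1e-9


class TestDeliverSpikes:
    @pytest.fixture(scope="class")
    def adj(self):
        return build_network(default_network_config(p_ei=1.0, p_ii=1.0))

    def test_no_spikes_no_drive(self, adj):
        drive = deliver_spikes(np.zeros(150, dtype=bool), adj)
        assert np.all(drive == 0.0)

    def test_excitatory_kicks_sum(self, adj):
        spiked = np.zeros(150, dtype=bool)
        spiked[[0, 1, 2]] = True  # three pyramidal cells
        drive = deliver_spikes(spiked, adj)
        assert drive[100] == pytest.approx(0.9)  # 3 spikes x +0.3 onto each interneuron

    def test_inhibitory_kick_is_negative_weight(self, adj):
        spiked = np.zeros(150, dtype=bool)
        spiked[100] = True
        drive = deliver_spikes(spiked, adj)
        assert drive[101] == pytest.approx(-0.3)
        assert drive[100] == 0.0  # no self-edge

    def test_current_pulse_mode_scales_by_dt(self, adj):
        spiked = np.zeros(150, dtype=bool)
        spiked[0] = True
        kick = deliver_spikes(spiked, adj, mode="voltage_kick")
        pulse = deliver_spikes(spiked, adj, mode="current_pulse", dt=0.1)
        np.testing.assert_allclose(pulse, kick / 0.1)


class TestSimulate:
    def test_bit_identical_reruns(self, small_config):
        r1, t1 = simulate(small_config)
        r2, t2 = simulate(small_config)
        assert np.array_equal(r1.neuron_id, r2.neuron_id)
        assert np.array_equal(r1.time_ms, r2.time_ms)
        assert np.array_equal(t1.v, t2.v)

    def test_zero_coupling_silences_interneurons(self):
        cfg = default_network_config(
            i_ext=10.0, p_ei=0.7, p_ii=0.4, w_exc=0.0, w_inh=-0.0,
            duration=2000.0, seed_topology=5, seed_init=6,
        )
        raster, _ = simulate(cfg)
        assert len(raster.for_population("fast_spiking")) == 0
        # decoupled pyramidal cells fire at the isolated-neuron rate
        f_pop = population_frequency(raster, "pyramidal")
        f_iso = fi_curve(PYRAMIDAL_PARAMS, np.array([10.0]), duration=2000.0)[0]
        assert f_pop == pytest.approx(f_iso, rel=0.05)

    def test_recorded_voltage_never_exceeds_threshold(self, small_config):
        _, traces = simulate(small_config)
        assert traces.v.max() <= 30.0

    def test_coupling_modes_agree(self):
        """A one-step current pulse of w/dt and a voltage kick of w are the
        same forward-Euler update up to float rounding; over a short horizon
        (before rounding differences can flip a spike step in the chaotic
        recurrent dynamics) the trajectories coincide."""
        base = dict(i_ext=22.0, duration=120.0, seed_topology=3, seed_init=4)
        cfg_kick = default_network_config(**base)
        r_kick, t_kick = simulate(cfg_kick)
        d = cfg_kick.to_dict()
        for s in d["synapses"]:
            s["coupling_mode"] = "current_pulse"
        cfg_cur = cfg_kick.from_dict(d)
        r_cur, t_cur = simulate(cfg_cur)
        assert np.array_equal(r_kick.neuron_id, r_cur.neuron_id)
        assert np.array_equal(r_kick.time_ms, r_cur.time_ms)
        np.testing.assert_allclose(t_kick.v, t_cur.v, atol=1e-7)

    def test_drive_locked_interneuron_rhythm(self):
        """Induced interneuron firing at the representative operating point is
        locked to the pyramidal volley rhythm with quiescence in between."""
        cfg = default_network_config(i_ext=22.0, duration=4000.0, seed_topology=1, seed_init=2)
        raster, _ = simulate(cfg)
        f = population_frequency(raster, "pyramidal")
        fs = raster.for_population("fast_spiking")
        assert len(fs) > 0
        # events per neuron recur at an integer multiple of the drive period
        period = 1000.0 / f
        checked = 0
        for nid in np.unique(fs.neuron_id)[:10]:
            t = np.sort(fs.spike_times_of(nid))
            t = t[t > 500]
            if t.size < 10:
                continue
            isi = np.median(np.diff(t))
            ratio = isi / period
            assert abs(ratio - round(ratio)) < 0.1
            checked += 1
        assert checked >= 3


class TestPopulationFrequency:
    def test_regular_train_is_exact(self):
        ids = np.repeat(np.arange(3), 10)
        times = np.tile(np.arange(0, 100, 10.0) + 600.0, 3)
        assert population_frequency(_raster(ids, times), transient_ms=500.0) == pytest.approx(100.0)

    def test_pooled_mean_isi(self):
        ids = [0, 0, 0, 1, 1, 1]
        times = [600, 610, 620, 600, 620, 640.0]
        # ISIs pooled: {10,10,20,20} -> mean 15 -> 1000/15
        assert population_frequency(_raster(ids, times)) == pytest.approx(1000.0 / 15.0)

    def test_empty_raster_raises(self):
        with pytest.raises(UndefinedFrequencyError):
            population_frequency(_raster(np.array([], dtype=int), []))


class TestFICurve:
    def test_zero_current_is_silent(self):
        assert fi_curve(PYRAMIDAL_PARAMS, np.array([0.0]), duration=1000.0)[0] == 0.0

    def test_monotone_nondecreasing(self):
        f = fi_curve(PYRAMIDAL_PARAMS, np.linspace(0, 30, 7), duration=1500.0)
        assert np.all(np.diff(f) >= -1e-9)

    def test_fast_spiking_outpaces_pyramidal(self):
        i = np.array([8.0, 15.0])
        f_rs = fi_curve(PYRAMIDAL_PARAMS, i, duration=1500.0)
        f_fs = fi_curve(FAST_SPIKING_PARAMS, i, duration=1500.0)
        assert np.all(f_fs > f_rs)


def test_neuron_params_validation():
    with pytest.raises(ConfigurationError):
        NeuronModelParams(a=0.1, b=0.2, c=35.0, d=2.0)  # reset above threshold
    with pytest.raises(ConfigurationError):
        NeuronModelParams(a=float("nan"), b=0.2, c=-65.0, d=2.0)
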