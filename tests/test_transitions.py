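"""Partition comparison, GMM phase clustering, perturbation protocol, CR."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from sklearn.metrics import adjusted_rand_score

from burstnet import default_network_config
from burstnet.fixtures import itinerant_switching_phases, random_partitions
from burstnet.network import build_network, simulate
from burstnet.phase import wrap_phase
from burstnet.transitions import (
    CRSummary,
    PerturbationSpec,
    TrialResult,
    adjusted_rand_index,
    collective_response,
    gmm_assign,
    paired_perturbation_trial,
    rand_index,
)


class TestRandIndex:
    def test_identical_partitions(self):
        a = np.array([0, 0, 1, 1, 2])
        assert rand_index(a, a) == 1.0

    def test_enumerated_worked_example(self):
        # pairs: (12)(34) same in A; (13)(24) same in B; agreement on 2 of 6
        a = np.array([1, 1, 2, 2])
        b = np.array([1, 2, 1, 2])
        assert rand_index(a, b) == pytest.approx(1.0 / 3.0)

    def test_two_items_both_split(self):
        assert rand_index(np.array([0, 1]), np.array([5, 9])) == 1.0

    def test_mismatched_sizes_rejected(self):
        with pytest.raises(ValueError):
            rand_index(np.array([0, 1]), np.array([0, 1, 2]))


class TestAdjustedRandIndex:
    def test_identical_partitions_are_one(self):
        a = np.array([0, 1, 0, 2, 1])
        assert adjusted_rand_index(a, a) == 1.0

    def test_closed_form_worked_example(self):
        a = np.array([1, 1, 2, 2])
        b = np.array([1, 2, 1, 2])
        assert adjusted_rand_index(a, b) == pytest.approx(-0.5)

    def test_degenerate_single_cluster_defined_as_one(self):
        a = np.zeros(6, dtype=int)
        assert adjusted_rand_index(a, a) == 1.0

    def test_random_partitions_mean_near_zero(self):
        rng = np.random.default_rng(42)
        vals = []
        for _ in range(1000):
            a = rng.integers(0, 3, 50)
            b = rng.integers(0, 3, 50)
            vals.append(adjusted_rand_index(a, b))
        assert abs(np.mean(vals)) < 0.02

    def test_agrees_with_sklearn_oracle(self):
        rng = np.random.default_rng(7)
        for _ in range(50):
            a = rng.integers(0, 4, 40)
            b = rng.integers(0, 4, 40)
            assert adjusted_rand_index(a, b) == pytest.approx(
                adjusted_rand_score(a, b), abs=1e-12
            )

    def test_closed_form_vs_monte_carlo(self):
        # smoke-level agreement; the full 100-pair / 1000-permutation
        # equivalence runs in the end-to-end suite
        rng = np.random.default_rng(3)
        diffs = []
        for i in range(20):
            a = rng.integers(0, 3, 50)
            b = rng.integers(0, 3, 50)
            cf = adjusted_rand_index(a, b)
            mc = adjusted_rand_index(a, b, method="permutation", n_permutations=1000, rng=i)
            diffs.append(abs(cf - mc))
        assert max(diffs) < 0.02

    @settings(derandomize=True, max_examples=30)
    @given(seed=st.integers(0, 5000))
    def test_symmetry_and_label_permutation_invariance(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.integers(0, 3, 30)
        b = rng.integers(0, 3, 30)
        assert adjusted_rand_index(a, b) == pytest.approx(adjusted_rand_index(b, a))
        relabel = rng.permutation(3)
        assert adjusted_rand_index(relabel[a], b) == pytest.approx(
            adjusted_rand_index(a, b)
        )


class TestGMMAssign:
    def test_two_planted_clusters_recovered_exactly(self):
        rng = np.random.default_rng(0)
        truth = np.repeat([0, 1], 25)
        phi = wrap_phase(truth * np.pi + rng.normal(0, 0.1, 50))
        labels = gmm_assign(phi, 2, seed=5).labels
        assert adjusted_rand_score(truth, labels) == 1.0

    def test_single_component_trivial(self):
        out = gmm_assign(np.linspace(-1, 1, 20), 1)
        assert np.all(out.labels == 0)

    def test_three_clusters_across_wrap_boundary(self):
        """Clusters at -2pi/3, 0, +2pi/3 under global rotations that push one
        cluster across +/-pi; the gap-rotation must keep recovery >= 0.95."""
        rng = np.random.default_rng(1)
        truth = np.repeat([0, 1, 2], 17)
        scores = []
        for seed in range(20):
            rot = rng.uniform(-np.pi, np.pi)
            phi = wrap_phase((truth - 1) * 2 * np.pi / 3 + rot + rng.normal(0, 0.15, truth.size))
            labels = gmm_assign(phi, 3, seed=seed).labels
            scores.append(adjusted_rand_score(truth, labels))
        assert np.mean(scores) >= 0.95

    def test_more_components_than_points_rejected(self):
        with pytest.raises(ValueError):
            gmm_assign(np.array([0.0, 1.0]), 3)


def _mk_trial(ari_values, t_p=1000.0):
    t = t_p + np.arange(len(ari_values), dtype=float) * 10.0
    return TrialResult(
        t_ms=t,
        ari=np.asarray(ari_values, float),
        spec=PerturbationSpec(k=1, weight=0.3, t_p_ms=t_p),
        n_clusters=2,
        baseline_g=0.5,
        accepted=True,
        status="ok",
    )


class TestCollectiveResponse:
    def test_unchanged_partitions_give_zero(self):
        cr = collective_response([_mk_trial([1.0] * 10)], window_ms=90.0)
        assert cr.cr == 0.0

    def test_scrambled_partitions_give_one(self):
        cr = collective_response([_mk_trial([0.0] * 10)], window_ms=90.0)
        assert cr.cr == 1.0

    def test_two_trial_average(self):
        trials = [_mk_trial([1.0] * 10), _mk_trial([0.5] * 10)]
        assert collective_response(trials, window_ms=90.0).cr == pytest.approx(0.25)

    def test_empty_trial_list_rejected(self):
        with pytest.raises(ValueError):
            collective_response([])


class TestPairedPerturbationTrial:
    @pytest.fixture(scope="class")
    def cfg(self):
        # operating point inside this model's two-cluster band
        from burstnet.experiments import drive_for_frequencies

        i_ext = float(drive_for_frequencies(np.array([104.0]))[0])
        return default_network_config(
            i_ext=i_ext, duration=4000.0, seed_topology=3, seed_init=4, record_decimation=2
        )

    def test_raw_states_identical_before_perturbation(self, cfg):
        adj = build_network(cfg)
        _, tb = simulate(cfg, adjacency=adj)
        targets = adj.global_indices("fast_spiking")[:5]
        _, tp = simulate(cfg, adjacency=adj, perturbation=(1500.0, targets, 0.3))
        pre = tb.time_ms < 1500.0
        assert np.array_equal(tb.v[pre], tp.v[pre])
        assert not np.array_equal(tb.v[~pre], tp.v[~pre])

    def test_zero_weight_perturbation_is_null(self, cfg):
        spec = PerturbationSpec(k=5, weight=0.0, t_p_ms=1500.0, seed_targets=1)
        trial = paired_perturbation_trial(cfg, spec, eval_post_ms=1000.0)
        assert trial.accepted
        assert np.all(trial.ari == 1.0)
        assert collective_response([trial], window_ms=1000.0).cr == 0.0

    def test_perturbation_decorrelates_after_tp(self, cfg):
        spec = PerturbationSpec(k=5, weight=0.3, t_p_ms=1500.0, seed_targets=1)
        trial = paired_perturbation_trial(cfg, spec, eval_post_ms=1500.0)
        assert trial.accepted
        pre = trial.ari[trial.t_ms < spec.t_p_ms - 200.0]
        post = trial.ari[trial.t_ms >= spec.t_p_ms + 200.0]
        # identical-initialization contract: pre-perturbation partitions match
        # (up to rare single-neuron flips from the acausal filter/Hilbert edge)
        assert (pre == 1.0).mean() >= 0.8
        assert pre.min() >= 0.5
        assert post.mean() < pre.mean()

    def test_unclustered_baseline_rejected(self):
        # low drive -> in-phase band edge; force rejection with a high floor
        cfg = default_network_config(
            i_ext=22.0, duration=3000.0, seed_topology=9, seed_init=10, record_decimation=2
        )
        spec = PerturbationSpec(k=3, weight=0.3, t_p_ms=1200.0, seed_targets=2)
        trial = paired_perturbation_trial(cfg, spec, stability_floor=0.99)
        assert not trial.accepted
        assert trial.status == "no_clustering"
        with pytest.raises(ValueError):
            collective_response([trial])

    def test_perturbation_spec_validation(self):
        with pytest.raises(ValueError):
            PerturbationSpec(k=0, weight=0.3, t_p_ms=1000.0)
        with pytest.raises(ValueError):
            PerturbationSpec(k=5, weight=0.3, t_p_ms=100.0)


class TestItinerantFixtureAssignments:
    def test_hopping_neuron_changes_cluster_only(self):
        series, before, after = itinerant_switching_phases(seed=6)
        t_pre = np.searchsorted(series.time_ms, 500.0)
        t_post = np.searchsorted(series.time_ms, 1500.0)
        lab_pre = gmm_assign(series.phases[t_pre], 2, seed=0).labels
        lab_post = gmm_assign(series.phases[t_post], 2, seed=0).labels
        assert adjusted_rand_score(before, lab_pre) == 1.0
        assert adjusted_rand_score(after, lab_post) == 1.0
        assert adjusted_rand_score(before, after) < 1.0
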