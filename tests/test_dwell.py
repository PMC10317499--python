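"""Dead-time resolution, cluster segmentation, dwell mixtures, L0 estimation."""

import numpy as np
import pytest

from etachan import core, synth
from etachan.core import DomainError
from etachan.dwell import (
    OPEN,
    SHUT,
    DwellSequence,
    analyze_intervals,
    cluster_po,
    estimate_unliganded_L0,
    fit_dwell_mixture,
    impose_dead_time,
    segment_clusters,
)


def seq_of(states, durations):
    return DwellSequence(states=np.array(states), durations=np.array(durations, float))


class TestDwellSequence:
    def test_alternation_enforced(self):
        with pytest.raises(DomainError):
            seq_of([1, 1, 0], [1, 1, 1])

    def test_positive_durations(self):
        with pytest.raises(DomainError):
            seq_of([1, 0], [1.0, 0.0])

    def test_frame_round_trip(self):
        s = seq_of([1, 0, 1], [1.0, 2.0, 3.0])
        back = DwellSequence.from_frame(s.to_frame())
        assert np.array_equal(back.states, s.states)
        assert np.array_equal(back.durations, s.durations)


class TestImposeDeadTime:
    def test_identity_when_all_resolved(self):
        s = seq_of([1, 0, 1], [1.0, 0.5, 2.0])
        r = impose_dead_time(s, 0.025)
        assert np.array_equal(r.durations, s.durations)

    def test_merge_example(self):
        s = seq_of([1, 0, 1], [1.0, 0.01, 2.0])
        r = impose_dead_time(s, 0.025)
        assert r.states.tolist() == [OPEN]
        assert r.durations.tolist() == [3.01]

    def test_conservation_and_idempotence(self, rng):
        n = 201
        states = np.arange(n) % 2
        durs = rng.exponential(0.05, n) + 1e-6
        s = DwellSequence(states=states, durations=durs)
        r = impose_dead_time(s, 0.025)
        if len(r):
            assert np.all(r.durations >= 0.025)
            r2 = impose_dead_time(r, 0.025)
            assert np.array_equal(r.durations, r2.durations)
        # conservation up to trimmed edge intervals
        assert r.total_duration <= s.total_duration + 1e-12
        trimmed = s.total_duration - r.total_duration
        assert trimmed < 2 * 0.025 + 1e-12 or len(r) == 0

    def test_edge_trimming_warns(self):
        s = seq_of([0, 1, 0], [0.001, 5.0, 0.002])
        with pytest.warns(UserWarning, match="trimmed 2"):
            r = impose_dead_time(s, 0.025)
        assert r.durations.tolist() == [5.0]

    def test_consecutive_unresolved_absorbed(self):
        s = seq_of([1, 0, 1, 0, 1], [1.0, 0.01, 0.004, 0.01, 2.0])
        r = impose_dead_time(s, 0.025)
        assert r.states.tolist() == [OPEN]
        assert r.durations[0] == pytest.approx(3.024)


class TestSegmentClusters:
    def test_single_cluster(self):
        s = seq_of([1, 0, 1, 0, 1], [1, 5, 1, 8, 1])
        cs = segment_clusters(s, tcrit=20)
        assert len(cs.clusters) == 1

    def test_example_gaps(self):
        s = seq_of(
            [1, 0, 1, 0, 1, 0, 1, 0, 1, 0, 1],
            [1, 5, 1, 50, 1, 8, 1, 120, 1, 5, 1],
        )
        cs = segment_clusters(s, tcrit=20)
        assert len(cs.clusters) == 3
        for c in cs.clusters:
            assert np.all(c.shut_durations <= 20)
            assert c.states[0] == OPEN and c.states[-1] == OPEN

    def test_all_isolated_openings_dropped(self):
        s = seq_of([1, 0, 1, 0, 1], [1, 30, 1, 40, 1])
        assert len(segment_clusters(s, tcrit=20).clusters) == 0

    def test_tcrit_must_exceed_dead_time(self):
        s = seq_of([1, 0, 1], [1, 2, 1])
        s.td = 25.0
        with pytest.raises(DomainError):
            segment_clusters(s, tcrit=20)


class TestDwellMixture:
    def test_single_exponential(self, rng):
        t = rng.exponential(10.0, 5000)
        t = t[t >= 0.025]
        f = fit_dwell_mixture(t, td=0.025, seed=0)
        assert f.n_components == 1
        assert f.taus[0] == pytest.approx(10.0, abs=3 * 10.0 / np.sqrt(len(t)))
        assert f.weights.sum() == pytest.approx(1.0)

    def test_two_components(self, rng):
        t = np.concatenate([rng.exponential(1.0, 3500), rng.exponential(50.0, 1500)])
        t = t[t >= 0.025]
        f = fit_dwell_mixture(t, td=0.025, seed=0)
        assert f.n_components == 2
        assert f.taus[0] == pytest.approx(1.0, rel=0.15)
        assert f.taus[1] == pytest.approx(50.0, rel=0.15)
        assert f.weights[0] == pytest.approx(0.7, abs=0.05)

    def test_truncation_handling(self, rng):
        # heavy censoring: naive mean overestimates tau, shifted MLE does not
        t = rng.exponential(1.0, 20000)
        t = t[t >= 0.5]
        assert t.mean() > 1.3  # naive estimate is badly biased
        f = fit_dwell_mixture(t, td=0.5, seed=0)
        assert f.taus[0] == pytest.approx(1.0, abs=3 * 1.0 / np.sqrt(len(t)))

    def test_loglik_nondecreasing_in_components(self, rng):
        from etachan.dwell import _fit_k

        t = np.concatenate([rng.exponential(1.0, 2000), rng.exponential(30.0, 1000)])
        u = t
        r = np.random.default_rng(0)
        lls = [_fit_k(u, k, r)[2] for k in (1, 2, 3)]
        assert lls[1] >= lls[0]
        assert lls[2] >= lls[1] - 1e-6

    def test_predominant_tau_tiebreak(self):
        from etachan.dwell import ExpMixtureFit

        f = ExpMixtureFit(
            taus=np.array([1.0, 5.0]), weights=np.array([0.5, 0.5]), logL=0.0, n=100, td=0.0
        )
        assert f.predominant_tau == 5.0

    def test_too_few_durations(self):
        with pytest.raises(DomainError):
            fit_dwell_mixture(np.ones(10), td=0.0)


class TestClusterPo:
    def test_arithmetic(self):
        assert cluster_po(1.0, 1.0) == 0.5
        assert cluster_po(2.0, 8.0) == pytest.approx(0.2)
        with pytest.raises(DomainError):
            cluster_po(0.0, 1.0)

    def test_simulated_po_matches_theory(self, truth, ec50, simulated_sequence):
        res = analyze_intervals(simulated_sequence, td=0.002, tcrit=20.0, seed=0)
        theory = core.po_curve(ec50, truth.KdC, truth.L2)
        # empirical sem across clusters
        per_cluster = [
            c.open_durations.sum() / c.durations.sum() for c in res["clusters"].clusters
        ]
        sem = np.std(per_cluster) / np.sqrt(len(per_cluster))
        assert res["po"] == pytest.approx(theory, abs=max(2 * sem, 0.02))

    def test_predominant_mode_differs_when_shut_mixture_splits(self, simulated_sequence):
        mean_mode = analyze_intervals(simulated_sequence, td=0.002, seed=0)
        pred_mode = analyze_intervals(simulated_sequence, td=0.002, seed=0,
                                      tau_mode="predominant")
        assert pred_mode["po"] != pytest.approx(mean_mode["po"], abs=1e-3)


class TestUnligandedL0:
    @staticmethod
    def _two_state(rng, n, mean_shut_ms, mean_open_ms):
        states = np.tile([SHUT, OPEN], n)
        durs = np.empty(2 * n)
        durs[0::2] = rng.exponential(mean_shut_ms, n)
        durs[1::2] = rng.exponential(mean_open_ms, n)
        return DwellSequence(states=states, durations=np.clip(durs, 1e-9, None))

    def test_recovery_within_20_percent(self, rng):
        # f0 = 0.1 s^-1, b0 = 5000 s^-1 -> L0 = 2e-5
        s = self._two_state(rng, 10_000, 10_000.0, 0.2)
        est = estimate_unliganded_L0(s, td=0.025)
        assert est.L0 == pytest.approx(2e-5, rel=0.20)
        assert est.L0 == pytest.approx(est.f0 / est.b0, rel=1e-12)

    def test_symmetric_rates(self, rng):
        s = self._two_state(rng, 5000, 1.0, 1.0)
        est = estimate_unliganded_L0(s, td=0.0)
        assert est.L0 == pytest.approx(1.0, rel=0.05)

    def test_time_unit_invariance(self, rng):
        s = self._two_state(rng, 2000, 50.0, 0.5)
        est_ms = estimate_unliganded_L0(s, td=0.01)
        s10 = DwellSequence(states=s.states, durations=s.durations * 10.0)
        est_scaled = estimate_unliganded_L0(s10, td=0.1)
        assert est_ms.L0 == pytest.approx(est_scaled.L0, rel=1e-9)

    def test_too_few_intervals(self):
        s = seq_of([0, 1] * 5, [1.0] * 10)
        with pytest.raises(DomainError):
            estimate_unliganded_L0(s, td=0.0)
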