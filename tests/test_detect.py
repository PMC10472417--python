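"""Detector, clustering, simulated review and agreement-metric tests."""

import numpy as np
import pytest

from hdesi import detect as det
from hdesi import simulate as sim
from hdesi.errors import InputError, ParameterError, UndefinedMetricError


def _marks(*times):
    return det.MarkList(times=np.array(times, float))


def _event(t, ch="E01", p=0.95, amp=50.0, rate=250.0):
    return det.DetectedEvent(
        peak_time_s=t,
        peak_sample=int(round(t * rate)),
        peak_channel=ch,
        probability=p,
        peak_amplitude_uV=amp,
    )


class TestDetectEvents:
    def test_noiseless_events_all_found(self, leadfield64, template250, source_index):
        rec = sim.simulate_recording(
            leadfield64,
            template250,
            10,
            source_index,
            amplitude_nAm=100.0,
            noise_rms_uV=0.0,
            duration_s=60,
            seed=5,
        )
        events = det.detect_events(rec, template250)
        truth = np.array([e.time_s for e in rec.events])
        strong = [e for e in events if e.probability >= 0.9]
        assert len(strong) == 10
        for e in strong:
            assert np.min(np.abs(truth - e.peak_time_s)) <= 0.020

    def test_noise_only_yields_fewer_high_probability_events(
        self, leadfield64, template250, source_index
    ):
        common = dict(duration_s=120, noise_rms_uV=15.0)
        spikes = sim.simulate_recording(
            leadfield64, template250, 15, source_index, amplitude_nAm=750.0,
            seed=1, **common
        )
        noise = sim.simulate_recording(
            leadfield64, template250, 0, source_index, seed=1, **common
        )
        n_spike = len(det.filter_by_probability(det.detect_events(spikes, template250), 0.9))
        n_noise = len(det.filter_by_probability(det.detect_events(noise, template250), 0.9))
        assert n_noise < n_spike

    def test_all_zero_data_no_detections(self, leadfield64, template250):
        rec = sim.SimulatedRecording(
            data=np.zeros((leadfield64.n_channels, 250 * 20)),
            sampling_rate_Hz=250.0,
            channel_ids=leadfield64.electrodes.channel_ids,
            events=(),
        )
        assert det.detect_events(rec, template250) == []

    def test_min_separation_respected(self, recording, template250):
        events = det.detect_events(recording, template250, min_separation_ms=500)
        times = np.array([e.peak_time_s for e in events])
        assert np.all(np.diff(times) >= 0.5 - 1e-9)

    def test_short_recording_rejected(self, leadfield64, template250):
        rec = sim.SimulatedRecording(
            data=np.zeros((leadfield64.n_channels, 250 * 5)),
            sampling_rate_Hz=250.0,
            channel_ids=leadfield64.electrodes.channel_ids,
            events=(),
        )
        with pytest.raises(InputError):
            det.detect_events(rec, template250)

    def test_rate_mismatch_rejected(self, recording):
        t1000 = sim.generate_ied_template(1000)
        with pytest.raises(ParameterError):
            det.detect_events(recording, t1000)


class TestFilterByProbability:
    def test_threshold_boundary_inclusive(self):
        """probability < 0.9 excluded; exactly 0.9 retained."""
        events = [_event(1.0, p=0.89), _event(2.0, p=0.90), _event(3.0, p=0.95)]
        kept = det.filter_by_probability(events, 0.9)
        assert len(kept) == 2
        assert all(e.probability >= 0.9 for e in kept)

    def test_pmin_zero_identity(self):
        events = [_event(1.0, p=0.1), _event(2.0, p=0.5)]
        assert det.filter_by_probability(events, 0.0) == events

    def test_pmin_one(self):
        events = [_event(1.0, p=0.999), _event(2.0, p=1.0)]
        assert det.filter_by_probability(events, 1.0) == [events[1]]

    def test_monotone_and_idempotent(self):
        rng = np.random.default_rng(0)
        events = [_event(float(i), p=float(p)) for i, p in enumerate(rng.random(50))]
        prev = len(events)
        for p_min in np.linspace(0, 1, 11):
            kept = det.filter_by_probability(events, p_min)
            assert len(kept) <= prev
            assert det.filter_by_probability(kept, p_min) == kept
            prev = len(kept)


class TestClusterByPeakElectrode:
    def test_single_channel(self):
        events = [_event(float(i), ch="E101") for i in range(5)]
        clusters = det.cluster_by_peak_electrode(events)
        assert len(clusters) == 1
        assert clusters[0].label == "E101"
        assert clusters[0].n_events == 5

    def test_conservation(self):
        rng = np.random.default_rng(1)
        events = [
            _event(float(i), ch=f"E{rng.integers(1, 6)}") for i in range(40)
        ]
        clusters = det.cluster_by_peak_electrode(events)
        assert sum(c.n_events for c in clusters) == 40

    def test_sort_and_tie_break(self):
        events = (
            [_event(float(i), ch="E1") for i in range(5)]
            + [_event(10.0 + i, ch="E2") for i in range(5)]
            + [_event(20.0 + i, ch="E3") for i in range(7)]
        )
        clusters = det.cluster_by_peak_electrode(events)
        assert [c.label for c in clusters] == ["E3", "E1", "E2"]

    def test_events_sorted_by_time(self):
        events = [_event(3.0, ch="E1"), _event(1.0, ch="E1"), _event(2.0, ch="E1")]
        (cluster,) = det.cluster_by_peak_electrode(events)
        assert [e.peak_time_s for e in cluster.events] == [1.0, 2.0, 3.0]


class TestMatchEvents:
    def test_identical_lists_full_match(self):
        a = _marks(1.0, 2.0, 3.0)
        assert len(det.match_events(a, a, 100)) == 3

    def test_disjoint_no_match(self):
        assert det.match_events(_marks(1.0), _marks(2.0), 100) == []

    def test_greedy_nearest(self):
        # oracle: exhaustive assignment over the two candidate pairings
        a = _marks(1.00, 1.05)
        b = _marks(1.02)
        matching = det.match_events(a, b, 30)
        assert matching == [(0, 0)]  # 1.00 is nearer to 1.02 than 1.05 is

    def test_one_to_one(self):
        a = _marks(1.0, 1.01, 1.02)
        b = _marks(1.005, 1.015)
        matching = det.match_events(a, b, 50)
        assert len(matching) == 2
        assert len({i for i, _ in matching}) == 2
        assert len({j for _, j in matching}) == 2


class TestSimulateReview:
    def test_zero_miss_rate_keeps_matched(self):
        cands = [_event(1.0), _event(2.0), _event(9.0)]
        truth = _marks(1.0, 2.0, 5.0)
        reviewed = det.simulate_review(cands, truth, tol_ms=100, reviewer_miss_rate=0.0)
        np.testing.assert_allclose(reviewed.times, [1.0, 2.0])
        assert reviewed.provenance == "reviewed"

    def test_full_miss_rate_empty(self):
        cands = [_event(1.0)]
        reviewed = det.simulate_review(cands, _marks(1.0), reviewer_miss_rate=1.0)
        assert len(reviewed) == 0

    def test_binomial_keep_rate(self):
        cands = [_event(float(t)) for t in range(2, 42)]
        truth = det.MarkList(times=np.arange(2.0, 42.0))
        miss = 0.3
        kept = [
            len(det.simulate_review(cands, truth, reviewer_miss_rate=miss, seed=s))
            for s in range(200)
        ]
        # binomial(40, 0.7): mean 28, sd ~2.9; mean over 200 seeds within 95% CI
        assert np.mean(kept) == pytest.approx(40 * (1 - miss), abs=0.6)


class TestAgreementFormulas:
    def test_sensitivity_identical(self):
        a = _marks(1.0, 2.0)
        assert det.detection_sensitivity(a, a, 100) == 100.0

    def test_sensitivity_three_of_four(self):
        vis = _marks(1.0, 2.0, 3.0, 4.0)
        auto = _marks(1.0, 2.0, 3.0, 9.0)
        assert det.detection_sensitivity(vis, auto, 100) == 75.0

    def test_sensitivity_empty_auto(self):
        assert det.detection_sensitivity(_marks(1.0), det.MarkList(np.array([])), 100) == 0.0

    def test_sensitivity_undefined(self):
        with pytest.raises(UndefinedMetricError):
            det.detection_sensitivity(det.MarkList(np.array([])), _marks(1.0), 100)

    def test_ppv_low_precision_regime(self):
        assert det.positive_predictive_value(100, 4) == pytest.approx(4.0)

    def test_ppv_bounds(self):
        assert det.positive_predictive_value(10, 10) == 100.0
        assert det.positive_predictive_value(10, 0) == 0.0
        with pytest.raises(UndefinedMetricError):
            det.positive_predictive_value(0, 0)

    def test_cluster_ied_fraction(self):
        assert det.cluster_ied_fraction(30, 120) == pytest.approx(25.0)


class TestSuccessRate:
    def _cohort(self, rank1_sizes):
        return [
            [det.EventCluster(label="E1", events=tuple(_event(2.0 * k, ch="E1") for k in range(n)))]
            for n in rank1_sizes
        ]

    def test_rank1_ten_of_twentytwo(self):
        """10 of 22 recordings qualify at rank 1 -> 45.45%."""
        cohort = self._cohort([35] * 10 + [10] * 12)
        assert det.success_rate(cohort, cluster_rank=1, min_ieds=30) == pytest.approx(
            45.45, abs=0.005
        )

    def test_rank10_nineteen_of_twentytwo(self):
        """19 of 22 recordings qualify within ranks 1-10 -> 86.36%."""
        cohort = self._cohort([35] * 19 + [5] * 3)
        assert det.success_rate(
            cohort, cluster_rank=10, min_ieds=30, within=True
        ) == pytest.approx(86.36, abs=0.005)

    def test_all_qualify(self):
        cohort = self._cohort([40, 41, 42])
        assert det.success_rate(cohort, 1, 30) == 100.0

    def test_min_ieds_inclusive(self):
        cohort = self._cohort([30])
        assert det.success_rate(cohort, 1, 30) == 100.0

    def test_empty_raises(self):
        with pytest.raises(UndefinedMetricError):
            det.success_rate([], 1, 30)


class TestCohensKappa:
    def test_perfect_agreement(self):
        assert det.cohens_kappa(1.0, 0.3) == 1.0

    def test_chance_agreement(self):
        assert det.cohens_kappa(0.6, 0.6) == 0.0

    def test_contingency_table_oracle(self):
        """Hand-computed 2x2 table: a=20, b=5, c=10, d=65.

        Pr(a) = 0.85; Pr(e) = 0.25*0.30 + 0.75*0.70 = 0.60; kappa = 0.625.
        """
        pr_a = (20 + 65) / 100
        p1 = (20 + 5) / 100  # rater A positive
        p2 = (20 + 10) / 100  # rater B positive
        pr_e = p1 * p2 + (1 - p1) * (1 - p2)
        assert pr_a == 0.85
        assert pr_e == pytest.approx(0.60)
        assert det.cohens_kappa(pr_a, pr_e) == pytest.approx(0.625)

    def test_pr_e_one_undefined(self):
        with pytest.raises(UndefinedMetricError):
            det.cohens_kappa(0.9, 1.0)

    def test_kappa_upper_bound(self):
        rng = np.random.default_rng(2)
        for _ in range(100):
            pr_a, pr_e = rng.random(), rng.uniform(0, 0.99)
            k = det.cohens_kappa(pr_a, pr_e)
            assert k <= 1.0
            assert (k == 1.0) == (pr_a == 1.0)

    def test_marklist_wrapper_against_table(self):
        """Construct epochs occupancies and check the wrapper's 2x2 table."""
        epoch = det.KAPPA_EPOCH_S
        # 10 epochs: A marks epochs {0,1,2,3}, B marks epochs {2,3,4}
        a = det.MarkList(times=np.array([0.5, 2.5, 4.5, 6.5]))
        b = det.MarkList(times=np.array([4.5, 6.5, 8.5]))
        res = det.kappa_from_marklists(a, b, duration_s=10 * epoch)
        both, only_a, only_b = 2, 2, 1
        neither = 10 - both - only_a - only_b
        pr_a = (both + neither) / 10
        p1, p2 = 4 / 10, 3 / 10
        pr_e = p1 * p2 + (1 - p1) * (1 - p2)
        assert res.pr_a == pytest.approx(pr_a)
        assert res.pr_e == pytest.approx(pr_e)
        assert res.kappa == pytest.approx((pr_a - pr_e) / (1 - pr_e))

    def test_marklist_wrapper_perfect(self):
        a = det.MarkList(times=np.array([1.0, 5.0]))
        res = det.kappa_from_marklists(a, a, duration_s=10.0)
        assert res.kappa == 1.0


class TestDetectorSensitivityVsSnr:
    def test_monotone_in_amplitude(self, leadfield64, template250, source_index):
        """Ground-truth sensitivity is non-decreasing over an SNR ladder."""
        sens = []
        for amp in (200.0, 450.0, 900.0):
            hits, total = 0, 0
            for seed in range(8):
                rec = sim.simulate_recording(
                    leadfield64, template250, 6, source_index,
                    amplitude_nAm=amp, noise_rms_uV=15.0, duration_s=40, seed=seed,
                )
                truth = det.MarkList(times=np.array([e.time_s for e in rec.events]))
                found = det.filter_by_probability(
                    det.detect_events(rec, template250), 0.9
                )
                auto = det.MarkList(times=np.array([e.peak_time_s for e in found]))
                hits += len(det.match_events(truth, auto, 100))
                total += len(truth)
            sens.append(hits / total)
        assert sens[0] <= sens[1] + 0.05
        assert sens[1] <= sens[2] + 0.05
        assert sens[-1] >= 0.9
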