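"""Tag-selection principles, subject assessment, accuracy, EPC mapping."""
import numpy as np
import pytest

import rfbreath as rb
from rfbreath.reconstruct import DiffSequence, Extremum
from rfbreath.select import TagReport


def make_report(body_part="chest", passes_length=True, passes_amplitude=True,
                rate_hz=0.25):
    est = rb.RateEstimate(rate_hz=rate_hz, peak_amplitude=1.0,
                          freqs=np.array([rate_hz]),
                          spectrum=np.array([1.0]), band=(0.1, 1.0))
    return TagReport(
        epc=rb.encode_epc(1, body_part), subject_id=1, body_part=body_part,
        fs_hz=30.0, duration_s=60.0, wavelet_level=5,
        diffs=DiffSequence(extrema=()), mean_abs_diff=0.5,
        passes_length=passes_length, passes_amplitude=passes_amplitude,
        rate=est)


class TestLengthPrinciple:
    def test_apnea_chest_window(self):
        # one extremum difference in a 16.5226 s window is below the
        # 2*fmin*dt = 1.6523 floor: not credible breathing
        assert rb.min_expected_extrema(16.5226) == pytest.approx(1.6523, abs=5e-5)
        assert rb.length_principle(1, 16.5226) is False

    def test_zero_differences_always_fail(self):
        assert rb.length_principle(0, 120.0) is False

    def test_normal_breathing_passes(self):
        assert rb.length_principle(30, 60.0) is True

    def test_invalid_args(self):
        with pytest.raises(rb.InvalidArgumentError):
            rb.length_principle(1, 0.0)
        with pytest.raises(rb.InvalidArgumentError):
            rb.length_principle(-1, 10.0)


class TestAmplitudePrinciple:
    def test_empty_fails(self):
        assert rb.amplitude_principle([], 0.1) is False

    def test_large_swings_pass(self):
        assert rb.amplitude_principle([0.5, -0.5], 0.1) is True

    def test_small_swings_fail(self):
        assert rb.amplitude_principle([0.01, -0.01], 0.1) is False

    def test_accepts_diff_sequence(self):
        ex = (Extremum(0, 0.0, "min", 0), Extremum(1, 1.0, "max", 1))
        assert rb.amplitude_principle(DiffSequence(extrema=ex), 0.1) is True

    def test_invalid_threshold(self):
        with pytest.raises(rb.InvalidArgumentError):
            rb.amplitude_principle([1.0], 0.0)


class TestAccuracy:
    def test_perfect(self):
        assert rb.accuracy(0.25, 0.25) == pytest.approx(100.0)

    @pytest.mark.parametrize("measured, actual, expected", [
        (0.388803, 0.3889, 99.98),
        (0.403683, 0.3670, 90.00),
        (0.4073239, 0.4043, 99.25),
    ])
    def test_field_measurements(self, measured, actual, expected):
        assert round(rb.accuracy(measured, actual), 2) == expected

    def test_gross_error_goes_negative(self):
        assert rb.accuracy(1.0, 0.25) < 0

    def test_invalid_reference(self):
        with pytest.raises(rb.InvalidArgumentError):
            rb.accuracy(0.25, 0.0)


class TestAssessSubject:
    def test_both_pass_prefers_chest(self):
        chest, abdomen = make_report("chest"), make_report("abdomen")
        selected, apnea = rb.assess_subject([abdomen, chest])
        assert selected is chest and apnea is False

    def test_failed_chest_falls_back_to_abdomen(self):
        chest = make_report("chest", passes_amplitude=False)
        abdomen = make_report("abdomen")
        selected, apnea = rb.assess_subject([chest, abdomen])
        assert selected is abdomen and apnea is False

    def test_both_fail_flags_apnea(self):
        chest = make_report("chest", passes_length=False)
        abdomen = make_report("abdomen", passes_amplitude=False)
        selected, apnea = rb.assess_subject([chest, abdomen])
        assert selected is None and apnea is True

    def test_wrong_cardinality_rejected(self):
        with pytest.raises(rb.InvalidArgumentError):
            rb.assess_subject([])


class TestEpcAndSubjectMap:
    @pytest.mark.parametrize("sid, bp", [(1, "chest"), (1, "abdomen"),
                                         (4095, "chest")])
    def test_roundtrip(self, sid, bp):
        assert rb.decode_epc(rb.encode_epc(sid, bp)) == (sid, bp)

    def test_encode_bounds(self):
        with pytest.raises(rb.InvalidArgumentError):
            rb.encode_epc(4096, "chest")
        with pytest.raises(rb.InvalidArgumentError):
            rb.encode_epc(1, "knee")

    def test_decode_unprogrammed_tag(self):
        with pytest.raises(rb.UnmappedTagError):
            rb.decode_epc("E28068940000000000000000")

    def test_map_lookup_and_error(self):
        epc = rb.encode_epc(7, "chest")
        smap = rb.SubjectMap.from_epcs([epc])
        assert smap.lookup(epc) == (7, "chest")
        with pytest.raises(rb.UnmappedTagError) as exc:
            smap.lookup("DEAD")
        assert "DEAD" in str(exc.value)

    def test_duplicate_body_part_rejected(self):
        with pytest.raises(rb.InvalidArgumentError):
            rb.SubjectMap(entries={"A": (1, "chest"), "B": (1, "chest")})

    def test_csv_roundtrip(self, tmp_path):
        smap = rb.SubjectMap.from_epcs(
            [rb.encode_epc(1, "chest"), rb.encode_epc(1, "abdomen"),
             rb.encode_epc(2, "chest")])
        path = tmp_path / "map.csv"
        smap.to_csv(path)
        assert rb.SubjectMap.from_csv(path).entries == smap.entries

    def test_subjects_groups_chest_first(self):
        smap = rb.SubjectMap.from_epcs(
            [rb.encode_epc(1, "abdomen"), rb.encode_epc(1, "chest")])
        groups = smap.subjects()
        assert list(groups[1].keys()) == ["chest", "abdomen"]


class TestMonitorEndToEnd:
    def test_selected_tags_accurate_on_multi_subject_scenes(self):
        """Every subject's selected tag recovers the true rate to >= 95%
        accuracy on three-subject synthetic scenes."""
        hits = total = 0
        for seed in range(10):
            sc = rb.default_scenario(3, seed=seed, noise_sigma_rad=0.05)
            streams, truth = rb.simulate_streams(sc, 120.0)
            smap = rb.SubjectMap.from_epcs(streams)
            report = rb.monitor(streams, smap)
            for sid, res in report.subjects.items():
                assert not res.apnea
                true_rate = truth[res.selected_epc].rate_hz
                total += 1
                hits += rb.accuracy(res.rate_hz, true_rate) >= 95.0
        assert hits == total

    def test_monitor_report_serialisable(self, breathing_scenario):
        import json
        streams, _ = rb.simulate_streams(breathing_scenario, 30.0)
        smap = rb.SubjectMap.from_epcs(streams)
        report = rb.monitor(streams, smap)
        payload = json.loads(json.dumps(report.to_dict()))
        assert set(payload) == {"tags", "subjects"}


class TestApneaDetection:
    def test_breath_hold_flagged(self):
        subj = rb.SubjectSpec(subject_id=1, apnea_intervals=((12.0, 30.0),))
        sc = rb.BreathingScenario(subjects=(subj,), seed=0)
        streams, _ = rb.simulate_streams(sc, 30.0)
        res = rb.detect_apnea(streams, rb.SubjectMap.from_epcs(streams))
        assert res[1].apnea is True
        assert res[1].flagged_windows

    def test_continuous_breathing_not_flagged(self, breathing_scenario):
        streams, _ = rb.simulate_streams(breathing_scenario, 30.0)
        res = rb.detect_apnea(streams, rb.SubjectMap.from_epcs(streams))
        assert res[1].apnea is False
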