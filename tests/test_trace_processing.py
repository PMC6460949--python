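"""dF/F0 baseline, trial-peak extraction, and responder detection."""

import numpy as np
import pytest

from s1pop.errors import (
    BaselineDegenerateError,
    ContractError,
    MissingTrialError,
    ProtocolError,
)
from s1pop.trace_processing import (
    FluorescenceRecording,
    compute_baseline,
    compute_dff,
    detect_responders,
    extract_trial_peaks,
)

from conftest import dff_from_peaks, grid_protocol


def baseline_oracle(trace, fraction=0.3):
    """Independent brute force: full sort, slice, mean."""
    trace = np.sort(np.asarray(trace, dtype=float))
    k = max(1, int(np.floor(fraction * trace.size)))
    return trace[:k].mean()


class TestComputeBaseline:
    @pytest.mark.parametrize(
        "trace, expected",
        [
            (np.full(17, 100.0), 100.0),  # constant: mean of any subset
            (np.arange(10.0), 1.0),  # lowest 3 of 0..9 are {0,1,2}
            (np.array([1.0] * 7 + [100.0] * 3), 1.0),  # lowest 3 all ones
        ],
    )
    def test_examples(self, trace, expected):
        assert compute_baseline(trace) == pytest.approx(expected)

    def test_matches_brute_force_oracle(self, rng):
        for _ in range(1000):
            n = int(rng.integers(4, 60))
            trace = rng.uniform(0.01, 50.0, size=n)
            assert compute_baseline(trace) == pytest.approx(
                baseline_oracle(trace)
            )

    def test_all_zero_trace_is_degenerate(self):
        with pytest.raises(BaselineDegenerateError):
            compute_baseline(np.zeros(10))

    def test_zero_floor_with_positive_tail_is_degenerate(self):
        # lowest 30% of [0,0,0,1] is {0}; baseline 0 leaves dF/F0 undefined
        with pytest.raises(BaselineDegenerateError):
            compute_baseline(np.array([0.0, 0.0, 0.0, 1.0]))

    def test_too_short_trace_rejected(self):
        with pytest.raises(ContractError):
            compute_baseline(np.array([1.0, 2.0, 3.0]))


class TestComputeDff:
    def test_f_equals_f0_maps_to_zero(self):
        rec = FluorescenceRecording(
            fluor=np.full((2, 20), 100.0), frame_period_s=0.229
        )
        dff = compute_dff(rec)
        assert np.all(dff.dff == 0.0)
        assert np.all(dff.f0 == 100.0)

    def test_doubling_gives_unity_and_threshold_boundary(self):
        f = np.full((1, 10), 10.0)
        f[0, 7] = 20.0  # F = 2 F0 -> dff 1.0
        f[0, 8] = 13.0  # F0=10, F=13 -> dff 0.3, the responder boundary
        dff = compute_dff(FluorescenceRecording(fluor=f, frame_period_s=0.1))
        assert dff.dff[0, 7] == pytest.approx(1.0)
        assert dff.dff[0, 8] == pytest.approx(0.3)

    def test_round_trip_reconstructs_fluorescence(self, rng):
        f = rng.uniform(10.0, 500.0, size=(5, 80))
        rec = FluorescenceRecording(fluor=f, frame_period_s=0.229)
        dff = compute_dff(rec)
        np.testing.assert_allclose(
            dff.f0[:, None] * (1.0 + dff.dff), f, rtol=1e-12
        )


class TestRecordingInvariants:
    @pytest.mark.parametrize(
        "fluor, period",
        [
            (np.full((2, 10), -1.0), 0.1),  # negative fluorescence
            (np.full((2, 10), np.nan), 0.1),  # non-finite
            (np.ones((2, 1)), 0.1),  # single frame
            (np.ones((2, 10)), 0.0),  # zero frame period
        ],
    )
    def test_invalid_recordings_rejected(self, fluor, period):
        with pytest.raises(ContractError):
            FluorescenceRecording(fluor=fluor, frame_period_s=period)


class TestExtractTrialPeaks:
    def test_zero_dff_gives_zero_peaks_and_fidelity(self):
        proto = grid_protocol(["a", "b"], n_trials=3)
        dff = dff_from_peaks(np.zeros((2, 2, 3)), proto)
        tensor = extract_trial_peaks(dff, proto)
        assert np.all(tensor.peaks == 0.0)
        assert np.all(tensor.fidelity == 0.0)

    def test_peak_is_window_maximum(self):
        proto = grid_protocol(["s"], n_trials=1, window=3)
        dff = dff_from_peaks(np.zeros((1, 1, 1)), proto)
        e = proto.events[0]
        dff.dff[0, e.onset_frame : e.onset_frame + 3] = [0.1, 0.5, 0.2]
        tensor = extract_trial_peaks(dff, proto)
        assert tensor.peaks[0, 0, 0] == pytest.approx(0.5)

    def test_fidelity_counts_threshold_exceedances(self):
        proto = grid_protocol(["s"], n_trials=5)
        peaks = np.array([[[0.4, 0.1, 0.5, 0.35, 0.2]]])
        tensor = extract_trial_peaks(dff_from_peaks(peaks, proto), proto)
        assert tensor.fidelity[0, 0] == pytest.approx(3 / 5)

    def test_fidelity_nondecreasing_as_threshold_drops(self, rng):
        proto = grid_protocol(["a", "b"], n_trials=5)
        peaks = rng.uniform(0, 1, size=(4, 2, 5))
        dff = dff_from_peaks(peaks, proto)
        fids = [
            extract_trial_peaks(dff, proto, response_threshold=thr).fidelity
            for thr in (0.6, 0.4, 0.2)
        ]
        assert np.all(fids[0] <= fids[1]) and np.all(fids[1] <= fids[2])

    def test_peaks_invariant_to_out_of_window_permutation(self, rng):
        proto = grid_protocol(["a", "b"], n_trials=2)
        peaks = rng.uniform(0.5, 2.0, size=(3, 2, 2))
        dff = dff_from_peaks(peaks, proto, base=0.0)
        in_window = np.zeros(dff.n_frames, dtype=bool)
        for e in proto.events:
            in_window[proto.window(e)] = True
        shuffled = dff.dff.copy()
        outside = np.flatnonzero(~in_window)
        shuffled[:, outside] = shuffled[:, rng.permutation(outside)]
        from s1pop.trace_processing import DffRecording

        dff2 = DffRecording(
            dff=shuffled, f0=dff.f0, frame_period_s=dff.frame_period_s
        )
        t1 = extract_trial_peaks(dff, proto)
        t2 = extract_trial_peaks(dff2, proto)
        np.testing.assert_array_equal(t1.peaks, t2.peaks)

    def test_max_per_cell_spans_whole_trace_by_default(self):
        proto = grid_protocol(["s"], n_trials=1)
        dff = dff_from_peaks(np.array([[[0.5]]]), proto)
        dff.dff[0, -1] = 3.0  # outside any window
        t_trace = extract_trial_peaks(dff, proto, max_scope="trace")
        t_win = extract_trial_peaks(dff, proto, max_scope="windows")
        assert t_trace.max_per_cell[0] == pytest.approx(3.0)
        assert t_win.max_per_cell[0] == pytest.approx(0.5)

    def test_protocol_beyond_recording_rejected(self):
        proto = grid_protocol(["s"], n_trials=1)
        dff = dff_from_peaks(np.zeros((1, 1, 1)), proto, n_frames=3)
        with pytest.raises(ProtocolError):
            extract_trial_peaks(dff, proto)

    def test_missing_trial_reported_with_indices(self):
        from conftest import make_event
        from s1pop.trace_processing import StimulusProtocol

        events = (
            make_event("a", 1, 2),
            make_event("a", 2, 10),
            make_event("b", 1, 18),
        )  # b trial 2 missing
        proto = StimulusProtocol(events=events)
        dff = dff_from_peaks(np.zeros((1, 1, 1)), grid_protocol(["x"], 1),
                             n_frames=40)
        with pytest.raises(MissingTrialError) as err:
            extract_trial_peaks(dff, proto)
        assert ("b", 2) in err.value.missing

    def test_overlapping_events_rejected(self):
        from conftest import make_event
        from s1pop.trace_processing import StimulusProtocol

        with pytest.raises(ProtocolError):
            StimulusProtocol(
                events=(make_event("a", 1, 0, duration=5),
                        make_event("b", 1, 3, duration=5)),
            )


class TestDetectResponders:
    @pytest.mark.parametrize(
        "peak, expected",
        [
            (0.29, False),  # below threshold
            (0.30, False),  # boundary excluded: the rule is strict >
            (0.31, True),
        ],
    )
    def test_threshold_is_strict(self, peak, expected):
        proto = grid_protocol(["s"], n_trials=1)
        tensor = extract_trial_peaks(
            dff_from_peaks(np.array([[[peak]]]), proto), proto
        )
        assert detect_responders(tensor)[0] == expected

    def test_single_supra_threshold_peak_suffices(self):
        proto = grid_protocol(["a", "b"], n_trials=3)
        peaks = np.zeros((1, 2, 3))
        peaks[0, 1, 2] = 0.31
        tensor = extract_trial_peaks(dff_from_peaks(peaks, proto), proto)
        assert detect_responders(tensor)[0]
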