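"""Streaming detection, bundle persistence and the stream CSV dialect."""

import json

import numpy as np
import pytest

import rehabband as rb
from rehabband.detect import is_action
from rehabband.errors import BundleLoadError, InputError
from rehabband.signals import flatten
from rehabband.stream import (
    initialize_reference,
    load_bundle,
    read_stream_csv,
    run_detector,
    save_bundle,
    write_stream_csv,
)


def _profile(seed=1):
    return rb.make_subject_profile(np.random.default_rng(seed))


class TestInitializeReference:
    def test_constant_stream(self):
        stream = np.tile([1000.0, 1100.0, 900.0], (40, 1))
        ref = initialize_reference(stream)
        np.testing.assert_array_equal(ref.ref, [1000.0, 1100.0, 900.0])

    def test_short_stream_rejected(self):
        with pytest.raises(InputError):
            initialize_reference(np.ones((29, 3)) * 1000)

    def test_noisy_rest_reference_within_standard_error(self):
        prof = _profile(3)
        stream, _ = rb.generate_session(prof, [("rest", 30)], seed=5)
        ref = initialize_reference(stream)
        bound = 3 * prof.noise_sd / np.sqrt(30)
        assert np.all(np.abs(ref.ref / prof.baseline - 1.0) < bound * 2)


class TestRunDetector:
    def test_pure_rest_emits_nothing(self, bundle):
        stream, _ = rb.generate_session(_profile(2), [("rest", 500)], seed=3)
        assert run_detector(bundle, stream) == []

    def test_posture_switch_ramp_rejected(self, bundle):
        sched = [("rest", 60), ("switch", 0.15), ("rest", 60), ("switch", 0.0), ("rest", 60)]
        stream, _ = rb.generate_session(_profile(2), sched, seed=4)
        assert run_detector(bundle, stream) == []

    def test_twenty_actions_recovered_in_order(self, bundle):
        rng = np.random.default_rng(100)
        prof = rb.make_subject_profile(rng)
        labels = list(rng.integers(1, 5, size=20))
        stream, truth = rb.generate_session(prof, rb.rest_action_schedule(labels), seed=200)
        events = run_detector(bundle, stream)
        assert len(events) == 20
        assert [e.label for e in events] == [t["label"] for t in truth]
        for e, t in zip(events, truth):
            assert 0 <= e.sample_index - t["onset"] <= 35

    def test_events_respect_refractory_spacing(self, bundle):
        rng = np.random.default_rng(101)
        prof = rb.make_subject_profile(rng)
        labels = list(rng.integers(1, 5, size=10))
        stream, _ = rb.generate_session(prof, rb.rest_action_schedule(labels, rest_len=40), seed=7)
        events = run_detector(bundle, stream)
        gaps = np.diff([e.sample_index for e in events])
        assert np.all(gaps >= bundle.detection.refractory)

    def test_deterministic(self, bundle):
        stream, _ = rb.generate_session(
            _profile(5), rb.rest_action_schedule([1, 3, 2]), seed=11
        )
        e1 = run_detector(bundle, stream)
        e2 = run_detector(bundle, stream)
        assert [e.to_dict() for e in e1] == [e.to_dict() for e in e2]

    def test_streaming_matches_batch_window_oracle(self, bundle):
        """Materializing every full window and replaying the documented
        gate/delay/refractory policy reproduces the streaming events."""
        rng = np.random.default_rng(102)
        prof = rb.make_subject_profile(rng)
        stream, _ = rb.generate_session(prof, rb.rest_action_schedule([2, 4, 1]), seed=13)
        events = run_detector(bundle, stream)

        cfg = bundle.detection
        ref = initialize_reference(stream, 30)
        norm = stream[30:] / ref.ref
        W = cfg.window_size
        windows = {
            30 + e: norm[e - W + 1 : e + 1].T for e in range(W - 1, norm.shape[0])
        }  # absolute index of newest sample -> 3x30 window
        oracle = []
        refractory = 0
        pending = None
        for idx in sorted(windows):
            if pending is not None:
                pending -= 1
                if pending <= 0:
                    code = bundle.autoencoder.encode(flatten(windows[idx]))
                    oracle.append((idx, rb.vote(bundle.ensemble, code).winner))
                    refractory = cfg.refractory
                    pending = None
                continue
            if refractory > 0:
                refractory -= 1
                continue
            if is_action(windows[idx], cfg):
                pending = cfg.classify_delay
        assert [(e.sample_index, e.label) for e in events] == oracle


class TestBundlePersistence:
    def test_roundtrip_predictions_bitwise_identical(self, bundle, tmp_path):
        path = tmp_path / "bundle.json"
        save_bundle(bundle, path)
        loaded = load_bundle(path)
        stream, _ = rb.generate_session(_profile(6), rb.rest_action_schedule([3, 1]), seed=21)
        e1 = run_detector(bundle, stream)
        e2 = run_detector(loaded, stream)
        assert [e.to_dict() for e in e1] == [e.to_dict() for e in e2]
        x = np.linspace(0.9, 1.2, 90)
        np.testing.assert_array_equal(
            loaded.autoencoder.encode(x), bundle.autoencoder.encode(x)
        )

    def test_corrupted_file_raises_load_error(self, bundle, tmp_path):
        path = tmp_path / "bundle.json"
        save_bundle(bundle, path)
        path.write_text(path.read_text()[: 200])
        with pytest.raises(BundleLoadError):
            load_bundle(path)

    def test_inconsistent_code_dims_rejected(self, bundle, tmp_path):
        path = tmp_path / "bundle.json"
        save_bundle(bundle, path)
        payload = json.loads(path.read_text())
        for m in payload["ensemble"]["members"]:
            m["weights"] = m["weights"][:-2]  # ensemble now expects 8-d codes
        path.write_text(json.dumps(payload))
        with pytest.raises(BundleLoadError):
            load_bundle(path)

    def test_unknown_version_rejected(self, bundle, tmp_path):
        path = tmp_path / "bundle.json"
        save_bundle(bundle, path)
        payload = json.loads(path.read_text())
        payload["format_version"] = 99
        path.write_text(json.dumps(payload))
        with pytest.raises(BundleLoadError):
            load_bundle(path)


class TestStreamCSV:
    def test_roundtrip(self, tmp_path):
        stream = np.random.default_rng(0).uniform(800, 1600, (50, 3))
        path = tmp_path / "stream.csv"
        write_stream_csv(path, stream)
        arr, skipped = read_stream_csv(path)
        np.testing.assert_allclose(arr, stream)
        assert skipped == 0

    def test_malformed_rows_skipped_with_count(self, tmp_path):
        path = tmp_path / "stream.csv"
        path.write_text("t,ch1,ch2,ch3\n0,1000,1100,900\n1,oops,1100,900\n2,1000\n3,1001,1099,901\n")
        arr, skipped = read_stream_csv(path)
        assert arr.shape == (2, 3)
        assert skipped == 2

    def test_strict_mode_aborts(self, tmp_path):
        path = tmp_path / "stream.csv"
        path.write_text("t,ch1,ch2,ch3\n0,oops,1100,900\n")
        with pytest.raises(InputError):
            read_stream_csv(path, strict=True)

    def test_wrong_header_rejected(self, tmp_path):
        path = tmp_path / "stream.csv"
        path.write_text("time,a,b,c\n0,1,2,3\n")
        with pytest.raises(InputError):
            read_stream_csv(path)
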