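"""Run extraction, short-run resolution (vs. brute-force reference), wave
selection and classifier-gated P suppression."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import ecgdelin as e
from ecgdelin.postprocess import Run, runs_from_labels
from ecgdelin.types import CLASS_NONE, CLASS_P, CLASS_QRS, CLASS_T

from conftest import label_array_from_runs


def one_hot_probs(labels):
    return e.ClassProbMap(np.eye(4)[np.asarray(labels, int)], fs=500.0)


def runs_to_labels(runs):
    out = []
    for r in runs:
        out.extend([r.label] * r.length)
    return np.array(out, dtype=np.int8)


# ---------------------------------------------------------------------------
# Brute-force reference for short-run resolution: operates directly on the
# label array, rescanning from scratch at every step.
# ---------------------------------------------------------------------------


def reference_resolve(labels, fs, min_wave_ms):
    labels = np.array(labels, dtype=np.int8)
    min_len = min_wave_ms * fs / 1000.0
    while True:
        runs = []
        start = 0
        for i in range(1, len(labels) + 1):
            if i == len(labels) or labels[i] != labels[start]:
                runs.append((int(labels[start]), start, i - 1))
                start = i
        candidates = []
        for idx, (label, s, t) in enumerate(runs):
            if t - s + 1 >= min_len:
                continue
            left = runs[idx - 1][0] if idx > 0 else None
            right = runs[idx + 1][0] if idx + 1 < len(runs) else None
            if label != CLASS_NONE:
                candidates.append((t - s + 1, s, left, right))
            elif left is not None and right is not None and left == right:
                candidates.append((t - s + 1, s, left, right))
        if not candidates:
            return labels
        length, s, left, right = min(candidates)
        t = s + length - 1
        if left is not None and right is not None and left == right:
            labels[s : t + 1] = left
        else:
            labels[s : t + 1] = CLASS_NONE


class TestExtractRuns:
    def test_run_length_encoding(self):
        labels = label_array_from_runs([(CLASS_P, 3), (CLASS_NONE, 2), (CLASS_QRS, 4)])
        runs = e.extract_runs(one_hot_probs(labels))
        assert runs == [Run(CLASS_P, 0, 2), Run(CLASS_NONE, 3, 4), Run(CLASS_QRS, 5, 8)]

    def test_uniform_tie_breaks_to_none(self):
        probs = e.ClassProbMap(np.full((10, 4), 0.25), fs=500.0)
        assert e.extract_runs(probs) == [Run(CLASS_NONE, 0, 9)]

    def test_single_sample(self):
        runs = e.extract_runs(one_hot_probs([CLASS_T]))
        assert runs == [Run(CLASS_T, 0, 0)]

    def test_runs_tile_signal(self, rng):
        probs = rng.dirichlet(np.ones(4), size=200)
        runs = e.extract_runs(e.ClassProbMap(probs, fs=500.0))
        pos = 0
        for r in runs:
            assert r.start == pos
            pos = r.end + 1
        assert pos == 200


class TestResolveShortRuns:
    def test_glue_same_label_neighbors(self):
        labels = label_array_from_runs([(CLASS_P, 30), (CLASS_NONE, 10), (CLASS_P, 25)])
        out = e.resolve_short_runs(runs_from_labels(labels), fs=500)
        assert out == [Run(CLASS_P, 0, 64)]

    def test_discard_between_different_labels(self):
        labels = label_array_from_runs([(CLASS_QRS, 40), (CLASS_T, 12), (CLASS_NONE, 50)])
        out = e.resolve_short_runs(runs_from_labels(labels), fs=500)
        assert out == [Run(CLASS_QRS, 0, 39), Run(CLASS_NONE, 40, 101)]

    def test_short_edge_run_becomes_none(self):
        labels = label_array_from_runs([(CLASS_P, 19), (CLASS_NONE, 100)])
        out = e.resolve_short_runs(runs_from_labels(labels), fs=500)
        assert out == [Run(CLASS_NONE, 0, 118)]

    def test_boundary_duration_kept(self):
        # 20 samples at 500 Hz is exactly 40 ms: not shorter, survives
        labels = label_array_from_runs([(CLASS_NONE, 30), (CLASS_P, 20), (CLASS_NONE, 30)])
        out = e.resolve_short_runs(runs_from_labels(labels), fs=500)
        assert Run(CLASS_P, 30, 49) in out

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_reference_on_random_masks(self, seed):
        rng = np.random.default_rng(seed)
        for _ in range(200):
            n = int(rng.integers(1, 40))
            labels = rng.integers(0, 4, n).astype(np.int8)
            got = runs_to_labels(e.resolve_short_runs(runs_from_labels(labels), 500, 6))
            want = reference_resolve(labels, 500, 6)
            assert np.array_equal(got, want), labels

    def test_no_short_wave_run_remains(self, rng):
        for _ in range(100):
            labels = rng.integers(0, 4, 50).astype(np.int8)
            out = e.resolve_short_runs(runs_from_labels(labels), 500, 40)
            for r in out:
                if r.label != CLASS_NONE:
                    assert r.length >= 20
            assert runs_to_labels(out).size == 50


@settings(max_examples=300, deadline=None, derandomize=True)
@given(st.lists(st.integers(0, 3), min_size=1, max_size=30))
def test_resolution_property(seq):
    """For arbitrary label sequences, resolution preserves tiling, leaves no
    short wave run, and agrees with the from-scratch reference."""
    labels = np.array(seq, dtype=np.int8)
    out = e.resolve_short_runs(runs_from_labels(labels), 500, 6)
    got = runs_to_labels(out)
    assert got.size == labels.size
    for r in out:
        if r.label != CLASS_NONE:
            assert r.length >= 3
    assert np.array_equal(got, reference_resolve(labels, 500, 6))


class TestSelectWaves:
    def test_longest_p_between_qrs_wins(self):
        runs = [
            Run(CLASS_QRS, 100, 140),
            Run(CLASS_NONE, 141, 379),
            Run(CLASS_P, 380, 400),
            Run(CLASS_NONE, 401, 429),
            Run(CLASS_P, 430, 480),
            Run(CLASS_NONE, 481, 599),
            Run(CLASS_QRS, 600, 640),
        ]
        d = e.select_waves(runs)
        assert [(iv.wave, iv.onset, iv.offset) for iv in d] == [
            ("QRS", 100, 140), ("P", 430, 480), ("QRS", 600, 640)
        ]

    def test_no_qrs_yields_empty(self):
        runs = [Run(CLASS_P, 0, 30), Run(CLASS_NONE, 31, 99)]
        assert len(e.select_waves(runs)) == 0

    def test_single_t_candidate_kept(self):
        runs = [Run(CLASS_QRS, 0, 40), Run(CLASS_T, 41, 100), Run(CLASS_QRS, 101, 140)]
        d = e.select_waves(runs)
        assert ("T", 41, 100) in [(iv.wave, iv.onset, iv.offset) for iv in d]

    def test_edge_waves_flag(self):
        runs = [Run(CLASS_P, 0, 30), Run(CLASS_QRS, 50, 90), Run(CLASS_T, 100, 160)]
        off = e.select_waves(runs)
        on = e.select_waves(runs, e.PostprocessOptions(include_edge_waves=True))
        assert [iv.wave for iv in off] == ["QRS"]
        assert sorted(iv.wave for iv in on) == ["P", "QRS", "T"]


class TestSuppressP:
    def test_renormalization_arithmetic(self):
        probs = e.ClassProbMap(np.array([[0.1, 0.6, 0.2, 0.1]]), fs=500.0)
        out = e.suppress_p(probs, e.RhythmProb(1.0))
        assert np.allclose(out.probs, [[0.25, 0.0, 0.5, 0.25]])

    def test_below_threshold_identity(self):
        probs = e.ClassProbMap(np.array([[0.1, 0.6, 0.2, 0.1]]), fs=500.0)
        out = e.suppress_p(probs, e.RhythmProb(0.1))
        assert np.array_equal(out.probs, probs.probs)

    def test_pure_p_row_falls_back_to_none(self):
        probs = e.ClassProbMap(np.array([[0.0, 1.0, 0.0, 0.0]]), fs=500.0)
        out = e.suppress_p(probs, e.RhythmProb(0.9))
        assert np.allclose(out.probs, [[1.0, 0.0, 0.0, 0.0]])


class TestDelineate:
    def test_identity_on_clean_mask(self, nsr_record):
        d = e.delineate(one_hot_probs(nsr_record.mask.labels),
                        options=e.PostprocessOptions(include_edge_waves=True))
        assert [(iv.wave, iv.onset, iv.offset) for iv in d] == [
            (iv.wave, iv.onset, iv.offset) for iv in nsr_record.truth
        ]

    def test_robust_to_isolated_wrong_samples(self, nsr_record, rng):
        labels = nsr_record.mask.labels.copy()
        # flip 10 isolated samples far apart, each deep inside a run (>= 40 ms
        # of identical labels on both sides), so every injected region and no
        # residual fragment is shorter than 40 ms
        flipped = 0
        for pos in np.linspace(100, len(labels) - 100, 60).astype(int):
            if flipped == 10:
                break
            if np.all(labels[pos - 20 : pos + 21] == labels[pos]):
                labels[pos] = (labels[pos] + 2) % 4
                flipped += 1
        assert flipped == 10
        d = e.delineate(one_hot_probs(labels),
                        options=e.PostprocessOptions(include_edge_waves=True))
        assert [(iv.wave, iv.onset, iv.offset) for iv in d] == [
            (iv.wave, iv.onset, iv.offset) for iv in nsr_record.truth
        ]

    def test_suppression_removes_all_p(self, nsr_record):
        d = e.delineate(one_hot_probs(nsr_record.mask.labels), rhythm=e.RhythmProb(1.0),
                        options=e.PostprocessOptions(include_edge_waves=True))
        assert len(d.of_wave("P")) == 0
        assert len(d.of_wave("QRS")) > 0

    def test_at_most_one_p_and_t_per_rr_interval(self, rng):
        for _ in range(20):
            probs = rng.dirichlet(np.full(4, 0.3), size=2000)
            d = e.delineate(e.ClassProbMap(probs, fs=500.0))
            qrs = d.of_wave("QRS")
            for a, b in zip(qrs, qrs[1:]):
                between_p = [iv for iv in d.of_wave("P") if a.offset < iv.onset < b.onset]
                between_t = [iv for iv in d.of_wave("T") if a.offset < iv.onset < b.onset]
                assert len(between_p) <= 1 and len(between_t) <= 1
            # sorted and non-overlapping
            for x, y in zip(d.intervals, d.intervals[1:]):
                assert x.offset < y.onset

    def test_idempotent_on_own_output(self, rng):
        for _ in range(10):
            probs = rng.dirichlet(np.full(4, 0.3), size=1500)
            first = e.delineate(e.ClassProbMap(probs, fs=500.0))
            mask = e.intervals_to_mask(first, 1500)
            second = e.delineate(one_hot_probs(mask.labels))
            assert second.intervals == first.intervals
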