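"""Boundary matching at the 150 ms tolerance and Se/PPV/F1/m/sigma metrics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import maximum_bipartite_matching

import ecgdelin as e
from ecgdelin.metrics import BOUNDARY_KINDS
from ecgdelin.types import ConfigError, ConsistencyError


def max_matching_cardinality(pred, truth, tol):
    """Independent oracle: maximum bipartite matching size."""
    if not pred or not truth:
        return 0
    adj = np.abs(np.asarray(pred)[:, None] - np.asarray(truth)[None, :]) <= tol
    if not adj.any():
        return 0
    match = maximum_bipartite_matching(csr_matrix(adj), perm_type="column")
    return int((match >= 0).sum())


class TestMatchBoundaries:
    def test_within_tolerance_is_tp(self):
        counts = e.match_boundaries([2140.0], [2000.0])
        assert (counts.tp, counts.fp, counts.fn) == (1, 0, 0)
        assert counts.deviations == [140.0]

    def test_outside_tolerance(self):
        counts = e.match_boundaries([2160.0], [2000.0])
        assert (counts.tp, counts.fp, counts.fn) == (0, 1, 1)

    def test_one_to_one_duplicate_prediction(self):
        counts = e.match_boundaries([950.0, 1050.0], [1000.0])
        assert (counts.tp, counts.fp, counts.fn) == (1, 1, 0)

    def test_crossing_instance_attains_maximum(self):
        # a greedy-by-deviation pairing would find only one match here
        counts = e.match_boundaries([9.0, 11.0], [0.0, 10.0], tol_ms=10.0)
        assert counts.tp == 2

    def test_unsorted_input_rejected(self):
        with pytest.raises(ConsistencyError):
            e.match_boundaries([3.0, 1.0], [0.0])

    @pytest.mark.parametrize("seed", range(4))
    def test_cardinality_matches_bipartite_oracle(self, seed):
        rng = np.random.default_rng(seed)
        for _ in range(300):
            npred, ntruth = rng.integers(0, 7, 2)
            pred = sorted(rng.uniform(0, 1000, npred))
            truth = sorted(rng.uniform(0, 1000, ntruth))
            counts = e.match_boundaries(pred, truth, tol_ms=150.0)
            assert counts.tp == max_matching_cardinality(pred, truth, 150.0)
            # conservation
            assert counts.tp + counts.fn == len(truth)
            assert counts.tp + counts.fp == len(pred)

    def test_shift_invariance(self, rng):
        pred = sorted(rng.uniform(0, 5000, 20))
        truth = sorted(rng.uniform(0, 5000, 18))
        a = e.match_boundaries(pred, truth)
        b = e.match_boundaries([p + 12345 for p in pred], [t + 12345 for t in truth])
        assert (a.tp, a.fp, a.fn) == (b.tp, b.fp, b.fn)
        assert np.allclose(sorted(a.deviations), sorted(b.deviations))


@settings(max_examples=200, deadline=None, derandomize=True)
@given(
    st.lists(st.integers(0, 2000), max_size=10),
    st.lists(st.integers(0, 2000), max_size=10),
)
def test_matching_conservation_property(pred, truth):
    """TP + FN always equals |truth| and TP + FP equals |pred|, with
    cardinality never exceeding the bipartite maximum."""
    pred, truth = sorted(pred), sorted(truth)
    counts = e.match_boundaries(pred, truth, tol_ms=150.0)
    assert counts.tp + counts.fn == len(truth)
    assert counts.tp + counts.fp == len(pred)
    assert counts.tp == max_matching_cardinality(pred, truth, 150.0)


class TestComputeMetrics:
    def test_simple_counts(self):
        entry = e.compute_metrics(e.MatchCounts(3, 1, 1, [0.0, 0.0, 0.0]))
        assert entry.se == entry.ppv == entry.f1 == 0.75

    def test_harmonic_mean_of_reported_rates(self):
        # reference P-onset (Se, PPV) operating points without and with
        # classification guidance; inputs are rounded to two decimals, so the
        # recombined F1 carries ~0.02 of rounding slack
        assert abs(100 * e.harmonic_f1(0.9543, 0.9753) - 96.47) <= 0.02
        assert abs(100 * e.harmonic_f1(0.9531, 0.9870) - 96.97) <= 0.02

    def test_error_statistics(self):
        entry = e.compute_metrics(e.MatchCounts(2, 0, 0, [10.0, -10.0]))
        assert entry.m == 0.0 and entry.sigma == 10.0

    def test_population_sigma(self):
        entry = e.compute_metrics(e.MatchCounts(2, 0, 0, [0.0, 2.0]))
        assert entry.sigma == 1.0  # population, not sample, standard deviation

    def test_zero_denominators_are_undefined_not_errors(self):
        entry = e.compute_metrics(e.MatchCounts(0, 0, 0, []))
        assert entry.se is None and entry.ppv is None and entry.f1 is None

    def test_f1_between_se_and_ppv(self, rng):
        for _ in range(50):
            tp, fp, fn = rng.integers(1, 30, 3)
            entry = e.compute_metrics(e.MatchCounts(int(tp), int(fp), int(fn),
                                                    [0.0] * int(tp)))
            assert min(entry.se, entry.ppv) - 1e-12 <= entry.f1 <= max(entry.se, entry.ppv) + 1e-12


def _simple_delineation(qrs_onsets, fs=500.0, wave="QRS", length=40, record_id=""):
    ivs = [e.WaveInterval(wave, s, s + length) for s in qrs_onsets]
    return e.Delineation(ivs, fs=fs, record_id=record_id)


class TestEvaluate:
    def test_perfect_predictions_everywhere(self, specs):
        records = [
            e.synthesize_record(specs[r], 10, 500, rng_seed=i, record_id=f"r{i}")
            for i, r in enumerate(["NSR", "ST", "AFIB", "AFL", "VT", "BBB", "AVB1"])
        ]
        preds = {r.truth.record_id: r.truth for r in records}
        truths = {r.truth.record_id: r.truth for r in records}
        rhythms = {r.truth.record_id: r.rhythm for r in records}
        results = e.evaluate(preds, truths, rhythms=rhythms)
        for stratum, kinds in results.items():
            for kind, entry in kinds.items():
                if entry.tp + entry.fn > 0:
                    assert entry.se == entry.ppv == entry.f1 == 1.0
        # rhythms without atrial activity have empty P cells
        for rhythm in ("AFIB", "AFL", "VT"):
            assert results[rhythm]["P_onset"].f1 is None

    def test_partial_mode_excludes_unannotated_predictions(self):
        truth = _simple_delineation([1000])  # boundaries at 2000/2080 ms
        pred = _simple_delineation([1000, 10000])  # second QRS 5 s away
        full = e.evaluate({"r": pred}, {"r": truth}, mode="full")
        partial = e.evaluate({"r": pred}, {"r": truth}, mode="partial")
        assert full["All"]["QRS_onset"].fp == 1
        assert partial["All"]["QRS_onset"].fp == 0
        assert partial["All"]["QRS_onset"].tp == 1

    def test_qtdb_style_truth_skips_t_onsets(self):
        truth = e.Delineation([e.WaveInterval("T", None, 500)], fs=500,
                              partial_flags={"T": True})
        pred = e.Delineation([e.WaveInterval("T", 400, 495)], fs=500)
        results = e.evaluate({"r": pred}, {"r": truth})
        assert results["All"]["T_onset"].tp + results["All"]["T_onset"].fp == 0
        assert results["All"]["T_offset"].tp == 1

    def test_best_lead_picks_lowest_error(self):
        truth = _simple_delineation([1000], record_id="r")
        lead1 = _simple_delineation([1030], record_id="r")  # 60 ms late
        lead2 = _simple_delineation([1005], record_id="r")  # 10 ms late
        results = e.evaluate({"r": [lead1, lead2]}, {"r": truth})
        assert results["All"]["QRS_onset"].m == 10.0

    def test_missing_rhythm_label_is_config_error(self):
        truth = _simple_delineation([1000])
        with pytest.raises(ConfigError):
            e.evaluate({"r": truth}, {"r": truth}, rhythms={})

    def test_report_table_layout(self):
        truth = _simple_delineation([1000])
        table = e.report_table(e.evaluate({"r": truth}, {"r": truth},
                                          rhythms={"r": "NSR"}))
        assert list(table.columns) == list(BOUNDARY_KINDS)
        assert list(table.index) == ["NSR", "All"]
        assert table.loc["NSR", "QRS_onset"] == 100.0
        assert np.isnan(table.loc["NSR", "P_onset"])
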