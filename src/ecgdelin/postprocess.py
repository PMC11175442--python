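"""Post-processing: from per-sample class probabilities to a delineation.

The algorithm has three steps:

1. take the per-sample argmax class and form maximal constant-label runs;
2. resolve runs shorter than 40 ms — a short run whose two neighbours share
   a label is glued into them, otherwise it is relabelled ``none``;
3. keep every QRS run, and between each pair of consecutive QRS runs keep
   only the single longest P run and the single longest T run.

An optional rhythm-classifier output gates a P-wave suppression step before
run extraction: when the two-way classifier calls the signal atrial
fibrillation or flutter, the P channel is zeroed and rows renormalized, so
no P wave can survive to the final delineation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .types import (
    CLASS_NONE,
    CLASS_P,
    CLASS_QRS,
    CLASS_T,
    ClassProbMap,
    ConsistencyError,
    Delineation,
    RhythmProb,
    WaveInterval,
)

#: Argmax tie-break priority (first wins): none > QRS > P > T.
_TIE_PRIORITY = (CLASS_NONE, CLASS_QRS, CLASS_P, CLASS_T)


@dataclass(frozen=True)
class Run:
    """A maximal constant-label run ``[start, end]`` (closed, in samples)."""

    label: int
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ConsistencyError(f"run start {self.start} > end {self.end}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass
class PostprocessOptions:
    min_wave_ms: float = 40.0
    include_edge_waves: bool = False
    suppression_threshold: float = 0.5

    def __post_init__(self) -> None:
        if self.min_wave_ms <= 0:
            raise ConsistencyError("min_wave_ms must be positive")


def runs_from_labels(labels: np.ndarray) -> list[Run]:
    """Run-length encode a label array into maximal constant runs."""
    labels = np.asarray(labels)
    if labels.size == 0:
        return []
    boundaries = np.flatnonzero(np.diff(labels)) + 1
    starts = np.concatenate(([0], boundaries))
    ends = np.concatenate((boundaries - 1, [labels.size - 1]))
    return [Run(int(labels[s]), int(s), int(e)) for s, e in zip(starts, ends)]


def extract_runs(probs: ClassProbMap) -> list[Run]:
    """Per-sample argmax followed by run-length encoding.

    Ties are broken by the fixed priority none > QRS > P > T so the result
    is deterministic even on degenerate probability maps.
    """
    reordered = probs.probs[:, list(_TIE_PRIORITY)]
    labels = np.asarray(_TIE_PRIORITY)[np.argmax(reordered, axis=1)]
    return runs_from_labels(labels)


def _check_tiling(runs: list[Run]) -> None:
    pos = 0
    for run in runs:
        if run.start != pos:
            raise ConsistencyError(f"runs do not tile the signal at sample {pos}")
        pos = run.end + 1


def _merge_equal_neighbors(runs: list[Run]) -> list[Run]:
    out: list[Run] = []
    for run in runs:
        if out and out[-1].label == run.label:
            out[-1] = Run(run.label, out[-1].start, run.end)
        else:
            out.append(run)
    return out


def resolve_short_runs(runs: list[Run], fs: float, min_wave_ms: float = 40.0) -> list[Run]:
    """Iteratively remove runs shorter than ``min_wave_ms``.

    Runs are processed shortest-first (leftmost on ties).  A short run whose
    two neighbours carry the same label is glued into a single run of that
    label; otherwise it is relabelled ``none`` and merged with any adjacent
    ``none`` runs.  Edge runs have one neighbour and take the second branch.
    A short ``none`` run between differing labels is already a fixed point
    and is left alone.  Terminates when no wave-labelled run shorter than
    the threshold remains; the output tiles the signal like the input.
    """
    if not runs:
        return []
    _check_tiling(runs)
    min_len = min_wave_ms * fs / 1000.0  # short <=> length*1000/fs < min_wave_ms
    runs = _merge_equal_neighbors(list(runs))

    def candidates() -> list[int]:
        idxs = []
        for i, run in enumerate(runs):
            if run.length >= min_len:
                continue
            if run.label != CLASS_NONE:
                idxs.append(i)
            else:
                left = runs[i - 1].label if i > 0 else None
                right = runs[i + 1].label if i + 1 < len(runs) else None
                if left is not None and right is not None and left == right:
                    idxs.append(i)  # short none gap glues its neighbours
        return idxs

    while True:
        idxs = candidates()
        if not idxs:
            break
        i = min(idxs, key=lambda j: (runs[j].length, runs[j].start))
        run = runs[i]
        left = runs[i - 1] if i > 0 else None
        right = runs[i + 1] if i + 1 < len(runs) else None
        if left is not None and right is not None and left.label == right.label:
            runs[i - 1 : i + 2] = [Run(left.label, left.start, right.end)]
        else:
            runs[i] = Run(CLASS_NONE, run.start, run.end)
            runs = _merge_equal_neighbors(runs)
    return runs


def select_waves(
    runs: list[Run],
    options: Optional[PostprocessOptions] = None,
    fs: float = 500.0,
    record_id: str = "",
    lead: str = "",
) -> Delineation:
    """Pick final wave intervals from resolved runs.

    Every QRS run becomes an interval.  Between consecutive QRS runs the
    single longest P run and the single longest T run (earliest on ties)
    survive; other P/T runs are dropped.  With ``include_edge_waves`` the
    longest P before the first QRS and the longest T after the last QRS are
    also kept.
    """
    options = options or PostprocessOptions()
    qrs_idx = [i for i, r in enumerate(runs) if r.label == CLASS_QRS]
    intervals: list[WaveInterval] = []
    for i in qrs_idx:
        intervals.append(WaveInterval("QRS", runs[i].start, runs[i].end))

    def longest(segment: list[Run], label: int) -> Optional[Run]:
        cands = [r for r in segment if r.label == label]
        if not cands:
            return None
        return max(cands, key=lambda r: (r.length, -r.start))

    for a, b in zip(qrs_idx, qrs_idx[1:]):
        between = runs[a + 1 : b]
        for label, wave in ((CLASS_P, "P"), (CLASS_T, "T")):
            best = longest(between, label)
            if best is not None:
                intervals.append(WaveInterval(wave, best.start, best.end))
    if options.include_edge_waves and qrs_idx:
        best_p = longest(runs[: qrs_idx[0]], CLASS_P)
        if best_p is not None:
            intervals.append(WaveInterval("P", best_p.start, best_p.end))
        best_t = longest(runs[qrs_idx[-1] + 1 :], CLASS_T)
        if best_t is not None:
            intervals.append(WaveInterval("T", best_t.start, best_t.end))
    return Delineation(intervals, fs=fs, record_id=record_id, lead=lead)


def suppress_p(
    probs: ClassProbMap, rhythm: RhythmProb, threshold: float = 0.5
) -> ClassProbMap:
    """Zero the P channel when the rhythm classifier calls AFIB/AFL.

    Below threshold the map is returned unchanged.  Rows that were almost
    pure P renormalize to the ``none`` class as a declared fallback.
    """
    if rhythm.p_af < threshold:
        return probs
    p = probs.probs.copy()
    p[:, CLASS_P] = 0.0
    totals = p.sum(axis=1)
    degenerate = totals < 1e-12
    p[degenerate, CLASS_NONE] = 1.0
    totals[degenerate] = 1.0
    p /= totals[:, None]
    return ClassProbMap(p, fs=probs.fs)


def delineate(
    probs: ClassProbMap,
    rhythm: Optional[RhythmProb] = None,
    fs: float = 500.0,
    options: Optional[PostprocessOptions] = None,
    record_id: str = "",
    lead: str = "",
) -> Delineation:
    """Full post-processing pipeline: probabilities to final delineation."""
    options = options or PostprocessOptions()
    if rhythm is not None:
        probs = suppress_p(probs, rhythm, options.suppression_threshold)
    runs = extract_runs(probs)
    runs = resolve_short_runs(runs, fs, options.min_wave_ms)
    return select_waves(runs, options, fs=fs, record_id=record_id, lead=lead)
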