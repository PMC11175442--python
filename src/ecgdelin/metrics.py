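"""Boundary-matching evaluation with the AAMI 150 ms tolerance.

A predicted onset/offset is a true positive when a ground-truth boundary of
the same kind lies within 150 ms; matching is one-to-one, greedy by
increasing absolute deviation.  From the pooled TP/FP/FN counts we report
sensitivity Se = TP/(TP+FN), positive predictive value PPV = TP/(TP+FP),
their harmonic mean F1, and the mean m and population standard deviation
sigma of the signed deviations (prediction - truth, in ms).

Results can be stratified by rhythm, restricted to the boundary kinds a
truth dialect actually annotates, and computed in a *partial* mode for
sparsely annotated references: a prediction with no ground-truth annotation
of any kind nearby is then excluded from FP counting, since absence of an
annotation does not imply absence of the wave.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

from .types import ConfigError, ConsistencyError, Delineation, RHYTHMS

#: The six boundary kinds, in reporting order.
BOUNDARY_KINDS = ("P_onset", "P_offset", "QRS_onset", "QRS_offset", "T_onset", "T_offset")

DEFAULT_TOL_MS = 150.0


@dataclass
class MatchCounts:
    """TP/FP/FN counts plus the signed deviation (ms) of each true positive."""

    tp: int = 0
    fp: int = 0
    fn: int = 0
    deviations: list[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn) < 0:
            raise ConsistencyError("counts must be non-negative")
        if len(self.deviations) != self.tp:
            raise ConsistencyError("need exactly one deviation per true positive")

    def __iadd__(self, other: "MatchCounts") -> "MatchCounts":
        self.tp += other.tp
        self.fp += other.fp
        self.fn += other.fn
        self.deviations.extend(other.deviations)
        return self


def _assign(pred: Sequence[float], truth: Sequence[float], tol_ms: float,
            ) -> list[tuple[int, int, float]]:
    """Optimal one-to-one pairing of boundary times.

    Among all pairings restricted to ``|pred - truth| <= tol_ms`` this
    returns one of maximum cardinality with minimum total absolute
    deviation, as ``(pred_idx, truth_idx, deviation)`` triples.  Solved as a
    rectangular assignment problem with a prohibitive cost on out-of-window
    pairs.
    """
    if not pred or not truth:
        return []
    parr = np.asarray(pred, dtype=float)
    tarr = np.asarray(truth, dtype=float)
    cost = np.abs(parr[:, None] - tarr[None, :])
    allowed = cost <= tol_ms
    if not allowed.any():
        return []
    big = tol_ms * (len(pred) + len(truth) + 1) + 1.0
    rows, cols = linear_sum_assignment(np.where(allowed, cost, big))
    return [
        (int(pi), int(tj), float(parr[pi] - tarr[tj]))
        for pi, tj in zip(rows, cols)
        if allowed[pi, tj]
    ]


def match_boundaries(
    pred: Sequence[float],
    truth: Sequence[float],
    tol_ms: float = DEFAULT_TOL_MS,
    scored_pred: Optional[Sequence[bool]] = None,
) -> MatchCounts:
    """One-to-one matching of predicted against true boundary times (ms).

    A prediction is a true positive when it is paired with a truth point
    within ``tol_ms`` (inclusive); the pairing is one-to-one, maximizes the
    number of matches, and among maximal pairings minimizes the total
    absolute deviation.  ``scored_pred`` optionally marks which predictions
    may count as FP when unmatched (all, by default); matched predictions
    always count as TP.
    """
    pred = list(pred)
    truth = list(truth)
    if any(b < a for a, b in zip(pred, pred[1:])):
        raise ConsistencyError("pred times must be sorted")
    if any(b < a for a, b in zip(truth, truth[1:])):
        raise ConsistencyError("truth times must be sorted")
    if scored_pred is None:
        scored_pred = [True] * len(pred)

    matches = _assign(pred, truth, tol_ms)
    used_p = {pi for pi, _, _ in matches}
    deviations = [dev for _, _, dev in matches]
    fp = sum(1 for pi in range(len(pred)) if pi not in used_p and scored_pred[pi])
    fn = len(truth) - len(matches)
    return MatchCounts(tp=len(matches), fp=fp, fn=fn, deviations=deviations)


@dataclass
class MetricsEntry:
    """Se/PPV/F1 (fractions) and error statistics (ms) for one boundary kind.

    Cells whose denominator is zero are ``None`` ("undefined"), rendered as
    ``-`` in tables.
    """

    se: Optional[float]
    ppv: Optional[float]
    f1: Optional[float]
    m: Optional[float]
    sigma: Optional[float]
    tp: int = 0
    fp: int = 0
    fn: int = 0


def harmonic_f1(se: float, ppv: float) -> float:
    """F1 as the harmonic mean of sensitivity and positive predictivity."""
    if se + ppv == 0:
        return 0.0
    return 2.0 * se * ppv / (se + ppv)


def compute_metrics(counts: MatchCounts) -> MetricsEntry:
    """Se, PPV, F1 and deviation statistics from match counts."""
    se = counts.tp / (counts.tp + counts.fn) if counts.tp + counts.fn else None
    ppv = counts.tp / (counts.tp + counts.fp) if counts.tp + counts.fp else None
    f1 = harmonic_f1(se, ppv) if se is not None and ppv is not None else None
    if counts.deviations:
        m = sum(counts.deviations) / len(counts.deviations)
        sigma = math.sqrt(
            sum((d - m) ** 2 for d in counts.deviations) / len(counts.deviations)
        )
    else:
        m = sigma = None
    return MetricsEntry(se=se, ppv=ppv, f1=f1, m=m, sigma=sigma,
                        tp=counts.tp, fp=counts.fp, fn=counts.fn)


def _kind_times(d: Delineation, kind: str) -> list[float]:
    wave, which = kind.rsplit("_", 1)
    return d.boundary_times_ms(wave, which)


def _all_truth_times(d: Delineation) -> list[float]:
    times = []
    for kind in BOUNDARY_KINDS:
        times.extend(_kind_times(d, kind))
    return sorted(times)


def _truth_has_kind(d: Delineation, kind: str) -> bool:
    wave, which = kind.rsplit("_", 1)
    if which == "onset" and d.partial_flags.get(wave, False):
        return False
    return True


DelinOrLeads = Union[Delineation, Sequence[Delineation]]


def _record_counts(
    pred: DelinOrLeads,
    truth: Delineation,
    kind: str,
    tol_ms: float,
    mode: str,
    beat_window_ms: float,
) -> MatchCounts:
    """Counts for one record and one boundary kind, handling multi-lead input.

    With several predicted leads, each lead is matched independently and,
    per truth point, the lead with the smallest absolute deviation
    contributes (best-lead convention); FP comes from the lead with the
    fewest unmatched predictions.
    """
    leads = [pred] if isinstance(pred, Delineation) else list(pred)
    truth_times = _kind_times(truth, kind)
    anchors = _all_truth_times(truth) if mode == "partial" else None

    per_lead = []
    for lead_pred in leads:
        pred_times = _kind_times(lead_pred, kind)
        scored = None
        if anchors is not None:
            scored = [
                any(abs(p - a) <= beat_window_ms for a in anchors) for p in pred_times
            ]
        per_lead.append(match_boundaries(pred_times, truth_times, tol_ms, scored))
    if len(per_lead) == 1:
        return per_lead[0]

    # best lead per truth point: redo matching keeping per-truth deviations
    best_dev: list[Optional[float]] = [None] * len(truth_times)
    for lead_pred in leads:
        pred_times = _kind_times(lead_pred, kind)
        for _, tj, dev in _assign(pred_times, truth_times, tol_ms):
            if best_dev[tj] is None or abs(dev) < abs(best_dev[tj]):
                best_dev[tj] = dev
    deviations = [d for d in best_dev if d is not None]
    fp = min(c.fp for c in per_lead)
    fn = sum(1 for d in best_dev if d is None)
    return MatchCounts(tp=len(deviations), fp=fp, fn=fn, deviations=deviations)


def evaluate(
    predictions: Mapping[str, DelinOrLeads],
    truths: Mapping[str, Delineation],
    rhythms: Optional[Mapping[str, str]] = None,
    mode: str = "full",
    tol_ms: float = DEFAULT_TOL_MS,
    beat_window_ms: float = 400.0,
) -> dict[str, dict[str, MetricsEntry]]:
    """Pooled per-boundary-kind metrics, overall and per rhythm stratum.

    Returns ``{stratum: {boundary_kind: MetricsEntry}}`` where strata are the
    rhythm labels present plus ``"All"`` (only ``"All"`` when ``rhythms`` is
    None).  Boundary kinds a record's truth dialect does not annotate are
    skipped for that record.
    """
    if mode not in ("full", "partial"):
        raise ConfigError(f"unknown evaluation mode {mode!r}")
    missing = set(predictions) - set(truths)
    if missing:
        raise ConsistencyError(f"predictions without truth: {sorted(missing)}")
    if rhythms is not None:
        unlabeled = set(predictions) - set(rhythms)
        if unlabeled:
            raise ConfigError(f"records without rhythm label: {sorted(unlabeled)}")

    strata: dict[str, dict[str, MatchCounts]] = {"All": {k: MatchCounts() for k in BOUNDARY_KINDS}}
    for rec_id, pred in predictions.items():
        truth = truths[rec_id]
        stratum = rhythms[rec_id] if rhythms is not None else None
        if stratum is not None and stratum not in strata:
            strata[stratum] = {k: MatchCounts() for k in BOUNDARY_KINDS}
        for kind in BOUNDARY_KINDS:
            if not _truth_has_kind(truth, kind):
                continue
            counts = _record_counts(pred, truth, kind, tol_ms, mode, beat_window_ms)
            strata["All"][kind] += counts
            if stratum is not None:
                strata[stratum][kind] += counts

    return {
        stratum: {kind: compute_metrics(counts) for kind, counts in kinds.items()}
        for stratum, kinds in strata.items()
    }


def report_table(results: dict[str, dict[str, MetricsEntry]], metric: str = "f1") -> pd.DataFrame:
    """Render one metric as a rhythm x boundary-kind table (percent for
    rates, ms for errors); undefined cells are NaN and print as ``-``."""
    order = [r for r in RHYTHMS if r in results] + (["All"] if "All" in results else [])
    rows = {}
    for stratum in order:
        row = {}
        for kind in BOUNDARY_KINDS:
            entry = results[stratum][kind]
            value = getattr(entry, metric)
            if value is not None and metric in ("se", "ppv", "f1"):
                value = 100.0 * value
            row[kind] = float("nan") if value is None else value
        rows[stratum] = row
    return pd.DataFrame.from_dict(rows, orient="index", columns=list(BOUNDARY_KINDS))
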