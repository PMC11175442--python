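"""Core domain types for ECG delineation.

An ECG delineation locates the onset and offset (not just the peak) of the
P wave, the QRS complex and the T wave in a voltage trace.  All types here
use 0-based sample indices and *closed* intervals ``[onset, offset]``: both
boundaries are annotated samples, matching fiducial-point annotation
practice.  Voltages are in millivolts throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

#: Per-sample class indices used by label masks and probability maps.
CLASS_NONE, CLASS_P, CLASS_QRS, CLASS_T = 0, 1, 2, 3
CLASS_NAMES = ("none", "P", "QRS", "T")
WAVE_NAMES = ("P", "QRS", "T")

#: Map wave name -> class index.
WAVE_TO_CLASS = {"P": CLASS_P, "QRS": CLASS_QRS, "T": CLASS_T}
CLASS_TO_WAVE = {v: k for k, v in WAVE_TO_CLASS.items()}

#: The rhythm taxonomy the generator and the classifier branch know about.
RHYTHMS = ("NSR", "ST", "BBB", "AVB1", "AFIB", "AFL", "VT")
#: Rhythms in which atrial activity is fibrillatory/flutter, i.e. no P wave.
AF_RHYTHMS = frozenset({"AFIB", "AFL"})
#: Rhythms with no delineated P wave at all (VT has AV dissociation and is
#: generated without labeled P waves).
NO_P_RHYTHMS = frozenset({"AFIB", "AFL", "VT"})


class EcgError(Exception):
    """Base error for this package."""


class InputError(EcgError, ValueError):
    """Invalid input data (non-finite samples, bad sampling rate, ...)."""


class FormatError(EcgError, ValueError):
    """Malformed file content (header, annotation stream, ...)."""


class ConfigError(EcgError, ValueError):
    """Invalid or inconsistent configuration."""


class ConsistencyError(EcgError, ValueError):
    """Mutually inconsistent arguments (length mismatch, overlap, ...)."""


@dataclass
class EcgSignal:
    """A sampled single-lead voltage trace.

    Parameters
    ----------
    samples:
        Voltage samples in mV.
    fs:
        Sampling frequency in Hz, ``> 0``.
    lead:
        Lead label, e.g. ``"I"`` or ``"II"``.
    record_id:
        Identifier of the source record.
    """

    samples: np.ndarray
    fs: float
    lead: str = "I"
    record_id: str = ""

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.ndim != 1 or self.samples.size == 0:
            raise InputError("samples must be a non-empty 1-D array")
        if not np.all(np.isfinite(self.samples)):
            raise InputError("samples contain non-finite values")
        if not (self.fs > 0):
            raise InputError(f"sampling frequency must be positive, got {self.fs}")

    @property
    def n_samples(self) -> int:
        return int(self.samples.size)

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs


@dataclass(frozen=True)
class WaveInterval:
    """A typed closed interval ``[onset, offset]`` in samples.

    ``onset`` may be ``None`` for annotation dialects that omit it for some
    boundary kinds (QTDB omits T onsets); such intervals are *partial* and
    can only be scored on the boundaries they carry.
    """

    wave: str
    onset: Optional[int]
    offset: int

    def __post_init__(self) -> None:
        if self.wave not in WAVE_TO_CLASS:
            raise InputError(f"unknown wave type {self.wave!r}")
        if self.offset < 0:
            raise InputError("offset must be >= 0")
        if self.onset is not None and not (0 <= self.onset <= self.offset):
            raise InputError(
                f"need 0 <= onset <= offset, got [{self.onset}, {self.offset}]"
            )

    @property
    def partial(self) -> bool:
        return self.onset is None

    @property
    def length(self) -> Optional[int]:
        return None if self.onset is None else self.offset - self.onset + 1

    def sort_key(self) -> int:
        return self.offset if self.onset is None else self.onset


@dataclass
class Delineation:
    """An ordered, typed set of wave intervals for one lead of one record.

    ``partial_flags`` marks per-wave that the source annotation dialect omits
    some boundary kind (e.g. ``{"T": True}`` for QTDB, whose T waves carry
    offsets only).
    """

    intervals: list[WaveInterval] = field(default_factory=list)
    fs: float = 500.0
    record_id: str = ""
    lead: str = ""
    partial_flags: dict[str, bool] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.intervals = sorted(self.intervals, key=WaveInterval.sort_key)
        complete = [iv for iv in self.intervals if iv.onset is not None]
        for a, b in zip(complete, complete[1:]):
            if b.onset <= a.offset and not self._any_partial():
                raise ConsistencyError(
                    f"overlapping intervals {a} and {b}; raw annotation files "
                    "may overlap only when flagged partial"
                )

    def _any_partial(self) -> bool:
        return any(self.partial_flags.values())

    def __len__(self) -> int:
        return len(self.intervals)

    def __iter__(self):
        return iter(self.intervals)

    def of_wave(self, wave: str) -> list[WaveInterval]:
        return [iv for iv in self.intervals if iv.wave == wave]

    def boundary_times_ms(self, wave: str, which: str) -> list[float]:
        """Sorted boundary times in ms for one wave kind.

        ``which`` is ``"onset"`` or ``"offset"``; partial intervals without
        the requested boundary are skipped.
        """
        out = []
        for iv in self.of_wave(wave):
            idx = iv.onset if which == "onset" else iv.offset
            if idx is None:
                continue
            out.append(idx * 1000.0 / self.fs)
        return sorted(out)


@dataclass
class LabelMask:
    """Per-sample class labels in {0: none, 1: P, 2: QRS, 3: T}.

    The one-hot encoding of these labels is the training target of the
    segmentation loss.
    """

    labels: np.ndarray
    fs: float = 500.0

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.int8)
        if self.labels.ndim != 1 or self.labels.size == 0:
            raise InputError("labels must be a non-empty 1-D array")
        if self.labels.min() < 0 or self.labels.max() > 3:
            raise InputError("labels must lie in {0, 1, 2, 3}")

    @property
    def n_samples(self) -> int:
        return int(self.labels.size)

    def one_hot(self) -> np.ndarray:
        """(n, 4) one-hot float array."""
        return np.eye(4, dtype=np.float64)[self.labels]


@dataclass
class ClassProbMap:
    """Per-sample probabilities over {none, P, QRS, T} at 500 Hz.

    ``probs`` has shape ``(n_samples, 4)`` with rows summing to one; it is
    the segmentation network's output and post-processing's input.
    """

    probs: np.ndarray
    fs: float = 500.0

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=np.float64)
        if self.probs.ndim != 2 or self.probs.shape[1] != 4:
            raise InputError("probs must have shape (n, 4)")
        if self.probs.min() < -1e-9 or self.probs.max() > 1 + 1e-9:
            raise InputError("probabilities must lie in [0, 1]")
        if not np.allclose(self.probs.sum(axis=1), 1.0, atol=1e-5):
            raise InputError("probability rows must sum to 1")

    @property
    def n_samples(self) -> int:
        return int(self.probs.shape[0])

    @classmethod
    def from_mask(cls, mask: LabelMask) -> "ClassProbMap":
        return cls(mask.one_hot(), fs=mask.fs)


@dataclass
class RhythmProb:
    """Two-way rhythm probability: AFIB-or-AFL vs anything else."""

    p_af: float

    def __post_init__(self) -> None:
        if not (0.0 - 1e-9 <= self.p_af <= 1.0 + 1e-9):
            raise InputError("p_af must lie in [0, 1]")
        self.p_af = float(min(1.0, max(0.0, self.p_af)))

    @property
    def p_other(self) -> float:
        return 1.0 - self.p_af


@dataclass
class SynthRecord:
    """A synthetic record: signal + exact ground truth + rhythm label."""

    signal: EcgSignal
    mask: LabelMask
    truth: Delineation
    rhythm: str

    def __post_init__(self) -> None:
        if self.rhythm not in RHYTHMS:
            raise ConfigError(f"unknown rhythm {self.rhythm!r}")
        if self.mask.n_samples != self.signal.n_samples:
            raise ConsistencyError("mask length must match signal length")

    @property
    def is_af(self) -> bool:
        return self.rhythm in AF_RHYTHMS


def validate_proportions(mix: dict[str, float], tol: float = 1e-9) -> None:
    for key in mix:
        if key not in RHYTHMS:
            raise ConfigError(f"unknown rhythm key {key!r}; valid: {RHYTHMS}")
    total = float(sum(mix.values()))
    if abs(total - 1.0) > tol:
        raise ConfigError(f"class proportions must sum to 1, got {total}")
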