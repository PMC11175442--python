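"""Signal and annotation I/O.

Readers and writers for a minimal subset of the WFDB family of formats
(format-16 ``.hea``/``.dat`` records and the binary annotation format with
``(`` wave ``)`` boundary grouping), CSV/JSON delineation tables, rational
resampling to the 500 Hz working grid, and interval <-> label-mask
conversion.

The WFDB support here is deliberately small: single-segment records, signal
format 16, one annotation stream per file.  It exists so that synthetic
datasets can be written and read in the field's standard container and so
that annotation round-trips are testable; it is not a general PhysioNet
client.
"""

from __future__ import annotations

import csv
import json
import os
import struct
from fractions import Fraction
from typing import Iterable, Optional, Sequence

import numpy as np
from scipy.signal import resample_poly

from .types import (
    CLASS_TO_WAVE,
    WAVE_TO_CLASS,
    ConsistencyError,
    Delineation,
    EcgSignal,
    FormatError,
    InputError,
    LabelMask,
    WaveInterval,
)

TARGET_FS = 500.0

# ---------------------------------------------------------------------------
# Resampling
# ---------------------------------------------------------------------------


def resample_to_500hz(signal: EcgSignal) -> EcgSignal:
    """Resample a signal to the 500 Hz working grid.

    Rational sampling-rate ratios use polyphase FIR resampling; irrational
    ones fall back to linear interpolation.  The mean is removed before
    filtering and restored afterwards so constant signals are exact fixed
    points.  A signal already at 500 Hz is returned unchanged (new object,
    identical samples).
    """
    if not (1.0 <= signal.fs <= 10_000.0):
        raise InputError(f"sampling frequency {signal.fs} outside sane range 1-10000 Hz")
    if signal.fs == TARGET_FS:
        return EcgSignal(signal.samples.copy(), TARGET_FS, signal.lead, signal.record_id)

    n = signal.n_samples
    ratio = Fraction(TARGET_FS / signal.fs).limit_denominator(10_000)
    mean = float(signal.samples.mean())
    centered = signal.samples - mean
    if abs(float(ratio) - TARGET_FS / signal.fs) < 1e-12:
        up, down = ratio.numerator, ratio.denominator
        out = resample_poly(centered, up, down, padtype="line")
    else:  # irrational ratio: linear interpolation on the time axis
        n_out = int(round(n * TARGET_FS / signal.fs))
        t_src = np.arange(n) / signal.fs
        t_dst = np.arange(n_out) / TARGET_FS
        out = np.interp(t_dst, t_src, centered)
    return EcgSignal(out + mean, TARGET_FS, signal.lead, signal.record_id)


# ---------------------------------------------------------------------------
# WFDB records (.hea + .dat, format 16)
# ---------------------------------------------------------------------------


def write_wfdb_record(path: str, signals: Sequence[EcgSignal], gain: float = 200.0) -> None:
    """Write signals as a single-segment WFDB record (format 16).

    ``path`` is the record path without extension.  All signals must share
    sampling rate and length; samples are quantized at ``gain`` adu/mV.
    """
    if not signals:
        raise InputError("need at least one signal")
    fs = signals[0].fs
    n = signals[0].n_samples
    for s in signals:
        if s.fs != fs or s.n_samples != n:
            raise ConsistencyError("all signals must share fs and length")
    record = os.path.basename(path)
    dat_name = record + ".dat"
    adc = np.round(np.stack([s.samples for s in signals], axis=1) * gain)
    adc = np.clip(adc, -32768, 32767).astype("<i2")
    lines = [f"{record} {len(signals)} {fs:g} {n}"]
    for i, s in enumerate(signals):
        checksum = int(adc[:, i].astype(np.int64).sum() % 65536)
        if checksum >= 32768:
            checksum -= 65536
        lines.append(
            f"{dat_name} 16 {gain:g}(0)/mV 16 0 {int(adc[0, i])} {checksum} 0 {s.lead}"
        )
    with open(path + ".hea", "w") as fh:
        fh.write("\n".join(lines) + "\n")
    with open(os.path.join(os.path.dirname(path) or ".", dat_name), "wb") as fh:
        fh.write(adc.reshape(-1).tobytes())


def _parse_gain_field(field: str) -> tuple[float, int]:
    """Parse a WFDB 'gain(baseline)/units' specification."""
    gain_part = field.split("/", 1)[0]
    baseline = 0
    if "(" in gain_part:
        gain_part, rest = gain_part.split("(", 1)
        baseline = int(rest.rstrip(")"))
    gain = float(gain_part) if gain_part else 200.0
    if gain == 0:
        gain = 200.0
    return gain, baseline


def read_wfdb_record(path: str, leads: Optional[Sequence[str]] = None) -> list[EcgSignal]:
    """Read a format-16 WFDB record; returns one EcgSignal per requested lead.

    File units are converted to mV via the per-signal gain/baseline; the
    native sampling rate is kept (resampling is never implicit).
    """
    hea_path = path + ".hea"
    try:
        with open(hea_path) as fh:
            raw_lines = [ln.split("#", 1)[0].strip() for ln in fh]
    except OSError as exc:
        raise FormatError(f"cannot read header {hea_path}: {exc}") from exc
    lines = [ln for ln in raw_lines if ln]
    if not lines:
        raise FormatError(f"empty header {hea_path}")
    head = lines[0].split()
    if len(head) < 4:
        raise FormatError(f"malformed record line in {hea_path}: {lines[0]!r}")
    try:
        record_id, n_sig, fs, n_samples = head[0], int(head[1]), float(head[2]), int(head[3])
    except ValueError as exc:
        raise FormatError(f"malformed record line in {hea_path}: {lines[0]!r}") from exc
    if len(lines) < 1 + n_sig:
        raise FormatError(f"header {hea_path} declares {n_sig} signals but lists fewer")

    sig_specs = []
    for ln in lines[1 : 1 + n_sig]:
        parts = ln.split()
        if len(parts) < 2:
            raise FormatError(f"malformed signal line in {hea_path}: {ln!r}")
        fmt = parts[1].split("x")[0].split(":")[0].split("+")[0]
        if fmt != "16":
            raise FormatError(f"unsupported WFDB signal format {parts[1]!r} (only 16)")
        gain, baseline = _parse_gain_field(parts[2]) if len(parts) > 2 else (200.0, 0)
        desc = parts[8] if len(parts) > 8 else f"sig{len(sig_specs)}"
        sig_specs.append((parts[0], gain, baseline, desc))

    dat_name = sig_specs[0][0]
    dat_path = os.path.join(os.path.dirname(path) or ".", dat_name)
    raw = np.fromfile(dat_path, dtype="<i2")
    if raw.size < n_samples * n_sig:
        raise FormatError(f"{dat_path} holds {raw.size} samples, expected {n_samples * n_sig}")
    frame = raw[: n_samples * n_sig].reshape(n_samples, n_sig)

    by_lead = {spec[3]: i for i, spec in enumerate(sig_specs)}
    wanted = list(leads) if leads is not None else [spec[3] for spec in sig_specs]
    out = []
    for lead in wanted:
        if lead not in by_lead:
            raise LookupError(f"lead {lead!r} not in record (has {sorted(by_lead)})")
        i = by_lead[lead]
        _, gain, baseline, _ = sig_specs[i]
        mv = (frame[:, i].astype(np.float64) - baseline) / gain
        out.append(EcgSignal(mv, fs, lead, record_id))
    return out


# ---------------------------------------------------------------------------
# WFDB annotations (MIT binary format)
# ---------------------------------------------------------------------------

# Annotation codes used for boundary streams.
_WFON, _WFOFF = 39, 40  # '(' and ')'
_PWAVE, _TWAVE, _NORMAL = 24, 27, 1
_SKIP, _NUM, _SUB, _CHN, _AUX = 59, 60, 61, 62, 63

#: Beat codes that open a QRS group (a subset of the WFDB beat table).
_QRS_CODES = {1, 2, 3, 4, 5, 6, 7, 8, 9, 10, 11, 12, 13, 25, 34, 35, 38, 41}

_SYMBOL_TO_CODE = {"(": _WFON, ")": _WFOFF, "p": _PWAVE, "t": _TWAVE, "N": _NORMAL}
_CODE_TO_SYMBOL = {v: k for k, v in _SYMBOL_TO_CODE.items()}


def write_wfdb_annotations(path: str, events: Iterable[tuple[int, str]]) -> None:
    """Write (sample, symbol) events as a binary WFDB annotation file.

    Symbols are from ``{'(', ')', 'p', 't', 'N'}``.  Events must be sorted by
    sample index.
    """
    buf = bytearray()
    prev = 0
    for sample, symbol in events:
        code = _SYMBOL_TO_CODE.get(symbol)
        if code is None:
            raise InputError(f"unsupported annotation symbol {symbol!r}")
        delta = sample - prev
        if delta < 0:
            raise InputError("events must be sorted by sample index")
        if delta >= 1024:
            # SKIP pseudo-annotation: 4-byte interval as two LE words, high first
            buf += struct.pack("<H", _SKIP << 10)
            buf += struct.pack("<HH", (delta >> 16) & 0xFFFF, delta & 0xFFFF)
            delta = 0
        buf += struct.pack("<H", (code << 10) | delta)
        prev = sample
    buf += struct.pack("<H", 0)  # end of stream
    with open(path, "wb") as fh:
        fh.write(buf)


def read_wfdb_annotation_events(path: str) -> list[tuple[int, int]]:
    """Decode a binary WFDB annotation file into (sample, code) events."""
    with open(path, "rb") as fh:
        data = fh.read()
    events: list[tuple[int, int]] = []
    t = 0
    i = 0
    pending_skip = 0
    while i + 1 < len(data) or (i + 1 == len(data) + 1):
        if i + 2 > len(data):
            break
        (word,) = struct.unpack_from("<H", data, i)
        i += 2
        code = word >> 10
        interval = word & 0x3FF
        if code == 0 and interval == 0:
            break
        if code == _SKIP:
            if i + 4 > len(data):
                raise FormatError(f"truncated SKIP at byte {i} in {path}")
            hi, lo = struct.unpack_from("<HH", data, i)
            i += 4
            value = (hi << 16) | lo
            if value & 0x80000000:
                value -= 1 << 32
            pending_skip += value
            continue
        if code == _AUX:
            i += interval + (interval & 1)
            continue
        if code in (_NUM, _SUB, _CHN):
            continue
        t += interval + pending_skip
        pending_skip = 0
        events.append((t, code))
    return events


def _code_to_wave(code: int) -> Optional[str]:
    if code == _PWAVE:
        return "P"
    if code == _TWAVE:
        return "T"
    if code in _QRS_CODES:
        return "QRS"
    return None


def read_boundary_annotations(
    path: str,
    dialect: str = "ludb",
    fs: float = TARGET_FS,
    record_id: str = "",
    lead: str = "",
) -> Delineation:
    """Parse a boundary annotation stream into a Delineation.

    The stream uses ``(`` wave-symbol ``)`` grouping, where the wave symbol is
    ``p``, ``t`` or a beat code (QRS).  Two dialects are understood:

    - ``"ludb"``: complete per-lead P/QRS/T on- and offsets; every group must
      be fully parenthesized.
    - ``"qtdb"``: T waves may carry an offset only (symbol + ``)`` without a
      preceding ``(``); such intervals are returned with ``onset=None`` and
      the T partial flag set.

    Sample indices are converted from the record's native ``fs`` to the
    500 Hz working grid.
    """
    if dialect not in ("ludb", "qtdb"):
        raise FormatError(f"unknown annotation dialect {dialect!r}")
    events = read_wfdb_annotation_events(path)

    def to500(sample: int) -> int:
        return int(round(sample * TARGET_FS / fs))

    intervals: list[WaveInterval] = []
    open_sample: Optional[int] = None
    wave: Optional[str] = None
    partial_t = False
    for pos, (sample, code) in enumerate(events):
        if code == _WFON:
            if open_sample is not None:
                raise FormatError(f"'(' inside an open group at event {pos} in {path}")
            open_sample = sample
            wave = None
        elif code == _WFOFF:
            if open_sample is None:
                if dialect == "qtdb" and wave == "T":
                    # T offset with no onset: partial interval (QTDB convention)
                    intervals.append(WaveInterval("T", None, to500(sample)))
                    partial_t = True
                    wave = None
                    continue
                raise FormatError(f"')' before '(' at event {pos} in {path}")
            if wave is None:
                raise FormatError(f"group without wave symbol closed at event {pos} in {path}")
            onset, offset = to500(open_sample), to500(sample)
            if offset < onset:
                raise FormatError(f"offset precedes onset at event {pos} in {path}")
            intervals.append(WaveInterval(wave, onset, offset))
            open_sample = None
            wave = None
        else:
            w = _code_to_wave(code)
            if w is None:
                continue  # peak/other annotations are ignored
            wave = w
    if open_sample is not None:
        raise FormatError(f"unmatched '(' at end of {path}")
    flags = {"T": True} if partial_t else {}
    return Delineation(intervals, fs=TARGET_FS, record_id=record_id, lead=lead, partial_flags=flags)


def write_boundary_annotations(path: str, d: Delineation) -> None:
    """Write a Delineation as a binary WFDB annotation stream (LUDB style).

    Partial intervals (missing onset) emit only the wave symbol and ``)``.
    """
    events: list[tuple[int, str]] = []
    symbol = {"P": "p", "QRS": "N", "T": "t"}
    for iv in d.intervals:
        if iv.onset is not None:
            mid = (iv.onset + iv.offset) // 2
            events.append((iv.onset, "("))
            events.append((mid, symbol[iv.wave]))
            events.append((iv.offset, ")"))
        else:
            events.append((max(iv.offset - 1, 0), symbol[iv.wave]))
            events.append((iv.offset, ")"))
    events.sort(key=lambda e: e[0])
    write_wfdb_annotations(path, events)


# ---------------------------------------------------------------------------
# Delineation tables (CSV / JSON)
# ---------------------------------------------------------------------------

_COLUMNS = ("record_id", "lead", "wave", "onset_sample", "offset_sample", "onset_s", "offset_s")


def write_delineation(d: Delineation, path: str, format: str = "csv") -> None:
    """Write a delineation as a CSV or JSON table (one row per interval)."""
    rows = []
    for iv in d.intervals:
        rows.append(
            {
                "record_id": d.record_id,
                "lead": d.lead,
                "wave": iv.wave,
                "onset_sample": "" if iv.onset is None else iv.onset,
                "offset_sample": iv.offset,
                "onset_s": "" if iv.onset is None else round(iv.onset / d.fs, 6),
                "offset_s": round(iv.offset / d.fs, 6),
            }
        )
    if format == "csv":
        with open(path, "w", newline="") as fh:
            writer = csv.DictWriter(fh, fieldnames=_COLUMNS)
            writer.writeheader()
            writer.writerows(rows)
    elif format == "json":
        payload = {
            "record_id": d.record_id,
            "lead": d.lead,
            "fs": d.fs,
            "partial_flags": d.partial_flags,
            "intervals": rows,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)
    else:
        raise InputError(f"unknown delineation format {format!r}")


def read_delineation(path: str, format: str = "csv", fs: float = TARGET_FS) -> Delineation:
    """Read back a delineation table written by :func:`write_delineation`."""
    if format == "csv":
        with open(path, newline="") as fh:
            rows = list(csv.DictReader(fh))
        record_id = rows[0]["record_id"] if rows else ""
        lead = rows[0]["lead"] if rows else ""
        flags: dict[str, bool] = {}
    elif format == "json":
        with open(path) as fh:
            payload = json.load(fh)
        rows = payload["intervals"]
        record_id, lead = payload["record_id"], payload["lead"]
        fs = payload.get("fs", fs)
        flags = {k: bool(v) for k, v in payload.get("partial_flags", {}).items()}
    else:
        raise InputError(f"unknown delineation format {format!r}")
    intervals = []
    for row in rows:
        onset_field = row["onset_sample"]
        onset = None if onset_field in ("", None) else int(onset_field)
        intervals.append(WaveInterval(row["wave"], onset, int(row["offset_sample"])))
        if onset is None:
            flags[row["wave"]] = True
    return Delineation(intervals, fs=fs, record_id=record_id, lead=lead, partial_flags=flags)


# ---------------------------------------------------------------------------
# Interval <-> mask conversion
# ---------------------------------------------------------------------------


def intervals_to_mask(d: Delineation, n_samples: int) -> LabelMask:
    """Rasterize complete intervals onto a per-sample label array.

    Samples inside each closed ``[onset, offset]`` get the wave's class
    index; everything else is class ``none``.  Intervals must be complete,
    in range, and pairwise non-overlapping.
    """
    labels = np.zeros(n_samples, dtype=np.int8)
    for iv in d.intervals:
        if iv.onset is None:
            raise ConsistencyError("cannot rasterize a partial interval (onset unknown)")
        if iv.onset < 0 or iv.offset >= n_samples:
            raise ConsistencyError(f"interval {iv} outside [0, {n_samples})")
        region = labels[iv.onset : iv.offset + 1]
        if np.any(region != 0):
            raise ConsistencyError(f"interval {iv} overlaps a previous interval")
        region[:] = WAVE_TO_CLASS[iv.wave]
    return LabelMask(labels, fs=d.fs)


def mask_to_delineation(mask: LabelMask, record_id: str = "", lead: str = "") -> Delineation:
    """Extract wave intervals from a label mask (inverse of rasterization)."""
    labels = mask.labels
    intervals = []
    boundaries = np.flatnonzero(np.diff(labels)) + 1
    starts = np.concatenate(([0], boundaries))
    ends = np.concatenate((boundaries - 1, [labels.size - 1]))
    for s, e in zip(starts, ends):
        cls = int(labels[s])
        if cls != 0:
            intervals.append(WaveInterval(CLASS_TO_WAVE[cls], int(s), int(e)))
    return Delineation(intervals, fs=mask.fs, record_id=record_id, lead=lead)
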