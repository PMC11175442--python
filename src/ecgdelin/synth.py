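"""Synthetic arrhythmia ECG generator with exact boundary ground truth.

Records are built from parametric beat templates placed on an RR schedule:
a Gaussian P bump, a piecewise-linear Q-R-S deflection and a skewed-Gaussian
T wave, each confined to its labelled interval.  Seven rhythm classes are
supported, separated by the features a delineator must cope with:

==========  =============================================================
NSR         regular rhythm, 60-100 bpm, normal PR and QRS
ST          sinus tachycardia, >= 100 bpm
BBB         bundle branch block: wide QRS (>= 120 ms)
AVB1        first-degree AV block: prolonged PR (>= 200 ms)
AFIB        irregular RR, no P waves, band-limited 4-9 Hz fibrillatory
            baseline (unlabelled)
AFL         no P waves, 4-5 Hz sawtooth flutter wave (unlabelled), fixed
            2:1 or 4:1 conduction
VT          ventricular tachycardia: fast (120-220 bpm), wide QRS, no P
==========  =============================================================

Each record carries a label mask and an interval list that are exactly
consistent with the template placement, so segmentation, post-processing
and metrics can be exercised end-to-end without external data.  Parameter
ranges are conventional clinical values; only the class-separating
constraints above matter for testing.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Union

import numpy as np
from scipy.signal import sawtooth

from .io import intervals_to_mask
from .types import (
    ConfigError,
    Delineation,
    EcgSignal,
    NO_P_RHYTHMS,
    RHYTHMS,
    SynthRecord,
    WaveInterval,
    validate_proportions,
)

Range = tuple[float, float]

#: Shortest wave interval the generator will emit (so that exact ground
#: truth survives the 40 ms post-processing rule unchanged).
MIN_WAVE_MS = 40.0
_ST_GAP_RANGE = (40.0, 100.0)  # gap between QRS offset and T onset (ms)
_ST_GAP_FLOOR = 20.0
_T_DUR_FLOOR = 60.0


@dataclass(frozen=True)
class BeatParams:
    """Per-beat timing/morphology parameters, durations in ms, amplitudes mV.

    ``pr`` and ``p_dur`` are ``None`` for rhythms without P waves
    (AFIB/AFL/VT).  ``qt`` is QRS onset to T offset.
    """

    rr: float
    pr: Optional[float]
    p_dur: Optional[float]
    qrs_dur: float
    t_dur: float
    st_gap: float
    p_amp: float
    r_amp: float
    t_amp: float

    def __post_init__(self) -> None:
        if min(self.qrs_dur, self.t_dur, self.rr) <= 0:
            raise ConfigError("durations must be positive")
        if (self.pr is None) != (self.p_dur is None):
            raise ConfigError("pr and p_dur must be both present or both absent")
        if self.pr is not None and self.pr < self.p_dur:
            raise ConfigError("PR interval cannot be shorter than the P duration")
        p = self.p_dur or 0.0
        if p + self.qrs_dur + self.t_dur >= self.rr:
            raise ConfigError("waves do not fit inside the RR interval")

    @property
    def qt(self) -> float:
        return self.qrs_dur + self.st_gap + self.t_dur


@dataclass
class RhythmSpec:
    """Parameter ranges for one rhythm class (all ms / bpm / mV ranges)."""

    rhythm: str
    hr_bpm: Range
    pr_ms: Optional[Range]
    p_dur_ms: Optional[Range]
    qrs_dur_ms: Range
    t_dur_ms: Range
    p_amp_mv: Range = (0.05, 0.2)
    r_amp_mv: Range = (0.5, 2.0)
    t_amp_mv: Range = (0.1, 0.5)
    rr_jitter_sigma: float = 0.0  # lognormal sigma on per-beat RR
    fib_amp_mv: Optional[Range] = None  # fibrillatory baseline (AFIB)
    flutter_amp_mv: Optional[Range] = None  # sawtooth flutter wave (AFL)
    flutter_hz: Range = (4.0, 5.0)
    flutter_conduction: tuple[int, ...] = (2, 4)

    def __post_init__(self) -> None:
        if self.rhythm not in RHYTHMS:
            raise ConfigError(f"unknown rhythm {self.rhythm!r}")
        for name in ("hr_bpm", "pr_ms", "p_dur_ms", "qrs_dur_ms", "t_dur_ms",
                     "p_amp_mv", "r_amp_mv", "t_amp_mv", "fib_amp_mv",
                     "flutter_amp_mv", "flutter_hz"):
            rng = getattr(self, name)
            if rng is not None and not (rng[0] <= rng[1]):
                raise ConfigError(f"range {name} must satisfy min <= max, got {rng}")
        has_p = self.rhythm not in NO_P_RHYTHMS
        if has_p and (self.pr_ms is None or self.p_dur_ms is None):
            raise ConfigError(f"{self.rhythm} requires PR and P-duration ranges")
        if not has_p and (self.pr_ms is not None or self.p_dur_ms is not None):
            raise ConfigError(f"{self.rhythm} must not carry P parameters")
        if has_p and self.pr_ms[0] < self.p_dur_ms[0]:
            raise ConfigError("PR range extends below the minimum P duration")


def default_specs() -> dict[str, RhythmSpec]:
    """The built-in rhythm specifications (fresh copies)."""
    return {
        "NSR": RhythmSpec("NSR", (60, 100), (120, 200), (80, 110), (80, 110), (120, 200)),
        "ST": RhythmSpec("ST", (100, 180), (100, 160), (80, 100), (80, 110), (120, 200)),
        "BBB": RhythmSpec("BBB", (60, 100), (120, 200), (80, 110), (120, 160), (120, 200)),
        "AVB1": RhythmSpec("AVB1", (60, 100), (200, 320), (80, 110), (80, 110), (120, 200)),
        "AFIB": RhythmSpec(
            "AFIB", (70, 150), None, None, (80, 110), (120, 200),
            rr_jitter_sigma=0.2, fib_amp_mv=(0.02, 0.08),
        ),
        "AFL": RhythmSpec(
            "AFL", (60, 150), None, None, (80, 110), (120, 200),
            flutter_amp_mv=(0.1, 0.2),
        ),
        "VT": RhythmSpec("VT", (120, 220), None, None, (120, 160), (100, 200),
                         r_amp_mv=(0.8, 2.0)),
    }


def _as_rng(seed: Union[int, np.random.Generator]) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


def _uniform(rng: np.random.Generator, r: Range) -> float:
    return float(rng.uniform(r[0], r[1]))


def sample_beat_params(spec: RhythmSpec, rng_seed: Union[int, np.random.Generator]) -> BeatParams:
    """Draw beat parameters uniformly from the spec's ranges.

    Class constraints (AVB1 PR >= 200 ms, BBB/VT QRS >= 120 ms, ST HR >=
    100 bpm, no P parameters for AFIB/AFL/VT) are enforced by the ranges
    themselves.  The T duration and ST-segment gap are clamped to the space
    the RR interval actually offers at fast rates.
    """
    rng = _as_rng(rng_seed)
    hr = _uniform(rng, spec.hr_bpm)
    rr = 60_000.0 / hr
    has_p = spec.rhythm not in NO_P_RHYTHMS
    pr = _uniform(rng, spec.pr_ms) if has_p else None
    p_dur = _uniform(rng, spec.p_dur_ms) if has_p else None
    if pr is not None and p_dur is not None and pr < p_dur:
        p_dur = pr  # PR measured onset-to-onset can never undercut the P width
    qrs = _uniform(rng, spec.qrs_dur_ms)
    st_gap = _uniform(rng, _ST_GAP_RANGE)
    t_dur = _uniform(rng, spec.t_dur_ms)

    # Fit the T wave into the cycle: QRS + ST gap + T (+ next PR) < RR.
    reserve = (pr if pr is not None else 0.0) + 10.0
    budget = rr - qrs - st_gap - reserve
    if budget < _T_DUR_FLOOR:
        st_gap = _ST_GAP_FLOOR
        budget = rr - qrs - st_gap - reserve
    if budget < MIN_WAVE_MS:
        raise ConfigError(
            f"infeasible ranges for {spec.rhythm}: no room for a T wave at {hr:.0f} bpm"
        )
    t_dur = float(min(t_dur, budget))
    return BeatParams(
        rr=rr, pr=pr, p_dur=p_dur, qrs_dur=qrs, t_dur=t_dur, st_gap=st_gap,
        p_amp=_uniform(rng, spec.p_amp_mv),
        r_amp=_uniform(rng, spec.r_amp_mv),
        t_amp=_uniform(rng, spec.t_amp_mv),
    )


# ---------------------------------------------------------------------------
# Wave templates (each confined to its labelled interval)
# ---------------------------------------------------------------------------


def _p_template(n: int, amp: float) -> np.ndarray:
    x = np.arange(n)
    center, sigma = (n - 1) / 2.0, max(n / 5.0, 1.0)
    bump = np.exp(-0.5 * ((x - center) / sigma) ** 2)
    return amp * (bump - bump[0])  # starts/ends at ~0


def _qrs_template(n: int, amp: float) -> np.ndarray:
    # piecewise-linear Q-R-S deflection
    knots_x = np.array([0.0, 0.12, 0.38, 0.52, 0.75, 1.0]) * (n - 1)
    knots_y = np.array([0.0, -0.15, 1.0, -0.25, -0.05, 0.0]) * amp
    return np.interp(np.arange(n), knots_x, knots_y)


def _t_template(n: int, amp: float) -> np.ndarray:
    # skewed bump: slower upstroke, faster downstroke
    x = np.arange(n)
    peak = 0.6 * (n - 1)
    sig_up, sig_down = max(peak / 2.2, 1.0), max((n - 1 - peak) / 2.2, 1.0)
    bump = np.where(
        x <= peak,
        np.exp(-0.5 * ((x - peak) / sig_up) ** 2),
        np.exp(-0.5 * ((x - peak) / sig_down) ** 2),
    )
    return amp * (bump - min(bump[0], bump[-1]))


_TEMPLATES = {"P": _p_template, "QRS": _qrs_template, "T": _t_template}


def _ms_to_samples(ms: float, fs: float) -> int:
    return max(int(round(ms * fs / 1000.0)), 1)


def synthesize_record(
    spec: RhythmSpec,
    duration_s: float = 10.0,
    fs: float = 500.0,
    rng_seed: Union[int, np.random.Generator] = 0,
    record_id: str = "",
    lead: str = "II",
) -> SynthRecord:
    """Generate one labelled record for the given rhythm.

    Beat templates are placed on a regular RR schedule (lognormal-jittered
    for AFIB); AFIB adds an unlabelled fibrillatory baseline and AFL an
    unlabelled sawtooth flutter wave.  Beats truncated at the record edges
    keep their waveform in the signal, but only waves lying fully inside
    the record (with their beat's QRS) enter the ground truth.
    """
    if duration_s <= 0:
        raise ConfigError("duration must be positive")
    if fs not in (250.0, 500.0, 250, 500):
        raise ConfigError(f"fs must be 250 or 500 Hz, got {fs}")
    rng = _as_rng(rng_seed)
    params = sample_beat_params(spec, rng)
    n = int(round(duration_s * fs))
    if duration_s * 1000.0 < params.rr:
        raise ConfigError("duration shorter than one beat")

    # --- RR schedule (QRS onset times, ms) --------------------------------
    flutter_hz = _uniform(rng, spec.flutter_hz)
    conduction = int(rng.choice(spec.flutter_conduction)) if spec.rhythm == "AFL" else 1
    if spec.rhythm == "AFL":
        base_rr = conduction * 1000.0 / flutter_hz  # ventricular RR locked to flutter
    else:
        base_rr = params.rr
    onsets_ms: list[float] = []
    t = _uniform(rng, (0.0, base_rr))
    while t < duration_s * 1000.0 + base_rr:
        onsets_ms.append(t)
        if spec.rr_jitter_sigma > 0:
            t += base_rr * float(rng.lognormal(0.0, spec.rr_jitter_sigma))
        else:
            t += base_rr
        t = t if len(onsets_ms) < 10_000 else float("inf")

    # --- intervals ---------------------------------------------------------
    has_p = spec.rhythm not in NO_P_RHYTHMS
    qrs_len = _ms_to_samples(params.qrs_dur, fs)
    p_len = _ms_to_samples(params.p_dur, fs) if has_p else 0
    min_len = _ms_to_samples(MIN_WAVE_MS, fs)
    # (wave, onset, offset, labelled): coordinates may run off the record.
    # Only waves lying fully inside the record, and whose beat's QRS does
    # too, are labelled: edge-truncated deflections stay in the signal as
    # unlabelled background, which keeps the class-duration constraints
    # (wide QRS, prolonged PR) and QRS-anchored wave selection exact.
    proto: list[tuple[str, int, int, bool]] = []

    def inside(a: int, b: int) -> bool:
        return a >= 0 and b <= n - 1

    for k, q_ms in enumerate(onsets_ms):
        q_on = int(round(q_ms * fs / 1000.0))
        q_off = q_on + qrs_len - 1
        qrs_kept = inside(q_on, q_off)
        proto.append(("QRS", q_on, q_off, qrs_kept))
        if has_p:
            p_on = q_on - _ms_to_samples(params.pr, fs)
            proto.append(("P", p_on, p_on + p_len - 1,
                          qrs_kept and inside(p_on, p_on + p_len - 1)))
        # T wave: clamp into the current RR gap
        next_q = onsets_ms[k + 1] if k + 1 < len(onsets_ms) else q_ms + base_rr
        gap_budget = (next_q - q_ms) - params.qrs_dur - params.st_gap - (
            params.pr + 10.0 if has_p else 10.0
        )
        t_dur = min(params.t_dur, gap_budget)
        if t_dur >= MIN_WAVE_MS:
            t_on = q_on + qrs_len + _ms_to_samples(params.st_gap, fs)
            t_off = t_on + _ms_to_samples(t_dur, fs) - 1
            proto.append(("T", t_on, t_off, qrs_kept and inside(t_on, t_off)))

    # --- signal from templates (before clipping, so edge beats look real) --
    signal = np.zeros(n)
    amp = {"P": params.p_amp, "QRS": params.r_amp, "T": params.t_amp}
    intervals: list[WaveInterval] = []
    for wave, onset, offset, labelled in proto:
        length = offset - onset + 1
        template = _TEMPLATES[wave](length, amp[wave])
        lo, hi = max(onset, 0), min(offset, n - 1)
        if lo > hi:
            continue
        signal[lo : hi + 1] += template[lo - onset : hi - onset + 1]
        if labelled and hi - lo + 1 >= min_len:
            intervals.append(WaveInterval(wave, lo, hi))

    # --- unlabelled atrial background -------------------------------------
    tt = np.arange(n) / fs
    if spec.fib_amp_mv is not None:
        target_sd = _uniform(rng, spec.fib_amp_mv)
        waves = np.zeros(n)
        for _ in range(20):
            f = _uniform(rng, (4.0, 9.0))
            phi = _uniform(rng, (0.0, 2.0 * math.pi))
            waves += np.cos(2.0 * math.pi * f * tt + phi)
        sd = float(waves.std()) or 1.0
        signal += waves * (target_sd / sd)
    if spec.flutter_amp_mv is not None:
        f_amp = _uniform(rng, spec.flutter_amp_mv)
        phi = _uniform(rng, (0.0, 2.0 * math.pi))
        signal += f_amp * sawtooth(2.0 * math.pi * flutter_hz * tt + phi)

    truth = Delineation(intervals, fs=fs, record_id=record_id, lead=lead)
    mask = intervals_to_mask(truth, n)
    return SynthRecord(
        signal=EcgSignal(signal, fs, lead, record_id),
        mask=mask,
        truth=truth,
        rhythm=spec.rhythm,
    )


def generate_dataset(
    n_records: int,
    class_mix: dict[str, float],
    duration_s: float = 10.0,
    fs: float = 500.0,
    seed: int = 0,
    specs: Optional[dict[str, RhythmSpec]] = None,
) -> tuple[list[SynthRecord], dict]:
    """Generate a dataset with class counts matching the mix to rounding.

    Counts use largest-remainder apportionment; record order is a seeded
    shuffle.  The returned manifest (seed, per-record rhythm and seed) makes
    the dataset fully reproducible.
    """
    validate_proportions(class_mix)
    if n_records <= 0:
        raise ConfigError("n_records must be positive")
    specs = specs or default_specs()
    items = sorted(class_mix.items())
    exact = [n_records * p for _, p in items]
    counts = [int(math.floor(e)) for e in exact]
    remainder = n_records - sum(counts)
    by_frac = sorted(range(len(items)), key=lambda i: (-(exact[i] - counts[i]), i))
    for i in by_frac[:remainder]:
        counts[i] += 1

    rhythm_list: list[str] = []
    for (rhythm, _), c in zip(items, counts):
        rhythm_list.extend([rhythm] * c)
    rng = np.random.default_rng(seed)
    rng.shuffle(rhythm_list)
    record_seeds = rng.integers(0, 2**31 - 1, size=n_records)

    records = []
    manifest_records = []
    for i, (rhythm, rec_seed) in enumerate(zip(rhythm_list, record_seeds)):
        rec_id = f"synth{i:04d}"
        rec = synthesize_record(
            specs[rhythm], duration_s, fs, int(rec_seed), record_id=rec_id
        )
        records.append(rec)
        manifest_records.append(
            {"record_id": rec_id, "rhythm": rhythm, "seed": int(rec_seed), "is_af": rec.is_af}
        )
    manifest = {
        "seed": int(seed),
        "n_records": int(n_records),
        "duration_s": float(duration_s),
        "fs": float(fs),
        "class_mix": dict(class_mix),
        "records": manifest_records,
    }
    return records, manifest
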