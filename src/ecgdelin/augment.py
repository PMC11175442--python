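"""Training-time augmentation: physiological-noise and geometry transforms.

Five transforms are implemented:

- *baseline wander*: a sum of 50 cosines at k * 0.01 Hz (k = 1..50) with
  amplitudes a_k ~ U[0, 1) and phases phi_k ~ U[0, 2 pi), confining its
  power to <= 0.5 Hz;
- *powerline noise*: a sum of 3 cosines at the mains frequency 50 Hz and
  its harmonics 100 and 150 Hz.  The three harmonics share a single random
  phase phi_1 by default (``powerline_independent_phases`` switches to one
  phase per harmonic);
- *random resize*: time-axis rescaling by exp(alpha), alpha ~ U[log 0.5,
  log 2]; the signal is linearly interpolated, the label mask is resized
  nearest-neighbour so labels stay crisp;
- *Gaussian noise* with sd 0.01 mV;
- *constant baseline shift*, offset ~ N(0, 0.1 mV).

Only resize touches the label mask.  All draws are deterministic given the
generator passed in.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Union

import numpy as np

from .types import ConfigError, EcgSignal, InputError, LabelMask, SynthRecord
from .io import mask_to_delineation


@dataclass
class AugmentConfig:
    delta_f_hz: float = 0.01
    mains_hz: float = 50.0
    n_blw_harmonics: int = 50
    n_pln_harmonics: int = 3
    gaussian_sd_mv: float = 0.01
    resize_log_range: tuple[float, float] = (math.log(0.5), math.log(2.0))
    baseline_shift_sd_mv: float = 0.1
    powerline_amp_scale: float = 0.02  # mV scale applied to the U[0,1) amplitudes
    baseline_wander_amp_scale: float = 0.05
    powerline_independent_phases: bool = False
    p_baseline_wander: float = 0.5
    p_powerline: float = 0.5
    p_resize: float = 0.5
    p_gaussian: float = 0.5
    p_baseline_shift: float = 0.5

    def __post_init__(self) -> None:
        if min(self.delta_f_hz, self.mains_hz, self.gaussian_sd_mv,
               self.baseline_shift_sd_mv) <= 0:
            raise ConfigError("scales and frequencies must be positive")
        if self.n_blw_harmonics <= 0 or self.n_pln_harmonics <= 0:
            raise ConfigError("harmonic counts must be positive")
        if not self.resize_log_range[0] <= self.resize_log_range[1]:
            raise ConfigError("resize_log_range must be ordered")
        for p in (self.p_baseline_wander, self.p_powerline, self.p_resize,
                  self.p_gaussian, self.p_baseline_shift):
            if not 0.0 <= p <= 1.0:
                raise ConfigError("application probabilities must lie in [0, 1]")


def _as_rng(seed: Union[int, np.random.Generator]) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


def baseline_wander(
    n_samples: int,
    fs: float,
    rng_seed: Union[int, np.random.Generator] = 0,
    coeffs: Optional[tuple[np.ndarray, np.ndarray]] = None,
    n_harmonics: int = 50,
    delta_f_hz: float = 0.01,
) -> np.ndarray:
    """Sum of ``n_harmonics`` cosines at k * delta_f Hz (unit-scale output).

    ``coeffs``, if given, is an explicit ``(a_k, phi_k)`` pair of length
    ``n_harmonics``; otherwise a_k ~ U[0, 1), phi_k ~ U[0, 2 pi).
    """
    if n_samples <= 0:
        raise InputError("n_samples must be positive")
    if coeffs is None:
        rng = _as_rng(rng_seed)
        a = rng.uniform(0.0, 1.0, n_harmonics)
        phi = rng.uniform(0.0, 2.0 * math.pi, n_harmonics)
    else:
        a, phi = (np.asarray(c, dtype=float) for c in coeffs)
        if a.shape != (n_harmonics,) or phi.shape != (n_harmonics,):
            raise InputError(f"coeffs must be two arrays of length {n_harmonics}")
    t = np.arange(n_samples) / fs
    k = np.arange(1, n_harmonics + 1)
    return (a[:, None] * np.cos(2.0 * math.pi * t[None, :] * (k * delta_f_hz)[:, None]
                                + phi[:, None])).sum(axis=0)


def powerline_noise(
    n_samples: int,
    fs: float,
    rng_seed: Union[int, np.random.Generator] = 0,
    coeffs: Optional[tuple[np.ndarray, np.ndarray]] = None,
    mains_hz: float = 50.0,
    n_harmonics: int = 3,
    independent_phases: bool = False,
) -> np.ndarray:
    """Sum of cosines at the mains frequency and its harmonics.

    By default all harmonics share the first phase.  Requires
    ``fs > 2 * n_harmonics * mains_hz`` so the highest harmonic is below
    Nyquist.
    """
    if n_samples <= 0:
        raise InputError("n_samples must be positive")
    if fs <= 2.0 * n_harmonics * mains_hz:
        raise ConfigError(
            f"fs={fs} aliases the {n_harmonics * mains_hz:g} Hz harmonic; need fs > "
            f"{2 * n_harmonics * mains_hz:g}"
        )
    if coeffs is None:
        rng = _as_rng(rng_seed)
        a = rng.uniform(0.0, 1.0, n_harmonics)
        phi = rng.uniform(0.0, 2.0 * math.pi, n_harmonics)
    else:
        a, phi = (np.asarray(c, dtype=float) for c in coeffs)
    if not independent_phases:
        phi = np.full(n_harmonics, phi[0])
    t = np.arange(n_samples) / fs
    k = np.arange(1, n_harmonics + 1)
    return (a[:, None] * np.cos(2.0 * math.pi * t[None, :] * (k * mains_hz)[:, None]
                                + phi[:, None])).sum(axis=0)


def resize_signal(samples: np.ndarray, factor: float) -> np.ndarray:
    """Linear-interpolation time rescaling of a 1-D signal."""
    n = samples.size
    n_out = max(int(round(n * factor)), 1)
    if n_out == n:
        return samples.copy()
    src = np.arange(n)
    dst = np.linspace(0, n - 1, n_out)
    return np.interp(dst, src, samples)


def resize_mask(labels: np.ndarray, factor: float) -> np.ndarray:
    """Nearest-neighbour time rescaling of a label array (labels stay crisp)."""
    n = labels.size
    n_out = max(int(round(n * factor)), 1)
    if n_out == n:
        return labels.copy()
    idx = np.clip(np.round(np.linspace(0, n - 1, n_out)).astype(int), 0, n - 1)
    return labels[idx]


def random_resize(
    record: SynthRecord,
    rng_seed: Union[int, np.random.Generator] = 0,
    alpha: Optional[float] = None,
    log_range: tuple[float, float] = (math.log(0.5), math.log(2.0)),
) -> SynthRecord:
    """Rescale the time axis of signal and mask by a common factor exp(alpha)."""
    rng = _as_rng(rng_seed)
    if alpha is None:
        alpha = float(rng.uniform(log_range[0], log_range[1]))
    elif not (log_range[0] - 1e-12 <= alpha <= log_range[1] + 1e-12):
        raise InputError(f"alpha {alpha} outside [{log_range[0]}, {log_range[1]}]")
    factor = math.exp(alpha)
    sig = record.signal
    new_samples = resize_signal(sig.samples, factor)
    new_labels = resize_mask(record.mask.labels, factor)
    mask = LabelMask(new_labels, fs=record.mask.fs)
    truth = mask_to_delineation(mask, record_id=record.truth.record_id, lead=record.truth.lead)
    return SynthRecord(
        signal=EcgSignal(new_samples, sig.fs, sig.lead, sig.record_id),
        mask=mask,
        truth=truth,
        rhythm=record.rhythm,
    )


def apply_augmentations(
    record: SynthRecord,
    config: Optional[AugmentConfig] = None,
    rng_seed: Union[int, np.random.Generator] = 0,
) -> SynthRecord:
    """Apply the five transforms, each with its configured probability.

    Resize (the only mask-affecting transform) is applied first so the
    additive noise standard deviations are not rescaled.
    """
    config = config or AugmentConfig()
    rng = _as_rng(rng_seed)

    out = record
    if rng.uniform() < config.p_resize:
        out = random_resize(out, rng, log_range=config.resize_log_range)
    samples = out.signal.samples.copy()
    n, fs = samples.size, out.signal.fs
    if rng.uniform() < config.p_baseline_wander:
        samples += config.baseline_wander_amp_scale * baseline_wander(
            n, fs, rng, n_harmonics=config.n_blw_harmonics, delta_f_hz=config.delta_f_hz
        )
    if rng.uniform() < config.p_powerline:
        samples += config.powerline_amp_scale * powerline_noise(
            n, fs, rng, mains_hz=config.mains_hz, n_harmonics=config.n_pln_harmonics,
            independent_phases=config.powerline_independent_phases,
        )
    if rng.uniform() < config.p_gaussian:
        samples += rng.normal(0.0, config.gaussian_sd_mv, n)
    if rng.uniform() < config.p_baseline_shift:
        samples += float(rng.normal(0.0, config.baseline_shift_sd_mv))
    return SynthRecord(
        signal=EcgSignal(samples, fs, out.signal.lead, out.signal.record_id),
        mask=out.mask,
        truth=out.truth,
        rhythm=out.rhythm,
    )
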