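"""Training loop: Adam, cosine-annealed learning rate, per-epoch augmentation.

Records (signal + label mask, plus an AF flag when the classifier branch is
trained) are cropped to their central window — the initial and final 2 s
are excluded, so 10-s records train on 6-s windows — augmented afresh each
epoch, batched, and optimized with Adam at an initial learning rate of
0.001 annealed to zero over the run.  All randomness flows from a single
seed, so two runs with the same configuration produce identical networks.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from . import nn
from .augment import AugmentConfig, apply_augmentations
from .losses import LossConfig, bce_loss_t, focal_loss_t
from .network import ModelConfig, SegmentationNetwork, build_network, pad_to_multiple
from .types import ConfigError, ConsistencyError, EcgSignal, LabelMask, SynthRecord


@dataclass
class TrainConfig:
    lr_init: float = 1e-3
    epochs: int = 50
    batch_size: int = 32
    seed: int = 0
    crop_margin_s: float = 2.0  # excluded at each end of every record
    augment: Optional[AugmentConfig] = field(default_factory=AugmentConfig)

    def __post_init__(self) -> None:
        if self.lr_init <= 0:
            raise ConfigError("lr_init must be positive")
        if self.epochs < 1 or self.batch_size < 1:
            raise ConfigError("epochs and batch_size must be >= 1")


def training_crop(record: SynthRecord, fs: Optional[float] = None,
                  margin_s: float = 2.0) -> SynthRecord:
    """Central window excluding ``margin_s`` seconds at each end.

    A 10-s record at 500 Hz becomes samples [1000, 4000), a 6-s window.
    Records of 4 s or less have no interior and are rejected.
    """
    fs = fs or record.signal.fs
    n = record.signal.n_samples
    margin = int(round(margin_s * fs))
    if n <= 2 * margin:
        raise ConfigError(
            f"record of {n / fs:g} s has no interior after two {margin_s:g} s margins"
        )
    sl = slice(margin, n - margin)
    mask = LabelMask(record.mask.labels[sl], fs=fs)
    from .io import mask_to_delineation  # local import to avoid a cycle

    return SynthRecord(
        signal=EcgSignal(record.signal.samples[sl], fs, record.signal.lead,
                         record.signal.record_id),
        mask=mask,
        truth=mask_to_delineation(mask, record.truth.record_id, record.truth.lead),
        rhythm=record.rhythm,
    )


def _standardize_length(samples: np.ndarray, labels: np.ndarray, target: int,
                        ) -> tuple[np.ndarray, np.ndarray]:
    """Center-crop or right edge-pad an augmented record to ``target`` samples."""
    n = samples.size
    if n > target:
        start = (n - target) // 2
        return samples[start : start + target], labels[start : start + target]
    if n < target:
        pad = target - n
        samples = np.concatenate([samples, np.full(pad, samples[-1])])
        labels = np.concatenate([labels, np.full(pad, labels[-1], dtype=labels.dtype)])
    return samples, labels


def train(
    dataset: Sequence[SynthRecord],
    model_config: Optional[ModelConfig] = None,
    loss_config: Optional[LossConfig] = None,
    train_config: Optional[TrainConfig] = None,
) -> tuple[SegmentationNetwork, list[float]]:
    """Train a network; returns the network and the per-epoch loss history."""
    model_config = model_config or ModelConfig()
    loss_config = loss_config or LossConfig()
    cfg = train_config or TrainConfig()
    if not dataset:
        raise ConfigError("empty training dataset")
    fs = dataset[0].signal.fs
    if fs != 500:
        raise ConsistencyError("training expects 500 Hz records; resample first")
    for rec in dataset:
        if rec.signal.fs != fs:
            raise ConsistencyError("all records must share the sampling rate")

    cropped = [training_crop(rec, fs, cfg.crop_margin_s) for rec in dataset]
    base_len = cropped[0].signal.n_samples
    padded_len = pad_to_multiple(np.zeros(base_len)).size

    network = build_network(model_config, init_seed=cfg.seed)
    optimizer = nn.Adam(network.params(), lr=cfg.lr_init)
    rng = np.random.default_rng(cfg.seed)

    n = len(cropped)
    steps_per_epoch = -(-n // cfg.batch_size)
    total_steps = cfg.epochs * steps_per_epoch
    history: list[float] = []
    step = 0
    for _ in range(cfg.epochs):
        order = rng.permutation(n)
        epoch_losses = []
        for b in range(steps_per_epoch):
            idx = order[b * cfg.batch_size : (b + 1) * cfg.batch_size]
            xs, ys, afs = [], [], []
            for i in idx:
                rec = cropped[i]
                if cfg.augment is not None:
                    rec = apply_augmentations(rec, cfg.augment, rng)
                samples, labels = _standardize_length(
                    rec.signal.samples, rec.mask.labels, base_len
                )
                samples = pad_to_multiple(samples)
                labels = np.concatenate(
                    [labels, np.full(padded_len - base_len, labels[-1], dtype=labels.dtype)]
                )
                xs.append(samples)
                ys.append(labels)
                afs.append(rec.is_af)
            x = nn.Tensor(np.stack(xs)[:, None, :])
            y = np.stack(ys).astype(np.int64)

            seg, rhythm = network.forward(x, training=True, dropout_rng=rng)
            loss = focal_loss_t(seg, y, loss_config.gamma, loss_config.log_floor)
            if model_config.with_classifier and rhythm is not None:
                bce = bce_loss_t(rhythm, np.array(afs), loss_config.log_floor)
                loss = loss + loss_config.alpha * bce

            optimizer.zero_grad()
            loss.backward()
            optimizer.lr = nn.cosine_lr(step, total_steps, cfg.lr_init)
            optimizer.step()
            step += 1
            epoch_losses.append(float(loss.data))
        history.append(float(np.mean(epoch_losses)))
    return network, history
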