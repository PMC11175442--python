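"""The 1D encoder-decoder segmentation network with full-scale skips.

The encoder produces five feature maps, halving the time resolution
between levels (deepest scale = input length / 16).  Each decoder stage
aggregates features from *all* encoder levels and all deeper decoder
levels — resampled to the stage's scale (average pooling downward, linear
interpolation upward) and reduced to a fixed per-source channel width —
concatenates them and fuses with a convolutional block.  A kernel-1
convolution plus per-sample softmax yields four class probabilities
{none, P, QRS, T} per time stamp.

An optional classifier branch average-pools the five encoder feature maps
to the deepest scale, concatenates them and applies two wide convolutions
(batch-normalized, with dropout), global average pooling and a two-way
softmax deciding whether the signal is an AFIB/AFL episode.  Its output
can gate P-wave suppression in post-processing.

All convolutions are stride 1 with length-preserving padding; activations
are leaky ReLU (negative slope 0.01); weights use He-style initialization.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Optional

import numpy as np

from . import nn
from .types import ClassProbMap, ConfigError, EcgSignal, InputError, RhythmProb

N_CLASSES = 4
N_LEVELS = 5
_POOL_TOTAL = 2 ** (N_LEVELS - 1)  # input must pad to a multiple of 16


@dataclass
class ModelConfig:
    """Architecture hyperparameters.

    The default configuration stays under the 2e7 trainable-parameter
    budget; ``reduced()`` gives a narrow variant (~2e5 parameters in the
    segmentation path) suitable for CPU-scale experiments.
    """

    encoder_channels: tuple[int, ...] = (32, 64, 128, 256, 512)
    convs_per_block: int = 2
    decoder_convs_per_block: int = 2
    kernel_size: int = 9
    padding: int = 4
    leaky_slope: float = 0.01
    agg_channels: int = 64  # per-source width in full-scale skip aggregation
    with_classifier: bool = False
    classifier_filters: int = 512
    classifier_kernel: int = 17
    dropout_rate: float = 0.2

    def __post_init__(self) -> None:
        if len(self.encoder_channels) != N_LEVELS:
            raise ConfigError(f"encoder_channels must list {N_LEVELS} widths")
        if self.kernel_size % 2 != 1:
            raise ConfigError("kernel_size must be odd")
        if self.padding != (self.kernel_size - 1) // 2:
            raise ConfigError("padding must preserve length: (kernel_size - 1) / 2")
        if self.convs_per_block < 1 or self.decoder_convs_per_block < 1:
            raise ConfigError("need at least one convolution per block")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ConfigError("dropout_rate must lie in [0, 1)")

    @classmethod
    def reduced(cls, with_classifier: bool = False) -> "ModelConfig":
        return cls(
            encoder_channels=(4, 8, 16, 32, 64),
            decoder_convs_per_block=1,
            agg_channels=8,
            with_classifier=with_classifier,
            classifier_filters=32,
        )

    def to_dict(self) -> dict:
        return {
            "encoder_channels": list(self.encoder_channels),
            "convs_per_block": self.convs_per_block,
            "decoder_convs_per_block": self.decoder_convs_per_block,
            "kernel_size": self.kernel_size,
            "padding": self.padding,
            "leaky_slope": self.leaky_slope,
            "agg_channels": self.agg_channels,
            "with_classifier": self.with_classifier,
            "classifier_filters": self.classifier_filters,
            "classifier_kernel": self.classifier_kernel,
            "dropout_rate": self.dropout_rate,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        d = dict(d)
        d["encoder_channels"] = tuple(d["encoder_channels"])
        return cls(**d)


class _ConvBlock:
    """(conv -> batchnorm -> leaky ReLU) x n."""

    def __init__(self, c_in: int, c_out: int, n_convs: int, kernel: int,
                 slope: float, rng: np.random.Generator):
        self.slope = slope
        self.convs = []
        self.norms = []
        for i in range(n_convs):
            self.convs.append(nn.Conv1d(c_in if i == 0 else c_out, c_out, kernel, rng=rng))
            self.norms.append(nn.BatchNorm1d(c_out))

    def __call__(self, x: nn.Tensor, training: bool) -> nn.Tensor:
        for conv, norm in zip(self.convs, self.norms):
            x = nn.leaky_relu(norm(conv(x), training), self.slope)
        return x

    def params(self) -> list[nn.Tensor]:
        out = []
        for conv, norm in zip(self.convs, self.norms):
            out.extend(conv.params())
            out.extend(norm.params())
        return out

    def norm_layers(self):
        return list(self.norms)


class SegmentationNetwork:
    """Full-scale-skip 1D segmentation network (built via build_network)."""

    def __init__(self, config: ModelConfig, init_seed: int = 0):
        self.config = config
        self.init_seed = int(init_seed)
        rng = np.random.default_rng(init_seed)
        ch = config.encoder_channels
        k, slope = config.kernel_size, config.leaky_slope

        self.encoder = []
        c_prev = 1
        for c in ch:
            self.encoder.append(_ConvBlock(c_prev, c, config.convs_per_block, k, slope, rng))
            c_prev = c

        # Decoder stages for levels 4..1; the stage at level i aggregates one
        # reduced-width feature from every encoder level and every deeper
        # decoder level (the deepest "decoder" feature is encoder level 5).
        agg = config.agg_channels
        dec_ch = agg * N_LEVELS
        self.skip_convs: dict[tuple[int, int], nn.Conv1d] = {}
        self.skip_norms: dict[tuple[int, int], nn.BatchNorm1d] = {}
        self.fuse_blocks: dict[int, _ConvBlock] = {}
        for level in range(N_LEVELS - 2, -1, -1):  # 3..0 (0-based level index)
            for src in range(N_LEVELS):
                c_src = ch[src] if src <= level or src == N_LEVELS - 1 else dec_ch
                self.skip_convs[(level, src)] = nn.Conv1d(c_src, agg, k, rng=rng)
                self.skip_norms[(level, src)] = nn.BatchNorm1d(agg)
            self.fuse_blocks[level] = _ConvBlock(
                dec_ch, dec_ch, config.decoder_convs_per_block, k, slope, rng
            )
        self.head = nn.Conv1d(dec_ch, N_CLASSES, 1, rng=rng)

        self.cls_convs: list[nn.Conv1d] = []
        self.cls_norms: list[nn.BatchNorm1d] = []
        self.cls_head: Optional[nn.Conv1d] = None
        if config.with_classifier:
            c_in = sum(ch)
            for i in range(2):
                self.cls_convs.append(
                    nn.Conv1d(c_in if i == 0 else config.classifier_filters,
                              config.classifier_filters, config.classifier_kernel, rng=rng)
                )
                self.cls_norms.append(nn.BatchNorm1d(config.classifier_filters))
            self.cls_head = nn.Conv1d(config.classifier_filters, 2, 1, rng=rng)

    # -- parameters --------------------------------------------------------

    def params(self) -> list[nn.Tensor]:
        out: list[nn.Tensor] = []
        for block in self.encoder:
            out.extend(block.params())
        for level in range(N_LEVELS - 2, -1, -1):
            for src in range(N_LEVELS):
                out.extend(self.skip_convs[(level, src)].params())
                out.extend(self.skip_norms[(level, src)].params())
            out.extend(self.fuse_blocks[level].params())
        out.extend(self.head.params())
        for conv, norm in zip(self.cls_convs, self.cls_norms):
            out.extend(conv.params())
            out.extend(norm.params())
        if self.cls_head is not None:
            out.extend(self.cls_head.params())
        return out

    def norm_layers(self) -> list[nn.BatchNorm1d]:
        out: list[nn.BatchNorm1d] = []
        for block in self.encoder:
            out.extend(block.norm_layers())
        for level in range(N_LEVELS - 2, -1, -1):
            for src in range(N_LEVELS):
                out.append(self.skip_norms[(level, src)])
            out.extend(self.fuse_blocks[level].norm_layers())
        out.extend(self.cls_norms)
        return out

    # -- forward -----------------------------------------------------------

    def forward(
        self,
        x: nn.Tensor,
        training: bool = False,
        dropout_rng: Optional[np.random.Generator] = None,
    ) -> tuple[nn.Tensor, Optional[nn.Tensor]]:
        """x is (N, 1, L) with L a multiple of 16.

        Returns per-sample class probabilities (N, 4, L) and, when the
        classifier branch is present, two-way rhythm probabilities (N, 2)
        with channel 1 = AFIB/AFL.
        """
        L = x.data.shape[2]
        if L % _POOL_TOTAL:
            raise InputError(f"core input length must be a multiple of {_POOL_TOTAL}")
        slope = self.config.leaky_slope
        enc: list[nn.Tensor] = []
        h = x
        for i, block in enumerate(self.encoder):
            if i > 0:
                h = nn.maxpool2(h)
            h = block(h, training)
            enc.append(h)

        dec: dict[int, nn.Tensor] = {N_LEVELS - 1: enc[-1]}
        for level in range(N_LEVELS - 2, -1, -1):
            target_len = L // (2**level)
            sources = []
            for src in range(N_LEVELS):
                feat = enc[src] if src <= level else dec[src]
                if src < level:
                    feat = nn.avgpool(feat, 2 ** (level - src))
                elif src > level:
                    feat = nn.upsample_linear(feat, target_len)
                feat = self.skip_convs[(level, src)](feat)
                feat = nn.leaky_relu(self.skip_norms[(level, src)](feat, training), slope)
                sources.append(feat)
            h = nn.concat(sources, axis=1)
            dec[level] = self.fuse_blocks[level](h, training)

        seg = nn.softmax(self.head(dec[0]), axis=1)

        rhythm = None
        if self.config.with_classifier:
            deepest_len = L // _POOL_TOTAL
            pooled = [
                nn.avgpool(enc[i], 2 ** (N_LEVELS - 1 - i)) if i < N_LEVELS - 1 else enc[i]
                for i in range(N_LEVELS)
            ]
            h = nn.concat(pooled, axis=1)
            rng = dropout_rng or np.random.default_rng(0)
            for conv, norm in zip(self.cls_convs, self.cls_norms):
                h = nn.leaky_relu(norm(conv(h), training), slope)
                h = nn.dropout(h, self.config.dropout_rate, rng, training)
            h = h.mean(axis=2, keepdims=True)  # global average pooling
            logits = self.cls_head(h)  # (N, 2, 1)
            rhythm = nn.softmax(logits.reshape(logits.shape[0], 2), axis=1)
        return seg, rhythm

    # -- persistence ---------------------------------------------------------

    def save(self, path: str, extra_meta: Optional[dict] = None) -> None:
        """Save config + weights + running statistics as an .npz checkpoint."""
        arrays = {f"p{i}": p.data for i, p in enumerate(self.params())}
        for i, norm in enumerate(self.norm_layers()):
            arrays[f"rm{i}"] = norm.running_mean
            arrays[f"rv{i}"] = norm.running_var
        meta = {
            "config": self.config.to_dict(),
            "init_seed": self.init_seed,
            "numpy_version": np.__version__,
        }
        if extra_meta:
            meta.update(extra_meta)
        arrays["meta"] = np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8)
        np.savez(path, **arrays)

    @classmethod
    def load(cls, path: str) -> "SegmentationNetwork":
        with np.load(path) as data:
            meta = json.loads(bytes(data["meta"].tobytes()).decode())
            net = cls(ModelConfig.from_dict(meta["config"]), meta.get("init_seed", 0))
            for i, p in enumerate(net.params()):
                p.data = data[f"p{i}"].astype(nn.DTYPE)
            for i, norm in enumerate(net.norm_layers()):
                norm.running_mean = data[f"rm{i}"].astype(nn.DTYPE)
                norm.running_var = data[f"rv{i}"].astype(nn.DTYPE)
        return net


def build_network(config: Optional[ModelConfig] = None, init_seed: int = 0) -> SegmentationNetwork:
    """Construct the network with He-initialized weights from ``init_seed``."""
    return SegmentationNetwork(config or ModelConfig(), init_seed)


def count_parameters(network) -> int:
    """Exact number of trainable scalars in any object exposing params()."""
    params = network.params() if hasattr(network, "params") else network
    return int(sum(p.data.size for p in params))


def pad_to_multiple(samples: np.ndarray, multiple: int = _POOL_TOTAL) -> np.ndarray:
    """Right edge-replication padding to a multiple of ``multiple``."""
    n = samples.size
    target = -(-n // multiple) * multiple
    if target == n:
        return samples
    return np.concatenate([samples, np.full(target - n, samples[-1])])


def segment(
    network: SegmentationNetwork, signal: EcgSignal
) -> tuple[ClassProbMap, Optional[RhythmProb]]:
    """Run inference on a 500 Hz signal of any length >= 16 samples.

    The input is right-padded (edge replication) to a multiple of 16 and
    the output cropped back; normalization layers use running statistics,
    so inference is deterministic.
    """
    if signal.fs != 500:
        raise InputError(
            f"segment expects a 500 Hz signal, got {signal.fs} Hz; resample first"
        )
    if signal.n_samples < _POOL_TOTAL:
        raise InputError(f"need at least {_POOL_TOTAL} samples")
    padded = pad_to_multiple(signal.samples)
    x = nn.Tensor(padded[None, None, :])
    seg, rhythm = network.forward(x, training=False)
    probs = seg.data[0].T[: signal.n_samples]  # (L, 4)
    prob_map = ClassProbMap(probs, fs=500.0)
    rp = RhythmProb(float(rhythm.data[0, 1])) if rhythm is not None else None
    return prob_map, rp
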