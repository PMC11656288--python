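"""Segmentation and refinement networks.

The segmenter is a V-Net-style encoder/decoder whose encoder stages 2..S
are fed, alongside the spatial feature map, the matching-resolution wavelet
sub-bands of the *input volume*.  Each level's eight sub-bands pass through
a sub-band attention block (global pooling + two fully connected stages +
sigmoid gate), are scaled by the resulting per-band weights, projected by a
1x1x1 convolution to a fixed channel budget, and channel-concatenated with
the encoder features before that stage's convolution.

During adaptation only the attention blocks and the batch-normalization
affine parameters are trainable; :func:`partition_parameters` computes that
split.
"""

from __future__ import annotations

import io
import json
import zipfile
from dataclasses import asdict, dataclass, field
from typing import Dict, Optional, Set, Tuple

import numpy as np

from . import wavelet as wv
from .nn import BatchNorm3d, Conv3d, Linear, Module, ModuleList, Tensor, concat, no_grad, upsample2

__all__ = [
    "NetworkConfig",
    "RefineNetConfig",
    "ParameterPartition",
    "ConfigurationError",
    "SubbandAttention",
    "WaVNet",
    "RefineNet",
    "build_wavnet",
    "build_refine_model",
    "subband_attention",
    "partition_parameters",
    "save_checkpoint",
    "load_checkpoint",
]

CHECKPOINT_SCHEMA_VERSION = 1


class ConfigurationError(ValueError):
    """Invalid or mutually inconsistent network configuration."""


@dataclass(frozen=True)
class NetworkConfig:
    """Architecture of the segmenter.

    ``encoder_channels`` gives the per-stage feature widths; wavelet
    sub-bands are projected to ``subband_channels`` channels before fusion.
    ``base_resolution`` must be divisible by ``2 ** (stages - 1)`` so that
    level-n sub-bands match stage-(n+1) feature maps exactly.
    """

    stages: int = 5
    encoder_channels: Tuple[int, ...] = (4, 8, 16, 16, 16)
    conv_kernel: int = 3
    downsample_stride: int = 2
    base_resolution: Tuple[int, int, int] = (64, 64, 32)
    num_classes: int = 1
    sa_reduction: int = 2
    subband_channels: int = 4
    use_wavelet: bool = True
    seed: int = 0

    def validate(self) -> None:
        if len(self.encoder_channels) != self.stages:
            raise ConfigurationError(
                f"encoder_channels has {len(self.encoder_channels)} entries "
                f"for {self.stages} stages"
            )
        if self.num_classes != 1:
            raise ConfigurationError("only the binary (single-channel sigmoid) head is supported")
        factor = 2 ** (self.stages - 1)
        for extent in self.base_resolution:
            if extent % factor:
                raise ConfigurationError(
                    f"base_resolution {self.base_resolution} not divisible by "
                    f"2**(stages-1) = {factor}"
                )


@dataclass(frozen=True)
class RefineNetConfig:
    """Reconstruction autoencoder: fixed 4-stage depth, sigmoid head."""

    depth: int = 4
    channels: Tuple[int, ...] = (4, 8, 16, 16)
    conv_kernel: int = 3
    seed: int = 1

    def validate(self) -> None:
        if self.depth != len(self.channels):
            raise ConfigurationError("channels must have one entry per stage")


@dataclass
class ParameterPartition:
    """Names of adaptable vs frozen parameters of a segmenter."""

    adaptable: Set[str]
    frozen: Set[str]

    def counts(self, model: Module) -> Tuple[int, int]:
        """(adaptable, total) scalar parameter counts."""
        sizes = {name: p.size for name, p in model.named_parameters()}
        n_adapt = sum(sizes[n] for n in self.adaptable)
        return n_adapt, sum(sizes.values())


class SubbandAttention(Module):
    """Channel attention over the eight sub-bands of one wavelet level.

    Global average pooling -> FC (reduce) -> ReLU -> FC (expand) -> sigmoid.
    ``force_weights`` overrides the computed gate (testing hook).
    """

    def __init__(self, n_bands: int, reduction: int, rng: np.random.Generator):
        super().__init__()
        self.n_bands = n_bands
        hidden = max(n_bands // reduction, 1)
        self.fc1 = Linear(n_bands, hidden, rng)
        self.fc2 = Linear(hidden, n_bands, rng)
        self.force_weights: Optional[np.ndarray] = None
        self.last_weights: Optional[np.ndarray] = None

    def forward(self, bands: Tensor) -> Tuple[Tensor, Tensor]:
        if bands.shape[0] != self.n_bands:
            raise ValueError(
                f"expected {self.n_bands} sub-band channels, got {bands.shape[0]}"
            )
        if self.force_weights is not None:
            weights = Tensor(np.asarray(self.force_weights, dtype=float))
        else:
            pooled = bands.mean(axis=(1, 2, 3))
            weights = self.fc2(self.fc1(pooled).relu()).sigmoid()
        self.last_weights = weights.data.copy()
        weighted = bands * weights.reshape(self.n_bands, 1, 1, 1)
        return weighted, weights


def subband_attention(bands, block: SubbandAttention) -> Tuple[Tensor, Tensor]:
    """Apply ``block`` to a stack of sub-bands (array or tensor)."""
    if not isinstance(bands, Tensor):
        bands = Tensor(np.asarray(bands, dtype=float))
    return block(bands)


class WaVNet(Module):
    """V-Net backbone with per-level wavelet sub-band fusion."""

    def __init__(self, config: NetworkConfig, filters: wv.WaveletFilters):
        super().__init__()
        config.validate()
        self.config = config
        self.filters = filters
        self.levels = config.stages - 1
        rng = np.random.default_rng(config.seed)
        ch = config.encoder_channels
        k = config.conv_kernel

        self.conv_in = Conv3d(1, ch[0], k, rng)
        self.bn_in = BatchNorm3d(ch[0])
        self.down_convs = ModuleList()
        self.down_bns = ModuleList()
        self.enc_convs = ModuleList()
        self.enc_bns = ModuleList()
        self.sa_blocks = ModuleList()
        self.band_proj = ModuleList()
        for s in range(1, config.stages):
            self.down_convs.append(
                Conv3d(ch[s - 1], ch[s], config.downsample_stride, rng,
                       stride=config.downsample_stride, padding=0)
            )
            self.down_bns.append(BatchNorm3d(ch[s]))
            fused_in = ch[s]
            if config.use_wavelet:
                self.sa_blocks.append(SubbandAttention(8, config.sa_reduction, rng))
                self.band_proj.append(Conv3d(8, config.subband_channels, 1, rng, padding=0))
                fused_in += config.subband_channels
            self.enc_convs.append(Conv3d(fused_in, ch[s], k, rng))
            self.enc_bns.append(BatchNorm3d(ch[s]))
        self.dec_convs = ModuleList()
        self.dec_bns = ModuleList()
        for s in range(config.stages - 2, -1, -1):
            self.dec_convs.append(Conv3d(ch[s + 1] + ch[s], ch[s], k, rng))
            self.dec_bns.append(BatchNorm3d(ch[s]))
        self.head = Conv3d(ch[0], config.num_classes, 1, rng, padding=0)

    # -- helpers --------------------------------------------------------------
    def compute_pyramid(self, volume: np.ndarray) -> Optional[wv.WaveletPyramid]:
        if not self.config.use_wavelet:
            return None
        return wv.multilevel_dwt(np.asarray(volume, dtype=float), self.levels, self.filters)

    def set_bn_running_updates(self, enabled: bool) -> None:
        for _, module in self.named_modules():
            if isinstance(module, BatchNorm3d):
                module.update_running = enabled

    def sa_weights(self) -> Dict[int, np.ndarray]:
        """Last attention weights per wavelet level (1-based)."""
        return {
            level + 1: block.last_weights
            for level, block in enumerate(self.sa_blocks)
            if block.last_weights is not None
        }

    # -- forward --------------------------------------------------------------
    def forward(
        self,
        volume,
        pyramid: Optional[wv.WaveletPyramid] = None,
        zero_wavelet: bool = False,
    ) -> Tensor:
        vol = np.asarray(volume, dtype=float) if not isinstance(volume, np.ndarray) else volume
        if vol.ndim != 3:
            raise ValueError(f"expected a 3-D volume, got shape {vol.shape}")
        factor = 2 ** (self.config.stages - 1)
        for axis, extent in enumerate(vol.shape):
            if extent % factor:
                raise ConfigurationError(
                    f"axis {axis} extent {extent} is not divisible by {factor}; "
                    f"stage-{self.config.stages} features would not match the "
                    f"level-{self.levels} sub-band extent {-(-extent // factor)}"
                )
        if self.config.use_wavelet and pyramid is None:
            pyramid = self.compute_pyramid(vol)

        x = Tensor(vol[None])
        feats = []
        h = self.bn_in(self.conv_in(x)).relu()
        feats.append(h)
        for s in range(1, self.config.stages):
            d = self.down_bns[s - 1](self.down_convs[s - 1](h)).relu()
            if self.config.use_wavelet:
                bands = np.stack(pyramid.bands_at(s))
                if bands.shape[1:] != d.shape[1:]:
                    raise ConfigurationError(
                        f"level-{s} sub-band extent {bands.shape[1:]} does not "
                        f"match stage-{s + 1} feature extent {d.shape[1:]}"
                    )
                weighted, _ = self.sa_blocks[s - 1](Tensor(bands))
                if zero_wavelet:
                    weighted = Tensor(np.zeros_like(weighted.data))
                proj = self.band_proj[s - 1](weighted)
                d = concat([d, proj], axis=0)
            h = self.enc_bns[s - 1](self.enc_convs[s - 1](d)).relu()
            feats.append(h)
        u = feats[-1]
        for i, s in enumerate(range(self.config.stages - 2, -1, -1)):
            u = concat([upsample2(u), feats[s]], axis=0)
            u = self.dec_bns[i](self.dec_convs[i](u)).relu()
        return self.head(u).sigmoid()

    def predict(self, volume, pyramid=None, use_batch_stats: bool = False) -> np.ndarray:
        """Probability map as a plain (D, H, W) array, without autograd.

        ``use_batch_stats`` selects training-mode normalization statistics
        (the adaptation convention) while never touching running buffers.
        """
        was_training = self.training
        self.train(use_batch_stats)
        self.set_bn_running_updates(False)
        try:
            with no_grad():
                out = self.forward(volume, pyramid=pyramid)
        finally:
            self.train(was_training)
            self.set_bn_running_updates(True)
        return out.data[0]


class RefineNet(Module):
    """Encoder/decoder reconstruction network with a sigmoid head.

    Maps a probability map (or binary mask) to a cleaned probability map of
    identical extents; input extents must be divisible by ``2**(depth-1)``.
    """

    def __init__(self, config: RefineNetConfig):
        super().__init__()
        config.validate()
        self.config = config
        rng = np.random.default_rng(config.seed)
        ch = config.channels
        k = config.conv_kernel
        self.conv_in = Conv3d(1, ch[0], k, rng)
        self.bn_in = BatchNorm3d(ch[0])
        self.down_convs = ModuleList()
        self.down_bns = ModuleList()
        for s in range(1, config.depth):
            self.down_convs.append(Conv3d(ch[s - 1], ch[s], 2, rng, stride=2, padding=0))
            self.down_bns.append(BatchNorm3d(ch[s]))
        self.dec_convs = ModuleList()
        self.dec_bns = ModuleList()
        for s in range(config.depth - 2, -1, -1):
            self.dec_convs.append(Conv3d(ch[s + 1] + ch[s], ch[s], k, rng))
            self.dec_bns.append(BatchNorm3d(ch[s]))
        self.head = Conv3d(ch[0], 1, 1, rng, padding=0)

    def forward(self, x) -> Tensor:
        if not isinstance(x, Tensor):
            x = Tensor(np.asarray(x, dtype=float))
        if x.ndim == 3:
            x = x.reshape(1, *x.shape)
        factor = 2 ** (self.config.depth - 1)
        for axis, extent in enumerate(x.shape[1:]):
            if extent % factor:
                raise ConfigurationError(
                    f"refine input axis {axis} extent {extent} not divisible by {factor}"
                )
        h = self.bn_in(self.conv_in(x)).relu()
        skips = [h]
        for conv, bn in zip(self.down_convs, self.down_bns):
            h = bn(conv(h)).relu()
            skips.append(h)
        for i, (conv, bn) in enumerate(zip(self.dec_convs, self.dec_bns)):
            h = concat([upsample2(h), skips[self.config.depth - 2 - i]], axis=0)
            h = bn(conv(h)).relu()
        return self.head(h).sigmoid()

    def predict(self, x) -> np.ndarray:
        was_training = self.training
        self.eval()
        try:
            with no_grad():
                out = self.forward(x)
        finally:
            self.train(was_training)
        return out.data[0]


def build_wavnet(config: NetworkConfig, filters: wv.WaveletFilters) -> WaVNet:
    """Construct a seeded segmenter from its configuration."""
    return WaVNet(config, filters)


def build_refine_model(config: RefineNetConfig) -> RefineNet:
    return RefineNet(config)


def partition_parameters(model: WaVNet) -> ParameterPartition:
    """Split parameters into the adaptable set (SA blocks + BN affine) and the rest.

    Raises
    ------
    ValueError
        If the model has no attention blocks or no batch-norm layers, which
        would silently yield an empty adaptable set.
    """
    sa_prefixes = []
    bn_prefixes = []
    for name, module in model.named_modules():
        if isinstance(module, SubbandAttention):
            sa_prefixes.append(name)
        elif isinstance(module, BatchNorm3d):
            bn_prefixes.append(name)
    if not sa_prefixes:
        raise ValueError("model has no sub-band attention blocks; refusing an empty partition")
    if not bn_prefixes:
        raise ValueError("model has no batch-normalization layers; refusing an empty partition")
    adaptable = set()
    for name, _ in model.named_parameters():
        if any(name.startswith(p + ".") for p in sa_prefixes + bn_prefixes):
            adaptable.add(name)
    all_names = {name for name, _ in model.named_parameters()}
    return ParameterPartition(adaptable=adaptable, frozen=all_names - adaptable)


# -- checkpointing ------------------------------------------------------------


def save_checkpoint(path, model: Module, meta: Optional[dict] = None) -> None:
    """Write a single-file archive: parameters, buffers, and JSON metadata.

    The metadata always records the schema version, the model class, its
    configuration, and (for segmenters) the wavelet family and parameter
    partition, so that the exact model is recoverable from the file alone.
    """
    meta = dict(meta or {})
    meta["schema_version"] = CHECKPOINT_SCHEMA_VERSION
    meta["model_class"] = type(model).__name__
    meta["config"] = asdict(model.config)
    if isinstance(model, WaVNet):
        meta["wavelet_family"] = model.filters.family_name
        partition = partition_parameters(model)
        meta["partition"] = {
            "adaptable": sorted(partition.adaptable),
            "frozen": sorted(partition.frozen),
        }
    state = model.state_dict()
    with zipfile.ZipFile(path, "w", zipfile.ZIP_DEFLATED) as archive:
        archive.writestr("meta.json", json.dumps(meta, indent=1))
        for key, array in state.items():
            buffer = io.BytesIO()
            np.save(buffer, array)
            archive.writestr(f"arrays/{key}.npy", buffer.getvalue())


def load_checkpoint(path) -> Tuple[Module, dict]:
    """Rebuild the model stored by :func:`save_checkpoint`."""
    with zipfile.ZipFile(path, "r") as archive:
        meta = json.loads(archive.read("meta.json"))
        state = {}
        for name in archive.namelist():
            if name.startswith("arrays/"):
                key = name[len("arrays/") : -len(".npy")]
                state[key] = np.load(io.BytesIO(archive.read(name)))
    if meta.get("schema_version") != CHECKPOINT_SCHEMA_VERSION:
        raise ValueError(f"unsupported checkpoint schema: {meta.get('schema_version')}")
    cfg = meta["config"]
    if meta["model_class"] == "WaVNet":
        config = NetworkConfig(
            **{
                **cfg,
                "encoder_channels": tuple(cfg["encoder_channels"]),
                "base_resolution": tuple(cfg["base_resolution"]),
            }
        )
        model: Module = WaVNet(config, wv.WaveletFilters.from_family(meta["wavelet_family"]))
    elif meta["model_class"] == "RefineNet":
        config = RefineNetConfig(**{**cfg, "channels": tuple(cfg["channels"])})
        model = RefineNet(config)
    else:
        raise ValueError(f"unknown model class {meta['model_class']!r}")
    model.load_state_dict(state)
    return model, meta
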