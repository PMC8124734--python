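"""Assembly of the multi-scale spatial/channel 3D U-Net.

One encoder per input modality (two stages of [conv3-BN-ReLU]x2
followed by multi-branch pooling, channel width doubling per stage),
a shared bottleneck formed by concatenating the deepest features of
all encoders, a shared two-stage decoder (deconv2-BN-ReLU then
[conv3-BN-ReLU]x2) whose skip connections concatenate the matching
stage outputs of every encoder, and three side-output heads at 1/4,
1/2 and 1/1 of the patch resolution. Each head is either a plain
1x1x1 convolution or a multi-branch dense-prediction (MDP) head; all
three are upsampled trilinearly to full resolution and fused by a
learned weighted sum into the final logits.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .blocks import MDPConfig, MDPHead, MPConfig, mp_forward
from .nn import BatchNorm3d, Conv3d, ConvTranspose3d, Module, Var, as_var
from .nn import functional as F

__all__ = ["NetworkConfig", "BranchOutputs", "MSCDUNet", "build_model", "predict_labels"]


@dataclass
class NetworkConfig:
    n_modalities: int = 3
    n_classes: int = 4
    base_width: int = 32
    mp: MPConfig = field(default_factory=MPConfig)
    mdp: MDPConfig = field(default_factory=MDPConfig)
    branch_mdp: list = field(default_factory=lambda: [True, True, False])
    patch_size: int = 32
    seed: int = 0

    def __post_init__(self):
        if not 1 <= self.n_modalities <= 3:
            raise ValueError("n_modalities must be 1, 2 or 3")
        if self.patch_size % 4 != 0:
            raise ValueError("patch_size must be divisible by 4 (two halvings)")
        if len(self.branch_mdp) != 3:
            raise ValueError("branch_mdp must have 3 entries (one per side output)")
        if self.mdp.n_classes != self.n_classes:
            raise ValueError(
                f"mdp.n_classes ({self.mdp.n_classes}) must equal "
                f"network n_classes ({self.n_classes})"
            )


@dataclass
class BranchOutputs:
    """Side-output logits (1/4, 1/2, 1/1 scale heads, all upsampled to
    full patch resolution) plus the fused logits."""

    side_logits: list
    fused_logits: Var

    def arrays(self):
        return [s.value for s in self.side_logits], self.fused_logits.value


class _ConvBlock(Module):
    """[conv3x3x3 - BN - ReLU] x 2."""

    def __init__(self, cin, cmid, cout, rng, dtype):
        super().__init__()
        self.conv1 = Conv3d(cin, cmid, 3, rng, dtype)
        self.bn1 = BatchNorm3d(cmid, dtype)
        self.conv2 = Conv3d(cmid, cout, 3, rng, dtype)
        self.bn2 = BatchNorm3d(cout, dtype)

    def __call__(self, x):
        x = F.relu(self.bn1(self.conv1(x)))
        return F.relu(self.bn2(self.conv2(x)))


class _Encoder(Module):
    """Two conv stages for one modality; exposes the pre-pooling
    features of both stages for the skip connections."""

    def __init__(self, w, mp_cfg, rng, dtype):
        super().__init__()
        self.stage1 = _ConvBlock(1, w, w, rng, dtype)
        self.stage2 = _ConvBlock(w * len(mp_cfg.kernels_stage1), 2 * w, 2 * w, rng, dtype)
        self.mp_cfg = mp_cfg

    def __call__(self, x):
        s1 = self.stage1(x)
        p1 = mp_forward(s1, self.mp_cfg, stage=1)
        s2 = self.stage2(p1)
        p2 = mp_forward(s2, self.mp_cfg, stage=2)
        return s1, s2, p2


class _DecoderStage(Module):
    def __init__(self, cin, skip_ch, cout, rng, dtype):
        super().__init__()
        self.up = ConvTranspose3d(cin, cout, rng, dtype)
        self.bn_up = BatchNorm3d(cout, dtype)
        self.convs = _ConvBlock(cout + skip_ch, cout, cout, rng, dtype)

    def __call__(self, x, skips):
        x = F.relu(self.bn_up(self.up(x)))
        return self.convs(F.concat([x] + skips, axis=1))


class _Head(Module):
    """Side-output head: plain 1x1x1 conv or conv-into-MDP."""

    def __init__(self, cin, cfg, use_mdp, rng, dtype):
        super().__init__()
        self.use_mdp = use_mdp
        if use_mdp:
            self.pre = Conv3d(cin, cfg.mdp.in_channels, 1, rng, dtype)
            self.mdp = MDPHead(cfg.mdp, rng, dtype)
        else:
            self.pre = Conv3d(cin, cfg.n_classes, 1, rng, dtype)
            self.mdp = None

    def __call__(self, x):
        x = self.pre(x)
        if self.use_mdp:
            x = self.mdp(x)
        return x


class MSCDUNet(Module):
    """The full segmentation network; see the module docstring."""

    def __init__(self, cfg: NetworkConfig, dtype=np.float32, f_init=(1.0, 1.0, 1.0)):
        super().__init__()
        self.cfg = cfg
        rng = np.random.default_rng(cfg.seed)
        w = cfg.base_width
        m = cfg.n_modalities
        b1 = len(cfg.mp.kernels_stage1)
        b2 = len(cfg.mp.kernels_stage2)
        self.encoders = [_Encoder(w, cfg.mp, rng, dtype) for _ in range(m)]
        bottleneck_ch = m * 2 * w * b2
        self.dec1 = _DecoderStage(bottleneck_ch, m * 2 * w, 2 * w, rng, dtype)
        self.dec2 = _DecoderStage(2 * w, m * w, w, rng, dtype)
        self.heads = [
            _Head(bottleneck_ch, cfg, cfg.branch_mdp[0], rng, dtype),
            _Head(2 * w, cfg, cfg.branch_mdp[1], rng, dtype),
            _Head(w, cfg, cfg.branch_mdp[2], rng, dtype),
        ]
        self.fusion_weights = Var(
            np.asarray(f_init, dtype=dtype), requires_grad=True
        )

    def forward(self, inputs) -> BranchOutputs:
        """Run a batch shaped (batch, n_modalities, P, P, P)."""
        x = as_var(inputs)
        b, m = x.value.shape[:2]
        p = self.cfg.patch_size
        if m != self.cfg.n_modalities:
            raise ValueError(
                f"expected {self.cfg.n_modalities} modality channels, got {m}"
            )
        if x.value.shape[2:] != (p, p, p):
            raise ValueError(
                f"expected patch size {(p, p, p)}, got {x.value.shape[2:]}"
            )
        skips1, skips2, deep = [], [], []
        for i, enc in enumerate(self.encoders):
            xi = Var(
                np.ascontiguousarray(x.value[:, i : i + 1]),
                [(x, lambda g, _i=i, _m=m: _expand_modality(g, _i, _m))],
            )
            s1, s2, p2 = enc(xi)
            skips1.append(s1)
            skips2.append(s2)
            deep.append(p2)
        bottleneck = F.concat(deep, axis=1) if len(deep) > 1 else deep[0]
        d1 = self.dec1(bottleneck, skips2)
        d2 = self.dec2(d1, skips1)
        taps = [bottleneck, d1, d2]
        factors = [4, 2, 1]
        side = [
            F.upsample_trilinear(head(tap), f)
            for head, tap, f in zip(self.heads, taps, factors)
        ]
        fused = F.weighted_sum(side, self.fusion_weights)
        return BranchOutputs(side_logits=side, fused_logits=fused)

    __call__ = forward


def _expand_modality(g, i, m):
    shape = list(g.shape)
    shape[1] = m
    out = np.zeros(shape, dtype=g.dtype)
    out[:, i : i + 1] = g
    return out


def build_model(cfg: NetworkConfig, dtype=np.float32, f_init=(1.0, 1.0, 1.0)) -> MSCDUNet:
    """Build the network with Xavier-initialized weights under cfg.seed."""
    return MSCDUNet(cfg, dtype=dtype, f_init=f_init)


def predict_labels(outputs: BranchOutputs) -> np.ndarray:
    """Voxel-wise argmax of the softmax of the fused logits.

    Softmax is monotone, so this is the argmax of the logits; numpy's
    argmax returns the first maximum, which implements the documented
    tie-break toward the smallest class index.
    """
    fused = outputs.fused_logits.value if isinstance(outputs.fused_logits, Var) else outputs.fused_logits
    return np.argmax(fused, axis=1).astype(np.int16)
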