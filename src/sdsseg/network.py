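"""Hybrid 2D/3D multi-scale attention segmentation network.

Two encoders run side by side: a 3D encoder of residual bottleneck
blocks consumes the five-slice context patch and captures through-plane
structure, while a 2D encoder of plain convolution blocks consumes the
center slice.  Bridge blocks pool the slice axis of each 3D stage and
fold it into channels so 3D features can be concatenated with the 2D
features at every level.  The decoder upsamples through DeConv blocks
whose skip connections are filtered by additive attention gates, and
emits four full-resolution probability maps: three auxiliary heads from
intermediate decoder levels plus the final segmentation head.

Channel widths double per level starting from ``base_channels``; the
reference scale uses 64, the desk scale 16.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import autograd as ag
from .autograd import Tensor
from .layers import BatchNorm, Conv, ConvTranspose2x, Module


@dataclass(frozen=True)
class NetworkConfig:
    base_channels: int = 16
    depth: int = 4                      # encoder levels; the architecture assumes 4
    in_plane: tuple[int, int] = (224, 224)
    context_slices: int = 5
    n_modalities: int = 4
    head_classes: tuple[int, int, int, int] = (2, 3, 4, 4)
    seed: int = 0

    def validate(self) -> None:
        if self.depth != 4:
            raise ValueError("the architecture is defined for 4 encoder levels")
        if self.base_channels < 2:
            raise ValueError("base_channels must be >= 2")
        if any(s % 16 for s in self.in_plane):
            raise ValueError("in_plane extents must be divisible by 16")
        if self.context_slices < 1 or self.context_slices % 2 == 0:
            raise ValueError("context_slices must be odd and >= 1")
        if len(self.head_classes) != 4:
            raise ValueError("exactly 4 output heads are required")


class ResBlock3d(Module):
    """Bottleneck residual block (1x1x1, 3x3x3, 1x1x1 convolutions).

    With ``downsample`` the first convolution and the shortcut use
    in-plane stride 2, halving height and width; the slice axis keeps
    stride 1.  The last convolution expands to 4x the bottleneck width.
    """

    def __init__(self, rng, cin: int, bottleneck: int, downsample: bool):
        cout = 4 * bottleneck
        s = (1, 2, 2) if downsample else 1
        self.conv1 = Conv(rng, cin, bottleneck, 1, stride=s, ndim=3)
        self.conv2 = Conv(rng, bottleneck, bottleneck, 3, pad=1, ndim=3)
        self.conv3 = Conv(rng, bottleneck, cout, 1, ndim=3)
        self.identity_shortcut = (not downsample) and cin == cout
        self.shortcut = None if self.identity_shortcut \
            else Conv(rng, cin, cout, 1, stride=s, ndim=3)
        self.downsample = downsample

    def __call__(self, x: Tensor) -> Tensor:
        if self.downsample and (x.shape[3] % 2 or x.shape[4] % 2):
            raise ValueError(f"cannot halve odd in-plane extents {x.shape[3:]}")
        a = ag.relu(self.conv1(x))
        a = ag.relu(self.conv2(a))
        a = self.conv3(a)
        b = x if self.identity_shortcut else self.shortcut(x)
        return ag.relu(a + b)


class ConvBlock2d(Module):
    """Two (conv 3x3 -> ReLU -> BN) stages followed by 2x2 max-pooling."""

    def __init__(self, rng, cin: int, cout: int):
        self.conv1 = Conv(rng, cin, cout, 3, pad=1)
        self.bn1 = BatchNorm(cout)
        self.conv2 = Conv(rng, cout, cout, 3, pad=1)
        self.bn2 = BatchNorm(cout)

    def __call__(self, x: Tensor) -> Tensor:
        if x.shape[2] % 2 or x.shape[3] % 2:
            raise ValueError(f"conv_block requires even in-plane extents, got {x.shape[2:]}")
        x = self.bn1(ag.relu(self.conv1(x)))
        x = self.bn2(ag.relu(self.conv2(x)))
        return ag.maxpool2d(x)


class BridgeBlock(Module):
    """Project 3D features and fold the slice axis into a 2D feature map.

    Convolution -> ReLU -> BN, then max-pooling over the full slice axis
    (reducing it to one plane) and a reshape that drops the axis.  The
    output is spatially aligned with the 2D encoder at the same level.
    """

    def __init__(self, rng, cin: int, cout: int):
        self.conv = Conv(rng, cin, cout, 1, ndim=3)
        self.bn = BatchNorm(cout)

    def __call__(self, x3d: Tensor) -> Tensor:
        x = self.bn(ag.relu(self.conv(x3d)))
        return ag.amax(x, axis=2)


class AttentionGate(Module):
    """Additive attention over a skip connection.

    alpha = sigmoid(psi^T relu(W_x x + W_g g + b_g) + b_psi), one scalar
    per pixel; the output is x * alpha broadcast over channels.  The
    gating signal comes from one level coarser, so it is upsampled 2x
    (nearest) when its spatial extent is half of x's.  The most recent
    attention map is exposed as ``last_alpha`` for inspection.
    """

    def __init__(self, rng, ch_x: int, ch_g: int, f_int: int | None = None):
        f_int = f_int or max(ch_x // 2, 1)
        self.wx = Conv(rng, ch_x, f_int, 1, bias=False)
        self.wg = Conv(rng, ch_g, f_int, 1, bias=True)     # bias b_g
        self.psi = Conv(rng, f_int, 1, 1, bias=True)       # bias b_psi
        self.last_alpha: np.ndarray | None = None

    def __call__(self, x: Tensor, g: Tensor) -> Tensor:
        if g.shape[2:] != x.shape[2:]:
            if tuple(2 * s for s in g.shape[2:]) != x.shape[2:]:
                raise ValueError(f"gate spatial {g.shape[2:]} incompatible with "
                                 f"input {x.shape[2:]}")
            g = ag.upsample2x(g)
        q = ag.relu(self.wx(x) + self.wg(g))
        # sigmoid saturates to exactly 0/1 in float32; keep alpha in the
        # open interval so the gate never fully kills or passes a pixel
        alpha = ag.clamp(ag.sigmoid(self.psi(q)), 1e-6, 1.0 - 1e-6)
        if not np.isfinite(alpha.data).all():
            raise FloatingPointError("non-finite attention activations")
        self.last_alpha = alpha.data
        return x * alpha


class DeConvBlock(Module):
    """2x nearest upsampling, concat of the gated skip, two conv stages."""

    def __init__(self, rng, cin_up: int, cin_skip: int, cout: int):
        cin = cin_up + cin_skip
        self.conv1 = Conv(rng, cin, cout, 3, pad=1)
        self.bn1 = BatchNorm(cout)
        self.conv2 = Conv(rng, cout, cout, 3, pad=1)
        self.bn2 = BatchNorm(cout)

    def __call__(self, x: Tensor, skip: Tensor) -> Tensor:
        up = ag.upsample2x(x)
        if up.shape[2:] != skip.shape[2:]:
            raise ValueError(f"upsampled {up.shape[2:]} does not match skip {skip.shape[2:]}")
        h = ag.concat([up, skip], axis=1)
        h = self.bn1(ag.relu(self.conv1(h)))
        return self.bn2(ag.relu(self.conv2(h)))


class AuxiliaryHead(Module):
    """Upscale an intermediate decoder feature to full size and classify.

    ``n_up`` stride-2 transposed convolutions (ReLU in between) reach the
    input resolution, then a 1x1 projection and per-pixel softmax.
    """

    def __init__(self, rng, cin: int, n_up: int, classes: int):
        if n_up < 1:
            raise ValueError("auxiliary head needs at least one upscaling step")
        chans = [cin]
        for _ in range(n_up):
            chans.append(max(chans[-1] // 2, 8))
        self.ups = [ConvTranspose2x(rng, chans[i], chans[i + 1]) for i in range(n_up)]
        self.proj = Conv(rng, chans[-1], classes, 1)
        self.classes = classes

    def __call__(self, x: Tensor) -> Tensor:
        for i, up in enumerate(self.ups):
            x = up(x)
            if i < len(self.ups) - 1:
                x = ag.relu(x)
        return ag.softmax_channel(self.proj(x))

    def logits(self, x: Tensor) -> Tensor:
        for i, up in enumerate(self.ups):
            x = up(x)
            if i < len(self.ups) - 1:
                x = ag.relu(x)
        return self.proj(x)


class SegmentationNet(Module):
    """The full four-head hybrid 2D/3D attention network."""

    def __init__(self, cfg: NetworkConfig):
        cfg.validate()
        self.cfg = cfg
        # Each block gets its own seeded stream, so the mainstream
        # initialization is identical across head configurations (required
        # when comparing supervision schemes from shared random weights).
        counter = iter(range(64))

        def rng():
            return np.random.default_rng((cfg.seed, next(counter)))

        B = cfg.base_channels
        widths = [B, 2 * B, 4 * B, 8 * B]
        bottlenecks = [max(w // 4, 1) for w in widths]

        # 3D encoder: four stages of (down-Res, Res) + bridge
        self.res_down = []
        self.res_same = []
        self.bridges = []
        cin3d = cfg.n_modalities
        for w, m in zip(widths, bottlenecks):
            self.res_down.append(ResBlock3d(rng(), cin3d, m, downsample=True))
            self.res_same.append(ResBlock3d(rng(), 4 * m, m, downsample=False))
            self.bridges.append(BridgeBlock(rng(), 4 * m, w))
            cin3d = 4 * m

        # 2D encoder: four Conv blocks, input of block i+1 is the level-i concat
        self.conv_blocks = []
        cin2d = cfg.n_modalities
        for w in widths:
            self.conv_blocks.append(ConvBlock2d(rng(), cin2d, w))
            cin2d = 2 * w  # conv output concatenated with same-width bridge

        enc_ch = [2 * w for w in widths]  # channels of concatenated level features

        # decoder: three gated DeConv stages, deepest first
        dec_ch = [widths[2], widths[1], widths[0]]  # outputs of d3, d2, d1
        self.gates = [
            AttentionGate(rng(), enc_ch[2], enc_ch[3]),
            AttentionGate(rng(), enc_ch[1], dec_ch[0]),
            AttentionGate(rng(), enc_ch[0], dec_ch[1]),
        ]
        self.deconvs = [
            DeConvBlock(rng(), enc_ch[3], enc_ch[2], dec_ch[0]),
            DeConvBlock(rng(), dec_ch[0], enc_ch[1], dec_ch[1]),
            DeConvBlock(rng(), dec_ch[1], enc_ch[0], dec_ch[2]),
        ]

        hc = cfg.head_classes
        self.aux_heads = [
            AuxiliaryHead(rng(), dec_ch[0], 3, hc[0]),
            AuxiliaryHead(rng(), dec_ch[1], 2, hc[1]),
            AuxiliaryHead(rng(), dec_ch[2], 1, hc[2]),
        ]
        self.final_up = ConvTranspose2x(rng(), dec_ch[2], dec_ch[2])
        self.final_proj = Conv(rng(), dec_ch[2], hc[3], 1)

    # -- forward -----------------------------------------------------
    def __call__(self, image2d, patch3d) -> list[Tensor]:
        """Run both encoders and the decoder; return 4 probability maps.

        ``image2d``: (N, M, H, W); ``patch3d``: (N, M, D, H, W).  Every
        returned map has spatial size (H, W); channel counts follow
        ``cfg.head_classes``.
        """
        x2 = ag.as_tensor(image2d)
        x3 = ag.as_tensor(patch3d)
        if x2.ndim == 3:
            x2 = ag.reshape(x2, (1,) + x2.shape)
        if x3.ndim == 4:
            x3 = ag.reshape(x3, (1,) + x3.shape)
        if x2.shape[2:] != tuple(self.cfg.in_plane):
            raise ValueError(f"expected in-plane size {self.cfg.in_plane}, "
                             f"got {x2.shape[2:]}")

        # 3D path
        bridge_feats = []
        h3 = x3
        for down, same, bridge in zip(self.res_down, self.res_same, self.bridges):
            h3 = same(down(h3))
            bridge_feats.append(bridge(h3))

        # 2D path with per-level concatenation
        enc_feats = []
        h2 = x2
        for block, bf in zip(self.conv_blocks, bridge_feats):
            h2 = ag.concat([block(h2), bf], axis=1)
            enc_feats.append(h2)

        e1, e2, e3, e4 = enc_feats
        d3 = self.deconvs[0](e4, self.gates[0](e3, e4))
        d2 = self.deconvs[1](d3, self.gates[1](e2, d3))
        d1 = self.deconvs[2](d2, self.gates[2](e1, d2))

        out = [head(feat) for head, feat in zip(self.aux_heads, (d3, d2, d1))]
        final = ag.softmax_channel(self.final_proj(ag.relu(self.final_up(d1))))
        out.append(final)
        return out

    def n_parameters(self) -> int:
        return sum(p.data.size for p in self.parameters())
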