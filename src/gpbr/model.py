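"""Dual-branch CAM classifier over a shared CNN backbone.

The backbone maps a (1, n_mels, T) log-mel input to a dense feature map
F of shape (d, h, w). Each classification head is a bias-free 1x1
convolution producing per-class activation maps

    M_j(x, y) = sum_k W_{j,k} F_k(x, y),

whose global average pool (GAP) equals the class score S_j — the same
number a fully connected layer on GAP(F) with the same weights would
give, since both orders of summation commute. Two independent heads share
the backbone: during training they compete (see :mod:`gpbr.losses`); at
inference a single head suffices.

The registry mirrors the standard torchvision-style architectures with
the classifier removed and the first convolution adapted to one input
channel. ``tinycnn`` is a small four-block backbone for desk-scale
training and tests.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from . import nn
from .features import MelFeature, standardize

__all__ = [
    "FeatureMap", "CamOutput", "DualBranchModel", "BACKBONES",
    "build_model", "cam_forward", "predict", "inference_parameter_count",
    "save_model", "load_model",
]


# ---------------------------------------------------------------------------
# backbone registry
# ---------------------------------------------------------------------------

def _conv_bn_act(in_ch, out_ch, k, s, p, rng, act=nn.ReLU, groups=1):
    return nn.Sequential(
        nn.Conv2d(in_ch, out_ch, k, s, p, groups=groups, rng=rng),
        nn.BatchNorm2d(out_ch), act(),
    )


def _tinycnn(in_channels: int, rng) -> tuple[nn.Module, int]:
    layers, ch = [], in_channels
    for out in (8, 16, 32, 64):
        layers += [nn.Conv2d(ch, out, 3, 1, 1, rng=rng), nn.BatchNorm2d(out),
                   nn.ReLU(), nn.MaxPool2d(2)]
        ch = out
    return nn.Sequential(*layers), 64


def _bottleneck(in_ch, planes, stride, rng):
    out_ch = planes * 4
    main = nn.Sequential(
        nn.Conv2d(in_ch, planes, 1, rng=rng), nn.BatchNorm2d(planes), nn.ReLU(),
        nn.Conv2d(planes, planes, 3, stride, 1, rng=rng), nn.BatchNorm2d(planes),
        nn.ReLU(),
        nn.Conv2d(planes, out_ch, 1, rng=rng), nn.BatchNorm2d(out_ch),
    )
    shortcut = None
    if stride != 1 or in_ch != out_ch:
        shortcut = nn.Sequential(nn.Conv2d(in_ch, out_ch, 1, stride, rng=rng),
                                 nn.BatchNorm2d(out_ch))
    return nn.Residual(main, shortcut, nn.ReLU())


def _resnet50(in_channels: int, rng) -> tuple[nn.Module, int]:
    layers = [nn.Conv2d(in_channels, 64, 7, 2, 3, rng=rng), nn.BatchNorm2d(64),
              nn.ReLU(), nn.MaxPool2d(3, 2, 1)]
    in_ch = 64
    for planes, blocks, stride in ((64, 3, 1), (128, 4, 2), (256, 6, 2), (512, 3, 2)):
        for b in range(blocks):
            layers.append(_bottleneck(in_ch, planes, stride if b == 0 else 1, rng))
            in_ch = planes * 4
    return nn.Sequential(*layers), 2048


def _vgg16(in_channels: int, rng) -> tuple[nn.Module, int]:
    cfg = [64, 64, "M", 128, 128, "M", 256, 256, 256, "M",
           512, 512, 512, "M", 512, 512, 512, "M"]
    layers, ch = [], in_channels
    for v in cfg:
        if v == "M":
            layers.append(nn.MaxPool2d(2))
        else:
            layers += [nn.Conv2d(ch, v, 3, 1, 1, bias=True, rng=rng), nn.ReLU()]
            ch = v
    return nn.Sequential(*layers), 512


def _mobilenet_v1(in_channels: int, rng) -> tuple[nn.Module, int]:
    def dw_sep(in_ch, out_ch, s):
        return nn.Sequential(
            nn.Conv2d(in_ch, in_ch, 3, s, 1, groups=in_ch, rng=rng),
            nn.BatchNorm2d(in_ch), nn.ReLU(),
            nn.Conv2d(in_ch, out_ch, 1, rng=rng), nn.BatchNorm2d(out_ch), nn.ReLU(),
        )
    cfg = [(64, 1), (128, 2), (128, 1), (256, 2), (256, 1), (512, 2),
           (512, 1), (512, 1), (512, 1), (512, 1), (512, 1), (1024, 2), (1024, 1)]
    layers = [_conv_bn_act(in_channels, 32, 3, 2, 1, rng)]
    ch = 32
    for out, s in cfg:
        layers.append(dw_sep(ch, out, s))
        ch = out
    return nn.Sequential(*layers), 1024


def _inverted_residual_v2(in_ch, out_ch, stride, expand, rng):
    hidden = in_ch * expand
    main_layers = []
    if expand != 1:
        main_layers += [nn.Conv2d(in_ch, hidden, 1, rng=rng),
                        nn.BatchNorm2d(hidden), nn.ReLU6()]
    main_layers += [
        nn.Conv2d(hidden, hidden, 3, stride, 1, groups=hidden, rng=rng),
        nn.BatchNorm2d(hidden), nn.ReLU6(),
        nn.Conv2d(hidden, out_ch, 1, rng=rng), nn.BatchNorm2d(out_ch),
    ]
    main = nn.Sequential(*main_layers)
    if stride == 1 and in_ch == out_ch:
        return nn.Residual(main)
    return main


def _mobilenet_v2(in_channels: int, rng) -> tuple[nn.Module, int]:
    cfg = [(1, 16, 1, 1), (6, 24, 2, 2), (6, 32, 3, 2), (6, 64, 4, 2),
           (6, 96, 3, 1), (6, 160, 3, 2), (6, 320, 1, 1)]
    layers = [_conv_bn_act(in_channels, 32, 3, 2, 1, rng, act=nn.ReLU6)]
    ch = 32
    for t, c, n, s in cfg:
        for i in range(n):
            layers.append(_inverted_residual_v2(ch, c, s if i == 0 else 1, t, rng))
            ch = c
    layers.append(_conv_bn_act(ch, 1280, 1, 1, 0, rng, act=nn.ReLU6))
    return nn.Sequential(*layers), 1280


def _make_divisible(v: float, divisor: int = 8) -> int:
    new_v = max(divisor, int(v + divisor / 2) // divisor * divisor)
    if new_v < 0.9 * v:
        new_v += divisor
    return new_v


def _mbconv_v3(in_ch, k, exp, out_ch, use_se, act_cls, stride, rng):
    layers = []
    if exp != in_ch:
        layers += [nn.Conv2d(in_ch, exp, 1, rng=rng), nn.BatchNorm2d(exp), act_cls()]
    layers += [nn.Conv2d(exp, exp, k, stride, k // 2, groups=exp, rng=rng),
               nn.BatchNorm2d(exp), act_cls()]
    if use_se:
        layers.append(nn.SqueezeExcite(exp, _make_divisible(exp // 4), rng,
                                       act=nn.ReLU(), gate=nn.HardSigmoid()))
    layers += [nn.Conv2d(exp, out_ch, 1, rng=rng), nn.BatchNorm2d(out_ch)]
    main = nn.Sequential(*layers)
    if stride == 1 and in_ch == out_ch:
        return nn.Residual(main)
    return main


def _mobilenet_v3(in_channels: int, rng) -> tuple[nn.Module, int]:
    HS, RE = nn.HardSwish, nn.ReLU
    cfg = [  # kernel, expanded, out, SE, activation, stride (large variant)
        (3, 16, 16, False, RE, 1), (3, 64, 24, False, RE, 2),
        (3, 72, 24, False, RE, 1), (5, 72, 40, True, RE, 2),
        (5, 120, 40, True, RE, 1), (5, 120, 40, True, RE, 1),
        (3, 240, 80, False, HS, 2), (3, 200, 80, False, HS, 1),
        (3, 184, 80, False, HS, 1), (3, 184, 80, False, HS, 1),
        (3, 480, 112, True, HS, 1), (3, 672, 112, True, HS, 1),
        (5, 672, 160, True, HS, 2), (5, 960, 160, True, HS, 1),
        (5, 960, 160, True, HS, 1),
    ]
    layers = [_conv_bn_act(in_channels, 16, 3, 2, 1, rng, act=HS)]
    ch = 16
    for k, exp, out, se, act, s in cfg:
        layers.append(_mbconv_v3(ch, k, exp, out, se, act, s, rng))
        ch = out
    layers.append(_conv_bn_act(ch, 960, 1, 1, 0, rng, act=HS))
    return nn.Sequential(*layers), 960


def _shufflenet_v2(in_channels: int, rng) -> tuple[nn.Module, int]:
    stage_out = (116, 232, 464)  # width multiplier 1.0
    repeats = (4, 8, 4)
    layers = [nn.Conv2d(in_channels, 24, 3, 2, 1, rng=rng), nn.BatchNorm2d(24),
              nn.ReLU(), nn.MaxPool2d(3, 2, 1)]
    ch = 24
    for out, n in zip(stage_out, repeats):
        layers.append(nn.ShuffleUnit(ch, out, 2, rng))
        for _ in range(n - 1):
            layers.append(nn.ShuffleUnit(out, out, 1, rng))
        ch = out
    layers += [nn.Conv2d(ch, 1024, 1, rng=rng), nn.BatchNorm2d(1024), nn.ReLU()]
    return nn.Sequential(*layers), 1024


def _mbconv_b0(in_ch, k, expand, out_ch, stride, rng):
    hidden = in_ch * expand
    layers = []
    if expand != 1:
        layers += [nn.Conv2d(in_ch, hidden, 1, rng=rng), nn.BatchNorm2d(hidden),
                   nn.SiLU()]
    layers += [nn.Conv2d(hidden, hidden, k, stride, k // 2, groups=hidden, rng=rng),
               nn.BatchNorm2d(hidden), nn.SiLU(),
               nn.SqueezeExcite(hidden, max(1, in_ch // 4), rng,
                                act=nn.SiLU(), gate=nn.Sigmoid()),
               nn.Conv2d(hidden, out_ch, 1, rng=rng), nn.BatchNorm2d(out_ch)]
    main = nn.Sequential(*layers)
    if stride == 1 and in_ch == out_ch:
        return nn.Residual(main)
    return main


def _efficientnet_b0(in_channels: int, rng) -> tuple[nn.Module, int]:
    cfg = [(1, 3, 1, 16, 1), (6, 3, 2, 24, 2), (6, 5, 2, 40, 2),
           (6, 3, 2, 80, 3), (6, 5, 1, 112, 3), (6, 5, 2, 192, 4),
           (6, 3, 1, 320, 1)]
    layers = [_conv_bn_act(in_channels, 32, 3, 2, 1, rng, act=nn.SiLU)]
    ch = 32
    for t, k, s, out, n in cfg:
        for i in range(n):
            layers.append(_mbconv_b0(ch, k, t, out, s if i == 0 else 1, rng))
            ch = out
    layers.append(_conv_bn_act(ch, 1280, 1, 1, 0, rng, act=nn.SiLU))
    return nn.Sequential(*layers), 1280


BACKBONES = {
    "tinycnn": _tinycnn,
    "resnet50": _resnet50,
    "vgg16": _vgg16,
    "mobilenet_v1": _mobilenet_v1,
    "mobilenet_v2": _mobilenet_v2,
    "mobilenet_v3": _mobilenet_v3,
    "shufflenet_v2": _shufflenet_v2,
    "efficientnet_b0": _efficientnet_b0,
}


# ---------------------------------------------------------------------------
# dual-branch model
# ---------------------------------------------------------------------------

@dataclass
class FeatureMap:
    """Backbone output F: batch of (d, h, w) local-feature grids."""

    F: np.ndarray  # (N, d, h, w)

    def __post_init__(self) -> None:
        self.F = np.asarray(self.F, dtype=np.float64)
        if self.F.ndim != 4:
            raise ValueError("feature map must be (N, d, h, w)")


@dataclass
class CamOutput:
    """Per-class activation maps M (N, C, h, w) and class scores S (N, C)."""

    M: np.ndarray
    S: np.ndarray

    def __post_init__(self) -> None:
        if self.M.shape[:2] != self.S.shape or self.M.ndim != 4:
            raise ValueError("M must be (N, C, h, w) with S of shape (N, C)")


class DualBranchModel(nn.Module):
    """Shared backbone with two competing bias-free 1x1-conv heads."""

    def __init__(self, backbone: nn.Module, head1: nn.Conv2d, head2: nn.Conv2d,
                 class_names: list[str], backbone_name: str = "",
                 feature_dim: int = 0):
        self.backbone = backbone
        self.head1 = head1
        self.head2 = head2
        self.class_names = list(class_names)
        self.backbone_name = backbone_name
        self.feature_dim = feature_dim

    @property
    def n_classes(self) -> int:
        return len(self.class_names)

    def forward_features(self, x: np.ndarray) -> FeatureMap:
        return FeatureMap(F=self.backbone(x))

    def forward(self, x: np.ndarray):
        """Both branches' CAM outputs for a batch of inputs."""
        fmap = self.forward_features(x)
        return cam_forward(fmap, self.head1), cam_forward(fmap, self.head2)


def build_model(backbone_name: str, n_classes: int, in_channels: int = 1,
                class_names: list[str] | None = None,
                seed: int = 0) -> DualBranchModel:
    """Instantiate a dual-branch model from the backbone registry."""
    if backbone_name not in BACKBONES:
        raise KeyError(
            f"unknown backbone {backbone_name!r}; available: {sorted(BACKBONES)}"
        )
    if n_classes < 2:
        raise ValueError("n_classes must be >= 2")
    rng = np.random.default_rng(seed)
    backbone, d = BACKBONES[backbone_name](in_channels, rng)
    head1 = nn.Conv2d(d, n_classes, 1, bias=False, rng=rng)
    head2 = nn.Conv2d(d, n_classes, 1, bias=False, rng=rng)
    names = class_names or [f"class_{i}" for i in range(n_classes)]
    if len(names) != n_classes:
        raise ValueError("class_names length must equal n_classes")
    return DualBranchModel(backbone, head1, head2, names,
                           backbone_name=backbone_name, feature_dim=d)


def cam_forward(fmap: FeatureMap, head: nn.Conv2d) -> CamOutput:
    """CAMs and scores from one head: M = conv1x1(F), S = GAP(M)."""
    if fmap.F.shape[1] != head.in_ch:
        raise ValueError(
            f"feature dim {fmap.F.shape[1]} does not match head input {head.in_ch}"
        )
    M = head(fmap.F)
    return CamOutput(M=M, S=M.mean(axis=(2, 3)))


def predict(model: DualBranchModel, feature: MelFeature,
            branch: str | int = 1) -> np.ndarray:
    """Class-score vector for one clip from branch 1, 2, or their mean.

    Scores are raw (pre-softmax); the per-clip standardized feature is fed
    to the network, matching the training-time scaling.
    """
    x = standardize(feature).values[None, ...]  # (1, 1, n_mels, T)
    model.eval()
    out1, out2 = model.forward(x)
    if str(branch) == "1":
        return out1.S[0]
    if str(branch) == "2":
        return out2.S[0]
    if str(branch) == "mean":
        return 0.5 * (out1.S[0] + out2.S[0])
    raise ValueError(f"branch must be 1, 2 or 'mean', got {branch!r}")


def inference_parameter_count(model: DualBranchModel) -> int:
    """Trainable parameters of the inference path (backbone + one head)."""
    return model.backbone.n_parameters() + model.head1.n_parameters()


# ---------------------------------------------------------------------------
# checkpoints
# ---------------------------------------------------------------------------

def _state_entries(model: DualBranchModel):
    """Deterministic (name, array) walk over params and BN running stats."""
    idx = 0
    stack: list[nn.Module] = [model]
    while stack:
        mod = stack.pop(0)
        for v in mod.__dict__.values():
            if isinstance(v, nn.Param):
                yield f"p{idx}", v.data
                idx += 1
        if isinstance(mod, nn.BatchNorm2d):
            yield f"p{idx}_rm", mod.running_mean
            yield f"p{idx}_rv", mod.running_var
            idx += 1
        stack = list(mod.children()) + stack


def save_model(model: DualBranchModel, path) -> None:
    meta = json.dumps({
        "backbone": model.backbone_name,
        "n_classes": model.n_classes,
        "class_names": model.class_names,
        "feature_dim": model.feature_dim,
    })
    arrays = {name: arr for name, arr in _state_entries(model)}
    np.savez(path, _meta=np.frombuffer(meta.encode(), dtype=np.uint8), **arrays)


def load_model(path) -> DualBranchModel:
    with np.load(path) as data:
        meta = json.loads(bytes(data["_meta"]).decode())
        model = build_model(meta["backbone"], meta["n_classes"],
                            class_names=meta["class_names"])
        for name, arr in _state_entries(model):
            arr[...] = data[name]
    return model
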