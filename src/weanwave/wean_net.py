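"""Two-branch CNN for weaning-outcome prediction.

Architecture
------------
Each branch is a MobileNetV3-Large feature extractor at 0.75 width
(stem conv, 15 inverted-residual bottlenecks, 1x1 head conv to 720
channels), applied to the folded 2-D image of one modality (3-channel
waveform / 25-channel numeric).  The two pre-pool 720-channel maps are
each adaptively average-pooled to 10 spatial slots and concatenated into
a 720 x 20 fused map, which an MLP (1x1 conv 720->36 + batch norm +
hard-swish, flatten to 720, two skip-connected subblocks 720->3724->720)
encodes to a 720-vector.  That vector is concatenated with the two
globally pooled 720-vectors and classified by two biased 1x1 convolutions
(2160 -> 1280, hard-swish, 1280 -> 1).  The single output is a logit for
*weaning failure* (the positive class); apply a sigmoid at predict time.

Global pooling makes the forward pass independent of the input sequence
length, so full uncropped recordings are used at inference.

With the default specification the census is exactly 17,124,721
trainable parameters; ``scripts/backsolve_census.py`` documents the
exhaustive search that fixes the MLP dimensions, which are not
architecturally constrained otherwise.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import numpy as np

from . import nn
from .preprocess import PreprocessConfig, prepare_inputs
from .vent_data import SBTRecord, ValidationError

__all__ = [
    "ConstructionError",
    "BneckSpec",
    "ExtractorSpec",
    "MLPSpec",
    "ModelSpec",
    "AssembledModel",
    "TABLE1_BNECKS",
    "build_extractor",
    "build_subblock",
    "build_mlp",
    "fuse_features",
    "assemble_model",
    "count_parameters",
    "parameter_census",
    "predict",
    "predict_proba_batch",
    "save_checkpoint",
    "load_checkpoint",
]


class ConstructionError(ValueError):
    """A model specification is internally inconsistent."""


def make_divisible(v: float, divisor: int = 8) -> int:
    """Round channel counts to a multiple of ``divisor``, never dropping
    below 90% of the requested width (the MobileNet rounding rule)."""
    new_v = max(divisor, int(v + divisor / 2) // divisor * divisor)
    if new_v < 0.9 * v:
        new_v += divisor
    return new_v


@dataclass(frozen=True)
class BneckSpec:
    """One inverted-residual bottleneck row."""

    kernel: int
    expand_size: int
    out_channels: int
    activation: str            # "relu" | "hard_swish"
    use_se: bool
    stride: int

    def __post_init__(self):
        if self.kernel not in (3, 5):
            raise ConstructionError(f"kernel must be 3 or 5, got {self.kernel}")
        if self.stride not in (1, 2):
            raise ConstructionError(f"stride must be 1 or 2, got {self.stride}")
        if self.activation not in ("relu", "hard_swish"):
            raise ConstructionError(f"unknown activation {self.activation!r}")
        if self.expand_size < self.out_channels:
            raise ConstructionError(
                f"expand_size {self.expand_size} < out_channels {self.out_channels}"
            )
        if self.out_channels < 1:
            raise ConstructionError("out_channels must be positive")


# The 15 bottleneck rows of the 0.75-width MobileNetV3-Large backbone:
# (kernel, expand, out, activation, squeeze-excitation, stride).  Expand
# and out channels follow the published table at 0.75 width with
# multiple-of-8 rounding; SE placement and strides follow the standard
# large layout (the row listing omits both).
TABLE1_BNECKS: tuple[BneckSpec, ...] = tuple(
    BneckSpec(k, e, o, a, se, s)
    for (k, e, o, a, se, s) in [
        (3, 16, 16, "relu", False, 1),
        (3, 64, 24, "relu", False, 2),
        (3, 72, 24, "relu", False, 1),
        (5, 72, 32, "relu", True, 2),
        (5, 96, 32, "relu", True, 1),
        (5, 96, 32, "relu", True, 1),
        (3, 192, 64, "hard_swish", False, 2),
        (3, 160, 64, "hard_swish", False, 1),
        (3, 144, 64, "hard_swish", False, 1),
        (3, 144, 64, "hard_swish", False, 1),
        (3, 384, 88, "hard_swish", True, 1),
        (3, 528, 88, "hard_swish", True, 1),
        (5, 528, 120, "hard_swish", True, 2),
        (5, 720, 120, "hard_swish", True, 1),
        (5, 720, 120, "hard_swish", True, 1),
    ]
)


@dataclass(frozen=True)
class ExtractorSpec:
    """Feature-extractor branch: stem conv, 15 bottlenecks, 720-ch head."""

    stem_in_channels: int
    stem_out: int = 16
    bnecks: tuple[BneckSpec, ...] = TABLE1_BNECKS
    head_conv_out: int = 720

    def __post_init__(self):
        if len(self.bnecks) != 15:
            raise ConstructionError(
                f"extractor requires exactly 15 bottlenecks, got {len(self.bnecks)}"
            )
        if self.head_conv_out != 720:
            raise ConstructionError("head conv out-channels must be 720")
        cin = self.stem_out
        for i, b in enumerate(self.bnecks):
            # the first bottleneck's expansion equals its input width
            if i == 0 and b.expand_size != cin:
                raise ConstructionError(
                    f"bneck row 1: expand {b.expand_size} != stem out {cin}"
                )
            cin = b.out_channels


@dataclass(frozen=True)
class MLPSpec:
    """Fused-feature encoder dimensions.

    ``subblock_dim`` must equal ``conv1x1_out * fusion_positions``
    (the flattened size after the 1x1 conv); the defaults are the
    back-solved values that reproduce the published parameter census.
    """

    conv1x1_in: int = 720
    conv1x1_out: int = 36
    subblock_dim: int = 720
    subblock_hidden: int = 3724

    def __post_init__(self):
        if min(self.conv1x1_in, self.conv1x1_out,
               self.subblock_dim, self.subblock_hidden) < 1:
            raise ConstructionError("MLP dimensions must be positive")


@dataclass(frozen=True)
class ModelSpec:
    waveform_extractor: ExtractorSpec = field(
        default_factory=lambda: ExtractorSpec(stem_in_channels=3))
    numeric_extractor: ExtractorSpec = field(
        default_factory=lambda: ExtractorSpec(stem_in_channels=25))
    fusion_positions: int = 20
    mlp: MLPSpec = field(default_factory=MLPSpec)
    classifier_hidden: int = 1280
    classifier_out: int = 1

    def __post_init__(self):
        if self.classifier_out != 1:
            raise ConstructionError("classifier_out must be 1 (single logit)")
        if self.classifier_hidden != 1280:
            raise ConstructionError("classifier_hidden must be 1280")
        if self.fusion_positions % 2 != 0 or self.fusion_positions < 2:
            raise ConstructionError(
                "fusion_positions must be an even positive number")


# ---------------------------------------------------------------------------
# components

_ACTS = {"relu": nn.ReLU, "hard_swish": nn.HardSwish}


class Bneck(nn.Module):
    """Inverted residual: 1x1 expand -> depthwise -> (SE) -> 1x1 project,
    residual skip when stride is 1 and channel widths match."""

    def __init__(self, cin: int, spec: BneckSpec, rng):
        self.spec = spec
        self.cin = cin
        act = _ACTS[spec.activation]
        self.expand = None
        if spec.expand_size != cin:
            self.expand = nn.Conv2d(cin, spec.expand_size, 1, rng=rng)
            self.bn_e = nn.BatchNorm2d(spec.expand_size)
            self.act_e = act()
        self.dw = nn.Conv2d(spec.expand_size, spec.expand_size, spec.kernel,
                            stride=spec.stride, groups=spec.expand_size, rng=rng)
        self.bn_d = nn.BatchNorm2d(spec.expand_size)
        self.act_d = act()
        self.se = None
        if spec.use_se:
            sq = make_divisible(spec.expand_size // 4, 8)
            self.se = nn.SqueezeExcite(spec.expand_size, sq, rng=rng)
        self.project = nn.Conv2d(spec.expand_size, spec.out_channels, 1, rng=rng)
        self.bn_p = nn.BatchNorm2d(spec.out_channels)
        self.residual = spec.stride == 1 and cin == spec.out_channels
        if self.residual:
            # zero-gamma init: residual blocks start as identities, which
            # preserves inter-sample signal through the deep stack and makes
            # short training runs effective from the first step
            self.bn_p.weight.data[...] = 0.0

    def forward(self, x, training=False):
        h = x
        if self.expand is not None:
            h = self.act_e(self.bn_e(self.expand(h, training), training))
        h = self.act_d(self.bn_d(self.dw(h, training), training))
        if self.se is not None:
            h = self.se(h, training)
        h = self.bn_p(self.project(h, training), training)
        return h + x if self.residual else h

    def backward(self, grad):
        g = self.project.backward(self.bn_p.backward(grad))
        if self.se is not None:
            g = self.se.backward(g)
        g = self.dw.backward(self.bn_d.backward(self.act_d.backward(g)))
        if self.expand is not None:
            g = self.expand.backward(self.bn_e.backward(self.act_e.backward(g)))
        return g + grad if self.residual else g


class Extractor(nn.Module):
    """Stem conv (stride 2) -> 15 bottlenecks -> 1x1 head conv to 720.

    ``forward`` returns the pre-pool 720-channel map; this map is also
    the Grad-CAM target layer.
    """

    def __init__(self, spec: ExtractorSpec, rng):
        self.spec = spec
        self.stem = nn.Conv2d(spec.stem_in_channels, spec.stem_out, 3,
                              stride=2, rng=rng)
        self.bn_s = nn.BatchNorm2d(spec.stem_out)
        self.act_s = nn.HardSwish()
        blocks = []
        cin = spec.stem_out
        for i, b in enumerate(spec.bnecks):
            try:
                blocks.append(Bneck(cin, b, rng))
            except (ConstructionError, ValueError) as exc:
                raise ConstructionError(f"bneck row {i + 1}: {exc}") from exc
            cin = b.out_channels
        self.blocks = nn.Sequential(*blocks)
        self.head = nn.Conv2d(cin, spec.head_conv_out, 1, rng=rng)
        self.bn_h = nn.BatchNorm2d(spec.head_conv_out)
        self.act_h = nn.HardSwish()

    @property
    def n_bnecks(self) -> int:
        return len(self.blocks.layers)

    def forward(self, x, training=False):
        h = self.act_s(self.bn_s(self.stem(x, training), training))
        h = self.blocks(h, training)
        return self.act_h(self.bn_h(self.head(h, training), training))

    def backward(self, grad):
        g = self.head.backward(self.bn_h.backward(self.act_h.backward(grad)))
        g = self.blocks.backward(g)
        return self.stem.backward(self.bn_s.backward(self.act_s.backward(g)))


class Subblock(nn.Module):
    """linear -> batch norm -> SiLU -> linear, skip add of the input,
    then SiLU.  Preserves its input dimension."""

    def __init__(self, dim: int, hidden: Optional[int] = None, rng=None):
        hidden = hidden or dim
        self.lin1 = nn.Linear(dim, hidden, rng=rng)
        self.bn = nn.BatchNorm1d(hidden)
        self.act1 = nn.SiLU()
        self.lin2 = nn.Linear(hidden, dim, rng=rng)
        self.act_out = nn.SiLU()

    def forward(self, x, training=False):
        h = self.lin2(self.act1(self.bn(self.lin1(x, training), training)))
        return self.act_out(h + x)

    def backward(self, grad):
        g = self.act_out.backward(grad)
        gb = self.lin1.backward(self.bn.backward(
            self.act1.backward(self.lin2.backward(g))))
        return gb + g


def build_subblock(dim: int, hidden: Optional[int] = None, rng=None) -> Subblock:
    if dim < 1:
        raise ConstructionError("subblock dim must be >= 1")
    return Subblock(dim, hidden, rng=rng or np.random.default_rng(0))


class MLP(nn.Module):
    """1x1 conv + BN + hard-swish on the fused map, flatten, two subblocks."""

    def __init__(self, spec: MLPSpec, positions: int, rng):
        if spec.conv1x1_out >= spec.conv1x1_in:
            raise ConstructionError(
                "MLP must encode to a lower dimension: "
                f"conv1x1_out {spec.conv1x1_out} >= conv1x1_in {spec.conv1x1_in}"
            )
        if spec.subblock_dim != spec.conv1x1_out * positions:
            raise ConstructionError(
                f"subblock_dim {spec.subblock_dim} != conv1x1_out x positions "
                f"({spec.conv1x1_out} x {positions})"
            )
        self.spec = spec
        self.conv = nn.Conv2d(spec.conv1x1_in, spec.conv1x1_out, 1, rng=rng)
        self.bn = nn.BatchNorm2d(spec.conv1x1_out)
        self.act = nn.HardSwish()
        self.sub1 = Subblock(spec.subblock_dim, spec.subblock_hidden, rng=rng)
        self.sub2 = Subblock(spec.subblock_dim, spec.subblock_hidden, rng=rng)

    def forward(self, fused, training=False):
        h = self.act(self.bn(self.conv(fused, training), training))
        self._map_shape = h.shape
        z = h.reshape(h.shape[0], -1)
        return self.sub2(self.sub1(z, training), training)

    def backward(self, grad):
        g = self.sub1.backward(self.sub2.backward(grad))
        g = g.reshape(self._map_shape)
        return self.conv.backward(self.bn.backward(self.act.backward(g)))


def build_mlp(spec: MLPSpec, positions: int = 20,
              rng=None) -> MLP:
    return MLP(spec, positions, rng or np.random.default_rng(0))


class _FusePool(nn.Module):
    """Adaptive-pool both branch maps to positions/2 slots and concatenate
    along the spatial axis -> (N, 720, 1, positions)."""

    def __init__(self, positions: int):
        if positions % 2 != 0:
            raise ValidationError("fusion positions must be even")
        self.positions = positions
        self.pool_w = nn.AdaptiveAvgPool2d((1, positions // 2))
        self.pool_n = nn.AdaptiveAvgPool2d((1, positions // 2))

    def forward(self, wave_map, num_map, training=False):
        if wave_map.shape[1] != num_map.shape[1]:
            raise ConstructionError(
                "fusion junction: branch channel widths differ "
                f"({wave_map.shape[1]} vs {num_map.shape[1]})"
            )
        pw = self.pool_w(wave_map, training)
        pn = self.pool_n(num_map, training)
        return np.concatenate([pw, pn], axis=3)

    def backward(self, grad):
        half = self.positions // 2
        return (self.pool_w.backward(grad[:, :, :, :half]),
                self.pool_n.backward(grad[:, :, :, half:]))


def fuse_features(wave_map: np.ndarray, num_map: np.ndarray,
                  positions: int = 20) -> np.ndarray:
    """Functional fusion of two pre-pool 720-channel maps (see _FusePool)."""
    return _FusePool(positions).forward(np.asarray(wave_map),
                                        np.asarray(num_map))


def build_extractor(spec: ExtractorSpec, rng=None) -> Extractor:
    return Extractor(spec, rng or np.random.default_rng(0))


class WeanNet(nn.Module):
    """The assembled two-branch network; ``forward`` returns logits (N,)."""

    def __init__(self, spec: ModelSpec, rng):
        self.spec = spec
        self.wave_extractor = Extractor(spec.waveform_extractor, rng)
        self.num_extractor = Extractor(spec.numeric_extractor, rng)
        self.fuse = _FusePool(spec.fusion_positions)
        self.mlp = MLP(spec.mlp, spec.fusion_positions, rng)
        cat_dim = spec.mlp.subblock_dim + 2 * spec.waveform_extractor.head_conv_out
        # classifier = two biased 1x1 convolutions on a 1x1 map, i.e. linears
        self.cls1 = nn.Linear(cat_dim, spec.classifier_hidden, rng=rng)
        self.cls_act = nn.HardSwish()
        self.cls2 = nn.Linear(spec.classifier_hidden, spec.classifier_out, rng=rng)
        self._cache = None

    def forward(self, xw, xn, training: bool = False):
        Aw = self.wave_extractor(xw, training)
        An = self.num_extractor(xn, training)
        vw = Aw.mean(axis=(2, 3))
        vn = An.mean(axis=(2, 3))
        fused = self.fuse.forward(Aw, An, training)
        z = self.mlp(fused, training)
        cat = np.concatenate([z, vw, vn], axis=1)
        logit = self.cls2(self.cls_act(self.cls1(cat, training)))[:, 0]
        self._cache = (Aw, An)
        return logit

    @property
    def feature_maps(self) -> tuple[np.ndarray, np.ndarray]:
        """Pre-pool 720-channel maps (waveform, numeric) of the last forward."""
        if self._cache is None:
            raise ValidationError("run forward before requesting feature maps")
        return self._cache

    def backward(self, dlogit: np.ndarray, into_extractors: bool = True):
        """Backpropagate d(loss)/d(logit); returns the gradients w.r.t. the
        two pre-pool feature maps (used by Grad-CAM).  With
        ``into_extractors`` the extractors' parameter grads are also
        accumulated."""
        Aw, An = self._cache
        g = self.cls2.backward(np.asarray(dlogit, dtype=np.float64)[:, None])
        g = self.cls1.backward(self.cls_act.backward(g))
        dz_dim = self.spec.mlp.subblock_dim
        gz = g[:, :dz_dim]
        gvw = g[:, dz_dim:dz_dim + 720]
        gvn = g[:, dz_dim + 720:]
        gfused = self.mlp.backward(gz)
        gAw_pool, gAn_pool = self.fuse.backward(gfused)
        hw_w = Aw.shape[2] * Aw.shape[3]
        hw_n = An.shape[2] * An.shape[3]
        gAw = gAw_pool + gvw[:, :, None, None] / hw_w
        gAn = gAn_pool + gvn[:, :, None, None] / hw_n
        if into_extractors:
            self.wave_extractor.backward(gAw)
            self.num_extractor.backward(gAn)
        return gAw, gAn


def parameter_census(model: nn.Module) -> list[tuple[str, tuple, int]]:
    return [(name, tuple(p.shape), p.size)
            for name, p in model.named_parameters()]


def count_parameters(model) -> int:
    """Total trainable entries; accepts a Module or AssembledModel."""
    if isinstance(model, AssembledModel):
        model = model.model
    return sum(p.size for p in model.parameters())


@dataclass
class AssembledModel:
    model: WeanNet
    spec: ModelSpec
    parameter_census: list[tuple[str, tuple, int]]

    @property
    def n_parameters(self) -> int:
        return sum(c for _, _, c in self.parameter_census)


def assemble_model(spec: Optional[ModelSpec] = None,
                   seed: int = 0) -> AssembledModel:
    """Build the full two-branch model from a specification.

    Initialization is deterministic under ``seed``.  Raises
    ConstructionError (naming the offending junction) on any internal
    width mismatch.
    """
    spec = spec or ModelSpec()
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    model = WeanNet(spec, rng)
    return AssembledModel(model=model, spec=spec,
                          parameter_census=parameter_census(model))


# ---------------------------------------------------------------------------
# inference


def predict_logit(assembled: AssembledModel, record: SBTRecord,
                  config: Optional[PreprocessConfig] = None) -> float:
    """Failure logit from the full-length record.

    Ranking metrics should use logits: extreme probabilities underflow to
    exactly 0 or 1 in floating point, collapsing distinct records into
    artificial ties.
    """
    config = config or PreprocessConfig()
    xw, xn = prepare_inputs(record, config, crop=False)
    if xw.shape[1] < 1 or xn.shape[1] < 1:
        raise ValidationError("sequence shorter than one fold row")
    return float(assembled.model.forward(xw[None], xn[None], training=False)[0])


def predict(assembled: AssembledModel, record: SBTRecord,
            config: Optional[PreprocessConfig] = None) -> float:
    """Probability of weaning *failure* from the full-length record."""
    return float(nn.sigmoid(predict_logit(assembled, record, config)))


def predict_logit_batch(assembled: AssembledModel, cohort,
                        config: Optional[PreprocessConfig] = None) -> np.ndarray:
    """Failure logits for every record (full-length inputs)."""
    return np.array([predict_logit(assembled, rec, config) for rec in cohort])


def predict_proba_batch(assembled: AssembledModel, cohort,
                        config: Optional[PreprocessConfig] = None) -> np.ndarray:
    """Failure probabilities for every record (full-length inputs)."""
    return nn.sigmoid(predict_logit_batch(assembled, cohort, config))


# ---------------------------------------------------------------------------
# checkpointing


def _walk_modules(module: nn.Module, prefix: str = ""):
    yield prefix.rstrip("."), module
    for name, child in module.__dict__.get("_children", {}).items():
        if isinstance(child, nn.Module):
            yield from _walk_modules(child, prefix + name + ".")


def _state_dict(model: nn.Module) -> dict[str, np.ndarray]:
    state = {name: p.data for name, p in model.named_parameters()}
    for mod_name, mod in _walk_modules(model):
        if hasattr(mod, "running_mean"):
            key = (mod_name + "." if mod_name else mod_name)
            state[key + "running_mean"] = mod.running_mean
            state[key + "running_var"] = mod.running_var
    return state


def save_checkpoint(assembled: AssembledModel, path) -> Path:
    """Single-file checkpoint with the parameter census embedded for an
    integrity check on load."""
    path = Path(path)
    if path.suffix != ".npz":
        path = path.with_name(path.name + ".npz")
    meta = {
        "census_total": assembled.n_parameters,
        "spec": _spec_to_dict(assembled.spec),
    }
    np.savez_compressed(path, __meta__=json.dumps(meta),
                        **_state_dict(assembled.model))
    return path


def load_checkpoint(path) -> AssembledModel:
    path = Path(path)
    with np.load(path, allow_pickle=False) as data:
        meta = json.loads(str(data["__meta__"]))
        spec = _spec_from_dict(meta["spec"])
        assembled = assemble_model(spec)
        state = _state_dict(assembled.model)
        for key, arr in state.items():
            if key not in data:
                raise ValidationError(f"checkpoint missing tensor {key!r}")
            if data[key].shape != arr.shape:
                raise ValidationError(f"checkpoint shape mismatch at {key!r}")
            arr[...] = data[key]
    if assembled.n_parameters != meta["census_total"]:
        raise ValidationError(
            "checkpoint census mismatch: "
            f"{assembled.n_parameters} != {meta['census_total']}"
        )
    return assembled


def _spec_to_dict(spec: ModelSpec) -> dict:
    return asdict(spec)


def _spec_from_dict(d: dict) -> ModelSpec:
    def ex(e):
        return ExtractorSpec(
            stem_in_channels=e["stem_in_channels"],
            stem_out=e["stem_out"],
            bnecks=tuple(BneckSpec(**b) for b in e["bnecks"]),
            head_conv_out=e["head_conv_out"],
        )

    return ModelSpec(
        waveform_extractor=ex(d["waveform_extractor"]),
        numeric_extractor=ex(d["numeric_extractor"]),
        fusion_positions=d["fusion_positions"],
        mlp=MLPSpec(**d["mlp"]),
        classifier_hidden=d["classifier_hidden"],
        classifier_out=d["classifier_out"],
    )
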