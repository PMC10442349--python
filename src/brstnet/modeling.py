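"""Backbone-agnostic gene-expression regressors with an auxiliary head.

An :class:`ExpressionModel` is a convolutional feature extractor whose
penultimate (pooled) features feed two linear heads: the *main* head predicts
the K highest-expressed genes and the *auxiliary* head — a single fully
connected layer — predicts all remaining genes.  Training minimizes

    L = L_main + lambda * L_aux

so the auxiliary task acts as a regularizer on the shared features; at
``lambda = 0`` the auxiliary head receives no gradient.

Both per-head losses default to mean squared error on log-transformed counts.
Targets are continuous, so a classification-style cross-entropy is not
meaningful here; ``smooth_l1`` is available as an alternative.

The backbone registry names the ten large architectures commonly used for
this task (ResNet101, Inception-v3, EfficientNet-b0..b5, ViT-B/16, ViT-B/32),
which are built through torchvision when a ``torch`` installation is present,
plus ``tiny_cnn`` — a small three-block NumPy convnet defined here that runs
everywhere and is the default for desk-scale experiments.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from . import _nn
from .core_io import ValidationError

__all__ = [
    "ExpressionModel",
    "LossSpec",
    "BACKBONES",
    "build_model",
    "combined_loss",
    "predict",
]

# torchvision constructors are looked up lazily; the names stay registered so
# configs validate and error messages can distinguish "unknown backbone" from
# "backbone needs torch".
_TORCH_BACKBONES = (
    "resnet101",
    "inception_v3",
    "efficientnet_b0",
    "efficientnet_b1",
    "efficientnet_b2",
    "efficientnet_b3",
    "efficientnet_b4",
    "efficientnet_b5",
    "vit_b16",
    "vit_b32",
)
BACKBONES = _TORCH_BACKBONES + ("tiny_cnn",)


@dataclass
class LossSpec:
    """Weight and per-head loss of the combined objective."""

    lambda_aux: float = 40.0
    loss: str = "mse"

    def __post_init__(self) -> None:
        if self.lambda_aux < 0:
            raise ValidationError("lambda_aux must be >= 0")
        if self.loss not in _nn.LOSS_FNS:
            raise ValidationError(
                f"unknown loss '{self.loss}'; choose from {sorted(_nn.LOSS_FNS)}"
            )

    @property
    def loss_fn(self) -> Callable:
        return _nn.LOSS_FNS[self.loss]


class ExpressionModel:
    """Feature extractor + main head (K genes) + optional auxiliary head."""

    def __init__(
        self,
        backbone_name: str,
        backbone: _nn.Sequential,
        feature_dim: int,
        n_main: int,
        n_aux: int,
        aux_enabled: bool,
        input_size: int,
        rng: np.random.Generator,
    ) -> None:
        self.backbone_name = backbone_name
        self.backbone = backbone
        self.feature_dim = feature_dim
        self.n_main = n_main
        self.n_aux = n_aux
        self.aux_enabled = aux_enabled and n_aux > 0
        self.input_size = input_size
        self.main_head = _nn.Linear(feature_dim, n_main, rng=rng)
        self.aux_head = (
            _nn.Linear(feature_dim, n_aux, rng=rng) if self.aux_enabled else None
        )

    # -- forward/backward -------------------------------------------------

    def forward(
        self, patches: np.ndarray, train: bool = True
    ) -> tuple[np.ndarray, np.ndarray | None]:
        if patches.ndim != 4 or patches.shape[1] != 3:
            raise ValidationError(
                f"expected (B, 3, s, s) standardized patches, got {patches.shape}"
            )
        if patches.shape[2] != self.input_size or patches.shape[3] != self.input_size:
            raise ValidationError(
                f"model expects {self.input_size}x{self.input_size} patches, "
                f"got {patches.shape[2]}x{patches.shape[3]}"
            )
        feats = self.backbone.forward(patches.astype(np.float32), train=train)
        main = self.main_head.forward(feats, train=train)
        aux = (
            self.aux_head.forward(feats, train=train) if self.aux_enabled else None
        )
        return main, aux

    def backward(self, grad_main: np.ndarray, grad_aux: np.ndarray | None) -> None:
        grad_feats = self.main_head.backward(grad_main)
        if self.aux_enabled and grad_aux is not None:
            grad_feats = grad_feats + self.aux_head.backward(grad_aux)
        self.backbone.backward(grad_feats)

    def parameters(self) -> list[tuple[_nn.Layer, str]]:
        params = self.backbone.parameters()
        params += [(self.main_head, n) for n in self.main_head.params]
        if self.aux_enabled:
            params += [(self.aux_head, n) for n in self.aux_head.params]
        return params

    def get_state(self) -> list[np.ndarray]:
        return _nn.get_state(self.parameters())

    def set_state(self, state: list[np.ndarray]) -> None:
        _nn.set_state(self.parameters(), state)


def _tiny_cnn(rng: np.random.Generator) -> tuple[_nn.Sequential, int]:
    """Three strided conv blocks + global average pooling -> 64 features."""
    layers = [
        _nn.Conv2d(3, 16, kernel=5, stride=2, pad=2, rng=rng),
        _nn.ReLU(),
        _nn.Conv2d(16, 32, kernel=3, stride=2, pad=1, rng=rng),
        _nn.ReLU(),
        _nn.Conv2d(32, 64, kernel=3, stride=2, pad=1, rng=rng),
        _nn.ReLU(),
        _nn.GlobalAvgPool(),
    ]
    return _nn.Sequential(layers), 64


def build_model(
    backbone_name: str,
    n_main: int,
    n_aux: int,
    aux_enabled: bool = True,
    pretrained: bool = False,
    input_size: int = 64,
    seed: int = 0,
) -> ExpressionModel:
    """Construct an expression model with randomly initialized weights.

    Weights are never pretrained by default (``pretrained`` is accepted for
    interface symmetry but only meaningful for torch backbones).  Two builds
    with the same seed have identical initial parameters.
    """
    if backbone_name not in BACKBONES:
        raise ValidationError(
            f"unknown backbone '{backbone_name}'; supported: {', '.join(BACKBONES)}"
        )
    rng = np.random.default_rng(seed)
    if backbone_name == "tiny_cnn":
        backbone, feature_dim = _tiny_cnn(rng)
    else:
        try:
            import torch  # noqa: F401
        except ImportError as exc:
            raise ValidationError(
                f"backbone '{backbone_name}' requires a torch/torchvision "
                "installation; 'tiny_cnn' is available without it"
            ) from exc
        raise NotImplementedError(
            f"torch backbone '{backbone_name}' wiring is not bundled; "
            "use tiny_cnn"
        )
    return ExpressionModel(
        backbone_name,
        backbone,
        feature_dim,
        n_main,
        n_aux,
        aux_enabled,
        input_size,
        rng,
    )


def combined_loss(
    main_pred: np.ndarray,
    main_target: np.ndarray,
    aux_pred: np.ndarray | None,
    aux_target: np.ndarray | None,
    spec: LossSpec,
) -> tuple[float, dict, np.ndarray, np.ndarray | None]:
    """Evaluate ``L = L_main + lambda * L_aux`` and the head gradients.

    Returns ``(total, components, grad_main, grad_aux)`` where ``components``
    holds the unweighted per-head losses.  ``grad_aux`` is ``None`` (and the
    auxiliary term is absent) when no auxiliary predictions are given;
    otherwise it is already scaled by lambda, so it vanishes at lambda = 0.
    """
    if main_pred.shape != main_target.shape:
        raise ValidationError(
            f"main shapes differ: {main_pred.shape} vs {main_target.shape}"
        )
    loss_fn = spec.loss_fn
    l_main, grad_main = loss_fn(main_pred, main_target)
    if aux_pred is None or aux_target is None or aux_target.shape[1] == 0:
        return l_main, {"main": l_main, "aux": 0.0}, grad_main, None
    if aux_pred.shape != aux_target.shape:
        raise ValidationError(
            f"aux shapes differ: {aux_pred.shape} vs {aux_target.shape}"
        )
    l_aux, grad_aux = loss_fn(aux_pred, aux_target)
    total = l_main + spec.lambda_aux * l_aux
    return (
        total,
        {"main": l_main, "aux": l_aux},
        grad_main,
        np.float32(spec.lambda_aux) * grad_aux,
    )


def predict(
    model: ExpressionModel, patches: np.ndarray, batch_size: int = 64
) -> tuple[np.ndarray, np.ndarray | None]:
    """Deterministic evaluation-mode prediction, batched.

    Batched and un-batched calls agree to float32 precision because every
    layer is a pure per-sample map.
    """
    mains, auxes = [], []
    for start in range(0, len(patches), batch_size):
        main, aux = model.forward(patches[start : start + batch_size], train=False)
        mains.append(main)
        if aux is not None:
            auxes.append(aux)
    main = (
        np.concatenate(mains)
        if mains
        else np.empty((0, model.n_main), dtype=np.float32)
    )
    aux = np.concatenate(auxes) if auxes else None
    return main, aux
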