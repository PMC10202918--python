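"""Saliency analyses for trained classifiers.

Three attribution mechanisms, all seeded from the pre-sigmoid class score
(the logit), which is standard practice and keeps the propagated
quantities on a common scale:

* **Layer-wise relevance propagation (LRP).**  The output score is
  redistributed backwards layer by layer, each lower-layer node j
  receiving R_j = sum_k z_jk / (sum_j z_jk) * R_k, where z_jk is node j's
  contribution to node k.  Fully connected layers use the basic LRP-0 rule
  (z_jk = a_j w_jk); convolutional layers use LRP-gamma, which favors
  positive contributions (z_jk = a_j (w_jk + gamma * max(w_jk, 0))).
  Denominators are epsilon-stabilized.  Bias terms enter the denominator
  but are not redistributed, so total relevance is conserved exactly only
  in bias-free networks.  Batchnorm layers are folded into the adjacent
  convolution beforehand, making every conv block a plain affine map.
  Max-pooling routes relevance to the winning input (winner-take-all);
  ReLU passes relevance through unchanged.

* **GradCAM.**  At a convolutional block output, each feature map n is
  weighted by the spatial mean of d(logit)/dA^n and the weighted sum is
  rectified: map = ReLU(sum_n w_n A^n).  The map lives at the feature-map
  resolution and is upsampled (linear interpolation) when combined with
  guided backpropagation.

* **Guided backpropagation (GBP).**  The plain gradient of the logit with
  respect to the input, except that at every ReLU the backward signal is
  zeroed both where the forward activation was non-positive (the ordinary
  rule) and where the incoming gradient is non-positive (the guiding
  gate).

* **Guided GradCAM (GGCAM)** is the elementwise product of the upsampled
  GradCAM map and the GBP gradient.
"""

from __future__ import annotations

from contextlib import contextmanager
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from . import nn

__all__ = [
    "PropagationRules",
    "RelevanceVolume",
    "lrp",
    "grad_cam",
    "guided_backprop",
    "guided_grad_cam",
    "fold_batchnorm",
]


@dataclass(frozen=True)
class PropagationRules:
    """LRP rule parameters: LRP-gamma on conv layers, LRP-0 on dense."""

    gamma: float = 0.25
    eps: float = 1e-9

    def __post_init__(self):
        if self.gamma < 0:
            raise ValueError("gamma must be nonnegative")
        if self.eps <= 0:
            raise ValueError("eps must be positive")


@dataclass
class RelevanceVolume:
    """Heatmap with provenance; same spatial shape as the model input."""

    values: np.ndarray
    method: str  # lrp | gradcam | gbp | ggcam
    model_id: str = ""
    sample_id: str = ""


def fold_batchnorm(conv: nn.Conv, bn: nn.BatchNorm) -> tuple[np.ndarray, np.ndarray]:
    """Effective (flat weight, bias) of conv followed by eval-mode batchnorm.

    BN(conv(x)) = s * (conv(x) - mean) + beta with s = gamma/sqrt(var+eps),
    an affine map per output channel, so w' = w * s and
    b' = (b - mean) * s + beta.
    """
    s = bn.gamma / np.sqrt(bn.running_var + bn.eps)
    w_eff = conv.w * s[None, :]
    b_eff = (conv.b - bn.running_mean) * s + bn.beta
    return w_eff.astype(np.float64), b_eff.astype(np.float64)


def _stabilize(z: np.ndarray, eps: float) -> np.ndarray:
    return z + eps * np.where(z >= 0, 1.0, -1.0)


def _affine_chain(model: nn.Sequential):
    """Collapse the layer list into LRP-ready ops, folding conv+batchnorm.

    Yields (kind, payload) with kind in {affine_conv, affine_dense, relu,
    pool, flatten}; ``in_act_index`` on affine ops says which recorded
    activation feeds them.
    """
    ops = []
    i = 0
    layers = model.layers
    while i < len(layers):
        layer = layers[i]
        if isinstance(layer, nn.Conv):
            if i + 1 < len(layers) and isinstance(layers[i + 1], nn.BatchNorm):
                w, b = fold_batchnorm(layer, layers[i + 1])
                ops.append(("affine_conv", (layer, w, b, i, i + 2)))
                i += 2
            else:
                ops.append(
                    ("affine_conv",
                     (layer, layer.w.astype(np.float64),
                      layer.b.astype(np.float64), i, i + 1))
                )
                i += 1
        elif isinstance(layer, nn.Dense):
            ops.append(
                ("affine_dense",
                 (layer, layer.w.astype(np.float64),
                  layer.b.astype(np.float64), i, i + 1))
            )
            i += 1
        elif isinstance(layer, nn.ReLU):
            ops.append(("relu", (layer, i, i + 1)))
            i += 1
        elif isinstance(layer, nn.MaxPool):
            ops.append(("pool", (layer, i, i + 1)))
            i += 1
        elif isinstance(layer, nn.Flatten):
            ops.append(("flatten", (layer, i, i + 1)))
            i += 1
        elif isinstance(layer, nn.BatchNorm):
            raise ValueError(
                "unsupported layer for LRP: BatchNorm not preceded by Conv "
                f"(layer index {i})"
            )
        else:
            raise ValueError(
                f"unsupported layer type for LRP: {type(layer).__name__} "
                f"(layer index {i})"
            )
    return ops


def _prepare_input(input_values: np.ndarray) -> np.ndarray:
    x = np.asarray(input_values, dtype=np.float32)
    return x[None, ..., None]  # add batch and channel axes


def lrp(
    model: nn.Sequential,
    input_values: np.ndarray,
    rules: PropagationRules = PropagationRules(),
    model_id: str = "",
    sample_id: str = "",
) -> RelevanceVolume:
    """Input-layer relevance heatmap for one sample.

    ``input_values`` is the bare spatial array (H, W[, D]); the returned
    heatmap has the same shape.  Relevance is seeded with the pre-sigmoid
    logit of the sample.
    """
    x = _prepare_input(input_values)
    logit = model.forward(x, record=True)
    acts = model.activations
    ops = _affine_chain(model)

    R = logit.astype(np.float64)  # (1, 1)
    for kind, payload in reversed(ops):
        if kind == "affine_dense":
            layer, w, b, i_in, _ = payload
            a = acts[i_in].astype(np.float64)
            z = a @ w + b
            s = R / _stabilize(z, rules.eps)
            R = a * (s @ w.T)
        elif kind == "affine_conv":
            layer, w, b, i_in, _ = payload
            a = acts[i_in].astype(np.float64)
            g = rules.gamma
            w_mod = w + g * np.maximum(w, 0.0)
            b_mod = b + g * np.maximum(b, 0.0)
            z = layer.conv_raw(a, w_mod, b_mod)
            s = R / _stabilize(z, rules.eps)
            R = a * layer.input_grad_raw(s, w_mod)
        elif kind == "pool":
            layer = payload[0]
            R = layer.backward(R)  # winner-take-all routing
        elif kind == "flatten":
            R = payload[0].backward(R)
        # relu: relevance passes through unchanged
    return RelevanceVolume(
        values=np.asarray(R)[0, ..., 0],
        method="lrp",
        model_id=model_id,
        sample_id=sample_id,
    )


def _last_pool_index(model: nn.Sequential) -> int:
    idx = [i for i, l in enumerate(model.layers) if isinstance(l, nn.MaxPool)]
    if not idx:
        raise ValueError("model has no pooling layer to target")
    return idx[-1]


def grad_cam(
    model: nn.Sequential,
    input_values: np.ndarray,
    target_layer: int | None = None,
    model_id: str = "",
    sample_id: str = "",
) -> RelevanceVolume:
    """Coarse class-activation map at a convolutional block output.

    ``target_layer`` indexes the layer whose *output* is the feature map
    (default: the last max-pool, i.e. the last conv block's output).  The
    map has the feature-map spatial shape and is nonnegative.
    """
    x = _prepare_input(input_values)
    model.forward(x, record=True)
    if target_layer is None:
        target_layer = _last_pool_index(model)
    if not 0 <= target_layer < len(model.layers):
        raise ValueError(f"target layer {target_layer} not in model")
    acts = model.activations
    A = acts[target_layer + 1]  # (1, *spatial, C)
    G = model.backward(np.ones((1, 1), dtype=np.float32), stop_at=target_layer + 1)
    spatial_axes = tuple(range(1, A.ndim - 1))
    w = G.mean(axis=spatial_axes, keepdims=True)  # (1, 1..., C)
    cam = np.maximum((w * A).sum(axis=-1), 0.0)[0]
    return RelevanceVolume(
        values=cam, method="gradcam", model_id=model_id, sample_id=sample_id
    )


@contextmanager
def _guided_relus(model: nn.Sequential):
    relus = [l for l in model.layers if isinstance(l, nn.ReLU)]
    if not relus:
        raise ValueError("model has no ReLU activations to guide")
    for l in relus:
        l.guided = True
    try:
        yield
    finally:
        for l in relus:
            l.guided = False


def guided_backprop(
    model: nn.Sequential,
    input_values: np.ndarray,
    model_id: str = "",
    sample_id: str = "",
) -> RelevanceVolume:
    """Gradient of the logit w.r.t. the input with guided ReLU gates."""
    x = _prepare_input(input_values)
    with _guided_relus(model):
        model.forward(x, record=True)
        g = model.backward(np.ones((1, 1), dtype=np.float32))
    return RelevanceVolume(
        values=np.asarray(g)[0, ..., 0],
        method="gbp",
        model_id=model_id,
        sample_id=sample_id,
    )


def upsample_to(map_values: np.ndarray, target_shape: tuple[int, ...]) -> np.ndarray:
    """Linear (bi/trilinear) upsampling of a coarse map to the input shape."""
    if map_values.shape == tuple(target_shape):
        return map_values
    factors = [t / s for t, s in zip(target_shape, map_values.shape)]
    return ndimage.zoom(map_values, factors, order=1, grid_mode=True, mode="nearest")


def guided_grad_cam(
    model: nn.Sequential,
    input_values: np.ndarray,
    target_layer: int | None = None,
    model_id: str = "",
    sample_id: str = "",
) -> RelevanceVolume:
    """GGCAM: upsampled GradCAM map times the guided-backprop gradient."""
    cam = grad_cam(model, input_values, target_layer)
    gbp = guided_backprop(model, input_values)
    up = upsample_to(cam.values, gbp.values.shape)
    return RelevanceVolume(
        values=up * gbp.values,
        method="ggcam",
        model_id=model_id,
        sample_id=sample_id,
    )
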