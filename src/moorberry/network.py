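"""A small, fully deterministic numpy neural network for patch classification.

The model is a multi-label classifier with a dual head: six sigmoid units for
class presence and one sigmoid unit regressing the blueberry pixel fraction
of the patch.  The total loss is a class-weighted binary cross-entropy over
the presence units plus a mean-squared-error term on the fraction unit; the
class weights counter the extreme imbalance of wetland mosaics (blueberry
weighted 8x soil and 4x the remaining classes by default).

Two backbones are registered:

* ``tiny_mlp`` — patches bilinearly resampled to a small square, flattened,
  passed through a dense ReLU layer (the trainable feature extractor) and
  the dual head.  With ``weights_mode="frozen"`` the extractor keeps its
  random initialization and only the head trains.
* ``color_hist`` — a parameterless color featurizer (4x4x4 joint RGB
  histogram plus per-channel mean/sd) followed by a dense ReLU layer and the
  dual head.

The registry is pluggable, so a heavyweight pretrained convolutional
extractor can be registered by downstream code without changing the trainer.

Training uses minibatch Adam with a seeded shuffle; identical data, config
and seed reproduce the training loss sequence bit for bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from skimage import transform as sktransform

from .scene import CLASSES

N_CLASSES = len(CLASSES)
FRACTION_UNIT = N_CLASSES  # index of the fraction-regression output


def _resize_features(images: np.ndarray, input_size: int) -> np.ndarray:
    n = len(images)
    out = np.empty((n, input_size * input_size * 3))
    for i in range(n):
        small = sktransform.resize(
            images[i].astype(np.float64) / 255.0,
            (input_size, input_size),
            order=1,
            anti_aliasing=True,
            preserve_range=True,
        )
        out[i] = small.ravel()
    return out


HIST_BINS = 4  # per channel; 4^3 joint color bins, wide enough to absorb noise
HIST_POWER = 0.1  # strong power transform: a few pixels of a rare color give
# a feature close to saturation, so presence matters more than abundance


def _hist_features(images: np.ndarray, input_size: int) -> np.ndarray:
    # input_size unused; 8x8x8 joint histogram + channel mean/sd
    n = len(images)
    nb = HIST_BINS**3
    out = np.empty((n, nb + 6))
    width = 256 // HIST_BINS
    for i in range(n):
        img = images[i].reshape(-1, 3)
        bins = np.minimum(img // width, HIST_BINS - 1)
        idx = (bins[:, 0] * HIST_BINS + bins[:, 1]) * HIST_BINS + bins[:, 2]
        hist = np.bincount(idx, minlength=nb) / len(idx)
        out[i, :nb] = hist**HIST_POWER
        out[i, nb : nb + 3] = img.mean(axis=0) / 255.0
        out[i, nb + 3 :] = img.std(axis=0) / 255.0
    return out


@dataclass
class Backbone:
    name: str
    featurize: Callable[[np.ndarray, int], np.ndarray]
    feature_dim: Callable[[int], int]
    hidden: int


BACKBONES: dict[str, Backbone] = {
    "tiny_mlp": Backbone("tiny_mlp", _resize_features, lambda s: 3 * s * s, 64),
    "color_hist": Backbone(
        "color_hist", _hist_features, lambda s: HIST_BINS**3 + 6, 32
    ),
}


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


@dataclass
class PatchNet:
    """Dense extractor + dual sigmoid head, with hand-written backprop."""

    backbone: str
    input_size: int
    w1: np.ndarray
    b1: np.ndarray
    w2: np.ndarray
    b2: np.ndarray
    _adam: dict = field(default_factory=dict, repr=False)

    @classmethod
    def initialize(
        cls, backbone: str, input_size: int, rng: np.random.Generator
    ) -> "PatchNet":
        bb = BACKBONES[backbone]
        d = bb.feature_dim(input_size)
        h = bb.hidden
        w1 = rng.normal(0.0, np.sqrt(2.0 / d), (d, h))
        w2 = rng.normal(0.0, np.sqrt(2.0 / h), (h, N_CLASSES + 1))
        return cls(backbone, input_size, w1, np.zeros(h), w2, np.zeros(N_CLASSES + 1))

    # -- forward -----------------------------------------------------------
    def featurize(self, images: np.ndarray) -> np.ndarray:
        return BACKBONES[self.backbone].featurize(images, self.input_size)

    def forward(self, feats: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        hidden = np.maximum(feats @ self.w1 + self.b1, 0.0)
        probs = _sigmoid(hidden @ self.w2 + self.b2)
        return hidden, probs

    def predict_proba(self, images: np.ndarray) -> np.ndarray:
        """(n, 7) sigmoid outputs: six class probabilities + fraction."""
        _, probs = self.forward(self.featurize(images))
        return probs

    # -- training ----------------------------------------------------------
    def loss_and_grads(
        self,
        feats: np.ndarray,
        y: np.ndarray,
        frac: np.ndarray,
        class_weights: np.ndarray,
        fraction_loss_weight: float,
    ) -> tuple[float, dict[str, np.ndarray]]:
        n = len(feats)
        hidden, probs = self.forward(feats)
        p = np.clip(probs[:, :N_CLASSES], 1e-9, 1 - 1e-9)
        pf = probs[:, FRACTION_UNIT]
        wsum = class_weights.sum()
        bce = -(y * np.log(p) + (1 - y) * np.log(1 - p))
        presence = (bce * class_weights).sum(axis=1).mean() / wsum
        mse = float(((pf - frac) ** 2).mean())
        loss = float(presence) + fraction_loss_weight * mse
        # gradient wrt pre-sigmoid logits
        dlogits = np.empty((n, N_CLASSES + 1))
        dlogits[:, :N_CLASSES] = (p - y) * class_weights / (wsum * n)
        dlogits[:, FRACTION_UNIT] = (
            fraction_loss_weight * 2.0 * (pf - frac) * pf * (1 - pf) / n
        )
        dw2 = hidden.T @ dlogits
        db2 = dlogits.sum(axis=0)
        dhidden = dlogits @ self.w2.T
        dhidden[hidden <= 0] = 0.0
        dw1 = feats.T @ dhidden
        db1 = dhidden.sum(axis=0)
        return loss, {"w1": dw1, "b1": db1, "w2": dw2, "b2": db2}

    def adam_step(
        self,
        grads: dict[str, np.ndarray],
        lr: float,
        frozen_extractor: bool,
        beta1: float = 0.9,
        beta2: float = 0.999,
        eps: float = 1e-8,
    ) -> None:
        names = ["w2", "b2"] if frozen_extractor else ["w1", "b1", "w2", "b2"]
        st = self._adam
        st["t"] = st.get("t", 0) + 1
        t = st["t"]
        for name in names:
            g = grads[name]
            m = st.setdefault(f"m_{name}", np.zeros_like(g))
            v = st.setdefault(f"v_{name}", np.zeros_like(g))
            m *= beta1
            m += (1 - beta1) * g
            v *= beta2
            v += (1 - beta2) * g**2
            mhat = m / (1 - beta1**t)
            vhat = v / (1 - beta2**t)
            param = getattr(self, name)
            param -= lr * mhat / (np.sqrt(vhat) + eps)

    def trainable_param_names(self, frozen_extractor: bool) -> tuple[str, ...]:
        return ("w2", "b2") if frozen_extractor else ("w1", "b1", "w2", "b2")

    # -- persistence ---------------------------------------------------------
    def state(self) -> dict[str, np.ndarray]:
        return {"w1": self.w1, "b1": self.b1, "w2": self.w2, "b2": self.b2}

    @classmethod
    def from_state(
        cls, backbone: str, input_size: int, state: dict[str, np.ndarray]
    ) -> "PatchNet":
        return cls(
            backbone,
            input_size,
            np.asarray(state["w1"]),
            np.asarray(state["b1"]),
            np.asarray(state["w2"]),
            np.asarray(state["b2"]),
        )
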