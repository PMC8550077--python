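"""Scikit-learn style estimator wrapping the segmentation network.

``OTUnetSegmenter`` follows the sklearn conventions — constructor stores
hyperparameters untouched, ``fit(X, y)`` learns and sets trailing-
underscore attributes, ``predict``/``predict_proba`` transform new images
— so it composes with sklearn model selection. X is a stack of images
(N, H, W) or (N, H, W, 3) with values in [0, 1] and spatial size divisible
by 32; y is the matching stack of binary lesion masks.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

from .backbones import BackboneSpec
from .decoder import OTUnet
from .losses import PoolingSpec, total_loss
from .metrics import confusion_metrics
from .nn import SGD, Adam
from .synth import mask_to_edge

__all__ = ["OTUnetSegmenter"]


class OTUnetSegmenter(BaseEstimator):
    """Parapapillary-atrophy segmenter with deep supervision.

    Parameters
    ----------
    backbone : {"vgg", "resnet", "res2net"}
        Encoder family.
    channel_counts : tuple of 5 ints, optional
        Pyramid widths; None selects the family's canonical widths.
        Small counts (e.g. ``(8, 8, 16, 24, 32)``) give a CPU-friendly model.
    reduce_channels : int
        Width of the decoder's reduced features.
    epochs, batch_size, learning_rate, optimizer :
        Optimisation settings (Adam by default).
    max_steps : int, optional
        Hard cap on total optimisation steps across epochs.
    weight_kernel, weight_gain :
        Boundary weight map: pooling window (odd) and the gain on
        |AVG(B) - B|.
    threshold : float
        Binarisation threshold for ``predict``.
    random_state : int
        Seeds initialisation and batch shuffling.
    """

    def __init__(self, backbone: str = "resnet", channel_counts=None,
                 reduce_channels: int = 32, epochs: int = 50,
                 batch_size: int = 8, learning_rate: float = 1e-4,
                 optimizer: str = "adam", max_steps: int | None = None,
                 weight_kernel: int = 31, weight_gain: float = 5.0,
                 reduction: str = "mean", threshold: float = 0.5,
                 random_state: int = 0, pretrained: bool = False,
                 weights_path=None, res2net_scale: int = 4,
                 res2net_width: int = 26):
        self.backbone = backbone
        self.channel_counts = channel_counts
        self.reduce_channels = reduce_channels
        self.epochs = epochs
        self.batch_size = batch_size
        self.learning_rate = learning_rate
        self.optimizer = optimizer
        self.max_steps = max_steps
        self.weight_kernel = weight_kernel
        self.weight_gain = weight_gain
        self.reduction = reduction
        self.threshold = threshold
        self.random_state = random_state
        self.pretrained = pretrained
        self.weights_path = weights_path
        self.res2net_scale = res2net_scale
        self.res2net_width = res2net_width

    # ------------------------------------------------------------------
    def _spec(self) -> BackboneSpec:
        return BackboneSpec(
            variant=self.backbone, channel_counts=self.channel_counts,
            pretrained=self.pretrained, weights_path=self.weights_path,
            res2net_scale=self.res2net_scale,
            res2net_width=self.res2net_width)

    def build_model(self) -> OTUnet:
        return OTUnet(spec=self._spec(), seed=self.random_state,
                      reduce_channels=self.reduce_channels)

    @staticmethod
    def _stack(X) -> np.ndarray:
        X = np.asarray(X, dtype=np.float32)
        if X.ndim == 2:
            X = X[None]
        if X.ndim == 4 and X.shape[-1] in (1, 3):
            X = X.transpose(0, 3, 1, 2)
        elif X.ndim == 3:
            X = X[:, None]
        if X.shape[2] % 32 or X.shape[3] % 32:
            raise ValueError(
                f"image size {X.shape[2:]} must be divisible by 32")
        return X

    def fit(self, X, y, edges=None):
        """Optimise the deep-supervision loss on (images, masks).

        ``edges`` (boundary maps) default to the 1-pixel inner boundary of
        each mask.
        """
        X = self._stack(X)
        y = np.asarray(y)
        if y.ndim == 2:
            y = y[None]
        if y.shape[0] != X.shape[0] or y.shape[-2:] != X.shape[-2:]:
            raise ValueError("X and y disagree in count or spatial size")
        if not np.all(np.isin(np.unique(y), (0, 1))):
            raise ValueError("y must be binary lesion masks")
        if edges is None:
            edges = np.stack([mask_to_edge(m, 1) for m in y])
        else:
            edges = np.asarray(edges)
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")

        pool = PoolingSpec.same_size(self.weight_kernel)
        self.model_ = self.build_model().train()
        params = self.model_.parameters()
        if self.optimizer == "adam":
            opt = Adam(params, lr=self.learning_rate)
        elif self.optimizer == "sgd":
            opt = SGD(params, lr=self.learning_rate, momentum=0.9)
        else:
            raise ValueError(f"unknown optimizer {self.optimizer!r}")

        rng = np.random.default_rng(
            np.random.SeedSequence(self.random_state, spawn_key=(2,)))
        n = X.shape[0]
        self.history_ = []
        step = 0
        stop = False
        for epoch in range(self.epochs):
            order = rng.permutation(n)
            epoch_terms: list[dict] = []
            for lo in range(0, n, self.batch_size):
                idx = order[lo:lo + self.batch_size]
                xb = X[idx]
                gb = y[idx][:, None].astype(np.float32)
                eb = edges[idx][:, None].astype(np.float32)
                out = self.model_(xb)
                report = total_loss(out, gb, eb, pool=pool,
                                    gain=self.weight_gain,
                                    reduction=self.reduction)
                if not np.isfinite(report.l_total):
                    raise FloatingPointError(
                        f"non-finite loss at step {step}: {report.as_dict()}")
                opt.zero_grad()
                report.tensor.backward()
                opt.step()
                epoch_terms.append(report.as_dict())
                step += 1
                if self.max_steps is not None and step >= self.max_steps:
                    stop = True
                    break
            if epoch_terms:
                mean_terms = {k: float(np.mean([t[k] for t in epoch_terms]))
                              for k in epoch_terms[0]}
                mean_terms["epoch"] = epoch
                mean_terms["steps"] = step
                self.history_.append(mean_terms)
            if stop:
                break
        self.model_.eval()
        self.n_iter_ = step
        self.n_features_in_ = int(np.prod(X.shape[1:]))
        return self

    # ------------------------------------------------------------------
    def predict_proba(self, X) -> np.ndarray:
        """Probability maps, shape (N, H, W)."""
        check_is_fitted(self, "model_")
        X = self._stack(X)
        self.model_.eval()
        probs = []
        for lo in range(0, X.shape[0], max(1, self.batch_size)):
            out = self.model_(X[lo:lo + max(1, self.batch_size)])
            probs.append(out["prob"].data[:, 0])
        return np.concatenate(probs, axis=0)

    def predict(self, X) -> np.ndarray:
        """Binary masks at ``threshold``, shape (N, H, W), uint8."""
        return (self.predict_proba(X) > self.threshold).astype(np.uint8)

    def score(self, X, y) -> float:
        """Mean Dice similarity coefficient over the batch."""
        y = np.asarray(y)
        if y.ndim == 2:
            y = y[None]
        preds = self.predict(X)
        return float(np.mean([
            confusion_metrics(p, m)["dsc"] for p, m in zip(preds, y)]))
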