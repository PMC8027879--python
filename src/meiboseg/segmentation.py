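"""U-Net gland segmentation with a combined cross-entropy + Dice loss.

The segmenter is a scikit-learn style estimator: ``fit`` trains a
small plain U-Net with Adam on image/mask pairs optimizing
``total_loss = ce_loss + dice_loss``, ``predict_proba`` returns
per-pixel gland probability maps at the input image's native
resolution, and ``predict`` thresholds them into binary masks.
Inference is strictly deterministic: running the same trained model on
the same image twice yields bitwise-identical masks (0% variability).

The cross-entropy is the standard negative weighted binary
log-likelihood

    CE = -(1/|Omega|) * sum_x w(x) [ g(x) log p(x) + (1-g(x)) log(1-p(x)) ]

with an all-ones default weight map, and the Dice loss is the soft
Dice with squared denominator

    Dice = 1 - (2 sum p g + s) / (sum g^2 + sum p^2 + s),   s = 1,

the smoothing constant s making the empty-vs-empty case 0.
"""

from __future__ import annotations

import numbers

import numpy as np
from scipy.special import expit
from skimage.transform import resize
from sklearn.base import BaseEstimator
from sklearn.model_selection import KFold
from sklearn.utils.validation import check_is_fitted

from ._nn import Adam, UNet

__all__ = [
    "ce_loss",
    "dice_loss",
    "total_loss",
    "binarize",
    "kfold_split",
    "UNetSegmenter",
]

_EPS = 1e-7


def _check_pair(pred, gt, w=None):
    pred = np.asarray(pred, dtype=np.float64)
    gt = np.asarray(gt, dtype=np.float64)
    if pred.shape != gt.shape:
        raise ValueError(f"shape mismatch: pred {pred.shape} vs gt {gt.shape}")
    if not (np.isfinite(pred).all() and np.isfinite(gt).all()):
        raise ValueError("non-finite values in loss inputs")
    if w is None:
        w = np.ones_like(pred)
    else:
        w = np.asarray(w, dtype=np.float64)
        if w.shape != pred.shape:
            raise ValueError(f"shape mismatch: weights {w.shape} vs pred {pred.shape}")
        if (w < 0).any():
            raise ValueError("weights must be non-negative")
    return pred, gt, w


def ce_loss(pred, gt, w=None) -> float:
    """Weighted binary cross-entropy, averaged over pixels.

    ``pred`` is a probability map in [0, 1] (clipped away from 0/1 for
    numerical safety), ``gt`` a binary mask, ``w`` an optional
    non-negative per-pixel weight map (default all ones).
    """
    pred, gt, w = _check_pair(pred, gt, w)
    p = np.clip(pred, _EPS, 1 - _EPS)
    ll = gt * np.log(p) + (1 - gt) * np.log(1 - p)
    return float(-(w * ll).sum() / pred.size)


def dice_loss(pred, gt, smooth: float = 1.0) -> float:
    """Soft Dice loss with squared denominator and smoothing ``s``.

    0 for a perfect binary prediction, 1 (up to smoothing) for
    disjoint non-empty masks, 0 for empty-vs-empty.
    """
    pred, gt, _ = _check_pair(pred, gt)
    num = 2.0 * (pred * gt).sum() + smooth
    den = (gt * gt).sum() + (pred * pred).sum() + smooth
    return float(1.0 - num / den)


def total_loss(pred, gt, w=None, smooth: float = 1.0) -> float:
    """Training objective: cross-entropy plus Dice loss, unweighted sum."""
    return ce_loss(pred, gt, w) + dice_loss(pred, gt, smooth)


def binarize(prob, threshold: float = 0.5) -> np.ndarray:
    """Threshold a probability map into a binary mask (prob >= t)."""
    if not 0 < threshold < 1:
        raise ValueError("threshold must be in (0, 1)")
    return np.asarray(prob) >= threshold


def kfold_split(item_ids, k: int, seed: int = 0):
    """Seeded k-fold partition of ids into (train, validation) tuples.

    Fold sizes differ by at most one; each id appears in exactly one
    validation fold. E.g. 628 ids with k=5 give validation folds of
    126/126/126/125/125 ids and 502 training ids for the 126-folds.
    """
    ids = list(item_ids)
    if not isinstance(k, numbers.Integral) or k < 2:
        raise ValueError("k must be an integer >= 2")
    if k > len(ids):
        raise ValueError(f"k={k} exceeds the {len(ids)} available items")
    kf = KFold(n_splits=k, shuffle=True, random_state=seed)
    return [
        ([ids[i] for i in tr], [ids[i] for i in va]) for tr, va in kf.split(np.arange(len(ids)))
    ]


def _prepare_images(X, input_size):
    """Normalize to [0,1] float32 and resize (bilinear) to input_size."""
    out = np.empty((len(X), *input_size), dtype=np.float32)
    for i, img in enumerate(X):
        a = np.asarray(img, dtype=np.float32)
        if a.ndim != 2:
            raise ValueError("images must be 2-D grayscale; convert color inputs first")
        if a.max() > 1.5:
            a = a / 255.0
        if a.shape != tuple(input_size):
            a = resize(a, input_size, order=1, preserve_range=True, anti_aliasing=False)
        out[i] = a
    return out


def _prepare_masks(y, input_size):
    out = np.empty((len(y), *input_size), dtype=np.float32)
    for i, m in enumerate(y):
        a = np.asarray(m)
        if a.ndim != 2:
            raise ValueError("masks must be 2-D")
        a = (a > 0).astype(np.float32)
        if a.shape != tuple(input_size):
            a = resize(a, input_size, order=0, preserve_range=True, anti_aliasing=False)
        out[i] = a
    return out


def _hard_dice(a, b) -> float:
    a = np.asarray(a, bool)
    b = np.asarray(b, bool)
    s = a.sum() + b.sum()
    if s == 0:
        return 1.0
    return float(2.0 * np.logical_and(a, b).sum() / s)


class UNetSegmenter(BaseEstimator):
    """Meibomian-gland segmenter: a small plain U-Net trained with
    Adam on the combined cross-entropy + Dice objective.

    Parameters
    ----------
    depth : number of pooling levels (input sides must divide 2**depth).
    base_channels : channels at the top level, doubling per level.
    epochs, batch_size, learning_rate : Adam training schedule.
    input_size : (H, W) the network operates on; inputs are resized in
        (bilinear for images, nearest for masks) and probability maps
        resized back out, so morphometry runs at native resolution.
    binarize_threshold : probability cut for ``predict``.
    encoder : 'plain' for the built-in U-Net. Naming a pretrained
        backbone without supplying ``encoder_weights`` raises — weights
        are never downloaded.
    pretrain_epochs : epochs for the optional transfer-learning stage
        run on an auxiliary image/mask set passed to ``fit``.
    random_state : seed for weight init and epoch shuffling.

    Attributes
    ----------
    model_ : the trained network.
    history_ : list of per-epoch dicts (stage, epoch, train_loss,
        val_loss, val_dice).
    """

    def __init__(
        self,
        depth: int = 2,
        base_channels: int = 8,
        epochs: int = 15,
        batch_size: int = 5,
        learning_rate: float = 1e-3,
        input_size: tuple[int, int] = (256, 256),
        binarize_threshold: float = 0.5,
        encoder: str = "plain",
        encoder_weights: str | None = None,
        pretrain_epochs: int = 5,
        smooth: float = 1.0,
        random_state: int = 0,
    ):
        self.depth = depth
        self.base_channels = base_channels
        self.epochs = epochs
        self.batch_size = batch_size
        self.learning_rate = learning_rate
        self.input_size = input_size
        self.binarize_threshold = binarize_threshold
        self.encoder = encoder
        self.encoder_weights = encoder_weights
        self.pretrain_epochs = pretrain_epochs
        self.smooth = smooth
        self.random_state = random_state

    # ------------------------------------------------------------------
    def _validate_config(self):
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if not 0 < self.binarize_threshold < 1:
            raise ValueError("binarize_threshold must be in (0, 1)")
        h, w = self.input_size
        f = 2**self.depth
        if h % f or w % f:
            raise ValueError(f"input_size {self.input_size} must be divisible by 2**depth={f}")
        if self.encoder != "plain" and self.encoder_weights is None:
            raise ValueError(
                f"encoder {self.encoder!r} needs locally available weights "
                "(encoder_weights=...); weights are never downloaded — "
                "use encoder='plain' for the built-in U-Net"
            )

    def build_model(self, rng: np.random.Generator | None = None) -> UNet:
        """Construct the (untrained) network for the current config."""
        self._validate_config()
        if rng is None:
            rng = np.random.default_rng(self.random_state)
        model = UNet(depth=self.depth, base_channels=self.base_channels, rng=rng)
        if self.encoder != "plain":
            with np.load(self.encoder_weights) as z:
                model.load_state_arrays([z[k] for k in sorted(z.files)])
        return model

    # ------------------------------------------------------------------
    def _batch_grad(self, model, xb, gb):
        """Forward + backward for one minibatch; returns the batch loss."""
        logits = model.forward(xb)
        p = expit(logits)
        n_pix = p.size
        pc = np.clip(p, _EPS, 1 - _EPS)
        ce = float(-(gb * np.log(pc) + (1 - gb) * np.log(1 - pc)).sum() / n_pix)
        num = 2.0 * (p * gb).sum() + self.smooth
        den = (gb * gb).sum() + (p * p).sum() + self.smooth
        dice = float(1.0 - num / den)
        # dCE/dz with z the logit is (p - g)/n; Dice chain-ruled via p(1-p)
        dz_ce = (p - gb) / n_pix
        dL_dp = (-2.0 * gb * den + 2.0 * p * num) / den**2
        dz = (dz_ce + dL_dp * p * (1 - p)).astype(np.float32)
        model.zero_grad()
        model.backward(dz)
        return ce + dice

    def _run_stage(self, model, opt, X, y, epochs, stage, rng, val=None):
        n = len(X)
        for epoch in range(epochs):
            order = rng.permutation(n)
            losses = []
            for s in range(0, n, self.batch_size):
                idx = order[s : s + self.batch_size]
                losses.append(self._batch_grad(model, X[idx], y[idx]))
                opt.step()
            rec = {"stage": stage, "epoch": epoch + 1, "train_loss": float(np.mean(losses))}
            if val is not None:
                xv, yv = val
                pv = expit(model.forward(xv))
                rec["val_loss"] = total_loss(pv, yv, smooth=self.smooth)
                rec["val_dice"] = float(
                    np.mean(
                        [
                            _hard_dice(pv[i] >= self.binarize_threshold, yv[i] > 0.5)
                            for i in range(len(pv))
                        ]
                    )
                )
            self.history_.append(rec)

    def fit(self, X, y, validation_data=None, pretrain_data=None):
        """Train on image/mask pairs.

        ``X`` and ``y`` are sequences of 2-D arrays (any sizes; resized
        to ``input_size``). ``validation_data=(Xv, yv)`` adds per-epoch
        validation loss and Dice to the history. ``pretrain_data=(Xa,
        ya)`` first runs a transfer-learning stage of
        ``pretrain_epochs`` on the auxiliary set, then training
        continues on the target set.
        """
        self._validate_config()
        if len(X) == 0:
            raise ValueError("empty training set")
        if len(X) != len(y):
            raise ValueError(f"{len(X)} images but {len(y)} masks")
        Xp = _prepare_images(X, self.input_size)
        yp = _prepare_masks(y, self.input_size)
        rng = np.random.default_rng(self.random_state)
        model = self.build_model(rng)
        opt = Adam(model.params(), lr=self.learning_rate)
        self.history_ = []
        val = None
        if validation_data is not None:
            val = (
                _prepare_images(validation_data[0], self.input_size),
                _prepare_masks(validation_data[1], self.input_size),
            )
        if pretrain_data is not None and self.pretrain_epochs > 0:
            Xa = _prepare_images(pretrain_data[0], self.input_size)
            ya = _prepare_masks(pretrain_data[1], self.input_size)
            self._run_stage(model, opt, Xa, ya, self.pretrain_epochs, "pretrain", rng, val)
        self._run_stage(model, opt, Xp, yp, self.epochs, "train", rng, val)
        self.model_ = model
        return self

    # ------------------------------------------------------------------
    def predict_proba(self, X) -> list[np.ndarray]:
        """Per-pixel gland probability maps at each image's native size."""
        check_is_fitted(self, "model_")
        out = []
        for img in X:
            a = np.asarray(img)
            orig = a.shape
            xb = _prepare_images([a], self.input_size)
            prob = expit(self.model_.forward(xb))[0].astype(np.float64)
            if orig != tuple(self.input_size):
                prob = resize(prob, orig, order=1, preserve_range=True, anti_aliasing=False)
            out.append(np.clip(prob, 0.0, 1.0))
        return out

    def predict(self, X) -> list[np.ndarray]:
        """Binary gland masks (probability >= binarize_threshold)."""
        return [binarize(p, self.binarize_threshold) for p in self.predict_proba(X)]

    def score(self, X, y) -> float:
        """Mean per-image hard Dice coefficient against reference masks."""
        preds = self.predict(X)
        return float(np.mean([_hard_dice(p, np.asarray(m) > 0) for p, m in zip(preds, y)]))

    # ------------------------------------------------------------------
    def save(self, path) -> None:
        """Write a checkpoint (weights + config + history) to .npz."""
        check_is_fitted(self, "model_")
        import json

        arrays = {f"w{i:03d}": a for i, a in enumerate(self.model_.state_arrays())}
        meta = json.dumps({"params": self.get_params(), "history": self.history_})
        np.savez(path, __meta__=np.frombuffer(meta.encode(), dtype=np.uint8), **arrays)

    @classmethod
    def load(cls, path) -> "UNetSegmenter":
        import json

        with np.load(path) as z:
            meta = json.loads(bytes(z["__meta__"]).decode())
            arrays = [z[k] for k in sorted(k for k in z.files if k.startswith("w"))]
        est = cls(**{k: tuple(v) if k == "input_size" else v for k, v in meta["params"].items()})
        est.model_ = UNet(depth=est.depth, base_channels=est.base_channels)
        est.model_.load_state_arrays(arrays)
        est.history_ = meta["history"]
        return est

    def crossval(self, X, y, k: int = 5, seed: int | None = None):
        """k-fold cross-validation; returns per-fold held-out Dice."""
        seed = self.random_state if seed is None else seed
        folds = kfold_split(range(len(X)), k, seed)
        scores = []
        for tr, va in folds:
            est = UNetSegmenter(**self.get_params())
            est.fit([X[i] for i in tr], [y[i] for i in tr])
            scores.append(est.score([X[i] for i in va], [y[i] for i in va]))
        return scores
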