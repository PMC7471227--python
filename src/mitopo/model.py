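"""Multi-input Wide&Deep CNN for topographic band-power images.

The convolutional stage uses I=2 kernels of 3x3 (stride 1, zero padding
preserving the 42x56 size, ReLU) followed by 2x2 max-pooling with stride 2
(42x56 -> 21x28).  Two ways of handling the per-band image stack are
supported (``band_mode``):

* ``"branches"`` (default): each band feeds its own convolution branch and
  the pooled maps of all branches are concatenated, so the flatten length is
  G*G'*I*N_f (e.g. 21*28*2*4 = 4704 for four bands) — the dimension the
  weight back-projection relevance construction works with, giving one
  relevance map per band;
* ``"channels"``: the band maps are the input channels of a single
  convolution producing I feature maps in total, so the flatten length is
  G*G'*I = 21*28*2 = 1176 independent of the band count — the sizing printed
  in the reference layer table (IN1..OU9).

After the flatten: batch normalization, a dense layer with ``h_u`` ReLU
units under Elastic-Net regularization, a second batch normalization, and a
softmax output with one unit per class.  Training minimizes the mean squared
error between the softmax output and one-hot labels with Adam (learning rate
1e-3 by default); cross-entropy is available behind a config flag.

The implementation is plain NumPy (im2col convolutions, hand-derived
backward passes, seeded initialization), which keeps runs bit-reproducible
for a given seed and fast enough for desk-scale CPU experiments.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field, replace
from itertools import product

import numpy as np
import pandas as pd

__all__ = ["ModelConfig", "TrainedModel", "Prediction", "WideDeepCNN",
           "build_model", "train", "predict", "grid_search",
           "HU_GRID", "REG_GRID"]

HU_GRID = tuple(range(50, 551, 50))
REG_GRID = (0.001, 0.01, 0.1)

_BN_EPS = 1e-3
_BN_MOMENTUM = 0.99


@dataclass
class ModelConfig:
    n_bands: int = 4
    n_kernels: int = 2            # I
    kernel_size: int = 3          # K
    pool_size: int = 2            # K'
    hidden_units: int = 100       # h_u
    l1: float = 0.0
    l2: float = 0.0
    lr: float = 1e-3
    n_classes: int = 2            # N_lambda
    epochs: int = 200
    batch_size: int = 16
    patience: int = 20            # early stopping on validation loss; 0 disables
    val_fraction: float = 0.1
    loss: str = "mse"             # or "xent"
    band_mode: str = "branches"   # or "channels"; see the module docstring
    bn_eps: float = _BN_EPS       # batch-norm variance floor; see train()
    input_dropout: float = 0.0    # training-time pixel dropout probability
    image_shape: tuple[int, int] = (42, 56)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_bands < 1 or self.n_kernels < 1:
            raise ValueError("n_bands and n_kernels must be >= 1")
        if self.kernel_size < 1 or self.pool_size < 1:
            raise ValueError("kernel and pool sizes must be positive")
        if self.hidden_units < self.n_classes:
            raise ValueError("hidden_units must be >= n_classes")
        if self.loss not in ("mse", "xent"):
            raise ValueError("loss must be 'mse' or 'xent'")
        if self.band_mode not in ("branches", "channels"):
            raise ValueError("band_mode must be 'branches' or 'channels'")
        if self.bn_eps <= 0:
            raise ValueError("bn_eps must be positive")
        if not 0.0 <= self.input_dropout < 1.0:
            raise ValueError("input_dropout must be in [0, 1)")
        h, w = self.image_shape
        if h % self.pool_size or w % self.pool_size:
            raise ValueError(
                f"image shape {self.image_shape} not divisible by pool "
                f"size {self.pool_size}")

    @property
    def pooled_shape(self) -> tuple[int, int]:
        return (self.image_shape[0] // self.pool_size,
                self.image_shape[1] // self.pool_size)

    @property
    def map_groups(self) -> int:
        """Number of pooled-map groups: one per band branch, or one in total."""
        return self.n_bands if self.band_mode == "branches" else 1

    @property
    def flatten_dim(self) -> int:
        g, g2 = self.pooled_shape
        return g * g2 * self.n_kernels * self.map_groups


@dataclass
class Prediction:
    probabilities: np.ndarray
    predicted: int


def _one_hot(y: np.ndarray, k: int) -> np.ndarray:
    out = np.zeros((len(y), k))
    out[np.arange(len(y)), y] = 1.0
    return out


class WideDeepCNN:
    """The network parameters plus forward/backward passes."""

    def __init__(self, cfg: ModelConfig, input_mask: np.ndarray | None = None):
        self.cfg = cfg
        self.input_mask = None if input_mask is None else np.asarray(input_mask, bool)
        rng = np.random.default_rng(cfg.seed)
        k, i, nb, hu, nc = (cfg.kernel_size, cfg.n_kernels, cfg.n_bands,
                            cfg.hidden_units, cfg.n_classes)
        d = cfg.flatten_dim
        he = lambda fan_in, shape: rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)
        if cfg.band_mode == "branches":
            conv_w = he(k * k, (nb, i, k, k))
            conv_b = np.zeros((nb, i))
        else:
            conv_w = he(k * k * nb, (i, nb, k, k))
            conv_b = np.zeros(i)
        self.params = {
            "conv_w": conv_w,
            "conv_b": conv_b,
            "bn1_g": np.ones(d), "bn1_b": np.zeros(d),
            "w1": he(d, (d, hu)), "b1": np.zeros(hu),
            "bn2_g": np.ones(hu), "bn2_b": np.zeros(hu),
            "w2": he(hu, (hu, nc)), "b2": np.zeros(nc),
        }
        self.running = {"bn1_m": np.zeros(d), "bn1_v": np.ones(d),
                        "bn2_m": np.zeros(hu), "bn2_v": np.ones(hu)}
        self.history: dict[str, list[float]] = {"loss": [], "val_loss": []}
        self._drop_rng = np.random.default_rng(cfg.seed + 555)
        self.trained = False

    # ---------------------------------------------------------------- forward
    def _check_input(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        nb = self.cfg.n_bands
        h, w = self.cfg.image_shape
        if x.ndim != 4 or x.shape[1:] != (nb, h, w):
            raise ValueError(
                f"expected input (n, {nb}, {h}, {w}), got {x.shape}")
        if self.input_mask is not None:
            x = x * self.input_mask
        return x

    def _patches(self, x: np.ndarray) -> np.ndarray:
        """im2col: (n, nb, H, W) -> (n, nb, H, W, k*k) with zero padding."""
        k = self.cfg.kernel_size
        p = k // 2
        h, w = self.cfg.image_shape
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
        cols = [xp[:, :, a:a + h, b:b + w] for a in range(k) for b in range(k)]
        return np.stack(cols, axis=-1)

    def forward(self, x: np.ndarray, training: bool = False) -> dict:
        cfg = self.cfg
        x = self._check_input(x)
        if training and cfg.input_dropout > 0.0:
            # spatial input dropout: forces the net to spread its evidence
            # across redundant discriminative sites instead of one
            keep = self._drop_rng.random(x.shape) >= cfg.input_dropout
            x = x * keep / (1.0 - cfg.input_dropout)
        n = x.shape[0]
        k, i = cfg.kernel_size, cfg.n_kernels
        gp, g2 = cfg.pooled_shape
        pr = self.params

        patches = self._patches(x)                                  # n,nb,H,W,kk
        if cfg.band_mode == "branches":
            kw = pr["conv_w"].reshape(cfg.n_bands, i, k * k)
            zc = np.einsum("nbhwp,bip->nbihw", patches, kw) \
                + pr["conv_b"][None, :, :, None, None]
        else:
            # bands are the input channels of one convolution
            kw = pr["conv_w"].reshape(i, cfg.n_bands, k * k)
            zc = np.einsum("nbhwp,ibp->nihw", patches, kw)[:, None] \
                + pr["conv_b"][None, None, :, None, None]
        ac = np.maximum(zc, 0.0)                                    # ReLU
        groups = cfg.map_groups

        # 2x2 max pooling with stride 2
        win = ac.reshape(n, groups, i, gp, cfg.pool_size, g2, cfg.pool_size)
        win = win.transpose(0, 1, 2, 3, 5, 4, 6).reshape(
            n, groups, i, gp, g2, cfg.pool_size ** 2)
        pool_idx = win.argmax(-1)
        pooled = np.take_along_axis(win, pool_idx[..., None], axis=-1)[..., 0]

        flat = pooled.reshape(n, cfg.flatten_dim)                   # band-major

        def bn(xf, gkey, bkey, mkey, vkey):
            if training:
                mu = xf.mean(0)
                var = xf.var(0)
                self.running[mkey] = (_BN_MOMENTUM * self.running[mkey]
                                      + (1 - _BN_MOMENTUM) * mu)
                self.running[vkey] = (_BN_MOMENTUM * self.running[vkey]
                                      + (1 - _BN_MOMENTUM) * var)
            else:
                mu, var = self.running[mkey], self.running[vkey]
            xh = (xf - mu) / np.sqrt(var + self.cfg.bn_eps)
            return xh, pr[gkey] * xh + pr[bkey], mu, var

        f_hat, f_bn, mu1, var1 = bn(flat, "bn1_g", "bn1_b", "bn1_m", "bn1_v")
        z1 = f_bn @ pr["w1"] + pr["b1"]
        h1 = np.maximum(z1, 0.0)
        h_hat, h_bn, mu2, var2 = bn(h1, "bn2_g", "bn2_b", "bn2_m", "bn2_v")
        logits = h_bn @ pr["w2"] + pr["b2"]
        logits = logits - logits.max(axis=1, keepdims=True)
        e = np.exp(logits)
        probs = e / e.sum(axis=1, keepdims=True)

        return {"x": x, "patches": patches, "zc": zc, "pool_idx": pool_idx,
                "flat": flat, "f_hat": f_hat, "f_bn": f_bn, "var1": var1,
                "z1": z1, "h1": h1, "h_hat": h_hat, "h_bn": h_bn, "var2": var2,
                "probs": probs, "n": n}

    # --------------------------------------------------------------- backward
    def _loss_and_dlogits(self, probs: np.ndarray, y1h: np.ndarray):
        n = probs.shape[0]
        if self.cfg.loss == "mse":
            loss = float(np.mean((probs - y1h) ** 2))
            dp = 2.0 * (probs - y1h) / probs.size
            dlog = probs * (dp - (dp * probs).sum(axis=1, keepdims=True))
        else:
            loss = float(-np.mean(np.sum(y1h * np.log(probs + 1e-12), axis=1)))
            dlog = (probs - y1h) / n
        return loss, dlog

    def penalty(self) -> float:
        w1 = self.params["w1"]
        return float(self.cfg.l1 * np.abs(w1).sum() + self.cfg.l2 * (w1 ** 2).sum())

    def backward(self, cache: dict, y1h: np.ndarray):
        cfg = self.cfg
        pr = self.params
        n = cache["n"]
        loss, dlog = self._loss_and_dlogits(cache["probs"], y1h)

        grads = {}
        grads["w2"] = cache["h_bn"].T @ dlog
        grads["b2"] = dlog.sum(0)
        dh_bn = dlog @ pr["w2"].T

        def bn_back(dxbn, xhat, var, gkey, bkey):
            grads[gkey] = (dxbn * xhat).sum(0)
            grads[bkey] = dxbn.sum(0)
            dxhat = dxbn * pr[gkey]
            inv = 1.0 / np.sqrt(var + self.cfg.bn_eps)
            return (inv / n) * (n * dxhat - dxhat.sum(0)
                                - xhat * (dxhat * xhat).sum(0))

        dh1 = bn_back(dh_bn, cache["h_hat"], cache["var2"], "bn2_g", "bn2_b")
        dz1 = dh1 * (cache["z1"] > 0)
        grads["w1"] = cache["f_bn"].T @ dz1 \
            + cfg.l1 * np.sign(pr["w1"]) + 2.0 * cfg.l2 * pr["w1"]
        grads["b1"] = dz1.sum(0)
        df_bn = dz1 @ pr["w1"].T
        dflat = bn_back(df_bn, cache["f_hat"], cache["var1"], "bn1_g", "bn1_b")

        # un-pool: route gradients to the argmax of each 2x2 window
        gp, g2 = cfg.pooled_shape
        i = cfg.n_kernels
        groups = cfg.map_groups
        dpool = dflat.reshape(n, groups, i, gp, g2)
        dwin = np.zeros((n, groups, i, gp, g2, cfg.pool_size ** 2))
        np.put_along_axis(dwin, cache["pool_idx"][..., None],
                          dpool[..., None], axis=-1)
        dwin = dwin.reshape(n, groups, i, gp, g2,
                            cfg.pool_size, cfg.pool_size)
        dac = dwin.transpose(0, 1, 2, 3, 5, 4, 6).reshape(
            n, groups, i, *cfg.image_shape)
        dzc = dac * (cache["zc"] > 0)

        k = cfg.kernel_size
        if cfg.band_mode == "branches":
            grads["conv_w"] = np.einsum("nbhwp,nbihw->bip", cache["patches"],
                                        dzc).reshape(cfg.n_bands, i, k, k)
            grads["conv_b"] = dzc.sum(axis=(0, 3, 4))
        else:
            dz4 = dzc[:, 0]
            grads["conv_w"] = np.einsum("nbhwp,nihw->ibp", cache["patches"],
                                        dz4).reshape(i, cfg.n_bands, k, k)
            grads["conv_b"] = dz4.sum(axis=(0, 2, 3))
        return loss, grads


@dataclass
class TrainedModel:
    """Thin façade over the network exposing the relevance-facing pieces."""

    net: WideDeepCNN

    @property
    def cfg(self) -> ModelConfig:
        return self.net.cfg

    @property
    def dense_weights(self) -> np.ndarray:
        """W of the first dense layer after the flatten (flatten_dim x h_u)."""
        return self.net.params["w1"]

    @property
    def history(self) -> dict:
        return self.net.history


def build_model(cfg: ModelConfig, input_mask: np.ndarray | None = None) -> TrainedModel:
    """An initialized (untrained) network for the given configuration."""
    if input_mask is not None and input_mask.shape != cfg.image_shape:
        raise ValueError("input mask shape must equal the image shape")
    return TrainedModel(WideDeepCNN(cfg, input_mask=input_mask))


def _stack_bands(images) -> np.ndarray:
    """Accept (n, nb, H, W) or a list of per-band (n, H, W) stacks."""
    if isinstance(images, (list, tuple)):
        return np.stack([np.asarray(b, dtype=float) for b in images], axis=1)
    x = np.asarray(images, dtype=float)
    if x.ndim == 3:
        x = x[:, None]
    return x


def train(model: TrainedModel, images, labels, cfg: ModelConfig | None = None
          ) -> TrainedModel:
    """Fit with Adam on MSE-vs-one-hot (default); early stop on val loss."""
    net = model.net
    cfg = cfg or net.cfg
    x = _stack_bands(images)
    y = np.asarray(labels, dtype=int)
    if len(x) != len(y):
        raise ValueError("images and labels disagree in length")
    y1h = _one_hot(y, cfg.n_classes)

    rng = np.random.default_rng(cfg.seed + 1)
    n = len(x)
    idx = rng.permutation(n)
    n_val = int(round(cfg.val_fraction * n)) if cfg.patience > 0 else 0
    val_idx, tr_idx = idx[:n_val], idx[n_val:]
    if len(tr_idx) == 0:
        raise ValueError("no training samples left after validation split")

    adam_m = {k: np.zeros_like(v) for k, v in net.params.items()}
    adam_v = {k: np.zeros_like(v) for k, v in net.params.items()}
    b1, b2, eps = 0.9, 0.999, 1e-8
    t = 0
    best = (np.inf, None, None)
    wait = 0

    for ep in range(cfg.epochs):
        order = rng.permutation(len(tr_idx))
        ep_loss = 0.0
        for s in range(0, len(order), cfg.batch_size):
            batch = tr_idx[order[s:s + cfg.batch_size]]
            cache = net.forward(x[batch], training=True)
            loss, grads = net.backward(cache, y1h[batch])
            if not np.isfinite(loss):
                raise FloatingPointError(
                    f"non-finite training loss at epoch {ep}; inputs or "
                    f"learning rate ({cfg.lr}) need attention")
            ep_loss += loss * len(batch)
            t += 1
            for k, g in grads.items():
                adam_m[k] = b1 * adam_m[k] + (1 - b1) * g
                adam_v[k] = b2 * adam_v[k] + (1 - b2) * g * g
                mhat = adam_m[k] / (1 - b1 ** t)
                vhat = adam_v[k] / (1 - b2 ** t)
                net.params[k] -= cfg.lr * mhat / (np.sqrt(vhat) + eps)
        net.history["loss"].append(ep_loss / len(tr_idx))

        if n_val:
            vp = net.forward(x[val_idx], training=False)["probs"]
            vloss, _ = net._loss_and_dlogits(vp, y1h[val_idx])
            net.history["val_loss"].append(vloss)
            if vloss < best[0] - 1e-9:
                best = (vloss, copy.deepcopy(net.params),
                        copy.deepcopy(net.running))
                wait = 0
            else:
                wait += 1
                if wait >= cfg.patience:
                    break

    if n_val and best[1] is not None:
        net.params, net.running = best[1], best[2]
    net.trained = True
    return model


def predict(model: TrainedModel, images) -> list[Prediction]:
    """Softmax probabilities per trial; argmax class (lowest index on ties)."""
    x = _stack_bands(images)
    probs = model.net.forward(x, training=False)["probs"]
    return [Prediction(probabilities=p, predicted=int(np.argmax(p))) for p in probs]


def predict_proba(model: TrainedModel, images) -> np.ndarray:
    x = _stack_bands(images)
    return model.net.forward(x, training=False)["probs"]


def grid_search(images, labels, hu_grid=HU_GRID, reg_grid=REG_GRID,
                base_cfg: ModelConfig | None = None, folds: int = 10,
                repeats: int = 1, seed: int = 0):
    """Exhaustive search over hidden units and the Elastic-Net penalties.

    Every (h_u, l1, l2) combination is scored by stratified cross-validation;
    returns (best ModelConfig by mean accuracy, score table with one row per
    config and fold).
    """
    from .evaluate import stratified_cv  # local import to avoid a cycle

    if not len(hu_grid) or not len(reg_grid):
        raise ValueError("empty hyperparameter grid")
    x = _stack_bands(images)
    y = np.asarray(labels)
    base = base_cfg or ModelConfig(n_bands=x.shape[1],
                                   image_shape=x.shape[2:], n_classes=len(set(y)))
    rows = []
    best_cfg, best_acc = None, -np.inf
    for hu, l1, l2 in product(hu_grid, reg_grid, reg_grid):
        cfg = replace(base, hidden_units=int(hu), l1=float(l1), l2=float(l2))
        res = stratified_cv(x, y, cfg, folds=folds, repeats=repeats, seed=seed)
        for (rep, fold), score in np.ndenumerate(res.fold_scores):
            rows.append({"hidden_units": hu, "l1": l1, "l2": l2,
                         "repeat": rep, "fold": fold, "accuracy": score})
        if res.mean > best_acc:
            best_acc, best_cfg = res.mean, cfg
    return best_cfg, pd.DataFrame(rows)
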