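"""Dual-branch convolutional classifier for back-splice site pairs.

Each branch ingests one one-hot 100x4 window (SA or SD) and applies
conv(valid) -> dropout -> conv(same, stride 2) -> dropout -> max-pool
-> dropout -> flatten; the two branch vectors are concatenated, batch
normalized and fed to a dense sigmoid unit.  Branch weights are not
shared, so each branch learns features specific to its side of the
junction.  Convolutions use ReLU activations; the loss is binary
cross-entropy optimized with RMSProp, with early stopping on a
validation split and best-weight restoration.

With the default hyperparameters the per-branch temporal lengths are
100 -> 89 (conv, width 12, valid) -> 45 (conv, width 30, 'same',
stride 2) -> 9 (pool 5/5), giving a 9*128 = 1152-wide flatten per
branch and a 2304-wide concatenated feature vector.
"""

from __future__ import annotations

import dataclasses
import hashlib
import io
import json
import math
from pathlib import Path
from typing import Sequence

import numpy as np
from sklearn.model_selection import train_test_split

from . import _nn
from .errors import ArchitectureInfeasible, DegenerateLabels, LengthMismatch
from .seqdata import WINDOW_LEN, SamplePair, encode_pairs

_BRANCHES = ("sa", "sd")


@dataclasses.dataclass(frozen=True)
class ModelConfig:
    """Architecture and training hyperparameters.

    Defaults are the tuned values of the reference recipe: 256 width-12
    valid conv filters, 128 width-30 'same' stride-2 filters, pool 5/5,
    dropout 0.7, batch normalization after concatenation, RMSProp with
    batch size 1024, max 100 epochs and early-stopping patience 20.
    """

    conv1_kernels: int = 256
    conv1_size: int = 12
    conv2_kernels: int = 128
    conv2_size: int = 30
    conv2_stride: int = 2
    pool_size: int = 5
    pool_stride: int = 5
    dropout1: float = 0.7
    dropout2: float = 0.7
    batchnorm: bool = True
    bn_as_dropout: bool = False
    learning_rate: float = 1e-3
    batch_size: int = 1024
    max_epochs: int = 100
    early_stopping_patience: int = 20
    validation_fraction: float = 0.1
    seed: int = 0

    def __post_init__(self):
        if self.pool_size != self.pool_stride:
            raise ValueError("only non-overlapping pooling is supported")
        for f in ("dropout1", "dropout2", "validation_fraction"):
            v = getattr(self, f)
            if not 0.0 <= v < 1.0:
                raise ValueError(f"{f} must be in [0,1)")
        if self.batchnorm and self.bn_as_dropout:
            raise ValueError("batchnorm and bn_as_dropout are mutually exclusive")
        for f in ("conv1_kernels", "conv1_size", "conv2_kernels", "conv2_size",
                  "conv2_stride", "pool_size", "batch_size", "max_epochs"):
            if getattr(self, f) < 1:
                raise ValueError(f"{f} must be positive")

    def variant(self, name: str) -> "ModelConfig":
        """One of the ablation variants: 'default', 'no_bn', 'bn_to_dropout'."""
        if name == "default":
            return dataclasses.replace(self, batchnorm=True, bn_as_dropout=False)
        if name == "no_bn":
            return dataclasses.replace(self, batchnorm=False, bn_as_dropout=False)
        if name == "bn_to_dropout":
            return dataclasses.replace(self, batchnorm=False, bn_as_dropout=True)
        raise ValueError(f"unknown variant {name!r}")


def compact_config(**overrides) -> ModelConfig:
    """A small configuration for quick experiments and simulations.

    Same topology as the default, with fewer filters, lighter dropout and
    smaller batches so that cross-validation on synthetic fixtures runs in
    minutes on one CPU.
    """
    base = dict(
        conv1_kernels=32,
        conv2_size=12,
        conv2_kernels=16,
        dropout1=0.2,
        dropout2=0.2,
        batch_size=256,
        learning_rate=1e-3,
        max_epochs=40,
        early_stopping_patience=6,
    )
    base.update(overrides)
    return ModelConfig(**base)


def shape_contract(cfg: ModelConfig) -> list[tuple[str, tuple[int, ...]]]:
    """Analytic per-layer output shapes (one branch, then the merge head).

    conv1 is 'valid' stride 1: L1 = 100 - conv1_size + 1.  conv2 is
    'same' with stride s: L2 = ceil(L1 / s).  Pooling is size 5 stride 5:
    Lp = floor(L2 / 5).  Flatten is Lp * conv2_kernels per branch and the
    concatenation doubles it.
    """
    l1 = WINDOW_LEN - cfg.conv1_size + 1
    if l1 < 1:
        raise ArchitectureInfeasible(f"conv1 output length {l1} < 1")
    l2 = math.ceil(l1 / cfg.conv2_stride)
    lp = l2 // cfg.pool_size
    if lp < 1:
        raise ArchitectureInfeasible(f"pooled length {lp} < 1")
    flat = lp * cfg.conv2_kernels
    shapes: list[tuple[str, tuple[int, ...]]] = [
        ("input", (WINDOW_LEN, 4)),
        ("conv1", (l1, cfg.conv1_kernels)),
        ("dropout1", (l1, cfg.conv1_kernels)),
        ("conv2", (l2, cfg.conv2_kernels)),
        ("dropout2", (l2, cfg.conv2_kernels)),
        ("maxpool", (lp, cfg.conv2_kernels)),
        ("dropout3", (lp, cfg.conv2_kernels)),
        ("flatten", (flat,)),
        ("concatenate", (2 * flat,)),
    ]
    if cfg.batchnorm:
        shapes.append(("batchnorm", (2 * flat,)))
    shapes.append(("dense", (1,)))
    return shapes


class TrainedModel:
    """Parameter state, config and training history of one classifier."""

    FORMAT_VERSION = 1

    def __init__(self, config: ModelConfig, seed: int | None = None):
        self.config = config
        shapes = dict(shape_contract(config))
        self.feature_width = shapes["concatenate"][0]
        seed = config.seed if seed is None else seed
        rng = np.random.default_rng(seed)
        c = config
        p: dict[str, np.ndarray] = {}
        for br in _BRANCHES:
            p[f"{br}_conv1_W"] = _nn.glorot_uniform(
                rng, (c.conv1_size, 4, c.conv1_kernels),
                fan_in=c.conv1_size * 4, fan_out=c.conv1_size * c.conv1_kernels,
            )
            p[f"{br}_conv1_b"] = np.zeros(c.conv1_kernels, dtype=np.float32)
            p[f"{br}_conv2_W"] = _nn.glorot_uniform(
                rng, (c.conv2_size, c.conv1_kernels, c.conv2_kernels),
                fan_in=c.conv2_size * c.conv1_kernels,
                fan_out=c.conv2_size * c.conv2_kernels,
            )
            p[f"{br}_conv2_b"] = np.zeros(c.conv2_kernels, dtype=np.float32)
        if c.batchnorm:
            p["bn_gamma"] = np.ones(self.feature_width, dtype=np.float32)
            p["bn_beta"] = np.zeros(self.feature_width, dtype=np.float32)
        p["dense_W"] = _nn.glorot_uniform(
            rng, (self.feature_width, 1), fan_in=self.feature_width, fan_out=1
        )
        p["dense_b"] = np.zeros(1, dtype=np.float32)
        self.params = p
        self.bn_mean = np.zeros(self.feature_width, dtype=np.float32)
        self.bn_var = np.ones(self.feature_width, dtype=np.float32)
        self.history: list[dict] = []
        self.best_epoch_: int | None = None
        self.stopped_epoch_: int | None = None
        self.best_param_hash_: str | None = None

    # -- forward passes -----------------------------------------------------

    def _branch_forward(self, x, br, train, rng):
        c = self.config
        p = self.params
        z1, c1 = _nn.conv1d_forward(x, p[f"{br}_conv1_W"], p[f"{br}_conv1_b"])
        a1 = np.maximum(z1, 0.0)
        d1, k1 = (a1, None) if not train else _nn.dropout_forward(a1, c.dropout1, rng)
        z2, c2 = _nn.conv1d_forward(
            d1, p[f"{br}_conv2_W"], p[f"{br}_conv2_b"],
            stride=c.conv2_stride, padding="same",
        )
        a2 = np.maximum(z2, 0.0)
        d2, k2 = (a2, None) if not train else _nn.dropout_forward(a2, c.dropout2, rng)
        pool, cp = _nn.maxpool_forward(d2, c.pool_size, c.pool_stride)
        d3, k3 = (pool, None) if not train else _nn.dropout_forward(pool, c.dropout2, rng)
        flat = d3.reshape(d3.shape[0], -1)
        cache = (c1, z1, k1, c2, z2, k2, cp, k3, d3.shape)
        inter = {"conv1": a1, "conv2": a2, "maxpool": pool, "flatten": flat}
        return flat, cache, inter

    def _branch_backward(self, dflat, br, cache):
        c = self.config
        p = self.params
        c1, z1, k1, c2, z2, k2, cp, k3, d3_shape = cache
        g = {}
        dd3 = dflat.reshape(d3_shape)
        dpool = _nn.dropout_backward(dd3, k3)
        dd2 = _nn.maxpool_backward(dpool, cp)
        da2 = _nn.dropout_backward(dd2, k2)
        dz2 = da2 * (z2 > 0)
        dd1, g[f"{br}_conv2_W"], g[f"{br}_conv2_b"] = _nn.conv1d_backward(
            dz2, p[f"{br}_conv2_W"], c2
        )
        da1 = _nn.dropout_backward(dd1, k1)
        dz1 = da1 * (z1 > 0)
        _, g[f"{br}_conv1_W"], g[f"{br}_conv1_b"] = _nn.conv1d_backward(
            dz1, p[f"{br}_conv1_W"], c1
        )
        return g

    def forward(self, xa, xd, train=False, rng=None, collect=False):
        """Probability for each pair; optionally intermediate activations.

        Returns (prob, cache, intermediates); cache is None in eval mode
        unless backprop is intended, intermediates None unless collect.
        """
        c = self.config
        p = self.params
        fa, ca, ia = self._branch_forward(xa, "sa", train, rng)
        fd, cd, id_ = self._branch_forward(xd, "sd", train, rng)
        feat = np.concatenate([fa, fd], axis=1)
        if c.batchnorm:
            h, cbn = _nn.batchnorm_forward(
                feat, p["bn_gamma"], p["bn_beta"], self.bn_mean, self.bn_var, train
            )
            kh = None
        elif c.bn_as_dropout and train:
            h, kh = _nn.dropout_forward(feat, c.dropout2, rng)
            cbn = None
        else:
            h, kh, cbn = feat, None, None
        logits = h @ p["dense_W"] + p["dense_b"]
        prob = _nn.sigmoid(logits[:, 0].astype(np.float64))
        cache = (ca, cd, fa.shape[1], cbn, kh, h)
        inter = None
        if collect:
            inter = {
                "sa": ia, "sd": id_, "concatenate": feat,
                "head": h, "prob": prob,
            }
        return prob, cache, inter

    def backward(self, prob, y, cache):
        """Gradient of mean BCE wrt all parameters, given a forward cache."""
        p = self.params
        ca, cd, split, cbn, kh, h = cache
        B = len(y)
        dlogit = ((prob - y) / B).astype(p["dense_W"].dtype)[:, None]
        g = {
            "dense_W": h.T @ dlogit,
            "dense_b": dlogit.sum(axis=0),
        }
        dh = dlogit @ p["dense_W"].T
        if self.config.batchnorm:
            dfeat, g["bn_gamma"], g["bn_beta"] = _nn.batchnorm_backward(
                dh, p["bn_gamma"], cbn
            )
        else:
            dfeat = _nn.dropout_backward(dh, kh)
        g.update(self._branch_backward(dfeat[:, :split], "sa", ca))
        g.update(self._branch_backward(dfeat[:, split:], "sd", cd))
        return g

    # -- public inference ---------------------------------------------------

    def predict_arrays(self, xa, xd, batch_size: int = 512) -> np.ndarray:
        self._check_inputs(xa, xd)
        out = []
        for i in range(0, len(xa), batch_size):
            prob, _, _ = self.forward(xa[i : i + batch_size], xd[i : i + batch_size])
            out.append(prob)
        return np.concatenate(out) if out else np.empty(0)

    @staticmethod
    def _check_inputs(xa, xd):
        for x in (xa, xd):
            if x.ndim != 3 or x.shape[1] != WINDOW_LEN or x.shape[2] != 4:
                raise LengthMismatch(
                    f"inputs must be (n, {WINDOW_LEN}, 4), got {x.shape}"
                )

    def param_hash(self) -> str:
        """SHA-256 of all parameter arrays and BN buffers (order-stable)."""
        h = hashlib.sha256()
        for k in sorted(self.params):
            h.update(k.encode())
            h.update(np.ascontiguousarray(self.params[k]).tobytes())
        h.update(self.bn_mean.tobytes())
        h.update(self.bn_var.tobytes())
        return h.hexdigest()

    def snapshot(self) -> dict:
        state = {k: v.copy() for k, v in self.params.items()}
        state["__bn_mean"] = self.bn_mean.copy()
        state["__bn_var"] = self.bn_var.copy()
        return state

    def restore(self, state: dict) -> None:
        for k in self.params:
            self.params[k] = state[k].copy()
        self.bn_mean = state["__bn_mean"].copy()
        self.bn_var = state["__bn_var"].copy()

    # -- persistence ---------------------------------------------------------

    def save(self, path: str | Path) -> None:
        meta = {
            "format_version": self.FORMAT_VERSION,
            "config": dataclasses.asdict(self.config),
            "history": self.history,
            "best_epoch": self.best_epoch_,
            "stopped_epoch": self.stopped_epoch_,
            "best_param_hash": self.best_param_hash_,
        }
        arrays = dict(self.params)
        arrays["__bn_mean"] = self.bn_mean
        arrays["__bn_var"] = self.bn_var
        buf = io.BytesIO()
        np.savez(buf, __meta=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
                 **arrays)
        Path(path).write_bytes(buf.getvalue())

    @classmethod
    def load(cls, path: str | Path) -> "TrainedModel":
        with np.load(Path(path), allow_pickle=False) as z:
            meta = json.loads(bytes(z["__meta"]).decode())
            arrays = {k: z[k] for k in z.files if k != "__meta"}
        model = cls(ModelConfig(**meta["config"]))
        for k in model.params:
            model.params[k] = arrays[k]
        model.bn_mean = arrays["__bn_mean"]
        model.bn_var = arrays["__bn_var"]
        model.history = meta["history"]
        model.best_epoch_ = meta["best_epoch"]
        model.stopped_epoch_ = meta["stopped_epoch"]
        model.best_param_hash_ = meta["best_param_hash"]
        return model


def build_model(cfg: ModelConfig, seed: int | None = None) -> TrainedModel:
    """Fresh (untrained) model with deterministic initialization."""
    return TrainedModel(cfg, seed=seed)


def _stratified_val_split(y: np.ndarray, fraction: float, seed: int):
    idx = np.arange(len(y))
    n_val = max(2, int(round(fraction * len(y))))
    train_idx, val_idx = train_test_split(
        idx, test_size=n_val, stratify=y, random_state=seed % (2**32)
    )
    return train_idx, val_idx


def train(
    model: TrainedModel,
    train_pairs: Sequence[SamplePair],
    val_pairs: Sequence[SamplePair] | None = None,
    verbose: bool = False,
) -> TrainedModel:
    """Fit with RMSProp + early stopping; restores best-validation weights.

    When no validation set is supplied, a stratified
    ``config.validation_fraction`` split is carved out of the training
    pairs.  Validation loss is monitored; training stops after
    ``early_stopping_patience`` consecutive non-improving epochs (or at
    ``max_epochs``) and the best epoch's weights are restored.
    """
    c = model.config
    xa, xd, y = encode_pairs(train_pairs)
    if len(np.unique(y)) < 2:
        raise DegenerateLabels("training set contains a single class")
    if val_pairs is None:
        tr, va = _stratified_val_split(y, c.validation_fraction, c.seed)
        xa_v, xd_v, y_v = xa[va], xd[va], y[va]
        xa, xd, y = xa[tr], xd[tr], y[tr]
    else:
        xa_v, xd_v, y_v = encode_pairs(val_pairs)

    rng = np.random.default_rng(c.seed + 1)
    opt = _nn.RMSProp(model.params, lr=c.learning_rate)
    best_loss = np.inf
    best_state = model.snapshot()
    best_epoch = 0
    wait = 0
    n = len(y)
    for epoch in range(1, c.max_epochs + 1):
        order = rng.permutation(n)
        losses = []
        for i in range(0, n, c.batch_size):
            b = order[i : i + c.batch_size]
            prob, cache, _ = model.forward(xa[b], xd[b], train=True, rng=rng)
            losses.append(_nn.bce_loss(prob, y[b]))
            grads = model.backward(prob, y[b], cache)
            opt.step(model.params, grads)
        val_prob = model.predict_arrays(xa_v, xd_v)
        val_loss = _nn.bce_loss(val_prob, y_v)
        model.history.append(
            {"epoch": epoch, "train_loss": float(np.mean(losses)), "val_loss": val_loss}
        )
        if verbose:
            print(
                f"epoch {epoch}: train_loss={np.mean(losses):.4f} val_loss={val_loss:.4f}",
                flush=True,
            )
        if val_loss < best_loss:
            best_loss = val_loss
            best_state = model.snapshot()
            best_epoch = epoch
            wait = 0
        else:
            wait += 1
            # patience 0 stops on the first non-improving epoch
            if wait >= c.early_stopping_patience:
                break
    model.stopped_epoch_ = epoch
    model.best_epoch_ = best_epoch
    model.restore(best_state)
    model.best_param_hash_ = model.param_hash()
    return model


def predict(model: TrainedModel, pairs: Sequence[SamplePair]) -> np.ndarray:
    """Back-splicing probability in [0,1] for each pair (inference mode)."""
    xa, xd, _ = encode_pairs(pairs)
    return model.predict_arrays(xa, xd)


def first_layer_activations(
    model: TrainedModel, pairs: Sequence[SamplePair], branch: str, batch_size: int = 512
) -> np.ndarray:
    """Post-ReLU conv1 activations, shape (n, 100-conv1_size+1, conv1_kernels).

    These per-position, per-filter scores are the candidate-motif
    evaluation matrix used by the motif-extraction pipeline.
    """
    branch = branch.lower()
    if branch not in _BRANCHES:
        raise ValueError("branch must be 'SA' or 'SD'")
    seqs = [p.sa_seq if branch == "sa" else p.sd_seq for p in pairs]
    from .seqdata import one_hot_encode

    out = []
    for i in range(0, len(seqs), batch_size):
        x = np.stack([one_hot_encode(s) for s in seqs[i : i + batch_size]])
        z, _ = _nn.conv1d_forward(
            x, model.params[f"{branch}_conv1_W"], model.params[f"{branch}_conv1_b"]
        )
        out.append(np.maximum(z, 0.0))
    return (
        np.concatenate(out)
        if out
        else np.empty((0, WINDOW_LEN - model.config.conv1_size + 1, model.config.conv1_kernels))
    )
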