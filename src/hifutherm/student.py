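"""Unimodal student distilled from the multimodal teacher.

The student sees only the target modality (B-mode by default).  Its
forward pass concatenates a 3-layer MLP embedding of the input patch with a
fixed-length prior vector distilled from the teacher's frozen
self-expressive matrix Z and common space D:

    prior = resize( conv1d( combine(Z, D) ) averaged over samples )

where ``combine`` is the Hadamard product when Z and D share a shape and
the matrix product Z D otherwise, the 1-D convolution (kernel width 3,
same padding) runs along the feature axis for dimensional matching, and a
linear resize maps the pooled row to length d'.  Because Z and D are sized
by the teacher's training set, the prior is necessarily a constant vector
at inference: the student needs nothing but a single-modality patch.

Training minimises the MSE between predicted and probe temperatures; only
the student MLP, the mapping (conv + resize) and the head update -- Z and D
stay frozen, byte for byte.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._nn import Adam, he_normal, init_mlp, mlp_backward, mlp_forward
from .teacher import TeacherArtifacts, fingerprint

__all__ = [
    "PriorKnowledge",
    "StudentModel",
    "StudentConfig",
    "combine_teacher_knowledge",
    "distillation_prior",
    "student_forward",
    "uskd_loss",
    "train_student",
]


@dataclass
class StudentConfig:
    """Student hyperparameters; optimiser settings mirror the teacher's."""

    lr: float = 1e-3
    decay: float = 0.99
    batch_size: int = 16
    epochs: int = 80
    max_iter: int = 10000
    c: int = 2
    d_prime: int = 64
    conv_width: int = 3
    combine_rule: str = "auto"   # "auto" | "elementwise" | "matmul"


@dataclass
class PriorKnowledge:
    """Distilled prior: pooled, dimension-matched aggregate of (Z, D)."""

    Z: np.ndarray
    D: np.ndarray
    prior: np.ndarray       # (d',)
    rule: str               # combine rule actually applied


@dataclass
class StudentModel:
    """Target-modality regressor with an embedded distilled prior."""

    mlp: list                      # [(W1, b1), (W2, b2)]: HW -> c*HW -> d'
    conv_kernel: np.ndarray        # (conv_width,)
    conv_bias: np.ndarray          # 0-d array
    map_W: np.ndarray              # (d', r) linear resize
    map_b: np.ndarray              # (d',)
    head_w: np.ndarray             # (2*d',)
    head_b: np.ndarray             # 0-d array
    prior_source: np.ndarray | None   # combined (S, r) matrix, constant
    prior: np.ndarray | None          # (d',), refreshed from mapping params
    combine_rule: str = "matmul"
    target_modality: str = "UBI"
    patch_mean: float = 0.0
    patch_std: float = 1.0
    label_mean: float = 0.0
    label_std: float = 1.0
    seed: int = 0
    distilled: bool = True
    log: pd.DataFrame | None = None
    teacher_fingerprint: str = ""
    train_fingerprint: str = ""

    @property
    def d_prime(self) -> int:
        return self.mlp[-1][0].shape[1]

    def refresh_prior(self) -> None:
        """Recompute the prior vector from the current mapping parameters."""
        if self.prior_source is None:
            return
        self.prior = _mapping_forward(
            self.prior_source, self.conv_kernel, float(self.conv_bias),
            self.map_W, self.map_b,
        )[0]

    def predict_patches(self, patches: np.ndarray) -> np.ndarray:
        """Temperatures (degC) for a batch of (N, H, W) target-modality patches."""
        return student_forward(patches, self)


def combine_teacher_knowledge(Z: np.ndarray, D: np.ndarray, rule: str = "auto"):
    """Combine Z and D into one matrix.

    The Hadamard product is only defined when D is square like Z; with the
    dimension-matching convolution in the pipeline, the default resolves to
    elementwise when shapes match and to the matrix product Z @ D otherwise.
    An explicit ``rule`` never falls back silently.
    """
    Z = np.asarray(Z, dtype=float)
    D = np.asarray(D, dtype=float)
    if rule == "auto":
        rule = "elementwise" if Z.shape == D.shape else "matmul"
    if rule == "elementwise":
        if Z.shape != D.shape:
            raise ValueError(
                f"elementwise combine needs matching shapes, got Z{Z.shape} vs "
                f"D{D.shape}; use rule='matmul' or 'auto'"
            )
        return Z * D, rule
    if rule == "matmul":
        return Z @ D, rule
    raise ValueError(f"unknown combine rule '{rule}'")


def _conv1d_same(rows: np.ndarray, kernel: np.ndarray, bias: float) -> np.ndarray:
    """Correlate each row with ``kernel`` (zero-padded 'same') and add bias."""
    from scipy.ndimage import correlate1d

    return correlate1d(np.atleast_2d(rows), kernel, axis=-1,
                       mode="constant", cval=0.0) + bias


def _mapping_forward(combined, kernel, bias, map_W, map_b):
    """prior = map_W @ mean_s(conv1d(combined rows)) + map_b.

    Returns (prior, pooled) where ``pooled`` is the length-r convolved mean
    row (cached for the backward pass; mean-pooling commutes with the
    convolution, so the gradient only needs the mean source row).
    """
    conv = _conv1d_same(combined, kernel, bias)
    pooled = conv.mean(axis=0)
    return map_W @ pooled + map_b, pooled


def distillation_prior(
    Z: np.ndarray,
    D: np.ndarray,
    conv_kernel: np.ndarray,
    conv_bias: float = 0.0,
    map_W: np.ndarray | None = None,
    map_b: np.ndarray | None = None,
    rule: str = "auto",
) -> PriorKnowledge:
    """Aggregate frozen (Z, D) into the fixed-length prior vector.

    Pure and deterministic: the same inputs always give the same prior.
    When ``map_W`` is omitted the resize defaults to the identity (prior
    length = combined feature width).
    """
    combined, applied = combine_teacher_knowledge(Z, D, rule)
    r = combined.shape[1]
    if map_W is None:
        map_W = np.eye(r)
    if map_b is None:
        map_b = np.zeros(map_W.shape[0])
    prior, _ = _mapping_forward(combined, np.asarray(conv_kernel, dtype=float),
                                float(conv_bias), map_W, map_b)
    if not np.all(np.isfinite(prior)):
        raise FloatingPointError("distilled prior is non-finite")
    return PriorKnowledge(Z=Z, D=D, prior=prior, rule=applied)


def student_forward(x_t: np.ndarray, model: StudentModel) -> np.ndarray:
    """Predict temperatures (degC) from target-modality patches.

    O_t = concat(MLP_t(x), prior); the prior contribution is identical for
    every sample.  Privileged modalities are deliberately not accepted here.
    """
    if model.prior is None:
        raise ValueError("student has no distilled prior; train or load one first")
    x = np.asarray(x_t, dtype=float)
    if x.ndim == 2:
        x = x[None]
    xn = (x.reshape(x.shape[0], -1) - model.patch_mean) / model.patch_std
    h, _ = mlp_forward(model.mlp, xn)
    o = np.concatenate([h, np.tile(model.prior, (h.shape[0], 1))], axis=1)
    y_n = o @ model.head_w + float(model.head_b)
    return y_n * model.label_std + model.label_mean


def uskd_loss(y: np.ndarray, y_hat: np.ndarray) -> float:
    """Mean squared error between labels and student predictions."""
    y = np.asarray(y, dtype=float)
    y_hat = np.asarray(y_hat, dtype=float)
    if y.shape != y_hat.shape:
        raise ValueError("label and prediction lengths differ")
    return float(np.mean((y - y_hat) ** 2))


def train_student(
    x_t: np.ndarray,
    y: np.ndarray,
    teacher: TeacherArtifacts,
    config: StudentConfig | None = None,
    seed: int = 0,
    val_x: np.ndarray | None = None,
    val_y: np.ndarray | None = None,
    distill: bool = True,
) -> StudentModel:
    """Train the student on (S, H, W) target-modality patches with Adam.

    Z and D are read from the frozen teacher and verified unchanged (by
    hash) after training; ``distill=False`` trains an otherwise identical
    model with a zero prior and no mapping updates, the ablation used to
    report the value of distillation.
    """
    cfg = config or StudentConfig()
    x = np.asarray(x_t, dtype=float)
    y = np.asarray(y, dtype=float)
    S, H, W = x.shape
    d_prime = cfg.d_prime
    r = teacher.D.shape[1]

    frozen_hash = fingerprint(teacher.Z, teacher.D)

    patch_mean = float(x.mean())
    patch_std = float(x.std()) or 1.0
    label_mean = float(y.mean())
    label_std = float(y.std()) or 1.0
    xn = (x.reshape(S, -1) - patch_mean) / patch_std
    yn = (y - label_mean) / label_std

    ss = np.random.SeedSequence(seed)
    rng_init, rng_shuffle = (np.random.default_rng(c) for c in ss.spawn(2))
    mlp = init_mlp([H * W, cfg.c * H * W, d_prime], rng_init)
    conv_kernel = rng_init.normal(0.0, 0.5, size=cfg.conv_width)
    conv_bias = np.array(0.0)
    map_W = he_normal(rng_init, r, d_prime).T   # (d', r)
    map_b = np.zeros(d_prime)
    head_w = np.zeros(2 * d_prime)
    head_b = np.array(0.0)

    if distill:
        combined, rule = combine_teacher_knowledge(teacher.Z, teacher.D,
                                                   cfg.combine_rule)
    else:
        combined, rule = None, "none"

    model = StudentModel(
        mlp=mlp, conv_kernel=conv_kernel, conv_bias=conv_bias,
        map_W=map_W, map_b=map_b, head_w=head_w, head_b=head_b,
        prior_source=combined, prior=np.zeros(d_prime),
        combine_rule=rule, patch_mean=patch_mean, patch_std=patch_std,
        label_mean=label_mean, label_std=label_std, seed=int(seed),
        distilled=distill, teacher_fingerprint=frozen_hash,
        train_fingerprint=fingerprint(x, y),
    )

    params = [p for layer in mlp for p in layer] + [head_w, head_b]
    if distill:
        params += [conv_kernel, conv_bias, map_W, map_b]
    opt = Adam(params)

    mean_source = combined.mean(axis=0) if distill else None
    half = cfg.conv_width // 2
    rows = []
    for epoch in range(cfg.epochs):
        lr = cfg.lr * cfg.decay**epoch
        order = rng_shuffle.permutation(S)
        epoch_losses = []
        for start in range(0, S, cfg.batch_size):
            idx = order[start:start + cfg.batch_size]
            xb, yb = xn[idx], yn[idx]
            B = len(idx)

            if distill:
                model.refresh_prior()
            prior = model.prior
            h, caches = mlp_forward(mlp, xb)
            o = np.concatenate([h, np.tile(prior, (B, 1))], axis=1)
            y_hat = o @ head_w + float(head_b)
            loss = float(np.mean((y_hat - yb) ** 2))
            if not np.isfinite(loss):
                raise FloatingPointError("student loss became non-finite")
            epoch_losses.append(loss)

            g_y = 2.0 * (y_hat - yb) / B
            g_head_w = o.T @ g_y
            g_head_b = np.array(float(g_y.sum()))
            g_o = np.outer(g_y, head_w)
            layer_grads, _ = mlp_backward(mlp, caches, g_o[:, :d_prime])
            grads = [g for pair in layer_grads for g in pair] + [g_head_w, g_head_b]
            if distill:
                g_prior = g_o[:, d_prime:].sum(axis=0)
                pooled = _conv1d_same(combined, conv_kernel,
                                      float(conv_bias)).mean(axis=0)
                g_map_W = np.outer(g_prior, pooled)
                g_map_b = g_prior
                g_pooled = map_W.T @ g_prior
                g_conv_bias = np.array(float(g_pooled.sum()))
                padded = np.pad(mean_source, (half, half))
                g_kernel = np.array([
                    float(g_pooled @ padded[k:k + len(mean_source)])
                    for k in range(cfg.conv_width)
                ])
                grads += [g_kernel, g_conv_bias, g_map_W, g_map_b]
            opt.step(grads, lr)

        if distill:
            model.refresh_prior()
        row = {"epoch": epoch, "loss": float(np.mean(epoch_losses))}
        if val_x is not None and val_y is not None:
            pred = student_forward(val_x, model)
            row["val_mse"] = float(np.mean((np.asarray(val_y) - pred) ** 2))
        rows.append(row)

    if fingerprint(teacher.Z, teacher.D) != frozen_hash:
        raise RuntimeError("frozen teacher tensors changed during student training")
    model.log = pd.DataFrame(rows)
    return model
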