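"""Multimodal teacher: encoders, self-expressive layer, DCCA common space.

The teacher ingests aligned patches of all privileged modalities and learns

* one MLP encoder per modality (input HW -> c*HW -> c*HW -> d', ReLU after
  every affine map),
* a shared self-expressive coefficient matrix Z (S x S, zero diagonal)
  expressing each sample as a linear combination of the others,
* a common space D: the top-r left singular vectors of the summed ridge
  projection matrix P = sum_m O_m (O_m^T O_m + r_m I)^-1 O_m^T, where
  O_m = Z f_m are the self-expressed embeddings,
* a linear head mapping rows of D to temperature.

The total loss is

    l = lam1 ||Z||_F^2 + lam2 sum_m ||Z f_m - f_m||_F^2
        - lam3 sum_i s_i + lam4 MSE(y, y_hat)

with s_i the top-r singular values of P.  Optimisation alternates: D is
recomputed by SVD each step and held constant while the encoders, Z and the
head take an Adam step -- the gradient of sum_i s_i through the SVD then
reduces to the gradient of Tr(D^T P D) at fixed D, which is exact for a
simple spectrum and avoids degenerate singular-value instabilities.

After training, Z and D (recomputed once from the final encoder state) are
frozen; they are the knowledge later distilled into the unimodal student.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._nn import Adam, init_mlp, mlp_backward, mlp_forward

__all__ = [
    "EncoderParams",
    "SelfExpressiveMatrix",
    "DccaState",
    "TeacherArtifacts",
    "TeacherConfig",
    "encode_modality",
    "apply_self_expression",
    "self_expressive_loss",
    "projection_matrix",
    "aggregate_projections",
    "common_space",
    "dcca_loss",
    "teacher_head",
    "mtke_total_loss",
    "train_teacher",
]


@dataclass
class EncoderParams:
    """Per-modality encoder: three (W, b) affine layers, ReLU after each."""

    layers: list  # [(W1, b1), (W2, b2), (W3, b3)]
    activation: str = "relu"
    modality: str = ""

    @property
    def input_width(self) -> int:
        return self.layers[0][0].shape[0]

    @property
    def output_width(self) -> int:
        return self.layers[-1][0].shape[1]


class SelfExpressiveMatrix:
    """Trainable S x S coefficient matrix with a structurally zero diagonal.

    The diagonal is masked out of the parameterisation (not penalised), so
    diag(Z) = 0 holds exactly at every step and the trivial identity
    solution is unreachable.
    """

    def __init__(self, theta: np.ndarray, trainable: bool = True):
        theta = np.asarray(theta, dtype=float)
        if theta.ndim != 2 or theta.shape[0] != theta.shape[1]:
            raise ValueError("Z parameterisation must be square")
        self.theta = theta
        self.trainable = trainable
        self._mask = 1.0 - np.eye(theta.shape[0])

    @property
    def matrix(self) -> np.ndarray:
        return self.theta * self._mask

    def mask_gradient(self, grad: np.ndarray) -> np.ndarray:
        return grad * self._mask

    @classmethod
    def initialize(cls, n_samples: int, rng: np.random.Generator, scale: float = 1e-2):
        return cls(scale * rng.standard_normal((n_samples, n_samples)))


@dataclass
class DccaState:
    """Intermediate quantities of one DCCA evaluation."""

    outputs: list            # O_m, each (S, d')
    ridges: list             # r_m per modality
    projections: list        # P_m, each (S, S)
    aggregate: np.ndarray    # P = sum_m P_m
    rank: int
    common: np.ndarray       # D, (S, r)
    singular_values: np.ndarray  # (r,)
    right_factor: np.ndarray     # right singular factor of P, (S, r)


@dataclass
class TeacherConfig:
    """Teacher hyperparameters; the reference optimiser settings are defaults."""

    lr: float = 1e-3
    decay: float = 0.99
    batch_size: int = 16
    epochs: int = 80
    max_iter: int = 10000
    lambdas: tuple = (1.0, 1.0, 1.0, 1.0)
    c: int = 2
    d_prime: int = 64
    r: int | None = None        # None -> min(32, S_train)
    r_m: float = 1e-3
    z_init_scale: float = 1e-2


@dataclass
class TeacherArtifacts:
    """Everything the distillation step and evaluation need from the teacher."""

    encoders: list                 # EncoderParams per modality
    Z: np.ndarray                  # frozen (S_train, S_train)
    D: np.ndarray                  # frozen (S_train, r)
    singular_values: np.ndarray
    ridge_maps: list               # R_m = (O^T O + r_m I)^-1 O^T D, (d', r)
    head_w: np.ndarray
    head_b: float
    patch_mean: np.ndarray         # (M,)
    patch_std: np.ndarray          # (M,)
    label_mean: float
    label_std: float
    config: TeacherConfig
    seed: int
    log: pd.DataFrame
    train_fingerprint: str = ""
    modality_names: tuple = ("UBI", "UEI", "UDI")

    def freeze(self) -> None:
        for arr in (self.Z, self.D):
            arr.setflags(write=False)


# --- operations -------------------------------------------------------------

def encode_modality(x_m: np.ndarray, params: EncoderParams) -> np.ndarray:
    """Map (S, H, W) patches of one modality to the (S, d') embedding f_m."""
    x = np.asarray(x_m, dtype=float)
    if x.ndim == 3:
        x = x.reshape(x.shape[0], -1)
    if x.shape[1] != params.input_width:
        raise ValueError(
            f"modality '{params.modality}' layer 1 expects input width "
            f"{params.input_width}, got {x.shape[1]}"
        )
    out, _ = mlp_forward(params.layers, x)
    if not np.all(np.isfinite(out)):
        raise FloatingPointError(f"non-finite embedding for modality '{params.modality}'")
    return out


def apply_self_expression(Z, f_m: np.ndarray) -> np.ndarray:
    """O_m = Z f_m; Z must have an exactly zero diagonal."""
    Zm = Z.matrix if isinstance(Z, SelfExpressiveMatrix) else np.asarray(Z, dtype=float)
    if np.any(np.diagonal(Zm) != 0.0):
        raise ValueError("self-expressive matrix must have a zero diagonal")
    if Zm.shape[1] != f_m.shape[0]:
        raise ValueError("Z and embedding sample counts disagree")
    return Zm @ f_m


def self_expressive_loss(Z, embeddings, lam1: float = 1.0, lam2: float = 1.0) -> float:
    """l_s = lam1 ||Z||_F^2 + lam2 sum_m ||Z f_m - f_m||_F^2."""
    if lam1 < 0 or lam2 < 0:
        raise ValueError("trade-off parameters must be >= 0")
    Zm = Z.matrix if isinstance(Z, SelfExpressiveMatrix) else np.asarray(Z, dtype=float)
    total = lam1 * float(np.sum(Zm * Zm))
    for f in embeddings:
        resid = Zm @ f - f
        total += lam2 * float(np.sum(resid * resid))
    return total


def projection_matrix(O_m: np.ndarray, r_m: float, method: str = "solve") -> np.ndarray:
    """P_m = O (O^T O + r_m I)^-1 O^T, symmetric with spectrum in [0, 1) for r_m > 0.

    ``method='svd'`` evaluates the equivalent singular-value form
    U diag(s^2/(s^2+r_m)) U^T, used as an independent cross-check.
    """
    O = np.asarray(O_m, dtype=float)
    if r_m < 0:
        raise ValueError("ridge must be >= 0")
    if method == "svd":
        U, s, _ = np.linalg.svd(O, full_matrices=False)
        gain = s**2 / (s**2 + r_m)
        if r_m == 0:
            nz = s > s.max(initial=0.0) * 1e-12
            gain = np.where(nz, 1.0, 0.0)
        P = (U * gain) @ U.T
    else:
        A = O.T @ O + r_m * np.eye(O.shape[1])
        if r_m == 0:
            cond = np.linalg.cond(A)
            if not np.isfinite(cond) or cond > 1e12:
                raise np.linalg.LinAlgError(
                    "scatter matrix is singular at r_m = 0; set r_m > 0"
                )
        P = O @ np.linalg.solve(A, O.T)
    return 0.5 * (P + P.T)


def aggregate_projections(projections) -> np.ndarray:
    """P = sum_m P_m (kept as the plain sum; the orthogonality side-constraint
    stated for it cannot hold for a sum of ridge projections and is therefore
    not enforced)."""
    projections = list(projections)
    P = np.zeros_like(projections[0])
    for Pm in projections:
        if Pm.shape != P.shape:
            raise ValueError("projection matrices must share a shape")
        P = P + Pm
    return P


def _fix_signs(D: np.ndarray) -> np.ndarray:
    """Flip each column so its largest-magnitude entry is positive."""
    idx = np.argmax(np.abs(D), axis=0)
    signs = np.sign(D[idx, np.arange(D.shape[1])])
    signs[signs == 0] = 1.0
    return D * signs


def common_space(P: np.ndarray, r: int):
    """Top-r left singular vectors and singular values of P.

    Returns (D, s) with D^T D = I_r and s sorted descending; columns are
    sign-fixed for reproducible artifacts.
    """
    P = np.asarray(P, dtype=float)
    S = P.shape[0]
    if not 1 <= r <= S:
        raise ValueError(f"rank r must satisfy 1 <= r <= {S}, got {r}")
    U, s, Vt = np.linalg.svd(P)
    D = _fix_signs(U[:, :r])
    return D, s[:r]


def _full_dcca(outputs, r_m, r) -> DccaState:
    ridges = [r_m] * len(outputs) if np.isscalar(r_m) else list(r_m)
    projections = [projection_matrix(O, rm) for O, rm in zip(outputs, ridges)]
    P = aggregate_projections(projections)
    U, s, Vt = np.linalg.svd(P)
    D = _fix_signs(U[:, :r])
    right = _fix_signs(Vt[:r].T)
    return DccaState(outputs=list(outputs), ridges=ridges, projections=projections,
                     aggregate=P, rank=r, common=D, singular_values=s[:r],
                     right_factor=right)


def dcca_loss(singular_values) -> float:
    """l_d = -sum of the top-r singular values (maximising shared structure)."""
    s = np.asarray(singular_values, dtype=float)
    if np.any(s < -1e-12):
        raise ValueError("singular values must be >= 0")
    return -float(np.sum(s))


def teacher_head(D: np.ndarray, head_w: np.ndarray, head_b: float) -> np.ndarray:
    """Linear projection-mapping head: y_hat_i = w . D_i + b."""
    D = np.asarray(D, dtype=float)
    w = np.asarray(head_w, dtype=float)
    if D.shape[1] != w.shape[0]:
        raise ValueError("head weight length must equal the common-space rank")
    return D @ w + head_b


def mtke_total_loss(Z, embeddings, singular_values, y, y_hat, lambdas=(1.0, 1.0, 1.0, 1.0)):
    """Four-term teacher loss; lambdas default to (1, 1, 1, 1)."""
    lam1, lam2, lam3, lam4 = lambdas
    y = np.asarray(y, dtype=float)
    y_hat = np.asarray(y_hat, dtype=float)
    l_s = self_expressive_loss(Z, embeddings, lam1, lam2)
    l_d = lam3 * dcca_loss(singular_values)
    mse = float(np.mean((y - y_hat) ** 2))
    return l_s + l_d + lam4 * mse


def ridge_maps(state: DccaState):
    """R_m = (O_m^T O_m + r_m I)^-1 O_m^T D for each modality.

    These realise D ~ O_m R_m per modality and double as the out-of-sample
    map from an embedding row to common-space coordinates.
    """
    maps = []
    for O, rm in zip(state.outputs, state.ridges):
        A = O.T @ O + rm * np.eye(O.shape[1])
        maps.append(np.linalg.solve(A, O.T @ state.common))
    return maps


def _dcca_output_grad(O: np.ndarray, r_m: float, C: np.ndarray) -> np.ndarray:
    """Gradient of Tr(D^T P_m D) with respect to O_m at fixed D (C = D D^T)."""
    A = O.T @ O + r_m * np.eye(O.shape[1])
    Ainv_Ot = np.linalg.solve(A, O.T)          # A^-1 O^T
    CO_Ainv = C @ Ainv_Ot.T                    # C O A^-1
    K = Ainv_Ot @ CO_Ainv                      # A^-1 O^T C O A^-1
    return 2.0 * CO_Ainv - 2.0 * O @ K


# --- training ---------------------------------------------------------------

def _normalize_patches(patches: np.ndarray, mean: np.ndarray, std: np.ndarray):
    return (patches - mean[:, None, None, None]) / std[:, None, None, None]


def fingerprint(*arrays) -> str:
    import hashlib

    h = hashlib.sha256()
    for a in arrays:
        h.update(np.ascontiguousarray(a).tobytes())
    return h.hexdigest()


def out_of_sample_predict(encoders, R_list, head_w, head_b, patches_norm):
    """Out-of-sample teacher prediction (normalized units): map embeddings of
    unseen samples into the common space through the per-modality ridge maps
    (Z has no rows for unseen samples), average over modalities, apply the
    head."""
    d_val = None
    for m, enc in enumerate(encoders):
        f = encode_modality(patches_norm[m], enc)
        contrib = f @ R_list[m]
        d_val = contrib if d_val is None else d_val + contrib
    d_val = d_val / len(encoders)
    return d_val @ head_w + head_b


def train_teacher(
    train, val, config: TeacherConfig | None = None, seed: int = 0
) -> TeacherArtifacts:
    """Train the multimodal teacher full-batch with Adam.

    ``train`` / ``val`` are :class:`~hifutherm.synthdata.MultimodalPatchSet`
    instances sharing modality count and patch size.  The self-expressive
    matrix spans the full training set, so the self-expressive and DCCA
    terms are inherently full-batch; at the sample counts this package
    targets the supervised term is computed full-batch as well, one Adam
    step per epoch (the configured minibatch size is retained as metadata).
    Identical seeds yield identical loss trajectories bit for bit.
    """
    cfg = config or TeacherConfig()
    if train.patches.shape[0] != val.patches.shape[0]:
        raise ValueError("train and val must share the modality count")
    if train.patches.shape[2:] != val.patches.shape[2:]:
        raise ValueError("train and val must share the patch size")

    M, S, H, W = train.patches.shape
    r = cfg.r if cfg.r is not None else min(32, S)
    if r > S:
        raise ValueError("rank r cannot exceed the number of training samples")
    lam1, lam2, lam3, lam4 = cfg.lambdas

    # normalisation statistics (stored; predictions are mapped back to degC)
    patch_mean = train.patches.mean(axis=(1, 2, 3))
    patch_std = train.patches.std(axis=(1, 2, 3))
    patch_std[patch_std < 1e-12] = 1.0
    label_mean = float(train.labels.mean())
    label_std = float(train.labels.std()) or 1.0

    x = _normalize_patches(train.patches, patch_mean, patch_std).reshape(M, S, H * W)
    xv = _normalize_patches(val.patches, patch_mean, patch_std)
    y = (train.labels - label_mean) / label_std

    ss = np.random.SeedSequence(seed)
    rngs = [np.random.default_rng(c) for c in ss.spawn(M + 1)]
    widths = [H * W, cfg.c * H * W, cfg.c * H * W, cfg.d_prime]
    encoders = [
        EncoderParams(init_mlp(widths, rngs[m]), modality=train.modality_names[m])
        for m in range(M)
    ]
    Z = SelfExpressiveMatrix.initialize(S, rngs[M], cfg.z_init_scale)
    head_w = np.zeros(r)
    head_b = np.array(0.0)

    params = [W_ for enc in encoders for layer in enc.layers for W_ in layer]
    params += [Z.theta, head_w, head_b]
    opt = Adam(params)

    rows = []
    state = None
    for epoch in range(cfg.epochs):
        lr = cfg.lr * cfg.decay**epoch

        embeddings, caches = [], []
        for m in range(M):
            f, cache = mlp_forward(encoders[m].layers, x[m])
            if not np.all(np.isfinite(f)):
                raise FloatingPointError(
                    f"non-finite embedding for modality "
                    f"'{train.modality_names[m]}' (loss component l_s)"
                )
            embeddings.append(f)
            caches.append(cache)
        Zm = Z.matrix
        outputs = [Zm @ f for f in embeddings]
        state = _full_dcca(outputs, cfg.r_m, r)
        D, s = state.common, state.singular_values
        y_hat = D @ head_w + float(head_b)

        resids = [Zm @ f - f for f in embeddings]
        l_s = lam1 * float(np.sum(Zm * Zm)) + lam2 * sum(
            float(np.sum(rr * rr)) for rr in resids
        )
        l_d = -float(np.sum(s))
        mse = float(np.mean((y - y_hat) ** 2))
        total = l_s + lam3 * l_d + lam4 * mse
        for name, value in (("l_s", l_s), ("l_d", l_d), ("mse", mse)):
            if not np.isfinite(value):
                raise FloatingPointError(f"teacher loss component '{name}' became non-finite")

        # gradients (D held constant within the step)
        C = D @ D.T
        gZ = 2.0 * lam1 * Zm
        g_head_w = D.T @ (2.0 * lam4 * (y_hat - y) / S)
        g_head_b = np.array(float(np.sum(2.0 * lam4 * (y_hat - y) / S)))
        enc_grads = []
        for m in range(M):
            gO = -lam3 * _dcca_output_grad(outputs[m], state.ridges[m], C)
            gZ += gO @ embeddings[m].T
            gf = Zm.T @ gO
            gZ += 2.0 * lam2 * resids[m] @ embeddings[m].T
            gf += 2.0 * lam2 * (Zm.T @ resids[m] - resids[m])
            layer_grads, _ = mlp_backward(encoders[m].layers, caches[m], gf)
            enc_grads.extend(g for pair in layer_grads for g in pair)
        grads = enc_grads + [Z.mask_gradient(gZ), g_head_w, g_head_b]
        opt.step(grads, lr)

        # validation monitoring with post-step parameters
        emb_post = [mlp_forward(encoders[m].layers, x[m])[0] for m in range(M)]
        Zp = Z.matrix
        state_post = _full_dcca([Zp @ f for f in emb_post], cfg.r_m, r)
        R_list = ridge_maps(state_post)
        yv_hat_n = out_of_sample_predict(encoders, R_list, head_w, float(head_b), xv)
        yv_hat = yv_hat_n * label_std + label_mean
        val_mse = float(np.mean((val.labels - yv_hat) ** 2))
        rows.append({"epoch": epoch, "l_s": l_s, "l_d": l_d, "mse": mse,
                     "l_mtke": total, "val_mse": val_mse})

    # final frozen state from the trained encoders on the full training set
    embeddings = [mlp_forward(encoders[m].layers, x[m])[0] for m in range(M)]
    Zfinal = Z.matrix.copy()
    state = _full_dcca([Zfinal @ f for f in embeddings], cfg.r_m, r)

    art = TeacherArtifacts(
        encoders=encoders,
        Z=Zfinal,
        D=state.common.copy(),
        singular_values=state.singular_values.copy(),
        ridge_maps=ridge_maps(state),
        head_w=head_w.copy(),
        head_b=float(head_b),
        patch_mean=patch_mean,
        patch_std=patch_std,
        label_mean=label_mean,
        label_std=label_std,
        config=cfg,
        seed=int(seed),
        log=pd.DataFrame(rows),
        train_fingerprint=fingerprint(train.patches, train.labels),
        modality_names=tuple(train.modality_names),
    )
    art.freeze()
    return art
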