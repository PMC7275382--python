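"""Neural matrix-factorization scoring kernels and their training loop.

Four kernels score an (RBP i, circRNA j) cell of the interaction matrix:

``mfnn``
    Two feed-forward "towers" map the raw interaction profiles — row
    ``y_i*`` (length N_c) and column ``y_*j`` (length N_r) — through ReLU
    layers into d-dimensional latent factors p_ri and q_cj; the score is
    the cosine of the two factors, clamped into [eps, 1-eps] before the
    binary cross-entropy loss (a negative cosine is collapsed to eps).

``gmf`` / ``mlp`` / ``neumf``
    The neural-collaborative-filtering family: per-ID embedding tables
    (one-hot inputs) combined by an element-wise product with a linear
    output (GMF), a multi-layer perceptron on the concatenated embeddings
    (MLP), or the concatenation of both branches' last hidden layers
    (NeuMF), each squashed by a sigmoid.

All forward/backward passes are explicit numpy; optimization is mini-batch
Adam.  Every source of randomness flows from a single integer seed, so a
fit is bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
import json

import numpy as np

from .data import InteractionMatrix

__all__ = [
    "KernelModel",
    "TrainConfig",
    "PairScores",
    "TrainingDivergedError",
    "KERNEL_KINDS",
    "init_model",
    "latent_rbp",
    "latent_circ",
    "score_pair",
    "score_pairs",
    "bce_loss",
    "loss_and_grads",
    "train",
    "save_checkpoint",
    "load_checkpoint",
]

KERNEL_KINDS = ("mfnn", "gmf", "mlp", "neumf")

_NORM_EPS = 1e-12  # guards the cosine denominator when ReLU zeroes a factor


class TrainingDivergedError(RuntimeError):
    pass


@dataclass
class TrainConfig:
    """Hyper-parameters of the mini-batch Adam training loop.

    Defaults follow the study configuration: batch size 256, learning rate
    1e-4, Adam, scores clamped at 1e-6.  ``epochs`` is an upper cap; early
    stopping monitors the 90/10 validation split with the given patience.
    """

    epochs: int = 100
    batch_size: int = 256
    learning_rate: float = 1e-4
    patience: int = 10
    init_std: float = 0.01
    seed: int = 0
    clamp_eps: float = 1e-6
    val_fraction: float = 0.1
    adam_beta1: float = 0.9
    adam_beta2: float = 0.999
    adam_eps: float = 1e-8

    def __post_init__(self) -> None:
        if self.epochs < 1 or self.batch_size < 1:
            raise ValueError("epochs and batch_size must be >= 1")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if not (0 < self.clamp_eps < 0.5):
            raise ValueError("clamp_eps must lie in (0, 0.5)")


@dataclass
class PairScores:
    """Scores for an explicit list of (i, j) cells, optionally labeled."""

    pairs: list[tuple[int, int]]
    scores: np.ndarray
    labels: np.ndarray | None = None
    raw: np.ndarray | None = None  # pre-clamp score (e.g. raw cosine)

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=np.float64)
        if self.labels is not None:
            self.labels = np.asarray(self.labels, dtype=np.float64)
            if len(self.labels) != len(self.scores):
                raise ValueError("labels/scores length mismatch")
        if len(self.pairs) != len(self.scores):
            raise ValueError("pairs/scores length mismatch")

    def __len__(self) -> int:
        return len(self.pairs)


@dataclass
class KernelModel:
    """One scoring kernel: architecture descriptor plus parameter arrays.

    ``layer_sizes`` semantics differ by kind.  For ``mfnn`` it is the tower
    layer widths ending in the latent dimension d (one entry = the default
    1-layer network).  For the embedding kernels the first entry is the
    embedding dimension d and any further entries are MLP hidden widths.
    """

    kind: str
    N_r: int
    N_c: int
    layer_sizes: tuple[int, ...]
    seed: int
    params: dict[str, np.ndarray]
    clamp_eps: float = 1e-6

    @property
    def latent_dim(self) -> int:
        return self.layer_sizes[-1] if self.kind == "mfnn" else self.layer_sizes[0]


def _mlp_hidden(layer_sizes: tuple[int, ...]) -> tuple[int, ...]:
    return tuple(layer_sizes[1:])


def init_model(
    kind: str,
    N_r: int,
    N_c: int,
    layer_sizes: tuple[int, ...] | list[int] = (64,),
    seed: int = 0,
    init_std: float = 0.01,
    clamp_eps: float = 1e-6,
) -> KernelModel:
    """Initialize all parameters i.i.d. Normal(0, init_std^2) under ``seed``."""
    kind = kind.lower()
    if kind not in KERNEL_KINDS:
        raise ValueError(f"unknown kernel kind {kind!r}; expected one of {KERNEL_KINDS}")
    layer_sizes = tuple(int(s) for s in layer_sizes)
    if not layer_sizes or any(s <= 0 for s in layer_sizes):
        raise ValueError("layer_sizes must be non-empty positive integers")
    rng = np.random.default_rng(seed)

    def g(*shape: int) -> np.ndarray:
        return rng.normal(0.0, init_std, size=shape)

    params: dict[str, np.ndarray] = {}
    if kind == "mfnn":
        widths_r = (N_c,) + layer_sizes
        widths_c = (N_r,) + layer_sizes
        for l in range(len(layer_sizes)):
            params[f"Wr{l}"] = g(widths_r[l], widths_r[l + 1])
            params[f"br{l}"] = g(widths_r[l + 1])
        for l in range(len(layer_sizes)):
            params[f"Wc{l}"] = g(widths_c[l], widths_c[l + 1])
            params[f"bc{l}"] = g(widths_c[l + 1])
    elif kind == "gmf":
        d = layer_sizes[0]
        params["P"] = g(N_r, d)
        params["Q"] = g(N_c, d)
        params["h"] = g(d)
        params["out_b"] = g(1)
    elif kind == "mlp":
        d = layer_sizes[0]
        params["P"] = g(N_r, d)
        params["Q"] = g(N_c, d)
        widths = (2 * d,) + _mlp_hidden(layer_sizes)
        for l in range(len(widths) - 1):
            params[f"W{l}"] = g(widths[l], widths[l + 1])
            params[f"b{l}"] = g(widths[l + 1])
        params["h"] = g(widths[-1])
        params["out_b"] = g(1)
    else:  # neumf: independent GMF and MLP halves trained jointly
        d = layer_sizes[0]
        params["Pg"] = g(N_r, d)
        params["Qg"] = g(N_c, d)
        params["Pm"] = g(N_r, d)
        params["Qm"] = g(N_c, d)
        widths = (2 * d,) + _mlp_hidden(layer_sizes)
        for l in range(len(widths) - 1):
            params[f"W{l}"] = g(widths[l], widths[l + 1])
            params[f"b{l}"] = g(widths[l + 1])
        params["h"] = g(d + widths[-1])
        params["out_b"] = g(1)
    return KernelModel(
        kind=kind,
        N_r=N_r,
        N_c=N_c,
        layer_sizes=layer_sizes,
        seed=seed,
        params=params,
        clamp_eps=clamp_eps,
    )


# ---------------------------------------------------------------------------
# forward passes


def _tower_forward(
    X: np.ndarray, params: dict[str, np.ndarray], prefix: str, n_layers: int
) -> tuple[np.ndarray, list[tuple[np.ndarray, np.ndarray]]]:
    """ReLU tower: h_{l+1} = relu(h_l W_l + b_l).  Returns output + cache."""
    h = X
    cache = []
    for l in range(n_layers):
        z = h @ params[f"W{prefix}{l}"] + params[f"b{prefix}{l}"]
        a = np.maximum(z, 0.0)
        cache.append((h, z))
        h = a
    return h, cache


def latent_rbp(model: KernelModel, row_profile: np.ndarray) -> np.ndarray:
    """Latent factor p_ri of an RBP from its interaction-profile row y_i*."""
    if model.kind != "mfnn":
        raise ValueError("latent_rbp is defined for the mfnn kernel only")
    x = np.atleast_2d(np.asarray(row_profile, dtype=np.float64))
    if x.shape[1] != model.N_c:
        raise ValueError(f"row profile length {x.shape[1]} != N_c={model.N_c}")
    out, _ = _tower_forward(x, model.params, "r", len(model.layer_sizes))
    return out[0]


def latent_circ(model: KernelModel, col_profile: np.ndarray) -> np.ndarray:
    """Latent factor q_cj of a circRNA from its profile column y_*j."""
    if model.kind != "mfnn":
        raise ValueError("latent_circ is defined for the mfnn kernel only")
    x = np.atleast_2d(np.asarray(col_profile, dtype=np.float64))
    if x.shape[1] != model.N_r:
        raise ValueError(f"column profile length {x.shape[1]} != N_r={model.N_r}")
    out, _ = _tower_forward(x, model.params, "c", len(model.layer_sizes))
    return out[0]


def _cosine_rows(P: np.ndarray, Q: np.ndarray) -> tuple[np.ndarray, dict]:
    """Row-wise cosine with an epsilon-guarded denominator."""
    dot = np.sum(P * Q, axis=1)
    np_ = np.sqrt(np.sum(P * P, axis=1))
    nq_ = np.sqrt(np.sum(Q * Q, axis=1))
    denom = (np_ + _NORM_EPS) * (nq_ + _NORM_EPS)
    cos = dot / denom
    return cos, {"dot": dot, "np": np_, "nq": nq_, "denom": denom}


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def _forward(
    model: KernelModel,
    bi: np.ndarray,
    bj: np.ndarray,
    Yin: np.ndarray | None,
) -> tuple[np.ndarray, dict]:
    """Raw (pre-clamp) scores for a batch of cells, with backprop cache."""
    p = model.params
    n_tower = len(model.layer_sizes)
    if model.kind == "mfnn":
        if Yin is None:
            raise ValueError("mfnn scoring requires the interaction matrix")
        Xr = Yin[bi, :]
        Xc = Yin[:, bj].T
        pr, cr = _tower_forward(Xr, p, "r", n_tower)
        qc, cc = _tower_forward(Xc, p, "c", n_tower)
        cos, ccache = _cosine_rows(pr, qc)
        return cos, {"pr": pr, "qc": qc, "cr": cr, "cc": cc, "cos": ccache}
    if model.kind == "gmf":
        pe, qe = p["P"][bi], p["Q"][bj]
        prod = pe * qe
        z = prod @ p["h"] + p["out_b"][0]
        return _sigmoid(z), {"pe": pe, "qe": qe, "prod": prod, "z": z}
    if model.kind == "mlp":
        pe, qe = p["P"][bi], p["Q"][bj]
        X = np.concatenate([pe, qe], axis=1)
        n_hidden = len(_mlp_hidden(model.layer_sizes))
        h, cache = _tower_forward(X, p, "", n_hidden)
        z = h @ p["h"] + p["out_b"][0]
        return _sigmoid(z), {"pe": pe, "qe": qe, "X": X, "hid": cache, "h_out": h, "z": z}
    # neumf
    pg, qg = p["Pg"][bi], p["Qg"][bj]
    pm, qm = p["Pm"][bi], p["Qm"][bj]
    prod = pg * qg
    X = np.concatenate([pm, qm], axis=1)
    n_hidden = len(_mlp_hidden(model.layer_sizes))
    h, cache = _tower_forward(X, p, "", n_hidden)
    fused = np.concatenate([prod, h], axis=1)
    z = fused @ p["h"] + p["out_b"][0]
    return _sigmoid(z), {
        "pg": pg, "qg": qg, "pm": pm, "qm": qm, "prod": prod,
        "X": X, "hid": cache, "h_out": h, "fused": fused, "z": z,
    }


def _clamp(raw: np.ndarray, eps: float) -> np.ndarray:
    return np.clip(raw, eps, 1.0 - eps)


def score_pair(
    model: KernelModel,
    i: int,
    j: int,
    Y: InteractionMatrix | np.ndarray,
    clamp_eps: float | None = None,
) -> float:
    """Clamped probability score of one (RBP i, circRNA j) cell."""
    return float(
        score_pairs(model, [(i, j)], Y, clamp_eps=clamp_eps).scores[0]
    )


def score_pairs(
    model: KernelModel,
    pairs: list[tuple[int, int]] | np.ndarray,
    Y: InteractionMatrix | np.ndarray | None,
    clamp_eps: float | None = None,
    labels: np.ndarray | None = None,
) -> PairScores:
    """Vectorized scoring of a list of cells; keeps the raw pre-clamp score."""
    eps = model.clamp_eps if clamp_eps is None else clamp_eps
    pair_list = [tuple(int(v) for v in ij) for ij in pairs]
    if not pair_list:
        return PairScores(pairs=[], scores=np.empty(0), labels=None, raw=np.empty(0))
    Yin = Y.Y if isinstance(Y, InteractionMatrix) else Y
    bi = np.array([ij[0] for ij in pair_list])
    bj = np.array([ij[1] for ij in pair_list])
    raw, _ = _forward(model, bi, bj, Yin)
    return PairScores(
        pairs=pair_list, scores=_clamp(raw, eps), labels=labels, raw=raw
    )


# ---------------------------------------------------------------------------
# loss and gradients


def bce_loss(scores: PairScores) -> float:
    """Summed binary cross-entropy  L = -sum[ y log f + (1-y) log(1-f) ].

    Scores must already be clamped into the open interval (0, 1); an exact
    0 or 1 is a contract violation, not a value to silently patch.
    """
    if scores.labels is None:
        raise ValueError("bce_loss requires labels")
    f = scores.scores
    if np.any(f <= 0.0) or np.any(f >= 1.0):
        raise ValueError("scores must be clamped strictly inside (0, 1)")
    y = scores.labels
    return float(-np.sum(y * np.log(f) + (1.0 - y) * np.log(1.0 - f)))


def _tower_backward(
    dh: np.ndarray,
    cache: list[tuple[np.ndarray, np.ndarray]],
    params: dict[str, np.ndarray],
    prefix: str,
    grads: dict[str, np.ndarray],
) -> np.ndarray:
    """Backprop through a ReLU tower; accumulates into ``grads``."""
    for l in range(len(cache) - 1, -1, -1):
        h_in, z = cache[l]
        dz = dh * (z > 0.0)
        grads[f"W{prefix}{l}"] += h_in.T @ dz
        grads[f"b{prefix}{l}"] += dz.sum(axis=0)
        dh = dz @ params[f"W{prefix}{l}"].T
    return dh


def loss_and_grads(
    model: KernelModel,
    bi: np.ndarray,
    bj: np.ndarray,
    y: np.ndarray,
    Yin: np.ndarray | None,
) -> tuple[float, dict[str, np.ndarray]]:
    """Mean clamped-BCE over the batch and its exact parameter gradients.

    The clamp is part of the objective: where the raw score is clipped the
    gradient is identically zero (matching the subgradient of ``np.clip``).
    """
    p = model.params
    eps = model.clamp_eps
    B = len(bi)
    raw, cache = _forward(model, bi, bj, Yin)
    f = _clamp(raw, eps)
    loss = float(-np.mean(y * np.log(f) + (1.0 - y) * np.log(1.0 - f)))
    if not np.isfinite(loss):
        raise TrainingDivergedError("non-finite loss")
    # d(mean BCE)/d raw, zero where the clamp is active
    active = (raw > eps) & (raw < 1.0 - eps)
    df = (f - y) / (f * (1.0 - f)) / B
    draw = np.where(active, df, 0.0)

    grads = {k: np.zeros_like(v) for k, v in p.items()}
    n_tower = len(model.layer_sizes)

    if model.kind == "mfnn":
        pr, qc = cache["pr"], cache["qc"]
        cc = cache["cos"]
        denom = cc["denom"][:, None]
        cos = raw[:, None]
        np_ = np.maximum(cc["np"], _NORM_EPS)[:, None]
        nq_ = np.maximum(cc["nq"], _NORM_EPS)[:, None]
        # d cos/d p = q/denom - cos * p / (|p| (|p|+eps)); symmetric in q
        dp = draw[:, None] * (qc / denom - cos * pr / (np_ * (cc["np"][:, None] + _NORM_EPS)))
        dq = draw[:, None] * (pr / denom - cos * qc / (nq_ * (cc["nq"][:, None] + _NORM_EPS)))
        _tower_backward(dp, cache["cr"], p, "r", grads)
        _tower_backward(dq, cache["cc"], p, "c", grads)
        return loss, grads

    # sigmoid-output kernels: d sigma/dz = s(1-s)
    s = raw
    dz = draw * s * (1.0 - s)
    if model.kind == "gmf":
        prod = cache["prod"]
        grads["h"] += prod.T @ dz
        grads["out_b"][0] += dz.sum()
        dprod = dz[:, None] * p["h"][None, :]
        np.add.at(grads["P"], bi, dprod * cache["qe"])
        np.add.at(grads["Q"], bj, dprod * cache["pe"])
        return loss, grads
    if model.kind == "mlp":
        grads["h"] += cache["h_out"].T @ dz
        grads["out_b"][0] += dz.sum()
        dh = dz[:, None] * p["h"][None, :]
        dX = _tower_backward(dh, cache["hid"], p, "", grads)
        d = model.layer_sizes[0]
        np.add.at(grads["P"], bi, dX[:, :d])
        np.add.at(grads["Q"], bj, dX[:, d:])
        return loss, grads
    # neumf
    d = model.layer_sizes[0]
    grads["h"] += cache["fused"].T @ dz
    grads["out_b"][0] += dz.sum()
    dfused = dz[:, None] * p["h"][None, :]
    dprod, dh = dfused[:, :d], dfused[:, d:]
    np.add.at(grads["Pg"], bi, dprod * cache["qg"])
    np.add.at(grads["Qg"], bj, dprod * cache["pg"])
    dX = _tower_backward(dh, cache["hid"], p, "", grads)
    np.add.at(grads["Pm"], bi, dX[:, :d])
    np.add.at(grads["Qm"], bj, dX[:, d:])
    return loss, grads


class _Adam:
    def __init__(self, params: dict[str, np.ndarray], cfg: TrainConfig):
        self.lr = cfg.learning_rate
        self.b1, self.b2, self.eps = cfg.adam_beta1, cfg.adam_beta2, cfg.adam_eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        b1t = 1.0 - self.b1**self.t
        b2t = 1.0 - self.b2**self.t
        for k, g in grads.items():
            self.m[k] = self.b1 * self.m[k] + (1.0 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1.0 - self.b2) * g * g
            mhat = self.m[k] / b1t
            vhat = self.v[k] / b2t
            params[k] -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def _stratified_split(
    y: np.ndarray, frac_val: float, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Indices of a label-stratified (train, validation) split."""
    tr, va = [], []
    for label in np.unique(y):
        idx = np.flatnonzero(y == label)
        idx = rng.permutation(idx)
        n_val = int(round(frac_val * len(idx)))
        va.append(idx[:n_val])
        tr.append(idx[n_val:])
    return np.sort(np.concatenate(tr)), np.sort(np.concatenate(va))


def train(
    model: KernelModel,
    train_pairs: PairScores,
    Y: InteractionMatrix | np.ndarray | None,
    cfg: TrainConfig,
    validation_pairs: PairScores | None = None,
) -> tuple[KernelModel, list[tuple[int, float, float]]]:
    """Fit a kernel by mini-batch Adam on the clamped-BCE objective.

    If no explicit validation set is given, a stratified ``val_fraction``
    split (default 90/10) is carved out of ``train_pairs``.  Training stops
    at the epoch cap or when validation loss has not improved for
    ``cfg.patience`` epochs; the best-validation parameters are restored.
    Returns the fitted model and a per-epoch (epoch, train, val) loss trace.
    """
    if train_pairs.labels is None:
        raise ValueError("train requires labeled pairs")
    Yin = Y.Y if isinstance(Y, InteractionMatrix) else Y
    rng = np.random.default_rng(cfg.seed)
    bi = np.array([ij[0] for ij in train_pairs.pairs])
    bj = np.array([ij[1] for ij in train_pairs.pairs])
    y = np.asarray(train_pairs.labels, dtype=np.float64)

    if validation_pairs is None and cfg.val_fraction > 0 and len(y) >= 10:
        tr_idx, va_idx = _stratified_split(y, cfg.val_fraction, rng)
        vi, vj, vy = bi[va_idx], bj[va_idx], y[va_idx]
        bi, bj, y = bi[tr_idx], bj[tr_idx], y[tr_idx]
    elif validation_pairs is not None:
        vi = np.array([ij[0] for ij in validation_pairs.pairs])
        vj = np.array([ij[1] for ij in validation_pairs.pairs])
        vy = np.asarray(validation_pairs.labels, dtype=np.float64)
    else:
        vi = vj = vy = None

    opt = _Adam(model.params, cfg)
    trace: list[tuple[int, float, float]] = []
    best_val = np.inf
    best_params = None
    bad_epochs = 0
    n = len(y)
    for epoch in range(1, cfg.epochs + 1):
        order = rng.permutation(n)
        epoch_loss = 0.0
        for start in range(0, n, cfg.batch_size):
            sel = order[start : start + cfg.batch_size]
            try:
                loss, grads = loss_and_grads(model, bi[sel], bj[sel], y[sel], Yin)
            except TrainingDivergedError as exc:
                raise TrainingDivergedError(
                    f"diverged at epoch {epoch}, batch {start // cfg.batch_size}"
                ) from exc
            opt.step(model.params, grads)
            epoch_loss += loss * len(sel)
        epoch_loss /= n
        if vy is not None and len(vy) > 0:
            vraw, _ = _forward(model, vi, vj, Yin)
            vf = _clamp(vraw, model.clamp_eps)
            val_loss = float(-np.mean(vy * np.log(vf) + (1 - vy) * np.log(1 - vf)))
        else:
            val_loss = epoch_loss
        trace.append((epoch, epoch_loss, val_loss))
        if val_loss < best_val - 1e-12:
            best_val = val_loss
            best_params = {k: v.copy() for k, v in model.params.items()}
            bad_epochs = 0
        else:
            bad_epochs += 1
            if bad_epochs >= cfg.patience:
                break
    if best_params is not None:
        model.params = best_params
    return model, trace


# ---------------------------------------------------------------------------
# checkpoints


def save_checkpoint(model: KernelModel, path: str | Path, cfg: TrainConfig | None = None) -> None:
    """Write weights (.npz) plus a JSON metadata sidecar."""
    path = Path(path)
    np.savez(path.with_suffix(".npz"), **model.params)
    meta = {
        "kind": model.kind,
        "N_r": model.N_r,
        "N_c": model.N_c,
        "layer_sizes": list(model.layer_sizes),
        "seed": model.seed,
        "clamp_eps": model.clamp_eps,
        "train_config": vars(cfg) if cfg is not None else None,
    }
    path.with_suffix(".json").write_text(json.dumps(meta, indent=2))


def load_checkpoint(path: str | Path) -> KernelModel:
    path = Path(path)
    meta = json.loads(path.with_suffix(".json").read_text())
    with np.load(path.with_suffix(".npz")) as npz:
        params = {k: npz[k].copy() for k in npz.files}
    return KernelModel(
        kind=meta["kind"],
        N_r=meta["N_r"],
        N_c=meta["N_c"],
        layer_sizes=tuple(meta["layer_sizes"]),
        seed=meta["seed"],
        params=params,
        clamp_eps=meta["clamp_eps"],
    )
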