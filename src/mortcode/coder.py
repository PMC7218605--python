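"""The probabilistic certificate coder: P(UCD | chain grid, age, year, gender).

Architecture (in order): one shared linear projection of the one-hot code
variables — realized, with identical mathematics, as an embedding lookup
into the projection matrix — at every grid position; linear projections of
the age, year and gender factors added to every non-padding cell of the
projected grid; a stack of ReLU convolution blocks; global pooling; and a
softmax regression over the V observed codes.  Parameters are fit by Adam
on mini-batch cross-entropy, with the best validation-accuracy epoch
retained.

The padding embedding is frozen at the zero vector and demographic
projections touch only non-padding cells, so widening the grid with extra
padding columns leaves every prediction unchanged (the model is
translation invariant in the grid width).
"""

from __future__ import annotations

import copy
import json
from dataclasses import dataclass, field, asdict

import numpy as np

from . import nn
from .certificate import Certificate, N_AGE_BINS, encode_grid
from .vocabulary import Vocabulary

__all__ = [
    "ModelConfig",
    "OptParams",
    "TrainedCoder",
    "build_model",
    "predict_proba",
    "predict_proba_batch",
    "predict_topk",
    "train",
    "save_coder",
    "load_coder",
]


@dataclass(frozen=True)
class ModelConfig:
    """Architecture hyper-parameters.

    ``conv_spec`` lists (kernel_height, kernel_width, channels) blocks.
    Defaults are sized for single-CPU training on a few-hundred-code
    vocabulary; ``embed_dim`` and channel counts scale up for larger
    corpora.
    """

    V: int
    embed_dim: int = 32
    conv_spec: tuple[tuple[int, int, int], ...] = ((3, 3, 64), (3, 3, 128))
    pooling: str = "global_max"
    use_gender: bool = True
    L: int = 6
    W: int = 20
    Y: int = 16
    seed: int = 0

    def __post_init__(self) -> None:
        if self.embed_dim < 1:
            raise ValueError("embed_dim must be >= 1")
        if not self.conv_spec:
            raise ValueError("at least one convolution block is required")
        for kh, kw, ch in self.conv_spec:
            if kh > self.L or kw > self.W:
                raise ValueError(f"kernel ({kh},{kw}) exceeds grid ({self.L},{self.W})")
            if ch < 1:
                raise ValueError("channel counts must be >= 1")
        if self.pooling not in ("global_max", "global_mean"):
            raise ValueError("pooling must be 'global_max' or 'global_mean'")
        if self.V < 2 or self.Y < 1:
            raise ValueError("V >= 2 and Y >= 1 required")


@dataclass(frozen=True)
class OptParams:
    lr: float = 1e-3
    batch_size: int = 256
    epochs: int = 8
    seed: int = 0


@dataclass
class TrainedCoder:
    """Architecture config plus the parameter collection Theta."""

    config: ModelConfig
    params: dict[str, np.ndarray]
    vocab_fingerprint: str
    history: dict = field(default_factory=dict)


def build_model(config: ModelConfig, vocab: Vocabulary) -> TrainedCoder:
    """Initialize an untrained coder (deterministic in ``config.seed``).

    The softmax layer starts at zero, so the untrained output
    distribution is exactly uniform.
    """
    if config.V != vocab.size:
        raise ValueError(f"config.V={config.V} does not match vocabulary size {vocab.size}")
    rng = np.random.default_rng(config.seed)
    D = config.embed_dim
    params: dict[str, np.ndarray] = {}
    params["code_embed"] = rng.normal(0.0, 0.1, size=(vocab.size + 2, D)).astype(nn.DTYPE)
    params["code_embed"][vocab.pad_index] = 0.0  # frozen at zero
    params["age_embed"] = rng.normal(0.0, 0.1, size=(N_AGE_BINS, D)).astype(nn.DTYPE)
    params["year_embed"] = rng.normal(0.0, 0.1, size=(config.Y, D)).astype(nn.DTYPE)
    if config.use_gender:
        params["gender_embed"] = rng.normal(0.0, 0.1, size=(2, D)).astype(nn.DTYPE)
    cin = D
    for i, (kh, kw, ch) in enumerate(config.conv_spec):
        std = np.sqrt(2.0 / (kh * kw * cin))
        params[f"conv{i}_w"] = rng.normal(0.0, std, size=(kh, kw, cin, ch)).astype(nn.DTYPE)
        params[f"conv{i}_b"] = np.zeros(ch, dtype=nn.DTYPE)
        cin = ch
    params["out_w"] = np.zeros((cin, config.V), dtype=nn.DTYPE)
    params["out_b"] = np.zeros(config.V, dtype=nn.DTYPE)
    return TrainedCoder(config=config, params=params, vocab_fingerprint=vocab.fingerprint)


def encode_batch(
    certs: list[Certificate],
    vocab: Vocabulary,
    L: int = 6,
    W: int = 20,
    fixed_year_index: int | None = None,
):
    """Stack certificates into (grids, age, year, gender) index arrays."""
    B = len(certs)
    grids = np.empty((B, L, W), dtype=np.int64)
    age = np.empty(B, dtype=np.int64)
    year = np.empty(B, dtype=np.int64)
    gender = np.empty(B, dtype=np.int64)
    for i, c in enumerate(certs):
        grids[i] = encode_grid(c, vocab, L, W)
        d = c.demographics
        age[i] = d.age_bin
        year[i] = d.year_index if fixed_year_index is None else fixed_year_index
        gender[i] = d.gender
    return grids, age, year, gender


def _forward(
    coder: TrainedCoder,
    grids: np.ndarray,
    age: np.ndarray,
    year: np.ndarray,
    gender: np.ndarray,
    pad_index: int,
    with_cache: bool = False,
):
    cfg = coder.config
    p = coder.params
    x = p["code_embed"][grids]
    nonpad = (grids != pad_index)[..., None]
    demo = p["age_embed"][age] + p["year_embed"][year]
    if cfg.use_gender:
        demo = demo + p["gender_embed"][gender]
    x = x + demo[:, None, None, :] * nonpad
    caches = []
    for i in range(len(cfg.conv_spec)):
        x, ccache = nn.conv2d_forward(x, p[f"conv{i}_w"], p[f"conv{i}_b"])
        x, rmask = nn.relu_forward(x)
        caches.append((ccache, rmask))
    if cfg.pooling == "global_max":
        pooled, pcache = nn.global_max_pool_forward(x)
    else:
        pooled, pcache = nn.global_mean_pool_forward(x)
    logits = pooled @ p["out_w"] + p["out_b"]
    if not with_cache:
        return logits, None
    return logits, (nonpad, caches, pooled, pcache)


def _backward(coder, dlogits, grids, age, year, gender, cache):
    cfg = coder.config
    p = coder.params
    nonpad, caches, pooled, pcache = cache
    grads: dict[str, np.ndarray] = {}
    grads["out_w"] = pooled.T @ dlogits
    grads["out_b"] = dlogits.sum(axis=0)
    dpooled = dlogits @ p["out_w"].T
    if cfg.pooling == "global_max":
        dx = nn.global_max_pool_backward(dpooled, pcache)
    else:
        dx = nn.global_mean_pool_backward(dpooled, pcache)
    for i in reversed(range(len(cfg.conv_spec))):
        ccache, rmask = caches[i]
        dx = nn.relu_backward(dx, rmask)
        dx, dw, db = nn.conv2d_backward(dx, p[f"conv{i}_w"], ccache)
        grads[f"conv{i}_w"] = dw
        grads[f"conv{i}_b"] = db
    D = cfg.embed_dim
    dE = np.zeros_like(p["code_embed"])
    np.add.at(dE, grids.ravel(), dx.reshape(-1, D))
    dE[-2] = 0.0  # pad row stays frozen
    grads["code_embed"] = dE
    ddemo = (dx * nonpad).sum(axis=(1, 2))
    dA = np.zeros_like(p["age_embed"])
    np.add.at(dA, age, ddemo)
    grads["age_embed"] = dA
    dY = np.zeros_like(p["year_embed"])
    np.add.at(dY, year, ddemo)
    grads["year_embed"] = dY
    if cfg.use_gender:
        dG = np.zeros_like(p["gender_embed"])
        np.add.at(dG, gender, ddemo)
        grads["gender_embed"] = dG
    return grads


def _check_fingerprint(coder: TrainedCoder, vocab: Vocabulary) -> None:
    if coder.vocab_fingerprint != vocab.fingerprint:
        raise ValueError(
            "vocabulary fingerprint mismatch: this coder was built against a "
            "different vocabulary"
        )


def predict_proba_batch(
    coder: TrainedCoder,
    certs: list[Certificate],
    vocab: Vocabulary,
    grid_width: int | None = None,
    fixed_year_index: int | None = None,
    batch_size: int = 512,
) -> np.ndarray:
    """Probability distributions over the vocabulary, one row per certificate."""
    _check_fingerprint(coder, vocab)
    W = grid_width if grid_width is not None else coder.config.W
    out = np.empty((len(certs), coder.config.V), dtype=np.float64)
    for lo in range(0, len(certs), batch_size):
        chunk = certs[lo:lo + batch_size]
        grids, age, year, gender = encode_batch(
            chunk, vocab, coder.config.L, W, fixed_year_index
        )
        logits, _ = _forward(coder, grids, age, year, gender, vocab.pad_index)
        out[lo:lo + len(chunk)] = nn.softmax(logits.astype(np.float64))
    return out


def predict_proba(
    coder: TrainedCoder,
    cert: Certificate,
    vocab: Vocabulary,
    grid_width: int | None = None,
) -> np.ndarray:
    return predict_proba_batch(coder, [cert], vocab, grid_width)[0]


def predict_topk(
    coder: TrainedCoder,
    cert: Certificate,
    vocab: Vocabulary,
    k: int,
) -> list[tuple[str, float]]:
    """The ``k`` most probable codes, ties broken by lowest vocabulary index."""
    if not 1 <= k <= coder.config.V:
        raise ValueError(f"k={k} outside 1..{coder.config.V}")
    probs = predict_proba(coder, cert, vocab)
    order = np.lexsort((np.arange(len(probs)), -probs))[:k]
    return [(vocab.code_at(int(i)), float(probs[i])) for i in order]


def train(
    coder: TrainedCoder,
    train_certs: list[Certificate],
    val_certs: list[Certificate],
    vocab: Vocabulary,
    opt: OptParams | None = None,
) -> TrainedCoder:
    """Fit by Adam on mini-batch cross-entropy.

    Returns a new coder holding the parameters of the best
    validation-accuracy epoch, with per-epoch train loss and validation
    accuracy in ``history``.  Deterministic under ``opt.seed`` (single
    threaded).
    """
    opt = opt or OptParams()
    if not train_certs:
        raise ValueError("empty training set")
    _check_fingerprint(coder, vocab)
    cfg = coder.config

    def labels_of(certs):
        y = np.empty(len(certs), dtype=np.int64)
        for i, c in enumerate(certs):
            if c.gold_ucd is None:
                raise ValueError(f"certificate {c.id} has no gold UCD label")
            try:
                y[i] = vocab.index_of(c.gold_ucd, strict=True)
            except KeyError as exc:
                raise ValueError(
                    f"certificate {c.id}: label {c.gold_ucd!r} outside the vocabulary"
                ) from exc
        return y

    Xg, Xa, Xy, Xs = encode_batch(train_certs, vocab, cfg.L, cfg.W)
    ytr = labels_of(train_certs)
    if val_certs:
        Vg, Va, Vy, Vs = encode_batch(val_certs, vocab, cfg.L, cfg.W)
        yva = labels_of(val_certs)

    work = copy.deepcopy(coder)
    optimizer = nn.Adam(work.params, lr=opt.lr)
    rng = np.random.default_rng(opt.seed)
    n = len(train_certs)
    history: dict[str, list] = {"train_loss": [], "val_accuracy": []}
    best_acc, best_params, best_epoch = -1.0, copy.deepcopy(work.params), 0

    for epoch in range(opt.epochs):
        order = rng.permutation(n)
        losses = []
        for lo in range(0, n, opt.batch_size):
            idx = order[lo:lo + opt.batch_size]
            g, a, y, s = Xg[idx], Xa[idx], Xy[idx], Xs[idx]
            logits, cache = _forward(work, g, a, y, s, vocab.pad_index, with_cache=True)
            loss, dlogits = nn.cross_entropy_loss(logits, ytr[idx])
            grads = _backward(work, dlogits, g, a, y, s, cache)
            optimizer.step(work.params, grads)
            work.params["code_embed"][vocab.pad_index] = 0.0
            losses.append(loss)
        history["train_loss"].append(float(np.mean(losses)))
        if val_certs:
            acc = _eval_accuracy(work, Vg, Va, Vy, Vs, yva, vocab.pad_index)
        else:
            acc = float("nan")
        history["val_accuracy"].append(acc)
        if not val_certs or acc > best_acc:
            best_acc = acc if val_certs else 0.0
            best_params = copy.deepcopy(work.params)
            best_epoch = epoch
    history["best_epoch"] = best_epoch
    return TrainedCoder(
        config=cfg,
        params=best_params,
        vocab_fingerprint=coder.vocab_fingerprint,
        history=history,
    )


def _eval_accuracy(coder, g, a, y, s, labels, pad_index, batch_size=1024) -> float:
    correct = 0
    for lo in range(0, len(labels), batch_size):
        logits, _ = _forward(
            coder, g[lo:lo + batch_size], a[lo:lo + batch_size],
            y[lo:lo + batch_size], s[lo:lo + batch_size], pad_index,
        )
        correct += int((logits.argmax(axis=1) == labels[lo:lo + batch_size]).sum())
    return correct / len(labels)


def save_coder(coder: TrainedCoder, path) -> None:
    """Self-describing checkpoint: config + parameter arrays + vocabulary
    fingerprint (NumPy ``.npz`` archive)."""
    meta = {
        "config": asdict(coder.config),
        "vocab_fingerprint": coder.vocab_fingerprint,
        "history": coder.history,
        "param_names": sorted(coder.params),
    }
    np.savez(
        path,
        __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
        **coder.params,
    )


def load_coder(path, vocab: Vocabulary | None = None) -> TrainedCoder:
    """Load a checkpoint; if ``vocab`` is given, its fingerprint must match."""
    with np.load(path) as data:
        meta = json.loads(bytes(data["__meta__"]).decode())
        cfg_d = dict(meta["config"])
        cfg_d["conv_spec"] = tuple(tuple(b) for b in cfg_d["conv_spec"])
        config = ModelConfig(**cfg_d)
        params = {k: data[k].copy() for k in meta["param_names"]}
    coder = TrainedCoder(
        config=config,
        params=params,
        vocab_fingerprint=meta["vocab_fingerprint"],
        history=meta.get("history", {}),
    )
    if vocab is not None:
        _check_fingerprint(coder, vocab)
    return coder
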