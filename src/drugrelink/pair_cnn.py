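"""Convolutional classifier over drug-disease embedding pairs.

Each candidate pair (r_i, d_j) is represented as a 2 x d1 matrix stacking
the drug embedding row over the disease embedding row, zero-padded by one
ring so the convolution sees the boundary.  Three conv+max-pool stages with
filter counts n_conv : 2*n_conv : 3*n_conv feed a fully-connected stack
(1024 -> dropout -> 1024 -> dropout -> 512) and a two-unit softmax; the
association probability is the positive-class softmax output.

Everything is numpy with explicit backward passes (im2col convolution,
argmax-routed pooling, inverted dropout), so the gradients can be audited
against finite differences.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._optim import Adam
from .vgae import NodeEmbeddings

__all__ = [
    "PairTensor",
    "CNNConfig",
    "CNNParams",
    "CNNForwardTrace",
    "PairPrediction",
    "build_pair_tensor",
    "conv_forward",
    "max_pool",
    "cnn_forward",
    "cnn_loss",
    "train_classifier",
    "predict_pairs",
]

_EPS = 1e-12


@dataclass
class PairTensor:
    """Padded 2 x d1 stack of one drug row and one disease row."""

    drug_id: str
    disease_id: str
    values: np.ndarray  # (2 + 2*pad) x (d1 + 2*pad), content centered

    def content(self) -> np.ndarray:
        return self.values[1:-1, 1:-1]


@dataclass
class CNNConfig:
    """Geometry and training settings for the pair classifier.

    Filter counts per stage are n_conv, 2*n_conv, 3*n_conv.  Filter and
    pooling shapes are free parameters; the defaults make the first stage
    span both embedding rows (2 x 3 filters) and the later stages slide
    along the embedding axis only.
    """

    n_conv: int = 16
    filters: tuple[tuple[int, int], ...] = ((2, 3), (1, 3), (1, 3))
    pools: tuple[tuple[int, int], ...] = ((1, 2), (1, 2), (1, 2))
    fc_sizes: tuple[int, int, int] = (1024, 1024, 512)
    dropout: float = 0.1
    lr: float = 1e-3
    epochs: int = 30
    batch_size: int = 128

    def __post_init__(self) -> None:
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must be in [0, 1)")
        if self.batch_size < 1:
            raise ValueError("batch size must be >= 1")
        if len(self.filters) != 3 or len(self.pools) != 3:
            raise ValueError("expected exactly three conv+pool stages")


@dataclass
class CNNParams:
    """Weights for the three conv stages, three FC layers and the softmax head."""

    conv: list[tuple[np.ndarray, np.ndarray]]  # [(W (K,C,l,w), b (K,))]
    fc: list[tuple[np.ndarray, np.ndarray]]
    out: tuple[np.ndarray, np.ndarray]  # W (F, 2), b (2,)
    config: CNNConfig

    def __post_init__(self) -> None:
        k0 = self.conv[0][0].shape[0]
        counts = [w.shape[0] for w, _ in self.conv]
        if counts != [k0, 2 * k0, 3 * k0]:
            raise ValueError(f"filter counts must be 1:2:3, got {counts}")

    def flat(self) -> list[np.ndarray]:
        out: list[np.ndarray] = []
        for w, b in self.conv:
            out += [w, b]
        for w, b in self.fc:
            out += [w, b]
        out += [self.out[0], self.out[1]]
        return out

    @classmethod
    def init(cls, d1: int, config: CNNConfig, rng: np.random.Generator) -> "CNNParams":
        h, w = 2 + 2, d1 + 2  # padded pair-tensor shape
        c_in = 1
        conv = []
        for stage, ((fl, fw), (pl, pw)) in enumerate(zip(config.filters, config.pools)):
            k = config.n_conv * (stage + 1)
            if fl > h or fw > w:
                raise ValueError(
                    f"stage {stage}: filter ({fl}, {fw}) larger than input ({h}, {w})"
                )
            fan_in = c_in * fl * fw
            conv.append((
                rng.standard_normal((k, c_in, fl, fw)) * np.sqrt(2.0 / fan_in),
                np.zeros(k),
            ))
            h, w = h - fl + 1, w - fw + 1
            h, w = -(-h // pl), -(-w // pw)  # ceil-mode pooling
            if h < 1 or w < 1:
                raise ValueError(f"stage {stage}: output collapsed to zero size")
            c_in = k
        flat_size = c_in * h * w
        fc = []
        n_in = flat_size
        for n_out in config.fc_sizes:
            fc.append((
                rng.standard_normal((n_in, n_out)) * np.sqrt(2.0 / n_in),
                np.zeros(n_out),
            ))
            n_in = n_out
        s = np.sqrt(6.0 / (n_in + 2))
        out = (rng.uniform(-s, s, size=(n_in, 2)), np.zeros(2))
        return cls(conv, fc, out, config)


@dataclass
class CNNForwardTrace:
    feature_maps: list[np.ndarray]
    pooled_maps: list[np.ndarray]
    latent: np.ndarray
    flattened: np.ndarray
    probability: float


@dataclass
class PairPrediction:
    drug_id: str
    disease_id: str
    probability: float
    label: int | None = None

    def __post_init__(self) -> None:
        if not 0.0 < self.probability < 1.0:
            raise ValueError(f"probability must lie in (0, 1), got {self.probability}")


def build_pair_tensor(emb: NodeEmbeddings, drug_id: str, disease_id: str,
                      drug_ids: list[str], disease_ids: list[str]) -> PairTensor:
    """Stack (drug row; disease row) and pad a zero ring around it."""
    try:
        i = drug_ids.index(drug_id)
    except ValueError:
        raise KeyError(f"unknown drug id {drug_id!r}") from None
    try:
        j = disease_ids.index(disease_id)
    except ValueError:
        raise KeyError(f"unknown disease id {disease_id!r}") from None
    content = np.stack([emb.drug_rows[i], emb.disease_rows[j]]).astype(float)
    padded = np.zeros((content.shape[0] + 2, content.shape[1] + 2))
    padded[1:-1, 1:-1] = content
    return PairTensor(drug_id, disease_id, padded)


# ---------------------------------------------------------------------------
# Conv / pool primitives (batched internally; single-sample API on top)

def _im2col(x: np.ndarray, fl: int, fw: int) -> np.ndarray:
    """(B, C, H, W) -> (B, H'*W', C*fl*fw) patches, stride 1, valid placement."""
    sw = np.lib.stride_tricks.sliding_window_view(x, (fl, fw), axis=(2, 3))
    b, c, ho, wo = sw.shape[:4]
    return np.ascontiguousarray(sw.transpose(0, 2, 3, 1, 4, 5)).reshape(b, ho * wo, c * fl * fw), ho, wo


def _conv_batch(x: np.ndarray, w: np.ndarray, b: np.ndarray):
    k, c, fl, fw = w.shape
    if fl > x.shape[2] or fw > x.shape[3]:
        raise ValueError(f"filter {w.shape[2:]} larger than input {x.shape[2:]}")
    patches, ho, wo = _im2col(x, fl, fw)
    pre = patches @ w.reshape(k, -1).T + b  # (B, H'W', K)
    pre = pre.transpose(0, 2, 1).reshape(x.shape[0], k, ho, wo)
    return np.maximum(pre, 0.0), pre, patches


def _conv_backward(g_out, pre, patches, x_shape, w):
    k, c, fl, fw = w.shape
    b_, _, ho, wo = g_out.shape
    g_pre = (g_out * (pre > 0)).reshape(b_, k, ho * wo).transpose(0, 2, 1)  # (B, H'W', K)
    g_w = np.einsum("bpk,bpf->kf", g_pre, patches).reshape(w.shape)
    g_b = g_pre.sum(axis=(0, 1))
    g_patches = g_pre @ w.reshape(k, -1)  # (B, H'W', C*fl*fw)
    g_patches = g_patches.reshape(b_, ho, wo, c, fl, fw)
    g_x = np.zeros(x_shape)
    for di in range(fl):
        for dj in range(fw):
            g_x[:, :, di:di + ho, dj:dj + wo] += g_patches[:, :, :, :, di, dj].transpose(0, 3, 1, 2)
    return g_x, g_w, g_b


def _pool_batch(x: np.ndarray, pl: int, pw: int):
    """Non-overlapping ceil-mode max pooling; returns (out, argmax windows)."""
    b, c, h, w = x.shape
    ho, wo = -(-h // pl), -(-w // pw)
    xp = np.full((b, c, ho * pl, wo * pw), -np.inf)
    xp[:, :, :h, :w] = x
    win = xp.reshape(b, c, ho, pl, wo, pw).transpose(0, 1, 2, 4, 3, 5).reshape(b, c, ho, wo, pl * pw)
    idx = win.argmax(-1)
    out = np.take_along_axis(win, idx[..., None], axis=-1)[..., 0]
    return out, idx


def _pool_backward(g_out, idx, x_shape, pl, pw):
    b, c, h, w = x_shape
    ho, wo = g_out.shape[2], g_out.shape[3]
    g_win = np.zeros((b, c, ho, wo, pl * pw))
    np.put_along_axis(g_win, idx[..., None], g_out[..., None], axis=-1)
    g_xp = g_win.reshape(b, c, ho, wo, pl, pw).transpose(0, 1, 2, 4, 3, 5).reshape(b, c, ho * pl, wo * pw)
    return g_xp[:, :, :h, :w]


def conv_forward(x: np.ndarray, w: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Single-sample conv stage: ReLU(W_k * patch + b_k), stride 1.

    ``x`` may be (H, W) single-channel or (C, H, W); returns (K, H', W').
    """
    x = np.asarray(x, dtype=float)
    if x.ndim == 2:
        x = x[None]
    out, _, _ = _conv_batch(x[None], w, b)
    return out[0]


def max_pool(m: np.ndarray, p_l: int, p_w: int) -> np.ndarray:
    """Non-overlapping max pooling with ceil-mode truncated final windows."""
    m = np.asarray(m, dtype=float)
    squeeze = m.ndim == 2
    if squeeze:
        m = m[None]
    if p_l > m.shape[1] or p_w > m.shape[2]:
        raise ValueError(f"pool window ({p_l}, {p_w}) exceeds map shape {m.shape[1:]}")
    out, _ = _pool_batch(m[None], p_l, p_w)
    return out[0, 0] if squeeze else out[0]


# ---------------------------------------------------------------------------
# Full network

def _forward_batch(x: np.ndarray, params: CNNParams, train_mode: bool,
                   rng: np.random.Generator | None):
    """Forward pass on (B, 1, H, W); returns probabilities and a cache."""
    cfg = params.config
    cache: dict = {"conv": [], "pool": [], "fc": [], "drop": []}
    cur = x
    for stage, ((w, b), (pl, pw)) in enumerate(zip(params.conv, cfg.pools)):
        act, pre, patches = _conv_batch(cur, w, b)
        if act.shape[2] < 1 or act.shape[3] < 1:
            raise ValueError(f"conv stage {stage} produced an empty feature map")
        pooled, idx = _pool_batch(act, pl, pw)
        cache["conv"].append((cur.shape, pre, patches, act.shape))
        cache["pool"].append((idx, act.shape, (pl, pw)))
        cur = pooled
    cache["latent_shape"] = cur.shape
    flat = cur.reshape(cur.shape[0], -1)
    cache["flat"] = flat
    h = flat
    for li, (w, b) in enumerate(params.fc):
        pre = h @ w + b
        act = np.maximum(pre, 0.0)
        mask = None
        if train_mode and cfg.dropout > 0.0 and li < 2:  # no dropout after the third FC layer
            mask = (rng.random(act.shape) >= cfg.dropout) / (1.0 - cfg.dropout)
            act = act * mask
        cache["fc"].append((h, pre))
        cache["drop"].append(mask)
        h = act
    w_o, b_o = params.out
    logits = h @ w_o + b_o
    logits = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(logits)
    probs = e / e.sum(axis=1, keepdims=True)
    cache["h_last"] = h
    cache["probs"] = probs
    return probs, cache


def _backward_batch(cache, labels: np.ndarray, params: CNNParams) -> list[np.ndarray]:
    """Mean softmax cross-entropy gradient through the whole stack."""
    cfg = params.config
    probs = cache["probs"]
    b_ = probs.shape[0]
    onehot = np.zeros_like(probs)
    onehot[np.arange(b_), labels] = 1.0
    g_logits = (probs - onehot) / b_
    w_o, _ = params.out
    g_wo = cache["h_last"].T @ g_logits
    g_bo = g_logits.sum(axis=0)
    g_h = g_logits @ w_o.T
    fc_grads: list[tuple[np.ndarray, np.ndarray]] = []
    for li in range(len(params.fc) - 1, -1, -1):
        h_in, pre = cache["fc"][li]
        mask = cache["drop"][li]
        if mask is not None:
            g_h = g_h * mask
        g_pre = g_h * (pre > 0)
        fc_grads.append((h_in.T @ g_pre, g_pre.sum(axis=0)))
        g_h = g_pre @ params.fc[li][0].T
    fc_grads.reverse()
    g_cur = g_h.reshape(cache["latent_shape"])
    conv_grads: list[tuple[np.ndarray, np.ndarray]] = []
    for stage in range(len(params.conv) - 1, -1, -1):
        idx, act_shape, (pl, pw) = cache["pool"][stage]
        g_act = _pool_backward(g_cur, idx, act_shape, pl, pw)
        x_shape, pre, patches, _ = cache["conv"][stage]
        g_cur, g_w, g_b = _conv_backward(g_act, pre, patches, x_shape, params.conv[stage][0])
        conv_grads.append((g_w, g_b))
    conv_grads.reverse()
    grads: list[np.ndarray] = []
    for g_w, g_b in conv_grads:
        grads += [g_w, g_b]
    for g_w, g_b in fc_grads:
        grads += [g_w, g_b]
    grads += [g_wo, g_bo]
    return grads


def cnn_forward(pair: PairTensor, params: CNNParams, train_mode: bool = False,
                seed: int | None = None) -> CNNForwardTrace:
    """Full forward pass on one pair, recording intermediate maps."""
    rng = np.random.default_rng(seed) if train_mode else None
    cfg = params.config
    cur = pair.values[None, None, :, :].astype(float)
    feature_maps: list[np.ndarray] = []
    pooled_maps: list[np.ndarray] = []
    for stage, ((w, b), (pl, pw)) in enumerate(zip(params.conv, cfg.pools)):
        act, _, _ = _conv_batch(cur, w, b)
        if act.shape[2] < 1 or act.shape[3] < 1:
            raise ValueError(f"conv stage {stage} produced an empty feature map")
        feature_maps.append(act[0])
        cur, _ = _pool_batch(act, pl, pw)
        pooled_maps.append(cur[0])
    probs, _ = _forward_batch(pair.values[None, None, :, :].astype(float), params,
                              train_mode, rng)
    flat = cur.reshape(-1)
    return CNNForwardTrace(
        feature_maps=feature_maps,
        pooled_maps=pooled_maps,
        latent=cur[0],
        flattened=flat,
        probability=float(probs[0, 1]),
    )


def cnn_loss(batch: list[PairPrediction]) -> float:
    """Mean binary cross-entropy between labels and predicted probabilities."""
    if any(p.label is None for p in batch):
        missing = next(p for p in batch if p.label is None)
        raise ValueError(f"pair ({missing.drug_id!r}, {missing.disease_id!r}) has no label")
    z = np.array([p.label for p in batch], dtype=float)
    zh = np.clip([p.probability for p in batch], _EPS, 1.0 - _EPS)
    return float(-(z * np.log(zh) + (1.0 - z) * np.log(1.0 - zh)).mean())


def _pair_batch_array(emb: NodeEmbeddings, pairs, drug_ids, disease_ids) -> np.ndarray:
    drug_index = {d: i for i, d in enumerate(drug_ids)}
    disease_index = {d: j for j, d in enumerate(disease_ids)}
    d1 = emb.x2.shape[1]
    x = np.zeros((len(pairs), 1, 4, d1 + 2))
    for n, (r, d) in enumerate(pairs):
        if r not in drug_index:
            raise KeyError(f"unknown drug id {r!r}")
        if d not in disease_index:
            raise KeyError(f"unknown disease id {d!r}")
        x[n, 0, 1, 1:-1] = emb.drug_rows[drug_index[r]]
        x[n, 0, 2, 1:-1] = emb.disease_rows[disease_index[d]]
    return x


def train_classifier(
    emb: NodeEmbeddings,
    pairs: list[tuple[str, str]],
    labels: list[int],
    drug_ids: list[str],
    disease_ids: list[str],
    config: CNNConfig | None = None,
    seed: int = 0,
) -> tuple[CNNParams, list[float]]:
    """Mini-batch Adam training; returns params and the per-epoch mean loss."""
    if not pairs:
        raise ValueError("empty training set")
    if len(pairs) != len(labels):
        raise ValueError("pairs and labels differ in length")
    config = config or CNNConfig()
    rng = np.random.default_rng(seed)
    d1 = emb.x2.shape[1]
    params = CNNParams.init(d1, config, rng)
    x = _pair_batch_array(emb, pairs, drug_ids, disease_ids)
    y = np.asarray(labels, dtype=int)
    flat = params.flat()
    opt = Adam(flat, lr=config.lr)
    trace: list[float] = []
    n = len(pairs)
    for _ in range(config.epochs):
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, config.batch_size):
            sel = order[start:start + config.batch_size]
            probs, cache = _forward_batch(x[sel], params, True, rng)
            p1 = np.clip(probs[np.arange(len(sel)), y[sel]], _EPS, 1.0)
            losses.append(-np.log(p1).mean() * len(sel))
            grads = _backward_batch(cache, y[sel], params)
            opt.step(grads)
        trace.append(float(np.sum(losses) / n))
    return params, trace


def predict_pairs(
    emb: NodeEmbeddings,
    params: CNNParams,
    pairs: list[tuple[str, str]],
    drug_ids: list[str],
    disease_ids: list[str],
    labels: list[int] | None = None,
) -> list[PairPrediction]:
    """Deterministic inference (dropout off), preserving input order."""
    if not pairs:
        return []
    x = _pair_batch_array(emb, pairs, drug_ids, disease_ids)
    probs_all = []
    for start in range(0, len(pairs), 512):
        probs, _ = _forward_batch(x[start:start + 512], params, False, None)
        probs_all.append(probs[:, 1])
    zh = np.clip(np.concatenate(probs_all), _EPS, 1.0 - _EPS)
    return [
        PairPrediction(r, d, float(p), None if labels is None else int(labels[k]))
        for k, ((r, d), p) in enumerate(zip(pairs, zh))
    ]
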