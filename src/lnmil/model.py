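"""Attention-based multiple-instance-learning model for slide-level LNM prediction.

The network has three parts:

* **FE** — a small convolutional feature extractor that maps any RGB patch to a
  512-dimensional feature vector (FV).  It is pre-trained as a patch-level
  binary classifier using bag-inherited labels (every patch of an LNM-positive
  slide counts as positive), then the classification head is discarded.
* **AM** — a two-layer tanh attention module (hidden width 128, optionally
  gated) producing one logit per patch; a softmax turns the logits into
  attention scores in [0, 1] summing to 1 over the bag.
* **CM** — an affine map 512 -> 1 with logistic output on the attention-weighted
  average of the FVs (the slide-level "WSI deep feature").

All parameters live in a flat ``dict[str, ndarray]`` inside
:class:`ModelParams`, serialized as a single ``.npz`` checkpoint that reloads
bit-exactly.  Training is plain Adam on weighted cross-entropy; every source of
randomness is derived from the caller's seed.
"""

from __future__ import annotations

import io
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import nn
from .nn import F32
from .tiling import Bag

EMBED_DIM = 512

DEFAULT_HYPER: dict = {
    "embed_dim": EMBED_DIM,
    "channels": (8, 16, 32, 64),
    "attn_hidden": 128,
    "gated": False,
    # FE pretraining
    "pretrain_epochs": 8,
    "pretrain_batch": 64,
    "pretrain_lr": 1e-3,
    "pretrain_max_patches": 3500,
    # end-to-end (bag-level) training
    "epochs": 30,
    "bag_batch": 8,
    "lr": 1e-3,
    "finetune_fe": False,
    "bag_cap": 500,
    "class_weighted": True,
}


@dataclass
class FeatureBag:
    """Per-patch 512-d feature matrix of one bag (row order = patch order)."""

    slide_id: str
    features: np.ndarray  # (N, 512)

    def __post_init__(self):
        self.features = np.asarray(self.features)
        if self.features.ndim != 2 or self.features.shape[1] != EMBED_DIM:
            raise ValueError(f"features must be (N, {EMBED_DIM})")
        if not np.all(np.isfinite(self.features)):
            raise ValueError("non-finite feature values")


@dataclass
class AttentionResult:
    """Attention scores (sum 1), pooled WSI feature and optional probability."""

    scores: np.ndarray
    wsi_feature: np.ndarray
    probability: float | None = None


@dataclass
class ModelParams:
    """Flat parameter container for FE / AM / CM plus hyperparameters."""

    weights: dict = field(default_factory=dict)
    hyper: dict = field(default_factory=lambda: dict(DEFAULT_HYPER))

    def copy(self) -> "ModelParams":
        return ModelParams({k: v.copy() for k, v in self.weights.items()}, dict(self.hyper))

    def save(self, path: str | Path) -> None:
        arrays = dict(self.weights)
        hyper = {k: (list(v) if isinstance(v, tuple) else v) for k, v in self.hyper.items()}
        arrays["__hyper__"] = np.frombuffer(json.dumps(hyper).encode(), dtype=np.uint8)
        np.savez(path, **arrays)

    @classmethod
    def load(cls, path: str | Path) -> "ModelParams":
        with np.load(path) as z:
            hyper = json.loads(bytes(z["__hyper__"]).decode())
            weights = {k: z[k] for k in z.files if k != "__hyper__"}
        for k in ("channels",):
            if k in hyper:
                hyper[k] = tuple(hyper[k])
        return cls(weights, hyper)


def _merged(hyper: dict | None) -> dict:
    h = dict(DEFAULT_HYPER)
    if hyper:
        h.update(hyper)
    return h


# ---------------------------------------------------------------------------
# feature extractor


def init_fe(hyper: dict | None = None, seed: int = 0) -> ModelParams:
    h = _merged(hyper)
    rng = np.random.default_rng(seed)
    w: dict = {}
    cin = 3
    for i, cout in enumerate(h["channels"], start=1):
        w[f"fe.conv{i}.W"] = nn.he_init(rng, (cout, cin, 3, 3), cin * 9)
        w[f"fe.conv{i}.b"] = np.zeros(cout, dtype=F32)
        cin = cout
    # the embedding sees concatenated global average + max pooling: the average
    # summarizes texture, the max preserves focal minority patterns in a patch
    w["fe.fc.W"] = nn.he_init(rng, (h["embed_dim"], 2 * cin), 2 * cin)
    w["fe.fc.b"] = np.zeros(h["embed_dim"], dtype=F32)
    return ModelParams(w, h)


def _prep_patches(patches: np.ndarray) -> np.ndarray:
    """(N, p, p, 3) uint8 -> (N, 3, p, p) float32 centered at 0."""
    x = np.asarray(patches, dtype=F32) / 255.0 - 0.5
    return np.ascontiguousarray(x.transpose(0, 3, 1, 2))


def _fe_forward(w: dict, x: np.ndarray, n_blocks: int):
    caches = []
    for i in range(1, n_blocks + 1):
        out, cache = nn.conv_forward(x, w[f"fe.conv{i}.W"], w[f"fe.conv{i}.b"], stride=2, pad=1)
        caches.append((cache, out))
        x = nn.relu(out)
    B, C = x.shape[:2]
    flat = x.reshape(B, C, -1)
    amax = flat.argmax(axis=2)
    pooled = np.concatenate(
        [flat.mean(axis=2), np.take_along_axis(flat, amax[:, :, None], axis=2)[:, :, 0]],
        axis=1,
    )  # (B, 2C): global average pool || global max pool
    emb_pre = pooled @ w["fe.fc.W"].T + w["fe.fc.b"]
    emb_relu = nn.relu(emb_pre)
    # L2-normalize the embedding: patch features live on the unit sphere, so a
    # rare focal texture is separable by direction without becoming a norm
    # outlier that dominates every downstream linear map
    nrm = np.sqrt((emb_relu * emb_relu).sum(axis=1, keepdims=True)) + F32(1e-6)
    emb = emb_relu / nrm
    return emb, (caches, pooled, emb_pre, x.shape, amax, emb_relu, nrm)


def _fe_backward(w: dict, fcache, demb: np.ndarray) -> dict:
    caches, pooled, emb_pre, last_shape, amax, emb_relu, nrm = fcache
    grads: dict = {}
    demb = demb.astype(F32)
    y = emb_relu / nrm
    drelu = (demb - y * (y * demb).sum(axis=1, keepdims=True)) / nrm
    dpre = nn.relu_backward(drelu, emb_pre)
    grads["fe.fc.W"] = dpre.T @ pooled
    grads["fe.fc.b"] = dpre.sum(axis=0)
    dpool = dpre @ w["fe.fc.W"]  # (B, 2C)
    B, C, H, W = last_shape
    davg, dmax = dpool[:, :C], dpool[:, C:]
    dflat = np.broadcast_to(davg[:, :, None] / (H * W), (B, C, H * W)).copy()
    np.put_along_axis(
        dflat, amax[:, :, None],
        np.take_along_axis(dflat, amax[:, :, None], axis=2) + dmax[:, :, None], axis=2,
    )
    dx = dflat.reshape(last_shape).astype(F32)
    for i in range(len(caches), 0, -1):
        cache, pre = caches[i - 1]
        dx = nn.relu_backward(dx, pre)
        dx, dW, db = nn.conv_backward(dx, w[f"fe.conv{i}.W"], cache)
        grads[f"fe.conv{i}.W"] = dW
        grads[f"fe.conv{i}.b"] = db
    return grads


def pretrain_fe(bags: list[Bag], hyper: dict | None = None, seed: int = 0) -> ModelParams:
    """Pre-train the FE as a patch classifier with bag-inherited labels.

    Patches from LNM-positive bags are labeled positive, the rest negative, a
    logistic head on the 512-d embedding is trained with class-weighted
    cross-entropy, and the encoder (plus the diagnostic head) is returned.
    """
    h = _merged(hyper)
    labels = {b.inherited_label for b in bags if len(b)}
    if labels != {0, 1}:
        raise ValueError("pretraining needs non-empty bags of both classes")
    X = np.concatenate([b.patches for b in bags if len(b)])
    y = np.concatenate([np.full(len(b), b.inherited_label) for b in bags if len(b)]).astype(F32)
    rng = np.random.default_rng(seed)
    if len(y) > h["pretrain_max_patches"]:
        idx = rng.choice(len(y), h["pretrain_max_patches"], replace=False)
        X, y = X[idx], y[idx]

    params = init_fe(h, seed=seed)
    w = params.weights
    w["pretrain_head.w"] = nn.he_init(rng, (h["embed_dim"],), h["embed_dim"])
    w["pretrain_head.b"] = np.zeros((), dtype=F32)
    # Pretraining is deliberately unweighted: bag-inherited patch labels are
    # noisy (most patches of a positive slide look normal), and upweighting
    # the minority class would push every normal patch toward p ~ 0.5.
    wts = np.ones(len(y), dtype=F32)

    opt = nn.Adam(lr=h["pretrain_lr"])
    n_blocks = len(h["channels"])
    bs = h["pretrain_batch"]
    for _ in range(h["pretrain_epochs"]):
        order = rng.permutation(len(y))
        for start in range(0, len(y), bs):
            sel = order[start : start + bs]
            xb = _prep_patches(X[sel])
            emb, fcache = _fe_forward(w, xb, n_blocks)
            logit = emb @ w["pretrain_head.w"] + w["pretrain_head.b"]
            p = nn.sigmoid(logit)
            g = (wts[sel] * (p - y[sel]) / len(sel)).astype(F32)
            grads = {
                "pretrain_head.w": emb.T @ g,
                "pretrain_head.b": np.asarray(g.sum(), dtype=F32),
            }
            demb = np.outer(g, w["pretrain_head.w"])
            grads.update(_fe_backward(w, fcache, demb))
            opt.step(w, grads)
    return params


def encode(fe: ModelParams, bag: Bag, chunk: int = 256) -> FeatureBag:
    """Apply the FE to every patch of the bag, preserving order."""
    if len(bag) == 0:
        raise ValueError(f"cannot encode empty bag {bag.slide_id!r}")
    n_blocks = len(_merged(fe.hyper)["channels"])
    outs = []
    for start in range(0, len(bag), chunk):
        x = _prep_patches(bag.patches[start : start + chunk])
        emb, _ = _fe_forward(fe.weights, x, n_blocks)
        outs.append(emb)
    return FeatureBag(slide_id=bag.slide_id, features=np.concatenate(outs))


def patch_scores(fe: ModelParams, bag: Bag) -> np.ndarray:
    """Diagnostic: pretraining-head probabilities per patch (needs the head)."""
    fbag = encode(fe, bag)
    w = fe.weights
    return nn.sigmoid(fbag.features @ w["pretrain_head.w"] + w["pretrain_head.b"])


# ---------------------------------------------------------------------------
# attention + classification


def init_am_cm(hyper: dict | None = None, seed: int = 0) -> dict:
    h = _merged(hyper)
    rng = np.random.default_rng(seed)
    d, k = h["embed_dim"], h["attn_hidden"]
    w = {
        "am.V": nn.he_init(rng, (k, d), d),
        "am.bv": np.zeros(k, dtype=F32),
        "am.w": nn.he_init(rng, (k,), k),
        "cm.w": (0.01 * rng.standard_normal(d)).astype(F32),
        "cm.b": np.zeros((), dtype=F32),
    }
    if h["gated"]:
        w["am.U"] = nn.he_init(rng, (k, d), d)
        w["am.bu"] = np.zeros(k, dtype=F32)
    return w


def attention_logits(w: dict, H: np.ndarray, gated: bool):
    a_pre = H @ w["am.V"].T + w["am.bv"]
    a = np.tanh(a_pre)
    if gated:
        g_pre = H @ w["am.U"].T + w["am.bu"]
        g = nn.sigmoid(g_pre)
        hvec = a * g
    else:
        g_pre = g = None
        hvec = a
    logits = hvec @ w["am.w"]
    return logits, (a_pre, a, g_pre, g, hvec)


def attend(am: ModelParams, fbag: FeatureBag) -> AttentionResult:
    """Softmax attention over patch features and weighted-average pooling.

    Scores are permutation-equivariant, the pooled WSI feature permutation-
    invariant; scores sum to 1.
    """
    H = np.asarray(fbag.features, dtype=np.float64)
    if not np.all(np.isfinite(H)):
        raise ValueError("non-finite features")
    logits, _ = attention_logits(am.weights, H.astype(F32), _merged(am.hyper)["gated"])
    scores = nn.softmax(logits)
    wsi = scores @ H
    return AttentionResult(scores=scores, wsi_feature=wsi)


def predict(cm: ModelParams, wsi_feature: np.ndarray) -> float:
    """Logistic LNM-positive probability from a 512-d WSI deep feature."""
    z = np.asarray(wsi_feature, dtype=np.float64).ravel()
    if z.shape[0] != _merged(cm.hyper)["embed_dim"] or not np.all(np.isfinite(z)):
        raise ValueError("wsi_feature must be a finite 512-d vector")
    return float(nn.sigmoid(np.atleast_1d(z @ cm.weights["cm.w"] + cm.weights["cm.b"]))[0])


def forward_bag(params: ModelParams, H: np.ndarray) -> AttentionResult:
    res = attend(params, FeatureBag(slide_id="", features=H))
    res.probability = predict(params, res.wsi_feature)
    return res


def predict_bag(params: ModelParams, bag: Bag) -> AttentionResult:
    """Full inference on one bag: encode, attend, classify (full bag, no cap)."""
    fbag = encode(params, bag)
    return forward_bag(params, fbag.features)


def _bag_backward(w: dict, H: np.ndarray, scores: np.ndarray, acache, g_out: float,
                  gated: bool):
    """Gradients of the bag loss wrt AM/CM weights and (optionally) features."""
    a_pre, a, g_pre, g, hvec = acache
    z = scores @ H
    grads = {"cm.w": (g_out * z).astype(F32), "cm.b": np.asarray(g_out, dtype=F32)}
    dz = g_out * w["cm.w"].astype(np.float64)
    ds = H @ dz
    dH = np.outer(scores, dz)
    dlogits = scores * (ds - float(scores @ ds))
    grads["am.w"] = (hvec.T @ dlogits).astype(F32)
    dh = np.outer(dlogits, w["am.w"].astype(np.float64))
    if gated:
        da = dh * g
        dgp = dh * a * g * (1.0 - g)
        dap = da * (1.0 - a * a)
        grads["am.U"] = (dgp.T @ H).astype(F32)
        grads["am.bu"] = dgp.sum(axis=0).astype(F32)
        dH += dap @ w["am.V"].astype(np.float64) + dgp @ w["am.U"].astype(np.float64)
    else:
        dap = dh * (1.0 - a * a)
        dH += dap @ w["am.V"].astype(np.float64)
    grads["am.V"] = (dap.T @ H).astype(F32)
    grads["am.bv"] = dap.sum(axis=0).astype(F32)
    return grads, dH


def train_end_to_end(bags: list[Bag], labels: list[int] | None = None,
                     init: ModelParams | None = None, hyper: dict | None = None,
                     seed: int = 0) -> ModelParams:
    """Train AM + CM (and optionally the FE) on bag-level labels.

    With ``finetune_fe=False`` (default) the FE from ``init`` is frozen and all
    patch features are precomputed once, which makes bag-level training cheap;
    with ``finetune_fe=True`` gradients flow through the encoder.  Loss is
    class-weighted binary cross-entropy; bags above ``bag_cap`` patches are
    subsampled (seeded) during training and used in full at inference.
    """
    h = _merged(hyper if hyper is not None else (init.hyper if init else None))
    bags = [b for b in bags if len(b)]
    y = np.array([b.inherited_label for b in bags] if labels is None else labels, dtype=np.float64)
    if set(np.unique(y)) != {0.0, 1.0}:
        raise ValueError("end-to-end training needs bags of both classes")
    rng = np.random.default_rng(seed)

    params = (init.copy() if init is not None else init_fe(h, seed=seed))
    params.hyper = h
    w = params.weights
    w.update(init_am_cm(h, seed=seed + 1))
    if "pretrain_head.w" in w:
        # warm-start the bag classifier from the patch-pretraining head: with
        # still-uniform attention the bag logit is then already the mean patch
        # evidence score, which gives the attention module a useful gradient
        # instead of a cold start that can settle on diluted mean pooling
        head = w["pretrain_head.w"]
        w["cm.w"] = (head / (np.linalg.norm(head) + 1e-8)).astype(F32)

    finetune = bool(h["finetune_fe"])
    n_blocks = len(h["channels"])
    feats = None
    if not finetune:
        feats = [encode(params, b).features.astype(np.float64) for b in bags]

    n_pos = float(y.sum())
    if h["class_weighted"]:
        wt = np.where(y == 1, len(y) / (2 * n_pos), len(y) / (2 * (len(y) - n_pos)))
    else:
        wt = np.ones(len(y))

    opt = nn.Adam(lr=h["lr"])
    cap = h["bag_cap"]
    history = []
    for epoch in range(h["epochs"]):
        order = rng.permutation(len(bags))
        ep_loss = 0.0
        for start in range(0, len(order), h["bag_batch"]):
            batch = order[start : start + h["bag_batch"]]
            acc: dict[str, np.ndarray] = {}
            for bi in batch:
                bag = bags[bi]
                if finetune:
                    idx = (rng.choice(len(bag), cap, replace=False)
                           if len(bag) > cap else np.arange(len(bag)))
                    x = _prep_patches(bag.patches[idx])
                    emb, fcache = _fe_forward(w, x, n_blocks)
                    H = emb.astype(np.float64)
                else:
                    H = feats[bi]
                    if len(H) > cap:
                        H = H[rng.choice(len(H), cap, replace=False)]
                logits, acache = attention_logits(w, H.astype(F32), h["gated"])
                scores = nn.softmax(logits)
                z = scores @ H
                p = float(nn.sigmoid(np.atleast_1d(z @ w["cm.w"] + w["cm.b"]))[0])
                eps = 1e-12
                ep_loss += -wt[bi] * (y[bi] * np.log(p + eps) + (1 - y[bi]) * np.log(1 - p + eps))
                g_out = wt[bi] * (p - y[bi]) / len(batch)
                grads, dH = _bag_backward(w, H, scores, acache, g_out, h["gated"])
                if finetune:
                    grads.update(_fe_backward(w, fcache, dH.astype(F32)))
                for k, gval in grads.items():
                    acc[k] = acc.get(k, 0) + gval
            opt.step(w, acc)
        ep_loss /= len(bags)
        if not np.isfinite(ep_loss):
            raise RuntimeError(f"training diverged (NaN loss) at epoch {epoch}")
        history.append(float(ep_loss))
    params.weights["__loss_history__"] = np.asarray(history)
    return params
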