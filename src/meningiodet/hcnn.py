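"""Hybrid CNN classifier with a spatial fuzzy c-means output layer.

The classifier stacks two valid convolutions (ReLU) and two non-overlapping
pooling layers over the 5-channel blockwise feature maps, then replaces the
usual dense softmax output with a two-cluster Spatial Fuzzy C-Means (SFCM)
layer operating on the flattened embedding (plus the five global scalar
features).

Training is two-stage:

1. the convolution filters are fitted by supervised backpropagation through a
   temporary 2-way softmax head (cross-entropy, Adam);
2. the head is discarded, embeddings are re-extracted, clustered with fuzzy
   c-means, and each cluster is mapped to the majority training label among
   its dominant members.

Everything is plain NumPy and fully deterministic given the config seed. The
filter counts default to the full-scale architecture (512 and 1024); reduced
counts (e.g. 16/32) train in seconds on a single CPU and are what the test
benchmarks use.
"""

from __future__ import annotations

import io
import json
import zipfile
from dataclasses import dataclass, field, asdict, replace
from typing import Optional

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy.spatial.distance import cdist

from .image_io import (
    BrainImage,
    DatasetManifest,
    MENINGIOMA,
    NON_MENINGIOMA,
    ValidationError,
    load_image,
)
from .ridgelet import ridgelet_forward
from .features import FEATURE_NAMES, blockwise_feature_maps, feature_vector


class DegenerateDataError(ValidationError):
    """All samples identical: fuzzy clustering into 2 clusters is undefined."""


class NotTrainedError(RuntimeError):
    """The model has no fitted SFCM state yet."""


@dataclass(frozen=True)
class HCNNConfig:
    """Architecture, SFCM and training hyperparameters.

    ``conv*_kernel`` are odd square kernel sides applied with unit stride and
    no padding; ``spatial_p``/``spatial_q`` are the membership/neighbourhood
    exponents of the SFCM re-weighting u' ~ u^p * h^q.
    """

    conv1_filters: int = 512
    conv1_kernel: int = 5
    conv2_filters: int = 1024
    conv2_kernel: int = 7
    pool_size: int = 2
    pool_mode: str = "max"
    clusters: int = 2
    fuzzifier_m: float = 2.0
    spatial_p: float = 1.0
    spatial_q: float = 1.0
    neighborhood_radius: int = 1
    max_iter: int = 100
    tol: float = 1e-5
    seed: int = 0
    # feature-map front end
    wavelet: str = "haar"
    block: int = 8
    stride: int = 4
    features: tuple = FEATURE_NAMES
    # stage-1 training
    train_filters: str = "backprop"  # or "random" (fixed random filters)
    embed_dim: int = 16
    epochs: int = 12
    batch_size: int = 16
    learning_rate: float = 1e-3
    center_loss_weight: float = 0.1  # pulls same-class embeddings together

    def __post_init__(self) -> None:
        for k in (self.conv1_kernel, self.conv2_kernel):
            if k < 3 or k % 2 == 0:
                raise ValidationError(f"conv kernels must be odd and >= 3, got {k}")
        if self.fuzzifier_m <= 1:
            raise ValidationError("fuzzifier_m must be > 1")
        if self.clusters != 2:
            raise ValidationError("the classifier is a two-cluster model")
        if self.pool_mode not in ("max", "mean"):
            raise ValidationError(f"pool_mode must be max or mean, got {self.pool_mode!r}")
        if self.train_filters not in ("backprop", "random"):
            raise ValidationError("train_filters must be 'backprop' or 'random'")
        if self.spatial_p < 0 or self.spatial_q < 0:
            raise ValidationError("spatial exponents must be >= 0")
        unknown = set(self.features) - set(FEATURE_NAMES)
        if unknown:
            raise ValidationError(f"unknown features: {sorted(unknown)}")
        object.__setattr__(self, "features", tuple(self.features))


# ---------------------------------------------------------------------------
# convolution / pooling primitives (batched internally, single-sample public)
# ---------------------------------------------------------------------------


def _conv_raw(X: np.ndarray, W: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Valid cross-correlation, unit stride. X (N,C,H,W), W (F,C,k,k) -> (N,F,H',W')."""
    k = W.shape[-1]
    if X.shape[-2] < k or X.shape[-1] < k:
        raise ValidationError(
            f"input spatial dims {X.shape[-2:]} smaller than kernel {W.shape[-2:]}"
        )
    win = sliding_window_view(X, (k, k), axis=(-2, -1))  # (N,C,H',W',k,k)
    return np.einsum("fckl,nchwkl->nfhw", W, win, optimize=True) + b[None, :, None, None]


def _conv_backward(X, W, dZ):
    """Gradients of the valid cross-correlation wrt W, b and X."""
    k = W.shape[-1]
    win = sliding_window_view(X, (k, k), axis=(-2, -1))
    dW = np.einsum("nfhw,nchwkl->fckl", dZ, win, optimize=True)
    db = dZ.sum(axis=(0, 2, 3))
    pad = k - 1
    dZp = np.pad(dZ, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    win2 = sliding_window_view(dZp, (k, k), axis=(-2, -1))  # (N,F,H,W,k,k)
    Wf = W[:, :, ::-1, ::-1]
    dX = np.einsum("nfhwkl,fckl->nchw", win2, Wf, optimize=True)
    return dW, db, dX


def conv_forward(x: np.ndarray, filters: np.ndarray, bias: np.ndarray) -> np.ndarray:
    """Valid (no-padding) cross-correlation with unit stride, then ReLU.

    ``x`` is (channels, H, W); ``filters`` is (n_filters, channels, k, k) with
    k odd; returns (n_filters, H-k+1, W-k+1).
    """
    x = np.asarray(x, dtype=np.float64)
    filters = np.asarray(filters, dtype=np.float64)
    if x.ndim != 3 or filters.ndim != 4:
        raise ValidationError("x must be (C,H,W) and filters (F,C,k,k)")
    if filters.shape[-1] != filters.shape[-2] or filters.shape[-1] % 2 == 0:
        raise ValidationError(f"kernel must be odd square, got {filters.shape[-2:]}")
    z = _conv_raw(x[None], filters, np.asarray(bias, dtype=np.float64))[0]
    return np.maximum(z, 0.0)


def _pool_batch(X: np.ndarray, size: int, mode: str):
    """Non-overlapping pooling; remainder rows/cols dropped. X (N,C,H,W)."""
    n, c, h, w = X.shape
    hp, wp = h // size, w // size
    if hp < 1 or wp < 1:
        raise ValidationError(f"spatial dims {(h, w)} smaller than pool size {size}")
    Xc = X[:, :, : hp * size, : wp * size]
    blocks = Xc.reshape(n, c, hp, size, wp, size).transpose(0, 1, 2, 4, 3, 5)
    flat = blocks.reshape(n, c, hp, wp, size * size)
    if mode == "max":
        idx = flat.argmax(axis=-1)
        out = np.take_along_axis(flat, idx[..., None], axis=-1)[..., 0]
        return out, idx
    return flat.mean(axis=-1), None


def _pool_backward(dOut, X_shape, size, mode, idx):
    n, c, h, w = X_shape
    hp, wp = h // size, w // size
    flat = np.zeros((n, c, hp, wp, size * size))
    if mode == "max":
        np.put_along_axis(flat, idx[..., None], dOut[..., None], axis=-1)
    else:
        flat[:] = (dOut / (size * size))[..., None]
    blocks = flat.reshape(n, c, hp, wp, size, size).transpose(0, 1, 2, 4, 3, 5)
    dX = np.zeros(X_shape)
    dX[:, :, : hp * size, : wp * size] = blocks.reshape(n, c, hp * size, wp * size)
    return dX


def pool_forward(x: np.ndarray, size: int = 2, mode: str = "max") -> np.ndarray:
    """Reduce non-overlapping size x size windows by max or mean."""
    if size < 1:
        raise ValidationError("pool size must be >= 1")
    if mode not in ("max", "mean"):
        raise ValidationError(f"pool mode must be max or mean, got {mode!r}")
    x = np.asarray(x, dtype=np.float64)
    out, _ = _pool_batch(x[None], size, mode)
    return out[0]


# ---------------------------------------------------------------------------
# spatial fuzzy c-means
# ---------------------------------------------------------------------------


@dataclass
class SFCMState:
    """Converged fuzzy clustering: centroids, memberships and diagnostics."""

    centroids: np.ndarray  # (clusters, dim)
    memberships: np.ndarray  # (samples, clusters), rows sum to 1
    objective_trace: list
    cluster_to_label: Optional[dict] = None
    n_iter: int = 0


def _fcm_memberships(points: np.ndarray, centroids: np.ndarray, m: float) -> np.ndarray:
    d2 = cdist(points, centroids, "sqeuclidean")
    zero = d2 < 1e-24
    u = np.empty_like(d2)
    power = 1.0 / (m - 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        inv = d2 ** (-power)
        u = inv / inv.sum(axis=1, keepdims=True)
    hit = zero.any(axis=1)
    if hit.any():
        u[hit] = zero[hit] / zero[hit].sum(axis=1, keepdims=True)
    return u


def _neighbor_sums(u: np.ndarray, positions: np.ndarray, radius: int) -> np.ndarray:
    """Per-sample sum of memberships over the Moore neighbourhood (incl. self)."""
    from scipy.ndimage import uniform_filter

    pos = np.asarray(positions, dtype=int)
    pos = pos - pos.min(axis=0)
    shape = tuple(pos.max(axis=0) + 1)
    win = 2 * radius + 1
    h = np.empty_like(u)
    grid = np.zeros(shape)
    for c in range(u.shape[1]):
        grid[:] = 0.0
        grid[pos[:, 0], pos[:, 1]] = u[:, c]
        summed = uniform_filter(grid, size=win, mode="constant", cval=0.0) * win**2
        h[:, c] = summed[pos[:, 0], pos[:, 1]]
    return h


def sfcm_cluster(
    points: np.ndarray,
    grid_positions: Optional[np.ndarray] = None,
    config: Optional[HCNNConfig] = None,
) -> SFCMState:
    """Fuzzy c-means with optional spatial membership re-weighting.

    Alternates the standard FCM membership/centroid updates (fuzzifier m,
    Euclidean distance). When ``grid_positions`` is given, each membership
    update is followed by u'_ik ~ u_ik^p * h_ik^q where h_ik sums the
    neighbours' memberships within ``neighborhood_radius`` (Moore
    neighbourhood), renormalised per sample. Without positions, or with
    p = 1 and q = 0, the procedure is plain FCM.
    """
    cfg = config if config is not None else HCNNConfig(conv1_filters=1, conv2_filters=1)
    X = np.asarray(points, dtype=np.float64)
    if X.ndim != 2:
        raise ValidationError("points must be (samples, dim)")
    n, dim = X.shape
    c = cfg.clusters
    if n < c:
        raise ValidationError(f"need at least {c} samples, got {n}")
    if np.ptp(X, axis=0).max() == 0:
        raise DegenerateDataError("all samples identical; 2-cluster split undefined")

    rng = np.random.default_rng(cfg.seed)
    # seeded init: distinct random samples, nudged apart if coincident
    idx = rng.choice(n, size=c, replace=False)
    centroids = X[idx].copy()
    if np.ptp(centroids, axis=0).max() == 0:
        centroids += rng.normal(scale=1e-6 + X.std(), size=centroids.shape)

    m = cfg.fuzzifier_m
    spatial = grid_positions is not None and not (
        cfg.spatial_p == 1.0 and cfg.spatial_q == 0.0
    )

    def _adjust(u_raw: np.ndarray) -> np.ndarray:
        if not spatial:
            return u_raw
        h = _neighbor_sums(u_raw, grid_positions, cfg.neighborhood_radius)
        w = (u_raw**cfg.spatial_p) * (h**cfg.spatial_q)
        total = w.sum(axis=1, keepdims=True)
        total[total == 0] = 1.0
        return w / total

    trace = []
    u_prev = None
    n_iter = 0
    for n_iter in range(1, cfg.max_iter + 1):
        u_raw = _fcm_memberships(X, centroids, m)
        # standard FCM objective at the fresh memberships / current centroids;
        # non-increasing across iterations for plain FCM
        trace.append(float((u_raw**m * cdist(X, centroids, "sqeuclidean")).sum()))
        u = _adjust(u_raw)
        um = u**m
        denom = um.sum(axis=0)[:, None]
        denom[denom == 0] = 1.0
        centroids = (um.T @ X) / denom
        if u_prev is not None and np.abs(u - u_prev).max() < cfg.tol:
            break
        u_prev = u
    # final memberships consistent with the returned centroids
    u = _adjust(_fcm_memberships(X, centroids, m))
    return SFCMState(
        centroids=centroids, memberships=u, objective_trace=trace, n_iter=n_iter
    )


# ---------------------------------------------------------------------------
# model, training, classification
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ClassificationResult:
    label: str
    memberships: dict  # class label -> membership in [0, 1]


@dataclass
class HCNNModel:
    """Fitted classifier: conv/pool weights, linear embedding layer and the
    frozen SFCM output layer. ``Wb``/``bb`` project the flattened conv
    features to the low-dimensional embedding that the SFCM layer clusters;
    the temporary softmax head used during supervised pretraining is not
    retained."""

    config: HCNNConfig
    W1: np.ndarray
    b1: np.ndarray
    W2: np.ndarray
    b2: np.ndarray
    Wb: Optional[np.ndarray] = None
    bb: Optional[np.ndarray] = None
    embed_mean: Optional[np.ndarray] = None
    embed_std: Optional[np.ndarray] = None
    sfcm: Optional[SFCMState] = None
    channel_stats: Optional[tuple] = None
    training_loss: list = field(default_factory=list)

    @property
    def trained(self) -> bool:
        return self.sfcm is not None and self.sfcm.cluster_to_label is not None


def _stack_forward(X, model_or_params, return_cache=False):
    """conv1 -> relu -> pool -> conv2 -> relu -> pool on a batch (N,C,H,W)."""
    m = model_or_params
    cfg = m["config"] if isinstance(m, dict) else m.config
    W1, b1, W2, b2 = (
        (m["W1"], m["b1"], m["W2"], m["b2"])
        if isinstance(m, dict)
        else (m.W1, m.b1, m.W2, m.b2)
    )
    Z1 = _conv_raw(X, W1, b1)
    A1 = np.maximum(Z1, 0.0)
    P1, idx1 = _pool_batch(A1, cfg.pool_size, cfg.pool_mode)
    Z2 = _conv_raw(P1, W2, b2)
    A2 = np.maximum(Z2, 0.0)
    P2, idx2 = _pool_batch(A2, cfg.pool_size, cfg.pool_mode)
    flat = P2.reshape(P2.shape[0], -1)
    if not return_cache:
        return flat
    return flat, (X, Z1, A1, P1, idx1, Z2, A2, P2, idx2)


def _stack_backward(dflat, cache, model_params, cfg):
    X, Z1, A1, P1, idx1, Z2, A2, P2, idx2 = cache
    dP2 = dflat.reshape(P2.shape)
    dA2 = _pool_backward(dP2, A2.shape, cfg.pool_size, cfg.pool_mode, idx2)
    dZ2 = dA2 * (Z2 > 0)
    dW2, db2, dP1 = _conv_backward(P1, model_params["W2"], dZ2)
    dA1 = _pool_backward(dP1, A1.shape, cfg.pool_size, cfg.pool_mode, idx1)
    dZ1 = dA1 * (Z1 > 0)
    dW1, db1, _ = _conv_backward(X, model_params["W1"], dZ1)
    return {"W1": dW1, "b1": db1, "W2": dW2, "b2": db2}


def _image_features(image: BrainImage, cfg: HCNNConfig):
    """FeatureMap channels + scalar feature subset for one image."""
    coeffs = ridgelet_forward(image, wavelet=cfg.wavelet)
    fmap = blockwise_feature_maps(
        coeffs, block=cfg.block, stride=cfg.stride, features=cfg.features
    )
    fv = feature_vector(coeffs).subset(cfg.features)
    return fmap.channels, fv


def _normalize_channels(channels: np.ndarray, stats=None):
    """Per-cell standardisation across the batch (N,C,H,W).

    The coefficient grid has a strong fixed structure (coarse wavelet bands
    carry values many orders of magnitude above the fine bands), identical in
    every image; z-scoring each (channel, row, col) cell over the training
    batch removes that structural pattern so the convolution stack sees the
    per-image anomaly signal on a well-conditioned scale. The statistics are
    frozen into the model and reused at inference.
    """
    if stats is None:
        mean = channels.mean(axis=0, keepdims=True)
        std = channels.std(axis=0, keepdims=True)
        std = np.where(std < 1e-12, 1.0, std)
        stats = (mean, std)
    mean, std = stats
    return (channels - mean) / std, stats


def _init_params(cfg: HCNNConfig, in_channels: int, rng) -> dict:
    k1, k2 = cfg.conv1_kernel, cfg.conv2_kernel
    W1 = rng.normal(
        scale=np.sqrt(2.0 / (in_channels * k1 * k1)),
        size=(cfg.conv1_filters, in_channels, k1, k1),
    )
    W2 = rng.normal(
        scale=np.sqrt(2.0 / (cfg.conv1_filters * k2 * k2)),
        size=(cfg.conv2_filters, cfg.conv1_filters, k2, k2),
    )
    return {
        "config": cfg,
        "W1": W1,
        "b1": np.zeros(cfg.conv1_filters),
        "W2": W2,
        "b2": np.zeros(cfg.conv2_filters),
    }


class _Adam:
    def __init__(self, params: dict, lr: float):
        self.lr = lr
        self.t = 0
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}

    def step(self, params: dict, grads: dict):
        self.t += 1
        b1, b2, eps = 0.9, 0.999, 1e-8
        for k, g in grads.items():
            self.m[k] = b1 * self.m[k] + (1 - b1) * g
            self.v[k] = b2 * self.v[k] + (1 - b2) * g * g
            mhat = self.m[k] / (1 - b1**self.t)
            vhat = self.v[k] / (1 - b2**self.t)
            params[k] = params[k] - self.lr * mhat / (np.sqrt(vhat) + eps)
        return params


def _softmax_ce(logits, y):
    z = logits - logits.max(axis=1, keepdims=True)
    ez = np.exp(z)
    probs = ez / ez.sum(axis=1, keepdims=True)
    n = len(y)
    loss = -np.log(probs[np.arange(n), y] + 1e-300).mean()
    dlogits = probs.copy()
    dlogits[np.arange(n), y] -= 1.0
    return loss, dlogits / n


def train(
    manifest: DatasetManifest,
    config: HCNNConfig,
    image_loader=load_image,
) -> HCNNModel:
    """Fit the full classifier on the manifest's training split.

    Raises a validation error if the training split is empty or single-class.
    Fully deterministic given ``config.seed``.
    """
    train_recs = [r for r in manifest.records if r.split == "train"]
    if not train_recs:
        raise ValidationError("empty training split")
    labels = {r.label for r in train_recs}
    if len(labels) < 2:
        raise ValidationError(f"training split must contain both classes, got {labels}")

    cfg = config
    feats = [
        _image_features(image_loader(r.image_path), cfg) for r in train_recs
    ]
    shapes = {f[0].shape for f in feats}
    if len(shapes) > 1:
        raise ValidationError(f"training images yield mixed feature-map shapes: {shapes}")
    X = np.stack([f[0] for f in feats])  # (N, C, U, V)
    S = np.stack([f[1] for f in feats])  # (N, n_features)
    y = np.array([0 if r.label == MENINGIOMA else 1 for r in train_recs])

    Xn, ch_stats = _normalize_channels(X)
    rng = np.random.default_rng(cfg.seed)
    params = _init_params(cfg, X.shape[1], rng)
    flat_dim = _stack_forward(Xn[:1], params).shape[1]
    params["Wb"] = rng.normal(scale=np.sqrt(1.0 / flat_dim), size=(cfg.embed_dim, flat_dim))
    params["bb"] = np.zeros(cfg.embed_dim)

    losses: list = []
    if cfg.train_filters == "backprop":
        head_W = rng.normal(scale=np.sqrt(2.0 / cfg.embed_dim), size=(2, cfg.embed_dim))
        head_b = np.zeros(2)
        params["head_W"], params["head_b"] = head_W, head_b
        opt = _Adam({k: v for k, v in params.items() if k != "config"}, cfg.learning_rate)
        n = len(y)
        centers = np.zeros((2, cfg.embed_dim))
        centers_seen = np.zeros(2, dtype=bool)
        lam = cfg.center_loss_weight
        for _ in range(cfg.epochs):
            order = rng.permutation(n)
            epoch_loss = 0.0
            for start in range(0, n, cfg.batch_size):
                sel = order[start : start + cfg.batch_size]
                flat, cache = _stack_forward(Xn[sel], params, return_cache=True)
                emb = flat @ params["Wb"].T + params["bb"]
                logits = emb @ params["head_W"].T + params["head_b"]
                loss, dlogits = _softmax_ce(logits, y[sel])
                demb = dlogits @ params["head_W"]
                # center loss: compact same-class embeddings so the fuzzy
                # output layer's Euclidean clusters match the classes
                if lam > 0:
                    for c in (0, 1):
                        batch_c = emb[y[sel] == c]
                        if len(batch_c):
                            if not centers_seen[c]:
                                centers[c] = batch_c.mean(axis=0)
                                centers_seen[c] = True
                            else:
                                centers[c] += 0.5 * (batch_c.mean(axis=0) - centers[c])
                    resid = emb - centers[y[sel]]
                    loss += lam * 0.5 * (resid**2).sum() / len(sel)
                    demb = demb + lam * resid / len(sel)
                epoch_loss += loss * len(sel)
                grads = {
                    "head_W": dlogits.T @ emb,
                    "head_b": dlogits.sum(axis=0),
                    "Wb": demb.T @ flat,
                    "bb": demb.sum(axis=0),
                }
                dflat = demb @ params["Wb"]
                grads.update(_stack_backward(dflat, cache, params, cfg))
                upd = opt.step({k: params[k] for k in grads}, grads)
                params.update(upd)
            losses.append(epoch_loss / n)
        params.pop("head_W"), params.pop("head_b")

    model = HCNNModel(
        config=cfg,
        W1=params["W1"],
        b1=params["b1"],
        W2=params["W2"],
        b2=params["b2"],
        Wb=params["Wb"],
        bb=params["bb"],
        channel_stats=ch_stats,
        training_loss=losses,
    )

    # stage 2: embeddings -> fuzzy clustering -> cluster/label map
    flat = _stack_forward(Xn, model)
    E = np.concatenate([flat @ model.Wb.T + model.bb, S], axis=1)
    mean, std = E.mean(axis=0), E.std(axis=0)
    std = np.where(std < 1e-12, 1.0, std)
    model.embed_mean, model.embed_std = mean, std
    En = (E - mean) / std
    state = sfcm_cluster(En, grid_positions=None, config=cfg)
    hard = state.memberships.argmax(axis=1)
    # choose the cluster->label map that best agrees with the training labels
    agree_identity = int(((hard == 0) & (y == 0)).sum() + ((hard == 1) & (y == 1)).sum())
    agree_swapped = len(y) - agree_identity
    if agree_identity >= agree_swapped:
        state.cluster_to_label = {0: MENINGIOMA, 1: NON_MENINGIOMA}
    else:
        state.cluster_to_label = {0: NON_MENINGIOMA, 1: MENINGIOMA}
    model.sfcm = state
    return model


def embed(image: BrainImage, model: HCNNModel) -> np.ndarray:
    """Standardised embedding of one image under a trained (or fitted) model."""
    cfg = model.config
    channels, scalars = _image_features(image, cfg)
    Xn, _ = _normalize_channels(channels[None], model.channel_stats)
    flat = _stack_forward(Xn, model)
    E = np.concatenate([flat[0] @ model.Wb.T + model.bb, scalars])
    if model.embed_mean is not None:
        E = (E - model.embed_mean) / model.embed_std
    return E


def classify(image: BrainImage, model: HCNNModel) -> ClassificationResult:
    """Label an image by fuzzy membership against the frozen SFCM centroids.

    Ties are broken toward the lower cluster index.
    """
    if not isinstance(model, HCNNModel) or not model.trained:
        raise NotTrainedError("classify requires a trained model")
    e = embed(image, model)
    u = _fcm_memberships(e[None], model.sfcm.centroids, model.config.fuzzifier_m)[0]
    best = int(np.argmax(u))  # argmax takes the lower index on exact ties
    label = model.sfcm.cluster_to_label[best]
    memberships = {
        model.sfcm.cluster_to_label[c]: float(u[c]) for c in range(len(u))
    }
    return ClassificationResult(label=label, memberships=memberships)


# ---------------------------------------------------------------------------
# model archive (deterministic zip of .npy arrays + JSON config)
# ---------------------------------------------------------------------------

_EPOCH = (1980, 1, 1, 0, 0, 0)  # fixed zip timestamp: byte-identical archives


def save_model(model: HCNNModel, path: str) -> None:
    """Serialise a trained model to a single zip archive.

    Arrays are stored as .npy members, the config and cluster map as JSON;
    member timestamps are fixed so identical models produce byte-identical
    files.
    """
    if not model.trained:
        raise NotTrainedError("refusing to save an untrained model")
    arrays = {
        "W1": model.W1,
        "b1": model.b1,
        "W2": model.W2,
        "b2": model.b2,
        "Wb": model.Wb,
        "bb": model.bb,
        "embed_mean": model.embed_mean,
        "embed_std": model.embed_std,
        "centroids": model.sfcm.centroids,
        "channel_mean": model.channel_stats[0],
        "channel_std": model.channel_stats[1],
    }
    meta = {
        "config": asdict(model.config),
        "cluster_to_label": {str(k): v for k, v in model.sfcm.cluster_to_label.items()},
        "training_loss": model.training_loss,
        "format": "meningiodet-model-v1",
    }
    with zipfile.ZipFile(path, "w", compression=zipfile.ZIP_DEFLATED) as zf:
        info = zipfile.ZipInfo("meta.json", date_time=_EPOCH)
        zf.writestr(info, json.dumps(meta, sort_keys=True))
        for name in sorted(arrays):
            buf = io.BytesIO()
            np.save(buf, arrays[name])
            zf.writestr(zipfile.ZipInfo(f"{name}.npy", date_time=_EPOCH), buf.getvalue())


def load_model(path: str) -> HCNNModel:
    with zipfile.ZipFile(path) as zf:
        meta = json.loads(zf.read("meta.json"))
        arrays = {}
        for name in zf.namelist():
            if name.endswith(".npy"):
                arrays[name[:-4]] = np.load(io.BytesIO(zf.read(name)))
    cfg_dict = meta["config"]
    cfg_dict["features"] = tuple(cfg_dict["features"])
    cfg = HCNNConfig(**cfg_dict)
    state = SFCMState(
        centroids=arrays["centroids"],
        memberships=np.zeros((0, cfg.clusters)),
        objective_trace=[],
        cluster_to_label={int(k): v for k, v in meta["cluster_to_label"].items()},
    )
    return HCNNModel(
        config=cfg,
        W1=arrays["W1"],
        b1=arrays["b1"],
        W2=arrays["W2"],
        b2=arrays["b2"],
        Wb=arrays["Wb"],
        bb=arrays["bb"],
        embed_mean=arrays["embed_mean"],
        embed_std=arrays["embed_std"],
        sfcm=state,
        channel_stats=(arrays["channel_mean"], arrays["channel_std"]),
        training_loss=list(meta.get("training_loss", [])),
    )
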