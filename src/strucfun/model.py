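"""The graph-convolutional function predictor and the sequence-only CNN
baseline.

The GCN follows the Kipf–Welling propagation rule on the symmetrically
normalized contact map with self-connections,

    H^(l+1) = ReLU( D~^{-1/2} (A + I) D~^{-1/2} H^(l) W^(l) ),

stacks N_l = 3 layers, concatenates the per-layer feature maps, sum-pools
over residues into a fixed-size protein representation, and classifies with
one fully connected hidden layer followed by a per-term 2-way softmax (a
positive and a negative activation per function term).  Training minimizes
a class-weighted cross-entropy with w_j = N / N_j^+ so rare terms weigh
more, with Adam (lr 1e-4, beta1 = beta2 = 0.95, batch 64), a 10% validation
split and early stopping (patience 5, best-validation checkpoint restored).
A term is called positive when its positive-class probability is strictly
above 0.5.

The baseline is a DeepGO-style 1D CNN over the one-hot sequence: parallel
convolutions of several filter lengths, ReLU, global max-pooling,
and a dense sigmoid head.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from . import autograd as ag
from .autograd import Tensor
from .nn import Adam, EarlyStopper, clone_params, glorot, set_params

logger = logging.getLogger(__name__)

EPS_CLIP = 1e-7


# --------------------------------------------------------------------------
# functional pieces (the equation surface; NumPy in, NumPy out)
# --------------------------------------------------------------------------

def normalize_adjacency(a: np.ndarray) -> np.ndarray:
    """Symmetrically normalized adjacency with self-connections:
    D~^{-1/2} (A + I) D~^{-1/2}."""
    a = np.asarray(a, dtype=float)
    if a.ndim != 2 or a.shape[0] != a.shape[1]:
        raise ValueError("adjacency must be square")
    if not np.array_equal(a, a.T):
        raise ValueError("adjacency must be symmetric")
    a_tilde = a + np.eye(a.shape[0])
    d = a_tilde.sum(axis=1)
    inv_sqrt = 1.0 / np.sqrt(d)
    return inv_sqrt[:, None] * a_tilde * inv_sqrt[None, :]


def graph_conv_layer(a_hat: np.ndarray, h: np.ndarray, w: np.ndarray) -> np.ndarray:
    """One graph convolution: ReLU(A_hat @ H @ W)."""
    a_hat, h, w = (np.asarray(m, dtype=float) for m in (a_hat, h, w))
    if a_hat.shape[1] != h.shape[0] or h.shape[1] != w.shape[0]:
        raise ValueError("shape mismatch in graph convolution")
    return np.maximum(a_hat @ h @ w, 0.0)


def concat_and_pool(layer_outputs: list, mask: np.ndarray | None = None) -> np.ndarray:
    """Concatenate per-layer residue features and sum-pool over residues.

    ``mask`` (length L, 1 for real residues) excludes padded rows."""
    rows = {np.asarray(h).shape[0] for h in layer_outputs}
    if len(rows) != 1:
        raise ValueError("layer outputs disagree on residue count")
    h = np.concatenate([np.asarray(x, dtype=float) for x in layer_outputs], axis=1)
    if mask is not None:
        h = h * np.asarray(mask, dtype=float)[:, None]
    return h.sum(axis=0)


def weighted_bce_loss(y_hat: np.ndarray, y: np.ndarray, weights: np.ndarray) -> float:
    """Class-weighted cross-entropy over paired indicators.

    L = -(1/N) sum_i sum_j sum_k w_j y_ijk ln(y_hat_ijk), with predictions
    clipped to [1e-7, 1 - 1e-7].  Natural-log convention.
    """
    y_hat = np.clip(np.asarray(y_hat, dtype=float), EPS_CLIP, 1 - EPS_CLIP)
    y = np.asarray(y, dtype=float)
    w = np.asarray(weights, dtype=float)
    if y_hat.shape != y.shape:
        raise ValueError("prediction/label shape mismatch")
    n = y.shape[0] if y.ndim == 3 else 1
    per = w[..., :, None] * y * np.log(y_hat)
    return float(-per.sum() / n)


# --------------------------------------------------------------------------
# models
# --------------------------------------------------------------------------

@dataclass
class GCNConfig:
    """Architecture of the graph-convolutional predictor.

    ``channels`` lists the output width of each graph layer (its length is
    N_l); ``input_channels`` is the width c0 of the fused residue features;
    ``fc_hidden`` is the post-pooling hidden width (desk default 64; 512 at
    full scale).  ``layer_variant`` tags the propagation rule; only the
    Kipf–Welling rule ships, but `GCNModel(conv_fn=...)` accepts any
    callable (A_hat, H, W) -> H as a replacement.
    """

    channels: tuple = (32, 32, 32)
    input_channels: int = 32
    fc_hidden: int = 64
    layer_variant: str = "kipf_welling"

    def __post_init__(self):
        if len(self.channels) < 1 or min(self.channels) < 1:
            raise ValueError("need at least one layer with width >= 1")


def _kipf_welling(a_hat: Tensor, h: Tensor, w: Tensor) -> Tensor:
    return ag.relu(a_hat @ h @ w)


class GCNModel:
    """Trainable GCN over residue contact maps.

    Parameters are autograd Tensors in ``self.params``; checkpoints are
    plain array snapshots, restored bit-exactly.
    """

    kind = "gcn"

    def __init__(self, n_terms: int, config: GCNConfig | None = None,
                 lm_dim: int | None = None, n_channels: int = 26,
                 seed: int = 0, conv_fn=None):
        self.n_terms = n_terms
        self.config = config or GCNConfig()
        self.lm_dim = lm_dim
        self.conv_fn = conv_fn or _kipf_welling
        rng = np.random.default_rng(seed)
        c0 = self.config.input_channels
        p: dict[str, Tensor] = {}
        p["W_x"] = Tensor(glorot(rng, n_channels, c0), requires_grad=True)
        if lm_dim is not None:
            p["W_lm"] = Tensor(glorot(rng, lm_dim, c0), requires_grad=True)
        p["b_fuse"] = Tensor(np.zeros(c0), requires_grad=True)
        widths = [c0, *self.config.channels]
        for li, (cin, cout) in enumerate(zip(widths[:-1], widths[1:])):
            p[f"W_conv{li}"] = Tensor(glorot(rng, cin, cout), requires_grad=True)
        pooled = sum(self.config.channels)
        # sum pooling scales with L, so the classifier weights start small
        # (and the head at zero) to keep initial term probabilities near 0.5
        # instead of saturating the softmax
        p["W_fc"] = Tensor(0.1 * glorot(rng, pooled, self.config.fc_hidden),
                           requires_grad=True)
        p["b_fc"] = Tensor(np.zeros(self.config.fc_hidden), requires_grad=True)
        p["W_head"] = Tensor(np.zeros((self.config.fc_hidden, n_terms * 2)),
                             requires_grad=True)
        p["b_head"] = Tensor(np.zeros(n_terms * 2), requires_grad=True)
        self.params = p

    def forward(self, x: np.ndarray, a_hat: np.ndarray,
                h_lm: np.ndarray | None = None,
                mask: np.ndarray | None = None) -> tuple[Tensor, list]:
        """Returns (per-term probability pairs (n_terms, 2), the per-layer
        feature maps H^(1..N_l) for saliency)."""
        p = self.params
        xt = Tensor(x)
        pre = xt @ p["W_x"] + p["b_fuse"]
        if h_lm is not None:
            if "W_lm" not in p:
                raise ValueError("model was built without a language-model pathway")
            if h_lm.shape[0] != x.shape[0]:
                raise ValueError("H^LM and X disagree on residue count")
            pre = pre + Tensor(h_lm) @ p["W_lm"]
        h = ag.relu(pre)
        mt = Tensor(np.asarray(mask, dtype=float)[:, None]) if mask is not None else None
        if mt is not None:
            h = h * mt
        at = Tensor(a_hat)
        fmaps = []
        for li in range(len(self.config.channels)):
            h = self.conv_fn(at, h, p[f"W_conv{li}"])
            if mt is not None:
                h = h * mt
            fmaps.append(h)
        pooled = ag.concatenate(fmaps, axis=1).sum(axis=0)
        hidden = ag.relu(pooled @ p["W_fc"] + p["b_fc"])
        logits = (hidden @ p["W_head"] + p["b_head"]).reshape(self.n_terms, 2)
        probs = ag.log_softmax(logits, axis=1).exp()
        return probs, fmaps

    def loss(self, inputs: dict, y_pairs: np.ndarray, weights: np.ndarray) -> Tensor:
        probs, _ = self.forward(inputs["x"], inputs["a_hat"],
                                inputs.get("h_lm"), inputs.get("mask"))
        logp = probs.clip(EPS_CLIP, 1 - EPS_CLIP).log()
        return -(logp * Tensor(weights[:, None] * y_pairs)).sum()

    def scores(self, inputs: dict) -> np.ndarray:
        probs, _ = self.forward(inputs["x"], inputs["a_hat"],
                                inputs.get("h_lm"), inputs.get("mask"))
        return probs.data[:, 0].copy()


@dataclass
class CNNConfig:
    """DeepGO-style sequence CNN: parallel 1D convolutions of several filter
    lengths over the one-hot sequence, ReLU, global max-pooling, dense
    sigmoid head.  Desk defaults (4 widths x 64 filters); the full-scale
    setting (16 widths x 512 filters) is reachable through these fields."""

    filter_widths: tuple = (8, 16, 24, 32)
    n_filters: int = 64


class CNNModel:
    kind = "cnn"

    def __init__(self, n_terms: int, config: CNNConfig | None = None,
                 n_channels: int = 26, seed: int = 0):
        self.n_terms = n_terms
        self.config = config or CNNConfig()
        rng = np.random.default_rng(seed)
        p: dict[str, Tensor] = {}
        for w in self.config.filter_widths:
            p[f"W_conv{w}"] = Tensor(glorot(rng, w * n_channels,
                                            self.config.n_filters),
                                     requires_grad=True)
            p[f"b_conv{w}"] = Tensor(np.zeros(self.config.n_filters),
                                     requires_grad=True)
        total = len(self.config.filter_widths) * self.config.n_filters
        p["W_head"] = Tensor(glorot(rng, total, n_terms), requires_grad=True)
        p["b_head"] = Tensor(np.zeros(n_terms), requires_grad=True)
        self.params = p
        self.n_channels = n_channels

    def features(self, x: np.ndarray, mask: np.ndarray | None = None) -> Tensor:
        """Global max-pooled convolutional features, shape (widths * filters,)."""
        L = x.shape[0]
        wmax = max(self.config.filter_widths)
        if L < wmax:
            logger.warning("sequence of length %d shorter than the largest "
                           "filter (%d); zero-padding", L, wmax)
            pad = np.zeros((wmax - L, x.shape[1]))
            x = np.vstack([x, pad])
            if mask is not None:
                mask = np.concatenate([mask, np.zeros(wmax - L)])
            L = wmax
        pooled = []
        for w in self.config.filter_widths:
            left = (w - 1) // 2
            right = w - 1 - left
            x_pad = np.vstack([np.zeros((left, x.shape[1])), x,
                               np.zeros((right, x.shape[1]))])
            windows = np.concatenate(
                [x_pad[off:off + L] for off in range(w)], axis=1)
            pre = Tensor(windows) @ self.params[f"W_conv{w}"]
            conv = ag.relu(pre + self.params[f"b_conv{w}"])
            if mask is not None:
                conv = conv * Tensor(np.asarray(mask, dtype=float)[:, None])
            pooled.append(conv.max(axis=0))
        return ag.concatenate(pooled, axis=0)

    def forward(self, x: np.ndarray, mask: np.ndarray | None = None) -> Tensor:
        """Positive-class probability per term, shape (n_terms,)."""
        feats = self.features(x, mask)
        return ag.sigmoid(feats @ self.params["W_head"] + self.params["b_head"])

    def loss(self, inputs: dict, y_pairs: np.ndarray, weights: np.ndarray) -> Tensor:
        probs = self.forward(inputs["x"], inputs.get("mask"))
        p_clip = probs.clip(EPS_CLIP, 1 - EPS_CLIP)
        y_pos = y_pairs[:, 0].astype(float)
        pos = (Tensor(weights * y_pos) * p_clip.log()).sum()
        neg = (Tensor(weights * (1 - y_pos)) * (1.0 - p_clip)
               .clip(EPS_CLIP, 1 - EPS_CLIP).log()).sum()
        return -(pos + neg)

    def scores(self, inputs: dict) -> np.ndarray:
        return self.forward(inputs["x"], inputs.get("mask")).data.copy()


# --------------------------------------------------------------------------
# training
# --------------------------------------------------------------------------

@dataclass
class TrainConfig:
    lr: float = 1e-4
    beta1: float = 0.95
    beta2: float = 0.95
    batch_size: int = 64
    max_epochs: int = 200
    patience: int = 5
    min_epochs: int = 1
    validation_fraction: float = 0.1
    max_grad_norm: float | None = None
    seed: int = 0


@dataclass
class ModelState:
    """A trained model: the model object (parameters restored to the best
    validation checkpoint) plus the training log."""

    model: object
    log: dict = field(default_factory=dict)


def prepare_gcn_inputs(records: list, lm_state=None) -> list:
    """Per-record input dicts for the GCN: one-hot features, normalized
    adjacency, optional frozen LM features."""
    from .features import extract_lm_features, one_hot_encode

    out = []
    for r in records:
        if r.contact_map is None:
            raise ValueError(f"record {r.id} has no contact map")
        d = {"x": one_hot_encode(r.sequence),
             "a_hat": normalize_adjacency(r.contact_map.adjacency)}
        if lm_state is not None:
            d["h_lm"] = extract_lm_features(lm_state, r.sequence)
        out.append(d)
    return out


def prepare_cnn_inputs(records: list) -> list:
    from .features import one_hot_encode

    return [{"x": one_hot_encode(r.sequence)} for r in records]


def _stratified_split(labels: np.ndarray, fraction: float,
                      rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Validation indices covering ~`fraction` of each term's positives
    (rarest terms first), topped up with unassigned proteins."""
    n = labels.shape[0]
    n_val = max(1, int(round(fraction * n)))
    chosen: list[int] = []
    taken = np.zeros(n, dtype=bool)
    counts = labels.sum(axis=0)
    for j in np.argsort(counts):
        if counts[j] < 2:
            continue  # cannot spare a positive for validation
        pos = np.flatnonzero((labels[:, j] == 1) & ~taken)
        want = max(1, int(round(fraction * counts[j]))) - \
            int(labels[chosen, j].sum()) if chosen else \
            max(1, int(round(fraction * counts[j])))
        if want > 0 and len(pos):
            picked = rng.permutation(pos)[:want]
            chosen.extend(int(i) for i in picked)
            taken[picked] = True
        if len(chosen) >= n_val:
            break
    rest = rng.permutation(np.flatnonzero(~taken))
    for i in rest:
        if len(chosen) >= n_val:
            break
        chosen.append(int(i))
        taken[i] = True
    val_idx = np.array(sorted(chosen[:n_val]))
    train_idx = np.flatnonzero(~np.isin(np.arange(n), val_idx))
    return val_idx, train_idx


def _clip_grad_norm(params: dict, max_norm: float) -> None:
    total = np.sqrt(sum(float((p.grad ** 2).sum())
                        for p in params.values() if p.grad is not None))
    if total > max_norm:
        scale = max_norm / total
        for p in params.values():
            if p.grad is not None:
                p.grad *= scale


def train_model(model, inputs: list, labels: np.ndarray, weights: np.ndarray,
                config: TrainConfig | None = None) -> ModelState:
    """Mini-batch Adam training with early stopping.

    ``labels`` is the (N, n_terms) binary matrix; paired indicators and the
    weighted cross-entropy are built internally.  Deterministic given
    ``config.seed``.  Returns the model restored to its best-validation
    checkpoint.
    """
    from .ontology import labels_to_pairs

    config = config or TrainConfig()
    n = len(inputs)
    if n < 2:
        raise ValueError("need at least 2 records to split off validation")
    y_pairs = labels_to_pairs(labels).astype(float)
    rng = np.random.default_rng(config.seed)
    val_idx, train_idx = _stratified_split(labels, config.validation_fraction, rng)
    if not len(train_idx):
        raise ValueError("validation split leaves no training data")

    opt = Adam(model.params, lr=config.lr, beta1=config.beta1, beta2=config.beta2)
    stopper = EarlyStopper(patience=config.patience)
    best_snapshot = clone_params(model.params)
    history: list[dict] = []

    def mean_loss(idx_set) -> float:
        tot = 0.0
        for i in idx_set:
            tot += float(model.loss(inputs[i], y_pairs[i], weights).data)
        return tot / len(idx_set)

    for epoch in range(1, config.max_epochs + 1):
        perm = rng.permutation(train_idx)
        epoch_loss = 0.0
        for start in range(0, len(perm), config.batch_size):
            batch = perm[start:start + config.batch_size]
            opt.zero_grad()
            total = None
            for i in batch:
                li = model.loss(inputs[i], y_pairs[i], weights)
                total = li if total is None else total + li
            total = total / float(len(batch))
            if not np.isfinite(total.data):
                raise RuntimeError(
                    f"training diverged at epoch {epoch}: non-finite loss"
                )
            total.backward()
            if config.max_grad_norm is not None:
                _clip_grad_norm(model.params, config.max_grad_norm)
            opt.step()
            epoch_loss += float(total.data) * len(batch)
        val_loss = mean_loss(val_idx)
        history.append({"epoch": epoch,
                        "train_loss": epoch_loss / len(train_idx),
                        "val_loss": val_loss})
        improved = val_loss < stopper.best
        stop = stopper.update(val_loss)
        if improved:
            best_snapshot = clone_params(model.params)
        if stop and epoch >= config.min_epochs:
            break

    set_params(model.params, best_snapshot)
    return ModelState(model=model, log={
        "history": history,
        "best_epoch": stopper.best_epoch,
        "best_val_loss": stopper.best,
        "stopped_epoch": len(history),
    })


def predict(model, inputs: dict, threshold: float = 0.5
            ) -> tuple[np.ndarray, np.ndarray]:
    """Per-term positive-probability scores and binary calls.

    A call is positive only when the score is strictly above the threshold
    (a score of exactly 0.5 is a negative call)."""
    scores = model.scores(inputs)
    return scores, scores > threshold


def predict_matrix(model, inputs: list) -> np.ndarray:
    """(N, n_terms) score matrix over a list of prepared inputs."""
    return np.stack([model.scores(d) for d in inputs])
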