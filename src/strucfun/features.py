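"""Residue-level input features.

Residues are encoded over a fixed 26-symbol vocabulary (20 standard amino
acids, 5 non-standard codes B/J/O/U/Z, and a gap symbol).  Three feature
pathways are provided:

* plain one-hot encoding X in {0,1}^(L x 26);
* hidden states H^LM of a 2-layer forward LSTM next-residue language model
  (frozen after its own training, used purely as a feature extractor);
* a learnable fused representation ReLU(H^LM W^LM + X W^X + b) that forms
  the input of the first graph-convolution layer and is trained jointly
  with the network.

The language model's full-scale setting (512 hidden units, a ~10M-sequence
domain corpus) is architecture-compatible but the defaults here are desk
scale: 64 hidden units trained on the synthetic corpus.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from . import autograd as ag
from .autograd import Tensor
from .nn import Adam, LSTMLayer, glorot

logger = logging.getLogger(__name__)

#: channel order: 20 standard (alphabetical) + 5 non-standard + gap
VOCAB = "ACDEFGHIKLMNPQRSTVWY" + "BJOUZ" + "-"
VOCAB_INDEX = {ch: i for i, ch in enumerate(VOCAB)}
GAP_INDEX = VOCAB_INDEX["-"]
N_CHANNELS = len(VOCAB)  # 26


def sequence_to_indices(sequence: str) -> np.ndarray:
    """Map a residue string to channel indices; unknown characters map to the
    gap channel (counted in a warning)."""
    idx = np.array([VOCAB_INDEX.get(ch, GAP_INDEX) for ch in sequence.upper()],
                   dtype=np.int64)
    unknown = sum(1 for ch in sequence.upper() if ch not in VOCAB_INDEX)
    if unknown:
        logger.warning("%d character(s) outside the residue vocabulary mapped "
                       "to the gap channel", unknown)
    return idx


def one_hot_encode(sequence: str) -> np.ndarray:
    """One-hot matrix X of shape (L, 26); each row sums to exactly 1."""
    if not sequence:
        raise ValueError("sequence must be non-empty")
    idx = sequence_to_indices(sequence)
    x = np.zeros((len(idx), N_CHANNELS))
    x[np.arange(len(idx)), idx] = 1.0
    return x


@dataclass
class LMConfig:
    hidden: int = 64
    n_layers: int = 2
    epochs: int = 5
    lr: float = 0.001
    batch_size: int = 128
    holdout_fraction: float = 0.1
    seed: int = 0


@dataclass
class LMState:
    """Parameters of the trained (frozen) language model plus its config and
    training log."""

    config: LMConfig
    params: dict = field(default_factory=dict)  # name -> np.ndarray
    log: dict = field(default_factory=dict)

    def to_arrays(self) -> dict:
        return {k: np.array(v, copy=True) for k, v in self.params.items()}


def _init_lm(config: LMConfig, rng: np.random.Generator):
    layers = []
    params: dict[str, Tensor] = {}
    in_dim = N_CHANNELS
    for li in range(config.n_layers):
        layer = LSTMLayer(in_dim, config.hidden, rng, prefix=f"lstm{li}")
        params.update(layer.params)
        layers.append(layer)
        in_dim = config.hidden
    # small-scale output head: near-zero logits at init, so an untrained
    # model scores sequences at ~uniform perplexity (~26)
    params["W_out"] = Tensor(0.01 * glorot(rng, config.hidden, N_CHANNELS),
                             requires_grad=True)
    params["b_out"] = Tensor(np.zeros(N_CHANNELS), requires_grad=True)
    return layers, params


def _lm_forward(layers, params, batch_idx: np.ndarray, return_hidden=False):
    """Forward pass over a (B, T) index batch.  Returns per-step logits
    (list of (B, 26) Tensors) or the top-layer hidden states."""
    B, T = batch_idx.shape
    hidden = layers[0].hidden
    h = [Tensor(np.zeros((B, hidden))) for _ in layers]
    c = [Tensor(np.zeros((B, hidden))) for _ in layers]
    outs = []
    eye = np.eye(N_CHANNELS)
    for t in range(T):
        x = Tensor(eye[batch_idx[:, t]])
        for li, layer in enumerate(layers):
            h[li], c[li] = layer.step(x, h[li], c[li])
            x = h[li]
        outs.append(h[-1] if return_hidden else
                    x @ params["W_out"] + params["b_out"])
    return outs


def _next_residue_loss(layers, params, batch_idx, mask) -> tuple[Tensor, int]:
    """Mean cross-entropy of predicting residue t+1 from positions <= t; the
    final position trains against the gap symbol (end-of-sequence)."""
    B, T = batch_idx.shape
    targets = np.concatenate([batch_idx[:, 1:],
                              np.full((B, 1), GAP_INDEX, dtype=np.int64)], axis=1)
    logits = _lm_forward(layers, params, batch_idx)
    total = None
    eye = np.eye(N_CHANNELS)
    for t in range(T):
        logp = ag.log_softmax(logits[t], axis=1)
        tgt = eye[targets[:, t]] * mask[:, t][:, None]
        step = -(logp * Tensor(tgt)).sum()
        total = step if total is None else total + step
    n = int(mask.sum())
    return total / float(n), n


def _batches(seqs: list[np.ndarray], batch_size: int, rng=None):
    order = np.arange(len(seqs))
    if rng is not None:
        rng.shuffle(order)
    for start in range(0, len(order), batch_size):
        chunk = [seqs[i] for i in order[start:start + batch_size]]
        T = max(len(s) for s in chunk)
        idx = np.full((len(chunk), T), GAP_INDEX, dtype=np.int64)
        mask = np.zeros((len(chunk), T))
        for r, s in enumerate(chunk):
            idx[r, :len(s)] = s
            mask[r, :len(s)] = 1.0
        yield idx, mask


def _corpus_ce(layers, params, seqs, batch_size) -> float:
    tot, n = 0.0, 0
    for idx, mask in _batches(seqs, batch_size):
        loss, cnt = _next_residue_loss(layers, params, idx, mask)
        tot += float(loss.data) * cnt
        n += cnt
    return tot / n


def train_language_model(sequences: list[str], config: LMConfig | None = None
                         ) -> LMState:
    """Train the next-residue LSTM language model.

    Deterministic given ``config.seed``.  The training log records held-out
    cross-entropy before and after training (natural log; perplexity is its
    exponential).
    """
    config = config or LMConfig()
    if len(sequences) < config.batch_size:
        raise ValueError(
            f"corpus of {len(sequences)} sequences is shorter than one batch "
            f"({config.batch_size}); reduce batch_size"
        )
    rng = np.random.default_rng(config.seed)
    encoded = [sequence_to_indices(s) for s in sequences]
    order = rng.permutation(len(encoded))
    n_hold = max(1, int(round(config.holdout_fraction * len(encoded))))
    hold = [encoded[i] for i in order[:n_hold]]
    train = [encoded[i] for i in order[n_hold:]]
    if not train:
        raise ValueError("corpus too small to leave a training split")

    layers, params = _init_lm(config, rng)
    opt = Adam(params, lr=config.lr, beta1=0.9, beta2=0.999)
    ce_before = _corpus_ce(layers, params, hold, config.batch_size)
    history = []
    for epoch in range(config.epochs):
        for idx, mask in _batches(train, config.batch_size, rng=rng):
            opt.zero_grad()
            loss, _ = _next_residue_loss(layers, params, idx, mask)
            loss.backward()
            opt.step()
        history.append(_corpus_ce(layers, params, hold, config.batch_size))
    state = LMState(config=config,
                    params={k: np.array(v.data, copy=True)
                            for k, v in params.items()},
                    log={"holdout_ce_before": ce_before,
                         "holdout_ce_by_epoch": history,
                         "holdout_ce_after": history[-1]})
    return state


def _rebuild(lm: LMState):
    rng = np.random.default_rng(0)  # shapes only; weights overwritten
    layers, params = _init_lm(lm.config, rng)
    for k, t in params.items():
        t.data = np.array(lm.params[k], copy=True)
        t.requires_grad = False
    return layers, params


def perplexity(lm: LMState, sequences: list[str]) -> float:
    """Corpus perplexity exp(mean next-residue cross-entropy)."""
    layers, params = _rebuild(lm)
    seqs = [sequence_to_indices(s) for s in sequences]
    return float(np.exp(_corpus_ce(layers, params, seqs, lm.config.batch_size)))


def extract_lm_features(lm: LMState, sequence: str) -> np.ndarray:
    """Top-layer hidden states, one row per residue: row i is the state after
    consuming residues 1..i (forward-only, so features of a prefix equal the
    prefix of the features).  No gradient flows into the language model."""
    layers, params = _rebuild(lm)
    idx = sequence_to_indices(sequence)[None, :]
    outs = _lm_forward(layers, params, idx, return_hidden=True)
    return np.stack([o.data[0] for o in outs])


def fuse_features(h_lm: np.ndarray | None, x: np.ndarray, w_lm: np.ndarray | None,
                  w_x: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Learnable fusion H^input = ReLU(H^LM W^LM + X W^X + b).

    With the language-model pathway disabled (``h_lm`` is None) the first
    term is omitted (the one-hot baseline).
    """
    x = np.asarray(x)
    pre = x @ w_x + b
    if h_lm is not None:
        h_lm = np.asarray(h_lm)
        if h_lm.shape[0] != x.shape[0]:
            raise ValueError(
                f"row mismatch: H^LM has {h_lm.shape[0]} rows, X has {x.shape[0]}"
            )
        pre = pre + h_lm @ w_lm
    return np.maximum(pre, 0.0)
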