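"""Bimodal convolution + context-attention network architecture.

Two input streams — receptor and epitope — are embedded, passed through
parallel 1-D convolution channels of varying kernel size (plus a residual
channel that forwards the raw embeddings), and coupled by *context
attention*: for each channel, attention weights over one stream's positions
are computed conditioned on the other stream,

    u = tanh(X1 W1 + W3 (X2 W2)) v,      alpha = softmax(u),

where X1 (T x H) is the reference, X2 (U x K) the context, and W1 (H x A),
W2 (K x A), W3 (T x U), v (A) are learned; both modalities meet in a common
attention space of dimension A. The attention weights filter the reference
stream (weighted-sum pooling over positions); pooled features of all
channels and both streams are concatenated and pushed through a dense stack
ending in a logistic unit that outputs the binding probability.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

from .autograd import Tensor, bce_with_logits, concat, take_rows, unfold1d
from .encoding import VOCAB_SIZE, EmbeddingSpec

__all__ = ["ModelConfig", "AttentionParams", "AttentionMap",
           "context_attention", "BimodalAttentionNetwork", "build_model"]


@dataclass
class ModelConfig:
    """All architecture hyperparameters.

    ``kernel_sizes_*`` list the convolution channels; a ``None`` entry is the
    residual channel that passes raw embeddings through. The number of
    channels must match between the streams because attention pairs them
    channel-wise. Convolutions are same-padded so sequence lengths are
    preserved — required for the T x U attention coupling matrix. Filter
    counts per convolution channel default to 32.
    """

    tcr_len: int = 500
    epitope_len: int = 500
    attention_dim: int = 16
    kernel_sizes_tcr: tuple = (3, 5, 11, None)
    kernel_sizes_epitope: tuple = (3, 5, 11, None)
    filters: int = 32
    dense_sizes: tuple = (368, 184)
    dropout: float = 0.5
    tcr_scheme: str = "blosum62"
    epitope_scheme: str = "blosum62"  # AA schemes, or "smiles" (learned)
    learned_dim: int = 32
    smiles_vocab_size: int = 64
    attention_masking: bool = False  # flank/pad tokens attend by default

    def __post_init__(self):
        if len(self.kernel_sizes_tcr) != len(self.kernel_sizes_epitope):
            raise ValueError("streams must have equal channel counts")
        for v in (self.tcr_len, self.epitope_len, self.attention_dim,
                  self.filters, *self.dense_sizes):
            if v <= 0:
                raise ValueError("all sizes must be positive")

    @classmethod
    def base(cls, **overrides) -> "ModelConfig":
        """Default configuration: kernels 3/5/11 + residual, A=16,
        dense 368/184, inputs padded to 500."""
        return cls(**overrides)

    @classmethod
    def pretrain(cls, **overrides) -> "ModelConfig":
        """Enlarged configuration for compound-protein pretraining:
        receptor length 1028, A=256, four convolution channels
        (no residual), dense 2048/1024/512."""
        params = dict(
            tcr_len=1028, epitope_len=500, attention_dim=256,
            kernel_sizes_tcr=(3, 7, 13, 19),
            kernel_sizes_epitope=(3, 7, 9, 13),
            dense_sizes=(2048, 1024, 512),
            epitope_scheme="smiles",
        )
        params.update(overrides)
        return cls(**params)

    @classmethod
    def reduced(cls, tcr_len: int = 24, epitope_len: int = 16,
                filters: int = 16, **overrides) -> "ModelConfig":
        """Desk-scale configuration for CPU experiments on short CDR3 /
        epitope sequences; architecture unchanged, lengths and filter
        counts shrunk. Defaults to learned 32-dim embeddings: with few
        filters, exact short motifs separate better in a learned space
        than on substitution-matrix rows.
        """
        params = dict(tcr_len=tcr_len, epitope_len=epitope_len,
                      filters=filters, tcr_scheme="learned",
                      epitope_scheme="learned")
        params.update(overrides)
        return cls(**params)

    def to_json(self) -> str:
        return json.dumps(asdict(self))

    @classmethod
    def from_json(cls, text: str) -> "ModelConfig":
        d = json.loads(text)
        for k in ("kernel_sizes_tcr", "kernel_sizes_epitope", "dense_sizes"):
            d[k] = tuple(d[k])
        return cls(**d)


@dataclass
class AttentionParams:
    """Parameters of one context-attention layer (reference T x H,
    context U x K, attention space A)."""

    W1: np.ndarray  # (H, A)
    W2: np.ndarray  # (K, A)
    W3: np.ndarray  # (T, U)
    v: np.ndarray   # (A,)


@dataclass
class AttentionMap:
    """Per-position attention weights for one (reference, context) pair."""

    alphas: np.ndarray
    context_id: str = ""

    def __post_init__(self):
        s = float(self.alphas.sum())
        if abs(s - 1.0) > 1e-6:
            raise ValueError(f"attention weights sum to {s}, not 1")


def context_attention(X1: np.ndarray, X2: np.ndarray,
                      params: AttentionParams):
    """Apply one context-attention layer to plain arrays.

    Returns (AttentionMap over the T reference positions, filtered reference
    = attention-weighted sum over positions, a length-H vector).
    """
    X1 = np.asarray(X1, dtype=float)
    X2 = np.asarray(X2, dtype=float)
    T, H = X1.shape
    U, K = X2.shape
    for name, got, want in (("W1", params.W1.shape, (H, "A")),
                            ("W2", params.W2.shape, (K, "A")),
                            ("W3", params.W3.shape, (T, U))):
        if got[0] != want[0] or (want[1] != "A" and got[1] != want[1]):
            raise ValueError(f"{name} has shape {got}, inconsistent with "
                             f"inputs T={T}, U={U}, H={H}, K={K}")
    if params.W1.shape[1] != params.W2.shape[1] or \
            params.W1.shape[1] != params.v.reshape(-1).shape[0]:
        raise ValueError("attention-space dimension A disagrees across "
                         "W1/W2/v")
    u = np.tanh(X1 @ params.W1 + params.W3 @ (X2 @ params.W2)) @ params.v.reshape(-1)
    e = np.exp(u - u.max())
    alphas = e / e.sum()
    filtered = alphas @ X1
    return AttentionMap(alphas=alphas), filtered


def build_model(config: ModelConfig, rng_seed: int = 0) -> "BimodalAttentionNetwork":
    return BimodalAttentionNetwork(config, rng_seed=rng_seed)


class BimodalAttentionNetwork:
    """The trainable network; parameters live in a flat name -> Tensor dict.

    Name prefixes define trainability scopes: everything under ``epi.``
    (epitope-stream embedding, convolutions and attention) freezes in
    ``semifrozen`` mode, leaving the receptor stream and the dense stack
    adaptable — the fine-tuning regime that protects pretrained epitope
    (SMILES) feature detectors from being unlearned on small data.
    """

    def __init__(self, config: ModelConfig, rng_seed: int = 0):
        self.config = config
        self.rng_seed = rng_seed
        rng = np.random.default_rng(rng_seed)
        self.params: dict[str, Tensor] = {}
        self._build(rng)
        self.mode = "all"

    # -- construction ------------------------------------------------------

    def _embedding_spec(self, stream: str) -> EmbeddingSpec:
        cfg = self.config
        scheme = cfg.tcr_scheme if stream == "tcr" else cfg.epitope_scheme
        seed = self.rng_seed + (17 if stream == "tcr" else 31)
        if scheme == "smiles":
            return EmbeddingSpec(scheme="learned", dim=cfg.learned_dim,
                                 vocab_size=cfg.smiles_vocab_size, rng_seed=seed)
        if scheme == "learned":
            return EmbeddingSpec(scheme="learned", dim=cfg.learned_dim,
                                 rng_seed=seed)
        return EmbeddingSpec(scheme=scheme, vocab_size=VOCAB_SIZE)

    @staticmethod
    def _glorot(rng, shape):
        fan_in = shape[0] if len(shape) > 1 else shape[0]
        fan_out = shape[-1]
        limit = np.sqrt(6.0 / (fan_in + fan_out))
        return rng.uniform(-limit, limit, size=shape)

    def _param(self, name, array, trainable=True):
        t = Tensor(array, requires_grad=True, name=name)
        t.trainable = trainable
        self.params[name] = t
        return t

    def _build(self, rng):
        cfg = self.config
        specs = {"tcr": self._embedding_spec("tcr"),
                 "epi": self._embedding_spec("epi")}
        self.embedding_specs = specs
        dims = {}
        for s in ("tcr", "epi"):
            self._param(f"{s}.embedding", specs[s].table,
                        trainable=specs[s].trainable)
            dims[s] = specs[s].dim

        lengths = {"tcr": cfg.tcr_len, "epi": cfg.epitope_len}
        kernels = {"tcr": cfg.kernel_sizes_tcr, "epi": cfg.kernel_sizes_epitope}
        chan_dim = {}  # (stream, channel) -> feature dim
        for s in ("tcr", "epi"):
            for ci, k in enumerate(kernels[s]):
                if k is None:
                    chan_dim[s, ci] = dims[s]
                    continue
                chan_dim[s, ci] = cfg.filters
                self._param(f"{s}.conv{ci}.W",
                            self._glorot(rng, (k * dims[s], cfg.filters)))
                self._param(f"{s}.conv{ci}.b", np.zeros(cfg.filters))

        A = cfg.attention_dim
        for s, o in (("tcr", "epi"), ("epi", "tcr")):
            for ci in range(len(kernels[s])):
                self._param(f"{s}.att{ci}.W1",
                            self._glorot(rng, (chan_dim[s, ci], A)))
                self._param(f"{s}.att{ci}.W2",
                            self._glorot(rng, (chan_dim[o, ci], A)))
                self._param(f"{s}.att{ci}.W3",
                            self._glorot(rng, (lengths[s], lengths[o])))
                self._param(f"{s}.att{ci}.v", self._glorot(rng, (A, 1)))

        feat = sum(chan_dim[s, ci] for s in ("tcr", "epi")
                   for ci in range(len(kernels[s])))
        sizes = [feat, *cfg.dense_sizes]
        for j, (a, b) in enumerate(zip(sizes[:-1], sizes[1:])):
            self._param(f"dense{j}.W", self._glorot(rng, (a, b)))
            self._param(f"dense{j}.b", np.zeros(b))
        self._param("out.W", self._glorot(rng, (sizes[-1], 1)))
        self._param("out.b", np.zeros(1))

    # -- scopes ------------------------------------------------------------

    def set_trainable_scopes(self, mode: str) -> "BimodalAttentionNetwork":
        """``all``: every parameter trainable; ``semifrozen``: the epitope
        stream (embedding, convolutions, attention) is frozen."""
        if mode not in ("all", "semifrozen"):
            raise ValueError(f"unknown trainable scope mode {mode!r}")
        for name, p in self.params.items():
            if name in ("tcr.embedding", "epi.embedding"):
                base = self.embedding_specs[name.split(".")[0]].trainable
            else:
                base = True
            frozen = mode == "semifrozen" and name.startswith("epi.")
            p.trainable = base and not frozen
        self.mode = mode
        return self

    def parameters(self) -> list[Tensor]:
        return list(self.params.values())

    @property
    def parameter_count(self) -> int:
        return int(sum(p.data.size for p in self.params.values()))

    # -- forward -----------------------------------------------------------

    def forward(self, tcr_idx: np.ndarray, epi_idx: np.ndarray,
                training: bool = False, dropout_rng=None,
                return_attention: bool = False) -> dict:
        """Run a batch through the network.

        ``tcr_idx`` (B, T) and ``epi_idx`` (B, U) are integer token arrays.
        Returns a dict with ``prob``/``logit`` Tensors and, on request,
        per-channel attention maps for both streams (arrays of shape (B, L)).
        """
        cfg = self.config
        tcr_idx = np.atleast_2d(np.asarray(tcr_idx, dtype=np.int64))
        epi_idx = np.atleast_2d(np.asarray(epi_idx, dtype=np.int64))
        if tcr_idx.shape[1] != cfg.tcr_len:
            raise ValueError(f"TCR token length {tcr_idx.shape[1]} != "
                             f"configured {cfg.tcr_len}")
        if epi_idx.shape[1] != cfg.epitope_len:
            raise ValueError(f"epitope token length {epi_idx.shape[1]} != "
                             f"configured {cfg.epitope_len}")
        if training and cfg.dropout > 0 and dropout_rng is None:
            raise ValueError("training-mode forward needs a dropout rng")

        emb = {"tcr": take_rows(self.params["tcr.embedding"], tcr_idx),
               "epi": take_rows(self.params["epi.embedding"], epi_idx)}
        kernels = {"tcr": cfg.kernel_sizes_tcr, "epi": cfg.kernel_sizes_epitope}

        feats = {}
        for s in ("tcr", "epi"):
            for ci, k in enumerate(kernels[s]):
                if k is None:
                    feats[s, ci] = emb[s]
                else:
                    x = unfold1d(emb[s], k) @ self.params[f"{s}.conv{ci}.W"] \
                        + self.params[f"{s}.conv{ci}.b"]
                    x = x.relu()
                    if training and cfg.dropout > 0:
                        x = x.dropout(cfg.dropout, dropout_rng)
                    feats[s, ci] = x

        pooled, attention = [], {"tcr": [], "epi": []}
        mask = None
        for s, o in (("tcr", "epi"), ("epi", "tcr")):
            for ci in range(len(kernels[s])):
                X1, X2 = feats[s, ci], feats[o, ci]
                p = self.params
                proj = X1 @ p[f"{s}.att{ci}.W1"] \
                    + p[f"{s}.att{ci}.W3"] @ (X2 @ p[f"{s}.att{ci}.W2"])
                B, L = X1.shape[0], X1.shape[1]
                u = (proj.tanh() @ p[f"{s}.att{ci}.v"]).reshape(B, L)
                if cfg.attention_masking:
                    idx = tcr_idx if s == "tcr" else epi_idx
                    mask = np.where(idx > 1, 0.0, -1e9)
                    u = u + Tensor(mask)
                alpha = u.softmax(axis=-1)
                pooled.append((alpha.reshape(B, L, 1) * X1).sum(axis=1))
                if return_attention:
                    attention[s].append(alpha.data.copy())

        h = concat(pooled, axis=-1)
        for j in range(len(cfg.dense_sizes)):
            h = (h @ self.params[f"dense{j}.W"] + self.params[f"dense{j}.b"]).relu()
            if training and cfg.dropout > 0:
                h = h.dropout(cfg.dropout, dropout_rng)
        logit = h @ self.params["out.W"] + self.params["out.b"]
        out = {"logit": logit, "prob": logit.sigmoid()}
        if return_attention:
            out["attention"] = attention
        return out

    def loss(self, tcr_idx, epi_idx, labels, training=True, dropout_rng=None):
        out = self.forward(tcr_idx, epi_idx, training=training,
                           dropout_rng=dropout_rng)
        return bce_with_logits(out["logit"], np.asarray(labels, float))

    def predict_proba(self, tcr_idx, epi_idx, batch_size: int = 256) -> np.ndarray:
        """Deterministic evaluation-mode probabilities."""
        tcr_idx = np.atleast_2d(tcr_idx)
        epi_idx = np.atleast_2d(epi_idx)
        probs = []
        for lo in range(0, tcr_idx.shape[0], batch_size):
            out = self.forward(tcr_idx[lo:lo + batch_size],
                               epi_idx[lo:lo + batch_size])
            probs.append(out["prob"].data.reshape(-1))
        return np.concatenate(probs)

    # -- persistence -------------------------------------------------------

    def save(self, path) -> None:
        arrays = {name: p.data for name, p in self.params.items()}
        np.savez(path, __config__=np.frombuffer(
            self.config.to_json().encode(), dtype=np.uint8), **arrays)

    @classmethod
    def load(cls, path) -> "BimodalAttentionNetwork":
        with np.load(path) as data:
            cfg = ModelConfig.from_json(bytes(data["__config__"]).decode())
            net = cls(cfg)
            for name in net.params:
                net.params[name].data = data[name].astype(np.float64)
        return net
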