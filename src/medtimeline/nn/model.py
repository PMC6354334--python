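"""The RNN-CNN relation classifier, its ablations, training and persistence.

Architecture per (entity, TE) pair:

* input layer — each sentence token is the concatenation of a word embedding
  (dim 50) and a position embedding for its signed offset from the target
  token (dim 30); the ten categorical relation features select rows of a
  feature embedding matrix (dim 20 each, Z of width 200);
* LSTM layer — a peephole BiLSTM (50 units per direction) over each sentence;
* CNN layer — sigmoid convolutions of widths 3/5/7 (100 filters each) with
  max-pooling give the sentence representation C;
* output layer — softmax over [C_M, C_T, Z] yields the probabilities of
  NONE / SIMULTANEOUS / BEFORE / AFTER.

The ``cnn`` variant convolves the input representations directly (no LSTM);
the ``rnn`` variant uses the concatenated final forward/backward LSTM states
as the sentence representation (no CNN).  Both sentence branches share one
set of encoder weights.  Training is plain mini-batch SGD on the mean
cross-entropy, with dropout on [C_M, C_T, Z] only.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from ..corpus import Relation
from ..features import CategoryTables
from . import layers
from .encoding import (
    PAD_ID,
    PairEncoder,
    SentenceEncoding,
    Vocabulary,
    batch_arrays,
)

#: fixed class order of the probability vector Y
RELATIONS = (Relation.NONE, Relation.SIMULTANEOUS, Relation.BEFORE, Relation.AFTER)
RELATION_TO_LABEL = {rel: i for i, rel in enumerate(RELATIONS)}

VARIANTS = ("rnn-cnn", "cnn", "rnn")
_VARIANT_ALIASES = {"cnn-only": "cnn", "rnn-only": "rnn"}


@dataclass
class ModelConfig:
    """Hyper-parameters; the defaults are the reference configuration."""

    word_dim: int = 50
    position_dim: int = 30
    feature_dim: int = 20
    lstm_units: int = 50
    filter_widths: tuple[int, ...] = (3, 5, 7)
    filters_per_width: int = 100
    max_len: int = 100
    dropout: float = 0.5
    batch_size: int = 32
    epochs: int = 20
    learning_rate: float = 0.1  # not part of the reference table; constant SGD
    variant: str = "rnn-cnn"
    n_features: int = 10

    def __post_init__(self) -> None:
        self.variant = _VARIANT_ALIASES.get(self.variant, self.variant)
        if self.variant not in VARIANTS:
            raise ValueError(f"unknown variant {self.variant!r}; use one of {VARIANTS}")
        self.filter_widths = tuple(int(w) for w in self.filter_widths)

    @property
    def input_dim(self) -> int:
        return self.word_dim + self.position_dim

    @property
    def sentence_rep_dim(self) -> int:
        if self.variant == "rnn":
            return 2 * self.lstm_units
        return len(self.filter_widths) * self.filters_per_width

    def to_dict(self) -> dict:
        doc = asdict(self)
        doc["filter_widths"] = list(self.filter_widths)
        return doc

    @classmethod
    def from_dict(cls, doc: dict) -> "ModelConfig":
        doc = dict(doc)
        doc["filter_widths"] = tuple(doc["filter_widths"])
        return cls(**doc)


@dataclass
class EncodedPair:
    """Numeric form of one candidate pair."""

    me: SentenceEncoding
    te: SentenceEncoding
    features: np.ndarray  # (n_features,) int row indices into E_g
    label: Optional[int] = None


def _uniform(rng: np.random.Generator, shape, dtype) -> np.ndarray:
    return rng.uniform(-1.0, 1.0, size=shape).astype(dtype)


def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int, shape, dtype):
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape).astype(dtype)


class RelationClassifier:
    """Holds parameters, vocabulary and category tables; predicts Y per pair."""

    def __init__(
        self,
        config: ModelConfig,
        encoder: PairEncoder,
        tables: CategoryTables,
        params: dict[str, np.ndarray] | None = None,
        seed: int = 0,
        dtype=np.float32,
        pretrained: dict[str, np.ndarray] | None = None,
    ):
        self.config = config
        self.encoder = encoder
        self.tables = tables
        self.dtype = np.dtype(dtype)
        self._rng = np.random.default_rng(seed)
        self.params = params if params is not None else self._init_params(pretrained)

    # ------------------------------------------------------------------ setup
    def _init_params(self, pretrained) -> dict[str, np.ndarray]:
        cfg = self.config
        rng = self._rng
        dt = self.dtype
        V = len(self.encoder.vocab)
        p: dict[str, np.ndarray] = {}
        p["E_w"] = _uniform(rng, (V, cfg.word_dim), dt)
        if pretrained:
            for token, row in pretrained.items():
                idx = self.encoder.vocab.index.get(token)
                if idx is not None and len(row) == cfg.word_dim:
                    p["E_w"][idx] = np.asarray(row, dtype=dt)
        p["E_w"][PAD_ID] = 0.0
        if V > 2:
            p["E_w"][1] = p["E_w"][2:].mean(axis=0)  # UNK = mean word vector
        p["E_d"] = _uniform(rng, (self.encoder.n_position_rows, cfg.position_dim), dt)
        p["E_d"][self.encoder.pad_position_row] = 0.0
        p["E_g"] = _uniform(rng, (self.tables.total_size, cfg.feature_dim), dt)

        D, H = cfg.input_dim, cfg.lstm_units
        if cfg.variant in ("rnn-cnn", "rnn"):
            for direction in ("f", "b"):
                p[f"lstm_{direction}_Wx"] = _glorot(rng, D, H, (D, 4 * H), dt)
                p[f"lstm_{direction}_Wh"] = _glorot(rng, H, H, (H, 4 * H), dt)
                for peep in ("Wci", "Wcf", "Wco"):
                    p[f"lstm_{direction}_{peep}"] = _glorot(rng, H, H, (H, H), dt)
                p[f"lstm_{direction}_b"] = np.zeros(4 * H, dtype=dt)
        if cfg.variant in ("rnn-cnn", "cnn"):
            d = 2 * H if cfg.variant == "rnn-cnn" else D
            L = cfg.filters_per_width
            for k in cfg.filter_widths:
                p[f"conv_k{k}_W"] = _glorot(rng, k * d, L, (k * d, L), dt)
                p[f"conv_k{k}_b"] = np.zeros(L, dtype=dt)
        F = 2 * cfg.sentence_rep_dim + cfg.n_features * cfg.feature_dim
        p["out_W"] = _glorot(rng, F, len(RELATIONS), (F, len(RELATIONS)), dt)
        p["out_b"] = np.zeros(len(RELATIONS), dtype=dt)
        return p

    # ---------------------------------------------------------------- batches
    def _assemble(self, pairs: Sequence[EncodedPair]):
        """Stack the ME and TE sentences of a batch into one 2B array set.

        Rows 0..B-1 are the entity sentences, rows B..2B-1 the TE sentences;
        both branches share the encoder weights, so they run as one batch.
        """
        cfg = self.config
        min_len = max(cfg.filter_widths) if cfg.variant != "rnn" else 1
        enc = self.encoder
        both = batch_arrays(
            [p.me for p in pairs] + [p.te for p in pairs],
            enc.pad_position_row, enc.max_len - 1, min_len,
        )
        feats = np.stack([p.features for p in pairs])
        labels = None
        if all(p.label is not None for p in pairs):
            labels = np.array([p.label for p in pairs], dtype=np.int64)
        return both, feats, labels

    # ---------------------------------------------------------------- forward
    def _branch_forward(self, ids, pos, mask, lens):
        cfg, p = self.config, self.params
        mask = mask.astype(self.dtype, copy=False)
        Xw = p["E_w"][ids]
        Xd = p["E_d"][pos]
        X = np.concatenate([Xw, Xd], axis=2)
        cache: dict = {"ids": ids, "pos": pos, "mask": mask, "lens": lens, "X": X}
        if cfg.variant == "rnn-cnn":
            H, finals, lstm_caches = layers.bilstm_forward(X, mask, p, "lstm")
            cache["lstm"] = lstm_caches
            pooled = []
            cache["conv"] = {}
            for k in cfg.filter_widths:
                pool_k, conv_cache = layers.conv_maxpool_forward(
                    H, lens, p[f"conv_k{k}_W"], p[f"conv_k{k}_b"], k
                )
                pooled.append(pool_k)
                cache["conv"][k] = conv_cache
            cache["H_shape"] = H.shape
            rep = np.concatenate(pooled, axis=1)
        elif cfg.variant == "cnn":
            pooled = []
            cache["conv"] = {}
            for k in cfg.filter_widths:
                pool_k, conv_cache = layers.conv_maxpool_forward(
                    X, lens, p[f"conv_k{k}_W"], p[f"conv_k{k}_b"], k
                )
                pooled.append(pool_k)
                cache["conv"][k] = conv_cache
            rep = np.concatenate(pooled, axis=1)
        else:  # rnn
            H, finals, lstm_caches = layers.bilstm_forward(X, mask, p, "lstm")
            cache["lstm"] = lstm_caches
            cache["H_shape"] = H.shape
            rep = np.concatenate(finals, axis=1)
        return rep, cache

    def _branch_backward(self, drep, cache, grads):
        cfg, p = self.config, self.params
        if cfg.variant == "rnn-cnn":
            dH = np.zeros(cache["H_shape"], dtype=self.dtype)
            L = cfg.filters_per_width
            for i, k in enumerate(cfg.filter_widths):
                dpool = drep[:, i * L : (i + 1) * L]
                dH_k, dW, db = layers.conv_maxpool_backward(
                    dpool, cache["conv"][k], p[f"conv_k{k}_W"]
                )
                dH += dH_k
                grads[f"conv_k{k}_W"] += dW
                grads[f"conv_k{k}_b"] += db
            dX, lstm_grads = layers.bilstm_backward(
                dH, None, cache["lstm"], p, "lstm"
            )
            for key, val in lstm_grads.items():
                grads[key] += val
        elif cfg.variant == "cnn":
            dX = np.zeros_like(cache["X"])
            L = cfg.filters_per_width
            for i, k in enumerate(cfg.filter_widths):
                dpool = drep[:, i * L : (i + 1) * L]
                dX_k, dW, db = layers.conv_maxpool_backward(
                    dpool, cache["conv"][k], p[f"conv_k{k}_W"]
                )
                dX += dX_k
                grads[f"conv_k{k}_W"] += dW
                grads[f"conv_k{k}_b"] += db
        else:  # rnn
            H_units = cfg.lstm_units
            dH = np.zeros(cache["H_shape"], dtype=self.dtype)
            dfinals = (drep[:, :H_units], drep[:, H_units:])
            dX, lstm_grads = layers.bilstm_backward(
                dH, dfinals, cache["lstm"], p, "lstm"
            )
            for key, val in lstm_grads.items():
                grads[key] += val
        wd = cfg.word_dim
        np.add.at(grads["E_w"], cache["ids"].ravel(),
                  dX[:, :, :wd].reshape(-1, wd))
        np.add.at(grads["E_d"], cache["pos"].ravel(),
                  dX[:, :, wd:].reshape(-1, cfg.position_dim))

    def _forward(self, both, feats, train: bool):
        cfg, params = self.config, self.params
        rep, cache_B = self._branch_forward(*both)
        B = rep.shape[0] // 2
        rep_M, rep_T = rep[:B], rep[B:]
        Z = params["E_g"][feats].reshape(B, -1).astype(self.dtype)
        A = np.concatenate([rep_M, rep_T, Z], axis=1)
        drop_mask = None
        if train and cfg.dropout > 0.0:
            keep = 1.0 - cfg.dropout
            drop_mask = (
                self._rng.random(A.shape) < keep
            ).astype(self.dtype) / keep
            A_used = A * drop_mask
        else:
            A_used = A
        probs = layers.output_forward(A_used, params["out_W"], params["out_b"])
        cache = {
            "branch": cache_B, "A_used": A_used,
            "drop_mask": drop_mask, "Z_feats": feats,
            "rep_dim": rep_M.shape[1],
        }
        return probs, cache

    # ----------------------------------------------------------------- public
    def predict_proba(self, pairs: Sequence[EncodedPair], batch_size: int = 256):
        """Probability vectors Y (rows sum to 1) in the fixed class order."""
        out = np.empty((len(pairs), len(RELATIONS)), dtype=self.dtype)
        for lo in range(0, len(pairs), batch_size):
            chunk = pairs[lo : lo + batch_size]
            both, feats, _ = self._assemble(chunk)
            probs, _ = self._forward(both, feats, train=False)
            out[lo : lo + len(chunk)] = probs
        return out

    def loss(self, pairs: Sequence[EncodedPair]) -> float:
        both, feats, labels = self._assemble(pairs)
        if labels is None:
            raise ValueError("loss needs labeled pairs")
        probs, _ = self._forward(both, feats, train=False)
        return layers.cross_entropy(probs, labels)

    def loss_and_grads(self, pairs: Sequence[EncodedPair], train: bool = True):
        both, feats, labels = self._assemble(pairs)
        if labels is None:
            raise ValueError("training needs labeled pairs")
        probs, cache = self._forward(both, feats, train=train)
        loss = layers.cross_entropy(probs, labels)
        grads = {key: np.zeros_like(val) for key, val in self.params.items()}
        dA, dWo, dbo = layers.output_backward(
            cache["A_used"], probs, labels, self.params["out_W"]
        )
        grads["out_W"] += dWo
        grads["out_b"] += dbo
        if cache["drop_mask"] is not None:
            dA = dA * cache["drop_mask"]
        R = cache["rep_dim"]
        drep_M, drep_T, dZ = dA[:, :R], dA[:, R : 2 * R], dA[:, 2 * R :]
        B = len(pairs)
        dZ = dZ.reshape(B, self.config.n_features, self.config.feature_dim)
        np.add.at(grads["E_g"], cache["Z_feats"].ravel(),
                  dZ.reshape(-1, self.config.feature_dim))
        drep = np.concatenate([drep_M, drep_T], axis=0)
        self._branch_backward(drep, cache["branch"], grads)
        # PAD rows are frozen at zero
        grads["E_w"][PAD_ID] = 0.0
        grads["E_d"][self.encoder.pad_position_row] = 0.0
        return loss, grads

    def sgd_step(self, pairs: Sequence[EncodedPair], lr: float) -> float:
        loss, grads = self.loss_and_grads(pairs, train=True)
        for key, grad in grads.items():
            self.params[key] -= lr * grad
        return loss

    # ------------------------------------------------------------ persistence
    def save(self, model_dir) -> None:
        model_dir = Path(model_dir)
        model_dir.mkdir(parents=True, exist_ok=True)
        np.savez(model_dir / "params.npz", **self.params)
        (model_dir / "config.json").write_text(
            json.dumps(
                {
                    "config": self.config.to_dict(),
                    "dtype": self.dtype.name,
                    "max_len": self.encoder.max_len,
                },
                indent=2,
            ),
            encoding="utf-8",
        )
        (model_dir / "vocab.json").write_text(
            json.dumps(self.encoder.vocab.to_dict(), ensure_ascii=False),
            encoding="utf-8",
        )
        (model_dir / "tables.json").write_text(
            json.dumps(self.tables.to_dict(), ensure_ascii=False),
            encoding="utf-8",
        )

    @classmethod
    def load(cls, model_dir) -> "RelationClassifier":
        model_dir = Path(model_dir)
        meta = json.loads((model_dir / "config.json").read_text(encoding="utf-8"))
        config = ModelConfig.from_dict(meta["config"])
        vocab = Vocabulary.from_dict(
            json.loads((model_dir / "vocab.json").read_text(encoding="utf-8"))
        )
        tables = CategoryTables.from_dict(
            json.loads((model_dir / "tables.json").read_text(encoding="utf-8"))
        )
        encoder = PairEncoder(vocab, max_len=meta["max_len"])
        with np.load(model_dir / "params.npz") as npz:
            params = {key: npz[key] for key in npz.files}
        return cls(config=config, encoder=encoder, tables=tables, params=params,
                   dtype=np.dtype(meta["dtype"]))


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------


@dataclass
class TrainLog:
    epoch_losses: list[float] = field(default_factory=list)


def train_model(
    model: RelationClassifier,
    pairs: Sequence[EncodedPair],
    seed: int = 0,
    verbose: bool = False,
) -> TrainLog:
    """Mini-batch SGD on mean cross-entropy; deterministic under one seed."""
    if not pairs:
        raise ValueError("training needs a non-empty pair set")
    for pair in pairs:
        if pair.label is None or not 0 <= pair.label < len(RELATIONS):
            raise ValueError("every training pair needs a label in the 4-class set")
    cfg = model.config
    rng = np.random.default_rng(seed)
    model._rng = np.random.default_rng(rng.integers(0, 2**31 - 1))
    # batches are drawn from shuffled, loosely length-sorted pairs so padding
    # inside a batch stays short; batch order is reshuffled every epoch
    lengths = np.array(
        [max(len(p.me.token_ids), len(p.te.token_ids)) for p in pairs]
    )
    log = TrainLog()
    for epoch in range(cfg.epochs):
        perm = rng.permutation(len(pairs))
        perm = perm[np.argsort(lengths[perm] // 4, kind="stable")]
        starts = np.arange(0, len(perm), cfg.batch_size)
        rng.shuffle(starts)
        total, count = 0.0, 0
        for lo in starts:
            batch = [pairs[i] for i in perm[lo : lo + cfg.batch_size]]
            total += model.sgd_step(batch, cfg.learning_rate) * len(batch)
            count += len(batch)
        log.epoch_losses.append(total / count)
        if verbose:
            print(f"epoch {epoch + 1:3d}  loss {log.epoch_losses[-1]:.4f}")
    return log
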