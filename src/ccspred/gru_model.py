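"""Residual CCS predictor: token embedding, two bidirectional GRU layers and
a charge-aware dense head on top of a frozen square-root baseline.

The model realizes the two-stage decomposition

    ccs_final(mz, c, s) = ccs_init(mz, c) + M(s, c, θ)

where ccs_init is the per-charge square-root projection (fit a priori and
kept frozen: its parameters are never updated by the optimizer) and M is a
recurrent network over the peptide token sequence s with the charge state
injected into the dense head as a one-hot indicator. Training minimizes mean
absolute error with Adam, reduces the learning rate tenfold after a
three-epoch validation plateau and stops after three further epochs without
improvement, returning the best-validation weights.
"""

from __future__ import annotations

import copy
import json
from dataclasses import dataclass, field, asdict

import numpy as np

from . import nn
from .baseline_model import SqrtFitParams, predict_init
from .chem import TokenVocab, default_vocab
from .io_formats import Dataset


@dataclass
class ModelConfig:
    embedding_dim: int = 128
    gru_units: tuple[int, int] = (128, 128)  # per direction, two layers
    dense_units: tuple[int, int] = (128, 64)
    dropout: float = 0.2
    max_charge: int = 4
    seed: int = 0

    def __post_init__(self):
        if min(self.embedding_dim, *self.gru_units, *self.dense_units) < 1:
            raise ValueError("all layer dimensions must be >= 1")
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must be in [0, 1)")


@dataclass
class TrainConfig:
    learning_rate: float = 1e-3
    batch_size: int = 128
    max_epochs: int = 100
    plateau_patience: int = 3  # epochs without val improvement before lr / 10
    stop_patience: int = 3  # further epochs without improvement before stop
    lr_factor: float = 0.1
    seed: int = 0

    def __post_init__(self):
        if self.plateau_patience < 1 or self.stop_patience < 1:
            raise ValueError("patience values must be >= 1")


class PredictionError(ValueError):
    """Raised when rows cannot be predicted (e.g. charge above max_charge)."""


class CcsModel:
    """Trainable residual network plus frozen baseline parameters."""

    def __init__(self, vocab: TokenVocab, baseline: SqrtFitParams, config: ModelConfig):
        self.vocab = vocab
        self.baseline = baseline  # frozen; not part of the optimizer's params
        self.config = config
        rng = np.random.default_rng(config.seed)
        if len(vocab) > 64:
            raise ValueError("vocabulary larger than embedding table limit")
        u1, u2 = config.gru_units
        d1, d2 = config.dense_units
        self.embedding = nn.Embedding(len(vocab), config.embedding_dim, rng)
        self.gru1 = nn.BiGRU(config.embedding_dim, u1, rng)
        self.gru2 = nn.BiGRU(2 * u1, u2, rng)
        self.dense1 = nn.Dense(2 * u2 + config.max_charge, d1, rng, activation="relu")
        self.dropout = nn.Dropout(config.dropout)
        self.dense2 = nn.Dense(d1, d2, rng, activation="relu")
        self.out = nn.Dense(d2, 1, rng, activation="linear")
        self._layers = [
            self.embedding,
            self.gru1,
            self.gru2,
            self.dense1,
            self.dense2,
            self.out,
        ]

    # ------------------------------------------------------------------
    @property
    def param_count(self) -> int:
        return sum(layer.param_count for layer in self._layers)

    def _param_pairs(self):
        for layer in self._layers:
            for name in layer.params:
                yield layer.params[name], layer.grads[name]

    def zero_grad(self):
        for layer in self._layers:
            layer.zero_grad()

    def get_weights(self) -> list[np.ndarray]:
        return [copy.deepcopy(layer.params[k]) for layer in self._layers for k in sorted(layer.params)]

    def set_weights(self, weights: list[np.ndarray]):
        i = 0
        for layer in self._layers:
            for k in sorted(layer.params):
                layer.params[k][...] = weights[i]
                i += 1

    def zero_residual(self):
        """Zero the output layer so the model reproduces the baseline exactly."""
        self.out.params["W"][...] = 0.0
        self.out.params["b"][...] = 0.0

    # ------------------------------------------------------------------
    def _encode_batch(self, sequences: list[str]) -> tuple[np.ndarray, np.ndarray]:
        ids = [self.vocab.encode(s) for s in sequences]
        T = max(len(x) for x in ids)
        arr = np.zeros((len(ids), T), dtype=np.int64)
        for i, x in enumerate(ids):
            arr[i, : len(x)] = x
        mask = (arr != 0).astype(float)
        return arr, mask

    def _charge_onehot(self, charges: np.ndarray) -> np.ndarray:
        onehot = np.zeros((len(charges), self.config.max_charge))
        onehot[np.arange(len(charges)), charges - 1] = 1.0
        return onehot

    def forward_residual(
        self, sequences: list[str], charges: np.ndarray, dropout_rng=None
    ) -> np.ndarray:
        """Sequence-specific residual M(s, c, θ) for a batch; (n,) array."""
        ids, mask = self._encode_batch(sequences)
        x = self.embedding.forward(ids)
        h1 = self.gru1.forward(x, mask, return_sequences=True)
        h2 = self.gru2.forward(h1, mask, return_sequences=False)
        feats = np.concatenate([h2, self._charge_onehot(charges)], axis=1)
        a1 = self.dense1.forward(feats)
        a1 = self.dropout.forward(a1, dropout_rng)
        a2 = self.dense2.forward(a1)
        out = self.out.forward(a2)
        self._ids = ids
        return out[:, 0]

    def backward(self, dresidual: np.ndarray):
        dout = dresidual[:, None]
        da2 = self.out.backward(dout)
        da1 = self.dense2.backward(da2)
        da1 = self.dropout.backward(da1)
        dfeats = self.dense1.backward(da1)
        dh2 = dfeats[:, : 2 * self.config.gru_units[1]]
        dh1 = self.gru2.backward(dh2)
        dx = self.gru1.backward(dh1)
        self.embedding.backward(self._ids, dx)

    # ------------------------------------------------------------------
    def save(self, prefix: str):
        """Write config JSON, baseline JSON and a weight archive.

        ``prefix`` is a path stem; writes ``<prefix>.config.json``,
        ``<prefix>.baseline.json`` and ``<prefix>.weights.npz`` (arrays keyed
        by layer and parameter name for portability).
        """
        cfg = asdict(self.config)
        cfg["vocab"] = list(self.vocab.tokens)
        with open(f"{prefix}.config.json", "w", encoding="utf-8") as fh:
            json.dump(cfg, fh, indent=2)
        self.baseline.to_json(f"{prefix}.baseline.json")
        arrays = {}
        names = ["embedding", "gru1", "gru2", "dense1", "dense2", "out"]
        for lname, layer in zip(names, self._layers):
            for k, v in layer.params.items():
                arrays[f"{lname}/{k}"] = v
        np.savez(f"{prefix}.weights.npz", **arrays)

    @classmethod
    def load(cls, prefix: str) -> "CcsModel":
        with open(f"{prefix}.config.json", encoding="utf-8") as fh:
            cfg = json.load(fh)
        vocab = TokenVocab(tuple(cfg.pop("vocab")))
        cfg["gru_units"] = tuple(cfg["gru_units"])
        cfg["dense_units"] = tuple(cfg["dense_units"])
        baseline = SqrtFitParams.from_json(f"{prefix}.baseline.json")
        model = cls(vocab, baseline, ModelConfig(**cfg))
        names = ["embedding", "gru1", "gru2", "dense1", "dense2", "out"]
        with np.load(f"{prefix}.weights.npz") as data:
            for lname, layer in zip(names, model._layers):
                for k in layer.params:
                    layer.params[k][...] = data[f"{lname}/{k}"]
        return model


def build_model(
    vocab: TokenVocab | None = None,
    baseline: SqrtFitParams | None = None,
    config: ModelConfig | None = None,
) -> CcsModel:
    """Construct the residual predictor (random init, reproducible by seed)."""
    if baseline is None:
        raise ValueError("a fitted baseline is required")
    return CcsModel(vocab or default_vocab(), baseline, config or ModelConfig())


def hand_param_count(vocab_size: int, cfg: ModelConfig) -> int:
    """Closed-form per-layer weight accounting, independent of the layers."""
    e = cfg.embedding_dim
    u1, u2 = cfg.gru_units
    d1, d2 = cfg.dense_units
    total = vocab_size * e
    total += 2 * 3 * (e * u1 + u1 * u1 + 2 * u1)  # BiGRU 1
    total += 2 * 3 * (2 * u1 * u2 + u2 * u2 + 2 * u2)  # BiGRU 2
    total += (2 * u2 + cfg.max_charge) * d1 + d1
    total += d1 * d2 + d2
    total += d2 * 1 + 1
    return total


def _dataset_arrays(ds: Dataset, model: CcsModel):
    seqs, charges, mzs, ccs = [], [], [], []
    bad = [i for i, r in enumerate(ds.records) if r.charge > model.config.max_charge]
    if bad:
        raise PredictionError(
            f"{len(bad)} rows with charge > {model.config.max_charge}: rows {bad[:10]}"
        )
    for rec in ds.records:
        seqs.append(rec.sequence)
        charges.append(rec.charge)
        mzs.append(rec.mz)
        ccs.append(rec.ccs if rec.ccs is not None else np.nan)
    return seqs, np.array(charges), np.array(mzs), np.array(ccs)


def _baseline_pred(model: CcsModel, charges: np.ndarray, mzs: np.ndarray) -> np.ndarray:
    out = np.empty(len(charges))
    for c in np.unique(charges):
        sel = charges == c
        out[sel] = predict_init(mzs[sel], int(c), model.baseline)
    return out


def _epoch_mae(model: CcsModel, seqs, charges, mzs, ccs, batch_size: int) -> float:
    errs = []
    for lo in range(0, len(seqs), batch_size):
        sl = slice(lo, lo + batch_size)
        res = model.forward_residual(seqs[sl], charges[sl])
        pred = _baseline_pred(model, charges[sl], mzs[sl]) + res
        errs.append(np.abs(pred - ccs[sl]))
    return float(np.mean(np.concatenate(errs)))


def train(
    model: CcsModel, train_ds: Dataset, val_ds: Dataset, cfg: TrainConfig | None = None
) -> tuple[CcsModel, list[dict]]:
    """Fit θ by Adam on MAE; baseline stays frozen.

    Returns the model carrying the best-validation weights and a history of
    per-epoch ``{"epoch", "train_mae", "val_mae", "lr"}`` rows.
    """
    cfg = cfg or TrainConfig()
    if not train_ds.records:
        raise ValueError("empty training set")
    seqs, charges, mzs, ccs = _dataset_arrays(train_ds, model)
    vseqs, vcharges, vmzs, vccs = _dataset_arrays(val_ds, model)
    if np.any(np.isnan(ccs)) or np.any(np.isnan(vccs)):
        raise ValueError("training and validation records must carry CCS")
    base = _baseline_pred(model, charges, mzs)

    rng = np.random.default_rng(cfg.seed)
    optimizer = nn.Adam(model._param_pairs(), lr=cfg.learning_rate)
    baseline_before = json.dumps({c: (model.baseline.w[c], model.baseline.b[c]) for c in model.baseline.charges})

    history: list[dict] = []
    best_val = np.inf
    best_weights = model.get_weights()
    wait = 0
    reduced = False
    n = len(seqs)
    for epoch in range(1, cfg.max_epochs + 1):
        order = rng.permutation(n)
        train_errs = []
        for lo in range(0, n, cfg.batch_size):
            idx = order[lo : lo + cfg.batch_size]
            bseqs = [seqs[i] for i in idx]
            res = model.forward_residual(bseqs, charges[idx], dropout_rng=rng)
            pred = base[idx] + res
            err = pred - ccs[idx]
            train_errs.append(np.abs(err))
            model.zero_grad()
            model.backward(np.sign(err) / len(idx))
            optimizer.step()
        val_mae = _epoch_mae(model, vseqs, vcharges, vmzs, vccs, cfg.batch_size)
        history.append(
            {
                "epoch": epoch,
                "train_mae": float(np.mean(np.concatenate(train_errs))),
                "val_mae": val_mae,
                "lr": optimizer.lr,
            }
        )
        if val_mae < best_val:
            best_val = val_mae
            best_weights = model.get_weights()
            wait = 0
        else:
            wait += 1
            if not reduced and wait >= cfg.plateau_patience:
                optimizer.lr *= cfg.lr_factor
                reduced = True
                wait = 0
            elif reduced and wait >= cfg.stop_patience:
                break

    model.set_weights(best_weights)
    baseline_after = json.dumps({c: (model.baseline.w[c], model.baseline.b[c]) for c in model.baseline.charges})
    assert baseline_before == baseline_after, "frozen baseline was modified"
    return model, history


def predict(model: CcsModel, ions: Dataset, batch_size: int = 256):
    """Predict ccs_final and the residual for every ion.

    Returns (ccs_final, residual) arrays aligned with ``ions.records``.
    """
    seqs, charges, mzs, _ = _dataset_arrays(ions, model)
    for c in np.unique(charges):
        if int(c) not in model.baseline.w:
            raise PredictionError(f"no fitted baseline for charge {int(c)}")
    residual = np.empty(len(seqs))
    for lo in range(0, len(seqs), batch_size):
        sl = slice(lo, lo + batch_size)
        residual[sl] = model.forward_residual(seqs[sl], charges[sl])
    ccs_final = _baseline_pred(model, charges, mzs) + residual
    return ccs_final, residual


def extract_embeddings(model: CcsModel) -> dict[str, np.ndarray]:
    """Learned embedding vector for every vocabulary token."""
    E = model.embedding.params["E"]
    return {tok: E[i].copy() for i, tok in enumerate(model.vocab.tokens)}
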