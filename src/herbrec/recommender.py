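"""Neural collaborative filtering from symptom sets to herb probabilities.

A patient is the mean of the embedding rows of their active symptoms, pushed
through a symptom-branch MLP; every herb is its embedding row pushed through
a herb-branch MLP; the predicted probability of prescribing herb j is the
sigmoid of the dot product of the two branch outputs.  Branch MLPs use ReLU
on hidden layers and a linear final layer by default: ReLU-ending both
branches would restrict every dot product to be nonnegative, flooring all
probabilities at 0.5 and making the dead-network state the cross-entropy
optimum for any herb prescribed in fewer than half the records.  The
ReLU-ended variant remains available via ``final_relu=True``.

Training minimizes
binary cross-entropy against the patient's full herb multi-hot (every herb
is a label; no negative sampling), averaged over herbs and batch, with L2
weight decay.  Embedding tables stay frozen; only the two branches train.

Defaults follow the tuned configuration: 7 dense layers on the symptom
branch, 5 on the herb branch, no dropout, weight decay 1e-3, Adam at 1e-3,
early stopping after 20 epochs without improvement.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .corpus import ClinicalRecord
from .cross_domain import EmbeddingTable
from .nn import Adam, Sequential, sigmoid

__all__ = [
    "RecommenderConfig", "RankedPrescription", "HerbRecommender",
    "patient_embedding", "herb_embeddings", "score", "bce_loss",
    "train_recommender", "recommend", "save_model", "load_model",
]

_EPS = 1e-7


@dataclass(frozen=True)
class RecommenderConfig:
    d: int = 500                 # embedding dimension
    mlp_s_depth: int = 7         # dense layers on the symptom branch
    mlp_h_depth: int = 5         # dense layers on the herb branch
    out_width: int = 128         # shared branch output width
    dropout: float = 0.0
    lam: float = 1e-3            # L2 weight decay
    lr: float = 1e-3
    max_epochs: int = 200
    patience: int = 20
    batch_size: int = 64
    seed: int = 0
    final_relu: bool = False     # ReLU-ended branches (see module docstring)

    def __post_init__(self):
        if self.mlp_s_depth < 1 or self.mlp_h_depth < 1:
            raise ValueError("MLP depths must be >= 1")
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must lie in [0, 1)")
        if self.lam < 0:
            raise ValueError("weight decay must be >= 0")


def _branch_widths(d: int, depth: int, out_width: int) -> list[int]:
    return [d] + [out_width] * depth


def patient_embedding(P_i: np.ndarray, E_s: np.ndarray, mlp_s: Sequential) -> np.ndarray:
    """Mean-pool the active symptom rows of E_s, then apply the symptom MLP.

    ``P_i`` is the patient's multi-hot vector over the symptom vocabulary
    (one entry per E_s row, values in {0, 1}).  The MLP owns its output
    activation (append a ReLU layer for the ReLU-ended variant).
    """
    P_i = np.asarray(P_i)
    if P_i.shape != (E_s.shape[0],):
        raise ValueError(f"multi-hot length {P_i.shape} != vocabulary size {E_s.shape[0]}")
    if not set(np.unique(P_i)) <= {0, 1, False, True}:
        raise ValueError("multi-hot entries must be 0 or 1")
    idx = np.flatnonzero(P_i)
    if idx.size == 0:
        raise ValueError("patient must have at least one active symptom")
    pooled = E_s[idx].mean(axis=0)
    return mlp_s(pooled[None, :])[0]


def herb_embeddings(E_h: np.ndarray, mlp_h: Sequential) -> np.ndarray:
    """Row-wise herb branch: the MLP applied to every embedding row."""
    E_h = np.asarray(E_h, dtype=float)
    if E_h.size == 0:
        raise ValueError("E_h must be nonempty")
    return mlp_h(E_h)


def score(Z_p: np.ndarray, Z_h: np.ndarray) -> np.ndarray:
    """Per-herb probabilities: sigmoid of the patient/herb dot products."""
    Z_p, Z_h = np.asarray(Z_p, dtype=float), np.asarray(Z_h, dtype=float)
    if not (np.isfinite(Z_p).all() and np.isfinite(Z_h).all()):
        raise ValueError("non-finite branch outputs")
    if Z_p.shape[-1] != Z_h.shape[-1]:
        raise ValueError(f"branch widths disagree: {Z_p.shape[-1]} vs {Z_h.shape[-1]}")
    return sigmoid(Z_p @ Z_h.T)


def bce_loss(y: np.ndarray, y_prob: np.ndarray) -> float:
    """Binary cross-entropy, mean over all herb slots (and batch), with
    probabilities clipped to [eps, 1-eps], eps=1e-7."""
    y = np.asarray(y, dtype=float)
    y_prob = np.asarray(y_prob, dtype=float)
    if y.shape != y_prob.shape:
        raise ValueError("label and probability shapes differ")
    p = np.clip(y_prob, _EPS, 1.0 - _EPS)
    return float(-np.mean(y * np.log(p) + (1.0 - y) * np.log(1.0 - p)))


@dataclass
class RankedPrescription:
    probabilities: np.ndarray     # over the full herb vocabulary
    ranked_herbs: list[str]       # top-K terms, descending probability
    ranked_indices: np.ndarray
    K: int


@dataclass
class HerbRecommender:
    """Trained two-branch NCF model over frozen embedding tables."""

    embeddings: EmbeddingTable
    mlp_s: Sequential
    mlp_h: Sequential
    config: RecommenderConfig
    loss_trace: list[float] = field(default_factory=list)

    def __post_init__(self):
        self._s_index = {t: i for i, t in enumerate(self.embeddings.symptom_terms)}

    def predict_proba(self, symptoms: Iterable[str]) -> np.ndarray:
        known = [self._s_index[s] for s in symptoms if s in self._s_index]
        unknown = [s for s in symptoms if s not in self._s_index]
        if unknown:
            warnings.warn(f"dropping {len(unknown)} unknown symptom term(s): {unknown[:5]}")
        if not known:
            raise ValueError("no input symptom is present in the vocabulary")
        hot = np.zeros(len(self.embeddings.symptom_terms))
        hot[known] = 1.0
        z_p = patient_embedding(hot, self.embeddings.E_s, self.mlp_s)
        z_h = herb_embeddings(self.embeddings.E_h, self.mlp_h)
        return score(z_p, z_h)


def recommend(model: HerbRecommender, symptoms: Iterable[str], K: int) -> RankedPrescription:
    """Top-K herbs by descending probability; ties break toward the lower
    vocabulary index, so rankings are deterministic."""
    if K < 1:
        raise ValueError("K must be >= 1")
    probs = model.predict_proba(symptoms)
    n = probs.shape[0]
    order = np.lexsort((np.arange(n), -probs))
    top = order[: min(K, n)]
    return RankedPrescription(
        probabilities=probs,
        ranked_herbs=[model.embeddings.herb_terms[i] for i in top],
        ranked_indices=top,
        K=K,
    )


def _pooled_patients(records: Sequence[ClinicalRecord], table: EmbeddingTable) -> tuple[np.ndarray, np.ndarray]:
    s_index = {t: i for i, t in enumerate(table.symptom_terms)}
    h_index = {t: i for i, t in enumerate(table.herb_terms)}
    X = np.zeros((len(records), table.d))
    Y = np.zeros((len(records), len(table.herb_terms)))
    for r, rec in enumerate(records):
        try:
            sid = [s_index[s] for s in rec.symptoms]
        except KeyError as exc:
            raise KeyError(f"symptom {exc.args[0]!r} missing from E_s") from None
        try:
            hid = [h_index[h] for h in rec.herbs]
        except KeyError as exc:
            raise KeyError(f"herb {exc.args[0]!r} missing from E_h") from None
        X[r] = table.E_s[sid].mean(axis=0)
        Y[r, hid] = 1.0
    return X, Y


def train_recommender(
    records: Sequence[ClinicalRecord],
    embeddings: EmbeddingTable,
    config: RecommenderConfig,
) -> HerbRecommender:
    """Mini-batch Adam on mean BCE over all herbs, embeddings frozen.

    Seeded shuffling makes runs bit-reproducible; early stopping restores the
    best branch weights seen, and the recorded loss trace is the per-epoch
    mean training loss.
    """
    if len(records) == 0:
        raise ValueError("training set must be nonempty")
    rng = np.random.default_rng(config.seed)
    d = embeddings.d
    mlp_s = Sequential.mlp(rng, _branch_widths(d, config.mlp_s_depth, config.out_width),
                           final_relu=config.final_relu)
    mlp_h = Sequential.mlp(rng, _branch_widths(d, config.mlp_h_depth, config.out_width),
                           final_relu=config.final_relu)
    model = HerbRecommender(embeddings, mlp_s, mlp_h, config)
    if config.max_epochs == 0:
        return model
    X, Y = _pooled_patients(records, embeddings)
    E_h = embeddings.E_h
    n, n_h = Y.shape
    opt = Adam(mlp_s.params() + mlp_h.params(), lr=config.lr)
    best_loss = np.inf
    best_state = None
    stall = 0
    for _ in range(config.max_epochs):
        perm = rng.permutation(n)
        epoch_loss = 0.0
        for start in range(0, n, config.batch_size):
            idx = perm[start:start + config.batch_size]
            xb, yb = X[idx], Y[idx]
            eh = E_h
            if config.dropout > 0.0:
                keep = 1.0 - config.dropout
                xb = xb * rng.binomial(1, keep, xb.shape) / keep
                eh = eh * rng.binomial(1, keep, eh.shape) / keep
            mlp_s.zero_grad(); mlp_h.zero_grad()
            z_p = mlp_s(xb)
            z_h = mlp_h(eh)
            logits = z_p @ z_h.T
            p = sigmoid(logits)
            pc = np.clip(p, _EPS, 1.0 - _EPS)
            batch_loss = float(-np.mean(yb * np.log(pc) + (1 - yb) * np.log(1 - pc)))
            if not np.isfinite(batch_loss):
                raise RuntimeError("non-finite recommender loss; lower lr")
            epoch_loss += batch_loss * len(idx)
            d_logits = (p - yb) / (len(idx) * n_h)
            mlp_s.backward(d_logits @ z_h)
            mlp_h.backward(d_logits.T @ z_p)
            opt.step(mlp_s.grads() + mlp_h.grads(), weight_decay=config.lam)
        epoch_loss /= n
        model.loss_trace.append(epoch_loss)
        if epoch_loss < best_loss - 1e-12:
            best_loss = epoch_loss
            best_state = (mlp_s.get_state(), mlp_h.get_state())
            stall = 0
        else:
            stall += 1
            if stall >= config.patience:
                break
    if best_state is not None:
        mlp_s.set_state(best_state[0])
        mlp_h.set_state(best_state[1])
    return model


# ---------------------------------------------------------------------------
# Checkpointing (single JSON file; refuses a mismatched vocabulary)


def _vocab_hash(terms: Sequence[str]) -> str:
    h = hashlib.sha256()
    for t in terms:
        h.update(t.encode("utf-8"))
        h.update(b"\x00")
    return h.hexdigest()


def save_model(model: HerbRecommender, path: str | Path) -> None:
    emb = model.embeddings
    blob = {
        "config": asdict(model.config),
        "symptom_terms": emb.symptom_terms,
        "herb_terms": emb.herb_terms,
        "symptom_vocab_hash": _vocab_hash(emb.symptom_terms),
        "herb_vocab_hash": _vocab_hash(emb.herb_terms),
        "E_s": emb.E_s.tolist(),
        "E_h": emb.E_h.tolist(),
        "mlp_s_state": [p.tolist() for p in model.mlp_s.get_state()],
        "mlp_h_state": [p.tolist() for p in model.mlp_h.get_state()],
        "loss_trace": model.loss_trace,
    }
    Path(path).write_text(json.dumps(blob), encoding="utf-8")


def load_model(
    path: str | Path,
    symptom_terms: Sequence[str] | None = None,
    herb_terms: Sequence[str] | None = None,
) -> HerbRecommender:
    """Rebuild a model from its checkpoint.  If vocabularies are supplied,
    their hashes must match the ones stored at save time."""
    blob = json.loads(Path(path).read_text(encoding="utf-8"))
    if symptom_terms is not None and _vocab_hash(symptom_terms) != blob["symptom_vocab_hash"]:
        raise ValueError("checkpoint was trained against a different symptom vocabulary")
    if herb_terms is not None and _vocab_hash(herb_terms) != blob["herb_vocab_hash"]:
        raise ValueError("checkpoint was trained against a different herb vocabulary")
    config = RecommenderConfig(**blob["config"])
    emb = EmbeddingTable(
        symptom_terms=list(blob["symptom_terms"]), E_s=np.array(blob["E_s"]),
        herb_terms=list(blob["herb_terms"]), E_h=np.array(blob["E_h"]),
    )
    rng = np.random.default_rng(config.seed)
    mlp_s = Sequential.mlp(rng, _branch_widths(emb.d, config.mlp_s_depth, config.out_width),
                           final_relu=config.final_relu)
    mlp_h = Sequential.mlp(rng, _branch_widths(emb.d, config.mlp_h_depth, config.out_width),
                           final_relu=config.final_relu)
    mlp_s.set_state([np.array(p) for p in blob["mlp_s_state"]])
    mlp_h.set_state([np.array(p) for p in blob["mlp_h_state"]])
    model = HerbRecommender(emb, mlp_s, mlp_h, config, loss_trace=list(blob["loss_trace"]))
    return model
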