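"""Cross-domain feature learning for symptoms and herbs.

Two single-hidden-layer autoencoders (one per entity kind) compress each
entity's co-occurrence profile — the row of the herb x symptom count matrix
for herbs, the column for symptoms — into a low-dimensional latent vector.
Profiles from the two corpora are zero-padded to a shared input width so one
autoencoder serves both domains.  The reconstruction loss is masked: only
positions with an observed (nonzero) count contribute, the implicit-feedback
AutoRec convention.

The correlation-pattern module (CPM) then refines the latent vectors with a
domain-adversarial objective: a feature extractor feeds both a rating
predictor (squared reconstruction error) and a domain classifier
(cross-entropy), and the classifier's gradient is reversed and scaled by mu
on its way into the extractor, pushing the extractor toward features the
classifier cannot separate by domain.  A single optimizer minimizes

    L = loss_pred - mu * loss_domain + lambda * ||theta||^2

realized with the gradient-reversal trick rather than an alternating
min-max.  The reversed gradient uses the confusion form (push the
classifier's predictions toward 0.5), which keeps adversarial pressure alive
when the classifier saturates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np

from .corpus import CooccurrenceMatrix
from .nn import Adam, Sequential, he_uniform, relu, sigmoid

__all__ = [
    "AutoencoderParams", "ObservedVector", "AutoencoderConfig", "CPMConfig",
    "CPMParams", "padded_profiles", "encode_decode", "cdl_loss",
    "train_autoencoder", "latent_features", "cpm_loss", "train_cpm",
    "assemble_embeddings", "write_embeddings_tsv", "read_embeddings_tsv",
]


@dataclass
class AutoencoderParams:
    """Weights of one autoencoder.

    Shapes follow the row-vector convention: encoding is
    ``relu(y @ W1 + b1)`` and decoding ``relu(h @ W2 + b2)``, so
    ``W1`` is (input_dim, latent_dim) and ``W2`` is (latent_dim, input_dim).
    Both activations are ReLU.
    """

    W1: np.ndarray
    b1: np.ndarray
    W2: np.ndarray
    b2: np.ndarray
    alpha: float = 0.0

    def __post_init__(self):
        if self.alpha < 0:
            raise ValueError("regularization strength alpha must be >= 0")
        n_in, latent = self.W1.shape
        if self.W2.shape != (latent, n_in):
            raise ValueError("W2 shape must be the transpose-shape of W1")
        if self.b1.shape != (latent,) or self.b2.shape != (n_in,):
            raise ValueError("bias shapes do not compose with the weights")

    @property
    def input_dim(self) -> int:
        return self.W1.shape[0]

    @property
    def latent_dim(self) -> int:
        return self.W1.shape[1]

    @classmethod
    def init(cls, rng: np.random.Generator, input_dim: int, latent_dim: int,
             alpha: float = 0.0) -> "AutoencoderParams":
        # nonnegative weights and slightly positive biases: the profiles and
        # their reconstruction targets are nonnegative counts, and with ReLU
        # on both layers a sign-symmetric init routinely drives every unit
        # into the dead region, from which gradient descent cannot recover
        return cls(
            W1=np.abs(he_uniform(rng, input_dim, latent_dim)),
            b1=np.full(latent_dim, 0.1),
            W2=np.abs(he_uniform(rng, latent_dim, input_dim)),
            b2=np.full(input_dim, 0.1),
            alpha=alpha,
        )

    def copy(self) -> "AutoencoderParams":
        return AutoencoderParams(self.W1.copy(), self.b1.copy(),
                                 self.W2.copy(), self.b2.copy(), self.alpha)


@dataclass(frozen=True)
class ObservedVector:
    """A padded co-occurrence profile with its observation mask."""

    values: np.ndarray
    mask: np.ndarray  # bool: True where the entry is observed
    entity: str
    domain: Literal["source", "target"]

    def __post_init__(self):
        if self.values.shape != self.mask.shape:
            raise ValueError("mask length must equal vector length")


def padded_profiles(
    cooc_source: CooccurrenceMatrix,
    cooc_target: CooccurrenceMatrix,
    kind: Literal["herb", "symptom"],
    log1p: bool = False,
) -> list[ObservedVector]:
    """Per-entity profiles from two per-domain count matrices, zero-padded
    to a common width so source and target vectors share dimensionality.

    Herb profiles are rows over that domain's symptom axis; symptom profiles
    are columns over the herb axis.  Observed positions are those with a
    nonzero count.  ``log1p`` optionally compresses the count scale.
    """
    vectors = []
    width = 0
    mats = []
    for cooc, domain in ((cooc_source, "source"), (cooc_target, "target")):
        mat = cooc if cooc.row_kind == kind else cooc.transpose()
        mats.append((mat, domain))
        width = max(width, mat.counts.shape[1])
    for mat, domain in mats:
        counts = mat.counts.astype(float)
        if log1p:
            counts = np.log1p(counts)
        n, w = counts.shape
        padded = np.zeros((n, width))
        padded[:, :w] = counts
        observed = padded > 0
        for i, term in enumerate(mat.row_terms):
            vectors.append(ObservedVector(padded[i], observed[i], term, domain))
    return vectors


def _stack(batch: Sequence[ObservedVector]) -> tuple[np.ndarray, np.ndarray]:
    Y = np.stack([v.values for v in batch])
    O = np.stack([v.mask for v in batch]).astype(float)
    return Y, O


def encode_decode(y: ObservedVector | np.ndarray, params: AutoencoderParams) -> np.ndarray:
    """Reconstruction ``relu(W2 relu(W1 y + b1) + b2)``."""
    vec = y.values if isinstance(y, ObservedVector) else np.asarray(y, dtype=float)
    if vec.shape[-1] != params.input_dim:
        raise ValueError(f"input width {vec.shape[-1]} != autoencoder width {params.input_dim}")
    h = relu(vec @ params.W1 + params.b1)
    return relu(h @ params.W2 + params.b2)


def latent_features(y: ObservedVector | np.ndarray, params: AutoencoderParams) -> np.ndarray:
    """Encoder half only: ``relu(W1 y + b1)``; entrywise nonnegative."""
    vec = y.values if isinstance(y, ObservedVector) else np.asarray(y, dtype=float)
    if vec.shape[-1] != params.input_dim:
        raise ValueError(f"input width {vec.shape[-1]} != autoencoder width {params.input_dim}")
    return relu(vec @ params.W1 + params.b1)


def cdl_loss(batch: Sequence[ObservedVector], params: AutoencoderParams) -> float:
    """Masked squared reconstruction error summed over the batch, plus the
    Frobenius/L2 penalty ``alpha (||W1||^2 + ||W2||^2 + ||b1||^2 + ||b2||^2)``."""
    if len(batch) == 0:
        raise ValueError("cdl_loss requires a nonempty batch")
    Y, O = _stack(batch)
    Yhat = encode_decode(Y, params)
    sq = float(np.sum(O * (Yhat - Y) ** 2))
    penalty = params.alpha * (
        np.sum(params.W1 ** 2) + np.sum(params.W2 ** 2)
        + np.sum(params.b1 ** 2) + np.sum(params.b2 ** 2)
    )
    return sq + float(penalty)


@dataclass(frozen=True)
class AutoencoderConfig:
    latent_dim: int
    alpha: float = 0.0
    lr: float = 1e-3
    max_epochs: int = 500
    patience: int = 20
    seed: int = 0


def train_autoencoder(vectors: Sequence[ObservedVector], config: AutoencoderConfig) -> AutoencoderParams:
    """Full-batch Adam on the masked regularized square loss.

    Seeded and reproducible; stops early after ``patience`` epochs without
    improvement and returns the best parameters seen, so the final loss never
    exceeds the loss at initialization.
    """
    if len(vectors) == 0:
        raise ValueError("training requires at least one vector")
    if config.latent_dim < 1:
        raise ValueError("latent_dim must be >= 1")
    rng = np.random.default_rng(config.seed)
    Y, O = _stack(vectors)
    params = AutoencoderParams.init(rng, Y.shape[1], config.latent_dim, config.alpha)
    if config.max_epochs == 0:
        return params
    arrays = [params.W1, params.b1, params.W2, params.b2]
    opt = Adam(arrays, lr=config.lr)
    a = config.alpha
    best_loss = cdl_loss(vectors, params)
    best_state = [p.copy() for p in arrays]
    stall = 0
    for _ in range(config.max_epochs):
        h_pre = Y @ params.W1 + params.b1
        h = relu(h_pre)
        out_pre = h @ params.W2 + params.b2
        out = relu(out_pre)
        resid = O * (out - Y)
        loss = float(np.sum(resid ** 2)) + a * float(
            np.sum(params.W1 ** 2) + np.sum(params.W2 ** 2)
            + np.sum(params.b1 ** 2) + np.sum(params.b2 ** 2))
        if not np.isfinite(loss):
            raise RuntimeError(f"non-finite autoencoder loss ({loss}); lower lr or alpha")
        d_out_pre = 2.0 * resid * (out_pre > 0)
        dW2 = h.T @ d_out_pre + 2 * a * params.W2
        db2 = d_out_pre.sum(axis=0) + 2 * a * params.b2
        dh = d_out_pre @ params.W2.T
        d_h_pre = dh * (h_pre > 0)
        dW1 = Y.T @ d_h_pre + 2 * a * params.W1
        db1 = d_h_pre.sum(axis=0) + 2 * a * params.b1
        opt.step([dW1, db1, dW2, db2])
        loss_now = cdl_loss(vectors, params)
        if loss_now < best_loss - 1e-12:
            best_loss = loss_now
            best_state = [p.copy() for p in arrays]
            stall = 0
        else:
            stall += 1
            if stall >= config.patience:
                break
    for p, s in zip(arrays, best_state):
        p[...] = s
    return params


# ---------------------------------------------------------------------------
# Correlation-pattern module (domain-adversarial refinement)


@dataclass
class CPMParams:
    """Extractor / rating-predictor / domain-classifier stacks plus the
    adversarial weight mu and L2 weight lam."""

    extractor: Sequential
    predictor: Sequential
    classifier: Sequential
    mu: float = 1.0
    lam: float = 0.0

    def __post_init__(self):
        if self.mu < 0 or self.lam < 0:
            raise ValueError("mu and lam must be >= 0")

    def sq_norm(self) -> float:
        return self.extractor.sq_norm() + self.predictor.sq_norm() + self.classifier.sq_norm()


@dataclass(frozen=True)
class CPMConfig:
    mu: float = 1.0
    lam: float = 0.0
    hidden: int = 64
    n_hidden_layers: int = 2
    lr: float = 1e-2          # full-batch training tolerates a larger Adam step
    max_epochs: int = 400
    patience: int = 50
    seed: int = 0


_DOMAIN_CODE = {"source": 0.0, "target": 1.0}


def _encode_labels(labels: Sequence[str]) -> np.ndarray:
    try:
        return np.array([_DOMAIN_CODE[l] for l in labels])
    except KeyError as exc:
        raise ValueError(f"domain label must be 'source' or 'target', got {exc.args[0]!r}") from None


def _bce_from_logits(logits: np.ndarray, y: np.ndarray) -> float:
    # log(1+exp(-|x|)) + max(x,0) - x*y, summed: stable BCE-with-logits
    return float(np.sum(np.logaddexp(0.0, logits) - logits * y))


def cpm_loss(
    features: np.ndarray,
    targets: np.ndarray,
    labels: Sequence[str],
    params: CPMParams,
) -> float:
    """The single adversarial objective: summed squared rating error, minus
    mu times the summed domain cross-entropy, plus lam times the squared norm
    of all three parameter sets."""
    features = np.atleast_2d(np.asarray(features, dtype=float))
    targets = np.atleast_2d(np.asarray(targets, dtype=float))
    if not (len(features) == len(targets) == len(labels)):
        raise ValueError("features, targets and labels must have equal counts")
    y = _encode_labels(labels)
    f = params.extractor(features)
    pred_loss = float(np.sum((params.predictor(f) - targets) ** 2))
    logits = params.classifier(f).ravel()
    ce = _bce_from_logits(logits, y)
    return pred_loss - params.mu * ce + params.lam * params.sq_norm()


def init_cpm(rng: np.random.Generator, dim: int, target_dim: int, config: CPMConfig) -> CPMParams:
    h = config.hidden
    ext_widths = [dim] + [h] * config.n_hidden_layers + [dim]
    pred_widths = [dim] + [h] * config.n_hidden_layers + [target_dim]
    clf_widths = [dim] + [h] * config.n_hidden_layers + [1]
    return CPMParams(
        extractor=Sequential.mlp(rng, ext_widths, final_relu=True),
        predictor=Sequential.mlp(rng, pred_widths, final_relu=False),
        classifier=Sequential.mlp(rng, clf_widths, final_relu=False),
        mu=config.mu, lam=config.lam,
    )


def train_cpm(
    source_features: np.ndarray,
    target_features: np.ndarray,
    config: CPMConfig,
    source_targets: np.ndarray | None = None,
    target_targets: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray, CPMParams]:
    """Domain-adversarial refinement of latent features.

    Rating targets default to the features themselves (self-reconstruction);
    pass the original co-occurrence profiles to reconstruct those instead.
    Returns the refined source and target feature matrices (extractor
    outputs) and the trained parameters.  Early stopping tracks the rating
    prediction loss, the only term that is bounded below.

    Inputs and targets are standardized (per-dimension z-score over the
    pooled domains) before training so the reconstruction and domain terms
    stay commensurate regardless of the latent-feature scale.
    """
    Fs = np.atleast_2d(np.asarray(source_features, dtype=float))
    Ft = np.atleast_2d(np.asarray(target_features, dtype=float))
    if Fs.size == 0 or Ft.size == 0:
        raise ValueError("both domains must contribute at least one feature vector")
    Ts = Fs if source_targets is None else np.atleast_2d(np.asarray(source_targets, dtype=float))
    Tt = Ft if target_targets is None else np.atleast_2d(np.asarray(target_targets, dtype=float))
    X = np.vstack([Fs, Ft])
    T = np.vstack([Ts, Tt])
    x_mean, x_sd = X.mean(axis=0), X.std(axis=0)
    t_mean, t_sd = T.mean(axis=0), T.std(axis=0)
    x_sd[x_sd == 0] = 1.0
    t_sd[t_sd == 0] = 1.0
    X = (X - x_mean) / x_sd
    T = (T - t_mean) / t_sd
    Fs = (Fs - x_mean) / x_sd
    Ft = (Ft - x_mean) / x_sd
    y = np.concatenate([np.zeros(len(Fs)), np.ones(len(Ft))])
    rng = np.random.default_rng(config.seed)
    params = init_cpm(rng, X.shape[1], T.shape[1], config)
    ext, pred, clf = params.extractor, params.predictor, params.classifier
    if config.max_epochs > 0:
        n, width = X.shape
        all_params = ext.params() + pred.params() + clf.params()
        opt = Adam(all_params, lr=config.lr)
        best_pred_loss = np.inf
        stall = 0
        for _ in range(config.max_epochs):
            ext.zero_grad(); pred.zero_grad(); clf.zero_grad()
            f = ext(X)
            p_out = pred(f)
            resid = p_out - T
            pred_loss = float(np.sum(resid ** 2))
            logits = clf(f).ravel()
            ce = _bce_from_logits(logits, y)
            if not (np.isfinite(pred_loss) and np.isfinite(ce)):
                raise RuntimeError("non-finite CPM loss; lower lr")
            # gradients are mean-scaled so the two loss terms are commensurate
            g_from_pred = pred.backward(2.0 * resid / resid.size)
            p = sigmoid(logits)
            clf.backward(((p - y) / n)[:, None])  # classifier learns the labels
            clf_grad_snapshot = [g.copy() for g in clf.grads()]
            # adversarial signal into the extractor: push predictions toward
            # 0.5 (confusion form of the reversed gradient; unlike the raw
            # reversed cross-entropy it does not vanish when the classifier
            # saturates)
            g_confusion = clf.backward(((p - 0.5) / n)[:, None])
            for g, s in zip(clf.grads(), clf_grad_snapshot):
                g[...] = s
            ext.backward(g_from_pred + params.mu * g_confusion)
            grads = ext.grads() + pred.grads() + clf.grads()
            opt.step(grads, weight_decay=params.lam)
            # stop when the rating loss stalls; the final parameters are kept
            # (restoring an earlier state would undo adversarial progress)
            if pred_loss < best_pred_loss - 1e-12:
                best_pred_loss = pred_loss
                stall = 0
            else:
                stall += 1
                if stall >= config.patience:
                    break
    return ext(Fs), ext(Ft), params


def domain_classifier_accuracy(params: CPMParams, source_features: np.ndarray,
                               target_features: np.ndarray) -> float:
    """Accuracy of the CPM's own domain classifier on extractor outputs."""
    Fs = np.atleast_2d(np.asarray(source_features, dtype=float))
    Ft = np.atleast_2d(np.asarray(target_features, dtype=float))
    X = np.vstack([Fs, Ft])
    y = np.concatenate([np.zeros(len(Fs)), np.ones(len(Ft))])
    p = sigmoid(params.classifier(params.extractor(X)).ravel())
    return float(np.mean((p > 0.5) == y))


# ---------------------------------------------------------------------------
# Assembling union-vocabulary embedding tables


def assemble_embeddings(
    source_features: dict[str, np.ndarray],
    target_features: dict[str, np.ndarray],
    union_terms: Sequence[str],
    policy: Literal["mean", "concat"] = "mean",
) -> tuple[np.ndarray, list[str]]:
    """Merge per-domain refined features into one union-vocabulary table.

    A term present in a single domain keeps its vector verbatim; a term in
    both gets the elementwise mean (default, keeps dimension fixed) or the
    concatenation of the two.  Returns (matrix, provenance) where provenance
    flags each row as 'source', 'target' or 'both'.
    """
    rows = []
    provenance = []
    for term in union_terms:
        in_s, in_t = term in source_features, term in target_features
        if in_s and in_t:
            u, v = source_features[term], target_features[term]
            rows.append((u + v) / 2.0 if policy == "mean" else np.concatenate([u, v]))
            provenance.append("both")
        elif in_s:
            u = source_features[term]
            rows.append(u if policy == "mean" else np.concatenate([u, np.zeros_like(u)]))
            provenance.append("source")
        elif in_t:
            v = target_features[term]
            rows.append(v if policy == "mean" else np.concatenate([np.zeros_like(v), v]))
            provenance.append("target")
        else:
            raise KeyError(f"term {term!r} has no feature in either domain")
    return np.stack(rows), provenance


@dataclass
class EmbeddingTable:
    """Union-vocabulary symptom and herb embeddings with row provenance."""

    symptom_terms: list[str]
    E_s: np.ndarray
    herb_terms: list[str]
    E_h: np.ndarray
    symptom_provenance: list[str] = field(default_factory=list)
    herb_provenance: list[str] = field(default_factory=list)

    def __post_init__(self):
        if self.E_s.shape[0] != len(self.symptom_terms):
            raise ValueError("E_s row count must equal the symptom vocabulary size")
        if self.E_h.shape[0] != len(self.herb_terms):
            raise ValueError("E_h row count must equal the herb vocabulary size")
        if not (np.isfinite(self.E_s).all() and np.isfinite(self.E_h).all()):
            raise ValueError("embedding tables contain undefined rows")

    @property
    def d(self) -> int:
        return self.E_s.shape[1]


def write_embeddings_tsv(terms: Sequence[str], matrix: np.ndarray, path: str | Path) -> None:
    """term <TAB> d tab-separated reals at 17 significant digits (exact round-trip)."""
    with open(path, "w", encoding="utf-8") as fh:
        for term, row in zip(terms, matrix, strict=True):
            fh.write(term + "\t" + "\t".join(f"{x:.17g}" for x in row) + "\n")


def read_embeddings_tsv(path: str | Path) -> tuple[list[str], np.ndarray]:
    terms, rows = [], []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            terms.append(parts[0])
            rows.append(np.array([float(x) for x in parts[1:]]))
    return terms, np.stack(rows)
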