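"""Linear-chain conditional random field for BILOU sequence tagging.

The model scores a tag sequence y for a token sequence x as

    score(x, y) = sum_i  sum_{f in feats(x, i)} W[f, y_i]  +  sum_i T[y_{i-1}, y_i]

and defines P(y | x) = exp(score) / Z(x), with Z computed by the forward
algorithm in log space.  Decoding is Viterbi with ties broken toward the
earlier tag in a fixed alphabet order.  Training minimizes the L2-regularized
negative log-likelihood by full-batch gradient descent with a fixed step —
deliberately simple and exactly reproducible.

The token encoder is pluggable: an encoder maps a token sequence to one
feature-string set per token.  The default encoder is purely lexical
(folded form, character 3-grams, shape, ±2 context) so that no pretrained
weights are required; a contextual-embedding encoder can be registered under
its own ``encoder_id`` and substituted without touching the model code.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np

from .fold import fold
from .ner import Token

FeatureExtractor = Callable[[Sequence[Token]], list[list[str]]]

_ENCODERS: dict[str, FeatureExtractor] = {}


def register_encoder(encoder_id: str, fn: FeatureExtractor) -> None:
    _ENCODERS[encoder_id] = fn


def get_encoder(encoder_id: str) -> FeatureExtractor:
    try:
        return _ENCODERS[encoder_id]
    except KeyError:
        raise KeyError(
            f"unknown encoder {encoder_id!r}; registered: {sorted(_ENCODERS)}"
        ) from None


def _shape(text: str) -> str:
    out = []
    for c in text:
        if c.isdigit():
            k = "9"
        elif c.isalpha():
            k = "x"
        else:
            k = c
        if not out or out[-1] != k:
            out.append(k)
    return "".join(out)


def sparse_features(tokens: Sequence[Token]) -> list[list[str]]:
    """Deterministic sparse lexical features with a ±2 token context window."""
    folded = [fold(t.text) for t in tokens]
    feats: list[list[str]] = []
    for i, t in enumerate(tokens):
        fs = [f"w={folded[i]}", f"shape={_shape(t.text)}"]
        for g in range(len(folded[i]) - 2):
            fs.append(f"3g={folded[i][g:g + 3]}")
        for off in (-2, -1, 1, 2):
            j = i + off
            ctx = folded[j] if 0 <= j < len(tokens) else "<pad>"
            fs.append(f"w[{off}]={ctx}")
        feats.append(fs)
    return feats


register_encoder("sparse-v1", sparse_features)


@dataclass
class CrfModel:
    """Weights and metadata of a trained (or hand-initialized) CRF."""

    tags: list[str]  # fixed alphabet order; ties in decoding resolve earliest
    feature_index: dict[str, int]
    emissions: np.ndarray  # (n_features, n_tags)
    transitions: np.ndarray  # (n_tags, n_tags), row = previous tag
    encoder_id: str = "sparse-v1"
    l2_sigma: float = 1.0
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        T = len(self.tags)
        if self.transitions.shape != (T, T):
            raise ValueError("transition matrix must cover all tag pairs")
        if not (np.isfinite(self.emissions).all() and np.isfinite(self.transitions).all()):
            raise ValueError("model weights must be finite")

    # -- scoring helpers ----------------------------------------------------

    def _emission_matrix(self, feats: list[list[str]]) -> np.ndarray:
        """Per-token emission scores, shape (n_tokens, n_tags)."""
        E = np.zeros((len(feats), len(self.tags)))
        for i, fs in enumerate(feats):
            for f in fs:
                idx = self.feature_index.get(f)
                if idx is not None:
                    E[i] += self.emissions[idx]
        return E

    def features_for(self, tokens: Sequence[Token]) -> list[list[str]]:
        return get_encoder(self.encoder_id)(tokens)


def sequence_score(model: CrfModel, feats: list[list[str]], tags: Sequence[str]) -> float:
    """Unnormalized score: emissions along the sequence plus transitions."""
    if len(feats) != len(tags):
        raise ValueError("feature and tag sequences must have the same length")
    if not tags:
        return 0.0
    tag_idx = [model.tags.index(t) for t in tags]
    E = model._emission_matrix(feats)
    s = float(sum(E[i, ti] for i, ti in enumerate(tag_idx)))
    s += float(
        sum(model.transitions[a, b] for a, b in zip(tag_idx[:-1], tag_idx[1:]))
    )
    return s


def log_partition(model: CrfModel, feats: list[list[str]]) -> float:
    """log Z(x) via the forward algorithm in log space."""
    if not feats:
        return 0.0
    E = model._emission_matrix(feats)
    alpha = E[0].copy()
    for i in range(1, len(feats)):
        # alpha'_b = logsumexp_a(alpha_a + T_ab) + E_ib
        M = alpha[:, None] + model.transitions
        mmax = M.max(axis=0)
        alpha = mmax + np.log(np.exp(M - mmax).sum(axis=0)) + E[i]
    amax = alpha.max()
    return float(amax + np.log(np.exp(alpha - amax).sum()))


def viterbi(model: CrfModel, tokens: Sequence[Token]) -> list[str]:
    """Argmax tag sequence; ties break toward the earlier tag in
    ``model.tags`` (np.argmax returns the first maximal index)."""
    if not tokens:
        return []
    feats = model.features_for(tokens)
    E = model._emission_matrix(feats)
    n, T = E.shape
    delta = E[0].copy()
    back = np.zeros((n, T), dtype=int)
    for i in range(1, n):
        M = delta[:, None] + model.transitions  # (prev, cur)
        back[i] = M.argmax(axis=0)
        delta = M.max(axis=0) + E[i]
    path = [int(delta.argmax())]
    for i in range(n - 1, 0, -1):
        path.append(int(back[i, path[-1]]))
    path.reverse()
    return [model.tags[t] for t in path]


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

def _forward_backward(model: CrfModel, E: np.ndarray):
    """Log-space forward/backward messages for one sequence."""
    n, T = E.shape
    log_alpha = np.zeros((n, T))
    log_beta = np.zeros((n, T))
    log_alpha[0] = E[0]
    for i in range(1, n):
        M = log_alpha[i - 1][:, None] + model.transitions
        mmax = M.max(axis=0)
        log_alpha[i] = mmax + np.log(np.exp(M - mmax).sum(axis=0)) + E[i]
    for i in range(n - 2, -1, -1):
        M = model.transitions + (E[i + 1] + log_beta[i + 1])[None, :]
        mmax = M.max(axis=1)
        log_beta[i] = mmax + np.log(np.exp(M - mmax.reshape(-1, 1)).sum(axis=1))
    amax = log_alpha[-1].max()
    logZ = float(amax + np.log(np.exp(log_alpha[-1] - amax).sum()))
    return log_alpha, log_beta, logZ


def negative_log_likelihood(
    model: CrfModel, corpus: list[tuple[list[list[str]], list[str]]]
) -> float:
    """L2-regularized NLL of the corpus under the model (training objective)."""
    nll = 0.0
    for feats, tags in corpus:
        nll += log_partition(model, feats) - sequence_score(model, feats, tags)
    reg = (np.sum(model.emissions**2) + np.sum(model.transitions**2)) / (
        2.0 * model.l2_sigma**2
    )
    return float(nll + reg)


def crf_train(
    corpus: list[tuple[list[Token], list[str]]],
    encoder_id: str = "sparse-v1",
    l2_sigma: float = 1.0,
    epochs: int = 50,
    seed: int = 0,
    learning_rate: float = 0.2,
    tags: list[str] | None = None,
) -> CrfModel:
    """Train a CRF by full-batch gradient descent on the regularized NLL.

    Deterministic given ``seed``: weights start at zero and the gradient is
    averaged over sequences, so the same corpus and hyperparameters always
    yield bitwise-identical weights.
    """
    if not corpus:
        raise ValueError("training corpus must be non-empty")
    for toks, tg in corpus:
        if len(toks) != len(tg):
            raise ValueError("token and tag sequences must have equal length")

    encoder = get_encoder(encoder_id)
    featurized = [(encoder(toks), tg) for toks, tg in corpus]

    if tags is None:
        tags = sorted({t for _, tg in corpus for t in tg} | {"O"})
    tag_pos = {t: i for i, t in enumerate(tags)}
    feature_index: dict[str, int] = {}
    for feats, _ in featurized:
        for fs in feats:
            for f in fs:
                feature_index.setdefault(f, len(feature_index))

    F, T = len(feature_index), len(tags)
    model = CrfModel(
        tags=tags,
        feature_index=feature_index,
        emissions=np.zeros((F, T)),
        transitions=np.zeros((T, T)),
        encoder_id=encoder_id,
        l2_sigma=l2_sigma,
        metadata={"epochs": epochs, "seed": seed, "learning_rate": learning_rate},
    )

    # precompute feature index lists per token for speed
    indexed = [
        ([[feature_index[f] for f in fs] for fs in feats], [tag_pos[t] for t in tg])
        for feats, tg in featurized
    ]
    N = len(indexed)

    for _ in range(epochs):
        gW = np.zeros_like(model.emissions)
        gT = np.zeros_like(model.transitions)
        for fidx, tidx in indexed:
            if not fidx:
                continue
            E = np.zeros((len(fidx), T))
            for i, fs in enumerate(fidx):
                for f in fs:
                    E[i] += model.emissions[f]
            log_alpha, log_beta, logZ = _forward_backward(model, E)
            # node marginals: alpha includes E[i], beta excludes it
            P = np.exp(log_alpha + log_beta - logZ)
            for i, (fs, ti) in enumerate(zip(fidx, tidx)):
                row = P[i]
                for f in fs:
                    gW[f] += row
                    gW[f, ti] -= 1.0
            # pairwise marginals
            for i in range(1, len(fidx)):
                M = (
                    log_alpha[i - 1][:, None]
                    + model.transitions
                    + (E[i] + log_beta[i])[None, :]
                    - logZ
                )
                gT += np.exp(M)
                gT[tidx[i - 1], tidx[i]] -= 1.0
        gW = gW / N + model.emissions / (model.l2_sigma**2 * N)
        gT = gT / N + model.transitions / (model.l2_sigma**2 * N)
        model.emissions -= learning_rate * gW
        model.transitions -= learning_rate * gT
    return model


# ---------------------------------------------------------------------------
# persistence
# ---------------------------------------------------------------------------

def save_model(model: CrfModel, path: str | Path) -> None:
    payload = {
        "tags": model.tags,
        "feature_index": model.feature_index,
        "emissions": model.emissions.tolist(),
        "transitions": model.transitions.tolist(),
        "encoder_id": model.encoder_id,
        "l2_sigma": model.l2_sigma,
        "metadata": model.metadata,
    }
    Path(path).write_text(json.dumps(payload), encoding="utf-8")


def load_model(path: str | Path) -> CrfModel:
    payload = json.loads(Path(path).read_text(encoding="utf-8"))
    return CrfModel(
        tags=payload["tags"],
        feature_index=payload["feature_index"],
        emissions=np.asarray(payload["emissions"], dtype=float),
        transitions=np.asarray(payload["transitions"], dtype=float),
        encoder_id=payload["encoder_id"],
        l2_sigma=payload["l2_sigma"],
        metadata=payload.get("metadata", {}),
    )
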