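"""Latent Dirichlet allocation by collapsed Gibbs sampling, plus the two
topic-based message-matching criteria used for filtering.

The model: each document d has a latent topic mixture θ_d ~ Dir(α), each
topic k a word distribution φ_k ~ Dir(β), and each token is drawn by first
sampling a topic z from θ_d, then a word from φ_z. Collapsed Gibbs sampling
integrates θ and φ out and resamples each token's assignment z from

    P(z_i = k | z_-i, w)  ∝  (n_dk + α) · (n_kw + β) / (n_k + V·β)

with the counts n_dk (document×topic), n_kw (topic×word), n_k (topic totals)
taken excluding position i. Smoothed point estimates of θ and φ are read off
the final count tables.

Two matching criteria turn a fitted model into a message filter:

* token criterion — the document has ≥ 1 token assigned to the topic in the
  final sampler state;
* θ-threshold criterion — the smoothed document-topic probability exceeds a
  cutoff τ (default 0.1), which selects documents more strongly about the
  topic (at the default it implies roughly two or more topic tokens for
  typical message lengths).

`GibbsLDA` wraps the sampler as a scikit-learn style estimator;
the module-level functions operate on the raw `TopicModelState` and are what
the estimator calls internally.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np
from sklearn.base import BaseEstimator

from ._gibbs import run_sweep
from .corpus import MessageCorpus
from .errors import EmptyInputError, InvalidConfigError

logger = logging.getLogger(__name__)

_FORMAT_VERSION = 1


@dataclass
class TopicModelState:
    """Full sampler state: assignments, count tables, and hyperparameters.

    Documents are stored flattened: ``w`` holds every token's vocabulary
    index, ``docptr[d]:docptr[d+1]`` delimits document d, ``doc_of[i]`` is
    the owning document of position i, and ``z[i]`` its topic assignment.
    """

    K: int
    alpha: float
    beta: float
    V: int
    doc_ids: list[str]
    w: np.ndarray
    docptr: np.ndarray
    doc_of: np.ndarray
    z: np.ndarray
    n_dk: np.ndarray
    n_kw: np.ndarray
    n_k: np.ndarray
    rng_seed: int
    iteration: int = 0
    vocab_symbols: list[str] = field(default_factory=list)

    @property
    def n_docs(self) -> int:
        return len(self.doc_ids)

    def doc_index(self, message_id: str) -> int:
        if not hasattr(self, "_id_to_doc"):
            self._id_to_doc = {m: i for i, m in enumerate(self.doc_ids)}
        return self._id_to_doc[message_id]

    def doc_length(self, doc: int) -> int:
        return int(self.docptr[doc + 1] - self.docptr[doc])

    # -- invariants ---------------------------------------------------------
    def recount(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Rebuild all count tables from scratch from (w, doc_of, z)."""
        n_dk = np.zeros((self.n_docs, self.K), dtype=np.int64)
        n_kw = np.zeros((self.K, self.V), dtype=np.int64)
        np.add.at(n_dk, (self.doc_of, self.z), 1)
        np.add.at(n_kw, (self.z, self.w), 1)
        return n_dk, n_kw, n_kw.sum(axis=1)

    def check_invariants(self) -> None:
        n_dk, n_kw, n_k = self.recount()
        if not (
            np.array_equal(n_dk, self.n_dk)
            and np.array_equal(n_kw, self.n_kw)
            and np.array_equal(n_k, self.n_k)
        ):
            raise AssertionError("count tables inconsistent with z")
        lengths = np.diff(self.docptr)
        if not np.array_equal(self.n_dk.sum(axis=1), lengths):
            raise AssertionError("n_dk rows do not sum to document lengths")

    def fingerprint(self) -> str:
        """Short content hash binding filter results to a fitted state."""
        h = hashlib.sha256()
        for arr in (self.w, self.docptr, self.z):
            h.update(np.ascontiguousarray(arr).tobytes())
        h.update(f"{self.K}|{self.alpha}|{self.beta}|{self.iteration}".encode())
        return h.hexdigest()[:16]

    # -- serialization ------------------------------------------------------
    def save(self, path) -> None:
        """Single-archive serialization: JSON metadata + dense arrays."""
        meta = {
            "format_version": _FORMAT_VERSION,
            "K": self.K,
            "alpha": self.alpha,
            "beta": self.beta,
            "V": self.V,
            "rng_seed": self.rng_seed,
            "iteration": self.iteration,
        }
        np.savez_compressed(
            path,
            meta=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
            doc_ids=np.array(self.doc_ids, dtype=object),
            vocab_symbols=np.array(self.vocab_symbols, dtype=object),
            w=self.w,
            docptr=self.docptr,
            z=self.z,
        )

    @classmethod
    def load(cls, path) -> "TopicModelState":
        with np.load(path, allow_pickle=True) as npz:
            meta = json.loads(bytes(npz["meta"].tobytes()).decode())
            if meta["format_version"] != _FORMAT_VERSION:
                raise InvalidConfigError(
                    f"unsupported model format {meta['format_version']}"
                )
            w = npz["w"]
            docptr = npz["docptr"]
            z = npz["z"]
            doc_ids = [str(x) for x in npz["doc_ids"]]
            vocab_symbols = [str(x) for x in npz["vocab_symbols"]]
        doc_of = np.repeat(
            np.arange(len(doc_ids), dtype=np.int32), np.diff(docptr)
        )
        state = cls(
            K=meta["K"],
            alpha=meta["alpha"],
            beta=meta["beta"],
            V=meta["V"],
            doc_ids=doc_ids,
            w=w,
            docptr=docptr,
            doc_of=doc_of,
            z=z,
            n_dk=np.empty(0),
            n_kw=np.empty(0),
            n_k=np.empty(0),
            rng_seed=meta["rng_seed"],
            iteration=meta["iteration"],
            vocab_symbols=vocab_symbols,
        )
        state.n_dk, state.n_kw, state.n_k = state.recount()
        return state


CorpusLike = Union[MessageCorpus, Sequence[Sequence[int]]]


def _encode_corpus(corpus: CorpusLike):
    """(doc_ids, token-index lists, V, vocab symbols) from either input form."""
    if isinstance(corpus, MessageCorpus):
        docs = corpus.token_index_lists()
        doc_ids = corpus.ids
        V = corpus.n_vocab
        symbols = [t for t, _ in sorted(corpus.vocabulary.items(), key=lambda kv: kv[1])]
    else:
        docs = [list(map(int, d)) for d in corpus]
        doc_ids = [str(i) for i in range(len(docs))]
        V = max((max(d) for d in docs if d), default=-1) + 1
        symbols = [str(i) for i in range(V)]
    return doc_ids, docs, V, symbols


def init_state(
    corpus: CorpusLike,
    K: int,
    alpha: Optional[float] = None,
    beta: float = 0.01,
    seed: int = 0,
    V: Optional[int] = None,
) -> TopicModelState:
    """Uniform-random initial assignment with consistent count tables."""
    if K < 1:
        raise InvalidConfigError(f"K must be >= 1, got {K}")
    if alpha is None:
        alpha = 50.0 / K
    if alpha <= 0 or beta <= 0:
        raise InvalidConfigError("Dirichlet concentrations must be positive")
    doc_ids, docs, V_data, symbols = _encode_corpus(corpus)
    if len(docs) == 0:
        raise EmptyInputError("cannot initialize on an empty corpus")
    if V is None:
        V = V_data
    elif V < V_data:
        raise InvalidConfigError(f"V={V} smaller than max token index + 1 ({V_data})")

    lengths = np.array([len(d) for d in docs], dtype=np.int64)
    docptr = np.zeros(len(docs) + 1, dtype=np.int64)
    np.cumsum(lengths, out=docptr[1:])
    w = np.fromiter(
        (t for d in docs for t in d), dtype=np.int32, count=int(docptr[-1])
    )
    doc_of = np.repeat(np.arange(len(docs), dtype=np.int32), lengths)

    rng = np.random.default_rng(seed)
    z = rng.integers(0, K, size=w.shape[0], dtype=np.int32)

    state = TopicModelState(
        K=K,
        alpha=float(alpha),
        beta=float(beta),
        V=int(V),
        doc_ids=doc_ids,
        w=w,
        docptr=docptr,
        doc_of=doc_of,
        z=z,
        n_dk=np.empty(0),
        n_kw=np.empty(0),
        n_k=np.empty(0),
        rng_seed=int(seed),
        iteration=0,
        vocab_symbols=symbols,
    )
    state.n_dk, state.n_kw, state.n_k = state.recount()
    return state


def conditional_distribution(
    state: TopicModelState, doc: int, pos: int
) -> np.ndarray:
    """Collapsed conditional P(z = k | z_-i, w) at one token position.

    ``pos`` indexes within the document. The token's own current assignment
    is excluded from the counts before applying the proportionality.
    """
    if not 0 <= doc < state.n_docs:
        raise IndexError(f"doc {doc} out of range")
    if not 0 <= pos < state.doc_length(doc):
        raise IndexError(f"pos {pos} out of range for doc {doc}")
    i = int(state.docptr[doc]) + pos
    t = int(state.w[i])
    k_old = int(state.z[i])

    n_dk = state.n_dk[doc].astype(np.float64).copy()
    n_kw_t = state.n_kw[:, t].astype(np.float64).copy()
    n_k = state.n_k.astype(np.float64).copy()
    n_dk[k_old] -= 1
    n_kw_t[k_old] -= 1
    n_k[k_old] -= 1

    p = (n_dk + state.alpha) * (n_kw_t + state.beta) / (n_k + state.V * state.beta)
    return p / p.sum()


def gibbs_sweep(state: TopicModelState) -> TopicModelState:
    """Resample every token once from its conditional, in place."""
    # int32 views for the kernel; counts are small enough everywhere.
    if state.n_dk.dtype != np.int32:
        state.n_dk = state.n_dk.astype(np.int32)
        state.n_kw = state.n_kw.astype(np.int32)
        state.n_k = state.n_k.astype(np.int32)
    run_sweep(
        state.w,
        state.doc_of,
        state.z,
        state.n_dk,
        state.n_kw,
        state.n_k,
        state.alpha,
        state.beta,
        state.rng_seed,
        state.iteration,
    )
    state.iteration += 1
    return state


def fit(
    corpus: CorpusLike,
    K: int = 100,
    iters: int = 1000,
    alpha: Optional[float] = None,
    beta: float = 0.01,
    seed: int = 0,
    log_every: int = 100,
) -> TopicModelState:
    """Run the sampler for ``iters`` full sweeps from a random initialization."""
    state = init_state(corpus, K=K, alpha=alpha, beta=beta, seed=seed)
    for sweep in range(iters):
        gibbs_sweep(state)
        if log_every and (sweep + 1) % log_every == 0:
            logger.info("gibbs sweep %d/%d", sweep + 1, iters)
    return state


def estimate_theta_phi(state: TopicModelState) -> tuple[np.ndarray, np.ndarray]:
    """Smoothed point estimates θ[d,k] and φ[k,w] from the count tables.

    θ[d,k] = (n_dk + α) / (len_d + Kα);  φ[k,w] = (n_kw + β) / (n_k + Vβ).
    An empty document falls back to the uniform prior row.
    """
    lengths = np.diff(state.docptr).astype(np.float64)
    theta = (state.n_dk + state.alpha) / (
        lengths[:, None] + state.K * state.alpha
    )
    phi = (state.n_kw + state.beta) / (
        state.n_k[:, None].astype(np.float64) + state.V * state.beta
    )
    return theta, phi


def topic_match(state: TopicModelState, topic: int, doc: int) -> bool:
    """Token criterion: ≥ 1 token of the document assigned to ``topic``."""
    if not 0 <= topic < state.K:
        raise IndexError(f"topic {topic} out of range")
    if not 0 <= doc < state.n_docs:
        raise IndexError(f"doc {doc} out of range")
    return bool(state.n_dk[doc, topic] >= 1)


def theta_threshold_match(
    state: TopicModelState, topic: int, doc: int, tau: float = 0.1
) -> bool:
    """θ-threshold criterion: smoothed θ[doc, topic] strictly exceeds τ."""
    if not 0 <= tau < 1:
        raise InvalidConfigError(f"tau must be in [0, 1), got {tau}")
    if not 0 <= topic < state.K:
        raise IndexError(f"topic {topic} out of range")
    if not 0 <= doc < state.n_docs:
        raise IndexError(f"doc {doc} out of range")
    length = state.doc_length(doc)
    theta_dk = (state.n_dk[doc, topic] + state.alpha) / (
        length + state.K * state.alpha
    )
    return bool(theta_dk > tau)


@dataclass
class TopicSummary:
    """Top words of one topic, probability-descending."""

    topic: int
    top_words: list[tuple[str, float]]


def top_words(state: TopicModelState, topic: int, n: int = 25) -> TopicSummary:
    """The n highest-probability words of a topic.

    Ties are broken by ascending token index so the ordering is reproducible.
    """
    if not 0 <= topic < state.K:
        raise IndexError(f"topic {topic} out of range")
    if not 1 <= n <= state.V:
        raise InvalidConfigError(f"n must be in [1, V={state.V}], got {n}")
    _, phi = estimate_theta_phi(state)
    row = phi[topic]
    order = np.lexsort((np.arange(state.V), -row))[:n]
    symbols = state.vocab_symbols or [str(i) for i in range(state.V)]
    return TopicSummary(
        topic=topic, top_words=[(symbols[i], float(row[i])) for i in order]
    )


class GibbsLDA(BaseEstimator):
    """Collapsed-Gibbs LDA as a scikit-learn style estimator.

    Parameters
    ----------
    n_topics : int
        Number of topics K.
    n_iter : int
        Full Gibbs sweeps to run.
    alpha : float or None
        Symmetric document-topic concentration; ``None`` means 50/K.
    beta : float
        Symmetric topic-word concentration.
    random_state : int
        Seed for initialization and the sampler trajectory.
    sample_average_start : int or None
        If set, θ and φ are additionally averaged over all sweeps with index
        ≥ this value (post-burn-in averaging); the default uses the final
        state only, matching the token-assignment filter semantics.

    Attributes
    ----------
    state_ : TopicModelState
        Final sampler state.
    components_ : ndarray of shape (K, V)
        Smoothed topic-word distributions φ.
    theta_ : ndarray of shape (n_docs, K)
        Smoothed document-topic distributions.
    """

    def __init__(
        self,
        n_topics: int = 100,
        n_iter: int = 1000,
        alpha: Optional[float] = None,
        beta: float = 0.01,
        random_state: int = 0,
        sample_average_start: Optional[int] = None,
    ):
        self.n_topics = n_topics
        self.n_iter = n_iter
        self.alpha = alpha
        self.beta = beta
        self.random_state = random_state
        self.sample_average_start = sample_average_start

    def fit(self, X: CorpusLike, y=None) -> "GibbsLDA":
        state = init_state(
            X,
            K=self.n_topics,
            alpha=self.alpha,
            beta=self.beta,
            seed=self.random_state,
        )
        theta_sum = phi_sum = None
        n_avg = 0
        for sweep in range(self.n_iter):
            gibbs_sweep(state)
            if (
                self.sample_average_start is not None
                and sweep >= self.sample_average_start
            ):
                theta, phi = estimate_theta_phi(state)
                theta_sum = theta if theta_sum is None else theta_sum + theta
                phi_sum = phi if phi_sum is None else phi_sum + phi
                n_avg += 1
            if (sweep + 1) % 100 == 0:
                logger.info("gibbs sweep %d/%d", sweep + 1, self.n_iter)
        self.state_ = state
        self.theta_, self.components_ = estimate_theta_phi(state)
        if n_avg:
            self.theta_mean_ = theta_sum / n_avg
            self.components_mean_ = phi_sum / n_avg
        return self

    def transform(self, X=None) -> np.ndarray:
        """Document-topic distributions of the training corpus.

        The collapsed sampler has no out-of-sample inference; ``X`` must be
        None or the training corpus itself.
        """
        if not hasattr(self, "state_"):
            raise InvalidConfigError("GibbsLDA is not fitted")
        return self.theta_

    def fit_transform(self, X: CorpusLike, y=None) -> np.ndarray:
        return self.fit(X).transform()

    def top_words(self, topic: int, n: int = 25) -> TopicSummary:
        return top_words(self.state_, topic, n)

    def save(self, path) -> None:
        self.state_.save(path)

    @classmethod
    def from_state(cls, state: TopicModelState) -> "GibbsLDA":
        est = cls(
            n_topics=state.K,
            n_iter=state.iteration,
            alpha=state.alpha,
            beta=state.beta,
            random_state=state.rng_seed,
        )
        est.state_ = state
        est.theta_, est.components_ = estimate_theta_phi(state)
        return est
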