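"""Synthetic corpora, pollution tables, and annotation sets with known truth.

The real study data — a national microblog stream and a government PM2.5
feed — cannot be redistributed, so every downstream stage is exercised on
generated data with a planted signal:

* cities get a pollution level (ADV drawn uniformly over a range; MDV a
  multiplicative factor above it) and a message total with the heavy
  right-skew seen in per-city social-media volumes (lognormal, with the
  dispersion calibrated so mean/median ≈ 5479/3079);
* each message is relevant to air quality with probability
  π_c = clip(π0 + b·ADV_c, 0, 1) — a linear pollution→relevance link whose
  infinite-sample rate/ADV Pearson correlation is known exactly (a logistic
  link is available as an option);
* message tokens come from planted topic-word distributions: relevant
  messages draw most tokens from a designated air-quality topic and carry an
  injected keyword token with high probability; irrelevant messages use
  background topics and inject keywords only rarely;
* URL flags, account types, and hierarchical content labels (firsthand,
  behavior, concern, request-action) are drawn with the study's observed
  proportions.

Tokens are abstract symbols; no natural-language realism is attempted — the
pipeline is language-agnostic after segmentation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .annotation import AnnotationRecord, record_from_bools
from .corpus import Message, MessageCorpus
from .errors import ConsistencyError, InvalidConfigError
from .filters import FilterResult
from .surveillance import PollutionTable

KEYWORD_SYMBOLS = ("pollution", "air", "breathe", "cough")

# Observed content-label proportions: firsthand|relevant = 90/114,
# behavior|firsthand = 32/90, concern|firsthand = 17/90,
# request-action|relevant = 3/114.
DEFAULT_LABEL_PROPS = (90 / 114, 32 / 90, 17 / 90, 3 / 114)

DEFAULT_ACCOUNT_PROBS = {
    "individual": 0.9931,
    "government": 0.0014,
    "company": 0.0049,
    "media": 0.0006,
}


@dataclass
class SyntheticConfig:
    """All generator knobs. Defaults are the emulated study conditions."""

    n_cities: int = 74
    messages_per_city: float = 5479.0
    #: lognormal sigma of per-city totals; sqrt(2·ln(5479/3079)) reproduces
    #: the observed mean/median ratio. 0 gives a constant per-city total.
    messages_dispersion: float = math.sqrt(2.0 * math.log(5479.0 / 3079.0))
    base_rate: float = 0.0  # π0
    slope: float = 1.25e-4  # b, probability per (µg/m³)
    link: str = "linear"  # or "logistic"
    pollution_range: tuple[float, float] = (25.0, 160.0)
    mdv_multiplier_range: tuple[float, float] = (2.5, 6.0)
    n_topics_true: int = 5
    vocab_size: int = 500
    topic_concentration: float = 0.05
    doc_length_mean: float = 9.0
    aq_topic_weight: float = 0.7
    #: φ* mass the air-quality topic gives the keyword tokens collectively;
    #: background topics give them none, so keyword occurrence in irrelevant
    #: messages is governed solely by keyword_noise_prob.
    aq_keyword_mass: float = 0.15
    keyword_injection_prob: float = 0.8
    keyword_noise_prob: float = 0.01
    url_prob_relevant: float = 0.15
    url_prob_irrelevant: float = 0.35
    label_props: tuple[float, float, float, float] = DEFAULT_LABEL_PROPS
    account_type_probs: dict = field(
        default_factory=lambda: dict(DEFAULT_ACCOUNT_PROBS)
    )
    seed: int = 0

    def __post_init__(self) -> None:
        probs = [
            self.base_rate,
            self.keyword_injection_prob,
            self.keyword_noise_prob,
            self.url_prob_relevant,
            self.url_prob_irrelevant,
            self.aq_topic_weight,
            self.aq_keyword_mass,
            *self.label_props,
        ]
        if any(not 0.0 <= p <= 1.0 for p in probs):
            raise InvalidConfigError("all probabilities must lie in [0, 1]")
        lo, hi = self.pollution_range
        if not lo < hi:
            raise InvalidConfigError("pollution_range must satisfy low < high")
        mlo, mhi = self.mdv_multiplier_range
        if mlo < 1.0 or mhi < mlo:
            raise InvalidConfigError("mdv_multiplier_range must have 1 <= low <= high")
        if self.n_cities < 2:
            raise InvalidConfigError(
                "n_cities must be >= 2 (correlation undefined otherwise)"
            )
        if self.n_topics_true < 2:
            raise InvalidConfigError("need >= 2 planted topics (1 AQ + background)")
        if self.vocab_size < len(KEYWORD_SYMBOLS):
            raise InvalidConfigError(
                f"vocab_size must be >= {len(KEYWORD_SYMBOLS)} (the keyword set)"
            )
        if self.link not in ("linear", "logistic"):
            raise InvalidConfigError(f"unknown link {self.link!r}")
        if self.messages_dispersion < 0 or self.messages_per_city < 1:
            raise InvalidConfigError("message-volume parameters out of range")
        if self.topic_concentration <= 0 or self.doc_length_mean < 1:
            raise InvalidConfigError("topic/document shape parameters out of range")

    def to_dict(self) -> dict:
        return asdict(self)


def vocab_symbols(vocab_size: int) -> list[str]:
    """Generator vocabulary: the four keyword symbols then abstract tokens."""
    syms = list(KEYWORD_SYMBOLS)
    syms += [f"w{i:05d}" for i in range(len(syms), vocab_size)]
    return syms


def relevance_probability(config: SyntheticConfig, adv: np.ndarray) -> np.ndarray:
    """π_c: the planted pollution→relevance link."""
    adv = np.asarray(adv, dtype=np.float64)
    if config.link == "linear":
        return np.clip(config.base_rate + config.slope * adv, 0.0, 1.0)
    # logistic option: matches the linear link's value and slope at the
    # midpoint of the pollution range.
    mid = float(np.mean(config.pollution_range))
    p_mid = float(np.clip(config.base_rate + config.slope * mid, 1e-9, 1 - 1e-9))
    k = config.slope / (p_mid * (1.0 - p_mid))
    return 1.0 / (1.0 + np.exp(-(np.log(p_mid / (1 - p_mid)) + k * (adv - mid))))


@dataclass
class GroundTruth:
    """Everything the generator knows that the pipeline must rediscover."""

    pollution: PollutionTable
    pi_by_city: dict[str, float]
    labels: pd.DataFrame  # index message id; columns city, relevant, firsthand,
    #                       behavior, concern, request_action (bool)
    phi_star: np.ndarray  # planted topic-word distributions, rows sum to 1
    aq_topic: int
    vocab: list[str]
    keywords: tuple[str, ...]
    expected_correlation: Optional[float]

    def oracle_filter(self) -> FilterResult:
        """A FilterResult matching exactly the truly relevant messages."""
        matched = frozenset(self.labels.index[self.labels["relevant"]])
        return FilterResult(
            matched=matched,
            n_total=len(self.labels),
            provenance={"expr": {"op": "oracle_relevance"}, "models": {}},
        )


def generate_pollution_table(config: SyntheticConfig) -> PollutionTable:
    """One row per city; ADV uniform over the range, MDV a multiple of ADV."""
    rng = np.random.default_rng(config.seed)
    lo, hi = config.pollution_range
    mlo, mhi = config.mdv_multiplier_range
    adv = rng.uniform(lo, hi, size=config.n_cities)
    mult = rng.uniform(mlo, mhi, size=config.n_cities)
    frame = pd.DataFrame(
        {
            "city": [f"city_{i:03d}" for i in range(config.n_cities)],
            "adv": adv,
            "mdv": adv * mult,
        }
    )
    return PollutionTable(frame=frame)


def _planted_phi(rng: np.random.Generator, n_topics: int, V: int, conc: float):
    phi = rng.dirichlet(np.full(V, conc), size=n_topics)
    # Dirichlet at tiny concentrations can underflow a coordinate to exactly
    # 0; renormalization keeps rows summing to 1.
    phi = np.maximum(phi, 0.0)
    return phi / phi.sum(axis=1, keepdims=True)


def generate_corpus(
    config: SyntheticConfig, pollution: PollutionTable
) -> tuple[MessageCorpus, GroundTruth]:
    """Generate the message corpus and its ground truth for a pollution table.

    The per-city relevance probability follows the configured link; message
    tokens are drawn from the planted topics (relevant messages weight the
    air-quality topic by ``aq_topic_weight`` and carry an injected keyword
    with probability ``keyword_injection_prob``); labels, URL flags and
    account types follow their configured proportions.
    """
    expected_cities = [f"city_{i:03d}" for i in range(config.n_cities)]
    if list(pollution.cities) != expected_cities and len(pollution) != config.n_cities:
        raise ConsistencyError(
            f"pollution table covers {len(pollution)} cities, "
            f"config expects {config.n_cities}"
        )

    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    V = config.vocab_size
    T = config.n_topics_true
    syms = vocab_symbols(V)
    n_kw = len(KEYWORD_SYMBOLS)
    phi = _planted_phi(rng, T, V, config.topic_concentration)
    # Keyword tokens are designated air-quality vocabulary: the AQ topic
    # carries them with a fixed mass share, background topics not at all, so
    # their appearance in irrelevant messages is purely keyword_noise_prob.
    phi[:, :n_kw] = 0.0
    phi = phi / phi.sum(axis=1, keepdims=True)
    aq = 0
    phi[aq] *= 1.0 - config.aq_keyword_mass
    phi[aq, :n_kw] = config.aq_keyword_mass / n_kw

    adv = pollution.frame["adv"].to_numpy()
    cities = pollution.frame["city"].tolist()
    pi = relevance_probability(config, adv)

    if config.messages_dispersion > 0:
        mu = math.log(config.messages_per_city) - config.messages_dispersion**2 / 2
        n_msgs = np.maximum(
            1,
            np.round(
                rng.lognormal(mu, config.messages_dispersion, size=len(cities))
            ).astype(np.int64),
        )
    else:
        n_msgs = np.full(len(cities), int(round(config.messages_per_city)), np.int64)

    p_fh, p_beh, p_con, p_act = config.label_props
    acct_names = list(config.account_type_probs) + ["other"]
    acct_p = np.array(
        list(config.account_type_probs.values())
        + [max(0.0, 1.0 - sum(config.account_type_probs.values()))]
    )
    acct_p = acct_p / acct_p.sum()

    messages: list[Message] = []
    label_rows = []
    msg_counter = 0
    for ci, city in enumerate(cities):
        m = int(n_msgs[ci])
        relevant = rng.random(m) < pi[ci]
        lengths = 1 + rng.poisson(config.doc_length_mean - 1.0, size=m)
        total_tokens = int(lengths.sum())

        rel_tok = np.repeat(relevant, lengths)
        topics = 1 + rng.integers(0, T - 1, size=total_tokens)
        aq_mask = rel_tok & (rng.random(total_tokens) < config.aq_topic_weight)
        topics[aq_mask] = aq
        words = np.empty(total_tokens, dtype=np.int64)
        for t in range(T):
            idx = np.flatnonzero(topics == t)
            if idx.size:
                words[idx] = rng.choice(V, size=idx.size, p=phi[t])

        inject_p = np.where(
            relevant, config.keyword_injection_prob, config.keyword_noise_prob
        )
        inject = rng.random(m) < inject_p
        inject_kw = rng.integers(0, len(KEYWORD_SYMBOLS), size=m)
        url_p = np.where(
            relevant, config.url_prob_relevant, config.url_prob_irrelevant
        )
        has_url = rng.random(m) < url_p
        accounts = rng.choice(len(acct_names), size=m, p=acct_p)

        firsthand = relevant & (rng.random(m) < p_fh)
        behavior = firsthand & (rng.random(m) < p_beh)
        concern = firsthand & (rng.random(m) < p_con)
        action = relevant & (rng.random(m) < p_act)
        users = rng.integers(0, 10_000_000, size=m)

        bounds = np.concatenate(([0], np.cumsum(lengths)))
        for j in range(m):
            toks = [syms[w] for w in words[bounds[j] : bounds[j + 1]]]
            if inject[j]:
                toks.append(syms[inject_kw[j]])
            mid = f"m{msg_counter:08d}"
            msg_counter += 1
            messages.append(
                Message(
                    id=mid,
                    user_id=f"u{users[j]:07d}",
                    city=city,
                    account_type=acct_names[accounts[j]],
                    tokens=toks,
                    has_url=bool(has_url[j]),
                )
            )
            label_rows.append(
                (
                    mid,
                    city,
                    bool(relevant[j]),
                    bool(firsthand[j]),
                    bool(behavior[j]),
                    bool(concern[j]),
                    bool(action[j]),
                )
            )

    labels = pd.DataFrame(
        label_rows,
        columns=[
            "message_id",
            "city",
            "relevant",
            "firsthand",
            "behavior",
            "concern",
            "request_action",
        ],
    ).set_index("message_id")

    if np.ptp(pi) == 0 or np.ptp(adv) == 0:
        expected = None
    else:
        expected = float(np.corrcoef(pi, adv)[0, 1])

    truth = GroundTruth(
        pollution=pollution,
        pi_by_city=dict(zip(cities, pi.tolist())),
        labels=labels,
        phi_star=phi,
        aq_topic=aq,
        vocab=syms,
        keywords=KEYWORD_SYMBOLS,
        expected_correlation=expected,
    )
    return MessageCorpus(messages), truth


def generate_topic_corpus(
    n_docs: int,
    n_topics: int,
    vocab_size: int,
    doc_length_mean: float = 20.0,
    concentration: float = 0.02,
    doc_alpha: float = 0.1,
    seed: int = 0,
) -> tuple[MessageCorpus, np.ndarray]:
    """A pure planted-topics corpus (no relevance structure) for recovery
    studies: θ_d ~ Dir(doc_alpha) over well-separated φ* rows."""
    rng = np.random.default_rng(seed)
    syms = [f"w{i:05d}" for i in range(vocab_size)]
    phi = _planted_phi(rng, n_topics, vocab_size, concentration)
    theta = rng.dirichlet(np.full(n_topics, doc_alpha), size=n_docs)
    lengths = 1 + rng.poisson(doc_length_mean - 1.0, size=n_docs)
    messages = []
    for d in range(n_docs):
        topics = rng.choice(n_topics, size=lengths[d], p=theta[d])
        toks = []
        for t in topics:
            toks.append(syms[rng.choice(vocab_size, p=phi[t])])
        messages.append(
            Message(
                id=f"d{d:06d}",
                user_id=f"u{d:06d}",
                city="city_000",
                account_type="individual",
                tokens=toks,
            )
        )
    return MessageCorpus(messages), phi


def generate_annotation_pair(
    truth: GroundTruth,
    coder_accuracy: float,
    n_messages: Optional[int] = None,
    seed: int = 0,
    message_ids: Optional[Sequence[str]] = None,
) -> tuple[list[AnnotationRecord], list[AnnotationRecord]]:
    """Two coders' records: each flips every true label independently with
    probability 1 − coder_accuracy, then codes are masked to the hierarchy
    under the coder's own parent codes."""
    if not 0.5 <= coder_accuracy <= 1.0:
        raise InvalidConfigError(
            f"coder_accuracy must be in [0.5, 1], got {coder_accuracy}"
        )
    rng = np.random.default_rng(seed)
    labels = truth.labels
    if message_ids is None:
        ids = list(labels.index)
        if n_messages is not None:
            if n_messages > len(ids):
                raise InvalidConfigError("n_messages exceeds corpus size")
            pick = rng.choice(len(ids), size=n_messages, replace=False)
            ids = [ids[i] for i in sorted(pick)]
    else:
        ids = list(message_ids)

    flip_p = 1.0 - coder_accuracy
    fields = ["relevant", "firsthand", "behavior", "concern", "request_action"]
    out: tuple[list[AnnotationRecord], list[AnnotationRecord]] = ([], [])
    for coder_idx, coder in enumerate(("coder_a", "coder_b")):
        sub = labels.loc[ids, fields].to_numpy(dtype=bool)
        flips = rng.random(sub.shape) < flip_p
        coded = sub ^ flips
        for row, mid in enumerate(ids):
            rel, fh, beh, con, act = coded[row]
            out[coder_idx].append(
                record_from_bools(
                    mid,
                    coder,
                    relevant=bool(rel),
                    firsthand=bool(fh),
                    behavior=bool(beh),
                    concern=bool(con),
                    request_action=bool(act),
                )
            )
    return out


def expected_kappa(coder_accuracy: float, prevalence: float) -> float:
    """Closed-form expected kappa for two symmetric-error coders.

    With both coders flipping the true binary label independently with
    probability q = 1 − a: p_o = a² + q² (prevalence-free), each coder's
    'yes' marginal is m = p·a + (1−p)·q, and p_e = m² + (1−m)².
    """
    a = coder_accuracy
    q = 1.0 - a
    p = prevalence
    p_o = a * a + q * q
    m = p * a + (1.0 - p) * q
    p_e = m * m + (1.0 - m) * (1.0 - m)
    if p_e >= 1.0:
        return 0.0
    return (p_o - p_e) / (1.0 - p_e)
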