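"""Message corpora, vocabularies, lexicons, and the preprocessing front end.

A corpus is a list of pre-segmented microblog messages plus a dense
token-symbol vocabulary. Segmentation itself is out of scope: readers accept
token lists (a tokenizer for raw text is a pluggable callable supplied by the
caller). Preprocessing removes stop words and infrequent tokens — the two
cleaning steps the pipeline assumes — and the health-lexicon prefilter
defines the working dataset the downstream stages consume.
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass, field, replace
from typing import Callable, Iterable, Iterator, Optional, Sequence

from .errors import EmptyInputError, InvalidConfigError

ACCOUNT_TYPES = ("individual", "government", "company", "media", "other")

# Scheme-prefixed links plus the Weibo short-link form. The dialect is fixed
# here; "contains a URL" means exactly this pattern.
_URL_RE = re.compile(r"(?:https?://\S+|\bt\.cn/\S+)", re.IGNORECASE)


def detect_url(raw_text: Optional[str], has_url_flag: bool = False) -> bool:
    """True iff ``raw_text`` contains a URL by the documented pattern.

    Falls back to the stored ``has_url`` flag when no raw text is available
    (synthetic corpora carry only the flag).
    """
    if raw_text is None:
        return bool(has_url_flag)
    return _URL_RE.search(raw_text) is not None


@dataclass
class Message:
    """One microblog post, already segmented into token symbols."""

    id: str
    user_id: str
    city: str
    account_type: str
    tokens: list[str]
    has_url: bool = False
    raw_text: Optional[str] = None

    def __post_init__(self) -> None:
        if self.account_type not in ACCOUNT_TYPES:
            raise InvalidConfigError(
                f"unknown account_type {self.account_type!r}; "
                f"expected one of {ACCOUNT_TYPES}"
            )

    def contains_url(self) -> bool:
        return detect_url(self.raw_text, self.has_url)


@dataclass
class Lexicon:
    """A named set of token symbols (health terms, stop words, keywords)."""

    terms: frozenset[str]
    name: str = "lexicon"

    def __post_init__(self) -> None:
        self.terms = frozenset(self.terms)

    def __contains__(self, term: str) -> bool:
        return term in self.terms

    def __len__(self) -> int:
        return len(self.terms)

    @classmethod
    def from_file(cls, path, name: Optional[str] = None) -> "Lexicon":
        """Read a UTF-8 plain-text lexicon, one term per line, ``#`` comments."""
        terms = []
        with open(path, encoding="utf-8") as fh:
            for line in fh:
                line = line.split("#", 1)[0].strip()
                if line:
                    terms.append(line)
        return cls(frozenset(terms), name=name or str(path))


class MessageCorpus:
    """Messages plus a dense token-symbol ↔ integer-index vocabulary.

    The vocabulary is sorted lexicographically so that index assignment is a
    pure function of the token set (reproducible across runs and orderings).
    """

    def __init__(
        self,
        messages: Sequence[Message],
        vocabulary: Optional[dict[str, int]] = None,
    ):
        self.messages: list[Message] = list(messages)
        ids = [m.id for m in self.messages]
        if len(set(ids)) != len(ids):
            dupes = [i for i, c in Counter(ids).items() if c > 1]
            raise InvalidConfigError(f"duplicate message ids: {dupes[:5]}")
        if vocabulary is None:
            vocabulary = self._build_vocabulary(self.messages)
        self._check_vocabulary(vocabulary)
        self.vocabulary: dict[str, int] = dict(vocabulary)
        self._by_id = {m.id: m for m in self.messages}

    @staticmethod
    def _build_vocabulary(messages: Iterable[Message]) -> dict[str, int]:
        seen: set[str] = set()
        for m in messages:
            seen.update(m.tokens)
        return {t: i for i, t in enumerate(sorted(seen))}

    @staticmethod
    def _check_vocabulary(vocab: dict[str, int]) -> None:
        if sorted(vocab.values()) != list(range(len(vocab))):
            raise InvalidConfigError("vocabulary indices must be dense 0..V-1")

    # -- container protocol -------------------------------------------------
    def __len__(self) -> int:
        return len(self.messages)

    def __iter__(self) -> Iterator[Message]:
        return iter(self.messages)

    def __getitem__(self, i: int) -> Message:
        return self.messages[i]

    def by_id(self, message_id: str) -> Message:
        return self._by_id[message_id]

    @property
    def ids(self) -> list[str]:
        return [m.id for m in self.messages]

    @property
    def n_vocab(self) -> int:
        return len(self.vocabulary)

    def city_totals(self) -> dict[str, int]:
        """Message count per city, recomputed from the messages."""
        return dict(Counter(m.city for m in self.messages))

    def token_index_lists(self) -> list[list[int]]:
        """Token lists encoded through the vocabulary (LDA input form)."""
        vocab = self.vocabulary
        return [[vocab[t] for t in m.tokens] for m in self.messages]

    def subset(self, keep_ids: Iterable[str]) -> "MessageCorpus":
        keep = set(keep_ids)
        return MessageCorpus([m for m in self.messages if m.id in keep])


@dataclass
class PreprocessReport:
    """What preprocessing removed and why."""

    n_messages_in: int
    n_messages_out: int
    n_dropped_empty: int
    n_tokens_removed_stopword: int
    n_tokens_removed_infrequent: int
    vocab_in: int
    vocab_out: int
    dropped_ids: list[str] = field(default_factory=list)


def preprocess_corpus(
    raw: MessageCorpus,
    stopwords: Optional[Lexicon] = None,
    min_count: int = 5,
) -> tuple[MessageCorpus, PreprocessReport]:
    """Remove stop words and infrequent tokens; drop token-empty messages.

    Token frequency is counted over the whole corpus *after* stop-word
    removal; tokens with corpus frequency < ``min_count`` are removed. The
    vocabulary is reindexed densely. Messages left without tokens are dropped
    and itemized in the report rather than silently discarded.
    """
    if min_count < 1:
        raise InvalidConfigError(f"min_count must be >= 1, got {min_count}")
    if len(raw) == 0:
        raise EmptyInputError("cannot preprocess an empty corpus")
    stop = stopwords.terms if stopwords is not None else frozenset()

    counts: Counter[str] = Counter()
    n_stop = 0
    for m in raw:
        for t in m.tokens:
            if t in stop:
                n_stop += 1
            else:
                counts[t] += 1
    keep_tokens = {t for t, c in counts.items() if c >= min_count}
    n_infreq = sum(c for t, c in counts.items() if t not in keep_tokens)

    kept_messages: list[Message] = []
    dropped: list[str] = []
    for m in raw:
        toks = [t for t in m.tokens if t in keep_tokens]
        if toks:
            kept_messages.append(replace(m, tokens=toks))
        else:
            dropped.append(m.id)

    report = PreprocessReport(
        n_messages_in=len(raw),
        n_messages_out=len(kept_messages),
        n_dropped_empty=len(dropped),
        n_tokens_removed_stopword=n_stop,
        n_tokens_removed_infrequent=n_infreq,
        vocab_in=raw.n_vocab,
        vocab_out=len(keep_tokens),
        dropped_ids=dropped,
    )
    return MessageCorpus(kept_messages), report


def lexicon_prefilter(corpus: MessageCorpus, health: Lexicon):
    """Ids of messages containing at least one lexicon term.

    This is the prefilter that defines the working dataset (e.g. a
    health-term list applied to the full message stream). Returns a
    :class:`~aqsurveil.filters.FilterResult` whose provenance records the
    lexicon name.
    """
    from .filters import FilterResult, Keyword  # local import: avoid cycle

    if len(health) == 0:
        raise InvalidConfigError("prefilter lexicon is empty")
    expr = Keyword(terms=health.terms)
    matched = frozenset(
        m.id for m in corpus if not health.terms.isdisjoint(m.tokens)
    )
    return FilterResult(
        matched=matched,
        n_total=len(corpus),
        provenance={"expr": expr.to_dict(), "lexicon": health.name, "models": {}},
    )


def filter_individuals(corpus: MessageCorpus) -> MessageCorpus:
    """Optional restriction to individual (non-organization) accounts."""
    return MessageCorpus([m for m in corpus if m.account_type == "individual"])


Tokenizer = Callable[[str], list[str]]


def tokenize_raw(
    messages: Iterable[Message], tokenizer: Tokenizer
) -> list[Message]:
    """Apply a user-supplied tokenizer to messages that carry only raw text."""
    out = []
    for m in messages:
        if m.tokens:
            out.append(m)
        elif m.raw_text is not None:
            out.append(replace(m, tokens=tokenizer(m.raw_text)))
        else:
            out.append(m)
    return out
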