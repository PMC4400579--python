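"""Message-filter algebra: keyword, topic, and URL primitives composed with
AND / OR / NOT.

A filter expression is a small immutable tree. Evaluating it over a corpus
yields a :class:`FilterResult`: the matched id set plus provenance (the
serialized expression and fingerprints of any referenced topic models), so
any result can be re-evaluated to the identical set later.

The combination the surveillance study leans on — a topic filter intersected
with a keyword filter, optionally excluding URL messages — is
``And(TopicMatch(...), Keyword({...}), Not(HasUrl()))``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Union

import yaml

from .corpus import Lexicon, Message, MessageCorpus
from .errors import ExpressionError, ModelDependencyError
from .lda import TopicModelState, theta_threshold_match, topic_match

ModelMap = Mapping[str, TopicModelState]


def keyword_match(msg: Message, terms: Union[Lexicon, frozenset, set]) -> bool:
    """True iff any term occurs among the message's tokens.

    Matching is exact token equality after segmentation, not substring search
    on raw text (see :func:`raw_substring_match` for the parity mode).
    """
    termset = terms.terms if isinstance(terms, Lexicon) else frozenset(terms)
    return not termset.isdisjoint(msg.tokens)


def raw_substring_match(msg: Message, terms: Union[Lexicon, frozenset, set]) -> bool:
    """Parity mode: substring search on raw text (token match as fallback)."""
    termset = terms.terms if isinstance(terms, Lexicon) else frozenset(terms)
    if msg.raw_text is None:
        return not termset.isdisjoint(msg.tokens)
    return any(t in msg.raw_text for t in termset)


class FilterExpr:
    """Base class for filter-expression nodes."""

    def to_dict(self) -> dict:
        raise NotImplementedError

    @staticmethod
    def from_dict(d: dict) -> "FilterExpr":
        op = d.get("op")
        if op == "keyword":
            return Keyword(frozenset(d["terms"]), substring=d.get("substring", False))
        if op == "topic":
            return TopicMatch(
                model=d["model"],
                topic=int(d["topic"]),
                criterion=d.get("criterion", "token"),
                tau=float(d.get("tau", 0.1)),
            )
        if op == "has_url":
            return HasUrl()
        if op == "and":
            return And(tuple(FilterExpr.from_dict(c) for c in d["children"]))
        if op == "or":
            return Or(tuple(FilterExpr.from_dict(c) for c in d["children"]))
        if op == "not":
            return Not(FilterExpr.from_dict(d["child"]))
        raise ExpressionError(f"unknown filter primitive {op!r}")

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), allow_unicode=True, sort_keys=True)

    @staticmethod
    def from_yaml(text: str) -> "FilterExpr":
        return FilterExpr.from_dict(yaml.safe_load(text))

    # -- operator sugar -----------------------------------------------------
    def __and__(self, other: "FilterExpr") -> "And":
        return And((self, other))

    def __or__(self, other: "FilterExpr") -> "Or":
        return Or((self, other))

    def __invert__(self) -> "Not":
        return Not(self)


@dataclass(frozen=True)
class Keyword(FilterExpr):
    terms: frozenset
    substring: bool = False

    def to_dict(self) -> dict:
        return {
            "op": "keyword",
            "terms": sorted(self.terms),
            "substring": self.substring,
        }


@dataclass(frozen=True)
class TopicMatch(FilterExpr):
    """Topic criterion against a named fitted model.

    ``criterion`` is ``"token"`` (≥ 1 token assigned to the topic in the
    final sampler state) or ``"theta"`` (smoothed θ[doc, topic] > τ).
    """

    model: str
    topic: int
    criterion: str = "token"
    tau: float = 0.1

    def __post_init__(self):
        if self.criterion not in ("token", "theta"):
            raise ExpressionError(f"unknown topic criterion {self.criterion!r}")

    def to_dict(self) -> dict:
        return {
            "op": "topic",
            "model": self.model,
            "topic": self.topic,
            "criterion": self.criterion,
            "tau": self.tau,
        }


@dataclass(frozen=True)
class HasUrl(FilterExpr):
    def to_dict(self) -> dict:
        return {"op": "has_url"}


@dataclass(frozen=True)
class And(FilterExpr):
    children: tuple

    def to_dict(self) -> dict:
        return {"op": "and", "children": [c.to_dict() for c in self.children]}


@dataclass(frozen=True)
class Or(FilterExpr):
    children: tuple

    def to_dict(self) -> dict:
        return {"op": "or", "children": [c.to_dict() for c in self.children]}


@dataclass(frozen=True)
class Not(FilterExpr):
    child: FilterExpr

    def to_dict(self) -> dict:
        return {"op": "not", "child": self.child.to_dict()}


@dataclass
class FilterResult:
    """Matched message ids plus everything needed to re-derive them."""

    matched: frozenset
    n_total: int
    provenance: dict = field(default_factory=dict)

    @property
    def n_matched(self) -> int:
        return len(self.matched)


def _collect_models(expr: FilterExpr, out: set) -> None:
    if isinstance(expr, TopicMatch):
        out.add(expr.model)
    elif isinstance(expr, (And, Or)):
        for c in expr.children:
            _collect_models(c, out)
    elif isinstance(expr, Not):
        _collect_models(expr.child, out)


def _eval_node(
    expr: FilterExpr,
    corpus: MessageCorpus,
    all_ids: frozenset,
    models: ModelMap,
) -> frozenset:
    if isinstance(expr, Keyword):
        match = raw_substring_match if expr.substring else keyword_match
        return frozenset(m.id for m in corpus if match(m, expr.terms))
    if isinstance(expr, HasUrl):
        return frozenset(m.id for m in corpus if m.contains_url())
    if isinstance(expr, TopicMatch):
        if expr.model not in models:
            raise ModelDependencyError(
                f"filter references model {expr.model!r} which was not supplied"
            )
        state = models[expr.model]
        out = []
        for m in corpus:
            try:
                doc = state.doc_index(m.id)
            except KeyError:
                raise ModelDependencyError(
                    f"message {m.id!r} is not a document of model {expr.model!r}"
                ) from None
            if expr.criterion == "token":
                hit = topic_match(state, expr.topic, doc)
            else:
                hit = theta_threshold_match(state, expr.topic, doc, expr.tau)
            if hit:
                out.append(m.id)
        return frozenset(out)
    if isinstance(expr, And):
        result = all_ids
        for c in expr.children:
            result = result & _eval_node(c, corpus, all_ids, models)
        return result
    if isinstance(expr, Or):
        result: frozenset = frozenset()
        for c in expr.children:
            result = result | _eval_node(c, corpus, all_ids, models)
        return result
    if isinstance(expr, Not):
        return all_ids - _eval_node(expr.child, corpus, all_ids, models)
    raise ExpressionError(f"unknown expression node {type(expr).__name__}")


def evaluate(
    expr: FilterExpr,
    corpus: MessageCorpus,
    models: Optional[ModelMap] = None,
) -> FilterResult:
    """Set-algebra evaluation of an expression tree over a corpus.

    AND is intersection, OR union, NOT complement within the corpus id set.
    Provenance records the serialized expression and a fingerprint of every
    referenced model, so the result can be reproduced exactly.
    """
    models = models or {}
    all_ids = frozenset(corpus.ids)
    matched = _eval_node(expr, corpus, all_ids, models)
    referenced: set = set()
    _collect_models(expr, referenced)
    missing = referenced - set(models)
    if missing:
        raise ModelDependencyError(f"missing models: {sorted(missing)}")
    provenance = {
        "expr": expr.to_dict(),
        "models": {name: models[name].fingerprint() for name in sorted(referenced)},
    }
    return FilterResult(matched=matched, n_total=len(corpus), provenance=provenance)


# -- study presets ----------------------------------------------------------

KEYWORD_TERMS = {
    "pollution": "pollution",
    "air": "air",
    "breathe": "breathe",
    "cough": "cough",
}
"""Default symbols for the four single-keyword filters. Real Chinese corpora
would use the segmented forms (污染, 空气, 呼吸, 咳嗽); synthetic corpora use
these abstract symbols."""


def presets(
    aq_topic: int,
    po_topic: Optional[int] = None,
    model: str = "lda",
    terms: Optional[Mapping[str, str]] = None,
) -> dict[str, FilterExpr]:
    """The study's filter grid: topics, keywords, and the best combinations.

    Returns each filter in its URL-inclusive form; callers add
    ``& Not(HasUrl())`` for the URL-excluded variant (the grid runner in
    :mod:`aqsurveil.pipeline` does both).
    """
    terms = dict(terms or KEYWORD_TERMS)
    out: dict[str, FilterExpr] = {
        "AQ": TopicMatch(model=model, topic=aq_topic),
    }
    if po_topic is not None:
        out["PO"] = TopicMatch(model=model, topic=po_topic)
    for name, term in terms.items():
        out[name] = Keyword(frozenset({term}))
    for kw in ("air", "pollution"):
        if kw in terms:
            out[f"AQ+{kw}"] = And(
                (TopicMatch(model=model, topic=aq_topic), Keyword(frozenset({terms[kw]})))
            )
    return out


def write_presets(directory, aq_topic: int, po_topic: Optional[int] = None) -> list:
    """Write each preset (± URL exclusion) as a YAML expression file."""
    import pathlib

    directory = pathlib.Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    written = []
    for name, expr in presets(aq_topic, po_topic).items():
        safe = name.replace("+", "_plus_").lower()
        for suffix, full in (
            ("", expr),
            ("_nourl", And((expr, Not(HasUrl())))),
        ):
            path = directory / f"{safe}{suffix}.yaml"
            path.write_text(full.to_yaml(), encoding="utf-8")
            written.append(path)
    return written
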