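"""Hierarchical message coding, dual-coder agreement, and summary trees.

The coding schema is a five-code tree: every message is coded *relevant*
(about air quality / pollution) or not; relevant messages are additionally
coded *firsthand* (the author's own experience rather than general
awareness) and *request_action*; firsthand messages are additionally coded
*behavior* (a reactive averting action, e.g. mask wearing) and *concern*
(an explicit health concern). Codes below an unsatisfied parent are
not-applicable (``na``).

Coding guidance (schema, not enforced in software): a general discomfort is
not coded as a health concern unless the health concern is explicit.

Agreement between two independent coders is quantified per code with
percent agreement and Cohen's kappa computed from the 2×2 contingency
table; by default a code's n counts only messages where the code is
applicable under *both* coders' own parent codes, which is why n shrinks
down the tree.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np

from .errors import (
    DuplicateRecordError,
    InsufficientDataError,
    KappaUndefinedError,
    MissingAdjudicationError,
)

CODES = ("relevant", "request_action", "firsthand", "behavior", "concern")
PARENT = {
    "relevant": None,
    "request_action": "relevant",
    "firsthand": "relevant",
    "behavior": "firsthand",
    "concern": "firsthand",
}
VALUES = ("y", "n", "na")


@dataclass
class AnnotationRecord:
    """One coder's codes for one message."""

    message_id: str
    coder_id: str
    codes: dict[str, str]

    def value(self, code: str) -> str:
        return self.codes[code]

    def applicable(self, code: str) -> bool:
        """True iff every ancestor of ``code`` is 'y' in this record."""
        parent = PARENT[code]
        while parent is not None:
            if self.codes.get(parent) != "y":
                return False
            parent = PARENT[parent]
        return True


def record_from_bools(
    message_id: str,
    coder_id: str,
    relevant: bool,
    firsthand: bool = False,
    behavior: bool = False,
    concern: bool = False,
    request_action: bool = False,
) -> AnnotationRecord:
    """Build a hierarchy-consistent record from boolean labels.

    Child booleans are ignored (coded ``na``) wherever the parent is false,
    so the result always satisfies the code tree.
    """
    codes = {"relevant": "y" if relevant else "n"}
    if relevant:
        codes["request_action"] = "y" if request_action else "n"
        codes["firsthand"] = "y" if firsthand else "n"
    else:
        codes["request_action"] = codes["firsthand"] = "na"
    if codes["firsthand"] == "y":
        codes["behavior"] = "y" if behavior else "n"
        codes["concern"] = "y" if concern else "n"
    else:
        codes["behavior"] = codes["concern"] = "na"
    return AnnotationRecord(message_id, coder_id, codes)


@dataclass
class Violation:
    message_id: str
    coder_id: str
    code: str
    reason: str


def validate_records(
    records: Iterable[AnnotationRecord],
) -> tuple[list[AnnotationRecord], list[Violation]]:
    """Split records into hierarchy-consistent ones and itemized violations.

    A record violates the tree when a child code carries y/n while its
    parent is not 'y', or is 'na' while its parent is 'y'. Violations are
    reported, never silently repaired. Duplicate (message, coder) pairs are
    an error.
    """
    records = list(records)
    seen: set[tuple[str, str]] = set()
    for r in records:
        key = (r.message_id, r.coder_id)
        if key in seen:
            raise DuplicateRecordError(f"duplicate record for {key}")
        seen.add(key)

    valid: list[AnnotationRecord] = []
    violations: list[Violation] = []
    for r in records:
        record_ok = True
        for code in CODES:
            v = r.codes.get(code)
            if v not in VALUES:
                violations.append(
                    Violation(r.message_id, r.coder_id, code, f"bad value {v!r}")
                )
                record_ok = False
                continue
            if PARENT[code] is None:
                if v == "na":
                    violations.append(
                        Violation(r.message_id, r.coder_id, code, "root code is na")
                    )
                    record_ok = False
                continue
            if r.applicable(code) and v == "na":
                violations.append(
                    Violation(
                        r.message_id, r.coder_id, code, "na under satisfied parent"
                    )
                )
                record_ok = False
            if not r.applicable(code) and v != "na":
                violations.append(
                    Violation(
                        r.message_id,
                        r.coder_id,
                        code,
                        f"{v!r} under unsatisfied parent {PARENT[code]!r}",
                    )
                )
                record_ok = False
        if record_ok:
            valid.append(r)
    return valid, violations


@dataclass
class AgreementResult:
    """Percent agreement and Cohen's kappa for one code."""

    code: str
    n: int
    p_o: float
    p_e: float
    kappa: float
    table: np.ndarray  # 2×2: rows coder A (y, n), cols coder B (y, n)


def kappa_from_table(table: np.ndarray) -> tuple[float, float, float]:
    """(p_o, p_e, kappa) from a 2×2 contingency table of paired codes.

    p_o is the diagonal mass; p_e the chance agreement from the marginal
    products; κ = (p_o − p_e) / (1 − p_e).
    """
    table = np.asarray(table, dtype=np.float64)
    n = table.sum()
    if n == 0:
        raise InsufficientDataError("empty contingency table")
    p = table / n
    p_o = float(np.trace(p))
    p_e = float(p.sum(axis=1) @ p.sum(axis=0))
    if p_e >= 1.0:
        raise KappaUndefinedError(
            f"chance agreement is 1 (both coders constant); p_o={p_o:.3f}", p_o=p_o
        )
    return p_o, p_e, (p_o - p_e) / (1.0 - p_e)


def agreement(
    records_a: Sequence[AnnotationRecord],
    records_b: Sequence[AnnotationRecord],
    code: str,
    applicability: str = "both",
) -> AgreementResult:
    """Dual-coder agreement for one code.

    ``applicability`` controls which messages enter n: ``"both"`` (default)
    counts messages where the code is applicable under both coders' own
    parent codes — the convention that makes n shrink down the code tree —
    while ``"either"`` requires it under at least one coder (the other
    coder's value then being 'na' and counted as a disagreement is not
    meaningful, so 'na' is treated as 'n' in that mode).
    """
    if code not in CODES:
        raise KeyError(f"unknown code {code!r}")
    a_by_id = {r.message_id: r for r in records_a}
    b_by_id = {r.message_id: r for r in records_b}
    shared = set(a_by_id) & set(b_by_id)
    if set(a_by_id) != set(b_by_id):
        raise InsufficientDataError(
            "coders cover different message sets; "
            f"{len(set(a_by_id) ^ set(b_by_id))} unmatched"
        )

    table = np.zeros((2, 2), dtype=np.int64)
    for mid in shared:
        ra, rb = a_by_id[mid], b_by_id[mid]
        if applicability == "both":
            if not (ra.applicable(code) and rb.applicable(code)):
                continue
            va, vb = ra.value(code), rb.value(code)
        else:
            if not (ra.applicable(code) or rb.applicable(code)):
                continue
            va = ra.value(code) if ra.value(code) != "na" else "n"
            vb = rb.value(code) if rb.value(code) != "na" else "n"
        table[0 if va == "y" else 1, 0 if vb == "y" else 1] += 1

    n = int(table.sum())
    if n < 2:
        raise InsufficientDataError(
            f"code {code!r} applicable to {n} jointly coded messages; need >= 2"
        )
    p_o, p_e, kappa = kappa_from_table(table)
    return AgreementResult(code=code, n=n, p_o=p_o, p_e=p_e, kappa=kappa, table=table)


def adjudicate(
    records_a: Sequence[AnnotationRecord],
    records_b: Sequence[AnnotationRecord],
    records_c: Sequence[AnnotationRecord],
) -> list[AnnotationRecord]:
    """Resolve dual-coder disagreements with a third coder's records.

    Codes are merged top-down the tree: where A and B agree the shared value
    passes through; where they genuinely disagree the tie-breaker's value is
    taken (missing coverage is an error). A coder's 'na' under their own
    unsatisfied parent means the coder never coded the cell, so once the
    parent resolves to 'y' the coder who did code it wins alone — only y/n
    conflicts reach the tie-breaker. Children of a resolved non-'y' parent
    are forced to 'na', so the output always satisfies the hierarchy.
    """
    a_by_id = {r.message_id: r for r in records_a}
    b_by_id = {r.message_id: r for r in records_b}
    c_by_id = {r.message_id: r for r in records_c}
    if set(a_by_id) != set(b_by_id):
        raise MissingAdjudicationError("coders A and B cover different messages")

    order = ("relevant", "request_action", "firsthand", "behavior", "concern")
    resolved: list[AnnotationRecord] = []
    for mid in a_by_id:
        ra, rb = a_by_id[mid], b_by_id[mid]
        codes: dict[str, str] = {}
        for code in order:
            parent = PARENT[code]
            if parent is not None and codes[parent] != "y":
                codes[code] = "na"
                continue
            va, vb = ra.value(code), rb.value(code)
            opinions = [v for v in (va, vb) if v != "na"]
            if len(set(opinions)) == 1:
                codes[code] = opinions[0]
            elif not opinions:
                codes[code] = "n"  # nobody coded it; parent came from C
            else:
                if mid not in c_by_id:
                    raise MissingAdjudicationError(
                        f"disagreement on {code!r} for message {mid!r} "
                        "has no tie-breaker record"
                    )
                vc = c_by_id[mid].value(code)
                codes[code] = "n" if vc == "na" else vc
        resolved.append(AnnotationRecord(mid, "resolved", codes))
    return resolved


@dataclass
class CodeNode:
    code: str
    count: int
    denominator: int
    proportion: Optional[float]  # None when the denominator is empty
    children: dict = field(default_factory=dict)

    @property
    def percent(self) -> Optional[float]:
        """Proportion as a percentage at one decimal, None if undefined."""
        if self.proportion is None:
            return None
        return round(100.0 * self.proportion, 1)


def summarize_codes(records: Sequence[AnnotationRecord]) -> CodeNode:
    """Hierarchical count/proportion tree over a resolved record set.

    Conditional proportions use the parent count as denominator (relevant of
    total; firsthand and request_action of relevant; behavior and concern of
    firsthand). An empty denominator yields an undefined (None) proportion,
    never 0.
    """
    total = len(records)
    n_rel = sum(1 for r in records if r.value("relevant") == "y")
    n_fh = sum(1 for r in records if r.codes.get("firsthand") == "y")
    n_beh = sum(1 for r in records if r.codes.get("behavior") == "y")
    n_con = sum(1 for r in records if r.codes.get("concern") == "y")
    n_act = sum(1 for r in records if r.codes.get("request_action") == "y")

    def node(code, count, denom, children=None):
        return CodeNode(
            code=code,
            count=count,
            denominator=denom,
            proportion=(count / denom) if denom else None,
            children=children or {},
        )

    firsthand = node(
        "firsthand",
        n_fh,
        n_rel,
        {
            "behavior": node("behavior", n_beh, n_fh),
            "concern": node("concern", n_con, n_fh),
        },
    )
    relevant = node(
        "relevant",
        n_rel,
        total,
        {
            "firsthand": firsthand,
            "request_action": node("request_action", n_act, n_rel),
        },
    )
    return CodeNode(
        code="total",
        count=total,
        denominator=total,
        proportion=1.0 if total else None,
        children={"relevant": relevant},
    )


def summary_to_dict(node: CodeNode) -> dict:
    return {
        "code": node.code,
        "count": node.count,
        "denominator": node.denominator,
        "percent": node.percent,
        "children": {k: summary_to_dict(v) for k, v in node.children.items()},
    }
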