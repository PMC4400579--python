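"""Readers and writers for the pipeline's file dialects.

All formats are plain text: messages as JSON-lines (one object per line,
canonical key order), pollution and rate tables as headered CSV, annotations
as CSV with ``y/n/na`` values, lexicons as one term per line. Writers emit a
canonical form, so write(read(x)) is byte-stable.
"""

from __future__ import annotations

import json
from typing import Iterable

import pandas as pd

from .annotation import CODES, AnnotationRecord
from .corpus import Lexicon, Message, MessageCorpus
from .errors import SchemaError
from .surveillance import CityRateTable, PollutionTable

_MESSAGE_FIELDS = ("id", "user_id", "city", "account_type", "tokens", "has_url")


def read_messages(path) -> MessageCorpus:
    """Read a JSON-lines message file; errors name the offending line."""
    messages = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            try:
                obj = json.loads(line)
            except json.JSONDecodeError as exc:
                raise SchemaError(f"{path}:{lineno}: invalid JSON ({exc.msg})") from exc
            missing = [f for f in _MESSAGE_FIELDS if f not in obj]
            if missing:
                raise SchemaError(f"{path}:{lineno}: missing fields {missing}")
            messages.append(
                Message(
                    id=str(obj["id"]),
                    user_id=str(obj["user_id"]),
                    city=str(obj["city"]),
                    account_type=str(obj["account_type"]),
                    tokens=[str(t) for t in obj["tokens"]],
                    has_url=bool(obj["has_url"]),
                    raw_text=obj.get("raw_text"),
                )
            )
    return MessageCorpus(messages)


def write_messages(corpus_or_messages, path) -> None:
    """Write messages as canonical JSON-lines (fixed key order, no spaces)."""
    messages: Iterable[Message] = (
        corpus_or_messages.messages
        if isinstance(corpus_or_messages, MessageCorpus)
        else corpus_or_messages
    )
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for m in messages:
            obj = {
                "id": m.id,
                "user_id": m.user_id,
                "city": m.city,
                "account_type": m.account_type,
                "tokens": list(m.tokens),
                "has_url": m.has_url,
            }
            if m.raw_text is not None:
                obj["raw_text"] = m.raw_text
            fh.write(json.dumps(obj, ensure_ascii=False, separators=(",", ":")))
            fh.write("\n")


def read_pollution(path) -> PollutionTable:
    frame = pd.read_csv(path, encoding="utf-8", float_precision="round_trip")
    missing = {"city", "adv", "mdv"} - set(frame.columns)
    if missing:
        raise SchemaError(f"{path}: missing column(s) {sorted(missing)}")
    return PollutionTable(frame=frame[["city", "adv", "mdv"]].copy())


def write_pollution(table: PollutionTable, path) -> None:
    table.to_csv(path)


def read_rates(path) -> CityRateTable:
    frame = pd.read_csv(path, encoding="utf-8", float_precision="round_trip")
    missing = {"city", "matched", "total", "rate"} - set(frame.columns)
    if missing:
        raise SchemaError(f"{path}: missing column(s) {sorted(missing)}")
    return CityRateTable(frame=frame)


def write_rates(table: CityRateTable, path) -> None:
    table.to_csv(path)


_ANNOTATION_COLUMNS = ("message_id", "coder_id") + CODES


def read_annotations(path) -> list[AnnotationRecord]:
    frame = pd.read_csv(path, encoding="utf-8", dtype=str)
    missing = set(_ANNOTATION_COLUMNS) - set(frame.columns)
    if missing:
        raise SchemaError(f"{path}: missing column(s) {sorted(missing)}")
    records = []
    for _, row in frame.iterrows():
        codes = {c: str(row[c]) for c in CODES}
        bad = [v for v in codes.values() if v not in ("y", "n", "na")]
        if bad:
            raise SchemaError(f"{path}: invalid code value(s) {bad}")
        records.append(
            AnnotationRecord(str(row["message_id"]), str(row["coder_id"]), codes)
        )
    return records


def write_annotations(records: Iterable[AnnotationRecord], path) -> None:
    rows = [
        {"message_id": r.message_id, "coder_id": r.coder_id, **r.codes}
        for r in records
    ]
    frame = pd.DataFrame(rows, columns=list(_ANNOTATION_COLUMNS))
    frame.to_csv(path, index=False, encoding="utf-8", lineterminator="\n")


def read_lexicon(path, name=None) -> Lexicon:
    return Lexicon.from_file(path, name=name)


def write_id_list(ids: Iterable[str], path) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for i in sorted(ids):
            fh.write(i)
            fh.write("\n")


def read_id_list(path) -> frozenset:
    with open(path, encoding="utf-8") as fh:
        return frozenset(line.strip() for line in fh if line.strip())
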