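"""Standoff corpus I/O (JSON-lines, UTF-8) and word-embedding import.

One JSON document per note with fields in a fixed order: ``note_id``,
``text``, ``sections`` (name/start/end), ``entities`` (id/start/end and an
optional ``gold_index``), ``temporal_expressions`` (id/start/end/value/kind),
``admission_te``, ``discharge_te``.  The writer is bit-stable: writing an
unchanged corpus reproduces the file byte for byte.
"""

from __future__ import annotations

import datetime
import json
from pathlib import Path
from typing import Union

import numpy as np

from .corpus import (
    ClinicalNote,
    CorpusValidationError,
    MedicalEntity,
    Span,
    TEKind,
    TemporalExpression,
)
from .sections import make_section

PathLike = Union[str, Path]


class CorpusParseError(ValueError):
    """Malformed corpus file; message names the line and field."""


def _parse_note(doc: dict, line_no: int) -> ClinicalNote:
    def need(field: str, obj: dict = doc):
        if field not in obj:
            raise CorpusParseError(f"line {line_no}: missing field {field!r}")
        return obj[field]

    note_id = str(need("note_id"))
    text = need("text")
    sections = [
        make_section(str(need("name", s)), int(need("start", s)), int(need("end", s)))
        for s in need("sections")
    ]
    entities = []
    for e in need("entities"):
        span = Span(int(need("start", e)), int(need("end", e)))
        gold = e.get("gold_index")
        entities.append(
            MedicalEntity(
                me_id=str(need("id", e)),
                span=span,
                surface=text[span.start : span.end],
                gold_index=None if gold is None else int(gold),
            )
        )
    tes = []
    for t in need("temporal_expressions"):
        span = Span(int(need("start", t)), int(need("end", t)))
        try:
            value = datetime.date.fromisoformat(str(need("value", t)))
        except ValueError as exc:
            raise CorpusParseError(
                f"line {line_no}: TE {t.get('id')!r} value {t.get('value')!r}: {exc}"
            ) from None
        tes.append(
            TemporalExpression(
                te_id=str(need("id", t)),
                span=span,
                surface=text[span.start : span.end],
                normalized_value=value,
                kind=TEKind(t.get("kind", "other")),
            )
        )
    return ClinicalNote(
        note_id=note_id,
        text=text,
        sections=sections,
        entities=entities,
        temporal_expressions=tes,
        admission_te_id=doc.get("admission_te"),
        discharge_te_id=doc.get("discharge_te"),
    )


def read_notes(path: PathLike) -> list[ClinicalNote]:
    """Read and validate a JSON-lines corpus; reject invalid notes."""
    notes = []
    with open(path, "r", encoding="utf-8") as fh:
        for line_no, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            try:
                doc = json.loads(line)
            except json.JSONDecodeError as exc:
                raise CorpusParseError(f"line {line_no}: invalid JSON: {exc}") from None
            note = _parse_note(doc, line_no)
            try:
                note.validate()
            except CorpusValidationError:
                raise
            notes.append(note)
    return notes


def note_to_doc(note: ClinicalNote) -> dict:
    """Serialize one note with keys in the documented order."""
    doc: dict = {"note_id": note.note_id, "text": note.text}
    doc["sections"] = [
        {"name": s.name, "start": s.span.start, "end": s.span.end}
        for s in note.sections
    ]
    doc["entities"] = [
        {
            "id": e.me_id,
            "start": e.span.start,
            "end": e.span.end,
            **({} if e.gold_index is None else {"gold_index": e.gold_index}),
        }
        for e in note.entities
    ]
    doc["temporal_expressions"] = [
        {
            "id": t.te_id,
            "start": t.span.start,
            "end": t.span.end,
            "value": t.normalized_value.isoformat(),
            "kind": t.kind.value,
        }
        for t in note.temporal_expressions
    ]
    doc["admission_te"] = note.admission_te_id
    doc["discharge_te"] = note.discharge_te_id
    return doc


def write_notes(notes: list[ClinicalNote], path: PathLike) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for note in notes:
            fh.write(json.dumps(note_to_doc(note), ensure_ascii=False))
            fh.write("\n")


def read_word2vec_text(path: PathLike) -> tuple[list[str], np.ndarray]:
    """Read a word2vec *text*-format table: "V D" header, then token + D floats.

    Returns (tokens, matrix of shape (V, D)).
    """
    with open(path, "r", encoding="utf-8") as fh:
        header = fh.readline().split()
        if len(header) != 2:
            raise CorpusParseError(f"{path}: expected 'V D' header, got {header!r}")
        n_vec, dim = int(header[0]), int(header[1])
        tokens: list[str] = []
        rows = np.empty((n_vec, dim), dtype=np.float64)
        for i in range(n_vec):
            parts = fh.readline().rstrip("\n").split(" ")
            if len(parts) != dim + 1:
                raise CorpusParseError(
                    f"{path}: line {i + 2}: expected token + {dim} floats"
                )
            tokens.append(parts[0])
            rows[i] = [float(x) for x in parts[1:]]
    return tokens, rows


def write_word2vec_text(tokens: list[str], matrix: np.ndarray, path: PathLike) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"{len(tokens)} {matrix.shape[1]}\n")
        for tok, row in zip(tokens, matrix):
            fh.write(tok + " " + " ".join(format(v, ".6g") for v in row) + "\n")
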