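"""Domain model for temporally indexed clinical notes.

A note carries raw text plus standoff annotations: named sections, medical
entities (MEs) and temporal expressions (TEs).  All TEs of a note, sorted by
their normalized calendar value, define a per-note timeline in which time
*nodes* (one per distinct value) receive odd IDs 1, 3, ..., 2n-1 and the time
*intervals* between / around them receive even IDs 0, 2, ..., 2n.  Every ME is
indexed to exactly one timeline ID, either directly (a node) or through the
interval just before/after a node.

The pairwise relation labels tie the two views together: for an (ME, TE) pair,
SIMULTANEOUS means the ME is indexed to the TE's node, BEFORE (AFTER) means it
is indexed to the interval immediately before (after) that node, and NONE
means the TE carries no information about the ME's index.
"""

from __future__ import annotations

import datetime
import re
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Optional


class Relation(str, Enum):
    """Pairwise temporal relation between a medical entity and a TE."""

    NONE = "NONE"
    SIMULTANEOUS = "SIMULTANEOUS"
    BEFORE = "BEFORE"
    AFTER = "AFTER"


#: Relations that carry indexing information (NONE never yields an index).
INDEXING_RELATIONS = (Relation.SIMULTANEOUS, Relation.BEFORE, Relation.AFTER)


class Anchor(str, Enum):
    """Which reference time a section is anchored to."""

    ADMISSION = "admission"
    DISCHARGE = "discharge"


class TEKind(str, Enum):
    """Role of a temporal expression within the note."""

    ADMISSION = "admission"
    DISCHARGE = "discharge"
    OTHER = "other"


@dataclass(frozen=True)
class Span:
    """0-based, half-open character interval."""

    start: int
    end: int

    def __post_init__(self) -> None:
        if not (0 <= self.start <= self.end):
            raise ValueError(f"invalid span ({self.start}, {self.end})")

    def __len__(self) -> int:
        return self.end - self.start

    def contains(self, other: "Span") -> bool:
        return self.start <= other.start and other.end <= self.end

    def overlaps(self, other: "Span") -> bool:
        return self.start < other.end and other.start < self.end


@dataclass
class Section:
    name: str
    span: Span
    anchor: Anchor
    anchor_relation: Relation


@dataclass
class MedicalEntity:
    me_id: str
    span: Span
    surface: str
    gold_index: Optional[int] = None


@dataclass
class TemporalExpression:
    te_id: str
    span: Span
    surface: str
    normalized_value: datetime.date
    kind: TEKind = TEKind.OTHER


@dataclass
class SentenceSpan:
    index: int
    span: Span
    section: Section


class CorpusValidationError(ValueError):
    """An annotation invariant is violated; message names the offending note."""


@dataclass
class ClinicalNote:
    note_id: str
    text: str
    sections: list[Section]
    entities: list[MedicalEntity]
    temporal_expressions: list[TemporalExpression]
    admission_te_id: Optional[str] = None
    discharge_te_id: Optional[str] = None

    # ------------------------------------------------------------------ lookup
    def te_by_id(self, te_id: str) -> TemporalExpression:
        for te in self.temporal_expressions:
            if te.te_id == te_id:
                return te
        raise KeyError(f"note {self.note_id}: unknown TE id {te_id!r}")

    def entity_by_id(self, me_id: str) -> MedicalEntity:
        for me in self.entities:
            if me.me_id == me_id:
                return me
        raise KeyError(f"note {self.note_id}: unknown ME id {me_id!r}")

    def section_of(self, span: Span) -> Section:
        for sec in self.sections:
            if sec.span.contains(span):
                return sec
        raise CorpusValidationError(
            f"note {self.note_id}: span ({span.start},{span.end}) "
            "lies in no section"
        )

    # -------------------------------------------------------------- validation
    def validate(self) -> None:
        n = len(self.text)
        text_span = Span(0, n)
        for sec in self.sections:
            if not text_span.contains(sec.span):
                raise CorpusValidationError(
                    f"note {self.note_id}: section {sec.name!r} out of bounds"
                )
        for prev, cur in zip(self.sections, self.sections[1:]):
            if prev.span.end > cur.span.start:
                raise CorpusValidationError(
                    f"note {self.note_id}: overlapping sections "
                    f"{prev.name!r} and {cur.name!r}"
                )
        spans = [(me.me_id, me.span) for me in self.entities]
        spans += [(te.te_id, te.span) for te in self.temporal_expressions]
        for ann_id, span in spans:
            if not text_span.contains(span):
                raise CorpusValidationError(
                    f"note {self.note_id}: span of {ann_id!r} out of bounds"
                )
            if not any(sec.span.contains(span) for sec in self.sections):
                crossing = any(sec.span.overlaps(span) for sec in self.sections)
                kind = "crosses a section boundary" if crossing else "lies in no section"
                raise CorpusValidationError(
                    f"note {self.note_id}: span of {ann_id!r} {kind}"
                )
        te_ids = {te.te_id for te in self.temporal_expressions}
        for label, ref in (
            ("admission", self.admission_te_id),
            ("discharge", self.discharge_te_id),
        ):
            if ref is not None and ref not in te_ids:
                raise CorpusValidationError(
                    f"note {self.note_id}: {label} TE id {ref!r} "
                    "does not refer to a TE of the note"
                )
        if self.entities and any(me.gold_index is not None for me in self.entities):
            timeline = build_timeline(self)
            for me in self.entities:
                if me.gold_index is not None and me.gold_index not in timeline.ids():
                    raise CorpusValidationError(
                        f"note {self.note_id}: gold index {me.gold_index} of "
                        f"{me.me_id!r} is not a valid timeline ID"
                    )


# ---------------------------------------------------------------------------
# Timeline
# ---------------------------------------------------------------------------


@dataclass
class TimeNode:
    """One distinct normalized value; holds all TE mentions sharing it."""

    value: datetime.date
    te_ids: list[str]
    node_id: int  # odd


@dataclass
class Timeline:
    """Ordered alternation of intervals (even IDs) and nodes (odd IDs).

    For n nodes the ID set is exactly {0, ..., 2n}: interval 0 precedes the
    first node (ID 1), interval 2n follows the last node (ID 2n-1).
    """

    nodes: list[TimeNode] = field(default_factory=list)

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    def ids(self) -> range:
        return range(0, 2 * self.n_nodes + 1)

    def node_id_of(self, te_id: str) -> int:
        for node in self.nodes:
            if te_id in node.te_ids:
                return node.node_id
        raise KeyError(f"TE {te_id!r} is not on this timeline")

    def tes_on_node_id(self, node_id: int) -> list[str]:
        for node in self.nodes:
            if node.node_id == node_id:
                return list(node.te_ids)
        raise KeyError(f"no node with ID {node_id}")

    @staticmethod
    def is_node_id(index: int) -> bool:
        return index % 2 == 1


def build_timeline(note: ClinicalNote) -> Timeline:
    """Sort TEs by normalized value, merge equal values, number 1,3,5,...

    Mentions sharing one normalized value share one node: the annotation
    scheme allocates one ID per *time*, not per mention.
    """
    for te in note.temporal_expressions:
        if te.normalized_value is None:
            raise CorpusValidationError(
                f"note {note.note_id}: TE {te.te_id!r} has no normalized value"
            )
    ordered = sorted(note.temporal_expressions, key=lambda t: t.normalized_value)
    nodes: list[TimeNode] = []
    for te in ordered:
        if nodes and nodes[-1].value == te.normalized_value:
            nodes[-1].te_ids.append(te.te_id)
        else:
            nodes.append(
                TimeNode(value=te.normalized_value, te_ids=[te.te_id],
                         node_id=2 * len(nodes) + 1)
            )
    return Timeline(nodes=nodes)


def relation_to_index(
    te: TemporalExpression, relation: Relation, timeline: Timeline
) -> int:
    """Map a non-NONE relation on a TE to the indexed timeline ID."""
    if relation not in INDEXING_RELATIONS:
        raise ValueError(f"relation {relation} never yields a timeline index")
    node_id = timeline.node_id_of(te.te_id)
    if relation is Relation.SIMULTANEOUS:
        return node_id
    if relation is Relation.BEFORE:
        return node_id - 1
    return node_id + 1


def gold_relation_for_pair(
    me: MedicalEntity, te: TemporalExpression, timeline: Timeline
) -> Relation:
    """Relation label implied by the ME's gold index for this TE.

    An interval gold index is adjacent to (at most) two nodes, so it yields
    AFTER for the preceding TE and BEFORE for the following one; both pairs
    count as positive.  Any TE two or more steps away yields NONE.
    """
    if me.gold_index is None:
        raise ValueError(f"entity {me.me_id!r} has no gold index")
    node_id = timeline.node_id_of(te.te_id)
    if me.gold_index == node_id:
        return Relation.SIMULTANEOUS
    if me.gold_index == node_id - 1:
        return Relation.BEFORE
    if me.gold_index == node_id + 1:
        return Relation.AFTER
    return Relation.NONE


# ---------------------------------------------------------------------------
# Sentence segmentation
# ---------------------------------------------------------------------------

#: Terminators that end a sentence (Chinese and ASCII), plus newline.
SENTENCE_TERMINATORS = "。！？；?!;\n"

_TERMINATOR_RE = re.compile("[" + re.escape(SENTENCE_TERMINATORS) + "]")


def segment_sentences(note: ClinicalNote) -> list[SentenceSpan]:
    """Split each section into sentences on 。！？； ? ! ; and newline.

    The terminator is attached to the preceding sentence; empty fragments are
    dropped; a boundary is suppressed when it would split an annotated entity
    or TE span.  Sentence spans tile each section.
    """
    protected = [me.span for me in note.entities] + [
        te.span for te in note.temporal_expressions
    ]

    def splits_annotation(pos: int) -> bool:
        return any(sp.start < pos < sp.end for sp in protected)

    sentences: list[SentenceSpan] = []
    for sec in note.sections:
        chunk = note.text[sec.span.start : sec.span.end]
        boundaries = []
        for m in _TERMINATOR_RE.finditer(chunk):
            pos = sec.span.start + m.end()
            if not splits_annotation(pos):
                boundaries.append(pos)
        start = sec.span.start
        for pos in boundaries + [sec.span.end]:
            if pos > start:
                sentences.append(
                    SentenceSpan(index=len(sentences), span=Span(start, pos),
                                 section=sec)
                )
                start = pos
    return sentences


def sentence_of(span: Span, sentences: Iterable[SentenceSpan]) -> SentenceSpan:
    for sent in sentences:
        if sent.span.contains(span):
            return sent
    raise CorpusValidationError(
        f"span ({span.start},{span.end}) is not inside any sentence"
    )


# ---------------------------------------------------------------------------
# Convenience date parsing (normalized values are otherwise required input)
# ---------------------------------------------------------------------------

_ISO_RE = re.compile(r"^(\d{4})-(\d{1,2})-(\d{1,2})$")
_CN_RE = re.compile(r"^(\d{4})年(\d{1,2})月(\d{1,2})日$")
_AGO_RE = re.compile(r"^(\d+)(?:天前| days ago)$")


def parse_date(
    surface: str, admission: Optional[datetime.date] = None
) -> datetime.date:
    """Parse YYYY-MM-DD, YYYY年MM月DD日, or "X天前"/"X days ago".

    Relative expressions are resolved against the admission date.  Anything
    else must arrive pre-normalized.
    """
    m = _ISO_RE.match(surface) or _CN_RE.match(surface)
    if m:
        return datetime.date(int(m.group(1)), int(m.group(2)), int(m.group(3)))
    m = _AGO_RE.match(surface)
    if m:
        if admission is None:
            raise ValueError(
                f"relative date {surface!r} needs an admission date to resolve"
            )
        return admission - datetime.timedelta(days=int(m.group(1)))
    raise ValueError(f"unsupported date surface {surface!r}")
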