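"""Per-entity candidate time selection.

Pairing every ME with every TE of a note floods training with negatives, so
the candidate set of an entity is restricted to its section: the section's
anchor time (admission or discharge TE, per the section inventory) plus all
TEs whose span lies inside the entity's section.  The anchor comes first,
then section TEs in text order, deduplicated — a deterministic ordering that
downstream tie-breaking relies on.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

from .corpus import (
    Anchor,
    ClinicalNote,
    CorpusValidationError,
    MedicalEntity,
    Relation,
    Section,
    Timeline,
    build_timeline,
    relation_to_index,
)


@dataclass
class CandidateSet:
    me_id: str
    candidates: list[str]  # TE ids, anchor first then text order
    covered: Optional[bool] = None  # gold index reachable via S/B/A


def section_anchor_te(section: Section, note: ClinicalNote) -> str:
    """The admission or discharge TE id the section is anchored to."""
    te_id = (
        note.admission_te_id
        if section.anchor is Anchor.ADMISSION
        else note.discharge_te_id
    )
    if te_id is None:
        raise CorpusValidationError(
            f"note {note.note_id}: section {section.name!r} needs the "
            f"{section.anchor.value} TE, which the note does not carry"
        )
    return te_id


def candidates_for_entity(
    me: MedicalEntity, note: ClinicalNote, timeline: Optional[Timeline] = None
) -> CandidateSet:
    """Anchor TE plus all TEs of the entity's section, in text order."""
    section = note.section_of(me.span)
    anchor_id = section_anchor_te(section, note)
    ordered = [anchor_id]
    for te in sorted(note.temporal_expressions, key=lambda t: t.span.start):
        if section.span.contains(te.span) and te.te_id not in ordered:
            ordered.append(te.te_id)

    covered = None
    if me.gold_index is not None:
        timeline = timeline or build_timeline(note)
        reachable = {
            relation_to_index(note.te_by_id(te_id), rel, timeline)
            for te_id in ordered
            for rel in (Relation.SIMULTANEOUS, Relation.BEFORE, Relation.AFTER)
        }
        covered = me.gold_index in reachable
    return CandidateSet(me_id=me.me_id, candidates=ordered, covered=covered)


@dataclass
class CoverageReport:
    n_notes: int
    n_entities: int
    n_covered: int
    total_pairs: int

    @property
    def coverage(self) -> float:
        return self.n_covered / self.n_entities

    @property
    def mean_candidates(self) -> float:
        return self.total_pairs / self.n_entities

    def to_dict(self) -> dict:
        return {
            "notes": self.n_notes,
            "entities": self.n_entities,
            "covered": self.n_covered,
            "coverage": self.coverage,
            "total_pairs": self.total_pairs,
            "mean_candidates": self.mean_candidates,
        }

    def to_text(self) -> str:
        rows = [
            ("Notes", f"{self.n_notes}"),
            ("Medical entities", f"{self.n_entities}"),
            ("Selected pairs", f"{self.total_pairs}"),
            ("Candidates per entity", f"{self.mean_candidates:.2f}"),
            ("Coverage", f"{self.coverage:.2%}"),
        ]
        width = max(len(k) for k, _ in rows)
        return "\n".join(f"{k:<{width}}  {v}" for k, v in rows)


def coverage_report(corpus: list[ClinicalNote]) -> CoverageReport:
    """Fraction of entities whose gold index is reachable from a candidate."""
    if not corpus:
        raise ValueError("coverage report needs a non-empty corpus")
    n_entities = n_covered = total_pairs = 0
    for note in corpus:
        timeline = build_timeline(note)
        for me in note.entities:
            if me.gold_index is None:
                raise CorpusValidationError(
                    f"note {note.note_id}: entity {me.me_id!r} lacks a gold index"
                )
            cand = candidates_for_entity(me, note, timeline)
            n_entities += 1
            n_covered += bool(cand.covered)
            total_pairs += len(cand.candidates)
    return CoverageReport(
        n_notes=len(corpus),
        n_entities=n_entities,
        n_covered=n_covered,
        total_pairs=total_pairs,
    )
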