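"""Section inventory of Chinese clinical notes and header matching.

Admission notes and discharge summaries follow a fixed sectional skeleton
(chief complaint, history of present illness, ...).  Each section name is
associated with a reference ("anchor") time — the admission or the discharge
time — and a default temporal relation of its content to that anchor: the
history of present illness happened *before* admission, the physical
examination *at* admission, discharge orders apply *after* discharge, and so
on.  This anchor/relation pair is what the candidate-selection and rule
baselines lean on.
"""

from __future__ import annotations

from typing import Mapping

import yaml

from .corpus import Anchor, ClinicalNote, Relation, Section, Span

#: section name -> (anchor, relation of the section content to the anchor)
SECTION_INFO: dict[str, tuple[Anchor, Relation]] = {
    "Chief complaint": (Anchor.ADMISSION, Relation.BEFORE),
    "History of present illness": (Anchor.ADMISSION, Relation.BEFORE),
    "Past medical history": (Anchor.ADMISSION, Relation.BEFORE),
    "Personal history": (Anchor.ADMISSION, Relation.BEFORE),
    "Conditions in admission": (Anchor.ADMISSION, Relation.BEFORE),
    "Physical examination": (Anchor.ADMISSION, Relation.SIMULTANEOUS),
    "Assistant examination": (Anchor.ADMISSION, Relation.SIMULTANEOUS),
    "Preliminary diagnosis": (Anchor.ADMISSION, Relation.SIMULTANEOUS),
    "Diagnosis on admission": (Anchor.ADMISSION, Relation.SIMULTANEOUS),
    "Diagnosis and treatment": (Anchor.ADMISSION, Relation.AFTER),
    "Conditions in discharge": (Anchor.DISCHARGE, Relation.SIMULTANEOUS),
    "Diagnosis on discharge": (Anchor.DISCHARGE, Relation.SIMULTANEOUS),
    "Discharge orders": (Anchor.DISCHARGE, Relation.AFTER),
    "Other": (Anchor.ADMISSION, Relation.SIMULTANEOUS),
}

SECTION_NAMES = tuple(SECTION_INFO)

#: Chinese surface headers and English names, both accepted at line starts.
DEFAULT_HEADER_LEXICON: dict[str, str] = {
    "主诉": "Chief complaint",
    "现病史": "History of present illness",
    "既往史": "Past medical history",
    "个人史": "Personal history",
    "入院情况": "Conditions in admission",
    "体格检查": "Physical examination",
    "辅助检查": "Assistant examination",
    "初步诊断": "Preliminary diagnosis",
    "入院诊断": "Diagnosis on admission",
    "诊疗经过": "Diagnosis and treatment",
    "出院情况": "Conditions in discharge",
    "出院诊断": "Diagnosis on discharge",
    "出院医嘱": "Discharge orders",
}
DEFAULT_HEADER_LEXICON.update({name: name for name in SECTION_NAMES if name != "Other"})


def make_section(name: str, start: int, end: int) -> Section:
    """Build a Section with anchor metadata looked up from the inventory."""
    anchor, rel = SECTION_INFO.get(name, SECTION_INFO["Other"])
    return Section(name=name, span=Span(start, end), anchor=anchor,
                   anchor_relation=rel)


def load_header_lexicon(path: str) -> dict[str, str]:
    """Load a user header lexicon (YAML mapping header -> section name)."""
    with open(path, "r", encoding="utf-8") as fh:
        lex = yaml.safe_load(fh)
    if not isinstance(lex, dict) or not lex:
        raise ValueError(f"{path}: header lexicon must be a non-empty mapping")
    unknown = set(lex.values()) - set(SECTION_NAMES)
    if unknown:
        raise ValueError(f"{path}: unknown section names {sorted(unknown)}")
    return {str(k): str(v) for k, v in lex.items()}


def match_sections(
    note_text: str, header_lexicon: Mapping[str, str] | None = None
) -> list[Section]:
    """Locate sections by matching known headers at line starts.

    Each section runs from its header to the next header (or end of text);
    unmatched leading text becomes an "Other" section.  A fallback for input
    that lacks explicit section annotations.
    """
    lexicon = dict(header_lexicon) if header_lexicon else DEFAULT_HEADER_LEXICON
    if not lexicon:
        raise ValueError("header lexicon is empty")
    # longest headers first so e.g. 入院诊断 wins over a hypothetical 入院 entry
    headers = sorted(lexicon, key=len, reverse=True)

    starts: list[tuple[int, str]] = []  # (char offset, section name)
    offset = 0
    for line in note_text.splitlines(keepends=True):
        stripped = line.lstrip()
        indent = len(line) - len(stripped)
        for header in headers:
            if stripped.startswith(header):
                starts.append((offset + indent, lexicon[header]))
                break
        offset += len(line)
    starts.sort(key=lambda item: item[0])

    sections: list[Section] = []
    if not starts:
        return [make_section("Other", 0, len(note_text))]
    if starts[0][0] > 0:
        sections.append(make_section("Other", 0, starts[0][0]))
    for (start, name), nxt in zip(starts, starts[1:] + [(len(note_text), "")]):
        sections.append(make_section(name, start, nxt[0]))
    return sections


def resolve_sections(note: ClinicalNote) -> None:
    """Fill anchor metadata in place; fall back to header matching if needed.

    Explicit section annotations in the input are trusted; matching runs only
    when the note carries none.
    """
    if not note.sections:
        note.sections = match_sections(note.text)
        return
    for sec in note.sections:
        anchor, rel = SECTION_INFO.get(sec.name, SECTION_INFO["Other"])
        sec.anchor, sec.anchor_relation = anchor, rel
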