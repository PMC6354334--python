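"""Seeded generator of synthetic section-structured clinical notes.

The generator emulates the *shape* of an annotated corpus of Chinese
admission/discharge notes — the fixed section skeleton, roughly 22 medical
entities and a handful of dated temporal expressions per note, and a ~68/32
split between time-node and time-interval gold indices — without any claim
to clinical realism.  Surface text is template-generated pseudo-clinical
prose over a small fixed vocabulary mixed with ISO date literals; what is
realistic, and what the rest of the package is tested on, is the positional
structure.

Every entity is planted by one template, and its gold timeline index is
*derived* from the template (via the planted TE and relation), so gold
labels are recoverable by construction:

* ``sim``            a date immediately precedes the entity in its sentence
                     -> SIMULTANEOUS with that TE (node);
* ``after``          date + procedure, then a 术后-style connective before
                     the entity -> AFTER that TE (interval);
* ``before``         date + 之前-style connective -> BEFORE that TE (interval);
* ``anchor_*``       a sentence without any TE -> the entity is indexed
                     through its section's anchor time and anchor relation.

Additionally the record-header ("Other") section lists *reference dates* —
the day before/after admission and separators between same-section content
dates — so that on the note's timeline no non-intended candidate TE is ever
within one step of an entity's gold index.  Planted relation labels are
therefore locally decidable from the sentence surfaces and the pair
features, which is what makes the corpus learnable by design.
"""

from __future__ import annotations

import datetime
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .corpus import (
    ClinicalNote,
    MedicalEntity,
    Relation,
    Span,
    TEKind,
    TemporalExpression,
    build_timeline,
    relation_to_index,
)
from .sections import make_section

ENTITY_SURFACES = (
    "发热", "咳嗽", "头痛", "腹痛", "恶心", "呕吐", "乏力", "腰痛", "水肿",
    "贫血", "高血压", "糖尿病", "感染", "结石", "出血", "心悸", "气促",
    "胸闷", "皮疹", "尿频", "眩晕", "腹泻",
)
SIM_VERBS = ("患者出现", "复查提示", "查见")
ANCHOR_PATTERNS = ("患者诉{e}明显。", "给予{e}治疗。", "查体见{e}。")
PROCEDURES = ("手术", "胃镜检查", "碎石术", "刮宫术")

_SECTION_ORDER = (
    "Other",
    "Chief complaint",
    "History of present illness",
    "Past medical history",
    "Physical examination",
    "Assistant examination",
    "Preliminary diagnosis",
    "Diagnosis and treatment",
    "Conditions in discharge",
    "Discharge orders",
)
_HEADERS = {
    "Chief complaint": "主诉",
    "History of present illness": "现病史",
    "Past medical history": "既往史",
    "Physical examination": "体格检查",
    "Assistant examination": "辅助检查",
    "Preliminary diagnosis": "初步诊断",
    "Diagnosis and treatment": "诊疗经过",
    "Conditions in discharge": "出院情况",
    "Discharge orders": "出院医嘱",
}

#: template -> (gold kind, candidate sections with sampling weights)
_NODE_TEMPLATES = {
    "sim": (("History of present illness", 0.6), ("Past medical history", 0.2),
            ("Diagnosis and treatment", 0.2)),
    "anchor_sim": (("Physical examination", 0.4), ("Assistant examination", 0.35),
                   ("Preliminary diagnosis", 0.25)),
    "anchor_dis_sim": (("Conditions in discharge", 1.0),),
}
_INTERVAL_TEMPLATES = {
    "after": (("Diagnosis and treatment", 1.0),),
    "before": (("History of present illness", 1.0),),
    "anchor_before": (("Chief complaint", 1.0),),
    "anchor_dis_after": (("Discharge orders", 1.0),),
    "anchor_dt_after": (("Diagnosis and treatment", 1.0),),
}
_NODE_WEIGHTS = {"sim": 0.60, "anchor_sim": 0.25, "anchor_dis_sim": 0.15}
_INTERVAL_WEIGHTS = {
    "after": 0.35, "before": 0.20, "anchor_before": 0.30,
    "anchor_dis_after": 0.10, "anchor_dt_after": 0.05,
}

#: history-side sections (content dates before admission) vs treatment side
_HISTORY_SECTIONS = {"History of present illness", "Past medical history"}

_CHUNK_SIZE = {"sim": 3, "after": 2, "before": 2}


@dataclass
class GeneratorConfig:
    n_notes: int = 100
    seed: int = 0
    mean_entities: float = 22.0
    mean_tes: float = 7.0
    node_interval_mix: tuple[float, float] = (0.68, 0.32)
    label_noise: float = 0.0
    discharge_gap_days: int = 30

    def validate(self) -> None:
        if self.n_notes <= 0:
            raise ValueError("n_notes must be positive")
        if self.mean_entities <= 0 or self.mean_tes < 1:
            raise ValueError("mean_entities must be > 0 and mean_tes >= 1")
        if abs(sum(self.node_interval_mix) - 1.0) > 1e-9 or any(
            p < 0 for p in self.node_interval_mix
        ):
            raise ValueError("node_interval_mix must be a 2-point distribution")
        if not 0.0 <= self.label_noise <= 1.0:
            raise ValueError("label_noise must lie in [0, 1]")
        if self.node_interval_mix[1] > 0 and self.mean_tes < 1:
            raise ValueError(
                "an interval share > 0 is infeasible without temporal expressions"
            )


@dataclass
class _Chunk:
    kind: str  # sim / after / before
    section: str
    entities: list[str]
    offset: Optional[int] = None  # date offset from admission, filled later


@dataclass
class _AnchorItem:
    template: str
    section: str
    entity: str
    relation: Relation


@dataclass
class _NoteBuilder:
    text: str = ""
    sections: list = field(default_factory=list)
    entities: list = field(default_factory=list)
    tes: list = field(default_factory=list)

    def add_te(self, note_id, start, end, value, kind) -> str:
        te_id = f"{note_id}-t{len(self.tes)}"
        self.tes.append(
            TemporalExpression(
                te_id=te_id, span=Span(start, end),
                surface=self.text[start:end], normalized_value=value, kind=kind,
            )
        )
        return te_id

    def add_entity(self, note_id, start, end) -> str:
        me_id = f"{note_id}-e{len(self.entities)}"
        self.entities.append(
            MedicalEntity(me_id=me_id, span=Span(start, end),
                          surface=self.text[start:end])
        )
        return me_id


def _weighted_choice(rng: np.random.Generator, weights: dict[str, float]) -> str:
    keys = list(weights)
    probs = np.array([weights[k] for k in keys], dtype=float)
    return keys[rng.choice(len(keys), p=probs / probs.sum())]


def _pick_section(rng: np.random.Generator, template: str) -> str:
    options = (_NODE_TEMPLATES | _INTERVAL_TEMPLATES)[template]
    names = [name for name, _ in options]
    probs = np.array([w for _, w in options], dtype=float)
    return names[rng.choice(len(names), p=probs / probs.sum())]


def _allocate_dates(
    rng: np.random.Generator, chunks: list[_Chunk], side_sections: set[str],
    sign: int,
) -> list[int]:
    """Assign even offsets to one side's chunks; return repair buffer offsets.

    Offsets are handed out round-robin across sections so that same-section
    content dates are rarely value-adjacent; where two still end up adjacent,
    an odd reference-date offset is inserted between them, guaranteeing that
    co-candidate TEs are never neighbouring timeline nodes.
    """
    side = [c for c in chunks if (c.section in side_sections) == (sign < 0)]
    by_section: dict[str, list[_Chunk]] = {}
    for chunk in side:
        by_section.setdefault(chunk.section, []).append(chunk)
    interleaved: list[_Chunk] = []
    pools = list(by_section.values())
    while any(pools):
        for pool in pools:
            if pool:
                interleaved.append(pool.pop(0))
    for i, chunk in enumerate(interleaved):
        chunk.offset = sign * 2 * (i + 1)
    buffers = []
    for a, b in zip(interleaved, interleaved[1:]):
        if a.section == b.section:
            buffers.append((a.offset + b.offset) // 2)  # odd midpoint
    return buffers


def generate_note(
    rng: np.random.Generator, config: GeneratorConfig, note_id: str
) -> tuple[ClinicalNote, dict]:
    n_entities = max(6, int(rng.poisson(config.mean_entities)))
    adm = datetime.date(2010, 1, 1) + datetime.timedelta(
        days=int(rng.integers(0, 2000))
    )

    # ---------------------------------------------------------------- plan
    chunk_open: dict[tuple[str, str], _Chunk] = {}
    chunks: list[_Chunk] = []
    anchors: list[_AnchorItem] = []
    for _ in range(n_entities):
        is_node = rng.random() < config.node_interval_mix[0]
        template = _weighted_choice(
            rng, _NODE_WEIGHTS if is_node else _INTERVAL_WEIGHTS
        )
        section = _pick_section(rng, template)
        surface = ENTITY_SURFACES[rng.integers(len(ENTITY_SURFACES))]
        if template in _CHUNK_SIZE:
            key = (template, section)
            chunk = chunk_open.get(key)
            if chunk is None or len(chunk.entities) >= _CHUNK_SIZE[template]:
                chunk = _Chunk(kind=template, section=section, entities=[])
                chunks.append(chunk)
                chunk_open[key] = chunk
            chunk.entities.append(surface)
        else:
            relation = {
                "anchor_sim": Relation.SIMULTANEOUS,
                "anchor_dis_sim": Relation.SIMULTANEOUS,
                "anchor_before": Relation.BEFORE,
                "anchor_dis_after": Relation.AFTER,
                "anchor_dt_after": Relation.AFTER,
            }[template]
            anchors.append(_AnchorItem(template, section, surface, relation))

    buffer_offsets = {-1, 1}
    buffer_offsets.update(_allocate_dates(rng, chunks, _HISTORY_SECTIONS, -1))
    buffer_offsets.update(_allocate_dates(rng, chunks, _HISTORY_SECTIONS, +1))
    max_treat = max((c.offset for c in chunks if c.offset and c.offset > 0),
                    default=0)
    dis_offset = max(config.discharge_gap_days, max_treat + 3)
    dis = adm + datetime.timedelta(days=dis_offset)

    # -------------------------------------------------------------- render
    b = _NoteBuilder()
    manifest_entities: dict[str, dict] = {}
    intended: dict[str, tuple[str, Relation]] = {}  # me_id -> (te_id, relation)

    def emit(text: str) -> int:
        start = len(b.text)
        b.text += text
        return start

    def emit_date(value: datetime.date, kind: TEKind) -> str:
        start = emit(value.isoformat())
        return b.add_te(note_id, start, len(b.text), value, kind)

    def emit_entities(surfaces: list[str]) -> list[str]:
        ids = []
        for i, surface in enumerate(surfaces):
            if i:
                emit("、")
            start = emit(surface)
            ids.append(b.add_entity(note_id, start, len(b.text)))
        return ids

    # Other (record header): admission/discharge dates and reference dates
    sec_start = emit("记录:入院日期")
    adm_te = emit_date(adm, TEKind.ADMISSION)
    emit(",出院日期")
    dis_te = emit_date(dis, TEKind.DISCHARGE)
    emit("。")
    if buffer_offsets:
        emit("参考日期")
        for i, off in enumerate(sorted(buffer_offsets)):
            if i:
                emit(",")
            emit_date(adm + datetime.timedelta(days=off), TEKind.OTHER)
        emit("。")
    emit("\n")
    b.sections.append(make_section("Other", sec_start, len(b.text)))

    anchor_te = {"admission": adm_te, "discharge": dis_te}
    by_section_chunks: dict[str, list[_Chunk]] = {}
    for chunk in chunks:
        by_section_chunks.setdefault(chunk.section, []).append(chunk)
    by_section_anchors: dict[str, list[_AnchorItem]] = {}
    for item in anchors:
        by_section_anchors.setdefault(item.section, []).append(item)

    for name in _SECTION_ORDER[1:]:
        sec_start = emit(_HEADERS[name] + ":")
        section = make_section(name, sec_start, sec_start)  # end fixed below
        wrote = False
        for chunk in by_section_chunks.get(name, []):
            date = adm + datetime.timedelta(days=chunk.offset)
            if chunk.kind == "sim":
                te_id = emit_date(date, TEKind.OTHER)
                emit(SIM_VERBS[rng.integers(len(SIM_VERBS))])
                me_ids = emit_entities(chunk.entities)
                emit("。")
                rel = Relation.SIMULTANEOUS
            elif chunk.kind == "after":
                te_id = emit_date(date, TEKind.OTHER)
                emit("行" + PROCEDURES[rng.integers(len(PROCEDURES))] + ",术后出现")
                me_ids = emit_entities(chunk.entities)
                emit("。")
                rel = Relation.AFTER
            else:  # before
                te_id = emit_date(date, TEKind.OTHER)
                emit("之前已有")
                me_ids = emit_entities(chunk.entities)
                emit("。")
                rel = Relation.BEFORE
            for me_id in me_ids:
                intended[me_id] = (te_id, rel)
                manifest_entities[me_id] = {
                    "template": chunk.kind, "te_id": te_id,
                    "relation": rel.value, "section": name,
                }
            wrote = True
        for item in by_section_anchors.get(name, []):
            pattern = ANCHOR_PATTERNS[rng.integers(len(ANCHOR_PATTERNS))]
            head, tail = pattern.split("{e}")
            emit(head)
            start = emit(item.entity)
            me_id = b.add_entity(note_id, start, len(b.text))
            emit(tail)
            anchor = section.anchor.value
            intended[me_id] = (anchor_te[anchor], item.relation)
            manifest_entities[me_id] = {
                "template": item.template, "te_id": anchor_te[anchor],
                "relation": item.relation.value, "section": name,
            }
            wrote = True
        if not wrote:
            emit("无特殊。")
        emit("\n")
        section.span = Span(sec_start, len(b.text))
        b.sections.append(section)

    note = ClinicalNote(
        note_id=note_id,
        text=b.text,
        sections=b.sections,
        entities=b.entities,
        temporal_expressions=b.tes,
        admission_te_id=adm_te,
        discharge_te_id=dis_te,
    )
    timeline = build_timeline(note)
    for me in note.entities:
        te_id, rel = intended[me.me_id]
        me.gold_index = relation_to_index(note.te_by_id(te_id), rel, timeline)
        if config.label_noise > 0 and rng.random() < config.label_noise:
            other_ids = [i for i in timeline.ids() if i != me.gold_index]
            me.gold_index = int(other_ids[rng.integers(len(other_ids))])
            manifest_entities[me.me_id]["noised"] = True
    note.validate()
    return note, {"note_id": note_id, "entities": manifest_entities}


def generate_corpus(
    config: GeneratorConfig,
) -> tuple[list[ClinicalNote], dict]:
    """Generate notes plus a manifest of planted relations (oracle input)."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    notes, per_note = [], []
    for i in range(config.n_notes):
        note, manifest = generate_note(rng, config, note_id=f"syn{i:04d}")
        notes.append(note)
        per_note.append(manifest)
    return notes, {"seed": config.seed, "notes": per_note}


def benchmark_split(
    n_train: int = 300, n_test: int = 100, seed: int = 7, **overrides
) -> tuple[list[ClinicalNote], list[ClinicalNote]]:
    """The canonical noise-free train/test split used for benchmarking."""
    cfg = GeneratorConfig(n_notes=n_train + n_test, seed=seed, **overrides)
    notes, _ = generate_corpus(cfg)
    return notes[:n_train], notes[n_train:]


def verify_manifest(notes: list[ClinicalNote], manifest: dict) -> float:
    """Re-derive each gold index from its planted template; return agreement.

    With zero label noise the agreement is 1.0 by construction; noised
    entities are excluded from the check.
    """
    by_id = {m["note_id"]: m["entities"] for m in manifest["notes"]}
    checked = agree = 0
    for note in notes:
        timeline = build_timeline(note)
        for me in note.entities:
            planted = by_id[note.note_id][me.me_id]
            if planted.get("noised"):
                continue
            expected = relation_to_index(
                note.te_by_id(planted["te_id"]),
                Relation(planted["relation"]),
                timeline,
            )
            checked += 1
            agree += expected == me.gold_index
    return agree / checked if checked else 1.0
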