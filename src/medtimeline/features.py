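"""Hand-crafted temporal-relation features for an (entity, TE) pair.

Ten categorical features computed purely from character spans, sections and
sentences:

1.  section name of the ME
2.  section name of the TE
3.  same-section flag
4.  TE kind (admission / discharge / other)
5.  any TE in the ME's sentence
6.  number of TEs in the ME's sentence (0 / 1 / more)
7.  same-sentence flag
8.  TE in front of / behind the ME within the sentence (n/a when not same
    sentence); "front" means the TE span starts before the ME span
9.  TE's sentence in front of / behind / same as the ME's sentence
10. any TE in front of the ME within the ME's section (sentence-level
    containment implies section-level, so the broader reading is used)

The TE under consideration itself counts toward features 5, 6 and 10 when it
lies in the relevant region.  Values are categorical; encoding uses
per-feature category tables fitted on training data with an OTHER bucket for
unseen values, serialized with the model so prediction-time encoding matches
training-time exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, fields

from .corpus import (
    ClinicalNote,
    MedicalEntity,
    SentenceSpan,
    TemporalExpression,
    sentence_of,
)

OTHER = "<OTHER>"


@dataclass(frozen=True)
class FeatureVector:
    me_section: str
    te_section: str
    same_section: str        # "true"/"false"
    te_kind: str             # "admission"/"discharge"/"other"
    te_in_me_sentence: str   # "true"/"false"
    te_count_me_sentence: str  # "0"/"1"/"more"
    same_sentence: str       # "true"/"false"
    te_side_in_sentence: str  # "front"/"behind"/"na"
    te_sentence_side: str    # "front"/"behind"/"same"
    te_front_in_section: str  # "true"/"false"

    def values(self) -> tuple[str, ...]:
        return tuple(getattr(self, f.name) for f in fields(self))


FEATURE_NAMES = tuple(f.name for f in fields(FeatureVector))

#: closed category sets; section-name features are data-driven (None)
FIXED_CATEGORIES: dict[str, tuple[str, ...] | None] = {
    "me_section": None,
    "te_section": None,
    "same_section": ("false", "true"),
    "te_kind": ("admission", "discharge", "other"),
    "te_in_me_sentence": ("false", "true"),
    "te_count_me_sentence": ("0", "1", "more"),
    "same_sentence": ("false", "true"),
    "te_side_in_sentence": ("front", "behind", "na"),
    "te_sentence_side": ("front", "behind", "same"),
    "te_front_in_section": ("false", "true"),
}


def _flag(value: bool) -> str:
    return "true" if value else "false"


def extract_relation_features(
    me: MedicalEntity,
    te: TemporalExpression,
    note: ClinicalNote,
    sentences: list[SentenceSpan] | None = None,
) -> FeatureVector:
    from .corpus import segment_sentences

    if sentences is None:
        sentences = segment_sentences(note)
    me_sec = note.section_of(me.span)
    te_sec = note.section_of(te.span)
    me_sent = sentence_of(me.span, sentences)
    te_sent = sentence_of(te.span, sentences)

    in_me_sentence = [
        t for t in note.temporal_expressions if me_sent.span.contains(t.span)
    ]
    n_in_sent = len(in_me_sentence)
    same_sentence = me_sent.index == te_sent.index

    if same_sentence:
        side = "front" if te.span.start < me.span.start else "behind"
    else:
        side = "na"
    if te_sent.index < me_sent.index:
        sent_side = "front"
    elif te_sent.index > me_sent.index:
        sent_side = "behind"
    else:
        sent_side = "same"
    any_front = any(
        t.span.start < me.span.start
        for t in note.temporal_expressions
        if me_sec.span.contains(t.span)
    )
    return FeatureVector(
        me_section=me_sec.name,
        te_section=te_sec.name,
        same_section=_flag(me_sec.name == te_sec.name and me_sec.span == te_sec.span),
        te_kind=te.kind.value,
        te_in_me_sentence=_flag(n_in_sent > 0),
        te_count_me_sentence="0" if n_in_sent == 0 else ("1" if n_in_sent == 1 else "more"),
        same_sentence=_flag(same_sentence),
        te_side_in_sentence=side,
        te_sentence_side=sent_side,
        te_front_in_section=_flag(any_front),
    )


@dataclass
class CategoryTables:
    """Per-feature category vocabularies (unseen values map to OTHER)."""

    tables: dict[str, list[str]]

    @classmethod
    def fit(cls, vectors: list[FeatureVector]) -> "CategoryTables":
        tables: dict[str, list[str]] = {}
        for name in FEATURE_NAMES:
            fixed = FIXED_CATEGORIES[name]
            if fixed is not None:
                tables[name] = list(fixed)
            else:
                seen = sorted({getattr(fv, name) for fv in vectors})
                tables[name] = seen + [OTHER]
        return cls(tables=tables)

    def index_of(self, name: str, value: str) -> int:
        table = self.tables[name]
        try:
            return table.index(value)
        except ValueError:
            return table.index(OTHER)

    def sizes(self) -> list[int]:
        return [len(self.tables[name]) for name in FEATURE_NAMES]

    @property
    def total_size(self) -> int:
        return sum(self.sizes())

    def to_dict(self) -> dict:
        return {"tables": self.tables}

    @classmethod
    def from_dict(cls, doc: dict) -> "CategoryTables":
        return cls(tables={k: list(v) for k, v in doc["tables"].items()})


def encode_one_hot(fv: FeatureVector, tables: CategoryTables) -> list[list[int]]:
    """One one-hot vector per feature; total length = sum of table sizes."""
    vectors = []
    for name, value in zip(FEATURE_NAMES, fv.values()):
        vec = [0] * len(tables.tables[name])
        vec[tables.index_of(name, value)] = 1
        vectors.append(vec)
    return vectors


def feature_indices(fv: FeatureVector, tables: CategoryTables) -> list[int]:
    """Category index per feature — the compact form the embedding layer uses.

    Indices address one shared category space: feature i's index is offset by
    the sizes of tables 1..i-1, so they select rows of a single E_g matrix.
    """
    out = []
    offset = 0
    for name, value in zip(FEATURE_NAMES, fv.values()):
        out.append(offset + tables.index_of(name, value))
        offset += len(tables.tables[name])
    return out
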