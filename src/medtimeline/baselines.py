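"""Rule-based indexer, linear-SVM relation classifier and the Merged ensemble.

The rule engine orders four rules and fires the first that matches:

R1  a TE precedes the ME in its sentence  -> nearest preceding TE, SIMULTANEOUS
R2  a TE follows the ME in the same sentence -> nearest following TE, SIMULTANEOUS
R3  a TE precedes the ME in its section   -> nearest preceding TE, SIMULTANEOUS
R4  otherwise -> the section's anchor TE with the section's anchor relation

Sentence- and section-level matches default to SIMULTANEOUS; only the anchor
fallback uses the section inventory's relation.  Every decision records the
rule that fired so deviations are auditable.

The SVM baseline classifies the same 4 relations from sparse indicators: a
bag of context words in a +/-5-token window around the ME target, the same
for the TE, and the one-hot relation features.  It is a linear one-vs-rest
SVM; class probabilities are the softmax of the per-class decision values so
the Merged combiner can average them with the neural models' outputs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from scipy import sparse
from sklearn.svm import LinearSVC

from .corpus import (
    ClinicalNote,
    MedicalEntity,
    Relation,
    SentenceSpan,
    sentence_of,
)
from .candidates import section_anchor_te
from .features import CategoryTables, FeatureVector, feature_indices
from .nn.encoding import Vocabulary, tokenize
from .nn.model import RELATIONS

DEFAULT_RULE_ORDER = (
    "nearest-front-te-in-sentence",
    "nearest-behind-te-in-sentence",
    "nearest-front-te-in-section",
    "section-anchor-time",
)


@dataclass
class RuleDecision:
    me_id: str
    te_id: str
    relation: Relation
    rule: str


def rule_based_index(
    me: MedicalEntity,
    note: ClinicalNote,
    sentences: list[SentenceSpan] | None = None,
    rule_order: Sequence[str] = DEFAULT_RULE_ORDER,
) -> RuleDecision:
    """Apply the ordered rules; exactly one fires on any valid note."""
    from .corpus import segment_sentences

    if sentences is None:
        sentences = segment_sentences(note)
    section = note.section_of(me.span)
    me_sent = sentence_of(me.span, sentences)
    in_sentence = [
        te for te in note.temporal_expressions
        if me_sent.span.contains(te.span)
    ]
    in_section = [
        te for te in note.temporal_expressions
        if section.span.contains(te.span)
    ]

    def decision(rule: str) -> Optional[RuleDecision]:
        if rule == "nearest-front-te-in-sentence":
            front = [te for te in in_sentence if te.span.start < me.span.start]
            if front:
                te = max(front, key=lambda t: t.span.start)
                return RuleDecision(me.me_id, te.te_id, Relation.SIMULTANEOUS, rule)
        elif rule == "nearest-behind-te-in-sentence":
            behind = [te for te in in_sentence if te.span.start >= me.span.start]
            if behind:
                te = min(behind, key=lambda t: t.span.start)
                return RuleDecision(me.me_id, te.te_id, Relation.SIMULTANEOUS, rule)
        elif rule == "nearest-front-te-in-section":
            front = [te for te in in_section if te.span.start < me.span.start]
            if front:
                te = max(front, key=lambda t: t.span.start)
                return RuleDecision(me.me_id, te.te_id, Relation.SIMULTANEOUS, rule)
        elif rule == "section-anchor-time":
            anchor_id = section_anchor_te(section, note)
            return RuleDecision(me.me_id, anchor_id, section.anchor_relation, rule)
        else:
            raise ValueError(f"unknown rule {rule!r}")
        return None

    for rule in rule_order:
        hit = decision(rule)
        if hit is not None:
            return hit
    raise RuntimeError(f"no rule fired for entity {me.me_id!r}")  # pragma: no cover


# ---------------------------------------------------------------------------
# SVM relation classifier
# ---------------------------------------------------------------------------

CONTEXT_WINDOW = 5  # tokens on each side of the target


@dataclass
class SvmInstance:
    me_context: list[str]
    te_context: list[str]
    features: FeatureVector
    label: Optional[int] = None


def context_window(
    note: ClinicalNote,
    sentence: SentenceSpan,
    target_start: int,
    target_end: int,
    window: int = CONTEXT_WINDOW,
) -> list[str]:
    """Bag of tokens within `window` tokens of the target, target excluded."""
    text = note.text[sentence.span.start : sentence.span.end]
    tokens = tokenize(text, offset=sentence.span.start)
    before = [t[0] for t in tokens if t[2] <= target_start]
    after = [t[0] for t in tokens if t[1] >= target_end]
    return before[-window:] + after[:window]


class SvmRelationModel:
    """Linear one-vs-rest SVM over sparse context/feature indicators."""

    def __init__(self, tables: CategoryTables, C: float = 1.0, seed: int = 0):
        self.tables = tables
        self.C = C
        self.seed = seed
        self.vocab = Vocabulary()  # PAD unused; UNK is the OTHER bucket
        self.coef_: np.ndarray | None = None
        self.intercept_: np.ndarray | None = None

    @property
    def width(self) -> int:
        return 2 * len(self.vocab) + self.tables.total_size

    def _vectorize(self, instances: Sequence[SvmInstance]):
        """Sparse indicator matrix (n_instances, width)."""
        V = len(self.vocab)
        rows, cols = [], []
        for r, inst in enumerate(instances):
            active = {self.vocab.get(tok) for tok in inst.me_context}
            active |= {V + self.vocab.get(tok) for tok in inst.te_context}
            active |= {
                2 * V + i for i in feature_indices(inst.features, self.tables)
            }
            rows.extend([r] * len(active))
            cols.extend(active)
        data = np.ones(len(rows), dtype=np.float64)
        return sparse.csr_matrix(
            (data, (rows, cols)), shape=(len(instances), self.width)
        )

    def fit(self, instances: Sequence[SvmInstance]) -> "SvmRelationModel":
        if not instances:
            raise ValueError("SVM training needs a non-empty instance set")
        labels = np.array([inst.label for inst in instances])
        if len(np.unique(labels)) < 2:
            raise ValueError("SVM training needs at least 2 classes")
        for inst in instances:  # two passes: fix vocabulary, then vectorize
            for tok in inst.me_context + inst.te_context:
                self.vocab.add(tok)
        X = self._vectorize(instances)
        svc = LinearSVC(C=self.C, random_state=self.seed)
        svc.fit(X, labels)
        # OvR coefficient rows follow svc.classes_; expand to the 4-class order.
        # Classes absent from training keep a -inf intercept (probability 0).
        self.coef_ = np.zeros((len(RELATIONS), X.shape[1]))
        self.intercept_ = np.full(len(RELATIONS), -np.inf)
        if len(svc.classes_) == 2:  # sklearn collapses binary OvR to one row
            pos, neg = int(svc.classes_[1]), int(svc.classes_[0])
            self.coef_[pos], self.intercept_[pos] = svc.coef_[0], svc.intercept_[0]
            self.coef_[neg], self.intercept_[neg] = -svc.coef_[0], -svc.intercept_[0]
        else:
            for row, cls in enumerate(svc.classes_):
                self.coef_[int(cls)] = svc.coef_[row]
                self.intercept_[int(cls)] = svc.intercept_[row]
        return self

    def decision_values(self, instances: Sequence[SvmInstance]) -> np.ndarray:
        if self.coef_ is None:
            raise RuntimeError("model is not fitted")
        X = self._vectorize(instances)
        return np.asarray(X @ self.coef_.T) + self.intercept_

    def predict_proba(self, instances: Sequence[SvmInstance]) -> np.ndarray:
        """Softmax over decision values — a simplex vector per instance."""
        scores = self.decision_values(instances)
        z = scores - scores.max(axis=1, keepdims=True)
        e = np.exp(z)
        return e / e.sum(axis=1, keepdims=True)

    # ------------------------------------------------------------ persistence
    def save(self, model_dir) -> None:
        model_dir = Path(model_dir)
        model_dir.mkdir(parents=True, exist_ok=True)
        np.savez(model_dir / "svm.npz", coef=self.coef_, intercept=self.intercept_)
        (model_dir / "svm_meta.json").write_text(
            json.dumps(
                {
                    "C": self.C,
                    "seed": self.seed,
                    "vocab": self.vocab.to_dict(),
                    "tables": self.tables.to_dict(),
                },
                ensure_ascii=False,
            ),
            encoding="utf-8",
        )

    @classmethod
    def load(cls, model_dir) -> "SvmRelationModel":
        model_dir = Path(model_dir)
        meta = json.loads((model_dir / "svm_meta.json").read_text(encoding="utf-8"))
        model = cls(
            tables=CategoryTables.from_dict(meta["tables"]),
            C=meta["C"],
            seed=meta["seed"],
        )
        model.vocab = Vocabulary.from_dict(meta["vocab"])
        with np.load(model_dir / "svm.npz") as npz:
            model.coef_ = npz["coef"]
            model.intercept_ = npz["intercept"]
        return model


# ---------------------------------------------------------------------------
# Merged ensemble
# ---------------------------------------------------------------------------


def merge_probabilities(per_model: Sequence[np.ndarray]) -> np.ndarray:
    """Elementwise arithmetic mean of the members' class probabilities."""
    if not per_model:
        raise ValueError("nothing to merge")
    arrays = [np.asarray(p, dtype=np.float64) for p in per_model]
    shape = arrays[0].shape
    if any(a.shape != shape for a in arrays):
        raise ValueError("probability vectors differ in shape")
    if shape[-1] != len(RELATIONS):
        raise ValueError(f"expected {len(RELATIONS)}-class probabilities")
    return np.mean(arrays, axis=0)
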