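"""Index selection and the evaluation protocol.

Selection: for each entity, over all (candidate TE, relation in
{SIMULTANEOUS, BEFORE, AFTER}) combinations, the highest predicted
probability wins (NONE is never selectable); ties break by smaller character
distance between TE and ME, then candidate order.  The winning pair maps to
a timeline ID.

Metrics:

* relation micro P/R/F1 over candidate pairs — positives are the non-NONE
  pairs; a pair counts as correct only when its predicted type equals gold;
* relaxed accuracy — the chosen TE matches the gold index (for an interval
  gold, the chosen TE is one of its at-most-two adjacent nodes);
* strict accuracy — the predicted timeline ID equals the gold index (TE and
  relation type both right); strict is the primary criterion;
* node/interval breakdown — strict P/R/F1 restricted to odd (node) and even
  (interval) predicted/gold IDs;
* error taxonomy — strictly-wrong entities split into selection errors
  (wrong TE entirely) and type errors (right TE, wrong relation type).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .candidates import CandidateSet
from .corpus import (
    ClinicalNote,
    MedicalEntity,
    Relation,
    Timeline,
    relation_to_index,
)
from .nn.model import RELATION_TO_LABEL, RELATIONS

logger = logging.getLogger(__name__)

_SELECTABLE = (Relation.SIMULTANEOUS, Relation.BEFORE, Relation.AFTER)


@dataclass
class IndexPrediction:
    me_id: str
    te_id: str
    relation: Relation
    confidence: float
    predicted_index: int


def _char_distance(me: MedicalEntity, note: ClinicalNote, te_id: str) -> int:
    te = note.te_by_id(te_id)
    if te.span.overlaps(me.span):
        return 0
    return max(te.span.start - me.span.end, me.span.start - te.span.end)


def select_index(
    me: MedicalEntity,
    candidates: CandidateSet,
    probs: np.ndarray,
    timeline: Timeline,
    note: ClinicalNote,
) -> IndexPrediction:
    """Pick the (candidate, relation) pair with the highest probability."""
    if not candidates.candidates:
        raise ValueError(f"entity {me.me_id!r} has an empty candidate set")
    if probs.shape != (len(candidates.candidates), len(RELATIONS)):
        raise ValueError(
            f"expected one probability vector per candidate, got {probs.shape}"
        )
    best = None
    for order, te_id in enumerate(candidates.candidates):
        dist = _char_distance(me, note, te_id)
        for rel in _SELECTABLE:
            p = float(probs[order, RELATION_TO_LABEL[rel]])
            key = (-p, dist, order)
            if best is None or key < best[0]:
                best = (key, te_id, rel, p)
    _, te_id, rel, p = best
    return IndexPrediction(
        me_id=me.me_id,
        te_id=te_id,
        relation=rel,
        confidence=p,
        predicted_index=relation_to_index(note.te_by_id(te_id), rel, timeline),
    )


# ---------------------------------------------------------------------------
# Relation-level micro P/R/F1
# ---------------------------------------------------------------------------


def relation_prf(
    gold: Sequence[Relation], predicted: Sequence[Relation]
) -> tuple[float, float, float]:
    """Micro precision/recall/F1 with NONE excluded from the positives."""
    if len(gold) != len(predicted):
        raise ValueError("gold and predicted pair universes differ in size")
    correct = sum(
        1 for g, p in zip(gold, predicted) if g == p and g != Relation.NONE
    )
    n_pred = sum(1 for p in predicted if p != Relation.NONE)
    n_gold = sum(1 for g in gold if g != Relation.NONE)
    precision = correct / n_pred if n_pred else 0.0
    recall = correct / n_gold if n_gold else 0.0
    f1 = (
        2 * precision * recall / (precision + recall)
        if precision + recall
        else 0.0
    )
    return precision, recall, f1


# ---------------------------------------------------------------------------
# Indexing accuracy, breakdown, error taxonomy
# ---------------------------------------------------------------------------


@dataclass
class _Scored:
    gold_index: int
    prediction: Optional[IndexPrediction]
    chosen_node_id: Optional[int]

    @property
    def strict(self) -> bool:
        return (
            self.prediction is not None
            and self.prediction.predicted_index == self.gold_index
        )

    @property
    def relaxed(self) -> bool:
        if self.prediction is None:
            return False
        if self.strict:
            return True
        if Timeline.is_node_id(self.gold_index):
            return self.chosen_node_id == self.gold_index
        return self.chosen_node_id in (self.gold_index - 1, self.gold_index + 1)


def _score_entities(
    gold_entities: list[tuple[MedicalEntity, Timeline]],
    predictions: dict[str, tuple[IndexPrediction, Timeline]],
) -> list[_Scored]:
    scored = []
    for me, timeline in gold_entities:
        if me.gold_index is None:
            raise ValueError(f"entity {me.me_id!r} lacks a gold index")
        hit = predictions.get(me.me_id)
        if hit is None:
            logger.warning("no prediction for entity %s; counted wrong", me.me_id)
            scored.append(_Scored(me.gold_index, None, None))
            continue
        pred, tl = hit
        scored.append(_Scored(me.gold_index, pred, tl.node_id_of(pred.te_id)))
    return scored


def indexing_accuracy(
    gold_entities: list[tuple[MedicalEntity, Timeline]],
    predictions: dict[str, tuple[IndexPrediction, Timeline]],
) -> tuple[float, float]:
    """(relaxed, strict) accuracy; strict <= relaxed on any input."""
    scored = _score_entities(gold_entities, predictions)
    if not scored:
        return 0.0, 0.0
    relaxed = sum(s.relaxed for s in scored) / len(scored)
    strict = sum(s.strict for s in scored) / len(scored)
    return relaxed, strict


def _prf(correct: int, n_pred: int, n_gold: int) -> tuple[float, float, float]:
    p = correct / n_pred if n_pred else 0.0
    r = correct / n_gold if n_gold else 0.0
    f = 2 * p * r / (p + r) if p + r else 0.0
    return p, r, f


def breakdown_by_kind(
    gold_entities: list[tuple[MedicalEntity, Timeline]],
    predictions: dict[str, tuple[IndexPrediction, Timeline]],
) -> dict[str, tuple[float, float, float]]:
    """Strict P/R/F1 separately for time-node (odd) and interval (even) IDs."""
    scored = _score_entities(gold_entities, predictions)
    out = {}
    for kind, is_kind in (
        ("node", Timeline.is_node_id),
        ("interval", lambda i: not Timeline.is_node_id(i)),
    ):
        correct = sum(1 for s in scored if s.strict and is_kind(s.gold_index))
        n_pred = sum(
            1
            for s in scored
            if s.prediction is not None and is_kind(s.prediction.predicted_index)
        )
        n_gold = sum(1 for s in scored if is_kind(s.gold_index))
        out[kind] = _prf(correct, n_pred, n_gold)
    return out


def error_taxonomy(
    gold_entities: list[tuple[MedicalEntity, Timeline]],
    predictions: dict[str, tuple[IndexPrediction, Timeline]],
) -> tuple[int, int]:
    """(selection errors, type errors); the two partition the strict errors.

    A strictly-wrong entity is a *type* error when the chosen TE still matches
    the gold index in the relaxed sense (right TE, wrong relation), otherwise
    a *selection* error (wrong TE entirely).
    """
    scored = _score_entities(gold_entities, predictions)
    selection = type_err = 0
    for s in scored:
        if s.strict:
            continue
        if s.relaxed:
            type_err += 1
        else:
            selection += 1
    return selection, type_err


# ---------------------------------------------------------------------------
# Report
# ---------------------------------------------------------------------------


@dataclass
class EvaluationReport:
    method: str
    relation_precision: float = 0.0
    relation_recall: float = 0.0
    relation_f1: float = 0.0
    relaxed_accuracy: float = 0.0
    strict_accuracy: float = 0.0
    node_prf: tuple[float, float, float] = (0.0, 0.0, 0.0)
    interval_prf: tuple[float, float, float] = (0.0, 0.0, 0.0)
    selection_errors: int = 0
    type_errors: int = 0
    n_entities: int = 0
    n_pairs: int = 0
    extra: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "method": self.method,
            "relation": {
                "precision": self.relation_precision,
                "recall": self.relation_recall,
                "f1": self.relation_f1,
            },
            "indexing": {
                "relaxed_accuracy": self.relaxed_accuracy,
                "strict_accuracy": self.strict_accuracy,
            },
            "breakdown": {
                "node": dict(zip(("precision", "recall", "f1"), self.node_prf)),
                "interval": dict(
                    zip(("precision", "recall", "f1"), self.interval_prf)
                ),
            },
            "errors": {
                "selection": self.selection_errors,
                "type": self.type_errors,
            },
            "n_entities": self.n_entities,
            "n_pairs": self.n_pairs,
            **({"extra": self.extra} if self.extra else {}),
        }

    def to_text(self) -> str:
        def pct(x: float) -> str:
            return f"{100 * x:6.2f}"

        lines = [
            f"Method: {self.method}",
            f"  Relation (micro)   P {pct(self.relation_precision)}  "
            f"R {pct(self.relation_recall)}  F1 {pct(self.relation_f1)}",
            f"  Indexing accuracy  Relaxed {pct(self.relaxed_accuracy)}  "
            f"Strict {pct(self.strict_accuracy)}",
            f"  Time node          P {pct(self.node_prf[0])}  "
            f"R {pct(self.node_prf[1])}  F1 {pct(self.node_prf[2])}",
            f"  Time interval      P {pct(self.interval_prf[0])}  "
            f"R {pct(self.interval_prf[1])}  F1 {pct(self.interval_prf[2])}",
            f"  Errors             selection {self.selection_errors}  "
            f"type {self.type_errors}",
        ]
        return "\n".join(lines)


def format_method_table(reports: dict[str, "EvaluationReport"]) -> str:
    """One aligned table per metric family, methods as rows."""

    def pct(x: float) -> str:
        return f"{100 * x:7.2f}"

    width = max(len(m) for m in reports) + 2
    lines = ["Temporal relation classification (micro, %)"]
    lines.append(f"{'Method':<{width}}{'P':>8}{'R':>8}{'F1':>8}")
    for method, r in reports.items():
        lines.append(
            f"{method:<{width}}{pct(r.relation_precision):>8}"
            f"{pct(r.relation_recall):>8}{pct(r.relation_f1):>8}"
        )
    lines.append("")
    lines.append("Temporal indexing accuracy (%)")
    lines.append(f"{'Method':<{width}}{'Relaxed':>9}{'Strict':>8}")
    for method, r in reports.items():
        lines.append(
            f"{method:<{width}}{pct(r.relaxed_accuracy):>9}"
            f"{pct(r.strict_accuracy):>8}"
        )
    lines.append("")
    lines.append("Time node / time interval indexing (strict, %)")
    lines.append(
        f"{'Method':<{width}}{'node P':>8}{'node R':>8}{'node F1':>8}"
        f"{'int P':>8}{'int R':>8}{'int F1':>8}"
    )
    for method, r in reports.items():
        lines.append(
            f"{method:<{width}}"
            + "".join(f"{pct(v):>8}" for v in (*r.node_prf, *r.interval_prf))
        )
    return "\n".join(lines)
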