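"""End-to-end orchestration: notes -> candidate pairs -> models -> reports.

The unit of prediction is the candidate pair (entity, candidate TE); all
methods — SVM, the neural variants and the Merged ensemble — emit one
4-class probability vector per pair, from which the per-entity timeline
index is selected.  The rule baseline decides an index directly; its
per-pair labels are implied (the chosen TE gets the chosen relation, every
other candidate NONE) so that relation metrics are comparable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .baselines import (
    SvmInstance,
    SvmRelationModel,
    context_window,
    merge_probabilities,
    rule_based_index,
)
from .candidates import CandidateSet, candidates_for_entity
from .corpus import (
    ClinicalNote,
    Relation,
    SentenceSpan,
    Timeline,
    build_timeline,
    gold_relation_for_pair,
    segment_sentences,
    sentence_of,
)
from .evaluate import (
    EvaluationReport,
    IndexPrediction,
    breakdown_by_kind,
    error_taxonomy,
    indexing_accuracy,
    relation_prf,
    select_index,
)
from .features import CategoryTables, FeatureVector, extract_relation_features, feature_indices
from .nn.encoding import PairEncoder, sentence_words_for_span
from .nn.model import (
    RELATIONS,
    RELATION_TO_LABEL,
    EncodedPair,
    ModelConfig,
    RelationClassifier,
    train_model,
)
from .sections import resolve_sections

PROB_METHODS = ("svm", "cnn", "rnn", "rnn-cnn")
ALL_METHODS = ("rule",) + PROB_METHODS + ("merged",)


@dataclass
class NoteContext:
    note: ClinicalNote
    sentences: list[SentenceSpan]
    timeline: Timeline
    candidates: dict[str, CandidateSet]


@dataclass
class PairRecord:
    note_id: str
    me_id: str
    te_id: str
    gold: Optional[Relation] = None


@dataclass
class _RawPairFeatures:
    me_words: list[str]
    me_target: int
    te_words: list[str]
    te_target: int
    fv: FeatureVector


@dataclass
class PairDataset:
    contexts: dict[str, NoteContext]
    records: list[PairRecord]
    raw: list[_RawPairFeatures] = field(default_factory=list)

    def gold_labels(self) -> list[Relation]:
        return [r.gold for r in self.records]


def prepare_pairs(notes: Sequence[ClinicalNote], with_gold: bool = True) -> PairDataset:
    contexts: dict[str, NoteContext] = {}
    records: list[PairRecord] = []
    raw: list[_RawPairFeatures] = []
    for note in notes:
        resolve_sections(note)
        sentences = segment_sentences(note)
        timeline = build_timeline(note)
        cands = {
            me.me_id: candidates_for_entity(me, note, timeline)
            for me in note.entities
        }
        contexts[note.note_id] = NoteContext(note, sentences, timeline, cands)
        for me in note.entities:
            me_sent = sentence_of(me.span, sentences)
            me_words, me_k = sentence_words_for_span(note, me_sent, me.span, me.surface)
            for te_id in cands[me.me_id].candidates:
                te = note.te_by_id(te_id)
                gold = None
                if with_gold and me.gold_index is not None:
                    gold = gold_relation_for_pair(me, te, timeline)
                records.append(PairRecord(note.note_id, me.me_id, te_id, gold))
                te_sent = sentence_of(te.span, sentences)
                te_words, te_k = sentence_words_for_span(
                    note, te_sent, te.span, te.surface
                )
                raw.append(
                    _RawPairFeatures(
                        me_words=me_words, me_target=me_k,
                        te_words=te_words, te_target=te_k,
                        fv=extract_relation_features(me, te, note, sentences),
                    )
                )
    return PairDataset(contexts=contexts, records=records, raw=raw)


# ---------------------------------------------------------------------------
# Encodings
# ---------------------------------------------------------------------------


def fit_neural_inputs(
    dataset: PairDataset, max_len: int = 100
) -> tuple[PairEncoder, CategoryTables]:
    sentences = []
    for rp in dataset.raw:
        sentences.append((rp.me_words, rp.me_target))
        sentences.append((rp.te_words, rp.te_target))
    encoder = PairEncoder.fit(sentences, max_len=max_len)
    tables = CategoryTables.fit([rp.fv for rp in dataset.raw])
    return encoder, tables


def encode_neural(
    dataset: PairDataset, encoder: PairEncoder, tables: CategoryTables
) -> list[EncodedPair]:
    pairs = []
    for record, rp in zip(dataset.records, dataset.raw):
        label = None if record.gold is None else RELATION_TO_LABEL[record.gold]
        pairs.append(
            EncodedPair(
                me=encoder.encode_sentence(rp.me_words, rp.me_target),
                te=encoder.encode_sentence(rp.te_words, rp.te_target),
                features=np.array(feature_indices(rp.fv, tables), dtype=np.int64),
                label=label,
            )
        )
    return pairs


def encode_svm(dataset: PairDataset) -> list[SvmInstance]:
    instances = []
    for record, rp in zip(dataset.records, dataset.raw):
        ctx = dataset.contexts[record.note_id]
        note = ctx.note
        me = note.entity_by_id(record.me_id)
        te = note.te_by_id(record.te_id)
        me_sent = sentence_of(me.span, ctx.sentences)
        te_sent = sentence_of(te.span, ctx.sentences)
        label = None if record.gold is None else RELATION_TO_LABEL[record.gold]
        instances.append(
            SvmInstance(
                me_context=context_window(note, me_sent, me.span.start, me.span.end),
                te_context=context_window(note, te_sent, te.span.start, te.span.end),
                features=rp.fv,
                label=label,
            )
        )
    return instances


# ---------------------------------------------------------------------------
# Training and prediction per method
# ---------------------------------------------------------------------------


@dataclass
class MethodBundle:
    method: str
    model: object
    encoder: Optional[PairEncoder] = None
    tables: Optional[CategoryTables] = None


def train_method(
    method: str,
    train_notes: Sequence[ClinicalNote],
    seed: int = 0,
    config: Optional[ModelConfig] = None,
    dataset: Optional[PairDataset] = None,
    verbose: bool = False,
) -> MethodBundle:
    """Fit one method; "rule" needs no fitting and returns an empty bundle."""
    if method == "rule":
        return MethodBundle(method="rule", model=None)
    dataset = dataset or prepare_pairs(train_notes)
    if method == "svm":
        tables = CategoryTables.fit([rp.fv for rp in dataset.raw])
        model = SvmRelationModel(tables=tables, seed=seed)
        model.fit(encode_svm(dataset))
        return MethodBundle(method="svm", model=model, tables=tables)
    if method in ("cnn", "rnn", "rnn-cnn"):
        config = config or ModelConfig()
        config.variant = method
        encoder, tables = fit_neural_inputs(dataset, max_len=config.max_len)
        pairs = encode_neural(dataset, encoder, tables)
        model = RelationClassifier(
            config=config, encoder=encoder, tables=tables, seed=seed
        )
        train_model(model, pairs, seed=seed, verbose=verbose)
        return MethodBundle(method=method, model=model, encoder=encoder, tables=tables)
    raise ValueError(f"unknown method {method!r}")


def predict_probabilities(
    bundle: MethodBundle, dataset: PairDataset
) -> np.ndarray:
    """(n_pairs, 4) probability rows aligned with ``dataset.records``."""
    if bundle.method == "svm":
        return bundle.model.predict_proba(encode_svm(dataset))
    if bundle.method in ("cnn", "rnn", "rnn-cnn"):
        pairs = encode_neural(dataset, bundle.model.encoder, bundle.model.tables)
        return bundle.model.predict_proba(pairs)
    raise ValueError(f"method {bundle.method!r} does not emit probabilities")


def _group_by_entity(dataset: PairDataset) -> dict[tuple[str, str], list[int]]:
    groups: dict[tuple[str, str], list[int]] = {}
    for i, record in enumerate(dataset.records):
        groups.setdefault((record.note_id, record.me_id), []).append(i)
    return groups


def select_indices(
    dataset: PairDataset, probs: np.ndarray
) -> dict[str, tuple[IndexPrediction, Timeline]]:
    """Per-entity index selection from per-pair probability rows."""
    out = {}
    for (note_id, me_id), rows in _group_by_entity(dataset).items():
        ctx = dataset.contexts[note_id]
        me = ctx.note.entity_by_id(me_id)
        cand = ctx.candidates[me_id]
        assert [dataset.records[i].te_id for i in rows] == cand.candidates
        pred = select_index(me, cand, probs[rows], ctx.timeline, ctx.note)
        out[me_id] = (pred, ctx.timeline)
    return out


def rule_predictions(
    dataset: PairDataset,
) -> tuple[dict[str, tuple[IndexPrediction, Timeline]], list[Relation]]:
    """Rule decisions as index predictions plus implied per-pair labels."""
    from .corpus import relation_to_index

    index_preds = {}
    pair_labels: list[Relation] = []
    decisions = {}
    for ctx in dataset.contexts.values():
        for me in ctx.note.entities:
            decision = rule_based_index(me, ctx.note, ctx.sentences)
            decisions[me.me_id] = decision
            index_preds[me.me_id] = (
                IndexPrediction(
                    me_id=me.me_id,
                    te_id=decision.te_id,
                    relation=decision.relation,
                    confidence=1.0,
                    predicted_index=relation_to_index(
                        ctx.note.te_by_id(decision.te_id),
                        decision.relation,
                        ctx.timeline,
                    ),
                ),
                ctx.timeline,
            )
    for record in dataset.records:
        decision = decisions[record.me_id]
        pair_labels.append(
            decision.relation if record.te_id == decision.te_id else Relation.NONE
        )
    return index_preds, pair_labels


def _gold_entities(dataset: PairDataset):
    out = []
    for ctx in dataset.contexts.values():
        for me in ctx.note.entities:
            out.append((me, ctx.timeline))
    return out


def evaluate_labels_and_indices(
    method: str,
    dataset: PairDataset,
    pair_labels: list[Relation],
    index_preds: dict[str, tuple[IndexPrediction, Timeline]],
) -> EvaluationReport:
    gold_labels = dataset.gold_labels()
    if any(g is None for g in gold_labels):
        raise ValueError("evaluation needs gold labels on every pair")
    p, r, f1 = relation_prf(gold_labels, pair_labels)
    gold_entities = _gold_entities(dataset)
    relaxed, strict = indexing_accuracy(gold_entities, index_preds)
    kinds = breakdown_by_kind(gold_entities, index_preds)
    sel, typ = error_taxonomy(gold_entities, index_preds)
    return EvaluationReport(
        method=method,
        relation_precision=p,
        relation_recall=r,
        relation_f1=f1,
        relaxed_accuracy=relaxed,
        strict_accuracy=strict,
        node_prf=kinds["node"],
        interval_prf=kinds["interval"],
        selection_errors=sel,
        type_errors=typ,
        n_entities=len(gold_entities),
        n_pairs=len(dataset.records),
    )


def evaluate_probabilities(
    method: str, dataset: PairDataset, probs: np.ndarray
) -> EvaluationReport:
    pair_labels = [RELATIONS[i] for i in probs.argmax(axis=1)]
    index_preds = select_indices(dataset, probs)
    return evaluate_labels_and_indices(method, dataset, pair_labels, index_preds)


# ---------------------------------------------------------------------------
# Experiments
# ---------------------------------------------------------------------------


def run_experiment(
    train_notes: Sequence[ClinicalNote],
    test_notes: Sequence[ClinicalNote],
    methods: Sequence[str] = ALL_METHODS,
    seed: int = 0,
    config: Optional[ModelConfig] = None,
    verbose: bool = False,
) -> tuple[dict[str, EvaluationReport], dict[str, MethodBundle], dict[str, np.ndarray]]:
    """Train/evaluate the requested methods on one split.

    "merged" averages the probabilities of all trained probability-emitting
    members, so it requires at least one of them.
    """
    train_ds = prepare_pairs(train_notes)
    test_ds = prepare_pairs(test_notes)
    reports: dict[str, EvaluationReport] = {}
    bundles: dict[str, MethodBundle] = {}
    probs_by_method: dict[str, np.ndarray] = {}
    for method in methods:
        if method == "rule":
            index_preds, pair_labels = rule_predictions(test_ds)
            reports["rule"] = evaluate_labels_and_indices(
                "rule", test_ds, pair_labels, index_preds
            )
        elif method in PROB_METHODS:
            cfg = None
            if config is not None and method != "svm":
                cfg = ModelConfig.from_dict(config.to_dict())
            bundle = train_method(
                method, train_notes, seed=seed, config=cfg,
                dataset=train_ds, verbose=verbose,
            )
            bundles[method] = bundle
            probs = predict_probabilities(bundle, test_ds)
            probs_by_method[method] = probs
            reports[method] = evaluate_probabilities(method, test_ds, probs)
        elif method == "merged":
            members = [m for m in PROB_METHODS if m in probs_by_method]
            if not members:
                raise ValueError("merged needs at least one probability method")
            merged = merge_probabilities([probs_by_method[m] for m in members])
            probs_by_method["merged"] = merged
            reports["merged"] = evaluate_probabilities("merged", test_ds, merged)
        else:
            raise ValueError(f"unknown method {method!r}")
    return reports, bundles, probs_by_method
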