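# Methods

## Problem and data model

A clinical note describes events scattered over calendar time: complaints
before admission, examinations on the day of admission, procedures during
the stay, orders that apply after discharge.  *Temporal indexing* places
every annotated medical entity (ME — a problem, test or treatment span) on a
per-note timeline built from the note's temporal expressions (TEs — date
spans with a normalized calendar value).

The timeline is the ordered alternation of **time nodes** and **time
intervals**: TEs are sorted by normalized value, mentions sharing one value
merge into a single node, and IDs are assigned 0, 1, 2, …, 2n — odd IDs for
the n nodes, even IDs for the n+1 intervals around them (interval 0 precedes
the first node; interval 2n follows the last).  An ME's index is one of
these IDs.  Two reading aids: TEs that repeat a date do *not* get separate
IDs (one ID per time, not per mention), and the trailing interval 2n is
annotatable (events after the last dated mention are real, e.g. discharge
orders).

Indexing is cast as pairwise classification.  For an (ME, TE) pair the
relation label is

* `SIMULTANEOUS` — the ME is indexed to the TE's node;
* `BEFORE` / `AFTER` — the ME is indexed to the interval immediately
  before / after that node;
* `NONE` — the TE's node is two or more steps away from the ME's index.

Note the deliberate asymmetry of interval indices: an interval is adjacent
to (at most) two nodes, so an interval-indexed ME yields `AFTER` for the
earlier neighbouring TE and `BEFORE` for the later one — both pairs are
positive training examples.

## Pipeline

1. **Candidate selection.**  Chinese admission/discharge notes share a
   fixed sectional skeleton, and each section name implies a reference
   ("anchor") time — admission or discharge — plus a default relation of its
   content to that anchor (history sections: before admission; examination
   sections: at admission; treatment course: after admission; discharge
   sections: at/after discharge).  An entity's candidate TEs are its
   section's anchor TE plus all TEs inside its section, anchor first, then
   text order, deduplicated.  This bounds the pair universe (≈3 candidates
   per entity) and with it the NONE-class imbalance.

2. **Relation classification.**  Each candidate pair receives a 4-class
   probability vector from one of: a rule engine, a linear SVM, or the
   neural models below.

3. **Index selection.**  Over all (candidate, relation ∈ {S, B, A})
   combinations the highest probability wins (`NONE` is never selectable);
   ties break by smaller character distance, then candidate order.  The
   winner maps deterministically to a timeline ID.

## The RNN-CNN classifier

Input: the ME's sentence, the TE's sentence, and ten categorical pair
features (section names, same-section/sentence flags, TE kind, in-sentence
TE counts, linear-order flags).  Tokenization is character-level with an
ASCII fallback (a date literal is one token); the target annotation is
collapsed to a single token carrying its surface form, because the input
representation assumes one target word per sentence.

* **Input layer.**  Token t is x_t = [E_w w_t, E_d d_t]: a 50-dim word
  embedding and a 30-dim embedding of the signed offset d_t = t − k from the
  target token k, clipped to ±(max_len − 1).  Each categorical feature g_i
  selects a 20-dim row of E_g; Z = [z_1 … z_10] (width 200).  E_d and E_g
  are initialized uniformly in [−1, 1]; E_w likewise, or from a word2vec
  text-format table when one is supplied.  The PAD rows of E_w/E_d are fixed
  at zero; the UNK vector is the mean of all word vectors.

* **LSTM layer.**  A bidirectional *peephole* LSTM, 50 units per direction:
  the input and forget gates additionally see c_{t−1} (full matrices W_ci,
  W_cf) and the output gate sees c_t (W_co), exactly as the gate equations
  are written.  h_t concatenates both directions (width 100).  PAD steps
  carry the state through unchanged, so padding never alters outputs.

* **CNN layer.**  Filter widths 3/5/7, 100 filters per width, *sigmoid*
  activation (as specified — not the now-conventional ReLU), max-pooled over
  the n − k + 1 windows inside the real sequence; a sentence shorter than
  the width keeps its single padded window.  C concatenates the 300 pooled
  values.

* **Output layer.**  Y = softmax(W_o · [C_M, C_T, Z] + b_o) over
  (NONE, SIMULTANEOUS, BEFORE, AFTER).

Ablations: the **CNN** variant convolves the input representations directly;
the **RNN** variant replaces the CNN by the concatenated final
forward/backward states.  Both sentence branches share one set of encoder
weights (the architecture describes a single LSTM/CNN layer applied to each
sentence, and the embedding matrices are explicitly shared); they are
processed as one stacked batch.

Training: mini-batch SGD (batch 32) on mean cross-entropy, 20 epochs,
dropout 0.5 on [C_M, C_T, Z] only, constant learning rate 0.1 (the learning
rate is not part of the reference hyper-parameter table; 0.1 is this
package's default and is logged with every run).  Batches are drawn from
shuffled, loosely length-sorted pairs so intra-batch padding stays short;
batch order is reshuffled per epoch; everything is reproducible bit-for-bit
under one seed.

The network is implemented directly in NumPy with hand-written analytic
backpropagation.  This keeps the peephole cell exactly as the equations
write it (off-the-shelf LSTM cells lack the peephole terms) and makes every
layer's gradient checkable against finite differences, which the test suite
does at 1e−4 on small float64 instances.  Training uses float32 by default;
float64 is available via the `dtype` argument and is what the gradient
checks run in.

## Baselines and ensemble

* **Rule.**  Ordered rules, first match fires: nearest preceding TE in the
  ME's sentence (SIMULTANEOUS); else nearest following TE in the sentence
  (SIMULTANEOUS); else nearest preceding TE in the section (SIMULTANEOUS);
  else the section's anchor TE with the section inventory's relation.  The
  published rule list ends in "etc."; rules 2–3 are this package's
  completion to make the engine total, and every decision records the rule
  that fired so the approximation is auditable.
* **SVM.**  Linear one-vs-rest SVM over sparse indicators: bags of context
  words within ±5 tokens of the ME and TE targets plus the one-hot pair
  features.  Class probabilities are the softmax of the per-class decision
  values — chosen over Platt scaling for determinism without an inner CV
  split — so the ensemble can average them.
* **Merged.**  The elementwise arithmetic mean of the members' (SVM, CNN,
  RNN, RNN-CNN) probability vectors per pair, then the usual index
  selection.

## Evaluation protocol

* **Relation micro P/R/F1** over candidate pairs; NONE is excluded from the
  positives (standard relation-extraction practice; NONE is "no relation",
  not a prediction target).
* **Relaxed accuracy** — the chosen TE matches the gold index: for a node
  gold, the TE lies on that node; for an interval gold, the TE is one of its
  at-most-two adjacent nodes (an interval has no single gold TE, so
  adjacency is the natural relaxed reading).
* **Strict accuracy** — predicted timeline ID equals the gold index (right
  TE *and* right relation type).  Strict is the primary criterion.
* **Node/interval breakdown** — strict P/R/F1 restricted to odd/even
  predicted and gold IDs.
* **Error taxonomy** — strictly-wrong entities are *type* errors when the
  relaxed condition still holds (right TE, wrong relation) and *selection*
  errors otherwise (wrong TE); the two partition the strict errors.

## Synthetic corpus

Real annotated notes of this kind are hospital data and not
redistributable, so the package ships a seeded generator that emulates the
corpus *shape*: the fixed section skeleton, ≈22 entities per note, dated
TEs, and a ≈0.68/0.32 node/interval split of gold indices.  Entities are
planted by templates whose gold index is *derived* from the construction:

* a date immediately preceding the entity in its sentence ⇒ SIMULTANEOUS
  with that TE (node gold);
* date + procedure + 术后-style connective ⇒ AFTER (interval gold);
* date + 之前-style connective ⇒ BEFORE (interval gold);
* a TE-free sentence ⇒ the section's anchor time and anchor relation
  (node or interval gold depending on the section).

A record-header ("Other") section lists the admission and discharge dates
plus *reference dates*: the day before/after admission and separator dates
between same-section content dates.  These guarantee that on the note's
timeline no non-intended candidate TE is ever within one step of an
entity's gold index, so every non-intended pair is exactly NONE and the
planted relation labels are locally decidable from sentence surface plus
pair features.  The test suite asserts this property pair-by-pair.

What this means for interpretation: the generator makes the task *solvable
by design* — features plus local surface determine the labels, candidate
coverage is exactly 1.0 at zero noise, and a well-implemented learner should
approach perfect held-out scores.  Passing the learnability tests therefore
validates the machinery (candidate generation, encoding, training, selection
and scoring), not clinical-grade performance; real notes carry discourse
ambiguity (e.g. shifting reference times for relative dates) that no
template reproduces.  Two further deliberate deviations from the real corpus
shape: reference dates push total TEs per note (≈14) above the nominal ≈7,
as the price of local decidability; and surface text is pseudo-clinical
prose over a small fixed vocabulary, since lexical realism is irrelevant to
the positional structure being tested.  A `label_noise` rate (default 0)
reassigns the configured share of gold indices uniformly to other timeline
IDs for robustness experiments.

The manifest emitted next to each corpus records every entity's template,
intended TE and relation, so oracle checks re-derive gold indices without
re-parsing text.

## Benchmark sizes and numerical choices

The canonical learnability benchmark trains on 300 generated notes and
evaluates on 100 (seed 7, noise 0) with the reference hyper-parameters; the
acceptance script runs the same protocol at 120/40 notes — sizes chosen so
the planted structure is still comfortably learnable while a full all-method
run stays desk-sized.  Degenerate inputs are defined rather than special-
cased: a note with zero TEs has the single interval ID 0; micro P/R/F1 use
0/0 → 0; an empty candidate set, a missing anchor TE or a missing gold index
raise errors naming the offender.  Ties in max-pooling resolve to the
earliest window (argmax), and index-selection ties resolve by character
distance then candidate order, so all results are order-deterministic.

## Known limitations

* TE recognition and full TIMEX normalization are out of scope: normalized
  values arrive with the input (a convenience parser covers ISO dates,
  YYYY年MM月DD日 and "X天前"-style offsets against the admission date).
* "100 convolution filters" is read as 100 per width (300 pooled values per
  sentence); the total-across-widths reading would shrink C to 100.
* Whether the published feature 9 had a "same sentence" category is
  unstated; it is included here to keep the function total.
* The discharge-anchored rows of the section inventory are reconstructed
  from a typographically garbled table; "Diagnosis and treatment" is mapped
  to admission/After as the layout suggests.
* Merged averages exactly the four probability-emitting members; the rule
  baseline emits hard decisions and is excluded from the ensemble.
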