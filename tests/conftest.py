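import datetime

import pytest
from hypothesis import HealthCheck, settings

from medtimeline.corpus import (
    ClinicalNote,
    MedicalEntity,
    Span,
    TEKind,
    TemporalExpression,
)
from medtimeline.sections import make_section

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def d(iso: str) -> datetime.date:
    return datetime.date.fromisoformat(iso)


@pytest.fixture
def two_section_note() -> ClinicalNote:
    """Handcrafted admission-note fragment with two sections.

    Layout (all offsets asserted below):

      Other:   记录:入院日期2011-10-09。          (admission TE t0)
      HPI:     现病史:2011-10-07患者出现发热。之前已有咳嗽。

    t0 is the admission anchor; t1 is an in-section content date followed by
    the entity 发热 in the same sentence; 咳嗽 sits in a TE-free sentence.
    """
    text = "记录:入院日期2011-10-09。\n现病史:2011-10-07患者出现发热。之前已有咳嗽。\n"
    other_end = text.index("\n") + 1
    sections = [
        make_section("Other", 0, other_end),
        make_section("History of present illness", other_end, len(text)),
    ]
    t0_start = text.index("2011-10-09")
    t1_start = text.index("2011-10-07")
    e0_start = text.index("发热")
    e1_start = text.index("咳嗽")
    note = ClinicalNote(
        note_id="fix1",
        text=text,
        sections=sections,
        entities=[
            MedicalEntity("e0", Span(e0_start, e0_start + 2), "发热"),
            MedicalEntity("e1", Span(e1_start, e1_start + 2), "咳嗽"),
        ],
        temporal_expressions=[
            TemporalExpression("t0", Span(t0_start, t0_start + 10), "2011-10-09",
                               d("2011-10-09"), TEKind.ADMISSION),
            TemporalExpression("t1", Span(t1_start, t1_start + 10), "2011-10-07",
                               d("2011-10-07"), TEKind.OTHER),
        ],
        admission_te_id="t0",
    )
    note.validate()
    return note


def make_timeline_note(values: list[str], note_id: str = "tl") -> ClinicalNote:
    """A minimal single-section note with one TE per value (for timelines)."""
    text = ""
    tes = []
    for i, value in enumerate(values):
        start = len(text)
        text += value + "。"
        tes.append(
            TemporalExpression(f"t{i}", Span(start, start + len(value)), value,
                               d(value), TEKind.OTHER)
        )
    text = text or "无。"
    return ClinicalNote(
        note_id=note_id,
        text=text,
        sections=[make_section("Other", 0, len(text))],
        entities=[],
        temporal_expressions=tes,
        admission_te_id=tes[0].te_id if tes else None,
    )


@pytest.fixture(scope="session")
def benchmark():
    """The canonical 300/100 noise-free split with all methods trained.

    Expensive (trains SVM + three neural variants for 20 epochs each), so it
    is built once per session and shared by the acceptance tests.
    """
    from medtimeline.pipeline import run_experiment
    from medtimeline.synthetic import benchmark_split

    train, test = benchmark_split(n_train=300, n_test=100, seed=7)
    reports, bundles, probs = run_experiment(
        train, test,
        methods=("rule", "svm", "cnn", "rnn", "rnn-cnn", "merged"),
        seed=7,
    )
    return {
        "train": train,
        "test": test,
        "reports": reports,
        "bundles": bundles,
        "probs": probs,
    }
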