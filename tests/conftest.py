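import copy

import pytest

from picopipe.corpus_io import tokenize
from picopipe.synthetic import SynthConfig, generate_separable_corpus
from picopipe.types import Abstract, EntityClass, EntitySpan, SectionLabel, Sentence


@pytest.fixture(scope="session")
def separable_corpus():
    """A small separable corpus shared (read-only) across tests."""
    return generate_separable_corpus(n_docs=60, seed=42)


@pytest.fixture()
def separable_corpus_copy(separable_corpus):
    return [copy.deepcopy(ab) for ab in separable_corpus]


def make_sentence(text: str, sid: int = 0, section: SectionLabel | None = None
                  ) -> Sentence:
    return Sentence(sid=sid, text=text, tokens=tokenize(text),
                    gold_section=section)


@pytest.fixture()
def covid_example():
    """The worked participant-span example: one gold span, two partial
    predictions ('86 hospitalized' and 'patients', omitting 'COVID-19')."""
    text = "86 hospitalized COVID-19 patients"
    sent = make_sentence(text, sid=0, section=SectionLabel.METHODS)
    gold = EntitySpan(sid=0, start=0, end=len(text), cls=EntityClass.P, text=text)
    pred1 = EntitySpan(sid=0, start=0, end=15, cls=EntityClass.P,
                       text=text[0:15])  # "86 hospitalized"
    pred2 = EntitySpan(sid=0, start=25, end=33, cls=EntityClass.P,
                       text=text[25:33])  # "patients"
    ab = Abstract(doc_id="covid-example", title="T", sentences=[sent],
                  entities=[gold], pred_entities=[pred1, pred2])
    ab.validate()
    return ab
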