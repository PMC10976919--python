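import random

import pytest

from tnstager.context_engine import assign_modifiers, find_mentions
from tnstager.corpus_io import RawReport, sectionize
from tnstager.findings import extract_nodes, extract_tumor, match_avidity
from tnstager.lexicon import load_lexicon
from tnstager.preprocess import (
    apply_blacklist,
    clean_text,
    extract_measurements,
    split_sentences,
)
from tnstager.staging import load_rules


@pytest.fixture(scope="session")
def lexicon():
    return load_lexicon()


@pytest.fixture(scope="session")
def rules():
    return load_rules()


@pytest.fixture()
def rng():
    return random.Random(1234)


class Analysis:
    """Bundle of intermediate pipeline products for white-box assertions."""

    def __init__(self, report, lexicon):
        cleaned = RawReport(report.report_id, clean_text(report.text), report.modality_hint)
        self.sectioned = sectionize(cleaned, lexicon)
        self.sentences = split_sentences(self.sectioned, lexicon)
        self.mentions = []
        self.measurements = []
        for sentence in self.sentences:
            ms = find_mentions(sentence, lexicon)
            self.mentions.extend(assign_modifiers(sentence, ms, lexicon))
            self.measurements.extend(extract_measurements(sentence))
        apply_blacklist(self.measurements, self.sentences, lexicon)
        self.tumor, self.tumor_notes = extract_tumor(
            self.mentions, self.measurements, self.sentences
        )
        self.nodes, self.node_notes = extract_nodes(
            self.mentions, self.measurements, self.sentences
        )
        match_avidity(self.mentions, self.tumor, self.nodes, self.sectioned.modality)


@pytest.fixture()
def analyze(lexicon):
    def _analyze(text, modality_hint=None, report_id="t"):
        return Analysis(RawReport(report_id, text, modality_hint), lexicon)

    return _analyze


@pytest.fixture()
def analyze_sentence(lexicon):
    """Mentions with final assertions for a single free-standing sentence."""

    def _one(text):
        report = RawReport("s", text)
        sectioned = sectionize(report, lexicon)
        sentences = split_sentences(sectioned, lexicon)
        mentions = []
        for sentence in sentences:
            ms = find_mentions(sentence, lexicon)
            mentions.extend(assign_modifiers(sentence, ms, lexicon))
        return mentions

    return _one
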