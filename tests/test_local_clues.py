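import dataclasses

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bionerds.candidates import CandidateMention, extract_noun_runs, merge_candidates
from bionerds.lexicon import dict_tag
from bionerds.local_clues import (
    POSITIVE_CLUES,
    Clue,
    ClueConfig,
    ClueEvent,
    fire_local_clues,
    score_mention,
)

TABLE_DEFAULTS = {
    "Dictionary": 5.50, "Title": 4.00, "Enum": 3.00, "Hearst": 4.00,
    "GoodHead": 2.00, "Version": 3.00, "Reference": 1.00, "HyperLink": 1.50,
    "MixedCase": 1.00, "UpperCase": 0.50, "Bioconductor": -1.75,
    "DictionaryWord": -4.00, "KnownAcronym": -15.00, "NegativeHead": -15.00,
    "LowerCase": -1.00, "PartialWord": -15.00, "CompoundFactor": 0.50,
    "Weak": 0.50, "threshold": 5.00,
}


@pytest.fixture(scope="module")
def fired(preprocess, lexicon):
    """Run everything up to local-clue scoring; candidates by surface."""

    def _run(text: str, config: ClueConfig | None = None):
        config = config or ClueConfig()
        doc, tokens, sentences = preprocess(text)
        matches = dict_tag(tokens, doc.text, lexicon, "resource_dict")
        matches += dict_tag(tokens, doc.text, lexicon, "bioconductor")
        runs = [
            c
            for s in sentences
            for c in extract_noun_runs(s, tokens, doc.text, lexicon)
        ]
        cands = merge_candidates(runs, matches, sentences, doc.text)
        fire_local_clues(cands, tokens, sentences, doc.text, lexicon, config)
        return {c.surface: c for c in cands}

    return _run


def clues_of(cand) -> set[Clue]:
    return {ev.clue for ev in cand.clue_events}


class TestConfig:
    def test_defaults_match_reference_scores(self):
        cfg = ClueConfig()
        for key, value in TABLE_DEFAULTS.items():
            assert getattr(cfg, key) == value

    def test_file_roundtrip_and_override(self, tmp_path):
        p = tmp_path / "clues.cfg"
        ClueConfig().to_file(p)
        assert ClueConfig.from_file(p) == ClueConfig()
        q = tmp_path / "override.cfg"
        q.write_text("threshold = 7.5\nDictionary = 2.0\n")
        cfg = ClueConfig.from_file(q)
        assert cfg.threshold == 7.5 and cfg.Dictionary == 2.0 and cfg.Title == 4.0
        bad = tmp_path / "bad.cfg"
        bad.write_text("NotAClue = 1\n")
        with pytest.raises(ValueError):
            ClueConfig.from_file(bad)


class TestTitleClue:
    def test_fires_on_name_separator_keyword(self, fired):
        c = fired("FooTool: a database of widgets\nBody text.")["FooTool"]
        assert Clue.TITLE in clues_of(c)

    def test_not_title_initial(self, fired):
        cands = fired("A survey of tools\nBody text.")
        assert all(Clue.TITLE not in clues_of(c) for c in cands.values())

    def test_no_keyword_in_remainder(self, fired):
        c = fired("FooTool: fast widget counting\nBody text.")["FooTool"]
        assert Clue.TITLE not in clues_of(c)


class TestListClues:
    def test_hearst_and_enum_costack(self, fired):
        cands = fired("we ran it\ntools such as MUMmer or Vmatch were used")
        for name in ("MUMmer", "Vmatch"):
            assert {Clue.HEARST, Clue.ENUM} <= clues_of(cands[name])

    def test_no_dict_member_no_enum(self, fired):
        cands = fired("we ran it\nwe saw apples, pears and oranges")
        for c in cands.values():
            assert Clue.ENUM not in clues_of(c)

    def test_one_dict_member_fires_all(self, fired):
        cands = fired("we ran it\nwe saw Foox, BLAST and Barx")
        for name in ("Foox", "BLAST", "Barx"):
            assert Clue.ENUM in clues_of(cands[name])

    def test_and_other_keyword_pattern(self, fired):
        cands = fired("we ran it\nwe saw Foox, Barx and other programs")
        for name in ("Foox", "Barx"):
            assert Clue.HEARST in clues_of(cands[name])


class TestHeadClues:
    def test_good_head(self, fired):
        c = fired("we ran it\nThe PolyFreq program was fast")["PolyFreq"]
        assert Clue.GOOD_HEAD in clues_of(c)

    def test_negative_head(self, fired):
        c = fired("we ran it\nsaved in FASTA format")["FASTA"]
        assert Clue.NEGATIVE_HEAD in clues_of(c)

    def test_plain_context_neither(self, fired):
        c = fired("we ran it\nBLAST results were good")["BLAST"]
        assert Clue.GOOD_HEAD not in clues_of(c)
        assert Clue.NEGATIVE_HEAD not in clues_of(c)


class TestContextClues:
    def test_version(self, fired):
        c = fired("we ran it\nwe ran MUMmer 3.0 today")["MUMmer"]
        assert Clue.VERSION in clues_of(c)

    def test_version_word_form(self, fired):
        c = fired("we ran it\nwe ran MUMmer version 3 today")["MUMmer"]
        assert Clue.VERSION in clues_of(c)

    def test_reference_bracketed(self, fired):
        c = fired("we ran it\nwe ran BLAST [3] today")["BLAST"]
        assert Clue.REFERENCE in clues_of(c)

    def test_reference_et_al(self, fired):
        c = fired("we ran it\nwe ran BLAST (Altschul et al., 1997) today")["BLAST"]
        assert Clue.REFERENCE in clues_of(c)

    def test_hyperlink(self, fired):
        c = fired("we ran it\nsee FooTool (http://foo.org) online")["FooTool"]
        assert Clue.HYPERLINK in clues_of(c)

    def test_plain_number_is_version_shape(self, fired):
        c = fired("we ran it\nwe ran BLAST 2 today")["BLAST"]
        assert Clue.VERSION in clues_of(c)


class TestOrthographicAndNegative:
    def test_upper_case(self, fired):
        c = fired("we ran it\nwe ran BLAST today")["BLAST"]
        assert Clue.UPPER_CASE in clues_of(c)

    def test_mixed_case(self, fired):
        c = fired("we ran it\nwe ran FooTool today")["FooTool"]
        assert Clue.MIXED_CASE in clues_of(c)

    def test_partial_word_identifier_prefix(self, fired):
        cands = fired("we ran it\nsee GO:001234 here")
        (c,) = [c for s, c in cands.items() if s.endswith("GO")]
        assert Clue.PARTIAL_WORD in clues_of(c)

    def test_english_word_lowercase_sums_to_minus_five(self, fired):
        c = fired("we ran it\nthe analysis was good")["analysis"]
        assert {Clue.DICTIONARY_WORD, Clue.LOWER_CASE} == clues_of(c)
        assert c.local_score == pytest.approx(-5.0)

    def test_acronym_penalty(self, fired):
        c = fired("we ran it\nthe DNA was pure")["DNA"]
        assert Clue.KNOWN_ACRONYM in clues_of(c)

    def test_at_most_one_case_clue(self, fired):
        cands = fired(
            "we ran it\nwe ran BLAST and FooTool and analysis and MiXeD CasE today"
        )
        case = {Clue.UPPER_CASE, Clue.MIXED_CASE, Clue.LOWER_CASE}
        for c in cands.values():
            assert len(clues_of(c) & case) <= 1

    def test_bioconductor_penalty_stacks_with_dictionary(self, fired):
        c = fired("we ran it\nwe loaded affy yesterday")["affy"]
        assert {Clue.DICTIONARY, Clue.BIOCONDUCTOR, Clue.LOWER_CASE} == clues_of(c)
        # 5.50 - 1.75 - 1.00 + 1 x 0.50 = 3.25, below the 5.00 threshold
        assert c.local_score == pytest.approx(3.25)
        assert c.local_score < ClueConfig().threshold


class TestScoreMention:
    def make(self, clues):
        cfg = ClueConfig()
        cand = CandidateMention(0, 1, "x", 0, "noun_run", 0, 1)
        cand.clue_events = [ClueEvent(c, cfg.score_of(c)) for c in clues]
        return cand, cfg

    def test_dictionary_only(self):
        cand, cfg = self.make([Clue.DICTIONARY])
        assert score_mention(cand, cfg) == pytest.approx(6.00)

    def test_no_clues_zero(self):
        cand, cfg = self.make([])
        assert score_mention(cand, cfg) == 0.0

    @given(st.sets(st.sampled_from(sorted(Clue, key=lambda c: c.value))))
    @settings(max_examples=200, deadline=None)
    def test_oracle_equivalence(self, clues):
        """Score equals an independent re-summation over the fired set:
        clue scores plus (distinct positive types) x compound factor."""
        clues = clues - {Clue.WEAK}
        cand, cfg = self.make(sorted(clues, key=lambda c: c.value))
        expected = sum(TABLE_DEFAULTS[c.value] for c in clues)
        expected += len([c for c in clues if c in POSITIVE_CLUES]) * 0.50
        assert score_mention(cand, cfg) == pytest.approx(expected)

    @given(
        st.sets(st.sampled_from(sorted(Clue, key=lambda c: c.value))),
        st.sampled_from(sorted(Clue, key=lambda c: c.value)),
    )
    @settings(max_examples=200, deadline=None)
    def test_monotonicity(self, clues, extra):
        """Adding a positive clue never lowers the score; adding a
        negative clue never raises it."""
        clues = clues - {Clue.WEAK, extra}
        if extra is Clue.WEAK:
            return
        base, cfg = self.make(sorted(clues, key=lambda c: c.value))
        more, _ = self.make(sorted(clues | {extra}, key=lambda c: c.value))
        if extra in POSITIVE_CLUES:
            assert score_mention(more, cfg) >= score_mention(base, cfg)
        else:
            assert score_mention(more, cfg) <= score_mention(base, cfg)

    def test_acronym_cannot_pass_with_few_weak_firings(self):
        """-15 + k x 0.5 stays below the +5 threshold for any k <= 40."""
        cand, cfg = self.make([Clue.KNOWN_ACRONYM])
        for k in range(20):
            assert score_mention(cand, cfg) + k * cfg.Weak < cfg.threshold

    def test_each_clue_fires_at_most_once(self, fired):
        cands = fired("we ran it\ntools such as MUMmer 3.0 [1] or Vmatch were used")
        for c in cands.values():
            types = [ev.clue for ev in c.clue_events]
            assert len(types) == len(set(types))
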