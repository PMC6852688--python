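"""Surface realization: similarity, titles, lists, examples, sentences."""

import pytest
from hypothesis import given
from hypothesis import strategies as st

from sctverbal.lexicon import load_lexicon
from sctverbal.planner import MessagePlan
from sctverbal.realize import (
    concatenate_list,
    jaro_winkler,
    make_title,
    realize_description,
    select_examples,
    split_examples,
)

LEX = load_lexicon()


class TestJaroWinkler:
    @pytest.mark.parametrize(
        "a,b,expected",
        [
            # hand-evaluated from the published formula before implementation:
            # jaro = (m/|a| + m/|b| + (m-t)/m)/3, boosted by 0.1*prefix*(1-jaro)
            ("MARTHA", "MARHTA", 0.9611111111),  # m=6, t=1, prefix=3
            ("DIXON", "DICKSONX", 0.8133333333),  # m=4, t=0, prefix=2
            ("DWAYNE", "DUANE", 0.84),  # m=4, t=0, prefix=1
            ("Asthma", "Asthma", 1.0),  # identity
            ("abc", "xyz", 0.0),  # disjoint alphabets
            ("influenza", "flu", 0.7777777778),  # m=3, t=0, no common prefix
            ("lupus erythematosus", "lupus", 0.8526315789),  # m=5, prefix capped at 4
        ],
    )
    def test_formula_oracle(self, a, b, expected):
        assert jaro_winkler(a, b) == pytest.approx(expected, abs=1e-9)

    def test_empty_strings(self):
        assert jaro_winkler("", "") == 1.0
        assert jaro_winkler("", "abc") == 0.0

    @given(st.text(max_size=20), st.text(max_size=20))
    def test_symmetric_and_bounded(self, a, b):
        s = jaro_winkler(a, b)
        assert 0.0 <= s <= 1.0
        assert s == pytest.approx(jaro_winkler(b, a))


class TestMakeTitle:
    def test_printed_examples_trigger_combined_form(self):
        assert make_title("Influenza", "flu") == "Influenza (also known as flu)"
        assert (
            make_title("Lupus erythematosus", "Lupus")
            == "Lupus erythematosus (also known as Lupus)"
        )

    def test_identical_terms_never_combine(self):
        assert make_title("Asthma", "Asthma") == "Asthma"
        assert make_title("Asthma", "asthma") == "Asthma"  # case-insensitive

    def test_near_identical_terms_stay_plain(self):
        assert make_title("Asthma", "Asthmas") == "Asthma"  # JW 0.977 above threshold

    def test_empty_preferred_rejected(self):
        with pytest.raises(ValueError):
            make_title("", "flu")


class TestConcatenateList:
    @pytest.mark.parametrize(
        "items,expected",
        [
            # grammar rule enumerated by hand for n = 1..5
            (["A"], "A"),
            (["A", "B"], "A and B"),
            (["A", "B", "C"], "A, B, and C"),
            (["A", "B", "C", "D"], "A, B, C, and D"),
            (["A", "B", "C", "D", "E"], "A, B, C, D, and E"),
            (
                ["Autoimmune disease", "Connective tissue disease"],
                "Autoimmune disease and Connective tissue disease",
            ),
        ],
    )
    def test_serial_comma_grammar(self, items, expected):
        assert concatenate_list(items) == expected

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError):
            concatenate_list([])


class TestSelectExamples:
    def test_below_cap_keeps_input_order(self):
        children = ["Systemic X", "Drug-induced X", "Neonatal X"]
        assert select_examples(children, "X", 3) == children
        assert select_examples(["Only one"], "X", 3) == ["Only one"]

    def test_above_cap_matches_brute_force(self):
        disease = "Panvexosis"
        children = [
            "Mildly atypical Panvexosis",
            "Acute Panvexosis",
            "Zubralic Panvexosis",
            "Panvexosis neonatorum",
            "Febrile Panvexosis",
            "Old Panvexosis",
        ]
        # independent exhaustive scoring of every child
        scored = sorted(
            ((1.0 - jaro_winkler(c.lower(), disease.lower()), c) for c in children),
            key=lambda t: (-t[0], t[1].lower()),
        )
        oracle = [c for _, c in scored[:3]]
        selected, rest = split_examples(children, disease, 3)
        assert selected == oracle
        assert sorted(selected + rest) == sorted(children)
        assert len(selected) == 3


class TestRealize:
    def _plan(self, name, messages=(), examples=(), other=()):
        return MessagePlan(
            disease_name=name,
            messages=[(LEX.by_key[k], list(names)) for k, names in messages],
            examples=list(examples),
            other_related=list(other),
        )

    def test_fused_definition_sentence(self):
        plan = self._plan(
            "Lupus erythematosus",
            messages=[
                ("is_a", ["Autoimmune disease", "Connective tissue disease"]),
                ("finding_site", ["Connective tissue"]),
            ],
        )
        desc = realize_description("Lupus erythematosus (also known as Lupus)", plan, LEX)
        assert desc.sentences[0] == (
            "Lupus erythematosus (also known as Lupus) is a kind of Autoimmune disease "
            "and Connective tissue disease that affects Connective tissue."
        )
        assert len(desc.sentences) == 1

    def test_article_flag_restores_the(self):
        plan = self._plan("X", messages=[("is_a", ["A"]), ("finding_site", ["B"])])
        desc = realize_description("X", plan, LEX, use_article=True)
        assert desc.sentences[0] == "X is a kind of A that affects the B."

    def test_single_is_a_without_finding_site(self):
        plan = self._plan("Asthma", messages=[("is_a", ["Respiratory disorder"])])
        desc = realize_description("Asthma", plan, LEX)
        assert desc.sentences == ["Asthma is a kind of Respiratory disorder."]

    def test_finding_site_alone_is_a_full_sentence(self):
        plan = self._plan("Asthma", messages=[("finding_site", ["Airway"])])
        desc = realize_description("Asthma", plan, LEX)
        assert desc.sentences == ["Asthma is a condition that affects Airway."]

    def test_examples_sentence_singular_and_plural(self):
        singular = realize_description(
            "X", self._plan("X", messages=[("is_a", ["P"])], examples=["Sub"]), LEX
        )
        assert "An example of X is Sub." in singular.sentences
        plural = realize_description(
            "X", self._plan("X", messages=[("is_a", ["P"])], examples=["Sub", "Dub"]), LEX
        )
        assert "Some examples of X are Sub and Dub." in plural.sentences

    def test_empty_plan_falls_back_to_title_sentence(self):
        desc = realize_description("Rarity", self._plan("Rarity"), LEX)
        assert desc.sentences == ["Rarity is a clinical concept defined in the terminology."]
        assert desc.full_text == desc.sentences[0]

    def test_sentences_capitalized_and_terminated(self, coverage_engine):
        from sctverbal.fixtures import read_manifest

        for cid, _ in read_manifest(coverage_engine.config.rf2_dir):
            desc = coverage_engine.generate_for_concept(cid)
            for sentence in desc.sentences:
                assert sentence.endswith(".")
                assert sentence[0].isupper()
            assert desc.full_text == " ".join(desc.sentences)

    def test_pattern_fidelity_on_full_plan(self):
        """Each non-fused sentence contains its entry's pattern verbatim."""
        messages = [
            (e.key, [f"T{e.rank}a", f"T{e.rank}b"])
            for e in LEX
            if e.key not in ("children", "other")
        ]
        plan = self._plan("Zedopathy", messages=messages, examples=["Sub A", "Sub B"], other=["Rel C"])
        desc = realize_description("Zedopathy", plan, LEX)
        fused = desc.sentences[0]
        assert LEX.by_key["is_a"].pattern in fused and LEX.by_key["finding_site"].pattern in fused
        text = desc.full_text
        for entry in LEX:
            assert entry.pattern in text
        # order of first occurrence follows effective rank order
        positions = [text.index(LEX.by_key["is_a"].pattern)]
        for key in ("pathological_process", "causative_agent", "clinical_course", "other"):
            positions.append(text.index(LEX.by_key[key].pattern))
        assert positions == sorted(positions)
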