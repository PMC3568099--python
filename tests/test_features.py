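"""Feature families: affixes, morphology, gazetteers, token contexts."""

import pytest
from hypothesis import given
from hypothesis import strategies as st

from phenochunk.corpus import Caption, Token
from phenochunk.features import (
    Dictionary,
    FeatureConfig,
    brief_shape,
    digit_pattern,
    extract_context,
    extract_dict,
    extract_morph,
    extract_simple,
    featurize_sequence,
    load_bundled_dictionaries,
    vowel_pattern,
    word_shape,
)
from phenochunk.lexicon import (
    RuleLexiconProvider,
    WordlistLexiconProvider,
    default_providers,
)


def _tok(text: str) -> Token:
    return Token(text, 0, len(text))


class TestSimpleFeatures:
    def test_prefixes_of_flattening(self, resources):
        s = extract_simple(_tok("flattening"), *resources.providers, 5)
        assert [s[f"p{i}"] for i in range(1, 6)] == ["f", "fl", "fla", "flat", "flatt"]

    def test_suffixes_of_flattening(self, resources):
        s = extract_simple(_tok("flattening"), *resources.providers, 5)
        assert [s[f"s{i}"] for i in range(1, 6)] == ["g", "ng", "ing", "ning", "ening"]

    def test_affixes_truncated_at_token_length(self, resources):
        s = extract_simple(_tok("ab"), *resources.providers, 5)
        prefixes = sorted(k for k in s if k[0] == "p" and k[1:].isdigit())
        assert prefixes == ["p1", "p2"]
        assert (s["p1"], s["p2"]) == ("a", "ab")

    def test_absent_secondary_lookup_yields_sentinel(self, resources):
        s = extract_simple(_tok("L4"), *resources.providers, 5)
        assert s["lemma_lex"] == "@"
        assert s["pos_lex"] == "@"

    def test_covered_word_has_concise_secondary_tag(self, resources):
        s = extract_simple(_tok("ribs"), *resources.providers, 5)
        assert s["lemma_lex"] == "rib"
        assert s["pos_lex"] == "noun"
        assert s["pos_nlp"] == "NNS"  # fine-grained primary tagset

    @given(st.text(alphabet=st.characters(categories=["Ll", "Lu", "Nd"]),
                   min_size=1, max_size=12))
    def test_affix_count_is_min_of_n_and_length(self, text):
        providers = default_providers()
        s = extract_simple(_tok(text), *providers, 5)
        n_prefix = sum(1 for k in s if k[0] == "p" and k[1:].isdigit())
        assert n_prefix == min(5, len(text))


class TestMorphFeatures:
    @pytest.mark.parametrize(
        "text,vowels,digits,shape,brief",
        [
            ("flattening", "--a--e-i--", "no*", "aaaaaaaaaa", "a"),
            ("Flattening", "--a--e-i--", "no*", "Aaaaaaaaaa", "Aa"),
            ("thorax", "--o-a-", "no*", "aaaaaa", "a"),
            ("L4", "-4", "L*", "A0", "A0"),
            ("bell-shaped", "-e-----a-e-", "no*", "aaaa-aaaaaa", "a-a"),
        ],
    )
    def test_patterns(self, text, vowels, digits, shape, brief):
        m = extract_morph(_tok(text))
        assert m["vowels"] == vowels
        assert m["digits"] == digits
        assert m["shape"] == shape
        assert m["brief_shape"] == brief

    def test_punctuation_flag(self):
        assert extract_morph(_tok("bell-shaped"))["punct"] == "true"
        assert extract_morph(_tok("thorax"))["punct"] == "false"

    @given(st.text(min_size=1, max_size=20))
    def test_shape_properties(self, text):
        assert vowel_pattern(text) != "" and len(vowel_pattern(text)) == len(text)
        if any(c.isdigit() for c in text):
            assert len(digit_pattern(text)) == len(text)
        else:
            assert digit_pattern(text) == "no*"
        shape = word_shape(text)
        # brief shape is the run-length compression of the shape
        compressed = []
        for c in shape:
            if not compressed or compressed[-1] != c:
                compressed.append(c)
        assert brief_shape(text) == "".join(compressed)


class TestDictionaryFeatures:
    def test_membership_is_case_folded(self, resources):
        dicts = [resources.dictionaries["conjunctions"],
                 resources.dictionaries["coordinates"]]
        f = extract_dict(_tok("Left"), dicts)
        assert f["dict_coordinates"] == "true"
        assert f["dict_conjunctions"] == "false"
        assert extract_dict(_tok("and"), dicts)["dict_conjunctions"] == "true"

    def test_domain_excerpts_contain_stock_terms(self, resources):
        assert "thorax" in resources.dictionaries["anatomy"]
        assert "bell-shaped" in resources.dictionaries["quality"]
        assert "thorax" not in resources.dictionaries["quality"]

    def test_dictionary_file_loader_ignores_comments(self, tmp_path):
        p = tmp_path / "d.txt"
        p.write_text("# heading\nfoo\nbar # inline\n\n")
        d = Dictionary.from_file("custom", p)
        assert d.terms == frozenset({"foo", "bar"})

    def test_empty_dictionary_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            Dictionary("d", frozenset())


class TestContextFeatures:
    SEQ = [_tok(w) for w in ("short", "and", "wide", "ribs")]

    def test_unigram_window(self):
        f = extract_context(self.SEQ, 1, ("uni", 1))
        assert f == {"u1[-1]": "short", "u1[+0]": "and", "u1[+1]": "wide"}

    def test_boundary_sentinel(self):
        f = extract_context(self.SEQ, 0, ("uni", 1))
        assert f["u1[-1]"] == "<PAD>"

    def test_bigram_pairs_match_bruteforce_enumeration(self):
        for i in range(len(self.SEQ)):
            for w in (1, 2, 3):
                f = extract_context(self.SEQ, i, ("bi", w))
                texts = [t.text for t in self.SEQ]
                expected = {}
                for o in range(-w, w):
                    a = texts[i + o] if 0 <= i + o < len(texts) else "<PAD>"
                    b = texts[i + o + 1] if 0 <= i + o + 1 < len(texts) else "<PAD>"
                    expected[f"b{w}[{o:+d}]"] = f"{a}|{b}"
                assert f == expected

    @pytest.mark.parametrize("gram,count", [("uni", 7), ("bi", 6), ("tri", 5)])
    def test_feature_counts_per_gram(self, gram, count):
        f = extract_context(self.SEQ, 1, (gram, 3))
        assert len(f) == count

    def test_index_out_of_range(self):
        with pytest.raises(IndexError):
            extract_context(self.SEQ, 9, ("uni", 1))


class TestFeaturizeSequence:
    def test_single_family_config(self, resources):
        cap = Caption.from_text("c1", "short ribs")
        cfg = FeatureConfig.make(enabled=["shape"])
        vecs = featurize_sequence(cap, cfg, resources.providers,
                                  resources.dictionaries)
        assert all(set(v.features) == {"shape"} for v in vecs)

    def test_unknown_feature_name_rejected(self):
        with pytest.raises(ValueError, match="unknown feature"):
            FeatureConfig.make(enabled=["sharpe"])

    def test_unloaded_dictionary_rejected(self, resources):
        cap = Caption.from_text("c1", "short ribs")
        cfg = FeatureConfig.make(dictionaries=["nosuch"])
        with pytest.raises(ValueError, match="not loaded"):
            featurize_sequence(cap, cfg, resources.providers,
                               resources.dictionaries)

    def test_deterministic_across_calls(self, resources):
        cap = Caption.from_text("c1", "bell-shaped thorax and short ribs")
        cfg = FeatureConfig.make(
            enabled=["prefix", "shape"], context_specs=[("bi", 2)],
            dictionaries=["conjunctions"],
        )
        a = featurize_sequence(cap, cfg, resources.providers, resources.dictionaries)
        b = featurize_sequence(cap, cfg, resources.providers, resources.dictionaries)
        assert [v.features for v in a] == [v.features for v in b]

    def test_config_yaml_round_trip(self):
        cfg = FeatureConfig.make(
            enabled=["prefix", "vowels"], affix_n=3,
            context_specs=[("uni", 5), ("bi", 3)],
            dictionaries=["ordinals", "anatomy"],
        )
        assert FeatureConfig.from_dict(cfg.to_dict()) == cfg


class TestLexiconProviders:
    def test_rule_provider_is_total_and_deterministic(self):
        p = RuleLexiconProvider()
        for w in ("flattening", "ribs", "L4", ",", "the"):
            assert p.lemma(w) is not None
            assert p.pos(w) is not None
            assert p.pos(w) == p.pos(w)

    def test_rule_lemmatizer_examples(self):
        p = RuleLexiconProvider()
        assert p.lemma("ribs") == "rib"
        assert p.lemma("are") == "be"
        assert p.lemma("epiphyses") == "epiphys"

    def test_wordlist_absence_is_none_not_error(self):
        p = WordlistLexiconProvider.bundled()
        assert p.lemma("zzgibberish") is None
        assert p.pos("of") == "prep"
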