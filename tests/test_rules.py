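"""Rule-based annotation: matching, fixups, and fixpoint behaviour.

Oracles here are deliberately naive re-derivations: an all-substring scan
with maximal filtering for dictionary matching, an O(n^2) union-find
closure for merging, and a character-walk word-extent expander for regex
expansion.
"""

import numpy as np
import pytest

from metanner.corpus_io import Sentence
from metanner.dictionary import MetaboliteDictionary
from metanner.rules import (
    PatternSet,
    RuleAnnotator,
    Span,
    balance_brackets,
    dictionary_match,
    extend_adjacent,
    merge_spans,
    regex_match_and_expand,
)

# ---------------------------------------------------------------------------
# oracles


def oracle_dictionary_match(text, entries):
    """All-substring scan with an independent boundary test, then keep only
    spans not contained in a longer candidate and drop overlaps greedily by
    length."""
    word = set("abcdefghijklmnopqrstuvwxyzABCDEFGHIJKLMNOPQRSTUVWXYZ0123456789-")
    low = text.lower()
    found = []
    for e in entries:
        el = e.lower()
        for i in range(len(low) - len(el) + 1):
            if low[i : i + len(el)] != el:
                continue
            if i > 0 and text[i - 1] in word:
                continue
            j = i + len(el)
            if j < len(text) and text[j] in word:
                continue
            found.append((i, j))
    kept = []
    for s, e in sorted(set(found), key=lambda x: (-(x[1] - x[0]), x[0])):
        if all(e <= ks or s >= ke for ks, ke in kept):
            kept.append((s, e))
    return sorted(kept)


def oracle_merge(spans, text):
    """Pairwise union-find closure of the merge relation."""
    items = [list(x) for x in sorted({(s.start, s.end) for s in spans})]
    changed = True
    while changed:
        changed = False
        for i in range(len(items)):
            for j in range(i + 1, len(items)):
                a, b = items[i], items[j]
                if a is b or a is None or b is None:
                    continue
                lo, hi = (a, b) if a[0] <= b[0] else (b, a)
                gap = text[min(lo[1], hi[0]) : hi[0]]
                if hi[0] <= lo[1] or gap == "" or gap.isspace():
                    a[0], a[1] = min(a[0], b[0]), max(a[1], b[1])
                    items[j] = None
                    items = [x for x in items if x is not None]
                    changed = True
                    break
            if changed:
                break
    return sorted((s, e) for s, e in items)


# ---------------------------------------------------------------------------
# dictionary matching


class TestDictionaryMatch:
    def test_longest_match_wins(self):
        d = MetaboliteDictionary(entries={"acetate", "ammonium acetate"})
        spans = dictionary_match("ammonium acetate buffer", d)
        assert [(s.start, s.end) for s in spans] == [(0, 16)]

    def test_exact_single_word(self):
        d = MetaboliteDictionary(entries={"glucose"})
        spans = dictionary_match("glucose", d)
        assert [(s.start, s.end) for s in spans] == [(0, 7)]

    def test_word_boundary_blocks_substring_hit(self):
        d = MetaboliteDictionary(entries={"glucose"})
        assert dictionary_match("glucoses", d) == []
        # the substring does occur, so only the boundary rule rejects it
        assert "glucose" in "glucoses"

    def test_hyphen_is_word_internal(self):
        d = MetaboliteDictionary(entries={"glucose"})
        assert dictionary_match("D-glucose", d) == []
        assert [(s.start, s.end) for s in dictionary_match("(glucose)", d)] == [(1, 8)]

    def test_equivalence_with_substring_oracle(self, dict30, big_fixture_sentences):
        for sent in big_fixture_sentences[:300]:
            got = [(s.start, s.end) for s in dictionary_match(sent.text, dict30)]
            assert got == oracle_dictionary_match(sent.text, dict30.entries)


# ---------------------------------------------------------------------------
# regex matching and expansion


class TestRegexExpand:
    def test_partial_match_expands_to_whole_word(self):
        ps = PatternSet([r"4-hydroxy-"])
        spans = regex_match_and_expand(
            "metabolised to 4-hydroxy-N-desmethyltamoxifen rapidly", ps
        )
        text = "metabolised to 4-hydroxy-N-desmethyltamoxifen rapidly"
        assert [text[s.start : s.end] for s in spans] == ["4-hydroxy-N-desmethyltamoxifen"]

    def test_no_match_is_empty(self):
        assert regex_match_and_expand("nothing here", PatternSet([r"zzz"])) == []

    def test_expansion_matches_character_walk_oracle(self, big_fixture_sentences):
        ps = PatternSet([r"hydroxy", r"\b[a-z]{4,}ate\b"])
        for sent in big_fixture_sentences[:200]:
            text = sent.text
            got = {(s.start, s.end) for s in regex_match_and_expand(text, ps)}
            want = set()
            for pat in ps.compiled:
                for m in pat.finditer(text):
                    s, e = m.start(), m.end()
                    while s > 0 and not text[s - 1].isspace():
                        s -= 1
                    while e < len(text) and not text[e].isspace():
                        e += 1
                    while e > s and text[e - 1] in ".,;!?":
                        e -= 1
                    while s < e and text[s] in ".,;!?":
                        s += 1
                    if s < e:
                        want.add((s, e))
            assert got == want


# ---------------------------------------------------------------------------
# adjacent-word extension


class TestExtendAdjacent:
    def test_acid_follower_appended(self):
        text = "raised citric acid levels"
        sp = extend_adjacent(Span(7, 13), text, stopwords=["the"])
        assert text[sp.start : sp.end] == "citric acid"

    def test_stopword_never_prepended(self):
        text = "in the glucose assay"
        sp = extend_adjacent(Span(7, 14), text, stopwords=["the", "in"])
        assert (sp.start, sp.end) == (7, 14)

    def test_hyphen_ending_word_prepended(self):
        text = "levels of gamma- aminobutyrate rose"
        sp = extend_adjacent(Span(17, 30), text, stopwords=["of"])
        assert text[sp.start : sp.end] == "gamma- aminobutyrate"

    def test_digit_ending_word_prepended(self):
        text = "fraction 3 methylhistidine content"
        sp = extend_adjacent(Span(11, 26), text, stopwords=[])
        assert text[sp.start : sp.end] == "3 methylhistidine"

    def test_never_produces_edge_whitespace(self, dict30, big_fixture_sentences, rng):
        for sent in big_fixture_sentences[:100]:
            n = len(sent.text)
            for _ in range(5):
                a = int(rng.integers(0, n - 1))
                b = int(rng.integers(a + 1, n + 1))
                # extension contract assumes a well-formed input span
                while a < b and sent.text[a].isspace():
                    a += 1
                while b > a and sent.text[b - 1].isspace():
                    b -= 1
                if a >= b:
                    continue
                sp = extend_adjacent(Span(a, b), sent.text)
                ent = sent.text[sp.start : sp.end]
                assert ent == ent.strip()
                assert 0 <= sp.start < sp.end <= n


# ---------------------------------------------------------------------------
# bracket balancing


class TestBalanceBrackets:
    @pytest.mark.parametrize(
        "raw,fixed",
        [
            ("S)-malate", "(S)-malate"),
            ("(R)-lactate", "(R)-lactate"),
            ("PC(16:0", "PC(16:0)"),
            ("[2-13C]glucose", "[2-13C]glucose"),
            ("2-13C]glucose", "[2-13C]glucose"),
        ],
    )
    def test_examples(self, raw, fixed):
        assert balance_brackets(raw) == fixed

    def test_balanced_by_count_oracle(self, rng):
        alphabet = "ab()[]{}"
        for _ in range(200):
            s = "".join(
                alphabet[i] for i in rng.integers(0, len(alphabet), size=8)
            )
            out = balance_brackets(s)
            for o, c in (("(", ")"), ("[", "]"), ("{", "}")):
                assert out.count(o) == out.count(c)


# ---------------------------------------------------------------------------
# merging


class TestMergeSpans:
    def test_whitespace_gap_merges(self):
        text = "x" * 30
        text = "aaaaaaaaaa1234567 9012aaaaaaaa"
        spans = [Span(10, 17), Span(18, 22)]
        out = merge_spans(spans, text)
        assert [(s.start, s.end) for s in out] == [(10, 22)]

    def test_overlap_merges(self):
        out = merge_spans([Span(0, 7), Span(4, 12)], "abcdefghijkl")
        assert [(s.start, s.end) for s in out] == [(0, 12)]

    def test_random_sets_equal_union_find_oracle(self, big_fixture_sentences, rng):
        for sent in big_fixture_sentences[:200]:
            n = len(sent.text)
            spans = []
            for _ in range(int(rng.integers(0, 6))):
                a = int(rng.integers(0, n - 1))
                b = int(rng.integers(a + 1, min(a + 12, n) + 1))
                spans.append(Span(a, b))
            got = [(s.start, s.end) for s in merge_spans(spans, sent.text)]
            assert got == oracle_merge(spans, sent.text)

    def test_output_has_no_mergeable_pair(self, big_fixture_sentences, rng):
        for sent in big_fixture_sentences[200:300]:
            n = len(sent.text)
            spans = [
                Span(a, min(a + 8, n))
                for a in rng.integers(0, n - 8, size=4).tolist()
            ]
            out = merge_spans(spans, sent.text)
            for i in range(len(out) - 1):
                gap = sent.text[out[i].end : out[i + 1].start]
                assert gap and not gap.isspace()


# ---------------------------------------------------------------------------
# the full pipeline


class TestAnnotateSentence:
    def test_coordinated_mention_yields_single_annotation(self):
        # semantic coordination is out of scope: only the full surface form
        # present in the dictionary is annotated
        d = MetaboliteDictionary(entries={"3-methylhistidine"})
        ann = RuleAnnotator(d, patterns=PatternSet([]))
        sent = Sentence(
            pmcid="PMC1",
            sentence_id="R00000",
            text="We report 1- and 3-methylhistidine in urine samples.",
        )
        recs = ann.annotate_sentence(sent)
        assert [r.entity for r in recs] == ["3-methylhistidine"]

    def test_sentence_without_metabolites_is_empty(self, rule_annotator):
        sent = Sentence("PMC1", "A00000", "Nothing relevant occurs here.")
        assert rule_annotator.annotate_sentence(sent) == []

    def test_planted_mentions_fully_recovered(self, rule_annotator, fixture_corpus):
        pred = []
        for s in fixture_corpus.sentences:
            pred.extend(rule_annotator.annotate_sentence(s))
        gold_keys = {g.key for g in fixture_corpus.gold}
        pred_keys = {p.key for p in pred}
        assert gold_keys <= pred_keys

    def test_fixpoint_idempotence(self, rule_annotator, big_fixture_sentences):
        for sent in big_fixture_sentences[:100]:
            spans = rule_annotator.annotate_text(sent.text)
            again = rule_annotator.postprocess(spans, sent.text)
            assert spans == again

    def test_entity_equals_substring(self, rule_annotator, fixture_corpus):
        for s in fixture_corpus.sentences[:100]:
            for r in rule_annotator.annotate_sentence(s):
                assert r.entity == s.text[r.start : r.end]
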