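"""Article reading, sentence identification and corpus file round trips."""

import json

import pytest

from metanner.corpus_io import (
    AnnotationRecord,
    Article,
    CapacityError,
    CorpusIntegrityError,
    SchemaError,
    Section,
    Sentence,
    check_corpus,
    read_article,
    read_corpus_files,
    split_and_identify,
    write_corpus_files,
)
from metanner.synthetic import make_corpus, write_article_json


def _write_maintext(tmp_path, paragraphs, pmcid="PMC1"):
    path = tmp_path / "maintext.json"
    path.write_text(json.dumps({"pmcid": pmcid, "paragraphs": paragraphs}))
    return path


class TestReadArticle:
    def test_introduction_dropped_and_codes_assigned(self, tmp_path):
        paragraphs = [
            {"body": "Intro text here.", "IAO_term": "introduction section"},
            {"body": "Methods text here.", "IAO_term": "methods section"},
            {"body": "Results text here.", "IAO_term": "results section"},
        ]
        art = read_article(_write_maintext(tmp_path, paragraphs))
        assert [s.code for s in art.sections] == ["M", "R"]

    def test_no_usable_sections_gives_empty_article(self, tmp_path, caplog):
        paragraphs = [{"body": "x.", "IAO_term": "introduction section"}]
        with caplog.at_level("WARNING"):
            art = read_article(_write_maintext(tmp_path, paragraphs))
        assert art.sections == []

    def test_combined_results_discussion_kept_as_rd(self, tmp_path):
        paragraphs = [
            {"body": "Mixed text.", "IAO_term": "results and discussion section"}
        ]
        art = read_article(_write_maintext(tmp_path, paragraphs))
        assert art.sections[0].code == "RD"
        assert art.sections[0].id_letter == "R"

    def test_missing_keys_raise_schema_error(self, tmp_path):
        path = tmp_path / "bad.json"
        path.write_text(json.dumps({"paragraphs": []}))
        with pytest.raises(SchemaError, match="pmcid"):
            read_article(path)

    def test_malformed_json_names_file(self, tmp_path):
        path = tmp_path / "broken.json"
        path.write_text("{not json")
        with pytest.raises(ValueError, match="broken.json"):
            read_article(path)

    def test_fixture_article_round_trip(self, names30, tmp_path):
        fx = make_corpus(3, names30, abbrev_rate=1.0, table_rate=1.0, seed=5)
        art = fx.articles[0]
        paths = write_article_json(art, tmp_path)
        loaded = read_article(
            paths["maintext"], paths.get("table"), paths.get("abbreviation")
        )
        assert loaded.pmcid == art.pmcid
        assert [s.code for s in loaded.sections] == [s.code for s in art.sections]
        assert sum(len(s.subsections) for s in loaded.sections) == sum(
            len(s.subsections) for s in art.sections
        )
        assert loaded.tables == art.tables
        assert loaded.abbreviations == art.abbreviations


class TestSplitAndIdentify:
    def test_sentence_ids_encode_position(self):
        art = Article(
            pmcid="PMC9",
            sections=[
                Section(
                    code="M",
                    iao_term="methods section",
                    subsections=["First methods sentence.", "One here. And a second."],
                )
            ],
        )
        sents = split_and_identify(art)
        ids = [s.sentence_id for s in sents]
        assert ids == ["M00000", "M01000", "M01001"]

    def test_first_abstract_sentence_is_all_zero(self):
        art = Article(
            pmcid="PMC9",
            sections=[Section("A", "textual abstract section", ["Only one."])],
        )
        assert split_and_identify(art)[0].sentence_id == "A00000"

    def test_fixture_ids_match_generator_ground_truth(self, fixture_corpus):
        regenerated = []
        for art in fixture_corpus.articles:
            regenerated.extend(split_and_identify(art))
        gen = {(s.pmcid, s.sentence_id): s.text for s in fixture_corpus.sentences}
        rec = {(s.pmcid, s.sentence_id): s.text for s in regenerated}
        assert gen == rec

    def test_subsection_overflow_raises(self):
        art = Article(
            pmcid="PMC9",
            sections=[Section("M", "methods section", ["One sentence."] * 101)],
        )
        with pytest.raises(CapacityError):
            split_and_identify(art)

    def test_rd_sentences_carry_r_letter_but_rd_group(self):
        art = Article(
            pmcid="PMC9",
            sections=[Section("RD", "results and discussion section", ["Text here."])],
        )
        (sent,) = split_and_identify(art)
        assert sent.sentence_id.startswith("R")
        assert sent.section_group == "RD"


class TestCorpusFiles:
    def _small(self):
        sents = [
            Sentence("PMC1", "A00000", "Glucose was measured."),
            Sentence("PMC1", "A00001", "No metabolites here."),
            Sentence("PMC1", "R00000", "Lactate rose."),
        ]
        anns = [
            AnnotationRecord("PMC1", "A00000", 0, 7, "Glucose"),
            AnnotationRecord("PMC1", "R00000", 0, 7, "Lactate"),
        ]
        return sents, anns

    def test_only_annotated_sentences_written(self, tmp_path):
        sents, anns = self._small()
        write_corpus_files(sents, anns, tmp_path / "c.txt", tmp_path / "a.tsv")
        rows = [
            ln
            for ln in (tmp_path / "c.txt").read_text().splitlines()
            if ln and not ln.startswith("#")
        ]
        assert len(rows) == 2

    def test_round_trip_is_byte_identical(self, tmp_path):
        sents, anns = self._small()
        write_corpus_files(sents, anns, tmp_path / "c.txt", tmp_path / "a.tsv")
        s2, a2 = read_corpus_files(tmp_path / "c.txt", tmp_path / "a.tsv")
        write_corpus_files(s2, a2, tmp_path / "c2.txt", tmp_path / "a2.tsv")
        assert (tmp_path / "c.txt").read_bytes() == (tmp_path / "c2.txt").read_bytes()
        assert (tmp_path / "a.tsv").read_bytes() == (tmp_path / "a2.tsv").read_bytes()

    def test_empty_annotations_give_header_only_files(self, tmp_path):
        sents, _ = self._small()
        write_corpus_files(sents, [], tmp_path / "c.txt", tmp_path / "a.tsv")
        assert (tmp_path / "c.txt").read_text() == ""
        assert all(
            ln.startswith("#")
            for ln in (tmp_path / "a.tsv").read_text().splitlines()
        )

    def test_unknown_sentence_reference_rejected(self, tmp_path):
        sents, anns = self._small()
        anns.append(AnnotationRecord("PMC1", "D00000", 0, 4, "oops"))
        with pytest.raises(CorpusIntegrityError):
            write_corpus_files(sents, anns, tmp_path / "c.txt", tmp_path / "a.tsv")

    def test_fixture_corpus_passes_invariant_check(self, fixture_corpus):
        check_corpus(fixture_corpus.sentences, fixture_corpus.all_gold)
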