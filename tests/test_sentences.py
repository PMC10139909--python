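import io
import math
import random

import pytest
from hypothesis import given, settings, strategies as st

from jatscite import (SentenceRecord, compute_progression, parse_article,
                      process_article, read_tsv, tokenize, write_tsv)
from jatscite.config import PipelineConfig
from jatscite.sentences import COLUMNS

from conftest import article_with, make_ref_list


class TestTokenize:
    def test_two_sentences_with_token(self):
        out = tokenize("First sentence. Second |B1|.")
        assert out == ["First sentence.", "Second |B1|."]

    def test_abbreviation_guard(self):
        # frozen from the tokenizer contract: "Fig." must not split
        assert tokenize("See Fig. 2 for details.") == ["See Fig. 2 for details."]

    def test_eg_guard(self):
        assert tokenize("Some markers (e.g. B1) were used. Next one.") == [
            "Some markers (e.g. B1) were used.", "Next one."]

    def test_initial_guard(self):
        assert tokenize("As shown by J. Smith earlier.") == [
            "As shown by J. Smith earlier."]

    def test_question_and_exclamation(self):
        assert tokenize("Why? Because. Done!") == ["Why?", "Because.", "Done!"]

    def test_no_split_before_lowercase(self):
        assert tokenize("approx. half of them agreed.") == [
            "approx. half of them agreed."]

    def test_empty(self):
        assert tokenize("") == []
        assert tokenize("   ") == []

    def test_decimal_numbers_not_split(self):
        assert tokenize("The value was 0.05 overall. Next.") == [
            "The value was 0.05 overall.", "Next."]

    @given(st.lists(st.sampled_from([
        "The assay was repeated. ", "Results were stable |B1|. ",
        "Cohorts differed. "]), min_size=1, max_size=6))
    def test_concatenation_recovers_input(self, sentences):
        text = "".join(sentences).strip()
        out = tokenize(text)
        assert " ".join(out) == text

    def test_tokens_never_split(self):
        text = "Alpha |B1|,|B2|,|B3| beta. Gamma |B4|."
        for sent in tokenize(text):
            assert sent.count("|") % 2 == 0


class TestComputeProgression:
    def test_single_sentence_is_100(self):
        assert compute_progression(1, 1) == 100

    def test_first_of_many(self):
        assert compute_progression(1, 200) == 1

    def test_midpoint(self):
        assert compute_progression(50, 200) == 25

    def test_invalid_raises(self):
        with pytest.raises(ValueError):
            compute_progression(0, 5)
        with pytest.raises(ValueError):
            compute_progression(6, 5)

    def test_brute_force_ceiling_across_all_sizes(self):
        # independent oracle: explicit ceiling, range and monotonicity checks
        for n in range(1, 301):
            prev = 0
            for i in range(1, n + 1):
                p = compute_progression(i, n)
                assert p == math.ceil(100 * i / n)
                assert 1 <= p <= 100
                assert p >= prev
                prev = p
            assert compute_progression(n, n) == 100


class TestBuildRecords:
    def _article(self):
        body = ('<sec><title>Results</title>'
                '<p>Filler sentence one. Cited here '
                '<xref rid="B1">[1]</xref>, <xref rid="B2">[2]</xref>. '
                "Filler sentence two.</p></sec>")
        return article_with(body, refs=make_ref_list(3))

    def test_multi_citation_sentence_multiplies_rows(self):
        records, _ = process_article(self._article())
        citing = [r for r in records if r.intxt_id]
        assert [r.intxt_id for r in citing] == ["B1", "B2"]
        assert citing[0].sentence_id == citing[1].sentence_id
        assert citing[0].text == citing[1].text
        assert citing[0].imrad == "R"

    def test_row_count_law(self):
        records, _ = process_article(self._article())
        body_rows = [r for r in records if r.location == "body"]
        # 3 sentences, one hosting 2 citations -> 4 rows
        assert len(body_rows) == 4
        assert body_rows[0].total_sentences == 3

    def test_non_citing_component(self):
        root = article_with("<p>One. Two. Three. Four. Five.</p>")
        records, _ = process_article(root)
        assert len(records) == 5
        assert all(r.intxt_id is None for r in records)
        assert all(r.total_sentences == 5 for r in records)

    def test_abstract_citation_is_noimrad(self):
        root = article_with(
            "<p>Body.</p>",
            refs=make_ref_list(1),
            abstract='<abstract><p>Shown before <xref rid="B1">[1]</xref>.'
                     "</p></abstract>")
        records, _ = process_article(root)
        row = next(r for r in records if r.intxt_id == "B1")
        assert row.location == "abstract"
        assert row.imrad == "NoIMRaD"
        assert row.intxt_pmid == "10000001"
        assert row.intxt_pmid_source == "xml"

    def test_contexts_only_flag(self):
        records, _ = process_article(
            self._article(), config=PipelineConfig(contexts_only=True))
        assert all(r.intxt_id for r in records)
        # sentence numbering still reflects the full component
        assert records[0].sentence_id == 2
        assert records[0].total_sentences == 3

    def test_table_cell_is_one_sentence(self):
        body = ('<table-wrap><table><tbody><tr>'
                '<td>p value below threshold. See <xref rid="B1">[1]</xref></td>'
                "</tr></tbody></table></table-wrap>")
        records, _ = process_article(article_with(body, refs=make_ref_list(1)))
        cells = [r for r in records if r.location == "table"]
        assert len(cells) == 1  # no tokenization inside the cell

    def test_maintext_progression_mode(self):
        body = "<p>One. Two. Three. Four.</p>"
        root = article_with(
            body, abstract="<abstract><p>Abs one. Abs two.</p></abstract>")
        config = PipelineConfig(progression_mode="maintext")
        records, _ = process_article(root, config=config)
        body_rows = [r for r in records if r.location == "body"]
        assert [r.progression for r in body_rows] == [25, 50, 75, 100]
        abs_rows = [r for r in records if r.location == "abstract"]
        assert [r.progression for r in abs_rows] == [50, 100]


def random_record(rng: random.Random) -> SentenceRecord:
    total = rng.randint(1, 40)
    sid = rng.randint(1, total)
    has_cit = rng.random() < 0.5
    return SentenceRecord(
        pmcid=str(rng.randint(1, 9999999)),
        pmid=str(rng.randint(1, 999999)) if rng.random() < 0.8 else None,
        location=rng.choice(["abstract", "body", "table", "fig", "back"]),
        imrad=rng.choice(["I", "M", "R", "D", "NoIMRaD"]),
        sentence_id=sid, total_sentences=total,
        intxt_id=f"B{rng.randint(1, 99)}" if has_cit else None,
        intxt_pmid=str(rng.randint(1, 99999999)) if has_cit and rng.random() < 0.7 else None,
        intxt_pmid_source=rng.choice(["", "xml", "xml,pmc"]) if has_cit else "",
        intxt_mark=rng.choice(["[1]", "3–6", "2,3"]) if has_cit else None,
        best_id=str(rng.randint(1, 99999999)) if has_cit and rng.random() < 0.6 else None,
        best_source=rng.choice(["", "xml", "xml,pmc", "matcher"]) if has_cit else "",
        best_id_diff=rng.choice(["SAME", "NONE", "INSERT", "SWAP", "DELETE",
                                 "PMID_XML", "NONE_XML"]) if has_cit else None,
        progression=math.ceil(100 * sid / total),
        text="A sentence with tab\tand newline\ncharacters.",
    )


class TestTsvRoundTrip:
    def test_empty_records_header_only(self):
        buf = io.StringIO()
        write_tsv([], buf)
        assert buf.getvalue() == "\t".join(COLUMNS + ["text"]) + "\n"

    def test_round_trip_identity(self):
        rng = random.Random(7)
        records = [random_record(rng) for _ in range(200)]
        buf = io.StringIO()
        write_tsv(records, buf)
        buf.seek(0)
        back = read_tsv(buf)
        # text was sanitized on write; apply the same mapping to the originals
        for rec in records:
            rec.text = "A sentence with tab and newline characters."
            rec.intxt_pmid_source = rec.intxt_pmid_source or ""
            rec.best_source = rec.best_source or ""
        assert back == records

    def test_comma_joined_source_stays_in_one_field(self):
        rec = random_record(random.Random(1))
        rec.intxt_id, rec.intxt_pmid_source = "B1", "xml,pmc"
        buf = io.StringIO()
        write_tsv([rec], buf)
        line = buf.getvalue().splitlines()[1]
        fields = line.split("\t")
        assert fields[8] == "xml,pmc"

    def test_no_text_mode_has_14_columns(self):
        rec = random_record(random.Random(2))
        buf = io.StringIO()
        write_tsv([rec], buf, include_text=False)
        header, line = buf.getvalue().splitlines()
        assert len(header.split("\t")) == 14
        assert len(line.split("\t")) == 14
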