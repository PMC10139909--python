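import re

import pytest
from hypothesis import given, strategies as st

from jatscite import (InlineCitation, annotate_fragment, expand_paired_range,
                      expand_single_range, find_explicit, is_range_separator)
from jatscite.citations import TOKEN_RE

from conftest import parse


def cite(rid, mark):
    return InlineCitation(intxt_id=rid, intxt_mark=mark)


class TestIsRangeSeparator:
    @pytest.mark.parametrize("s", ["-", "–", "−", "--",
                                   "––", "−−",
                                   " - ", " – ", "-–"])
    def test_separators(self, s):
        assert is_range_separator(s)

    @pytest.mark.parametrize("s", [", ", ",", "and", "", "---", " ", "a-b"])
    def test_non_separators(self, s):
        assert not is_range_separator(s)


class TestFindExplicit:
    def test_single_xref(self, registry10):
        el = parse('<p>as shown <xref ref-type="bibr" rid="B2">2</xref>.</p>')
        cits = find_explicit(el, registry10)
        assert [(c.intxt_id, c.intxt_mark, c.implicit) for c in cits] == [
            ("B2", "2", False)]

    def test_multi_rid_shares_marker(self, registry10):
        # oracle: split the rid on whitespace and check both ids resolve
        el = parse('<p><xref rid="B1 B2">1,2</xref></p>')
        rids = el.find("xref").get("rid").split()
        assert all(r in registry10 for r in rids)
        cits = find_explicit(el, registry10)
        assert [c.intxt_id for c in cits] == rids
        assert {c.intxt_mark for c in cits} == {"1,2"}

    def test_figure_xref_ignored(self, registry10):
        el = parse('<p>see <xref ref-type="fig" rid="fig1">Figure 1</xref></p>')
        assert find_explicit(el, registry10) == []

    def test_unresolvable_rid_skipped(self, registry10):
        el = parse('<p><xref rid="B99">99</xref> and <xref rid="B1">1</xref></p>')
        assert [c.intxt_id for c in find_explicit(el, registry10)] == ["B1"]


class TestExpandPairedRange:
    def test_interior_entries(self, registry10):
        out = expand_paired_range(cite("B3", "3"), cite("B6", "6"), registry10)
        assert [c.intxt_id for c in out] == ["B4", "B5"]
        assert all(c.implicit for c in out)

    def test_adjacent_endpoints_empty(self, registry10):
        assert expand_paired_range(cite("B3", "3"), cite("B4", "4"),
                                   registry10) == []

    def test_reversed_warns_and_is_empty(self, registry10, caplog):
        with caplog.at_level("WARNING"):
            out = expand_paired_range(cite("B6", "6"), cite("B3", "3"), registry10)
        assert out == []
        assert any("reversed" in r.message for r in caplog.records)

    def test_all_ordered_pairs_against_enumeration_oracle(self, registry10):
        # brute-force oracle on a 10-entry registry: only forward gaps expand
        ids = [e.ref_id for e in registry10]
        for i, a in enumerate(ids):
            for j, b in enumerate(ids):
                out = expand_paired_range(cite(a, str(i + 1)),
                                          cite(b, str(j + 1)), registry10)
                expected = ids[i + 1:j] if j > i else []
                assert [c.intxt_id for c in out] == expected


class TestExpandSingleRange:
    @pytest.mark.parametrize("sep", ["–", "−", "-", "--"])
    def test_numeric_labels(self, registry10, sep):
        out = expand_single_range(cite("B3", f"3{sep}6"), registry10)
        assert [c.intxt_id for c in out] == ["B4", "B5", "B6"]
        assert all(c.implicit for c in out)

    def test_degenerate_range_empty(self, registry10):
        assert expand_single_range(cite("B3", "3–3"), registry10) == []

    def test_position_fallback_without_labels(self, registry10_unlabelled):
        assert not registry10_unlabelled.has_labels
        out = expand_single_range(cite("B3", "3–6"), registry10_unlabelled)
        assert [c.intxt_id for c in out] == ["B4", "B5", "B6"]

    def test_overrun_expands_prefix_with_warning(self, registry10, caplog):
        with caplog.at_level("WARNING"):
            out = expand_single_range(cite("B8", "8–15"), registry10)
        assert [c.intxt_id for c in out] == ["B9", "B10"]
        assert any("no reference labelled" in r.message for r in caplog.records)

    def test_size_law(self, registry10):
        for a in range(1, 10):
            for b in range(a + 1, 11):
                out = expand_single_range(cite(f"B{a}", f"{a}-{b}"), registry10)
                assert len(out) == b - a


class TestAnnotateFragment:
    def test_simple_replacement(self, registry10):
        el = parse('<p>suffer from osteoporosis '
                   '<xref rid="B1">[1]</xref>, <xref rid="B2">[2]</xref>.</p>')
        text, cits = annotate_fragment(el, registry10)
        assert text == "suffer from osteoporosis |B1|, |B2|."
        assert [(c.intxt_id, c.implicit) for c in cits] == [
            ("B1", False), ("B2", False)]

    def test_no_citations_identity(self, registry10):
        el = parse("<p>Plain text only.</p>")
        text, cits = annotate_fragment(el, registry10)
        assert text == "Plain text only."
        assert cits == []

    def test_paired_range_tokens(self, registry10):
        el = parse('<p>as in [<xref rid="B3">3</xref>–'
                   '<xref rid="B6">6</xref>].</p>')
        text, cits = annotate_fragment(el, registry10)
        tokens = TOKEN_RE.findall(text)
        assert sorted(tokens) == ["B3", "B4", "B5", "B6"]
        assert [c.intxt_id for c in cits] == tokens
        implicit = {c.intxt_id: c.implicit for c in cits}
        assert implicit == {"B3": False, "B6": False, "B4": True, "B5": True}
        assert {c.intxt_mark for c in cits if c.implicit} == {"3–6"}

    def test_single_range_tokens(self, registry10):
        el = parse('<p>as in [<xref rid="B3">3−6</xref>].</p>')
        text, cits = annotate_fragment(el, registry10)
        assert TOKEN_RE.findall(text) == ["B3", "B4", "B5", "B6"]
        assert [c.implicit for c in cits] == [False, True, True, True]

    def test_spans_point_at_tokens(self, registry10):
        el = parse('<p>x <xref rid="B2">[2]</xref> y</p>')
        text, cits = annotate_fragment(el, registry10)
        start, end = cits[0].span
        assert text[start:end] == "|B2|"

    def test_comma_list_not_treated_as_range(self, registry10):
        el = parse('<p><xref rid="B1">1</xref>, <xref rid="B3">3</xref></p>')
        text, cits = annotate_fragment(el, registry10)
        assert TOKEN_RE.findall(text) == ["B1", "B3"]
        assert not any(c.implicit for c in cits)

    def test_alphanumeric_range_not_expanded(self, registry10, caplog):
        el = parse('<p><xref rid="B3">3a–3c</xref></p>')
        with caplog.at_level("WARNING"):
            text, cits = annotate_fragment(el, registry10)
        assert [c.intxt_id for c in cits] == ["B3"]
        assert any("unexpanded" in r.message for r in caplog.records)

    def test_token_conservation_property(self, registry10):
        el = parse('<p>a [<xref rid="B2">2</xref>-<xref rid="B5">5</xref>] '
                   'b <xref rid="B7 B8">7,8</xref> c '
                   '<xref rid="B1">[1]</xref>.</p>')
        text, cits = annotate_fragment(el, registry10)
        assert sorted(TOKEN_RE.findall(text)) == sorted(c.intxt_id for c in cits)

    def test_stripping_tokens_recovers_untagged_text(self, registry10):
        el = parse('<p>alpha <xref rid="B1">[1]</xref> beta.</p>')
        text, _ = annotate_fragment(el, registry10)
        assert re.sub(r"\|[^|]+\|", "[1]", text) == "alpha [1] beta."


@given(st.integers(1, 9), st.integers(2, 10),
       st.sampled_from(["-", "–", "−", "--"]))
def test_range_size_property(a, b, sep):
    from conftest import make_ref_list
    from jatscite import extract_references
    reg = extract_references(
        parse("<article><back>" + make_ref_list(10) + "</back></article>"))
    out = expand_single_range(cite(f"B{a}", f"{a}{sep}{b}"), reg)
    assert len(out) == max(0, b - a)
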