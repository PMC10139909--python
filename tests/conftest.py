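import xml.etree.ElementTree as ET

import pytest

from jatscite import ReferenceRegistry, extract_references


def parse(xml: str) -> ET.Element:
    return ET.fromstring(xml)


def make_ref_list(n: int, labelled: bool = True) -> str:
    refs = []
    for i in range(1, n + 1):
        label = f"<label>{i}</label>" if labelled else ""
        refs.append(
            f'<ref id="B{i}">{label}<mixed-citation>Author {i}. Title {i}. '
            f'Journal. 2019.<pub-id pub-id-type="pmid">{10000000 + i}</pub-id>'
            f"</mixed-citation></ref>")
    return "<ref-list>" + "".join(refs) + "</ref-list>"


def article_with(body: str, refs: str = "", abstract: str = "",
                 back_extra: str = "") -> ET.Element:
    return parse(
        '<article><front><article-meta>'
        '<article-id pub-id-type="pmc">123456</article-id>'
        '<article-id pub-id-type="pmid">777777</article-id>'
        f"{abstract}"
        "</article-meta></front>"
        f"<body>{body}</body>"
        f"<back>{back_extra}{refs}</back></article>")


@pytest.fixture
def registry10() -> ReferenceRegistry:
    """Ten un-nested labelled references B1..B10."""
    root = parse("<article><back>" + make_ref_list(10) + "</back></article>")
    return extract_references(root)


@pytest.fixture
def registry10_unlabelled() -> ReferenceRegistry:
    root = parse("<article><back>" + make_ref_list(10, labelled=False)
                 + "</back></article>")
    return extract_references(root)
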