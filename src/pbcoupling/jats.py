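"""Reader for JATS/NXML full-text articles (the PubMed Central XML schema).

Citations are recognized from typed bibliography cross-references
(``<xref ref-type="bibr" rid="...">``): citation markers are *excluded* from
the normalized body token stream, and each marker records a mention position
equal to the number of body tokens accumulated before it — i.e. the insertion
point of the marker in the stopword-removed stream.  Grouped markers
(``rid="B3 B4"`` or adjacent xrefs with no text between them) give every
member reference the same mention position.

Only body paragraphs contribute tokens and mentions; tables, figures and
supplementary-material blocks are skipped.  Abstract tokens are placed at the
start of the body stream and recorded as ``abstract_span`` so the
title+abstract field view can be recovered.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import IO

from lxml import etree

from .corpus import Article, Reference, Section, resolve_citation_identity
from .errors import ParseError, ValidationError
from .preprocess import DEFAULT_CONFIG, PreprocessingConfig, preprocess_text

# Subtrees that never contribute body tokens or citation mentions.
_SKIP_TAGS = {
    "table-wrap",
    "table",
    "fig",
    "fig-group",
    "graphic",
    "media",
    "supplementary-material",
    "disp-formula",
    "inline-formula",
    "object-id",
    "alternatives",
}


def _localname(elem: etree._Element) -> str:
    if not isinstance(elem.tag, str):  # comments, processing instructions
        return ""
    return etree.QName(elem).localname


@dataclass
class _BodyState:
    config: PreprocessingConfig
    tokens: list[str] = field(default_factory=list)
    mentions: dict[str, list[int]] = field(default_factory=dict)

    def add_text(self, text: str | None) -> None:
        if text:
            self.tokens.extend(preprocess_text(text, self.config))

    def add_mention(self, rid_attr: str | None) -> None:
        pos = len(self.tokens)
        for rid in (rid_attr or "").split():
            self.mentions.setdefault(rid, []).append(pos)


def _walk(elem: etree._Element, state: _BodyState) -> None:
    """Accumulate tokens/mentions from ``elem``'s text and children.

    The caller is responsible for ``elem.tail``.
    """
    tag = _localname(elem)
    if tag in _SKIP_TAGS:
        return
    if tag == "xref":
        # Citation markers are excluded from the token stream; bibliography
        # references additionally record a mention at the current position.
        if elem.get("ref-type") == "bibr":
            state.add_mention(elem.get("rid"))
        return
    state.add_text(elem.text)
    for child in elem:
        _walk(child, state)
        state.add_text(child.tail)


def _text_content(elem: etree._Element | None) -> str:
    if elem is None:
        return ""
    return " ".join(elem.itertext())


def _parse_reference(ref_elem: etree._Element, index: int) -> Reference:
    ref_id = ref_elem.get("id") or f"ref{index}"
    pmid = doi = None
    for pub_id in ref_elem.iter():
        if _localname(pub_id) == "pub-id":
            kind = (pub_id.get("pub-id-type") or "").lower()
            if kind == "pmid" and pmid is None:
                pmid = pub_id.text
            elif kind == "doi" and doi is None:
                doi = pub_id.text
    raw = _text_content(ref_elem)
    identity = resolve_citation_identity(pmid=pmid, doi=doi, raw=raw)
    return Reference(ref_id=ref_id, cited_article_id=identity, mention_positions=())


def read_jats_article(
    source: str | bytes | Path | IO[bytes],
    config: PreprocessingConfig = DEFAULT_CONFIG,
    article_id: str | None = None,
) -> Article:
    """Parse one JATS/NXML document into an :class:`Article`.

    ``source`` may be a path, raw XML text/bytes, or a binary file object.
    Raises :class:`ParseError` on malformed XML and :class:`ValidationError`
    when the document has no article title.
    """
    try:
        if isinstance(source, bytes):
            root = etree.fromstring(source)
        elif isinstance(source, str) and source.lstrip().startswith("<"):
            root = etree.fromstring(source.encode("utf-8"))
        else:
            root = etree.parse(str(source) if isinstance(source, Path) else source).getroot()
    except (etree.XMLSyntaxError, OSError) as exc:
        raise ParseError(f"malformed or unreadable XML: {exc}") from exc

    title_elem = root.find(".//{*}front//{*}article-title")
    if title_elem is None:
        title_elem = root.find(".//{*}article-title")
    title_text = _text_content(title_elem).strip()
    if not title_text:
        raise ValidationError("article has no <article-title>")

    if article_id is None:
        id_elem = root.find(".//{*}front//{*}article-id")
        article_id = (id_elem.text or "").strip() if id_elem is not None else ""
        if not article_id:
            article_id = title_text

    state = _BodyState(config=config)

    # Abstract tokens open the body stream so the title+abstract view is a
    # prefix span; abstract xrefs do not count as mentions.
    abstract_elem = root.find(".//{*}front//{*}abstract")
    state.add_text(_text_content(abstract_elem))
    abstract_span = (0, len(state.tokens))

    sections: list[Section] = []
    body_elem = root.find(".//{*}body")
    if body_elem is not None:
        for child in body_elem:
            if _localname(child) == "sec":
                sec_title = _text_content(child.find("{*}title")).strip()
                start = len(state.tokens)
                _walk(child, state)
                sections.append(Section(title_text=sec_title, span=(start, len(state.tokens))))
            else:
                _walk(child, state)
            state.add_text(child.tail)

    references: list[Reference] = []
    for i, ref_elem in enumerate(root.findall(".//{*}back//{*}ref-list//{*}ref")):
        ref = _parse_reference(ref_elem, i)
        positions = tuple(sorted(state.mentions.get(ref.ref_id, ())))
        references.append(
            Reference(
                ref_id=ref.ref_id,
                cited_article_id=ref.cited_article_id,
                mention_positions=positions,
            )
        )

    article = Article(
        article_id=article_id,
        title_tokens=preprocess_text(title_text, config),
        body_tokens=tuple(state.tokens),
        abstract_span=abstract_span,
        sections=tuple(sections),
        references=tuple(references),
    )
    article.validate()
    return article
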