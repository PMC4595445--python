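"""Article/corpus data model, JSON corpus dialect, and qrels I/O.

An :class:`Article` stores its title and body as already-normalized token
streams (stopwords removed).  Citation mention positions are *insertion
points* into the body stream: the index of the first body token that follows
the citation marker, so they lie in ``[0, len(body_tokens)]`` and the context
window of a mention at ``p`` is ``body_tokens[p - alpha : p]``.

JSON corpus dialect (UTF-8, one object per file)::

    {
      "articles": {
        "<article_id>": {
          "title_tokens": ["epo", "anemia"],
          "body_tokens": ["anemia", "erythropoietin", ...],
          "abstract_span": [0, 12],
          "sections": [{"title": "Results", "span": [40, 90]}, ...],
          "references": [
            {"ref_id": "B1",
             "cited_article_id": "pmid:123456",   # or null if unresolved
             "mention_positions": [17, 55]},
            ...
          ]
        }, ...
      }
    }

Qrels are tab-separated text with four columns and no header::

    topic_id <TAB> target_article_id <TAB> candidate_article_id <TAB> label

where label 1 marks an expert-judged highly related candidate and 0 a
near-miss candidate.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Mapping

from .errors import ValidationError

_ALNUM_RE = re.compile(r"[^a-z0-9]+")


def resolve_citation_identity(
    pmid: str | None = None, doi: str | None = None, raw: str | None = None
) -> str | None:
    """Normalize a cited work to a global identity string.

    Resolution order: PMID, then DOI, then a lowercase-alphanumeric
    normalization of the raw citation string.  Returns ``None`` when nothing
    usable is available (the reference stays unresolved and never matches
    another article's reference).
    """
    if pmid:
        return f"pmid:{pmid.strip()}"
    if doi:
        return f"doi:{doi.strip().lower()}"
    if raw:
        norm = _ALNUM_RE.sub("", raw.lower())
        if norm:
            return f"raw:{norm}"
    return None


@dataclass(frozen=True)
class Section:
    """A body section: its raw title and a half-open token span."""

    title_text: str
    span: tuple[int, int]


@dataclass(frozen=True)
class Reference:
    """One bibliography entry of an article.

    ``mention_positions`` is sorted ascending; empty means the reference is
    listed but never cited in the body.
    """

    ref_id: str
    cited_article_id: str | None
    mention_positions: tuple[int, ...] = ()


@dataclass(frozen=True)
class Article:
    article_id: str
    title_tokens: tuple[str, ...]
    body_tokens: tuple[str, ...]
    abstract_span: tuple[int, int] = (0, 0)
    sections: tuple[Section, ...] = ()
    references: tuple[Reference, ...] = ()

    def validate(self) -> None:
        n = len(self.body_tokens)
        aid = self.article_id
        if not aid:
            raise ValidationError("article_id must be non-empty")

        def check_span(span: tuple[int, int], name: str) -> None:
            lo, hi = span
            if not (0 <= lo <= hi <= n):
                raise ValidationError(
                    f"{name} {span!r} out of bounds for body of length {n} "
                    f"(article_id={aid})"
                )

        check_span(self.abstract_span, "abstract_span")
        prev_end = None
        for sec in self.sections:
            check_span(sec.span, f"section span of {sec.title_text!r}")
            if prev_end is not None and sec.span[0] < prev_end:
                raise ValidationError(
                    f"section spans overlap or are unordered at "
                    f"{sec.title_text!r} (article_id={aid})"
                )
            prev_end = sec.span[1]
        seen: set[str] = set()
        for ref in self.references:
            if ref.ref_id in seen:
                raise ValidationError(
                    f"duplicate ref_id {ref.ref_id!r} (article_id={aid})"
                )
            seen.add(ref.ref_id)
            positions = ref.mention_positions
            if tuple(sorted(positions)) != positions:
                raise ValidationError(
                    f"mention_positions of {ref.ref_id!r} not sorted "
                    f"(article_id={aid})"
                )
            for p in positions:
                if not (0 <= p <= n):
                    raise ValidationError(
                        f"mention_positions of {ref.ref_id!r} contains {p}, "
                        f"outside [0, {n}] (article_id={aid})"
                    )

    def get_reference(self, ref_id: str) -> Reference:
        for ref in self.references:
            if ref.ref_id == ref_id:
                return ref
        from .errors import UnknownReferenceError

        raise UnknownReferenceError(
            f"reference {ref_id!r} not found in article {self.article_id!r}"
        )

    @property
    def abstract_tokens(self) -> tuple[str, ...]:
        lo, hi = self.abstract_span
        return self.body_tokens[lo:hi]


@dataclass
class Corpus:
    articles: dict[str, Article] = field(default_factory=dict)

    def add(self, article: Article) -> None:
        if article.article_id in self.articles:
            raise ValidationError(f"duplicate article_id {article.article_id!r}")
        article.validate()
        self.articles[article.article_id] = article

    def __getitem__(self, article_id: str) -> Article:
        return self.articles[article_id]

    def __len__(self) -> int:
        return len(self.articles)

    def __iter__(self) -> Iterator[Article]:
        return iter(self.articles.values())

    def __eq__(self, other: object) -> bool:
        return isinstance(other, Corpus) and self.articles == other.articles


@dataclass(frozen=True)
class Topic:
    """One retrieval topic: a target article and its labelled candidates."""

    topic_id: str
    target_id: str
    candidate_ids: tuple[str, ...]
    highly_related_ids: frozenset[str]

    def validate(self) -> None:
        if not self.highly_related_ids:
            raise ValidationError(
                f"topic {self.topic_id!r} has no highly related candidate"
            )
        if not self.highly_related_ids <= set(self.candidate_ids):
            raise ValidationError(
                f"topic {self.topic_id!r}: highly related ids not a subset of "
                f"candidates"
            )
        if self.target_id in self.candidate_ids:
            raise ValidationError(
                f"topic {self.topic_id!r}: target appears among candidates"
            )


@dataclass
class Qrels:
    topics: list[Topic] = field(default_factory=list)

    def validate(self) -> None:
        seen: set[str] = set()
        for topic in self.topics:
            if topic.topic_id in seen:
                raise ValidationError(f"duplicate topic_id {topic.topic_id!r}")
            seen.add(topic.topic_id)
            topic.validate()

    def __iter__(self) -> Iterator[Topic]:
        return iter(self.topics)

    def __len__(self) -> int:
        return len(self.topics)


# ---------------------------------------------------------------------------
# JSON corpus dialect
# ---------------------------------------------------------------------------


def _article_to_obj(article: Article) -> dict:
    return {
        "title_tokens": list(article.title_tokens),
        "body_tokens": list(article.body_tokens),
        "abstract_span": list(article.abstract_span),
        "sections": [
            {"title": sec.title_text, "span": list(sec.span)}
            for sec in article.sections
        ],
        "references": [
            {
                "ref_id": ref.ref_id,
                "cited_article_id": ref.cited_article_id,
                "mention_positions": list(ref.mention_positions),
            }
            for ref in article.references
        ],
    }


def _article_from_obj(article_id: str, obj: Mapping) -> Article:
    try:
        article = Article(
            article_id=article_id,
            title_tokens=tuple(obj["title_tokens"]),
            body_tokens=tuple(obj["body_tokens"]),
            abstract_span=tuple(obj.get("abstract_span", (0, 0))),  # type: ignore[arg-type]
            sections=tuple(
                Section(title_text=s["title"], span=tuple(s["span"]))  # type: ignore[arg-type]
                for s in obj.get("sections", ())
            ),
            references=tuple(
                Reference(
                    ref_id=r["ref_id"],
                    cited_article_id=r.get("cited_article_id"),
                    mention_positions=tuple(r.get("mention_positions", ())),
                )
                for r in obj.get("references", ())
            ),
        )
    except (KeyError, TypeError) as exc:
        raise ValidationError(
            f"malformed article record (article_id={article_id!r}): {exc}"
        ) from exc
    article.validate()
    return article


def write_corpus_json(corpus: Corpus, path: str | Path) -> None:
    obj = {
        "articles": {
            aid: _article_to_obj(article) for aid, article in corpus.articles.items()
        }
    }
    Path(path).write_text(
        json.dumps(obj, indent=1, sort_keys=True, ensure_ascii=False) + "\n",
        encoding="utf-8",
    )


def read_corpus_json(path: str | Path) -> Corpus:
    try:
        obj = json.loads(Path(path).read_text(encoding="utf-8"))
    except json.JSONDecodeError as exc:
        raise ValidationError(f"corpus file {path} is not valid JSON: {exc}") from exc
    if not isinstance(obj, dict) or "articles" not in obj:
        raise ValidationError(f"corpus file {path} lacks an 'articles' mapping")
    corpus = Corpus()
    for aid, art_obj in obj["articles"].items():
        corpus.add(_article_from_obj(aid, art_obj))
    return corpus


# ---------------------------------------------------------------------------
# Qrels TSV
# ---------------------------------------------------------------------------


def write_qrels(qrels: Qrels, path: str | Path) -> None:
    lines = []
    for topic in qrels:
        for cid in topic.candidate_ids:
            label = 1 if cid in topic.highly_related_ids else 0
            lines.append(f"{topic.topic_id}\t{topic.target_id}\t{cid}\t{label}")
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def read_qrels(path: str | Path) -> Qrels:
    rows: dict[str, tuple[str, list[str], set[str]]] = {}
    for lineno, line in enumerate(
        Path(path).read_text(encoding="utf-8").splitlines(), start=1
    ):
        if not line.strip():
            continue
        parts = line.split("\t")
        if len(parts) != 4:
            raise ValidationError(
                f"qrels line {lineno}: expected 4 tab-separated fields, "
                f"got {len(parts)}"
            )
        topic_id, target_id, cand_id, label = parts
        if label not in {"0", "1"}:
            raise ValidationError(f"qrels line {lineno}: label must be 0 or 1")
        if topic_id not in rows:
            rows[topic_id] = (target_id, [], set())
        stored_target, cands, relevant = rows[topic_id]
        if stored_target != target_id:
            raise ValidationError(
                f"qrels line {lineno}: conflicting target for topic {topic_id!r}"
            )
        cands.append(cand_id)
        if label == "1":
            relevant.add(cand_id)
    qrels = Qrels(
        topics=[
            Topic(
                topic_id=tid,
                target_id=target,
                candidate_ids=tuple(cands),
                highly_related_ids=frozenset(relevant),
            )
            for tid, (target, cands, relevant) in rows.items()
        ]
    )
    qrels.validate()
    return qrels
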