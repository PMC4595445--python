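import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from pbcoupling.corpus import Article, Corpus, Reference, Section
from pbcoupling.preprocess import DEFAULT_CONFIG

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def prep_config():
    return DEFAULT_CONFIG


def make_article(
    article_id,
    title_tokens=(),
    body_tokens=(),
    refs=(),
    sections=(),
    abstract_span=(0, 0),
):
    """Terse article builder: refs are (ref_id, identity, mention_positions)."""
    article = Article(
        article_id=article_id,
        title_tokens=tuple(title_tokens),
        body_tokens=tuple(body_tokens),
        abstract_span=tuple(abstract_span),
        sections=tuple(Section(t, tuple(s)) for t, s in sections),
        references=tuple(
            Reference(ref_id=r, cited_article_id=ident, mention_positions=tuple(pos))
            for r, ident, pos in refs
        ),
    )
    article.validate()
    return article


def random_article(rng: np.random.Generator, article_id: str, identity_pool) -> Article:
    """Small random article for oracle-equivalence property tests."""
    vocab = [f"w{i}" for i in range(15)]
    body_len = int(rng.integers(0, 30))
    body = tuple(str(rng.choice(vocab)) for _ in range(body_len))
    title = tuple(
        sorted(set(str(rng.choice(vocab)) for _ in range(int(rng.integers(1, 4)))))
    )
    n_refs = int(rng.integers(0, 6))
    refs = []
    for i in range(n_refs):
        if rng.random() < 0.2:
            identity = None
        else:
            identity = str(rng.choice(identity_pool))
        n_mentions = int(rng.integers(0, 4)) if body_len else 0
        positions = tuple(
            sorted(set(int(p) for p in rng.integers(0, body_len + 1, size=n_mentions)))
        )
        refs.append(
            Reference(
                ref_id=f"B{i}", cited_article_id=identity, mention_positions=positions
            )
        )
    article = Article(
        article_id=article_id,
        title_tokens=title,
        body_tokens=body,
        references=tuple(refs),
    )
    article.validate()
    return article


def random_corpus_pair(rng: np.random.Generator):
    pool = [f"pmid:{i}" for i in range(8)]
    return random_article(rng, "a1", pool), random_article(rng, "a2", pool)
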