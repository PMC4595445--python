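"""Independent brute-force reference implementations used only by tests.

These deliberately avoid the package's caching scorer and vectorized paths:
context windows are rebuilt by rescanning the token stream, the article
score enumerates every reference pair, and average precision follows the
summation formula literally.
"""

from __future__ import annotations


def brute_context_passage(article, ref_id, alpha):
    tokens = set(article.title_tokens)
    ref = next(r for r in article.references if r.ref_id == ref_id)
    for p in ref.mention_positions:
        i = p - 1
        taken = 0
        while i >= 0 and taken < alpha:
            tokens.add(article.body_tokens[i])
            i -= 1
            taken += 1
    return tokens


def brute_importance(article, ref_id, strategy):
    ref = next(r for r in article.references if r.ref_id == ref_id)
    if strategy == "frequency":
        return 2.0 if len(ref.mention_positions) >= 2 else 1.0
    if strategy == "position":
        if not ref.mention_positions:
            return 1.0
        return 1.0 + max(ref.mention_positions) / len(article.body_tokens)
    if strategy == "section":
        starts = [
            sec.span[0]
            for sec in article.sections
            if "result" in sec.title_text.lower()
        ]
        if not starts:
            return 1.0
        return 2.0 if any(p >= starts[0] for p in ref.mention_positions) else 1.0
    raise ValueError(strategy)


def brute_link_sim(ref1, art1, ref2, art2, alpha, link_on=True, text_on=True):
    r1 = next(r for r in art1.references if r.ref_id == ref1)
    r2 = next(r for r in art2.references if r.ref_id == ref2)
    same = r1.cited_article_id is not None and r1.cited_article_id == r2.cited_article_id
    if link_on and same:
        return 1.0
    if not text_on:
        return 0.0
    cp1 = brute_context_passage(art1, ref1, alpha)
    cp2 = brute_context_passage(art2, ref2, alpha)
    union = cp1 | cp2
    if not union:
        return 0.0
    return len(cp1 & cp2) / len(union)


def brute_pbc(art1, art2, alpha, strategy="frequency", link_on=True, text_on=True):
    o1 = [r.ref_id for r in art1.references]
    o2 = [r.ref_id for r in art2.references]
    if not o1 or not o2:
        return 0.0

    def weighted(c1, c2):
        sim = brute_link_sim(c1, art1, c2, art2, alpha, link_on, text_on)
        return sim * (
            brute_importance(art1, c1, strategy) + brute_importance(art2, c2, strategy)
        ) / 2.0

    total = 0.0
    for c1 in o1:
        total += max(weighted(c1, c2) for c2 in o2)
    for c2 in o2:
        total += max(weighted(c1, c2) for c1 in o1)
    return total / (len(o1) + len(o2))


def brute_average_precision(ranked_ids, relevant_ids):
    relevant = set(relevant_ids)
    full = list(ranked_ids) + sorted(relevant - set(ranked_ids))
    ranks = [idx + 1 for idx, cid in enumerate(full) if cid in relevant]
    k = len(relevant)
    return sum((j + 1) / arc for j, arc in enumerate(ranks)) / k
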