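"""Span alignment: decide which reference/system pairs match and count errors.

Matching is per document and, unless evaluation is collapsed, per scoring
category. Candidate pairs are those whose spans satisfy the match policy
(exact offsets / any overlap / system covers reference) and whose mapped
scoring categories agree; among the candidates a maximum-cardinality
one-to-one matching is selected. Maximum matching — rather than greedy
first-come pairing — is what makes the bookkeeping laws hold on every
input: ``tp + fn`` equals the number of mapped reference annotations,
``tp + fp`` the number of mapped system annotations, and the matched-pair
sets nest across policies (exact ⊆ fully-contained ⊆ partial).

Counts are invariant across equal-cardinality matchings; the reported
pair list is additionally normalized (earlier reference span first, then
larger overlap) so reports diff cleanly between runs.

Cross-category confusions never become true positives in per-category
mode: a reference of category A overlapped only by a system span of
category B yields fn(A) paired with fp(B). Collapsing to tier 0 is the way
to credit such pairs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import networkx as nx

from .annotations import (
    Annotation,
    AnnotationSet,
    CountTriple,
    MatchPolicy,
    TextDocument,
)
from .errors import UsageError
from .schema import SchemaConfig, TierLevel, UNMAPPED, map_to_scoring_category

__all__ = [
    "MatchPair",
    "DocumentEvaluation",
    "CorpusEvaluation",
    "spans_match",
    "evaluate_document",
    "evaluate_corpus",
    "ALL_CATEGORIES",
]

logger = logging.getLogger(__name__)

ALL_CATEGORIES = "ALL"


def spans_match(
    ref_span: tuple[int, int], sys_span: tuple[int, int], policy: MatchPolicy
) -> bool:
    """Does *sys_span* count as a match for *ref_span* under *policy*?

    exact — identical offsets; partial — any overlap; fully_contained —
    the system span covers the whole reference span (extra text before or
    after is allowed, less is not). Containment is deliberately
    asymmetric: it encodes "no PII leaked past the system's redaction".
    """
    rb, re_ = ref_span
    sb, se = sys_span
    if rb >= re_ or sb >= se:
        raise UsageError(f"invalid span: ref={ref_span} sys={sys_span}")
    if policy is MatchPolicy.EXACT:
        return rb == sb and re_ == se
    if policy is MatchPolicy.PARTIAL:
        return max(rb, sb) < min(re_, se)
    return sb <= rb and se >= re_


@dataclass(frozen=True)
class MatchPair:
    """One reference/system annotation pair credited as a true positive."""

    ref: Annotation
    sys: Annotation
    policy: MatchPolicy
    tier: TierLevel


@dataclass
class DocumentEvaluation:
    """Counts for one document at one (tier, policy, collapsed?) setting.

    ``counts`` maps scoring category → CountTriple; in collapsed mode the
    single key is ``"ALL"``. ``n_unmapped_ref``/``n_unmapped_sys`` record
    annotations excluded because their category has no score value at the
    tier.
    """

    doc_id: str
    counts: dict[str, CountTriple]
    pairs: list[MatchPair]
    n_unmapped_ref: int = 0
    n_unmapped_sys: int = 0

    @property
    def total(self) -> CountTriple:
        out = CountTriple()
        for c in self.counts.values():
            out = out + c
        return out


def _overlap(a: Annotation, b: Annotation) -> int:
    return max(0, min(a.end, b.end) - max(a.begin, b.begin))


def _matching_size(edges: set[tuple[int, int]]) -> int:
    if not edges:
        return 0
    g = nx.Graph()
    top = {("r", i) for i, _ in edges}
    g.add_nodes_from(top)
    g.add_nodes_from(("s", j) for _, j in edges)
    g.add_edges_from((("r", i), ("s", j)) for i, j in edges)
    return len(nx.bipartite.hopcroft_karp_matching(g, top_nodes=top)) // 2


def _normalized_max_matching(
    refs: Sequence[Annotation],
    syss: Sequence[Annotation],
    edges: set[tuple[int, int]],
) -> list[tuple[int, int]]:
    """Pick one maximum matching deterministically.

    References are visited in canonical order; each is paired with its
    most-preferred candidate (largest overlap, then earliest system span)
    that still permits a maximum matching on the remainder — checked by a
    matching-size query, which is cheap at clinical-note scale.
    """
    target = _matching_size(edges)
    chosen: list[tuple[int, int]] = []
    active = set(edges)
    for i in range(len(refs)):
        if target == 0:
            break
        cands = sorted(
            (j for (i2, j) in active if i2 == i),
            key=lambda j: (-_overlap(refs[i], syss[j]), syss[j].begin, syss[j].end),
        )
        matched = False
        for j in cands:
            sub = {(a, b) for (a, b) in active if a != i and b != j}
            if _matching_size(sub) == target - 1:
                chosen.append((i, j))
                active = sub
                target -= 1
                matched = True
                break
        if not matched:
            active = {(a, b) for (a, b) in active if a != i}
    return chosen


def evaluate_document(
    ref: AnnotationSet,
    sys: AnnotationSet,
    ref_cfg: SchemaConfig,
    sys_cfg: SchemaConfig,
    tier: TierLevel,
    policy: MatchPolicy,
    collapsed: bool = False,
) -> DocumentEvaluation:
    """Score one document's system output against its reference annotations.

    Annotations whose native category has no score value at *tier* are
    excluded (neither fp nor fn) with a logged count. The result is a pure
    function of the inputs.
    """
    if ref.doc_id != sys.doc_id:
        raise UsageError(
            f"reference ({ref.doc_id!r}) and system ({sys.doc_id!r}) annotation "
            "sets refer to different documents"
        )

    def mapped(anns: AnnotationSet, cfg: SchemaConfig) -> tuple[list[Annotation], list[str], int]:
        kept, cats, dropped = [], [], 0
        for a in anns:
            c = map_to_scoring_category(cfg, a.native_category, tier)
            if c == UNMAPPED:
                dropped += 1
            else:
                kept.append(a)
                cats.append(c)
        return kept, cats, dropped

    refs, ref_cats, n_unmapped_ref = mapped(ref, ref_cfg)
    syss, sys_cats, n_unmapped_sys = mapped(sys, sys_cfg)
    if n_unmapped_ref or n_unmapped_sys:
        logger.debug(
            "%s: excluded %d reference / %d system unmapped annotation(s) at %s",
            ref.doc_id,
            n_unmapped_ref,
            n_unmapped_sys,
            tier.value,
        )

    edges = {
        (i, j)
        for i, r in enumerate(refs)
        for j, s in enumerate(syss)
        if (collapsed or ref_cats[i] == sys_cats[j])
        and spans_match(r.span, s.span, policy)
    }
    chosen = _normalized_max_matching(refs, syss, edges)
    matched_r = {i for i, _ in chosen}
    matched_s = {j for _, j in chosen}

    counts: dict[str, CountTriple] = {}

    def bump(cat: str, tp: int = 0, fp: int = 0, fn: int = 0) -> None:
        counts[cat] = counts.get(cat, CountTriple()) + CountTriple(tp, fp, fn)

    key = (lambda _c: ALL_CATEGORIES) if collapsed else (lambda c: c)
    for i, j in chosen:
        bump(key(ref_cats[i]), tp=1)
    for i in range(len(refs)):
        if i not in matched_r:
            bump(key(ref_cats[i]), fn=1)
    for j in range(len(syss)):
        if j not in matched_s:
            bump(key(sys_cats[j]), fp=1)

    pairs = [
        MatchPair(refs[i], syss[j], policy, tier)
        for i, j in sorted(chosen, key=lambda ij: (refs[ij[0]].begin, refs[ij[0]].end))
    ]
    return DocumentEvaluation(
        doc_id=ref.doc_id,
        counts=counts,
        pairs=pairs,
        n_unmapped_ref=n_unmapped_ref,
        n_unmapped_sys=n_unmapped_sys,
    )


@dataclass
class CorpusEvaluation:
    """Micro-aggregated counts over all documents of a corpus.

    ``per_category`` comes from per-category matching; ``collapsed`` from
    category-blind matching (its tp can only be larger or equal, since
    cross-category pairs are credited there).
    """

    per_category: dict[str, CountTriple] = field(default_factory=dict)
    collapsed: CountTriple = field(default_factory=CountTriple)
    n_docs: int = 0
    n_unmapped_ref: int = 0
    n_unmapped_sys: int = 0


def evaluate_corpus(
    doc_pairs: Iterable[tuple[AnnotationSet, Optional[AnnotationSet]]],
    ref_cfg: SchemaConfig,
    sys_cfg: SchemaConfig,
    tier: TierLevel,
    policy: MatchPolicy,
) -> CorpusEvaluation:
    """Sum document evaluations over a corpus, per category and collapsed.

    A ``None`` system side (document the system never produced) counts as
    an empty annotation set: every mapped reference annotation in it
    becomes a false negative. Duplicate doc_ids are a usage error.
    """
    out = CorpusEvaluation()
    seen: set[str] = set()
    for ref_set, sys_set in doc_pairs:
        if ref_set.doc_id in seen:
            raise UsageError(f"duplicate doc_id {ref_set.doc_id!r} in corpus")
        seen.add(ref_set.doc_id)
        if sys_set is None:
            sys_set = AnnotationSet(ref_set.doc_id)
        per = evaluate_document(
            ref_set, sys_set, ref_cfg, sys_cfg, tier, policy, collapsed=False
        )
        col = evaluate_document(
            ref_set, sys_set, ref_cfg, sys_cfg, tier, policy, collapsed=True
        )
        for cat, c in per.counts.items():
            out.per_category[cat] = out.per_category.get(cat, CountTriple()) + c
        out.collapsed = out.collapsed + col.counts.get(ALL_CATEGORIES, CountTriple())
        out.n_docs += 1
        out.n_unmapped_ref += per.n_unmapped_ref
        out.n_unmapped_sys += per.n_unmapped_sys
    return out
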