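"""Shared fixtures and the independent matching oracle.

The oracle enumerates every injective reference→system assignment by
recursion and returns the size of the largest one whose pairs all satisfy
the candidate predicate. It shares no code with the alignment module's
matcher, so agreement between the two is evidence, not tautology.
"""

from __future__ import annotations

import itertools

import numpy as np
import pytest

from deideval import (
    Annotation,
    AnnotationSet,
    MatchPolicy,
    Provenance,
    TextDocument,
    load_schema,
    spans_match,
)
from deideval.schema import TierLevel


@pytest.fixture(scope="session")
def tiers_cfg():
    return load_schema("tiers")


@pytest.fixture(scope="session")
def cfg_2006():
    return load_schema("i2b2-2006")


@pytest.fixture(scope="session")
def cfg_2016():
    return load_schema("i2b2-2014-2016")


@pytest.fixture(scope="session")
def cfg_musc():
    return load_schema("musc")


def brute_force_max_matching(
    refs: list[Annotation],
    syss: list[Annotation],
    policy: MatchPolicy,
    ref_cats: list[str] | None = None,
    sys_cats: list[str] | None = None,
) -> int:
    """Max one-to-one matching size by exhaustive recursion (≤~8 per side)."""

    def ok(i: int, j: int) -> bool:
        if ref_cats is not None and ref_cats[i] != sys_cats[j]:
            return False
        return spans_match(refs[i].span, syss[j].span, policy)

    def rec(i: int, used: frozenset[int]) -> int:
        if i == len(refs):
            return 0
        best = rec(i + 1, used)  # leave ref i unmatched
        for j in range(len(syss)):
            if j not in used and ok(i, j):
                best = max(best, 1 + rec(i + 1, used | {j}))
        return best

    return rec(0, frozenset())


def random_annotated_doc(
    rng: np.random.Generator,
    doc_id: str = "doc",
    max_each: int = 6,
    doc_len: int = 40,
    categories: tuple[str, ...] = ("Date", "Patient", "Phone"),
) -> tuple[TextDocument, AnnotationSet, AnnotationSet]:
    """A small document with random, possibly overlapping spans on both sides."""
    doc = TextDocument(doc_id, "x" * doc_len)

    def side(n: int, prov: Provenance) -> AnnotationSet:
        anns = AnnotationSet(doc_id)
        for _ in range(n):
            b = int(rng.integers(0, doc_len - 1))
            e = int(rng.integers(b + 1, min(b + 12, doc_len) + 1))
            cat = categories[int(rng.integers(0, len(categories)))]
            anns.add(Annotation(doc_id, b, e, cat, prov))
        return anns

    return (
        doc,
        side(int(rng.integers(0, max_each + 1)), Provenance.REFERENCE),
        side(int(rng.integers(0, max_each + 1)), Provenance.SYSTEM),
    )
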