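"""Core domain types for span-based PII annotation scoring.

A document is a flat Unicode string; an annotation is a half-open
character-offset interval ``[begin, end)`` over that string carrying the
*native* category label used by whichever corpus or system produced it.
Offsets count Unicode code points, 0-based. Zero-length spans are invalid:
they make every overlap predicate vacuously false and are rejected at
validation time rather than silently dropped.

Annotations never match across documents; ``doc_id`` partitions every
downstream computation.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

__all__ = [
    "TextDocument",
    "Annotation",
    "AnnotationSet",
    "MatchPolicy",
    "CountTriple",
    "Provenance",
    "validate_annotation_set",
]


class Provenance(str, enum.Enum):
    """Which side of the evaluation an annotation belongs to."""

    REFERENCE = "reference"
    SYSTEM = "system"


class MatchPolicy(str, enum.Enum):
    """Span-alignment semantics deciding when two spans count as a match.

    * ``EXACT`` — character offsets of the two annotations must be identical.
    * ``PARTIAL`` — any overlap between the two spans suffices.
    * ``FULLY_CONTAINED`` — the system span must cover the entire reference
      span; it may include extra text before or after, but not less. This is
      the policy under which a match guarantees no PII leaked.
    """

    EXACT = "exact"
    PARTIAL = "partial"
    FULLY_CONTAINED = "fully_contained"


@dataclass(frozen=True)
class TextDocument:
    """One clinical note: an opaque id plus its full text."""

    doc_id: str
    text: str

    def __post_init__(self) -> None:
        if not self.doc_id:
            raise ValueError("doc_id must be non-empty")


@dataclass(frozen=True, order=True)
class Annotation:
    """A character-offset span with a native category label.

    ``begin`` is inclusive, ``end`` exclusive, both counted in Unicode code
    points of the referenced document's text.
    """

    doc_id: str = field(compare=False)
    begin: int
    end: int
    native_category: str
    provenance: Provenance = field(default=Provenance.REFERENCE, compare=False)

    def __post_init__(self) -> None:
        if not self.native_category:
            raise ValueError("native_category must be non-empty")

    @property
    def span(self) -> tuple[int, int]:
        return (self.begin, self.end)

    @property
    def length(self) -> int:
        return self.end - self.begin


class AnnotationSet:
    """All annotations of one provenance on one document, canonically sorted.

    Sort order is ``(begin, end, native_category)``; the order is restored
    after any mutation, so serializing and re-reading a set reproduces the
    identical sequence. Overlapping and nested members are permitted — real
    system output frequently contains both.
    """

    def __init__(self, doc_id: str, annotations: Iterable[Annotation] = ()) -> None:
        if not doc_id:
            raise ValueError("doc_id must be non-empty")
        self.doc_id = doc_id
        self._anns: list[Annotation] = []
        for a in annotations:
            self._check_member(a)
            self._anns.append(a)
        self._sort()

    def _check_member(self, a: Annotation) -> None:
        if a.doc_id != self.doc_id:
            raise ValueError(
                f"annotation doc_id {a.doc_id!r} does not match set doc_id {self.doc_id!r}"
            )

    def _sort(self) -> None:
        self._anns.sort(key=lambda a: (a.begin, a.end, a.native_category))

    def add(self, a: Annotation) -> None:
        self._check_member(a)
        self._anns.append(a)
        self._sort()

    def __iter__(self) -> Iterator[Annotation]:
        return iter(self._anns)

    def __len__(self) -> int:
        return len(self._anns)

    def __getitem__(self, i: int) -> Annotation:
        return self._anns[i]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, AnnotationSet):
            return NotImplemented
        return self.doc_id == other.doc_id and self._anns == other._anns

    def __repr__(self) -> str:
        return f"AnnotationSet({self.doc_id!r}, {len(self._anns)} annotations)"


@dataclass(frozen=True)
class CountTriple:
    """True-positive / false-positive / false-negative counts for one cell.

    For any single evaluation cell the conservation laws hold by
    construction: ``tp + fn`` equals the number of reference annotations in
    the cell and ``tp + fp`` the number of system annotations.
    """

    tp: int = 0
    fp: int = 0
    fn: int = 0

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn) < 0:
            raise ValueError("counts must be nonnegative")

    def __add__(self, other: "CountTriple") -> "CountTriple":
        return CountTriple(self.tp + other.tp, self.fp + other.fp, self.fn + other.fn)


def validate_annotation_set(doc: TextDocument, anns: AnnotationSet) -> list[str]:
    """Check every annotation's offsets against the document text.

    Returns one human-readable violation string per offending annotation;
    an empty list means the set is valid. A ``doc_id`` mismatch between
    *doc* and *anns* is a usage error (raised), not a validation failure.
    """
    if doc.doc_id != anns.doc_id:
        raise ValueError(
            f"document {doc.doc_id!r} and annotation set {anns.doc_id!r} do not refer "
            "to the same note"
        )
    n = len(doc.text)
    violations: list[str] = []
    for a in anns:
        if a.begin >= a.end:
            violations.append(
                f"annotation ({a.begin}, {a.end}, {a.native_category!r}): "
                "zero-length or inverted span (begin must be < end)"
            )
        elif a.begin < 0:
            violations.append(
                f"annotation ({a.begin}, {a.end}, {a.native_category!r}): "
                "begin < 0"
            )
        elif a.end > n:
            violations.append(
                f"annotation ({a.begin}, {a.end}, {a.native_category!r}): "
                f"end > text length {n}"
            )
    return violations
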