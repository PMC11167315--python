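"""Annotation file readers/writers and score-table output.

Two input dialects are supported:

* **brat standoff** — a ``.txt`` file with the note body plus a ``.ann``
  file of textbound lines ``T<id><TAB><Type> <begin> <end><TAB><surface>``.
  Non-textbound lines (relations, events, notes) are ignored with a logged
  count. The type field is taken as the native category.
* **inline XML** — a single file with a ``TEXT`` element holding the note
  body verbatim and a ``TAGS`` element of empty children, each carrying
  ``start``, ``end`` and ``TYPE`` attributes. A tag yields an annotation
  when its element name or TYPE value equals some rule's extraction locator
  in the schema config; unmatched tags are counted and logged.

Offsets in both dialects are 0-based, half-open, counted in Unicode code
points *after* CRLF→LF normalization — normalization is part of the offset
contract, so files written on Windows score identically to their LF twins.

Score tables are written as CSV (fixed header) or JSON (array of objects);
undefined metrics become empty cells / ``null``. Output is byte-identical
for identical input — no timestamps, no environment leakage.
"""

from __future__ import annotations

import csv
import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from lxml import etree

from .annotations import (
    Annotation,
    AnnotationSet,
    CountTriple,
    MatchPolicy,
    Provenance,
    TextDocument,
    validate_annotation_set,
)
from .errors import ReadError
from .metrics import f_beta, precision, recall
from .schema import SchemaConfig, TierLevel

__all__ = [
    "ScoreTableRow",
    "read_brat_standoff",
    "write_brat_standoff",
    "read_inline_xml",
    "write_inline_xml",
    "write_score_table",
    "SCORE_TABLE_COLUMNS",
]

logger = logging.getLogger(__name__)


def _normalize(text: str) -> str:
    return text.replace("\r\n", "\n")


# ---------------------------------------------------------------------------
# brat standoff


def read_brat_standoff(
    text_path: str | Path,
    ann_path: str | Path,
    provenance: Provenance = Provenance.REFERENCE,
) -> tuple[TextDocument, AnnotationSet]:
    """Read a brat ``.txt``/``.ann`` pair into a document and annotation set.

    The document id is the text file's stem. Offsets are validated against
    the text; a surface string that disagrees with ``text[begin:end]`` is a
    logged warning, not an error (trailing-whitespace quirks are common in
    real standoff exports).
    """
    text_path, ann_path = Path(text_path), Path(ann_path)
    doc = TextDocument(text_path.stem, _normalize(text_path.read_text(encoding="utf-8")))
    anns = AnnotationSet(doc.doc_id)
    skipped = 0
    for lineno, raw in enumerate(
        ann_path.read_text(encoding="utf-8").splitlines(), start=1
    ):
        if not raw.strip():
            continue
        if not raw.startswith("T"):
            skipped += 1
            continue
        fields = raw.split("\t")
        if len(fields) < 2:
            raise ReadError(f"{ann_path}:{lineno}: malformed textbound line {raw!r}")
        head = fields[1].split()
        if len(head) != 3:
            raise ReadError(
                f"{ann_path}:{lineno}: expected 'Type begin end' in {fields[1]!r}"
            )
        cat, begin_s, end_s = head
        try:
            begin, end = int(begin_s), int(end_s)
        except ValueError:
            raise ReadError(f"{ann_path}:{lineno}: non-integer offsets in {raw!r}") from None
        a = Annotation(doc.doc_id, begin, end, cat, provenance)
        probe = AnnotationSet(doc.doc_id, [a])
        bad = validate_annotation_set(doc, probe)
        if bad:
            raise ReadError(f"{ann_path}:{lineno}: {bad[0]}")
        if len(fields) >= 3 and fields[2] != doc.text[begin:end]:
            logger.warning(
                "%s:%d: surface %r != text slice %r",
                ann_path,
                lineno,
                fields[2],
                doc.text[begin:end],
            )
        anns.add(a)
    if skipped:
        logger.info("%s: ignored %d non-textbound line(s)", ann_path, skipped)
    return doc, anns


def write_brat_standoff(
    doc: TextDocument,
    anns: AnnotationSet,
    text_path: str | Path,
    ann_path: str | Path,
) -> None:
    """Write a document + annotation set as a brat ``.txt``/``.ann`` pair."""
    Path(text_path).write_text(doc.text, encoding="utf-8")
    lines = [
        f"T{i}\t{a.native_category} {a.begin} {a.end}\t{doc.text[a.begin:a.end]}"
        for i, a in enumerate(anns, start=1)
    ]
    Path(ann_path).write_text("\n".join(lines) + ("\n" if lines else ""), encoding="utf-8")


# ---------------------------------------------------------------------------
# inline XML


def read_inline_xml(
    xml_path: str | Path,
    cfg: SchemaConfig,
    provenance: Provenance = Provenance.REFERENCE,
) -> tuple[TextDocument, AnnotationSet]:
    """Read one note from the inline XML dialect.

    The note body is taken verbatim from the ``TEXT`` element; each child
    of ``TAGS`` whose element name or ``TYPE`` attribute equals a rule's
    locator in *cfg* becomes an annotation labelled with that rule's native
    category. Tags matching no rule are counted and logged, not scored.
    """
    xml_path = Path(xml_path)
    try:
        tree = etree.parse(str(xml_path))
    except etree.XMLSyntaxError as e:
        raise ReadError(f"{xml_path}: not well-formed XML: {e}") from None
    root = tree.getroot()
    text_el = root.find("TEXT")
    tags_el = root.find("TAGS")
    if text_el is None or tags_el is None:
        raise ReadError(f"{xml_path}: expected TEXT and TAGS elements under the root")
    doc_id = root.get("id") or xml_path.stem
    doc = TextDocument(doc_id, _normalize(text_el.text or ""))
    anns = AnnotationSet(doc_id)
    unmatched = 0
    for tag in tags_el:
        rule = cfg.rule_for_locator(tag.tag) or cfg.rule_for_locator(
            tag.get("TYPE", "")
        )
        if rule is None:
            unmatched += 1
            continue
        try:
            begin, end = int(tag.get("start")), int(tag.get("end"))
        except (TypeError, ValueError):
            raise ReadError(
                f"{xml_path}: tag <{tag.tag}> has non-integer start/end attributes"
            ) from None
        a = Annotation(doc_id, begin, end, rule.native_name, provenance)
        bad = validate_annotation_set(doc, AnnotationSet(doc_id, [a]))
        if bad:
            raise ReadError(f"{xml_path}: tag <{tag.tag} start={begin} end={end}>: {bad[0]}")
        anns.add(a)
    if unmatched:
        logger.info(
            "%s: %d tag(s) matched no rule in schema %s",
            xml_path,
            unmatched,
            cfg.schema_id,
        )
    return doc, anns


def write_inline_xml(
    doc: TextDocument,
    anns: AnnotationSet,
    xml_path: str | Path,
    cfg: SchemaConfig | None = None,
) -> None:
    """Write a document + annotation set in the inline XML dialect.

    Tags are emitted with the rule's locator as element name and TYPE when
    *cfg* is given, otherwise with the native category verbatim.
    """
    root = etree.Element("deidevalDoc", id=doc.doc_id)
    text_el = etree.SubElement(root, "TEXT")
    text_el.text = etree.CDATA(doc.text)
    tags_el = etree.SubElement(root, "TAGS")
    for a in anns:
        name = a.native_category
        if cfg is not None:
            rule = cfg.rule_for_native(a.native_category)
            if rule is not None:
                name = rule.locator
        etree.SubElement(
            tags_el, name, start=str(a.begin), end=str(a.end), TYPE=name
        )
    etree.ElementTree(root).write(
        str(xml_path), encoding="utf-8", xml_declaration=True, pretty_print=True
    )


# ---------------------------------------------------------------------------
# score tables


SCORE_TABLE_COLUMNS = [
    "corpus_id",
    "system_id",
    "tier",
    "scoring_category",
    "policy",
    "tp",
    "fp",
    "fn",
    "precision",
    "recall",
    "f1",
    "f2",
]


@dataclass(frozen=True)
class ScoreTableRow:
    """One (corpus, system, tier, category, policy) cell with its metrics.

    ``scoring_category`` is ``"ALL"`` for collapsed evaluation. Metric
    fields are fractions in [0, 1] or ``None`` for undefined (zero
    denominator).
    """

    corpus_id: str
    system_id: str
    tier: TierLevel
    scoring_category: str
    policy: MatchPolicy
    counts: CountTriple
    precision: float | None
    recall: float | None
    f1: float | None
    f2: float | None

    @classmethod
    def from_counts(
        cls,
        corpus_id: str,
        system_id: str,
        tier: TierLevel,
        scoring_category: str,
        policy: MatchPolicy,
        counts: CountTriple,
    ) -> "ScoreTableRow":
        return cls(
            corpus_id,
            system_id,
            tier,
            scoring_category,
            policy,
            counts,
            precision(counts),
            recall(counts),
            f_beta(counts, 1.0),
            f_beta(counts, 2.0),
        )


def _fmt(v: float | None) -> str:
    return "" if v is None else f"{v:.4f}"


def write_score_table(
    rows: Sequence[ScoreTableRow], path: str | Path, format: str = "csv"
) -> None:
    """Write rows as CSV (4-decimal metrics) or JSON (full precision).

    Output depends only on *rows*: identical input gives byte-identical
    files.
    """
    path = Path(path)
    if format == "csv":
        with path.open("w", encoding="utf-8", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(SCORE_TABLE_COLUMNS)
            for r in rows:
                w.writerow(
                    [
                        r.corpus_id,
                        r.system_id,
                        r.tier.value,
                        r.scoring_category,
                        r.policy.value,
                        r.counts.tp,
                        r.counts.fp,
                        r.counts.fn,
                        _fmt(r.precision),
                        _fmt(r.recall),
                        _fmt(r.f1),
                        _fmt(r.f2),
                    ]
                )
    elif format == "json":
        payload = [
            {
                "corpus_id": r.corpus_id,
                "system_id": r.system_id,
                "tier": r.tier.value,
                "scoring_category": r.scoring_category,
                "policy": r.policy.value,
                "tp": r.counts.tp,
                "fp": r.counts.fp,
                "fn": r.counts.fn,
                "precision": r.precision,
                "recall": r.recall,
                "f1": r.f1,
                "f2": r.f2,
            }
            for r in rows
        ]
        path.write_text(json.dumps(payload, indent=2) + "\n", encoding="utf-8")
    else:
        raise ValueError(f"unknown score table format {format!r}")
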