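"""Synthetic annotated corpora with controllable error channels.

The corpora this engine was designed around are restricted releases of
clinical notes, so the test bed is generated: documents of random filler
text with planted, mutually non-overlapping PII spans labelled from the
canonical tier-2 taxonomy, plus degraded copies standing in for system
output. The degradation channels are the failure modes real
deidentification systems exhibit:

* **misses** — a reference span dropped entirely (probability ``p_miss``);
* **spurious spans** — extra output in non-PII filler (Poisson rate per
  document), e.g. a date-like lab value flagged as PII;
* **boundary jitter** — offsets perturbed, either expand-only (the span
  grows but still covers the truth, as over-redacting systems do) or
  shifted boundaries that may truncate it;
* **category confusion** — a correct span relabelled (patient names
  flagged as provider names being the classic case).

Filler is random characters, not clinical prose: the scoring engine is
offset-based and never inspects content, so linguistic realism would buy
nothing. What the generator consequently does NOT emulate is any
correlation between text content and system behaviour — passing tests
show the bookkeeping is right, not that any real system performs well.

Because misses, spurious spans and expand-only jitter act independently
per annotation, collapsed recall and precision under the partial and
fully-contained policies have closed forms (:func:`expected_metrics`),
which the end-to-end tests recover from the full pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np

from .annotations import (
    Annotation,
    AnnotationSet,
    MatchPolicy,
    Provenance,
    TextDocument,
    validate_annotation_set,
)
from .errors import GenerationError, UsageError
from .formats import write_brat_standoff, write_inline_xml
from .schema import SchemaConfig, load_schema

__all__ = [
    "GeneratorParams",
    "PerturbationParams",
    "generate_reference_corpus",
    "perturb_to_system_output",
    "expected_metrics",
    "write_corpus_dir",
    "sample_sentence",
    "DEFAULT_CATEGORY_WEIGHTS",
]

# Rough frequency profile of PII mentions in clinical notes: dates and
# provider/patient names dominate, identifiers and contact details trail.
DEFAULT_CATEGORY_WEIGHTS: dict[str, float] = {
    "Date": 0.28,
    "Provider": 0.16,
    "Patient": 0.12,
    "Hospital": 0.09,
    "Age": 0.06,
    "Phone": 0.05,
    "MedicalRecord": 0.05,
    "City": 0.04,
    "Street": 0.03,
    "State": 0.03,
    "Zip": 0.02,
    "Profession": 0.03,
    "OtherID": 0.04,
}

_FILLER = "abcdefghijklmnopqrstuvwxyz    "
_SPAN_CHARS = "ABCDEFGHIJKLMNOPQRSTUVWXYZ0123456789"


@dataclass(frozen=True)
class GeneratorParams:
    """Shape of the synthetic reference corpus.

    ``mean_annotations_per_doc`` is a Poisson mean; span lengths are
    ``1 + Poisson(mean_span_length - 1)`` so every span has length ≥ 1.
    ``doc_length``, when given, fixes each document's length exactly and
    makes over-full documents a :class:`GenerationError`; left ``None``,
    documents are sized to fit their spans plus random filler gaps.
    """

    n_docs: int = 100
    mean_annotations_per_doc: float = 10.0
    category_weights: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CATEGORY_WEIGHTS)
    )
    mean_span_length: float = 8.0
    mean_gap_length: float = 30.0
    filler_alphabet: str = _FILLER
    doc_length: Optional[int] = None
    seed: int = 0

    def __post_init__(self) -> None:
        w = list(self.category_weights.values())
        if not w or min(w) < 0 or max(w) <= 0:
            raise UsageError("category_weights need at least one positive weight")
        if self.mean_span_length < 1:
            raise UsageError("mean_span_length must be ≥ 1")
        if self.n_docs < 0 or self.mean_annotations_per_doc < 0:
            raise UsageError("n_docs and mean_annotations_per_doc must be ≥ 0")


JITTER_MODES = ("none", "expand_only", "shift")


@dataclass(frozen=True)
class PerturbationParams:
    """Error-channel settings degrading a reference corpus into system output.

    ``confusion`` maps each true category to a distribution over emitted
    categories (rows must sum to 1); categories absent from the mapping
    pass through unchanged.
    """

    p_miss: float = 0.0
    spurious_rate: float = 0.0
    jitter_mode: str = "none"
    jitter_max: int = 0
    confusion: Mapping[str, Mapping[str, float]] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_miss <= 1.0:
            raise UsageError("p_miss must lie in [0, 1]")
        if self.spurious_rate < 0:
            raise UsageError("spurious_rate must be ≥ 0")
        if self.jitter_mode not in JITTER_MODES:
            raise UsageError(f"jitter_mode must be one of {JITTER_MODES}")
        if self.jitter_max < 0:
            raise UsageError("jitter_max must be ≥ 0")
        for cat, row in self.confusion.items():
            total = sum(row.values())
            if abs(total - 1.0) > 1e-9 or min(row.values(), default=0.0) < 0:
                raise UsageError(f"confusion row for {cat!r} must sum to 1")


Corpus = list[tuple[TextDocument, AnnotationSet]]


def generate_reference_corpus(p: GeneratorParams) -> Corpus:
    """Generate documents with planted, non-overlapping PII spans.

    Deterministic given ``p.seed``; every document passes
    :func:`validate_annotation_set` with zero violations by construction.
    """
    rng = np.random.default_rng(p.seed)
    cats = sorted(p.category_weights)
    weights = np.array([p.category_weights[c] for c in cats], dtype=float)
    weights = weights / weights.sum()
    filler = np.array(list(p.filler_alphabet))
    span_chars = np.array(list(_SPAN_CHARS))

    corpus: Corpus = []
    for d in range(p.n_docs):
        doc_id = f"synth-{d:04d}"
        k = int(rng.poisson(p.mean_annotations_per_doc))
        span_lens = (1 + rng.poisson(max(p.mean_span_length - 1, 0), size=k)).tolist()
        if p.doc_length is not None:
            # k+1 gaps of at least one filler character keep spans separated
            # and leave room for spurious placement at the edges.
            need = sum(span_lens) + (k + 1)
            if need > p.doc_length:
                raise GenerationError(
                    f"{doc_id}: {k} spans of total length {sum(span_lens)} cannot "
                    f"fit in doc_length={p.doc_length}"
                )
            extra = p.doc_length - need
            gap_lens = (1 + rng.multinomial(extra, [1.0 / (k + 1)] * (k + 1))).tolist()
        else:
            gap_lens = (1 + rng.poisson(p.mean_gap_length, size=k + 1)).tolist()

        pieces: list[str] = []
        pos = 0
        anns = AnnotationSet(doc_id)
        chosen = rng.choice(len(cats), size=k, p=weights)
        for i in range(k):
            g = gap_lens[i]
            pieces.append("".join(rng.choice(filler, size=g)))
            pos += g
            L = span_lens[i]
            pieces.append("".join(rng.choice(span_chars, size=L)))
            anns.add(
                Annotation(doc_id, pos, pos + L, cats[int(chosen[i])], Provenance.REFERENCE)
            )
            pos += L
        pieces.append("".join(rng.choice(filler, size=gap_lens[k])))
        doc = TextDocument(doc_id, "".join(pieces))
        assert not validate_annotation_set(doc, anns)
        corpus.append((doc, anns))
    return corpus


def _filler_gaps(doc_len: int, anns: AnnotationSet) -> list[tuple[int, int]]:
    """Maximal intervals of the document not covered by any planted span."""
    gaps = []
    pos = 0
    for a in anns:
        if a.begin > pos:
            gaps.append((pos, a.begin))
        pos = max(pos, a.end)
    if pos < doc_len:
        gaps.append((pos, doc_len))
    return gaps


def perturb_to_system_output(
    corpus: Corpus, q: PerturbationParams
) -> list[AnnotationSet]:
    """Degrade a reference corpus through the four error channels.

    Deterministic given ``q.seed``. Each error channel draws from its own
    RNG stream spawned from the seed, so switching one channel on or off
    (e.g. adding expand-only jitter) never reshuffles the decisions of the
    others — the miss pattern and the spurious spans are identical across
    jitter modes at a fixed seed. Spurious spans are placed only inside
    filler gaps, never overlapping a planted reference span, so every
    spurious span is a guaranteed false positive under any policy.
    Jitter that would push a boundary out of bounds is clipped.
    """
    rng_miss, rng_jitter, rng_confuse, rng_spur = (
        np.random.default_rng(s) for s in np.random.SeedSequence(q.seed).spawn(4)
    )
    out: list[AnnotationSet] = []
    for doc, ref in corpus:
        n = len(doc.text)
        sys_set = AnnotationSet(doc.doc_id)
        for a in ref:
            if rng_miss.random() < q.p_miss:
                continue
            b, e = a.begin, a.end
            if q.jitter_mode == "expand_only" and q.jitter_max > 0:
                b = max(0, b - int(rng_jitter.integers(0, q.jitter_max + 1)))
                e = min(n, e + int(rng_jitter.integers(0, q.jitter_max + 1)))
            elif q.jitter_mode == "shift" and q.jitter_max > 0:
                b = b + int(rng_jitter.integers(-q.jitter_max, q.jitter_max + 1))
                e = e + int(rng_jitter.integers(-q.jitter_max, q.jitter_max + 1))
                b = min(max(b, 0), n - 1)
                e = min(max(e, b + 1), n)
            cat = a.native_category
            row = q.confusion.get(cat)
            if row:
                emitted = sorted(row)
                probs = np.array([row[c] for c in emitted])
                cat = emitted[int(rng_confuse.choice(len(emitted), p=probs / probs.sum()))]
            sys_set.add(Annotation(doc.doc_id, b, e, cat, Provenance.SYSTEM))

        if q.spurious_rate > 0:
            rng = rng_spur
            n_spur = int(rng.poisson(q.spurious_rate))
            gaps = [g for g in _filler_gaps(n, ref) if g[1] - g[0] >= 1]
            if gaps:
                lens = np.array([g[1] - g[0] for g in gaps], dtype=float)
                for _ in range(n_spur):
                    gi = int(rng.choice(len(gaps), p=lens / lens.sum()))
                    gb, ge = gaps[gi]
                    L = min(int(1 + rng.poisson(3)), ge - gb)
                    start = gb + int(rng.integers(0, ge - gb - L + 1))
                    cats = sorted(DEFAULT_CATEGORY_WEIGHTS)
                    cat = cats[int(rng.integers(0, len(cats)))]
                    sys_set.add(
                        Annotation(doc.doc_id, start, start + L, cat, Provenance.SYSTEM)
                    )
        out.append(sys_set)
    return out


def expected_metrics(
    p: GeneratorParams, q: PerturbationParams, policy: MatchPolicy
) -> tuple[Optional[float], Optional[float]]:
    """Closed-form expected (precision, recall), collapsed at tier 0.

    Valid only when matches survive the channels intact: jitter must be
    ``none`` or ``expand_only`` (an expanded span still overlaps and still
    contains its reference) and the policy ``partial`` or
    ``fully_contained``. Every surviving span is a true positive and every
    spurious span a false positive, so with N = n_docs ×
    mean_annotations_per_doc planted spans::

        E[recall]    = 1 − p_miss
        E[precision] = N(1 − p_miss) / (N(1 − p_miss) + n_docs · spurious_rate)

    These are expectations over the generation randomness, not per-seed
    identities.
    """
    if q.jitter_mode not in ("none", "expand_only"):
        raise UsageError(
            "no closed form under shift jitter: truncated spans may fail to match"
        )
    if policy not in (MatchPolicy.PARTIAL, MatchPolicy.FULLY_CONTAINED):
        raise UsageError("no closed form under exact policy: any jitter breaks matches")
    n_planted = p.n_docs * p.mean_annotations_per_doc
    surviving = n_planted * (1.0 - q.p_miss)
    spurious = p.n_docs * q.spurious_rate
    recall = 1.0 - q.p_miss if n_planted > 0 else None
    denom = surviving + spurious
    precision = surviving / denom if denom > 0 else None
    return precision, recall


def write_corpus_dir(
    corpus: Corpus,
    ann_sets: Sequence[AnnotationSet] | None,
    out_dir: str | Path,
    dialect: str,
    cfg: SchemaConfig | None = None,
) -> None:
    """Write a corpus (optionally with substituted annotation sets) to disk.

    ``dialect`` is ``brat`` (``.txt`` + ``.ann`` per document) or
    ``inline_xml`` (one ``.xml`` per document). When *ann_sets* is given it
    replaces each document's annotations — the way degraded system output
    is written next to the shared texts.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if cfg is None:
        cfg = load_schema("tiers")
    for i, (doc, ref) in enumerate(corpus):
        anns = ref if ann_sets is None else ann_sets[i]
        if dialect == "brat":
            write_brat_standoff(doc, anns, out / f"{doc.doc_id}.txt", out / f"{doc.doc_id}.ann")
        elif dialect == "inline_xml":
            write_inline_xml(doc, anns, out / f"{doc.doc_id}.xml", cfg)
        else:
            raise UsageError(f"unknown dialect {dialect!r}")


def sample_sentence() -> tuple[TextDocument, dict[str, AnnotationSet]]:
    """A handcrafted synthetic sentence annotated under each shipped schema.

    Illustrates how the same surface PII receives different native labels
    per schema — e.g. the provider name is "Doctor" in the shared-task
    schemas but "Provider" at MUSC — and how schema coverage differs (the
    2006 schema has no Profession category, so the occupation span simply
    has no annotation there). Synthetic: composed for documentation and
    tests, not drawn from any clinical source.
    """
    text = (
        "Dr. Emily Carter saw John Brown, a 92 year old baker, "
        "at Port City General Hospital on 2019-03-01; call 555-123-4567."
    )
    doc = TextDocument("sample-0001", text)

    def span(s: str) -> tuple[int, int]:
        i = text.index(s)
        return i, i + len(s)

    surface_cats = {
        # surface → native category per schema (None = not annotated there)
        "Emily Carter": {"tiers": "Provider", "i2b2-2006": "Doctor", "i2b2-2014-2016": "Doctor", "musc": "Provider"},
        "John Brown": {"tiers": "Patient", "i2b2-2006": "Patient", "i2b2-2014-2016": "Patient", "musc": "Patient"},
        "92": {"tiers": "Age", "i2b2-2006": "Age", "i2b2-2014-2016": "Age", "musc": "Age"},
        "baker": {"tiers": "Profession", "i2b2-2006": None, "i2b2-2014-2016": "Profession", "musc": "Profession"},
        "Port City General Hospital": {"tiers": "Hospital", "i2b2-2006": "Hospital", "i2b2-2014-2016": "Hospital", "musc": "Hospital"},
        "2019-03-01": {"tiers": "Date", "i2b2-2006": "Date", "i2b2-2014-2016": "Date", "musc": "Date"},
        "555-123-4567": {"tiers": "Phone", "i2b2-2006": "Phone", "i2b2-2014-2016": "Phone", "musc": "Phone"},
    }
    by_schema: dict[str, AnnotationSet] = {}
    for schema_id in ("tiers", "i2b2-2006", "i2b2-2014-2016", "musc"):
        anns = AnnotationSet(doc.doc_id)
        for surface, cats in surface_cats.items():
            cat = cats[schema_id]
            if cat is None:
                continue
            b, e = span(surface)
            anns.add(Annotation(doc.doc_id, b, e, cat, Provenance.REFERENCE))
        by_schema[schema_id] = anns
    return doc, by_schema
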