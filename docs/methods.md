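# Methods

## Scoring model

The unit of comparison is the character-offset span. An annotation is
`(doc_id, begin, end, native_category)` with `0 ≤ begin < end ≤ |text|`,
half-open, counted in Unicode code points after CRLF→LF normalization of
the document text. Code points (rather than bytes or UTF-16 units) were
chosen because they make offset arithmetic unambiguous across platforms;
anyone comparing against a byte-offset tool must convert first.
Zero-length spans are rejected at validation: every match predicate is
vacuous on them, so silently keeping them would distort FN counts.

Scoring proceeds per document in four steps:

1. **Category mapping.** Each side's native labels are mapped to scoring
   categories at the requested tier through its schema config. Labels with
   no score value at that tier (`unmapped`) are excluded entirely —
   neither FP nor FN — with a logged count. This is deliberate: a system
   that cannot express a category should not be charged precision errors
   for it, but the exclusion must be visible, hence the logging.
2. **Candidate pairs.** A reference/system pair is a candidate when the
   spans satisfy the policy (exact offsets; any overlap; or system covers
   reference) and, unless evaluation is collapsed, the mapped categories
   are equal.
3. **One-to-one matching.** A maximum-cardinality bipartite matching over
   the candidates determines the true positives. Maximum matching was
   chosen over greedy pairing because it is order-independent and makes
   two laws hold unconditionally: conservation (`tp+fn = |ref|`,
   `tp+fp = |sys|` in every cell) and policy nesting
   (`tp(exact) ≤ tp(fully_contained) ≤ tp(partial)`). One system span can
   satisfy at most one reference span; a system that emits two fragments
   over one reference earns one TP and one FP. Many-to-one merging is a
   non-goal, and scorers that allow it will disagree with this engine on
   fragmented-span edge cases.
4. **Tallying.** Matched pairs count TP in their shared category;
   unmatched reference spans FN in theirs; unmatched system spans FP in
   theirs. A confusion (reference A overlapped only by system B) is
   therefore visible as a paired fn(A)/fp(B), never a TP — collapsing to
   tier 0 is the mechanism for crediting cross-category matches.

Counts are invariant across equal-cardinality matchings; the reported
pair *list* is normalized (earlier reference span first, preferring the
larger-overlap partner) by a greedy pass that force-pairs a candidate and
checks, with a matching-size query, that the optimum is preserved. This
costs extra matching computations per document but documents are small
(tens of annotations), so the audit-friendly determinism is cheap.

## Tiers and shipped schemas

Four schema configs ship with the package, in a sectioned key-value
format documented in `deideval.schema`:

* `tiers` — the canonical taxonomy: 29 tier-2 categories in the seven
  tier-1 groups (Address, Age, ContactInformation, Identifiers, Names,
  Occupations, Time). The Names group holds Patient, Provider, Relative,
  OtherPerson and Username. The synthetic generator plants annotations in
  this schema.
* `i2b2-2006` — the eight-category discharge-summary inventory: its
  "Location" native is the whole Address group, "MedicalRecord" is the
  only Identifier, and Age means only ages over 89 (the strict HIPAA Safe
  Harbor notion); other schemas treat all ages as PII.
* `i2b2-2014-2016` — the 28-category inventory shared by the two later
  shared-task corpora. Phone and Fax map to a joint tier-1 scoring value
  `PhoneFax` in this configuration, so its tier-1 inventory is not
  identical to the canonical seven groups; tier-1 labels are per-schema,
  and cross-schema scoring assumes both sides' configs use the same
  labels at the chosen tier.
* `musc` — a clinical-note schema with merged `StreetCity` and
  `StateCountry` labels (an annotation-guideline change made them
  unsplittable) kept as their own tier-2 values, and all identifiers
  except SSN grouped as `Other ID`.

Within every shipped config, two natives sharing a tier-2 value share
their tier-1 value, and every mapped category collapses to `PII` at
tier 0 (enforced by tests).

## Synthetic corpora

The generator emulates the *shape* of an annotated clinical corpus, not
its language: filler is random characters because the scoring engine
never inspects content. Defaults: 100 documents, Poisson(10) planted
spans per document, span length `1 + Poisson(7)` characters, filler gaps
`1 + Poisson(30)` characters, category frequencies skewed the way PII is
in real notes (dates and provider/patient names dominate). Planted spans
are mutually non-overlapping by construction. An optional fixed document
length turns over-full documents into a generation error instead.

Degradation channels, each with its own RNG stream spawned from the seed
(so toggling one channel never reshuffles another's decisions):

* `p_miss` — independent span dropout;
* `spurious_rate` — Poisson-many extra spans per document, placed only in
  filler gaps so each is a guaranteed FP under every policy;
* jitter — `expand_only` grows boundaries by up to `jitter_max`
  characters (the span still covers the truth), `shift` moves either
  boundary and may truncate; out-of-bounds jitter is clipped;
* `confusion` — per-category relabelling matrix.

With jitter ∈ {none, expand_only} and policy ∈ {partial,
fully_contained}, every surviving span matches its own reference and
every spurious span is an FP, giving closed forms

```
E[recall]    = 1 − p_miss
E[precision] = N(1−p_miss) / (N(1−p_miss) + n_docs·spurious_rate),   N = n_docs·mean_spans
```

No closed form is claimed for shift jitter or the exact policy, and
requesting one raises an error. End-to-end tests recover these
expectations within ±0.02 at ~5,000 planted spans; at that size the
binomial standard error of recall is ≈0.006, so the tolerance is ~3σ.
What a passing pipeline demonstrates is that the bookkeeping —
extraction, mapping, matching, counting, metric arithmetic — is correct;
it says nothing about any real system's performance, and the generator
deliberately omits real-data features such as content-correlated errors,
document-length heterogeneity and annotator disagreement.

## Metrics and aggregation

Precision, recall and F_β are computed from summed counts (micro) or as
unweighted means of per-group values (macro); the two differ in general
and both are exposed. Zero-denominator metrics are `undefined` (`None` in
memory, empty CSV cell, JSON `null`) and are skipped — with a reported
skip count — by the macro average, never imputed as 0 or 1. Tables round
to 4 decimals; JSON keeps full precision. Timing records
(seconds-per-note, notes-per-second) from the external-command runner are
reported but never asserted in tests: they are hardware-dependent, and
tool start-up cost is amortised rather than separated.

## Problem sizes

The default test suite and the acceptance script use corpora of 500–520
documents (~5,000–5,200 planted spans) for parameter recovery, 500–1,000
randomized small documents for the oracle-equivalence and conservation
audits, and a 13×13 endpoint grid for exhaustive policy checks; the whole
suite runs in a few seconds on one CPU.

## Known limitations

* One-to-one matching only; no partial-credit or token-level scoring.
* Tier-1 scoring values are per-schema labels, so schemas with divergent
  tier-1 inventories (e.g. `PhoneFax`) only align against configs using
  the same labels.
* Two input dialects (brat standoff, inline XML); converting a real
  system's bespoke output into one of them is the caller's job.
* Offsets are code-point based; byte-offset producers must convert.
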