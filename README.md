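# deideval

Span-alignment scoring for clinical text deidentification.

Automated deidentifiers tag spans of protected health information (PHI) —
names, dates, medical record numbers, addresses — in clinical notes so the
text can be shared for research. Evaluating such a system means comparing
its output spans against human reference annotations, which is harder than
it sounds: every corpus and every system uses its own category inventory
("Doctor" vs "Provider" vs "HCPName"), and a span that is slightly too long
or too short may still prevent any PII from leaking. `deideval` is a
self-contained scoring engine for exactly this comparison, aimed at anyone
benchmarking off-the-shelf deidentification tools against annotated
corpora.

## What it computes

Both sides' *native* categories are first mapped, via declarative schema
configuration files, onto shared *scoring* categories at a chosen tier:

* **tier 0** — everything is one category, `PII`;
* **tier 1** — seven semantic groups (Address, Age, ContactInformation,
  Identifiers, Names, Occupations, Time);
* **tier 2** — fine-grained HIPAA-style categories (Patient, Provider,
  Date, Phone, SSN, ...).

Reference and system annotations on each document are then aligned under
one of three match policies over character offsets `[begin, end)`:

* **exact** — offsets identical;
* **partial** — any overlap;
* **fully contained** — the system span covers the whole reference span
  (if so, no PII leaked, however sloppy the boundaries).

A maximum-cardinality one-to-one matching between the two sides yields
TP/FP/FN counts per scoring category (and collapsed across categories),
from which the usual metrics follow:

```
P = TP/(TP+FP)    R = TP/(TP+FN)    F_β = (1+β²)·P·R / (β²·P + R)
```

with F₂ (β = 2) weighting recall above precision — apt when a missed
identifier is costlier than an over-redaction. Zero-denominator cells are
reported as *undefined*, never imputed.

Because the shared-task corpora this engine targets are access-restricted,
the package includes a first-class synthetic corpus generator: documents
with planted PII spans, degraded into "system output" through known error
channels (miss rate, spurious spans, boundary jitter, category confusion)
whose expected precision and recall have closed forms, so the whole
pipeline is testable end-to-end without any clinical data.

## Worked example

Generate a 20-document synthetic corpus whose "system output" misses 10%
of spans and adds one spurious span per document, then score it:

```sh
deideval simulate --seed 42 --n-docs 20 --mean-annotations 8 \
    --p-miss 0.1 --spurious-rate 1.0 --out-dir demo/sim
deideval score --manifest demo/manifest.yaml
```

with `demo/manifest.yaml`:

```yaml
output_dir: demo/results
tiers: [tier0, tier1]
policies: [partial, fully_contained]
corpora:
  synth:
    documents_dir: demo/sim/reference/xml
    dialect: inline_xml
    schema: tiers
systems:
  degraded:
    schema: tiers
    outputs:
      synth: demo/sim/system/xml
```

This prints `wrote 18 rows to demo/results/scores.csv`; the table begins

```
corpus_id,system_id,tier,scoring_category,policy,tp,fp,fn,precision,recall,f1,f2
synth,degraded,tier0,ALL,partial,145,21,15,0.8735,0.9062,0.8896,0.8995
synth,degraded,tier0,ALL,fully_contained,145,21,15,0.8735,0.9062,0.8896,0.8995
synth,degraded,tier1,ALL,partial,145,21,15,0.8735,0.9062,0.8896,0.8995
synth,degraded,tier1,Address,partial,31,6,3,0.8378,0.9118,0.8732,0.8960
synth,degraded,tier1,Age,partial,7,0,2,1.0000,0.7778,0.8750,0.8140
```

Reading the first row: of 160 planted PII spans, 145 were recovered
(recall 0.9062 ≈ the configured 90% survival rate), and 21 of the 166
system spans were spurious (precision 0.8735). The per-group tier-1 rows
break the same counts down by semantic family. Rerunning the manifest
reproduces the files byte-for-byte.

The same engine reads real annotation data in brat standoff (`.txt` +
`.ann`) or an inline XML dialect (`TEXT` body plus `TAGS` of
`start`/`end`/`TYPE` elements), with shipped schema configs for the common
shared-task category inventories (`deideval.available_schemas()`), and a
`deideval run` subcommand that drives an external deidentifier over a
corpus while recording wall-clock seconds-per-note and notes-per-second.

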