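"""Native-to-scoring category mapping at three granularity tiers.

Every corpus and every deidentification system labels PII with its own
*native* categories ("DOCTOR", "Fax", "StreetCity", ...). Before two
annotation sets can be compared they are mapped onto shared *scoring*
categories at a chosen tier:

* **tier 0** — everything collapses to the single label ``PII``;
* **tier 1** — a handful of semantic groups (the canonical taxonomy has
  seven: Address, Age, ContactInformation, Identifiers, Names,
  Occupations, Time);
* **tier 2** — the finest-grained division, approximating the HIPAA Safe
  Harbor categories with the practical extensions common in clinical NLP
  (e.g. all ages, not only those over 89);
* **native** — no mapping at all; annotations score against their raw
  labels.

The mapping lives in a plain-text configuration file, one per schema, so
that extraction logic and category alignment stay separate from the
matching algorithms. The dialect is a sectioned key-value format::

    schema: i2b2-2006
    dialect: inline_xml

    [Doctor]
    locator: DOCTOR
    tier0: PII
    tier1: Names
    tier2: Provider

``locator`` tells the file readers how to recognise the category in the
source files (for the XML dialect: an element name or TYPE attribute
value; for brat standoff: the textbound type field). ``tier1`` and
``tier2`` may carry the sentinel ``unmapped``, in which case annotations
of that category are excluded from scoring entirely at that tier —
neither false positives nor false negatives — because forcing a label the
schema cannot express would make precision meaningless. ``tier0`` must
always be ``PII``.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass, field
from importlib import resources as _importlib_resources
from pathlib import Path
from typing import Iterable

from .errors import ConfigError

__all__ = [
    "TierLevel",
    "NativeCategoryRule",
    "SchemaConfig",
    "UNMAPPED",
    "parse_schema_config",
    "map_to_scoring_category",
    "list_scoring_categories",
    "available_schemas",
    "load_schema",
]

logger = logging.getLogger(__name__)

UNMAPPED = "unmapped"

_DIALECTS = ("brat", "inline_xml")


class TierLevel(str, enum.Enum):
    TIER0 = "tier0"
    TIER1 = "tier1"
    TIER2 = "tier2"
    NATIVE = "native"


@dataclass(frozen=True)
class NativeCategoryRule:
    """Extraction locator and per-tier scoring values for one native category."""

    native_name: str
    locator: str
    tier1: str
    tier2: str
    tier0: str = "PII"

    def __post_init__(self) -> None:
        if not self.native_name:
            raise ConfigError("native_name must be non-empty")
        if self.tier0 != "PII":
            raise ConfigError(
                f"[{self.native_name}] tier0 must be 'PII', got {self.tier0!r}"
            )

    def score_value(self, tier: TierLevel) -> str:
        if tier is TierLevel.NATIVE:
            return self.native_name
        if tier is TierLevel.TIER0:
            return self.tier0
        if tier is TierLevel.TIER1:
            return self.tier1
        return self.tier2


@dataclass
class SchemaConfig:
    """A validated set of category rules for one corpus or system schema."""

    schema_id: str
    file_dialect: str
    rules: list[NativeCategoryRule]
    _by_native: dict[str, NativeCategoryRule] = field(init=False, repr=False)
    _warned: set[str] = field(init=False, repr=False, default_factory=set)

    def __post_init__(self) -> None:
        if self.file_dialect not in _DIALECTS:
            raise ConfigError(
                f"unknown dialect {self.file_dialect!r}; expected one of {_DIALECTS}"
            )
        if not self.rules:
            raise ConfigError(f"schema {self.schema_id!r} declares no categories")
        self._by_native = {}
        locators: dict[str, str] = {}
        for r in self.rules:
            if r.native_name in self._by_native:
                raise ConfigError(
                    f"schema {self.schema_id!r}: duplicate native category "
                    f"{r.native_name!r}"
                )
            if r.locator in locators:
                raise ConfigError(
                    f"schema {self.schema_id!r}: categories {locators[r.locator]!r} "
                    f"and {r.native_name!r} share extraction locator {r.locator!r}"
                )
            self._by_native[r.native_name] = r
            locators[r.locator] = r.native_name

    # -- text round-trip ---------------------------------------------------

    @classmethod
    def from_text(cls, text: str, source: str = "<string>") -> "SchemaConfig":
        """Parse the sectioned key-value dialect; errors name the line."""
        schema_id: str | None = None
        dialect: str | None = None
        rules: list[NativeCategoryRule] = []
        section: str | None = None
        pending: dict[str, str] = {}

        def flush(lineno: int) -> None:
            nonlocal section, pending
            if section is None:
                return
            missing = [k for k in ("locator", "tier0", "tier1", "tier2") if k not in pending]
            if missing:
                raise ConfigError(
                    f"{source}: category [{section}] is missing required "
                    f"key(s) {', '.join(missing)} (section ending near line {lineno})"
                )
            rules.append(
                NativeCategoryRule(
                    native_name=section,
                    locator=pending["locator"],
                    tier0=pending["tier0"],
                    tier1=pending["tier1"],
                    tier2=pending["tier2"],
                )
            )
            section, pending = None, {}

        for lineno, raw in enumerate(text.splitlines(), start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            if line.startswith("[") and line.endswith("]"):
                flush(lineno)
                section = line[1:-1].strip()
                if not section:
                    raise ConfigError(f"{source}:{lineno}: empty section header")
                continue
            if ":" not in line:
                raise ConfigError(
                    f"{source}:{lineno}: expected 'key: value', got {raw!r}"
                )
            key, _, value = line.partition(":")
            key, value = key.strip(), value.strip()
            if section is None:
                if key == "schema":
                    schema_id = value
                elif key == "dialect":
                    dialect = value
                else:
                    raise ConfigError(
                        f"{source}:{lineno}: unexpected header key {key!r} "
                        "(only 'schema' and 'dialect' allowed before the first section)"
                    )
            else:
                if key not in ("locator", "tier0", "tier1", "tier2"):
                    raise ConfigError(f"{source}:{lineno}: unknown key {key!r}")
                pending[key] = value
        flush(lineno=len(text.splitlines()))

        if schema_id is None:
            raise ConfigError(f"{source}: missing 'schema:' header")
        if dialect is None:
            raise ConfigError(f"{source}: missing 'dialect:' header")
        return cls(schema_id=schema_id, file_dialect=dialect, rules=rules)

    def to_text(self) -> str:
        lines = [f"schema: {self.schema_id}", f"dialect: {self.file_dialect}", ""]
        for r in self.rules:
            lines += [
                f"[{r.native_name}]",
                f"locator: {r.locator}",
                f"tier0: {r.tier0}",
                f"tier1: {r.tier1}",
                f"tier2: {r.tier2}",
                "",
            ]
        return "\n".join(lines)

    # -- lookups -----------------------------------------------------------

    def rule_for_native(self, native_category: str) -> NativeCategoryRule | None:
        return self._by_native.get(native_category)

    def rule_for_locator(self, locator: str) -> NativeCategoryRule | None:
        for r in self.rules:
            if r.locator == locator:
                return r
        return None


def parse_schema_config(path: str | Path) -> SchemaConfig:
    """Load and validate a schema configuration file."""
    p = Path(path)
    return SchemaConfig.from_text(p.read_text(encoding="utf-8"), source=str(p))


def map_to_scoring_category(
    cfg: SchemaConfig, native_category: str, tier: TierLevel
) -> str:
    """Map a native label to its scoring category at *tier*.

    Total over strings: an unknown native category maps to ``unmapped``
    (with one logged warning per distinct name per config); ``native`` tier
    passes the label through untouched.
    """
    if tier is TierLevel.NATIVE:
        return native_category
    rule = cfg.rule_for_native(native_category)
    if rule is None:
        if native_category not in cfg._warned:
            cfg._warned.add(native_category)
            logger.warning(
                "schema %s: native category %r has no rule; excluded from scoring",
                cfg.schema_id,
                native_category,
            )
        return UNMAPPED
    return rule.score_value(tier)


def list_scoring_categories(cfg: SchemaConfig, tier: TierLevel) -> list[str]:
    """Distinct score values at *tier*, excluding ``unmapped``, sorted."""
    return sorted({r.score_value(tier) for r in cfg.rules} - {UNMAPPED})


# -- shipped schema resources ---------------------------------------------

def _resource_dir():
    return _importlib_resources.files("deideval") / "resources" / "schemas"


def available_schemas() -> list[str]:
    """Ids of the schema configs shipped with the package."""
    return sorted(
        p.name[: -len(".cfg")]
        for p in _resource_dir().iterdir()
        if p.name.endswith(".cfg")
    )


def load_schema(schema_id: str) -> SchemaConfig:
    """Load a shipped schema config by id (see :func:`available_schemas`)."""
    res = _resource_dir() / f"{schema_id}.cfg"
    try:
        text = res.read_text(encoding="utf-8")
    except FileNotFoundError:
        raise ConfigError(
            f"no shipped schema {schema_id!r}; available: {available_schemas()}"
        ) from None
    return SchemaConfig.from_text(text, source=f"resource:{schema_id}.cfg")
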