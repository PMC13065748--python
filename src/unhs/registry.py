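"""UNHS concept registry: allocation, extensions, operational codes, I/O.

The registry binds each health service to a sequential numeric identifier,
its generated code, an optional source-classification reference
(``<prefix>-<source code>``), a service domain, and multilingual labels
(fr/en/es/pt).  National extensions are dot-suffixed children of a parent
code (``AROEM.1``); operational codes have no international equivalent.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Tuple

from . import codec

__all__ = [
    "LANGUAGES",
    "DOMAINS",
    "DOMAIN_ALIASES",
    "SourceClassification",
    "DEFAULT_CLASSIFICATIONS",
    "Concept",
    "RegistryError",
    "LookupResult",
    "Registry",
    "read_registry",
    "write_registry",
]

#: Label languages of the released nomenclature.
LANGUAGES: Tuple[str, ...] = ("fr", "en", "es", "pt")

#: The twelve service-domain acronyms.
DOMAINS: Tuple[str, ...] = (
    "PROC", "EVAL", "MED", "PROT", "CONS", "TRANS",
    "LOG", "LAB", "IMG", "RXT", "PHY", "MENT",
)

#: Accepted input aliases -> canonical acronym (TRAN appears in some tables).
DOMAIN_ALIASES: Dict[str, str] = {"TRAN": "TRANS"}


def canonical_domain(domain: str) -> str:
    """Canonical acronym, accepting known aliases; raises on unknowns."""
    d = domain.strip().upper()
    d = DOMAIN_ALIASES.get(d, d)
    if d not in DOMAINS:
        raise RegistryError(f"unknown domain acronym {domain!r}")
    return d


@dataclass(frozen=True)
class SourceClassification:
    """An international source classification with its code prefix and the
    service domains it feeds."""

    name: str
    prefix: str
    domains: frozenset

    def __post_init__(self):
        if len(self.prefix) != 1 or not self.prefix.isalpha():
            raise RegistryError(f"prefix must be a single letter, got {self.prefix!r}")


def _cls(name: str, prefix: str, *domains: str) -> SourceClassification:
    return SourceClassification(name, prefix, frozenset(domains))


#: The six international classifications: prefix and domain assignment.
DEFAULT_CLASSIFICATIONS: Tuple[SourceClassification, ...] = (
    _cls("ICD-10-PCS", "I", "MENT", "PHY", "PROC", "IMG", "RXT"),
    _cls("CPT", "C", "EVAL"),
    _cls("HCPCS", "H", "CONS", "PROT", "TRANS"),
    _cls("LOINC", "L", "LAB"),
    _cls("RxNorm", "R", "MED"),
    _cls("UB04", "U", "LOG"),
)


@dataclass(frozen=True)
class Concept:
    """One registry row.

    ``code`` is canonical text.  For extensions ``parent`` holds the parent
    code and ``code`` is ``parent + "." + k``; otherwise ``code`` encodes
    ``identifier`` directly.  ``operational`` concepts carry no source_ref.
    """

    identifier: int
    code: str
    domain: str
    labels: Dict[str, str] = field(default_factory=dict)
    source_ref: Optional[str] = None
    parent: Optional[str] = None
    operational: bool = False

    def label(self, language: str = "en") -> Optional[str]:
        return self.labels.get(language)

    def extension_suffix(self) -> int:
        if self.parent is None:
            raise RegistryError(f"{self.code} is not an extension")
        return int(self.code.rpartition(".")[2])


class RegistryError(ValueError):
    """Registry invariant violation or invalid operation."""


@dataclass(frozen=True)
class LookupResult:
    """In-band result of :meth:`Registry.lookup`: distinguishes absence
    from checksum-invalid queries."""

    status: str  # "found" | "not_found" | "invalid_code"
    concept: Optional[Concept] = None
    reason: Optional[str] = None

    @property
    def found(self) -> bool:
        return self.status == "found"


class Registry:
    """Mutable concept registry with sequential identifier allocation.

    Every concept — plain, extension, or operational — draws the next
    identifier from one counter, so after N allocations the identifier set
    is exactly 1..N.  Extension codes are parent-derived; the extension
    row's own identifier is bookkeeping only and is never encoded.
    """

    def __init__(
        self,
        classifications: Iterable[SourceClassification] = DEFAULT_CLASSIFICATIONS,
    ):
        self.classifications: Dict[str, SourceClassification] = {}
        for c in classifications:
            if c.prefix in self.classifications:
                raise RegistryError(f"duplicate classification prefix {c.prefix!r}")
            self.classifications[c.prefix] = c
        self._by_code: Dict[str, Concept] = {}
        self._by_source: Dict[Tuple[str, str, str], str] = {}
        self.next_identifier: int = 1

    # -- accessors ---------------------------------------------------------

    @property
    def concepts(self) -> List[Concept]:
        return list(self._by_code.values())

    def __len__(self) -> int:
        return len(self._by_code)

    def __contains__(self, code: str) -> bool:
        return code.strip().upper() in self._by_code

    def classification_for(self, name_or_prefix: str) -> SourceClassification:
        for c in self.classifications.values():
            if name_or_prefix in (c.name, c.prefix):
                return c
        raise RegistryError(f"unknown classification {name_or_prefix!r}")

    # -- mutation ----------------------------------------------------------

    def register_concept(
        self,
        source_code: str,
        classification: SourceClassification,
        domain: str,
        labels: Dict[str, str],
    ) -> Concept:
        """Allocate the next identifier for a service drawn from an
        international classification and generate its code."""
        domain = canonical_domain(domain)
        if classification.prefix not in self.classifications:
            raise RegistryError(f"classification {classification.name!r} is not registered")
        if domain not in classification.domains:
            raise RegistryError(
                f"domain {domain} is not served by {classification.name} "
                f"(expected one of {sorted(classification.domains)})"
            )
        _require_labels(labels)
        key = (classification.prefix, source_code, domain)
        if key in self._by_source:
            raise RegistryError(
                f"{classification.name} code {source_code!r} in domain {domain} "
                f"is already registered as {self._by_source[key]}"
            )
        n = self._allocate()
        concept = Concept(
            identifier=n,
            code=codec.make_code(n).canonical_text,
            domain=domain,
            labels=dict(labels),
            source_ref=f"{classification.prefix}-{source_code}",
        )
        self._insert(concept)
        self._by_source[key] = concept.code
        return concept

    def add_extension(self, parent_code: str, labels: Dict[str, str]) -> Concept:
        """Append the next dot-suffixed national extension under a parent.

        The child inherits the parent's domain and source_ref; suffixes are
        dense from 1.  Extensions of extensions are rejected (single-level
        hierarchy only).
        """
        _require_labels(labels)
        parent_code = parent_code.strip().upper()
        parent = self._by_code.get(parent_code)
        if parent is None:
            raise RegistryError(f"unknown parent code {parent_code!r}")
        if parent.parent is not None:
            raise RegistryError(
                f"{parent_code} is itself an extension; extensions nest one level only"
            )
        k = 1 + max(
            (c.extension_suffix() for c in self._by_code.values() if c.parent == parent_code),
            default=0,
        )
        concept = Concept(
            identifier=self._allocate(),
            code=f"{parent_code}.{k}",
            domain=parent.domain,
            labels=dict(labels),
            source_ref=parent.source_ref,
            parent=parent_code,
            operational=parent.operational,
        )
        self._insert(concept)
        return concept

    def add_operational(self, domain: str, labels: Dict[str, str]) -> Concept:
        """Allocate an operational code: a service with no international
        equivalent, hence no source reference."""
        domain = canonical_domain(domain)
        _require_labels(labels)
        n = self._allocate()
        concept = Concept(
            identifier=n,
            code=codec.make_code(n).canonical_text,
            domain=domain,
            labels=dict(labels),
            operational=True,
        )
        self._insert(concept)
        return concept

    # -- queries -----------------------------------------------------------

    def lookup(self, code: str) -> LookupResult:
        """Find a concept by code; checksum failures are reported distinctly
        from simple absence.  Never raises."""
        text = (code or "").strip().upper()
        result = codec.validate_code(text)
        if not result.valid:
            return LookupResult(status="invalid_code", reason=result.reason)
        concept = self._by_code.get(text)
        if concept is None:
            return LookupResult(status="not_found", reason=f"code {text} is not registered")
        return LookupResult(status="found", concept=concept)

    def labels_index(self, normalizer=None) -> Dict[str, str]:
        """Map of (optionally normalized) label text -> code, all languages.

        On normalized-label collisions the earliest-registered concept wins,
        keeping the mapping deterministic.
        """
        index: Dict[str, str] = {}
        for concept in self._by_code.values():
            for lang in LANGUAGES:
                text = concept.labels.get(lang)
                if not text:
                    continue
                key = normalizer(text) if normalizer else text
                index.setdefault(key, concept.code)
        return index

    # -- audit -------------------------------------------------------------

    def audit(self) -> List[str]:
        """Check every registry invariant; returns a list of violations
        (empty means the registry is sound)."""
        problems: List[str] = []
        seen_ids: Dict[int, str] = {}
        suffixes: Dict[str, List[int]] = {}
        for concept in self._by_code.values():
            c = concept.code
            if concept.identifier in seen_ids:
                problems.append(
                    f"{c}: identifier {concept.identifier} also used by {seen_ids[concept.identifier]}"
                )
            seen_ids[concept.identifier] = c
            if concept.identifier >= self.next_identifier:
                problems.append(f"{c}: identifier {concept.identifier} >= next_identifier")
            if not concept.labels or not any(concept.labels.values()):
                problems.append(f"{c}: no label in any language")
            if concept.domain not in DOMAINS:
                problems.append(f"{c}: unknown domain {concept.domain}")
            if concept.operational and concept.source_ref is not None and concept.parent is None:
                problems.append(f"{c}: operational concept carries a source_ref")
            if concept.source_ref is not None:
                prefix = concept.source_ref.split("-", 1)[0]
                cls = self.classifications.get(prefix)
                if cls is None:
                    problems.append(f"{c}: source_ref prefix {prefix!r} has no classification")
                elif concept.domain not in cls.domains:
                    problems.append(
                        f"{c}: domain {concept.domain} not in {cls.name}'s domain set"
                    )
            if concept.parent is not None:
                parent = self._by_code.get(concept.parent)
                if parent is None:
                    problems.append(f"{c}: parent {concept.parent} missing")
                elif parent.parent is not None:
                    problems.append(f"{c}: parent {concept.parent} is itself an extension")
                base, _, suffix = c.partition(".")
                if base != concept.parent or not suffix:
                    problems.append(f"{c}: code does not extend its parent {concept.parent}")
                else:
                    suffixes.setdefault(concept.parent, []).append(int(suffix))
                if not codec.validate_code(base).valid:
                    problems.append(f"{c}: parent part fails its checksum")
            else:
                result = codec.validate_code(c)
                if not result.valid:
                    problems.append(f"{c}: {result.reason}")
                elif codec.make_code(concept.identifier).canonical_text != c:
                    problems.append(
                        f"{c}: code does not encode identifier {concept.identifier}"
                    )
        for parent, ks in suffixes.items():
            if sorted(ks) != list(range(1, len(ks) + 1)):
                problems.append(
                    f"{parent}: extension suffixes {sorted(ks)} are not dense from 1"
                )
        return problems

    # -- internals ---------------------------------------------------------

    def _allocate(self) -> int:
        n = self.next_identifier
        self.next_identifier += 1
        return n

    def _insert(self, concept: Concept) -> None:
        if concept.code in self._by_code:
            raise RegistryError(f"code {concept.code} already registered")
        self._by_code[concept.code] = concept


# ---------------------------------------------------------------------------
# Persistence: TSV (default) / CSV / JSON with row-level diagnostics.
# ---------------------------------------------------------------------------

_HEADER = [
    "identifier", "code", "source_ref", "domain",
    "label_fr", "label_en", "label_es", "label_pt", "operational",
]

_DELIMS = {"tsv": "\t", "csv": ","}


def write_registry(registry: Registry, path, dialect: str = "tsv") -> None:
    """Serialize to delimited text (or JSON when dialect="json"), ordered by
    identifier so output is canonical."""
    path = Path(path)
    rows = sorted(registry.concepts, key=lambda c: c.identifier)
    if dialect == "json":
        payload = {
            "classifications": [
                {"name": c.name, "prefix": c.prefix, "domains": sorted(c.domains)}
                for c in registry.classifications.values()
            ],
            "concepts": [_concept_to_dict(c) for c in rows],
        }
        path.write_text(json.dumps(payload, indent=2, ensure_ascii=False) + "\n", encoding="utf-8")
        return
    delim = _require_dialect(dialect)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, delimiter=delim, lineterminator="\n")
        writer.writerow(_HEADER)
        for c in rows:
            writer.writerow([
                c.identifier, c.code, c.source_ref or "", c.domain,
                c.labels.get("fr", ""), c.labels.get("en", ""),
                c.labels.get("es", ""), c.labels.get("pt", ""),
                "true" if c.operational else "false",
            ])


def read_registry(
    path,
    dialect: str = "tsv",
    classifications: Iterable[SourceClassification] = DEFAULT_CLASSIFICATIONS,
) -> Registry:
    """Load and fully validate a registry file.

    Every row's checksum and all registry invariants are checked before the
    registry is returned; malformed rows are rejected with their line
    number.
    """
    path = Path(path)
    delim = _require_dialect(dialect)
    registry = Registry(classifications)
    max_id = 0
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh, delimiter=delim)
        try:
            header = next(reader)
        except StopIteration:
            raise RegistryError(f"{path}: empty file, header required") from None
        if header != _HEADER:
            raise RegistryError(
                f"{path}:1: bad header {header!r}; expected {_HEADER!r}"
            )
        for lineno, row in enumerate(reader, start=2):
            if not row or (len(row) == 1 and not row[0].strip()):
                continue
            if len(row) != len(_HEADER):
                raise RegistryError(
                    f"{path}:{lineno}: expected {len(_HEADER)} fields, found {len(row)}"
                )
            try:
                concept = _row_to_concept(row)
            except (ValueError, RegistryError) as exc:
                raise RegistryError(f"{path}:{lineno}: {exc}") from None
            base = concept.code.partition(".")[0]
            result = codec.validate_code(base)
            if not result.valid:
                raise RegistryError(f"{path}:{lineno}: {concept.code}: {result.reason}")
            try:
                registry._insert(concept)
            except RegistryError as exc:
                raise RegistryError(f"{path}:{lineno}: {exc}") from None
            if concept.source_ref and concept.parent is None:
                prefix, _, source_code = concept.source_ref.partition("-")
                registry._by_source[(prefix, source_code, concept.domain)] = concept.code
            max_id = max(max_id, concept.identifier)
    registry.next_identifier = max_id + 1
    problems = registry.audit()
    if problems:
        raise RegistryError(f"{path}: invariant violations: " + "; ".join(problems))
    return registry


def _row_to_concept(row: List[str]) -> Concept:
    identifier = int(row[0])
    code = row[1].strip().upper()
    parsed = codec.parse_code(code)
    labels = {
        lang: text.strip()
        for lang, text in zip(LANGUAGES, row[4:8])
        if text.strip()
    }
    operational = {"true": True, "false": False}.get(row[8].strip().lower())
    if operational is None:
        raise RegistryError(f"operational flag must be true/false, got {row[8]!r}")
    return Concept(
        identifier=identifier,
        code=code,
        domain=canonical_domain(row[3]),
        labels=labels,
        source_ref=row[2].strip() or None,
        parent=parsed.base_text if parsed.extension is not None else None,
        operational=operational,
    )


def _concept_to_dict(c: Concept) -> dict:
    return {
        "identifier": c.identifier,
        "code": c.code,
        "source_ref": c.source_ref,
        "domain": c.domain,
        "labels": {lang: c.labels.get(lang) for lang in LANGUAGES if c.labels.get(lang)},
        "parent": c.parent,
        "operational": c.operational,
    }


def _require_dialect(dialect: str) -> str:
    try:
        return _DELIMS[dialect]
    except KeyError:
        raise RegistryError(f"unknown dialect {dialect!r}; use tsv or csv") from None


def _require_labels(labels: Dict[str, str]) -> None:
    if not labels or not any(v and v.strip() for v in labels.values()):
        raise RegistryError("at least one non-empty label is required")
    unknown = set(labels) - set(LANGUAGES)
    if unknown:
        raise RegistryError(f"unknown label language(s) {sorted(unknown)}")
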