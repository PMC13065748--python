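"""Billing-catalog consistency assessment and registry coverage analysis.

Two quantitative procedures over facility rate lists:

* the multi-facility coding-consistency assessment — how harmonized are the
  local billing catalogs (shared labels, duplicate codes, code reuse)?
* the coverage analysis — what share of local billable items the
  nomenclature absorbs directly, via national extensions or header codes,
  or only through operational codes.

Items are aligned across facilities by normalized label; an explicit
concept key (expert review output) overrides the label rule wherever
supplied.  All percentages are reported with their denominators and
rounded half-up to one decimal.
"""

from __future__ import annotations

import csv
import difflib
import re
import unicodedata
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

from . import codec
from .registry import Registry, canonical_domain

__all__ = [
    "CatalogItem",
    "FacilityCatalog",
    "ItemCluster",
    "ConsistencyReport",
    "CoverageReport",
    "MatchStatus",
    "ItemMatch",
    "MappingHint",
    "AssessmentError",
    "normalize_label",
    "cluster_items",
    "consistency_metrics",
    "match_catalog_to_registry",
    "coverage_report",
    "read_catalog",
    "write_catalog",
    "round_pct",
]


class AssessmentError(ValueError):
    """Invalid assessment input (bad hints, unknown items or domains)."""


# ---------------------------------------------------------------------------
# Catalogs
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CatalogItem:
    local_code: str
    label: str
    price: Optional[float] = None

    def __post_init__(self):
        if self.price is not None and self.price < 0:
            raise AssessmentError(f"negative price {self.price} for {self.local_code!r}")


@dataclass
class FacilityCatalog:
    """One facility's billable items.  Duplicate codes and labels are
    allowed — they are precisely what the assessment measures."""

    facility_id: str
    items: List[CatalogItem] = field(default_factory=list)

    def __post_init__(self):
        if not self.facility_id:
            raise AssessmentError("facility_id must be non-empty")

    def __len__(self) -> int:
        return len(self.items)


_CATALOG_HEADER = ["facility_id", "local_code", "label", "price"]


def read_catalog(path, dialect: str = "csv") -> List[FacilityCatalog]:
    """Read catalogs from delimited text (one or more facilities per file).

    Header: facility_id, local_code, label, price (price optional/blank).
    """
    delim = {"csv": ",", "tsv": "\t"}.get(dialect)
    if delim is None:
        raise AssessmentError(f"unknown dialect {dialect!r}")
    by_facility: Dict[str, FacilityCatalog] = {}
    path = Path(path)
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh, delimiter=delim)
        header = next(reader, None)
        if header != _CATALOG_HEADER:
            raise AssessmentError(
                f"{path}:1: bad header {header!r}; expected {_CATALOG_HEADER!r}"
            )
        for lineno, row in enumerate(reader, start=2):
            if not row or (len(row) == 1 and not row[0].strip()):
                continue
            if len(row) != 4:
                raise AssessmentError(f"{path}:{lineno}: expected 4 fields, found {len(row)}")
            facility_id, local_code, label, price_text = (c.strip() for c in row)
            try:
                price = float(price_text) if price_text else None
            except ValueError:
                raise AssessmentError(f"{path}:{lineno}: bad price {price_text!r}") from None
            catalog = by_facility.setdefault(facility_id, FacilityCatalog(facility_id))
            catalog.items.append(CatalogItem(local_code, label, price))
    return list(by_facility.values())


def write_catalog(catalogs: Iterable[FacilityCatalog], path, dialect: str = "csv") -> None:
    delim = {"csv": ",", "tsv": "\t"}[dialect]
    with Path(path).open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, delimiter=delim, lineterminator="\n")
        writer.writerow(_CATALOG_HEADER)
        for catalog in catalogs:
            for item in catalog.items:
                writer.writerow([
                    catalog.facility_id, item.local_code, item.label,
                    "" if item.price is None else f"{item.price:g}",
                ])


# ---------------------------------------------------------------------------
# Label normalization and clustering
# ---------------------------------------------------------------------------

_PUNCT_RE = re.compile(r"[^0-9A-Z]+")


def normalize_label(text: str) -> str:
    """Canonical form for label comparison: uppercase, accents stripped,
    punctuation collapsed to single spaces.  Idempotent."""
    decomposed = unicodedata.normalize("NFKD", text)
    ascii_text = "".join(c for c in decomposed if not unicodedata.combining(c))
    return _PUNCT_RE.sub(" ", ascii_text.upper()).strip()


@dataclass
class ItemCluster:
    """Items across facilities judged to be the same service, keyed by
    normalized label or by an explicit concept key."""

    cluster_id: int
    key: str
    members: List[Tuple[str, int]]  # (facility_id, item index)
    canonical_label: str


def cluster_items(
    catalogs: Sequence[FacilityCatalog],
    concept_key: Optional[Mapping[Tuple[str, int], str]] = None,
) -> List[ItemCluster]:
    """Group items into cross-facility clusters.

    By default the key is the normalized label; ``concept_key`` maps
    (facility_id, item index) to an explicit key and always wins where
    present.  Keys referencing unknown items are rejected.
    """
    if not catalogs:
        raise AssessmentError("at least one catalog is required")
    known = {(c.facility_id, i) for c in catalogs for i in range(len(c.items))}
    if concept_key:
        unknown = set(concept_key) - known
        if unknown:
            raise AssessmentError(f"concept key references unknown items: {sorted(unknown)[:5]}")
    groups: Dict[str, List[Tuple[str, int]]] = defaultdict(list)
    labels: Dict[str, str] = {}
    for catalog in catalogs:
        for i, item in enumerate(catalog.items):
            normalized = normalize_label(item.label)
            key = normalized
            if concept_key and (catalog.facility_id, i) in concept_key:
                key = concept_key[(catalog.facility_id, i)]
            groups[key].append((catalog.facility_id, i))
            labels.setdefault(key, normalized)
    return [
        ItemCluster(cluster_id=cid, key=key, members=members, canonical_label=labels[key])
        for cid, (key, members) in enumerate(sorted(groups.items()))
    ]


# ---------------------------------------------------------------------------
# Consistency metrics
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ConsistencyReport:
    """The four harmonization statistics, each with its denominator.

    * consistent: of the clusters present in every facility, the share
      whose raw labels agree verbatim everywhere.
    * duplicate_within: share of items that are duplicate entries of the
      same service in one facility (same cluster, shared local code).
    * multiple_across: of the clusters present in two or more facilities,
      the share realized with two or more distinct (code, label) pairs.
    * code_reuse: of the distinct (facility, local code) pairs, the share
      attached to two or more different services.
    """

    pct_consistent_across_facilities: float
    pct_duplicate_within_facility: float
    pct_multiple_codes_across_facilities: float
    pct_code_reuse_for_different_services: float
    denominators: Dict[str, int]

    def to_rows(self) -> List[Tuple[str, float, int]]:
        d = self.denominators
        return [
            ("Consistent nomenclature across facilities",
             self.pct_consistent_across_facilities, d["consistent"]),
            ("Duplicate codes in the same health facility",
             self.pct_duplicate_within_facility, d["duplicate_within"]),
            ("Multiple codes across different facilities",
             self.pct_multiple_codes_across_facilities, d["multiple_across"]),
            ("Same code for different services",
             self.pct_code_reuse_for_different_services, d["code_reuse"]),
        ]


def round_pct(numerator: int, denominator: int) -> float:
    """Percentage rounded half-up to one decimal; 0.0 on an empty denominator."""
    if denominator == 0:
        return 0.0
    pct = Decimal(numerator) * 100 / Decimal(denominator)
    return float(pct.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def consistency_metrics(
    catalogs: Sequence[FacilityCatalog],
    clusters: Sequence[ItemCluster],
) -> ConsistencyReport:
    """Compute the four-facility harmonization statistics over clusters
    built from exactly these catalogs."""
    items = {
        (c.facility_id, i): item
        for c in catalogs for i, item in enumerate(c.items)
    }
    claimed = {m for cl in clusters for m in cl.members}
    if claimed != set(items):
        raise AssessmentError("clusters do not partition these catalogs' items")

    n_facilities = len(catalogs)
    in_all = [cl for cl in clusters if len({f for f, _ in cl.members}) == n_facilities]
    consistent = sum(
        1 for cl in in_all
        if len({items[m].label for m in cl.members}) == 1
    )

    in_multi = [cl for cl in clusters if len({f for f, _ in cl.members}) >= 2]
    multi_coded = sum(
        1 for cl in in_multi
        if len({(items[m].local_code, items[m].label) for m in cl.members}) >= 2
    )

    # duplicate entries of the same service: same facility, same cluster,
    # shared local code
    duplicate_items = 0
    for cl in clusters:
        per_facility: Dict[str, Counter] = defaultdict(Counter)
        for facility_id, i in cl.members:
            per_facility[facility_id][items[(facility_id, i)].local_code] += 1
        for counts in per_facility.values():
            duplicate_items += sum(k for k in counts.values() if k >= 2)

    # code reuse: a (facility, code) pair attached to >= 2 clusters
    code_clusters: Dict[Tuple[str, str], set] = defaultdict(set)
    for cl in clusters:
        for facility_id, i in cl.members:
            code_clusters[(facility_id, items[(facility_id, i)].local_code)].add(cl.cluster_id)
    reused = sum(1 for s in code_clusters.values() if len(s) >= 2)

    return ConsistencyReport(
        pct_consistent_across_facilities=round_pct(consistent, len(in_all)),
        pct_duplicate_within_facility=round_pct(duplicate_items, len(items)),
        pct_multiple_codes_across_facilities=round_pct(multi_coded, len(in_multi)),
        pct_code_reuse_for_different_services=round_pct(reused, len(code_clusters)),
        denominators={
            "consistent": len(in_all),
            "duplicate_within": len(items),
            "multiple_across": len(in_multi),
            "code_reuse": len(code_clusters),
        },
    )


# ---------------------------------------------------------------------------
# Coverage analysis
# ---------------------------------------------------------------------------

class MatchStatus:
    """Coverage status classes for a billable item."""

    DIRECT = "direct"
    EXTENSION_REQUIRED = "extension_required"
    OPERATIONAL_ONLY = "operational_only"
    HEADER_MAPPED = "header_mapped"
    UNMATCHED = "unmatched"

    ALL = (DIRECT, EXTENSION_REQUIRED, OPERATIONAL_ONLY, HEADER_MAPPED, UNMATCHED)


@dataclass(frozen=True)
class MappingHint:
    """Expert-review hint for one catalog item.

    ``relation`` is one of "direct", "extension", "header", "operational";
    ``code`` names the registry concept involved (absent for operational
    items).  ``domain`` optionally supplies the item's service domain.
    """

    relation: str
    code: Optional[str] = None
    domain: Optional[str] = None

    _RELATIONS = {
        "direct": MatchStatus.DIRECT,
        "extension": MatchStatus.EXTENSION_REQUIRED,
        "header": MatchStatus.HEADER_MAPPED,
        "operational": MatchStatus.OPERATIONAL_ONLY,
    }

    def status(self) -> str:
        try:
            return self._RELATIONS[self.relation]
        except KeyError:
            raise AssessmentError(f"unknown hint relation {self.relation!r}") from None


@dataclass(frozen=True)
class ItemMatch:
    """Coverage classification of one catalog item."""

    item_index: int
    status: str
    code: Optional[str] = None
    domain: Optional[str] = None
    fuzzy: bool = False


def match_catalog_to_registry(
    catalog: FacilityCatalog,
    registry: Registry,
    mapping: Optional[Mapping[int, MappingHint]] = None,
    fuzzy_threshold: Optional[float] = None,
) -> List[ItemMatch]:
    """Classify each item of one catalog against the registry.

    Hints win over label matching.  Without a hint an item is ``direct``
    when its normalized label equals a registry label, otherwise
    ``unmatched`` (or a flagged fuzzy ``direct`` when ``fuzzy_threshold``
    is set and the best similarity ratio reaches it — off by default).
    Hint codes failing their checksum are rejected.
    """
    mapping = mapping or {}
    for i, hint in mapping.items():
        if i < 0 or i >= len(catalog.items):
            raise AssessmentError(f"hint references unknown item index {i}")
        if hint.code is not None:
            base = hint.code.partition(".")[0]
            result = codec.validate_code(base)
            if not result.valid:
                raise AssessmentError(f"hint code {hint.code!r}: {result.reason}")

    label_index = registry.labels_index(normalizer=normalize_label)
    fuzzy_keys = sorted(label_index) if fuzzy_threshold is not None else []

    matches: List[ItemMatch] = []
    for i, item in enumerate(catalog.items):
        hint = mapping.get(i)
        if hint is not None:
            status = hint.status()
            domain = hint.domain
            if domain is None and hint.code is not None:
                found = registry.lookup(hint.code)
                if found.found:
                    domain = found.concept.domain
            matches.append(ItemMatch(i, status, code=hint.code, domain=domain))
            continue
        key = normalize_label(item.label)
        code = label_index.get(key)
        if code is not None:
            concept = registry.lookup(code).concept
            matches.append(ItemMatch(i, MatchStatus.DIRECT, code=code, domain=concept.domain))
            continue
        if fuzzy_threshold is not None and fuzzy_keys:
            best = max(
                fuzzy_keys,
                key=lambda k: difflib.SequenceMatcher(None, key, k).ratio(),
            )
            ratio = difflib.SequenceMatcher(None, key, best).ratio()
            if ratio >= fuzzy_threshold:
                code = label_index[best]
                concept = registry.lookup(code).concept
                matches.append(
                    ItemMatch(i, MatchStatus.DIRECT, code=code,
                              domain=concept.domain, fuzzy=True)
                )
                continue
        matches.append(ItemMatch(i, MatchStatus.UNMATCHED))
    return matches


@dataclass(frozen=True)
class CoverageRow:
    """One domain's (or the overall) coverage shares, in percent of all
    items in the row."""

    domain: str
    n_items: int
    international_coverage_pct: float      # direct matches
    national_extension_pct: float          # extension_required + header_mapped
    operational_only_pct: float
    unmatched_pct: float
    overall_coverage_pct: float            # international + national extension


@dataclass(frozen=True)
class CoverageReport:
    rows: Tuple[CoverageRow, ...]
    overall: CoverageRow
    status_counts: Dict[str, Dict[str, int]]


def coverage_report(
    statuses_by_domain: Mapping[str, Sequence[str]],
) -> CoverageReport:
    """Aggregate per-item coverage statuses into per-domain and overall rows.

    Keys are domain acronyms (validated); values are sequences of
    :class:`MatchStatus` values.  Operational-only items are excluded from
    the overall-coverage numerator; every share is reported so alternative
    roll-ups can be recomputed.
    """
    counts: Dict[str, Dict[str, int]] = {}
    for domain, statuses in statuses_by_domain.items():
        domain = canonical_domain(domain)
        c = counts.setdefault(domain, {s: 0 for s in MatchStatus.ALL})
        for s in statuses:
            if s not in c:
                raise AssessmentError(f"unknown status {s!r}")
            c[s] += 1

    def row(domain: str, c: Dict[str, int]) -> CoverageRow:
        n = sum(c.values())
        covered = (
            c[MatchStatus.DIRECT]
            + c[MatchStatus.EXTENSION_REQUIRED]
            + c[MatchStatus.HEADER_MAPPED]
        )
        return CoverageRow(
            domain=domain,
            n_items=n,
            international_coverage_pct=round_pct(c[MatchStatus.DIRECT], n),
            national_extension_pct=round_pct(
                c[MatchStatus.EXTENSION_REQUIRED] + c[MatchStatus.HEADER_MAPPED], n
            ),
            operational_only_pct=round_pct(c[MatchStatus.OPERATIONAL_ONLY], n),
            unmatched_pct=round_pct(c[MatchStatus.UNMATCHED], n),
            overall_coverage_pct=round_pct(covered, n),
        )

    rows = tuple(row(d, c) for d, c in sorted(counts.items()))
    total = {s: sum(c[s] for c in counts.values()) for s in MatchStatus.ALL}
    return CoverageReport(rows=rows, overall=row("Overall", total), status_counts=counts)
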